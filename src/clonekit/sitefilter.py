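"""Site filtering: missingness, minor allele frequency, physical thinning.

The three filters are applied in a fixed order — missingness, then MAF,
then distance thinning — because the thinning outcome depends on which
sites are still present. Six standard configurations (missingness
threshold x thinning distance) are expressible purely through
:class:`FilterConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, EmptyInputError, GenotypeMatrix, ParameterError


@dataclass
class FilterConfig:
    """Filtering thresholds.

    ``max_missing`` is interpreted per ``missing_mode``: in ``"count"``
    mode a site is kept iff strictly fewer than ``max_missing`` samples
    are missing; in ``"fraction"`` mode iff the missing fraction is
    <= ``max_missing``. ``min_maf`` keeps sites with MAF >= the threshold
    (a site at exactly the threshold is kept). ``thin_bp`` is the minimum
    spacing between kept sites on a chromosome.
    """

    max_missing: float = 10
    missing_mode: str = "count"
    min_maf: float = 0.05
    thin_bp: int = 1

    def __post_init__(self) -> None:
        if self.missing_mode not in ("count", "fraction"):
            raise ParameterError("missing_mode must be 'count' or 'fraction'")
        if self.missing_mode == "fraction" and not 0 <= self.max_missing <= 1:
            raise ParameterError("fractional max_missing must lie in [0,1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ParameterError("min_maf must lie in [0, 0.5]")
        if self.thin_bp < 1:
            raise ParameterError("thin_bp must be >= 1")


def filter_missingness(
    G: GenotypeMatrix, max_missing: float, mode: str = "count"
) -> np.ndarray:
    """Boolean keep-mask over sites by missing-call count or fraction."""
    n_missing = (G.calls == MISSING).sum(axis=0)
    if mode == "count":
        return n_missing < max_missing
    if mode == "fraction":
        if not 0 <= max_missing <= 1:
            raise ParameterError("fractional threshold must lie in [0,1]")
        return n_missing <= max_missing * G.n_samples
    raise ParameterError(f"unknown missingness mode {mode!r}")


def site_alt_freq(G: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per site over non-missing calls
    (NaN where every call is missing)."""
    obs = G.calls != MISSING
    alt = np.where(obs, G.calls, 0).sum(axis=0).astype(float)
    n_alleles = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


def filter_maf(G: GenotypeMatrix, min_maf: float) -> np.ndarray:
    """Keep sites with folded MAF >= ``min_maf``; monomorphic and
    all-missing sites are always removed."""
    p = site_alt_freq(G)
    maf = np.fmin(p, 1.0 - p)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(maf), False, (maf >= min_maf) & (maf > 0))


def thin_by_distance(sites: pd.DataFrame, thin_bp: int) -> np.ndarray:
    """Greedy per-chromosome thinning: keep the first site, then each
    subsequent site only if it is >= ``thin_bp`` from the last kept one."""
    if thin_bp < 1:
        raise ParameterError("thin_bp must be >= 1")
    keep = np.zeros(len(sites), dtype=bool)
    last_kept: dict[str, int] = {}
    for idx, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        prev = last_kept.get(chrom)
        if prev is None or pos - prev >= thin_bp:
            keep[idx] = True
            last_kept[chrom] = pos
    return keep


def apply_filters(
    G: GenotypeMatrix, sites: pd.DataFrame, cfg: FilterConfig
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Run missingness -> MAF -> thinning; return survivors and a
    per-stage survivor report."""
    if len(sites) != G.n_sites:
        raise ParameterError("site table and genotype matrix disagree on sites")
    stages = [("input", np.ones(G.n_sites, dtype=bool))]

    mask = filter_missingness(G, cfg.max_missing, cfg.missing_mode)
    stages.append(("missingness", mask.copy()))
    G1, s1 = G.take_sites(mask), sites.loc[mask].reset_index(drop=True)

    mask2 = filter_maf(G1, cfg.min_maf)
    G2, s2 = G1.take_sites(mask2), s1.loc[mask2].reset_index(drop=True)
    stages.append(("maf", mask2))

    mask3 = thin_by_distance(s2, cfg.thin_bp)
    G3, s3 = G2.take_sites(mask3), s2.loc[mask3].reset_index(drop=True)
    stages.append(("thin", mask3))

    report = pd.DataFrame(
        {
            "stage": [name for name, _ in stages],
            "sites_surviving": [
                G.n_sites,
                int(stages[1][1].sum()),
                int(mask2.sum()),
                int(mask3.sum()),
            ],
        }
    )
    if G3.n_sites == 0:
        raise EmptyInputError(
            "no sites survive filtering; relax thresholds\n" + report.to_string()
        )
    return G3, s3, report
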