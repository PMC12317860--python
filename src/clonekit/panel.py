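"""Minimal discriminating SNP panels, MAF and PIC.

A fingerprinting panel is a smallest set of SNPs such that every pair of
samples differs in dosage at >= 1 panel SNP (set cover over sample
pairs). A pair counts as distinguished at a site only when both calls
are observed — a panel must never rely on missingness patterns. The
production selector is greedy (largest marginal pair coverage, ties by
genomic order); an exhaustive subset-enumeration selector is provided
as an oracle for small instances.

Marker informativeness is reported as minor allele frequency and
Botstein's polymorphic information content,
``PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``
(= ``1 - p^2 - q^2 - 2 p^2 q^2`` for a biallelic site, maximum 0.375 at
MAF 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, ParameterError
from .sitefilter import site_alt_freq


@dataclass
class PanelResult:
    site_ids: list
    table: pd.DataFrame
    residual_pairs: list

    @property
    def size(self) -> int:
        return len(self.site_ids)


def site_maf(G: GenotypeMatrix) -> np.ndarray:
    """Folded minor allele frequency per site (NaN when all calls are
    missing)."""
    p = site_alt_freq(G)
    return np.fmin(p, 1.0 - p)


def pic(freqs) -> float:
    """Botstein polymorphic information content for one marker."""
    p = np.asarray(freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError(f"allele frequencies must sum to 1, got {p.sum()}")
    het = 1.0 - np.sum(p**2)
    pairs = [2.0 * p[i] ** 2 * p[j] ** 2
             for i, j in combinations(range(len(p)), 2)]
    return float(het - sum(pairs))


def site_pic(G: GenotypeMatrix) -> np.ndarray:
    """PIC per biallelic site from observed allele frequencies."""
    p = site_alt_freq(G)
    q = 1.0 - p
    return 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2


def _pair_cover(calls: np.ndarray, pairs: list) -> np.ndarray:
    """Boolean (n_sites x n_pairs): site distinguishes pair (both
    observed, dosages differ)."""
    i = np.array([a for a, _ in pairs], dtype=int)
    j = np.array([b for _, b in pairs], dtype=int)
    gi = calls[i, :]  # n_pairs x n_sites
    gj = calls[j, :]
    ok = (gi != MISSING) & (gj != MISSING) & (gi != gj)
    return ok.T


def greedy_min_panel(
    G: GenotypeMatrix, sites: pd.DataFrame, targets=None
) -> PanelResult:
    """Greedy set-cover panel over the target samples (default: all).

    At each step the site distinguishing the most still-indistinguishable
    pairs is selected (ties broken by genomic (chrom, pos) order, i.e.
    site-table order); selection stops when every distinguishable pair is
    covered or no site adds coverage. Pairs left uncovered are reported
    as ``residual_pairs`` — after a full greedy run they are genuinely
    indistinguishable using all sites.
    """
    ids = list(G.sample_ids)
    if targets is None:
        targets = ids
    t_idx = [ids.index(t) for t in targets]
    if len(t_idx) < 2:
        raise ParameterError("need >= 2 target samples for a panel")
    if len(sites) != G.n_sites:
        raise ParameterError("site table and genotype matrix disagree")

    pairs = list(combinations(t_idx, 2))
    cover = _pair_cover(G.calls, pairs)
    remaining = np.ones(len(pairs), dtype=bool)
    chosen: list[int] = []
    while remaining.any():
        gain = (cover & remaining[None, :]).sum(axis=1)
        best = int(np.argmax(gain))  # first max = genomic order
        if gain[best] == 0:
            break
        chosen.append(best)
        remaining &= ~cover[best]
    residual = [
        (ids[pairs[p][0]], ids[pairs[p][1]]) for p in np.flatnonzero(remaining)
    ]
    site_ids = [sites["site_id"].iat[c] for c in chosen]
    return PanelResult(
        site_ids=site_ids,
        table=panel_report(G, sites, site_ids),
        residual_pairs=residual,
    )


def exhaustive_min_panel(
    G: GenotypeMatrix, max_sites: int = 20
) -> list:
    """Smallest panel by increasing-size subset enumeration (oracle for
    small instances; ties resolved lexicographically by site order).
    Returns site column indices."""
    if G.n_sites > max_sites:
        raise ParameterError(
            f"{G.n_sites} sites exceeds the exhaustive bound {max_sites}; "
            "use greedy_min_panel"
        )
    pairs = list(combinations(range(G.n_samples), 2))
    cover = _pair_cover(G.calls, pairs)
    coverable = cover.any(axis=0)  # pairs distinguishable at all
    if not coverable.any():
        return []
    target = coverable
    for size in range(1, G.n_sites + 1):
        for subset in combinations(range(G.n_sites), size):
            if (cover[list(subset)].any(axis=0) >= target).all():
                return list(subset)
    return list(range(G.n_sites))


def panel_report(G: GenotypeMatrix, sites: pd.DataFrame, panel_ids) -> pd.DataFrame:
    """Fingerprint-panel table: SNP_ID, CHROM, POSITION, MAF, PIC,
    reference and alternate alleles (MAF and PIC to the reporting
    precision used in panel tables: 4 and 3 decimals)."""
    lookup = {sid: j for j, sid in enumerate(sites["site_id"])}
    unknown = [p for p in panel_ids if p not in lookup]
    if unknown:
        raise ParameterError(f"panel sites absent from site table: {unknown}")
    maf = site_maf(G)
    picv = site_pic(G)
    rows = []
    for sid in panel_ids:
        j = lookup[sid]
        rows.append(
            {
                "SNP_ID": sid,
                "CHROM": sites["chrom"].iat[j],
                "POSITION": int(sites["pos"].iat[j]),
                "MAF": round(float(maf[j]), 4),
                "PIC": round(float(picv[j]), 3),
                "Reference allele": sites["ref"].iat[j],
                "Alternate allele": sites["alt"].iat[j],
            }
        )
    cols = ["SNP_ID", "CHROM", "POSITION", "MAF", "PIC",
            "Reference allele", "Alternate allele"]
    return pd.DataFrame(rows, columns=cols)
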