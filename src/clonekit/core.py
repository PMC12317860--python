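"""Core containers shared by every stage of the pipeline.

Genotypes are stored as diploid alternate-allele dosages: 0 (homozygous
reference), 1 (heterozygous), 2 (homozygous alternate), or :data:`MISSING`.
The :data:`MISSING` sentinel is reserved — code must mask it out before any
arithmetic, never fold it into sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call. Always mask, never add.
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "site_id"]


class ClonekitError(Exception):
    """Base class for all package errors."""


class ParameterError(ClonekitError, ValueError):
    """An argument is outside its documented domain."""


class EmptyInputError(ClonekitError, ValueError):
    """An operation received (or produced) no usable data."""


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of diploid allele dosages.

    Parameters
    ----------
    calls
        Integer array of shape ``(n_samples, n_sites)`` with entries in
        ``{0, 1, 2, MISSING}``.
    sample_ids
        Ordered, unique sample identifiers, one per row.
    """

    calls: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ParameterError("calls must be a 2-D samples x sites array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.calls.shape[0]:
            raise ParameterError(
                f"{len(self.sample_ids)} sample ids for {self.calls.shape[0]} rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParameterError("sample ids must be unique")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ParameterError(f"invalid dosage values {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        """New matrix restricted to the given site mask / index array."""
        return GenotypeMatrix(self.calls[:, mask_or_index], list(self.sample_ids))

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[index, :], [self.sample_ids[i] for i in index]
        )


def make_site_table(
    chrom, pos, ref, alt, site_id=None
) -> pd.DataFrame:
    """Build a site table (one row per biallelic SNP).

    ``site_id`` defaults to ``"{chrom}_{pos}"``. Sites must be unique by
    (chrom, pos) and are returned sorted by (chrom, pos).
    """
    df = pd.DataFrame(
        {
            "chrom": [str(c) for c in chrom],
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": [str(r) for r in ref],
            "alt": [str(a) for a in alt],
        }
    )
    if (df["pos"] < 1).any():
        raise ParameterError("positions are 1-based and must be >= 1")
    if site_id is None:
        df["site_id"] = [f"{c}_{p}" for c, p in zip(df["chrom"], df["pos"])]
    else:
        df["site_id"] = [str(s) for s in site_id]
    if df.duplicated(["chrom", "pos"]).any():
        raise ParameterError("duplicate (chrom, pos) in site table")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def normalise_name(name: str) -> str:
    """Canonical key for cultivar-name matching: trim, collapse whitespace,
    case-fold. Originals are preserved elsewhere for reporting."""
    return " ".join(str(name).split()).casefold()


UNKNOWN_NAME = "UNKNOWN"


def is_unknown_name(name: str) -> bool:
    return normalise_name(name) == normalise_name(UNKNOWN_NAME)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix in [0, 1].

    ``n_sites_used[i, j]`` counts the pairwise-complete sites behind each
    entry (diagonal entries hold the per-sample call count).
    """

    values: np.ndarray
    labels: list[str]
    n_sites_used: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ParameterError("distance matrix must be square")
        if len(self.labels) != n:
            raise ParameterError("label count must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ParameterError("distance matrix must be symmetric")
        if (np.diag(self.values) != 0).any():
            raise ParameterError("distance matrix diagonal must be zero")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ParameterError("p-distances must lie in [0, 1]")
        if self.n_sites_used is None:
            self.n_sites_used = np.zeros((n, n), dtype=np.int64)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])
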