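"""Maturity-class genotyping from the two-primer indel assay.

The flowering-time indel near the COL307 gene separates the
late-maturing (insertion haplotype B) and extremely-early-maturing
(deletion haplotype C) lineages; early-maturing hybrids are
heterozygous. The assay scores presence/absence of amplification with an
insertion-specific (amp_B) and a deletion-specific (amp_C) primer pair,
so the call is a pure function of the two booleans.
"""

from __future__ import annotations

import pandas as pd

from .core import ParameterError

B_HOM = "B-homozygote"   # insertion/insertion -> late maturing
C_HOM = "C-homozygote"   # deletion/deletion -> extremely early
HET = "heterozygote"     # one of each -> early-maturing hybrid
FAILED = "failed"

CLASSES = [B_HOM, C_HOM, HET, FAILED]


def classify_maturity(amp_b: bool, amp_c: bool) -> str:
    """(amp_B, amp_C) -> maturity genotype call."""
    if amp_b and amp_c:
        return HET
    if amp_b:
        return B_HOM
    if amp_c:
        return C_HOM
    return FAILED


_TRUTHY = {"1", "true", "yes", "y", "+"}
_FALSY = {"0", "false", "no", "n", "-", ""}


def _to_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().casefold()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ParameterError(f"cannot interpret amplification flag {v!r}")


def read_assay(path) -> pd.DataFrame:
    """Read the assay TSV (sample_id, amp_B, amp_C) and call each row."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    need = {"sample_id", "amp_B", "amp_C"}
    if not need.issubset(df.columns):
        raise ParameterError(f"assay TSV needs columns {sorted(need)}")
    df["amp_B"] = df["amp_B"].map(_to_bool)
    df["amp_C"] = df["amp_C"].map(_to_bool)
    df["call"] = [classify_maturity(b, c)
                  for b, c in zip(df["amp_B"], df["amp_C"])]
    return df


def tabulate_assay(calls: pd.DataFrame, membership=None):
    """Per-class counts (always summing to the row count) and, when
    per-sample cluster labels are supplied, a class x cluster
    contingency table."""
    if calls["sample_id"].duplicated().any():
        dups = calls.loc[calls["sample_id"].duplicated(), "sample_id"]
        raise ParameterError(f"duplicate assay rows for: {list(dups)}")
    counts = pd.Series(
        {c: int((calls["call"] == c).sum()) for c in CLASSES}, name="count"
    )
    if membership is None:
        return counts, None
    lab = pd.Series(membership)
    merged = calls.assign(cluster=calls["sample_id"].map(lab))
    crosstab = pd.crosstab(merged["call"], merged["cluster"])
    return counts, crosstab
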