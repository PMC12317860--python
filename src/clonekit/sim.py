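"""Synthetic genotype cohorts with known truth.

Emulates the structure of a clonally-propagated tree-crop germplasm
collection: two (or more) divergent gene pools, early-generation hybrids
(F1-like 50/50 and BC1-like 25/75 ancestry), clonal groups of 2–9 trees
sharing a cultivar name, and reduced-representation genotyping noise
(heterozygote miscalls, dosage errors, missingness). Every cohort comes
with a :class:`TruthRecord` so downstream stages have parameter-recovery
tests.

The pool model is Balding–Nichols style: an ancestral allele frequency
``p`` per site, drawn uniform on [0.05, 0.95] so that MAF filtering does
not degenerate, and per-pool frequencies Beta-distributed around ``p``
with divergence controlled by ``fst``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GenotypeMatrix,
    ParameterError,
    make_site_table,
)


@dataclass
class PoolFrequencies:
    """Per-pool allele frequencies: ``freqs`` is K_pools x L, all in (0, 1)."""

    freqs: np.ndarray
    fst: float
    seed: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2:
            raise ParameterError("freqs must be K_pools x L")
        if (self.freqs <= 0).any() or (self.freqs >= 1).any():
            raise ParameterError("pool frequencies must lie strictly inside (0,1)")

    @property
    def k_pools(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_sites(self) -> int:
        return self.freqs.shape[1]


@dataclass
class CohortSpec:
    """Composition of a synthetic cohort.

    ``n_per_pool[k]`` pure founders from pool k; ``hybrids`` is a list of
    ``(ancestry_toward_pool_1, count)``; ``clone_groups`` is a list of
    ``(founder_index, copies)`` where the group comprises the founder
    sample plus ``copies - 1`` exact duplicates (group size = copies,
    2..9 in the emulated collection). ``noise`` is
    ``(het_miscall_rate, allele_error_rate, missing_rate)``.
    ``mislabel_fraction`` renames that fraction of clone copies to a fresh
    cultivar name, deliberately creating synonyms; ``unknown_fraction``
    blanks names to UNKNOWN.
    """

    n_per_pool: tuple = (10, 10)
    hybrids: list = field(default_factory=list)
    clone_groups: list = field(default_factory=list)
    n_sites: int = 2000
    noise: tuple = (0.05, 0.005, 0.05)
    mislabel_fraction: float = 0.0
    unknown_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_pool):
            raise ParameterError("founder counts must be non-negative")
        for q1, cnt in self.hybrids:
            if not 0.0 <= q1 <= 1.0:
                raise ParameterError(f"hybrid ancestry {q1} outside [0,1]")
            if cnt < 0:
                raise ParameterError("hybrid counts must be non-negative")
        for _, copies in self.clone_groups:
            if copies < 2:
                raise ParameterError("clone groups need copies >= 2")
        if not all(0.0 <= r <= 1.0 for r in self.noise):
            raise ParameterError("noise rates must lie in [0,1]")

    @property
    def n_founders(self) -> int:
        return sum(self.n_per_pool) + sum(c for _, c in self.hybrids)


@dataclass
class TruthRecord:
    """Ground truth emitted with every cohort: true ancestry matrix
    (rows sum to 1), the true clone partition (covers every sample exactly
    once) and the pre-noise founder genotypes."""

    true_q: np.ndarray
    clone_partition: list
    founder_genotypes: np.ndarray
    founder_of_sample: list

    def groups(self) -> list:
        """Clone groups of size >= 2 (the partition minus singletons)."""
        return [g for g in self.clone_partition if len(g) >= 2]


def simulate_pools(
    k_pools: int, n_sites: int, fst: float, seed: int
) -> PoolFrequencies:
    """Draw per-pool allele frequencies under a Balding–Nichols model.

    Ancestral frequencies are uniform on [0.05, 0.95]; for ``fst > 0``
    pool frequencies are Beta(p(1-fst)/fst, (1-p)(1-fst)/fst), and for
    ``fst = 0`` every pool equals the ancestral frequency exactly.
    """
    if k_pools < 1 or n_sites < 1:
        raise ParameterError("k_pools and n_sites must be >= 1")
    if not 0.0 <= fst < 1.0:
        raise ParameterError(f"fst must lie in [0, 1), got {fst}")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.05, 0.95, size=n_sites)
    if fst == 0.0:
        freqs = np.tile(anc, (k_pools, 1))
    else:
        a = anc * (1.0 - fst) / fst
        b = (1.0 - anc) * (1.0 - fst) / fst
        freqs = rng.beta(a, b, size=(k_pools, n_sites))
        freqs = np.clip(freqs, 1e-4, 1.0 - 1e-4)
    return PoolFrequencies(freqs=freqs, fst=fst, seed=seed)


def _founder_ancestries(spec: CohortSpec, k_pools: int) -> np.ndarray:
    rows = []
    for k, n in enumerate(spec.n_per_pool):
        q = np.zeros(k_pools)
        q[k] = 1.0
        rows.extend([q] * n)
    for q1, cnt in spec.hybrids:
        q = np.zeros(k_pools)
        q[0] = q1
        if k_pools > 1:
            q[1] = 1.0 - q1
        rows.extend([q] * cnt)
    if not rows:
        return np.zeros((0, k_pools))
    return np.vstack(rows)


def simulate_cohort(
    spec: CohortSpec, pools: PoolFrequencies
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Generate a cohort: founders, clones, names, noise, truth.

    Founder genotypes are Binomial(2, p_il) with
    ``p_il = sum_k q_ik f_kl``. Clone copies are exact duplicates of their
    founder before noise; noise is applied to the whole cohort with
    :func:`corrupt_genotypes` using ``spec.noise`` and ``spec.seed``.
    Clone groups share the founder's cultivar name unless mislabelled.
    """
    if len(spec.n_per_pool) > pools.k_pools:
        raise ParameterError("spec requests more pools than provided")
    k_pools = pools.k_pools
    n_founders = spec.n_founders
    for f_idx, _ in spec.clone_groups:
        if not 0 <= f_idx < n_founders:
            raise ParameterError(f"clone founder index {f_idx} out of range")
    seen = [f for f, _ in spec.clone_groups]
    if len(seen) != len(set(seen)):
        raise ParameterError("a founder may anchor at most one clone group")

    rng = np.random.default_rng(spec.seed)
    L = spec.n_sites
    if pools.n_sites < L:
        raise ParameterError("pools carry fewer sites than spec.n_sites")
    freqs = pools.freqs[:, :L]

    q_founders = _founder_ancestries(spec, k_pools)
    p = q_founders @ freqs  # n_founders x L
    founder_geno = rng.binomial(2, p).astype(np.int8) if n_founders else np.zeros(
        (0, L), dtype=np.int8
    )

    # Assemble samples: founders in order, then clone copies appended.
    copies_of = dict(spec.clone_groups)
    sample_rows = []
    names = []
    founder_of = []
    partition_map: dict[int, list[int]] = {}
    for i in range(n_founders):
        partition_map[i] = [len(sample_rows)]
        sample_rows.append(founder_geno[i])
        names.append(f"CV{i:03d}")
        founder_of.append(i)
    for f_idx, copies in spec.clone_groups:
        for _ in range(copies - 1):
            partition_map[f_idx].append(len(sample_rows))
            sample_rows.append(founder_geno[f_idx])
            names.append(f"CV{f_idx:03d}")
            founder_of.append(f_idx)

    n = len(sample_rows)
    calls = (
        np.vstack(sample_rows).astype(np.int8)
        if n
        else np.zeros((0, L), dtype=np.int8)
    )
    sample_ids = [f"S{i:03d}" for i in range(n)]

    # Deliberate naming faults. Mislabelling renames clone copies (making
    # the group a synonym set); unknowns blank the name entirely.
    clone_copy_rows = [r for f in copies_of for r in partition_map[f][1:]]
    n_mislabel = int(round(spec.mislabel_fraction * len(clone_copy_rows)))
    for j, row in enumerate(
        rng.permutation(np.array(clone_copy_rows, dtype=int))[:n_mislabel]
    ):
        names[row] = f"SYN{j:03d}"
    n_unknown = int(round(spec.unknown_fraction * n))
    for row in rng.permutation(n)[:n_unknown]:
        names[row] = "UNKNOWN"

    if n:
        calls = corrupt_genotypes(
            GenotypeMatrix(calls, sample_ids),
            *spec.noise,
            seed=int(rng.integers(2**31 - 1)),
        ).calls
    G = GenotypeMatrix(calls, sample_ids)

    samples = pd.DataFrame({"sample_id": sample_ids, "cultivar_name": names})
    true_q = (
        q_founders[np.array(founder_of, dtype=int)] if n else np.zeros((0, k_pools))
    )
    partition = [
        sorted(sample_ids[r] for r in rows) for rows in partition_map.values()
    ]
    truth = TruthRecord(
        true_q=true_q,
        clone_partition=partition,
        founder_genotypes=founder_geno,
        founder_of_sample=founder_of,
    )
    return G, samples, truth


def default_site_table(n_sites: int, per_chrom: int = 1000, spacing: int = 1000):
    """Evenly spaced synthetic SNP coordinates (ref C, alt T)."""
    chrom = [f"Chr{1 + i // per_chrom}" for i in range(n_sites)]
    pos = [spacing * (1 + i % per_chrom) for i in range(n_sites)]
    return make_site_table(chrom, pos, ["C"] * n_sites, ["T"] * n_sites)


def corrupt_genotypes(
    G: GenotypeMatrix,
    het_miscall_rate: float,
    allele_error_rate: float,
    missing_rate: float,
    seed: int,
) -> GenotypeMatrix:
    """Apply the three-rate genotyping-noise model, in fixed order.

    1. each heterozygote independently becomes a random homozygote
       (0 or 2, equiprobable) with probability ``het_miscall_rate``;
    2. each call is perturbed by +-1 dosage (clipped to [0, 2]) with
       probability ``allele_error_rate``;
    3. each call is set missing with probability ``missing_rate``.

    Calls already missing in the input stay missing.
    """
    for r in (het_miscall_rate, allele_error_rate, missing_rate):
        if not 0.0 <= r <= 1.0:
            raise ParameterError(f"noise rate {r} outside [0,1]")
    rng = np.random.default_rng(seed)
    calls = G.calls.copy()
    obs = calls != MISSING

    hit = obs & (calls == 1) & (rng.random(calls.shape) < het_miscall_rate)
    calls[hit] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(hit.sum()))

    hit = obs & (rng.random(calls.shape) < allele_error_rate)
    delta = rng.choice(np.array([-1, 1], dtype=np.int8), size=int(hit.sum()))
    calls[hit] = np.clip(calls[hit] + delta, 0, 2)

    hit = obs & (rng.random(calls.shape) < missing_rate)
    calls[hit] = MISSING
    return GenotypeMatrix(calls, list(G.sample_ids))
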