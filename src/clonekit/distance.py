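"""Pairwise p-distances from dosage genotypes, with site bootstrap.

The per-site distance between two diploid calls is |dosage_i - dosage_j|/2
(identical 0; het vs hom 0.5; opposite homozygotes 1) and the pairwise
distance is the mean over pairwise-complete sites (both calls observed).
Missing data are handled by pairwise deletion, so different pairs may use
different site sets; the per-pair count is kept in ``n_sites_used``.

p-distances are not guaranteed metric (the triangle inequality may fail);
symmetry and the [0, 1] range are guaranteed.
"""

from __future__ import annotations

import logging
import os

import numpy as np

from .core import MISSING, DistanceMatrix, GenotypeMatrix, ParameterError

logger = logging.getLogger(__name__)


class ZeroOverlapError(ParameterError):
    """A sample pair shares no non-missing site."""

    def __init__(self, pairs):
        self.pairs = pairs
        super().__init__(
            f"no pairwise-complete sites for sample pair(s): {pairs}"
        )


def pdistance_pair(g_i, g_j) -> tuple[float, int]:
    """p-distance between two dosage vectors over pairwise-complete sites."""
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ParameterError("dosage vectors must have equal length")
    both = (g_i != MISSING) & (g_j != MISSING)
    n_used = int(both.sum())
    if n_used == 0:
        raise ZeroOverlapError([("g_i", "g_j")])
    d = float(
        np.abs(g_i[both].astype(np.int16) - g_j[both]).sum() / (2.0 * n_used)
    )
    return d, n_used


def distance_matrix(G: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs p-distance matrix (symmetric, zero diagonal)."""
    if G.n_samples < 2:
        raise ParameterError("need at least 2 samples for a distance matrix")
    calls = G.calls.astype(np.int16)
    obs = calls != MISSING
    n = G.n_samples
    values = np.zeros((n, n))
    used = np.zeros((n, n), dtype=np.int64)
    used[np.diag_indices(n)] = obs.sum(axis=1)
    bad_pairs = []
    for i in range(n - 1):
        both = obs[i] & obs[i + 1 :]
        cnt = both.sum(axis=1)
        diff = np.abs(calls[i] - calls[i + 1 :]) * both
        zero = cnt == 0
        if zero.any():
            bad_pairs.extend(
                (G.sample_ids[i], G.sample_ids[i + 1 + int(j)])
                for j in np.flatnonzero(zero)
            )
            cnt = np.where(zero, 1, cnt)
        row = diff.sum(axis=1) / (2.0 * cnt)
        values[i, i + 1 :] = values[i + 1 :, i] = row
        used[i, i + 1 :] = used[i + 1 :, i] = cnt
    if bad_pairs:
        raise ZeroOverlapError(bad_pairs)
    return DistanceMatrix(values=values, labels=list(G.sample_ids),
                          n_sites_used=used)


def bootstrap_matrices(
    G: GenotypeMatrix, B: int, seed: int, max_retries: int = 10
):
    """Yield ``B`` site-bootstrap distance matrices.

    Each replicate resamples sites with replacement to the original site
    count. A replicate in which some pair loses all shared sites is
    redrawn (logged); after ``max_retries`` failures the error propagates.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, G.n_sites, size=G.n_sites)
            try:
                out.append(distance_matrix(G.take_sites(idx)))
                break
            except ZeroOverlapError:
                logger.warning("bootstrap replicate %d redrawn (attempt %d)",
                               b, attempt + 1)
                if attempt == max_retries:
                    raise
    return out


def write_phylip(D: DistanceMatrix, path) -> str:
    """Square PHYLIP distance matrix (the dialect FastME/PHYLIP read)."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for i, label in enumerate(D.labels):
            row = " ".join(f"{v:.6f}" for v in D.values[i])
            fh.write(f"{label[:10]:<10} {row}\n")
    return path
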