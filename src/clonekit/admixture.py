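"""Maximum-likelihood admixture estimation by EM, with Evanno deltaK.

The model is the standard unsupervised admixture likelihood for unlinked
biallelic SNPs: sample i carries ancestry proportions q_i over K
ancestral populations with allele frequencies f_k, and each diploid
dosage g_il is Binomial(2, p_il) with ``p_il = sum_k q_ik f_kl``,

    log L = sum_il [ g_il log p_il + (2 - g_il) log(1 - p_il) ],

missing calls skipped. The fit uses the classic EM updates (each
iteration provably does not decrease the likelihood, which is asserted),
multiple seeded restarts, and model choice across K by the Evanno deltaK
second-difference statistic computed on per-run final log-likelihoods.
This is a deliberate reinterpretation of MCMC-based Bayesian clustering:
the likelihood model is the same, the maximisation is deterministic per
seed, and deltaK transfers to per-run log-likelihoods — only the
argmax-K behaviour, not the posterior, is comparable to an MCMC run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, ParameterError

_F_EPS = 1e-6


@dataclass
class AdmixtureFit:
    """EM result: Q (n x K, rows sum to 1), F (K x L in
    [1e-6, 1-1e-6]), final log-likelihood and its per-iteration
    trajectory (non-decreasing)."""

    Q: np.ndarray
    F: np.ndarray
    loglik: float
    trajectory: np.ndarray
    K: int
    seed: int
    converged: bool


def _loglik(g, obs, p) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = np.where(obs, g * np.log(p) + (2.0 - g) * np.log1p(-p), 0.0)
    return float(ll.sum())


def em_admixture(
    G: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """Fit the K-population admixture model by EM.

    Q is initialised from a symmetric Dirichlet and F from the observed
    per-site frequencies with seeded jitter; F is clipped to
    [1e-6, 1-1e-6] every iteration. Convergence is declared when the
    relative log-likelihood change drops below ``tol``.
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    if K > G.n_samples:
        raise ParameterError(f"K={K} exceeds sample count {G.n_samples}")
    obs = G.observed()
    empty = ~obs.any(axis=1)
    if empty.any():
        bad = [G.sample_ids[i] for i in np.flatnonzero(empty)]
        raise ParameterError(f"samples with no observed calls: {bad}")

    rng = np.random.default_rng(seed)
    g = np.where(obs, G.calls, 0).astype(float)
    n, L = g.shape
    n_obs = obs.sum(axis=1).astype(float)

    with np.errstate(invalid="ignore"):
        base = np.where(obs, g, np.nan)
    pbar = np.nanmean(base, axis=0) / 2.0
    pbar = np.nan_to_num(pbar, nan=0.5)
    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(
        pbar[None, :] + rng.normal(0.0, 0.05, size=(K, L)), _F_EPS, 1 - _F_EPS
    )

    traj = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        ll = _loglik(g, obs, P)
        if traj and ll < traj[-1] - 1e-6 * max(1.0, abs(traj[-1])):
            raise AssertionError(
                f"EM log-likelihood decreased: {traj[-1]} -> {ll}"
            )
        traj.append(ll)
        if np.isfinite(prev) and abs(ll - prev) < tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = ll

        # E/M in one pass: responsibilities for alt and ref alleles
        alt_w = np.where(obs, g / P, 0.0)          # n x L
        ref_w = np.where(obs, (2.0 - g) / (1.0 - P), 0.0)
        new_Q = np.empty_like(Q)
        new_F = np.empty_like(F)
        for k in range(K):
            a_k = Q[:, k, None] * F[k][None, :] * alt_w        # n x L
            b_k = Q[:, k, None] * (1.0 - F[k])[None, :] * ref_w
            new_Q[:, k] = (a_k.sum(axis=1) + b_k.sum(axis=1)) / (2.0 * n_obs)
            num = a_k.sum(axis=0)
            den = num + b_k.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                new_F[k] = np.where(den > 0, num / den, F[k])
        Q = new_Q / new_Q.sum(axis=1, keepdims=True)
        F = np.clip(new_F, _F_EPS, 1 - _F_EPS)

    return AdmixtureFit(
        Q=Q, F=F, loglik=traj[-1], trajectory=np.asarray(traj), K=K,
        seed=seed, converged=converged,
    )


def best_of_restarts(
    G: GenotypeMatrix,
    K: int,
    restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[AdmixtureFit, list]:
    """Run ``restarts`` seeded EM fits; return (best fit, all fits)."""
    rng = np.random.default_rng(seed)
    fits = [
        em_admixture(G, K, seed=int(rng.integers(2**31 - 1)),
                     max_iter=max_iter, tol=tol)
        for _ in range(restarts)
    ]
    best = max(fits, key=lambda f: f.loglik)
    return best, fits


def admixture_scan(
    G: GenotypeMatrix,
    k_values,
    restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[dict, dict]:
    """Fit every K in ``k_values`` with restarts.

    Returns (best fit per K, final log-likelihoods per K).
    """
    best_fits: dict[int, AdmixtureFit] = {}
    logliks: dict[int, list] = {}
    rng = np.random.default_rng(seed)
    for K in sorted(k_values):
        best, fits = best_of_restarts(
            G, K, restarts=restarts, seed=int(rng.integers(2**31 - 1)),
            max_iter=max_iter, tol=tol,
        )
        best_fits[K] = best
        logliks[K] = [f.loglik for f in fits]
    return best_fits, logliks


def evanno_delta_k(logliks: dict) -> pd.DataFrame:
    """Evanno deltaK from per-K collections of final log-likelihoods.

    For each interior K of a contiguous range,
    ``deltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))``
    with the sample standard deviation across runs. Where sd is zero the
    statistic is undefined: ``defined`` is False and deltaK is NaN
    (never silently infinite).
    """
    ks = sorted(logliks)
    if len(ks) < 3:
        raise ParameterError("deltaK needs a contiguous K range of length >= 3")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ParameterError(f"K values must be contiguous, got {ks}")
    for k in ks:
        if len(logliks[k]) < 2:
            raise ParameterError(f"deltaK needs >= 2 runs per K (K={k})")
    mean = {k: float(np.mean(logliks[k])) for k in ks}
    sd = {k: float(np.std(logliks[k], ddof=1)) for k in ks}
    rows = []
    for k in ks[1:-1]:
        num = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1])
        defined = sd[k] > 0
        rows.append(
            {
                "K": k,
                "mean_loglik": mean[k],
                "sd_loglik": sd[k],
                "delta_k": num / sd[k] if defined else np.nan,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def best_k(delta_table: pd.DataFrame) -> int:
    """K with the largest defined deltaK."""
    ok = delta_table[delta_table["defined"]]
    if ok.empty:
        raise ParameterError("deltaK undefined at every K (zero run variance)")
    return int(ok.loc[ok["delta_k"].idxmax(), "K"])


def classify_membership(Q: np.ndarray, threshold: float = 0.80) -> list:
    """Per-sample label: ``cluster{k}`` (1-based) when the largest
    ancestry coefficient strictly exceeds ``threshold``, else
    ``admixed``."""
    Q = np.asarray(Q, dtype=float)
    labels = []
    for row in Q:
        k = int(np.argmax(row))
        labels.append(f"cluster{k + 1}" if row[k] > threshold else "admixed")
    return labels


def classify_hybrid_class(q_row, tol: float = 0.02) -> str:
    """Classify a two-pool ancestry row as F1-like (50/50 within
    ``tol``), BC1-like (25/75 or 75/25 within ``tol``) or other.
    F1 takes precedence (classes cannot overlap for tol <= 0.125)."""
    q_row = np.asarray(q_row, dtype=float)
    if q_row.shape != (2,):
        raise ParameterError("hybrid classification requires K = 2")
    q1 = float(q_row[0])
    if abs(q1 - 0.5) <= tol:
        return "F1-like"
    if abs(q1 - 0.25) <= tol or abs(q1 - 0.75) <= tol:
        return "BC1-like"
    return "other"


def align_clusters(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permute the columns of Q to best match a reference Q (greedy
    correlation matching, the label-switching fix used when comparing
    runs or truth)."""
    Q = np.asarray(Q, float)
    Q_ref = np.asarray(Q_ref, float)
    K = Q.shape[1]
    if Q_ref.shape[1] != K:
        raise ParameterError("cluster counts differ")
    corr = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            corr[a, b] = -np.sum((Q[:, a] - Q_ref[:, b]) ** 2)
    perm = [-1] * K
    used_a, used_b = set(), set()
    for _ in range(K):
        best = None
        for a in range(K):
            if a in used_a:
                continue
            for b in range(K):
                if b in used_b:
                    continue
                if best is None or corr[a, b] > corr[best]:
                    best = (a, b)
        a, b = best
        perm[b] = a
        used_a.add(a)
        used_b.add(b)
    return Q[:, perm]
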