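"""Model-based admixture inference on pseudo-haploid calls.

A Gibbs sampler over the classic no-admixture-prior mixture model: each
non-missing single-allele call draws a latent cluster of origin z from
Categorical(q_i · f), where q_i is the individual's admixture proportion
vector (Dirichlet(alpha) prior) and f is the call's frequency under each
cluster (Beta(1, 1) prior on the per-cluster allele-2 frequencies).
Conjugate updates alternate with the z draws.  Marginal likelihoods per K
use the harmonic-approximation estimator mean(lnL) − var(lnL)/2, and the
number of clusters is chosen with the second-order ΔK statistic over
replicate runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from numba import njit, uint64
from scipy.optimize import linear_sum_assignment

from . import _rng
from .popstruct import MISSING, PseudoHaploidMatrix

__all__ = [
    "AdmixtureResult",
    "KSelectionTable",
    "admixture_gibbs",
    "estimate_marginal_likelihood",
    "evanno_delta_k",
    "align_replicates",
    "run_admixture_scan",
]


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray                 # (n, K) posterior-mean admixture proportions
    P: np.ndarray                 # (K, L) posterior-mean allele-2 frequencies
    loglik_trace: np.ndarray      # retained (post-burn-in, thinned) steps
    lnP_X_given_K: float
    run_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        if ((self.P < 0) | (self.P > 1)).any():
            raise ValueError("P entries must lie in [0, 1]")


@dataclass
class KSelectionTable:
    """Replicate marginal likelihoods per K with the ΔK statistic."""

    table: pd.DataFrame  # columns: K, n_reps, mean_lnP, sd_lnP, delta_k

    @property
    def best_k(self) -> int:
        t = self.table.dropna(subset=["delta_k"])
        if t.empty:
            raise ValueError("delta_k undefined for every interior K")
        return int(t.loc[t["delta_k"].idxmax(), "K"])


@njit(cache=True, fastmath=True)
def _admixture_kernel(calls, K, steps, burnin, thin, alpha, seed):
    """calls: (L, n) int8 with 0 = allele 1, 1 = allele 2, -1 = missing.

    The latent-origin draw is branchless over clusters (cumulative weights,
    z = Σ [u >= cum_k]) and the call type enters arithmetically
    (f = (1-cc) + (2cc-1)·p), which keeps the hot loop free of
    data-dependent branches.
    """
    state = _rng.seed_state(seed)
    c = state[0]
    L, n = calls.shape
    Q = np.empty((n, K))
    P = np.empty((L, K))  # allele-2 frequency per locus x cluster
    prior = np.full(K, alpha)
    for i in range(n):
        _rng.dirichlet_into(state, prior, Q[i])
    for l in range(L):
        for k in range(K):
            P[l, k] = _rng.uniform(state)
    c = state[0]
    # per-cell arithmetic encoding of the call: f_k = av + bv * p_k
    av = np.empty((L, n))
    bv = np.empty((L, n))
    ci = np.empty((L, n), np.int64)   # 1 for allele-2 calls
    ok = np.empty((L, n), np.int64)   # 0 for missing
    for l in range(L):
        for i in range(n):
            cc = calls[l, i]
            if cc < 0:
                av[l, i] = 1.0
                bv[l, i] = 0.0
                ci[l, i] = 0
                ok[l, i] = 0
            else:
                av[l, i] = 1.0 - cc
                bv[l, i] = 2.0 * cc - 1.0
                ci[l, i] = cc
                ok[l, i] = 1
    cnt_q = np.zeros((n, K), np.int64)
    a1 = np.zeros((L, K), np.int64)
    a2 = np.zeros((L, K), np.int64)
    Qsum = np.zeros((n, K))
    Psum = np.zeros((L, K))
    n_trace = (steps + thin - 1) // thin
    trace = np.empty(n_trace)
    w = np.empty(K)
    alph = np.empty(K)
    ti = 0
    n_ret = 0
    for step in range(steps):
        cnt_q[:, :] = 0
        a1[:, :] = 0
        a2[:, :] = 0
        for l in range(L):
            pl = P[l]
            arow = av[l]
            brow = bv[l]
            crow = ci[l]
            orow = ok[l]
            a1row = a1[l]
            a2row = a2[l]
            for i in range(n):
                if orow[i] == 0:
                    continue
                acc = 0.0
                a = arow[i]
                b = brow[i]
                for k in range(K):
                    acc += Q[i, k] * (a + b * pl[k])
                    w[k] = acc
                cnt = c + _rng.GOLD
                c = cnt
                t = (cnt ^ (cnt >> uint64(30))) * _rng.M1
                t = (t ^ (t >> uint64(27))) * _rng.M2
                t = t ^ (t >> uint64(31))
                u = float(t >> uint64(11)) * _rng.INV_2_53 * acc
                z = 0
                for k in range(K - 1):
                    z += u >= w[k]
                cnt_q[i, z] += 1
                a2row[z] += crow[i]
                a1row[z] += 1 - crow[i]
        state[0] = c
        for i in range(n):
            for k in range(K):
                alph[k] = alpha + cnt_q[i, k]
            _rng.dirichlet_into(state, alph, Q[i])
        for l in range(L):
            for k in range(K):
                P[l, k] = _rng.beta(state, 1.0 + a2[l, k], 1.0 + a1[l, k])
        c = state[0]
        if step >= burnin:
            Qsum += Q
            Psum += P
            n_ret += 1
        if step % thin == 0:
            ll = 0.0
            for l in range(L):
                pl = P[l]
                arow = av[l]
                brow = bv[l]
                orow = ok[l]
                for i in range(n):
                    if orow[i] == 0:
                        continue
                    mix = 0.0
                    a = arow[i]
                    b = brow[i]
                    for k in range(K):
                        mix += Q[i, k] * (a + b * pl[k])
                    ll += np.log(mix + 1e-300)
            trace[ti] = ll
            ti += 1
    return Qsum / n_ret, Psum.T / n_ret, trace[:ti]


def admixture_gibbs(
    phm: PseudoHaploidMatrix,
    K: int,
    steps: int = 10_000,
    burnin: int = 5_000,
    thin: int = 10,
    alpha: float = 1.0,
    seed: int = 0,
) -> AdmixtureResult:
    """Gibbs sampling of admixture proportions and cluster frequencies.

    Defaults are the desk-scale settings (10,000 steps / 5,000 burn-in);
    the full-scale schedule (100,000 / 50,000) is available through the
    pipeline configuration.  Missing calls contribute nothing to any
    update.  Q and P are posterior means over post-burn-in steps; the
    log-likelihood trace is recorded every ``thin`` steps.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if phm.calls.size == 0:
        raise ValueError("empty call matrix")
    if not steps > burnin >= 0:
        raise ValueError("require steps > burnin >= 0")
    calls01 = np.full(phm.calls.shape, -1, dtype=np.int8)
    calls01[phm.calls == 1] = 0
    calls01[phm.calls == 2] = 1
    calls_t = np.ascontiguousarray(calls01.T)
    Q, P, full_trace = _admixture_kernel(
        calls_t, K, steps, burnin, thin, float(alpha), int(seed)
    )
    # renormalize away accumulated floating error
    Q = Q / Q.sum(axis=1, keepdims=True)
    retained = full_trace[(np.arange(len(full_trace)) * thin) >= burnin]
    lnp = estimate_marginal_likelihood(retained) if len(retained) >= 2 else np.nan
    return AdmixtureResult(
        K=K,
        Q=Q,
        P=np.clip(P, 0.0, 1.0),
        loglik_trace=retained,
        lnP_X_given_K=lnp,
        run_meta={
            "steps": steps,
            "burnin": burnin,
            "thin": thin,
            "alpha": alpha,
            "seed": int(seed),
            "full_trace": full_trace,
        },
    )


def estimate_marginal_likelihood(loglik_trace) -> float:
    """Harmonic-approximation estimator: mean(trace) − var(trace)/2."""
    t = np.asarray(loglik_trace, dtype=np.float64)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("trace must contain at least 2 values")
    return float(t.mean() - t.var(ddof=1) / 2.0)


def evanno_delta_k(replicate_lnP: Dict[int, Sequence[float]]) -> KSelectionTable:
    """Second-order ΔK statistic over replicate marginal likelihoods.

    ΔK(K) = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / sd(L(K)), with the
    sample (n−1) standard deviation; undefined (NaN) at the endpoints of
    the K range and wherever sd is zero.
    """
    ks = sorted(int(k) for k in replicate_lnP)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(replicate_lnP[k]) < 2:
            raise ValueError(f"K={k} has fewer than 2 replicates")
    means = {k: float(np.mean(replicate_lnP[k])) for k in ks}
    sds = {k: float(np.std(replicate_lnP[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1] or sds[k] == 0.0:
            dk = np.nan
        else:
            dk = abs(means[k + 1] - 2.0 * means[k] + means[k - 1]) / sds[k]
        rows.append(
            {"K": k, "n_reps": len(replicate_lnP[k]), "mean_lnP": means[k],
             "sd_lnP": sds[k], "delta_k": dk}
        )
    return KSelectionTable(table=pd.DataFrame(rows))


def align_replicates(Q_list: Sequence[np.ndarray]):
    """Resolve label switching across replicate runs.

    Each run's cluster columns are permuted to minimize the summed
    absolute difference to the first run (optimal assignment).  Returns
    (aligned list, permutation list); each permutation maps aligned column
    a to original column perm[a].
    """
    if not Q_list:
        return [], []
    shape = Q_list[0].shape
    for Q in Q_list:
        if Q.shape != shape:
            raise ValueError("all Q matrices must share shape")
    ref = Q_list[0]
    aligned, perms = [], []
    for Q in Q_list:
        cost = np.abs(ref[:, :, None] - Q[:, None, :]).sum(axis=0)
        _, col = linear_sum_assignment(cost)
        aligned.append(Q[:, col])
        perms.append(col)
    return aligned, perms


def run_admixture_scan(
    phm: PseudoHaploidMatrix,
    k_values: Sequence[int],
    replicates: int = 10,
    steps: int = 10_000,
    burnin: int = 5_000,
    thin: int = 10,
    alpha: float = 1.0,
    seed: int = 0,
):
    """Replicate admixture runs over a K range.

    Returns (KSelectionTable, results dict {K: [AdmixtureResult, ...]});
    replicate r of K uses a seed derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    results: Dict[int, list] = {}
    lnp: Dict[int, list] = {}
    for k in k_values:
        child = ss.spawn(1)[0]
        run_seeds = child.generate_state(replicates) % (2**31 - 1)
        results[k] = [
            admixture_gibbs(
                phm, k, steps=steps, burnin=burnin, thin=thin, alpha=alpha,
                seed=int(s),
            )
            for s in run_seeds
        ]
        lnp[k] = [r.lnP_X_given_K for r in results[k]]
    return evanno_delta_k(lnp), results
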