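"""Bayesian genotype / allele-frequency inference from read counts.

The model treats per-individual genotypes and per-population allele
frequencies as unknowns.  Reads at a biallelic site are a noisy channel on
the genotype: with per-read miscall rate ``err``, an alternate read arises
with probability ``err`` from genotype 0 (homozygous reference), ``0.5``
from a heterozygote, and ``1 - err`` from genotype 2.  Within each
population genotypes follow Hardy–Weinberg proportions given that
population's allele frequency ``p``, which carries a Beta(1, 1) prior.

Inference is by Gibbs sampling: alternate genotype draws from the
read-likelihood × HWE categorical posterior with Beta conjugate updates of
``p``.  A fast EM point estimator over the same model backs the diversity
statistics (``pi``, Watterson's theta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit, uint64
from scipy.special import gammaln

from . import _rng

logger = logging.getLogger(__name__)

__all__ = [
    "ReadCountMatrix",
    "GenotypePosterior",
    "AlleleFrequencyPosterior",
    "DiversityEstimates",
    "genotype_likelihoods",
    "gibbs_allele_frequency",
    "em_allele_frequencies",
    "diversity_estimates",
]


@dataclass
class ReadCountMatrix:
    """Per individual × locus reference/alternate read counts.

    Attributes
    ----------
    loci : array of str
        Locus identifiers, unique.
    individuals : array of str
        Individual identifiers, unique.
    populations : array of str
        Population label per individual (aligned with ``individuals``).
    ref, alt : int arrays, shape (n_individuals, n_loci)
        Reference / alternate read counts.
    """

    loci: np.ndarray
    individuals: np.ndarray
    populations: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.loci = np.asarray(self.loci, dtype=object)
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.ref = np.asarray(self.ref, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        n, L = self.ref.shape
        if self.alt.shape != (n, L):
            raise ValueError("ref and alt count shapes differ")
        if len(self.individuals) != n or len(self.loci) != L:
            raise ValueError("identifier lengths do not match count matrix")
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if any(not str(p) for p in self.populations):
            raise ValueError("population labels must be non-empty")
        if len(set(self.loci)) != L:
            raise ValueError("locus identifiers must be unique")
        if len(set(self.individuals)) != n:
            raise ValueError("individual identifiers must be unique")

    @property
    def n_individuals(self) -> int:
        return self.ref.shape[0]

    @property
    def n_loci(self) -> int:
        return self.ref.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    @property
    def pop_labels(self) -> list:
        """Unique population labels in order of first appearance."""
        seen: dict = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def pop_indices(self) -> np.ndarray:
        """Integer population index per individual, following pop_labels."""
        lut = {p: i for i, p in enumerate(self.pop_labels)}
        return np.array([lut[p] for p in self.populations], dtype=np.int64)

    def subset(self, ind_mask=None, locus_mask=None) -> "ReadCountMatrix":
        im = np.ones(self.n_individuals, bool) if ind_mask is None else np.asarray(ind_mask, bool)
        lm = np.ones(self.n_loci, bool) if locus_mask is None else np.asarray(locus_mask, bool)
        return ReadCountMatrix(
            loci=self.loci[lm],
            individuals=self.individuals[im],
            populations=self.populations[im],
            ref=self.ref[np.ix_(im, lm)],
            alt=self.alt[np.ix_(im, lm)],
        )


@dataclass
class GenotypePosterior:
    """Posterior probabilities of genotypes g in {0, 1, 2} alternate copies."""

    prob: np.ndarray  # (n_individuals, n_loci, 3)
    individuals: np.ndarray
    loci: np.ndarray

    def __post_init__(self) -> None:
        s = self.prob.sum(axis=2)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("genotype posterior triples must sum to 1")


@dataclass
class AlleleFrequencyPosterior:
    """Post-burn-in MCMC draws of allele frequency per population × locus."""

    draws: np.ndarray  # (n_pops, n_loci, n_draws)
    populations: list
    loci: np.ndarray
    mcmc_meta: dict = field(default_factory=dict)

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=2)


@dataclass
class DiversityEstimates:
    """Per-population diversity summaries over a set of assayed sites."""

    populations: list
    pi: np.ndarray            # mean expected heterozygosity over variable sites
    theta_w: np.ndarray       # S / a_{2n-1} for the variable-site set
    theta_w_per_site: np.ndarray  # theta_w divided by the number of assayed sites
    S: np.ndarray             # segregating (variable) site count
    n: np.ndarray             # diploid sample size

    def __post_init__(self) -> None:
        if (self.pi < 0).any() or (self.theta_w < 0).any():
            raise ValueError("diversity estimates must be non-negative")


def _error_channel(err: float) -> np.ndarray:
    if not 0.0 <= err < 0.5:
        raise ValueError(f"per-read error rate must be in [0, 0.5), got {err}")
    return np.array([err, 0.5, 1.0 - err])


def genotype_likelihoods(ref_count, alt_count, err: float) -> np.ndarray:
    """Unnormalized binomial read likelihoods for genotypes 0/1/2.

    L(g) = C(d, a) * e(g)^a * (1 - e(g))^(d - a) with d total reads,
    a alternate reads, e(0)=err, e(1)=0.5, e(2)=1-err.  Zero depth yields
    (1, 1, 1): the data carry no information.
    """
    e = _error_channel(err)
    ref = np.asarray(ref_count, dtype=np.float64)
    alt = np.asarray(alt_count, dtype=np.float64)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    d = ref + alt
    logc = gammaln(d + 1) - gammaln(alt + 1) - gammaln(ref + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            logc[..., None]
            + alt[..., None] * np.log(e)
            + ref[..., None] * np.log1p(-e)
        )
    # 0 * log(0) situations (err == 0 with zero matching reads) -> 0
    ll = np.where(np.isnan(ll), -np.inf, ll)
    ll = np.where((d == 0)[..., None], 0.0, ll)
    return np.exp(ll)


def _normalized_likelihoods(rcm: ReadCountMatrix, err: float) -> np.ndarray:
    lik = genotype_likelihoods(rcm.ref, rcm.alt, err)
    tot = lik.sum(axis=2, keepdims=True)
    tot[tot == 0] = 1.0
    return lik / tot


@njit(cache=True, fastmath=True)
def _gibbs_kernel(lik, pop_start, steps, burnin, thin, seed):
    """Gibbs alternation over genotypes and allele frequencies.

    lik : (L, n, 3) normalized genotype likelihoods, individuals grouped
    contiguously by population (``pop_start`` holds the n_pops+1 segment
    offsets).  Returns (draws (n_pops, L, kept), gcount (L, n, 3)).

    The genotype draw is branchless (g = [u >= w0] + [u >= w0+w1]) and the
    splitmix64 counter lives in a register, both of which matter at ~10^9
    draws per chain.
    """
    state = _rng.seed_state(seed)
    c = state[0]
    L, n, _ = lik.shape
    n_pops = len(pop_start) - 1
    kept = (steps - burnin + thin - 1) // thin
    draws = np.empty((n_pops, L, kept))
    gcount = np.zeros((L, n, 3), np.int32)
    p = np.full((n_pops, L), 0.5)
    ki = 0
    for step in range(steps):
        rec = step >= burnin
        keep = rec and (step - burnin) % thin == 0
        for l in range(L):
            row = lik[l]
            grow = gcount[l]
            for k in range(n_pops):
                pk = p[k, l]
                q = 1.0 - pk
                h0 = q * q
                h1 = 2.0 * pk * q
                h2 = pk * pk
                alt = 0
                lo = pop_start[k]
                hi = pop_start[k + 1]
                if rec:
                    for i in range(lo, hi):
                        w0 = row[i, 0] * h0
                        w1 = w0 + row[i, 1] * h1
                        w2 = w1 + row[i, 2] * h2
                        c = c + _rng.GOLD
                        t = c
                        t = (t ^ (t >> uint64(30))) * _rng.M1
                        t = (t ^ (t >> uint64(27))) * _rng.M2
                        t = t ^ (t >> uint64(31))
                        u = float(t >> uint64(11)) * _rng.INV_2_53 * w2
                        g = (u >= w0) + (u >= w1)
                        alt += g
                        grow[i, g] += 1
                else:
                    for i in range(lo, hi):
                        w0 = row[i, 0] * h0
                        w1 = w0 + row[i, 1] * h1
                        w2 = w1 + row[i, 2] * h2
                        c = c + _rng.GOLD
                        t = c
                        t = (t ^ (t >> uint64(30))) * _rng.M1
                        t = (t ^ (t >> uint64(27))) * _rng.M2
                        t = t ^ (t >> uint64(31))
                        u = float(t >> uint64(11)) * _rng.INV_2_53 * w2
                        alt += (u >= w0) + (u >= w1)
                state[0] = c
                pv = _rng.beta(state, 1.0 + alt, 1.0 + 2.0 * (hi - lo) - alt)
                c = state[0]
                p[k, l] = pv
                if keep:
                    draws[k, l, ki] = pv
        if keep:
            ki += 1
    return draws, gcount


def gibbs_allele_frequency(
    rcm: ReadCountMatrix,
    err: float = 0.005,
    steps: int = 100_000,
    burnin: int = 10_000,
    thin: int = 10,
    seed: int = 0,
):
    """Joint MCMC of genotypes and per-population allele frequencies.

    Parameters follow the model defaults: 100,000 steps with a 10,000-step
    burn-in, thinning 10 for the stored frequency draws.  The genotype
    posterior is the empirical frequency of sampled genotypes over all
    post-burn-in steps.

    Returns
    -------
    (AlleleFrequencyPosterior, GenotypePosterior)
    """
    if not steps > burnin >= 0:
        raise ValueError("require steps > burnin >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    pops = rcm.pop_labels
    counts = {p: 0 for p in pops}
    for p in rcm.populations:
        counts[p] += 1
    empty = [p for p, c in counts.items() if c == 0]
    if rcm.n_individuals == 0 or empty:
        raise ValueError(f"population(s) without individuals: {empty or pops}")
    # group individuals contiguously by population for the kernel
    pidx = rcm.pop_indices()
    order = np.argsort(pidx, kind="stable")
    inv_order = np.argsort(order)
    pop_start = np.zeros(len(pops) + 1, dtype=np.int64)
    np.cumsum(np.bincount(pidx, minlength=len(pops)), out=pop_start[1:])
    lik = _normalized_likelihoods(rcm, err)[order]
    lik = np.ascontiguousarray(np.swapaxes(lik, 0, 1))
    draws, gcount = _gibbs_kernel(lik, pop_start, steps, burnin, thin, int(seed))
    prob = np.swapaxes(gcount, 0, 1).astype(np.float64)[inv_order] / (steps - burnin)
    afp = AlleleFrequencyPosterior(
        draws=draws,
        populations=pops,
        loci=rcm.loci,
        mcmc_meta={
            "steps": steps,
            "burnin": burnin,
            "thin": thin,
            "seed": int(seed),
            "err": err,
        },
    )
    gp = GenotypePosterior(prob=prob, individuals=rcm.individuals, loci=rcm.loci)
    return afp, gp


def em_allele_frequencies(
    likelihoods: np.ndarray, iterations: int = 20, p_init: float = 0.5
) -> float:
    """EM point estimate of the allele frequency for one locus/population.

    E-step: genotype posterior ∝ L(g)·HWE(g | p).  M-step: p ← Σ E[g] / 2N.
    20 iterations by default.
    """
    lik = np.asarray(likelihoods, dtype=np.float64)
    if lik.ndim != 2 or lik.shape[1] != 3 or lik.shape[0] == 0:
        raise ValueError("likelihoods must be a non-empty (N, 3) array")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    p = _em_vectorized(lik[None, ...].swapaxes(0, 1), iterations, p_init)
    return float(p[0])


def _em_vectorized(lik: np.ndarray, iterations: int, p_init: float = 0.5) -> np.ndarray:
    """EM across loci at once.  lik: (n_individuals, L, 3) -> p: (L,)."""
    n, L, _ = lik.shape
    p = np.full(L, p_init)
    g = np.arange(3.0)
    for _ in range(iterations):
        q = 1.0 - p
        hwe = np.stack([q * q, 2 * p * q, p * p], axis=-1)  # (L, 3)
        w = lik * hwe[None, :, :]
        tot = w.sum(axis=2, keepdims=True)
        tot[tot == 0] = 1.0
        eg = (w * g).sum(axis=2) / tot[..., 0]  # (n, L)
        p = eg.sum(axis=0) / (2.0 * n)
    return np.clip(p, 0.0, 1.0)


def observed_loglik(lik: np.ndarray, p: np.ndarray) -> float:
    """Observed-data log likelihood Σ_i log Σ_g L_i(g) HWE(g|p) at one locus."""
    q = 1.0 - p
    hwe = np.array([q * q, 2 * p * q, p * p])
    mix = lik @ hwe
    return float(np.sum(np.log(np.maximum(mix, 1e-300))))


def diversity_estimates(
    rcm: ReadCountMatrix,
    err: float = 0.005,
    iterations: int = 20,
    tol: float = 1e-6,
) -> DiversityEstimates:
    """Per-population π, segregating sites and Watterson's θ via EM.

    A site counts as variable when its EM frequency estimate is farther than
    ``tol`` from both 0 and 1.  π is the mean over variable sites of
    2p̂(1−p̂)·2n/(2n−1); θ_W = S / Σ_{i=1}^{2n−1} 1/i, reported for the
    variable-site set and per assayed site.
    """
    pops = rcm.pop_labels
    lik = _normalized_likelihoods(rcm, err)
    pi = np.zeros(len(pops))
    theta = np.zeros(len(pops))
    theta_site = np.zeros(len(pops))
    S = np.zeros(len(pops), dtype=np.int64)
    ns = np.zeros(len(pops), dtype=np.int64)
    pidx = rcm.pop_indices()
    for k, pop in enumerate(pops):
        mask = pidx == k
        n = int(mask.sum())
        if n < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        p_hat = _em_vectorized(lik[mask], iterations)
        variable = (p_hat > tol) & (p_hat < 1.0 - tol)
        s = int(variable.sum())
        a_n = np.sum(1.0 / np.arange(1, 2 * n))
        ns[k] = n
        S[k] = s
        theta[k] = s / a_n
        theta_site[k] = theta[k] / rcm.n_loci if rcm.n_loci else 0.0
        if s:
            het = 2.0 * p_hat[variable] * (1.0 - p_hat[variable])
            pi[k] = float(np.mean(het * (2 * n) / (2 * n - 1)))
    return DiversityEstimates(
        populations=pops, pi=pi, theta_w=theta, theta_w_per_site=theta_site, S=S, n=ns
    )
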