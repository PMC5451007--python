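"""Fast counter-based PRNG primitives for the numba Gibbs kernels.

The samplers in :mod:`flightdiff.genomod` and :mod:`flightdiff.admixture`
draw on the order of 10^9 variates per chain, which rules out the stock
numba random machinery.  Uniforms come from splitmix64 (Steele, Lea &
Flood's SplittableRandom mixer, which passes BigCrush) driven by a Weyl
counter: successive draws have no loop-carried arithmetic dependency, so
the hot loops stay superscalar-friendly.  Normals use the Marsaglia polar
method, gammas Marsaglia–Tsang, betas the gamma ratio.  State is a single
``uint64`` counter in a 1-element array threaded through the callers, so
every chain is a pure function of its integer seed; kernels may mirror the
counter into a local register (see ``GOLD``/``M1``/``M2``) and resync.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53
GOLD = uint64(0x9E3779B97F4A7C15)
M1 = uint64(0xBF58476D1CE4E5B9)
M2 = uint64(0x94D049BB133111EB)
_SEED_SCRAMBLE = uint64(0xDA942042E4DD58B5)


@njit(cache=True)
def seed_state(seed):
    """One-element uint64 counter state from an integer seed."""
    s = np.empty(1, np.uint64)
    s[0] = uint64(seed) * _SEED_SCRAMBLE + uint64(1)
    return s


@njit(cache=True, inline="always")
def uniform(s):
    """Uniform double in [0, 1) with 53 random bits (splitmix64 step)."""
    s[0] = s[0] + GOLD
    t = s[0]
    t = (t ^ (t >> uint64(30))) * M1
    t = (t ^ (t >> uint64(27))) * M2
    t = t ^ (t >> uint64(31))
    return float(t >> uint64(11)) * INV_2_53


@njit(cache=True, inline="always")
def normal(s):
    """Standard normal via the Marsaglia polar method (spare discarded)."""
    while True:
        u = 2.0 * uniform(s) - 1.0
        v = 2.0 * uniform(s) - 1.0
        r = u * u + v * v
        if 0.0 < r < 1.0:
            return u * np.sqrt(-2.0 * np.log(r) / r)


@njit(cache=True)
def gamma(s, shape):
    """Gamma(shape, 1) via Marsaglia–Tsang, with the a<1 boost."""
    a = shape
    boost = 1.0
    if a < 1.0:
        # G(a) = G(a+1) * U^{1/a}
        boost = np.power(uniform(s) + 1e-300, 1.0 / a)
        a = a + 1.0
    d = a - 1.0 / 3.0
    c = 1.0 / np.sqrt(9.0 * d)
    while True:
        x = normal(s)
        v = 1.0 + c * x
        if v <= 0.0:
            continue
        v = v * v * v
        u = uniform(s)
        x2 = x * x
        if u < 1.0 - 0.0331 * x2 * x2:
            return boost * d * v
        if np.log(u + 1e-300) < 0.5 * x2 + d * (1.0 - v + np.log(v)):
            return boost * d * v


@njit(cache=True, inline="always")
def beta(s, a, b):
    x = gamma(s, a)
    y = gamma(s, b)
    return x / (x + y)


@njit(cache=True)
def dirichlet_into(s, alpha, out):
    """Fill ``out`` with a Dirichlet(alpha) draw (in-place)."""
    tot = 0.0
    for k in range(alpha.shape[0]):
        g = gamma(s, alpha[k])
        out[k] = g
        tot += g
    for k in range(alpha.shape[0]):
        out[k] /= tot
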