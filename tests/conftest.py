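import numpy as np
import pytest

from flightdiff import genomod, synthdata


@pytest.fixture(scope="session")
def two_pop_sim():
    """Moderately divergent two-population read-count simulation with truth."""
    freqs = synthdata.sim_pop_frequencies(300, ["early", "late"], 0.3, seed=101)
    rcm, truth = synthdata.sim_read_counts(
        freqs, 12, coverage=10.0, err=0.005, missing_rate=0.05, seed=102
    )
    return rcm, truth


@pytest.fixture(scope="session")
def small_afp(two_pop_sim):
    """Allele-frequency posterior for the shared two-population simulation."""
    rcm, _ = two_pop_sim
    afp, gp = genomod.gibbs_allele_frequency(
        rcm, err=0.005, steps=3000, burnin=1000, thin=5, seed=103
    )
    return afp, gp


def make_rcm(ref, alt, populations=None, loci=None):
    """ReadCountMatrix from raw count arrays with auto-generated labels."""
    ref = np.asarray(ref)
    n, L = ref.shape
    pops = (
        np.array(populations, dtype=object)
        if populations is not None
        else np.array(["pop1"] * n, dtype=object)
    )
    return genomod.ReadCountMatrix(
        loci=np.array(
            loci if loci is not None else [f"L{j}" for j in range(L)], dtype=object
        ),
        individuals=np.array([f"ind{i}" for i in range(n)], dtype=object),
        populations=pops,
        ref=ref,
        alt=np.asarray(alt),
    )
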