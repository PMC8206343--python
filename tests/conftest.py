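import numpy as np
import pytest

from tensorsig.simulate import (
    TruthPriors,
    make_variant_fixture,
    sample_counts,
    sample_truth,
)

#: compact tensor shape used by unit tests that exercise the model maths
SMALL_STATES = (3, 2, 2)
SMALL_P = 5


@pytest.fixture(scope="session")
def variant_fixture(tmp_path_factory):
    """Toy genome + tracks + VCF with planted per-variant truth."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_variant_fixture(seed=7, outdir=outdir)


@pytest.fixture(scope="session")
def small_truth():
    return sample_truth(
        2, 4, seed=13, state_sizes=SMALL_STATES, p=SMALL_P,
        priors=TruthPriors(mutations_per_sample=500.0, n_categories=4),
    )


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return sample_counts(small_truth, seed=14)


def random_core(rng, p=SMALL_P, s=2):
    t0 = rng.random((2, 2, p, s)) + 0.05
    return t0 / t0.sum(axis=2, keepdims=True)


def random_factors(rng, s=2, state_sizes=SMALL_STATES, q=4):
    te, tn, tc = state_sizes
    def pos(shape):
        return np.exp(rng.normal(0, 0.4, shape))
    s0 = rng.random((q, s)) + 0.05
    from tensorsig.model import TensorFactors
    return TensorFactors(
        b_t=pos(s), b_r=pos(s), a_t=pos(s), a_r=pos(s),
        m=rng.uniform(0.2, 0.95, s),
        k_epi=np.vstack([np.ones((1, s)), pos((te - 1, s))]),
        k_nuc=np.vstack([np.ones((1, s)), pos((tn - 1, s))]),
        k_clu=np.vstack([np.ones((1, s)), pos((tc - 1, s))]),
        s0=s0 / s0.sum(axis=0, keepdims=True),
    )
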