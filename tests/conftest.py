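import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zipscore.alphabet import AminoAlphabet
from zipscore.model import ScoreModel, _Dense, _ReLU
from zipscore.profiler import ZipperProfile
from zipscore.synthetic import make_ground_truth
from zipscore.table import build_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_alphabet():
    """Four-letter alphabet: 4**6 = 4096 hexapeptides, exhaustively checkable."""
    return AminoAlphabet("ACDE")


@pytest.fixture(scope="session")
def small_scorer(small_alphabet):
    """Additive noiseless ground truth over the reduced alphabet."""
    return make_ground_truth(seed=5, alphabet=small_alphabet)


@pytest.fixture(scope="session")
def small_table(small_scorer):
    """Exhaustive score table of the reduced-alphabet ground truth."""
    model = _ground_truth_as_model(small_scorer)
    return build_table(model, batch_size=512)


def _ground_truth_as_model(scorer) -> ScoreModel:
    """Exact network realisation of an additive scorer.

    One identity-like hidden layer with a large positive bias keeps every
    ReLU active, so the affine ground truth is reproduced to float32
    round-off: hidden_j = x_j + C, output = sum_j w_j (x_j + C) + b.
    """
    a = scorer.alphabet.size
    n_in = 6 * a
    rng = np.random.default_rng(0)
    d1, d2 = _Dense(n_in, n_in, rng), _Dense(n_in, 1, rng)
    shift = 10.0
    d1.W[...] = np.eye(n_in, dtype=np.float32)
    d1.b[...] = shift
    flat = scorer.position_weights.reshape(-1)  # (6*A,) position-major
    d2.W[:, 0] = flat.astype(np.float32)
    d2.b[0] = np.float32(scorer.base - shift * flat.sum())
    return ScoreModel(layers=[d1, _ReLU(), d2], alphabet=scorer.alphabet,
                      metadata={"source": "exact additive realisation"})


@pytest.fixture
def exact_model_factory():
    return _ground_truth_as_model


def random_call_profile(rng, length=None, p=0.2) -> ZipperProfile:
    """Random zipper-call vector packaged as a profile (scores −30 / 0)."""
    if length is None:
        length = int(rng.integers(6, 501))
    calls = rng.random(max(length - 5, 0)) < p
    scores = np.where(calls, -30.0, 0.0).astype(np.float32)
    return ZipperProfile(protein_id="synthetic", sequence="A" * length,
                         scores=scores)
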