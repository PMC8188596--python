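import numpy as np
import pytest

import poolbo as pb


@pytest.fixture(scope="session")
def small_fixture() -> pb.Fixture:
    """300-molecule noiseless linear landscape."""
    return pb.generate_pool(pb.LandscapeSpec(n_molecules=300), seed=101)


@pytest.fixture(scope="session")
def noisy_fixture() -> pb.Fixture:
    """1000 molecules, noise at 10% of the signal sd.

    The noiseless draw with the same seed shares the weight vector, so its
    signal sd fixes the noise scale before noise is added.
    """
    base = pb.generate_pool(pb.LandscapeSpec(n_molecules=1000), seed=202)
    sigma = 0.1 * pb.signal_sd(base)
    return pb.generate_pool(
        pb.LandscapeSpec(n_molecules=1000, noise_sigma=sigma), seed=202
    )


@pytest.fixture(scope="session")
def recovery_fixture() -> pb.Fixture:
    """2000-molecule noiseless landscape for surrogate-recovery checks."""
    return pb.generate_pool(pb.LandscapeSpec(n_molecules=2000), seed=11)


@pytest.fixture(scope="session")
def trained_nn(recovery_fixture):
    """An NN surrogate trained on 10% of the recovery fixture (shared to
    keep the suite fast); returns (model, train_idx, test_idx)."""
    fx = recovery_fixture
    rng = np.random.default_rng(5)
    idx = rng.permutation(fx.pool.size)
    n_tr = fx.pool.size // 10
    tr, te = idx[:n_tr], idx[n_tr:]
    data = pb.TrainingSet(fx.pool.fingerprints[tr], fx.true_objective[tr])
    model = pb.NeuralNetSurrogate(
        pb.SurrogateSpec(architecture="nn"), seed=0
    ).fit(data)
    return model, tr, te
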