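import numpy as np
import pytest

from cisne import DoseEffectDataset, predict_fa

NINE_DOSES = 10.0 * 2.0 ** np.arange(-4, 5)


def exact_dataset(m, D, doses=NINE_DOSES, label="exact"):
    """Noise-free dataset lying exactly on the MEE curve."""
    return DoseEffectDataset(label=label, doses=doses,
                             fa=predict_fa((m, D), doses))


def noisy_dataset(m, D, sigma, rng, doses=NINE_DOSES, label="noisy"):
    fa = predict_fa((m, D), doses) + rng.normal(0, sigma, len(doses))
    return DoseEffectDataset(label=label, doses=doses, fa=fa)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def sigmoidal_exact():
    return exact_dataset(2.0, 10.0)
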