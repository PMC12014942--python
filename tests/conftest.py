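import numpy as np
import pytest

from sfdiskin.optics import AcquisitionGeometry, ChromophoreTable


@pytest.fixture(scope="session")
def geom():
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def table():
    return ChromophoreTable.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# shared heavyweight artifacts for the acceptance tests: one synthetic
# corpus and one pair of trained networks (with / without the TV penalty),
# built once per session
# ---------------------------------------------------------------------------

CORPUS_N_PAIRS = 1248          # training-corpus size (matches the assembled
                               # experimental dataset scale)
CORPUS_HELD_OUT = 64
CORPUS_IMAGE_SIZE = 64
CORPUS_SNR_DB = 50.0
TRAIN_EPOCHS = 40


@pytest.fixture(scope="session")
def corpus(geom, table):
    from sfdiskin.phantoms import make_corpus

    pairs = make_corpus(CORPUS_N_PAIRS + CORPUS_HELD_OUT, CORPUS_IMAGE_SIZE,
                        geom, table, snr_db=CORPUS_SNR_DB, seed=100)
    X = np.stack([m.data for m, _ in pairs])
    Y = np.stack([p.data for _, p in pairs])
    return {
        "X_train": X[:CORPUS_N_PAIRS], "Y_train": Y[:CORPUS_N_PAIRS],
        "X_test": X[CORPUS_N_PAIRS:], "Y_test": Y[CORPUS_N_PAIRS:],
    }


@pytest.fixture(scope="session")
def trained_models(corpus):
    """TV-off and TV-on networks trained on the session corpus."""
    from sfdiskin.network import (NetworkConfig, NormalizationSpec, SFDINet,
                                  TrainingConfig, train)

    norm = NormalizationSpec()
    data = (corpus["X_train"], corpus["Y_train"])
    net_off = SFDINet(NetworkConfig(seed=0))
    net_off, hist_off = train(net_off, data,
                              TrainingConfig(epochs=TRAIN_EPOCHS, seed=0,
                                             tv_weights=(0.0,) * 7), norm)
    net_on = SFDINet(NetworkConfig(seed=0))
    net_on, hist_on = train(net_on, data,
                            TrainingConfig(epochs=TRAIN_EPOCHS, seed=0), norm)
    return {"tv_off": net_off, "tv_on": net_on, "norm": norm,
            "hist_off": hist_off, "hist_on": hist_on}
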