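import numpy as np
import pytest

from stroopsom import LateralSOM, StroopModel, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


# A reduced model that trains in a few seconds: smaller grid, shorter
# schedule, and a laxer response criterion so every stage still functions.
SMALL_PARAMS = dict(rows=10, cols=10, epochs=300, entropy_threshold=2.0, seed=7)


@pytest.fixture(scope="session")
def small_model(lexicon):
    return StroopModel(**SMALL_PARAMS).fit(lexicon)


@pytest.fixture(scope="session")
def default_model(lexicon):
    """A model trained at the full default configuration (one fixed seed)."""
    return StroopModel(seed=3).fit(lexicon)


def make_som(units, input_vectors, labels=None, rows=None, cols=None,
             temperature=0.7, alpha=0.8, beta=0.1, sigma=0.25):
    """Build a fitted LateralSOM with hand-set unit vectors (no training)."""
    units = np.asarray(units, dtype=float)
    if rows is None:
        rows, cols = 1, units.shape[0]
    params = LateralSOM(rows=rows, cols=cols, temperature=temperature,
                        alpha=alpha, beta=beta, sigma_start=sigma,
                        sigma_end=sigma).get_params()
    if labels is None:
        labels = list(range(len(input_vectors)))
    return LateralSOM.from_dict({
        "params": params, "labels": labels,
        "input_vectors": np.asarray(input_vectors, dtype=float).tolist(),
        "units": units.tolist()})
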