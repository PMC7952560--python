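import numpy as np
import pytest

from deamtools.enrichment import BarcodeManifest
from deamtools.fluctuation import FluctuationExperiment


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def small_experiment():
    return FluctuationExperiment(
        counts=(0, 0, 1, 0, 3, 0, 12, 0),
        n_final=1e7,
        plating_fraction=1.0,
        label="fixture",
    )


@pytest.fixture
def tiny_manifest():
    return BarcodeManifest(
        wells={
            "w1": ("AAAAAAAA", "TTTTTTTT"),
            "w2": ("CCCCCCCC", "GGGGGGGG"),
            "w3": ("ACACACAC", "TGTGTGTG"),
        },
        max_mismatch=1,
    )
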