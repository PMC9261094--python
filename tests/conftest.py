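import logging

import numpy as np
import pytest

from semsim.embeddings import EmbeddingTable
from semsim.synth import SynthConfig, SynthModel

logging.getLogger("semsim").setLevel(logging.ERROR)


@pytest.fixture
def toy_table() -> EmbeddingTable:
    """Three orthogonal unit vectors: cat, dog, the."""
    return EmbeddingTable(
        dimension=3,
        vectors={
            "cat": np.array([1.0, 0.0, 0.0]),
            "dog": np.array([0.0, 1.0, 0.0]),
            "the": np.array([0.0, 0.0, 1.0]),
        },
        source_label="toy",
    )


@pytest.fixture(scope="session")
def full_model() -> SynthModel:
    """Study-sized generator at its default calibration targets."""
    return SynthModel(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def null_model(full_model) -> SynthModel:
    """Matched-null generator (equal p_stay) sharing the same embedding."""
    return SynthModel(SynthConfig(seed=11), null=True, share_from=full_model)


@pytest.fixture(scope="session")
def small_model() -> SynthModel:
    """Reduced cohort for fast pipeline tests."""
    cfg = SynthConfig(
        seed=5, n_FES=14, n_HC=12, n_followup_FES=8, n_followup_HC=6,
        calibration_sims=60, refine_sims=400,
    )
    return SynthModel(cfg)
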