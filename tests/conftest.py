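import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from il10pep import (DescriptorConfig, PipelineConfig, SyntheticSpec,
                     generate_synthetic)

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """70 peptides with a strong planted composition bias."""
    return generate_synthetic(
        SyntheticSpec(n_pos=30, n_neg=40, bias_strength=2.0, seed=11))


@pytest.fixture
def fast_config():
    """AAC-only pipeline without SMOTE/selection: fast but complete."""
    return PipelineConfig(
        smote=None, selection_threshold=None,
        descriptor=DescriptorConfig(families=("AAC",)),
        classifier_params={"n_estimators": 50},
    )


@pytest.fixture
def fasta_writer(tmp_path):
    def _write(name, records):
        path = tmp_path / name
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))
        return path
    return _write
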