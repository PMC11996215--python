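"""Shared fixtures: a worked-example annotation table and small synthetic data."""

import numpy as np
import pytest

from pcgseg.io import RegionTable
from pcgseg.preprocess import PreprocessConfig
from pcgseg.synthetic import SynthConfig

#: Worked-example annotation: two heart cycles in the three-column region
#: format used by the annotated corpora (1-based limits, shared boundaries).
EXAMPLE_ROWS = (
    (1, 555, "S1"),
    (555, 1035, "systolic"),
    (1035, 1515, "S2"),
    (1515, 2235, "diastolic"),
    (2235, 2795, "S1"),
    (2795, 3275, "systolic"),
    (3275, 3755, "S2"),
    (3755, 4555, "diastolic"),
)


@pytest.fixture
def example_table() -> RegionTable:
    return RegionTable(EXAMPLE_ROWS)


@pytest.fixture
def example_table_file(tmp_path):
    path = tmp_path / "regions.tsv"
    path.write_text(
        "\n".join(f"{s}\t{e}\t\"{c}\"" for s, e, c in EXAMPLE_ROWS) + "\n"
    )
    return path


@pytest.fixture
def fast_synth_cfg() -> SynthConfig:
    """Small, quick generator settings for unit tests."""
    return SynthConfig(duration_s=6.0, seed=123)


@pytest.fixture
def fast_pp_cfg() -> PreprocessConfig:
    """Conditioning chain with decimation for short model sequences."""
    return PreprocessConfig(decimate_factor=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
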