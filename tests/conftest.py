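import numpy as np
import pytest

from mtdti.config import PipelineConfig


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """A three-subject, three-lesion cohort on a small grid for fast tests."""
    return PipelineConfig.model_validate(
        {
            "phantom": {
                "grid_shape": [32, 32, 32],
                "dwi_grid_shape": [21, 21, 21],
                "n_subjects": 3,
                "lesions_by_subject": {"S01": [2], "S02": [4, 6]},
                "missed_exams": [["S02", 8]],
                "missed_dti": [["S01", 4]],
                "lesion_volume_mean_mm3": 60.0,
                "lesion_volume_sd_mm3": 30.0,
                "lesion_volume_range_mm3": [20.0, 120.0],
            }
        }
    )
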