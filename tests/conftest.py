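import numpy as np
import pytest

from tauquant import CohortConfig, FrameSchedule, GroupSpec, PipelineConfig
from tauquant.phantom import default_scene, make_cohort
from tauquant.pipeline import quantify_cohort


@pytest.fixture(scope="session")
def schedule():
    """The 22-frame/60-min dynamic acquisition schedule."""
    return FrameSchedule.thk5317()


@pytest.fixture(scope="session")
def scene():
    return default_scene()


@pytest.fixture(scope="session")
def two_group_cohort():
    """10 controls vs 10 dementia-stage subjects at default noise/PSF,
    quantified through the full DVR + PVC + ROI pipeline.  Shared by the
    discrimination and PVC-range checks."""
    config = CohortConfig(
        groups={
            "HC": GroupSpec(n=10, limbic_dvr=(1.03, 0.03), isocortical_dvr=(1.02, 0.03)),
            "AD_dementia": GroupSpec(
                n=10, limbic_dvr=(1.30, 0.08), isocortical_dvr=(1.25, 0.08)
            ),
        },
        seed=7,
    )
    subjects = make_cohort(config)
    results, table = quantify_cohort(subjects, PipelineConfig(seed=7))
    return subjects, results, table
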