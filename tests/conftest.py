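import numpy as np
import pytest

from cce_triage import (
    FrameRecord,
    PolypAnnotation,
    PolypSpec,
    StudyConfig,
    generate_study,
    load_preset,
)


def make_frames(scores, head="front", study_id="s1", dt=2.0):
    """Frames on one head with the given scores at a uniform grid."""
    return [
        FrameRecord(
            study_id=study_id,
            head=head,
            frame_index=i,
            timestamp_s=i * dt,
            score=float(s),
        )
        for i, s in enumerate(scores)
    ]


@pytest.fixture
def table1_config():
    return load_preset("table1", seed=7)


@pytest.fixture
def table1_study(table1_config):
    return generate_study(table1_config)


@pytest.fixture
def small_config():
    """A compact two-head study used where full scale is unnecessary."""
    return StudyConfig(
        duration_s=2000.0,
        frame_interval_s=2.0,
        polyp_spec=[
            PolypSpec(4.0, "sessile", 3, "front"),
            PolypSpec(8.0, "flat", 6, "rear"),
            PolypSpec(5.5, "pedunculated", 12, "front"),
            PolypSpec(11.0, "sessile", 5, "rear"),
            PolypSpec(3.0, "flat", 2, "front"),
        ],
        seed=11,
        study_id="small",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
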