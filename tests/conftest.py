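import numpy as np
import pytest

from larvatox.behavior_qc import LocomotionTrace, PhotoperiodSchedule


@pytest.fixture
def assay_schedule() -> PhotoperiodSchedule:
    """The full behavioral protocol: 4 light-dark cycles, 3-min phases, 6-s bins."""
    return PhotoperiodSchedule()


@pytest.fixture
def mini_schedule() -> PhotoperiodSchedule:
    """Tiny schedule for brute-force-checkable traces: 2 cycles × 5-bin phases."""
    return PhotoperiodSchedule(phase_length_s=30, n_cycles=2, bin_width_s=6)


def make_trace(
    schedule: PhotoperiodSchedule,
    light_value: float = 1.0,
    dark_value: float = 3.0,
    larva_id: str = "t0",
    group: str = "g",
) -> LocomotionTrace:
    """Constant-per-phase trace: a clean scototaxis pattern by default."""
    phases = schedule.phase_labels()
    values = np.where(phases == "light", light_value, dark_value).astype(float)
    return LocomotionTrace(larva_id, group, values, schedule)
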