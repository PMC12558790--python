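import numpy as np
import pytest

from oculoscreen import CohortConfig, GazeRecording, PipelineConfig, Test, generate_cohort

Test.__test__ = False  # the exam enum is not a pytest collection target


def make_recording(
    n: int = 200,
    rate_hz: float = 120.0,
    left=None,
    right=None,
    left_valid=None,
    right_valid=None,
    test: Test = Test.DOT,
    participant_id: str = "p",
) -> GazeRecording:
    """Small hand-built recording; defaults to a smooth deterministic path."""
    t = np.arange(n) / rate_hz
    if left is None:
        left = np.column_stack([100 + 10 * t, 200 + 5 * t])
    if right is None:
        right = np.asarray(left) + [3.0, -2.0]
    if left_valid is None:
        left_valid = np.ones(n, dtype=bool)
    if right_valid is None:
        right_valid = np.ones(n, dtype=bool)
    return GazeRecording(
        participant_id=participant_id,
        test=test,
        rate_hz=rate_hz,
        t=t,
        left=np.asarray(left, dtype=float),
        right=np.asarray(right, dtype=float),
        left_valid=left_valid,
        right_valid=right_valid,
    )


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """6 abnormal + 6 normal participants, deformations on, fixed seed."""
    return generate_cohort(6, 6, CohortConfig(), seed=13)


@pytest.fixture(scope="session")
def undeformed_cohort():
    """4 + 4 cohort without tracker deformation, for mechanism tests."""
    return generate_cohort(4, 4, CohortConfig(apply_deformations=False), seed=5)
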