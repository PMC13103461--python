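"""Streaming landmark capture with stabilization and restart.

Recording a fiducial with a tracked pointer begins with holding the probe
still.  To suppress hand tremor, a fixed-length series of tip positions
(default 60 samples at 40 Hz, i.e. 1.5 s) is collected and averaged.  Probe
slippage is detected by a step rule: if any sample lands more than
``max_step_mm`` (default 0.5 mm) from its predecessor, the series so far is
discarded and collection restarts.  The restarted series begins *at* the
violating sample — a probe that slipped is assumed to now rest at a new,
stable position — and the first sample of any series has no predecessor, so
it can never trigger a restart.  Both choices are configurable.

All tip points are expected in the reference-sensor frame, so head motion
during the capture does not perturb the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from . import geometry
from .errors import AcquisitionTimeoutError, InstabilityError
from .geometry import PoseSample, RigidTransform, as_point

__all__ = ["AcquisitionConfig", "AcquisitionResult", "acquire_landmark", "probe_tip_point"]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Parameters of the stabilization-and-restart state machine.

    Attributes
    ----------
    n_samples:
        Length of a complete measurement series (>= 2).
    rate_hz:
        Nominal sampling rate; only used to report a duration.
    max_step_mm:
        Maximum allowed Euclidean step between consecutive raw samples.
    max_restarts:
        Abort with :class:`~emnav.errors.InstabilityError` after this many
        restarts; ``None`` means unlimited.
    restart_seeds_with_violator:
        If True (default) the sample that broke the step rule becomes the
        first sample of the new series; if False it is dropped entirely.
    """

    n_samples: int = 60
    rate_hz: float = 40.0
    max_step_mm: float = 0.5
    max_restarts: Optional[int] = None
    restart_seeds_with_violator: bool = True

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.max_step_mm <= 0:
            raise ValueError("max_step_mm must be positive")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.max_restarts is not None and self.max_restarts < 0:
            raise ValueError("max_restarts must be >= 0 or None")


@dataclass(frozen=True)
class AcquisitionResult:
    """Outcome of a successful landmark capture."""

    mean_point: np.ndarray  # arithmetic mean of the accepted series, reference frame (mm)
    samples_used: int
    restarts: int
    duration_s: float


def acquire_landmark(stream: Iterable, config: AcquisitionConfig = AcquisitionConfig()) -> AcquisitionResult:
    """Run the stabilization state machine over a stream of probe-tip points.

    Returns the arithmetic mean of the first contiguous run of
    ``config.n_samples`` points in which every consecutive pair is at most
    ``config.max_step_mm`` apart.  Deterministic: the same stream always
    yields the same result.

    Raises
    ------
    AcquisitionTimeoutError
        If the stream ends before a valid series completes.
    InstabilityError
        If more than ``config.max_restarts`` series were discarded.
    """
    series: list[np.ndarray] = []
    restarts = 0
    consumed = 0
    for raw in stream:
        point = as_point(raw)
        consumed += 1
        if series and np.linalg.norm(point - series[-1]) > config.max_step_mm:
            restarts += 1
            if config.max_restarts is not None and restarts > config.max_restarts:
                raise InstabilityError(
                    f"acquisition restarted {restarts} times "
                    f"(limit {config.max_restarts}); probe is unstable"
                )
            series = [point] if config.restart_seeds_with_violator else []
        else:
            series.append(point)
        if len(series) == config.n_samples:
            return AcquisitionResult(
                mean_point=np.mean(series, axis=0),
                samples_used=len(series),
                restarts=restarts,
                duration_s=consumed / config.rate_hz,
            )
    raise AcquisitionTimeoutError(
        f"stream ended after {consumed} samples without a stable series of "
        f"{config.n_samples} ({restarts} restarts)"
    )


def probe_tip_point(
    probe_pose: PoseSample,
    reference: PoseSample,
    tip_offset,
    sync_tol_s: float = geometry.DEFAULT_SYNC_TOL_S,
) -> np.ndarray:
    """Tip position in the reference-sensor frame.

    ``tip_offset`` is the probe-tip location in the probe's own sensor frame
    (from tip calibration); the probe and reference samples must be
    synchronous within ``sync_tol_s``.
    """
    rel: RigidTransform = geometry.relative_pose(probe_pose, reference, sync_tol_s)
    return rel.apply(as_point(tip_offset))
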