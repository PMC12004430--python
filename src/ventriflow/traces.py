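"""Core time-series containers shared by the simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import DataError
from .units import FLOW_UNIT

#: Maximum tolerated deviation of a sampling interval from 1/sample_rate [s].
UNIFORMITY_TOL_S = 1e-9


@dataclass
class FlowTrace:
    """Uniformly sampled signed volumetric flow.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing and uniformly spaced.
    q : ndarray
        Signed flow in µL/min, positive during ejection.
    sample_rate : float
        Sampling rate in Hz; ``t`` must agree with it to within 1 ns.
    units_label : str
        Human-readable flow unit (canonical traces use µL/min).
    metadata : dict
        Free-form provenance (generator parameters, detrending, resampling...).
    """

    t: np.ndarray
    q: np.ndarray
    sample_rate: float
    units_label: str = FLOW_UNIT
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.t.ndim != 1 or self.q.ndim != 1:
            raise DataError("FlowTrace arrays must be one-dimensional")
        if len(self.t) != len(self.q):
            raise DataError(
                f"time and flow lengths differ: {len(self.t)} != {len(self.q)}"
            )
        if len(self.t) < 2:
            raise DataError("FlowTrace needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError("FlowTrace times must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sample_rate)) > UNIFORMITY_TOL_S:
            raise DataError(
                "FlowTrace sampling is not uniform at the declared "
                f"sample_rate={self.sample_rate} Hz"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span of the trace in seconds."""
        return float(self.t[-1] - self.t[0])

    def with_flow(self, q: np.ndarray, **meta: Any) -> "FlowTrace":
        """Return a copy with ``q`` replaced and metadata merged."""
        out = replace(self, q=np.asarray(q, dtype=float))
        out.metadata = {**self.metadata, **meta}
        return out


@dataclass
class MotionTrace:
    """Rectified per-frame motion magnitude from video or a generator.

    ``magnitude[i]`` is the mean optical displacement (px) between frames
    ``i`` and ``i + frame_offset``; for generated traces ``frame_offset`` is 1
    and the magnitude is a plain per-frame |Δdisplacement|. Sign-reversal
    integration divides by ``frame_offset`` so displacement stays in px.
    """

    frame_index: np.ndarray
    magnitude: np.ndarray
    fps: float
    frame_offset: int = 1
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if len(self.frame_index) != len(self.magnitude):
            raise DataError("frame_index and magnitude lengths differ")
        if np.any(self.magnitude < 0):
            raise DataError("motion magnitude must be rectified (non-negative)")
        if self.fps <= 0:
            raise DataError("fps must be positive")
        if self.frame_offset < 1:
            raise DataError("frame_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.magnitude)

    @property
    def time(self) -> np.ndarray:
        """Time of each entry's first frame, in seconds."""
        return self.frame_index / self.fps
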