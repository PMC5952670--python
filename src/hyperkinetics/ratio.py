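"""Ratiometric processing: 490/420 ratio traces, baselines, dynamic range.

The 490/420 excitation ratio cancels expression level and ROI size; the
dynamic range (basal → maximum under the saturating pulse) provides the
normalization denominator so rise and recovery kinetics can be compared
across cells and conditions on a common percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .io import AcquisitionTrace
from .protocol import ProtocolSchedule

__all__ = [
    "RatioTrace",
    "DynamicRange",
    "DegenerateCellError",
    "BaselineWindowError",
    "compute_ratio",
    "estimate_baseline",
    "dynamic_range",
    "normalize",
]


class DegenerateCellError(ValueError):
    """Cell with no usable dynamic range (flat or inverted response)."""


class BaselineWindowError(ValueError):
    """Baseline window empty or too short."""


@dataclass
class RatioTrace:
    """Per-frame 490/420 ratio on a minutes time axis."""

    cell_id: str
    time_min: np.ndarray
    ratio: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if len(self.time_min) != len(self.ratio):
            raise ValueError("time and ratio lengths differ")


@dataclass(frozen=True)
class DynamicRange:
    r_basal: float
    r_max: float

    @property
    def span(self) -> float:
        return self.r_max - self.r_basal


def compute_ratio(trace: AcquisitionTrace, offset420: float = 0.0,
                  offset490: float = 0.0) -> RatioTrace:
    """Frame-wise F490/F420 ratio.

    Optional constant background offsets are subtracted per channel first
    (0 by default; ROI-level background handling is assumed upstream).
    """
    f420 = trace.f420 - offset420
    f490 = trace.f490 - offset490
    if np.any(f420 <= 0):
        raise ValueError(f"cell {trace.cell_id}: non-positive F420 after offset")
    if np.any(f490 <= 0):
        raise ValueError(f"cell {trace.cell_id}: non-positive F490 after offset")
    return RatioTrace(
        cell_id=trace.cell_id,
        time_min=trace.time_min,
        ratio=f490 / f420,
        metadata=dict(trace.metadata),
    )


def estimate_baseline(rt: RatioTrace, schedule: ProtocolSchedule,
                      window_min: float = 2.0) -> float:
    """Basal ratio: mean over the ``window_min`` minutes preceding the
    first pulse."""
    pulses = schedule.pulses
    if not pulses:
        raise BaselineWindowError("schedule has no pulse to anchor the baseline window")
    t_pulse = pulses[0][0]
    mask = (rt.time_min >= t_pulse - window_min) & (rt.time_min < t_pulse)
    if mask.sum() < 2:
        raise BaselineWindowError(
            f"only {int(mask.sum())} frame(s) in the {window_min}-min baseline window; "
            "record a longer baseline or widen the window"
        )
    return float(np.mean(rt.ratio[mask]))


def dynamic_range(rt: RatioTrace, schedule: ProtocolSchedule,
                  window_min: float = 2.0, median_filter_frames: int = 0,
                  min_span_frac: float = 0.05) -> DynamicRange:
    """Basal ratio and maximal ratio under the saturating (highest-
    concentration) pulse.

    Cells whose span is non-positive or below ``min_span_frac`` of the
    basal ratio are rejected as degenerate (no interpretable response).
    An optional 3-frame median filter guards against single-frame spikes.
    """
    r_basal = estimate_baseline(rt, schedule, window_min=window_min)
    pulses = schedule.pulses
    t0, t1, _ = max(pulses, key=lambda p: p[2])
    mask = (rt.time_min >= t0) & (rt.time_min <= t1)
    if not np.any(mask):
        raise DegenerateCellError(f"cell {rt.cell_id}: no frames in the saturating pulse")
    values = rt.ratio
    if median_filter_frames and median_filter_frames > 1:
        values = median_filter(values, size=median_filter_frames, mode="nearest")
    r_max = float(np.max(values[mask]))
    span = r_max - r_basal
    if span <= 0 or span < min_span_frac * r_basal:
        raise DegenerateCellError(
            f"cell {rt.cell_id}: degenerate dynamic range "
            f"(basal {r_basal:.4g}, max {r_max:.4g})"
        )
    return DynamicRange(r_basal=r_basal, r_max=r_max)


def normalize(rt: RatioTrace, dr: DynamicRange) -> RatioTrace:
    """Express the ratio as percent of the dynamic range: 0 at basal, 100
    at the saturating maximum (noise can transiently exceed the band)."""
    if dr.span <= 0:
        raise DegenerateCellError(f"cell {rt.cell_id}: non-positive dynamic range span")
    return RatioTrace(
        cell_id=rt.cell_id,
        time_min=rt.time_min,
        ratio=100.0 * (rt.ratio - dr.r_basal) / dr.span,
        metadata=dict(rt.metadata),
    )
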