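"""Phase segmentation, pulse-response metrics, and the recovery-rate fit.

The headline statistic is the recovery rate k: after the oxidant washout
the normalized biosensor signal is fitted to a single decaying exponential
with three free parameters,

    y(t) = y0 + A · exp(−k · (t − t0)),

where t0 is fixed at the first post-washout frame.  Because the membrane
equilibration and peroxide disposal clear intracellular H2O2 much faster
than the disulfide is re-reduced, the fitted k estimates the cell's
disulfide-reduction rate k_red — the operational measure of intracellular
antioxidant (reducing) capacity.  The rate is invariant to the scale of
the fitted signal, hence identical on the raw-ratio and the normalized
(percent of dynamic range) representations.

The fit is exposed statsmodels-style: build a :class:`RecoveryModel` from
the recovery-phase samples, call :meth:`~RecoveryModel.fit`, and read
estimates, standard errors, goodness of fit and a ``summary()`` table off
the returned :class:`RecoveryResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .io import AcquisitionTrace
from .protocol import ProtocolSchedule, ScheduleError
from .ratio import (
    DegenerateCellError,
    DynamicRange,
    RatioTrace,
    compute_ratio,
    dynamic_range,
    estimate_baseline,
    normalize,
)

__all__ = [
    "PhaseSegmentation",
    "ResponseSummary",
    "RecoveryModel",
    "RecoveryResults",
    "CellRecord",
    "FitError",
    "segment_phases",
    "response_amplitude",
    "fit_exponential_recovery",
    "pooled_recovery_curve",
    "analyze_trace",
    "analyze_experiment",
]

K_MAX = 1000.0  # upper bound on the recovery rate (per min)
R_ACCEPT = 0.8  # default goodness-of-fit threshold for group statistics


class FitError(ValueError):
    """Raised when a recovery fit cannot be attempted."""


@dataclass(frozen=True)
class PhaseSegmentation:
    """Protocol phases as half-open time intervals in minutes."""

    baseline: tuple[float, float]
    pulse1: tuple[float, float] | None
    conc1_uM: float | None
    washout1: tuple[float, float] | None
    pulse2: tuple[float, float] | None
    conc2_uM: float | None
    recovery: tuple[float, float]


def segment_phases(schedule: ProtocolSchedule, trace_times_min=None) -> PhaseSegmentation:
    """Map the pulse schedule onto baseline / pulse / washout / recovery
    intervals.  The recovery phase starts at the final ``pulse_end`` —
    the first frames after oxidant washout."""
    pulses = schedule.pulses
    if not pulses:
        raise ScheduleError("schedule has no pulses to segment")
    end = schedule.duration_min
    if trace_times_min is not None and len(trace_times_min):
        end = float(np.max(trace_times_min))
        if pulses[-1][1] > end + 1e-9:
            raise ScheduleError("pulse extends beyond the end of the recording")
    p1 = pulses[0]
    p2 = pulses[1] if len(pulses) > 1 else None
    return PhaseSegmentation(
        baseline=(0.0, p1[0]),
        pulse1=(p1[0], p1[1]),
        conc1_uM=p1[2],
        washout1=(p1[1], p2[0]) if p2 else None,
        pulse2=(p2[0], p2[1]) if p2 else None,
        conc2_uM=p2[2] if p2 else None,
        recovery=(pulses[-1][1], end),
    )


@dataclass(frozen=True)
class ResponseSummary:
    """Pulse response amplitudes relative to the basal ratio."""

    delta_r_50: float | None
    delta_r_500: float | None
    t_plateau_50: float | None  # min from pulse onset to 95% of plateau
    warnings: tuple[str, ...] = ()


def _window_max(rt: RatioTrace, interval) -> float:
    t0, t1 = interval
    mask = (rt.time_min >= t0) & (rt.time_min <= t1)
    if not np.any(mask):
        raise FitError(f"no frames inside pulse window [{t0}, {t1}] min")
    return float(np.max(rt.ratio[mask]))


def response_amplitude(rt: RatioTrace, seg: PhaseSegmentation,
                       r_basal: float) -> ResponseSummary:
    """Max-within-pulse minus basal, per pulse, plus the time for the
    first pulse to reach 95% of its within-window maximum.

    With a two-pulse protocol the first pulse is reported as the
    submaximal (50 µM) response and the second as the saturating (500 µM)
    one; a single pulse is assigned by its concentration.
    """
    warnings: list[str] = []
    d1 = _window_max(rt, seg.pulse1) - r_basal
    if seg.pulse2 is not None:
        d2 = _window_max(rt, seg.pulse2) - r_basal
        delta_50, delta_500 = d1, d2
    elif seg.conc1_uM is not None and seg.conc1_uM >= 100.0:
        delta_50, delta_500 = None, d1
    else:
        delta_50, delta_500 = d1, None

    t_plateau = None
    if delta_50 is not None:
        t0, t1 = seg.pulse1
        mask = (rt.time_min >= t0) & (rt.time_min <= t1)
        t_win = rt.time_min[mask]
        y_win = rt.ratio[mask]
        target = r_basal + 0.95 * (np.max(y_win) - r_basal)
        hit = np.nonzero(y_win >= target)[0]
        if hit.size:
            t_plateau = float(t_win[hit[0]] - t0)
    if delta_50 is not None and delta_50 < 0:
        warnings.append("negative submaximal response")
    if (delta_50 is not None and delta_500 is not None and delta_500 < delta_50):
        warnings.append("saturating response smaller than submaximal response")
    return ResponseSummary(delta_r_50=delta_50, delta_r_500=delta_500,
                           t_plateau_50=t_plateau, warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# Recovery fit
# ---------------------------------------------------------------------------


class RecoveryModel:
    """Three-parameter exponential decay model of the post-washout signal.

    Parameters
    ----------
    t_min : array
        Sample times (minutes); the fit origin ``t0`` is the first sample.
    y : array
        Signal (normalized percent of dynamic range, or raw ratio — the
        fitted rate is identical up to affine rescaling of y).

    Examples
    --------
    >>> res = RecoveryModel(t, y).fit()
    >>> res.k, res.bse["k"], res.r
    """

    def __init__(self, t_min, y):
        t_min = np.asarray(t_min, dtype=float)
        y = np.asarray(y, dtype=float)
        if t_min.shape != y.shape or t_min.ndim != 1:
            raise FitError("t_min and y must be 1-D arrays of equal length")
        if len(y) < 5:
            raise FitError(f"recovery fit needs >= 5 frames, got {len(y)}")
        if np.any(~np.isfinite(t_min)) or np.any(~np.isfinite(y)):
            raise FitError("non-finite values in recovery window")
        self.t0 = float(t_min[0])
        self.t = t_min
        self.y = y

    def _initial_guess(self) -> tuple[float, float, float]:
        """Deterministic initialization from a log-linear regression of
        (y − min(y) + ε) against time."""
        y = self.y
        y0 = float(np.min(y))
        amp = float(y[0] - y0)
        eps = max(1e-3 * (np.max(y) - y0), 1e-9)
        z = np.log(y - y0 + eps)
        slope, intercept = np.polyfit(self.t - self.t0, z, 1)
        k0 = max(-slope, 1e-6)
        return y0, max(amp, eps), min(k0, K_MAX)

    def fit(self, max_iter: int = 500) -> "RecoveryResults":
        y0_init, a_init, k_init = self._initial_guess()
        params = Parameters()
        yspan = float(np.max(self.y) - np.min(self.y))
        pad = max(yspan, abs(float(np.mean(self.y))), 1.0)
        params.add("y0", value=y0_init, min=float(np.min(self.y)) - 10 * pad,
                   max=float(np.max(self.y)) + 10 * pad)
        params.add("A", value=a_init, min=0.0, max=max(10 * pad, 10 * a_init))
        params.add("k", value=k_init, min=0.0, max=K_MAX)
        t_rel = self.t - self.t0

        def residual(p):
            return p["y0"].value + p["A"].value * np.exp(-p["k"].value * t_rel) - self.y

        out = minimize(residual, params, method="least_squares",
                       max_nfev=max_iter * len(params), xtol=1e-10, ftol=1e-10,
                       gtol=1e-10)
        p = out.params
        fitted = p["y0"].value + p["A"].value * np.exp(-p["k"].value * t_rel)
        # goodness of fit: correlation between fitted and observed values
        if np.std(fitted) > 0 and np.std(self.y) > 0:
            r = float(np.corrcoef(fitted, self.y)[0, 1])
            identifiable = True
        else:
            r = 0.0
            identifiable = False
        at_bound = p["k"].value >= K_MAX * (1 - 1e-9)
        converged = bool(out.success) and not at_bound and identifiable
        bse = {name: (float(p[name].stderr) if p[name].stderr is not None else np.nan)
               for name in ("y0", "A", "k")}
        return RecoveryResults(
            model=self,
            y0=float(p["y0"].value),
            A=float(p["A"].value),
            k=float(p["k"].value),
            bse=bse,
            r=r,
            n_points=len(self.y),
            converged=converged,
            identifiable=identifiable,
            t0=self.t0,
        )


@dataclass
class RecoveryResults:
    """Estimates and diagnostics of a recovery-rate fit."""

    model: RecoveryModel
    y0: float
    A: float
    k: float
    bse: dict
    r: float
    n_points: int
    converged: bool
    identifiable: bool
    t0: float

    @property
    def params(self) -> dict:
        return {"y0": self.y0, "A": self.A, "k": self.k}

    def predict(self, t_min=None) -> np.ndarray:
        t = self.model.t if t_min is None else np.asarray(t_min, dtype=float)
        return self.y0 + self.A * np.exp(-self.k * (t - self.t0))

    def summary(self) -> str:
        lines = [
            "Exponential recovery fit: y(t) = y0 + A·exp(−k·(t − t0))",
            f"  n = {self.n_points} frames, t0 = {self.t0:.3f} min",
            f"  k  = {self.k:.4g} /min  (SE {self.bse.get('k', float('nan')):.3g})",
            f"  A  = {self.A:.4g}       (SE {self.bse.get('A', float('nan')):.3g})",
            f"  y0 = {self.y0:.4g}      (SE {self.bse.get('y0', float('nan')):.3g})",
            f"  r (fitted vs observed) = {self.r:.4f}",
            f"  converged = {self.converged}, identifiable = {self.identifiable}",
        ]
        return "\n".join(lines)


def fit_exponential_recovery(rt: RatioTrace, seg: PhaseSegmentation,
                             max_iter: int = 500) -> RecoveryResults:
    """Fit the three-parameter exponential to the recovery phase of a
    (normalized or raw) ratio trace.

    The fit uses the frames strictly after the final ``pulse_end``: a frame
    acquired at the washout instant itself still sees the oxidant and would
    otherwise distort the estimated rate.
    """
    t0, t1 = seg.recovery
    mask = (rt.time_min > t0 + 1e-12) & (rt.time_min <= t1 + 1e-12)
    return RecoveryModel(rt.time_min[mask], rt.ratio[mask]).fit(max_iter=max_iter)


def pooled_recovery_curve(normalized: list[RatioTrace], seg: PhaseSegmentation
                          ) -> pd.DataFrame:
    """Mean ± SE of normalized traces over the recovery phase.

    Cells are aligned on the grid of the first cell by nearest frame.
    Returns a DataFrame with columns ``time_min, mean, se, n``.
    """
    if len(normalized) < 2:
        raise FitError("pooled curve needs at least 2 cells")
    t0, t1 = seg.recovery
    ref = normalized[0]
    mask = (ref.time_min >= t0) & (ref.time_min <= t1)
    grid = ref.time_min[mask]
    if grid.size == 0:
        raise FitError("no frames in recovery window")
    rows = np.empty((len(normalized), grid.size))
    for i, rt in enumerate(normalized):
        idx = np.abs(rt.time_min[None, :] - grid[:, None]).argmin(axis=1)
        rows[i] = rt.ratio[idx]
    mean = rows.mean(axis=0)
    se = rows.std(axis=0, ddof=1) / np.sqrt(len(normalized))
    return pd.DataFrame({"time_min": grid, "mean": mean, "se": se,
                         "n": len(normalized)})


# ---------------------------------------------------------------------------
# Per-cell pipeline
# ---------------------------------------------------------------------------


@dataclass
class CellRecord:
    """Full analysis of one cell: basal ratio, responses, recovery fit."""

    cell_id: str
    metadata: dict
    r_basal: float
    dr: DynamicRange
    response: ResponseSummary
    fit: RecoveryResults

    def as_row(self) -> dict:
        meta = dict(self.metadata)
        return {
            "experiment_id": meta.get("experiment_id", "exp0"),
            "cell_id": self.cell_id,
            "cell_line": meta.get("cell_line", ""),
            "compartment": meta.get("compartment", ""),
            "treatment": meta.get("treatment", ""),
            "r_basal": self.r_basal,
            "r_max": self.dr.r_max,
            "delta_r_50": self.response.delta_r_50,
            "delta_r_500": self.response.delta_r_500,
            "t_plateau_50_min": self.response.t_plateau_50,
            "recovery_k_per_min": self.fit.k,
            "recovery_k_se": self.fit.bse.get("k"),
            "fit_r": self.fit.r,
            "fit_converged": self.fit.converged,
            "n_recovery_frames": self.fit.n_points,
        }


def analyze_trace(trace: AcquisitionTrace, schedule: ProtocolSchedule,
                  baseline_window_min: float = 2.0,
                  fit_on: str = "normalized") -> CellRecord:
    """Run the full single-cell chain: ratio → baseline → dynamic range →
    response amplitudes → normalized recovery fit."""
    rt = compute_ratio(trace)
    seg = segment_phases(schedule, rt.time_min)
    r_basal = estimate_baseline(rt, schedule, window_min=baseline_window_min)
    dr = dynamic_range(rt, schedule, window_min=baseline_window_min)
    resp = response_amplitude(rt, seg, r_basal)
    target = normalize(rt, dr) if fit_on == "normalized" else rt
    fit = fit_exponential_recovery(target, seg)
    return CellRecord(cell_id=trace.cell_id, metadata=dict(trace.metadata),
                      r_basal=r_basal, dr=dr, response=resp, fit=fit)


def analyze_experiment(traces: list[AcquisitionTrace], schedule: ProtocolSchedule,
                       baseline_window_min: float = 2.0,
                       fit_on: str = "normalized") -> tuple[pd.DataFrame, list[str]]:
    """Analyze every cell; degenerate cells are excluded and listed.

    Returns ``(results_table, excluded_cell_ids)``.
    """
    rows, excluded = [], []
    for tr in traces:
        try:
            rec = analyze_trace(tr, schedule, baseline_window_min=baseline_window_min,
                                fit_on=fit_on)
        except DegenerateCellError:
            excluded.append(tr.cell_id)
            continue
        rows.append(rec.as_row())
    return pd.DataFrame(rows), excluded
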