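"""Velocity from segmented acceleration, and session-level aggregation.

The acceleration norm over a strike segment is integrated with the
trapezoidal rule,

    v_j = sum_{k=1..j} (a[k-1] + a[k]) / 2 * dt_k,

using the actual per-interval timestamps (no resampling).  The initial
velocity at strike onset is taken as 0: the athlete starts from a
stationary guard position.  Because the integrand is a norm (>= 0) the
velocity profile is non-decreasing, so the velocity at the impact peak
is also the segment's maximum — this differs from component-wise
integration and is documented deliberately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .config import AnalysisConfig
from .io import AccelerationTrace
from .segmentation import StrikeSegment, segment_session

logger = logging.getLogger(__name__)


@dataclass
class VelocityProfile:
    """Cumulative velocity over one strike segment.

    ``v[0] == 0`` and ``v`` is non-decreasing; ``impact_velocity`` is
    the final element — the speed at bag contact.
    """

    timestamps: np.ndarray
    v: np.ndarray

    @property
    def impact_velocity(self) -> float:
        return float(self.v[-1])


@dataclass
class SessionResult:
    """Per-strike impact velocities and session aggregates.

    ``session_average`` is the arithmetic mean over valid strikes and
    ``session_peak`` the maximum; both are NaN when no strike is valid.
    """

    strike_velocities: list[tuple[float, bool, str]]
    session_average: float
    session_peak: float
    n_valid: int


def integrate_velocity(segment: StrikeSegment) -> VelocityProfile:
    """Trapezoidal integration of the norm over [A_initial, A_peak].

    Exact to machine precision for integrands piecewise linear on the
    sample grid.  Raises on invalid segments — filter them first.
    """
    if not segment.valid:
        raise ValueError(
            f"cannot integrate invalid segment ({segment.invalid_reason}); "
            "filter invalid strikes before integration"
        )
    if segment.n_samples < 2:
        raise ValueError("segment must have at least 2 samples")
    v = cumulative_trapezoid(segment.a_abs, segment.timestamps, initial=0.0)
    return VelocityProfile(timestamps=segment.timestamps.copy(), v=v)


def session_metrics(
    strikes: Sequence[tuple[Optional[VelocityProfile], bool, str]],
) -> SessionResult:
    """Aggregate per-strike velocities into session average and peak.

    ``strikes`` holds (profile-or-None, valid, invalid_reason) per
    strike; invalid strikes are excluded from the aggregates.  With zero
    valid strikes the aggregates are NaN and a warning is logged.
    """
    if len(strikes) == 0:
        raise ValueError("at least one strike must be supplied")
    rows: list[tuple[float, bool, str]] = []
    valid_vs: list[float] = []
    for profile, valid, reason in strikes:
        v = profile.impact_velocity if profile is not None else math.nan
        rows.append((v, valid, reason))
        if valid:
            valid_vs.append(v)
    if valid_vs:
        avg = float(np.mean(valid_vs))
        peak = float(np.max(valid_vs))
    else:
        logger.warning("no valid strikes in session; aggregates undefined")
        avg = peak = math.nan
    return SessionResult(
        strike_velocities=rows,
        session_average=avg,
        session_peak=peak,
        n_valid=len(valid_vs),
    )


def analyze_session(
    trace: AccelerationTrace, config: AnalysisConfig | None = None
) -> SessionResult:
    """Full pipeline on one recording: segmentation then integration.

    Deterministic for a fixed trace and config.  Fewer detected strikes
    than expected produces a warning, not an error; a trace with no
    strikes at all yields an n_valid=0 result.
    """
    return StrikeSessionModel(trace, config).fit().session


class StrikeSessionModel:
    """Strike-velocity model for one accelerometer recording.

    Wraps the full pipeline (norm → threshold → peak detection →
    backward segmentation → validity rules → trapezoidal integration)
    behind a fit() interface::

        res = StrikeSessionModel(trace).fit()
        print(res.summary())

    Parameters
    ----------
    trace : AccelerationTrace
        One recording: ~5 s stationary baseline followed by the strikes.
    config : AnalysisConfig, optional
        Pipeline settings; defaults match the field protocol (2 m/s²
        threshold, 5 s baseline, 5 strikes, 0.6 s onset lookback).
    """

    def __init__(self, trace: AccelerationTrace, config: AnalysisConfig | None = None):
        self.trace = trace
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(cls, path, config: AnalysisConfig | None = None) -> "StrikeSessionModel":
        from .io import read_phyphox_csv

        return cls(read_phyphox_csv(path), config)

    def fit(self) -> "StrikeSessionResults":
        segments, threshold = segment_session(self.trace, self.config)
        strikes: list[tuple[Optional[VelocityProfile], bool, str]] = []
        profiles: list[Optional[VelocityProfile]] = []
        for seg in segments:
            if seg.valid:
                prof = integrate_velocity(seg)
            else:
                prof = None
            profiles.append(prof)
            strikes.append((prof, seg.valid, seg.invalid_reason))
        if strikes:
            session = session_metrics(strikes)
        else:
            logger.warning("no strikes detected in trace %r", self.trace.label)
            session = SessionResult([], math.nan, math.nan, 0)
        return StrikeSessionResults(
            model=self,
            segments=segments,
            profiles=profiles,
            threshold=threshold,
            session=session,
        )


@dataclass
class StrikeSessionResults:
    """Fitted strike velocities for one session.

    Attributes
    ----------
    segments : list of StrikeSegment
        Detected strikes in time order (valid and invalid).
    profiles : list of VelocityProfile or None
        Velocity profile per strike; None where the segment was invalid.
    threshold : float
        Strike-recognition threshold actually used, m/s².
    session : SessionResult
        Per-strike velocities plus session average/peak.
    """

    model: StrikeSessionModel
    segments: list[StrikeSegment]
    profiles: list[Optional[VelocityProfile]]
    threshold: float
    session: SessionResult

    @property
    def impact_velocities(self) -> np.ndarray:
        """Impact velocities of the valid strikes, m/s."""
        return np.array(
            [v for v, valid, _ in self.session.strike_velocities if valid]
        )

    def summary(self) -> str:
        ses = self.session
        lines = [
            "Strike session results",
            "======================",
            f"trace: {self.model.trace.label or '<in-memory>'}",
            f"threshold: {self.threshold:.3g} m/s^2   "
            f"strikes detected: {len(self.segments)}   valid: {ses.n_valid}",
            "",
            f"{'strike':>6} {'impact velocity (m/s)':>22} {'valid':>6}  flag",
        ]
        for i, (v, valid, reason) in enumerate(ses.strike_velocities, start=1):
            vtxt = f"{v:.2f}" if math.isfinite(v) else "--"
            lines.append(f"{i:>6} {vtxt:>22} {str(valid):>6}  {reason}")
        if ses.n_valid:
            lines += [
                "",
                f"session average: {ses.session_average:.2f} m/s",
                f"session peak:    {ses.session_peak:.2f} m/s",
            ]
        else:
            lines += ["", "no valid strikes: session aggregates undefined"]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Norm trace with detected peaks, onsets, and threshold line."""
        import matplotlib.pyplot as plt

        from .segmentation import acceleration_norm

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        norm = acceleration_norm(self.model.trace)
        ax.plot(norm.timestamps, norm.a_abs, color="black", lw=0.8, label="|a|")
        ax.axhline(self.threshold, ls="--", color="grey", label="threshold")
        for seg in self.segments:
            color = "tab:green" if seg.valid else "tab:red"
            ax.axvspan(seg.timestamps[0], seg.timestamps[-1], alpha=0.25, color=color)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("acceleration norm (m/s$^2$)")
        ax.legend(loc="upper right")
        return ax
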