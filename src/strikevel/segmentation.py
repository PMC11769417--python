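"""Strike segmentation on the acceleration norm.

The triaxial signal is reduced to its Euclidean norm
A = sqrt(Ax² + Ay² + Az²), an orientation-free scalar.  The sample of
maximum norm (A_peak) marks the instant of impact on the bag; scanning
backwards from it, the first sample strictly below a noise threshold
(A_initial) marks strike onset.  The inclusive slice [A_initial, A_peak]
is the strike segment handed to the velocity integrator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig, ValidityConfig
from .io import AccelerationTrace

logger = logging.getLogger(__name__)

# A gravity-free accelerometer at rest reads ~0; one reporting gravity
# reads ~9.81 m/s².  Baseline norms in this band trigger a warning.
GRAVITY_BAND = (8.5, 11.0)


@dataclass
class NormSeries:
    """Acceleration norm over time."""

    timestamps: np.ndarray
    a_abs: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.a_abs = np.asarray(self.a_abs, dtype=float)
        if len(self.timestamps) != len(self.a_abs):
            raise ValueError("timestamps and a_abs must have the same length")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class StrikeSegment:
    """One strike from onset (A_initial) to impact (A_peak), inclusive.

    ``start_index``/``peak_index`` are 0-based indices into the parent
    norm series; ``timestamps``/``a_abs`` hold the inclusive slice.
    """

    start_index: int
    peak_index: int
    timestamps: np.ndarray
    a_abs: np.ndarray
    threshold: float
    valid: bool = True
    invalid_reason: str = ""

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def n_samples(self) -> int:
        return len(self.a_abs)


def acceleration_norm(trace: AccelerationTrace) -> NormSeries:
    """Euclidean norm of the triaxial acceleration at each sample.

    Invariant under axis permutation and per-axis sign flips.
    """
    a_abs = np.sqrt(trace.ax**2 + trace.ay**2 + trace.az**2)
    return NormSeries(timestamps=trace.timestamps.copy(), a_abs=a_abs)


def baseline_window(norm: NormSeries, baseline_seconds: float) -> NormSeries:
    """The leading noise-only window (athlete stationary in guard)."""
    t0 = norm.timestamps[0]
    mask = norm.timestamps <= t0 + baseline_seconds
    return NormSeries(norm.timestamps[mask], norm.a_abs[mask])


def estimate_threshold(
    baseline: NormSeries,
    mode: str = "fixed",
    fixed_value: float = 2.0,
    k: float = 3.0,
) -> float:
    """Strike-recognition threshold in m/s².

    ``fixed`` returns ``fixed_value`` (default 2 m/s², adequate for
    gravity-free smartphone accelerometer noise).  ``adaptive`` returns
    mean + k·SD of the baseline norm (sample SD, n-1 denominator; SD is
    0 for a single-sample window).
    """
    if mode == "fixed":
        return float(fixed_value)
    if mode == "adaptive":
        if len(baseline) == 0:
            raise ValueError("adaptive threshold requires a non-empty baseline window")
        mean = float(np.mean(baseline.a_abs))
        sd = float(np.std(baseline.a_abs, ddof=1)) if len(baseline) > 1 else 0.0
        return mean + k * sd
    raise ValueError(f"unknown threshold mode {mode!r}")


def check_gravity(
    norm: NormSeries,
    baseline_seconds: float = 5.0,
    subtract: bool = False,
) -> tuple[NormSeries, bool]:
    """Warn if the baseline norm suggests the trace includes gravity.

    A gravity-free sensor reads near 0 at rest; a median baseline norm
    in [8.5, 11] m/s² means the export almost certainly includes g and a
    2 m/s² threshold would never be crossed downward.  The data are
    never altered silently: only when ``subtract`` is set is the median
    baseline norm removed (floored at 0).

    Returns the (possibly corrected) norm series and a flag saying
    whether gravity was suspected.
    """
    base = baseline_window(norm, baseline_seconds)
    if len(base) == 0:
        return norm, False
    med = float(np.median(base.a_abs))
    suspected = GRAVITY_BAND[0] <= med <= GRAVITY_BAND[1]
    if suspected:
        logger.warning(
            "baseline norm median %.2f m/s^2 lies in %s: trace appears to include "
            "gravity; %s",
            med,
            GRAVITY_BAND,
            "subtracting median baseline norm" if subtract else
            "pass subtract_gravity=True to correct",
        )
        if subtract:
            corrected = np.maximum(norm.a_abs - med, 0.0)
            return NormSeries(norm.timestamps, corrected), True
    return norm, suspected


def detect_impacts(
    norm: NormSeries,
    threshold: float,
    n_expected: int = 5,
    min_separation: float = 1.0,
    baseline_end: float = 5.0,
) -> list[int]:
    """Locate up to ``n_expected`` impact peaks after the baseline.

    Iteratively selects the global maximum of the not-yet-masked region,
    masks ±``min_separation`` seconds around it, and repeats until
    ``n_expected`` peaks are found or no remaining sample exceeds the
    threshold.  Returns indices sorted by time; logs a warning (and
    never raises) when fewer than expected are found.
    """
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    t = norm.timestamps
    searchable = (t > t[0] + baseline_end) & (norm.a_abs > threshold)
    working = np.where(searchable, norm.a_abs, -np.inf)
    peaks: list[int] = []
    for _ in range(n_expected):
        idx = int(np.argmax(working))
        if working[idx] == -np.inf:
            break
        peaks.append(idx)
        working[np.abs(t - t[idx]) <= min_separation] = -np.inf
    if len(peaks) < n_expected:
        logger.warning(
            "expected %d strikes but detected %d (threshold %.3g m/s^2)",
            n_expected, len(peaks), threshold,
        )
    return sorted(peaks)


def segment_strike(
    norm: NormSeries,
    peak_index: int,
    threshold: float,
    max_lookback: float = 0.6,
) -> StrikeSegment:
    """Segment one strike by scanning backwards from its impact peak.

    The onset A_initial is the first sample (descending timestamps from
    ``peak_index``) whose norm is strictly below ``threshold``; ties at
    exactly the threshold do not terminate the scan.  If no crossing is
    found within ``max_lookback`` seconds the segment is flagged invalid
    with reason "no onset crossing".
    """
    if not 0 <= peak_index < len(norm):
        raise IndexError(f"peak_index {peak_index} out of range for length {len(norm)}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t_peak = norm.timestamps[peak_index]
    start_index = None
    i = peak_index - 1
    while i >= 0 and t_peak - norm.timestamps[i] <= max_lookback:
        if norm.a_abs[i] < threshold:
            start_index = i
            break
        i -= 1
    if start_index is None:
        start_index = max(i + 1, 0)
        sl = slice(start_index, peak_index + 1)
        return StrikeSegment(
            start_index=start_index,
            peak_index=peak_index,
            timestamps=norm.timestamps[sl].copy(),
            a_abs=norm.a_abs[sl].copy(),
            threshold=threshold,
            valid=False,
            invalid_reason="no onset crossing",
        )
    sl = slice(start_index, peak_index + 1)
    return StrikeSegment(
        start_index=start_index,
        peak_index=peak_index,
        timestamps=norm.timestamps[sl].copy(),
        a_abs=norm.a_abs[sl].copy(),
        threshold=threshold,
    )


def apply_validity_rules(
    segment: StrikeSegment,
    rules: ValidityConfig | None = None,
) -> StrikeSegment:
    """Flag abnormal strike segments as invalid.

    A segment is invalid when it has fewer than ``min_samples`` samples,
    its duration falls outside [min_duration_s, max_duration_s], or it
    contains a non-finite sample.  Already-invalid segments keep their
    original reason.
    """
    if not segment.valid:
        return segment
    rules = rules or ValidityConfig()
    reason = ""
    # timestamp-difference rounding must not flip a boundary decision
    eps = 1e-6 * max(rules.min_duration_s, rules.max_duration_s)
    if segment.n_samples < rules.min_samples:
        reason = "too few samples"
    elif not np.all(np.isfinite(segment.a_abs)):
        reason = "non-finite sample"
    elif not (rules.min_duration_s - eps
              <= segment.duration
              <= rules.max_duration_s + eps):
        reason = "duration out of range"
    if reason:
        segment.valid = False
        segment.invalid_reason = reason
    return segment


def segment_session(
    trace: AccelerationTrace, config: AnalysisConfig | None = None
) -> tuple[list[StrikeSegment], float]:
    """Run the full segmentation chain on one recording.

    Norm → gravity check → threshold → peak detection → per-strike
    backward segmentation → validity rules.  Returns the segments (in
    time order) and the threshold used.
    """
    config = config or AnalysisConfig()
    norm = acceleration_norm(trace)
    norm, _ = check_gravity(norm, config.baseline_seconds, config.subtract_gravity)
    base = baseline_window(norm, config.baseline_seconds)
    threshold = estimate_threshold(
        base, mode=config.threshold.mode,
        fixed_value=config.threshold.value, k=config.threshold.k,
    )
    peaks = detect_impacts(
        norm, threshold,
        n_expected=config.n_strikes,
        min_separation=config.min_separation_s,
        baseline_end=config.baseline_seconds,
    )
    segments = [
        apply_validity_rules(
            segment_strike(norm, p, threshold, config.max_lookback_s),
            config.validity,
        )
        for p in peaks
    ]
    return segments, threshold
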