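"""Optokinetic response (OKR) quantification.

An OKR trace is a sawtooth of slow tracking phases (the eye follows the
rotating drum) interrupted by fast resetting saccades.  This module extracts
eye angles from dorsal-view frames, segments slow phases from saccades,
fits the slow-phase velocity (deg/s), computes the optokinetic gain
(eye velocity / drum velocity), and counts eye-tracking movements (ETMs)
per 15-second interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

DEFAULT_DRUM_VELOCITY = 20.0  # deg/s
DEFAULT_SPATIAL_FREQUENCY = 0.15  # cycles/deg
ETM_WINDOW_S = 15.0


@dataclass
class AngleTrace:
    """Binocular eye-angle time series (deg) at uniform sampling."""

    time: np.ndarray
    angle_left: np.ndarray
    angle_right: np.ndarray
    sample_rate: float
    stimulus: dict = field(default_factory=lambda: {
        "drum_velocity": DEFAULT_DRUM_VELOCITY,
        "spatial_frequency": DEFAULT_SPATIAL_FREQUENCY,
        "direction": "cw",
    })

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle_left = np.asarray(self.angle_left, dtype=float)
        self.angle_right = np.asarray(self.angle_right, dtype=float)
        if not (len(self.time) == len(self.angle_left) == len(self.angle_right)):
            raise ValueError("time and angle arrays must have equal length")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - dt.mean()) > 0.01 * dt.mean()):
                raise ValueError("sampling must be uniform within 1%")
        if not (np.isfinite(self.angle_left).all() and np.isfinite(self.angle_right).all()):
            raise ValueError("angles must be finite")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / self.sample_rate

    @property
    def mean_angle(self) -> np.ndarray:
        """Conjugate (binocular mean) angle."""
        return 0.5 * (self.angle_left + self.angle_right)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "angle_left_deg": self.angle_left,
                "angle_right_deg": self.angle_right,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, stimulus: dict | None = None) -> "AngleTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t)))
        kwargs = {"stimulus": stimulus} if stimulus is not None else {}
        return cls(
            time=t,
            angle_left=df["angle_left_deg"].to_numpy(),
            angle_right=df["angle_right_deg"].to_numpy(),
            sample_rate=rate,
            **kwargs,
        )


@dataclass
class PhaseSegmentation:
    """Saccade times and slow-phase segments (t_start, t_end, slope, r2)."""

    saccade_times: np.ndarray
    slow_segments: list[tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        self.saccade_times = np.asarray(self.saccade_times, dtype=float)
        for (t0, t1, _, _) in self.slow_segments:
            if t1 <= t0:
                raise ValueError("segments must have positive duration")
        starts = [s[0] for s in self.slow_segments]
        if starts != sorted(starts):
            raise ValueError("segments must be ordered")


@dataclass
class OkrResult:
    """Per-fish OKR summary: gains per direction, ETM counts, response flag."""

    gain_tn: float
    gain_nt: float
    etm_per_15s: list[int]
    n_segments: int
    no_response: bool


def _smoothed_velocity(angle: np.ndarray, sample_rate: float, window_s: float) -> np.ndarray:
    n = len(angle)
    window = max(5, int(round(window_s * sample_rate)) | 1)  # odd, >= 5
    window = min(window, n if n % 2 == 1 else n - 1)
    if window < 5:
        return np.gradient(angle) * sample_rate
    return savgol_filter(angle, window_length=window, polyorder=2, deriv=1,
                         delta=1.0 / sample_rate)


def detect_saccades(
    trace: AngleTrace,
    velocity_threshold: float = 100.0,
    smooth_window_s: float = 0.2,
    merge_within_s: float = 0.1,
) -> np.ndarray:
    """Detect fast-phase (saccade) times on the conjugate angle.

    A saccade is a sample where the smoothed angular velocity exceeds
    ``velocity_threshold`` (deg/s) with sign opposite the stimulus direction
    (resetting movements run against the drum); when the stimulus direction
    is unknown or alternating, velocity magnitude is used.  Events closer
    than ``merge_within_s`` are merged.
    """
    if len(trace.time) < 2:
        raise ValueError("trace must have at least 2 samples")
    vel = _smoothed_velocity(trace.mean_angle, trace.sample_rate, smooth_window_s)
    drum = float(trace.stimulus.get("drum_velocity", 0.0))
    direction = trace.stimulus.get("direction", "cw")
    if direction == "alternating" or drum == 0.0:
        hits = np.abs(vel) > velocity_threshold
    else:
        # slow phase follows the drum; saccades run the other way
        hits = (-np.sign(drum)) * vel > velocity_threshold
    if not hits.any():
        return np.array([])
    idx = np.flatnonzero(hits)
    groups = np.split(idx, np.flatnonzero(np.diff(trace.time[idx]) > merge_within_s) + 1)
    times = np.array([trace.time[g[np.argmax(np.abs(vel[g]))]] for g in groups])
    return times


def segment_slow_phases(
    trace: AngleTrace,
    saccade_times: np.ndarray,
    margin_s: float = 0.15,
    min_duration_s: float = 0.3,
) -> PhaseSegmentation:
    """Fit linear slopes to the inter-saccade slow phases.

    Each candidate segment spans between consecutive saccades (and the trace
    ends), trimmed by ``margin_s`` on both sides to exclude smoothing spill
    from the saccade itself; segments shorter than ``min_duration_s`` are
    dropped.  Slopes come from a least-squares line fit to the conjugate
    angle.
    """
    t = trace.time
    angle = trace.mean_angle
    edges = np.concatenate([[t[0] - margin_s], np.sort(saccade_times), [t[-1] + margin_s]])
    segments: list[tuple[float, float, float, float]] = []
    for a, b in zip(edges[:-1], edges[1:]):
        t0, t1 = a + margin_s, b - margin_s
        if t1 - t0 < min_duration_s:
            continue
        m = (t >= t0) & (t <= t1)
        if m.sum() < 3:
            continue
        x, y = t[m], angle[m]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        segments.append((float(t0), float(t1), float(slope), r2))
    return PhaseSegmentation(saccade_times=np.sort(saccade_times), slow_segments=segments)


def slow_phase_velocity(
    trace: AngleTrace,
    segmentation: PhaseSegmentation,
    r2_min: float = 0.8,
) -> tuple[float, int]:
    """Median slow-phase slope (deg/s, signed) over qualifying segments.

    Segments must reach ``r2_min`` on the linear fit to count as genuine
    tracking; a fish with no qualifying segment has no detectable response
    and ``nan`` is returned with segment count 0.
    """
    slopes = [s for (_, _, s, r2) in segmentation.slow_segments if r2 >= r2_min]
    if not slopes:
        return float("nan"), 0
    return float(np.median(slopes)), len(slopes)


def optokinetic_gain(eye_velocity: float, drum_velocity: float) -> float:
    """Gain = |slow-phase eye velocity| / |drum velocity|."""
    if drum_velocity == 0:
        raise ValueError("drum_velocity must be nonzero")
    return abs(eye_velocity) / abs(drum_velocity)


def count_etms(
    trace: AngleTrace,
    segmentation: PhaseSegmentation,
    window_s: float = ETM_WINDOW_S,
) -> list[int]:
    """ETM counts per consecutive ``window_s`` bin (trailing partial bin
    dropped).  One ETM is one saccade-delimited tracking cycle, so the count
    per bin is the number of saccades falling in it."""
    duration = trace.duration
    if duration < window_s:
        raise ValueError(f"trace duration {duration:.1f}s shorter than window {window_s}s")
    n_bins = int(duration / window_s)
    t0 = trace.time[0]
    counts = [0] * n_bins
    for ts in segmentation.saccade_times:
        k = int((ts - t0) / window_s)
        if 0 <= k < n_bins:
            counts[k] += 1
    return counts


def analyze_okr(
    trace: AngleTrace,
    velocity_threshold: float = 100.0,
    r2_min: float = 0.8,
    etm_window_s: float = ETM_WINDOW_S,
) -> OkrResult:
    """Full per-fish OKR analysis: saccade detection, slow-phase slopes,
    per-direction gains and ETM counts.

    Direction convention: slow-phase segments whose slope sign matches the
    drum direction are temporal-to-nasal for the eye leading the stimulus;
    with a unidirectional drum both gains equal the single measured gain and
    the absent direction is NaN when no opposite-sign segments exist.
    """
    saccades = detect_saccades(trace, velocity_threshold=velocity_threshold)
    seg = segment_slow_phases(trace, saccades)
    drum = float(trace.stimulus.get("drum_velocity", DEFAULT_DRUM_VELOCITY))

    good = [(s, r2) for (_, _, s, r2) in seg.slow_segments if r2 >= r2_min]
    etms = count_etms(trace, seg, window_s=etm_window_s)
    if not good:
        return OkrResult(
            gain_tn=float("nan"),
            gain_nt=float("nan"),
            etm_per_15s=[0] * len(etms),
            n_segments=0,
            no_response=True,
        )
    with_drum = [s for s, _ in good if np.sign(s) == np.sign(drum) or drum == 0]
    against_drum = [s for s, _ in good if np.sign(s) == -np.sign(drum) and drum != 0]
    gain_tn = optokinetic_gain(float(np.median(with_drum)), drum) if with_drum else float("nan")
    gain_nt = optokinetic_gain(float(np.median(against_drum)), drum) if against_drum else gain_tn
    return OkrResult(
        gain_tn=gain_tn,
        gain_nt=gain_nt,
        etm_per_15s=etms,
        n_segments=len(good),
        no_response=False,
    )


def track_eye_angles(
    frames: np.ndarray,
    sample_rate: float,
    stimulus: dict | None = None,
    max_bad_frac: float = 0.1,
) -> AngleTrace:
    """Extract binocular eye angles from dorsal-view frames.

    Eyes are the two largest dark connected components per frame; each eye's
    angle is the orientation of its second-order image moments, assigned
    left/right by lateral position, converted to degrees (counter-clockwise,
    x right / y up) and unwrapped over time with a 180° period.

    Raises if more than ``max_bad_frac`` of the frames do not contain two
    eye candidates.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be (n, h, w)")
    n = len(frames)
    left = np.full(n, np.nan)
    right = np.full(n, np.nan)
    for i, img in enumerate(frames):
        img = img.astype(float)
        if img.max() == img.min():
            continue
        dark = img < threshold_otsu(img)
        lab = sk_label(dark)
        regions = sorted(regionprops(lab), key=lambda r: r.area, reverse=True)[:2]
        if len(regions) < 2:
            continue
        regions.sort(key=lambda r: r.centroid[1])  # by column: left first
        for store, region in zip((left, right), regions):
            # regionprops orientation is measured from the row axis; convert
            # to CCW-from-x-axis (y up) degrees in (-90, 90]
            theta = np.rad2deg(region.orientation) + 90.0
            store[i] = ((theta + 90.0) % 180.0) - 90.0
    bad = np.isnan(left) | np.isnan(right)
    if bad.mean() > max_bad_frac:
        raise ValueError(
            f"{int(bad.sum())}/{n} frames lack two eye candidates "
            f"(> {max_bad_frac:.0%} allowed)"
        )
    t = np.arange(n) / sample_rate
    for arr in (left, right):
        if bad.any():
            arr[bad] = np.interp(t[bad], t[~bad], arr[~bad])
        arr[:] = np.unwrap(arr, period=180.0)
    kwargs = {"stimulus": stimulus} if stimulus is not None else {}
    return AngleTrace(time=t, angle_left=left, angle_right=right,
                      sample_rate=sample_rate, **kwargs)
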