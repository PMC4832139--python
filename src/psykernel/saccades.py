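"""Acceleration-based detection of target-directed saccades at 60 Hz.

A saccade toward a displaced item is accepted when (a) the per-sample
acceleration magnitude exceeds an adaptive threshold — mean + 1 SD of the
acceleration in the 2 s window preceding the displacement — and (b) the
instantaneous movement direction lies within ±22.5° of the straight line
from the current gaze position to the displaced item.  Accepted events are
classified by latency: express [25, 150) ms, regular [150, 250] ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, PreprocessingError
from .observer import GazeTrace
from .stimulus import DisplacementEvent

CONE_HALF_ANGLE_DEG = 22.5
EXPRESS_RANGE_MS = (25.0, 150.0)   # [25, 150)
REGULAR_RANGE_MS = (150.0, 250.0)  # [150, 250]
DEFAULT_SEARCH_WINDOW_MS = (0.0, 250.0)
DEFAULT_MAX_GAP_MS = 200.0
DEFAULT_THRESHOLD_WINDOW_MS = 2000.0


@dataclass
class SaccadeEvent:
    """One accepted target-directed eye movement."""

    trial_id: int
    onset_ms: float
    latency_ms: float
    direction_deg: float
    deviation_deg: float
    peak_acc: float
    klass: str


def classify_saccade(latency_ms: float) -> str:
    """Partition latency into express [25,150), regular [150,250], else
    unclassified."""
    if EXPRESS_RANGE_MS[0] <= latency_ms < EXPRESS_RANGE_MS[1]:
        return "express"
    if REGULAR_RANGE_MS[0] <= latency_ms <= REGULAR_RANGE_MS[1]:
        return "regular"
    return "unclassified"


def interpolate_blinks(trace: GazeTrace,
                       max_gap_ms: float = DEFAULT_MAX_GAP_MS) -> GazeTrace:
    """Linearly interpolate short invalid runs; leave long ones invalid.

    Runs no longer than ``max_gap_ms`` that are flanked by valid samples are
    filled linearly and marked valid.  No samples are added or removed.
    """
    if not trace.valid.any():
        raise PreprocessingError("gaze trace is entirely invalid")
    dt = float(np.median(np.diff(trace.time_ms)))
    max_run = int(round(max_gap_ms / dt))
    valid = trace.valid.copy()
    x = trace.x.copy()
    y = trace.y.copy()
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run = j - i
        if run <= max_run and i > 0 and j < n:
            frac = (trace.time_ms[i:j] - trace.time_ms[i - 1]) / (
                trace.time_ms[j] - trace.time_ms[i - 1])
            x[i:j] = x[i - 1] + frac * (x[j] - x[i - 1])
            y[i:j] = y[i - 1] + frac * (y[j] - y[i - 1])
            valid[i:j] = True
        i = j
    return GazeTrace(trace.time_ms.copy(), x, y, valid)


def acceleration_series(trace: GazeTrace) -> np.ndarray:
    """Per-sample acceleration magnitude (°/s²) by double forward difference.

    velocity[i] = (p[i+1] − p[i]) · fs; the acceleration vector at sample i
    is (velocity[i] − velocity[i−1]) · fs, so the series is NaN at both ends
    and wherever an invalid sample enters either difference.
    """
    n = len(trace)
    if np.count_nonzero(trace.valid) < 3:
        raise InsufficientDataError("need at least 3 valid samples")
    fs = trace.sample_rate
    pos = trace.positions().copy()
    pos[~trace.valid] = np.nan
    vel = np.full((n, 2), np.nan)
    vel[:-1] = np.diff(pos, axis=0) * (fs / 1.0)
    acc_vec = np.full((n, 2), np.nan)
    acc_vec[1:] = np.diff(vel, axis=0) * fs
    return np.hypot(acc_vec[:, 0], acc_vec[:, 1])


def velocity_series(trace: GazeTrace) -> np.ndarray:
    """Forward-difference velocity vectors (°/s), NaN at the last sample."""
    n = len(trace)
    fs = trace.sample_rate
    pos = trace.positions().copy()
    pos[~trace.valid] = np.nan
    vel = np.full((n, 2), np.nan)
    vel[:-1] = np.diff(pos, axis=0) * fs
    return vel


def direction_series(trace: GazeTrace) -> np.ndarray:
    """Central-difference movement vectors (°/s) used for the direction cone.

    The central estimate is defined at deceleration samples (where the
    forward difference is already zero) and is aligned with the
    second-difference acceleration series.
    """
    n = len(trace)
    fs = trace.sample_rate
    pos = trace.positions().copy()
    pos[~trace.valid] = np.nan
    vel = np.full((n, 2), np.nan)
    vel[1:-1] = (pos[2:] - pos[:-2]) * (fs / 2.0)
    return vel


def adaptive_threshold(acc: np.ndarray, time_ms: np.ndarray, t_disp: float,
                       window_ms: float = DEFAULT_THRESHOLD_WINDOW_MS,
                       min_valid_fraction: float = 0.5) -> float:
    """mean + 1·SD (population) of acceleration in [t_disp − window, t_disp).

    NaN samples (ends, blinks) are excluded; if fewer than
    ``min_valid_fraction`` of the window's nominal samples remain the trial
    is un-analyzable and :class:`InsufficientDataError` is raised.
    """
    dt = float(time_ms[1] - time_ms[0])
    i0 = int(np.searchsorted(time_ms, t_disp - window_ms, side="left"))
    i1 = int(np.searchsorted(time_ms, t_disp, side="left"))
    vals = acc[i0:i1]
    vals = vals[np.isfinite(vals)]
    nominal = window_ms / dt
    if len(vals) == 0 or len(vals) < min_valid_fraction * nominal:
        raise InsufficientDataError(
            f"threshold window before t={t_disp} has too few valid samples")
    return float(np.mean(vals) + np.std(vals))  # population SD (n divisor)


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _target_position(disp: DisplacementEvent, t_ms: float) -> np.ndarray:
    """Displaced item's position at time t (it keeps moving after the jump);
    before the displacement this is the item's pre-jump trajectory."""
    dt_s = (t_ms - disp.time_ms) / 1000.0
    ref = disp.post_position if t_ms >= disp.time_ms else disp.pre_position
    return ref + disp.pre_velocity * dt_s


def _events_in_window(trace: GazeTrace, acc: np.ndarray, vel: np.ndarray,
                      disp: DisplacementEvent, threshold: float,
                      t_lo: float, t_hi: float,
                      lo_open: bool) -> list[tuple[SaccadeEvent, int]]:
    """Group supra-threshold runs inside (t_lo, t_hi] or [t_lo, t_hi).

    Returns (event, onset sample index) pairs; ``vel`` supplies the
    movement-direction estimate per sample.
    """
    t = trace.time_ms
    if lo_open:
        lo = int(np.searchsorted(t, t_lo, side="right"))
        hi = int(np.searchsorted(t, t_hi, side="right"))
    else:
        lo = int(np.searchsorted(t, t_lo, side="left"))
        hi = int(np.searchsorted(t, t_hi, side="left"))
    if hi <= lo:
        return []
    idx = np.arange(lo, hi)
    with np.errstate(invalid="ignore"):
        supra = acc[lo:hi] > threshold
    events: list[tuple[SaccadeEvent, int]] = []
    i = 0
    while i < idx.size:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j < idx.size and supra[j]:
            j += 1
        run = idx[i:j]
        peak = float(np.nanmax(acc[run]))
        for k in run:
            v = vel[k]
            if not np.all(np.isfinite(v)) or (v[0] == 0 and v[1] == 0):
                continue
            gaze = np.array([trace.x[k], trace.y[k]])
            line = _target_position(disp, t[k]) - gaze
            dev = _angle_between_deg(v, line)
            if np.isfinite(dev) and dev <= CONE_HALF_ANGLE_DEG:
                latency = float(t[k] - disp.time_ms)
                events.append((SaccadeEvent(
                    trial_id=-1, onset_ms=float(t[k]), latency_ms=latency,
                    direction_deg=float(np.degrees(np.arctan2(v[1], v[0]))),
                    deviation_deg=dev, peak_acc=peak,
                    klass=classify_saccade(latency)), int(k)))
                break
        i = j
    return events


def detect_target_saccades(
        trace: GazeTrace, disp: DisplacementEvent,
        acc: np.ndarray | None = None,
        threshold: float | None = None,
        search_window_ms: tuple[float, float] = DEFAULT_SEARCH_WINDOW_MS,
) -> list[SaccadeEvent]:
    """Detect saccades toward the displaced item within the search window.

    Onset is the first sample of each supra-threshold run whose movement
    direction falls inside the ±22.5° cone around the gaze→target line;
    separate runs (split by sub-threshold gaps) may yield multiple events.
    An empty list means no saccade was detected.
    """
    if acc is None:
        acc = acceleration_series(trace)
    if threshold is None:
        threshold = adaptive_threshold(acc, trace.time_ms, disp.time_ms)
    vel = direction_series(trace)
    t0 = disp.time_ms + search_window_ms[0]
    t1 = disp.time_ms + search_window_ms[1]
    return [ev for ev, _ in _events_in_window(trace, acc, vel, disp,
                                              threshold, t0, t1,
                                              lo_open=True)]


def detect_session(trace: GazeTrace,
                   displacements: list[DisplacementEvent],
                   interpolate: bool = True,
                   max_gap_ms: float = DEFAULT_MAX_GAP_MS) -> pd.DataFrame:
    """Run blink interpolation + detection for every trial of a session.

    Returns one row per accepted saccade (trial_id, onset_ms, latency_ms,
    klass, direction_deg, deviation_deg, peak_acc); trials whose threshold
    window is un-analyzable are skipped.  Samples belonging to saccades
    accepted on earlier trials are excluded from later threshold windows
    (alongside blink samples), so one response does not inflate the
    baseline of the next trial.
    """
    if interpolate:
        trace = interpolate_blinks(trace, max_gap_ms)
    acc = acceleration_series(trace)
    vel = direction_series(trace)
    acc_baseline = acc.copy()
    rows = []
    for trial_id, disp in enumerate(displacements):
        try:
            thr = adaptive_threshold(acc_baseline, trace.time_ms,
                                     disp.time_ms)
        except InsufficientDataError:
            continue
        evs = _events_in_window(
            trace, acc, vel, disp, thr,
            disp.time_ms + DEFAULT_SEARCH_WINDOW_MS[0],
            disp.time_ms + DEFAULT_SEARCH_WINDOW_MS[1], lo_open=True)
        for ev, onset_idx in evs:
            ev.trial_id = trial_id
            rows.append(vars(ev))
            acc_baseline[max(onset_idx - 1, 0):onset_idx + 6] = np.nan
    return pd.DataFrame(rows, columns=["trial_id", "onset_ms", "latency_ms",
                                       "direction_deg", "deviation_deg",
                                       "peak_acc", "klass"])


def pre_post_saccade_counts(trace: GazeTrace,
                            displacements: list[DisplacementEvent],
                            window_ms: float = 250.0):
    """Per-trial counts of target-directed movements before vs after each
    displacement, plus a paired t-test across trials.

    The pre-window [t−w, t) uses the item's pre-displacement trajectory as
    the target; the post-window (t, t+w] uses the displaced trajectory.
    """
    from .stats import paired_t  # local import avoids a cycle

    if len(displacements) < 2:
        raise InsufficientDataError("need at least 2 trials")
    acc = acceleration_series(trace)
    vel = direction_series(trace)
    pre_counts, post_counts = [], []
    for disp in displacements:
        try:
            thr = adaptive_threshold(acc, trace.time_ms, disp.time_ms)
        except InsufficientDataError:
            continue
        pre = _events_in_window(trace, acc, vel, disp, thr,
                                disp.time_ms - window_ms, disp.time_ms,
                                lo_open=False)
        post = _events_in_window(trace, acc, vel, disp, thr,
                                 disp.time_ms, disp.time_ms + window_ms,
                                 lo_open=True)
        pre_counts.append(len(pre))
        post_counts.append(len(post))
    pre_arr = np.asarray(pre_counts, dtype=float)
    post_arr = np.asarray(post_counts, dtype=float)
    result = paired_t(post_arr, pre_arr)
    return pre_arr, post_arr, result
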