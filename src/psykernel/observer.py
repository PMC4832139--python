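"""Synthetic observer: gaze traces and button presses from a known kernel.

The observer fixates near the display center with Gaussian jitter.  Each
trial is declared detected with a probability that grows with the
Mahalanobis distance of the (motion-normalized) displacement from a
ground-truth detection kernel; detected trials probabilistically trigger an
express saccade, a regular saccade, and/or a button press.  This module
exists so every downstream stage has a fully known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .stimulus import StimulusLog

SACCADE_SAMPLES = 3            # ballistic flight duration in samples
HOLD_SAMPLES = 15              # dwell at target; keeps the return drift
                               # outside the 250 ms post-displacement window
RETURN_SAMPLES = 30            # slow linear drift back to fixation
_BALLISTIC_FRACTIONS = np.array([1.0 / 9.0, 4.0 / 9.0, 1.0])


@dataclass
class ObserverConfig:
    """Ground-truth detection kernel and response-generation parameters."""

    kernel_center: tuple[float, float] = (0.0, 0.0)
    kernel_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0225, 0.0), (0.0, 0.0225))          # 0.15 normalized-unit radius
    steepness: float = 6.0
    p_express: float = 0.35
    p_regular: float = 0.35
    p_press: float = 0.5
    express_latency_range: tuple[float, float] = (25.0, 150.0)
    regular_latency_range: tuple[float, float] = (150.0, 250.0)
    press_latency_range: tuple[float, float] = (300.0, 1200.0)
    fixation_sd: float = 0.0
    sample_rate: float = 60.0
    blink_rate_hz: float = 0.0
    blink_duration_range_ms: tuple[float, float] = (100.0, 300.0)
    direction_noise_deg: float = 0.0

    def __post_init__(self) -> None:
        cov = np.asarray(self.kernel_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ConfigurationError("kernel_cov must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ConfigurationError("kernel_cov must be positive definite")
        for p in (self.p_express, self.p_regular, self.p_press):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if not (self.express_latency_range[1] <= self.regular_latency_range[0]
                and self.express_latency_range[0]
                < self.express_latency_range[1]
                < self.regular_latency_range[1]):
            raise ConfigurationError(
                "latency ranges must be ordered and non-overlapping")
        if self.fixation_sd < 0 or self.sample_rate <= 0:
            raise ConfigurationError("invalid fixation_sd or sample_rate")


@dataclass
class GazeTrace:
    """Uniformly sampled gaze positions; ``valid`` is False during blinks."""

    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def sample_rate(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.time_ms)))

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ms": self.time_ms, "x": self.x, "y": self.y,
                      "valid": self.valid.astype(int)}).to_csv(path,
                                                               index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GazeTrace":
        df = pd.read_csv(path)
        return cls(df["time_ms"].to_numpy(), df["x"].to_numpy(),
                   df["y"].to_numpy(), df["valid"].to_numpy().astype(bool))


@dataclass
class ResponseLog:
    """Button presses plus per-trial ground truth of the simulated observer."""

    presses: list[float] = field(default_factory=list)
    ground_truth: pd.DataFrame | None = None

    def presses_to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ms": self.presses}).to_csv(path, index=False)

    @classmethod
    def presses_from_csv(cls, path: str | Path) -> "ResponseLog":
        df = pd.read_csv(path)
        return cls(presses=df["time_ms"].tolist())


def detection_probability(kernel_center, kernel_cov, point,
                          steepness: float) -> float:
    """P(detect) = logistic in the Mahalanobis distance from the kernel.

    Returns ``1 / (1 + exp(-steepness * (M - 1)))`` where ``M`` is the
    Mahalanobis distance of ``point`` from ``kernel_center`` under
    ``kernel_cov``: points on the 1-SD ellipse (M = 1) are detected with
    probability one half; points well outside are almost always detected.
    """
    center = np.asarray(kernel_center, dtype=float)
    cov = np.asarray(kernel_cov, dtype=float)
    d = np.asarray(point, dtype=float) - center
    try:
        m = float(np.sqrt(d @ np.linalg.solve(cov, d)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular kernel covariance") from exc
    return float(1.0 / (1.0 + np.exp(-steepness * (m - 1.0))))


def _normalized_point(event) -> np.ndarray:
    """Motion-direction-rotated, speed-normalized displacement vector."""
    v = event.pre_velocity
    speed = float(np.hypot(*v))
    theta = np.arctan2(v[1], v[0])
    d = event.displacement
    c, s = np.cos(-theta), np.sin(-theta)
    return np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]]) / speed


def simulate_responses(stim: StimulusLog, obs: ObserverConfig,
                       seed: int) -> tuple[GazeTrace, ResponseLog]:
    """Generate one session of gaze samples and button presses.

    Per trial, in RNG order: a detection draw; then (detected trials only)
    an express draw + latency, a regular draw + latency, and a press draw +
    latency.  Saccades are ballistic 3-sample flights toward the displaced
    item's current position, held briefly, then drifted slowly back to
    fixation.  Responses whose onset would land after the next trial's
    displacement (or past the end of the trace) are suppressed and logged.
    Blinks (if enabled) are appended as contiguous invalid runs.
    """
    if not stim.displacements:
        raise ValueError("stimulus log contains no displacement events")
    rng = np.random.default_rng(seed)
    dt = 1000.0 / obs.sample_rate
    n_samples = int(round(stim.duration_ms / dt)) + 1
    time_ms = np.arange(n_samples) * dt
    gaze = rng.normal(0.0, obs.fixation_sd, size=(n_samples, 2))
    valid = np.ones(n_samples, dtype=bool)

    presses: list[float] = []
    records = []
    events = stim.displacements
    for i, ev in enumerate(events):
        next_t = events[i + 1].time_ms if i + 1 < len(events) else np.inf
        point = _normalized_point(ev)
        p_det = detection_probability(obs.kernel_center, obs.kernel_cov,
                                      point, obs.steepness)
        detected = bool(rng.random() < p_det)
        rec = {"trial_id": i, "time_ms": ev.time_ms, "p_detect": p_det,
               "detected": detected, "express_latency_ms": np.nan,
               "regular_latency_ms": np.nan, "press_latency_ms": np.nan,
               "suppressed": False}
        if detected:
            for kind, p, lat_range in (
                    ("express", obs.p_express, obs.express_latency_range),
                    ("regular", obs.p_regular, obs.regular_latency_range)):
                if rng.random() < p:
                    latency = rng.uniform(*lat_range)
                    ok = _insert_saccade(gaze, time_ms, ev, latency, obs,
                                         next_t, rng)
                    if ok:
                        rec[f"{kind}_latency_ms"] = latency
                    else:
                        rec["suppressed"] = True
            if rng.random() < obs.p_press:
                latency = rng.uniform(*obs.press_latency_range)
                t_press = ev.time_ms + latency
                if t_press < min(next_t, time_ms[-1]):
                    presses.append(float(t_press))
                    rec["press_latency_ms"] = latency
                else:
                    rec["suppressed"] = True
        records.append(rec)

    if obs.blink_rate_hz > 0:
        _insert_blinks(valid, dt, obs, rng)
    if not valid.any():
        valid[:] = True  # pathological blink config; keep trace usable

    trace = GazeTrace(time_ms=time_ms, x=gaze[:, 0], y=gaze[:, 1],
                      valid=valid)
    log = ResponseLog(presses=presses, ground_truth=pd.DataFrame(records))
    return trace, log


def _insert_saccade(gaze: np.ndarray, time_ms: np.ndarray, ev, latency: float,
                    obs: ObserverConfig, next_t: float,
                    rng: np.random.Generator) -> bool:
    """Overwrite a saccade-to-target segment; False if suppressed."""
    dt = 1000.0 / obs.sample_rate
    onset = int(np.ceil((ev.time_ms + latency) / dt))
    onset_t = onset * dt
    if onset_t >= next_t or onset + SACCADE_SAMPLES >= len(time_ms):
        return False
    # item keeps moving after the displacement
    target = (ev.post_position
              + ev.pre_velocity * (onset_t - ev.time_ms) / 1000.0)
    start = gaze[onset - 1].copy()
    vec = target - start
    if obs.direction_noise_deg > 0:
        ang = np.deg2rad(rng.normal(0.0, obs.direction_noise_deg))
        c, s = np.cos(ang), np.sin(ang)
        vec = np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])
    for k, frac in enumerate(_BALLISTIC_FRACTIONS):
        gaze[onset + k] = start + frac * vec
    end_pos = start + vec
    hold_end = min(onset + SACCADE_SAMPLES + HOLD_SAMPLES, len(time_ms))
    gaze[onset + SACCADE_SAMPLES:hold_end] = end_pos
    ret_end = min(hold_end + RETURN_SAMPLES, len(time_ms))
    n_ret = ret_end - hold_end
    if n_ret > 0:
        fracs = np.linspace(0.0, 1.0, n_ret + 1)[1:, None]
        jitter = rng.normal(0.0, obs.fixation_sd, size=(n_ret, 2))
        gaze[hold_end:ret_end] = end_pos * (1.0 - fracs) + jitter
    return True


def _insert_blinks(valid: np.ndarray, dt: float, obs: ObserverConfig,
                   rng: np.random.Generator) -> None:
    """Poisson-rate contiguous invalid runs of 100–300 ms."""
    duration_s = len(valid) * dt / 1000.0
    n_blinks = rng.poisson(obs.blink_rate_hz * duration_s)
    for _ in range(n_blinks):
        start = rng.integers(len(valid))
        length = int(round(rng.uniform(*obs.blink_duration_range_ms) / dt))
        valid[start:start + max(length, 1)] = False
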