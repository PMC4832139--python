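"""Multi-item linear-motion display with bouncing walls and trajectory displacements.

The scene holds identical circles moving at constant speed along straight
lines, reflecting off the display edges (with a tiny speed perturbation per
bounce).  At scheduled times one item is instantaneously displaced by a
motion-relative vector and then continues on a parallel trajectory; each
displacement is one trial and is logged with full ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SchedulingError

#: Motion-relative displacement orientations (degrees, CCW from heading).
ORIENTATIONS_DEG = (0.0, 45.0, 90.0, 135.0, 180.0, -135.0, -90.0, -45.0)

#: Displacement amplitude grid (degrees of visual angle).
AMPLITUDES_DEG = tuple(np.arange(1, 17) * 0.5)

#: Inter-displacement interval bounds (ms).
GAP_RANGE_MS = (2000.0, 4000.0)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and kinematics of the stimulus display.

    Defaults follow a 30° horizontal field rendered at a 4:3 aspect
    (so 22.5° vertically), ten items of 1° radius moving at 18°/s, a
    ±0.001°/s speed perturbation per wall bounce, and a 60 Hz frame rate.
    """

    width: float = 30.0
    height: float = 22.5
    n_items: int = 10
    item_radius: float = 1.0
    speed: float = 18.0
    bounce_jitter: float = 0.001
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("display dimensions must be positive")
        if self.n_items < 0:
            raise ConfigurationError("n_items must be >= 0")
        if self.speed <= 0:
            raise ConfigurationError("speed must be positive")
        if self.item_radius <= 0:
            raise ConfigurationError("item_radius must be positive")
        if self.bounce_jitter < 0:
            raise ConfigurationError("bounce_jitter must be >= 0")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.frame_rate

    @property
    def motion_bounds(self) -> tuple[float, float]:
        """Half-extents reachable by item centers (wall minus radius)."""
        return (self.width / 2.0 - self.item_radius,
                self.height / 2.0 - self.item_radius)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(**d)


@dataclass
class ItemState:
    """One moving circle: index, position (x, y) in degrees, velocity in °/s.

    The origin is the display center, +x right, +y up.
    """

    item_id: int
    position: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)

    @property
    def speed(self) -> float:
        return float(np.hypot(*self.velocity))


@dataclass
class DisplacementEvent:
    """Ground truth for one trial: an instantaneous trajectory displacement."""

    time_ms: float
    item_id: int
    rel_orientation_deg: float
    amplitude_deg: float
    pre_position: np.ndarray
    post_position: np.ndarray
    pre_velocity: np.ndarray

    def __post_init__(self) -> None:
        self.pre_position = np.asarray(self.pre_position, dtype=float)
        self.post_position = np.asarray(self.post_position, dtype=float)
        self.pre_velocity = np.asarray(self.pre_velocity, dtype=float)

    @property
    def displacement(self) -> np.ndarray:
        return self.post_position - self.pre_position


@dataclass
class StimulusLog:
    """Complete record of a simulated session."""

    config: SceneConfig
    displacements: list[DisplacementEvent]
    seed: int
    item_tracks: pd.DataFrame | None = None
    duration_ms: float = 0.0
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    def displacements_frame(self) -> pd.DataFrame:
        if self._frame is None:
            rows = [
                {
                    "time_ms": e.time_ms,
                    "item_id": e.item_id,
                    "rel_orientation_deg": e.rel_orientation_deg,
                    "amplitude_deg": e.amplitude_deg,
                    "pre_x": e.pre_position[0],
                    "pre_y": e.pre_position[1],
                    "post_x": e.post_position[0],
                    "post_y": e.post_position[1],
                    "vx": e.pre_velocity[0],
                    "vy": e.pre_velocity[1],
                }
                for e in self.displacements
            ]
            self._frame = pd.DataFrame(
                rows,
                columns=["time_ms", "item_id", "rel_orientation_deg",
                         "amplitude_deg", "pre_x", "pre_y", "post_x",
                         "post_y", "vx", "vy"],
            )
        return self._frame

    def write(self, out_dir: str | Path, tracks: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.displacements_frame().to_csv(out / "displacements.csv", index=False)
        if tracks and self.item_tracks is not None:
            self.item_tracks.to_csv(out / "tracks.csv", index=False)
        sidecar = {"config": self.config.to_dict(), "seed": self.seed,
                   "duration_ms": self.duration_ms}
        (out / "session.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, in_dir: str | Path) -> "StimulusLog":
        src = Path(in_dir)
        sidecar = json.loads((src / "session.json").read_text())
        frame = pd.read_csv(src / "displacements.csv")
        events = [
            DisplacementEvent(
                time_ms=r.time_ms, item_id=int(r.item_id),
                rel_orientation_deg=r.rel_orientation_deg,
                amplitude_deg=r.amplitude_deg,
                pre_position=(r.pre_x, r.pre_y),
                post_position=(r.post_x, r.post_y),
                pre_velocity=(r.vx, r.vy),
            )
            for r in frame.itertuples()
        ]
        tracks_path = src / "tracks.csv"
        tracks = pd.read_csv(tracks_path) if tracks_path.exists() else None
        return cls(config=SceneConfig.from_dict(sidecar["config"]),
                   displacements=events, seed=sidecar["seed"],
                   item_tracks=tracks, duration_ms=sidecar["duration_ms"])


def events_from_frame(frame: pd.DataFrame) -> list[DisplacementEvent]:
    """Rebuild DisplacementEvents from a displacements.csv table."""
    return [
        DisplacementEvent(
            time_ms=r.time_ms, item_id=int(r.item_id),
            rel_orientation_deg=r.rel_orientation_deg,
            amplitude_deg=r.amplitude_deg,
            pre_position=(r.pre_x, r.pre_y),
            post_position=(r.post_x, r.post_y),
            pre_velocity=(r.vx, r.vy),
        )
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# scene initialization and kinematics
# ---------------------------------------------------------------------------

def _init_arrays(config: SceneConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random positions inside the motion bounds, random headings at speed."""
    bx, by = config.motion_bounds
    if bx <= 0 or by <= 0:
        raise ConfigurationError("item radius exceeds display half-extent")
    n = config.n_items
    pos = np.empty((n, 2))
    pos[:, 0] = rng.uniform(-bx, bx, size=n)
    pos[:, 1] = rng.uniform(-by, by, size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    vel = config.speed * np.column_stack([np.cos(theta), np.sin(theta)])
    return pos, vel


def init_scene(config: SceneConfig, seed: int) -> list[ItemState]:
    """Create ``config.n_items`` items at random positions and headings."""
    rng = np.random.default_rng(seed)
    pos, vel = _init_arrays(config, rng)
    return [ItemState(i, pos[i].copy(), vel[i].copy())
            for i in range(config.n_items)]


def _step(pos: np.ndarray, vel: np.ndarray, dt_ms: float,
          config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Advance positions in place by one interval; reflect at walls.

    A wall contact reflects the normal velocity component, then perturbs the
    item's speed by a uniform draw in ±bounce_jitter (one draw per contact,
    x-wall contacts resolved before y-wall contacts, in item order).
    Returns a boolean mask of items that bounced this step.
    """
    dt_s = dt_ms / 1000.0
    pos += vel * dt_s
    bounds = config.motion_bounds
    bounced = np.zeros(len(pos), dtype=bool)
    for axis in (0, 1):
        b = bounds[axis]
        for sign in (1.0, -1.0):
            over = sign * pos[:, axis] > b
            if not over.any():
                continue
            idx = np.flatnonzero(over)
            pos[idx, axis] = sign * 2.0 * b - pos[idx, axis]
            vel[idx, axis] *= -1.0
            speed = np.hypot(vel[idx, 0], vel[idx, 1])
            jitter = rng.uniform(-config.bounce_jitter, config.bounce_jitter,
                                 size=idx.size)
            scale = (speed + jitter) / speed
            vel[idx] *= scale[:, None]
            bounced[idx] = True
    return bounced


def advance(items: list[ItemState], dt_ms: float, rng: np.random.Generator,
            config: SceneConfig | None = None) -> list[ItemState]:
    """Move every item forward by ``dt_ms``, bouncing off the walls.

    ``dt_ms`` of 0 returns an identical copy.  The input list is not
    modified.
    """
    if dt_ms < 0:
        raise ValueError("dt_ms must be >= 0")
    config = config or SceneConfig(n_items=len(items))
    pos = np.array([it.position for it in items], dtype=float).reshape(-1, 2)
    vel = np.array([it.velocity for it in items], dtype=float).reshape(-1, 2)
    if dt_ms > 0 and len(items):
        _step(pos, vel, dt_ms, config, rng)
    return [ItemState(it.item_id, pos[i].copy(), vel[i].copy())
            for i, it in enumerate(items)]


# ---------------------------------------------------------------------------
# displacement sampling
# ---------------------------------------------------------------------------

def _wall_distance(pos: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Distance of each item center to its nearest display boundary."""
    dx = config.width / 2.0 - np.abs(pos[:, 0])
    dy = config.height / 2.0 - np.abs(pos[:, 1])
    return np.minimum(dx, dy)


def _displace(pre_pos: np.ndarray, vel: np.ndarray, rel_deg: float,
              amplitude: float) -> np.ndarray:
    theta = np.arctan2(vel[1], vel[0]) + np.deg2rad(rel_deg)
    return pre_pos + amplitude * np.array([np.cos(theta), np.sin(theta)])


def _sample_displacement_arrays(
        pos: np.ndarray, vel: np.ndarray, rng: np.random.Generator,
        config: SceneConfig, time_ms: float = 0.0,
        rel_orientation_deg: float | None = None,
        max_attempts: int = 100) -> DisplacementEvent:
    if rel_orientation_deg is None:
        rel_orientation_deg = ORIENTATIONS_DEG[
            rng.integers(len(ORIENTATIONS_DEG))]
    dist = _wall_distance(pos, config)
    for _ in range(max_attempts):
        amplitude = AMPLITUDES_DEG[rng.integers(len(AMPLITUDES_DEG))]
        eligible = np.flatnonzero(dist >= 2.0 * amplitude)
        if eligible.size:
            item = int(eligible[rng.integers(eligible.size)])
            post = _displace(pos[item], vel[item], rel_orientation_deg,
                             amplitude)
            return DisplacementEvent(
                time_ms=time_ms, item_id=item,
                rel_orientation_deg=float(rel_orientation_deg),
                amplitude_deg=float(amplitude),
                pre_position=pos[item].copy(), post_position=post,
                pre_velocity=vel[item].copy())
    raise SchedulingError(
        f"no eligible item after {max_attempts} amplitude redraws")


def sample_displacement(items: list[ItemState], rng: np.random.Generator,
                        config: SceneConfig, time_ms: float = 0.0,
                        rel_orientation_deg: float | None = None,
                        max_attempts: int = 100) -> DisplacementEvent:
    """Draw one displacement event from the current scene.

    Amplitude is drawn uniformly from the 0.5°–8° grid and the orientation
    uniformly from the eight motion-relative angles (unless given).  Items
    closer than twice the drawn amplitude to any boundary are ineligible;
    if no item qualifies the amplitude is redrawn, up to ``max_attempts``
    times, before a :class:`SchedulingError` is raised.
    """
    if not items:
        raise SchedulingError("no items in scene")
    pos = np.array([it.position for it in items], dtype=float)
    vel = np.array([it.velocity for it in items], dtype=float)
    ev = _sample_displacement_arrays(pos, vel, rng, config, time_ms,
                                     rel_orientation_deg, max_attempts)
    ev.item_id = items[ev.item_id].item_id
    return ev


def _orientation_deck(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced, shuffled orientation sequence (each value n/8 ± 1 times)."""
    base, extra = divmod(n_trials, len(ORIENTATIONS_DEG))
    deck = list(ORIENTATIONS_DEG) * base
    if extra:
        deck += list(rng.choice(ORIENTATIONS_DEG, size=extra, replace=False))
    deck = np.asarray(deck, dtype=float)
    rng.shuffle(deck)
    return deck


def run_session(config: SceneConfig, n_trials: int, seed: int,
                record_tracks: bool = True,
                post_roll_ms: float = 2000.0) -> StimulusLog:
    """Simulate a full session of ``n_trials`` displacement trials.

    Event times are spaced by fresh uniform draws in [2000, 4000] ms,
    rounded to the nearest frame (exact frame multiples at 60 Hz, so the
    bounds are preserved).  The run is bit-for-bit reproducible from
    (config, n_trials, seed).  RNG draw order: item positions/headings,
    orientation deck, inter-event gaps, then frame-loop bounce jitters
    interleaved with per-event amplitude/item draws.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    rng = np.random.default_rng(seed)
    pos, vel = _init_arrays(config, rng)
    deck = _orientation_deck(n_trials, rng)

    dt = config.dt_ms
    gaps_ms = rng.uniform(*GAP_RANGE_MS, size=n_trials)
    gap_frames = np.rint(gaps_ms / dt).astype(int)
    # rounding must not push a gap outside the hard [2000, 4000] ms bounds
    gap_frames = np.clip(gap_frames,
                         int(np.ceil(GAP_RANGE_MS[0] / dt - 1e-9)),
                         int(np.floor(GAP_RANGE_MS[1] / dt + 1e-9)))
    event_frames = np.cumsum(gap_frames)
    n_frames = (int(event_frames[-1]) if n_trials else 0) + \
        int(round(post_roll_ms / dt))

    n = config.n_items
    if record_tracks:
        pos_hist = np.empty((n_frames + 1, n, 2))
        bounce_hist = np.zeros((n_frames + 1, n), dtype=bool)
        pos_hist[0] = pos

    events: list[DisplacementEvent] = []
    event_set = {int(f): i for i, f in enumerate(event_frames)}
    for f in range(1, n_frames + 1):
        bounced = _step(pos, vel, dt, config, rng)
        if record_tracks:
            pos_hist[f] = pos
            bounce_hist[f] = bounced
        trial = event_set.get(f)
        if trial is not None:
            ev = _sample_displacement_arrays(
                pos, vel, rng, config, time_ms=f * dt,
                rel_orientation_deg=deck[trial])
            pos[ev.item_id] = ev.post_position
            events.append(ev)

    tracks = None
    if record_tracks:
        frames = np.repeat(np.arange(n_frames + 1), n)
        tracks = pd.DataFrame({
            "frame": frames,
            "time_ms": frames * dt,
            "item_id": np.tile(np.arange(n), n_frames + 1),
            "x": pos_hist[:, :, 0].ravel(),
            "y": pos_hist[:, :, 1].ravel(),
            "bounced": bounce_hist.ravel(),
        })
    return StimulusLog(config=config, displacements=events, seed=seed,
                       item_tracks=tracks, duration_ms=n_frames * dt)
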