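"""Psychophysical-kernel estimation by reverse correlation.

Displacements are expressed in a motion-normalized frame (rotated so the
item's heading is +x, scaled by its speed).  Detected and undetected
densities are estimated on a common grid, their rectified difference is
resampled, and the covariance ellipse of the sampled points — the
psychophysical kernel — is summarized by area, eccentricity, shift and
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import KERNEL_CATEGORIES
from .exceptions import DegenerateKernelError, InsufficientDataError
from .stimulus import DisplacementEvent

GRID_SIZE = 101
GRID_EXTENT = 0.5          # grid spans [-0.5, 0.5]² in normalized units
DEFAULT_N_SAMPLES = 1000
DEFAULT_MIN_TRIALS = 20
CIRCULARITY_AXIS_RATIO = 0.95


@dataclass
class NormalizedDisplacement:
    """Displacement in the motion frame: x along the heading, y across it,
    both in units of (degrees displaced) / (degrees-per-second speed)."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class DensityGrid:
    """Normalized 2D probability mass on a square grid over ±GRID_EXTENT."""

    values: np.ndarray           # [iy, ix], sums to 1
    x_centers: np.ndarray
    y_centers: np.ndarray

    @property
    def cell_size(self) -> float:
        return float(self.x_centers[1] - self.x_centers[0])


@dataclass
class PsychophysicalKernel:
    """Fitted 2D-Gaussian summary of the non-detection density."""

    center: np.ndarray
    covariance: np.ndarray
    area: float
    eccentricity: float
    shift: float
    orientation: float
    n_points: int
    circular: bool = False

    @property
    def along_motion_shift(self) -> float:
        """Signed center projection on the motion axis (diagnostic)."""
        return float(self.center[0])


def normalize_displacement(event: DisplacementEvent,
                           speed: float | None = None,
                           ) -> NormalizedDisplacement:
    """Rotate the displacement into the item's motion frame and scale by
    speed (the item's own pre-displacement speed unless given)."""
    v = np.asarray(event.pre_velocity, dtype=float)
    vnorm = float(np.hypot(*v))
    if vnorm == 0:
        raise ValueError("pre-displacement velocity must be nonzero")
    if speed is None:
        speed = vnorm
    theta = np.arctan2(v[1], v[0])
    d = event.displacement
    c, s = np.cos(-theta), np.sin(-theta)
    return NormalizedDisplacement(
        x=float((c * d[0] - s * d[1]) / speed),
        y=float((s * d[0] + c * d[1]) / speed))


def _as_points(points) -> np.ndarray:
    arr = np.array([
        p.as_array() if isinstance(p, NormalizedDisplacement) else p
        for p in points], dtype=float)
    return arr.reshape(-1, 2)


def _silverman_bandwidths(pts: np.ndarray) -> np.ndarray:
    """Per-axis Silverman bandwidth for a 2D Gaussian product kernel."""
    n = len(pts)
    sd = np.std(pts, axis=0, ddof=1) if n > 1 else np.zeros(2)
    factor = n ** (-1.0 / 6.0)  # d=2: n^(-1/(d+4))
    h = sd * factor
    fallback = 2.0 * GRID_EXTENT / (GRID_SIZE - 1)
    return np.maximum(h, fallback)


def estimate_density(points, grid_size: int = GRID_SIZE,
                     bandwidth: tuple[float, float] | None = None,
                     ) -> DensityGrid:
    """Gaussian KDE of normalized displacements on the common grid.

    Product kernel with per-axis Silverman bandwidths (unless given);
    the grid is normalized to total mass 1.
    """
    pts = _as_points(points)
    if len(pts) == 0:
        raise InsufficientDataError("cannot estimate density of no points")
    h = (np.asarray(bandwidth, dtype=float) if bandwidth is not None
         else _silverman_bandwidths(pts))
    centers = np.linspace(-GRID_EXTENT, GRID_EXTENT, grid_size)
    gx = np.exp(-0.5 * ((centers[:, None] - pts[None, :, 0]) / h[0]) ** 2)
    gy = np.exp(-0.5 * ((centers[:, None] - pts[None, :, 1]) / h[1]) ** 2)
    grid = gy @ gx.T          # [iy, ix]
    total = grid.sum()
    if total == 0:
        raise DegenerateKernelError("all density mass fell outside the grid")
    return DensityGrid(values=grid / total, x_centers=centers,
                       y_centers=centers)


def nondetection_density(detected: DensityGrid,
                         undetected: DensityGrid) -> DensityGrid:
    """Rectified, renormalized difference undetected − detected."""
    if detected.values.shape != undetected.values.shape:
        raise ValueError("density grids have mismatched geometry")
    diff = np.clip(undetected.values - detected.values, 0.0, None)
    total = diff.sum()
    if total == 0:
        raise DegenerateKernelError(
            "detected and undetected densities are identical")
    return DensityGrid(values=diff / total,
                       x_centers=undetected.x_centers.copy(),
                       y_centers=undetected.y_centers.copy())


def _ellipse_properties(center: np.ndarray, cov: np.ndarray
                        ) -> tuple[float, float, float, float, bool]:
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise DegenerateKernelError("sampled covariance is rank-deficient")
    a, b = np.sqrt(evals[1]), np.sqrt(evals[0])   # semi-axes, a >= b
    area = float(np.pi * np.sqrt(np.linalg.det(cov)))
    eccentricity = float(np.sqrt(1.0 - (b / a) ** 2))
    shift = float(np.hypot(*center))
    major = evecs[:, 1]
    orientation = float(np.degrees(np.arctan2(major[1], major[0])))
    if orientation <= -90.0:
        orientation += 180.0
    elif orientation > 90.0:
        orientation -= 180.0
    circular = (b / a) > CIRCULARITY_AXIS_RATIO
    if circular:
        orientation = 0.0
    return area, eccentricity, shift, orientation, circular


def fit_kernel(density: DensityGrid, n_samples: int = DEFAULT_N_SAMPLES,
               seed: int | None = None) -> PsychophysicalKernel:
    """Sample the density and fit the covariance ellipse of the points.

    Cells are drawn proportionally to their mass with uniform jitter inside
    each cell; the kernel center/covariance are the sample mean/covariance.
    """
    rng = np.random.default_rng(seed)
    probs = density.values.ravel()
    idx = rng.choice(probs.size, size=n_samples, p=probs)
    iy, ix = np.unravel_index(idx, density.values.shape)
    cell = density.cell_size
    pts = np.column_stack([
        density.x_centers[ix] + rng.uniform(-cell / 2, cell / 2, n_samples),
        density.y_centers[iy] + rng.uniform(-cell / 2, cell / 2, n_samples)])
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    area, ecc, shift, orient, circular = _ellipse_properties(center, cov)
    return PsychophysicalKernel(center=center, covariance=cov, area=area,
                                eccentricity=ecc, shift=shift,
                                orientation=orient, n_points=n_samples,
                                circular=circular)


def kernel_pipeline(displacements: list[DisplacementEvent],
                    outcomes: pd.DataFrame, category: str,
                    min_trials: int = DEFAULT_MIN_TRIALS,
                    n_samples: int = DEFAULT_N_SAMPLES,
                    grid_size: int = GRID_SIZE,
                    seed: int | None = None,
                    ) -> PsychophysicalKernel | None:
    """normalize → densities → rectified difference → ellipse fit.

    ``category`` selects the detected set; trials categorized "undetected"
    form the non-detection set.  Returns None (skip) when either set has
    fewer than ``min_trials`` trials.
    """
    cats = outcomes.set_index("trial_id")["category"]
    det_ids = cats.index[cats == category]
    und_ids = cats.index[cats == "undetected"]
    if len(det_ids) < min_trials or len(und_ids) < min_trials:
        return None
    det_pts = [normalize_displacement(displacements[i]) for i in det_ids]
    und_pts = [normalize_displacement(displacements[i]) for i in und_ids]
    det_density = estimate_density(det_pts, grid_size)
    und_density = estimate_density(und_pts, grid_size)
    diff = nondetection_density(det_density, und_density)
    kernel = fit_kernel(diff, n_samples=n_samples, seed=seed)
    kernel.n_points = len(det_ids) + len(und_ids)
    return kernel


def kernels_table(displacements, outcomes: pd.DataFrame,
                  subject: str = "s1",
                  categories=KERNEL_CATEGORIES,
                  seed: int | None = None, **kwargs) -> pd.DataFrame:
    """One kernel row per response category (skipping sparse ones)."""
    rows = []
    for k, cat in enumerate(categories):
        cat_seed = None if seed is None else seed + k
        kern = kernel_pipeline(displacements, outcomes, cat, seed=cat_seed,
                               **kwargs)
        if kern is None:
            continue
        rows.append({
            "subject": subject, "category": cat,
            "center_x": kern.center[0], "center_y": kern.center[1],
            "cov_xx": kern.covariance[0, 0], "cov_xy": kern.covariance[0, 1],
            "cov_yy": kern.covariance[1, 1], "area": kern.area,
            "eccentricity": kern.eccentricity, "shift": kern.shift,
            "orientation": kern.orientation, "n_points": kern.n_points})
    return pd.DataFrame(rows, columns=[
        "subject", "category", "center_x", "center_y", "cov_xx", "cov_xy",
        "cov_yy", "area", "eccentricity", "shift", "orientation", "n_points"])
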