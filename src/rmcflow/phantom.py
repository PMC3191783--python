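"""Synthetic test images with analytically known contours.

The generator emulates a dark, smoothly lobed lesion on a light background,
the typical appearance of a skin lesion under epiluminescence microscopy.
The object is star-shaped with radius function

    r(theta) = r0 * (1 + sum_k a_k * cos(k*theta + phi_k)),

so the ground-truth contour is analytic and can be sampled to any density.
Intensities ramp linearly from background to interior over one cell width
(a half-cell antialias), and optional additive Gaussian noise is clipped to
``[0, 1]``.  Identical parameters and seed give bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec


@dataclass(frozen=True)
class BlobShape:
    """Star-shaped object descriptor: base radius plus cosine harmonics.

    ``harmonics`` is a tuple of ``(k, a_k, phi_k)`` triples; the summed
    amplitude must stay below 1 so the radius never vanishes.
    """

    r0: float = 0.3
    center: tuple[float, float] = (0.5, 0.5)
    harmonics: tuple[tuple[int, float, float], ...] = (
        (2, 0.08, 0.5),
        (3, 0.05, 1.1),
        (5, 0.03, 2.3),
    )

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("degenerate shape: base radius must be positive")
        amp = sum(abs(a) for _, a, _ in self.harmonics)
        if amp >= 1:
            raise ValueError("harmonic amplitudes must sum below 1")

    @property
    def max_radius(self) -> float:
        return self.r0 * (1 + sum(abs(a) for _, a, _ in self.harmonics))

    def radius(self, theta) -> np.ndarray:
        r = np.ones_like(np.asarray(theta, dtype=float))
        for k, a, phi in self.harmonics:
            r = r + a * np.cos(k * np.asarray(theta) + phi)
        return self.r0 * r


def circle_shape(radius: float, center=(0.5, 0.5)) -> BlobShape:
    """Convenience: a plain circle (no harmonics)."""
    return BlobShape(r0=radius, center=tuple(center), harmonics=())


@dataclass
class Phantom:
    """Synthetic image plus its analytic ground-truth contour."""

    image: np.ndarray
    truth_contour: np.ndarray  # (K, 2) columns (x, y), closed polyline
    grid: GridSpec
    shape: BlobShape
    noise_sigma: float
    seed: int
    interior: float
    background: float

    @property
    def midlevel(self) -> float:
        """Intensity level halfway between interior and background."""
        return 0.5 * (self.interior + self.background)


def generate_phantom(
    n: int,
    shape: BlobShape | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    interior: float = 0.2,
    background: float = 0.9,
    min_contrast: float = 0.2,
) -> Phantom:
    """Generate an ``n x n`` phantom with known contour.

    Parameters
    ----------
    n : int
        Grid size per side (>= 16); 840 matches the reference test image.
    shape : BlobShape
        Object descriptor; default is a smooth three-harmonic blob.
    noise_sigma : float
        Standard deviation of additive Gaussian noise (clipped to [0, 1]).
    seed : int
        RNG seed; only the noise is random.
    interior, background : float
        Object and background intensities (dark lesion on light ground).
    """
    if n < 16:
        raise ValueError(f"grid size too small: n={n} < 16")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if shape is None:
        shape = BlobShape()
    if abs(background - interior) < min_contrast:
        raise ValueError("interior/background contrast below configured minimum")

    grid = GridSpec(n, n)
    x, y = grid.cell_centers()
    cx, cy = shape.center
    dist = np.hypot(x - cx, y - cy)
    theta = np.arctan2(y - cy, x - cx)
    r_theta = shape.radius(theta)
    if shape.max_radius + cx > 1 or cx - shape.max_radius < 0 or \
            shape.max_radius + cy > 1 or cy - shape.max_radius < 0:
        raise ValueError("object exits the unit square")

    # one-cell linear ramp across the boundary: midlevel sits on r(theta)
    edge_width = max(grid.hx, grid.hy)
    inside_frac = np.clip((r_theta - dist) / edge_width + 0.5, 0.0, 1.0)
    image = background + (interior - background) * inside_frac
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    # sample the analytic contour with vertex spacing below one cell
    h = min(grid.hx, grid.hy)
    n_theta = max(64, int(np.ceil(2 * np.pi * shape.max_radius / (0.5 * h))))
    th = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    r = shape.radius(th)
    contour = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])

    return Phantom(
        image=image,
        truth_contour=contour,
        grid=grid,
        shape=shape,
        noise_sigma=noise_sigma,
        seed=seed,
        interior=interior,
        background=background,
    )


def make_seed_function(
    grid: GridSpec, center: tuple[float, float], radius: float
) -> np.ndarray:
    """Initial segmentation function: a smooth bump on a disk.

    ``u0(x) = cos^2(pi * d / (2 * radius))`` for ``d < radius`` and zero
    outside, where ``d`` is the distance to ``center``.  Peak value 1 at the
    center, identically zero on the domain boundary, compatible with the
    homogeneous Dirichlet condition.  The disk must lie strictly inside the
    domain.
    """
    cx, cy = center
    if radius <= 0:
        raise ValueError("seed radius must be positive")
    if (cx - radius <= 0 or cx + radius >= 1
            or cy - radius <= 0 or cy + radius >= grid.height):
        raise ValueError("seed disk must lie strictly inside the domain")
    x, y = grid.cell_centers()
    d = np.hypot(x - cx, y - cy)
    u0 = np.where(d < radius, np.cos(np.pi * d / (2 * radius)) ** 2, 0.0)
    u0[0, :] = u0[-1, :] = 0.0
    u0[:, 0] = u0[:, -1] = 0.0
    return u0
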