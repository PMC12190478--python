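"""Visual-field sampling and aperture-vignetted grating stimuli.

The simulated visual field is a square pixel lattice spanning the central
120 deg of visual space.  Stimuli are static sinusoidal luminance gratings
(contrast in [-1, 1] around a gray background at 0) restricted by
hard-edged apertures: the vignetting of a grating by an aperture edge is
the physical effect the downstream population model is built to probe.

Orientation convention: ``theta_c = 0`` is a horizontal grating (stripes
along x), angles increase counterclockwise in a y-up Cartesian frame, and
orientations are treated modulo 180 deg.  Internally the carrier wave
vector points at ``theta_c + 90`` deg, so grating orientation aligns with
the polar angle of its spectral energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "FieldGrid",
    "GratingSpec",
    "ApertureSpec",
    "APERTURE_SHAPES",
    "make_grid",
    "render_grating",
    "aperture_mask",
    "aperture_signed_distance",
    "render_stimulus",
    "make_stimulus_set",
    "DEFAULT_ORIENTATIONS",
    "DEFAULT_PHASES",
]

#: The 12 grating orientations used to probe orientation selectivity (deg).
DEFAULT_ORIENTATIONS: tuple[float, ...] = tuple(float(t) for t in range(0, 180, 15))

#: The 4 grating phases averaged over to suppress phase-dependent responses (deg).
DEFAULT_PHASES: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)

APERTURE_SHAPES = (
    "circle",
    "square",
    "diamond",
    "half_circle_horizontal_edge",
    "half_circle_vertical_edge",
    "none",
)


@dataclass(frozen=True)
class FieldGrid:
    """Square pixel lattice over the visual field.

    Pixel centers span ``[-half_extent, half_extent)`` with a half-open
    convention: 200 pixels over +/-60 deg gives a step of 0.6 deg/px and a
    Nyquist frequency of 0.8333 cycles/deg, comfortably above every
    stimulus and receptive-field frequency used here.
    """

    half_extent: float = 60.0
    n_pixels: int = 200
    pixel_centers: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.half_extent <= 0:
            raise ValueError("half_extent must be positive")
        if self.n_pixels < 2:
            raise ValueError("n_pixels must be at least 2")
        centers = -self.half_extent + self.pixel_size * np.arange(self.n_pixels)
        object.__setattr__(self, "pixel_centers", centers)

    @property
    def pixel_size(self) -> float:
        """Degrees per pixel."""
        return 2.0 * self.half_extent / self.n_pixels

    @property
    def nyquist(self) -> float:
        """Highest representable spatial frequency, cycles/deg."""
        return 1.0 / (2.0 * self.pixel_size)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays in degrees, indexed [y, x], y-up."""
        return np.meshgrid(self.pixel_centers, self.pixel_centers)


def make_grid(half_extent: float = 60.0, n_pixels: int = 200) -> FieldGrid:
    """Build the pixel sampling of visual space."""
    return FieldGrid(half_extent=float(half_extent), n_pixels=int(n_pixels))


@dataclass(frozen=True)
class GratingSpec:
    """Static sinusoidal grating: orientation (deg), spatial frequency
    (cycles/deg), phase (deg), contrast fraction."""

    theta_c: float
    sf: float
    phase: float = 0.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.sf <= 0:
            raise ValueError("spatial frequency must be positive")

    @property
    def theta_g(self) -> float:
        """Carrier (wave-vector) direction in radians.

        ``theta_c + 90`` keeps the stripes of a ``theta_c``-oriented
        grating at polar angle ``theta_c`` (counterclockwise, y-up): the
        energy of a horizontal grating sits on the vertical frequency
        axis.  (In a row-down image convention the same geometry carries
        an overall minus sign; only the y-up form is used here.)
        """
        return np.pi * (self.theta_c + 90.0) / 180.0


@dataclass(frozen=True)
class ApertureSpec:
    """Hard-boundary aperture.

    ``size`` is the radius for circle / half-circle shapes and the side
    length for square / diamond (the diamond is the square rotated 45 deg).
    Half-circle variants mask one half of the circle: the
    ``horizontal_edge`` condition masks the bottom half (leaving a
    horizontal straight edge through the center), the ``vertical_edge``
    condition masks the left half.
    """

    shape: str = "circle"
    size: float = 30.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape not in APERTURE_SHAPES:
            raise ValueError(
                f"unknown aperture shape {self.shape!r}; expected one of {APERTURE_SHAPES}"
            )
        if self.shape != "none" and self.size <= 0:
            raise ValueError("aperture size must be positive")


def render_grating(grid: FieldGrid, spec: GratingSpec) -> np.ndarray:
    """Render the full-field grating: ``contrast * cos(2 pi v (cos(tg) x + sin(tg) y) + phase)``."""
    X, Y = grid.mesh()
    tg = spec.theta_g
    phase = np.deg2rad(spec.phase)
    arg = 2.0 * np.pi * spec.sf * (np.cos(tg) * X + np.sin(tg) * Y) + phase
    return spec.contrast * np.cos(arg)


def aperture_signed_distance(spec: ApertureSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed distance (deg) to the aperture boundary: positive inside.

    For the square/diamond this is the Chebyshev distance in the (rotated)
    frame, which equals the perpendicular distance to the nearest side
    everywhere inside. ``none`` returns +inf (everything inside).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx, cy = spec.center
    dx, dy = x - cx, y - cy
    if spec.shape == "none":
        return np.full(np.broadcast(dx, dy).shape, np.inf)
    if spec.shape == "circle":
        return spec.size - np.hypot(dx, dy)
    if spec.shape == "square":
        return spec.size / 2.0 - np.maximum(np.abs(dx), np.abs(dy))
    if spec.shape == "diamond":
        s = np.sqrt(0.5)
        u, v = s * (dx + dy), s * (dy - dx)
        return spec.size / 2.0 - np.maximum(np.abs(u), np.abs(v))
    if spec.shape == "half_circle_horizontal_edge":
        # bottom half masked: kept region y > cy within the circle
        return np.minimum(spec.size - np.hypot(dx, dy), dy)
    if spec.shape == "half_circle_vertical_edge":
        # left half masked: kept region x > cx within the circle
        return np.minimum(spec.size - np.hypot(dx, dy), dx)
    raise ValueError(f"unknown aperture shape {spec.shape!r}")


def aperture_mask(grid: FieldGrid, spec: ApertureSpec) -> np.ndarray:
    """Binary mask: 1 where the pixel center lies strictly inside the aperture."""
    X, Y = grid.mesh()
    return (aperture_signed_distance(spec, X, Y) > 0).astype(float)


def render_stimulus(grid: FieldGrid, grating: GratingSpec, aperture: ApertureSpec) -> np.ndarray:
    """Aperture-vignetted grating; background (masked) pixels are exactly 0."""
    return render_grating(grid, grating) * aperture_mask(grid, aperture)


def make_stimulus_set(
    grid: FieldGrid,
    sf: float,
    aperture: ApertureSpec,
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS,
    phases: tuple[float, ...] = DEFAULT_PHASES,
    contrast: float = 1.0,
) -> xr.DataArray:
    """Render the orientation x phase stimulus battery for one aperture.

    Returns a DataArray with dims ``(orientation, phase, y, x)``; the mask
    is applied once and broadcast over all gratings.
    """
    mask = aperture_mask(grid, aperture)
    images = np.empty(
        (len(orientations), len(phases), grid.n_pixels, grid.n_pixels), dtype=float
    )
    for i, theta in enumerate(orientations):
        for j, ph in enumerate(phases):
            g = GratingSpec(theta_c=theta, sf=sf, phase=ph, contrast=contrast)
            images[i, j] = render_grating(grid, g)
    images *= mask
    return xr.DataArray(
        images,
        dims=("orientation", "phase", "y", "x"),
        coords={
            "orientation": list(orientations),
            "phase": list(phases),
            "y": grid.pixel_centers,
            "x": grid.pixel_centers,
        },
        attrs={
            "sf": sf,
            "aperture_shape": aperture.shape,
            "aperture_size": aperture.size if aperture.shape != "none" else np.nan,
            "aperture_center_x": aperture.center[0],
            "aperture_center_y": aperture.center[1],
            "contrast": contrast,
        },
        name="stimuli",
    )


def stimulus_manifest(stimuli: xr.DataArray) -> pd.DataFrame:
    """Tabular manifest of a stimulus set (one row per rendered image)."""
    rows = []
    for theta in stimuli.orientation.values:
        for ph in stimuli.phase.values:
            rows.append(
                {
                    "orientation_deg": float(theta),
                    "phase_deg": float(ph),
                    "sf_cpd": stimuli.attrs["sf"],
                    "aperture_shape": stimuli.attrs["aperture_shape"],
                    "aperture_size_deg": stimuli.attrs["aperture_size"],
                }
            )
    return pd.DataFrame(rows)
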