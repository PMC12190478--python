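"""Anatomical (mm) to visual (deg) coordinate mapping and response sampling.

The superficial colliculus surface is related to the visual field by a
smooth, roughly 90-deg-clockwise rotation with spatial warping.  The
transform is learned from a small set of paired control points by
scattered-data interpolation (two scalar interpolants, one per visual
coordinate), exact at the control points and continuous inside their
convex hull; anatomical samples outside the hull are flagged and excluded
from maps rather than extrapolated.

Because measured control points are study-specific, a synthetic generator
provides a realistic stand-in: a jittered 3x3 grid plus center point in
the +/-0.83 mm anatomical window, mapped by a 90-deg clockwise rotation,
an mm-to-deg scaling into the +/-40 deg visual window, and an optional
smooth low-order polynomial warp.  Measured points can be supplied via
CSV with columns (anat_x_mm, anat_y_mm, vis_x_deg, vis_y_deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import CloughTocher2DInterpolator, LinearNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "ControlPointSet",
    "RetinotopyTransform",
    "AnatGrid",
    "ANAT_HALF_EXTENT_MM",
    "VISUAL_HALF_EXTENT_DEG",
    "synth_control_points",
    "similarity_transform",
    "fit_transform",
    "anat_to_visual",
    "sample_responses",
]

ANAT_HALF_EXTENT_MM = 0.83
VISUAL_HALF_EXTENT_DEG = 40.0
#: deg of visual space per mm of tissue under the synthetic similarity map
MM_TO_DEG = VISUAL_HALF_EXTENT_DEG / ANAT_HALF_EXTENT_MM


@dataclass(frozen=True)
class ControlPointSet:
    """Paired anatomical features (mm) and visual targets (deg)."""

    anat: np.ndarray  # (n, 2) mm
    visual: np.ndarray  # (n, 2) deg

    def __post_init__(self) -> None:
        anat = np.atleast_2d(np.asarray(self.anat, dtype=float))
        visual = np.atleast_2d(np.asarray(self.visual, dtype=float))
        if anat.shape != visual.shape or anat.shape[1] != 2:
            raise ValueError("anat and visual must both be (n, 2)")
        if anat.shape[0] < 3:
            raise ValueError("at least 3 control points required")
        if len(np.unique(anat.round(12), axis=0)) != len(anat):
            raise ValueError("duplicate anatomical control points")
        object.__setattr__(self, "anat", anat)
        object.__setattr__(self, "visual", visual)

    @property
    def n(self) -> int:
        return self.anat.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anat_x_mm": self.anat[:, 0],
                "anat_y_mm": self.anat[:, 1],
                "vis_x_deg": self.visual[:, 0],
                "vis_y_deg": self.visual[:, 1],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ControlPointSet":
        return cls(
            anat=df[["anat_x_mm", "anat_y_mm"]].to_numpy(),
            visual=df[["vis_x_deg", "vis_y_deg"]].to_numpy(),
        )


@dataclass(frozen=True)
class AnatGrid:
    """Evenly spaced anatomical sampling grid (241 x 241 = 58,081 samples)."""

    half_extent: float = ANAT_HALF_EXTENT_MM
    n_per_axis: int = 241

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(-self.half_extent, self.half_extent, self.n_per_axis)

    @property
    def step(self) -> float:
        return 2.0 * self.half_extent / (self.n_per_axis - 1)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.axis, self.axis)

    def coords(self) -> np.ndarray:
        """(n_samples, 2) anatomical coordinates, row-major over (y, x)."""
        X, Y = self.mesh()
        return np.column_stack([X.ravel(), Y.ravel()])


def similarity_transform(anat: np.ndarray) -> np.ndarray:
    """The generating 90-deg clockwise rotation + mm-to-deg scaling:
    (x, y) mm -> (y, -x) * MM_TO_DEG deg."""
    anat = np.atleast_2d(np.asarray(anat, dtype=float))
    return np.column_stack([anat[:, 1], -anat[:, 0]]) * MM_TO_DEG


def _poly_warp(anat: np.ndarray, warp_amplitude: float) -> np.ndarray:
    """Smooth low-order warp, bounded by warp_amplitude * visual half-width."""
    xn = anat[:, 0] / ANAT_HALF_EXTENT_MM
    yn = anat[:, 1] / ANAT_HALF_EXTENT_MM
    scale = warp_amplitude * VISUAL_HALF_EXTENT_DEG
    return np.column_stack([scale * xn * yn, 0.5 * scale * (xn**2 - yn**2)])


def synth_control_points(seed: int = 0, warp_amplitude: float = 0.1) -> ControlPointSet:
    """Generate 10 paired control points emulating the measured retinotopy.

    Anatomical features: a jittered 3x3 grid plus a jittered center point
    (grid coverage keeps large apertures inside the interpolation hull).
    Visual targets: similarity transform plus the polynomial warp; with
    ``warp_amplitude = 0`` the targets are an exact rotation + scaling.
    Degenerate (collinear / duplicate) draws are re-sampled from a fresh
    substream.
    """
    if warp_amplitude < 0:
        raise ValueError("warp_amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        g = 0.72 * ANAT_HALF_EXTENT_MM
        gx, gy = np.meshgrid([-g, 0.0, g], [-g, 0.0, g])
        anat = np.column_stack([gx.ravel(), gy.ravel()])
        anat = np.vstack([anat, [0.25 * g, -0.2 * g]])
        anat = anat + rng.uniform(-0.06, 0.06, size=anat.shape)
        anat = np.clip(anat, -ANAT_HALF_EXTENT_MM, ANAT_HALF_EXTENT_MM)
        try:
            visual = similarity_transform(anat)
            if warp_amplitude > 0:
                visual = visual + _poly_warp(anat, warp_amplitude)
            pts = ControlPointSet(anat=anat, visual=visual)
            fit_transform(pts)  # raises on collinear/degenerate geometry
            return pts
        except (ValueError, QhullError):
            continue
    raise RuntimeError("could not draw a non-degenerate control-point set")


@dataclass(frozen=True)
class RetinotopyTransform:
    """Two scattered-data interpolants: anatomical (x, y) -> visual x or y."""

    points: ControlPointSet
    method: str = "clough_tocher"
    _fx: object = field(init=False, repr=False, compare=False)
    _fy: object = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        interp = {
            "clough_tocher": CloughTocher2DInterpolator,
            "linear": LinearNDInterpolator,
        }
        if self.method not in interp:
            raise ValueError(f"unknown interpolation method {self.method!r}")
        cls = interp[self.method]
        try:
            fx = cls(self.points.anat, self.points.visual[:, 0])
            fy = cls(self.points.anat, self.points.visual[:, 1])
        except QhullError as err:
            raise ValueError(f"degenerate control-point geometry: {err}") from err
        object.__setattr__(self, "_fx", fx)
        object.__setattr__(self, "_fy", fy)

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return np.column_stack([self._fx(coords), self._fy(coords)])


def fit_transform(points: ControlPointSet, method: str = "clough_tocher") -> RetinotopyTransform:
    """Fit the anatomical-to-visual transform (exact at control points)."""
    return RetinotopyTransform(points=points, method=method)


def anat_to_visual(
    t: RetinotopyTransform, coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map anatomical mm pairs to visual deg pairs.

    Returns ``(visual, in_hull)``; points outside the control-point hull
    get NaN coordinates and ``in_hull = False`` (a flag, not an error).
    """
    visual = t(coords)
    in_hull = np.isfinite(visual).all(axis=1)
    return visual, in_hull


def sample_responses(
    visual_coords: np.ndarray,
    lattice_axis: np.ndarray,
    tensor: xr.DataArray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a phase-averaged response tensor at arbitrary visual coordinates.

    Bilinear interpolation within the enclosing lattice cell realizes the
    distance-weighted average of the 4 surrounding lattice nodes (and is
    exact for linear response fields).  Coordinates outside the lattice
    are excluded (NaN responses, ``valid = False``); NaN coordinates (e.g.
    out-of-hull anatomical samples) are likewise excluded.

    For V1-like tensors (with an ``rf_orientation`` dim) interpolation is
    performed per RF orientation and then one random RF orientation is
    selected per coordinate; ``rng`` must then be provided.

    Returns ``(responses, valid)`` with responses shaped
    ``(n_orientations, n_coords)``.
    """
    coords = np.atleast_2d(np.asarray(visual_coords, dtype=float))
    if coords.shape[1] != 2:
        raise ValueError("visual_coords must be (n, 2)")
    if np.isinf(coords).any():
        raise ValueError("infinite coordinates rejected")
    finite = np.isfinite(coords).all(axis=1)  # NaN marks out-of-hull: excluded
    ax = np.asarray(lattice_axis, dtype=float)
    lo, hi = ax[0], ax[-1]
    inside = finite.copy()
    inside[finite] &= (
        (coords[finite, 0] >= lo)
        & (coords[finite, 0] <= hi)
        & (coords[finite, 1] >= lo)
        & (coords[finite, 1] <= hi)
    )

    has_rf_orient = "rf_orientation" in tensor.dims
    n_or = tensor.sizes["orientation"]
    n_pts = coords.shape[0]
    out = np.full((n_or, n_pts), np.nan)
    if inside.any():
        xq = coords[inside, 0]
        yq = coords[inside, 1]
        # enclosing-cell indices and fractional offsets
        ix = np.clip(np.searchsorted(ax, xq, side="right") - 1, 0, ax.size - 2)
        iy = np.clip(np.searchsorted(ax, yq, side="right") - 1, 0, ax.size - 2)
        step = ax[1] - ax[0]
        fx = (xq - ax[ix]) / step
        fy = (yq - ax[iy]) / step
        w00 = (1 - fy) * (1 - fx)
        w01 = (1 - fy) * fx
        w10 = fy * (1 - fx)
        w11 = fy * fx

        def bilinear(vals: np.ndarray) -> np.ndarray:
            # vals: (n_or, ny, nx) -> (n_or, n_inside)
            return (
                vals[:, iy, ix] * w00
                + vals[:, iy, ix + 1] * w01
                + vals[:, iy + 1, ix] * w10
                + vals[:, iy + 1, ix + 1] * w11
            )

        if has_rf_orient:
            if rng is None:
                raise ValueError("rng required to pick random RF orientations")
            vals = tensor.transpose("orientation", "loc_y", "loc_x", "rf_orientation").values
            n_rf = vals.shape[-1]
            per_orient = np.stack(
                [bilinear(vals[..., k]) for k in range(n_rf)], axis=-1
            )  # (n_or, n_inside, n_rf)
            pick = rng.integers(0, n_rf, size=per_orient.shape[1])
            out[:, inside] = np.take_along_axis(
                per_orient, pick[None, :, None], axis=2
            )[..., 0]
        else:
            vals = tensor.transpose("orientation", "loc_y", "loc_x").values
            out[:, inside] = bilinear(vals)
    return out, inside
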