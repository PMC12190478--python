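"""Population pooling, orientation-preference maps and selectivity summaries.

Population responses emulate widefield imaging pixels: single-unit
responses sampled on the anatomical grid are blurred with a small
Gaussian kernel (default sd 0.0083 mm, ~0.44 deg of visual space) so each
sample pools roughly a 4x4 to 5x5 patch of underlying units.  Orientation
preference and selectivity use doubled-angle circular statistics over the
stimulus orientation set:

    z = sum_theta R(theta) exp(2 i theta)
    gOSI = |z| / sum_theta R(theta)        preferred = arg(z) / 2  mod 180

gOSI is 0 for untuned responses and 1 for a response concentrated at one
orientation; because the stimulus orientations are evenly spaced, adding a
baseline to all responses leaves the preferred orientation unchanged and
only shrinks gOSI.  The radial-alignment score summarizes a map against
the vignetting prediction: +1 when preferences along the aperture edge
are radial (orthogonal to the edge, i.e. pointing at the stimulus
center), -1 when anti-radial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

from .field_stimuli import ApertureSpec, aperture_signed_distance

__all__ = [
    "OrientationMap",
    "VonMisesFit",
    "smooth_population",
    "gosi",
    "preferred_orientation",
    "normalize_gosi_map",
    "fit_von_mises",
    "von_mises",
    "radial_alignment_score",
    "edge_band_mask",
    "edge_normal_direction",
    "interior_mask",
    "build_orientation_map",
]


@dataclass(frozen=True)
class OrientationMap:
    """Per-anatomical-sample orientation preference and selectivity.

    All arrays share one flat shape (one entry per anatomical sample).
    ``pref_deg`` in [0, 180) and ``gosi_raw`` in [0, 1] are NaN where
    ``valid`` is False (out-of-hull, out-of-lattice, or zero response);
    ``gosi_display`` is the per-condition min-max normalized gOSI used as
    transparency/threshold in rendered maps.
    """

    anat: np.ndarray  # (n, 2) mm
    visual: np.ndarray  # (n, 2) deg (NaN outside hull)
    pref_deg: np.ndarray
    gosi_raw: np.ndarray
    valid: np.ndarray
    gosi_display: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.anat.shape[0]

    def to_frame(self) -> pd.DataFrame:
        disp = self.gosi_display if self.gosi_display is not None else np.full(self.n, np.nan)
        return pd.DataFrame(
            {
                "anat_x_mm": self.anat[:, 0],
                "anat_y_mm": self.anat[:, 1],
                "vis_x_deg": self.visual[:, 0],
                "vis_y_deg": self.visual[:, 1],
                "pref_deg": self.pref_deg,
                "gosi_raw": self.gosi_raw,
                "gosi_display": disp,
                "valid": self.valid,
            }
        )


def smooth_population(
    responses: np.ndarray,
    kernel_sd_mm: float = 0.0083,
    step_mm: float = 2 * 0.83 / 240,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-smooth per-condition responses on the anatomical grid.

    ``responses`` is (..., ny, nx); invalid samples are excluded and the
    kernel renormalized over valid neighbors (no zero-padding dimming at
    map borders).  Smoothing preserves constants and, for interior
    deltas, total mass.
    """
    if kernel_sd_mm < step_mm / 10.0:
        warnings.warn("smoothing kernel is much smaller than the grid step (near-identity)")
    sigma_px = kernel_sd_mm / step_mm
    resp = np.asarray(responses, dtype=float)
    if valid is None:
        valid = np.isfinite(resp).all(axis=tuple(range(resp.ndim - 2)))
    v = valid.astype(float)
    filled = np.where(valid, resp, 0.0)
    out = np.empty_like(resp)
    denom = gaussian_filter(v, sigma_px, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        for idx in np.ndindex(resp.shape[:-2]):
            num = gaussian_filter(filled[idx], sigma_px, mode="constant")
            out[idx] = np.where(valid, num / denom, np.nan)
    return out


def _doubled_angle_sum(resp: np.ndarray, orientations_deg: np.ndarray) -> np.ndarray:
    theta = 2.0 * np.deg2rad(np.asarray(orientations_deg, dtype=float))
    phasors = np.exp(1j * theta)
    return np.tensordot(phasors, resp, axes=([0], [0]))


def gosi(resp: np.ndarray, orientations_deg: np.ndarray) -> np.ndarray:
    """Global orientation selectivity index |sum R e^{2i theta}| / sum R.

    ``resp`` has the orientation axis first; all responses must be
    non-negative.  All-zero response vectors yield NaN (undefined).
    """
    resp = np.asarray(resp, dtype=float)
    if (resp < 0).any():
        raise ValueError("gOSI requires non-negative responses")
    total = resp.sum(axis=0)
    z = _doubled_angle_sum(resp, orientations_deg)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.abs(z) / total
    return np.where(total > 0, out, np.nan)


def preferred_orientation(resp: np.ndarray, orientations_deg: np.ndarray) -> np.ndarray:
    """Doubled-angle circular-mean preferred orientation, deg in [0, 180).

    Undefined (NaN) for all-zero responses and for balanced ties where the
    doubled-angle vector sum vanishes.
    """
    resp = np.asarray(resp, dtype=float)
    total = resp.sum(axis=0)
    z = _doubled_angle_sum(resp, orientations_deg)
    pref = np.mod(np.rad2deg(np.angle(z)) / 2.0, 180.0)
    defined = (total > 0) & (np.abs(z) > 1e-12 * np.maximum(total, 1e-300))
    return np.where(defined, pref, np.nan)


def normalize_gosi_map(m: OrientationMap) -> OrientationMap:
    """Min-max normalize gOSI over valid samples (display/threshold only)."""
    vals = m.gosi_raw[m.valid]
    if vals.size == 0:
        raise ValueError("no valid samples to normalize")
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    if hi == lo:
        raise ValueError("constant gOSI field cannot be display-scaled")
    disp = (m.gosi_raw - lo) / (hi - lo)
    return replace(m, gosi_display=np.where(m.valid, disp, np.nan))


@dataclass(frozen=True)
class VonMisesFit:
    """Circular von Mises tuning fit on doubled angles:
    R(theta) = baseline + amplitude * exp(kappa * (cos(2(theta - mu)) - 1))."""

    amplitude: float
    kappa: float
    mu_deg: float
    baseline: float

    def __call__(self, theta_deg: np.ndarray) -> np.ndarray:
        return von_mises(np.asarray(theta_deg, dtype=float), self.amplitude, self.kappa,
                         self.mu_deg, self.baseline)

    def curve_0_360(self, n: int = 360) -> tuple[np.ndarray, np.ndarray]:
        """Tuning curve over [0, 360) by duplication, for polar display."""
        theta = np.linspace(0.0, 360.0, n, endpoint=False)
        return theta, self(np.mod(theta, 180.0))


def von_mises(theta_deg, amplitude, kappa, mu_deg, baseline):
    d = np.deg2rad(2.0 * (theta_deg - mu_deg))
    return baseline + amplitude * np.exp(kappa * (np.cos(d) - 1.0))


def fit_von_mises(resp: np.ndarray, orientations_deg: np.ndarray | None = None) -> VonMisesFit:
    """Least-squares von Mises fit to orientation-tuning responses.

    Defaults to 36 evenly spaced orientations over [0, 180).  Initial
    values come from the circular-mean preference and the response range;
    non-convergence raises with diagnostics.
    """
    resp = np.asarray(resp, dtype=float)
    if orientations_deg is None:
        orientations_deg = np.arange(resp.size) * 180.0 / resp.size
    theta = np.asarray(orientations_deg, dtype=float)
    if resp.ndim != 1 or resp.size != theta.size:
        raise ValueError("resp and orientations must be 1-D and equal length")
    if (resp < 0).any():
        raise ValueError("von Mises fit expects non-negative responses")
    lo, hi = float(resp.min()), float(resp.max())
    if hi == lo:
        return VonMisesFit(amplitude=0.0, kappa=0.0, mu_deg=0.0, baseline=lo)
    mu0 = preferred_orientation(resp, theta)
    mu0 = float(mu0) if np.isfinite(mu0) else float(theta[int(np.argmax(resp))])
    p0 = [hi - lo, 2.0, mu0, lo]
    try:
        popt, _ = curve_fit(
            von_mises,
            theta,
            resp,
            p0=p0,
            bounds=([0.0, 0.0, -360.0, -np.inf], [np.inf, 500.0, 540.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"von Mises fit failed to converge (p0={p0}, range=[{lo}, {hi}]): {err}"
        ) from err
    amp, kappa, mu, base = popt
    return VonMisesFit(amplitude=float(amp), kappa=float(kappa),
                       mu_deg=float(np.mod(mu, 180.0)), baseline=float(base))


def edge_band_mask(
    m: OrientationMap,
    aperture: ApertureSpec,
    inner: float = -2.0,
    outer: float = 2.0,
) -> np.ndarray:
    """Valid samples within a signed-distance band of the aperture boundary.

    ``inner``/``outer`` bound the signed distance (positive inside), so
    the default (-2, 2) is a symmetric 2-deg strip around the boundary.
    For center-surround RFs the scientifically meaningful edge zone is the
    inward annulus ``(sigma_center, sigma_surround)``: units whose
    excitatory center lies inside the stimulus while the suppressive
    surround still overlaps the edge — these are the units whose tuning
    is edge-dominated.  Units with the center itself on the boundary
    behave instead like detectors of the vignette stripe parallel to the
    edge, and units deeper inside see an effectively full-field grating.
    """
    d = aperture_signed_distance(aperture, m.visual[:, 0], m.visual[:, 1])
    return m.valid & np.isfinite(d) & (d >= inner) & (d <= outer)


def edge_normal_direction(
    aperture: ApertureSpec, x: np.ndarray, y: np.ndarray, eps: float = 1e-4
) -> np.ndarray:
    """Orientation (deg, mod 180) of the outward normal of the nearest
    aperture edge — the local 'radial' direction.  For circles this equals
    the polar angle about the aperture center; for squares and diamonds it
    is the perpendicular of the nearest side."""
    dx = (
        aperture_signed_distance(aperture, x + eps, y)
        - aperture_signed_distance(aperture, x - eps, y)
    ) / (2 * eps)
    dy = (
        aperture_signed_distance(aperture, x, y + eps)
        - aperture_signed_distance(aperture, x, y - eps)
    ) / (2 * eps)
    return np.rad2deg(np.arctan2(-dy, -dx))


def interior_mask(
    m: OrientationMap, aperture: ApertureSpec, depth: float = 10.0
) -> np.ndarray:
    """Valid samples mapping well inside the aperture (>= depth deg from the edge)."""
    d = aperture_signed_distance(aperture, m.visual[:, 0], m.visual[:, 1])
    return m.valid & np.isfinite(d) & (d >= depth)


def radial_alignment_score(
    m: OrientationMap,
    stim_center: tuple[float, float] = (0.0, 0.0),
    band: np.ndarray | None = None,
    aperture: ApertureSpec | None = None,
    inner: float = -2.0,
    outer: float = 2.0,
    direction: str = "edge_normal",
    weight_by_gosi: bool = True,
) -> float:
    """Alignment of preferred orientations with the local radial direction
    over an aperture-edge band: mean of cos(2 (pref - radial_direction)).

    +1 means perfectly radial (edge-orthogonal) preferences, -1 perfectly
    anti-radial (edge-parallel), 0 the random-preference null.

    ``direction="edge_normal"`` (default) measures against the outward
    normal of the nearest edge — identical to the polar angle about
    ``stim_center`` for centered circles, and the correct notion of
    "orthogonal to the edge" for squares and diamonds.
    ``direction="center"`` uses atan2(y - yc, x - xc) regardless of shape.

    ``weight_by_gosi`` weights each sample by its raw gOSI, mirroring the
    selectivity-transparency weighting with which preference maps are
    read: weakly tuned samples carry proportionally little evidence about
    map organization.  Pass either an explicit boolean ``band`` over
    samples or an ``aperture`` (with ``inner``/``outer``) from which the
    band is derived; an aperture is required for edge-normal directions.
    """
    if band is None:
        if aperture is None:
            raise ValueError("provide either band or aperture")
        band = edge_band_mask(m, aperture, inner, outer)
    band = band & m.valid & np.isfinite(m.pref_deg)
    if not band.any():
        raise ValueError("empty edge band")
    x, y = m.visual[band, 0], m.visual[band, 1]
    if direction == "edge_normal":
        if aperture is None:
            raise ValueError("edge-normal direction requires the aperture")
        radial = edge_normal_direction(aperture, x, y)
    elif direction == "center":
        radial = np.rad2deg(np.arctan2(y - stim_center[1], x - stim_center[0]))
    else:
        raise ValueError("direction must be 'edge_normal' or 'center'")
    c = np.cos(np.deg2rad(2.0 * (m.pref_deg[band] - radial)))
    if weight_by_gosi:
        w = m.gosi_raw[band]
        total = float(np.sum(w))
        if total <= 0:
            raise ValueError("all-zero gOSI weights in the band")
        return float(np.sum(w * c) / total)
    return float(np.mean(c))


def build_orientation_map(
    responses: np.ndarray,
    orientations_deg: np.ndarray,
    anat: np.ndarray,
    visual: np.ndarray,
    valid: np.ndarray,
    baseline: float = 0.0,
) -> OrientationMap:
    """Assemble an OrientationMap from per-sample orientation responses.

    ``responses`` is (n_orientations, n_samples); a known baseline (the
    noise model's beta) is subtracted and responses floored at zero before
    the circular statistics, since gOSI is defined on non-negative
    stimulus-driven responses.
    """
    resp = np.maximum(np.asarray(responses, dtype=float) - baseline, 0.0)
    resp = np.where(valid[None, :], resp, 0.0)
    with np.errstate(invalid="ignore"):
        pref = preferred_orientation(resp, orientations_deg)
        g = gosi(resp, orientations_deg)
    ok = valid & np.isfinite(pref) & np.isfinite(g)
    return OrientationMap(
        anat=np.asarray(anat, dtype=float),
        visual=np.asarray(visual, dtype=float),
        pref_deg=np.where(ok, pref, np.nan),
        gosi_raw=np.where(ok, g, np.nan),
        valid=ok,
    )
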