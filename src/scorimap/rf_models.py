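"""Receptive-field models: center-surround (difference-of-Gaussians) and
V1-like (Gabor) spatial RFs, plus their spectral properties.

The center-surround RF is

    f(x, y) = G(r; sigma_center) - w_s * G(r; sigma_surround)

with unit-peak Gaussians ``G(r; s) = exp(-r^2 / (2 s^2))`` and surround
weight ``w_s = cs_ratio * sigma_center^2 / sigma_surround^2`` so that the
surround-to-center VOLUME ratio equals ``cs_ratio``.  This RF is bandpass:
its amplitude spectrum is itself a difference of Gaussians with peak
(preferred) spatial frequency

    f* = sqrt( ln(cs_ratio * ss^2 / sc^2) / (2 pi^2 (ss^2 - sc^2)) )

which evaluates to 0.08 cycles/deg for (sc, ss, cs) = (0.8, 4.7, 0.4) and
0.04 cycles/deg for (1.5, 11.4, 0.8) - the two parameterizations the
simulations are built around.

The V1-like RF multiplies a sinusoidal carrier at the RF's preferred
frequency and orientation with an elongated Gaussian envelope whose major
axis runs parallel to the carrier stripes; 0/90 deg carrier-phase pairs
support phase-invariant (energy) responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_stimuli import FieldGrid, GratingSpec

__all__ = [
    "DoGParams",
    "GaborParams",
    "make_dog",
    "dog_spectrum_closed_form",
    "dog_preferred_sf_closed_form",
    "dog_preferred_sf",
    "make_gabor",
    "spectral_overlap",
    "spectral_overlap_map",
]


@dataclass(frozen=True)
class DoGParams:
    """Center-surround RF parameters.

    ``cs_ratio`` is the surround-to-center volume ratio; ``cs_ratio = 0``
    denotes a pure Gaussian (no surround, lowpass).  ``polarity`` +1 is
    On-center, -1 the mirrored Off-center partner.
    """

    center: tuple[float, float] = (0.0, 0.0)
    sigma_center: float = 0.8
    sigma_surround: float = 4.7
    cs_ratio: float = 0.4
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.cs_ratio < 0:
            raise ValueError("cs_ratio must be non-negative")
        if self.sigma_center <= 0:
            raise ValueError("sigma_center must be positive")
        if self.cs_ratio > 0 and self.sigma_surround <= self.sigma_center:
            raise ValueError("sigma_surround must exceed sigma_center")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")

    @property
    def surround_weight(self) -> float:
        """Peak amplitude of the surround Gaussian under volume-ratio semantics."""
        if self.cs_ratio == 0:
            return 0.0
        return self.cs_ratio * self.sigma_center**2 / self.sigma_surround**2


@dataclass(frozen=True)
class GaborParams:
    """V1-like RF parameters.

    The envelope axes derive from the carrier frequency:
    ``sigma_min = n_subregions / (4 sqrt(2) f_pref)`` (across the stripes,
    fitting ``n_subregions`` excitatory+inhibitory subregions) and
    ``sigma_maj = (lw_ratio / n_subregions) * sigma_min`` (along the
    stripes).  ``aspect_convention="ratio_times_n"`` switches to
    ``sigma_maj = lw_ratio * n_subregions * sigma_min``.
    """

    center: tuple[float, float] = (0.0, 0.0)
    f_pref: float = 0.08
    theta_c: float = 0.0
    phase: float = 0.0
    n_subregions: int = 2
    lw_ratio: float = 4.0
    aspect_convention: str = "ratio_over_n"

    def __post_init__(self) -> None:
        if self.f_pref <= 0:
            raise ValueError("f_pref must be positive")
        if self.aspect_convention not in ("ratio_over_n", "ratio_times_n"):
            raise ValueError("unknown aspect_convention")

    @property
    def sigma_min(self) -> float:
        return self.n_subregions / (4.0 * np.sqrt(2.0) * self.f_pref)

    @property
    def sigma_maj(self) -> float:
        if self.aspect_convention == "ratio_times_n":
            return self.lw_ratio * self.n_subregions * self.sigma_min
        return (self.lw_ratio / self.n_subregions) * self.sigma_min


def make_dog(params: DoGParams, grid: FieldGrid, amplitude_ratio: bool = False) -> np.ndarray:
    """Render the center-surround RF on the pixel grid.

    ``amplitude_ratio=True`` is a compatibility switch that treats
    ``cs_ratio`` as the surround peak-amplitude ratio instead of the
    volume ratio.
    """
    X, Y = grid.mesh()
    xo, yo = params.center
    r2 = (X - xo) ** 2 + (Y - yo) ** 2
    center = np.exp(-r2 / (2.0 * params.sigma_center**2))
    if params.cs_ratio == 0:
        return params.polarity * center
    w = params.cs_ratio if amplitude_ratio else params.surround_weight
    surround = np.exp(-r2 / (2.0 * params.sigma_surround**2))
    return params.polarity * (center - w * surround)


def dog_spectrum_closed_form(params: DoGParams, freq: np.ndarray | float) -> np.ndarray:
    """Analytic amplitude spectrum of the center-surround RF along a radial
    frequency axis (up to a global positive constant).

    A(f) = 2 pi sc^2 [ exp(-2 pi^2 sc^2 f^2) - cs_ratio exp(-2 pi^2 ss^2 f^2) ]

    With balanced volumes (cs_ratio = 1) the DC term vanishes.
    """
    f2 = np.square(np.asarray(freq, dtype=float))
    sc2 = params.sigma_center**2
    out = np.exp(-2.0 * np.pi**2 * sc2 * f2)
    if params.cs_ratio > 0:
        out = out - params.cs_ratio * np.exp(-2.0 * np.pi**2 * params.sigma_surround**2 * f2)
    return 2.0 * np.pi * sc2 * out


def dog_preferred_sf_closed_form(params: DoGParams) -> float:
    """Argmax of the closed-form spectrum, cycles/deg (0 for lowpass RFs)."""
    sc2, ss2 = params.sigma_center**2, params.sigma_surround**2
    if params.cs_ratio == 0:
        return 0.0
    arg = params.cs_ratio * ss2 / sc2
    if arg <= 1.0:  # spectrum monotone decreasing: lowpass
        return 0.0
    return float(np.sqrt(np.log(arg) / (2.0 * np.pi**2 * (ss2 - sc2))))


def dog_preferred_sf(params: DoGParams, grid: FieldGrid) -> float:
    """Preferred spatial frequency from the discrete spectrum.

    Renders the RF, takes the 2-D amplitude spectrum, slices along the
    horizontal frequency axis through the origin (any axis is equivalent
    for a circularly symmetric RF), and localizes the peak with parabolic
    refinement around the maximum bin.

    Raises if the peak sits at the Nyquist edge, where localization is
    unreliable.
    """
    rf = make_dog(params, grid)
    spectrum = np.abs(np.fft.fft2(rf))
    freqs = np.fft.fftfreq(grid.n_pixels, d=grid.pixel_size)
    half = grid.n_pixels // 2
    sl = spectrum[0, :half]
    f = freqs[:half]
    i = int(np.argmax(sl))
    if i >= half - 1:
        raise ValueError("spectral peak at the Nyquist edge; grid resolution too coarse")
    if i == 0:
        return 0.0
    a, b, c = sl[i - 1], sl[i], sl[i + 1]
    denom = a - 2.0 * b + c
    shift = 0.0 if denom == 0 else 0.5 * (a - c) / denom
    return float(f[i] + shift * (f[1] - f[0]))


def make_gabor(params: GaborParams, grid: FieldGrid) -> np.ndarray:
    """Render the V1-like RF: oriented carrier times elongated envelope.

    The carrier phase is referenced at the RF center, so translating the
    RF translates carrier and envelope together (quadrature pairs and
    orientation tuning are independent of absolute position).  The
    envelope is unit-peak, i.e. rescaled to [0, 1].
    """
    X, Y = grid.mesh()
    xo, yo = params.center
    dx, dy = X - xo, Y - yo
    # carrier: grating at f_pref/theta_c with phase origin at the RF center
    tg = GratingSpec(theta_c=params.theta_c, sf=params.f_pref, phase=params.phase).theta_g
    arg = 2.0 * np.pi * params.f_pref * (np.cos(tg) * dx + np.sin(tg) * dy)
    carrier = np.cos(arg + np.deg2rad(params.phase))
    # envelope: major axis parallel to the stripes (stripe direction = theta_c)
    a = np.deg2rad(params.theta_c)
    u = np.cos(a) * dx + np.sin(a) * dy  # along stripes
    v = -np.sin(a) * dx + np.cos(a) * dy  # across stripes
    envelope = np.exp(
        -(u**2 / (2.0 * params.sigma_maj**2) + v**2 / (2.0 * params.sigma_min**2))
    )
    return carrier * envelope


def spectral_overlap_map(rf: np.ndarray, stim: np.ndarray) -> np.ndarray:
    """2-D frequency-domain overlap (Re[conj(RF spectrum) * stimulus spectrum] / N),
    origin-centered; its sum equals the spatial dot product (Parseval)."""
    if rf.shape != stim.shape:
        raise ValueError("RF and stimulus must share the same grid")
    prod = np.conj(np.fft.fft2(rf)) * np.fft.fft2(stim)
    return np.fft.fftshift(prod.real) / rf.size


def spectral_overlap(rf: np.ndarray, stim: np.ndarray) -> float:
    """Stimulus-RF inner product computed in the frequency domain."""
    return float(spectral_overlap_map(rf, stim).sum())
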