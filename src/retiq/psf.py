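"""Fourier-optics computation of the eye's PSF and MTF from a Zernike wavefront.

The pupil function ``P = A * exp(i 2π W / λ)`` is sampled on a square grid
(pupil occupying ``pupil_fill_fraction`` of the array width, i.e. the array is
zero-padded by ``1/fill`` relative to the pupil) and the monochromatic PSF is
``|FFT(P)|²`` normalized to unit energy.  The angular pixel scale follows from
the FFT geometry: ``Δθ = λ / (N · dx)`` radians with ``dx`` the pupil-plane
sample spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .optics import ZernikeWavefront
from .zernike import zernike_basis

__all__ = [
    "SamplingConfig",
    "PSFImage",
    "MTFImage",
    "compute_psf",
    "diffraction_limited_psf",
    "compute_mtf",
]

RAD_TO_ARCMIN = 180.0 / math.pi * 60.0


@dataclass(frozen=True)
class SamplingConfig:
    """PSF sampling: grid size, pupil fill fraction and the analysis window.

    ``pupil_fill_fraction ≤ 0.5`` guarantees at least 2× zero-padding of the
    pupil, which keeps the complex field Nyquist-sampled for the wavefront
    slopes encountered over the supported search ranges.  ``psf_window_arcmin``
    is the half-width of the region retained for metric computation, so that
    wrap-around energy at the array edge cannot leak into entropy/variance
    style metrics.
    """

    grid_size: int = 256
    pupil_fill_fraction: float = 0.5
    psf_window_arcmin: float = 30.0

    def __post_init__(self) -> None:
        n = self.grid_size
        if n < 128 or (n & (n - 1)) != 0:
            raise ValueError("grid_size must be a power of two ≥ 128")
        if not (0.0 < self.pupil_fill_fraction <= 0.5):
            raise ValueError("pupil_fill_fraction must lie in (0, 0.5]")
        if not self.psf_window_arcmin > 0.0:
            raise ValueError("psf_window_arcmin must be positive")

    @property
    def pupil_samples(self) -> int:
        return int(round(self.grid_size * self.pupil_fill_fraction))


@dataclass(frozen=True, eq=False)
class PSFImage:
    """Sampled retinal point-spread function.

    ``intensity`` is non-negative and sums to one over the full grid;
    ``pixel_scale`` is in arcmin/pixel.  The PSF is centered at index
    ``(N//2, N//2)`` by the FFT-shift convention.
    """

    intensity: np.ndarray
    pixel_scale: float
    wavelength: float
    pupil_diameter: float
    window_arcmin: float

    def __post_init__(self) -> None:
        s = float(self.intensity.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"PSF must be normalized to unit sum (got {s!r})")
        if float(self.intensity.min()) < 0.0:
            raise ValueError("PSF intensities must be non-negative")

    @property
    def n(self) -> int:
        return self.intensity.shape[0]

    @property
    def center(self) -> int:
        return self.n // 2

    @property
    def window_half_px(self) -> int:
        """Half-width, in pixels, of the metric-analysis window."""
        return min(int(self.window_arcmin / self.pixel_scale), self.center - 1)

    def windowed(self) -> np.ndarray:
        """The intensity restricted to the analysis window (view, not a copy)."""
        c, h = self.center, self.window_half_px
        return self.intensity[c - h : c + h + 1, c - h : c + h + 1]

    def same_sampling(self, other: "PSFImage") -> bool:
        return (
            self.intensity.shape == other.intensity.shape
            and abs(self.pixel_scale - other.pixel_scale) < 1e-12
            and self.wavelength == other.wavelength
            and self.pupil_diameter == other.pupil_diameter
        )


@dataclass(frozen=True, eq=False)
class MTFImage:
    """Modulation transfer function: |FT(PSF)| normalized at zero frequency."""

    modulation: np.ndarray
    frequency_scale: float  # cycles/degree per pixel

    def __post_init__(self) -> None:
        c = self.modulation.shape[0] // 2
        if abs(float(self.modulation[c, c]) - 1.0) > 1e-9:
            raise ValueError("MTF must equal 1 at zero frequency")

    @property
    def n(self) -> int:
        return self.modulation.shape[0]


@lru_cache(maxsize=8)
def _pupil_geometry(cfg: SamplingConfig):
    """Pupil mask indices and the Zernike basis on them, cached per config."""
    n = cfg.grid_size
    npup = cfg.pupil_samples
    axis = np.arange(n) - n // 2
    xx, yy = np.meshgrid(axis, axis)  # yy rows, xx cols
    rho = np.hypot(xx, yy) / (npup / 2.0)
    inside = rho <= 1.0
    theta = np.arctan2(yy[inside], xx[inside])
    basis = zernike_basis(rho[inside], theta)  # (15, npix)
    basis.flags.writeable = False
    mask = inside
    mask.flags.writeable = False
    return mask, basis


def _pixel_scale_arcmin(w_pupil_mm: float, wavelength_nm: float, cfg: SamplingConfig) -> float:
    dx_mm = w_pupil_mm / cfg.pupil_samples
    theta_pix_rad = (wavelength_nm * 1e-6) / (cfg.grid_size * dx_mm)
    return theta_pix_rad * RAD_TO_ARCMIN


def compute_psf(w: ZernikeWavefront, cfg: SamplingConfig = SamplingConfig()) -> PSFImage:
    """Monochromatic PSF of the eye described by ``w``.

    The wavefront (µm) is summed from the Zernike terms on the unit pupil,
    converted to phase at the wavefront's wavelength, and propagated by FFT.
    """
    mask, basis = _pupil_geometry(cfg)
    wave_um = w.coefficients @ basis  # µm on pupil pixels
    phase = (2.0 * math.pi / (w.wavelength * 1e-3)) * wave_um
    field = np.zeros(mask.shape, dtype=complex)
    field[mask] = np.exp(1j * phase)
    amp = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field)))
    psf = np.abs(amp) ** 2
    psf /= psf.sum()
    psf.flags.writeable = False
    return PSFImage(
        intensity=psf,
        pixel_scale=_pixel_scale_arcmin(w.pupil_diameter, w.wavelength, cfg),
        wavelength=w.wavelength,
        pupil_diameter=w.pupil_diameter,
        window_arcmin=cfg.psf_window_arcmin,
    )


@lru_cache(maxsize=64)
def _dl_psf_cached(pupil_diameter: float, wavelength: float, cfg: SamplingConfig) -> PSFImage:
    w = ZernikeWavefront(np.zeros(15), pupil_diameter, wavelength)
    return compute_psf(w, cfg)


def diffraction_limited_psf(
    pupil_diameter: float, wavelength: float, cfg: SamplingConfig = SamplingConfig()
) -> PSFImage:
    """Aberration-free PSF for the same pupil and wavelength (cached)."""
    return _dl_psf_cached(round(float(pupil_diameter), 6), float(wavelength), cfg)


def compute_mtf(psf: PSFImage) -> MTFImage:
    """MTF of a PSF: magnitude of its Fourier transform, DC-normalized."""
    spec = np.fft.fft2(np.fft.ifftshift(psf.intensity))
    mod = np.abs(spec)
    mod /= mod[0, 0]
    mod = np.fft.fftshift(mod)
    mod.flags.writeable = False
    theta_pix_rad = psf.pixel_scale / RAD_TO_ARCMIN
    freq_scale_cpd = (1.0 / (psf.n * theta_pix_rad)) * (math.pi / 180.0)
    return MTFImage(modulation=mod, frequency_scale=freq_scale_cpd)
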