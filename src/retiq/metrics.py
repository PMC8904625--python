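"""Retinal image-quality metrics (IQM) computed from PSF/MTF pairs.

Eight metrics are provided, each a scalar function of the eye's PSF and the
diffraction-limited PSF at the same pupil and wavelength:

=========  =============================================================
name       definition
=========  =============================================================
sr         Strehl ratio, ``max(PSF) / max(PSF_DL)``
fwhm       mean full width at half maximum over azimuthal cross-sections
entropy    ``-Σ PSF · ln PSF`` on the unit-sum PSF (0·ln 0 := 0)
iv         intensity variance, ``mean(PSF²) - mean(PSF)²``
std        ``SD(PSF) / SD(PSF_DL)``
ns         neural sharpness, ``∫PSF·g / ∫PSF_DL·g`` (bivariate Gaussian g)
vsx        visual Strehl (spatial), ``∫PSF·C / ∫PSF_DL·C`` with C the
           inverse Fourier transform of the neural CSF
vsmtf      visual Strehl (frequency), ``∬CSF_N·MTF / ∬CSF_N·MTF_DL``
=========  =============================================================

``fwhm`` and ``entropy`` are *minimized* when image quality improves; all
other metrics are maximized.  The orientation is encoded once on
:class:`MetricSpec` and honored by every optimizer.

The neural contrast sensitivity function defaults to the classic radial
Mannos–Sakrison model ``A(f) = a (b + c f) exp(-(c f)^d)``, a band-pass curve
peaking near 8 cycles/degree; the normalized-metric and refraction-recovery
properties of the package hold for any band-pass CSF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
from scipy.ndimage import map_coordinates

from .psf import PSFImage, compute_mtf

__all__ = [
    "METRIC_NAMES",
    "MetricSpec",
    "NeuralWeights",
    "get_metric",
    "default_metrics",
    "compute_metric",
    "compute_metrics",
    "fwhm",
    "make_neural_weights",
    "neural_csf",
]

METRIC_NAMES = ("sr", "fwhm", "entropy", "iv", "std", "ns", "vsx", "vsmtf")
_MINIMIZED = frozenset({"fwhm", "entropy"})


@dataclass(frozen=True)
class MetricSpec:
    """A named metric with its orientation and weighting parameters.

    ``ns_sigma_arcmin`` is the std of the neural-sharpness Gaussian weight
    (1 arcmin default); ``csf_params`` are the Mannos–Sakrison coefficients
    ``(a, b, c, d)`` used by vsx/vsmtf.
    """

    name: str
    ns_sigma_arcmin: float = 1.0
    csf_params: tuple[float, float, float, float] = (2.6, 0.0192, 0.114, 1.1)

    def __post_init__(self) -> None:
        if self.name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.name!r}; choose from {METRIC_NAMES}")
        if not self.ns_sigma_arcmin > 0.0:
            raise ValueError("ns_sigma_arcmin must be positive")

    @property
    def orientation(self) -> str:
        """'minimize' for fwhm/entropy, 'maximize' otherwise."""
        return "minimize" if self.name in _MINIMIZED else "maximize"

    @property
    def minimize(self) -> bool:
        return self.name in _MINIMIZED


def get_metric(name: str, **params) -> MetricSpec:
    """Look up a metric by its registry name (case-insensitive)."""
    return MetricSpec(name.lower(), **params)


def default_metrics() -> tuple[MetricSpec, ...]:
    """All eight metrics with default parameters."""
    return tuple(MetricSpec(n) for n in METRIC_NAMES)


# ---------------------------------------------------------------------------
# Neural weighting functions
# ---------------------------------------------------------------------------

def neural_csf(freq_cpd: np.ndarray, params: tuple[float, float, float, float]) -> np.ndarray:
    """Radial neural contrast sensitivity, Mannos–Sakrison parametrization."""
    a, b, c, d = params
    f = np.abs(freq_cpd)
    return a * (b + c * f) * np.exp(-((c * f) ** d))


@dataclass(frozen=True, eq=False)
class NeuralWeights:
    """Spatial and frequency weights matched to one PSF sampling geometry."""

    g: np.ndarray  # bivariate Gaussian, peak 1 at grid center
    C: np.ndarray  # inverse FT of the CSF, spatial weight
    csf: np.ndarray  # CSF_N on the MTF frequency grid
    pixel_scale: float
    frequency_scale: float


@lru_cache(maxsize=32)
def _weights_cached(
    n: int,
    pixel_scale: float,
    sigma_arcmin: float,
    csf_params: tuple[float, float, float, float],
) -> NeuralWeights:
    c = n // 2
    axis = (np.arange(n) - c) * pixel_scale  # arcmin
    xx, yy = np.meshgrid(axis, axis)
    g = np.exp(-(xx**2 + yy**2) / (2.0 * sigma_arcmin**2))

    theta_pix_rad = pixel_scale / (180.0 / math.pi * 60.0)
    freq_scale = (1.0 / (n * theta_pix_rad)) * (math.pi / 180.0)  # cpd per pixel
    faxis = (np.arange(n) - c) * freq_scale
    fx, fy = np.meshgrid(faxis, faxis)
    csf = neural_csf(np.hypot(fx, fy), csf_params)
    C = np.fft.fftshift(np.real(np.fft.ifft2(np.fft.ifftshift(csf))))
    for arr in (g, csf, C):
        arr.flags.writeable = False
    return NeuralWeights(g=g, C=C, csf=csf, pixel_scale=pixel_scale, frequency_scale=freq_scale)


def make_neural_weights(spec: MetricSpec, psf: PSFImage) -> NeuralWeights:
    """Neural weighting grids matching the sampling of ``psf``."""
    return _weights_cached(
        psf.n, round(psf.pixel_scale, 12), spec.ns_sigma_arcmin, spec.csf_params
    )


# ---------------------------------------------------------------------------
# FWHM
# ---------------------------------------------------------------------------

def _peak_index(img: np.ndarray) -> tuple[int, int]:
    peak_val = img.max()
    rows, cols = np.nonzero(img == peak_val)
    if rows.size == 1:
        return int(rows[0]), int(cols[0])
    # break ties by proximity to the intensity centroid
    total = img.sum()
    r_c = (np.arange(img.shape[0]) @ img.sum(axis=1)) / total
    c_c = (np.arange(img.shape[1]) @ img.sum(axis=0)) / total
    d2 = (rows - r_c) ** 2 + (cols - c_c) ** 2
    k = int(np.argmin(d2))
    return int(rows[k]), int(cols[k])


def fwhm(psf: PSFImage, n_azimuths: int = 36) -> float:
    """Mean full width at half maximum of the PSF, in arcmin.

    Cross-sections through the peak are taken at ``n_azimuths`` equally spaced
    orientations.  Along each ray the *outermost* crossing of half the peak
    intensity is located by linear interpolation, and the full width is the
    sum of the two opposite half-widths.  For a unimodal PSF this is the
    textbook FWHM; for a structured (speckled or ringed) PSF it measures the
    envelope within which the intensity still reaches half maximum, so a
    spread-out PSF is never scored as narrow just because its brightest
    speckle is sharp.  Raises if the half-max envelope is not contained in
    the analysis window.
    """
    img = psf.intensity
    pr, pc = _peak_index(img)
    half = img[pr, pc] / 2.0

    max_r_px = min(
        psf.window_arcmin / psf.pixel_scale,
        pr, pc, img.shape[0] - 1 - pr, img.shape[1] - 1 - pc,
    )
    dr = 0.25  # radial sampling step in pixels
    radii = np.arange(0.0, max_r_px, dr)
    if radii.size < 2:  # peak at the array border: wrap-around artifact
        raise ValueError("PSF peak too close to the array edge for a FWHM estimate")
    az = np.pi * np.arange(n_azimuths) / n_azimuths
    directions = np.concatenate([az, az + np.pi])  # both sides of each section
    rows = pr + np.sin(directions)[:, None] * radii[None, :]
    cols = pc + np.cos(directions)[:, None] * radii[None, :]
    vals = map_coordinates(img, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
    vals = vals.reshape(2 * n_azimuths, radii.size)

    above = vals >= half
    if above[:, -1].any():
        raise ValueError("PSF half-maximum envelope extends beyond the analysis window")
    # index of the outermost sample still at/above half (ray starts at the peak)
    last = radii.size - 1 - np.argmax(above[:, ::-1], axis=1)
    rows_idx = np.arange(vals.shape[0])
    v_hi = vals[rows_idx, last]
    v_lo = vals[rows_idx, last + 1]
    r_cross = radii[last] + dr * (v_hi - half) / (v_hi - v_lo)
    widths = r_cross[:n_azimuths] + r_cross[n_azimuths:]
    return float(widths.mean() * psf.pixel_scale)


# ---------------------------------------------------------------------------
# Metric evaluation
# ---------------------------------------------------------------------------

def _check_pair(psf: PSFImage, psf_dl: PSFImage) -> None:
    if not psf.same_sampling(psf_dl):
        raise ValueError("PSF and diffraction-limited PSF must share pupil, wavelength and sampling")


def compute_metrics(
    psf: PSFImage,
    psf_dl: PSFImage,
    specs: Iterable[MetricSpec],
    on_error: str = "raise",
) -> dict[str, float]:
    """Evaluate several metrics on one PSF, sharing the MTF computation.

    With ``on_error='nan'`` a metric that cannot be evaluated (e.g. a PSF so
    spread that its half-max envelope leaves the analysis window) yields NaN
    instead of raising; the optimizers rank NaN as worst.
    """
    _check_pair(psf, psf_dl)
    if on_error not in ("raise", "nan"):
        raise ValueError("on_error must be 'raise' or 'nan'")
    out: dict[str, float] = {}
    win = psf.windowed()
    win_dl = psf_dl.windowed()
    mtf_pair: list = [None, None]  # lazily computed, shared across specs
    for spec in specs:
        try:
            v = _evaluate(spec, psf, psf_dl, win, win_dl, mtf_pair)
            if not math.isfinite(v):
                raise ValueError(f"metric {spec.name!r} evaluated to a non-finite value")
        except ValueError:
            if on_error == "raise":
                raise
            v = float("nan")
        out[spec.name] = v
    return out


def _evaluate(spec, psf, psf_dl, win, win_dl, mtf_pair):
    name = spec.name
    if name == "sr":
        return float(psf.intensity.max() / psf_dl.intensity.max())
    if name == "fwhm":
        return fwhm(psf)
    if name == "entropy":
        p = win[win > 0]
        return float(-(p * np.log(p)).sum())
    if name == "iv":
        return float((win**2).mean() - win.mean() ** 2)
    if name == "std":
        sd_dl = win_dl.std()
        if sd_dl == 0.0:
            raise ValueError("reference PSF has zero intensity variance")
        return float(win.std() / sd_dl)
    h = psf.window_half_px
    c = psf.center
    if name == "ns":
        w = make_neural_weights(spec, psf)
        gw = w.g[c - h : c + h + 1, c - h : c + h + 1]
        return float((win * gw).sum() / (win_dl * gw).sum())
    if name == "vsx":
        w = make_neural_weights(spec, psf)
        cw = w.C[c - h : c + h + 1, c - h : c + h + 1]
        return float((win * cw).sum() / (win_dl * cw).sum())
    if name == "vsmtf":
        if mtf_pair[0] is None:
            mtf_pair[0] = compute_mtf(psf)
            mtf_pair[1] = compute_mtf(psf_dl)
        w = make_neural_weights(spec, psf)
        return float(
            (w.csf * mtf_pair[0].modulation).sum() / (w.csf * mtf_pair[1].modulation).sum()
        )
    raise ValueError(f"unknown metric {name!r}")  # pragma: no cover


def compute_metric(psf: PSFImage, psf_dl: PSFImage, spec: MetricSpec) -> float:
    """Evaluate a single image-quality metric (see module docstring)."""
    return compute_metrics(psf, psf_dl, [spec])[spec.name]
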