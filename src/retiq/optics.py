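"""Refraction representations and conversions.

Clinical refractions are handled in three interchangeable forms:

* :class:`SpheroCylinder` — sphere / cylinder / axis in diopters and degrees,
  negative-cylinder convention (the optometric standard).
* :class:`PowerVector` — the Fourier form ``(M, J0, J45)`` where ``M`` is the
  spherical equivalent and ``J0``/``J45`` are the Jackson cross-cylinder
  components::

      M   = S + C/2
      J0  = -(C/2) * cos(2*axis)
      J45 = -(C/2) * sin(2*axis)

* Second-order Zernike coefficients on a given pupil (paraxial conversion).

The wavefront-error sign convention is the one under which a myopic eye
(``M < 0``) has a positive defocus coefficient ``c(2,0)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpheroCylinder",
    "PowerVector",
    "ZernikeWavefront",
    "ChromaticModel",
    "to_power_vector",
    "from_power_vector",
    "sc_to_zernike",
    "zernike_to_sc",
    "rescale_pupil",
    "chromatic_correct",
]

_SQRT3 = math.sqrt(3.0)
_SQRT5 = math.sqrt(5.0)
_SQRT6 = math.sqrt(6.0)


# ---------------------------------------------------------------------------
# Sphero-cylinder and power vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpheroCylinder:
    """A sphero-cylindrical prescription (negative-cylinder convention).

    Positive-cylinder input is transposed on construction; the axis is
    normalized into [0, 180) and canonicalized to 0 when the cylinder
    vanishes.
    """

    sphere: float
    cylinder: float = 0.0
    axis: float = 0.0

    def __post_init__(self) -> None:
        s = float(self.sphere)
        c = float(self.cylinder)
        a = float(self.axis)
        if not (math.isfinite(s) and math.isfinite(c) and math.isfinite(a)):
            raise ValueError("sphere, cylinder and axis must be finite")
        if c > 0.0:  # transpose to negative-cylinder form
            s, c, a = s + c, -c, a + 90.0
        a = a % 180.0
        if c == 0.0:
            a = 0.0
        object.__setattr__(self, "sphere", s)
        object.__setattr__(self, "cylinder", c)
        object.__setattr__(self, "axis", a)

    def __str__(self) -> str:
        return f"{self.sphere:+.2f}/{self.cylinder:+.2f}x{self.axis:.0f}"

    @classmethod
    def parse(cls, text: str) -> "SpheroCylinder":
        """Parse the clinical text form ``"S/CxA"``, e.g. ``"-2.00/-1.00x180"``."""
        m = re.fullmatch(
            r"\s*([+-]?\d+(?:\.\d+)?)\s*/\s*([+-]?\d+(?:\.\d+)?)\s*[xX]\s*(\d+(?:\.\d+)?)\s*",
            text,
        )
        if m is None:
            raise ValueError(f"cannot parse prescription {text!r}; expected 'S/CxA'")
        return cls(float(m.group(1)), float(m.group(2)), float(m.group(3)))

    def to_dict(self) -> dict:
        return {"sphere": self.sphere, "cylinder": self.cylinder, "axis": self.axis}


@dataclass(frozen=True)
class PowerVector:
    """Power-vector refraction (M, J0, J45), all in diopters."""

    M: float
    J0: float = 0.0
    J45: float = 0.0

    def __post_init__(self) -> None:
        for name in ("M", "J0", "J45"):
            if not math.isfinite(float(getattr(self, name))):
                raise ValueError(f"{name} must be finite")

    def __add__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.M + other.M, self.J0 + other.J0, self.J45 + other.J45)

    def __sub__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.M - other.M, self.J0 - other.J0, self.J45 - other.J45)

    def to_dict(self) -> dict:
        return {"M": self.M, "J0": self.J0, "J45": self.J45}

    def to_sphero_cylinder(self) -> SpheroCylinder:
        return from_power_vector(self)


def to_power_vector(sc: SpheroCylinder) -> PowerVector:
    """Convert a sphero-cylinder to its power-vector form."""
    ax = math.radians(sc.axis)
    half_c = sc.cylinder / 2.0
    return PowerVector(
        M=sc.sphere + half_c,
        J0=-half_c * math.cos(2.0 * ax),
        J45=-half_c * math.sin(2.0 * ax),
    )


def from_power_vector(pv: PowerVector) -> SpheroCylinder:
    """Invert :func:`to_power_vector` (cylinder emitted in negative form)."""
    cyl = -2.0 * math.hypot(pv.J0, pv.J45)
    sphere = pv.M - cyl / 2.0
    if cyl == 0.0:
        axis = 0.0
    else:
        axis = math.degrees(0.5 * math.atan2(pv.J45, pv.J0)) % 180.0
    return SpheroCylinder(sphere, cyl, axis)


# ---------------------------------------------------------------------------
# Zernike wavefront
# ---------------------------------------------------------------------------

class ZernikeWavefront:
    """An ocular wavefront as OSA-indexed Zernike coefficients on a pupil.

    Parameters
    ----------
    coefficients : array-like, µm
        OSA/ANSI single-index coefficients ``j = 0..14`` (orders 0–4).
        Shorter vectors are zero-padded.  Piston and tilt (j = 0, 1, 2) are
        forced to zero: they do not affect image quality.
    pupil_diameter : float, mm
    wavelength : float, nm
        Wavelength the coefficients refer to (default photopic 555 nm).
    """

    __slots__ = ("coefficients", "pupil_diameter", "wavelength")

    N_COEFF = 15

    def __init__(
        self,
        coefficients: Sequence[float] | np.ndarray,
        pupil_diameter: float,
        wavelength: float = 555.0,
    ) -> None:
        c = np.asarray(coefficients, dtype=float).ravel()
        if c.size > self.N_COEFF:
            raise ValueError(f"at most {self.N_COEFF} coefficients (orders 0-4) supported")
        full = np.zeros(self.N_COEFF)
        full[: c.size] = c
        full[:3] = 0.0
        if not np.all(np.isfinite(full)):
            raise ValueError("coefficients must be finite")
        if np.any(np.abs(full) >= 50.0):
            raise ValueError("coefficient magnitudes must be < 50 µm")
        if not (1.0 < float(pupil_diameter) < 10.0):
            raise ValueError("pupil_diameter must lie in (1, 10) mm")
        if not float(wavelength) > 0.0:
            raise ValueError("wavelength must be positive")
        full.flags.writeable = False
        self.coefficients = full
        self.pupil_diameter = float(pupil_diameter)
        self.wavelength = float(wavelength)

    @property
    def pupil_radius(self) -> float:
        """Pupil radius in mm."""
        return self.pupil_diameter / 2.0

    def rms(self, orders: str = "all") -> float:
        """RMS wavefront error in µm ('all', 'low' = order 2, 'high' = orders 3-4)."""
        c = self.coefficients
        if orders == "all":
            sel = c[3:]
        elif orders == "low":
            sel = c[3:6]
        elif orders == "high":
            sel = c[6:]
        else:
            raise ValueError("orders must be 'all', 'low' or 'high'")
        return float(np.sqrt(np.sum(sel**2)))

    def with_coefficients(self, updates: Mapping[int, float]) -> "ZernikeWavefront":
        c = self.coefficients.copy()
        for j, v in updates.items():
            c[j] = v
        return ZernikeWavefront(c, self.pupil_diameter, self.wavelength)

    def __repr__(self) -> str:
        return (
            f"ZernikeWavefront(rms={self.rms():.3f} µm, "
            f"pupil={self.pupil_diameter:g} mm, λ={self.wavelength:g} nm)"
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "pupil_diameter": self.pupil_diameter,
            "wavelength": self.wavelength,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ZernikeWavefront":
        return cls(d["coefficients"], d["pupil_diameter"], d.get("wavelength", 555.0))


# ---------------------------------------------------------------------------
# Paraxial sphero-cylinder <-> Zernike conversions
# ---------------------------------------------------------------------------

def sc_to_zernike(pv: PowerVector, pupil_diameter: float) -> np.ndarray:
    """Second-order Zernike coefficients (µm) producing the refraction ``pv``.

    Returns the OSA triple ``[c(2,-2), c(2,0), c(2,+2)]`` (j = 3, 4, 5) for a
    pupil of the given diameter in mm.  With ``r`` the pupil radius::

        c(2,0)  = -M  * r**2 / (4*sqrt(3))
        c(2,+2) = -J0 * r**2 / (2*sqrt(6))
        c(2,-2) = -J45* r**2 / (2*sqrt(6))
    """
    if not pupil_diameter > 0.0:
        raise ValueError("pupil_diameter must be positive")
    r2 = (pupil_diameter / 2.0) ** 2
    c20 = -pv.M * r2 / (4.0 * _SQRT3)
    c22 = -pv.J0 * r2 / (2.0 * _SQRT6)
    c2m2 = -pv.J45 * r2 / (2.0 * _SQRT6)
    return np.array([c2m2, c20, c22])


def zernike_to_sc(
    w: ZernikeWavefront, include_sa_correction: bool = False
) -> PowerVector:
    """Paraxial refraction of a wavefront from its second-order terms.

    With ``include_sa_correction`` the standard paraxial fourth-order
    spherical-aberration adjustment is added to the spherical equivalent::

        M = (-4*sqrt(3)*c(2,0) + 12*sqrt(5)*c(4,0)) / r**2

    (off by default; it matches the curvature of the wavefront at the pupil
    center rather than the least-squares defocus).
    """
    r2 = w.pupil_radius**2
    c2m2, c20, c22 = w.coefficients[3:6]
    m = -4.0 * _SQRT3 * c20 / r2
    if include_sa_correction:
        m += 12.0 * _SQRT5 * w.coefficients[12] / r2
    j0 = -2.0 * _SQRT6 * c22 / r2
    j45 = -2.0 * _SQRT6 * c2m2 / r2
    return PowerVector(m, j0, j45)


def rescale_pupil(w: ZernikeWavefront, new_diameter: float) -> ZernikeWavefront:
    """Re-express a wavefront over a smaller concentric pupil.

    The wavefront surface is evaluated on the subaperture and re-fit to the
    Zernike basis of the new unit pupil by least squares; because the
    restriction of a degree-4 polynomial is again a degree-4 polynomial the
    fit is exact up to floating-point conditioning.  Only shrinking is
    allowed — the wavefront is unknown outside the measured pupil.
    """
    if not 0.0 < new_diameter <= w.pupil_diameter:
        raise ValueError("new_diameter must be positive and not exceed the measured pupil")
    if new_diameter == w.pupil_diameter:
        return w
    from .zernike import zernike_basis  # local import to avoid a cycle

    s = new_diameter / w.pupil_diameter
    r = np.sqrt(np.linspace(0.0, 1.0, 40))  # uniform-in-area radial samples
    t = np.linspace(0.0, 2.0 * np.pi, 41)[:-1]
    rho, theta = np.meshgrid(r, t)
    basis_new = zernike_basis(rho.ravel(), theta.ravel())
    basis_old = zernike_basis(s * rho.ravel(), theta.ravel())
    surface = w.coefficients @ basis_old
    coeffs, *_ = np.linalg.lstsq(basis_new.T, surface, rcond=None)
    coeffs[:3] = 0.0
    coeffs[np.abs(coeffs) < 1e-14] = 0.0
    return ZernikeWavefront(coeffs, new_diameter, w.wavelength)


# ---------------------------------------------------------------------------
# Chromatic correction
# ---------------------------------------------------------------------------

def _chromatic_eye_refraction(wavelength_nm: float) -> float:
    # Reduced-eye chromatic difference of refraction (diopters, zero near 589 nm).
    return 1.68524 - 633.46 / (wavelength_nm - 214.102)


@dataclass(frozen=True)
class ChromaticModel:
    """Spherical-equivalent chromatic correction between two wavelengths.

    The chromatic difference of refraction of the eye is purely spherical, so
    the correction shifts ``M`` by ``delta_m`` diopters and leaves J0/J45
    untouched.  ``offset_function(measurement_nm, reference_nm)`` returns that
    shift; the default is the reduced-eye dispersion formula.  The shift is
    exactly zero when both wavelengths coincide.
    """

    measurement_wavelength: float = 555.0
    reference_wavelength: float = 555.0
    offset_function: Callable[[float, float], float] | None = None

    @property
    def delta_m(self) -> float:
        if self.measurement_wavelength == self.reference_wavelength:
            return 0.0
        fn = self.offset_function
        if fn is None:
            fn = lambda meas, ref: (
                _chromatic_eye_refraction(ref) - _chromatic_eye_refraction(meas)
            )
        return float(fn(self.measurement_wavelength, self.reference_wavelength))

    @classmethod
    def identity(cls) -> "ChromaticModel":
        return cls(555.0, 555.0)

    @classmethod
    def reduced_eye(
        cls, measurement_wavelength: float = 850.0, reference_wavelength: float = 555.0
    ) -> "ChromaticModel":
        """Reduced-eye dispersion model (e.g. near-IR aberrometer → photopic)."""
        return cls(measurement_wavelength, reference_wavelength)

    def inverse(self) -> "ChromaticModel":
        return replace(
            self,
            measurement_wavelength=self.reference_wavelength,
            reference_wavelength=self.measurement_wavelength,
            offset_function=self.offset_function,
        )


def chromatic_correct(pv: PowerVector, model: ChromaticModel) -> PowerVector:
    """Apply a chromatic spherical-equivalent shift to a power vector."""
    return PowerVector(pv.M + model.delta_m, pv.J0, pv.J45)
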