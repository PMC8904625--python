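"""OSA/ANSI-indexed Zernike polynomials on the unit pupil (orders 0–4).

Single-index ``j`` maps to (radial order ``n``, azimuthal frequency ``m``) in
OSA order; each polynomial carries the ANSI normalization
``sqrt(2(n+1)/(1+δ_m0))`` so it has unit variance over the unit disk.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["OSA_NM", "osa_index", "zernike", "zernike_basis"]

# j -> (n, m) for j = 0..14
OSA_NM: tuple[tuple[int, int], ...] = (
    (0, 0),
    (1, -1), (1, 1),
    (2, -2), (2, 0), (2, 2),
    (3, -3), (3, -1), (3, 1), (3, 3),
    (4, -4), (4, -2), (4, 0), (4, 2), (4, 4),
)


def osa_index(n: int, m: int) -> int:
    """Single OSA index j for radial order n and azimuthal frequency m."""
    return (n * (n + 2) + m) // 2


def _radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m_abs) // 2 + 1):
        coef = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        out += coef * rho ** (n - 2 * k)
    return out


def zernike(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Normalized Zernike polynomial Z_j evaluated at polar pupil coordinates."""
    n, m = OSA_NM[j]
    norm = math.sqrt(2.0 * (n + 1) / (1.0 + (1.0 if m == 0 else 0.0)))
    rad = _radial(n, abs(m), np.asarray(rho, dtype=float))
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(-m * theta)
    else:
        ang = np.ones_like(rad)
    return norm * rad * ang


def zernike_basis(rho: np.ndarray, theta: np.ndarray, n_coeff: int = 15) -> np.ndarray:
    """Stack of Z_0..Z_{n_coeff-1}, shape ``(n_coeff,) + rho.shape``."""
    return np.stack([zernike(j, rho, theta) for j in range(n_coeff)])
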