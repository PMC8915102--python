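"""Real spherical-harmonic basis evaluation.

Shared by the phantom generator (band-limited angular perturbation fields)
and the shape-marker module (surface expansion).  The basis is the standard
orthonormal real form: for degree ``tau`` and order ``beta``,

* ``beta = 0``   : Re(Y_tau^0)
* ``beta > 0``   : sqrt(2) * (-1)^beta * Re(Y_tau^beta)   (cosine branch)
* ``beta < 0``   : sqrt(2) * (-1)^beta * Im(Y_tau^|beta|) (sine branch)

with the complex Y including the Condon-Shortley phase and the associated
Legendre polynomial evaluated in cos(theta).  ``theta`` is the polar angle
from +z in [0, pi], ``phi`` the azimuth from +x in [0, 2*pi).
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["real_sh_degree_block", "real_sh_design_matrix", "n_sh_coefficients"]


def n_sh_coefficients(max_order: int) -> int:
    """Number of real SH basis functions of degree <= max_order."""
    return (max_order + 1) ** 2


def real_sh_degree_block(tau: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Evaluate all ``2*tau + 1`` real SH functions of degree ``tau``.

    Returns an array of shape ``(len(theta), 2*tau + 1)`` with columns ordered
    ``beta = -tau, ..., -1, 0, 1, ..., tau``.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.empty((theta.size, 2 * tau + 1))
    # m = 0 column
    out[:, tau] = sph_harm_y(tau, 0, theta, phi).real
    sqrt2 = np.sqrt(2.0)
    for m in range(1, tau + 1):
        y = sph_harm_y(tau, m, theta, phi)
        sign = -1.0 if (m % 2) else 1.0
        out[:, tau + m] = sqrt2 * sign * y.real
        out[:, tau - m] = sqrt2 * sign * y.imag
    return out


def real_sh_design_matrix(max_order: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Stack degree blocks 0..max_order into an ``(n, (max_order+1)**2)`` matrix.

    Columns are ordered by degree, then by order ``-tau..tau`` within a degree.
    """
    blocks = [real_sh_degree_block(tau, theta, phi) for tau in range(max_order + 1)]
    return np.hstack(blocks)


def sh_index(tau: int, beta: int) -> int:
    """Flat column index of (degree tau, order beta) in the design matrix."""
    if not -tau <= beta <= tau:
        raise ValueError(f"order {beta} out of range for degree {tau}")
    return tau * tau + tau + beta
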