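"""Real symmetric spherical-harmonics basis (even degrees only).

Convention: for each even degree l and order m, the real basis function is

    m < 0:  sqrt(2) * Re[ Y_l^{|m|} ]
    m = 0:  Y_l^0
    m > 0:  sqrt(2) * Im[ Y_l^m ]

with Y_l^m the orthonormal complex spherical harmonics (polar angle theta,
azimuth phi).  Coefficients are ordered by ascending l, then ascending m, so
order 8 yields (8+1)(8+2)/2 = 45 coefficients.  Only even degrees appear:
diffusion signals and ODFs are antipodally symmetric.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre, sph_harm_y


def lm_pairs(order: int) -> list[tuple[int, int]]:
    """(l, m) index map for an even-order symmetric basis."""
    if order % 2 or order < 0:
        raise ValueError("order must be a non-negative even integer")
    return [(l, m) for l in range(0, order + 1, 2) for m in range(-l, l + 1)]


def n_coefficients(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def real_sh_basis(order: int, directions: np.ndarray) -> np.ndarray:
    """Design matrix of the real symmetric basis at unit ``directions`` (n, 3)."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    cols = []
    for l, m in lm_pairs(order):
        if m < 0:
            cols.append(np.sqrt(2.0) * sph_harm_y(l, -m, theta, phi).real)
        elif m == 0:
            cols.append(sph_harm_y(l, 0, theta, phi).real)
        else:
            cols.append(np.sqrt(2.0) * sph_harm_y(l, m, theta, phi).imag)
    return np.stack(cols, axis=-1)


def degrees(order: int) -> np.ndarray:
    """Degree l of each coefficient."""
    return np.array([l for l, _ in lm_pairs(order)])


def laplace_beltrami(order: int) -> np.ndarray:
    """Diagonal of the squared Laplace-Beltrami operator, (l(l+1))^2."""
    l = degrees(order)
    return (l * (l + 1.0)) ** 2


def funk_radon_diagonal(order: int) -> np.ndarray:
    """Funk-Radon transform eigenvalues 2*pi*P_l(0) per coefficient.

    The transform is diagonal in the SH basis (Funk-Hecke theorem); P_l(0)
    alternates in sign and shrinks with l.
    """
    l = degrees(order)
    return 2.0 * np.pi * eval_legendre(l, 0.0)
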