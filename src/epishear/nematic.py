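"""Vectorized helpers for 2D symmetric-traceless (nematic) tensors.

A nematic is stored as a component pair ``(n_xx, n_xy)`` representing the
matrix ``[[n_xx, n_xy], [n_xy, -n_xx]]``.  Its norm ``|n|`` and axis angle
``phi`` (mod pi) satisfy ``n_xx = |n| cos(2 phi)``, ``n_xy = |n| sin(2 phi)``,
so rotating the underlying material by ``phi0`` advances the tensor angle by
``2 phi0``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "nematic_to_matrix",
    "matrix_to_nematic",
    "rotate_nematic",
    "exp_traceless",
    "log_spd_unimodular",
    "rotation_matrix",
]


def nematic_to_matrix(nxx, nxy):
    """Component pair -> stacked 2x2 symmetric traceless matrices (…,2,2)."""
    nxx = np.asarray(nxx, dtype=float)
    nxy = np.asarray(nxy, dtype=float)
    out = np.empty(nxx.shape + (2, 2))
    out[..., 0, 0] = nxx
    out[..., 0, 1] = nxy
    out[..., 1, 0] = nxy
    out[..., 1, 1] = -nxx
    return out


def matrix_to_nematic(m):
    """Symmetric-traceless part of stacked 2x2 matrices -> (n_xx, n_xy)."""
    m = np.asarray(m, dtype=float)
    nxx = 0.5 * (m[..., 0, 0] - m[..., 1, 1])
    nxy = 0.5 * (m[..., 0, 1] + m[..., 1, 0])
    return nxx, nxy


def rotate_nematic(nxx, nxy, phi):
    """Rotate a nematic by material angle ``phi`` (tensor angle 2*phi)."""
    c = np.cos(2.0 * np.asarray(phi, dtype=float))
    s = np.sin(2.0 * np.asarray(phi, dtype=float))
    return c * nxx - s * nxy, s * nxx + c * nxy


def rotation_matrix(phi):
    """Stacked 2x2 rotation matrices for angles ``phi``."""
    phi = np.asarray(phi, dtype=float)
    c, s = np.cos(phi), np.sin(phi)
    out = np.empty(phi.shape + (2, 2))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def exp_traceless(nxx, nxy):
    """Matrix exponential of the traceless symmetric matrix (n_xx, n_xy).

    Closed form: ``exp(N) = cosh(|n|) I + sinh(|n|)/|n| N`` with the
    ``|n| -> 0`` limit handled by series.
    """
    nxx = np.asarray(nxx, dtype=float)
    nxy = np.asarray(nxy, dtype=float)
    q = np.hypot(nxx, nxy)
    small = q < 1e-12
    qs = np.where(small, 1.0, q)
    fac = np.where(small, 1.0 + q * q / 6.0, np.sinh(qs) / qs)
    out = np.zeros(nxx.shape + (2, 2))
    out[..., 0, 0] = np.cosh(q) + fac * nxx
    out[..., 0, 1] = fac * nxy
    out[..., 1, 0] = fac * nxy
    out[..., 1, 1] = np.cosh(q) - fac * nxx
    return out


def log_spd_unimodular(m):
    """Matrix log of stacked SPD 2x2 matrices with det 1 -> (n_xx, n_xy).

    For ``M = exp(N)`` with N traceless symmetric, ``cosh(|n|) = tr(M)/2``
    and ``N = (M - cosh(|n|) I) * |n|/sinh(|n|)``.
    """
    m = np.asarray(m, dtype=float)
    tr_half = 0.5 * (m[..., 0, 0] + m[..., 1, 1])
    # guard against round-off pushing tr/2 slightly below 1
    tr_half = np.maximum(tr_half, 1.0)
    q = np.arccosh(tr_half)
    small = q < 1e-8
    qs = np.where(small, 1.0, q)
    fac = np.where(small, 1.0 - q * q / 6.0, qs / np.sinh(qs))
    nxx = fac * (m[..., 0, 0] - tr_half)
    nxy = fac * m[..., 0, 1]
    return nxx, nxy
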