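"""Core polarization algebra: Stokes vectors and elementary Mueller matrices.

A Stokes vector ``S = (s0, s1, s2, s3)`` describes a quasi-monochromatic
beam: ``s0`` is the total intensity, ``s1`` the horizontal/vertical linear
component, ``s2`` the +/-45 deg linear component and ``s3`` the circular
component.  A sample acts on it linearly through a 4x4 real Mueller matrix.
This module provides constructors for the elementary Mueller matrices
(rotated linear retarder, linear diattenuator, diagonal depolarizer,
circular rotator) and physical-validity checks; everything downstream --
the polarimeter digital twin, the eigenvalue calibration, the Lu-Chipman
decomposition and the ring-phantom generator -- is built on top of these.

Conventions (used consistently across the package):

* All angles in public interfaces are degrees, measured counter-clockwise
  from horizontal while looking into the beam; radians are internal only.
* Right-circular polarization is ``S = (1, 0, 0, 1)``.
* The linear retarder follows the Lu-Chipman sign convention: at zero axis
  the matrix is ``diag-block [[cos d, sin d], [-sin d, cos d]]`` in the
  (s2, s3) plane, so a quarter-wave plate at 0 deg maps ``(1,0,0,1)`` to
  ``(1,0,1,0)``.
* Element indexing in documentation is 1-based (``m11`` top-left), as in
  the optics literature; code uses 0-based numpy indices.

All constructors broadcast: scalar arguments give a single ``(4, 4)``
matrix, array arguments of shape ``B`` give a ``B + (4, 4)`` stack.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElementarySampleSpec",
    "rotation_mueller",
    "make_linear_retarder",
    "make_linear_diattenuator",
    "make_diagonal_depolarizer",
    "make_rotator",
    "stokes_linear",
    "stokes_circular",
    "degree_of_polarization",
    "coherency_matrix",
    "is_physical",
]

ELEMENT_KINDS = ("retarder", "diattenuator", "depolarizer", "rotator", "air")


def _broadcast(*args):
    arrs = [np.asarray(a, dtype=float) for a in args]
    shape = np.broadcast_shapes(*(a.shape for a in arrs))
    return [np.broadcast_to(a, shape) for a in arrs], shape


def rotation_mueller(angle_deg) -> np.ndarray:
    """Mueller rotation matrix R(theta) for a frame rotation by ``angle_deg``.

    Rotating an element by theta is ``R(theta) @ M @ R(-theta)``.  The
    matrix carries ``cos(2 theta)`` / ``sin(2 theta)`` entries because the
    Stokes parameters (s1, s2) transform at twice the geometric angle.
    """
    a = 2.0 * np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    M = np.zeros(a.shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 3, 3] = 1.0
    M[..., 1, 1] = c
    M[..., 1, 2] = -s
    M[..., 2, 1] = s
    M[..., 2, 2] = c
    return M


def make_linear_retarder(retardance_deg, axis_deg) -> np.ndarray:
    """Mueller matrix of a linear retarder.

    Parameters
    ----------
    retardance_deg : float or array
        Phase retardance delta between fast and slow axis, degrees.
    axis_deg : float or array
        Fast-axis orientation, degrees counter-clockwise from horizontal.

    Returns
    -------
    ndarray, shape ``(..., 4, 4)`` with determinant 1 and ``m11 = 1``.
    """
    (d, t), shape = _broadcast(np.deg2rad(retardance_deg), np.deg2rad(axis_deg))
    cd, sd = np.cos(d), np.sin(d)
    C, S = np.cos(2 * t), np.sin(2 * t)
    M = np.zeros(shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 1, 1] = C * C + S * S * cd
    M[..., 1, 2] = C * S * (1 - cd)
    M[..., 1, 3] = -S * sd
    M[..., 2, 1] = C * S * (1 - cd)
    M[..., 2, 2] = S * S + C * C * cd
    M[..., 2, 3] = C * sd
    M[..., 3, 1] = S * sd
    M[..., 3, 2] = -C * sd
    M[..., 3, 3] = cd
    return M


def make_linear_diattenuator(q_transmittance, r_transmittance, axis_deg) -> np.ndarray:
    """Mueller matrix of a linear (partial) polarizer.

    ``q`` is the intensity transmittance along the transmission axis, ``r``
    the transmittance perpendicular to it; diattenuation
    ``D = (q - r)/(q + r)``.  ``r = 0`` gives an ideal polarizer.
    """
    (q, r, t), shape = _broadcast(q_transmittance, r_transmittance, axis_deg)
    if np.any(r > q + 1e-12):
        raise ValueError("require r_transmittance <= q_transmittance")
    if np.any(q > 1 + 1e-12) or np.any(r < -1e-12):
        raise ValueError("transmittances must lie in [0, 1] with r <= q")
    M = np.zeros(shape + (4, 4))
    g = np.sqrt(q * r)
    M[..., 0, 0] = 0.5 * (q + r)
    M[..., 0, 1] = 0.5 * (q - r)
    M[..., 1, 0] = 0.5 * (q - r)
    M[..., 1, 1] = 0.5 * (q + r)
    M[..., 2, 2] = g
    M[..., 3, 3] = g
    return rotation_mueller(t) @ M @ rotation_mueller(-t)


def make_diagonal_depolarizer(a, b, c) -> np.ndarray:
    """Diagonal depolarizer ``diag(1, a, b, c)``.

    ``a``/``b`` attenuate the two linear polarization channels (H/V and
    +/-45 deg) and ``c`` the circular channel; all must lie in [0, 1].
    ``(1, 1, 1)`` is the identity (no depolarization).
    """
    (a_, b_, c_), shape = _broadcast(a, b, c)
    for v in (a_, b_, c_):
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("depolarizer diagonal values must lie in [0, 1]")
    M = np.zeros(shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 1, 1] = a_
    M[..., 2, 2] = b_
    M[..., 3, 3] = c_
    return M


def make_rotator(rotation_deg) -> np.ndarray:
    """Circular retarder (optical rotator) rotating the polarization
    ellipse by ``rotation_deg``; its Mueller matrix is the frame rotation
    ``R(rotation_deg)`` (entries at twice the angle)."""
    return rotation_mueller(rotation_deg)


def stokes_linear(angle_deg) -> np.ndarray:
    """Unit-intensity fully linearly polarized Stokes vector at ``angle_deg``."""
    a = 2.0 * np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack(
        [np.ones_like(a), np.cos(a), np.sin(a), np.zeros_like(a)], axis=-1
    )


def stokes_circular(handedness: int = 1) -> np.ndarray:
    """Unit-intensity circular Stokes vector; ``+1`` right, ``-1`` left."""
    if handedness not in (1, -1):
        raise ValueError("handedness must be +1 or -1")
    return np.array([1.0, 0.0, 0.0, float(handedness)])


def degree_of_polarization(S) -> np.ndarray:
    """DOP = |(s1, s2, s3)| / s0; 1 for fully polarized light."""
    S = np.asarray(S, dtype=float)
    return np.linalg.norm(S[..., 1:], axis=-1) / S[..., 0]


# ---------------------------------------------------------------------------
# physicality checks

_PAULI = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)


def _poincare_grid() -> np.ndarray:
    """Deterministic 26-direction grid on the Poincare sphere: the 6 axis
    points, 12 edge midpoints and 8 corner directions of the unit cube."""
    dirs = []
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                if i == j == k == 0:
                    continue
                v = np.array([i, j, k], dtype=float)
                dirs.append(v / np.linalg.norm(v))
    return np.array(dirs)  # (26, 3)


_GRID = _poincare_grid()
_GRID_STOKES = np.concatenate([np.ones((26, 1)), _GRID], axis=1)  # (26, 4)


def coherency_matrix(M) -> np.ndarray:
    """Hermitian coherency matrix of a Mueller matrix (Cloude).

    ``H = 1/4 sum_ij m_ij (sigma_i kron sigma_j*)``; M is a physical
    (completely positive) map iff H is positive semi-definite.
    """
    M = np.asarray(M, dtype=float)
    H = np.zeros(M.shape[:-2] + (4, 4), dtype=complex)
    for i in range(4):
        for j in range(4):
            basis = np.kron(_PAULI[i], _PAULI[j].conj())
            H = H + 0.25 * M[..., i, j, None, None] * basis
    return H


def is_physical(M, tol: float = 1e-9, method: str = "grid"):
    """Check that a Mueller matrix maps physical light to physical light.

    ``method="grid"`` (default, cheap): propagates a fixed 26-direction set
    of fully polarized Stokes vectors and requires every output to have
    nonnegative intensity and degree of polarization <= 1 + ``tol``.
    ``method="cloude"`` (stricter): requires the coherency-matrix
    eigenvalues to be >= ``-tol`` times the largest eigenvalue.

    Returns a boolean (or boolean array for a stack of matrices).
    """
    M = np.asarray(M, dtype=float)
    if method == "cloude":
        ev = np.linalg.eigvalsh(coherency_matrix(M))
        scale = np.maximum(ev[..., -1], 1e-300)
        return np.all(ev >= -tol * scale, axis=-1)
    if method != "grid":
        raise ValueError(f"unknown method {method!r}")
    out = np.einsum("...ij,nj->...ni", M, _GRID_STOKES)
    s0 = out[..., 0]
    pol = np.linalg.norm(out[..., 1:], axis=-1)
    ok = (s0 >= -tol) & (pol <= s0 + tol)
    return np.all(ok, axis=-1)


# ---------------------------------------------------------------------------
# elementary sample specification


@dataclass(frozen=True)
class ElementarySampleSpec:
    """Parametric description of an elementary polarization element.

    Used both for the calibration reference set (air, polarizers, wave
    plates) and for specifying synthetic samples.  ``axis_deg`` is the
    fast axis for a retarder and the transmission axis for a diattenuator.
    """

    kind: str
    retardance_deg: float = 0.0
    axis_deg: float = 0.0
    q_transmittance: float = 1.0
    r_transmittance: float = 0.0
    depolarizer_diag: tuple = (1.0, 1.0, 1.0)
    rotation_deg: float = 0.0

    def __post_init__(self):
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if not (
            -1e-12 <= self.r_transmittance <= self.q_transmittance <= 1 + 1e-12
        ):
            raise ValueError("require 0 <= r <= q <= 1")
        if any(not (-1e-12 <= v <= 1 + 1e-12) for v in self.depolarizer_diag):
            raise ValueError("depolarizer diagonal must lie in [0, 1]")

    def to_mueller(self) -> np.ndarray:
        if self.kind == "air":
            return np.eye(4)
        if self.kind == "retarder":
            return make_linear_retarder(self.retardance_deg, self.axis_deg)
        if self.kind == "diattenuator":
            return make_linear_diattenuator(
                self.q_transmittance, self.r_transmittance, self.axis_deg
            )
        if self.kind == "depolarizer":
            return make_diagonal_depolarizer(*self.depolarizer_diag)
        return make_rotator(self.rotation_deg)

    def with_axis(self, axis_deg: float) -> "ElementarySampleSpec":
        return dataclasses.replace(self, axis_deg=float(axis_deg))


def ideal_polarizer(axis_deg: float) -> ElementarySampleSpec:
    return ElementarySampleSpec("diattenuator", axis_deg=axis_deg)


def quarter_wave_plate(axis_deg: float) -> ElementarySampleSpec:
    return ElementarySampleSpec("retarder", retardance_deg=90.0, axis_deg=axis_deg)
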