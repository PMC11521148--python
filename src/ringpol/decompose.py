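"""Scalar polarimetric parameter maps: Lu-Chipman polar decomposition and
the Mueller matrix transformation.

The Lu-Chipman polar decomposition (MMPD) factors an arbitrary Mueller
matrix into the ordered product

    ``M = M_depol @ M_ret @ M_diat``

of a depolarizer, a retarder and a diattenuator, from which the scalar
parameters follow:

* diattenuation        ``D  = |(m12, m13, m14)| / m11``
* total retardance     ``R  = arccos(tr(M_ret)/2 - 1)``           (deg)
* linear retardance    ``delta = arccos(sqrt((mR22+mR33)^2
                                 + (mR32-mR23)^2) - 1)``          (deg)
* circular retardance  ``psi = 1/2 arctan((mR32-mR23)/(mR22+mR33))``
  (the optical rotation; the retarder block carries 2 psi)        (deg)
* depolarization       ``Delta  = 1 - |tr m_depol| / 3``
* linear depol.        ``DeltaL = 1 - (|mD11| + |mD22|) / 2``
* circular depol.      ``DeltaC = 1 - |mD33|``

with ``mR``/``mD`` the 3x3 sub-blocks of the retarder/depolarizer factors
(1-based indices as in the optics literature).  The linear/circular
depolarization split is read off the diagonal of the depolarizer block,
which is appropriate for near-diagonal depolarizers like cleared tissue;
an eigenvalue-based variant is available behind ``diag_depol=False``.

The MMT parameters are rotation invariant by construction:

    ``b = (m22 + m33)/2``,
    ``t = sqrt((m22 - m33)^2 + (m23 + m32)^2) / 2``,
    ``A = 2 b t / (b^2 + t^2)``  (degree of anisotropy, 0..1).

All functions are vectorized over leading axes; a single (4, 4) matrix
works as a one-pixel image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reconstruct import MuellerImage

__all__ = ["MMPDResult", "MMTResult", "mmpd_decompose", "mmt_transform"]

_EPS = 1e-12


@dataclass
class MMPDResult:
    """Per-pixel Lu-Chipman factors and scalar maps (angles in degrees)."""

    M_depol: np.ndarray
    M_ret: np.ndarray
    M_diat: np.ndarray
    D: np.ndarray
    R_deg: np.ndarray
    delta_deg: np.ndarray
    psi_deg: np.ndarray
    Delta: np.ndarray
    DeltaL: np.ndarray
    DeltaC: np.ndarray
    axis_deg: np.ndarray
    counters: dict = field(default_factory=dict)

    def maps(self) -> dict:
        return {
            "D": self.D,
            "R_deg": self.R_deg,
            "delta_deg": self.delta_deg,
            "psi_deg": self.psi_deg,
            "Delta": self.Delta,
            "DeltaL": self.DeltaL,
            "DeltaC": self.DeltaC,
            "axis_deg": self.axis_deg,
        }


@dataclass
class MMTResult:
    b: np.ndarray
    t: np.ndarray
    A_mmt: np.ndarray

    def maps(self) -> dict:
        return {"b": self.b, "t": self.t, "A_mmt": self.A_mmt}


def _clip_count(x, lo, hi, counters, key):
    clipped = np.count_nonzero((x < lo) | (x > hi))
    if clipped:
        counters[key] = counters.get(key, 0) + int(clipped)
    return np.clip(x, lo, hi)


def mmpd_decompose(M, diag_depol: bool = True) -> MMPDResult:
    """Lu-Chipman polar decomposition, vectorized over leading axes.

    Accepts a ``(..., 4, 4)`` array or a :class:`MuellerImage`.  Pixels
    must have ``m11 > 0``; NaN pixels propagate to NaN maps.  Negative
    square-root arguments are clipped at zero and counted in
    ``result.counters`` as a per-image quality metric, as are arccos
    argument clips and depolarizer-sign ties.
    """
    if isinstance(M, MuellerImage):
        M = M.field
    M = np.asarray(M, dtype=float)
    if M.shape[-2:] != (4, 4):
        raise ValueError("expected trailing shape (4, 4)")
    counters: dict = {}

    m11 = M[..., 0, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        Mn = M / m11[..., None, None]

    # --- diattenuator factor ------------------------------------------------
    d = Mn[..., 0, 1:]                     # diattenuation vector
    D = np.linalg.norm(d, axis=-1)
    D_ = _clip_count(D, 0.0, 1.0, counters, "diattenuation_clips")
    dn = np.where(D_[..., None] > _EPS, d / np.maximum(D_, _EPS)[..., None], 0.0)
    sq = np.sqrt(np.clip(1.0 - D_**2, 0.0, None))
    I3 = np.eye(3)
    dd = dn[..., :, None] * dn[..., None, :]
    mD = sq[..., None, None] * (I3 - dd) + dd
    MD = np.zeros_like(Mn)
    MD[..., 0, 0] = 1.0
    MD[..., 0, 1:] = d
    MD[..., 1:, 0] = d
    MD[..., 1:, 1:] = mD
    # pseudo-inverse handles the singular D = 1 limit of an ideal polarizer
    MD_inv = np.linalg.pinv(np.nan_to_num(MD, nan=0.0))
    MD_inv = np.where(np.isfinite(Mn).all(axis=(-2, -1))[..., None, None], MD_inv, np.nan)
    Mp = Mn @ MD_inv

    # --- depolarizer factor from the square-root construction ---------------
    mp = Mp[..., 1:, 1:]
    G = mp @ np.swapaxes(mp, -1, -2)
    G = 0.5 * (G + np.swapaxes(G, -1, -2))  # enforce exact symmetry
    Gs = np.nan_to_num(G, nan=0.0)
    lam = np.linalg.eigvalsh(Gs)           # ascending
    neg = np.count_nonzero(lam < -1e-12)
    if neg:
        counters["sqrt_clips"] = int(neg)
    lam = np.clip(lam, 0.0, None)
    r1, r2, r3 = (np.sqrt(lam[..., k]) for k in (0, 1, 2))
    c1 = r1 + r2 + r3
    c2 = r1 * r2 + r2 * r3 + r3 * r1
    c3 = r1 * r2 * r3
    det = np.linalg.det(np.nan_to_num(mp, nan=0.0))
    ties = np.count_nonzero(np.abs(det) < 1e-300)
    if ties:
        counters["det_sign_ties"] = int(ties)
    sgn = np.where(det < 0, -1.0, 1.0)
    inner = np.linalg.pinv(Gs + c2[..., None, None] * I3) @ (
        c1[..., None, None] * Gs + c3[..., None, None] * I3
    )
    mDelta = sgn[..., None, None] * inner
    P = Mn[..., 1:, 0]
    m3 = Mn[..., 1:, 1:]
    denom = np.maximum(1.0 - D_**2, _EPS)
    PDelta = (P - np.einsum("...ij,...j->...i", m3, d)) / denom[..., None]
    MDelta = np.zeros_like(Mn)
    MDelta[..., 0, 0] = 1.0
    MDelta[..., 1:, 0] = PDelta
    MDelta[..., 1:, 1:] = mDelta

    # --- retarder factor -----------------------------------------------------
    mDelta_inv = np.linalg.pinv(np.nan_to_num(mDelta, nan=0.0))
    MR = np.zeros_like(Mn)
    MR[..., 0, 0] = 1.0
    mR = mDelta_inv @ Mp[..., 1:, 1:]
    MR[..., 1:, 0] = np.einsum(
        "...ij,...j->...i", mDelta_inv, Mp[..., 1:, 0] - PDelta
    )
    MR[..., 1:, 1:] = mR

    # --- scalar maps ---------------------------------------------------------
    nanpix = ~np.isfinite(Mn).all(axis=(-2, -1))
    trR = 1.0 + mR[..., 0, 0] + mR[..., 1, 1] + mR[..., 2, 2]
    R = np.arccos(_clip_count(trR / 2.0 - 1.0, -1.0, 1.0, counters, "arccos_clips"))
    lin = np.hypot(mR[..., 0, 0] + mR[..., 1, 1], mR[..., 1, 0] - mR[..., 0, 1])
    delta = np.arccos(_clip_count(lin - 1.0, -1.0, 1.0, counters, "arccos_clips"))
    psi = 0.5 * np.arctan2(mR[..., 1, 0] - mR[..., 0, 1], mR[..., 0, 0] + mR[..., 1, 1])

    # fast axis of the linear component: peel the rotator off the retarder
    # factor (MR = MLR(delta, theta) @ MCR(psi)) before reading the
    # retardance vector, else the axis is biased by psi/2
    c2p, s2p = np.cos(2 * psi), np.sin(2 * psi)
    Rz = np.zeros(psi.shape + (3, 3))
    Rz[..., 0, 0] = c2p
    Rz[..., 0, 1] = s2p
    Rz[..., 1, 0] = -s2p
    Rz[..., 1, 1] = c2p
    Rz[..., 2, 2] = 1.0
    mLR = mR @ Rz
    sind = np.sin(delta)
    with np.errstate(invalid="ignore", divide="ignore"):
        a1 = (mLR[..., 1, 2] - mLR[..., 2, 1]) / (2 * sind)
        a2 = (mLR[..., 2, 0] - mLR[..., 0, 2]) / (2 * sind)
    axis = np.where(sind > 1e-9, 0.5 * np.arctan2(a2, a1), np.nan)
    axis = np.rad2deg(axis) % 180.0

    if diag_depol:
        e1, e2, e3 = (np.abs(mDelta[..., k, k]) for k in (0, 1, 2))
    else:
        # eigenvalue variant: principal depolarization factors
        ev = np.abs(np.linalg.eigvals(np.nan_to_num(mDelta, nan=0.0)))
        ev = np.sort(ev, axis=-1)[..., ::-1]
        e1, e2, e3 = ev[..., 0], ev[..., 1], ev[..., 2]
    trD = np.abs(mDelta[..., 0, 0]) + np.abs(mDelta[..., 1, 1]) + np.abs(mDelta[..., 2, 2])
    Delta = 1.0 - trD / 3.0
    DeltaL = 1.0 - (e1 + e2) / 2.0
    DeltaC = 1.0 - e3

    def _nanify(x):
        return np.where(nanpix, np.nan, x)

    return MMPDResult(
        M_depol=MDelta,
        M_ret=MR,
        M_diat=MD,
        D=_nanify(D_),
        R_deg=_nanify(np.rad2deg(R)),
        delta_deg=_nanify(np.rad2deg(delta)),
        psi_deg=_nanify(np.rad2deg(psi)),
        Delta=_nanify(Delta),
        DeltaL=_nanify(DeltaL),
        DeltaC=_nanify(DeltaC),
        axis_deg=_nanify(axis),
        counters=counters,
    )


def mmt_transform(M) -> MMTResult:
    """Mueller matrix transformation parameters b, t and the degree of
    anisotropy ``A = 2bt/(b^2 + t^2)`` (0 where b = t = 0).

    Expects matrices normalized to ``m11 = 1``; a :class:`MuellerImage`
    that is not yet normalized is normalized on the fly.
    """
    if isinstance(M, MuellerImage):
        X = M.field
        if not M.normalized:
            with np.errstate(invalid="ignore", divide="ignore"):
                X = X / X[..., 0, 0][..., None, None]
        M = X
    M = np.asarray(M, dtype=float)
    b = 0.5 * (M[..., 1, 1] + M[..., 2, 2])
    t = 0.5 * np.hypot(M[..., 1, 1] - M[..., 2, 2], M[..., 1, 2] + M[..., 2, 1])
    denom = b**2 + t**2
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > _EPS, 2 * b * t / np.maximum(denom, _EPS), 0.0)
    A = np.where(np.isfinite(M).all(axis=(-2, -1)), A, np.nan)
    return MMTResult(b=b, t=t, A_mmt=A)
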