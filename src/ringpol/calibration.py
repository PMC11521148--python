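"""Eigenvalue calibration of the polarimeter (ECM).

The characteristic matrices W and A of a real bench contain systematic
imperfections, so they are measured rather than assumed.  The eigenvalue
calibration method recovers them from acquisitions of a small set of
reference samples -- air, a linear polarizer at several axis angles, and
a quarter-wave plate -- without requiring those references to be mounted
at exactly their nominal angles.

The logic rests on a similarity relation.  With ``B0 = A W`` (air) and
``B_i = A M_i W`` for reference i, the 6x6 matrix

    ``C_i = pinv(B0) B_i = pinv(W) M_i W``

satisfies ``W C_i = M_i W`` exactly (A has full column rank, W full row
rank), so the four nonzero eigenvalues of ``C_i`` equal the eigenvalues of
``M_i``.  Those eigenvalues are basis invariant: they expose the reference
transmittances and retardance but not its axis angle.  The classical
square-matrix formulation is thereby generalized to the over-determined
8x6 frame geometry purely through pseudo-inverses.

Calibration then proceeds in three steps:

1. ``fit_reference_parameters`` reads transmittances / retardance off the
   eigenvalue spectrum of each ``C_i``.
2. ``solve_W`` finds W (up to scale, fixed by ``W[1,1] = 1``) as the null
   vector of the stacked linear operator ``X -> M_i X - X C_i``, with the
   reference axis angles refined numerically when the nominal angles do
   not already annihilate the kernel.  One reference axis is held fixed:
   a common rotation of all references and of W is a gauge freedom.
3. ``solve_A`` recovers A from the air acquisition, ``A = B0 pinv(W)``.

Eigenvalue spectra of the reference elements (used by step 1):

* linear diattenuator (q, r): ``{q, r, sqrt(q r), sqrt(q r)}`` -- all real;
* linear retarder with retardance d: ``{1, 1, exp(+i d), exp(-i d)}`` --
  a complex conjugate pair whose argument is the retardance;
* air: ``{1, 1, 1, 1}``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .instrument import InstrumentModel
from .mueller import ElementarySampleSpec

__all__ = [
    "CalibrationError",
    "AmbiguousCalibrationError",
    "ReferenceAcquisitionSet",
    "CalibrationResult",
    "similarity_reduce",
    "fit_reference_parameters",
    "solve_W",
    "solve_A",
    "calibrate",
]


class CalibrationError(RuntimeError):
    pass


class AmbiguousCalibrationError(CalibrationError):
    """The ECM kernel has more than one null direction: the reference set
    does not pin down the instrument (e.g. a single polarizer only)."""


@dataclass
class ReferenceAcquisitionSet:
    """Air acquisition ``b_air`` (8x6) plus further reference acquisitions,
    each paired with the nominal description of the mounted element."""

    b_air: np.ndarray
    refs: tuple  # ((ElementarySampleSpec, 8x6 ndarray), ...)
    coarse_aligned: bool = True  # null-intensity bench pre-alignment done

    def __post_init__(self):
        self.b_air = np.asarray(self.b_air, dtype=float)
        if self.b_air.shape != (8, 6):
            raise ValueError("b_air must be 8x6")
        if np.nanmin(self.b_air) < 0 or any(
            np.nanmin(np.asarray(b)) < 0 for _, b in self.refs
        ):
            raise ValueError("reference intensities must be nonnegative")


@dataclass
class CalibrationResult:
    instrument: InstrumentModel
    fitted_refs: tuple
    residual: float  # smallest-to-next singular-value ratio of the kernel


def similarity_reduce(b0: np.ndarray, b_i: np.ndarray) -> np.ndarray:
    """``C_i = pinv(b0) b_i``; its 4 nonzero eigenvalues equal those of the
    reference Mueller matrix.  Requires rank(b0) = 4.

    The pseudo-inverse is truncated to rank 4: ``b0 = A W`` has exactly
    rank 4 in physics, and noise-induced spurious singular values would
    otherwise be inverted and dominate the spectrum.
    """
    b0 = np.asarray(b0, dtype=float)
    b_i = np.asarray(b_i, dtype=float)
    U, s, Vt = np.linalg.svd(b0, full_matrices=False)
    if s[3] < 1e-6 * s[0]:
        raise CalibrationError("air acquisition is rank deficient: calibration impossible")
    pinv4 = (Vt[:4].T / s[:4]) @ U[:, :4].T
    return pinv4 @ b_i


def _principal_eigenvalues(C: np.ndarray) -> np.ndarray:
    """Four largest-magnitude eigenvalues of C (the two ~0 ones of the
    rank-4 similarity are discarded)."""
    ev = np.linalg.eigvals(C)
    order = np.argsort(-np.abs(ev))
    return ev[order][:4]


def fit_reference_parameters(
    C_i: np.ndarray, nominal: ElementarySampleSpec
) -> ElementarySampleSpec:
    """Extract the basis-invariant parameters of a reference element from
    the eigenvalue spectrum of its similarity matrix.

    The axis angle cannot be read off the spectrum; it stays at its nominal
    value here and is refined in :func:`solve_W`.
    """
    lam = _principal_eigenvalues(C_i)
    scale = np.max(np.abs(lam))
    if scale == 0:
        raise CalibrationError("degenerate reference: zero eigenvalue spectrum")
    # near-zero eigenvalues of a strong polarizer are (numerically)
    # degenerate and scatter as noise^(1/3); kind checks therefore only
    # consider eigenvalues comparable to the dominant one
    sig = lam[np.abs(lam) > 0.5 * scale]
    if nominal.kind == "diattenuator":
        if np.max(np.abs(sig.imag) / np.abs(sig)) > 0.2:
            raise CalibrationError(
                "complex eigenvalues: inconsistent with a diattenuator reference"
            )
        q = float(np.clip(np.max(sig.real), 0.0, 1.0))
        r = float(np.clip(np.min(lam.real), 0.0, q))
        return dataclasses.replace(nominal, q_transmittance=q, r_transmittance=r)
    if nominal.kind == "retarder":
        pair = sig[np.abs(sig.imag) / np.abs(sig) > 0.2]
        if pair.size < 2:
            raise CalibrationError(
                "no complex eigenvalue pair: inconsistent with a retarder reference"
            )
        pair = pair[np.argsort(-np.abs(pair.imag))][:2]
        ret = float(np.rad2deg(np.mean(np.abs(np.angle(pair)))))
        return dataclasses.replace(nominal, retardance_deg=ret)
    if nominal.kind == "air":
        return nominal
    raise CalibrationError(f"cannot fit reference of kind {nominal.kind!r}")


def _kernel_matrix(C_list, specs) -> np.ndarray:
    I4, I6 = np.eye(4), np.eye(6)
    blocks = []
    for C, spec in zip(C_list, specs):
        M = spec.to_mueller()
        blocks.append(np.kron(I6, M) - np.kron(C.T, I4))
    return np.vstack(blocks)


def _kernel_sv(C_list, specs):
    K = _kernel_matrix(C_list, specs)
    U, s, Vt = np.linalg.svd(K)
    return s, Vt


def solve_W(
    C_list,
    fitted_refs,
    fit_axes: bool = True,
    accept_residual: float = 1e-9,
    degeneracy_tol: float = 1e-6,
):
    """Solve for the PSG matrix W from the similarity matrices.

    Minimizes ``sum_i || M_i(theta_i) W - W C_i ||^2`` over W and the free
    reference axis angles; for exact data the minimum is a null vector of
    the stacked kernel.  The first axis-bearing reference keeps its nominal
    angle (rotation gauge).  Returns ``(W, residual, refined_refs)`` with
    the residual the smallest-to-next singular-value ratio of the kernel.

    Raises :class:`AmbiguousCalibrationError` when the kernel null space
    has dimension > 1 within ``degeneracy_tol`` (under-constrained
    reference set).
    """
    specs = list(fitted_refs)
    axis_bearing = [
        i for i, s in enumerate(specs) if s.kind in ("diattenuator", "retarder")
    ]
    free = axis_bearing[1:]  # first one fixes the rotation gauge

    def assemble(angles):
        out = list(specs)
        for k, i in enumerate(free):
            out[i] = out[i].with_axis(angles[k])
        return out

    s, Vt = _kernel_sv(C_list, specs)
    if fit_axes and free and s[-1] / max(s[0], 1e-300) > accept_residual:
        x0 = np.array([specs[i].axis_deg for i in free], dtype=float)

        def objective(angles):
            sv, _ = _kernel_sv(C_list, assemble(angles))
            return sv[-1]

        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
        )
        specs = assemble(res.x)
        s, Vt = _kernel_sv(C_list, specs)

    if s[-2] / max(s[0], 1e-300) < degeneracy_tol:
        raise AmbiguousCalibrationError(
            "ECM kernel null space has dimension > 1: reference set is degenerate"
        )
    w = Vt[-1]
    W = w.reshape(6, 4).T  # column-stacked vec(W)
    if abs(W[0, 0]) < 1e-6 * np.max(np.abs(W)):
        raise CalibrationError("recovered W has vanishing W[1,1]; cannot fix scale")
    W = W / W[0, 0]
    residual = float(s[-1] / max(s[-2], 1e-300))
    return W, residual, tuple(specs)


def solve_A(b0: np.ndarray, W: np.ndarray, rel_tol: float = 0.1) -> np.ndarray:
    """Recover the PSA matrix from the air acquisition: ``A = b0 pinv(W)``.

    The forward check ``||A W - b0|| / ||b0||`` must stay below
    ``rel_tol``; a larger residual signals an inconsistent air measurement.
    """
    b0 = np.asarray(b0, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.linalg.matrix_rank(W, tol=1e-8 * max(np.linalg.norm(W), 1e-300)) < 4:
        raise CalibrationError("W is rank deficient; cannot solve for A")
    A = b0 @ np.linalg.pinv(W)
    resid = np.linalg.norm(A @ W - b0) / max(np.linalg.norm(b0), 1e-300)
    if resid > rel_tol:
        raise CalibrationError(
            f"air acquisition inconsistent with W (relative residual {resid:.3g})"
        )
    return A


def _validate_reference_set(refs):
    pol_axes = {
        round(s.axis_deg % 180.0, 6) for s, _ in refs if s.kind == "diattenuator"
    }
    n_ret = sum(1 for s, _ in refs if s.kind == "retarder")
    if len(pol_axes) < 2 or n_ret < 1:
        raise CalibrationError(
            "reference set must span diattenuation and retardance: need a "
            "polarizer at >= 2 distinct axes plus a retarder"
        )


def calibrate(
    refset: ReferenceAcquisitionSet,
    fit_axes: bool = True,
    a_rel_tol: float = 0.1,
) -> CalibrationResult:
    """Full eigenvalue calibration from a reference acquisition set.

    Chains ``similarity_reduce`` -> ``fit_reference_parameters`` ->
    ``solve_W`` -> ``solve_A``.  Deterministic.  All references are used
    simultaneously in one stacked kernel system.
    """
    _validate_reference_set(refset.refs)
    C_list, fitted = [], []
    for nominal, b_i in refset.refs:
        C = similarity_reduce(refset.b_air, b_i)
        C_list.append(C)
        fitted.append(fit_reference_parameters(C, nominal))
    W, residual, fitted = solve_W(C_list, fitted, fit_axes=fit_axes)
    A = solve_A(refset.b_air, W, rel_tol=a_rel_tol)
    return CalibrationResult(
        instrument=InstrumentModel(W=W, A=A), fitted_refs=tuple(fitted), residual=residual
    )


def calibrate_per_pixel(
    b_air: np.ndarray, refs, smooth_sigma: float = 0.0, **kw
):
    """Pixel-by-pixel calibration: ``b_air`` is (H, W, 8, 6) and each
    reference acquisition likewise.  Runs the global calibration at every
    pixel; optionally smooths the recovered W/A fields with a Gaussian of
    ``smooth_sigma`` pixels (off by default).

    Returns ``(W_field, A_field, residual_field)``.
    """
    from scipy.ndimage import gaussian_filter

    b_air = np.asarray(b_air, dtype=float)
    H, Wd = b_air.shape[:2]
    W_field = np.zeros((H, Wd, 4, 6))
    A_field = np.zeros((H, Wd, 8, 4))
    resid = np.zeros((H, Wd))
    for y in range(H):
        for x in range(Wd):
            rs = ReferenceAcquisitionSet(
                b_air[y, x], tuple((s, b[y, x]) for s, b in refs)
            )
            out = calibrate(rs, **kw)
            W_field[y, x] = out.instrument.W
            A_field[y, x] = out.instrument.A
            resid[y, x] = out.residual
    if smooth_sigma > 0:
        W_field = gaussian_filter(W_field, sigma=(smooth_sigma, smooth_sigma, 0, 0))
        A_field = gaussian_filter(A_field, sigma=(smooth_sigma, smooth_sigma, 0, 0))
    return W_field, A_field, resid
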