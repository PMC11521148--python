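"""Eigenvalue calibration: similarity spectra, reference fitting, W/A recovery."""

import numpy as np
import pytest

from ringpol import (
    AmbiguousCalibrationError,
    ArmErrors,
    CalibrationError,
    build_instrument,
    calibrate,
    forward_acquire,
    ideal_schedule,
    mmpd_decompose,
    reconstruct_mueller,
)
from ringpol.calibration import (
    ReferenceAcquisitionSet,
    fit_reference_parameters,
    similarity_reduce,
    solve_A,
    solve_W,
)
from ringpol.mueller import ElementarySampleSpec
from ringpol.synth import REFERENCE_ELEMENTS, make_reference_acquisitions


def _ref_b(instrument, spec):
    return forward_acquire(spec.to_mueller(), instrument).as_matrix()


def _align_scale(X, X0):
    s = np.sum(X0 * X) / np.sum(X * X)
    return s * X


class TestSimilarityReduce:
    def test_air_spectrum_is_all_ones(self, instrument):
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        C = similarity_reduce(b0, b0)
        ev = np.sort(np.abs(np.linalg.eigvals(C)))[::-1]
        np.testing.assert_allclose(ev[:4], 1.0, atol=1e-9)
        np.testing.assert_allclose(ev[4:], 0.0, atol=1e-9)

    def test_polarizer_spectrum(self, instrument):
        # eigenvalues of the (q, r) diattenuator are {q, r, sqrt(qr), sqrt(qr)}
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        q, r = 0.95, 0.02
        spec = ElementarySampleSpec("diattenuator", axis_deg=30, q_transmittance=q,
                                    r_transmittance=r)
        C = similarity_reduce(b0, _ref_b(instrument, spec))
        ev = np.linalg.eigvals(C)
        ev = np.sort(ev[np.argsort(-np.abs(ev))][:4].real)[::-1]
        np.testing.assert_allclose(ev, sorted([q, np.sqrt(q * r), np.sqrt(q * r), r],
                                              reverse=True), atol=1e-9)

    def test_qwp_spectrum_has_quarter_wave_pair(self, instrument):
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        spec = ElementarySampleSpec("retarder", retardance_deg=90, axis_deg=45)
        C = similarity_reduce(b0, _ref_b(instrument, spec))
        ev = np.linalg.eigvals(C)
        ev4 = ev[np.argsort(-np.abs(ev))][:4]
        pair = ev4[np.argsort(-np.abs(ev4.imag))][:2]
        np.testing.assert_allclose(sorted(pair.imag), [-1, 1], atol=1e-9)
        ones = ev4[np.argsort(-np.abs(ev4.imag))][2:]
        np.testing.assert_allclose(ones.real, 1.0, atol=1e-9)

    def test_rank_deficient_air_rejected(self):
        with pytest.raises(CalibrationError):
            similarity_reduce(np.ones((8, 6)), np.ones((8, 6)))


class TestFitReferenceParameters:
    def test_ideal_qwp(self, instrument):
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        nominal = ElementarySampleSpec("retarder", retardance_deg=90, axis_deg=0)
        C = similarity_reduce(b0, _ref_b(instrument, nominal))
        fitted = fit_reference_parameters(C, nominal)
        assert fitted.retardance_deg == pytest.approx(90.0, abs=1e-9)

    def test_true_retardance_87_under_nominal_90(self, instrument):
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        true = ElementarySampleSpec("retarder", retardance_deg=87, axis_deg=10)
        C = similarity_reduce(b0, _ref_b(instrument, true))
        fitted = fit_reference_parameters(
            C, ElementarySampleSpec("retarder", retardance_deg=90, axis_deg=10)
        )
        assert fitted.retardance_deg == pytest.approx(87.0, abs=1e-9)

    def test_polarizer_transmittances_recovered(self, instrument):
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        true = ElementarySampleSpec("diattenuator", axis_deg=45, q_transmittance=0.95,
                                    r_transmittance=0.02)
        C = similarity_reduce(b0, _ref_b(instrument, true))
        fitted = fit_reference_parameters(C, true.with_axis(45))
        assert fitted.q_transmittance == pytest.approx(0.95, abs=1e-9)
        assert fitted.r_transmittance == pytest.approx(0.02, abs=1e-9)

    def test_spectrum_invariant_to_reference_axis(self, instrument):
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        rets = []
        for axis in (0.0, 37.0, 90.0):
            spec = ElementarySampleSpec("retarder", retardance_deg=78, axis_deg=axis)
            C = similarity_reduce(b0, _ref_b(instrument, spec))
            rets.append(fit_reference_parameters(C, spec).retardance_deg)
        np.testing.assert_allclose(rets, 78.0, atol=1e-9)

    def test_wrong_kind_detected(self, instrument):
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        pol = ElementarySampleSpec("diattenuator", axis_deg=0)
        C = similarity_reduce(b0, _ref_b(instrument, pol))
        with pytest.raises(CalibrationError, match="complex"):
            fit_reference_parameters(
                C, ElementarySampleSpec("retarder", retardance_deg=90)
            )


def _calibration_inputs(instrument, noise=None, seed=None):
    refs = make_reference_acquisitions(instrument, noise=noise, seed=seed)
    C_list, fitted = [], []
    for nominal, b in refs.refs:
        C = similarity_reduce(refs.b_air, b)
        C_list.append(C)
        fitted.append(fit_reference_parameters(C, nominal))
    return refs, C_list, fitted


class TestSolveW:
    def test_ideal_round_trip(self, instrument):
        _, C_list, fitted = _calibration_inputs(instrument)
        W, residual, _ = solve_W(C_list, fitted)
        np.testing.assert_allclose(W, instrument.W / instrument.W[0, 0], atol=1e-8)
        assert residual < 1e-10

    def test_perturbed_column_recovered(self):
        inst = build_instrument(
            ideal_schedule(), psg_errors=ArmErrors(polarizer_offset_deg=2.0)
        )
        _, C_list, fitted = _calibration_inputs(inst)
        W, _, _ = solve_W(C_list, fitted)
        np.testing.assert_allclose(W, inst.W / inst.W[0, 0], atol=1e-8)

    def test_single_reference_is_ambiguous(self, instrument):
        _, C_list, fitted = _calibration_inputs(instrument)
        with pytest.raises(AmbiguousCalibrationError):
            solve_W(C_list[:1], fitted[:1])


class TestSolveA:
    def test_ideal(self, instrument):
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        A = solve_A(b0, instrument.W)
        np.testing.assert_allclose(A, instrument.A, atol=1e-10)

    def test_noisy_air_within_two_percent(self, instrument, rng):
        b0 = _ref_b(instrument, ElementarySampleSpec("air"))
        noisy = b0 * (1 + rng.normal(0, 0.01, b0.shape))  # SNR ~ 100
        A = solve_A(noisy, instrument.W)
        err = np.abs(A - instrument.A).max() / np.abs(instrument.A).max()
        assert err <= 0.02

    def test_rank_deficient_W_rejected(self, instrument):
        W = instrument.W.copy()
        W[3] = 0.0
        with pytest.raises(CalibrationError):
            solve_A(_ref_b(instrument, ElementarySampleSpec("air")), W)


class TestCalibrate:
    def test_exact_recovery_of_perturbed_instrument(self):
        inst = build_instrument(
            ideal_schedule(),
            psg_errors=ArmErrors(2.0, -1.5, 4.0, 0.002),
            psa_errors=ArmErrors(-1.0, 2.5, -3.0),
        )
        result = calibrate(make_reference_acquisitions(inst))
        np.testing.assert_allclose(
            result.instrument.W, inst.W / inst.W[0, 0], atol=1e-8
        )
        A = _align_scale(result.instrument.A, inst.A)
        np.testing.assert_allclose(A, inst.A, atol=1e-8)

    def test_one_percent_noise_keeps_decomposition_near_one_percent(self, instrument, rng):
        refs = make_reference_acquisitions(instrument)
        noisy = ReferenceAcquisitionSet(
            b_air=refs.b_air * (1 + rng.normal(0, 0.01, (8, 6))),
            refs=tuple(
                (s, b * (1 + rng.normal(0, 0.01, (8, 6)))) for s, b in refs.refs
            ),
        )
        result = calibrate(noisy, fit_axes=False)
        # glass-slide-like identity sample through the miscalibrated matrices
        stack = forward_acquire(np.eye(4), instrument)
        res = mmpd_decompose(reconstruct_mueller(stack, result.instrument))
        assert res.D < 0.05
        assert res.Delta < 0.05
        assert res.R_deg < 3.0

    def test_kernel_residual_grows_with_noise(self, instrument, rng):
        residuals = []
        for sigma in (0.0, 1e-4, 1e-2):
            refs = make_reference_acquisitions(instrument)
            noisy = ReferenceAcquisitionSet(
                b_air=refs.b_air * (1 + rng.normal(0, sigma, (8, 6))),
                refs=tuple(
                    (s, b * (1 + rng.normal(0, sigma, (8, 6)))) for s, b in refs.refs
                ),
            )
            residuals.append(calibrate(noisy, fit_axes=False).residual)
        assert residuals[0] < residuals[1] < residuals[2]

    def test_reference_set_must_span(self, instrument):
        refs = make_reference_acquisitions(instrument)
        only_pols = tuple(r for r in refs.refs if r[0].kind == "diattenuator")
        with pytest.raises(CalibrationError):
            calibrate(ReferenceAcquisitionSet(refs.b_air, only_pols))

    def test_missing_air_rejected(self, instrument):
        with pytest.raises(ValueError, match="air"):
            make_reference_acquisitions(
                instrument, elements=tuple(e for e in REFERENCE_ELEMENTS if e.kind != "air")
            )
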