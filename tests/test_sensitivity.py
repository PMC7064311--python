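"""Sensitivity functions: energy forms, the first-order shift relation, and
the balancing adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rdspeech import (
    energies,
    modal_distributions,
    predict_shift,
    resonances,
    sensitivity_functions,
)
from rdspeech.sensitivity import (
    DegenerateSensitivityError,
    adjust_and_normalize,
)


class TestEnergies:
    def test_zero_flow_means_zero_kinetic_energy(self, uniform):
        p = np.ones(uniform.n_sections, dtype=complex)
        u = np.zeros(uniform.n_sections, dtype=complex)
        e = energies(uniform, p, u)
        assert np.all(e.kinetic == 0)
        assert np.all(e.potential > 0)

    def test_energies_are_quadratic_in_amplitude(self, uniform, lossless):
        f1 = resonances(uniform, None, lossless).f_R[0]
        p, u = modal_distributions(uniform, None, lossless, f1)
        e1 = energies(uniform, p, u)
        e2 = energies(uniform, 3.0 * p, 3.0 * u)
        np.testing.assert_allclose(e2.kinetic, 9.0 * e1.kinetic)
        np.testing.assert_allclose(e2.potential, 9.0 * e1.potential)

    def test_first_mode_energy_distribution(self, uniform, lossless):
        # quarter-wave mode: kinetic energy concentrated toward the lips,
        # potential toward the glottis
        f1 = resonances(uniform, None, lossless).f_R[0]
        p, u = modal_distributions(uniform, None, lossless, f1)
        e = energies(uniform, p, u)
        n = uniform.n_sections // 2
        assert e.kinetic[-n:].sum() > e.kinetic[:n].sum()
        assert e.potential[:n].sum() > e.potential[-n:].sum()


class TestSensitivityFunctions:
    def test_magnitudes_bounded_by_one(self, neutral, branch, losses):
        sf = sensitivity_functions(neutral, branch, losses)
        assert np.all(np.abs(sf.S) <= 1.0)

    def test_uniform_tube_first_resonance_polarity(self, uniform, lossless):
        # constriction at the lips lowers the first resonance: S_1 > 0 there
        sf = sensitivity_functions(uniform, None, lossless)
        assert np.all(sf.S[0][-5:] > 0)
        assert np.all(sf.S[0][:5] < 0)

    def test_uniform_relative_perturbation_produces_no_shift(
        self, uniform, lossless
    ):
        # scaling every area equally leaves resonances unchanged, so the
        # sensitivities of a uniform tube must sum to ~0
        sf = sensitivity_functions(uniform, None, lossless)
        assert np.all(np.abs(sf.S.sum(axis=1)) < 0.05)

    def test_invariant_to_source_amplitude(self, uniform, lossless):
        # the energy ratio cancels any overall modal amplitude
        f1 = resonances(uniform, None, lossless).f_R[0]
        p, u = modal_distributions(uniform, None, lossless, f1)
        for scale in (1.0, 10.0):
            e = energies(uniform, scale * p, scale * u)
            s = (e.kinetic - e.potential) / (e.kinetic + e.potential).sum()
            if scale == 1.0:
                s_ref = s
        np.testing.assert_allclose(s, s_ref, rtol=1e-12)


class TestPredictShift:
    def test_zero_perturbation_zero_shift(self, neutral, branch, losses):
        sf = sensitivity_functions(neutral, branch, losses)
        np.testing.assert_array_equal(
            predict_shift(sf, np.zeros(neutral.n_sections)), np.zeros(3)
        )

    def test_linearity_sign_flip(self, neutral, branch, losses):
        sf = sensitivity_functions(neutral, branch, losses)
        d = np.zeros(neutral.n_sections)
        d[40] = 0.01
        np.testing.assert_allclose(
            predict_shift(sf, -d), -predict_shift(sf, d)
        )

    def test_lip_dilation_raises_first_resonance(self, uniform, lossless):
        sf = sensitivity_functions(uniform, None, lossless)
        base = resonances(uniform, None, lossless).f_R
        d = np.zeros(uniform.n_sections)
        d[-1] = 0.01
        pred = predict_shift(sf, d)
        assert pred[0] > 0
        pert = uniform.with_areas(uniform.areas * (1 + d))
        actual = (resonances(pert, None, lossless).f_R - base) / base
        np.testing.assert_allclose(pred, actual, rtol=0.10)

    def test_first_order_prediction_matches_recomputation(
        self, uniform, lossless
    ):
        # brute-force oracle: perturb one section by 1%, re-find resonances
        sf = sensitivity_functions(uniform, None, lossless)
        base = resonances(uniform, None, lossless).f_R
        rng = np.random.default_rng(11)
        for i in rng.choice(uniform.n_sections, 5, replace=False):
            d = np.zeros(uniform.n_sections)
            d[i] = 0.01
            pred = predict_shift(sf, d)
            pert = uniform.with_areas(uniform.areas * (1 + d))
            actual = (resonances(pert, None, lossless).f_R - base) / base
            assert np.all(
                (np.abs(pred - actual) <= 0.10 * np.abs(actual))
                | (np.abs(pred - actual) <= 1e-3)
            )


class TestAdjustAndNormalize:
    def test_peak_magnitude_is_one(self, neutral, branch, losses):
        sf = sensitivity_functions(neutral, branch, losses)
        for z in sf.Z:
            assert np.max(np.abs(z)) == pytest.approx(1.0)

    def test_polarity_preserved(self, neutral, branch, losses):
        sf = sensitivity_functions(neutral, branch, losses)
        for s, z in zip(sf.S, sf.Z):
            nz = s != 0
            np.testing.assert_array_equal(np.sign(z[nz]), np.sign(s[nz]))

    def test_non_negative_input_gives_non_negative_output(self):
        s = np.abs(np.sin(np.linspace(0, 3, 44))) + 0.01
        z = adjust_and_normalize(s)
        assert np.all(z >= 0)

    def test_all_zero_input_rejected(self):
        with pytest.raises(DegenerateSensitivityError):
            adjust_and_normalize(np.zeros(44))

    @given(
        arrays(
            float,
            44,
            elements=st.floats(-1, 1, allow_nan=False, width=32),
        ).filter(lambda s: np.any(s != 0))
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_guarantees_hold_for_arbitrary_input(self, s):
        z = adjust_and_normalize(s)
        assert np.max(np.abs(z)) == pytest.approx(1.0)
        nz = s != 0
        assert np.all(np.sign(z[nz]) == np.sign(s[nz]))
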