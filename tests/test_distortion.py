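import numpy as np
import pytest

from ppgphylo.distortion import (
    DistortionConfig,
    dissimilarity_matrix,
    itakura,
    itakura_saito,
    itakura_symmetric,
    log_spectral,
    model_distortion,
    weighted_cepstral,
)
from ppgphylo.lpc import DegenerateSignalError, cepstrum_from_lpc, spectrum_grid
from ppgphylo.signal_io import SESSION_LABELS, Signal
from ppgphylo.synth import SynthConfig, generate_session

from conftest import model_from_reflections


def _scaled_gain(model, factor):
    """Same all-pole shape, gain (and hence r) multiplied by ``factor``."""
    from ppgphylo.lpc import LPCModel

    return LPCModel(order=model.order, a=model.a.copy(),
                    sigma2=model.sigma2 * factor, r=model.r * factor)


class TestItakuraSaito:
    def test_identical_models_give_zero(self, make_random_model, rng):
        m = make_random_model(rng)
        assert itakura_saito(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_constant_gain_ratio_closed_form(self, make_random_model, rng):
        m = make_random_model(rng)
        m2 = _scaled_gain(m, 0.5)  # P/P' = 2 everywhere
        expected = 2.0 - np.log(2.0) - 1.0
        assert itakura_saito(m, m2) == pytest.approx(expected, rel=1e-9)

    def test_grid_refinement_oracle_ar1(self):
        a = model_from_reflections([-0.5], 1.0)
        b = model_from_reflections([-0.3], 1.0)
        coarse = itakura_saito(a, b, G=1024)
        fine = itakura_saito(a, b, G=2**16)
        assert coarse == pytest.approx(fine, abs=1e-6)

    def test_non_negative_on_random_pairs(self, make_random_model, rng):
        for _ in range(10):
            m1, m2 = make_random_model(rng), make_random_model(rng)
            assert itakura_saito(m1, m2) >= 0.0


class TestItakura:
    def test_self_comparison_exactly_zero(self, make_random_model, rng):
        m = make_random_model(rng)
        assert itakura(m, m) == 0.0

    def test_non_negative_minimization_property(self, make_random_model, rng):
        for _ in range(10):
            m1, m2 = make_random_model(rng), make_random_model(rng)
            assert itakura(m1, m2) >= 0.0

    def test_generally_asymmetric(self):
        m1 = model_from_reflections([-0.6, 0.2], 1.0)
        m2 = model_from_reflections([0.4, -0.1], 2.0)
        assert abs(itakura(m1, m2) - itakura(m2, m1)) > 1e-4

    def test_closed_form_equals_spectral_integral_oracle(self, make_random_model,
                                                         rng):
        """log(a^T R' a / sigma'^2) vs log of the |A|^2/|A'|^2 quadrature.

        Holds exactly when R' is the model-implied autocorrelation of S'.
        """
        omega = spectrum_grid(2**16)
        for _ in range(5):
            m1, m2 = make_random_model(rng, rmax=0.9), make_random_model(rng, rmax=0.9)
            e1 = np.exp(-1j * np.outer(omega, np.arange(m1.order + 1)))
            ratio = np.abs(e1 @ m1.a_full) ** 2 / np.abs(e1 @ m2.a_full) ** 2
            integral = np.trapezoid(ratio, dx=np.pi / (omega.size - 1)) / np.pi
            assert itakura(m1, m2) == pytest.approx(np.log(integral), abs=1e-6)

    def test_symmetrized_is_mean_of_directions(self, make_random_model, rng):
        m1, m2 = make_random_model(rng), make_random_model(rng)
        expected = 0.5 * (itakura(m1, m2) + itakura(m2, m1))
        assert itakura_symmetric(m1, m2) == pytest.approx(expected)
        assert itakura_symmetric(m2, m1) == pytest.approx(expected)


class TestLogSpectral:
    def test_identical_models_zero_and_symmetric(self, make_random_model, rng):
        m1, m2 = make_random_model(rng), make_random_model(rng)
        assert log_spectral(m1, m1) == pytest.approx(0.0, abs=1e-12)
        assert log_spectral(m1, m2) == pytest.approx(log_spectral(m2, m1))

    @pytest.mark.parametrize("m_exp", [1, 2, 4])
    def test_gain_offset_closed_form(self, make_random_model, rng, m_exp):
        model = make_random_model(rng)
        scaled = _scaled_gain(model, 1.0 / np.e)  # V = 1 everywhere
        assert log_spectral(model, scaled, m=m_exp) == pytest.approx(1.0, rel=1e-9)

    def test_grid_refinement_oracle_ar1(self):
        a = model_from_reflections([-0.5], 1.0)
        b = model_from_reflections([-0.3], 1.0)
        assert log_spectral(a, b, G=1024) == pytest.approx(
            log_spectral(a, b, G=2**16), abs=1e-4
        )


class TestWeightedCepstral:
    def test_identical_zero_and_symmetric(self, make_random_model, rng):
        m1, m2 = make_random_model(rng), make_random_model(rng)
        assert weighted_cepstral(m1, m1) == 0.0
        assert weighted_cepstral(m1, m2) == pytest.approx(weighted_cepstral(m2, m1))

    def test_base_case_reduces_to_squared_a1_difference(self, make_random_model,
                                                        rng):
        m1, m2 = make_random_model(rng), make_random_model(rng)
        expected = (m2.a[0] - m1.a[0]) ** 2  # w(1) = 1 + 0.5 sin(pi) = 1
        assert weighted_cepstral(m1, m2, L=1, h=0.5) == pytest.approx(expected)

    def test_term_by_term_summation_oracle(self, make_random_model, rng):
        L, h = 11, 5.5
        for _ in range(5):
            m1, m2 = make_random_model(rng), make_random_model(rng)
            c1, c2 = cepstrum_from_lpc(m1, L), cepstrum_from_lpc(m2, L)
            expected = sum(
                (1.0 + h * np.sin(n * np.pi / L)) * (c1[n] - c2[n]) ** 2
                for n in range(1, L + 1)
            )
            assert weighted_cepstral(m1, m2, L=L, h=h) == pytest.approx(
                expected, abs=1e-12
            )

    def test_invalid_truncation_rejected(self, make_random_model, rng):
        with pytest.raises(ValueError):
            weighted_cepstral(make_random_model(rng), make_random_model(rng), L=0)


class TestMeasureFamilyProperties:
    def test_grid_convergence_on_smooth_pairs(self, make_random_model, rng):
        for _ in range(5):
            m1, m2 = make_random_model(rng, rmax=0.9), make_random_model(rng, rmax=0.9)
            assert abs(
                itakura_saito(m1, m2, 1024) - itakura_saito(m1, m2, 2048)
            ) < 1e-4 * max(1.0, itakura_saito(m1, m2, 2048))
            assert abs(
                log_spectral(m1, m2, G=1024) - log_spectral(m1, m2, G=2048)
            ) < 1e-4

    def test_monotone_in_ar1_pole_separation(self):
        """Every measure grows with |rho - rho'| on the AR(1) family."""
        reference = model_from_reflections([0.0], 1.0)
        rhos = np.linspace(0.0, 0.8, 9)
        models = [model_from_reflections([-rho], 1.0) for rho in rhos]
        for measure in ("ISD", "ID", "ID_s", "LSD", "WCD"):
            config = DistortionConfig(measure=measure, p=1, L=1, h=0.5)
            values = [model_distortion(m, reference, config) for m in models]
            diffs = np.diff(values)
            assert np.all(diffs >= -1e-12), (measure, values)


class TestDissimilarityMatrix:
    def test_identical_signals_give_zero_matrix(self, rng):
        x = rng.normal(size=400)
        signals = {"a": Signal(x, "a"), "b": Signal(x.copy(), "b")}
        m = dissimilarity_matrix(signals, DistortionConfig(measure="ID", p=4))
        np.testing.assert_allclose(m.values, 0.0, atol=1e-10)

    def test_session_matrix_shape_and_labels(self):
        signals = generate_session(config=SynthConfig(seed=11, coupling=0.3))
        m = dissimilarity_matrix(
            {s.label: s for s in signals}, DistortionConfig(measure="LSD")
        )
        assert m.labels == SESSION_LABELS
        assert m.values.shape == (4, 4)
        assert np.all(np.diag(m.values) == 0.0)
        np.testing.assert_array_equal(m.values, m.values.T)

    @pytest.mark.parametrize("measure", ["ISD", "ID", "ID_s", "LSD", "WCD"])
    def test_matrix_symmetric_for_every_measure(self, rng, measure):
        signals = generate_session(config=SynthConfig(seed=5, coupling=0.5))
        m = dissimilarity_matrix(
            {s.label: s for s in signals}, DistortionConfig(measure=measure)
        )
        np.testing.assert_array_equal(m.values, m.values.T)
        assert np.all(m.values >= 0.0)

    def test_input_order_permutes_labels_consistently(self):
        signals = list(generate_session(config=SynthConfig(seed=7)))
        config = DistortionConfig(measure="WCD")
        m1 = dissimilarity_matrix({s.label: s for s in signals}, config)
        rev = dissimilarity_matrix({s.label: s for s in signals[::-1]}, config)
        np.testing.assert_allclose(
            rev.permuted(m1.labels).values, m1.values, rtol=1e-12
        )

    def test_degenerate_signal_error_names_label(self):
        signals = {
            "good": Signal(np.sin(0.3 * np.arange(200)), "good"),
            "flat": Signal(np.zeros(200), "flat"),
        }
        with pytest.raises(DegenerateSignalError, match="flat"):
            dissimilarity_matrix(signals, DistortionConfig(measure="ID"))

    def test_needs_two_signals(self):
        with pytest.raises(ValueError):
            dissimilarity_matrix(
                {"only": Signal(np.sin(0.3 * np.arange(100)), "only")},
                DistortionConfig(),
            )
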