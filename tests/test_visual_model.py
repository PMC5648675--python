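import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chromaderm as cd
from chromaderm.spectra import Spectrum, default_grid, flat_spectrum
from chromaderm.visual_model import (
    PhotoreceptorClass,
    VisualSystem,
    achromatic_contrast,
    chromatic_contrast,
    contrast_vs_white,
    derive_weber_fractions,
    pigment_template,
    quantal_catch,
)


def rnl_distance_oracle(df, w):
    """Independent RNL evaluation: noise-weighted projection.

    The chromatic distance is the generalized-least-squares distance of the
    log-contrast vector from the achromatic (all-equal) axis: minimize over
    c of sum_i (df_i - c)^2 / w_i^2. This derivation never touches the
    product-form expression used by the implementation.
    """
    df = np.asarray(df, float)
    w2 = np.asarray(w, float) ** 2
    c = np.sum(df / w2) / np.sum(1.0 / w2)
    return float(np.sqrt(np.sum((df - c) ** 2 / w2)))


class TestPigmentTemplate:
    def test_peak_is_one_at_lambda_max(self):
        t = pigment_template(571.0)
        i = np.argmin(np.abs(t.wavelengths_nm - 571.0))
        assert t.values[i] == pytest.approx(1.0)
        assert np.argmax(t.values) == i

    def test_unimodal_short_wave_limb(self):
        t = pigment_template(571.0)
        wl = t.wavelengths_nm
        v450 = t.values[wl == 450.0][0]
        v530 = t.values[wl == 530.0][0]
        assert v450 < v530

    def test_matches_independent_template_evaluation(self):
        # frozen from a direct evaluation of the published A1 alpha-band
        # nomogram equations at lambda_max=571, lambda=500, peak-normalized
        # on the 1-nm grid
        t = pigment_template(571.0)
        v500 = t.values[t.wavelengths_nm == 500.0][0]
        assert v500 == pytest.approx(0.4098785878550015, abs=1e-6)

    def test_lambda_max_outside_grid_raises(self):
        with pytest.raises(ValueError):
            pigment_template(250.0)


class TestQuantalCatch:
    def test_unit_factors_reduce_to_sensitivity_integral(self):
        grid = default_grid()
        sens = pigment_template(500.0, grid)
        one = flat_spectrum(1.0, grid=grid)
        q = quantal_catch(sens, one, flat_spectrum(1.0, "irradiance", grid))
        assert q == pytest.approx(np.trapezoid(sens.values, grid), rel=1e-12)

    def test_linear_in_irradiance(self):
        grid = default_grid()
        sens = pigment_template(450.0, grid)
        refl = flat_spectrum(0.3, grid=grid)
        irr = flat_spectrum(0.7, "irradiance", grid)
        irr2 = flat_spectrum(1.4, "irradiance", grid)
        assert quantal_catch(sens, refl, irr2) == pytest.approx(
            2 * quantal_catch(sens, refl, irr), rel=1e-12)

    def test_matches_explicit_loop_summation(self):
        grid = default_grid()
        gauss = Spectrum(grid, np.exp(-((grid - 520.0) / 40.0) ** 2),
                         kind="sensitivity")
        refl = flat_spectrum(0.5, grid=grid)
        irr = flat_spectrum(2.0, "irradiance", grid)
        q = quantal_catch(gauss, refl, irr)
        prod = gauss.values * refl.values * irr.values
        acc = 0.0
        for i in range(grid.size - 1):  # explicit trapezoid accumulation
            acc += 0.5 * (prod[i] + prod[i + 1]) * (grid[i + 1] - grid[i])
        assert q == pytest.approx(acc, rel=1e-9)

    def test_grid_mismatch_rejected(self):
        sens = pigment_template(500.0)
        short = Spectrum([300.0, 700.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            quantal_catch(sens, short, flat_spectrum(1.0, "irradiance"))


class TestWeberDerivation:
    def test_reference_class_keeps_stated_noise(self, tawny_system):
        assert tawny_system.get("LWS").weber_fraction == pytest.approx(0.1)

    def test_equal_abundances_give_equal_noise(self):
        sys = VisualSystem(classes=tuple(
            PhotoreceptorClass(n, lm, 2.0)
            for n, lm in [("UVS", 365), ("SWS", 440), ("MWS", 493), ("LWS", 571)]))
        derived = derive_weber_fractions(sys)
        assert all(c.weber_fraction == pytest.approx(0.1) for c in derived.classes)

    def test_square_root_abundance_rule(self, tawny_system):
        # eta_UVS = 1 against eta_LWS = 6: omega = 0.1 * sqrt(6)
        assert tawny_system.get("UVS").weber_fraction == pytest.approx(
            0.1 * np.sqrt(6.0), rel=1e-12)

    def test_idempotent(self, tawny_system):
        twice = derive_weber_fractions(tawny_system)
        assert twice == tawny_system

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValueError):
            PhotoreceptorClass("LWS", 571, 0.0)


class TestChromaticContrast:
    def test_identical_stimulus_gives_zero(self, tawny_system):
        assert chromatic_contrast(np.zeros(4), tawny_system) == 0.0

    def test_dichromat_closed_form(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            df = rng.normal(size=2)
            w = rng.uniform(0.02, 0.5, size=2)
            expected = abs(df[0] - df[1]) / np.sqrt(w[0] ** 2 + w[1] ** 2)
            assert chromatic_contrast(df, w) == pytest.approx(expected, abs=1e-9)

    def test_matches_projection_oracle_tetrachromat(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            df = rng.normal(size=4)
            w = rng.uniform(0.02, 0.5, size=4)
            assert chromatic_contrast(df, w) == pytest.approx(
                rnl_distance_oracle(df, w), abs=1e-9)

    @given(st.floats(-3, 3), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_intensity_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        df = rng.normal(size=4)
        w = rng.uniform(0.05, 0.4, size=4)
        assert chromatic_contrast(df + shift, w) == pytest.approx(
            chromatic_contrast(df, w), abs=1e-9)

    def test_monotone_in_lws_deviation(self, tawny_system):
        # dS is minimized when the LWS log contrast sits at the
        # noise-weighted mean of the other channels; pulling it further
        # from that point (others fixed) never decreases dS
        w = tawny_system.weber_fractions()
        inv_w2 = 1.0 / w[:3] ** 2
        rng = np.random.default_rng(3)
        for _ in range(50):
            df = rng.normal(size=4)
            pivot = np.sum(df[:3] * inv_w2) / np.sum(inv_w2)
            scales = np.linspace(0.0, 3.0, 7)
            vals = []
            for s in scales:
                d = df.copy()
                d[3] = pivot + s * (df[3] - pivot)
                vals.append(chromatic_contrast(d, w))
            assert np.all(np.diff(vals) >= -1e-12)

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            chromatic_contrast(np.array([0.1]), np.array([0.1]))


class TestAchromaticContrast:
    def test_equal_catches_give_zero(self):
        assert achromatic_contrast(3.0, 3.0, 0.05) == 0.0

    def test_ratio_e_gives_twenty(self):
        assert achromatic_contrast(np.e, 1.0, 0.05) == pytest.approx(20.0)

    def test_hand_arithmetic(self):
        assert achromatic_contrast(np.exp(0.3135), 1.0, 0.05) == pytest.approx(6.27)

    def test_symmetric(self):
        assert achromatic_contrast(2.0, 5.0, 0.05) == pytest.approx(
            achromatic_contrast(5.0, 2.0, 0.05))

    def test_nonpositive_catch_rejected(self):
        with pytest.raises(ValueError):
            achromatic_contrast(0.0, 1.0, 0.05)


class TestContrastVsWhite:
    def test_white_standard_against_itself(self, tawny_system):
        res = contrast_vs_white(flat_spectrum(0.99), tawny_system)
        assert res["chromatic_jnd"] == pytest.approx(0.0, abs=1e-9)
        assert res["achromatic_jnd"] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(res["log_achromatic_jnd"])

    def test_flat_darker_surface(self, tawny_system):
        # flat spectra stimulate all classes in the same ratio: chromatic 0,
        # achromatic ln(exp(0.25)) / 0.05 = 5
        res = contrast_vs_white(flat_spectrum(0.99 * np.exp(-0.25)), tawny_system)
        assert res["chromatic_jnd"] == pytest.approx(0.0, abs=1e-9)
        assert res["achromatic_jnd"] == pytest.approx(5.0, rel=1e-9)
        assert res["log_achromatic_jnd"] == pytest.approx(np.log(5.0), rel=1e-9)

    def test_orange_more_chromatic_than_equal_mean_gray(self, tawny_system):
        orange = cd.generate_reflectance("orange", seed=1)
        gray = flat_spectrum(float(orange.values.mean()))
        assert (contrast_vs_white(orange, tawny_system)["chromatic_jnd"]
                > contrast_vs_white(gray, tawny_system)["chromatic_jnd"])

    def test_irradiance_scale_invariance(self, tawny_system):
        orange = cd.generate_reflectance("orange", seed=1)
        base = contrast_vs_white(orange, tawny_system,
                                 irradiance=flat_spectrum(1.0, "irradiance"))
        scaled = contrast_vs_white(orange, tawny_system,
                                   irradiance=flat_spectrum(37.0, "irradiance"))
        assert scaled["chromatic_jnd"] == pytest.approx(
            base["chromatic_jnd"], rel=1e-9)
        assert scaled["achromatic_jnd"] == pytest.approx(
            base["achromatic_jnd"], abs=1e-9)

    def test_zero_reflectance_propagates_catch_error(self, tawny_system):
        zero = Spectrum(default_grid(), np.zeros(401))
        with pytest.raises(ValueError):
            contrast_vs_white(zero, tawny_system)
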