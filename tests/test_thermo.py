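"""Melting and ITC thermodynamics: relations, fitters, round trips."""

import numpy as np
import pytest

from asitekit import reference
from asitekit.synthetic import (
    ItcSimParams,
    MeltSimParams,
    generate_itc_series,
    generate_melting_curve,
)
from asitekit.thermo import (
    C_TO_K,
    ItcSeries,
    MeltingCurve,
    R_KCAL,
    T_REF,
    fit_itc,
    fit_two_state,
    fraction_from_ka,
    gibbs,
    gibbs_from_ka,
    ka_from_fraction,
    ka_from_gibbs,
    ka_of_temperature,
    melting_temperature,
    vant_hoff_fit,
    vant_hoff_from_curve,
)


class TestKaRelations:
    def test_half_fraction_closed_form(self):
        assert ka_from_fraction(0.5, 2e-6) == pytest.approx(2e6)
        assert ka_from_fraction(0.5, 2e-6) == pytest.approx(4.0 / 2e-6)

    def test_monotone_vanishing_limit(self):
        c0 = 1e-6
        fs = np.array([1e-6, 1e-4, 1e-2, 0.1, 0.5, 0.9])
        kas = ka_from_fraction(fs, c0)
        assert np.all(np.diff(kas) > 0)
        assert kas[0] < 1e1

    @pytest.mark.parametrize("f", [1e-6, 0.01, 0.25, 0.5, 0.75, 0.99])
    def test_quadratic_inversion_identity(self, f):
        c0 = 2e-6
        assert fraction_from_ka(ka_from_fraction(f, c0), c0) == pytest.approx(
            f, abs=1e-12
        )

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, f):
        with pytest.raises(ValueError):
            ka_from_fraction(f, 1e-6)


class TestGibbs:
    def test_reference_oligomer_values(self):
        """dH = -40.6, TdS = -30.8 gives dG = -9.8 kcal/mol; the same value
        follows from Ka = 1.9e7 at 294.15 K."""
        assert gibbs(-40.6, -30.8) == pytest.approx(-9.8)
        assert gibbs_from_ka(1.9e7, T_REF) == pytest.approx(-9.8, abs=0.05)

    def test_unit_ka_zero_free_energy(self):
        assert gibbs_from_ka(1.0, 300.0) == 0.0

    def test_nonpositive_ka_rejected(self):
        with pytest.raises(ValueError):
            gibbs_from_ka(0.0)

    def test_inverse_of_ka_from_gibbs(self):
        assert gibbs_from_ka(ka_from_gibbs(-9.5)) == pytest.approx(-9.5)


class TestVantHoff:
    def test_exact_linear_data_recovered(self):
        dh, ds = -90.0, -0.28
        t = np.linspace(290.0, 340.0, 12)
        ka = ka_of_temperature(t, dh, ds)
        fit_dh, fit_ds = vant_hoff_fit(t, ka)
        assert fit_dh == pytest.approx(dh, rel=1e-9)
        assert fit_ds == pytest.approx(ds, rel=1e-9)

    def test_constant_ka_zero_enthalpy(self):
        t = np.linspace(290, 340, 8)
        dh, _ = vant_hoff_fit(t, np.full(8, 1e6))
        assert dh == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        t = np.linspace(285, 345, 20)
        lnka = -(-85.0) / (R_KCAL * t) + (-0.26) / R_KCAL
        lnka += rng.normal(0, 0.05, size=20)
        dh, ds = vant_hoff_fit(t, np.exp(lnka))
        x = np.vstack([1.0 / t, np.ones(20)]).T
        slope, intercept = np.linalg.solve(x.T @ x, x.T @ lnka)
        assert dh == pytest.approx(-slope * R_KCAL, rel=1e-9)
        assert ds == pytest.approx(intercept * R_KCAL, rel=1e-9)

    def test_nonpositive_ka_rejected(self):
        with pytest.raises(ValueError):
            vant_hoff_fit(np.array([290.0, 300.0, 310.0]),
                          np.array([1e5, -1.0, 1e3]))


class TestMeltingFit:
    def test_round_trip_recovery_noiseless(self):
        """Noiseless generated curve refits all six parameters to < 1e-3
        relative error."""
        ds = -81.5 / T_REF
        p = MeltSimParams(dH=-99.8, dS=ds)
        fit = fit_two_state(generate_melting_curve(p))
        assert fit.success
        assert fit.dH == pytest.approx(-99.8, rel=1e-3)
        assert fit.dS == pytest.approx(ds, rel=1e-3)
        assert fit.baseline_folded[0] == pytest.approx(0.60, rel=1e-3)
        assert fit.baseline_unfolded[1] == pytest.approx(0.0010, rel=1e-3)

    def test_reference_prokaryotic_free_energy_and_tm(self):
        """The study's prokaryotic parameters round-trip to dG = -18.3
        kcal/mol and Tm = 52.9 +- 0.5 degC."""
        ref = reference.MELT_UV["prokaryotic"]
        p = MeltSimParams(dH=ref["dH"], dS=ref["TdS"] / T_REF)
        fit = fit_two_state(generate_melting_curve(p))
        assert fit.dG == pytest.approx(-18.3, abs=0.05)
        assert fit.Tm_C == pytest.approx(52.9, abs=0.5)

    def test_internal_consistency(self):
        p = MeltSimParams(dH=-90.2, dS=-76.1 / T_REF)
        fit = fit_two_state(generate_melting_curve(p))
        assert fit.dG == pytest.approx(fit.dH - T_REF * fit.dS, rel=1e-12)
        assert fit.TdS == pytest.approx(T_REF * fit.dS, rel=1e-12)
        # f(Tm) = 0.5 by the Tm definition
        assert fit.fraction(np.array([fit.Tm_C]))[0] == pytest.approx(0.5, abs=1e-9)

    def test_flat_curve_flagged(self):
        t = np.linspace(10, 90, 40)
        curve = MeltingCurve(t, 0.6 + 0.001 * t, c0=2e-6)
        fit = fit_two_state(curve)
        assert not fit.success

    def test_transition_outside_range_flagged(self):
        """A complex melting below the measured window (like the weak
        oligomer/eukaryotic duplexes) is reported as a failed two-state fit."""
        ds = -60.0 / T_REF
        # Tm around -20 degC
        dh = melting_temperature_inverse(-20.0, ds, 2e-6)
        p = MeltSimParams(dH=dh, dS=ds, T_min=10, T_max=90)
        fit = fit_two_state(generate_melting_curve(p))
        assert not fit.success
        assert "0.5" in fit.message

    def test_monotone_tm_in_enthalpy(self):
        """At fixed dS, a more negative dH gives a higher Tm."""
        ds = -0.25
        tms = [melting_temperature(dh, ds, 2e-6) for dh in (-70, -80, -90, -100)]
        assert np.all(np.diff(tms) > 0)
        # and the fitted Tm of generated curves follows the same order
        fits = [
            fit_two_state(generate_melting_curve(MeltSimParams(dH=dh, dS=ds)))
            for dh in (-80.0, -95.0)
        ]
        assert fits[1].Tm_C > fits[0].Tm_C

    def test_vant_hoff_window_recovers_parameters(self):
        ds = -76.1 / T_REF
        p = MeltSimParams(dH=-90.2, dS=ds)
        curve = generate_melting_curve(p)
        fit = fit_two_state(curve)
        dh, ds_fit = vant_hoff_from_curve(curve, fit)
        assert dh == pytest.approx(-90.2, rel=1e-6)
        assert ds_fit == pytest.approx(ds, rel=1e-6)


def melting_temperature_inverse(tm_C: float, ds: float, c0: float) -> float:
    """dH that places the melting midpoint at ``tm_C`` for given dS."""
    return (ds - R_KCAL * np.log(4.0 / c0)) * (tm_C + C_TO_K)


class TestItcFit:
    def test_round_trip_recovery_noiseless(self):
        """Noiseless series refits (Ka, dH, n) to < 1e-3 relative error,
        in both dilution-heat modes."""
        ka = ka_from_gibbs(-9.5)
        p = ItcSimParams(ka=ka, dH=-76.0, n=0.85, qdil=-0.4)
        series = generate_itc_series(p)
        for mode in (-0.4, "free"):
            fit = fit_itc(series, qdil=mode)
            assert fit.success
            assert fit.ka == pytest.approx(ka, rel=1e-3)
            assert fit.dH == pytest.approx(-76.0, rel=1e-3)
            assert fit.n == pytest.approx(0.85, rel=1e-3)

    def test_internal_consistency(self):
        p = ItcSimParams(ka=2.4e7, dH=-115.1, n=0.89)
        fit = fit_itc(generate_itc_series(p), qdil=0.0)
        assert fit.dG == pytest.approx(-R_KCAL * fit.T * np.log(fit.ka), rel=1e-12)
        assert fit.TdS == pytest.approx(fit.dH - fit.dG, rel=1e-12)

    def test_stoichiometry_near_09_for_duplexes(self):
        """Duplex titrations with the study's parameters fit n ~ 0.9."""
        for system in ("prokaryotic", "eukaryotic"):
            ref = reference.ITC[system]
            p = ItcSimParams(ka=ref["Ka"], dH=ref["dH"], n=ref["n"])
            fit = fit_itc(generate_itc_series(p), qdil=0.0)
            assert fit.n == pytest.approx(ref["n"], abs=0.005)
            assert 0.8 < fit.n < 1.0

    def test_identical_heats_flagged(self):
        series = ItcSeries(
            heats=np.full(12, -0.5),
            injection_volumes=np.full(12, 2e-6),
            cell_conc=10e-6, syringe_conc=100e-6, cell_volume=190e-6,
        )
        fit = fit_itc(series)
        assert not fit.success
        assert fit.dH == 0.0
        assert np.isnan(fit.ka)

    def test_no_plateau_warns_and_floats_qdil(self):
        """A truncated titration (no saturation) falls back to floating the
        dilution heat."""
        ka = ka_from_gibbs(-9.5)
        p = ItcSimParams(ka=ka, dH=-76.0, n=0.85, qdil=-0.3,
                         injection_volumes=np.full(8, 2e-6))
        series = generate_itc_series(p)
        with pytest.warns(UserWarning, match="saturation"):
            fit = fit_itc(series, qdil="post_saturation")
        assert fit.qdil_mode == "free"
        assert fit.ka == pytest.approx(ka, rel=0.01)

    def test_post_saturation_mode_close_on_saturated_series(self):
        p = ItcSimParams(ka=5e8, dH=-60.0, n=0.9, qdil=-0.2,
                         injection_volumes=np.full(25, 2e-6))
        fit = fit_itc(generate_itc_series(p), qdil="post_saturation")
        assert fit.qdil_mode == "post_saturation"
        assert fit.qdil == pytest.approx(-0.2, abs=0.02)
        assert fit.n == pytest.approx(0.9, rel=0.01)
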