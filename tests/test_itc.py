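"""Independent-sites ITC: forward model, blank subtraction, and fitting."""

import numpy as np
import pytest

from cdbind import (
    ITCBindingParams,
    ITCDesign,
    Thermogram,
    blank_subtract,
    fit_independent_model,
    simulate_thermogram,
)
from cdbind.binding_core import EquilibriumInput, complex_concentration
from cdbind.itc import IndependentSitesITC
from conftest import ITC_DH_CAL, ITC_K, ITC_N


@pytest.fixture
def paper_params():
    return ITCBindingParams(K=ITC_K, n=ITC_N, dH=ITC_DH_CAL)


class TestSimulate:
    def test_zero_enthalpy_gives_zero_heats(self, itc_design):
        tg = simulate_thermogram(ITCBindingParams(K=ITC_K, n=1.0, dH=0.0), itc_design)
        assert all(q == 0.0 for q in tg.heats)

    def test_vanishing_K_gives_vanishing_heats(self, itc_design, paper_params):
        tg = simulate_thermogram(
            ITCBindingParams(K=1e-8, n=1.0, dH=ITC_DH_CAL), itc_design
        )
        assert max(abs(q) for q in tg.heats) < 1e-12

    def test_exothermic_sign_propagates(self, itc_design, paper_params):
        tg = simulate_thermogram(paper_params, itc_design)
        assert all(q < 0 for q in tg.heats)

    def test_saturation_decay(self, itc_design, paper_params):
        """Late injections release less heat as the cell saturates."""
        tg = simulate_thermogram(paper_params, itc_design)
        assert abs(tg.heats[-1]) < abs(tg.heats[0])

    def test_first_injection_against_direct_equilibrium(self, itc_design, paper_params):
        """Oracle: solve the post-injection equilibrium directly.

        One 10 uL shot of 3 mM guest into 0.75 mM host (V0 = 1 mL) with the
        symmetric overfilled-cell displacement and expelled-heat correction.
        """
        V0 = itc_design.cell_volume
        dv = itc_design.injection_volumes[0]
        M1 = itc_design.cell_conc_initial * (1 - dv / (2 * V0)) / (1 + dv / (2 * V0))
        X1 = itc_design.syringe_conc * (dv / V0) / (1 + dv / (2 * V0))
        hg1 = complex_concentration(EquilibriumInput(X1, ITC_N * M1, ITC_K))
        Q1 = ITC_DH_CAL * V0 * hg1
        q1 = Q1 + (dv / V0) * Q1 / 2
        tg = simulate_thermogram(paper_params, itc_design)
        assert tg.heats[0] == pytest.approx(q1, rel=1e-12)
        # frozen magnitude for the study design: -13.50 ucal
        assert tg.heats[0] * 1e6 == pytest.approx(-13.4999807, abs=1e-4)

    def test_heat_conservation_without_displacement(self, itc_design, paper_params):
        """With a closed cell the heats telescope to dH * V0 * [HG]_final."""
        tg = simulate_thermogram(paper_params, itc_design, displacement=False)
        X_final = itc_design.syringe_conc * sum(itc_design.injection_volumes) \
            / itc_design.cell_volume
        hg = complex_concentration(
            EquilibriumInput(X_final, ITC_N * itc_design.cell_conc_initial, ITC_K)
        )
        assert sum(tg.heats) == pytest.approx(
            ITC_DH_CAL * itc_design.cell_volume * hg, rel=1e-12
        )

    def test_molar_ratio_axis(self, itc_design, paper_params):
        tg = simulate_thermogram(paper_params, itc_design)
        assert np.all(np.diff(tg.molar_ratios) > 0)
        # 25 x 10 uL of 3 mM into 0.75 mM ends slightly above equimolar
        assert tg.molar_ratios[-1] == pytest.approx(8.0 / 7.0, rel=1e-10)

    def test_overfill_warning(self, paper_params):
        design = ITCDesign(
            cell_volume=2.0e-4,
            cell_conc_initial=0.75e-3,
            syringe_conc=3e-3,
            injection_volumes=(1e-5,) * 25,
        )
        with pytest.warns(RuntimeWarning, match="cumulative injected volume"):
            simulate_thermogram(paper_params, design)


class TestBlankSubtract:
    def test_self_subtraction_cancels(self, itc_design, paper_params):
        tg = simulate_thermogram(paper_params, itc_design)
        out = blank_subtract(tg, tg)
        assert all(q == 0.0 for q in out.heats)
        assert out.molar_ratios == tg.molar_ratios

    def test_zero_control_is_identity(self, itc_design, paper_params):
        tg = simulate_thermogram(paper_params, itc_design)
        zeros = Thermogram(heats=(0.0,) * len(tg.heats), molar_ratios=tg.molar_ratios)
        assert blank_subtract(tg, zeros).heats == tg.heats

    def test_elementwise_arithmetic(self):
        s = Thermogram(heats=(-10e-6, -8e-6), molar_ratios=(0.1, 0.2))
        c = Thermogram(heats=(-1e-6, -1e-6), molar_ratios=(0.1, 0.2))
        out = blank_subtract(s, c)
        assert np.allclose(out.heats, (-9e-6, -7e-6))

    def test_length_mismatch_is_an_error(self):
        s = Thermogram(heats=(-1e-6,) * 3, molar_ratios=(0.1, 0.2, 0.3))
        c = Thermogram(heats=(-1e-6,) * 2, molar_ratios=(0.1, 0.2))
        with pytest.raises(ValueError, match="mismatch"):
            blank_subtract(s, c)


class TestFit:
    def test_paper_parameters_round_trip(self, itc_design, paper_params):
        tg = simulate_thermogram(paper_params, itc_design)
        with pytest.warns(RuntimeWarning, match="Wiseman"):
            params, result, est = fit_independent_model(tg, itc_design)
        assert params.K == pytest.approx(ITC_K, rel=1e-3)
        assert params.n == pytest.approx(ITC_N, abs=0.01)
        assert params.dH == pytest.approx(ITC_DH_CAL, rel=1e-3)
        # full linkage closes on the fitted result
        assert result.dG == pytest.approx(-4.147, abs=0.01)
        assert result.dS == pytest.approx(10.51, abs=0.05)

    @pytest.mark.parametrize("K", [1e2, 1e3, 1e5])
    @pytest.mark.parametrize("n", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("dH", [-1e3, -1e4])
    def test_forward_inverse_consistency_grid(self, itc_design, K, n, dH):
        truth = ITCBindingParams(K=K, n=n, dH=dH)
        tg = simulate_thermogram(truth, itc_design)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            params, _, _ = fit_independent_model(tg, itc_design)
        assert params.K == pytest.approx(K, rel=1e-3)
        assert params.n == pytest.approx(n, rel=1e-3)
        assert params.dH == pytest.approx(dH, rel=1e-3)

    def test_scaled_heats_scale_dH_only(self, itc_design, paper_params):
        tg = simulate_thermogram(paper_params, itc_design)
        scaled = Thermogram(
            heats=tuple(2.5 * q for q in tg.heats), molar_ratios=tg.molar_ratios
        )
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            p1, _, _ = fit_independent_model(tg, itc_design, fix_n=1.0)
            p2, _, _ = fit_independent_model(scaled, itc_design, fix_n=1.0)
        assert p2.K == pytest.approx(p1.K, rel=1e-6)
        assert p2.dH == pytest.approx(2.5 * p1.dH, rel=1e-9)

    def test_flat_thermogram_is_unidentifiable(self, itc_design):
        tg = Thermogram(heats=(0.0,) * 25, molar_ratios=tuple(np.linspace(0.05, 1.1, 25)))
        with pytest.raises(ValueError, match="flat thermogram"):
            fit_independent_model(tg, itc_design)

    def test_low_c_warning_attached(self, itc_design, paper_params):
        """The study's own regime (c ~ 0.8) must carry an identifiability note."""
        tg = simulate_thermogram(paper_params, itc_design)
        with pytest.warns(RuntimeWarning, match="Wiseman"):
            _, _, est = fit_independent_model(tg, itc_design)
        assert est.c_ == pytest.approx(0.822, abs=0.001)
        assert est.warnings_

    def test_discard_first_flag(self, itc_design, paper_params):
        tg = simulate_thermogram(paper_params, itc_design)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            params, _, _ = fit_independent_model(
                tg, itc_design, fix_n=1.0, discard_first=True
            )
        assert params.K == pytest.approx(ITC_K, rel=1e-3)

    def test_sklearn_interface(self, itc_design, paper_params):
        tg = simulate_thermogram(paper_params, itc_design)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            est = IndependentSitesITC(fix_n=1.0).fit(
                np.asarray(itc_design.injection_volumes), np.asarray(tg.heats)
            )
        assert est.get_params()["fix_n"] == 1.0
        pred = est.predict(np.asarray(itc_design.injection_volumes))
        assert np.allclose(pred, tg.heats, rtol=1e-6)
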