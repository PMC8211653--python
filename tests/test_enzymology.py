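"""Inhibition kinetics, modality classification and DSF melt analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from assaykit import (
    ValidationError,
    apparent_ic50,
    classify_modality,
    delta_tm,
    initial_rates,
    melt_tm,
    modality_rate,
)
from assaykit.enzymology import MODALITIES
from assaykit.simulate import (
    DNA_GRID_NM,
    GeneratorConfig,
    gen_melt,
    gen_progress_grid,
    gen_rate_table,
)

from conftest import boltzmann_curve

KIN = dict(vmax=100.0, km=50.0, ki=10.0)


class TestRateLaws:
    @pytest.mark.parametrize("modality", MODALITIES)
    def test_no_inhibitor_limit_is_michaelis_menten(self, modality):
        S = np.array(DNA_GRID_NM)
        v = modality_rate(S, 0.0, modality=modality, alpha=0.5, **KIN)
        assert np.allclose(v, KIN["vmax"] * S / (KIN["km"] + S))

    def test_competitive_saturates_to_vmax(self):
        v = modality_rate(1e9, 50.0, modality="competitive", **KIN)
        assert v == pytest.approx(KIN["vmax"], rel=1e-6)

    def test_uncompetitive_high_substrate_limit(self):
        I = 50.0
        v = modality_rate(1e9, I, modality="uncompetitive", **KIN)
        assert v == pytest.approx(KIN["vmax"] / (1 + I / KIN["ki"]), rel=1e-6)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValidationError):
            modality_rate(10.0, 1.0, modality="competitive", vmax=100.0, km=-1.0, ki=10.0)

    @pytest.mark.parametrize(
        "modality,trend",
        [("competitive", 1), ("uncompetitive", -1), ("noncompetitive", 0)],
    )
    def test_apparent_ic50_trend_matches_numeric_half_inhibition(self, modality, trend):
        """Closed-form apparent IC50 equals the numerically solved I at half the
        uninhibited rate, and moves with S in the modality-specific direction."""
        S_vals = np.array([5.0, 50.0, 200.0])
        ic = apparent_ic50(S_vals, modality=modality, **{k: KIN[k] for k in ("km", "ki")})
        for S, expected in zip(S_vals, ic):
            v0 = modality_rate(S, 0.0, modality=modality, **KIN)
            solved = brentq(lambda I: modality_rate(S, I, modality=modality, **KIN) - v0 / 2, 1e-9, 1e6)
            assert solved == pytest.approx(expected, rel=1e-9)
        diffs = np.diff(ic)
        if trend > 0:
            assert (diffs > 0).all()
        elif trend < 0:
            assert (diffs < 0).all()
        else:
            assert np.allclose(diffs, 0.0)


def _progress_frame(times, signals, S=100.0, I=0.0):
    return pd.DataFrame(
        {
            "varied_substrate": "DNA",
            "substrate_conc": S,
            "inhibitor_nM": I,
            "time_min": times,
            "replicate": 1,
            "signal": signals,
        }
    )


class TestInitialRates:
    TIMES = np.array([0.0, 5.0, 15.0, 30.0, 45.0, 60.0])

    def test_exact_line_recovered(self):
        rates = initial_rates(_progress_frame(self.TIMES, 100.0 * self.TIMES))
        assert rates.loc[0, "rate"] == pytest.approx(100.0)
        assert rates.loc[0, "n_points_used"] == 6
        assert rates.loc[0, "flag"] == ""

    def test_baseline_offset_does_not_change_rate(self):
        a = initial_rates(_progress_frame(self.TIMES, 100.0 * self.TIMES))
        b = initial_rates(_progress_frame(self.TIMES, 500.0 + 100.0 * self.TIMES))
        assert a.loc[0, "rate"] == pytest.approx(b.loc[0, "rate"])

    def test_flat_trace_zero_rate_flagged(self):
        rates = initial_rates(_progress_frame(self.TIMES, np.full(6, 300.0)))
        assert rates.loc[0, "rate"] == 0.0
        assert rates.loc[0, "flag"] == "flat"

    def test_saturating_trace_matches_taylor_oracle_with_strict_window(self):
        # S(t) = A(1 - exp(-kt)); initial slope A*k. A strict linearity
        # threshold shrinks the window to the first 3 points where the
        # Taylor expansion holds to ~3%.
        A, k = 5000.0, 0.004
        sig = A * (1 - np.exp(-k * self.TIMES))
        rates = initial_rates(_progress_frame(self.TIMES, sig), r2_min=0.9999)
        assert rates.loc[0, "n_points_used"] == 3
        assert rates.loc[0, "rate"] == pytest.approx(A * k, rel=0.05)

    def test_decreasing_trace_flagged_nonmonotone(self):
        rates = initial_rates(_progress_frame(self.TIMES, 1000.0 - 10.0 * self.TIMES))
        assert rates.loc[0, "flag"] == "nonmonotone"

    def test_noiseless_grid_recovers_generator_truth(self):
        prog, truth = gen_progress_grid("uncompetitive", grid="dna_grid", config=GeneratorConfig(seed=1, cv=0.0))
        rates = initial_rates(prog).merge(truth, on=["substrate_conc", "inhibitor_nM"], suffixes=("", "_true"))
        assert np.allclose(rates["rate"], rates["rate_true"], rtol=1e-9)

    def test_depletion_bends_endpoint_but_not_initial_window(self):
        prog, truth = gen_progress_grid(
            "uncompetitive", grid="dna_grid", config=GeneratorConfig(seed=1, cv=0.0), depletion_conversion=0.5
        )
        # strict linearity threshold shrinks the window ahead of the bend
        rates = initial_rates(prog, r2_min=0.9995).merge(
            truth, on=["substrate_conc", "inhibitor_nM"], suffixes=("", "_true")
        )
        assert np.allclose(rates["rate"], rates["rate_true"], rtol=0.12)
        # ...while a naive endpoint slope underestimates systematically
        end = prog[prog["time_min"] == 60.0].set_index(["substrate_conc", "inhibitor_nM"])["signal"]
        start = prog[prog["time_min"] == 0.0].set_index(["substrate_conc", "inhibitor_nM"])["signal"]
        endpoint_rate = ((end - start) / 60.0).reset_index(name="rate_end")
        merged = endpoint_rate.merge(truth, on=["substrate_conc", "inhibitor_nM"])
        assert (merged["rate_end"] < 0.8 * merged["rate"]).all()


class TestClassifyModality:
    @pytest.mark.parametrize("modality", MODALITIES)
    @pytest.mark.parametrize("grid", ["dna_grid", "dntp_grid"])
    def test_noiseless_self_consistency(self, modality, grid):
        params = {"alpha": 0.25} if modality == "mixed" else {}
        rates, truth = gen_rate_table(modality, params, grid, config=GeneratorConfig(seed=0, cv=0.0))
        fit = classify_modality(rates)
        assert fit.winner == modality
        assert fit.delta_aicc > 10
        for name in ("vmax", "km", "ki"):
            assert fit.params[modality][name] == pytest.approx(truth[name], rel=1e-4)
        if modality == "mixed":
            assert fit.params["mixed"]["alpha"] == pytest.approx(0.25, rel=1e-3)

    def test_missing_zero_inhibitor_rejected(self):
        rates, _ = gen_rate_table(config=GeneratorConfig(seed=0, cv=0.0))
        with pytest.raises(ValidationError, match="I = 0"):
            classify_modality(rates[rates["inhibitor_nM"] > 0])

    def test_small_grid_rejected(self):
        rates, _ = gen_rate_table(config=GeneratorConfig(seed=0, cv=0.0))
        tiny = rates[rates["substrate_conc"].isin(list(DNA_GRID_NM[:3]))]
        with pytest.raises(ValidationError, match="substrate levels"):
            classify_modality(tiny)

    def test_near_unity_alpha_mixed_collapses_to_noncompetitive(self):
        rates, _ = gen_rate_table("noncompetitive", grid="dntp_grid", config=GeneratorConfig(seed=19, cv=0.05))
        fit = classify_modality(rates)
        assert fit.winner == "noncompetitive"
        assert fit.aicc["mixed"] <= fit.aicc["noncompetitive"]  # umbrella fit was numerically better
        assert fit.collapsed_from_mixed


class TestMeltTm:
    def test_sigmoid_midpoint_within_grid_step(self):
        T, F = boltzmann_curve(45.0)
        res = melt_tm(T, F)
        assert res.ok
        assert abs(res.tm - 45.0) <= 0.5

    def test_offset_and_gain_invariance(self):
        T, F = boltzmann_curve(52.3)
        a = melt_tm(T, F)
        b = melt_tm(T, 3.7 * F + 1234.0)
        assert a.tm == pytest.approx(b.tm, abs=1e-9)

    def test_two_transition_curve_reports_dominant_and_secondary(self):
        T, F1 = boltzmann_curve(48.0, amp=1000.0, slope=0.0)
        _, F2 = boltzmann_curve(70.0, amp=400.0, slope=0.0, floor=0.0)
        res = melt_tm(T, F1 + F2)
        assert res.ok
        assert abs(res.tm - 48.0) <= 0.5
        assert len(res.secondary) == 1
        assert abs(res.secondary[0] - 70.0) <= 0.5

    def test_transition_free_trace_flagged(self):
        T = np.arange(20.0, 99.1, 0.5)
        res = melt_tm(T, 100.0 + 2.0 * (T - 20.0))
        assert not res.ok and np.isnan(res.tm)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match=">= 20"):
            melt_tm(np.linspace(20, 99, 10), np.linspace(0, 1, 10))


class TestDeltaTm:
    def test_dna_dependent_stabilizer_shifts_only_with_dna(self):
        melt, _ = gen_melt(dtm_max=3.0, config=GeneratorConfig(seed=2), n_replicates=4)
        shifts = delta_tm(melt)
        top_plus = shifts[shifts["with_dna"]].sort_values("conc_nM")["delta_tm"].iloc[-1]
        assert top_plus == pytest.approx(3.0 * 12000 / 12300, abs=0.75)
        assert shifts[~shifts["with_dna"]]["delta_tm"].abs().max() < 0.75

    def test_inactive_compound_shows_no_shift_at_any_dose(self):
        melt, _ = gen_melt(dtm_max=0.0, config=GeneratorConfig(seed=3), n_replicates=4)
        shifts = delta_tm(melt)
        assert shifts["delta_tm"].abs().max() < 0.75

    def test_antisymmetry_under_swapping_compound_and_reference(self):
        melt, _ = gen_melt(dtm_max=3.0, config=GeneratorConfig(seed=4, cv=0.0), n_replicates=1, point_noise=0.0)
        shifts = delta_tm(melt)
        swapped = melt.copy()
        top = melt["conc_nM"].max()
        is_comp = (melt["condition"] == "protein+DNA+compound") & (melt["conc_nM"] == top)
        is_ref = melt["condition"] == "protein+DNA"
        swapped.loc[is_comp, "condition"] = "protein+DNA"
        swapped.loc[is_comp, "conc_nM"] = 0.0
        swapped.loc[is_ref, "condition"] = "protein+DNA+compound"
        swapped.loc[is_ref, "conc_nM"] = top
        keep = swapped["condition"].isin(["protein", "protein+compound", "protein+DNA", "protein+DNA+compound"])
        sw = delta_tm(swapped[keep])
        orig = shifts[(shifts["with_dna"]) & (shifts["conc_nM"] == top)]["delta_tm"].iloc[0]
        new = sw[(sw["with_dna"]) & (sw["conc_nM"] == top)]["delta_tm"].iloc[0]
        assert new == pytest.approx(-orig, abs=1e-6)

    def test_missing_reference_condition_is_an_error(self):
        melt, _ = gen_melt(config=GeneratorConfig(seed=5), n_replicates=1, temp_step=1.0)
        no_ref = melt[melt["condition"] != "protein"]
        with pytest.raises(ValidationError, match="reference"):
            delta_tm(no_ref)
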