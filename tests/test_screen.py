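"""Drug Effect scoring, Z-standardization and hit calling."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assaykit import (
    ValidationError,
    call_hits,
    combine_replicates,
    drug_effect,
    plate_median_normalize,
    score_screen,
    screen_qc,
    z_standardize,
)
from assaykit.simulate import GeneratorConfig, gen_screen

from conftest import make_plate


class TestCombineReplicates:
    @pytest.fixture
    def norm_three_reps(self):
        frames = [
            make_plate([2.0 ** v], replicate=r)  # one library well per replicate
            for r, v in ((1, -1.0), (2, -1.2), (3, -0.8))
        ]
        return plate_median_normalize(pd.concat(frames, ignore_index=True))

    def test_median_of_three_replicates(self):
        # plate of 3 wells so the plate median is nonzero and known
        frames = []
        for r, v in ((1, -1.0), (2, -1.2), (3, -0.8)):
            frames.append(make_plate([1000.0 * 2.0 ** v, 1000.0, 1000.0], replicate=r))
        norm = plate_median_normalize(pd.concat(frames, ignore_index=True))
        per = combine_replicates(norm)
        row = per[per["perturbation_id"] == "siRNA_0001"].iloc[0]
        assert row["value"] == pytest.approx(-1.0)
        assert row["n_replicates_used"] == 3

    def test_single_replicate_passes_through(self):
        norm = plate_median_normalize(make_plate([500.0, 1000.0, 2000.0]))
        per = combine_replicates(norm)
        assert per.loc[per["perturbation_id"] == "siRNA_0001", "value"].iloc[0] == pytest.approx(-1.0)

    def test_mean_and_median_differ_on_skewed_replicates(self):
        # replicate pm values {0, 0, 3}: mean 1.0 vs median 0 — why the method matters
        frames = [make_plate([1000.0 * 2.0 ** v, 1000.0, 1000.0], replicate=r) for r, v in ((1, 0), (2, 0), (3, 3))]
        norm = plate_median_normalize(pd.concat(frames, ignore_index=True))
        med = combine_replicates(norm, "median")
        mean = combine_replicates(norm, "mean")
        assert med.loc[0, "value"] == pytest.approx(0.0)
        assert mean.loc[0, "value"] == pytest.approx(1.0)


class TestDrugEffectAndZ:
    def test_identical_arms_give_zero_and_antisymmetry(self):
        assert drug_effect(-0.4, -0.4) == 0.0
        assert drug_effect(-1.0, 0.5) == -drug_effect(0.5, -1.0)

    def test_halved_drug_signal_gives_de_minus_one(self, two_arm_plate):
        res = score_screen(two_arm_plate)
        row = res[res["perturbation_id"] == "siRNA_0001"].iloc[0]
        assert row["de"] == pytest.approx(-1.0)

    def test_z_hand_example(self):
        assert z_standardize([-2.0, 0.0, 2.0]).tolist() == [-1.0, 0.0, 1.0]

    def test_two_mads_below_median_is_z_minus_two(self):
        # definitional equivalence: Z = -2 <=> two MADs below the median effect
        base = [-1.0, -1.0, 0.0, 0.0, 0.0, 1.0, 1.0, 2.0]  # median 0, MAD 1
        de = np.array(base + [-2.0])
        z = z_standardize(de)
        assert np.median(de) == 0.0 and np.median(np.abs(de)) == 1.0
        assert z[-1] == -2.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(-5, 5), st.data())
    def test_location_invariance(self, shift, data):
        de = np.array(data.draw(st.lists(st.floats(-3, 3), min_size=4, max_size=30)))
        if np.median(np.abs(de - np.median(de))) < 1e-6:  # (near-)degenerate MAD
            return
        assert np.allclose(z_standardize(de + shift), z_standardize(de), atol=1e-9)

    def test_mad_zero_falls_back_to_sd_with_warning(self):
        with pytest.warns(RuntimeWarning, match="MAD"):
            z = z_standardize([0.0, 0.0, 0.0, 5.0])
        assert np.all(np.isfinite(z))

    def test_fewer_than_three_values_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            z_standardize([1.0, 2.0])

    def test_scaled_mad_flag_applies_consistency_factor(self):
        z_raw = z_standardize([-2.0, 0.0, 2.0])
        z_scaled = z_standardize([-2.0, 0.0, 2.0], scaled_mad=True)
        assert np.allclose(z_scaled * 1.4826, z_raw)


class TestHitCalling:
    def test_boundary_is_strict(self):
        assert call_hits([-2.0]).tolist() == [False]
        assert call_hits([-2.0000001]).tolist() == [True]

    def test_counting_at_default_threshold(self):
        assert call_hits([-3.0, -1.0, 0.0]).sum() == 1


class TestScreenPipeline:
    def test_pipeline_equivalence_with_brute_force(self):
        """Full-pipeline DE equals the direct log2/median formula."""
        cfg = GeneratorConfig(seed=21)
        wells, _ = gen_screen(50, cfg, n_replicates=1)
        res = score_screen(wells)
        lib = wells[wells["role"] == "library"]
        for pert in ["siRNA_0001", "siRNA_0025", "siRNA_0050"]:
            de = 0.0
            for arm, sign in (("drug", 1.0), ("vehicle", -1.0)):
                sub = lib[lib["arm"] == arm]
                sig = sub.loc[sub["perturbation_id"] == pert, "signal"].iloc[0]
                plate_med = np.median(np.log2(sub["signal"]))
                de += sign * (np.log2(sig) - plate_med)
            assert res.loc[res["perturbation_id"] == pert, "de"].iloc[0] == pytest.approx(de)

    def test_monotonicity_in_drug_arm_signal(self, two_arm_plate):
        base = score_screen(two_arm_plate).set_index("perturbation_id")
        lowered = two_arm_plate.copy()
        mask = (lowered["perturbation_id"] == "siRNA_0002") & (lowered["arm"] == "drug")
        lowered.loc[mask, "signal"] *= 0.5
        after = score_screen(lowered).set_index("perturbation_id")
        assert after.loc["siRNA_0002", "de_z"] <= base.loc["siRNA_0002", "de_z"]

    def test_single_arm_perturbation_excluded_with_warning(self, two_arm_plate, caplog):
        wells = two_arm_plate[
            ~((two_arm_plate["perturbation_id"] == "siRNA_0004") & (two_arm_plate["arm"] == "vehicle"))
        ]
        with caplog.at_level(logging.WARNING, logger="assaykit.screen"):
            res = score_screen(wells)
        assert "siRNA_0004" not in set(res["perturbation_id"])
        assert any("one arm" in rec.message for rec in caplog.records)

    def test_output_sorted_by_z_ascending(self, two_arm_plate):
        res = score_screen(two_arm_plate)
        assert (np.diff(res["de_z"]) >= 0).all()


class TestScreenQC:
    def test_separation_of_ten_percent_positive_controls(self):
        wells = make_plate([1000.0] * 8, neg_signals=[1000.0] * 12, pos_signals=[100.0] * 4)
        qc = screen_qc(plate_median_normalize(wells))
        assert qc.loc[0, "separation"] == pytest.approx(np.log2(0.1))
        assert not qc.loc[0, "flagged"]

    def test_identical_controls_flagged(self):
        wells = make_plate([1000.0] * 8, neg_signals=[1000.0] * 12, pos_signals=[1000.0] * 4)
        qc = screen_qc(plate_median_normalize(wells))
        assert qc.loc[0, "separation"] == 0.0
        assert qc.loc[0, "flagged"]

    def test_missing_controls_marked_not_computable(self):
        wells = make_plate([1000.0] * 8, neg_signals=[1000.0] * 12)
        qc = screen_qc(plate_median_normalize(wells))
        assert not qc.loc[0, "computable"]

    def test_synthetic_screen_with_kill_control_passes_everywhere(self):
        wells, _ = gen_screen(200, GeneratorConfig(seed=5), n_replicates=2)
        qc = screen_qc(plate_median_normalize(wells))
        assert qc["computable"].all()
        assert not qc["flagged"].any()
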