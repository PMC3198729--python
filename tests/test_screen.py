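import math

import numpy as np
import pandas as pd
import pytest

from sirnawalk.screen import (
    PLATE_COLUMNS,
    discrimination,
    normalize_fluorescence,
    normalize_luciferase,
    screen_discrimination,
    simulate_screen,
    ttest_unpaired_two_tailed,
)


def lucif_plate(rows):
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


class TestNormalizeLuciferase:
    def test_experimental_ratio_scaled_by_control_mean(self):
        rows = []
        for i in range(2):
            rows += [
                (f"e{i}", "p4", "mut", "renilla", "experimental", 50.0),
                (f"e{i}", "p4", "mut", "firefly", "experimental", 100.0),
                (f"c{i}", "ns", "mut", "renilla", "nonspecific_control", 100.0),
                (f"c{i}", "ns", "mut", "firefly", "nonspecific_control", 100.0),
            ]
        norm = normalize_luciferase(lucif_plate(rows))
        exp = norm[norm["group"] == "experimental"]
        assert np.allclose(exp["norm_value"], 0.5)

    def test_controls_self_normalize_to_mean_one(self, rng):
        rows = []
        for i in range(6):
            rows += [
                (f"c{i}", "ns", "wt", "renilla", "nonspecific_control", float(rng.uniform(50, 150))),
                (f"c{i}", "ns", "wt", "firefly", "nonspecific_control", float(rng.uniform(50, 150))),
                (f"e{i}", "p4", "wt", "renilla", "experimental", 60.0),
                (f"e{i}", "p4", "wt", "firefly", "experimental", 100.0),
            ]
        norm = normalize_luciferase(lucif_plate(rows))
        ctrl = norm[norm["group"] == "nonspecific_control"]
        assert ctrl["norm_value"].mean() == pytest.approx(1.0)

    def test_zero_firefly_rejected(self):
        rows = [
            ("e0", "p4", "wt", "renilla", "experimental", 50.0),
            ("e0", "p4", "wt", "firefly", "experimental", 0.0),
            ("c0", "ns", "wt", "renilla", "nonspecific_control", 100.0),
            ("c0", "ns", "wt", "firefly", "nonspecific_control", 100.0),
        ]
        with pytest.raises(ValueError, match="firefly"):
            normalize_luciferase(lucif_plate(rows))

    def test_missing_control_group_rejected(self):
        rows = [
            ("e0", "p4", "wt", "renilla", "experimental", 50.0),
            ("e0", "p4", "wt", "firefly", "experimental", 100.0),
        ]
        with pytest.raises(ValueError, match="nonspecific_control"):
            normalize_luciferase(lucif_plate(rows))

    def test_scale_invariance(self):
        plate = simulate_screen(0.7, 0.3, cv=0.08, seed=42)
        scaled = plate.copy()
        scaled["value"] *= 37.5
        a = normalize_luciferase(plate)["norm_value"]
        b = normalize_luciferase(scaled)["norm_value"]
        assert np.allclose(a, b)


class TestNormalizeFluorescence:
    @staticmethod
    def plate(exp_value):
        rows = [
            ("b0", "target_alone", "wt", "eGFP", "background", 90.0),
            ("b1", "target_alone", "wt", "eGFP", "background", 110.0),
            ("c0", "ns", "wt", "eGFP", "nonspecific_control", 1100.0),
            ("c1", "ns", "wt", "eGFP", "nonspecific_control", 1100.0),
            ("e0", "p13", "wt", "eGFP", "experimental", exp_value),
            ("e1", "p13", "wt", "eGFP", "experimental", exp_value),
        ]
        return lucif_plate(rows)

    def test_background_subtracted_and_control_scaled(self):
        norm = normalize_fluorescence(self.plate(1100.0))
        exp = norm[norm["group"] == "experimental"]
        assert np.allclose(exp["norm_value"], 1.0)

    def test_reading_at_background_floors_to_zero(self):
        norm = normalize_fluorescence(self.plate(100.0))
        exp = norm[norm["group"] == "experimental"]
        assert np.allclose(exp["norm_value"], 0.0)

    def test_control_not_above_background_rejected(self):
        plate = self.plate(500.0)
        plate.loc[plate["group"] == "nonspecific_control", "value"] = 50.0
        with pytest.raises(ValueError, match="control mean"):
            normalize_fluorescence(plate)

    def test_channels_are_independent(self):
        # changing the mutant (mCherry) effect must not move the wt estimate
        a = simulate_screen(1.0, 0.2, mode="fluorescence", cv=0.0, seed=0)
        b = simulate_screen(1.0, 0.9, mode="fluorescence", cv=0.0, seed=0)
        ra = screen_discrimination(a, mode="fluorescence")["construct"]
        rb = screen_discrimination(b, mode="fluorescence")["construct"]
        assert ra.wt_rel == pytest.approx(rb.wt_rel)
        assert ra.mut_rel != pytest.approx(rb.mut_rel)


class TestTTest:
    def test_identical_groups_give_p_one(self):
        assert ttest_unpaired_two_tailed([1, 1, 1], [1, 1, 1])[2] == 1.0

    def test_separated_groups_give_tiny_p(self, rng):
        a = rng.normal(0.0, 1e-4, size=6)
        b = 1.0 + rng.normal(0.0, 1e-4, size=6)
        assert ttest_unpaired_two_tailed(a, b)[2] < 1e-6

    def test_matches_closed_form_on_fixed_table(self):
        # worked 6-vs-6 example computed independently from the textbook formula
        a = [4.2, 4.8, 5.1, 4.9, 5.3, 4.6]
        b = [5.8, 6.1, 5.6, 6.4, 5.9, 6.2]
        na, nb = len(a), len(b)
        ma, mb = np.mean(a), np.mean(b)
        sp2 = (np.var(a, ddof=1) * (na - 1) + np.var(b, ddof=1) * (nb - 1)) / (na + nb - 2)
        t_expected = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        t, df, p = ttest_unpaired_two_tailed(a, b)
        assert t == pytest.approx(t_expected)
        assert df == 10
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t_expected), df=10))

    def test_degenerate_unequal_constant_groups_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ttest_unpaired_two_tailed([1, 1, 1], [2, 2, 2])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ttest_unpaired_two_tailed([1.0], [1.0, 2.0])


class TestDiscrimination:
    def test_fold_from_reported_relative_expressions(self):
        # wt retained at 59%, mutant at 17% -> 3.47-fold, mutant-selective
        r = discrimination([0.59] * 6, [0.17] * 6, construct_id="p13")
        assert r.fold_discrimination == pytest.approx(0.59 / 0.17)
        assert round(r.fold_discrimination, 1) == 3.5
        assert r.report()["fold_discrimination"] == 3.47

    def test_equal_expression_gives_unit_fold_and_zero_difference(self):
        r = discrimination([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert r.fold_discrimination == 1.0
        assert r.silencing_difference == 0.0
        assert r.p_value == 1.0

    def test_silencing_difference_in_percentage_points(self):
        # 92% mutant silencing vs 31% wild-type silencing
        r = discrimination([0.69] * 6, [0.08] * 6)
        assert r.mut_silencing == pytest.approx(92.0)
        assert r.wt_silencing == pytest.approx(31.0)
        assert r.silencing_difference == pytest.approx(61.0)

    def test_complete_mutant_silencing_flags_infinite_fold(self):
        r = discrimination([0.5] * 3, [0.0] * 3)
        assert r.infinite_fold and math.isinf(r.fold_discrimination)

    def test_reciprocal_folds_multiply_to_one(self):
        wt, mut = [0.61] * 4, [0.23] * 4
        f = discrimination(wt, mut).fold_discrimination
        g = discrimination(mut, wt).fold_discrimination
        assert f * g == pytest.approx(1.0)


class TestSimulateScreen:
    def test_same_seed_reproduces_the_plate(self):
        a = simulate_screen(0.6, 0.2, cv=0.1, seed=7)
        b = simulate_screen(0.6, 0.2, cv=0.1, seed=7)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("mode", ["luciferase", "fluorescence"])
    def test_noiseless_pipeline_recovers_truth_exactly(self, mode):
        plate = simulate_screen(0.59, 0.17, mode=mode, cv=0.0, seed=1)
        r = screen_discrimination(plate, mode=mode)["construct"]
        assert r.wt_rel == pytest.approx(0.59)
        assert r.mut_rel == pytest.approx(0.17)
        assert r.fold_discrimination == pytest.approx(0.59 / 0.17)

    def test_replicate_structure(self):
        plate = simulate_screen(1.0, 0.2, n=6, seed=0)
        exp = plate[(plate["group"] == "experimental") & (plate["channel"] == "renilla")]
        assert exp.groupby("target").size().eq(6).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_screen(1.0, 0.2, cv=-0.1)
        with pytest.raises(ValueError):
            simulate_screen(1.0, 0.2, n=1)
        with pytest.raises(ValueError):
            simulate_screen(-1.0, 0.2)

    def test_fold_recovery_is_unbiased_at_moderate_noise(self):
        folds = []
        for s in range(60):
            plate = simulate_screen(1.0, 0.2, cv=0.10, n=6, seed=1000 + s)
            folds.append(screen_discrimination(plate)["construct"].fold_discrimination)
        assert np.mean(folds) == pytest.approx(5.0, rel=0.05)
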