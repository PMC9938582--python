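"""Visit-window assignment, paired shift tests, swap permutation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import glycoresponse as gr
from glycoresponse.longitudinal import _wilcoxon, build_pairs


def _samples(visits):
    """visits: list of (patient_id, sample_id, day)."""
    return pd.DataFrame(visits, columns=["patient_id", "sample_id", "days_from_ici_start"])


class TestAssignWindows:
    def test_typical_early_and_late_visits(self):
        asg = gr.assign_windows(
            _samples([("p1", "b", -5), ("p1", "e", 21), ("p1", "l", 43)])
        )
        w = asg.set_index("sample_id")["window"]
        assert w["b"] == "baseline" and w["e"] == "early" and w["l"] == "late"

    def test_first_week_discarded(self):
        asg = gr.assign_windows(_samples([("p1", "b", 0), ("p1", "x", 6)]))
        row = asg.set_index("sample_id").loc["x"]
        assert row["window"] == "discarded"
        assert "one week" in row["reason_discarded"]

    def test_after_twelve_weeks_discarded(self):
        asg = gr.assign_windows(_samples([("p1", "b", 0), ("p1", "x", 90)]))
        assert asg.set_index("sample_id").loc["x", "window"] == "discarded"

    def test_nearest_to_window_median_wins(self):
        asg = gr.assign_windows(
            _samples([("p1", "b", 0), ("p1", "a", 16), ("p1", "c", 27)])
        )
        w = asg.set_index("sample_id")["window"]
        assert w["a"] == "early" and w["c"] == "discarded"  # |16-21| < |27-21|

    def test_equidistant_tie_goes_to_earlier_sample(self):
        asg = gr.assign_windows(
            _samples([("p1", "b", 0), ("p1", "a", 15), ("p1", "c", 27)])
        )
        w = asg.set_index("sample_id")["window"]
        assert w["a"] == "early" and w["c"] == "discarded"

    def test_seven_week_gap_drops_early_assignment(self):
        asg = gr.assign_windows(_samples([("p1", "b", -40), ("p1", "e", 20)]))
        row = asg.set_index("sample_id").loc["e"]
        assert row["window"] == "discarded"
        assert "7 weeks" in row["reason_discarded"]

    def test_no_baseline_excludes_patient(self):
        asg = gr.assign_windows(_samples([("p1", "e", 20)]))
        assert (asg["window"] == "discarded").all()
        assert "no baseline" in asg["reason_discarded"].iloc[0]

    def test_input_order_irrelevant(self):
        visits = [("p1", "b", -3), ("p1", "a", 18), ("p1", "c", 25), ("p2", "b2", 0),
                  ("p2", "l2", 60)]
        frames = [
            gr.assign_windows(_samples(list(perm))).sort_values("sample_id").reset_index(drop=True)
            for perm in itertools.islice(itertools.permutations(visits), 6)
        ]
        for f in frames[1:]:
            pd.testing.assert_frame_equal(frames[0], f)


class TestPairedShift:
    def test_constant_shift_minimal_exact_p(self):
        base = pd.DataFrame({"V": np.arange(20, dtype=float)}, index=range(20))
        follow = base + 1.0
        res = gr.paired_shift_test(base, follow, threshold=0.05)
        # all 20 signed ranks on one side: p = 2 / 2^20
        assert res.loc["V", "p"] == pytest.approx(2 / 2**20, rel=1e-6)
        assert res.loc["V", "median_difference"] == -1.0

    def test_identical_arms_p_one(self):
        base = pd.DataFrame({"V": np.arange(10, dtype=float)})
        with pytest.warns(UserWarning, match="zero"):
            res = gr.paired_shift_test(base, base.copy(), threshold=0.05)
        assert res.loc["V", "p"] == 1.0

    def test_arm_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame({"V": rng.standard_normal(15)})
        follow = pd.DataFrame({"V": rng.standard_normal(15) + 0.4})
        r1 = gr.paired_shift_test(base, follow, 0.05)
        r2 = gr.paired_shift_test(follow, base, 0.05)
        assert r1.loc["V", "p"] == pytest.approx(r2.loc["V", "p"], rel=1e-12)
        assert r1.loc["V", "median_difference"] == -r2.loc["V", "median_difference"]

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(1)
        diff = rng.standard_normal(9)
        p = _wilcoxon(diff)
        # full enumeration of all 2^9 sign assignments
        ranks = stats.rankdata(np.abs(diff))
        w_obs = ranks[diff > 0].sum()
        n = len(diff)
        total = ranks.sum()
        stat_obs = min(w_obs, total - w_obs)
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            w = ranks[np.array(signs, dtype=bool)].sum()
            if min(w, total - w) <= stat_obs:
                count += 1
        assert p == pytest.approx(count / 2**n, rel=1e-9)


class TestSwapPermutation:
    def _pairs(self, shift, n=50, seed=2):
        rng = np.random.default_rng(seed)
        base = pd.DataFrame({"V": rng.standard_normal(n)})
        follow = pd.DataFrame({"V": base["V"] + shift + 0.5 * rng.standard_normal(n)})
        return base, follow

    def test_strong_shift_scaled_down(self):
        base, follow = self._pairs(shift=1.0)
        res = gr.swap_permutation_validate(base, follow, threshold=0.0025,
                                           n_perm=99, seed=3, criterion="observed")
        assert res.loc["V", "eP"] == pytest.approx(1 / 100)

    def test_determinism(self):
        base, follow = self._pairs(shift=0.2)
        a = gr.swap_permutation_validate(base, follow, 0.05, n_perm=50, seed=4)
        b = gr.swap_permutation_validate(base, follow, 0.05, n_perm=50, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_pair_multiset_invariance(self):
        # swapping arms for any subset leaves each patient's value pair intact
        rng = np.random.default_rng(5)
        base = rng.standard_normal(20)
        follow = rng.standard_normal(20)
        swap = rng.random(20) < 0.5
        b2 = np.where(swap, follow, base)
        f2 = np.where(swap, base, follow)
        for i in range(20):
            assert {b2[i], f2[i]} == {base[i], follow[i]}


class TestShiftVsOrr:
    def test_threshold_is_alpha_over_number_tested(self, preprocessed):
        values, clinical = preprocessed
        shifts = values[["GP8", "GP22"]] * 0.1  # stand-in shifts
        res = gr.shift_vs_orr(
            shifts, clinical["orr"], clinical[["age", "sex", "bmi", "ldh_high", "ecog"]]
        )
        assert (res["threshold"] == 0.05 / 2).all()

    def test_planted_differential_shift_detected(self):
        rng = np.random.default_rng(6)
        n = 200
        clinical = pd.DataFrame(
            {
                "age": rng.normal(60, 10, n),
                "sex": rng.integers(0, 2, n),
                "bmi": rng.normal(28, 4, n),
                "ldh_high": rng.integers(0, 2, n),
                "ecog": rng.choice([0, 1, 2], n),
                "orr": rng.integers(0, 2, n),
            },
            index=[f"P{i}" for i in range(n)],
        )
        shifts = pd.DataFrame(
            {"V": 1.2 * clinical["orr"] + rng.standard_normal(n)}, index=clinical.index
        )
        res = gr.shift_vs_orr(shifts, clinical["orr"], clinical)
        assert res.loc["V", "significant"]
        assert res.loc["V", "beta"] > 0

    def test_end_to_end_planted_shift(self, tmp_path):
        cfg = gr.SimulationConfig(planted_shift_effects={"GP8": 0.2, "GP22": -0.3})
        cohort = gr.simulate_cohort(cfg, seed=11)
        asg = gr.assign_windows(cohort.peaks)
        keep = asg.loc[asg["window"] != "discarded", "sample_id"]
        g = gr.preprocess_chain(
            cohort.peaks[cohort.peaks["sample_id"].isin(keep)],
            stop_after="batch_corrected",
        )
        base, follow = build_pairs(g.values, asg, "early")
        res = gr.paired_shift_test(base, follow, threshold=0.05 / 20)
        assert res.loc["GP22", "significant"]
        assert res.loc["GP22", "median_difference"] > 0  # planted decrease on treatment
        assert res.loc["GP8", "median_difference"] < 0
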