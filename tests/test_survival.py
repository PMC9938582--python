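"""Cox fits, PH diagnostics, time partitioning, stratified permutation, KM."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import glycoresponse as gr
from glycoresponse import _coxlib


def _brute_force_efron(times, events, x):
    """Maximise the Efron partial likelihood by generic optimisation."""
    times, events, x = map(np.asarray, (times, events, x))

    def negll(beta):
        b = beta[0]
        eta = x * b
        ll = 0.0
        for t in np.unique(times[events == 1]):
            D = np.flatnonzero((times == t) & (events == 1))
            R = np.flatnonzero(times >= t)
            d = len(D)
            sR = np.exp(eta[R]).sum()
            sD = np.exp(eta[D]).sum()
            ll += eta[D].sum()
            for el in range(d):
                ll -= np.log(sR - el / d * sD)
        return -ll

    res = optimize.minimize_scalar(lambda b: negll([b]), bounds=(-10, 10), method="bounded",
                                   options={"xatol": 1e-10})
    return res.x


class TestCoxCore:
    def test_matches_brute_force_on_six_row_toy(self):
        # alternating covariate keeps the partial likelihood non-degenerate
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 1, 1, 1, 1]
        x = [1, 0, 1, 0, 0, 1]
        s = _coxlib.build_structure(times, events)
        beta, *_ = _coxlib.newton_fit(np.array(x, dtype=float)[:, None], s)
        assert beta[0] == pytest.approx(_brute_force_efron(times, events, x), abs=1e-6)

    def test_matches_brute_force_with_ties(self):
        times = [2, 2, 3, 3, 5, 7, 9, 9]
        events = [1, 1, 1, 0, 1, 1, 1, 0]
        x = [0.5, -1, 2, 0, 1, -0.5, 0.3, 1.2]
        s = _coxlib.build_structure(times, events)
        beta, *_ = _coxlib.newton_fit(np.array(x, dtype=float)[:, None], s)
        assert beta[0] == pytest.approx(_brute_force_efron(times, events, x), abs=1e-6)

    def test_matches_lifelines_with_covariates_and_truncation(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        n = 150
        X = rng.standard_normal((n, 3))
        t = rng.exponential(1 / np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1]))
        e = (rng.random(n) < 0.8).astype(int)
        entry = np.minimum(t * 0.3, 0.1)
        s = _coxlib.build_structure(t, e, entry)
        beta, _, cov, conv = _coxlib.newton_fit(X, s)
        assert conv
        df = pd.DataFrame(X, columns=list("abc"))
        df["T"], df["E"], df["entry"] = t, e, entry
        cph = lifelines.CoxPHFitter().fit(df, "T", "E", entry_col="entry")
        np.testing.assert_allclose(beta, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(
            np.sqrt(np.diag(cov)), cph.standard_errors_.to_numpy(), atol=1e-5
        )


class TestCoxFit:
    def test_planted_hr_recovered(self):
        cfg = gr.SimulationConfig(n_patients=500, planted_hr_effects={"GP6": 2.0})
        cohort = gr.simulate_cohort(cfg, seed=2)
        pre = cohort.peaks[cohort.peaks.days_from_ici_start <= 0]
        g = gr.preprocess_chain(pre)
        vals = g.values.set_axis(g.meta.loc[g.values.index, "patient_id"], axis=0)
        cl = cohort.clinical.set_index("patient_id")
        outcome = pd.DataFrame({"time": cl.pfs_days, "event": cl.pfs_event})
        fit = gr.cox_fit(vals["GP6"], outcome, cl[["age", "sex", "bmi", "ldh_high", "ecog"]])
        assert fit.converged
        assert abs(fit.beta - np.log(2.0)) < 3 * fit.se
        assert fit.ci_low < fit.hr < fit.ci_high

    def test_degenerate_glycan_gives_null_result(self, preprocessed):
        values, clinical = preprocessed
        outcome = pd.DataFrame(
            {"time": clinical.pfs_days, "event": clinical.pfs_event}
        )
        zero = pd.Series(0.0, index=values.index, name="null_glycan")
        fit = gr.cox_fit(zero, outcome, clinical[["age", "sex", "bmi", "ldh_high", "ecog"]])
        assert fit.hr == 1.0
        assert fit.p_lrt == 1.0

    def test_event_floor_enforced(self, preprocessed):
        values, clinical = preprocessed
        outcome = pd.DataFrame({"time": clinical.pfs_days, "event": 0})
        outcome.iloc[:3, 1] = 1
        with pytest.raises(ValueError, match="events"):
            gr.cox_fit(values["GP1"], outcome, None, min_events=10)


class TestPHDiagnostics:
    def test_single_term_global_equals_term_test(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.standard_normal(n)
        t = rng.exponential(1 / np.exp(0.5 * x))
        s = _coxlib.build_structure(t, np.ones(n, dtype=int))
        X = x[:, None]
        beta, _, cov, _ = _coxlib.newton_fit(X, s)
        stat, p = _coxlib.grambsch_therneau_global(beta, X, s, cov)
        # df = 1: the global chi-square is the term's own test by construction
        from scipy import stats as st

        assert p == pytest.approx(st.chi2.sf(stat, 1))

    def test_detects_sign_reversal(self):
        # effect +b before median time, -b after: strong PH violation
        rng = np.random.default_rng(4)
        n = 500
        x = rng.standard_normal(n)
        t = np.empty(n)
        early = rng.random(n) < 0.5
        t[early] = rng.exponential(1 / np.exp(1.2 * x[early]), early.sum())
        t[early] = np.minimum(t[early], 1.0)
        t[~early] = 1.0 + rng.exponential(1 / np.exp(-1.2 * x[~early]), (~early).sum())
        s = _coxlib.build_structure(t, np.ones(n, dtype=int))
        X = x[:, None]
        beta, _, cov, _ = _coxlib.newton_fit(X, s)
        _, p = _coxlib.grambsch_therneau_global(beta, X, s, cov)
        assert p < 0.01

    def test_calibrated_under_proportional_hazards(self):
        rej = 0
        n_sim = 150
        for i in range(n_sim):
            rng = np.random.default_rng(1000 + i)
            x = rng.standard_normal((100, 2))
            t = rng.exponential(1 / np.exp(0.4 * x[:, 0]))
            s = _coxlib.build_structure(t, np.ones(100, dtype=int))
            beta, _, cov, conv = _coxlib.newton_fit(x, s)
            if not conv:
                continue
            _, p = _coxlib.grambsch_therneau_global(beta, x, s, cov)
            rej += p < 0.05
        assert 0.02 <= rej / n_sim <= 0.09


class TestTimePartition:
    def test_piecewise_hr_recovered(self):
        cfg = gr.SimulationConfig(
            n_patients=800,
            piecewise_hr={"GP6": (3.0, 1.0, 180.0)},
            censor_rate=0.1,
            baseline_hazard_pfs=1 / 500,
            admin_censor_day=1000,
        )
        cohort = gr.simulate_cohort(cfg, seed=3)
        pre = cohort.peaks[cohort.peaks.days_from_ici_start <= 0]
        g = gr.preprocess_chain(pre)
        vals = g.values.set_axis(g.meta.loc[g.values.index, "patient_id"], axis=0)
        cl = cohort.clinical.set_index("patient_id")
        outcome = pd.DataFrame({"time": cl.pfs_days, "event": cl.pfs_event})
        fits = {
            f.term: f
            for f in gr.time_partitioned_cox(
                vals["GP6"], outcome, cl[["age", "sex", "bmi", "ldh_high", "ecog"]]
            )
        }
        assert 2.2 <= fits["short"].hr <= 4.0
        assert 0.8 <= fits["long"].hr <= 1.3

    def test_event_counts_partition(self, preprocessed):
        from glycoresponse.survival import _term_dataset

        _, clinical = preprocessed
        outcome = pd.DataFrame({"time": clinical.pfs_days, "event": clinical.pfs_event})
        terms = _term_dataset(outcome)
        total = sum(int(t["event"].sum()) for t in terms.values())
        assert total == int(outcome["event"].sum())

    def test_cuts_beyond_followup_skipped(self, preprocessed):
        values, clinical = preprocessed
        outcome = pd.DataFrame({"time": clinical.pfs_days, "event": clinical.pfs_event})
        fits = gr.time_partitioned_cox(
            values["GP1"], outcome,
            clinical[["age", "sex", "bmi", "ldh_high", "ecog"]],
            cuts=(5000.0, 6000.0),
        )
        assert {f.term for f in fits} == {"short"}


class TestQuartilePermutation:
    def test_strong_effect_scaled_down(self):
        cfg = gr.SimulationConfig(n_patients=300, planted_hr_effects={"GP6": 2.5})
        cohort = gr.simulate_cohort(cfg, seed=5)
        pre = cohort.peaks[cohort.peaks.days_from_ici_start <= 0]
        g = gr.preprocess_chain(pre)
        vals = g.values.set_axis(g.meta.loc[g.values.index, "patient_id"], axis=0)
        cl = cohort.clinical.set_index("patient_id")
        outcome = pd.DataFrame({"time": cl.pfs_days, "event": cl.pfs_event})
        res = gr.quartile_stratified_permutation(
            vals["GP6"], outcome, cl[["age", "sex", "bmi", "ldh_high", "ecog"]],
            threshold=0.0025, n_perm=99, seed=6, criterion="observed",
        )
        assert res["eP"] == pytest.approx(1 / 100)

    def test_determinism_and_stratum_multisets(self, preprocessed):
        values, clinical = preprocessed
        outcome = pd.DataFrame({"time": clinical.pfs_days, "event": clinical.pfs_event})
        cov = clinical[["age", "sex", "bmi", "ldh_high", "ecog"]]
        a = gr.quartile_stratified_permutation(
            values["GP6"], outcome, cov, 0.0025, n_perm=20, seed=9
        )
        b = gr.quartile_stratified_permutation(
            values["GP6"], outcome, cov, 0.0025, n_perm=20, seed=9
        )
        assert a["eP"] == b["eP"]
        assert sum(a["strata_sizes"]) == len(values["GP6"].dropna())


class TestKaplanMeier:
    def test_product_limit_on_five_subject_toy(self):
        # survival 1, 3+, 5, 7, 9+: S = 4/5 after t=1, then 4/5 * 2/3 after 5,
        # then 4/5 * 2/3 * 1/2 after 7
        glycan = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], name="g")
        outcome = pd.DataFrame(
            {"time": [1, 3, 5, 7, 9], "event": [1, 0, 1, 1, 0]}
        )
        res = gr.km_tertiles(glycan, outcome)
        # reconstruct a single pooled curve via one-group fit for the check
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(outcome["time"], outcome["event"])
        expected = [1.0, 0.8, 0.8, 0.8 * 2 / 3, 0.8 * 2 / 3 * 0.5]
        np.testing.assert_allclose(
            km.survival_function_.iloc[:, 0].to_numpy()[: len(expected)],
            expected, atol=1e-12,
        )
        for curve in res["curves"].values():
            assert curve["survival"].iloc[0] == 1.0

    def test_extreme_separation(self):
        rng = np.random.default_rng(7)
        n = 60
        glycan = pd.Series(np.concatenate([rng.uniform(0, 1, 20),
                                           rng.uniform(1, 2, 20),
                                           rng.uniform(2, 3, 20)]))
        time = np.concatenate([np.full(20, 1.0), np.full(20, 50.0), np.full(20, 100.0)])
        event = np.concatenate([np.ones(20), np.zeros(20), np.zeros(20)]).astype(int)
        res = gr.km_tertiles(glycan, pd.DataFrame({"time": time, "event": event}))
        assert res["logrank_p"] < 1e-6

    def test_needs_three_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            gr.km_tertiles(
                pd.Series([1.0, 1.0, 2.0]),
                pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1]}),
            )
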