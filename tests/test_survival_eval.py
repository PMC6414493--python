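"""Score evaluation: Cox fits, nested LR tests, PH diagnostics,
Kaplan–Meier quantile curves and the APOE e3/e3 subgroup."""

import numpy as np
import pandas as pd
import pytest

from polyhazard.polygenic_scores import ScoreSet, adjust_and_standardize
from polyhazard.survival_eval import (evaluate_score, km_quantile_curves,
                                      lr_nested_test, ph_assumption_test,
                                      subgroup_e33)
from polyhazard.synthetic_cohort import (CohortConfig, impute_age_at_onset,
                                         simulate_cohort)


def _eta_scores(cohort):
    df = pd.DataFrame({"score_combined": cohort.phenotype["true_eta"].to_numpy()})
    return ScoreSet(raw=df, standardized=df)


@pytest.fixture(scope="module")
def clean_cohort():
    cfg = CohortConfig(n_individuals=2500, n_snps=30, n_blocks=30, n_causal=10,
                       causal_effect_sd=0.3, birth_cohort_fraction=0.0,
                       onset_missing_fraction=0.0, seed=13)
    return simulate_cohort(cfg)


class TestEvaluateScore:
    def test_unit_coefficient_on_true_eta(self, clean_cohort):
        ev = evaluate_score(clean_cohort, _eta_scores(clean_cohort),
                            "combined_only", ph_test=False)
        assert abs(ev.beta_score - 1.0) <= 2 * ev.se
        assert ev.converged and ev.n_events > 0

    def test_permuted_score_is_null(self, clean_cohort):
        rng = np.random.default_rng(0)
        eta = rng.permutation(clean_cohort.phenotype["true_eta"].to_numpy())
        df = pd.DataFrame({"score_combined": eta})
        ev = evaluate_score(clean_cohort, ScoreSet(raw=df, standardized=df),
                            "combined_only", ph_test=False)
        assert ev.p > 0.001

    def test_apoe_plus_score_reports_both_terms(self, small_cohort):
        ph = small_cohort.phenotype
        raw = pd.DataFrame({
            "score_apoe": -0.47 * ph["apoe_e2_count"] + 1.03 * ph["apoe_e4_count"],
            "score_snps": small_cohort.dosages[:, :10].sum(axis=1),
        })
        sc = adjust_and_standardize(
            ScoreSet(raw=raw), ph[["sex", "pc1", "pc2", "pc3"]].to_numpy(float))
        ev = evaluate_score(small_cohort, sc, "apoe_plus_score", ph_test=True)
        assert np.isfinite(ev.beta_apoe) and np.isfinite(ev.beta_score)
        assert ev.beta_apoe > 0  # APOE e4 raises hazard by construction
        assert set(ev.ph_test_p) >= {"score_apoe", "score_snps", "GLOBAL"}

    def test_zero_variance_score_rejected(self, small_cohort):
        df = pd.DataFrame({"score_combined": np.zeros(small_cohort.n_individuals)})
        with pytest.raises(ValueError, match="degenerate|constant"):
            evaluate_score(small_cohort, ScoreSet(raw=df, standardized=df),
                           "combined_only", ph_test=False)

    def test_collinear_terms_rejected(self, small_cohort):
        v = small_cohort.phenotype["pc1"].to_numpy()  # duplicates a covariate
        df = pd.DataFrame({"score_combined": v})
        with pytest.raises(ValueError, match="collinear"):
            evaluate_score(small_cohort, ScoreSet(raw=df, standardized=df),
                           "combined_only", ph_test=False)


class TestLrNestedTest:
    def _fits(self, cohort):
        ph = cohort.phenotype
        rng = np.random.default_rng(1)
        raw = pd.DataFrame({
            "score_apoe": -0.47 * ph["apoe_e2_count"] + 1.03 * ph["apoe_e4_count"],
            "score_snps": rng.normal(size=len(ph)),
        })
        sc = adjust_and_standardize(
            ScoreSet(raw=raw), ph[["sex", "pc1", "pc2", "pc3"]].to_numpy(float))
        full = evaluate_score(cohort, sc, "apoe_plus_score", ph_test=False)
        red = evaluate_score(cohort, sc, "apoe_only", ph_test=False)
        return full, red

    def test_identical_models_give_zero_stat_unit_p(self, small_cohort):
        full, _ = self._fits(small_cohort)
        lr, df, p = lr_nested_test(full, full)
        assert lr == 0.0 and df == 0 and p == 1.0

    def test_noise_term_small_stat(self, small_cohort):
        full, red = self._fits(small_cohort)
        lr, df, p = lr_nested_test(full, red)
        assert df == 1 and lr >= 0 and p > 0.001

    def test_predictive_score_strongly_rejected(self, clean_cohort):
        ph = clean_cohort.phenotype
        raw = pd.DataFrame({
            "score_apoe": -0.47 * ph["apoe_e2_count"] + 1.03 * ph["apoe_e4_count"],
            "score_snps": ph["true_eta"].to_numpy(),
        })
        sc = adjust_and_standardize(
            ScoreSet(raw=raw), ph[["sex", "pc1", "pc2", "pc3"]].to_numpy(float))
        full = evaluate_score(clean_cohort, sc, "apoe_plus_score", ph_test=False)
        red = evaluate_score(clean_cohort, sc, "apoe_only", ph_test=False)
        lr, df, p = lr_nested_test(full, red)
        assert p < 1e-6
        # Wald and LR agree on the verdict in the large-effect regime
        assert (full.p < 0.05) == (p < 0.05)

    def test_non_nested_rejected(self, small_cohort):
        full, red = self._fits(small_cohort)
        with pytest.raises(ValueError, match="nest"):
            lr_nested_test(red, full)


class TestPhAssumption:
    def test_nonsignificant_under_ph(self, clean_cohort):
        out = ph_assumption_test(clean_cohort, _eta_scores(clean_cohort),
                                 "combined_only")
        assert out["score_combined"] > 0.01
        assert 0 <= out["GLOBAL"] <= 1

    def test_detects_sign_reversal(self):
        from polyhazard._cox import SurvData, cox_fit, zph_test
        from polyhazard.synthetic_cohort import simulate_times_sign_reversal
        rng = np.random.default_rng(2)
        n = 4000
        x = rng.normal(size=n)
        t = simulate_times_sign_reversal(0.5 * x, 6.0, 90.0, rng, tau=65.0)
        assess = np.clip(rng.normal(72, 8, n), 1, None)
        event = (t <= assess).astype(int)
        time = np.where(event == 1, t, assess)
        sd = SurvData(time, event)
        fit = cox_fit(x, data=sd)
        assert zph_test(fit, sd, x)["p"][0] < 0.05


class TestKMQuantileCurves:
    def _scores(self, values):
        df = pd.DataFrame({"score_combined": np.asarray(values, float)})
        return ScoreSet(raw=df, standardized=df)

    def test_bin_sizes_100_distinct(self, small_cohort):
        sub = small_cohort.subset_individuals(np.arange(100))
        km = km_quantile_curves(sub, self._scores(np.arange(100.0)))
        assert [km.group_n[g] for g in
                ("0-5%", "5-25%", "25-75%", "75-95%", "95-100%")] == [5, 20, 50, 20, 5]

    def test_no_censoring_closed_form(self):
        """All events at distinct ages: S after the k-th of n events is
        exactly 1 - k/n inside each group."""
        n = 40
        ph = pd.DataFrame({
            "id": [f"i{k}" for k in range(n)], "status": "case",
            "age_at_onset": 50.0 + np.arange(n),
            "age_last_assessment": 100.0, "sex": 0,
            "pc1": 0.0, "pc2": 0.0, "pc3": 0.0,
            "apoe_e2_count": 0.0, "apoe_e4_count": 0.0,
        })
        from polyhazard.synthetic_cohort import CohortData
        meta = pd.DataFrame({"id": ["v1"], "chromosome": ["1"], "position": [1],
                             "effect_allele": ["A"], "other_allele": ["G"],
                             "true_beta": [0.0]})
        cohort = CohortData(np.zeros((n, 1)), meta, ph)
        km = km_quantile_curves(cohort, self._scores(np.arange(float(n))))
        mid = km.curves["25-75%"]  # 20 members, all events, distinct ages
        mid = mid[mid["age"] > 0].reset_index(drop=True)  # drop the S(0)=1 row
        expect = 1 - np.arange(1, len(mid) + 1) / len(mid)
        np.testing.assert_allclose(mid["survival"], expect, atol=1e-12)

    def test_curves_monotone_in_unit_interval(self, small_cohort):
        s = small_cohort.dosages[:, 0] + np.random.default_rng(3).normal(
            0, 0.01, small_cohort.n_individuals)
        km = km_quantile_curves(small_cohort, self._scores(s))
        for c in km.curves.values():
            assert c["survival"].iloc[0] <= 1.0
            assert c["survival"].is_monotonic_decreasing
            assert (c["survival"] >= 0).all()

    def test_risk_groups_ordered_by_survival(self):
        """Strong positive score effect: the age at which S(t) crosses 0.75
        decreases from the bottom-5% group to the top-5% group."""
        cfg = CohortConfig(n_individuals=6000, n_snps=5, n_blocks=5, n_causal=0,
                           apoe_like=True, birth_cohort_fraction=0.0,
                           onset_missing_fraction=0.0, seed=21)
        cohort = simulate_cohort(cfg)
        km = km_quantile_curves(cohort, self._scores(
            cohort.phenotype["true_eta"].to_numpy()))

        def age_at(curve, level):
            below = curve[curve["survival"] <= level]
            return below["age"].iloc[0] if len(below) else np.inf

        ages = [age_at(km.curves[g], 0.75) for g in
                ("0-5%", "5-25%", "25-75%", "75-95%", "95-100%")]
        finite = [a for a in ages if np.isfinite(a)]
        assert finite == sorted(finite, reverse=True)
        assert ages[-1] < ages[0]

    def test_empty_bins_warn(self, small_cohort):
        with pytest.warns(UserWarning, match="empty"):
            km = km_quantile_curves(
                small_cohort, self._scores(np.zeros(small_cohort.n_individuals)))
        assert km.group_n["0-5%"] == small_cohort.n_individuals


class TestSubgroupE33:
    def test_keeps_only_double_zero_counts(self, small_cohort):
        sub = subgroup_e33(small_cohort)
        assert (sub.phenotype["apoe_e2_count"] == 0).all()
        assert (sub.phenotype["apoe_e4_count"] == 0).all()
        n_expected = int(((small_cohort.phenotype["apoe_e2_count"] == 0)
                          & (small_cohort.phenotype["apoe_e4_count"] == 0)).sum())
        assert sub.n_individuals == n_expected > 0

    def test_missing_counts_rejected(self, small_cohort):
        bad = small_cohort.subset_individuals(np.arange(20))
        bad.phenotype.loc[0, "apoe_e2_count"] = np.nan
        with pytest.raises(ValueError, match="lack APOE"):
            subgroup_e33(bad)
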