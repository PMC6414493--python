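"""Score construction: allele alignment, weighted sums, APOE handling,
covariate adjustment and standardization."""

import numpy as np
import pandas as pd
import pytest

from polyhazard.io import load_published_weights
from polyhazard.polygenic_scores import (ScoreSet, WeightTable,
                                         adjust_and_standardize,
                                         align_alleles, build_score_set,
                                         compute_score, score_correlation)
from polyhazard.synthetic_cohort import CohortData


def _weights(rows):
    return WeightTable(pd.DataFrame(rows))


def _tiny_cohort(dosages, e2=None, e4=None, ids=("v1", "v2")):
    n, m = dosages.shape
    meta = pd.DataFrame({
        "id": list(ids), "chromosome": "1",
        "position": 1000 * (np.arange(m) + 1),
        "effect_allele": "A", "other_allele": "G", "true_beta": 0.0,
    })
    ph = pd.DataFrame({
        "id": [f"i{k}" for k in range(n)], "status": "control",
        "age_at_onset": np.nan, "age_last_assessment": 70.0, "sex": 0,
        "pc1": 0.0, "pc2": 0.0, "pc3": 0.0,
        "apoe_e2_count": e2 if e2 is not None else np.zeros(n),
        "apoe_e4_count": e4 if e4 is not None else np.zeros(n),
    })
    return CohortData(dosages.astype(float), meta, ph)


class TestAlignAlleles:
    META = pd.DataFrame({"id": ["v1", "v2", "v3"],
                         "effect_allele": ["A", "A", "A"],
                         "other_allele": ["G", "G", "G"]})

    def test_match_flip_and_drop(self):
        w = _weights([
            {"id": "v1", "effect_allele": "A", "weight": 0.5, "source": "t"},
            {"id": "v2", "effect_allele": "G", "weight": 0.2, "source": "t"},
            {"id": "v3", "effect_allele": "T", "weight": 0.1, "source": "t"},
        ])
        with pytest.warns(UserWarning, match="dropped 1"):
            out = align_alleles(w, self.META)
        t = out.table.set_index("id")
        assert not t.at["v1", "flip"]
        assert t.at["v2", "flip"]
        assert "v3" not in t.index
        assert out.dropped["reason"].tolist() == ["allele_mismatch"]

    def test_apoe_rows_pass_through(self):
        w = _weights([
            {"id": "APOE_e4", "effect_allele": "e4", "weight": 1.03, "source": "t"},
        ])
        out = align_alleles(w, self.META)
        assert len(out.table) == 1 and not out.table["flip"].iloc[0]

    def test_duplicate_conflicting_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _weights([
                {"id": "v1", "effect_allele": "A", "weight": 0.5, "source": "t"},
                {"id": "v1", "effect_allele": "G", "weight": 0.3, "source": "t"},
            ])


class TestComputeScore:
    def test_weighted_sum_arithmetic(self):
        cohort = _tiny_cohort(np.array([[2.0, 1.0]]))
        w = align_alleles(_weights([
            {"id": "v1", "effect_allele": "A", "weight": 0.5, "source": "t"},
            {"id": "v2", "effect_allele": "A", "weight": -0.2, "source": "t"},
        ]), cohort.variant_meta)
        sc = compute_score(cohort, w, "snps")
        assert sc.raw["score_snps"].iloc[0] == pytest.approx(0.8)
        assert sc.n_snps_used["snps"] == 2

    def test_flip_uses_complement_dosage(self):
        cohort = _tiny_cohort(np.array([[2.0, 1.0]]))
        w = align_alleles(_weights([
            {"id": "v1", "effect_allele": "G", "weight": 0.5, "source": "t"},
        ]), cohort.variant_meta)
        sc = compute_score(cohort, w, "snps")
        assert sc.raw["score_snps"].iloc[0] == pytest.approx(0.5 * (2 - 2.0))

    def test_apoe_published_weights(self):
        """One e4 copy scores 1.03; an e2/e2 homozygote scores -0.94."""
        cohort = _tiny_cohort(np.zeros((2, 2)),
                              e2=np.array([0.0, 2.0]), e4=np.array([1.0, 0.0]))
        w = load_published_weights("phs")
        sc = compute_score(cohort, w, "apoe")
        assert sc.raw["score_apoe"].iloc[0] == pytest.approx(1.03)
        assert sc.raw["score_apoe"].iloc[1] == pytest.approx(-0.94)

    def test_missing_apoe_counts_excluded(self):
        cohort = _tiny_cohort(np.zeros((2, 2)),
                              e2=np.array([np.nan, 0.0]), e4=np.array([1.0, 1.0]))
        w = load_published_weights("phs")
        sc = compute_score(cohort, w, "apoe")
        assert np.isnan(sc.raw["score_apoe"].iloc[0])
        assert sc.raw["score_apoe"].iloc[1] == pytest.approx(1.03)

    def test_missing_dosage_contributes_variant_mean(self):
        d = np.array([[2.0, 0.0], [np.nan, 0.0], [1.0, 0.0]])
        cohort = _tiny_cohort(d)
        w = align_alleles(_weights([
            {"id": "v1", "effect_allele": "A", "weight": 1.0, "source": "t"},
        ]), cohort.variant_meta)
        sc = compute_score(cohort, w, "snps")
        assert sc.raw["score_snps"].iloc[1] == pytest.approx(1.5)  # mean of 2,1

    def test_combined_is_sum_of_parts(self, small_cohort):
        w = _weights([
            {"id": "APOE_e2", "effect_allele": "e2", "weight": -0.47, "source": "t"},
            {"id": "APOE_e4", "effect_allele": "e4", "weight": 1.03, "source": "t"},
            {"id": small_cohort.variant_meta["id"].iloc[0],
             "effect_allele": "A", "weight": 0.3, "source": "t"},
            {"id": small_cohort.variant_meta["id"].iloc[5],
             "effect_allele": "A", "weight": -0.2, "source": "t"},
        ])
        aligned = align_alleles(w, small_cohort.variant_meta)
        ss = build_score_set(small_cohort, aligned)
        np.testing.assert_allclose(
            ss.raw["score_combined"],
            ss.raw["score_apoe"] + ss.raw["score_snps"])

    def test_variant_order_invariance(self, small_cohort):
        ids = small_cohort.variant_meta["id"].iloc[[0, 5, 9]].tolist()
        rows = [{"id": v, "effect_allele": "A", "weight": w, "source": "t"}
                for v, w in zip(ids, (0.3, -0.2, 0.1))]
        a = compute_score(small_cohort,
                          align_alleles(_weights(rows), small_cohort.variant_meta), "snps")
        b = compute_score(small_cohort,
                          align_alleles(_weights(rows[::-1]), small_cohort.variant_meta), "snps")
        np.testing.assert_allclose(a.raw["score_snps"], b.raw["score_snps"],
                                   atol=1e-12)

    def test_empty_weight_table_rejected(self, small_cohort):
        empty = WeightTable(pd.DataFrame(columns=["id", "effect_allele", "weight"]))
        with pytest.raises(ValueError, match="empty"):
            compute_score(small_cohort, empty, "snps")


class TestAdjustAndStandardize:
    def _scores(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return ScoreSet(raw=pd.DataFrame({"score_snps": rng.normal(size=n)})), rng

    def test_output_mean_zero_sd_one(self):
        sc, rng = self._scores()
        covs = rng.normal(size=(200, 4))
        out = adjust_and_standardize(sc, covs)
        col = out.standardized["score_snps"]
        assert abs(col.mean()) < 1e-8
        assert col.std(ddof=0) == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_covariates_reduce_to_zscore(self):
        sc, _ = self._scores()
        covs = np.zeros((200, 1))  # degenerate column -> lstsq drops signal
        out = adjust_and_standardize(sc, covs)
        raw = sc.raw["score_snps"].to_numpy()
        z = (raw - raw.mean()) / raw.std(ddof=0)
        np.testing.assert_allclose(out.standardized["score_snps"], z, atol=1e-8)

    def test_score_equal_to_covariate_combination_raises(self):
        rng = np.random.default_rng(1)
        covs = rng.normal(size=(100, 2))
        sc = ScoreSet(raw=pd.DataFrame({"score_snps": covs @ [1.0, -2.0] + 3}))
        with pytest.raises(ValueError, match="zero residual variance"):
            adjust_and_standardize(sc, covs)

    def test_joint_coding_flip_leaves_score_unchanged(self, small_cohort):
        """Recoding a variant's dosage d -> 2-d while its aligned flip flag
        toggles leaves every individual's score identical."""
        j = 3
        vid = small_cohort.variant_meta["id"].iloc[j]
        rows = [{"id": vid, "effect_allele": "A", "weight": 0.4, "source": "t"}]
        w1 = align_alleles(_weights(rows), small_cohort.variant_meta)
        s1 = compute_score(small_cohort, w1, "snps").raw["score_snps"]

        recoded = CohortData(small_cohort.dosages.copy(),
                             small_cohort.variant_meta.copy(),
                             small_cohort.phenotype.copy())
        recoded.dosages[:, j] = 2.0 - recoded.dosages[:, j]
        recoded.variant_meta.loc[j, ["effect_allele", "other_allele"]] = ["G", "A"]
        w2 = align_alleles(_weights(rows), recoded.variant_meta)
        assert bool(w2.table["flip"].iloc[0])
        s2 = compute_score(recoded, w2, "snps").raw["score_snps"]
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestScoreCorrelation:
    def _std(self, values):
        df = pd.DataFrame({"score_combined": values})
        return ScoreSet(raw=df, standardized=df)

    def test_identical_weights_give_unit_correlation(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=50)
        assert score_correlation(self._std(v), self._std(v)) == pytest.approx(1.0)

    def test_negated_weights_give_minus_one(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=50)
        assert score_correlation(self._std(v), self._std(-v)) == pytest.approx(-1.0)

    def test_too_few_individuals(self):
        with pytest.raises(ValueError, match="3 individuals"):
            score_correlation(self._std([1.0, 2.0]), self._std([1.0, 2.0]))
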