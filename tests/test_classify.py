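"""Correlation analysis, composite response scoring, thresholding and PAM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bh3rank.classify import (
    KMedoids,
    classify_threshold,
    gene_drug_correlation,
    pam_cluster,
    pam_features,
    tumor_response_score,
)
from bh3rank.priming import PrimingMatrix
from bh3rank.qpcr import ExpressionTable


def make_pm(priming: pd.DataFrame) -> PrimingMatrix:
    shape = priming.shape
    return PrimingMatrix(
        priming=priming,
        replicate_cv=pd.DataFrame(0.0, index=priming.index, columns=priming.columns),
        clamped=pd.DataFrame(False, index=priming.index, columns=priming.columns),
        n_clamped=0,
    )


def make_expr(rq: pd.DataFrame) -> ExpressionTable:
    return ExpressionTable(ddct=-np.log2(rq), rq=rq)


class TestGeneDrugCorrelation:
    def test_perfect_anticorrelation(self):
        rq = pd.DataFrame({"G": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        prim = pd.DataFrame({"d": [80.0, 60.0, 40.0, 20.0]}, index=list("abcd"))
        cm = gene_drug_correlation(make_expr(rq), make_pm(prim))
        assert cm.r.at["G", "d"] == pytest.approx(-1.0)
        assert cm.p.at["G", "d"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors_give_zero(self):
        rq = pd.DataFrame({"G": [1.0, 2.0, 3.0]}, index=list("abc"))
        prim = pd.DataFrame({"d": [50.0, 60.0, 50.0]}, index=list("abc"))
        cm = gene_drug_correlation(make_expr(rq), make_pm(prim))
        assert cm.r.at["G", "d"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(0)
        tumors = [f"T{i}" for i in range(10)]
        rq = pd.DataFrame(rng.uniform(0.25, 4, size=(10, 3)), index=tumors,
                          columns=["G1", "G2", "G3"])
        prim = pd.DataFrame(rng.uniform(0, 100, size=(10, 4)), index=tumors,
                            columns=["d1", "d2", "d3", "d4"])
        cm = gene_drug_correlation(make_expr(rq), make_pm(prim))
        for g in rq.columns:
            for d in prim.columns:
                ref = sps.pearsonr(rq[g], prim[d])
                assert cm.r.at[g, d] == pytest.approx(ref.statistic, abs=1e-9)
                assert cm.p.at[g, d] == pytest.approx(ref.pvalue, abs=1e-9)
            avg = prim.mean(axis=1)
            ref = sps.pearsonr(rq[g], avg)
            assert cm.r.at[g, "average_priming"] == pytest.approx(ref.statistic, abs=1e-9)

    def test_constant_input_flagged_undefined(self):
        rq = pd.DataFrame({"G": [2.0, 2.0, 2.0]}, index=list("abc"))
        prim = pd.DataFrame({"d": [10.0, 20.0, 30.0]}, index=list("abc"))
        cm = gene_drug_correlation(make_expr(rq), make_pm(prim))
        assert np.isnan(cm.r.at["G", "d"])

    def test_gender_stratification(self):
        rng = np.random.default_rng(1)
        tumors = [f"T{i}" for i in range(8)]
        rq = pd.DataFrame({"G": rng.uniform(0.5, 2, 8)}, index=tumors)
        prim = pd.DataFrame({"d": rng.uniform(0, 100, 8)}, index=tumors)
        meta = pd.DataFrame({"gender": ["male"] * 4 + ["female"] * 4}, index=tumors)
        out = gene_drug_correlation(
            make_expr(rq), make_pm(prim), metadata=meta, group_by="gender"
        )
        assert set(out) == {"male", "female"}
        male_ref = sps.pearsonr(rq["G"][:4], prim["d"][:4])
        assert out["male"].r.at["G", "d"] == pytest.approx(male_ref.statistic, abs=1e-9)
        assert out["male"].n.at["G", "d"] == 4

    def test_requires_three_shared_tumors(self):
        rq = pd.DataFrame({"G": [1.0, 2.0]}, index=["a", "b"])
        prim = pd.DataFrame({"d": [10.0, 20.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="3 tumors"):
            gene_drug_correlation(make_expr(rq), make_pm(prim))


class TestResponseScore:
    def test_identical_tumors_score_zero(self):
        rq = pd.DataFrame(2.0, index=list("abc"), columns=["G1", "TP53"])
        prim = pd.DataFrame(50.0, index=list("abc"), columns=["d1", "d2"])
        s = tumor_response_score(make_expr(rq), make_pm(prim))
        assert (s == 0).all()

    def test_higher_priming_scores_higher(self):
        rq = pd.DataFrame(2.0, index=list("abc"), columns=["G1", "TP53"])
        prim = pd.DataFrame({"d": [30.0, 50.0, 70.0]}, index=list("abc"))
        s = tumor_response_score(make_expr(rq), make_pm(prim))
        assert s["c"] > s["b"] > s["a"]

    def test_five_tumor_hand_computed_z_sum(self):
        rng = np.random.default_rng(2)
        tumors = list("abcde")
        rq = pd.DataFrame(
            rng.uniform(0.5, 4, size=(5, 3)), index=tumors, columns=["G1", "G2", "TP53"]
        )
        prim = pd.DataFrame(rng.uniform(10, 90, size=(5, 2)), index=tumors,
                            columns=["d1", "d2"])
        s = tumor_response_score(make_expr(rq), make_pm(prim))

        def z(v):
            return (v - v.mean()) / v.std(ddof=0)

        expected = (
            z(prim.mean(axis=1))
            - z(np.log2(rq[["G1", "G2"]]).mean(axis=1))
            + z(np.log2(rq["TP53"]))
        )
        pd.testing.assert_series_equal(s, expected.rename("score"), atol=1e-12)

    def test_empty_protective_set_warns_and_omits_term(self):
        rq = pd.DataFrame(
            [[1.0], [2.0], [4.0]], index=list("abc"), columns=["G1"]
        )
        prim = pd.DataFrame(50.0, index=list("abc"), columns=["d"])
        with pytest.warns(UserWarning, match="protective"):
            s = tumor_response_score(
                make_expr(rq), make_pm(prim), protective_genes=["TP53"]
            )
        assert s["a"] > s["c"]  # only the resistance term varies


class TestThresholdClassification:
    def test_forced_labels(self):
        scores = pd.Series([-2.0, 0.0, 2.0], index=list("abc"))
        tc = classify_threshold(scores, cut_low=-1.0, cut_high=1.0)
        assert tc.labels.to_dict() == {"a": "resistant", "b": "moderate", "c": "sensitive"}

    def test_all_equal_scores_all_moderate_under_default_terciles(self):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        tc = classify_threshold(scores)
        assert (tc.labels == "moderate").all()

    def test_boundary_score_is_sensitive(self):
        scores = pd.Series([1.0, 0.0, -1.0], index=list("abc"))
        tc = classify_threshold(scores, cut_low=-0.5, cut_high=1.0)
        assert tc.labels["a"] == "sensitive"  # >= cut_high convention

    def test_nonfinite_scores_excluded_with_warning(self):
        scores = pd.Series([1.0, np.nan, -1.0], index=list("abc"))
        with pytest.warns(UserWarning, match="non-finite"):
            tc = classify_threshold(scores, cut_low=-0.5, cut_high=0.5)
        assert "b" not in tc.labels.index

    def test_invalid_cuts_rejected(self):
        with pytest.raises(ValueError):
            classify_threshold(pd.Series([1.0, 2.0, 3.0]), cut_low=1.0, cut_high=0.0)

    def test_planted_separated_classes_recovered(self):
        # class means 8 within-class SDs apart: latent draws cannot interleave,
        # so with cuts in the gaps the assignment is forced
        from bh3rank.classify import tumor_response_score
        from bh3rank.cohort import CohortParams, generate_cohort
        from bh3rank.priming import percent_priming
        from bh3rank.qpcr import delta_delta_ct

        params = CohortParams(
            n_tumors=31, class_score_means=(-8.0, 0.0, 8.0),
            ct_noise_sd=0.1, priming_noise_sd=1.0, rfu_noise_cv=0.0,
            gender_effect=0.0, seed=5,
        )
        cohort = generate_cohort(params)
        expr = delta_delta_ct(cohort.ct_table)
        pm = percent_priming(cohort.plate)
        scores = tumor_response_score(expr, pm)
        by_class = scores.groupby(cohort.true_classes).agg(["min", "max"])
        cut_low = (by_class.at["resistant", "max"] + by_class.at["moderate", "min"]) / 2
        cut_high = (by_class.at["moderate", "max"] + by_class.at["sensitive", "min"]) / 2
        tc = classify_threshold(scores, cut_low=cut_low, cut_high=cut_high)
        assert (tc.labels.sort_index() == cohort.true_classes.sort_index()).all()


def exhaustive_kmedoids_cost(X: np.ndarray, k: int) -> float:
    from scipy.spatial.distance import cdist

    D = cdist(X, X)
    best = np.inf
    for meds in itertools.combinations(range(len(X)), k):
        best = min(best, D[:, meds].min(axis=1).sum())
    return float(best)


class TestKMedoids:
    def test_separated_triplets_forced_clusters(self):
        X = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2, 20.0, 20.1, 20.2]).reshape(-1, 1)
        km = KMedoids(n_clusters=3).fit(X)
        labels = km.labels_
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:6])) == 1
        assert len(set(labels[6:])) == 1
        assert len({labels[0], labels[3], labels[6]}) == 3
        # within-triplet cost: each triplet's medoid is its middle point
        assert km.inertia_ == pytest.approx(3 * 0.2)

    def test_k1_matches_brute_force_medoid_scan(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2))
        km = KMedoids(n_clusters=1).fit(X)
        from scipy.spatial.distance import cdist

        D = cdist(X, X)
        assert km.inertia_ == pytest.approx(D.sum(axis=0).min())

    @pytest.mark.parametrize("k", [2, 3])
    def test_small_instances_swap_local_optimality(self, k):
        # the algorithm's guarantee: no single (medoid, non-medoid) exchange
        # improves the final cost, and the cost never undercuts the exhaustive
        # optimum; on most small instances the two coincide
        from scipy.spatial.distance import cdist

        rng = np.random.default_rng(4)
        exact = 0
        for _ in range(25):
            n = int(rng.integers(k + 1, 9))
            X = rng.normal(size=(n, 3))
            km = KMedoids(n_clusters=k).fit(X)
            opt = exhaustive_kmedoids_cost(X, k)
            assert km.inertia_ >= opt - 1e-9
            D = cdist(X, X)
            meds = list(km.medoid_indices_)
            for i in range(k):
                for h in range(n):
                    if h in meds:
                        continue
                    trial = meds.copy()
                    trial[i] = h
                    assert D[:, trial].min(axis=1).sum() >= km.inertia_ - 1e-9
            exact += km.inertia_ == pytest.approx(opt, abs=1e-9)
        assert exact >= 15  # swap-local optima occur but are the minority

    def test_deterministic_fit(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        a, b = KMedoids(n_clusters=3).fit(X), KMedoids(n_clusters=3).fit(X)
        assert np.array_equal(a.medoid_indices_, b.medoid_indices_)
        assert a.inertia_ == b.inertia_

    def test_k_exceeding_distinct_points_rejected(self):
        X = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(ValueError, match="distinct"):
            KMedoids(n_clusters=3).fit(X)

    def test_medoid_cost_consistency(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 2))
        km = KMedoids(n_clusters=3).fit(X)
        from scipy.spatial.distance import cdist

        D = cdist(X, X)
        cost = sum(
            D[i, km.medoid_indices_[km.labels_[i]]] for i in range(len(X))
        )
        assert km.inertia_ == pytest.approx(cost, abs=1e-9)
        # each medoid belongs to its own cluster
        for ci, m in enumerate(km.medoid_indices_):
            assert km.labels_[m] == ci

    def test_predict_assigns_nearest_medoid(self):
        X = np.array([[0.0], [10.0], [20.0]])
        km = KMedoids(n_clusters=3).fit(X)
        assert list(km.predict(np.array([[1.0], [19.0]]))) == [
            km.labels_[0], km.labels_[2],
        ]

    def test_get_set_params_round_trip(self):
        km = KMedoids(n_clusters=2)
        km.set_params(**km.get_params())
        assert km.get_params() == {"n_clusters": 2, "metric": "euclidean"}


class TestPamClassification:
    def test_labels_ranked_by_priming(self, small_cohort):
        from bh3rank.priming import percent_priming

        pm = percent_priming(small_cohort.plate)
        feats = pam_features(small_cohort.ct_table, pm)
        tc = pam_cluster(feats, k=3)
        prim_cols = [c for c in feats.columns if c.startswith("priming:")]
        mean_by_label = feats[prim_cols].mean(axis=1).groupby(tc.labels).mean()
        assert mean_by_label["sensitive"] > mean_by_label["moderate"] > mean_by_label["resistant"]

    def test_recovers_well_separated_planted_classes(self):
        # balanced classes with 8-SD gaps: between-class distance dominates
        # within-class spread, so the planted partition is the cost optimum
        from sklearn.metrics import adjusted_rand_score

        from bh3rank.cohort import CohortParams, generate_cohort
        from bh3rank.priming import percent_priming

        params = CohortParams(
            n_tumors=30, class_proportions=(1 / 3, 1 / 3, 1 / 3),
            class_score_means=(-8.0, 0.0, 8.0), gender_effect=0.0, seed=11,
        )
        cohort = generate_cohort(params)
        pm = percent_priming(cohort.plate)
        tc = pam_cluster(pam_features(cohort.ct_table, pm), k=3)
        ari = adjusted_rand_score(
            cohort.true_classes.sort_index(), tc.labels.sort_index()
        )
        assert ari >= 0.99

    def test_fig6_sign_structure(self, small_cohort):
        # resistance genes anticorrelate with priming; the protective gene correlates
        from bh3rank.classify import gene_drug_correlation
        from bh3rank.priming import percent_priming
        from bh3rank.qpcr import delta_delta_ct

        expr = delta_delta_ct(small_cohort.ct_table)
        pm = percent_priming(small_cohort.plate)
        cm = gene_drug_correlation(expr, pm)
        for gene in cm.r.index:
            for drug in pm.drug_ids:
                if gene == "TP53":
                    assert cm.r.at[gene, drug] > 0
                else:
                    assert cm.r.at[gene, drug] < 0
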