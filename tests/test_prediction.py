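import numpy as np
import pandas as pd
import pytest

from overlapnet.devstats import CohortPanel
from overlapnet.prediction import (
    FEATURE_NAMES,
    SvrConfig,
    age_prediction_null,
    contribution_weights,
    fa_strength,
    predict_age,
    predict_entropy_from_structure,
    resample_and_predict,
    residualize_for_prediction,
    select_independent_scans,
    stratified_folds,
    structure_prediction_null,
    univariate_structure_correlations,
)
from overlapnet.synthdata import gen_longitudinal_cohort, gen_parcellation, gen_structural_features


def planted_age_features(n=80, nodes=15, informative=5, snr=2.0, seed=0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(6, 14, n)
    x = rng.normal(0, 1, (n, nodes))
    z = (ages - ages.mean()) / ages.std()
    x[:, :informative] += snr * z[:, None]
    return x, ages


class TestSelectIndependentScans:
    def test_one_scan_per_subject(self):
        panel, _ = gen_longitudinal_cohort(seed=0, node_slopes=[0.0])
        sub = select_independent_scans(panel, seed=1)
        assert len(sub) == 305
        assert sub.data["subject_id"].is_unique

    def test_single_scan_subjects_always_kept(self):
        panel, _ = gen_longitudinal_cohort(n_subjects=20, node_slopes=[0.0], seed=2)
        singles = panel.data.groupby("subject_id").filter(lambda g: len(g) == 1)
        sub = select_independent_scans(panel, seed=3)
        assert set(singles["scan_id"]).issubset(set(sub.data["scan_id"]))

    def test_different_seeds_differ_for_multiscan_subjects(self):
        panel, _ = gen_longitudinal_cohort(n_subjects=100, node_slopes=[0.0], seed=4)
        picks = [set(select_independent_scans(panel, seed=s).data["scan_id"]) for s in range(5)]
        assert any(picks[0] != other for other in picks[1:])


class TestStratifiedFolds:
    def test_sizes_differ_by_at_most_one(self):
        ages = np.random.default_rng(0).uniform(6, 14, 37)
        folds = stratified_folds(ages, k=10, seed=0)
        sizes = np.bincount(folds)[1:]
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 37

    def test_twenty_items_ten_folds_all_pairs(self):
        folds = stratified_folds(np.arange(20.0), k=10, seed=1)
        assert np.all(np.bincount(folds)[1:] == 2)

    def test_leave_one_out_boundary(self):
        folds = stratified_folds(np.arange(8.0), k=8, seed=2)
        assert sorted(folds) == list(range(1, 9))

    def test_better_age_balance_than_random_splits(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(6, 14, 100)
        folds = stratified_folds(ages, k=10, seed=3)
        dev = max(abs(ages[folds == f].mean() - ages.mean()) for f in range(1, 11))
        random_devs = []
        for s in range(200):
            perm = rng.permutation(np.arange(100) % 10 + 1)
            random_devs.append(max(abs(ages[perm == f].mean() - ages.mean()) for f in range(1, 11)))
        assert dev < np.quantile(random_devs, 0.05)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.arange(5.0), k=10)


class TestPredictAge:
    def test_planted_signal_beats_null(self):
        x, ages = planted_age_features(seed=5)
        folds = stratified_folds(ages, k=10, seed=5)
        res = age_prediction_null(x, ages, folds, n=99, seed=5)
        assert res.r > np.quantile(res.null_r, 0.95)
        assert res.p < 0.05

    def test_prediction_invariant_to_feature_order(self):
        x, ages = planted_age_features(seed=6)
        folds = stratified_folds(ages, k=10, seed=6)
        perm = np.random.default_rng(6).permutation(x.shape[1])
        a = predict_age(x, ages, folds)
        b = predict_age(x[:, perm], ages, folds)
        assert np.allclose(a.predicted, b.predicted, atol=1e-6)

    def test_no_test_set_leakage_into_scaler(self):
        """An extreme outlier in a test row must not change predictions for
        the other test rows of the same fold (train-only min-max scaling)."""
        x, ages = planted_age_features(seed=7)
        folds = stratified_folds(ages, k=10, seed=7)
        target_fold = 1
        rows = np.flatnonzero(folds == target_fold)
        x2 = x.copy()
        x2[rows[0]] = 1e6
        a = predict_age(x, ages, folds)
        b = predict_age(x2, ages, folds)
        assert np.allclose(a.predicted[rows[1:]], b.predicted[rows[1:]])

    def test_null_p_floor(self):
        x, ages = planted_age_features(n=40, seed=8)
        folds = stratified_folds(ages, k=10, seed=8)
        res = age_prediction_null(x, ages, folds, n=19, seed=8)
        assert res.p >= 1 / 20


class TestResampleAndPredict:
    def test_single_scan_subjects_give_degenerate_distribution(self):
        panel, _ = gen_longitudinal_cohort(
            n_subjects=40, scans_per_subject_distribution={1: 40},
            node_slopes=np.full(8, 0.05), noise_sd=0.02, seed=9)
        out = resample_and_predict(panel, n_repeats=3, seed=9)
        assert np.allclose(out["r"], out["r"][0])

    def test_distribution_summary_reported(self):
        panel, _ = gen_longitudinal_cohort(n_subjects=50, node_slopes=np.full(6, 0.04),
                                           noise_sd=0.05, seed=10)
        out = resample_and_predict(panel, n_repeats=5, seed=10, collect_weights=True)
        assert out["r_q05"] <= out["r_mean"] <= out["r_q95"]
        assert out["mean_weights"].shape == (6,)


class TestContributionWeights:
    def test_single_informative_node_has_max_weight(self):
        rng = np.random.default_rng(11)
        n, nodes = 100, 10
        ages = rng.uniform(6, 14, n)
        x = rng.normal(0, 1, (n, nodes))
        x[:, 4] += 3.0 * (ages - ages.mean()) / ages.std()
        w = contribution_weights(x, ages).weights
        assert np.argmax(np.abs(w)) == 4

    def test_zero_targets_give_near_zero_weights(self):
        rng = np.random.default_rng(12)
        w = contribution_weights(rng.normal(0, 1, (50, 5)), np.zeros(50)).weights
        assert np.abs(w).max() < 0.05

    def test_system_aggregation_preserves_sign_partition(self):
        parc = gen_parcellation(16, seed=0)
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, (60, 16))
        y = x[:, 0] - x[:, 8] + rng.normal(0, 0.1, 60)
        cw = contribution_weights(x, y, parc=parc)
        pos = [v for v in cw.system_positive.values() if not np.isnan(v)]
        neg = [v for v in cw.system_negative.values() if not np.isnan(v)]
        assert all(v > 0 for v in pos)
        assert all(v < 0 for v in neg)


class TestResidualize:
    def test_mfd_effect_removed(self):
        panel, _ = gen_longitudinal_cohort(n_subjects=120, node_slopes=[0.02],
                                           betas={"mFD": 1.0}, seed=14)
        raw_r = np.corrcoef(panel.data["node0"], panel.data["mFD"])[0, 1]
        adj = residualize_for_prediction(panel, ["node0"])
        adj_r = np.corrcoef(adj.data["node0"], adj.data["mFD"])[0, 1]
        assert abs(adj_r) < abs(raw_r)
        assert abs(adj_r) < 0.1

    def test_fixed_age_signal_preserved(self):
        panel, _ = gen_longitudinal_cohort(n_subjects=120, node_slopes=[0.05], seed=15)
        adj = residualize_for_prediction(panel, ["node0"])
        r = np.corrcoef(adj.data["node0"], adj.data["age"])[0, 1]
        assert r > 0.5

    def test_near_identity_without_covariate_effects(self):
        panel, _ = gen_longitudinal_cohort(
            n_subjects=100, node_slopes=[0.05],
            betas={"sex": 0.0, "mFD": 0.0},
            re_sds={"intercept": 1e-4, "slope": 1e-4}, seed=16)
        adj = residualize_for_prediction(panel, ["node0"])
        # BLUP shrinkage absorbs a little residual noise, so near- not exact identity
        assert np.corrcoef(adj.data["node0"], panel.data["node0"])[0, 1] > 0.95


class TestFaStrength:
    def test_zero_matrix(self):
        assert np.all(fa_strength(np.zeros((4, 4))) == 0)

    def test_hand_row_sum(self):
        fa = np.zeros((3, 3))
        fa[0, 1] = fa[1, 0] = 0.4
        fa[0, 2] = fa[2, 0] = 0.5
        assert fa_strength(fa)[0] == pytest.approx(0.9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        fa = rng.uniform(0, 1, (20, 20))
        fa = (fa + fa.T) / 2
        expected = np.array([sum(fa[i, j] for j in range(20) if j != i) for i in range(20)])
        assert np.allclose(fa_strength(fa), expected)

    def test_asymmetry_rejected(self):
        fa = np.zeros((3, 3))
        fa[0, 1] = 0.5
        with pytest.raises(ValueError, match="asymmetric"):
            fa_strength(fa)


class TestStructurePrediction:
    def test_planted_coupling_beats_per_scan_null(self):
        rng = np.random.default_rng(17)
        scans = []
        for s in range(3):
            h = np.clip(rng.normal(0.5, 0.2, 50), 0, 1)
            feats, _ = gen_structural_features(h, noise_sd=0.3, seed=s)
            scans.append((feats, h))
        out = structure_prediction_null(scans, shuffles_per_scan=30, seed=17)
        assert out["n_null"] == 90
        assert np.all(out["observed_r"] > out["threshold_95"])
        assert np.all(out["significant"])

    def test_null_count_bookkeeping(self):
        rng = np.random.default_rng(18)
        scans = []
        for s in range(2):
            h = rng.uniform(0, 1, 30)
            feats, _ = gen_structural_features(h, noise_sd=5.0, seed=s + 10)
            scans.append((feats, h))
        out = structure_prediction_null(scans, shuffles_per_scan=3, seed=18)
        assert out["n_null"] == 6

    def test_dominant_feature_recovers_largest_weight(self):
        rng = np.random.default_rng(19)
        h = np.clip(rng.normal(0.5, 0.2, 60), 0, 1)
        loadings = np.zeros(6)
        loadings[1] = 1.0  # thickness-analog carries all signal
        feats, _ = gen_structural_features(h, loadings=loadings, noise_sd=0.1, seed=19)
        res, w = predict_entropy_from_structure(feats, h, seed=19)
        assert res.r > 0.5
        assert np.argmax(np.abs(w)) == 1

    def test_missing_feature_column_rejected(self):
        df = pd.DataFrame({n: np.zeros(20) for n in FEATURE_NAMES[:-1]})
        with pytest.raises(ValueError, match="missing columns"):
            predict_entropy_from_structure(df, np.zeros(20))


class TestUnivariateCorrelations:
    def test_perfect_and_anti_correlation(self):
        h = np.linspace(0, 1, 30)
        feats = pd.DataFrame({n: h if i == 0 else -h for i, n in enumerate(FEATURE_NAMES)})
        rs = univariate_structure_correlations(feats, h)
        assert rs["CV"] == pytest.approx(1.0)
        assert rs["CT"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=(40, 6))
        h = rng.normal(size=40)
        rs = univariate_structure_correlations(x, h)
        for col, name in enumerate(FEATURE_NAMES):
            cov = np.mean((x[:, col] - x[:, col].mean()) * (h - h.mean()))
            expected = cov / (x[:, col].std() * h.std())
            assert rs[name] == pytest.approx(expected, abs=1e-10)
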