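"""Support-vector-regression prediction pipelines.

Two directions are covered: predicting chronological age from a scan's
node-wise entropy map (scan-level, age-stratified 10-fold cross-validation,
with repeated random selection of one scan per subject and a
label-permutation null), and predicting a scan's entropy map from six
node-wise structural features — cortical volume (CV), thickness (CT),
curvature (CC), folding index (FI), surface area (SA) and white-matter FA
strength — with node-level 10-fold cross-validation and a pooled
shuffled-entropy null.  The SVR is linear-kernel epsilon-SVR with C = 1 and
epsilon = 0.1; features are min-max scaled on each training split and the
scaling applied unchanged to the test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .devstats import CohortPanel, fit_mixed_linear
from .netio import Parcellation, SYSTEMS

__all__ = [
    "SvrConfig",
    "PredictionResult",
    "ContributionWeights",
    "select_independent_scans",
    "stratified_folds",
    "predict_age",
    "age_prediction_null",
    "resample_and_predict",
    "contribution_weights",
    "residualize_for_prediction",
    "fa_strength",
    "predict_entropy_from_structure",
    "structure_prediction_null",
    "univariate_structure_correlations",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("CV", "CT", "CC", "FI", "SA", "FA_strength")


@dataclass
class SvrConfig:
    C: float = 1.0
    epsilon: float = 0.1
    scale_features: bool = True

    def make(self) -> SVR:
        return SVR(kernel="linear", C=self.C, epsilon=self.epsilon)


@dataclass
class PredictionResult:
    predicted: np.ndarray
    actual: np.ndarray
    r: float
    p: float | None = None
    null_r: np.ndarray | None = field(default=None, repr=False)
    seed: int | None = None


@dataclass
class ContributionWeights:
    weights: np.ndarray  # per-feature signed weights
    system_positive: dict[str, float] | None = None
    system_negative: dict[str, float] | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _minmax_fit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    span[span == 0] = 1.0  # constant feature -> scaled to 0
    return lo, span


def select_independent_scans(panel: CohortPanel, seed: int) -> CohortPanel:
    """Keep one uniformly chosen scan per subject; deterministic per seed."""
    rng = np.random.default_rng(seed)
    picks = []
    for _, grp in panel.data.groupby("subject_id", sort=True):
        picks.append(grp.index[rng.integers(len(grp))])
    return CohortPanel(panel.data.loc[sorted(picks)].reset_index(drop=True))


def stratified_folds(ages: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Age-stratified fold assignment (ids 1..k), sizes differing by <= 1.

    Items are sorted by age, taken in consecutive blocks of k, shuffled
    within each block and dealt round-robin, so every fold samples the whole
    age range and fold age-means stay close to the global mean.
    """
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} items")
    rng = np.random.default_rng(seed)
    order = np.argsort(ages, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = order[start:start + k]
        rng.shuffle(block)
        for pos, item in enumerate(block):
            folds[item] = pos % k + 1
    return folds


def _cv_predict(features: np.ndarray, targets: np.ndarray, folds: np.ndarray,
                config: SvrConfig) -> np.ndarray:
    pred = np.empty_like(targets, dtype=float)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        x_tr, x_te = features[train], features[test]
        if config.scale_features:
            lo, span = _minmax_fit(x_tr)
            x_tr = (x_tr - lo) / span
            x_te = (x_te - lo) / span
        model = config.make()
        model.fit(x_tr, targets[train])
        pred[test] = model.predict(x_te)
    return pred


def predict_age(features: np.ndarray, ages: np.ndarray, folds: np.ndarray,
                svr_config: SvrConfig | None = None) -> PredictionResult:
    """Out-of-fold age prediction; accuracy is Pearson r (predicted, actual)."""
    config = svr_config or SvrConfig()
    features = np.asarray(features, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if features.shape[0] != ages.size or ages.size != np.asarray(folds).size:
        raise ValueError("features, ages and folds must align")
    pred = _cv_predict(features, ages, np.asarray(folds), config)
    return PredictionResult(predicted=pred, actual=ages, r=_pearson(pred, ages))


def age_prediction_null(features: np.ndarray, ages: np.ndarray, folds: np.ndarray,
                        n: int = 1000, seed: int = 0,
                        svr_config: SvrConfig | None = None) -> PredictionResult:
    """Permutation null for age prediction: shuffle ages, rerun the pipeline.

    p = (1 + #{null r >= observed r}) / (1 + n).
    """
    config = svr_config or SvrConfig()
    obs = predict_age(features, ages, folds, config)
    rng = np.random.default_rng(seed)
    null = np.empty(n)
    ages = np.asarray(ages, dtype=float)
    for i in range(n):
        null[i] = predict_age(features, rng.permutation(ages), folds, config).r
    p = (1.0 + np.count_nonzero(null >= obs.r)) / (1.0 + n)
    return PredictionResult(predicted=obs.predicted, actual=obs.actual, r=obs.r,
                            p=p, null_r=null, seed=seed)


def resample_and_predict(panel: CohortPanel, measures: list[str] | None = None,
                         n_repeats: int = 1000, seed: int = 0, k: int = 10,
                         svr_config: SvrConfig | None = None,
                         collect_weights: bool = False) -> dict:
    """Repeat (one scan per subject -> stratified folds -> SVR) ``n_repeats`` times.

    Returns the distribution of accuracies r and, optionally, contribution
    weights averaged over the resamples (each from a full-data refit).
    """
    config = svr_config or SvrConfig()
    measures = measures if measures is not None else panel.measures
    rng = np.random.default_rng(seed)
    rs = np.empty(n_repeats)
    weight_acc = None
    for rep in range(n_repeats):
        sub_seed = int(rng.integers(2**31 - 1))
        sub = select_independent_scans(panel, seed=sub_seed)
        x = sub.data[measures].to_numpy(dtype=float)
        ages = sub.data["age"].to_numpy(dtype=float)
        # fold seed fixed across repeats: identical scan selections give identical r
        folds = stratified_folds(ages, k=k, seed=seed)
        rs[rep] = predict_age(x, ages, folds, config).r
        if collect_weights:
            w = contribution_weights(x, ages, config).weights
            weight_acc = w if weight_acc is None else weight_acc + w
    out = {"r": rs, "r_mean": float(np.mean(rs)),
           "r_q05": float(np.quantile(rs, 0.05)), "r_q95": float(np.quantile(rs, 0.95))}
    if collect_weights:
        out["mean_weights"] = weight_acc / n_repeats
    return out


def contribution_weights(features: np.ndarray, targets: np.ndarray,
                         svr_config: SvrConfig | None = None,
                         parc: Parcellation | None = None) -> ContributionWeights:
    """Full-data linear-SVR fit; primal coefficients as feature importances.

    With a parcellation, positive and negative node weights are additionally
    averaged within each functional system (zero-filled systems excluded as
    NaN).
    """
    config = svr_config or SvrConfig()
    x = np.asarray(features, dtype=float)
    if config.scale_features:
        lo, span = _minmax_fit(x)
        x = (x - lo) / span
    model = config.make()
    model.fit(x, np.asarray(targets, dtype=float))
    w = model.coef_.ravel()
    sys_pos = sys_neg = None
    if parc is not None:
        sys_pos, sys_neg = {}, {}
        for s in SYSTEMS:
            idx = [i for i, lab in enumerate(parc.systems) if lab == s]
            ws = w[idx]
            pos, neg = ws[ws > 0], ws[ws < 0]
            sys_pos[s] = float(pos.mean()) if pos.size else float("nan")
            sys_neg[s] = float(neg.mean()) if neg.size else float("nan")
    return ContributionWeights(weights=w, system_positive=sys_pos, system_negative=sys_neg)


def residualize_for_prediction(panel: CohortPanel, measures: list[str] | None = None) -> CohortPanel:
    """Remove sex, head-motion and subject-specific random effects per measure.

    Each measure is fitted with the linear mixed model; the estimated
    B_sex*sex, B_mFD*mFD and subject random intercept/slope contributions
    are subtracted, leaving the population intercept plus fixed-age signal
    (and residual noise).  Measures whose fit fails are left as missing.
    """
    measures = measures if measures is not None else panel.measures
    df = panel.data.copy()
    for m in measures:
        fit = fit_mixed_linear(panel, m)
        if not fit.converged or fit.result is None:
            df[m] = np.nan
            continue
        res = fit.result
        adj = df[m].to_numpy(dtype=float).copy()
        adj -= fit.fixed["sex"]["beta"] * df["sex"].to_numpy(dtype=float)
        adj -= fit.fixed["mFD"]["beta"] * df["mFD"].to_numpy(dtype=float)
        re = res.random_effects
        for idx, row in df.iterrows():
            eff = re.get(row["subject_id"])
            if eff is None:
                continue
            adj[idx] -= float(eff.get("Group", 0.0))
            if "age" in eff:
                adj[idx] -= float(eff["age"]) * row["age"]
        df[m] = adj
    return CohortPanel(df)


def fa_strength(fa_matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Nodal FA strength: row sums of the mean-FA matrix, diagonal excluded."""
    fa = np.asarray(fa_matrix, dtype=float)
    if fa.ndim != 2 or fa.shape[0] != fa.shape[1]:
        raise ValueError("FA matrix must be square")
    if not np.allclose(fa, fa.T, atol=tol):
        raise ValueError("FA matrix asymmetric beyond tolerance")
    if np.any(fa < 0):
        raise ValueError("FA values must be nonnegative")
    return fa.sum(axis=1) - np.diag(fa)


def _as_feature_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        return features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def predict_entropy_from_structure(features, entropy: np.ndarray, k: int = 10, seed: int = 0,
                                   svr_config: SvrConfig | None = None) -> tuple[PredictionResult, np.ndarray]:
    """Node-wise k-fold prediction of one scan's entropy map from structure.

    Folds over nodes are random (unstratified).  Returns the pooled
    out-of-fold result and the feature weights from a whole-scan refit.
    """
    config = svr_config or SvrConfig()
    x = _as_feature_matrix(features)
    y = np.asarray(entropy, dtype=float)
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if y.size < k:
        raise ValueError("fewer non-missing nodes than folds")
    rng = np.random.default_rng(seed)
    folds = rng.permutation(np.arange(y.size) % k + 1)
    pred = _cv_predict(x, y, folds, config)
    result = PredictionResult(predicted=pred, actual=y, r=_pearson(pred, y), seed=seed)
    weights = contribution_weights(x, y, config).weights
    return result, weights


def structure_prediction_null(scans: list[tuple[object, np.ndarray]], shuffles_per_scan: int = 100,
                              seed: int = 0, k: int = 10,
                              svr_config: SvrConfig | None = None) -> dict:
    """Pooled shuffled-entropy null across scans for the structure pipeline.

    For every scan the entropy map is shuffled across nodes
    ``shuffles_per_scan`` times and the node-wise CV prediction rerun; all
    null accuracies are pooled (n_scans x shuffles values).  Returns the
    pooled null, its 95th percentile, the observed per-scan accuracies and
    per-scan significance against the pooled threshold.
    """
    config = svr_config or SvrConfig()
    rng = np.random.default_rng(seed)
    observed = []
    null_vals = []
    for features, entropy in scans:
        scan_seed = int(rng.integers(2**31 - 1))
        x = _as_feature_matrix(features)
        y = np.asarray(entropy, dtype=float)
        ok = ~np.isnan(y)
        x, y = x[ok], y[ok]
        if y.size < k:
            raise ValueError("fewer non-missing nodes than folds")
        folds = np.random.default_rng(scan_seed).permutation(np.arange(y.size) % k + 1)
        pred = _cv_predict(x, y, folds, config)
        observed.append(_pearson(pred, y))
        for _ in range(shuffles_per_scan):
            shuffled = rng.permutation(y)
            null_vals.append(_pearson(_cv_predict(x, shuffled, folds, config), shuffled))
    null = np.asarray(null_vals)
    thr = float(np.quantile(null, 0.95))
    observed = np.asarray(observed)
    return {
        "null_r": null,
        "threshold_95": thr,
        "observed_r": observed,
        "significant": observed > thr,
        "n_null": int(null.size),
    }


def univariate_structure_correlations(features, entropy: np.ndarray) -> dict[str, float]:
    """Pearson r between each structural feature and the entropy map."""
    x = _as_feature_matrix(features)
    y = np.asarray(entropy, dtype=float)
    ok = ~np.isnan(y)
    names = list(FEATURE_NAMES) if x.shape[1] == len(FEATURE_NAMES) else [f"f{i}" for i in range(x.shape[1])]
    out = {}
    for col, name in enumerate(names):
        xi = x[ok, col]
        out[name] = _pearson(xi, y[ok]) if np.std(xi) > 0 else float("nan")
    return out
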