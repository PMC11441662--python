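"""Longitudinal age-effect statistics for connectome measures.

Developmental change in a brain measure y observed for subject i at scan j
is modelled with linear mixed effects fitted by maximum likelihood:

    linear:     y_ij = b0 + b_i + (B_age + b_age,i) age_ij
                       + B_sex sex_i + B_mFD mFD_ij + e_ij
    quadratic:  ... + (B_age2 + b_age2,i) age_ij^2 ...

with subject-specific random intercepts and age slopes (independent by
default).  The model per measure is chosen by AIC; node-wise p-values of the
fixed age effect are corrected across nodes with Benjamini-Hochberg FDR.
Spatial correspondence tests use variogram-matching surrogate maps that
preserve a map's value multiset and approximate its spatial autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortPanel",
    "MixedModelFit",
    "fit_mixed_linear",
    "fit_mixed_quadratic",
    "select_by_aic",
    "fdr_correct",
    "nodewise_age_effects",
    "sa_surrogates",
    "sa_corrected_correlation",
    "variogram",
    "decile_bins",
]

REQUIRED_COLUMNS = ("subject_id", "scan_id", "age", "sex", "mFD")


@dataclass
class CohortPanel:
    """Longitudinal scan table: one row per scan, measure columns alongside."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        sex_per_subject = self.data.groupby("subject_id")["sex"].nunique()
        if (sex_per_subject > 1).any():
            raise ValueError("sex must be constant within subject")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CohortPanel":
        """Read a cohort CSV (subject_id, scan_id, age, sex, mFD, measures...)."""
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def measures(self) -> list[str]:
        return [c for c in self.data.columns if c not in REQUIRED_COLUMNS]

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MixedModelFit:
    model: str  # "linear" | "quadratic"
    measure: str
    fixed: dict[str, dict[str, float]]  # term -> {beta, se, t, p}
    random_variances: dict[str, float]
    llf: float
    aic: float
    converged: bool
    fallback: str | None = None  # None | "intercept_only" | "failed"
    result: object = field(default=None, repr=False)  # statsmodels results

    def ci95(self, term: str) -> tuple[float, float]:
        fx = self.fixed[term]
        return fx["beta"] - 1.96 * fx["se"], fx["beta"] + 1.96 * fx["se"]


def _diagonal_free(k_fe: int, k_re: int) -> MixedLMParams:
    return MixedLMParams.from_components(fe_params=np.ones(k_fe), cov_re=np.eye(k_re))


def _fit_one(panel: CohortPanel, measure: str, quadratic: bool,
             diagonal_re: bool = True) -> MixedModelFit:
    df = panel.data[["subject_id", "age", "sex", "mFD", measure]].dropna().copy()
    df = df.rename(columns={measure: "y"})
    df["age2"] = df["age"] ** 2
    if df["subject_id"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    re_formula = "~age + age2" if quadratic else "~age"
    fixed_formula = "y ~ age + age2 + sex + mFD" if quadratic else "y ~ age + sex + mFD"
    name = "quadratic" if quadratic else "linear"

    def try_fit(re_f: str):
        model = smf.mixedlm(fixed_formula, df, groups=df["subject_id"], re_formula=re_f)
        k_re = model.k_re
        free = _diagonal_free(model.k_fe, k_re) if (diagonal_re and k_re > 1) else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, free=free, method=["lbfgs", "bfgs"])
        return res

    fallback = None
    try:
        res = try_fit(re_formula)
        if not res.converged:
            raise RuntimeError("non-convergence")
    except Exception:
        fallback = "intercept_only"
        try:
            res = try_fit("~1")
        except Exception:
            return MixedModelFit(model=name, measure=measure, fixed={}, random_variances={},
                                 llf=float("nan"), aic=float("nan"), converged=False,
                                 fallback="failed")
    fixed = {}
    for term in res.fe_params.index:
        key = {"Intercept": "intercept", "age": "age", "age2": "age2", "sex": "sex", "mFD": "mFD"}.get(term, term)
        fixed[key] = {
            "beta": float(res.fe_params[term]),
            "se": float(res.bse_fe[term]),
            "t": float(res.tvalues[term]),
            "p": float(res.pvalues[term]),
        }
    rv = {str(k): float(v) for k, v in np.ndenumerate(np.diag(np.atleast_2d(res.cov_re)))} if res.k_re else {}
    return MixedModelFit(model=name, measure=measure, fixed=fixed, random_variances=rv,
                         llf=float(res.llf), aic=float(res.aic),
                         converged=bool(res.converged), fallback=fallback, result=res)


def fit_mixed_linear(panel: CohortPanel, measure: str, diagonal_re: bool = True) -> MixedModelFit:
    """ML mixed model with random intercept + random age slope."""
    return _fit_one(panel, measure, quadratic=False, diagonal_re=diagonal_re)


def fit_mixed_quadratic(panel: CohortPanel, measure: str, diagonal_re: bool = True) -> MixedModelFit:
    """As the linear model plus fixed and random age^2 terms."""
    return _fit_one(panel, measure, quadratic=True, diagonal_re=diagonal_re)


def select_by_aic(fits: list[MixedModelFit]) -> MixedModelFit:
    """Minimum-AIC choice among converged fits; exact tie favours the simpler model."""
    order = {"linear": 0, "quadratic": 1}
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged fit to select from")
    return min(ok, key=lambda f: (f.aic, order.get(f.model, 99)))


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def nodewise_age_effects(panel: CohortPanel, measures: list[str] | None = None,
                         q: float = 0.05) -> pd.DataFrame:
    """AIC-selected age effect per node, FDR-corrected across nodes.

    For each measure both the linear and quadratic models are fitted; the
    AIC winner contributes its highest-order fixed age term (age for linear,
    age^2 for quadratic) to the node-wise t/p map.
    """
    measures = measures if measures is not None else panel.measures
    rows = []
    for m in measures:
        lin = fit_mixed_linear(panel, m)
        quad = fit_mixed_quadratic(panel, m)
        chosen = select_by_aic([lin, quad])
        term = "age" if chosen.model == "linear" else "age2"
        fx = chosen.fixed.get(term, {"t": float("nan"), "p": float("nan")})
        rows.append({"measure": m, "model": chosen.model, "t": fx["t"], "p": fx["p"],
                     "fallback": chosen.fallback})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["p_adj"] = np.nan
    df["significant"] = False
    if ok.any():
        rej, adj = fdr_correct(df.loc[ok, "p"].to_numpy(), q=q)
        df.loc[ok, "p_adj"] = adj
        df.loc[ok, "significant"] = rej
    return df


# ---------------------------------------------------------------------------
# spatial-autocorrelation-preserving surrogates


def variogram(values: np.ndarray, distances: np.ndarray, n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Empirical semivariogram over distance-quantile lag bins.

    Returns (bin centre distances, gamma) with
    gamma(h) = 0.5 * mean (x_i - x_j)^2 over pairs in the bin.
    """
    iu, ju = np.triu_indices(distances.shape[0], k=1)
    d = distances[iu, ju]
    sq = 0.5 * (values[iu] - values[ju]) ** 2
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-12
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    centres = np.empty(n_bins)
    gamma = np.empty(n_bins)
    for b in range(n_bins):
        mask = which == b
        centres[b] = d[mask].mean() if mask.any() else np.nan
        gamma[b] = sq[mask].mean() if mask.any() else np.nan
    return centres, gamma


def _smooth(values: np.ndarray, distances: np.ndarray, bandwidth: float) -> np.ndarray:
    k = np.exp(-0.5 * (distances / bandwidth) ** 2)
    return (k @ values) / k.sum(axis=1)


def sa_surrogates(values: np.ndarray, distances: np.ndarray, n: int, seed: int,
                  n_bins: int = 10, bandwidth_grid: np.ndarray | None = None) -> np.ndarray:
    """Variogram-matching surrogate maps preserving the value multiset.

    Each surrogate permutes the map, smooths the permutation with Gaussian
    distance kernels from a candidate bandwidth grid (5 log-spaced widths by
    default, spanning the distance range), keeps the candidate whose
    variogram best matches the original's, and finally rank-remaps the
    smoothed field back onto the original values.  Every surrogate is thus
    an exact permutation of the input with similar spatial autocorrelation.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("cannot build surrogates for a constant map")
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != values.shape[0] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric and match the map")
    rng = np.random.default_rng(seed)
    pos = d[np.triu_indices_from(d, k=1)]
    if bandwidth_grid is None:
        lo, hi = np.quantile(pos, [0.05, 1.0])
        bandwidth_grid = np.geomspace(max(lo, 1e-6) * 0.1, hi, 5)
    _, gamma_obs = variogram(values, d, n_bins=n_bins)
    sorted_vals = np.sort(values)
    out = np.empty((n, values.size))
    for s in range(n):
        perm = rng.permutation(values)
        best, best_err = perm, np.inf
        for bw in bandwidth_grid:
            cand = _smooth(perm, d, bw)
            if np.ptp(cand) == 0:
                continue
            # rank-remap before scoring so the score reflects the final map
            remapped = np.empty_like(cand)
            remapped[np.argsort(cand, kind="stable")] = sorted_vals
            _, gamma_c = variogram(remapped, d, n_bins=n_bins)
            err = float(np.nansum((gamma_c - gamma_obs) ** 2))
            if err < best_err:
                best, best_err = remapped, err
        # score the raw permutation too (white-noise maps need no smoothing)
        _, gamma_p = variogram(perm, d, n_bins=n_bins)
        if float(np.nansum((gamma_p - gamma_obs) ** 2)) < best_err:
            best = perm
        out[s] = best
    return out


def sa_corrected_correlation(map_a: np.ndarray, map_b: np.ndarray, distances: np.ndarray,
                             n: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Pearson r of two maps with a spatial-autocorrelation-corrected p.

    The null correlates ``map_b`` with surrogates of ``map_a``; p is the
    two-sided add-one fraction of |null r| >= |observed r|.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share the node set")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    surr = sa_surrogates(a, distances, n=n, seed=seed)
    bs = (b - b.mean()) / b.std()
    ss = (surr - surr.mean(axis=1, keepdims=True)) / surr.std(axis=1, ddof=0, keepdims=True)
    null_r = (ss @ bs) / a.size
    p = (1.0 + np.count_nonzero(np.abs(null_r) >= abs(r_obs))) / (1.0 + n)
    return r_obs, p


def decile_bins(values: np.ndarray) -> list[np.ndarray]:
    """Split nodes into 10 near-equal bins by descending value.

    Returns 10 boolean masks that partition the node set; the first masks
    hold the largest values.  With a remainder, the leading bins get the
    extra node (e.g., 232 nodes -> 24, 24, 23, ..., 23).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 10:
        raise ValueError("need at least 10 nodes for decile bins")
    order = np.argsort(-values, kind="stable")
    masks = []
    for chunk in np.array_split(order, 10):
        m = np.zeros(n, dtype=bool)
        m[chunk] = True
        masks.append(m)
    return masks
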