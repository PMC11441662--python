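"""Synthetic cohorts with planted ground truth.

Three generators cover the inputs the analysis consumes, each seeded and
exactly reproducible:

* correlation matrices with planted overlapping modular block structure —
  every node belongs to one or two modules and the expected correlation of
  a node pair grows with the fraction of memberships they share;
* longitudinal measure panels following the linear mixed-effects generative
  model (subject random intercepts and age slopes, sex and head-motion
  covariates, ages 6-14 with 1-3 scans per subject about a year apart);
* node-wise structural feature tables linearly coupled to an entropy map
  with Gaussian noise (thickness loading positive, the other five negative).

Planted parameters are returned alongside the data as a
:class:`SyntheticTruth` so recovery can be scored.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netio import CorrelationMatrix, Parcellation, SYSTEMS
from .devstats import CohortPanel
from .prediction import FEATURE_NAMES

__all__ = [
    "SyntheticTruth",
    "substream",
    "gen_overlapping_network",
    "gen_longitudinal_cohort",
    "gen_structural_features",
    "gen_coordinates",
    "gen_parcellation",
    "simulate_dataset",
]

# scans-per-subject composition of a paper-scale accelerated cohort:
# 166 single-scan + 92 two-scan + 47 three-scan subjects = 491 scans
DEFAULT_SCAN_DISTRIBUTION = {1: 166, 2: 92, 3: 47}


@dataclass
class SyntheticTruth:
    """Planted parameters serialized beside every generated dataset."""

    seed: int
    memberships: list[tuple[int, ...]] | None = None
    within_strength: float | None = None
    between_strength: float | None = None
    noise_sd: float | None = None
    node_slopes: np.ndarray | None = None
    betas: dict[str, float] | None = None
    re_sds: dict[str, float] | None = None
    loadings: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named child RNG derived deterministically from one master seed."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def gen_overlapping_network(n_nodes: int = 232, n_modules: int = 7, overlap_fraction: float = 0.3,
                            within_strength: float = 0.6, between_strength: float = 0.05,
                            noise_sd: float = 0.05, seed: int = 0) -> tuple[CorrelationMatrix, SyntheticTruth]:
    """Correlation matrix with planted overlapping modular blocks.

    Nodes are dealt round-robin into ``n_modules`` primary modules; an
    ``overlap_fraction`` of nodes gains a second membership in another,
    randomly chosen module (spreading membership pairs so that same-pair
    dual nodes do not themselves form a coherent block).  The pre-noise
    correlation of pair (i, j) is

        between + within * |m_i & m_j| / min(|m_i|, |m_j|)

    (the denominator is the largest membership count the pair could share),
    plus N(0, noise_sd) noise, symmetrized, clipped into (-1, 1), with a
    unit diagonal.
    """
    if not (0 <= overlap_fraction <= 1):
        raise ValueError("overlap_fraction must be in [0, 1]")
    if not (-1 < between_strength and between_strength + within_strength < 1):
        raise ValueError("strengths must keep correlations inside (-1, 1)")
    rng = substream(seed, "network")
    primary = np.arange(n_nodes) % n_modules
    n_dual = int(round(overlap_fraction * n_nodes))
    dual_nodes = rng.choice(n_nodes, size=n_dual, replace=False)
    memberships: list[tuple[int, ...]] = []
    dual_set = set(dual_nodes.tolist())
    for i in range(n_nodes):
        if i in dual_set and n_modules > 1:
            second = int(rng.integers(n_modules - 1))
            if second >= primary[i]:
                second += 1
            memberships.append((int(primary[i]), second))
        else:
            memberships.append((int(primary[i]),))
    base = np.full((n_nodes, n_nodes), between_strength)
    for i in range(n_nodes):
        mi = set(memberships[i])
        for j in range(i + 1, n_nodes):
            mj = set(memberships[j])
            shared = len(mi & mj)
            if shared:
                max_share = min(len(mi), len(mj))
                base[i, j] = base[j, i] = between_strength + within_strength * shared / max_share
    noise = rng.normal(0.0, noise_sd, size=(n_nodes, n_nodes))
    noise = (noise + noise.T) / 2.0
    values = np.clip(base + noise, -0.999, 0.999)
    np.fill_diagonal(values, 1.0)
    corr = CorrelationMatrix(values=values, node_ids=[str(i) for i in range(n_nodes)])
    truth = SyntheticTruth(seed=seed, memberships=memberships, within_strength=within_strength,
                           between_strength=between_strength, noise_sd=noise_sd,
                           extra={"n_modules": n_modules, "dual_nodes": sorted(int(d) for d in dual_nodes)})
    return corr, truth


def gen_longitudinal_cohort(n_subjects: int | None = None,
                            scans_per_subject_distribution: dict[int, int] | None = None,
                            age_range: tuple[float, float] = (6.0, 14.0),
                            node_slopes: np.ndarray | None = None,
                            betas: dict[str, float] | None = None,
                            re_sds: dict[str, float] | None = None,
                            noise_sd: float = 0.05,
                            seed: int = 0) -> tuple[CohortPanel, SyntheticTruth]:
    """Accelerated-longitudinal cohort following the linear mixed model.

    Baseline ages are uniform over ``age_range``; follow-up scans arrive at
    roughly one-year intervals (jitter sd 0.1 yr).  Each node measure is
    generated as intercept + subject random intercept + (slope + subject
    random slope) * age + B_sex * sex + B_mFD * mFD + noise, with sex
    Bernoulli(0.5) and mFD from a right-skewed lognormal (median ~0.1 mm).
    """
    dist = dict(scans_per_subject_distribution or DEFAULT_SCAN_DISTRIBUTION)
    if any(k < 1 or v < 0 for k, v in dist.items()):
        raise ValueError("invalid scans-per-subject distribution")
    if n_subjects is not None:
        total = sum(dist.values())
        scaled = {k: max(0, int(round(v * n_subjects / total))) for k, v in dist.items()}
        scaled[1] = scaled.get(1, 0) + n_subjects - sum(scaled.values())
        dist = scaled
    slopes = np.atleast_1d(np.asarray(node_slopes if node_slopes is not None else [0.02], dtype=float))
    betas = {"intercept": 0.5, "sex": 0.02, "mFD": 0.1, **(betas or {})}
    re_sds = {"intercept": 0.05, "slope": 0.01, **(re_sds or {})}
    rng = substream(seed, "cohort")
    n_nodes = slopes.size
    rows = []
    subject = 0
    for n_scans, count in sorted(dist.items()):
        for _ in range(count):
            sid = f"sub{subject:04d}"
            sex = int(rng.integers(2))
            baseline = rng.uniform(age_range[0], max(age_range[0], age_range[1] - (n_scans - 1)))
            b_int = rng.normal(0.0, re_sds["intercept"], size=n_nodes)
            b_slope = rng.normal(0.0, re_sds["slope"], size=n_nodes)
            for scan in range(n_scans):
                age = baseline + scan * 1.0 + (rng.normal(0.0, 0.1) if scan else 0.0)
                mfd = float(np.exp(rng.normal(np.log(0.1), 0.4)))
                y = (betas["intercept"] + b_int + (slopes + b_slope) * age
                     + betas["sex"] * sex + betas["mFD"] * mfd
                     + rng.normal(0.0, noise_sd, size=n_nodes))
                row = {"subject_id": sid, "scan_id": f"{sid}_s{scan}", "age": age,
                       "sex": sex, "mFD": mfd}
                row.update({f"node{k}": y[k] for k in range(n_nodes)})
                rows.append(row)
            subject += 1
    panel = CohortPanel(pd.DataFrame(rows))
    truth = SyntheticTruth(seed=seed, node_slopes=slopes, betas=betas,
                           re_sds=re_sds, noise_sd=noise_sd,
                           extra={"scan_distribution": dist, "age_range": list(age_range)})
    return panel, truth


def gen_structural_features(entropy_map: np.ndarray, loadings: np.ndarray | None = None,
                            noise_sd: float = 0.5, seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Six node-wise structural features linearly coupled to an entropy map.

    feature_f = loading_f * standardized(entropy) + N(0, noise_sd).  Default
    loadings follow the empirical sign pattern: cortical thickness couples
    positively with entropy, the other five features negatively.
    """
    y = np.asarray(entropy_map, dtype=float)
    if loadings is None:
        loadings = np.array([-0.5, 0.5, -0.5, -0.5, -0.5, -0.5])
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (len(FEATURE_NAMES),):
        raise ValueError(f"loadings must have length {len(FEATURE_NAMES)}")
    rng = substream(seed, "features")
    ok = ~np.isnan(y)
    z = np.full_like(y, np.nan)
    z[ok] = (y[ok] - y[ok].mean()) / (y[ok].std() if y[ok].std() > 0 else 1.0)
    table = {}
    for f, name in enumerate(FEATURE_NAMES):
        table[name] = loadings[f] * z + rng.normal(0.0, noise_sd, size=y.size)
    df = pd.DataFrame(table)
    df.insert(0, "node_id", np.arange(y.size))
    truth = SyntheticTruth(seed=seed, loadings=loadings, noise_sd=noise_sd)
    return df, truth


def gen_coordinates(n_nodes: int, seed: int = 0, radius: float = 100.0) -> np.ndarray:
    """Quasi-uniform node coordinates on a sphere (Fibonacci lattice).

    A seeded random rotation decorrelates the lattice across seeds; all
    points lie at ``radius`` from the origin.
    """
    if n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    idx = np.arange(n_nodes, dtype=float) + 0.5
    phi = np.arccos(1 - 2 * idx / n_nodes)
    golden = np.pi * (1 + 5**0.5)
    theta = golden * idx
    pts = np.column_stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)])
    rng = substream(seed, "coords")
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return radius * pts @ q


def simulate_dataset(out_dir, seed: int = 0, n_nodes: int = 232, n_subjects: int | None = None,
                     density_grid: tuple[float, ...] = (0.10, 0.15, 0.20, 0.30)) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Produces a correlation matrix CSV, cohort CSV, structural feature TSV,
    coordinate/parcellation TSV and a planted-truth JSON, all derived from
    one master seed.  Returns the file paths.  ``density_grid`` is recorded
    in the truth file as the densities the study is meant to be analysed at.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corr, net_truth = gen_overlapping_network(n_nodes=n_nodes, seed=seed)
    slopes = np.zeros(min(n_nodes, 20))
    slopes[: len(slopes) // 4] = 0.02
    panel, coh_truth = gen_longitudinal_cohort(n_subjects=n_subjects, node_slopes=slopes, seed=seed)
    rng = substream(seed, "dataset-entropy")
    entropy = np.clip(rng.normal(0.5, 0.15, n_nodes), 0, 1)
    feats, feat_truth = gen_structural_features(entropy, seed=seed)
    parc = gen_parcellation(n_nodes, seed=seed)

    paths = {
        "correlation": out / "correlation.csv",
        "cohort": out / "cohort.csv",
        "features": out / "features.tsv",
        "parcellation": out / "parcellation.tsv",
        "truth": out / "truth.json",
    }
    np.savetxt(paths["correlation"], corr.values, delimiter=",")
    panel.data.to_csv(paths["cohort"], index=False)
    feats.to_csv(paths["features"], sep="\t", index=False)
    pd.DataFrame({
        "node_id": parc.node_ids,
        "name": parc.names,
        "system": parc.systems,
        "x": parc.coordinates[:, 0],
        "y": parc.coordinates[:, 1],
        "z": parc.coordinates[:, 2],
    }).to_csv(paths["parcellation"], sep="\t", index=False)
    truth = {
        "seed": seed,
        "density_grid": list(density_grid),
        "network": {"n_modules": net_truth.extra["n_modules"],
                    "dual_nodes": net_truth.extra["dual_nodes"],
                    "within": net_truth.within_strength,
                    "between": net_truth.between_strength,
                    "noise_sd": net_truth.noise_sd},
        "cohort": {"node_slopes": list(map(float, coh_truth.node_slopes)),
                   "betas": coh_truth.betas, "re_sds": coh_truth.re_sds,
                   "noise_sd": coh_truth.noise_sd},
        "features": {"loadings": list(map(float, feat_truth.loadings)),
                     "noise_sd": feat_truth.noise_sd},
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return {k: str(v) for k, v in paths.items()}


def gen_parcellation(n_nodes: int, seed: int = 0) -> Parcellation:
    """Parcellation with 8 systems in contiguous node blocks plus sphere coords."""
    blocks = np.array_split(np.arange(n_nodes), len(SYSTEMS))
    systems = [""] * n_nodes
    for s, block in zip(SYSTEMS, blocks):
        for i in block:
            systems[i] = s
    return Parcellation(node_ids=[str(i) for i in range(n_nodes)], systems=systems,
                        coordinates=gen_coordinates(n_nodes, seed=seed),
                        names=[f"region_{i}" for i in range(n_nodes)])
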