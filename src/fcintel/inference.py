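"""Permutation inference, multiple-comparison control, and graph-metric
characterization of relevant connections.

Permutation tests rebuild the full prediction pipeline (fold construction,
deconfounding, training) on target-shuffled data, so the null preserves
every stage; p-values use the bias-avoiding (b+1)/(m+1) estimator and are
computed on Fisher-z-transformed correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .prediction import TrainConfig, cross_validated_predict

logger = logging.getLogger(__name__)

__all__ = ["PermutationResult", "permutation_test_performance",
           "model_difference_test", "paired_t_test", "fdr_correct",
           "within_module_degree_z", "participation_coefficient",
           "node_occurrence", "relevant_vs_random_edge_comparison"]


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the p-value."""

    observed: float
    null: np.ndarray
    p: float
    transform: str = "fisher_z"
    m: int = 0
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _p_plus_one(b: int, m: int) -> float:
    return (b + 1) / (m + 1)


def _zr(r):
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def permutation_test_performance(features, target, confounds, families,
                                 selection=None,
                                 config: TrainConfig = TrainConfig(),
                                 n_folds: int = 5, n_repetitions: int = 10,
                                 m: int = 100, seed: int = 0
                                 ) -> PermutationResult:
    """Permutation test of cross-validated prediction performance.

    Observed statistic: mean r over ``n_repetitions`` fold seeds. Null:
    ``m`` single-repetition pipeline runs on target scores shuffled across
    subjects before fold construction and deconfounding (full retraining).
    One-sided p on the Fisher-z scale: (#{null >= observed} + 1) / (m + 1).
    """
    if m < 1:
        raise ValueError("need at least one permutation")
    obs = cross_validated_predict(features, target, confounds, families,
                                  selection=selection, config=config,
                                  n_folds=n_folds,
                                  n_repetitions=n_repetitions,
                                  seed=seed).mean_r
    rng = np.random.default_rng(seed + 1)
    null = np.empty(m)
    y = np.asarray(target, float)
    for i in range(m):
        y_perm = rng.permutation(y)
        null[i] = cross_validated_predict(
            features, y_perm, confounds, families, selection=selection,
            config=config, n_folds=n_folds, n_repetitions=1,
            seed=seed + 1000 + i).mean_r
    b = int(np.sum(_zr(null) >= _zr(obs)))
    return PermutationResult(observed=float(obs), null=null,
                             p=_p_plus_one(b, m), m=m, seed=seed)


def model_difference_test(features, target, confounds, families,
                          selection_a, selection_b,
                          config: TrainConfig = TrainConfig(),
                          n_folds: int = 5, n_repetitions: int = 10,
                          m: int = 100, seed: int = 0) -> PermutationResult:
    """Permutation test for a performance difference between two
    connection selections on the same cohort and targets.

    Statistic: z(r_A) - z(r_B) from correct-score runs. Null: paired runs
    of both selections on the same shuffled targets. Two-sided p.
    """
    if m < 1:
        raise ValueError("need at least one permutation")
    kw = dict(config=config, n_folds=n_folds)
    r_a = cross_validated_predict(features, target, confounds, families,
                                  selection=selection_a,
                                  n_repetitions=n_repetitions, seed=seed,
                                  **kw).mean_r
    r_b = cross_validated_predict(features, target, confounds, families,
                                  selection=selection_b,
                                  n_repetitions=n_repetitions, seed=seed,
                                  **kw).mean_r
    obs = float(_zr(r_a) - _zr(r_b))
    rng = np.random.default_rng(seed + 1)
    y = np.asarray(target, float)
    null = np.empty(m)
    for i in range(m):
        y_perm = rng.permutation(y)
        ra = cross_validated_predict(features, y_perm, confounds, families,
                                     selection=selection_a, n_repetitions=1,
                                     seed=seed + 1000 + i, **kw).mean_r
        rb = cross_validated_predict(features, y_perm, confounds, families,
                                     selection=selection_b, n_repetitions=1,
                                     seed=seed + 1000 + i, **kw).mean_r
        null[i] = _zr(ra) - _zr(rb)
    b = int(np.sum(np.abs(null) >= abs(obs)))
    return PermutationResult(observed=obs, null=null, p=_p_plus_one(b, m),
                             m=m, seed=seed,
                             extra={"r_a": float(r_a), "r_b": float(r_b)})


def paired_t_test(a, b) -> tuple[float, float]:
    """Paired t test (n-1 degrees of freedom) between two aligned
    performance vectors. Zero-variance differences are degenerate:
    identical vectors give (0, 1); a constant nonzero difference gives
    an infinite t (flagged in the log) with p = 0."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need paired vectors of length >= 3")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        logger.warning("paired_t_test: constant nonzero differences "
                       "(infinite t)")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------

def _prepare_weights(w: np.ndarray, negative: str) -> np.ndarray:
    w = np.asarray(w, float).copy()
    np.fill_diagonal(w, 0.0)
    if negative == "zero":
        if (w < 0).any():
            logger.info("negative weights set to zero for graph metrics")
        w[w < 0] = 0.0
    elif negative == "abs":
        w = np.abs(w)
    elif negative != "keep":
        raise ValueError("negative must be 'zero', 'abs' or 'keep'")
    return w


def _module_strengths(w: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """kappa[i, s] = sum of node i's weights to module s."""
    modules, inv = np.unique(partition, return_inverse=True)
    onehot = np.eye(len(modules))[inv]
    return w @ onehot


def within_module_degree_z(w: np.ndarray, partition,
                           negative: str = "zero") -> np.ndarray:
    """Within-module degree z-score per node.

    z_i = (kappa_i - mean_{module} kappa) / SD_{module} kappa, with
    kappa_i node i's strength (weighted degree) to its own module. Modules
    with zero strength SD get z = 0 (logged).
    """
    partition = np.asarray(partition)
    w = _prepare_weights(w, negative)
    if len(partition) != len(w):
        raise ValueError("partition must cover all nodes")
    modules, inv = np.unique(partition, return_inverse=True)
    kappa_all = _module_strengths(w, partition)
    kappa = kappa_all[np.arange(len(w)), inv]
    z = np.zeros(len(w))
    for s in range(len(modules)):
        members = inv == s
        mu, sd = kappa[members].mean(), kappa[members].std()
        if sd == 0:
            logger.info("module %r has zero within-degree SD; z set to 0",
                        modules[s])
            continue
        z[members] = (kappa[members] - mu) / sd
    return z


def participation_coefficient(w: np.ndarray, partition,
                              negative: str = "zero") -> np.ndarray:
    """Participation coefficient PC_i = 1 - sum_s (kappa_is / k_i)^2.

    kappa_is is node i's strength to module s and k_i its total strength.
    Zero-strength nodes get PC = 0 (logged). With m modules PC lies in
    [0, 1 - 1/m] for nonnegative weights.
    """
    partition = np.asarray(partition)
    w = _prepare_weights(w, negative)
    if len(partition) != len(w):
        raise ValueError("partition must cover all nodes")
    kappa = _module_strengths(w, partition)
    k = kappa.sum(axis=1)
    pc = np.zeros(len(w))
    nz = k != 0
    if (~nz).any():
        logger.info("%d zero-strength node(s): PC set to 0", int((~nz).sum()))
    pc[nz] = 1.0 - np.sum((kappa[nz] / k[nz, None]) ** 2, axis=1)
    return pc


# ---------------------------------------------------------------------------
# Relevant-vs-random edge comparison
# ---------------------------------------------------------------------------

def node_occurrence(edge_indices, edge_index) -> np.ndarray:
    """How often each node appears as an endpoint of the given edges."""
    rows, cols = edge_index.pairs()
    idx = np.asarray(edge_indices)
    counts = np.zeros(edge_index.n_nodes, dtype=int)
    np.add.at(counts, rows[idx], 1)
    np.add.at(counts, cols[idx], 1)
    return counts


def relevant_vs_random_edge_comparison(selection_indices,
                                       edge_properties: dict | None = None,
                                       node_properties: dict | None = None,
                                       edge_index=None, n_edges: int | None = None,
                                       n_perm: int = 1000, seed: int = 0
                                       ) -> pd.DataFrame:
    """Compare properties of a relevant-edge set against random edge sets.

    For each per-edge property (e.g. confound correlation, retest ICC) the
    statistic is the mean over selected edges; for each per-node property
    (e.g. participation coefficient) it is the occurrence-weighted node
    average sum(count_i * metric_i) / sum(count_i). The null distribution
    comes from ``n_perm`` equally sized uniformly drawn edge sets; p is
    two-sided with the (b+1)/(m+1) estimator.
    """
    sel = np.asarray(selection_indices)
    edge_properties = edge_properties or {}
    node_properties = node_properties or {}
    if node_properties and edge_index is None:
        raise ValueError("node properties need an edge_index")
    if n_edges is None:
        if edge_index is not None:
            n_edges = edge_index.n_edges
        elif edge_properties:
            n_edges = len(next(iter(edge_properties.values())))
        else:
            raise ValueError("cannot infer the edge pool size")
    k = len(sel)
    if k > n_edges:
        raise ValueError("selection larger than the edge pool")
    rng = np.random.default_rng(seed)
    draws = [rng.choice(n_edges, size=k, replace=False)
             for _ in range(n_perm)]

    def node_stat(idx, metric):
        counts = node_occurrence(idx, edge_index)
        tot = counts.sum()
        return float(counts @ metric / tot) if tot else 0.0

    rows = []
    for name, prop in edge_properties.items():
        prop = np.asarray(prop, float)
        obs = float(np.nanmean(prop[sel]))
        null = np.array([np.nanmean(prop[d]) for d in draws])
        rows.append((name, obs, null))
    for name, metric in node_properties.items():
        metric = np.asarray(metric, float)
        obs = node_stat(sel, metric)
        null = np.array([node_stat(d, metric) for d in draws])
        rows.append((name, obs, null))

    out = []
    for name, obs, null in rows:
        b = int(min(np.sum(null >= obs), np.sum(null <= obs)))
        p = min(1.0, 2.0 * _p_plus_one(b, n_perm))
        out.append({"property": name, "observed": obs,
                    "null_mean": float(null.mean()), "p": p,
                    "n_perm": n_perm})
    return pd.DataFrame(out)
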