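"""Functional connectivity construction and edge bookkeeping.

Builds Fisher-z connectivity matrices from node time series, averages
phase-encoding runs, derives connection-wise latent connectivity across
states, and computes per-edge test-retest reliability. Also owns the node
atlas and the edge-index convention (strict upper triangle, row-major,
0-based) used by every other module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

logger = logging.getLogger(__name__)

#: Canonical seven cortical network labels (Yeo-style partition).
SEVEN_NETWORKS = ("VIS", "SMN", "DAN", "VAN", "LIM", "CON", "DMN")

#: Correlations at or beyond this magnitude are clipped before atanh.
R_CLIP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# Atlas and edge indexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeAtlas:
    """Node parcellation: network label and optional centroid per node.

    Parameters
    ----------
    networks : array of str, shape (n_nodes,)
        Network label of each node (node ids are 0..n_nodes-1).
    centroids : array, shape (n_nodes, 3), optional
        Node centroid coordinates in millimetres.
    """

    networks: np.ndarray
    centroids: np.ndarray | None = None

    def __post_init__(self):
        nets = np.asarray(self.networks, dtype=object)
        object.__setattr__(self, "networks", nets)
        if self.centroids is not None:
            c = np.asarray(self.centroids, dtype=float)
            if c.shape != (len(nets), 3):
                raise ValueError(
                    f"centroids shape {c.shape} does not match {len(nets)} nodes"
                )
            object.__setattr__(self, "centroids", c)

    @property
    def n_nodes(self) -> int:
        return len(self.networks)

    @property
    def network_names(self) -> list[str]:
        """Unique network labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.networks:
            seen.setdefault(lab, None)
        return list(seen)

    def nodes_in(self, network: str) -> np.ndarray:
        """Indices of nodes belonging to ``network``."""
        idx = np.flatnonzero(self.networks == network)
        if idx.size == 0:
            raise KeyError(f"unknown network label: {network!r}")
        return idx

    @classmethod
    def default(cls, n_nodes: int = 100,
                networks: Sequence[str] = SEVEN_NETWORKS,
                seed: int = 0) -> "NodeAtlas":
        """A synthetic atlas: nodes dealt round-robin to ``networks`` with
        centroids on a jittered 3-D grid (deterministic per seed)."""
        rng = np.random.default_rng(seed)
        labels = np.array([networks[i % len(networks)] for i in range(n_nodes)],
                          dtype=object)
        # crude cortical-scale coordinates: clustered by network
        base = rng.uniform(-60, 60, size=(len(networks), 3))
        cent = np.empty((n_nodes, 3))
        for i in range(n_nodes):
            cent[i] = base[i % len(networks)] + rng.normal(0, 15, 3)
        return cls(networks=labels, centroids=cent)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"node_id": np.arange(self.n_nodes),
                           "network": self.networks})
        if self.centroids is not None:
            df[["x", "y", "z"]] = self.centroids
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NodeAtlas":
        df = df.sort_values("node_id")
        cent = None
        if {"x", "y", "z"}.issubset(df.columns):
            cent = df[["x", "y", "z"]].to_numpy(float)
        return cls(networks=df["network"].to_numpy(object), centroids=cent)


class EdgeIndex:
    """Bijection between node pairs (i, j), i < j, and flat edge indices.

    Flat indices run row-major over the strict upper triangle:
    (0,1), (0,2), ..., (0,n-1), (1,2), ...
    """

    def __init__(self, n_nodes: int):
        if n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        self.n_nodes = int(n_nodes)
        self._rows, self._cols = np.triu_indices(n_nodes, k=1)
        # lookup table (i, j) -> flat
        self._flat = np.full((n_nodes, n_nodes), -1, dtype=np.int64)
        self._flat[self._rows, self._cols] = np.arange(self.n_edges)
        self._flat[self._cols, self._rows] = np.arange(self.n_edges)

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def flat(self, i, j) -> np.ndarray:
        """Flat index of edge (i, j) (order-insensitive)."""
        out = self._flat[i, j]
        if np.any(np.asarray(out) < 0):
            raise IndexError("diagonal entries are not edges")
        return out

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) node arrays aligned with flat edge order."""
        return self._rows, self._cols

    def to_matrix(self, vec: np.ndarray) -> np.ndarray:
        """Symmetric matrix (zero diagonal) from an edge vector."""
        vec = np.asarray(vec)
        if vec.shape[-1] != self.n_edges:
            raise ValueError("edge vector length mismatch")
        m = np.zeros(vec.shape[:-1] + (self.n_nodes, self.n_nodes), vec.dtype)
        m[..., self._rows, self._cols] = vec
        m[..., self._cols, self._rows] = vec
        return m

    def to_vector(self, mat: np.ndarray) -> np.ndarray:
        """Edge vector from a symmetric matrix (upper triangle)."""
        mat = np.asarray(mat)
        if mat.shape[-2:] != (self.n_nodes, self.n_nodes):
            raise ValueError("matrix shape mismatch")
        return mat[..., self._rows, self._cols]


@dataclass
class ConnectomeSet:
    """Per-subject, per-state functional connectivity in edge-vector form.

    ``values`` has shape (n_subjects, n_states, n_edges), Fisher-z units.
    ``runs`` optionally holds the two phase-encoding runs whose mean is
    ``values``, shape (n_subjects, n_states, 2, n_edges).
    """

    values: np.ndarray
    states: list[str]
    subjects: list[str]
    atlas: NodeAtlas
    runs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (subjects, states, edges)")
        n_sub, n_state, n_edge = self.values.shape
        if n_state != len(self.states) or n_sub != len(self.subjects):
            raise ValueError("values shape does not match states/subjects")
        self.edge_index = EdgeIndex(self.atlas.n_nodes)
        if self.edge_index.n_edges != n_edge:
            raise ValueError("atlas node count mismatch with edge dimension")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[2]

    def state_idx(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"state {state!r} not in {self.states}") from None

    def state(self, state: str) -> np.ndarray:
        """Edge-vector matrix (subjects x edges) for one state."""
        return self.values[:, self.state_idx(state), :]

    def matrix(self, subject_pos: int, state: str) -> np.ndarray:
        """Symmetric FC matrix for one subject and state."""
        return self.edge_index.to_matrix(self.values[subject_pos,
                                                     self.state_idx(state)])

    def subset(self, subject_ids: Sequence[str]) -> "ConnectomeSet":
        pos = [self.subjects.index(s) for s in subject_ids]
        return ConnectomeSet(values=self.values[pos],
                             states=list(self.states),
                             subjects=list(subject_ids),
                             atlas=self.atlas,
                             runs=None if self.runs is None else self.runs[pos],
                             meta=dict(self.meta))

    def with_state(self, name: str, values: np.ndarray) -> "ConnectomeSet":
        """Return a copy with an extra state appended."""
        if name in self.states:
            raise ValueError(f"state {name!r} already present")
        vals = np.concatenate([self.values, values[:, None, :]], axis=1)
        return ConnectomeSet(values=vals, states=self.states + [name],
                             subjects=list(self.subjects), atlas=self.atlas,
                             meta=dict(self.meta))


# ---------------------------------------------------------------------------
# FC construction
# ---------------------------------------------------------------------------

def fisher_z(r: np.ndarray, clip: bool = True) -> np.ndarray:
    """Fisher z-transform atanh(r), clipping |r| at ``R_CLIP`` if requested.

    Degenerate correlations (|r| = 1) produce infinite z; by default they
    are clipped to the documented bound and a warning is logged.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        if np.any(np.abs(r) >= R_CLIP):
            logger.warning("clipping %d correlation(s) with |r| >= %.0e",
                           int(np.sum(np.abs(r) >= R_CLIP)), 1 - R_CLIP)
        r = np.clip(r, -R_CLIP, R_CLIP)
    elif np.any(np.abs(r) > 1):
        raise ValueError("correlations outside [-1, 1]")
    return np.arctanh(r)


def timeseries_to_fc(ts: np.ndarray, clip: bool = True) -> np.ndarray:
    """Fisher-z connectivity matrix from node time series.

    Parameters
    ----------
    ts : array, shape (n_nodes, n_timepoints)
        One node's activity per row. Requires >= 3 time points and no
        constant series.

    Returns
    -------
    array, shape (n_nodes, n_nodes)
        Symmetric matrix of atanh(Pearson r); zero diagonal.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a (nodes x time) matrix with >= 3 time points")
    sd = ts.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series for node(s) {bad.tolist()}")
    r = np.corrcoef(ts)
    np.fill_diagonal(r, 0.0)
    z = fisher_z(r, clip=clip)
    np.fill_diagonal(z, 0.0)
    return z


def average_phase_runs(fc_a: np.ndarray, fc_b: np.ndarray) -> np.ndarray:
    """Elementwise mean of two same-shape FC arrays on the Fisher-z scale."""
    fc_a = np.asarray(fc_a, float)
    fc_b = np.asarray(fc_b, float)
    if fc_a.shape != fc_b.shape:
        raise ValueError(f"shape mismatch: {fc_a.shape} vs {fc_b.shape}")
    return 0.5 * (fc_a + fc_b)


# ---------------------------------------------------------------------------
# Connection-wise latent FC
# ---------------------------------------------------------------------------

@dataclass
class LatentFCModel:
    """One-factor model per edge across states.

    ``loadings`` has shape (n_edges, n_states); ``scores`` holds the
    standardized per-subject latent edge values, shape (n_subjects, n_edges).
    Edges with a zero-variance state are flagged in ``fallback_edges`` and
    scored by the documented fallback (standardized state mean).
    """

    loadings: np.ndarray
    scores: np.ndarray
    states: list[str]
    fallback_edges: np.ndarray


def _one_factor_pa(z: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Principal-axis one-factor loadings on standardized data ``z``
    (subjects x states). Fallback estimator for non-convergent ML fits."""
    r = np.corrcoef(z, rowvar=False)
    comm = np.abs(r - np.eye(len(r))).max(axis=1)
    for _ in range(n_iter):
        rr = r.copy()
        np.fill_diagonal(rr, comm)
        w, v = np.linalg.eigh(rr)
        lam = v[:, -1] * np.sqrt(max(w[-1], 0.0))
        new_comm = np.clip(lam ** 2, 0, 1)
        if np.max(np.abs(new_comm - comm)) < 1e-6:
            comm = new_comm
            break
        comm = new_comm
    return lam


def latent_fc(connectomes: ConnectomeSet, mode: str = "rest+tasks",
              rest_state: str = "rest") -> LatentFCModel:
    """Connection-wise latent connectivity across states.

    For every edge independently, a one-factor model is fitted across the
    chosen states (observations are subjects); the standardized factor
    score summarizes that edge's connectivity. ``mode`` selects the states:
    ``"rest+tasks"`` uses all measured states, ``"tasks-only"`` drops
    ``rest_state``.

    Loadings signs are fixed so each edge's mean loading is positive.
    """
    if mode not in ("rest+tasks", "tasks-only"):
        raise ValueError(f"unknown mode {mode!r}")
    states = list(connectomes.states)
    if mode == "tasks-only":
        states = [s for s in states if s != rest_state]
    if len(states) < 3:
        raise ValueError("need >= 3 states for a per-edge factor model")
    idx = [connectomes.state_idx(s) for s in states]
    x = connectomes.values[:, idx, :]          # subjects x states x edges
    n_sub, n_state, n_edge = x.shape

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    # constant states detected with a relative tolerance (exact zeros are
    # not reachable in floating point for nonzero constants)
    zero_var = (sd <= 1e-10 * np.maximum(1.0, np.abs(mu))).any(axis=0)
    loadings = np.zeros((n_edge, n_state))
    scores = np.empty((n_sub, n_edge))

    for e in range(n_edge):
        if zero_var[e]:
            # fallback: standardized state mean (constant states ignored)
            m = x[:, :, e].mean(axis=1)
            s = m.std()
            scores[:, e] = (m - m.mean()) / s if s > 0 else 0.0
            continue
        z = (x[:, :, e] - mu[:, e]) / sd[:, e]
        try:
            fa = FactorAnalysis(n_components=1, svd_method="lapack")
            fa.fit(z)
            lam = fa.components_[0]
            fs = fa.transform(z)[:, 0]
        except Exception:                      # non-convergence -> PA fallback
            lam = _one_factor_pa(z)
            psi = np.clip(1 - lam ** 2, 1e-6, None)
            w = lam / psi
            fs = z @ w / (1 + lam @ w)
        if lam.mean() < 0:
            lam, fs = -lam, -fs
        loadings[e] = lam
        s = fs.std()
        scores[:, e] = (fs - fs.mean()) / s if s > 0 else 0.0

    if zero_var.any():
        logger.warning("latent_fc: %d zero-variance edge(s) used the "
                       "state-mean fallback", int(zero_var.sum()))
    return LatentFCModel(loadings=loadings, scores=scores, states=states,
                         fallback_edges=np.flatnonzero(zero_var))


# ---------------------------------------------------------------------------
# Test-retest reliability
# ---------------------------------------------------------------------------

def icc_retest(run1: np.ndarray, run2: np.ndarray) -> np.ndarray:
    """Per-edge ICC(2,1) between two phase-encoding runs.

    Two-way random effects, absolute agreement, single measurement:

        ICC = (MSR - MSE) / (MSR + MSE + 2 (MSC - MSE) / n)

    with n subjects and k = 2 repeated measurements. Inputs are
    (subjects x edges) arrays of paired observations. Edges with zero
    between-subject variance yield NaN and are flagged via a log warning.
    """
    run1 = np.asarray(run1, float)
    run2 = np.asarray(run2, float)
    if run1.shape != run2.shape:
        raise ValueError("paired run arrays must have the same shape")
    if run1.ndim == 1:
        run1, run2 = run1[:, None], run2[:, None]
    n = run1.shape[0]
    if n < 3:
        raise ValueError("need >= 3 subjects")
    k = 2
    x = np.stack([run1, run2], axis=1)         # subjects x 2 x edges
    grand = x.mean(axis=(0, 1))
    subj_mean = x.mean(axis=1)                 # subjects x edges
    meas_mean = x.mean(axis=0)                 # 2 x edges
    ssr = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ssc = n * ((meas_mean - grand) ** 2).sum(axis=0)
    sst = ((x - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    undef = ~np.isfinite(icc)
    if undef.any():
        logger.warning("icc_retest: %d edge(s) with undefined ICC",
                       int(undef.sum()))
        icc = np.where(undef, np.nan, icc)
    return icc
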