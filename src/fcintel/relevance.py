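"""Layer-wise relevance propagation (LRP) and the stepwise procedure
identifying the connections most relevant to a prediction.

LRP distributes a network's scalar output back through the layers: each
neuron's relevance is shared among its inputs in proportion to their
contribution ``a_j w_jk`` to the neuron's pre-activation, stabilized by
the epsilon rule. For a bias-free network relevance is conserved — the
per-input relevances sum to the output (up to epsilon-controlled
leakage); with biases, the absorbed share is reported, not hidden.

The stepwise variant trains a model on all edges, attributes on the
training data, removes the currently most relevant block of edges,
retrains on the remainder, and repeats — yielding a full priority
ordering of edges that is robust to redundancy between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prediction import MLPRegressor, TrainConfig, train_mlp, \
    _family_validation_split

logger = logging.getLogger(__name__)

__all__ = ["lrp_attribute", "RelevanceMap", "aggregate_relevance",
           "stepwise_lrp", "overlap_fraction", "geometric_schedule"]

EPSILON = 1e-6


def lrp_attribute(model: MLPRegressor, inputs: np.ndarray,
                  epsilon: float = EPSILON) -> np.ndarray:
    """Per-feature relevance for each input row (epsilon rule).

    Propagates the scalar output back layer by layer:

        R_j = sum_k  a_j w_jk / (z_k + eps * sign(z_k)) * R_k

    with ``z_k`` the pre-activation (bias included). Dropout is inactive
    at attribution time. Returns an (n_samples, n_features) array of
    signed relevances.
    """
    x = np.asarray(inputs, float)
    if x.ndim == 1:
        x = x[None, :]
    if not np.isfinite(x).all():
        raise ValueError("non-finite inputs")
    acts, _ = model._forward(x)
    rel = acts[-1]                              # (n, 1): output is relevance
    for li in range(len(model.weights) - 1, -1, -1):
        w = model.weights[li]
        a_prev = acts[li]
        z = a_prev @ w + model.biases[li]       # pre-activation, bias incl.
        stab = z + epsilon * np.where(z >= 0, 1.0, -1.0)
        s = rel / stab
        rel = a_prev * (s @ w.T)
    return rel


@dataclass
class RelevanceMap:
    """Aggregated per-edge relevance with provenance.

    ``magnitude`` (mean |R| over subjects and runs) drives the ranking;
    ``signed`` (mean R) is retained for reporting.
    """

    magnitude: np.ndarray
    signed: np.ndarray
    n_runs: int = 1
    meta: dict = field(default_factory=dict)

    @property
    def ranking(self) -> np.ndarray:
        """Edge indices from most to least relevant (ties by edge index)."""
        return np.argsort(-self.magnitude, kind="stable")

    def to_frame(self, edge_index=None, atlas=None) -> pd.DataFrame:
        df = pd.DataFrame({"edge": np.arange(len(self.magnitude)),
                           "relevance": self.magnitude,
                           "signed_relevance": self.signed})
        if edge_index is not None:
            rows, cols = edge_index.pairs()
            df["node_i"], df["node_j"] = rows, cols
            if atlas is not None:
                df["network_i"] = atlas.networks[rows]
                df["network_j"] = atlas.networks[cols]
        df["rank"] = np.argsort(df["relevance"].to_numpy() * -1,
                                kind="stable").argsort()
        return df


def summarize_relevance(per_sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(mean |R|, mean R) over samples."""
    return np.mean(np.abs(per_sample), axis=0), np.mean(per_sample, axis=0)


def aggregate_relevance(maps: list[RelevanceMap]) -> RelevanceMap:
    """Mean relevance per edge across folds/repetitions.

    Deterministic and invariant to the order of the inputs; all maps must
    cover the same edge set.
    """
    if not maps:
        raise ValueError("nothing to aggregate")
    n = len(maps[0].magnitude)
    if any(len(m.magnitude) != n for m in maps):
        raise ValueError("mismatched edge sets")
    # sort per edge before reducing so the mean is bit-identical under any
    # permutation of the input runs
    mag = np.sort(np.stack([m.magnitude for m in maps]), axis=0).mean(axis=0)
    sgn = np.sort(np.stack([m.signed for m in maps]), axis=0).mean(axis=0)
    return RelevanceMap(magnitude=mag, signed=sgn,
                        n_runs=sum(m.n_runs for m in maps))


def geometric_schedule(n_edges: int, frac: float = 0.01,
                       minimum: int = 10, rounds: int | None = None) -> list[int]:
    """Default removal schedule: top ``frac`` of remaining edges per round
    (at least ``minimum``), until exhausted or ``rounds`` reached."""
    out, remaining = [], n_edges
    while remaining > 0 and (rounds is None or len(out) < rounds):
        step = min(remaining, max(minimum, int(round(frac * remaining))))
        out.append(step)
        remaining -= step
    return out


def stepwise_lrp(x: np.ndarray, y: np.ndarray, schedule: list[int],
                 config: TrainConfig = TrainConfig(), seed: int = 0,
                 families: np.ndarray | None = None,
                 hidden: tuple = (100,)) -> tuple[np.ndarray, pd.DataFrame]:
    """Iterative train / attribute / remove-top-block edge prioritization.

    Each round trains an MLP on the remaining edges (early stopping on a
    seeded validation split, family-aware when ``families`` is given),
    attributes on the training data, records the currently most relevant
    ``schedule[i]`` edges as the next priority block, removes them, and
    retrains. Edges never removed are appended afterwards, ordered by the
    final round's relevance.

    Returns
    -------
    (order, rounds)
        ``order`` is the full priority ordering (best first);
        ``rounds`` is a per-round log (edges removed, model epochs).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, n_edges = x.shape
    if sum(schedule) > n_edges:
        raise ValueError("schedule removes more edges than exist")
    if families is None:
        families = np.arange(n)
    remaining = np.arange(n_edges)
    order: list[int] = []
    rows = []
    rel_remaining = None
    for rnd, count in enumerate(schedule):
        if len(remaining) == 0:
            raise ValueError("no edges left before the schedule is exhausted")
        rng = np.random.default_rng([seed, rnd, 11])
        fit_idx, val_idx = _family_validation_split(
            np.arange(n), families, config.val_fraction, rng)
        model = train_mlp(x[fit_idx][:, remaining], y[fit_idx],
                          x[val_idx][:, remaining], y[val_idx],
                          hidden=hidden, config=config,
                          seed=int(rng.integers(2 ** 31)))
        per_sample = lrp_attribute(model, x[fit_idx][:, remaining])
        mag, _ = summarize_relevance(per_sample)
        local_rank = np.argsort(-mag, kind="stable")
        take = local_rank[:count]
        block = remaining[take]                    # within-block: by relevance
        order.extend(block.tolist())
        keep = np.ones(len(remaining), bool)
        keep[take] = False
        rel_remaining = mag[keep]
        remaining = remaining[keep]
        rows.append({"round": rnd, "removed": count,
                     "remaining": len(remaining),
                     "epochs": model.log["epochs_run"]})
    if len(remaining):
        # leftover edges: ranked by the last model's relevance
        if rel_remaining is None:
            raise ValueError("empty schedule")
        order.extend(remaining[np.argsort(-rel_remaining,
                                          kind="stable")].tolist())
    return np.asarray(order), pd.DataFrame(rows)


def overlap_fraction(top_k_a, top_k_b) -> float:
    """Percentage overlap 100 |a & b| / k of two equally sized edge sets."""
    a, b = set(np.asarray(top_k_a).tolist()), set(np.asarray(top_k_b).tolist())
    if len(a) != len(b):
        raise ValueError("sets must have equal k")
    if not a:
        raise ValueError("empty sets")
    return 100.0 * len(a & b) / len(a)
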