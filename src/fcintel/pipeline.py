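"""Configuration-driven orchestration of the full analysis on synthetic
data: generate -> score -> connect -> select -> predict -> attribute ->
test, with an optional family-aware lockbox split mirroring the
main / lockbox / external three-level validation design.

Every output is determined by the config and the code version; a JSON
manifest (seeds, stage timings, config) accompanies each run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth, psychometrics, connectome, selection as sel_mod
from .prediction import (TrainConfig, cross_validated_predict, fit_full,
                         transfer_predict)
from .relevance import stepwise_lrp, geometric_schedule
from .inference import permutation_test_performance
from .synth import GeneratorConfig, CONFOUND_NAMES

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "split_lockbox"]


@dataclass
class ExperimentConfig:
    """Everything a run needs; serializable to/from YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    components: tuple = ("g", "gc", "gf")
    states: tuple | str = "all"          # "all" = measured + latent
    include_latent: bool = True
    selections: tuple = ("whole_brain",)  # or "networks", "random_edges:k", ...
    train: TrainConfig = field(default_factory=TrainConfig)
    n_folds: int = 5
    n_repetitions: int = 10
    lockbox_fraction: float = 196 / 806
    run_lockbox: bool = False
    attribution_rounds: int = 0          # stepwise-LRP rounds (0 = skip)
    attribution_frac: float = 0.01
    permutations: int = 0                # permutation-test m (0 = skip)
    jobs: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        gen = GeneratorConfig(**d.pop("generator", {}))
        train_d = d.pop("train", {})
        if "grid" in train_d:
            train_d["grid"] = tuple(tuple(g) for g in train_d["grid"])
        train = TrainConfig(**train_d)
        for key in ("components", "selections"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("states"), list):
            d["states"] = tuple(d["states"])
        return cls(generator=gen, train=train, **d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def split_lockbox(cohort: pd.DataFrame, fraction: float, seed: int = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Family-aware main/lockbox split: no family straddles the boundary.

    Families are shuffled (seeded) and assigned greedily to the lockbox
    until its target size would be exceeded. Raises if no family subset
    can come within one maximal family size of the target.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    fams = cohort["family_id"].to_numpy()
    uniq, counts = np.unique(fams, return_counts=True)
    order = rng.permutation(len(uniq))
    target = int(round(fraction * len(cohort)))
    lock, n_lock = [], 0
    for i in order:
        if n_lock + counts[i] <= target:
            lock.append(uniq[i])
            n_lock += counts[i]
    if target > 0 and n_lock < target - counts.max():
        raise ValueError("fraction infeasible given family sizes")
    in_lock = cohort["family_id"].isin(lock)
    return cohort.loc[~in_lock].copy(), cohort.loc[in_lock].copy()


def _resolve_selections(spec, atlas, relevance=None, seed=0):
    """Turn selection spec strings into ConnectionSelection objects."""
    out = []
    n_edges = sel_mod.n_connections(atlas.n_nodes)
    for item in spec:
        if item == "whole_brain":
            out.append(sel_mod.whole_brain(atlas))
        elif item == "networks":
            out.extend(sel_mod.enumerate_network_selections(atlas))
        elif item.startswith("random_edges:"):
            k = int(item.split(":")[1])
            out.append(sel_mod.random_edge_selection(k, n_edges, seed))
        elif item.startswith("random_nodes:"):
            m = int(item.split(":")[1])
            out.append(sel_mod.random_node_selection(m, atlas, seed))
        elif item.startswith("top_relevant:"):
            if relevance is None:
                raise ValueError("top_relevant selection needs a relevance map")
            k = int(item.split(":")[1])
            out.append(sel_mod.top_k_selection(relevance, k))
        else:
            raise ValueError(f"unknown selection spec {item!r}")
    # deduplicate by provenance
    seen, uniq = set(), []
    for s in out:
        if s.provenance not in seen:
            seen.add(s.provenance)
            uniq.append(s)
    return uniq


def _predict_cell(args):
    (comp, state, sel_prov, x, y, conf, fams, cfg) = args
    res = cross_validated_predict(x, y, conf, fams, config=cfg.train,
                                  n_folds=cfg.n_folds,
                                  n_repetitions=cfg.n_repetitions,
                                  seed=cfg.seed)
    rows = []
    for _, rrow in res.per_rep.iterrows():
        hp = [h["hidden"] for h in res.hyperparams
              if h["rep"] == rrow["rep"]]
        rows.append({"component": comp, "state": state,
                     "selection": sel_prov, "rep": int(rrow["rep"]),
                     "r": rrow["r"], "mse": rrow["mse"],
                     "rmse": rrow["rmse"], "mae": rrow["mae"],
                     "hidden": ";".join(map(str, hp))})
    return rows


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Execute the configured experiment end to end.

    Writes cohort/scores/results/relevance tables (tab-delimited), the
    connectome container, and a JSON run manifest. Returns a dict of the
    in-memory results. Any stage failure aborts with the stage name after
    persisting completed outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _plain(dataclasses.asdict(config)),
                "stages": {}, "seed": config.seed}
    results: dict = {}
    stage = "generate"
    try:
        t0 = time.time()
        cohort, truth = synth.generate_cohort(config.generator, config.seed)
        cohort_inc = synth.exclude_by_motion(cohort)
        synth.save_cohort(cohort_inc, out / "cohort.tsv")
        manifest["stages"]["generate"] = {
            "seconds": time.time() - t0, "n_generated": len(cohort),
            "n_included": len(cohort_inc)}
        logger.info("generate: %d subjects (%d after motion exclusion)",
                    len(cohort), len(cohort_inc))

        stage = "score"
        t0 = time.time()
        scores = psychometrics.score_cohort(cohort_inc)
        scores.to_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
        manifest["stages"]["score"] = {"seconds": time.time() - t0}

        stage = "connect"
        t0 = time.time()
        atlas = connectome.NodeAtlas.default(config.generator.n_nodes,
                                             config.generator.networks)
        measured = tuple(s for s in synth.MEASURED_STATES
                         if s in config.generator.state_signal)
        conn_all = synth.generate_connectomes(truth, atlas, states=measured,
                                              cohort=cohort)
        conn = conn_all.subset(list(cohort_inc["subject_id"]))
        if config.include_latent and len(measured) >= 3:
            lat = connectome.latent_fc(conn, mode="rest+tasks")
            conn = conn.with_state("latent", lat.scores)
            n_tasks = sum(s != "rest" for s in measured)
            if n_tasks >= 3:
                lat_t = connectome.latent_fc(
                    connectome.ConnectomeSet(
                        values=conn.values[:, :len(measured), :],
                        states=list(measured), subjects=conn.subjects,
                        atlas=atlas),
                    mode="tasks-only")
                conn = conn.with_state("latent_task", lat_t.scores)
        synth.save_connectomes(conn, out / "connectomes.npz",
                               out / "connectomes.json")
        manifest["stages"]["connect"] = {"seconds": time.time() - t0,
                                         "states": conn.states}

        stage = "select"
        selections = _resolve_selections(config.selections, atlas,
                                         seed=config.seed)
        (out / "selections.json").write_text(json.dumps(
            [json.loads(s.to_json()) for s in selections]))
        manifest["stages"]["select"] = {"n_selections": len(selections)}

        states = (conn.states if config.states == "all"
                  else [s for s in config.states if s in conn.states])
        confounds = cohort_inc[list(CONFOUND_NAMES)].to_numpy(float)
        families = cohort_inc["family_id"].to_numpy()

        stage = "predict"
        t0 = time.time()
        cells = [(comp, state, s.provenance,
                  conn.state(state)[:, s.mask],
                  scores.component(comp), confounds, families, config)
                 for comp in config.components
                 for state in states
                 for s in selections]
        if config.jobs > 1:
            from joblib import Parallel, delayed
            cell_rows = Parallel(n_jobs=config.jobs)(
                delayed(_predict_cell)(c) for c in cells)
        else:
            cell_rows = [_predict_cell(c) for c in cells]
        rows = [r for rr in cell_rows for r in rr]
        results["results"] = pd.DataFrame(rows)
        results["results"].to_csv(out / "results.tsv", sep="\t", index=False)
        manifest["stages"]["predict"] = {"seconds": time.time() - t0,
                                         "n_models": len(cells)}

        if config.attribution_rounds > 0:
            stage = "attribute"
            t0 = time.time()
            rel_rows = []
            ei = conn.edge_index
            for comp in config.components:
                for state in states:
                    x = conn.state(state)
                    sched = geometric_schedule(
                        x.shape[1], frac=config.attribution_frac,
                        rounds=config.attribution_rounds)
                    order, _ = stepwise_lrp(
                        x, scores.component(comp), sched,
                        config=config.train, seed=config.seed,
                        families=families)
                    rank = np.empty(len(order), int)
                    rank[order] = np.arange(len(order))
                    ri, ci = ei.pairs()
                    rel_rows.append(pd.DataFrame(
                        {"component": comp, "state": state,
                         "edge": np.arange(len(order)),
                         "node_i": ri, "node_j": ci, "rank": rank}))
            results["relevance"] = pd.concat(rel_rows, ignore_index=True)
            results["relevance"].to_csv(out / "relevance.tsv", sep="\t",
                                        index=False)
            manifest["stages"]["attribute"] = {"seconds": time.time() - t0}

        if config.permutations > 0:
            stage = "test"
            t0 = time.time()
            test_rows = []
            for comp in config.components:
                perm = permutation_test_performance(
                    conn.state(states[0])[:, selections[0].mask],
                    scores.component(comp), confounds, families,
                    config=config.train, n_folds=config.n_folds,
                    n_repetitions=config.n_repetitions,
                    m=config.permutations, seed=config.seed)
                test_rows.append({"component": comp, "state": states[0],
                                  "selection": selections[0].provenance,
                                  "observed_r": perm.observed, "p": perm.p,
                                  "m": perm.m, "seed": perm.seed})
            results["tests"] = pd.DataFrame(test_rows)
            results["tests"].to_csv(out / "tests.tsv", sep="\t", index=False)
            manifest["stages"]["test"] = {"seconds": time.time() - t0}

        if config.run_lockbox:
            stage = "lockbox"
            t0 = time.time()
            main_df, lock_df = split_lockbox(cohort_inc,
                                             config.lockbox_fraction,
                                             config.seed)
            main_ids = list(main_df["subject_id"])
            lock_ids = list(lock_df["subject_id"])
            sc_main = psychometrics.score_cohort(main_df)
            sc_lock = psychometrics.score_cohort(lock_df)
            conn_main = conn.subset(main_ids)
            conn_lock = conn.subset(lock_ids)
            lb_rows = []
            for comp in config.components:
                for s in selections:
                    fitted = fit_full(
                        conn_main.state(states[0]), sc_main.component(comp),
                        main_df[list(CONFOUND_NAMES)].to_numpy(float),
                        main_df["family_id"].to_numpy(), config.train,
                        selection=s, seed=config.seed)
                    tr = transfer_predict(
                        fitted, conn_lock.state(states[0]),
                        sc_lock.component(comp),
                        lock_df[list(CONFOUND_NAMES)].to_numpy(float),
                        selection=s)
                    lb_rows.append({"component": comp, "state": states[0],
                                    "selection": s.provenance,
                                    "r_lockbox": tr["r"]})
            results["lockbox"] = pd.DataFrame(lb_rows)
            results["lockbox"].to_csv(out / "lockbox.tsv", sep="\t",
                                      index=False)
            # cross-level performance-pattern correlation per component
            pattern_r = {}
            if len(selections) >= 3:
                main_r = (results["results"]
                          .query("state == @states[0]")
                          .groupby(["component", "selection"])["r"]
                          .mean().reset_index())
                merged = main_r.merge(results["lockbox"],
                                      on=["component", "selection"])
                for comp, grp in merged.groupby("component"):
                    pattern_r[comp] = float(
                        np.corrcoef(grp["r"], grp["r_lockbox"])[0, 1])
            manifest["stages"]["lockbox"] = {"seconds": time.time() - t0,
                                             "n_main": len(main_df),
                                             "n_lockbox": len(lock_df),
                                             "pattern_r": pattern_r}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    results["manifest"] = manifest
    return results
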