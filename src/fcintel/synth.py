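"""Synthetic study generator: cohort, cognitive measures, multi-state
connectomes, and planted ground truth.

The generator emulates the statistical structure a connectome-based
intelligence-prediction analysis assumes: three correlated latent
intelligence components (general / crystallized / fluid), family
clustering, confounds correlated with the target, state-varying signal
strength, and a planted, partially redundant set of intelligence-relevant
edges. Defaults follow the cohort conditions of a large young-adult
neuroimaging study (806 subjects, 100 cortical nodes in seven networks,
rest plus seven task states, component inter-correlations
0.78 / 0.76 / 0.49).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import NodeAtlas, EdgeIndex, ConnectomeSet, SEVEN_NETWORKS

__all__ = [
    "GeneratorConfig", "LoadingSpec", "GroundTruth",
    "generate_cohort", "generate_cognitive_measures", "generate_connectomes",
    "exclude_by_motion", "planted_features",
    "MEASURE_NAMES", "FLUID_MEASURES", "CRYSTALLIZED_MEASURES",
    "MEASURED_STATES",
]

# The 12 cognitive measures; seven define the fluid factor, two the
# crystallized composite, the remainder load on the general factor only.
FLUID_MEASURES = (
    "pic_seq_memory", "card_sort", "flanker", "matrix_reasoning",
    "processing_speed", "line_orientation", "list_sorting",
)
CRYSTALLIZED_MEASURES = ("picture_vocab", "reading_recog")
OTHER_MEASURES = ("word_memory", "episodic_memory", "sustained_attention")
MEASURE_NAMES = FLUID_MEASURES + CRYSTALLIZED_MEASURES + OTHER_MEASURES

#: The eight measured states (rest + seven in-scanner tasks). Latent FC
#: states are derived downstream, not generated.
MEASURED_STATES = ("rest", "wm", "gambling", "motor", "language",
                   "social", "relational", "emotion")

#: Per-state signal scale defaults: cognitively demanding states carry more
#: intelligence signal than e.g. the emotion or motor task.
DEFAULT_STATE_SIGNAL = {
    "rest": 0.8, "wm": 1.2, "gambling": 0.7, "motor": 0.6,
    "language": 1.3, "social": 1.0, "relational": 0.7, "emotion": 0.5,
}

CONFOUND_NAMES = ("age", "sex", "handedness", "mean_fd", "spike_proportion")

#: Target Pearson correlations between each confound and the general
#: component (study-reported values).
DEFAULT_CONFOUND_TARGET_CORR = {
    "age": -0.13, "sex": 0.18, "handedness": 0.00,
    "mean_fd": -0.20, "spike_proportion": -0.20,
}


@dataclass
class LoadingSpec:
    """Per-measure factor loadings for the cognitive-measure model.

    Each measure m is generated as

        x_m = a_m * latent(general) + b_m * group_m + noise,

    where ``group_m`` is the fluid group factor (the part of the fluid
    component orthogonal to g) for the seven fluid measures, the raw
    crystallized component for the two crystallized measures, and absent
    otherwise. Noise SD defaults to the value giving unit total variance.
    """

    general: dict = field(default_factory=dict)   # measure -> a_m
    group: dict = field(default_factory=dict)     # measure -> (factor, b_m)
    noise_sd: dict = field(default_factory=dict)  # measure -> sd (optional)

    @classmethod
    def default(cls) -> "LoadingSpec":
        general, group = {}, {}
        for m in FLUID_MEASURES:
            general[m] = 0.5
            group[m] = ("fluid", 0.55)
        for m in CRYSTALLIZED_MEASURES:
            general[m] = 0.0
            group[m] = ("crystallized", 0.94)
        for m, a in zip(OTHER_MEASURES, (0.70, 0.75, 0.80)):
            general[m] = a
        return cls(general=general, group=group)

    def noise_for(self, measure: str) -> float:
        if measure in self.noise_sd:
            return float(self.noise_sd[measure])
        a = self.general.get(measure, 0.0)
        b = self.group.get(measure, (None, 0.0))[1]
        var = 1.0 - a * a - b * b
        if var < 0:
            raise ValueError(f"loadings for {measure!r} imply variance > 1")
        return float(np.sqrt(var))


@dataclass
class GeneratorConfig:
    """All distributional parameters of the synthetic study."""

    n_subjects: int = 806
    # component correlation targets: (g-gc, g-gf, gc-gf)
    component_corr: tuple = (0.78, 0.76, 0.49)
    family_icc: float = 0.3            # share of latent variance at family level
    family_geom_p: float = 0.45        # truncated-geometric family-size law
    max_family_size: int = 5
    confound_target_corr: dict = field(
        default_factory=lambda: dict(DEFAULT_CONFOUND_TARGET_CORR))
    # connectome parameters
    n_nodes: int = 100
    networks: tuple = SEVEN_NETWORKS
    state_signal: dict = field(
        default_factory=lambda: dict(DEFAULT_STATE_SIGNAL))
    n_relevant: int = 1000             # planted edge count
    n_blocks: int = 10                 # redundancy blocks among planted edges
    block_coherence: float = 0.7       # corr of each block latent with target
    relevant_component: str = "g"      # component the planted edges carry
    beta: float = 0.016                # per-edge signal coefficient
    edge_mean: float = 0.3             # mean of per-edge baseline (Fisher z)
    edge_mean_sd: float = 0.25
    edge_noise_sd: tuple = (0.15, 0.3)  # per-edge noise SD ~ U(range)
    node_noise_sd: float = 0.1         # node-factor noise (edges sharing a
                                       # node are correlated, as in real FC)
    retest_reliability: tuple = (0.3, 0.8)  # per-edge ICC target ~ U(range)
    confound_leakage: dict = field(default_factory=lambda: {
        "age": 0.03, "sex": 0.03, "mean_fd": 0.08})
    store_runs: bool = False

    def corr_matrix(self) -> np.ndarray:
        r_ggc, r_ggf, r_gcgf = self.component_corr
        return np.array([[1.0, r_ggc, r_ggf],
                         [r_ggc, 1.0, r_gcgf],
                         [r_ggf, r_gcgf, 1.0]])


@dataclass
class GroundTruth:
    """Planted latent structure of a synthetic study.

    ``relevant_edges`` / ``effect_sizes`` are populated by
    :func:`generate_connectomes`; per-state entries reference the same
    planted set, whose signal is scaled by the state's signal parameter.
    """

    true_g: np.ndarray
    true_gc: np.ndarray
    true_gf: np.ndarray
    generator_config: GeneratorConfig
    seed: int
    relevant_edges: dict = field(default_factory=dict)   # state -> indices
    effect_sizes: np.ndarray | None = None               # per planted edge
    edge_blocks: np.ndarray | None = None                # block id per planted edge
    block_latents: np.ndarray | None = None              # subjects x blocks

    def component(self, name: str) -> np.ndarray:
        try:
            return {"g": self.true_g, "gc": self.true_gc,
                    "gf": self.true_gf}[name]
        except KeyError:
            raise KeyError(f"unknown component {name!r}") from None

    def fluid_group_factor(self) -> np.ndarray:
        """Part of the fluid component orthogonal to g, standardized.

        Computed from the configured (population) correlation, not the
        sample one, so it is deterministic given the latents.
        """
        r = self.generator_config.component_corr[1]
        return (self.true_gf - r * self.true_g) / np.sqrt(1 - r * r)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _family_sizes(n: int, p: float, cap: int, rng) -> np.ndarray:
    sizes = []
    total = 0
    while total < n:
        s = min(int(rng.geometric(p)), cap)
        s = min(s, n - total)
        sizes.append(s)
        total += s
    return np.asarray(sizes)


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0,
                    loading_spec: LoadingSpec | None = None
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a synthetic cohort table and its ground truth.

    The three latent components are multivariate normal with the configured
    correlation targets; a family-level random effect (share
    ``family_icc`` of variance) induces family clustering without changing
    the marginal correlations. Confounds are constructed to hit the
    configured confound-target correlations (sex via a thresholded latent
    with the point-biserial correction; handedness independent uniform).

    Returns
    -------
    (cohort, truth)
        ``cohort`` is one row per subject with ids, family ids, confounds
        and the 12 cognitive measures. Deterministic per (config, seed).
    """
    config = config or GeneratorConfig()
    if config.n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    corr = config.corr_matrix()
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-10:
        raise ValueError(
            f"component correlation targets are not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g})")
    rng = np.random.default_rng(seed)
    n = config.n_subjects

    sizes = _family_sizes(n, config.family_geom_p, config.max_family_size, rng)
    fam_of = np.repeat(np.arange(len(sizes)), sizes)

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    fam_eff = rng.standard_normal((len(sizes), 3)) @ chol.T
    indiv = rng.standard_normal((n, 3)) @ chol.T
    rho = config.family_icc
    latents = np.sqrt(rho) * fam_eff[fam_of] + np.sqrt(1 - rho) * indiv
    g, gc, gf = latents[:, 0], latents[:, 1], latents[:, 2]
    g_std = (g - g.mean()) / g.std()

    targets = config.confound_target_corr

    def corr_latent(r):
        if abs(r) >= 1:
            raise ValueError("confound-target correlation must be in (-1, 1)")
        return r * g_std + np.sqrt(1 - r * r) * rng.standard_normal(n)

    age = np.clip(28.6 + 3.6 * corr_latent(targets["age"]), 22, 37)
    # sex: threshold a latent; point-biserial attenuation factor
    # phi(0)/sqrt(p(1-p)) = 0.7979 at p = 0.5 is divided out of the target.
    r_sex = targets["sex"] / 0.7978845608
    sex = (corr_latent(r_sex) > 0).astype(int)
    handedness = rng.uniform(-100, 100, n)
    if targets.get("handedness", 0.0) != 0.0:
        hand_lat = corr_latent(targets["handedness"])
        handedness = 200 * (pd.Series(hand_lat).rank().to_numpy() / (n + 1)) - 100
    mean_fd = np.clip(0.12 + 0.035 * corr_latent(targets["mean_fd"]), 0.01, None)
    spikes = np.clip(0.08 + 0.03 * corr_latent(targets["spike_proportion"]),
                     0.0, 1.0)
    max_spike = np.exp(rng.normal(-0.5, 0.8, n))

    truth = GroundTruth(true_g=g, true_gc=gc, true_gf=gf,
                        generator_config=config, seed=seed)
    measures = generate_cognitive_measures(
        truth, loading_spec or LoadingSpec.default(),
        rng=np.random.default_rng(rng.integers(2 ** 31)))

    cohort = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "family_id": [f"F{f:05d}" for f in fam_of],
        "age": age, "sex": sex, "handedness": handedness,
        "mean_fd": mean_fd, "spike_proportion": spikes,
        "max_spike": max_spike,
    })
    for name in MEASURE_NAMES:
        cohort[name] = measures[name].to_numpy()
    return cohort, truth


def generate_cognitive_measures(truth: GroundTruth,
                                loading_spec: LoadingSpec,
                                rng=None, seed: int = 0) -> pd.DataFrame:
    """Generate the 12 cognitive measures from the latent components.

    Measures follow the linear factor model of :class:`LoadingSpec`:
    the seven fluid measures load on g and on the fluid group factor,
    the two crystallized measures on the crystallized component, the
    remaining measures on g only.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(truth.true_g)
    groups = {"fluid": truth.fluid_group_factor(),
              "crystallized": truth.true_gc,
              "general": truth.true_g}
    out = {}
    for m in MEASURE_NAMES:
        a = loading_spec.general.get(m, 0.0)
        x = a * truth.true_g
        if m in loading_spec.group:
            factor, b = loading_spec.group[m]
            if factor not in groups:
                raise ValueError(f"unknown group factor {factor!r}")
            x = x + b * groups[factor]
        out[m] = x + loading_spec.noise_for(m) * rng.standard_normal(n)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Connectomes
# ---------------------------------------------------------------------------

def generate_connectomes(truth: GroundTruth, atlas: NodeAtlas | None = None,
                         states: Sequence[str] = MEASURED_STATES,
                         seed: int | None = None,
                         cohort: pd.DataFrame | None = None) -> ConnectomeSet:
    """Generate per-subject, per-state symmetric Fisher-z connectomes.

    Every edge e = (i_node, j_node) of subject i in state s is

        fc = mu_e + beta_e * gamma_s * u_{b(e),i} + leak_i
             + a_{i_node} + a_{j_node} + eps,

    where ``u_b`` is the redundancy-block latent (correlation
    ``block_coherence`` with the designated intelligence component),
    ``gamma_s`` the state signal scale, ``leak`` the additive confound
    leakage, ``a`` are per-subject node factors (SD ``node_noise_sd``)
    that correlate edges sharing a node, and ``eps`` edge noise. Noise is
    split into a retest-stable and a run-specific part so phase-run pairs
    have per-edge ICC near the configured reliability. Non-planted edges
    carry no component signal.

    Fills ``truth.relevant_edges`` and ``truth.effect_sizes``. Deterministic
    per seed (defaults to the cohort seed + 1).
    """
    cfg = truth.generator_config
    atlas = atlas or NodeAtlas.default(cfg.n_nodes, cfg.networks)
    if atlas.n_nodes != cfg.n_nodes:
        raise ValueError("atlas node count mismatch with generator config")
    unknown = [s for s in states if s not in cfg.state_signal]
    if unknown:
        raise KeyError(f"state(s) {unknown} not in configured state set")
    seed = truth.seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)

    n = len(truth.true_g)
    ei = EdgeIndex(atlas.n_nodes)
    n_edges = ei.n_edges
    if cfg.n_relevant > n_edges:
        raise ValueError("more planted edges than edges available")

    mu = rng.normal(cfg.edge_mean, cfg.edge_mean_sd, n_edges)
    sigma = rng.uniform(*cfg.edge_noise_sd, n_edges)
    rel = rng.uniform(*cfg.retest_reliability, n_edges)

    planted = np.sort(rng.choice(n_edges, size=cfg.n_relevant, replace=False))
    blocks = rng.integers(0, cfg.n_blocks, size=cfg.n_relevant)
    comp = truth.component(cfg.relevant_component)
    comp = (comp - comp.mean()) / comp.std()
    w = cfg.block_coherence
    u = w * comp[:, None] + np.sqrt(1 - w * w) * rng.standard_normal(
        (n, cfg.n_blocks))
    betas = np.full(cfg.n_relevant, cfg.beta) * rng.choice(
        [1.0, -1.0], size=cfg.n_relevant)   # signed effects

    # confound leakage: per-edge coefficients on z-scored confounds
    leak = np.zeros((n, n_edges))
    if cfg.confound_leakage and cohort is not None:
        for cname, scale in cfg.confound_leakage.items():
            c = cohort[cname].to_numpy(float)
            sd = c.std()
            if sd == 0:
                continue
            cz = (c - c.mean()) / sd
            coefs = rng.normal(0.0, scale, n_edges)
            leak += np.outer(cz, coefs)

    gammas = np.array([cfg.state_signal[s] for s in states])
    signal = np.zeros((n, n_edges))
    signal[:, planted] = u[:, blocks] * betas

    values = np.empty((n, len(states), n_edges))
    runs = (np.empty((n, len(states), 2, n_edges)) if cfg.store_runs else None)
    # split total noise (edge + node-factor) into stable vs run-specific so
    # the per-edge retest ICC lands near the configured reliability
    ns2 = 2.0 * cfg.node_noise_sd ** 2
    total = sigma ** 2 + ns2
    sd_stable = np.sqrt(np.clip(rel * total - ns2, 0.0, None))
    sd_run = np.sqrt((1 - rel) * total)
    rows_e, cols_e = ei.pairs()
    for si, gamma in enumerate(gammas):
        node_fac = rng.standard_normal((n, atlas.n_nodes)) * cfg.node_noise_sd
        base = (mu + gamma * signal + leak
                + node_fac[:, rows_e] + node_fac[:, cols_e])
        stable = rng.standard_normal((n, n_edges)) * sd_stable
        d1 = rng.standard_normal((n, n_edges)) * sd_run
        d2 = rng.standard_normal((n, n_edges)) * sd_run
        r1, r2 = base + stable + d1, base + stable + d2
        values[:, si] = 0.5 * (r1 + r2)
        if runs is not None:
            runs[:, si, 0], runs[:, si, 1] = r1, r2

    truth.relevant_edges = {s: planted for s in states}
    truth.effect_sizes = betas
    truth.edge_blocks = blocks
    truth.block_latents = u
    subjects = (list(cohort["subject_id"]) if cohort is not None
                else [f"S{i:05d}" for i in range(n)])
    meta = {"seed": int(seed), "edge_convention": "upper-triangle row-major",
            "generator": {k: v for k, v in asdict(cfg).items()
                          if not isinstance(v, np.ndarray)}}
    return ConnectomeSet(values=values, states=list(states),
                         subjects=subjects, atlas=atlas, runs=runs, meta=meta)


def exclude_by_motion(cohort: pd.DataFrame, mean_fd_max: float = 0.2,
                      spike_prop_max: float = 0.2,
                      max_spike_mm: float = 5.0) -> pd.DataFrame:
    """Apply the head-motion exclusion rules.

    Retains subjects with mean FD < ``mean_fd_max`` (mm), proportion of
    spikes < ``spike_prop_max``, and no spike above ``max_spike_mm`` (mm);
    order preserved.
    """
    if min(mean_fd_max, spike_prop_max, max_spike_mm) <= 0:
        raise ValueError("thresholds must be positive")
    keep = ((cohort["mean_fd"] < mean_fd_max)
            & (cohort["spike_proportion"] < spike_prop_max)
            & (cohort["max_spike"] <= max_spike_mm))
    return cohort.loc[keep].copy()


# ---------------------------------------------------------------------------
# Direct feature-space simulation (for attribution/recovery studies)
# ---------------------------------------------------------------------------

def planted_features(n_subjects: int, n_features: int, n_planted: int,
                     beta: float = 0.3, noise_sd: float = 1.0,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix with a planted linear signal in a random subset.

    Each planted feature equals ``beta * y + noise``; the rest are pure
    noise. Returns (X, y, planted_indices). The expected correlation of a
    planted feature with y is beta / sqrt(beta^2 + noise_sd^2).
    """
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n_subjects)
    x = rng.normal(0.0, noise_sd, (n_subjects, n_features))
    planted = np.sort(rng.choice(n_features, n_planted, replace=False))
    x[:, planted] += beta * y[:, None]
    return x, y, planted


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def load_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_connectomes(conn: ConnectomeSet, array_path, sidecar_path) -> None:
    """Array container (.npz) + JSON sidecar with atlas/states/convention."""
    np.savez_compressed(array_path, values=conn.values,
                        **({"runs": conn.runs} if conn.runs is not None else {}))
    sidecar = {
        "states": conn.states,
        "subjects": conn.subjects,
        "atlas": conn.atlas.to_frame().to_dict(orient="list"),
        "edge_convention": "upper-triangle row-major 0-based",
        "meta": {k: v for k, v in conn.meta.items() if k != "generator"},
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, default=str)


def load_connectomes(array_path, sidecar_path) -> ConnectomeSet:
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    arr = np.load(array_path)
    atlas = NodeAtlas.from_frame(pd.DataFrame(sidecar["atlas"]))
    return ConnectomeSet(values=arr["values"], states=sidecar["states"],
                         subjects=sidecar["subjects"], atlas=atlas,
                         runs=arr["runs"] if "runs" in arr else None,
                         meta=sidecar.get("meta", {}))
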