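"""Cross-validated prediction of intelligence from connectivity features.

The prediction protocol:

* 5-fold cross-validation with families kept intact and folds stratified
  on family-average target scores; typically repeated over 10 fold seeds.
* Out-of-sample deconfounding: confounds are regressed out of target and
  features with coefficients and z-standardization parameters estimated on
  the training fold only, then applied unchanged to the test fold.
* A small feed-forward neural network (ReLU, dropout 0.25, MSE loss,
  full-batch SGD at learning rate 0.01) with early stopping on a
  family-aware validation split; the architecture (1-3 hidden layers of
  10/50/100 units) is chosen by an inner 3-fold search.
* Performance as Pearson r between observed and predicted scores plus
  MSE / RMSE / MAE computed after dividing both vectors by the range of
  the observed scores.

Every source of randomness (fold construction, validation splits, weight
initialization, dropout) is derived from explicit integer seeds and never
from data values, so training artifacts are byte-reproducible — the basis
of the leakage audit in :func:`leakage_audit`.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "FoldAssignment", "make_folds", "DeconfoundModel",
           "fit_deconfounder", "apply_deconfounder", "MLPRegressor",
           "train_mlp", "tune_hyperparameters", "cross_validated_predict",
           "performance_metrics", "PredictionResult", "fit_full",
           "transfer_predict", "leakage_audit", "DEFAULT_GRID"]

#: Architecture grid: 1-3 hidden layers of 10, 50 or 100 units.
DEFAULT_GRID = tuple((w,) * d for d in (1, 2, 3) for w in (10, 50, 100))


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults are the study protocol)."""

    lr: float = 0.01
    dropout: float = 0.25
    max_epochs: int = 20000
    patience: int = 100
    val_fraction: float = 0.2        # early-stop split in the outer loop
    inner_val_fraction: float = 0.3  # early-stop split during tuning
    grid: tuple = DEFAULT_GRID
    inner_folds: int = 3
    batch_size: int | None = None    # None = full batch

    def scaled(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Fold index per subject; families are never split across folds."""

    fold: np.ndarray
    n_folds: int
    seed: int

    def test_idx(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold == f)

    def train_idx(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold != f)


def make_folds(families: np.ndarray, target: np.ndarray, n_folds: int = 5,
               seed: int = 0) -> FoldAssignment:
    """Family-aware stratified fold assignment.

    Families are sorted by family-average target, dealt round-robin into
    folds in strata of ``n_folds`` consecutive families (shuffled within
    each stratum with the given seed). This keeps families intact while
    approximately equalizing fold-wise target distributions.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    families = np.asarray(families)
    target = np.asarray(target, float)
    if families.shape != target.shape:
        raise ValueError("families and target must align")
    if np.isnan(target).any():
        raise ValueError("every subject needs a target score")
    rng = np.random.default_rng(seed)

    fam_ids, fam_inv = np.unique(families, return_inverse=True)
    fam_mean = np.bincount(fam_inv, weights=target) / np.bincount(fam_inv)
    fam_size = np.bincount(fam_inv)
    if fam_size.max() > len(families) / n_folds:
        logger.warning("a family is larger than n/n_folds; folds will be "
                       "unbalanced")
    order = np.argsort(fam_mean, kind="stable")
    fam_fold = np.empty(len(fam_ids), dtype=int)
    # deal sorted families stratum by stratum, shuffling fold order within
    for start in range(0, len(order), n_folds):
        stratum = order[start:start + n_folds]
        fold_order = rng.permutation(n_folds)[:len(stratum)]
        fam_fold[stratum] = fold_order
    return FoldAssignment(fold=fam_fold[fam_inv], n_folds=n_folds, seed=seed)


def _family_validation_split(train_idx: np.ndarray, families: np.ndarray,
                             fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Family-aware split of a training fold into fit and validation parts."""
    fams = families[train_idx]
    uniq = np.unique(fams)
    uniq = uniq[rng.permutation(len(uniq))]
    target_n = max(1, int(round(fraction * len(train_idx))))
    val_fams, n_val = [], 0
    for f in uniq:
        if n_val >= target_n:
            break
        val_fams.append(f)
        n_val += int(np.sum(fams == f))
    val_mask = np.isin(fams, val_fams)
    return train_idx[~val_mask], train_idx[val_mask]


# ---------------------------------------------------------------------------
# Deconfounding
# ---------------------------------------------------------------------------

@dataclass
class DeconfoundModel:
    """Linear confound regression + z-standardization, train-estimated.

    Stores, per variable (target and each feature), the OLS coefficients
    on [1, confounds] and the mean/SD of the training residuals. Applying
    the model to new data uses these training parameters only.
    """

    coef_y: np.ndarray
    coef_x: np.ndarray
    mean_y: float
    sd_y: float
    mean_x: np.ndarray
    sd_x: np.ndarray
    n_confounds: int

    def digest_bytes(self) -> bytes:
        h = hashlib.sha256()
        for a in (self.coef_y, self.coef_x, np.array([self.mean_y, self.sd_y]),
                  self.mean_x, self.sd_x):
            h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
        return h.digest()


def _design(confounds: np.ndarray) -> np.ndarray:
    confounds = np.atleast_2d(np.asarray(confounds, float))
    if confounds.shape[0] == 1 and confounds.ndim == 2:
        confounds = confounds.T if confounds.shape[1] > 1 else confounds
    return np.column_stack([np.ones(len(confounds)), confounds])


def fit_deconfounder(features: np.ndarray, target: np.ndarray,
                     confounds: np.ndarray,
                     on_zero_variance: str = "raise") -> DeconfoundModel:
    """Fit confound regressions for the target and every feature.

    Training residuals are exactly orthogonal to the confounds (OLS) and
    are z-standardized; the same coefficients and M/SD are later applied
    to test data. Raises on rank-deficient confounds. A zero-variance
    target residual (target fully explained by confounds) raises by
    default; with ``on_zero_variance="keep"`` the SD is set to 1 so the
    raw (all-zero) residuals pass through unscaled.
    """
    x = np.asarray(features, float)
    y = np.asarray(target, float)
    c = _design(confounds)
    if np.linalg.matrix_rank(c) < c.shape[1]:
        raise ValueError("confound matrix is rank deficient")
    coef_y, *_ = np.linalg.lstsq(c, y, rcond=None)
    coef_x, *_ = np.linalg.lstsq(c, x, rcond=None)
    ry = y - c @ coef_y
    rx = x - c @ coef_x
    sd_y = ry.std()
    sd_x = rx.std(axis=0)
    if sd_y == 0:
        if on_zero_variance == "raise":
            raise ValueError("target fully explained by confounds "
                             "(zero-variance residual)")
        logger.warning("zero-variance target residual kept unscaled")
        sd_y = 1.0
    sd_x = np.where(sd_x == 0, 1.0, sd_x)
    return DeconfoundModel(coef_y=coef_y, coef_x=coef_x,
                           mean_y=float(ry.mean()), sd_y=float(sd_y),
                           mean_x=rx.mean(axis=0), sd_x=sd_x,
                           n_confounds=c.shape[1] - 1)


def apply_deconfounder(model: DeconfoundModel, features: np.ndarray,
                       target: np.ndarray, confounds: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Residualize and standardize data with training-fold parameters."""
    c = _design(confounds)
    if c.shape[1] - 1 != model.n_confounds:
        raise ValueError("confound set differs from the one seen at fit time")
    x = np.asarray(features, float)
    y = np.asarray(target, float)
    if x.shape[1] != model.coef_x.shape[1]:
        raise ValueError("feature set differs from the one seen at fit time")
    ry = (y - c @ model.coef_y - model.mean_y) / model.sd_y
    rx = (x - c @ model.coef_x - model.mean_x) / model.sd_x
    return rx, ry


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

class MLPRegressor:
    """Minimal feed-forward regressor: ReLU hidden layers, scalar linear
    output, inverted dropout, full-batch (or mini-batch) SGD on MSE loss,
    early stopping on a held-out validation set.

    Weights are He-initialized from the provided seed; dropout masks come
    from the same generator, so training is deterministic per seed.
    """

    def __init__(self, n_features: int, hidden: tuple = (100,),
                 lr: float = 0.01, dropout: float = 0.25, seed: int = 0):
        self.hidden = tuple(hidden)
        self.lr = lr
        self.dropout = dropout
        self.seed = seed
        rng = np.random.default_rng(seed)
        dims = [n_features, *self.hidden, 1]
        self.weights = [rng.normal(0, np.sqrt(2.0 / dims[i]),
                                   (dims[i], dims[i + 1]))
                        for i in range(len(dims) - 1)]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.log: dict = {}

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def _forward(self, x, rng=None):
        """Returns (activations per layer incl. input, dropout masks)."""
        acts, masks = [x], []
        a = x
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if li < len(self.weights) - 1:
                a = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0:
                    mask = (rng.random(a.shape) >= self.dropout) / (
                        1.0 - self.dropout)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                a = z
            acts.append(a)
        return acts, masks

    def predict(self, x: np.ndarray) -> np.ndarray:
        acts, _ = self._forward(np.asarray(x, float))
        return acts[-1][:, 0]

    def fit(self, x, y, x_val, y_val, max_epochs: int = 20000,
            patience: int = 100, batch_size: int | None = None
            ) -> "MLPRegressor":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        rng = np.random.default_rng(self.seed + 1)
        best_loss = np.inf
        best_epoch = -1
        best_weights = None
        history = []
        stop_reason = "max_epochs"
        n = len(x)
        for epoch in range(max_epochs):
            if batch_size is None or batch_size >= n:
                batches = [np.arange(n)]
            else:
                perm = rng.permutation(n)
                batches = [perm[i:i + batch_size]
                           for i in range(0, n, batch_size)]
            for idx in batches:
                self._step(x[idx], y[idx], rng)
            with np.errstate(over="ignore", invalid="ignore"):
                val_loss = float(np.mean((self.predict(x_val) - y_val) ** 2))
            if not np.isfinite(val_loss):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch}; lower the learning rate")
            history.append(val_loss)
            if val_loss < best_loss:
                best_loss = val_loss
                best_epoch = epoch
                best_weights = ([w.copy() for w in self.weights],
                                [b.copy() for b in self.biases])
            elif epoch - best_epoch >= patience:
                stop_reason = "early_stop"
                break
        if best_weights is not None:
            self.weights, self.biases = best_weights
        self.log = {"epochs_run": epoch + 1, "stop_reason": stop_reason,
                    "best_epoch": best_epoch, "best_val_loss": best_loss,
                    "val_history": np.asarray(history)}
        return self

    def _step(self, x, y, rng):
        acts, masks = self._forward(x, rng=rng)
        n = len(x)
        delta = 2.0 * (acts[-1][:, 0] - y)[:, None] / n   # dL/d output
        for li in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[li]
            gw = a_prev.T @ delta
            gb = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.weights[li].T
                delta *= (acts[li] > 0)          # ReLU gate (post-dropout)
                if masks[li - 1] is not None:
                    delta *= masks[li - 1]
            self.weights[li] -= self.lr * gw
            self.biases[li] -= self.lr * gb

    def digest_bytes(self) -> bytes:
        h = hashlib.sha256()
        for w, b in zip(self.weights, self.biases):
            h.update(np.ascontiguousarray(w).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        h.update(np.ascontiguousarray(self.log.get("val_history",
                                                   np.empty(0))).tobytes())
        return h.digest()


def train_mlp(x_train, y_train, x_val, y_val, hidden: tuple = (100,),
              config: TrainConfig = TrainConfig(), seed: int = 0
              ) -> MLPRegressor:
    """Train one MLP with early stopping; see :class:`MLPRegressor`."""
    model = MLPRegressor(n_features=x_train.shape[1], hidden=hidden,
                         lr=config.lr, dropout=config.dropout, seed=seed)
    return model.fit(x_train, y_train, x_val, y_val,
                     max_epochs=config.max_epochs, patience=config.patience,
                     batch_size=config.batch_size)


def tune_hyperparameters(x, y, families, config: TrainConfig,
                         seed: int = 0) -> tuple:
    """Choose the architecture minimizing mean inner-fold validation loss.

    Inner loop: family-aware 3-fold CV over the training data; each inner
    fit holds out ``inner_val_fraction`` of its training part (family-aware)
    for early stopping. Ties are broken by the smaller parameter count.
    """
    if not config.grid:
        raise ValueError("empty architecture grid")
    if len(config.grid) == 1:
        return tuple(config.grid[0])
    folds = make_folds(families, y, n_folds=config.inner_folds, seed=seed)
    results = []
    for hidden in config.grid:
        losses = []
        for f in range(config.inner_folds):
            tr, te = folds.train_idx(f), folds.test_idx(f)
            if len(te) < 2 or len(tr) < 4:
                raise ValueError("inner folds too small")
            rng = np.random.default_rng([seed, f, 7])
            fit_idx, val_idx = _family_validation_split(
                tr, families, config.inner_val_fraction, rng)
            model = train_mlp(x[fit_idx], y[fit_idx], x[val_idx], y[val_idx],
                              hidden=hidden, config=config,
                              seed=int(rng.integers(2 ** 31)))
            losses.append(float(np.mean((model.predict(x[te]) - y[te]) ** 2)))
        n_params = MLPRegressor(x.shape[1], hidden).n_params
        results.append((float(np.mean(losses)), n_params, tuple(hidden)))
    results.sort(key=lambda t: (t[0], t[1]))
    return results[0][2]


# ---------------------------------------------------------------------------
# Metrics and results
# ---------------------------------------------------------------------------

def performance_metrics(y: np.ndarray, y_hat: np.ndarray) -> dict:
    """Pearson r plus range-normalized MSE / RMSE / MAE.

    Error metrics are computed after dividing both vectors by
    ``max(y) - min(y)`` (the range of the observed scores).
    """
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if len(y) < 3 or y.shape != y_hat.shape:
        raise ValueError("need aligned vectors of length >= 3")
    rng_y = y.max() - y.min()
    if rng_y == 0:
        raise ValueError("constant observed scores")
    r = float(np.corrcoef(y, y_hat)[0, 1])
    err = (y_hat - y) / rng_y
    mse = float(np.mean(err ** 2))
    return {"r": r, "mse": mse, "rmse": float(np.sqrt(mse)),
            "mae": float(np.mean(np.abs(err)))}


@dataclass
class PredictionResult:
    """Out-of-fold predictions and metrics, per repetition and averaged."""

    predictions: np.ndarray          # (n_reps, n_subjects), deconfounded scale
    observed: np.ndarray             # (n_reps, n_subjects), deconfounded scale
    per_rep: pd.DataFrame            # one row per repetition: r/mse/rmse/mae
    hyperparams: list                # chosen architecture per (rep, fold)
    artifacts: dict = field(default_factory=dict)

    @property
    def mean_r(self) -> float:
        return float(self.per_rep["r"].mean())

    def mean_metrics(self) -> dict:
        return self.per_rep[["r", "mse", "rmse", "mae"]].mean().to_dict()


def _run_fold(x, y, confounds, families, folds, f, config, seed, rep,
              collect_artifacts, corrupt_test=None):
    tr, te = folds.train_idx(f), folds.test_idx(f)
    y_run = y.copy()
    x_run = x
    if corrupt_test is not None:
        y_run, x_run = corrupt_test(y_run, x.copy(), te, f)
    dec = fit_deconfounder(x_run[tr], y_run[tr], confounds[tr])
    xt, yt = apply_deconfounder(dec, x_run[tr], y_run[tr], confounds[tr])
    xe, ye = apply_deconfounder(dec, x_run[te], y_run[te], confounds[te])
    tune_seed = int(np.random.default_rng([seed, rep, f, 3]).integers(2 ** 31))
    hidden = tune_hyperparameters(xt, yt, families[tr], config,
                                  seed=tune_seed)
    rng = np.random.default_rng([seed, rep, f, 5])
    fit_rel, val_rel = _family_validation_split(
        np.arange(len(tr)), families[tr], config.val_fraction, rng)
    model = train_mlp(xt[fit_rel], yt[fit_rel], xt[val_rel], yt[val_rel],
                      hidden=hidden, config=config,
                      seed=int(rng.integers(2 ** 31)))
    y_pred = model.predict(xe)
    art = None
    if collect_artifacts:
        h = hashlib.sha256()
        h.update(dec.digest_bytes())
        h.update(repr(hidden).encode())
        h.update(model.digest_bytes())
        art = h.hexdigest()
    return te, y_pred, ye, hidden, art, model, dec


def cross_validated_predict(features: np.ndarray, target: np.ndarray,
                            confounds: np.ndarray, families: np.ndarray,
                            selection=None, config: TrainConfig = TrainConfig(),
                            n_folds: int = 5, n_repetitions: int = 10,
                            seed: int = 0, collect_artifacts: bool = False,
                            _corrupt_test=None) -> PredictionResult:
    """Family-aware, deconfounded, cross-validated prediction.

    Repeats ``n_repetitions`` times with fresh stratified folds (fold seed
    = ``seed`` + repetition); reports metrics per repetition and their
    mean. ``selection`` optionally restricts the feature columns (a
    :class:`~fcintel.selection.ConnectionSelection` or an index/mask).
    """
    x = np.asarray(features, float)
    y = np.asarray(target, float)
    confounds = np.asarray(confounds, float)
    families = np.asarray(families)
    if selection is not None:
        mask = getattr(selection, "mask", np.asarray(selection))
        x = x[:, mask]
        if x.shape[1] == 0:
            raise ValueError("empty connection selection")
    n = len(y)
    preds = np.full((n_repetitions, n), np.nan)
    obs = np.full((n_repetitions, n), np.nan)
    rows, hps, artifacts = [], [], {}
    for rep in range(n_repetitions):
        folds = make_folds(families, y, n_folds=n_folds, seed=seed + rep)
        for f in range(n_folds):
            te, y_pred, ye, hidden, art, _, _ = _run_fold(
                x, y, confounds, families, folds, f, config, seed, rep,
                collect_artifacts, corrupt_test=_corrupt_test)
            preds[rep, te] = y_pred
            obs[rep, te] = ye
            hps.append({"rep": rep, "fold": f, "hidden": hidden})
            if art is not None:
                artifacts[(rep, f)] = art
        rows.append({"rep": rep,
                     **performance_metrics(obs[rep], preds[rep])})
    assert not np.isnan(preds).any(), "out-of-fold coverage violated"
    return PredictionResult(predictions=preds, observed=obs,
                            per_rep=pd.DataFrame(rows), hyperparams=hps,
                            artifacts=artifacts)


# ---------------------------------------------------------------------------
# Transfer (lockbox / external replication)
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Deconfounder + predictor trained on a full sample."""

    deconfounder: DeconfoundModel
    model: MLPRegressor
    hidden: tuple


def fit_full(features, target, confounds, families,
             config: TrainConfig = TrainConfig(), selection=None,
             seed: int = 0) -> FittedModel:
    """Train one model on an entire cohort (for transfer evaluation)."""
    x = np.asarray(features, float)
    if selection is not None:
        mask = getattr(selection, "mask", np.asarray(selection))
        x = x[:, mask]
    y = np.asarray(target, float)
    confounds = np.asarray(confounds, float)
    families = np.asarray(families)
    dec = fit_deconfounder(x, y, confounds)
    xt, yt = apply_deconfounder(dec, x, y, confounds)
    hidden = tune_hyperparameters(xt, yt, families, config,
                                  seed=int(np.random.default_rng(
                                      [seed, 3]).integers(2 ** 31)))
    rng = np.random.default_rng([seed, 5])
    fit_rel, val_rel = _family_validation_split(
        np.arange(len(y)), families, config.val_fraction, rng)
    model = train_mlp(xt[fit_rel], yt[fit_rel], xt[val_rel], yt[val_rel],
                      hidden=hidden, config=config,
                      seed=int(rng.integers(2 ** 31)))
    return FittedModel(deconfounder=dec, model=model, hidden=hidden)


def transfer_predict(fitted: FittedModel, features, target, confounds,
                     selection=None) -> dict:
    """Apply a trained deconfounder+predictor to a new cohort unchanged."""
    x = np.asarray(features, float)
    if selection is not None:
        mask = getattr(selection, "mask", np.asarray(selection))
        x = x[:, mask]
    xt, yt = apply_deconfounder(fitted.deconfounder, x,
                                np.asarray(target, float),
                                np.asarray(confounds, float))
    y_pred = fitted.model.predict(xt)
    return {"predictions": y_pred, "observed": yt,
            **performance_metrics(yt, y_pred)}


# ---------------------------------------------------------------------------
# Leakage audit
# ---------------------------------------------------------------------------

def leakage_audit(features, target, confounds, families,
                  config: TrainConfig = TrainConfig(), n_folds: int = 5,
                  seed: int = 0) -> bool:
    """Poisoned-test-fold check for train/test leakage.

    For each fold, test-fold targets and features are corrupted (targets
    shuffled and scaled, features overwritten with noise) and the pipeline
    re-run with identical seeds and fold assignment; the fold's
    training-derived artifacts (deconfounder parameters, chosen
    architecture, early-stop trace, final weights) must be byte-identical
    to the clean run. Returns True iff the audit passes for every fold.
    """
    base = cross_validated_predict(features, target, confounds, families,
                                   config=config, n_folds=n_folds,
                                   n_repetitions=1, seed=seed,
                                   collect_artifacts=True)
    for f in range(n_folds):
        rng = np.random.default_rng(seed + 999 + f)

        def corrupt(y, x, te, fold, _f=f, _rng=rng):
            if fold == _f:
                y[te] = _rng.permutation(y[te]) * 3.0 + 11.0
                x[te] = _rng.normal(0, 5, x[te].shape)
            return y, x

        poisoned = cross_validated_predict(
            features, target, confounds, families, config=config,
            n_folds=n_folds, n_repetitions=1, seed=seed,
            collect_artifacts=True, _corrupt_test=corrupt)
        if poisoned.artifacts[(0, f)] != base.artifacts[(0, f)]:
            logger.error("leakage audit FAILED at fold %d", f)
            return False
    return True
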