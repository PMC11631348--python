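"""Intelligence score construction.

Three scores per subject:

* ``g`` — general intelligence, the general factor of an exploratory
  bifactor model (Schmid-Leiman orthogonalization of a two-stage EFA with
  oblimin-rotated group factors) over all 12 cognitive measures.
* ``gf`` — fluid intelligence, a single-factor EFA over the seven fluid
  measures (with one factor the configured oblimin rotation is a no-op,
  but its name is recorded in the fit metadata).
* ``gc`` — crystallized intelligence, the sum of the z-standardized
  picture-vocabulary and reading-recognition scores.

Factor scores use the regression (Thurstone) method and are standardized.
Subjects with missing measures must be dropped listwise by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .synth import MEASURE_NAMES, FLUID_MEASURES, CRYSTALLIZED_MEASURES

logger = logging.getLogger(__name__)

__all__ = ["IntelligenceScores", "estimate_g_bifactor", "estimate_gf_efa",
           "compute_gc_composite", "score_cohort", "oblimin_rotate"]


@dataclass
class IntelligenceScores:
    """Standardized per-subject intelligence components."""

    g: np.ndarray
    gc: np.ndarray
    gf: np.ndarray
    subject_ids: list | None = None
    fit_info: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"g": self.g, "gc": self.gc, "gf": self.gf})
        if self.subject_ids is not None:
            df.insert(0, "subject_id", self.subject_ids)
        return df

    def component(self, name: str) -> np.ndarray:
        return {"g": self.g, "gc": self.gc, "gf": self.gf}[name]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance input column")
    return (x - x.mean(axis=0)) / sd


def _regression_scores(z: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Thurstone regression factor scores from standardized data and a
    single loading vector, using the observed correlation matrix."""
    r = np.corrcoef(z, rowvar=False)
    w = np.linalg.solve(r + 1e-10 * np.eye(len(r)), loadings)
    s = z @ w
    return (s - s.mean()) / s.std()


def oblimin_rotate(loadings: np.ndarray, gamma: float = 0.0,
                   max_iter: int = 500, tol: float = 1e-6
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Oblique oblimin rotation by the gradient-projection algorithm.

    Returns (pattern matrix, factor correlation matrix). ``gamma = 0``
    is the quartimin criterion. A single factor is returned unchanged.
    """
    a = np.asarray(loadings, float)
    p, k = a.shape
    if k == 1:
        return a.copy(), np.ones((1, 1))
    n_mat = np.ones((k, k)) - np.eye(k)

    def criterion(t):
        li = np.linalg.inv(t)
        lam = a @ li.T
        l2 = lam ** 2
        c = l2 - gamma / p * np.ones((p, p)) @ l2
        f = np.sum(l2 * (c @ n_mat)) / 4
        gq = lam * (c @ n_mat)
        grad = -(lam.T @ gq @ li).T
        return f, grad, lam

    t = np.eye(k)
    f, grad, lam = criterion(t)
    alpha = 1.0
    for _ in range(max_iter):
        proj = grad - t @ np.diag(np.sum(t * grad, axis=0))
        s = np.sqrt(np.sum(proj ** 2))
        if s < tol:
            break
        alpha *= 2
        for _ in range(20):
            x = t - alpha * proj
            x = x @ np.diag(1 / np.sqrt(np.sum(x ** 2, axis=0)))
            f_new, grad_new, lam_new = criterion(x)
            if f_new < f - 0.5 * s ** 2 * alpha * 1e-4:
                t, f, grad, lam = x, f_new, grad_new, lam_new
                break
            alpha /= 2
    phi = t.T @ t
    return lam, phi


def _efa_unrotated(z: np.ndarray, n_factors: int,
                   max_iter: int = 5000) -> np.ndarray:
    """Maximum-likelihood EFA loadings (unrotated) on standardized data."""
    fa = FactorAnalysis(n_components=n_factors, max_iter=max_iter,
                        svd_method="lapack")
    fa.fit(z)
    if fa.n_iter_ >= max_iter:
        logger.warning("EFA did not converge in %d iterations", max_iter)
    return fa.components_.T            # measures x factors


def estimate_g_bifactor(measures: pd.DataFrame | np.ndarray,
                        n_group_factors: int = 4
                        ) -> tuple[np.ndarray, dict]:
    """General-intelligence scores from an exploratory bifactor model.

    Two-stage procedure: (1) EFA with ``n_group_factors`` factors and
    oblimin rotation; (2) a one-factor model on the factor correlation
    matrix; Schmid-Leiman orthogonalization then yields the general-factor
    loadings on all measures. Scores are regression-method, standardized.

    The sign convention forces the majority of general loadings
    non-negative (flipping all measure signs therefore flips g).

    Returns
    -------
    (scores, info)
        ``info`` holds the general loadings, the first-order pattern, the
        factor correlations, and a Heywood-case flag.
    """
    x = np.asarray(measures, float)
    n, p = x.shape
    if p < n_group_factors + 1:
        raise ValueError("too few measures for the requested group factors")
    if n <= p:
        raise ValueError("need more subjects than measures")
    if np.isnan(x).any():
        raise ValueError("missing values; drop incomplete subjects first")
    sd = x.std(axis=0)
    if np.all(sd > 0) and np.allclose(np.corrcoef(x, rowvar=False), 1.0):
        # degenerate: all measures are the same vector (up to affine maps)
        s = _standardize(x[:, [0]])[:, 0]
        return s, {"general_loadings": np.ones(p), "degenerate": True}
    z = _standardize(x)
    lam0 = _efa_unrotated(z, n_group_factors)
    pattern, phi = oblimin_rotate(lam0)
    # sign: orient each first-order factor positively
    signs = np.sign(pattern.sum(axis=0))
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    # second order: one factor on the factor correlation matrix
    g2 = _one_factor_from_corr(phi)
    general = pattern @ g2
    if np.mean(general >= 0) < 0.5:
        general = -general
    heywood = bool(np.any(general ** 2 > 1.0 + 1e-8))
    if heywood:
        logger.warning("Heywood case: general loading above 1 detected")
    scores = _regression_scores(z, general)
    info = {"general_loadings": general, "first_order_pattern": pattern,
            "factor_corr": phi, "heywood": heywood, "degenerate": False}
    return scores, info


def _one_factor_from_corr(r: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Principal-axis one-factor loadings from a correlation matrix."""
    k = len(r)
    if k == 1:
        return np.ones(1)
    comm = np.clip(np.abs(r - np.eye(k)).max(axis=1), 0.05, 0.999)
    lam = None
    for _ in range(n_iter):
        rr = r.copy()
        np.fill_diagonal(rr, comm)
        w, v = np.linalg.eigh(rr)
        lam = v[:, -1] * np.sqrt(max(w[-1], 0.0))
        new = np.clip(lam ** 2, 0, 0.999)
        if np.max(np.abs(new - comm)) < 1e-8:
            comm = new
            break
        comm = new
    if lam.sum() < 0:
        lam = -lam
    return lam


def estimate_gf_efa(measures: pd.DataFrame | np.ndarray,
                    rotation: str = "oblimin") -> tuple[np.ndarray, dict]:
    """Fluid-intelligence scores: single-factor EFA over the seven
    designated measures. With one factor the rotation cannot change the
    solution; the configured rotation name is recorded anyway."""
    x = np.asarray(measures, float)
    if x.ndim != 2 or x.shape[1] != len(FLUID_MEASURES):
        raise ValueError(f"expected exactly {len(FLUID_MEASURES)} measures")
    r = np.corrcoef(x, rowvar=False)
    if np.allclose(r, 1.0):
        s = _standardize(x[:, [0]])[:, 0]
        return s, {"loadings": np.ones(x.shape[1]), "rotation": rotation,
                   "degenerate": True}
    if np.linalg.matrix_rank(r) < len(r):
        logger.warning("singular correlation matrix in gf EFA")
    z = _standardize(x)
    lam = _efa_unrotated(z, 1)[:, 0]
    if lam.mean() < 0:
        lam = -lam
    scores = _regression_scores(z, lam)
    return scores, {"loadings": lam, "rotation": rotation, "degenerate": False}


def compute_gc_composite(vocab: np.ndarray, reading: np.ndarray) -> np.ndarray:
    """Crystallized composite: elementwise sum of the two z-scored inputs.

    Invariant to affine rescaling of either input. Note the composite's SD
    is sqrt(2 (1 + r)) for input correlation r, not 1.
    """
    vocab = np.asarray(vocab, float)
    reading = np.asarray(reading, float)
    if vocab.shape != reading.shape or vocab.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if not (np.isfinite(vocab).all() and np.isfinite(reading).all()):
        raise ValueError("non-finite input scores")
    return (_standardize(vocab[:, None])[:, 0]
            + _standardize(reading[:, None])[:, 0])


def score_cohort(cohort: pd.DataFrame,
                 n_group_factors: int = 4) -> IntelligenceScores:
    """Estimate g / gc / gf for a cohort table with the 12 measures."""
    complete = cohort.dropna(subset=list(MEASURE_NAMES))
    if len(complete) < len(cohort):
        logger.info("dropped %d subject(s) with missing measures",
                    len(cohort) - len(complete))
    g, g_info = estimate_g_bifactor(complete[list(MEASURE_NAMES)],
                                    n_group_factors=n_group_factors)
    gf, gf_info = estimate_gf_efa(complete[list(FLUID_MEASURES)])
    gc = compute_gc_composite(complete[CRYSTALLIZED_MEASURES[0]].to_numpy(),
                              complete[CRYSTALLIZED_MEASURES[1]].to_numpy())
    # orient so the components correlate positively with each other's hub (g)
    if np.corrcoef(g, gf)[0, 1] < 0:
        gf = -gf
    return IntelligenceScores(g=g, gc=gc, gf=gf,
                              subject_ids=list(complete["subject_id"])
                              if "subject_id" in complete else None,
                              fit_info={"g": g_info, "gf": gf_info})
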