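"""Ensemble habitat-suitability modelling.

Presence-background ensemble with AUC-weighted model averaging: candidate
algorithms are scored by cross-validated AUC (4 random folds of presences and
of 2000 background points, repeated 5 times), the 10 best of 12 candidates
are retained, and the ensemble suitability is their AUC-weighted average,
itself averaged over the 5 calibration repeats.  Two presence thresholds are
derived from the final suitability surface: the minimum presence score and
the score retaining a 0.90 true positive rate.  Collinear predictors are
pruned beforehand by stepwise variance-inflation-factor elimination, and
future projections can be screened for novel climate (cells outside the
current min-max range of any predictor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grid import GridLayer, GridSpec

logger = logging.getLogger(__name__)

#: Minimum number of unique presence cells for a species to be modelled.
MIN_UNIQUE_OBSERVATIONS = 30

DEFAULT_N_BACKGROUND = 2000
DEFAULT_N_FOLDS = 4
DEFAULT_N_REPEATS = 5
DEFAULT_VIF_THRESHOLD = 20.0
N_KEPT_SUBMODELS = 10


class SpeciesRejected(ValueError):
    """Raised when a species fails the minimum-unique-observations rule."""


# ---------------------------------------------------------------------------
# Candidate submodels
# ---------------------------------------------------------------------------

class _SklearnCandidate:
    """Wraps a scikit-learn classifier into the fit/score suitability contract."""

    def __init__(self, factory):
        self._factory = factory
        self._model = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self._model = self._factory()
        self._model.fit(X, y)

    def score(self, X: np.ndarray) -> np.ndarray:
        proba = self._model.predict_proba(X)
        pos = list(self._model.classes_).index(1)
        return proba[:, pos]


class _BioclimEnvelope:
    """Rectilinear climate envelope: suitability from per-variable percentile
    depth of a point within the presence sample (BIOCLIM-style)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        self._pres = X[y == 1]

    def score(self, X: np.ndarray) -> np.ndarray:
        scores = np.ones(len(X))
        for j in range(X.shape[1]):
            ref = self._pres[:, j]
            # fraction of presence values at or below x, folded so the median
            # scores 1 and values outside the presence range score 0
            frac = np.searchsorted(np.sort(ref), X[:, j], side="right") / len(ref)
            depth = 1.0 - 2.0 * np.abs(frac - 0.5)
            outside = (X[:, j] < ref.min()) | (X[:, j] > ref.max())
            depth[outside] = 0.0
            scores = np.minimum(scores, depth)
        return scores


class _MahalanobisEnvelope:
    """Suitability from Mahalanobis distance to the presence centroid."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        pres = X[y == 1]
        self._mean = pres.mean(axis=0)
        cov = np.cov(pres, rowvar=False)
        cov = np.atleast_2d(cov) + 1e-6 * np.eye(X.shape[1])
        self._icov = np.linalg.inv(cov)

    def score(self, X: np.ndarray) -> np.ndarray:
        d = X - self._mean
        d2 = np.einsum("ij,jk,ik->i", d, self._icov, d)
        return np.exp(-0.5 * d2 / X.shape[1])


def _logistic(**kw):
    return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000, **kw))


def default_candidates() -> dict[str, callable]:
    """The registry of 12 candidate submodel factories, in rank-tie order."""
    return {
        "glm_linear": lambda: _SklearnCandidate(_logistic),
        "glm_quadratic": lambda: _SklearnCandidate(
            lambda: make_pipeline(
                StandardScaler(),
                PolynomialFeatures(degree=2, include_bias=False),
                LogisticRegression(max_iter=1000),
            )
        ),
        "gam_spline": lambda: _SklearnCandidate(
            lambda: make_pipeline(
                StandardScaler(),
                SplineTransformer(n_knots=5, degree=3),
                LogisticRegression(max_iter=1000),
            )
        ),
        "tree": lambda: _SklearnCandidate(
            lambda: DecisionTreeClassifier(max_depth=6, random_state=0)
        ),
        "random_forest": lambda: _SklearnCandidate(
            lambda: RandomForestClassifier(
                n_estimators=100, min_samples_leaf=2, random_state=0, n_jobs=1
            )
        ),
        "gbm": lambda: _SklearnCandidate(
            lambda: GradientBoostingClassifier(
                n_estimators=100, max_depth=3, random_state=0
            )
        ),
        "knn": lambda: _SklearnCandidate(
            lambda: make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=15))
        ),
        "naive_bayes": lambda: _SklearnCandidate(GaussianNB),
        "bioclim_envelope": _BioclimEnvelope,
        "mahalanobis": _MahalanobisEnvelope,
        "fda": lambda: _SklearnCandidate(
            lambda: make_pipeline(
                StandardScaler(),
                PolynomialFeatures(degree=2, include_bias=False),
                QuadraticDiscriminantAnalysis(reg_param=0.1),
            )
        ),
        "neural_net": lambda: _SklearnCandidate(
            lambda: make_pipeline(
                StandardScaler(),
                MLPClassifier(
                    hidden_layer_sizes=(8,), max_iter=500, random_state=0,
                    alpha=1e-2,
                ),
            )
        ),
    }


# ---------------------------------------------------------------------------
# Variable selection
# ---------------------------------------------------------------------------

def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_k = 1/(1 - R^2) of column k regressed (with intercept) on the rest."""
    n, p = X.shape
    vifs = np.empty(p)
    for k in range(p):
        y = X[:, k]
        others = np.delete(X, k, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            vifs[k] = np.inf
            continue
        r2 = 1.0 - resid @ resid / ss_tot
        vifs[k] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vifs


def vif_stepwise(
    env: dict[str, GridLayer], threshold: float = DEFAULT_VIF_THRESHOLD
) -> list[str]:
    """Stepwise collinearity pruning: repeatedly drop the variable with the
    largest VIF while that VIF exceeds the threshold.

    Returns the retained variable names (in their original order); all
    retained variables have VIF <= threshold.
    """
    names = list(env)
    if len(names) < 2:
        raise ValueError("need at least two variables")
    mask = np.logical_and.reduce([env[n].mask for n in names])
    X = np.column_stack([env[n].values[mask] for n in names])
    if X.shape[0] < len(names) + 2:
        raise ValueError("too few masked cells for VIF regression")
    keep = list(range(len(names)))
    while len(keep) >= 2:
        vifs = _vif_values(X[:, keep])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        dropped = names[keep[worst]]
        logger.info("vif_stepwise: dropping %s (VIF=%.3g)", dropped, vifs[worst])
        del keep[worst]
    return [names[k] for k in keep]


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 * P(pos = neg)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("auc requires non-empty score lists")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """A calibrated ensemble: retained variables, per-candidate mean test
    AUCs, the kept candidates' normalized weights, the final averaged
    suitability surface and the two presence thresholds."""

    retained_variables: list[str]
    candidate_aucs: dict[str, float]
    weights: dict[str, float]
    suitability: GridLayer
    threshold_min: float
    threshold_tpr90: float
    presence_rows: np.ndarray = field(repr=False, default=None)
    presence_cols: np.ndarray = field(repr=False, default=None)
    fitted_repeats: list = field(repr=False, default_factory=list)

    def report(self) -> pd.DataFrame:
        """Per-candidate calibration report (mean AUC and ensemble weight)."""
        return pd.DataFrame(
            {
                "candidate": list(self.candidate_aucs),
                "mean_auc": [self.candidate_aucs[c] for c in self.candidate_aucs],
                "weight": [self.weights.get(c, 0.0) for c in self.candidate_aucs],
            }
        )


def occurrences_to_cells(
    presences: pd.DataFrame, spec: GridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Unique (row, col) grid cells of occurrence records; points outside the
    grid are dropped."""
    cols = np.floor((presences["lon"].to_numpy() - spec.origin_lon) / spec.cell_size)
    rows = np.floor((spec.origin_lat - presences["lat"].to_numpy()) / spec.cell_size)
    ok = (cols >= 0) & (cols < spec.n_cols) & (rows >= 0) & (rows < spec.n_rows)
    cells = np.unique(
        np.stack([rows[ok].astype(int), cols[ok].astype(int)], axis=1), axis=0
    )
    return cells[:, 0], cells[:, 1]


def _env_matrix(env: dict[str, GridLayer], variables: list[str], rows, cols) -> np.ndarray:
    return np.column_stack([env[v].values[rows, cols] for v in variables])


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.arange(n) % n_folds
    rng.shuffle(folds)
    return folds


def calibrate_ensemble(
    presences: pd.DataFrame,
    env: dict[str, GridLayer],
    variables: list[str] | None = None,
    *,
    n_background: int = DEFAULT_N_BACKGROUND,
    n_folds: int = DEFAULT_N_FOLDS,
    n_repeats: int = DEFAULT_N_REPEATS,
    n_kept: int = N_KEPT_SUBMODELS,
    min_unique_obs: int = MIN_UNIQUE_OBSERVATIONS,
    candidates: dict | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Calibrate the AUC-weighted ensemble on presence records.

    Per repeat: draw background cells (without replacement, excluding
    presence cells), split presences and backgrounds into ``n_folds`` random
    subsets, fit every candidate on each training split and score the held
    out fold by AUC.  Candidate AUCs are averaged over folds and repeats; the
    ``n_kept`` best candidates (ties broken by registry order) carry
    AUC-proportional weights.  Each repeat's ensemble surface is the weighted
    average of the kept candidates refit on that repeat's full data, and the
    final suitability is the mean surface over repeats, from which both
    presence thresholds are taken.
    """
    candidates = default_candidates() if candidates is None else candidates
    spec = next(iter(env.values())).spec
    variables = list(env) if variables is None else list(variables)
    missing = [v for v in variables if v not in env]
    if missing:
        raise KeyError(f"environment stack lacks variable(s): {missing}")

    p_rows, p_cols = occurrences_to_cells(presences, spec)
    n_pres = p_rows.size
    if n_pres < min_unique_obs:
        raise SpeciesRejected(
            f"only {n_pres} unique presence cells; the species-selection rule "
            f"requires a minimum of {min_unique_obs} unique observations"
        )

    mask = np.logical_and.reduce([env[v].mask for v in variables])
    grid_rows, grid_cols = np.nonzero(mask)
    presence_flat = set(zip(p_rows.tolist(), p_cols.tolist()))
    bg_pool = np.array(
        [i for i, rc in enumerate(zip(grid_rows.tolist(), grid_cols.tolist()))
         if rc not in presence_flat]
    )

    X_pres = _env_matrix(env, variables, p_rows, p_cols)
    X_grid = _env_matrix(env, variables, grid_rows, grid_cols)

    rng = np.random.default_rng(seed)
    names = list(candidates)
    auc_sums = {c: 0.0 for c in names}
    auc_counts = {c: 0 for c in names}
    repeat_state = []  # per-repeat candidate scores on the masked grid
    fitted_repeats = []  # per-repeat fitted candidate objects

    for _rep in range(n_repeats):
        take = min(n_background, bg_pool.size)
        bg_idx = rng.choice(bg_pool, size=take, replace=False)
        X_bg = X_grid[bg_idx]

        pres_folds = _fold_indices(n_pres, n_folds, rng)
        bg_folds = _fold_indices(take, n_folds, rng)

        for fold in range(n_folds):
            X_tr = np.vstack([X_pres[pres_folds != fold], X_bg[bg_folds != fold]])
            y_tr = np.concatenate(
                [np.ones((pres_folds != fold).sum()), np.zeros((bg_folds != fold).sum())]
            )
            X_te_pos = X_pres[pres_folds == fold]
            X_te_neg = X_bg[bg_folds == fold]
            for cname in names:
                try:
                    model = candidates[cname]()
                    model.fit(X_tr, y_tr)
                    a = auc(model.score(X_te_pos), model.score(X_te_neg))
                except Exception as exc:  # candidate failure -> AUC 0
                    logger.warning("candidate %s failed in CV: %s", cname, exc)
                    a = 0.0
                auc_sums[cname] += a
                auc_counts[cname] += 1

        # Full fit for this repeat's ensemble surface; the fitted candidates
        # are retained so the ensemble can be projected onto future stacks.
        X_full = np.vstack([X_pres, X_bg])
        y_full = np.concatenate([np.ones(n_pres), np.zeros(take)])
        grid_scores = {}
        fitted = {}
        for cname in names:
            try:
                model = candidates[cname]()
                model.fit(X_full, y_full)
                grid_scores[cname] = np.clip(model.score(X_grid), 0.0, 1.0)
                fitted[cname] = model
            except Exception as exc:
                logger.warning("candidate %s failed in full fit: %s", cname, exc)
        repeat_state.append(grid_scores)
        fitted_repeats.append(fitted)

    mean_aucs = {
        c: (auc_sums[c] / auc_counts[c]) if auc_counts[c] else 0.0 for c in names
    }
    # Rank by mean AUC, ties (and the cut at the n_kept-th rank) broken by
    # registry order; failed candidates (AUC 0 and no surface) cannot enter.
    usable = [c for c in names if all(c in st for st in repeat_state) and mean_aucs[c] > 0]
    ranked = sorted(usable, key=lambda c: (-mean_aucs[c], names.index(c)))
    kept = ranked[:n_kept]
    if len(kept) < n_kept:
        logger.warning(
            "only %d of %d candidates usable; weights renormalized over survivors",
            len(kept), len(names),
        )
    total = sum(mean_aucs[c] for c in kept)
    weights = {c: mean_aucs[c] / total for c in kept}

    surfaces = []
    for st in repeat_state:
        ens = np.zeros(X_grid.shape[0])
        for c in kept:
            ens += weights[c] * st[c]
        surfaces.append(ens)
    final = np.mean(surfaces, axis=0)

    suit_vals = np.zeros(spec.shape)
    suit_vals[grid_rows, grid_cols] = final
    suitability = GridLayer(spec, suit_vals, mask)

    pres_scores = suitability.values[p_rows, p_cols]
    t_min = threshold_min_scores(pres_scores)
    t_90 = threshold_tpr90_scores(pres_scores)

    return EnsembleModel(
        retained_variables=variables,
        candidate_aucs=mean_aucs,
        weights=weights,
        suitability=suitability,
        threshold_min=t_min,
        threshold_tpr90=t_90,
        presence_rows=p_rows,
        presence_cols=p_cols,
        fitted_repeats=fitted_repeats,
    )


# ---------------------------------------------------------------------------
# Thresholds and prediction
# ---------------------------------------------------------------------------

def threshold_min_scores(pres_scores: np.ndarray) -> float:
    """Minimum predicted suitability over presence cells."""
    pres_scores = np.asarray(pres_scores, dtype=float)
    if pres_scores.size == 0:
        raise ValueError("need at least one presence score")
    return float(pres_scores.min())


def threshold_tpr90_scores(pres_scores: np.ndarray, tpr: float = 0.90) -> float:
    """Largest threshold t with fraction(presence scores >= t) >= tpr."""
    pres_scores = np.asarray(pres_scores, dtype=float)
    if pres_scores.size == 0:
        raise ValueError("need at least one presence score")
    candidates = np.unique(pres_scores)
    ok = [t for t in candidates if (pres_scores >= t).mean() >= tpr]
    return float(max(ok))


def threshold_min(suitability: GridLayer, presences: pd.DataFrame) -> float:
    rows, cols = occurrences_to_cells(presences, suitability.spec)
    return threshold_min_scores(suitability.values[rows, cols])


def threshold_tpr90(suitability: GridLayer, presences: pd.DataFrame) -> float:
    rows, cols = occurrences_to_cells(presences, suitability.spec)
    return threshold_tpr90_scores(suitability.values[rows, cols])


def project_suitability(model: EnsembleModel, env: dict[str, GridLayer]) -> GridLayer:
    """Project the calibrated ensemble onto a (possibly future) climate stack.

    Scores every valid cell of *env* with each repeat's fitted kept
    candidates, applies the stored AUC weights and averages over repeats.
    """
    missing = [v for v in model.retained_variables if v not in env]
    if missing:
        raise KeyError(f"environment stack lacks variable(s): {missing}")
    spec = env[model.retained_variables[0]].spec
    mask = np.logical_and.reduce([env[v].mask for v in model.retained_variables])
    rows, cols = np.nonzero(mask)
    X = _env_matrix(env, model.retained_variables, rows, cols)
    surfaces = []
    for fitted in model.fitted_repeats:
        ens = np.zeros(X.shape[0])
        for cname, w in model.weights.items():
            ens += w * np.clip(fitted[cname].score(X), 0.0, 1.0)
        surfaces.append(ens)
    vals = np.zeros(spec.shape)
    vals[rows, cols] = np.mean(surfaces, axis=0)
    return GridLayer(spec, vals, mask)


def predict_presence(
    model: EnsembleModel,
    env: dict[str, GridLayer] | None = None,
    which_threshold: str = "minimum",
) -> GridLayer:
    """Boolean presence layer (0/1 values) on any scenario's climate stack.

    ``which_threshold`` selects ``"minimum"`` (every training presence
    retained) or ``"tpr90"`` (90% of training presences retained).  With no
    *env*, the calibration suitability surface is thresholded directly.
    """
    if which_threshold == "minimum":
        t = model.threshold_min
    elif which_threshold == "tpr90":
        t = model.threshold_tpr90
    else:
        raise ValueError(f"unknown threshold {which_threshold!r}")
    suit = model.suitability if env is None else project_suitability(model, env)
    vals = (suit.values >= t) & suit.mask
    return GridLayer(suit.spec, vals.astype(float), suit.mask.copy())


def detect_novel(
    current: dict[str, GridLayer],
    future: dict[str, GridLayer],
    variables: list[str],
    reference_mask: np.ndarray | None = None,
) -> GridLayer:
    """Cells whose future climate leaves the current min-max envelope.

    A cell is novel iff at least one variable's future value falls strictly
    outside the closed [min, max] range of current values over the reference
    mask (default: the full valid extent).
    """
    first = current[variables[0]]
    spec = first.spec
    if reference_mask is None:
        reference_mask = np.logical_and.reduce([current[v].mask for v in variables])
    novel = np.zeros(spec.shape, dtype=bool)
    out_mask = np.logical_and.reduce([future[v].mask for v in variables])
    for v in variables:
        if future[v].spec != spec:
            raise ValueError("current and future stacks must share one grid")
        ref = current[v].values[reference_mask]
        lo, hi = ref.min(), ref.max()
        novel |= (future[v].values < lo) | (future[v].values > hi)
    return GridLayer(spec, (novel & out_mask).astype(float), out_mask)
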