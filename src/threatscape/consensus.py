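"""Cultural-consensus analysis of expert survey ratings.

Experts rate a block of items (candidate distribution maps, or a species'
sensitivity to each threat) on a 1-5 scale.  Inter-expert agreement is
measured by pairwise Spearman correlation; a one-factor maximum-likelihood
factor analysis of the correlation matrix yields each expert's loading on
the shared consensus factor, which is used as that expert's competence
weight.  Item scores are then competence-weighted means of the ratings, and
the mean weight over valid experts is reported as the panel's average
concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

MIN_OVERLAP = 2  # rated items two experts must share for a correlation


@dataclass
class ConsensusResult:
    weights: pd.Series            # competence weight per valid expert, in [0, 1]
    scores: pd.Series             # weighted score per item, in [1, 5] (NaN if undefined)
    average_concordance: float    # mean weight over valid experts
    consensus_rate: float         # first-factor share of variance
    n_valid_experts: int
    flagged_experts: list[str]    # dropped or zero-variance experts

    def select_best(self) -> str:
        return select_best(self.scores)


def spearman_matrix(ratings: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations between experts (rows).

    Pairs sharing fewer than two rated items, and any expert whose usable
    ratings have zero variance, yield missing entries.
    """
    experts = ratings.index
    n = len(experts)
    corr = np.full((n, n), np.nan)
    values = ratings.to_numpy(dtype=float)
    for i in range(n):
        corr[i, i] = 1.0
        for j in range(i + 1, n):
            both = np.isfinite(values[i]) & np.isfinite(values[j])
            if both.sum() < MIN_OVERLAP:
                continue
            xi, xj = values[i, both], values[j, both]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue  # zero-variance: correlation undefined
            rho = spearmanr(xi, xj).statistic
            corr[i, j] = corr[j, i] = rho
    return pd.DataFrame(corr, index=experts, columns=experts)


def _one_factor_ml(R: np.ndarray) -> tuple[np.ndarray, bool]:
    """One-factor ML factor analysis of a correlation matrix.

    Model: R = lambda lambda' + diag(1 - lambda^2).  Returns the loading
    vector and a convergence flag.  Minimizes the standard ML discrepancy
    log|Sigma| + tr(R Sigma^-1) - log|R| - p over loadings in (-1, 1).
    """
    p = R.shape[0]
    eigval, eigvec = np.linalg.eigh(R)
    v = eigvec[:, -1] * np.sqrt(max(eigval[-1], 0.0))
    start = np.clip(v if v.sum() >= 0 else -v, -0.99, 0.99)

    sign, logdet_r = np.linalg.slogdet(R)
    if sign <= 0:
        return start, False

    def discrepancy(lam: np.ndarray) -> float:
        psi = np.clip(1.0 - lam**2, 1e-6, None)
        sigma = np.outer(lam, lam) + np.diag(psi)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        inv = np.linalg.inv(sigma)
        return logdet + np.trace(R @ inv) - logdet_r - p

    res = optimize.minimize(
        discrepancy, start, method="L-BFGS-B",
        bounds=[(-0.999, 0.999)] * p,
    )
    lam = res.x if res.success else start
    if lam.sum() < 0:
        lam = -lam
    return lam, bool(res.success)


def _principal_loadings(R: np.ndarray) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(R)
    v = eigvec[:, -1]
    if v.sum() < 0:
        v = -v
    v = v * np.sqrt(max(eigval[-1], 0.0))
    return np.clip(v, 0.0, 1.0)


def competence_weights(corr: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-expert competence weights from the correlation matrix.

    Weights are the experts' loadings on the single common factor fitted by
    maximum likelihood (negative loadings floored at 0); missing entries are
    imputed with the mean of the two experts' available correlations.  Falls
    back to principal-eigenvector loadings on non-convergence, and to mean
    correlation with others when fewer than three experts are available.
    Also returns the first factor's share of variance (the consensus rate).
    """
    experts = corr.index
    R = corr.to_numpy(dtype=float).copy()
    n = len(experts)

    if n < 3:
        off = R.copy()
        np.fill_diagonal(off, np.nan)
        w = np.nanmean(off, axis=1)
        w = np.clip(np.nan_to_num(w), 0.0, 1.0)
        rate = float(np.nanmean(off)) if np.isfinite(np.nanmean(off)) else 0.0
        return pd.Series(w, index=experts), max(rate, 0.0)

    # Impute missing off-diagonal entries with the mean of the two experts'
    # available off-diagonal correlations.
    off = R.copy()
    np.fill_diagonal(off, np.nan)
    row_mean = np.array([
        np.nanmean(row) if np.isfinite(row).any() else 0.0 for row in off
    ])
    for i in range(n):
        for j in range(n):
            if i != j and not np.isfinite(R[i, j]):
                R[i, j] = 0.5 * (row_mean[i] + row_mean[j])
    np.fill_diagonal(R, 1.0)

    lam, converged = _one_factor_ml(R)
    if not converged:
        logger.warning("one-factor ML did not converge; using principal loadings")
        lam = _principal_loadings(R)
    weights = np.clip(lam, 0.0, 1.0)
    rate = float((lam**2).sum() / n)
    return pd.Series(weights, index=experts), min(max(rate, 0.0), 1.0)


def weighted_scores(ratings: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Competence-weighted mean rating per item, over experts who rated it.

    Items rated only by zero-weight experts get NaN and are flagged.
    """
    w = weights.reindex(ratings.index).fillna(0.0).to_numpy()
    vals = ratings.to_numpy(dtype=float)
    scores = np.full(ratings.shape[1], np.nan)
    for j in range(ratings.shape[1]):
        rated = np.isfinite(vals[:, j])
        denom = w[rated].sum()
        if denom > 0:
            scores[j] = (w[rated] * vals[rated, j]).sum() / denom
        else:
            logger.warning(
                "item %s rated only by zero-weight experts; score undefined",
                ratings.columns[j],
            )
    return pd.Series(scores, index=ratings.columns)


def select_best(scores: pd.Series) -> str:
    """Item with the highest weighted score; ties go to the lowest index."""
    defined = scores.dropna()
    if defined.empty:
        raise ValueError("no defined scores to select from")
    best = defined.max()
    winners = defined.index[defined == best]
    if len(winners) > 1:
        logger.warning("tie for best item among %s; keeping %s", list(winners), winners[0])
    return winners[0]


def analyze_panel(ratings: pd.DataFrame, min_items: int = MIN_OVERLAP) -> ConsensusResult:
    """Full consensus analysis of one survey block.

    Experts with fewer than ``min_items`` usable ratings are dropped before
    the correlation step and excluded from the valid-expert count.
    """
    usable = ratings.notna().sum(axis=1) >= min_items
    dropped = list(ratings.index[~usable])
    panel = ratings.loc[usable]
    if panel.shape[0] < 2:
        raise ValueError("need at least two experts with usable ratings")

    corr = spearman_matrix(panel)
    off = corr.to_numpy().copy()
    np.fill_diagonal(off, np.nan)
    zero_var = [e for k, e in enumerate(panel.index) if not np.isfinite(off[k]).any()]
    if zero_var:
        logger.warning("experts with undefined correlations flagged: %s", zero_var)

    weights, rate = competence_weights(corr)
    scores = weighted_scores(panel, weights)
    valid = [e for e in panel.index if e not in zero_var]
    avg = float(weights.loc[valid].mean()) if valid else 0.0
    return ConsensusResult(
        weights=weights,
        scores=scores,
        average_concordance=avg,
        consensus_rate=rate,
        n_valid_experts=len(valid),
        flagged_experts=dropped + zero_var,
    )


def normalize_sensitivity(score: float, mode: str = "affine") -> float:
    """Map a 1-5 weighted sensitivity score onto [0, 1].

    ``affine``: (S - 1) / 4 (default, maps the printed scale ends to 0 and 1);
    ``ratio``: S / 5.
    """
    if mode == "affine":
        return (score - 1.0) / 4.0
    if mode == "ratio":
        return score / 5.0
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize_sensitivities(scores: pd.Series, mode: str = "affine") -> pd.Series:
    """Vector version; the extra ``minmax`` mode rescales the given score set
    to span [0, 1] (degenerate sets map to 0)."""
    if mode == "minmax":
        lo, hi = scores.min(), scores.max()
        if hi == lo:
            return scores * 0.0
        return (scores - lo) / (hi - lo)
    return scores.apply(lambda s: normalize_sensitivity(s, mode))
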