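"""Marker importance, minimal marker count, and noise-ablation analysis.

SVM-RFE ranks the nine viscoelastic markers by the kernel-space margin
criterion ``W^2 = sum_ij a_i a_j y_i y_j kappa(x_i, x_j)``: at each round
the feature whose removal (zeroing in z-scored space) changes ``W^2``
least is eliminated; reversing the elimination order yields the ranking.
Multi-class tasks sum the criterion over one-vs-one subproblems.

Feature ablation replaces markers cumulatively with standard-normal noise
(in z-scored space) in a given importance order, retraining the classifier
at every step, so each curve point isolates the information lost with the
replaced markers rather than a train/test distribution shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .classify import (
    _sigma_to_gamma,
    cross_validate,
    evaluate,
    split_train_test,
    train_classifier,
)

__all__ = [
    "AblationReport",
    "rfe_rank",
    "optimal_marker_count",
    "ablate_features",
    "ablation_report",
]


@dataclass(frozen=True)
class AblationReport:
    ranking: list[str]  # most to least important
    normalized_importance: dict[str, float]  # max = 1
    curve_high_to_low: np.ndarray  # length n_features + 1, baseline first
    curve_low_to_high: np.ndarray
    optimal_k: int
    accuracy_vs_k: np.ndarray


def _w2(sv: np.ndarray, coef: np.ndarray, gamma: float) -> float:
    sq = np.sum(sv**2, axis=1)
    k = np.exp(-gamma * (sq[:, None] + sq[None, :] - 2.0 * sv @ sv.T))
    return float(coef @ k @ coef)


def _margin_drop(x: np.ndarray, y: np.ndarray, C: float, gamma: float) -> np.ndarray:
    """|W^2(full) - W^2(feature zeroed)| for every feature of x.

    W^2 = sum_ij a_i a_j y_i y_j kappa(x_i, x_j), summed over one-vs-one
    subproblems; the dual coefficients of the full model are kept fixed
    while each (z-scored) feature is zeroed in turn — the standard
    sensitivity used by nonlinear SVM-RFE.
    """
    drops = np.zeros(x.shape[1])
    for ca, cb in combinations(np.unique(y), 2):
        m = (y == ca) | (y == cb)
        svc = SVC(C=C, kernel="rbf", gamma=gamma)
        svc.fit(x[m], y[m])
        sv = x[m][svc.support_]
        coef = svc.dual_coef_[0]  # a_i y_i
        base = _w2(sv, coef, gamma)
        for col in range(x.shape[1]):
            sv_z = sv.copy()
            sv_z[:, col] = 0.0
            drops[col] += abs(base - _w2(sv_z, coef, gamma))
    return drops


def rfe_rank(
    table: pd.DataFrame,
    features: list[str],
    C: float = 10.0,
    sigma: float = 2.0,
) -> tuple[list[str], dict[str, float]]:
    """SVM-RFE ranking and normalized importance of the given markers.

    Importance of a marker is the margin change ``|Delta W^2|`` recorded at
    its elimination round, normalized so the top marker scores exactly 1.
    """
    if len(features) == 1:
        return list(features), {features[0]: 1.0}
    x_full = table[list(features)].to_numpy(dtype=float)
    x_full = (x_full - x_full.mean(0)) / np.where(x_full.std(0) == 0, 1, x_full.std(0))
    y = table["status"].to_numpy()
    gamma = _sigma_to_gamma(sigma)

    remaining = list(range(len(features)))
    eliminated: list[tuple[int, float]] = []
    survivor_drop = 1.0
    while len(remaining) > 1:
        drops = _margin_drop(x_full[:, remaining], y, C, gamma)
        weakest = int(np.argmin(drops))
        strongest = int(np.argmax(drops))
        survivor_drop = float(drops[strongest])  # survivor's drop, last round
        eliminated.append((remaining[weakest], float(drops[weakest])))
        remaining.pop(weakest)
    eliminated.append((remaining[0], survivor_drop))
    order = [idx for idx, _ in reversed(eliminated)]
    drops = {idx: d for idx, d in eliminated}
    max_drop = max(drops.values()) or 1.0
    ranking = [features[i] for i in order]
    importance = {features[i]: drops[i] / max_drop for i in order}
    return ranking, importance


def optimal_marker_count(
    table: pd.DataFrame,
    ranking: list[str] | None = None,
    k_folds: int = 10,
    C: float = 10.0,
    sigma: float = 2.0,
    seed: int = 0,
    plateau_tol: float = 0.005,
) -> tuple[int, np.ndarray]:
    """Cross-validated accuracy of the top-m ranked markers, m = 1..len.

    Returns the smallest m whose k-fold accuracy is within ``plateau_tol``
    of the maximum, together with the full accuracy-vs-m series.
    """
    from .extraction import MARKERS

    if ranking is None:
        ranking, _ = rfe_rank(table, MARKERS, C=C, sigma=sigma)
    accs = []
    for m in range(1, len(ranking) + 1):
        _, _, acc, _ = cross_validate(
            table, ranking[:m], k=k_folds, c_grid=(C,), sigma_grid=(sigma,), seed=seed
        )
        accs.append(acc)
    accs = np.array(accs)
    k_star = int(np.argmax(accs >= accs.max() - plateau_tol)) + 1
    return k_star, accs


def ablation_report(
    table: pd.DataFrame,
    k_folds: int = 10,
    seed: int = 0,
    C: float = 10.0,
    sigma: float = 2.0,
) -> AblationReport:
    """Full marker-importance analysis: ranking, optimal count, both curves."""
    train, _ = split_train_test(table, seed=seed)
    ranking, importance = rfe_rank(train, list(train.columns.drop(["status", "measurement_id"], errors="ignore")), C=C, sigma=sigma)
    k_star, acc_vs_k = optimal_marker_count(table, ranking, k_folds=k_folds,
                                            C=C, sigma=sigma, seed=seed)
    return AblationReport(
        ranking=ranking,
        normalized_importance=importance,
        curve_high_to_low=ablate_features(table, ranking, "high_to_low", seed=seed, C=C, sigma=sigma),
        curve_low_to_high=ablate_features(table, ranking, "low_to_high", seed=seed, C=C, sigma=sigma),
        optimal_k=k_star,
        accuracy_vs_k=acc_vs_k,
    )


def ablate_features(
    table: pd.DataFrame,
    ranking: list[str],
    order: str = "high_to_low",
    seed: int = 0,
    C: float = 10.0,
    sigma: float = 2.0,
    train_frac: float = 0.7,
) -> np.ndarray:
    """Accuracy after cumulative Gaussian-noise replacement of markers.

    At step j the first j markers of ``ranking`` (reversed for
    ``low_to_high``) are replaced by fresh N(0, 1) draws in z-scored space
    in both splits and the classifier is retrained; step 0 is the intact
    baseline.  The returned curve has ``len(ranking) + 1`` entries.
    """
    if order not in ("high_to_low", "low_to_high"):
        raise ValueError("order must be 'high_to_low' or 'low_to_high'")
    seq = list(ranking) if order == "high_to_low" else list(reversed(ranking))
    rng = np.random.default_rng(seed)
    train, test = split_train_test(table, train_frac=train_frac, seed=seed)
    accs = []
    for step in range(len(seq) + 1):
        tr = train.copy()
        te = test.copy()
        for feat in seq[:step]:
            mu, sd = tr[feat].mean(), tr[feat].std() or 1.0
            tr[feat] = mu + sd * rng.standard_normal(len(tr))
            te[feat] = mu + sd * rng.standard_normal(len(te))
        clf = train_classifier(tr, list(ranking), C=C, sigma=sigma)
        accs.append(evaluate(clf, te).accuracy)
    return np.array(accs)
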