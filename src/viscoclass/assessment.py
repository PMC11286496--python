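"""Drug-efficacy readout from pairwise classifier accuracies.

A treated group that has moved back toward the healthy state becomes hard
to distinguish from healthy tissue (treated-vs-healthy accuracy near
chance) while remaining easy to distinguish from diseased tissue.  The
recovery index is the gap between the two pairwise test accuracies,
``acc(treated vs diseased) - acc(treated vs healthy)``: near +0.5 for full
recovery, near -0.5 for no effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import (
    DEFAULT_C_GRID,
    DEFAULT_SIGMA_GRID,
    cross_validate,
    evaluate,
    split_train_test,
    train_classifier,
)
from .extraction import MARKERS

__all__ = ["RecoveryReport", "recovery_report", "pairwise_accuracy"]

#: verdict thresholds on the two pairwise accuracies
FULL_RECOVERY_TH = 0.60
NO_RECOVERY_TD = 0.60
CONFUSED_WITH = 0.80


@dataclass(frozen=True)
class RecoveryReport:
    acc_treated_vs_healthy: float
    acc_treated_vs_diseased: float
    recovery_index: float
    verdict: str

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def pairwise_accuracy(
    table: pd.DataFrame,
    status_a: int,
    status_b: int,
    features: list[str] | None = None,
    seed: int = 0,
    tune: bool = True,
    k: int = 10,
) -> float:
    """Test accuracy of a binary classifier between two status groups.

    Standard protocol: stratified 70/30 split, hyperparameters tuned by
    stratified k-fold grid search on the training split when ``tune``.
    """
    features = features or MARKERS
    sub = table[table["status"].isin([status_a, status_b])]
    train, test = split_train_test(sub, seed=seed)
    if tune:
        C, sigma, _, _ = cross_validate(
            train, features, k=k, c_grid=DEFAULT_C_GRID,
            sigma_grid=DEFAULT_SIGMA_GRID, seed=seed,
        )
    else:
        C, sigma = 10.0, 2.0
    clf = train_classifier(train, features, C=C, sigma=sigma)
    return evaluate(clf, test).accuracy


def recovery_report(
    table: pd.DataFrame,
    features: list[str] | None = None,
    seed: int = 0,
    tune: bool = True,
) -> RecoveryReport:
    """Quantify how far the treated group has moved from diseased to healthy.

    Requires all three statuses {0, 1, 2} in the table.  Verdict rules:
    full recovery when the treated group is confusable with healthy
    (acc <= 0.60) yet separable from diseased (acc >= 0.80); no recovery in
    the symmetric case; partial recovery otherwise.
    """
    present = set(table["status"].unique())
    if not {0, 1, 2} <= present:
        raise ValueError(f"need statuses {{0, 1, 2}}, table has {sorted(present)}")
    acc_th = pairwise_accuracy(table, 1, 0, features, seed=seed, tune=tune)
    acc_td = pairwise_accuracy(table, 1, 2, features, seed=seed, tune=tune)
    if acc_th <= FULL_RECOVERY_TH and acc_td >= CONFUSED_WITH:
        verdict = "full_recovery"
    elif acc_td <= NO_RECOVERY_TD and acc_th >= CONFUSED_WITH:
        verdict = "no_recovery"
    else:
        verdict = "partial_recovery"
    return RecoveryReport(
        acc_treated_vs_healthy=acc_th,
        acc_treated_vs_diseased=acc_td,
        recovery_index=acc_td - acc_th,
        verdict=verdict,
    )
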