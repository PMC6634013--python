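"""Diagnostic-accuracy statistics for truth-vs-app comparisons.

The reference standard assigns each recording one of three truths (AF,
flutter, sinus rhythm); the app gives a binary reading (AF / no AF).  The
3x2 contingency table supports two conventions for flutter: excluded from
the accuracy metrics (flutter treated as a standalone category) or counted
as a true negative.  Sensitivity is unaffected by the choice, specificity
and kappa are not.

Sensitivity and specificity carry exact (Clopper-Pearson) binomial
confidence intervals by default, Wilson optionally; Cohen's kappa carries a
large-sample standard-error interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "InvalidLabelError",
    "UndefinedMetricError",
    "ContingencyTable",
    "build_contingency",
    "sensitivity",
    "specificity",
    "cohens_kappa",
    "binomial_ci",
    "af_prevalence",
    "evaluate_corpus",
    "evaluate_matched",
    "TRUTH_LABELS",
    "PREDICTION_LABELS",
]

TRUTH_LABELS = ("af", "aflutter", "sr")
PREDICTION_LABELS = ("app_af", "app_no_af")


class InvalidLabelError(ValueError):
    """Label outside the declared truth/prediction vocabulary."""


class UndefinedMetricError(ValueError):
    """Metric undefined for these counts (empty margin or degenerate table)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of truth (AF / flutter / SR) against the binary app reading."""

    af_app_af: int = 0
    af_app_no_af: int = 0
    aflutter_app_af: int = 0
    aflutter_app_no_af: int = 0
    sr_app_af: int = 0
    sr_app_no_af: int = 0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return (
            self.af_app_af
            + self.af_app_no_af
            + self.aflutter_app_af
            + self.aflutter_app_no_af
            + self.sr_app_af
            + self.sr_app_no_af
        )

    def binary_counts(self, flutter_handling: str = "excluded"):
        """Collapse to (tp, fn, fp, tn) under the given flutter convention."""
        tp, fn = self.af_app_af, self.af_app_no_af
        fp, tn = self.sr_app_af, self.sr_app_no_af
        if flutter_handling == "as_negative":
            fp += self.aflutter_app_af
            tn += self.aflutter_app_no_af
        elif flutter_handling != "excluded":
            raise ValueError("flutter_handling must be 'excluded' or 'as_negative'")
        return tp, fn, fp, tn

    def as_dict(self) -> dict:
        return {
            "af": [self.af_app_af, self.af_app_no_af],
            "aflutter": [self.aflutter_app_af, self.aflutter_app_no_af],
            "sr": [self.sr_app_af, self.sr_app_no_af],
        }


def build_contingency(
    truth_labels: Sequence[str], predictions: Sequence[str]
) -> ContingencyTable:
    """Tally aligned truth/prediction pairs into a contingency table."""
    if len(truth_labels) != len(predictions):
        raise ValueError("truth and prediction sequences differ in length")
    counts = {(t, p): 0 for t in TRUTH_LABELS for p in PREDICTION_LABELS}
    for t, p in zip(truth_labels, predictions):
        if t not in TRUTH_LABELS:
            raise InvalidLabelError(f"unknown truth label {t!r}")
        if p not in PREDICTION_LABELS:
            raise InvalidLabelError(f"unknown prediction label {p!r}")
        counts[(t, p)] += 1
    return ContingencyTable(
        af_app_af=counts[("af", "app_af")],
        af_app_no_af=counts[("af", "app_no_af")],
        aflutter_app_af=counts[("aflutter", "app_af")],
        aflutter_app_no_af=counts[("aflutter", "app_no_af")],
        sr_app_af=counts[("sr", "app_af")],
        sr_app_no_af=counts[("sr", "app_no_af")],
    )


def binomial_ci(
    x: int, n: int, alpha: float = 0.05, method: str = "exact"
) -> tuple[float, float]:
    """Two-sided binomial confidence interval for ``x`` successes in ``n``.

    ``method='exact'`` gives the Clopper-Pearson interval (guaranteed
    coverage at least 1 - alpha); ``'wilson'`` the Wilson score interval.
    """
    if n <= 0 or not (0 <= x <= n):
        raise ValueError("require 0 <= x <= n and n > 0")
    sm_method = {"exact": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError("method must be 'exact' or 'wilson'")
    lo, hi = proportion_confint(x, n, alpha=alpha, method=sm_method)
    return float(lo), float(hi)


def _proportion_with_ci(x: int, n: int, alpha: float, method: str):
    if n == 0:
        raise UndefinedMetricError("empty margin")
    return x / n, binomial_ci(x, n, alpha=alpha, method=method)


def sensitivity(
    table: ContingencyTable,
    flutter_handling: str = "excluded",
    alpha: float = 0.05,
    ci_method: str = "exact",
):
    """True-positive rate TP / (TP + FN) with its binomial CI.

    Identical under both flutter conventions (flutter only contributes to
    the negative margin).
    """
    tp, fn, _, _ = table.binary_counts(flutter_handling)
    return _proportion_with_ci(tp, tp + fn, alpha, ci_method)


def specificity(
    table: ContingencyTable,
    flutter_handling: str = "excluded",
    alpha: float = 0.05,
    ci_method: str = "exact",
):
    """True-negative rate TN / (TN + FP) with its binomial CI."""
    _, _, fp, tn = table.binary_counts(flutter_handling)
    return _proportion_with_ci(tn, tn + fp, alpha, ci_method)


def cohens_kappa(
    table: ContingencyTable,
    flutter_handling: str = "as_negative",
    alpha: float = 0.05,
):
    """Chance-corrected agreement on the binary collapse of the table.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    row/column marginals; the CI uses the large-sample standard error
    sqrt(p_o (1 - p_o)) / ((1 - p_e) sqrt(n)) with normal quantiles.
    """
    tp, fn, fp, tn = table.binary_counts(flutter_handling)
    n = tp + fn + fp + tn
    if n == 0:
        raise UndefinedMetricError("empty table")
    p_o = (tp + tn) / n
    p_pos_truth = (tp + fn) / n
    p_pos_pred = (tp + fp) / n
    p_e = p_pos_truth * p_pos_pred + (1 - p_pos_truth) * (1 - p_pos_pred)
    if p_e >= 1.0:
        raise UndefinedMetricError("degenerate marginals (expected agreement 1)")
    kappa = (p_o - p_e) / (1 - p_e)
    se = math.sqrt(p_o * (1 - p_o) / n) / (1 - p_e)
    z = norm.ppf(1 - alpha / 2)
    return kappa, (kappa - z * se, kappa + z * se)


def af_prevalence(
    table: ContingencyTable, flutter_handling: str = "excluded"
) -> float:
    """Fraction of recordings whose reference truth is AF."""
    tp, fn, fp, tn = table.binary_counts(flutter_handling)
    n = tp + fn + fp + tn
    if n == 0:
        raise UndefinedMetricError("empty table")
    return (tp + fn) / n


def evaluate_corpus(
    truth_labels: Sequence[str],
    predictions: Sequence[str],
    alpha: float = 0.05,
    ci_method: str = "exact",
) -> dict:
    """Full accuracy report under both flutter conventions.

    Returns the raw table plus sensitivity/specificity (flutter excluded)
    and specificity/kappa (flutter as negative), each with its CI, in a
    JSON-ready dict.
    """
    table = build_contingency(truth_labels, predictions)
    sens, sens_ci = sensitivity(table, "excluded", alpha, ci_method)
    spec_ex, spec_ex_ci = specificity(table, "excluded", alpha, ci_method)
    spec_neg, spec_neg_ci = specificity(table, "as_negative", alpha, ci_method)
    kappa, kappa_ci = cohens_kappa(table, "as_negative", alpha)
    return {
        "table": table.as_dict(),
        "n_pairs": table.total,
        "flutter_excluded": {
            "sensitivity": sens,
            "sensitivity_ci": list(sens_ci),
            "specificity": spec_ex,
            "specificity_ci": list(spec_ex_ci),
            "prevalence": af_prevalence(table, "excluded"),
        },
        "flutter_as_negative": {
            "sensitivity": sens,
            "specificity": spec_neg,
            "specificity_ci": list(spec_neg_ci),
            "kappa": kappa,
            "kappa_ci": list(kappa_ci),
        },
        "methods": {"ci": ci_method, "kappa_ci": "large-sample normal"},
    }


def evaluate_matched(
    truths_by_id: dict,
    predictions_by_id: dict,
    alpha: float = 0.05,
    ci_method: str = "exact",
) -> dict:
    """As :func:`evaluate_corpus`, matching recordings by id.

    Every recording in the truth manifest must have exactly one prediction;
    missing or extra predictions are reported by id.
    """
    missing = sorted(set(truths_by_id) - set(predictions_by_id))
    extra = sorted(set(predictions_by_id) - set(truths_by_id))
    if missing:
        raise ValueError(f"missing decisions for recordings: {', '.join(missing)}")
    if extra:
        raise ValueError(f"decisions for unknown recordings: {', '.join(extra)}")
    ids = sorted(truths_by_id)
    return evaluate_corpus(
        [truths_by_id[i] for i in ids],
        [predictions_by_id[i] for i in ids],
        alpha=alpha,
        ci_method=ci_method,
    )
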