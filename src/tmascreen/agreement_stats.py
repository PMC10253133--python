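"""Diagnostic agreement statistics for core-level calls.

Pipeline calls are compared against reference (expert) labels for a
chosen positive class — by default the MLH1-deficient tumour, the
clinically actionable category. Flagged and invalid cores are excluded
before tabulation (they are routed to manual review, not called).
Sensitivity and specificity carry exact Clopper-Pearson binomial
confidence intervals; chance-corrected agreement is Cohen's kappa with an
asymptotic Wald interval,

    kappa = (po - pe) / (1 - pe),
    SE    = sqrt( po (1 - po) / ( n (1 - pe)^2 ) ),

whose upper bound is deliberately not truncated at 1 (conventional
reporting of the Wald interval).

The module can also reconstruct a 2x2 confusion table from its printed
marginals (``reconstruct_confusion``): given the number of classified
cores, the false positive/negative counts implied by 100% sensitivity and
a single error, and the rounded specificity, the integer table is
uniquely determined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "AgreementReport",
    "DEFAULT_POSITIVE_CLASS",
    "confusion",
    "clopper_pearson",
    "sensitivity_specificity",
    "cohens_kappa",
    "agreement_report",
    "reconstruct_confusion",
    "reconstruct_reference_confusion",
]

DEFAULT_POSITIVE_CLASS = "MLH1DeficientTumour"
_EXCLUDED_CALLS = ("Flagged", "Invalid")


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 core counts; the positive class is fixed by the caller."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementReport:
    """Percentages to 2 decimals, kappa to 3, matching clinical
    reporting style."""

    sensitivity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None
    kappa: float
    kappa_ci: tuple[float, float]
    kappa_p: float
    n_classified: int

    def to_text(self) -> str:
        lines = [f"n classified = {self.n_classified}"]
        if self.sensitivity is not None:
            lo, hi = self.sensitivity_ci
            lines.append(f"sensitivity = {self.sensitivity:.2f}% (95% CI {lo:.2f}, {hi:.2f})")
        if self.specificity is not None:
            lo, hi = self.specificity_ci
            lines.append(f"specificity = {self.specificity:.2f}% (95% CI {lo:.2f}, {hi:.2f})")
        p = "p < 0.001" if self.kappa_p < 0.001 else f"p = {self.kappa_p:.3g}"
        lines.append(
            f"kappa = {self.kappa:.3f} (95% CI {self.kappa_ci[0]:.3f}, "
            f"{self.kappa_ci[1]:.3f}) ({p})"
        )
        return "\n".join(lines)


def confusion(
    calls: pd.DataFrame,
    reference: pd.DataFrame,
    positive_class: str = DEFAULT_POSITIVE_CLASS,
) -> ConfusionTable:
    """Cross-tabulate pipeline calls against reference labels.

    Both frames need ``core_label`` and ``call`` columns; flagged and
    invalid pipeline calls are excluded first. Every remaining pipeline
    core must exist in the reference, whose calls may not be flags.
    """
    kept = calls[~calls["call"].isin(_EXCLUDED_CALLS)]
    ref = reference.set_index("core_label")["call"]
    if ref.isin(_EXCLUDED_CALLS).any():
        bad = list(ref[ref.isin(_EXCLUDED_CALLS)].index)
        raise ValueError(f"reference contains flagged/invalid calls: {bad}")
    missing = sorted(set(kept["core_label"]) - set(ref.index))
    if missing:
        raise ValueError(f"cores absent from reference: {missing}")
    pred = kept["call"].to_numpy() == positive_class
    truth = ref.loc[kept["core_label"]].to_numpy() == positive_class
    return ConfusionTable(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def clopper_pearson(
    successes: int, trials: int, level: float = 95.0
) -> tuple[float, float]:
    """Exact binomial confidence interval, returned as percentages."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(
        successes, trials, alpha=1.0 - level / 100.0, method="beta"
    )
    return float(lo) * 100.0, float(hi) * 100.0


def sensitivity_specificity(table: ConfusionTable, level: float = 95.0) -> dict:
    """Point estimates (percent) with Clopper-Pearson CIs; a statistic
    with an empty margin is reported as None."""
    out: dict = {}
    if table.tp + table.fn >= 1:
        out["sensitivity"] = 100.0 * table.tp / (table.tp + table.fn)
        out["sensitivity_ci"] = clopper_pearson(table.tp, table.tp + table.fn, level)
    else:
        out["sensitivity"] = None
        out["sensitivity_ci"] = None
    if table.tn + table.fp >= 1:
        out["specificity"] = 100.0 * table.tn / (table.tn + table.fp)
        out["specificity_ci"] = clopper_pearson(table.tn, table.tn + table.fp, level)
    else:
        out["specificity"] = None
        out["specificity_ci"] = None
    return out


def cohens_kappa(table: ConfusionTable, level: float = 95.0) -> dict:
    """Cohen's kappa with an asymptotic Wald CI and a kappa=0 Wald test.

    po = (tp+tn)/n;  pe = ((tp+fp)(tp+fn) + (fn+tn)(fp+tn)) / n^2.
    The upper CI bound is not truncated at 1.
    """
    n = table.total
    if n < 2:
        raise ValueError("kappa needs at least 2 cores")
    po = (table.tp + table.tn) / n
    pe = (
        (table.tp + table.fp) * (table.tp + table.fn)
        + (table.fn + table.tn) * (table.fp + table.tn)
    ) / (n * n)
    if pe >= 1.0:
        raise ValueError("chance agreement is 1; kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    se = np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    z = norm.ppf(0.5 + level / 200.0)
    if se > 0:
        p = 2.0 * norm.sf(abs(kappa) / se)
    else:
        p = 0.0
    return {
        "kappa": float(kappa),
        "kappa_ci": (float(kappa - z * se), float(kappa + z * se)),
        "kappa_se": float(se),
        "kappa_p": float(p),
    }


def agreement_report(table: ConfusionTable, level: float = 95.0) -> AgreementReport:
    ss = sensitivity_specificity(table, level)
    kk = cohens_kappa(table, level)
    return AgreementReport(
        sensitivity=ss["sensitivity"],
        sensitivity_ci=ss["sensitivity_ci"],
        specificity=ss["specificity"],
        specificity_ci=ss["specificity_ci"],
        kappa=kk["kappa"],
        kappa_ci=kk["kappa_ci"],
        kappa_p=kk["kappa_p"],
        n_classified=table.total,
    )


def reconstruct_confusion(
    n_classified: int,
    n_false_positive: int,
    sensitivity_pct: float,
    specificity_pct: float,
    decimals: int = 2,
) -> ConfusionTable:
    """Recover the unique integer 2x2 table from printed marginals.

    With sensitivity 100% the false-negative count is 0; the true
    negatives are the unique integer tn for which
    tn/(tn + fp) rounds to the printed specificity; true positives make
    up the remainder of ``n_classified``.
    """
    if abs(sensitivity_pct - 100.0) > 1e-9:
        raise ValueError("reconstruction implemented for sensitivity = 100% only")
    fn = 0
    fp = n_false_positive
    candidates = [
        tn
        for tn in range(n_classified - fp + 1)
        if round(100.0 * tn / (tn + fp), decimals) == round(specificity_pct, decimals)
        and tn + fp + fn <= n_classified
    ]
    if len(candidates) != 1:
        raise ValueError(
            f"printed marginals admit {len(candidates)} tables, not 1: {candidates}"
        )
    tn = candidates[0]
    tp = n_classified - tn - fp - fn
    if tp < 0:
        raise ValueError("inconsistent marginals")
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def reconstruct_reference_confusion() -> ConfusionTable:
    """The study-scale reference table: 74 classified cores, one false
    positive, sensitivity 100%, specificity 98.25% — which pins down
    tp=17, fn=0, fp=1, tn=56."""
    return reconstruct_confusion(
        n_classified=74, n_false_positive=1,
        sensitivity_pct=100.0, specificity_pct=98.25,
    )
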