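"""Per-core certification of histology and MLH1 status.

Each core's classified cells are tallied; histology (normal epithelium vs
tumour) and marker status (MLH1 proficient vs deficient) are each
certified when the leading fraction reaches an inclusive >=75% threshold,
assessed independently of one another. The marker fraction is computed
over epithelial cells only (normal epithelium plus tumour) — stromal and
immune cells express MLH1 regardless of tumour status and would otherwise
confound the call. Cores failing either threshold are flagged for manual
review with the failing dimension as the reason; cores with too few cells
are invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .cell_detection import POSITIVE, NEGATIVE, UNSCORED

__all__ = [
    "CoreSummary",
    "CoreCall",
    "CertificationParams",
    "CALLS",
    "FLAG_REASONS",
    "summarize_core",
    "certify",
    "certify_all",
]

CALLS = (
    "MLH1ProficientNormal",
    "MLH1DeficientNormal",
    "MLH1ProficientTumour",
    "MLH1DeficientTumour",
    "Flagged",
    "Invalid",
)
FLAG_REASONS = ("none", "Histology", "MLH1", "Both")


@dataclass(frozen=True)
class CoreSummary:
    """Cell tallies for one core (unscored cells excluded)."""

    core_label: str
    n_normal: int = 0
    n_tumour: int = 0
    n_immune: int = 0
    n_stroma: int = 0
    n_epi_pos: int = 0
    n_epi_neg: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_normal, self.n_tumour, self.n_immune, self.n_stroma,
                  self.n_epi_pos, self.n_epi_neg)
        if any(c < 0 for c in counts):
            raise ValueError("negative cell count")
        if self.n_epi_pos + self.n_epi_neg != self.n_normal + self.n_tumour:
            raise ValueError(
                "epithelial marker counts must sum to the epithelial cell count"
            )

    @property
    def n_total(self) -> int:
        return self.n_normal + self.n_tumour + self.n_immune + self.n_stroma

    @property
    def n_epithelial(self) -> int:
        return self.n_normal + self.n_tumour


@dataclass(frozen=True)
class CoreCall:
    core_label: str
    call: str
    flag_reason: str = "none"
    histology_fraction: float = float("nan")
    marker_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")
        if self.flag_reason not in FLAG_REASONS:
            raise ValueError(f"unknown flag reason {self.flag_reason!r}")
        if (self.call == "Flagged") != (self.flag_reason != "none"):
            raise ValueError("flag_reason must be set iff the call is Flagged")


@dataclass(frozen=True)
class CertificationParams:
    """``threshold`` is the certification fraction (inclusive >=);
    ``histology_denominator`` chooses whether histology fractions are
    taken over all classified cells or epithelial cells only;
    ``min_cells`` guards against certifying near-empty cores."""

    threshold: float = 0.75
    histology_denominator: str = "all_cells"  # or "epithelial_cells"
    min_cells: int = 20

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0.5, 1]")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")
        if self.histology_denominator not in ("all_cells", "epithelial_cells"):
            raise ValueError("histology_denominator must be all_cells or epithelial_cells")


def summarize_core(cells: pd.DataFrame, core_label: str = "") -> CoreSummary:
    """Tally one core's cells by tissue class and epithelial marker
    status; unscored cells are excluded."""
    if cells.empty:
        return CoreSummary(core_label=core_label)
    scored = cells[cells["base_class"] != UNSCORED]
    tc = scored["tissue_class"]
    epi = scored[tc.isin(["NormalEpithelium", "Tumour"])]
    return CoreSummary(
        core_label=core_label,
        n_normal=int((tc == "NormalEpithelium").sum()),
        n_tumour=int((tc == "Tumour").sum()),
        n_immune=int((tc == "ImmuneInfiltrate").sum()),
        n_stroma=int((tc == "Stroma").sum()),
        n_epi_pos=int((epi["base_class"] == POSITIVE).sum()),
        n_epi_neg=int((epi["base_class"] == NEGATIVE).sum()),
    )


def certify(summary: CoreSummary, params: CertificationParams = CertificationParams()) -> CoreCall:
    """Apply the certification decision tree to one core.

    Histology certifies Normal (or Tumour) when that class reaches the
    threshold fraction of the denominator; MLH1 certifies Proficient
    (Deficient) when the positive (negative) fraction of epithelial cells
    reaches it. Both certain -> combined call; otherwise Flagged with the
    uncertain dimension(s) as reason; below ``min_cells`` -> Invalid.
    At any threshold > 0.5 at most one class per dimension can certify.
    """
    if summary.n_total < params.min_cells:
        return CoreCall(core_label=summary.core_label, call="Invalid")
    thr = params.threshold
    denom = (
        summary.n_total
        if params.histology_denominator == "all_cells"
        else summary.n_epithelial
    )
    if denom > 0:
        f_normal = summary.n_normal / denom
        f_tumour = summary.n_tumour / denom
        if f_normal >= thr:
            histology, hist_frac = "Normal", f_normal
        elif f_tumour >= thr:
            histology, hist_frac = "Tumour", f_tumour
        else:
            histology, hist_frac = None, max(f_normal, f_tumour)
    else:
        histology, hist_frac = None, float("nan")
    n_epi = summary.n_epi_pos + summary.n_epi_neg
    if n_epi > 0:
        f_pos = summary.n_epi_pos / n_epi
        f_neg = summary.n_epi_neg / n_epi
        if f_pos >= thr:
            marker, marker_frac = "Proficient", f_pos
        elif f_neg >= thr:
            marker, marker_frac = "Deficient", f_neg
        else:
            marker, marker_frac = None, max(f_pos, f_neg)
    else:
        marker, marker_frac = None, float("nan")
    if histology is not None and marker is not None:
        call = f"MLH1{marker}{histology}"
        if call == "MLH1DeficientNormal":
            warnings.warn(
                f"core {summary.core_label}: MLH1-deficient normal epithelium "
                "called — biologically unexpected, check staining",
                stacklevel=2,
            )
        return CoreCall(
            core_label=summary.core_label,
            call=call,
            histology_fraction=hist_frac,
            marker_fraction=marker_frac,
        )
    if histology is None and marker is None:
        reason = "Both"
    elif histology is None:
        reason = "Histology"
    else:
        reason = "MLH1"
    return CoreCall(
        core_label=summary.core_label,
        call="Flagged",
        flag_reason=reason,
        histology_fraction=hist_frac,
        marker_fraction=marker_frac,
    )


def certify_all(
    cells: pd.DataFrame,
    params: CertificationParams = CertificationParams(),
    core_labels: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Certify every core; returns the per-core call table and outcome
    tallies.

    ``core_labels`` fixes the set of cores to report (e.g. the valid
    cores of the dearrayed grid); cores with no assigned cells come out
    Invalid. Cells with empty ``core_label`` are ignored.
    """
    assigned = cells[cells["core_label"] != ""] if len(cells) else cells
    groups = {k: g for k, g in assigned.groupby("core_label")} if len(assigned) else {}
    labels = core_labels if core_labels is not None else sorted(groups)
    rows = []
    for label in labels:
        g = groups.get(label)
        summary = summarize_core(g if g is not None else pd.DataFrame(), label)
        call = certify(summary, params)
        rows.append(
            {
                "core_label": label,
                "call": call.call,
                "flag_reason": call.flag_reason,
                "histology_fraction": call.histology_fraction,
                "marker_fraction": call.marker_fraction,
                "n_normal": summary.n_normal,
                "n_tumour": summary.n_tumour,
                "n_immune": summary.n_immune,
                "n_stroma": summary.n_stroma,
                "n_epi_pos": summary.n_epi_pos,
                "n_epi_neg": summary.n_epi_neg,
                "n_total": summary.n_total,
            }
        )
    calls = pd.DataFrame(rows)
    tallies = {
        "n_cores": len(calls),
        "certified": int((~calls["call"].isin(["Flagged", "Invalid"])).sum()) if len(calls) else 0,
        "flagged": int((calls["call"] == "Flagged").sum()) if len(calls) else 0,
        "flagged_histology": int((calls["flag_reason"] == "Histology").sum()) if len(calls) else 0,
        "flagged_mlh1": int((calls["flag_reason"] == "MLH1").sum()) if len(calls) else 0,
        "flagged_both": int((calls["flag_reason"] == "Both").sum()) if len(calls) else 0,
        "invalid": int((calls["call"] == "Invalid").sum()) if len(calls) else 0,
    }
    return calls, tallies
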