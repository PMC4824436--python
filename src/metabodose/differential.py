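"""Two-group differential abundance: Student's t-test and fold changes.

One comparison produces one :class:`DifferentialResult` per metabolite:
a two-sided pooled-variance t-test P-value, the fold change
mean(test)/mean(reference) on normalized intensities, and the up/down
direction. No multiple-testing correction is applied to the primary
calls (the classical raw ``P < 0.05`` workflow for identified GC-MS
panels); a Benjamini–Hochberg column is available for reuse via
:func:`results_to_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AbundanceTable, TableError

__all__ = [
    "DifferentialResult",
    "compare_groups",
    "summarize_filter",
    "rank_extremes",
    "results_to_frame",
]


@dataclass(frozen=True)
class DifferentialResult:
    metabolite: str
    p_value: float
    fold_change: float
    significant: bool

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1.0 else "down"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise TableError(
                f"{self.metabolite}: p-value {self.p_value} outside [0, 1]"
            )
        if self.fold_change <= 0.0:
            raise TableError(
                f"{self.metabolite}: fold change must be positive"
            )


def _pooled_t_p(x: np.ndarray, y: np.ndarray, welch: bool) -> float:
    """Two-sided t-test P-value with the degenerate-variance convention:
    if neither group varies, p=1 for equal means, p=0 otherwise."""
    if np.std(x) == 0.0 and np.std(y) == 0.0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.pvalue)


def compare_groups(
    table: AbundanceTable,
    test: str,
    reference: str,
    alpha: float = 0.05,
    welch: bool = False,
) -> list[DifferentialResult]:
    """Compare two genotype groups metabolite-by-metabolite.

    Fold change is the ratio of arithmetic group means, test over
    reference; results are returned in the table's metabolite order.
    """
    for g in (test, reference):
        if g not in table.genotype_set:
            raise TableError(f"genotype {g!r} not present in table")
        if int((table.genotypes == g).sum()) < 2:
            raise TableError(f"genotype {g!r} has fewer than 2 replicates")
    if table.n_missing():
        raise TableError("table contains missing values; impute first")

    x_block = table.group_data(test).to_numpy()
    y_block = table.group_data(reference).to_numpy()
    results = []
    for j, name in enumerate(table.metabolite_names):
        x, y = x_block[:, j], y_block[:, j]
        ref_mean = float(np.mean(y))
        if ref_mean == 0.0:
            raise TableError(f"{name}: reference group mean is zero")
        p = _pooled_t_p(x, y, welch)
        fc = float(np.mean(x)) / ref_mean
        results.append(
            DifferentialResult(
                metabolite=name, p_value=p, fold_change=fc,
                significant=p < alpha,
            )
        )
    return results


def summarize_filter(
    results: list[DifferentialResult], alpha: float = 0.05
) -> dict[str, int]:
    """Counts at the significance filter: total significant and the
    up/down partition (n_sig = n_up + n_down)."""
    if not results:
        raise TableError("no results to summarize")
    sig = [r for r in results if r.p_value < alpha]
    n_up = sum(1 for r in sig if r.direction == "up")
    return {"n_sig": len(sig), "n_up": n_up, "n_down": len(sig) - n_up}


def rank_extremes(
    results: list[DifferentialResult], n_top: int = 5
) -> dict[str, list[DifferentialResult]]:
    """Deterministic extremes report: largest and smallest fold changes
    and smallest P-values, ties broken by metabolite name."""
    if not results:
        raise TableError("no results to rank")
    by_fc_desc = sorted(results, key=lambda r: (-r.fold_change, r.metabolite))
    by_fc_asc = sorted(results, key=lambda r: (r.fold_change, r.metabolite))
    by_p = sorted(results, key=lambda r: (r.p_value, r.metabolite))
    return {
        "largest_fold_change": by_fc_desc[:n_top],
        "smallest_fold_change": by_fc_asc[:n_top],
        "smallest_p": by_p[:n_top],
    }


def results_to_frame(
    results: list[DifferentialResult], fdr: bool = True
) -> pd.DataFrame:
    """Tabular view of a comparison; optional BH-FDR column for reuse
    (never used for the primary significance calls)."""
    frame = pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in results],
            "p_value": [r.p_value for r in results],
            "fold_change": [r.fold_change for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
        }
    )
    if fdr and len(frame):
        frame["q_value_bh"] = stats.false_discovery_control(
            frame["p_value"].to_numpy(), method="bh"
        )
    return frame
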