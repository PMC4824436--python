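"""Cross-genotype consensus analysis.

Three questions asked of a multi-allele design:

* Are the two mutant alleles metabolically equivalent? The
  allele-discordance ratio counts metabolites that differ significantly
  *between* the alleles; a ratio at or below the test's own false-positive
  rate (alpha) is read as systematic error rather than allele-specific
  biology.
* Which changes are allele-specific? Set algebra over the two
  mutant-vs-wild-type significant sets (the Venn view).
* Which changes are gene-linked? The consensus call: metabolites
  significant in both the mutant-vs-wild-type comparison and the
  mutant-vs-rescue comparison, with the same direction, both oriented so
  that the gene-deficient condition is the test group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core_data import TableError
from .differential import DifferentialResult

__all__ = [
    "ComparisonSet",
    "ConsensusCall",
    "discordance_ratio",
    "allele_discordance",
    "allele_specific_sets",
    "consensus_call",
]


@dataclass
class ComparisonSet:
    """One two-group comparison plus its derived significant set."""

    label: str
    results: list[DifferentialResult] = field(repr=False)
    #: True when the gene-deficient condition is the test (numerator) group
    deficient_is_test: bool | None = None

    @property
    def panel(self) -> frozenset[str]:
        return frozenset(r.metabolite for r in self.results)

    @property
    def significant(self) -> dict[str, str]:
        """metabolite -> direction, over significant results only."""
        return {r.metabolite: r.direction for r in self.results
                if r.significant}

    def p_value(self, metabolite: str) -> float:
        for r in self.results:
            if r.metabolite == metabolite:
                return r.p_value
        raise KeyError(metabolite)


@dataclass(frozen=True)
class ConsensusCall:
    metabolite: str
    direction: str
    p_mut_vs_wt: float
    p_deficient_vs_rescue: float

    @property
    def evidence(self) -> float:
        """Combined evidence, sum of -log10 P (ranking only)."""
        return -math.log10(self.p_mut_vs_wt) - math.log10(
            self.p_deficient_vs_rescue
        )


def discordance_ratio(
    n_significant: int, panel_size: int, alpha: float = 0.05
) -> dict:
    """Allele-discordance record from counts.

    ``percentage`` is reported at one decimal;
    ``within_systematic_error`` is true when the percentage does not
    exceed 100*alpha — i.e. the between-allele differences are no more
    frequent than the test's nominal false-positive rate.
    """
    if panel_size <= 0:
        raise TableError("panel_size must be positive")
    if not (0 <= n_significant <= panel_size):
        raise TableError("count must lie in [0, panel_size]")
    pct = round(100.0 * n_significant / panel_size, 1)
    return {
        "count": n_significant,
        "panel_size": panel_size,
        "percentage": pct,
        "within_systematic_error": pct <= 100.0 * alpha,
    }


def allele_discordance(
    results_between_alleles: list[DifferentialResult],
    panel_size: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Discordance record from an allele-vs-allele comparison."""
    n_sig = sum(1 for r in results_between_alleles if r.p_value < alpha)
    size = panel_size if panel_size is not None else len(
        results_between_alleles
    )
    return discordance_ratio(n_sig, size, alpha)


def allele_specific_sets(
    cmp_a: ComparisonSet, cmp_b: ComparisonSet
) -> dict[str, set[str]]:
    """Venn partition of the two significant sets (same metabolite panel
    required)."""
    if cmp_a.panel != cmp_b.panel:
        raise TableError(
            f"comparisons {cmp_a.label!r} and {cmp_b.label!r} cover "
            "different metabolite panels"
        )
    sig_a = set(cmp_a.significant)
    sig_b = set(cmp_b.significant)
    return {
        "only_a": sig_a - sig_b,
        "only_b": sig_b - sig_a,
        "shared": sig_a & sig_b,
    }


def consensus_call(
    cmp_mut_vs_wt: ComparisonSet,
    cmp_deficient_vs_rescue: ComparisonSet,
) -> list[ConsensusCall]:
    """Direction-consistent consensus across genetic settings.

    Both comparisons must be explicitly oriented with the gene-deficient
    condition as the test group (``deficient_is_test=True``); without
    that flag, agreeing directions would be meaningless. Output is
    sorted by combined evidence (descending), ties by name.
    """
    for cmp_ in (cmp_mut_vs_wt, cmp_deficient_vs_rescue):
        if cmp_.deficient_is_test is None:
            raise TableError(
                f"comparison {cmp_.label!r} lacks an orientation flag"
            )
        if not cmp_.deficient_is_test:
            raise TableError(
                f"comparison {cmp_.label!r} must be oriented with the "
                "gene-deficient condition as the test group"
            )
    sig_a = cmp_mut_vs_wt.significant
    sig_b = cmp_deficient_vs_rescue.significant
    calls = [
        ConsensusCall(
            metabolite=m,
            direction=sig_a[m],
            p_mut_vs_wt=cmp_mut_vs_wt.p_value(m),
            p_deficient_vs_rescue=cmp_deficient_vs_rescue.p_value(m),
        )
        for m in sig_a
        if m in sig_b and sig_a[m] == sig_b[m]
    ]
    return sorted(calls, key=lambda c: (-c.evidence, c.metabolite))
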