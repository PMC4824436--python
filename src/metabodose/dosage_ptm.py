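"""Pavlidis template matching (PTM) against gene-dosage templates.

Each metabolite's profile is correlated with a user-supplied template
vector laid out over an ordered genotype series (typically wild type ->
heterozygote -> homozygote). By default the template value for a genotype
is broadcast to every replicate of that genotype and Pearson correlation
is computed over replicate-level points, giving the test its n-2 degrees
of freedom — the convention of the original microarray tool. A metabolite
matches a template when the correlation is positive and significant.

The two default templates encode a linear gene-dosage trend: (1, 0.5, 0)
for dosage-dependent down-regulation and (0, 0.5, 1) for up-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import AbundanceTable, TableError

__all__ = [
    "TemplateMatch",
    "TEMPLATE_DOWN",
    "TEMPLATE_UP",
    "match_template",
    "dosage_report",
]

TEMPLATE_DOWN = (1.0, 0.5, 0.0)
TEMPLATE_UP = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class TemplateMatch:
    metabolite: str
    template: str
    r: float
    p_value: float
    matched: bool
    degenerate: bool = False


def match_template(
    table: AbundanceTable,
    genotype_order: tuple[str, ...],
    template: tuple[float, ...],
    threshold: float = 0.05,
    label: str = "custom",
    means_only: bool = False,
) -> list[TemplateMatch]:
    """Correlate every metabolite with a dosage template.

    ``matched`` requires r > 0 and a two-sided P below ``threshold``; a
    constant metabolite profile has no defined correlation and is
    reported unmatched with ``degenerate=True`` rather than NaN.

    ``means_only=True`` correlates the per-genotype means against the
    template directly (df = len(template) - 2) instead of broadcasting to
    replicate level.
    """
    if len(genotype_order) < 3:
        raise TableError("genotype_order must list at least 3 genotypes")
    if len(template) != len(genotype_order):
        raise TableError("template length must equal genotype_order length")
    if float(np.std(template)) == 0.0:
        raise TableError("template must be non-constant")
    for g in genotype_order:
        if g not in table.genotype_set:
            raise TableError(f"genotype {g!r} not present in table")
    if table.n_missing():
        raise TableError("PTM input must have no missing values")

    blocks = [table.group_data(g).to_numpy() for g in genotype_order]
    if means_only:
        y_matrix = np.vstack([b.mean(axis=0) for b in blocks])
        x = np.asarray(template, dtype=float)
    else:
        y_matrix = np.vstack(blocks)
        x = np.concatenate(
            [np.full(b.shape[0], t) for b, t in zip(blocks, template)]
        )

    out = []
    for j, name in enumerate(table.metabolite_names):
        y = y_matrix[:, j]
        if float(np.std(y)) == 0.0:
            out.append(
                TemplateMatch(
                    metabolite=name, template=label, r=0.0, p_value=1.0,
                    matched=False, degenerate=True,
                )
            )
            continue
        r, p = stats.pearsonr(x, y)
        out.append(
            TemplateMatch(
                metabolite=name, template=label, r=float(r),
                p_value=float(p),
                matched=bool(p < threshold and r > 0.0),
            )
        )
    return out


def dosage_report(
    matches_up: list[TemplateMatch], matches_down: list[TemplateMatch]
) -> dict[str, list[TemplateMatch]]:
    """Two named dosage clusters, members sorted by descending r.

    A metabolite cannot match both monotone templates (both correlations
    cannot be positive); this is asserted, not silently resolved.
    """
    up = sorted(
        (m for m in matches_up if m.matched),
        key=lambda m: (-m.r, m.metabolite),
    )
    down = sorted(
        (m for m in matches_down if m.matched),
        key=lambda m: (-m.r, m.metabolite),
    )
    overlap = {m.metabolite for m in up} & {m.metabolite for m in down}
    if overlap:
        raise AssertionError(
            "metabolite(s) matched both monotone templates: "
            + ", ".join(sorted(overlap))
        )
    return {"dosage_up": up, "dosage_down": down}
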