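"""Packaged fixtures: the published 46-row differential table and small
demonstration annotation / reaction-pair files.

The differential table is transcribed verbatim from print. P-values that
were printed as ``0.000`` (three-decimal rounding) are right-censored:
the true value is below 5e-4, so the loader represents them by that upper
bound. This keeps the printed ordering usable — in particular the
minimum-P metabolite is the one printed in scientific notation — without
inventing values below the censoring limit.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .differential import DifferentialResult

__all__ = [
    "load_table1",
    "table1_path",
    "demo_annotations_path",
    "demo_reaction_pairs_path",
]

#: printed "0.000" means p < 0.0005 at the table's three-decimal precision
CENSORED_P = 5e-4


def _data_path(name: str) -> Path:
    return Path(resources.files("metabodose").joinpath("data", name))


def table1_path() -> Path:
    return _data_path("table1.tsv")


def demo_annotations_path() -> Path:
    return _data_path("annotations_demo.csv")


def demo_reaction_pairs_path() -> Path:
    return _data_path("reaction_pairs.tsv")


def _parse_p(text: str) -> float:
    value = float(text)
    if value == 0.0:
        return CENSORED_P
    return value


def load_table1(alpha: float = 0.05) -> list[DifferentialResult]:
    """The packaged homozygote-vs-wild-type differential table
    (46 metabolites, all significant at the printed P < 0.05)."""
    frame = pd.read_csv(table1_path(), sep="\t", dtype=str)
    return [
        DifferentialResult(
            metabolite=row["name"],
            p_value=_parse_p(row["p_value"]),
            fold_change=float(row["fold_change"]),
            significant=_parse_p(row["p_value"]) < alpha,
        )
        for _, row in frame.iterrows()
    ]
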