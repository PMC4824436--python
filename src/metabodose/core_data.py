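"""Abundance-table data model, I/O, normalization and the presence filter.

The central container is :class:`AbundanceTable`: a samples x metabolites
matrix of raw or normalized ion intensities with one genotype label per
sample. Missing measurements are held as NaN and are never silently
treated as zero; the presence filter, the half-minimum imputation and the
mTIC normalization below are the standard preprocessing chain applied
before any statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "MetaboliteAnnotation",
    "read_abundance_table",
    "write_abundance_table",
    "read_genotype_map",
    "read_annotations",
    "presence_filter",
    "normalize_tic",
    "impute_missing",
]


class TableError(ValueError):
    """Raised for any structural violation of an abundance table."""


@dataclass(frozen=True)
class MetaboliteAnnotation:
    """Per-metabolite chemical annotation.

    Either ``smiles`` or ``fingerprint_hex`` may be set (not both); a
    metabolite with neither can still appear in abundance tables but is
    excluded from the chemical-similarity network layer.
    """

    name: str
    compound_id: str | None = None
    smiles: str | None = None
    fingerprint_hex: str | None = None
    pathway_tag: str | None = None

    def __post_init__(self) -> None:
        if self.smiles and self.fingerprint_hex:
            raise TableError(
                f"annotation for {self.name!r}: smiles and fingerprint are "
                "mutually exclusive"
            )

    @property
    def has_structure(self) -> bool:
        return bool(self.smiles or self.fingerprint_hex)


@dataclass
class AbundanceTable:
    """Samples x metabolites intensity matrix with genotype labels.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one float column per
        metabolite; NaN marks a missing measurement.
    genotypes
        Series mapping every sample id in ``data.index`` to its genotype
        label.
    """

    data: pd.DataFrame
    genotypes: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.columns = [str(c).strip() for c in self.data.columns]
        dupes = pd.Index(self.data.columns)[
            pd.Index(self.data.columns).duplicated()
        ].unique()
        if len(dupes):
            raise TableError(
                "duplicate metabolite name(s): " + ", ".join(map(str, dupes))
            )
        missing = [s for s in self.data.index if s not in self.genotypes.index]
        if missing:
            raise TableError(
                "sample(s) without genotype label: " + ", ".join(map(str, missing))
            )
        self.genotypes = self.genotypes.reindex(self.data.index)
        with np.errstate(invalid="ignore"):
            if (self.data.to_numpy() < 0).any():
                raise TableError("negative intensity encountered")

    # -- basic views ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    @property
    def genotype_set(self) -> list[str]:
        """Genotype labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.genotypes:
            seen.setdefault(g, None)
        return list(seen)

    def group_values(self, genotype: str, metabolite: str) -> np.ndarray:
        """Non-validated raw values of one metabolite within one genotype."""
        mask = (self.genotypes == genotype).to_numpy()
        return self.data.loc[mask, metabolite].to_numpy()

    def group_data(self, genotype: str) -> pd.DataFrame:
        mask = (self.genotypes == genotype).to_numpy()
        return self.data.loc[mask]

    def require_group_sizes(self, minimum: int = 2) -> None:
        """Group statistics need at least ``minimum`` replicates everywhere."""
        counts = self.genotypes.value_counts()
        small = counts[counts < minimum]
        if len(small):
            raise TableError(
                f"genotype group(s) with <{minimum} samples: "
                + ", ".join(small.index.astype(str))
            )

    def with_data(self, data: pd.DataFrame) -> "AbundanceTable":
        return AbundanceTable(data=data, genotypes=self.genotypes.copy())

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_abundance_table(
    path: str | Path, genotype_map: Mapping[str, str]
) -> AbundanceTable:
    """Read a delimited abundance table (header row = metabolite names,
    first column = sample id) and attach genotype labels.

    Empty cells are recorded as missing (NaN), never as zero. Duplicate
    metabolite columns and samples absent from ``genotype_map`` are hard
    errors.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)[1:]
    names = [h.strip() for h in header]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise TableError(
            "duplicate metabolite name(s): " + ", ".join(dupes)
        )
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str).str.strip()
    frame.index.name = None
    unknown = [s for s in frame.index if s not in genotype_map]
    if unknown:
        raise TableError(
            "sample(s) missing from genotype map: " + ", ".join(unknown)
        )
    genotypes = pd.Series({s: genotype_map[s] for s in frame.index})
    return AbundanceTable(data=frame, genotypes=genotypes)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path), index_label="sample")


def read_genotype_map(path: str | Path) -> dict[str, str]:
    """Two-column delimited file: sample id, genotype label."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#")
    if frame.shape[1] < 2:
        raise TableError(f"{path}: genotype map needs two columns")
    return {
        str(s).strip(): str(g).strip()
        for s, g in zip(frame.iloc[:, 0], frame.iloc[:, 1])
    }


def read_annotations(path: str | Path) -> dict[str, MetaboliteAnnotation]:
    """Read the annotation CSV (name, compound_id, smiles, fingerprint,
    pathway_tag); returns a dict keyed by trimmed metabolite name."""
    frame = pd.read_csv(Path(path), dtype=str).fillna("")
    records: dict[str, MetaboliteAnnotation] = {}
    for _, row in frame.iterrows():
        name = row["name"].strip()
        if name in records:
            raise TableError(f"duplicate annotation for {name!r}")
        records[name] = MetaboliteAnnotation(
            name=name,
            compound_id=row.get("compound_id", "").strip() or None,
            smiles=row.get("smiles", "").strip() or None,
            fingerprint_hex=row.get("fingerprint", "").strip() or None,
            pathway_tag=row.get("pathway_tag", "").strip() or None,
        )
    return records


# ---------------------------------------------------------------------------
# Preprocessing chain: presence filter -> imputation -> mTIC normalization
# ---------------------------------------------------------------------------

def presence_filter(
    table: AbundanceTable, min_fraction: float = 0.8
) -> AbundanceTable:
    """Keep a metabolite only if it is observed (non-missing) in at least
    ``min_fraction`` of the samples of EVERY genotype group.

    The 80% default is the conventional reporting rule for identified
    GC-MS metabolites. Column order is preserved; an empty result is an
    error rather than an empty table.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise TableError("min_fraction must be in (0, 1]")
    keep = np.ones(table.n_metabolites, dtype=bool)
    for genotype in table.genotype_set:
        block = table.group_data(genotype)
        frac = block.notna().mean(axis=0).to_numpy()
        keep &= frac >= min_fraction
    if not keep.any():
        raise TableError(
            f"presence filter at {min_fraction:.2f} removed every metabolite"
        )
    cols = [m for m, k in zip(table.metabolite_names, keep) if k]
    return table.with_data(table.data[cols])


def impute_missing(table: AbundanceTable) -> AbundanceTable:
    """Replace each missing cell by half the minimum observed value of that
    metabolite across all samples (half-minimum policy, the common
    left-censoring convention for metabolomics detection limits)."""
    data = table.data.copy()
    if data.isna().all(axis=0).any():
        bad = data.columns[data.isna().all(axis=0)]
        raise TableError(
            "metabolite(s) entirely missing: " + ", ".join(map(str, bad))
        )
    fill = data.min(axis=0, skipna=True) / 2.0
    return table.with_data(data.fillna(fill))


def normalize_tic(
    table: AbundanceTable, rescale: str = "mean"
) -> AbundanceTable:
    """mTIC normalization: divide each sample by its summed intensity over
    all (identified) metabolites, removing per-sample loading and
    instrument drift.

    With ``rescale="mean"`` (default) the fractions are multiplied by the
    cohort mean of the per-sample totals so values stay on the original
    intensity scale; ``rescale="none"`` leaves pure fractions. Either way
    every sample ends up with an identical metabolite sum.
    """
    if rescale not in {"mean", "none"}:
        raise TableError(f"unknown rescale mode {rescale!r}")
    totals = table.data.sum(axis=1, skipna=True)
    zero = totals[~(totals > 0)]
    if len(zero):
        raise TableError(
            "sample(s) with non-positive total signal: "
            + ", ".join(zero.index.astype(str))
        )
    fractions = table.data.div(totals, axis=0)
    if rescale == "mean":
        fractions = fractions * float(totals.mean())
    return table.with_data(fractions)
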