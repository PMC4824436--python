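"""Synthetic abundance-table generator with planted effect structure.

Emulates the study design this pipeline targets: 5 genotypes (wild type,
heterozygote, homozygous mutant, rescue, driver-mutant) x 6 replicates x
109 identified metabolites, with multiplicative lognormal noise and four
planted effect classes:

* ``dosage_down`` / ``dosage_up`` — monotone gene-dosage trends across
  WT -> het -> hom, with the heterozygote at half the homozygote effect on
  the log scale (linear in gene dose);
* ``consensus`` — metabolites altered concordantly in both null alleles
  (hom and the driver mutant) relative to WT, and restored to the WT mean
  in the rescue genotype;
* ``marker`` — one metabolite with a very large fold change in every
  non-wild-type genotype, emulating a genetic-background artifact (the
  eye-pigment marker) rather than a gene effect.

The generator returns the table together with a truth record so that
downstream recovery tests never reach into generator internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import AbundanceTable, TableError

__all__ = ["SimulationConfig", "TruthRecord", "generate"]

GENOTYPES_DEFAULT = ("WT", "het", "hom", "rescue", "gal4")

#: gene-dose fraction of the full (homozygote) effect per genotype
_DOSAGE_FRACTION = {"WT": 0.0, "het": 0.5, "hom": 1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and planted-effect layout for :func:`generate`."""

    n_metabolites: int = 109
    replicates_per_genotype: int = 6
    genotypes: tuple[str, ...] = GENOTYPES_DEFAULT
    baseline_log_mean: float = 10.0   # natural-log mean of baseline intensity
    baseline_log_sd: float = 1.5      # between-metabolite spread of baselines
    cv: float = 0.2                   # multiplicative noise CV (natural scale)
    planted_dosage_down: tuple[int, ...] = tuple(range(0, 17))
    planted_dosage_up: tuple[int, ...] = tuple(range(17, 26))
    planted_consensus: tuple[int, ...] = (26, 27, 28)
    consensus_signs: tuple[int, ...] = (-1, -1, 1)
    marker_index: int | None = 29
    marker_effect_log2: float = 4.71  # ~26-fold, the background-marker scale
    effect_size_log2: float = 1.0     # magnitude for dosage/consensus classes
    #: planted effects sit below this baseline-abundance quantile, keeping
    #: perturbed compounds off the TIC-dominant set (TIC normalization
    #: assumes the compounds carrying most of the total signal are stable)
    planted_abundance_quantile: float = 0.8
    #: the marker emulates a trace compound (natural-log offset from the
    #: cohort baseline mean); even at a 26-fold change it stays a small
    #: fraction of total ion current
    marker_baseline_log_offset: float = -3.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [
            set(self.planted_dosage_down),
            set(self.planted_dosage_up),
            set(self.planted_consensus),
            {self.marker_index} if self.marker_index is not None else set(),
        ]
        union: set[int] = set()
        for s in sets:
            if union & s:
                raise TableError("planted metabolite sets must be disjoint")
            union |= s
        if union and (min(union) < 0 or max(union) >= self.n_metabolites):
            raise TableError("planted index out of range")
        if len(self.consensus_signs) != len(self.planted_consensus):
            raise TableError("one sign per consensus metabolite required")
        if any(s not in (-1, 1) for s in self.consensus_signs):
            raise TableError("consensus signs must be ±1")
        if self.effect_size_log2 == 0.0 or not np.isfinite(self.effect_size_log2):
            raise TableError("effect_size_log2 must be finite and nonzero")
        if len({"WT", "het", "hom"} - set(self.genotypes)) and (
            self.planted_dosage_down or self.planted_dosage_up
        ):
            raise TableError("dosage plants require WT/het/hom genotypes")
        if not (0.0 <= self.missing_rate < 1.0):
            raise TableError("missing_rate must be in [0, 1)")
        if not (0.0 < self.planted_abundance_quantile <= 1.0):
            raise TableError("planted_abundance_quantile must be in (0, 1]")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a generated table."""

    classes: dict[str, str]                 # metabolite -> effect class
    group_means: pd.DataFrame = field(repr=False)  # genotype x metabolite
    config: SimulationConfig | None = None

    def members(self, effect_class: str) -> list[str]:
        return [m for m, c in self.classes.items() if c == effect_class]

    def null_members(self) -> list[str]:
        return self.members("null")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes,
            "group_means": {
                g: self.group_means.loc[g].to_dict()
                for g in self.group_means.index
            },
            "config": asdict(self.config) if self.config else None,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _log_effects(config: SimulationConfig) -> np.ndarray:
    """Natural-log effect offsets, genotypes x metabolites."""
    ln2 = np.log(2.0)
    offsets = np.zeros((len(config.genotypes), config.n_metabolites))
    gidx = {g: i for i, g in enumerate(config.genotypes)}
    for sign, planted in (
        (-1, config.planted_dosage_down),
        (+1, config.planted_dosage_up),
    ):
        for g, frac in _DOSAGE_FRACTION.items():
            if g in gidx:
                offsets[gidx[g], list(planted)] = (
                    sign * config.effect_size_log2 * ln2 * frac
                )
    for m, sign in zip(config.planted_consensus, config.consensus_signs):
        for g in ("hom", "gal4"):
            if g in gidx:
                offsets[gidx[g], m] = sign * config.effect_size_log2 * ln2
    if config.marker_index is not None:
        for g in config.genotypes:
            if g != "WT":
                offsets[gidx[g], config.marker_index] = (
                    config.marker_effect_log2 * ln2
                )
    return offsets


def generate(config: SimulationConfig) -> tuple[AbundanceTable, TruthRecord]:
    """Draw one abundance table from the generative model.

    Intensities are ``mean * exp(eps)`` with ``eps ~ N(-sigma^2/2, sigma^2)``
    and ``sigma^2 = ln(1 + cv^2)``, so every value is strictly positive,
    the expectation equals the truth mean, and ``cv=0`` reproduces the
    truth means exactly. The same seed yields a bit-identical table.
    """
    rng = np.random.default_rng(config.seed)
    names = [f"M{i:03d}" for i in range(config.n_metabolites)]
    baselines = rng.normal(
        config.baseline_log_mean, config.baseline_log_sd, config.n_metabolites
    )
    planted = sorted(
        set(config.planted_dosage_down)
        | set(config.planted_dosage_up)
        | set(config.planted_consensus)
    )
    if planted and config.planted_abundance_quantile < 1.0:
        # truncated-normal baselines below the abundance quantile
        from scipy.special import ndtri

        u = rng.random(len(planted))
        baselines[planted] = (
            config.baseline_log_mean
            + config.baseline_log_sd
            * ndtri(u * config.planted_abundance_quantile)
        )
    if config.marker_index is not None:
        baselines[config.marker_index] += config.marker_baseline_log_offset
    means = np.exp(baselines[None, :] + _log_effects(config))

    sigma = float(np.sqrt(np.log1p(config.cv**2)))
    n_rep = config.replicates_per_genotype
    rows, sample_ids, genotypes = [], [], []
    for gi, g in enumerate(config.genotypes):
        eps = rng.normal(-sigma**2 / 2.0, sigma, (n_rep, config.n_metabolites))
        rows.append(means[gi] * np.exp(eps))
        sample_ids += [f"{g}_{r + 1}" for r in range(n_rep)]
        genotypes += [g] * n_rep
    values = np.vstack(rows)

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    table = AbundanceTable(
        data=pd.DataFrame(values, index=sample_ids, columns=names),
        genotypes=pd.Series(genotypes, index=sample_ids),
    )

    classes = {m: "null" for m in names}
    for i in config.planted_dosage_down:
        classes[names[i]] = "dosage_down"
    for i in config.planted_dosage_up:
        classes[names[i]] = "dosage_up"
    for i, sign in zip(config.planted_consensus, config.consensus_signs):
        classes[names[i]] = "consensus_up" if sign > 0 else "consensus_down"
    if config.marker_index is not None:
        classes[names[config.marker_index]] = "marker"

    truth = TruthRecord(
        classes=classes,
        group_means=pd.DataFrame(
            means, index=list(config.genotypes), columns=names
        ),
        config=config,
    )
    return table, truth
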