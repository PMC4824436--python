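"""End-to-end pipeline orchestration and the printed-table replication.

`run_pipeline` chains the stages — preprocessing, differential
comparisons, PCA/HCA, dosage template matching, the two-layer network,
and the cross-genotype consensus — over one abundance table, writing
every stage output plus a manifest (config hash, output hashes, seed,
versions) so a rerun with identical inputs is auditable as bit-identical
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .core_data import (
    AbundanceTable,
    TableError,
    impute_missing,
    normalize_tic,
    presence_filter,
    read_abundance_table,
    read_annotations,
    read_genotype_map,
)
from .chem_network import (
    assemble_network,
    build_reaction_layer,
    build_similarity_layer,
    fingerprints_from_annotations,
    write_graphml,
    write_node_attributes,
    write_sif,
)
from .consensus import (
    ComparisonSet,
    allele_discordance,
    allele_specific_sets,
    consensus_call,
)
from .differential import (
    compare_groups,
    rank_extremes,
    results_to_frame,
    summarize_filter,
)
from .dosage_ptm import TEMPLATE_DOWN, TEMPLATE_UP, dosage_report, match_template
from .fixtures import load_table1
from .multivariate import cluster_hca, run_pca

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "replicate_table1"]


@dataclass
class PipelineConfig:
    """One YAML document drives the whole run; every CLI flag mirrors a
    key here."""

    abundance_path: str
    genotype_map_path: str | None = None
    genotype_map: dict[str, str] = field(default_factory=dict)
    annotation_path: str | None = None
    reaction_pairs_path: str | None = None
    out_dir: str = "metabodose_out"
    alpha: float = 0.05
    presence_fraction: float = 0.8
    tic_rescale: str = "mean"
    tanimoto_threshold: float = 0.7
    pca_scaling: str = "autoscale"
    welch: bool = False
    dosage_order: tuple[str, ...] = ("WT", "het", "hom")
    template_down: tuple[float, ...] = TEMPLATE_DOWN
    template_up: tuple[float, ...] = TEMPLATE_UP
    ptm_threshold: float = 0.05
    # comparisons: (label, test, reference); the first is mutant-vs-WT
    comparisons: tuple[tuple[str, str, str], ...] = (
        ("hom_vs_wt", "hom", "WT"),
        ("gal4_vs_wt", "gal4", "WT"),
        ("gal4_vs_rescue", "gal4", "rescue"),
        ("hom_vs_gal4", "hom", "gal4"),
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise TableError("alpha must be in (0, 1)")
        if not (0.0 < self.presence_fraction <= 1.0):
            raise TableError("presence_fraction must be in (0, 1]")
        if not (0.0 < self.tanimoto_threshold <= 1.0):
            raise TableError("tanimoto_threshold must be in (0, 1]")
        for key in ("abundance_path", "genotype_map_path",
                    "annotation_path", "reaction_pairs_path"):
            value = getattr(self, key)
            if value and not Path(value).exists():
                raise TableError(f"{key}: no such file {value!r}")
        if not self.genotype_map and not self.genotype_map_path:
            raise TableError("a genotype map (inline or file) is required")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()


def preprocess(table: AbundanceTable, config: PipelineConfig) -> AbundanceTable:
    """presence filter -> half-minimum imputation -> mTIC normalization."""
    table = presence_filter(table, config.presence_fraction)
    table = impute_missing(table)
    return normalize_tic(table, rescale=config.tic_rescale)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def save_text(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        outputs[name] = _sha256(path)

    def save_json(name: str, obj) -> None:
        save_text(name, json.dumps(obj, indent=1, sort_keys=True, default=str))

    gmap = dict(config.genotype_map)
    if config.genotype_map_path:
        gmap.update(read_genotype_map(config.genotype_map_path))

    # --- stage 1: core_data -------------------------------------------
    stage = "core_data"
    try:
        raw = read_abundance_table(config.abundance_path, gmap)
        table = preprocess(raw, config)
        path = out / "normalized.tsv"
        table.data.to_csv(path, sep="\t", index_label="sample")
        outputs["normalized.tsv"] = _sha256(path)

        # --- stage 2: differential ------------------------------------
        stage = "differential"
        comparisons: dict[str, ComparisonSet] = {}
        for label, test, reference in config.comparisons:
            if test not in table.genotype_set or (
                reference not in table.genotype_set
            ):
                log.warning("skipping comparison %s: genotype absent", label)
                continue
            results = compare_groups(
                table, test, reference, alpha=config.alpha, welch=config.welch
            )
            deficient_is_test = test in {"hom", "gal4"}
            comparisons[label] = ComparisonSet(
                label=label, results=results,
                deficient_is_test=deficient_is_test,
            )
            frame = results_to_frame(results)
            save_text(f"differential_{label}.tsv",
                      frame.to_csv(sep="\t", index=False))
        primary_label = config.comparisons[0][0]
        primary = comparisons[primary_label]
        save_json("differential_counts.json", {
            label: summarize_filter(c.results, config.alpha)
            for label, c in comparisons.items()
        })

        # --- stage 3: multivariate ------------------------------------
        stage = "multivariate"
        pca = run_pca(table, scaling=config.pca_scaling)
        save_text("pca_scores.tsv", pca.scores.to_csv(sep="\t"))
        save_text("pca_variance.tsv", "\n".join(
            f"PC{i + 1}\t{v:.6f}"
            for i, v in enumerate(pca.variance_fraction)
        ) + "\n")
        save_text("hca_samples.nwk", cluster_hca(table, "samples").to_newick()
                  + "\n")

        # --- stage 4: dosage_ptm --------------------------------------
        stage = "dosage_ptm"
        if all(g in table.genotype_set for g in config.dosage_order):
            down = match_template(
                table, config.dosage_order, config.template_down,
                threshold=config.ptm_threshold, label="monotone-down",
            )
            up = match_template(
                table, config.dosage_order, config.template_up,
                threshold=config.ptm_threshold, label="monotone-up",
            )
            report = dosage_report(up, down)
            save_json("dosage_clusters.json", {
                k: [{"metabolite": m.metabolite, "r": m.r,
                     "p_value": m.p_value} for m in v]
                for k, v in report.items()
            })

        # --- stage 5: chem_network ------------------------------------
        stage = "chem_network"
        similarity: set = set()
        reaction: set = set()
        if config.annotation_path:
            annotations = read_annotations(config.annotation_path)
            cohort = {
                n: a for n, a in annotations.items()
                if n in set(table.metabolite_names)
            }
            fps = fingerprints_from_annotations(cohort)
            similarity = build_similarity_layer(
                fps, config.tanimoto_threshold
            )
        if config.reaction_pairs_path:
            reaction = build_reaction_layer(
                config.reaction_pairs_path, set(table.metabolite_names)
            )
        network = assemble_network(
            similarity, reaction, primary.results,
            threshold=config.tanimoto_threshold,
        )
        write_sif(network, out / "network.sif")
        outputs["network.sif"] = _sha256(out / "network.sif")
        write_node_attributes(network, out / "network_nodes.tsv")
        outputs["network_nodes.tsv"] = _sha256(out / "network_nodes.tsv")
        write_graphml(network, out / "network.graphml")
        outputs["network.graphml"] = _sha256(out / "network.graphml")

        # --- stage 6: consensus ---------------------------------------
        stage = "consensus"
        consensus_payload: dict = {}
        if "hom_vs_gal4" in comparisons:
            consensus_payload["allele_discordance"] = allele_discordance(
                comparisons["hom_vs_gal4"].results,
                panel_size=table.n_metabolites, alpha=config.alpha,
            )
        if "gal4_vs_wt" in comparisons:
            venn = allele_specific_sets(primary, comparisons["gal4_vs_wt"])
            consensus_payload["allele_specific"] = {
                k: sorted(v) for k, v in venn.items()
            }
        if "gal4_vs_rescue" in comparisons:
            calls = consensus_call(primary, comparisons["gal4_vs_rescue"])
            consensus_payload["consensus"] = [
                {"metabolite": c.metabolite, "direction": c.direction,
                 "p_mut_vs_wt": c.p_mut_vs_wt,
                 "p_deficient_vs_rescue": c.p_deficient_vs_rescue}
                for c in calls
            ]
        save_json("consensus.json", consensus_payload)
    except TableError as err:
        raise TableError(f"stage {stage}: {err}") from err

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": outputs,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return manifest


def replicate_table1(alpha: float = 0.05) -> dict:
    """Recompute the headline statistics of the packaged differential
    table from its printed values alone: the significance-filter counts,
    the fold-change extremes, and the styled network node attributes."""
    results = load_table1(alpha=alpha)
    counts = summarize_filter(results, alpha=alpha)
    extremes = rank_extremes(results)
    network = assemble_network(set(), set(), results)
    nodes = {
        n: dict(network.nodes[n]) for n in sorted(network.nodes)
    }
    return {
        "counts": counts,
        "max_fold_change": {
            "metabolite": extremes["largest_fold_change"][0].metabolite,
            "fold_change": extremes["largest_fold_change"][0].fold_change,
        },
        "second_fold_change": {
            "metabolite": extremes["largest_fold_change"][1].metabolite,
            "fold_change": extremes["largest_fold_change"][1].fold_change,
        },
        "min_p": {
            "metabolite": extremes["smallest_p"][0].metabolite,
            "p_value": extremes["smallest_p"][0].p_value,
            "fold_change": extremes["smallest_p"][0].fold_change,
        },
        "nodes": nodes,
    }
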