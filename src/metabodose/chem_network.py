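"""Two-layer metabolic network: Tanimoto chemical similarity + reaction pairs.

Nodes are cohort metabolites; edges come in two tagged layers. The
similarity layer connects pairs whose binary substructure fingerprints
have Tanimoto coefficient (|intersection| / |union|) at or above a cutoff
(0.7 by default). The reaction-pair layer connects metabolites
interconverted by a single enzymatic reaction, read from a curated edge
list. Differential results style the nodes: size grows with |log2 fold
change| and color marks direction (red up, blue down) only for
significant metabolites.

Fingerprints are either supplied precomputed (hex-encoded bit strings,
the canonical reproducible path) or computed from SMILES as Morgan
circular fingerprints (radius 2, 1024 bits); the scheme is recorded in
the graph metadata because edge sets depend on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .core_data import MetaboliteAnnotation, TableError
from .differential import DifferentialResult

__all__ = [
    "Fingerprint",
    "tanimoto",
    "fingerprints_from_annotations",
    "build_similarity_layer",
    "build_reaction_layer",
    "assemble_network",
    "write_sif",
    "read_sif",
    "write_node_attributes",
    "write_graphml",
    "read_graphml",
]

log = logging.getLogger(__name__)

MORGAN_RADIUS = 2
MORGAN_NBITS = 1024


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint as a set of on-bits."""

    bits: frozenset[int]
    n_bits: int
    provenance: str = "given"

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.n_bits:
            raise TableError("fingerprint bit index out of range")

    @classmethod
    def from_hex(cls, text: str, provenance: str = "given") -> "Fingerprint":
        """Hex string -> bit set; bit 0 is the MSB of the first nibble."""
        text = text.strip()
        n_bits = 4 * len(text)
        value = int(text, 16)
        bits = frozenset(
            i for i in range(n_bits) if value >> (n_bits - 1 - i) & 1
        )
        return cls(bits=bits, n_bits=n_bits, provenance=provenance)

    @classmethod
    def from_smiles(cls, smiles: str) -> "Fingerprint":
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise TableError(f"unparseable SMILES: {smiles!r}")
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=MORGAN_RADIUS, fpSize=MORGAN_NBITS
        )
        fp = gen.GetFingerprint(mol)
        return cls(
            bits=frozenset(int(b) for b in fp.GetOnBits()),
            n_bits=MORGAN_NBITS,
            provenance="computed-from-SMILES",
        )

    def to_hex(self) -> str:
        value = 0
        for i in self.bits:
            value |= 1 << (self.n_bits - 1 - i)
        return format(value, f"0{self.n_bits // 4}x")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b|; symmetric, in [0, 1]."""
    if a.n_bits != b.n_bits:
        raise TableError("fingerprints have different bit lengths")
    union = a.bits | b.bits
    if not union:
        raise TableError("Tanimoto undefined for two empty fingerprints")
    return len(a.bits & b.bits) / len(union)


def fingerprints_from_annotations(
    annotations: dict[str, MetaboliteAnnotation],
) -> dict[str, Fingerprint]:
    """Resolve each annotated metabolite to a fingerprint; metabolites
    without structure are skipped with a logged warning (they stay in the
    network as nodes, just without similarity edges)."""
    fps: dict[str, Fingerprint] = {}
    n_bits_seen: set[int] = set()
    for name, ann in annotations.items():
        if ann.fingerprint_hex:
            fps[name] = Fingerprint.from_hex(ann.fingerprint_hex)
        elif ann.smiles:
            fps[name] = Fingerprint.from_smiles(ann.smiles)
        else:
            log.warning("no structure for %s; excluded from similarity layer",
                        name)
            continue
        n_bits_seen.add(fps[name].n_bits)
    if len(n_bits_seen) > 1:
        raise TableError(
            f"inconsistent fingerprint lengths: {sorted(n_bits_seen)}"
        )
    return fps


def build_similarity_layer(
    fingerprints: dict[str, Fingerprint], threshold: float = 0.7
) -> set[tuple[str, str, float]]:
    """All-pairs Tanimoto edges at or above the cutoff, endpoints ordered
    by name."""
    if not (0.0 < threshold <= 1.0):
        raise TableError("similarity threshold must be in (0, 1]")
    names = sorted(fingerprints)
    edges: set[tuple[str, str, float]] = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            score = tanimoto(fingerprints[a], fingerprints[b])
            if score >= threshold:
                edges.add((a, b, score))
    return edges


def build_reaction_layer(
    pairs_file: str | Path, node_names: set[str]
) -> set[tuple[str, str]]:
    """Read a two-column (tab or comma) metabolite-pair edge list,
    keeping only pairs with both endpoints in the cohort; pairs are
    order-normalized and deduplicated."""
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(
        Path(pairs_file).read_text().splitlines(), start=1
    ):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in
                 (line.split("\t") if "\t" in line else line.split(","))]
        if len(parts) != 2 or not all(parts):
            raise TableError(
                f"{pairs_file}:{lineno}: expected exactly two metabolite names"
            )
        a, b = parts
        if a == b:
            raise TableError(f"{pairs_file}:{lineno}: self-pair {a!r}")
        if a not in node_names or b not in node_names:
            log.info("reaction pair (%s, %s) dropped: endpoint not in cohort",
                     a, b)
            continue
        edges.add((min(a, b), max(a, b)))
    return edges


def node_size(abs_log2_fc: float, min_size: float = 10.0,
              max_size: float = 60.0, slope: float = 10.0) -> float:
    """Affine, monotone map from |log2 FC| to a display size, clipped."""
    return float(min(max_size, min_size + slope * abs_log2_fc))


def assemble_network(
    similarity: set[tuple[str, str, float]],
    reaction: set[tuple[str, str]],
    differential: list[DifferentialResult],
    threshold: float = 0.7,
    size_min: float = 10.0,
    size_max: float = 60.0,
) -> nx.MultiGraph:
    """Merge both edge layers over differential-styled nodes.

    A pair present in both layers keeps two tagged parallel edges (typed
    interactions). Node color is assigned only to significant
    metabolites: red for fold change > 1, blue for < 1.
    """
    import math

    by_name = {r.metabolite: r for r in differential}
    graph = nx.MultiGraph(
        fingerprint_scheme=f"morgan-r{MORGAN_RADIUS}-{MORGAN_NBITS}bit",
        similarity_threshold=threshold,
    )
    for name, r in by_name.items():
        attrs = {
            "fold_change": r.fold_change,
            "p_value": r.p_value,
            "direction": r.direction,
            "significant": r.significant,
            "node_size": node_size(
                abs(math.log2(r.fold_change)), size_min, size_max
            ),
        }
        if r.significant:
            attrs["node_color"] = "red" if r.fold_change > 1.0 else "blue"
        graph.add_node(name, **attrs)

    for a, b, score in similarity:
        for n in (a, b):
            if n not in by_name:
                raise TableError(f"similarity edge endpoint {n!r} lacks a "
                                 "differential result")
        graph.add_edge(a, b, key="similarity", layer="similarity",
                       tanimoto=score)
    for a, b in reaction:
        for n in (a, b):
            if n not in by_name:
                raise TableError(f"reaction edge endpoint {n!r} lacks a "
                                 "differential result")
        graph.add_edge(a, b, key="reaction_pair", layer="reaction_pair")
    return graph


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def write_sif(graph: nx.MultiGraph, path: str | Path) -> None:
    """Three-column SIF: node <TAB> layer <TAB> node, one line per tagged
    edge; isolated nodes appear as single-column lines."""
    lines = []
    connected: set[str] = set()
    for a, b, data in sorted(
        graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["layer"])
    ):
        lines.append(f"{a}\t{data['layer']}\t{b}")
        connected |= {a, b}
    for node in sorted(set(graph.nodes) - connected):
        lines.append(node)
    Path(path).write_text("\n".join(lines) + "\n")


def read_sif(path: str | Path) -> nx.MultiGraph:
    graph = nx.MultiGraph()
    for lineno, line in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            graph.add_node(parts[0])
        elif len(parts) == 3:
            a, layer, b = parts
            graph.add_edge(a, b, key=layer, layer=layer)
        else:
            raise TableError(f"{path}:{lineno}: malformed SIF line")
    return graph


def write_node_attributes(graph: nx.MultiGraph, path: str | Path) -> None:
    """Cytoscape-style node attribute TSV."""
    header = "name\tfold_change\tp_value\tnode_size\tnode_color"
    rows = [header]
    for node in sorted(graph.nodes):
        d = graph.nodes[node]
        rows.append(
            f"{node}\t{d.get('fold_change', '')}\t{d.get('p_value', '')}"
            f"\t{d.get('node_size', '')}\t{d.get('node_color', '')}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def write_graphml(graph: nx.MultiGraph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path: str | Path) -> nx.MultiGraph:
    return nx.read_graphml(path, force_multigraph=True)
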