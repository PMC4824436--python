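"""Build the two-layer metabolic network over the printed panel.

Chemical-similarity edges come from pairwise Tanimoto comparison of
Morgan fingerprints (cutoff 0.7) computed from the packaged demo SMILES;
biochemical edges come from the packaged curated reaction-pair list.
Nodes are styled by the printed differential results: size tracks
|log2 fold change|, color marks direction for significant metabolites.
Exports SIF + node attributes + GraphML into ./network_out/.
"""

from pathlib import Path

import metabodose as md
from metabodose.fixtures import (
    demo_annotations_path,
    demo_reaction_pairs_path,
)

results = md.load_table1()
cohort = {r.metabolite for r in results}

annotations = md.read_annotations(demo_annotations_path())
fingerprints = md.fingerprints_from_annotations(
    {n: a for n, a in annotations.items() if n in cohort}
)
similarity = md.build_similarity_layer(fingerprints, threshold=0.7)
reaction = md.build_reaction_layer(demo_reaction_pairs_path(), cohort)
network = md.assemble_network(similarity, reaction, results)

out = Path("network_out")
out.mkdir(exist_ok=True)
md.write_sif(network, out / "network.sif")
md.write_node_attributes(network, out / "network_nodes.tsv")
md.write_graphml(network, out / "network.graphml")

n_sim = sum(1 for *_, d in network.edges(data=True)
            if d["layer"] == "similarity")
n_rxn = network.number_of_edges() - n_sim
print(f"{network.number_of_nodes()} nodes, "
      f"{n_sim} similarity edges (Tanimoto >= 0.7), "
      f"{n_rxn} reaction-pair edges -> {out}/")
colored = [n for n in network.nodes if "node_color" in network.nodes[n]]
print(f"{len(colored)} significant nodes carry a color attribute")
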