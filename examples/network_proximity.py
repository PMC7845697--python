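"""Score a compound against a disease with network proximity and propagation.

Builds a toy interaction network, places a disease module and one compound
whose targets neighbour it, and prints the five proximity distances plus the
random-walk-with-restart disease score.  Smaller distances (and larger
propagation scores) mean the compound's targets sit closer to the disease
neighbourhood.
"""

import networkx as nx

from phytoscreen.interaction_features import (
    PROXIMITY_METHODS,
    PropagationProblem,
    build_seed_vector,
    disease_score,
    node_index,
    normalize_adjacency,
    rwr,
)
from phytoscreen.io_core import CompoundProfile

graph = nx.Graph()
graph.add_edges_from([
    ("t1", "g1"), ("g1", "g2"), ("g2", "g3"), ("g1", "g3"),  # disease module
    ("t2", "x1"), ("x1", "x2"), ("x2", "g3"),                # a longer route
    ("x1", "t1"),
])
disease_genes = {"g1", "g2", "g3"}
profile = CompoundProfile("cmp", direct_targets={"t1"}, indirect_targets={"t2"})

print("proximity of compound targets {t1,t2} to module {g1,g2,g3}:")
for name, method in PROXIMITY_METHODS.items():
    d = method(profile.targets, disease_genes, graph)
    print(f"  {name:<10} {d: .3f}")

index = node_index(graph)
p0, _ = build_seed_vector(profile, index)   # direct target weighted 1.0, indirect 0.3
p, iterations = rwr(PropagationProblem(W=normalize_adjacency(graph), p0=p0, r=0.7))
score = disease_score(p, disease_genes, index)
print(f"RWR disease score (restart 0.7, {iterations} iterations): {score:.3f}")
print("the score is the stationary walker mass on the disease genes;")
print("a target adjacent to the module concentrates mass there.")
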