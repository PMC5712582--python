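"""Curation round: sample edges, simulate verdicts, score agreement.

Samples 60 edges from a synthetic graph (15 shared across all 3 curators),
simulates curator verdicts with a known accept rate, and reports accuracy
(majority rule on shared edges) and Fleiss' kappa over the shared subset.
"""

import itertools
import random

from cellkine.curation import accuracy, fleiss_kappa, sample_edges
from cellkine.graph import KGEdge, KnowledgeGraph

rng = random.Random(0)
pairs = list(itertools.product([f"cell{i}" for i in range(20)], [f"CYT{j}" for j in range(20)]))
graph = KnowledgeGraph(
    [KGEdge(c, k, rng.random(), 0.1, (("p1", "S."),)) for c, k in rng.sample(pairs, 200)]
)

assignment = sample_edges(graph, n_total=60, n_curators=3, n_shared=15, seed=1)
print(f"sampled {len(assignment.sampled_edges)} edges; "
      f"each of 3 curators rates {len(assignment.per_curator[0])} (15 shared)")

# simulate three curators who accept ~70% of edges, with independent noise
verdicts: dict[tuple[str, str], list[str]] = {}
matrix = []
for edge in assignment.sampled_edges:
    raters = [c for c, edges in enumerate(assignment.per_curator) if edge in edges]
    votes = ["accept" if rng.random() < 0.7 else "reject" for _ in raters]
    verdicts[edge] = votes
    if len(raters) == 3:
        matrix.append([votes.count("accept"), votes.count("reject")])

print(f"graph accuracy (majority on shared edges): {accuracy(verdicts):.3f}")
print(f"Fleiss' kappa on the {len(matrix)} shared edges: {fleiss_kappa(matrix):.3f}")
print("-> kappa near 0 is expected here: simulated verdicts are independent coin flips")
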