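"""Map-equation communities and the structure-vs-cooperation relation.

Detects flow communities of the provider network by greedily minimizing
the two-level map equation, tabulates per-community structure (degree,
strength, distance, clustering, assortativity) and the geometric mean of
strength mu_G(s) as the community's cooperation level, then regresses
mu_G(s) on the structural features across communities.
"""

import carenet as cn
from carenet.community import (
    community_features,
    detect_communities,
    structure_vs_cooperation,
)

cfg = cn.SynthConfig(n_patients=600, n_providers=120, seed=42)
providers, patients, claims, truth = cn.simulate(cfg)
G = cn.giant_component(cn.project_cosine(cn.build_bipartite(claims), providers))

part = detect_communities(G, seed=0)
print(f"two-level map equation: {part.n_communities} communities, "
      f"L = {part.L:.3f} bits")

table = community_features(G, part, providers, cn.strengths(G))
cols = ["community", "n_nodes", "n_edges", "avg_degree", "avg_strength",
        "avg_distance", "avg_clustering", "assortativity", "mu_g_s"]
print(table[cols].head(7).round(3).to_string(index=False))

big = table[table["n_nodes"] >= 5]
rel = structure_vs_cooperation(big)
print("\nmu_G(s) vs structure across communities "
      "(slope / Pearson r per feature):")
print(rel.round(3).to_string(index=False))
print("\nshorter-distance, less disassortative communities carry higher "
      "cooperation in this run")
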