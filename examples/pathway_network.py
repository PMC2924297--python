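"""From pathway states to a learned Bayesian network with link strengths.

Pathway states are called by pooling member-gene means per experiment;
GES then searches equivalence classes under the BIC score, the CPDAG is
extended to a DAG, CPTs are fitted, and each edge's influence is reported
as the entropy-reduction ('true link strength') percentage.
"""

import synechonet as sn

truth = sn.random_network(6, edge_prob=0.4, coupling=0.85, seed=1)
compendium, ledger = sn.generate_compendium(
    n_genes=300, n_experiments=300, n_core=0, n_regulators=1,
    targets_per_regulator=1, network=truth, genes_per_pathway=8, seed=2,
    replicate_range=(3, 5),
)

pw = sn.build_pathway_state_matrix(compendium, ledger.membership, alpha=0.05)
reports = sn.select_pathways(pw, ledger.membership, min_genes=3, min_frac=0.10)
selected = [r.pathway for r in reports if r.selected]
print(f"pathways selected for modelling: {selected}")

data = sn.to_observations(pw)
cpdag = sn.ges(data, max_parents=4)
print(f"learned CPDAG: directed {sorted(cpdag.directed_edges)}, "
      f"undirected {sorted(tuple(sorted(e)) for e in cpdag.undirected_edges)}")
print(f"true edges: {sorted(truth.dag.edges)}")

dag = sn.cpdag_to_dag(cpdag)
model = sn.fit_cpts(dag, data, pseudocount=1.0)
print("edge strengths (percent of child entropy explained by the parent):")
for ls in sn.all_link_strengths(model):
    print(f"  {ls.parent} -> {ls.child}: {ls.percent:.1f}%")
# Strengths well above 0 mean the parent's state materially constrains the
# child's; 100% would be a deterministic copy.
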