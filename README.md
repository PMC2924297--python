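# synechonet

Integrative analysis of multi-experiment expression compendia for
*Synechocystis*-style cyanobacterial studies. Microarray experiments from
different laboratories and platforms cannot be compared on fold-change
amplitude; they can be compared on the *direction* of regulation. This
package discretizes replicate log2(treatment/control) ratios into trinary
states, identifies the genes that respond to almost everything (the core
transcriptional response), links them to candidate regulators, collapses
genes into KEGG-pathway states, learns a Bayesian network over pathways,
and answers "what happens to everything else if I push this pathway down?"
by exact probabilistic inference. It is written for computational
biologists integrating heterogeneous stress-response compendia, and ships
a synthetic-data generator with full ground truth so that every stage is
testable without any downloads.

## The methods in brief

- **Discretization.** For gene *g* in experiment *e* with replicate
  log-ratios x₁…xₙ (n ≥ 3), a one-sample Kolmogorov–Smirnov test compares
  the sample against a zero-mean reference N(0, σ̂). If the null is
  rejected at α = 0.05 the state is sign(x̄) ∈ {+1, −1}, else 0.
- **Core transcriptional response (CTR).** Genes whose state is nonzero in
  more than 50% of the experiments where they are observed. Plasmid-encoded
  genes are removed first.
- **Coregulation.** For a regulatory gene r and target t, agreement =
  1 − d_H(r, t)/n over jointly observed experiments (d_H = Hamming
  distance); edges are drawn above 60% agreement, plus a greedy set cover
  reporting which regulators jointly cover the CTR.
- **Pathway states.** Member-gene means in one experiment are pooled into
  a population and passed through the same KS construction, giving each
  pathway a trinary state in every experiment; pathways with < 3 genes or
  rare regulation are dropped.
- **Network.** Greedy Equivalence Search over CPDAGs with the decomposable
  BIC score, BIC = Σ log L̂(node | parents) − (d/2)·ln M; CPTs by
  Laplace-smoothed counts; edge influence as the true-link-strength
  percentage 100·(H(child) − H(child | parent))/H(child) in bits.
- **Inference.** Moralize, min-fill triangulate, build a junction tree, and
  run two-pass sum-product message passing; perturbation scenarios clamp
  pathways to states and report signed posterior changes per node.

## Worked example

`examples/pathway_network.py` simulates 300 experiments from a known
6-pathway network (coupling 0.85), calls pathway states, learns the
structure and quantifies the edges:

```
pathways selected for modelling: ['P01', 'P02', 'P03', 'P04', 'P05', 'P06']
learned CPDAG: directed [('P01', 'P04'), ('P01', 'P06'), ('P03', 'P04'),
                         ('P04', 'P05'), ('P05', 'P06')], undirected []
true edges: [('P01', 'P04'), ('P01', 'P06'), ('P03', 'P04'),
             ('P04', 'P05'), ('P05', 'P06')]
edge strengths (percent of child entropy explained by the parent):
  P01 -> P04: 15.9%
  P01 -> P06: 14.4%
  P03 -> P04: 14.6%
  P04 -> P05: 37.2%
  P05 -> P06: 22.2%
```

The learned equivalence class matches the generating DAG exactly here, and
the strengths say, e.g., that knowing P04's state removes 37% of the
uncertainty about P05's. The other scripts in `examples/` walk through
discretization, CTR + coregulation + the PerR-consensus motif survey,
perturbation scenarios, and the end-to-end pipeline; each prints the
numbers it computes and what they mean.

A thin CLI mirrors the stages (`synechonet run|simulate|discretize|ctr|
coregulate|pathways|learn|strength|infer|scan`); `synechonet run --config
config.yaml` executes everything and writes per-stage TSVs plus a manifest
that fully determines the run.

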