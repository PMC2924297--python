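# Methods

This note documents the statistical procedures, their assumptions, the
tunable parameters, and the deliberate design choices, in the order the
pipeline applies them.

## Normalization

`lowess_normalize` removes intensity-dependent dye bias from two-channel
records: with treatment and control intensities T and C, it computes
M = log2(T/C) and A = ½·log2(T·C) and fits a robust locally weighted
linear regression of M on A. Weights are tricube over the `span` fraction
of nearest neighbours (default 0.3); after each of `robust_iterations`
(default 3) passes, points are reweighted by a bisquare of residuals
scaled by 6·median|residual|. A degenerate robust scale (median residual
exactly 0, as happens when the bulk is perfectly interpolated) keeps
zero-residual points and drops the rest, so a lone outlier cannot drag the
trend to itself. The implementation agrees with
`statsmodels.nonparametric.lowess` to ~1e-14 on non-degenerate data (a
test asserts this) but handles the degenerate case explicitly. The fit
needs at least 10 records. Most users start from already-normalized
log-ratio compendia and never call this.

## Trinary discretization

Replicate log-ratios are reduced to {−1, 0, +1} per (gene, experiment) by
a one-sample KS test against a zero-mean reference. The reference is a
named strategy:

- `fitted` (default): N(0, σ̂) with σ̂ the sample standard deviation of
  the cell's own replicates. This isolates a pure location shift and needs
  no user parameter.
- `pooled`: N(0, σ_pooled) with a per-experiment scale pooled across genes
  (√(ΣSS/Σdof)); useful when per-cell replicate counts are tiny and the
  platform noise is homogeneous.

Asymptotic KS p-values are used. With the fitted scale this construction
is deliberately conservative: on null Gaussian replicates the nonzero-call
rate at α = 0.05 is ≈ 6–7% at n = 4 and ≈ 4–5% at n = 6–8 (exact
small-sample p-values would push n = 4 to ≈ 10%, which is why the
asymptotic form is the right partner for the fitted scale). A calibration
test asserts the [0.005, 0.07] bracket by simulation.

Degenerate inputs: fewer than `min_replicates` (default 3) finite values
gives state 0 with undefined p (a single replicate cannot support a test);
zero-variance samples take the sign of the common value directly, since
the KS statistic is undefined there. Cells never measured are missing, and
experiments in which no gene reaches `min_replicates` are reported as
under-replicated so the caller can exclude them from gene-level analyses
(the pipeline does). Calls are invariant to gene/experiment order, and
shrinking α can only remove calls.

## Core transcriptional response

Per gene, the regulation fraction is (#experiments with state ≠ 0) /
(#experiments with a state present); missing cells leave both counts. The
CTR is the set with fraction strictly greater than `ctr_threshold`
(default 0.5) — strict because the defining notion is "more than half".
Genes observed nowhere are reported separately rather than silently
dropped. The summary percentage is rounded to the nearest integer (ties
away from zero). Plasmid-encoded genes are removed before all of this;
the annotation table drives the filter and unannotated genes are a hard
error, not a silent pass-through.

## Coregulation network

Agreement between two trinary profiles is the fraction of jointly
observed experiments carrying identical states, i.e. 1 − normalized
Hamming distance. Positions where either profile is missing are excluded
from numerator and denominator — penalizing platform absence would
conflate coverage with disagreement. Pairs with no joint observation are
an explicit undefined-agreement signal. Edges require agreement strictly
above `coregulation_cutoff` (default 0.6, anchored by the divergently
transcribed perR/aphC promoter pair whose profiles agree in 61% of
experiments). A greedy set cover (largest marginal target gain,
lexicographic ties) reports which regulators jointly cover a requested
fraction of the CTR; greedy is a documented convention, not a claim of
optimality.

## Motif survey

`scan_consensus` finds exact IUPAC matches (all 15 ambiguity codes) of a
consensus in upstream sequences, overlapping matches included, 0-based
offsets. The default 15-bp PerR consensus TTATAATNATTATAA is its own
reverse complement, so the default scan is single-strand; a
`both_strands` flag exists for non-palindromic consensi and reports
reverse-strand hits on forward coordinates. Upstream-region extraction is
the caller's responsibility; the synthetic generator uses 300 bp windows.

## Pathway states

For one pathway in one experiment, the per-gene replicate means of its
member genes form a population tested with the same KS construction
(sign of the population mean sets the direction). Means rather than raw
replicates are pooled so that a heavily replicated gene cannot dominate
the pathway call; `pooling="raw"` is available as a sensitivity analysis.
Pathway calls use **all** experiments — a single replicate contributes its
value to the pool — because pooling across members restores statistical
support that individual genes lack. Genes in several pathways contribute
to each. Pathways are selected for network modelling when they have at
least `min_genes` (default 3) members and are regulated in at least
`min_frac` (default 0.10) of experiments; the 0.10 default is an explicit,
documented surrogate for a manual curation step that has no stated numeric
criterion.

## Structure learning

The score is BIC on the natural-log scale,
Σ_nodes log L̂(node | parents) − (d/2)·ln M with d = Σ (r−1)·q free
multinomial parameters (r = 3 states, q = parent configurations, M =
experiments). It decomposes over (node, parent-set) families (cached) and
is likelihood-equivalent, so Markov-equivalent DAGs score identically — a
test asserts this exhaustively on 3 nodes.

GES searches equivalence classes directly: the forward phase repeatedly
applies the valid Insert(X, Y, T) with the largest positive gain
(validity: NA_YX ∪ T a clique; every semi-directed Y⇝X path blocked), the
backward phase the best Delete(X, Y, H) (NA_YX \ H a clique). After each
operator the graph is re-completed to a CPDAG (consistent extension, then
v-structure pattern closed under the orientation rules). Ties go to the
lexicographically smallest (parent, child, subset) move, making runs
reproducible. `max_parents` (default 4) caps family enumeration: with
3-state nodes a fifth parent already gives more free parameters per family
than a pathway-scale compendium has observations. Constant columns simply
never gain score and remain isolated.

CPDAG → DAG extension uses the Dor–Tarsi procedure, consuming eligible
nodes in reverse-lexicographic order so the later node of an undirected
pair becomes the sink (A—B extends to A→B). The extension provably
preserves skeleton and v-structures (tested on random instances); which
consistent extension is displayed is a convention, not an inference.

CPTs are (count + pseudocount)/(total + 3·pseudocount) with Laplace
pseudocount 1 by default; unseen parent configurations then fall back to
uniform. The BIC score itself always uses raw MLE counts.

## Link strength

For an edge parent → child, the strength is
100·(H(child) − H(child | parent))/H(child), entropies in bits, computed
from the exact model-implied pairwise joint (all other variables
marginalized by variable elimination). It is 0 iff the pair is independent
in the model joint, 100 for a deterministic copy of a uniform parent, and
0 by convention when H(child) = 0. The default marginal form matches the
single-parent phrasing of the measure; `mode="conditional"` instead
conditions on the child's co-parents (conditional mutual information over
conditional entropy), which attributes influence more sharply when parents
are correlated.

## Junction-tree inference

The DAG is moralized, triangulated by min-fill elimination (lexicographic
ties), and its maximal cliques joined by a maximum-weight spanning tree on
separator sizes (Kruskal with a deterministic edge order); components of a
disconnected model are joined with empty separators so the result is one
tree. Each CPT multiplies into exactly one clique containing its family.
Propagation is Shafer–Shenoy two-pass sum-product, so marginals are
independent of the root (tested). Only hard evidence is supported —
scenarios clamp pathways to observed states. Evidence with zero
probability under the model raises an explicit impossible-evidence error
rather than dividing by zero; with MLE-fitted CPTs (pseudocount 0) this is
a real, reportable outcome. Exact inference is entirely adequate at the
treewidths induced by pathway-scale networks; no approximate inference is
provided.

## Synthetic data

The generator emulates the statistical structure of a heterogeneous
stress-response compendium and is a pure function of its seed:

- experiments with 2–8 replicates (uniform), so the min-replicates gate is
  genuinely exercised and a realistic fraction of experiments is usable
  only at pathway level;
- core genes shifted by ±`effect_size` (random sign per gene×experiment)
  in 70% of experiments; condition-specific background genes in 10%;
- regulator profiles active in half the experiments, targets copying the
  regulator's state with probability 0.8 (otherwise one of the two other
  states);
- pathway member genes following pathway states ancestrally sampled from
  a known random network (12 pathways × 8 genes, forward-edge probability
  0.3, parent-agreement coupling 0.85 by default);
- replicate noise N(0, σ = 0.3) around `effect_size` = 2.0 · state, or a
  scaled t(3) in the heavy-tail mode;
- 5% of background genes annotated as plasmid-encoded so the chromosomal
  filter does real work; 3000 genes × 60 experiments by default.

Effect 2.0 at σ 0.3 corresponds to a clearly differentially expressed
gene (≈ 4-fold, signal-to-noise ≈ 6.7) — the regime in which the original
discretize-then-integrate design is intended to operate. What the
generator does **not** emulate: dye-swap designs, probe-level artifacts,
batch/laboratory effects, correlated noise across genes, and
platform-specific missingness patterns. Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
assumptions, not robustness to every failure mode of real microarray
compendia (the heavy-tail mode probes one such deviation).

Gene roles (pathway member / regulator / target / core / background) are
disjoint blocks by construction; requesting more role genes than exist is
an error. The ground-truth ledger records everything needed to score every
stage — planted cores, regulator pairs, the true network, the planted
pathway- and gene-state matrices — without re-reading generator internals.

## Problem sizes used in the checks

The bundled checks run the discretizer calibration on 10,000 null genes
with 4 replicates; junction-tree equivalence against exhaustive
enumeration on fifty 8-node models (3⁸ joint states); GES recovery on
6-node networks at coupling 0.85 with M = 5000 over ten seeds (≥ 9
expected to match skeleton and v-structures — a random draw can
occasionally produce a class that is hard to separate at finite M); and
the end-to-end recovery on the default 3000 × 60 synthetic study. These
sizes exercise every code path at full fidelity while keeping a complete
run in the tens of seconds on a single core.

## Known limitations

- The zero-mean reference for the KS test is a modelling choice; the
  strategy seam (`fitted` / `pooled`) exists precisely because the
  construction used by the original analyses of this kind is typically
  under-specified. Conclusions that depend on the exact null calibration
  at n = 3–4 replicates should be checked under both.
- One row per gene is assumed; multi-probe reconciliation across platforms
  is upstream of this package.
- The learned network is an equivalence class; displayed edge directions
  beyond compelled ones are conventions.
- Link-strength percentages depend on the fitted CPTs and hence on the
  pseudocount at small M.
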