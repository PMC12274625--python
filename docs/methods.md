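# Methods

This note records the models, parameter choices and numerical decisions
behind `radnet`, and what the synthetic benchmark does and does not show.

## Study design emulated by the generator

The synthetic module emulates a paired irradiation study: each of five
donors contributes one control and one irradiated sample, and expression is
measured on a mixed panel of genes, transcription factors and miRNAs. The
default scale (2,000 genes, 80 TFs, 150 miRNAs) is a deliberate ~1:8
reduction of a realistic blood-lymphocyte panel so the full pipeline and the
test suite run in seconds; all rates and effect sizes are kept at realistic
values rather than scaled with the panel.

Per feature, log2 expression is baseline + donor shift + noise, with a
planted ±`effect_lfc` added to irradiated samples of true differential
features. Planted-feature count is `round(frac_true_de × n_features)`
(default 5%), signs 50/50. Noise variances follow a scaled inverse
chi-square family `s0²·d0/χ²(d0)` with `d0 = 4` and `s0 = noise_sd`
(default 0.5 log2 units). The family is planted on the scale the moderated
t estimates — the per-donor *difference* variance (each sample carries half
of it) — so a method-of-moments fit on generated data recovers `(d0, s0²)`
directly; the test suite checks exactly that.

The interactome budget is `density × n_nodes` edges (default 3 per node),
split 70/20/8/2 across PPI, miRNA–gene, TF–gene and TF–miRNA layers. The
PPI layer grows by preferential attachment over the protein nodes and is
topped up with degree-proportional extra edges to hit its budget exactly;
regulator edges attach to genes with degree-proportional probability, so
hubs arise naturally in all layers. Planted cliques (defaults: one 6-clique
and one 5-clique) are embedded in the PPI layer with confidences in the
upper part of `confidence_range` (at least 0.75 when the range allows) so
they survive the strict >0.7 confidence filter; background PPI confidences
are uniform over the whole range. One self-loop and one duplicate PPI row
are injected on purpose to exercise the cleaning stage.

Annotation structure is planted the same way: a few gene sets and diseases
are stacked with true differential features well above their random share,
and one reversal compound's reference ranking pushes planted up-features to
the bottom and down-features to the top.

What the generator does **not** emulate: probe-level microarray artifacts
(beyond ids for the collapse test), correlated co-expression, batch
effects, miRNA–target expression coupling, and annotation databases with
realistic ontology structure. Passing tests therefore demonstrate that each
algorithm recovers the signal class it is designed for — not that the
pipeline is robust to every failure mode of real array data.

## Differential expression

Moderated paired t with Smyth-style empirical Bayes: hyperparameters
`(d0, s0²)` are fitted by matching the mean and variance of `log s²` using
digamma/trigamma identities, inverting the trigamma by Newton iteration.
If the trigamma equation has no positive solution the prior df are taken as
infinite (pure pooling). Zero-variance features are shrunk to the pooled
posterior and logged rather than dropped. `d0_override` exposes the
unmoderated (`0`) and fully pooled (`inf`) limits, which the tests compare
against an ordinary paired t and a common-scale t respectively.

Calling rules: genes on BH-adjusted p, miRNAs on raw p (a small miRNA panel
yields nothing at FDR level in a 5-donor design, so the raw-p rule is the
pragmatic standard; it is an explicit, overridable flag). The fold-change
inequality `|log2FC| > 1` is strict; p thresholds are inclusive.

## Propagation

The update `DDₜ = r·W·DDₜ₋₁ + (1−r)·DD₀` is implemented with `r = 0.7`
multiplying the **walk** term, i.e. restart mass 0.3. Describing `r` as a
"restart probability" usually implies the opposite assignment; both
behaviours are supported (`r_is_restart_mass=True` gives restart mass
`r`), and the default follows the update rule as written above. `W` is the
column-stochastic degree normalisation of the undirected adjacency; the
propagation rejects graphs with isolated nodes, and the pipeline restricts
to the largest connected component first (flag, default on). Convergence is
declared at L1 change < 1e−10; the map is an `r`-contraction, so the
residual decreases geometrically and the closed form
`(1−r)(I−rW)⁻¹DD₀` (kept as a test oracle) is the unique fixed point.
Key-molecule count uses `floor(top_fraction × m)` — 179 of 17,939 at 1% —
with boundary ties broken by ascending node id.

## MCODE

Reimplemented from the published algorithm: vertex weight = (highest core
number k of the closed neighbourhood) × (density of that k-core), greedy
expansion admitting neighbours with weight > seed weight × (1 −
node_score_cutoff), haircut to the 2-core, optional fluff (off by default,
as in the plugin defaults). Deviations worth noting: modules are strictly
node-disjoint (each node is consumed by the first module that admits it);
seed and neighbour visit order is descending weight then ascending node id,
making results deterministic where the original plugin's order is
unspecified; if the haircut disconnects a module the seed's component is
kept. Density excludes self-loops (the graph is simple by construction).
The score filter `score > 3` is strict and applied after post-processing.

## Enrichment, diseases, drugs

All set tests are hypergeometric upper tails. Universe choices: gene-set
validation of key molecules uses the protein-coding network nodes (miRNAs
excluded, signature and gene sets being gene-based); disease tests use the
annotated network molecules; both are arguments, not constants. Module
significance uses raw p < 0.05 (one module against a small standard
collection); per-disease and per-category significance use BH-adjusted
p ≤ 0.05. The category roll-up tests "significant diseases in category"
against Hypergeometric(N = tested diseases, K = category size,
n = significant diseases) — a disease-level reading; a molecule-level
reading would be equally defensible but is not implemented.

Connectivity scoring follows the classic rank-based KS algebra: for a tag
list of size `t` in a profile of size `n`, `a = max_j(j/t − V(j)/n)`,
`b = max_j(V(j)/n − (j−1)/t)`, statistic `a` if `a > b` else `−b`; raw
score `KSup − KSdown` when the two signs differ, else 0. Note the statistic
is not perfectly antisymmetric under profile reversal (a single tag at rank
1 of 10 scores +0.9, at rank 10 it scores −1.0); antisymmetry under
*swapping the up and down lists* is exact, and that is the invariant the
tests assert. Normalisation is batch-wise (positives by max positive,
negatives by |min negative|), "candidate drugs" are the `top_k = 10` most
negative — a rank-based operationalisation of "significant negative
scores", since no universal numeric cutoff exists for this statistic.

## Determinism and problem sizes

One `rng_seed` drives named, independent substreams (truth, expression,
interactome, annotations), so regenerating one input never perturbs
another, and reruns are byte-identical (fixed float formatting, sorted JSON
keys, no timestamps). Default problem sizes — 2,230 features, ~6,700 edge
rows, 20 compounds, 30 diseases — were chosen so a full pipeline run takes
well under a second and the whole test suite a few seconds, while every
rate of interest (calibration, sensitivity, FDR, clique recovery, reversal
ranking) is still measured on hundreds of decisions.

## Known limitations

- Single flattened network; no layer-specific or directed transition
  kernels.
- The moderated t omits array weights, trend/robust variants and
  duplicate-correlation modelling.
- Greedy disjoint MCODE will not reproduce an overlapping-complex plugin
  output node-for-node on dense graphs.
- The disease-category test treats diseases as exchangeable units; MeSH
  tree structure is not modelled.
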