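# Methods

This note documents the statistical model behind `coexcand`, the choices
made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Differential expression

The input is an FPKM matrix for two genotypes (case = high-metabolite,
control = low) with at least two biological replicates each; the package
neither re-normalizes nor models counts — FPKM is taken as given.

*Flooring.* Every FPKM value below 1 is set to 1 before fold-change
arithmetic. This is a detection floor: ratios between transcripts that
are effectively absent in both genotypes are forced to 1 (log₂FC = 0)
rather than amplifying quantification noise. Flooring is idempotent and
applied at the value level, before averaging across replicates.

*Fold change.* log₂FC = log₂(mean floored case) − log₂(mean floored
control), implemented as a difference of logarithms so that exchanging
the genotype labels negates the result exactly (bitwise), which the test
suite relies on.

*Test.* A two-sided pooled-variance Student's *t*-test on log₂(floored
FPKM) across replicates. With three replicates per genotype no dispersion
model is fittable and the *t*-test is the simplest defensible replicated
test; Welch's variant and count-based models are deliberately out of
scope. The scale is exposed (`scale="raw"` tests unlogged values) but the
log2 default is fixed. No multiple-testing correction is applied — the
DEG threshold is a fold-change filter first, and candidates are validated
downstream by qPCR rather than by FDR control. Degenerate zero-variance
comparisons return *p* = 1 for equal means and *p* = 0 otherwise, so a
constant gene can never be called and a noiseless planted effect always
is.

*Thresholds.* DEG sets are computed jointly at |log₂FC| ≥ 2, 3, 4, 5 with
*p* < α (default 0.05). Membership is nested downward by construction;
`direction` refers to the base (smallest) threshold.

## Network prediction

The co-expression network is an undirected simple graph with strictly
positive log-likelihood scores (LLS) on edges, read from a three-column
edge list. Duplicate pairs collapse to the maximum weight (with a
warning); self-loops and non-positive weights are hard errors.

*Guide scoring.* score(g) = Σ LLS(g, guide) over direct edges only.
"Closely connected" is read as 1-hop adjacency because the statistic is a
sum of edge scores, which only direct links define; diffusion or
random-walk propagation is a non-goal. Guide genes are excluded from
their own ranking by default (the point is new members), and genes with
score 0 are omitted rather than ranked last.

*Known-pathway preprocessing.* Before guide scoring, the curated pathway
list is restricted to members that have at least one edge to another
member (`connected_pathway_subset`) — an isolated "known" gene
contributes no network evidence and would only dilute the guide set.

*DEG-seeded scoring.* The same scorer seeded with the differential subset
of the connected known genes. Its candidate pool is restricted the same
way (its own seeds excluded); whether pathway genes at large should also
be excluded is not determinable, so the rule mirrors the guide approach.

*Hub enrichment.* Any gene of degree ≥ `min_degree` (default 5) is a hub;
smaller neighborhoods give degenerate p-values. For a hub with *n*
neighbors, *k* of them differential, the statistic is the one-sided
upper-tail hypergeometric P(X ≥ k) with population size `universe`
(default: all network genes; exposed because the appropriate background —
all genes or only annotated ones — is a modelling choice) and K = number
of DEGs present in the network. Ranking is by raw ascending *p*; a
Benjamini–Hochberg column is emitted for reference but never used for
selection, since the method ranks rather than thresholds.

*Determinism.* All rankings are totally ordered: statistic, then (hub
only) larger overlap *k*, then lexicographic gene id. `top_n` is a pure
prefix of that order.

## Integration

Candidates = union over approaches of (top-N genes ∩ DEGs at the base
threshold). Filtering happens **after** the top-N cut: each approach
contributes a fixed-size, comparable list, and only its differential
members graduate. Support = number of nominating approaches. Up-regulation
is reported but not enforced (an `up_only` flag exists); the expectation
that pathway candidates are up-regulated in the high-metabolite genotype
is an observation to be checked, not a constraint to be imposed. The
output order (descending support, ascending best rank, gene id) is the
package's convention.

## qPCR validation

Livak relative quantification with amplification efficiency fixed at 2:
rq = 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference per sample and ΔΔCt the
difference of genotype means. Technical replicates of a (sample, gene)
pair are averaged to one Ct before ΔCt, keeping the *t*-test at the
biological-replicate level (n = 3 per genotype). Efficiency correction
from dilution series is out of scope. Per-sample additive Ct offsets
(pipetting/efficiency artifacts common to all genes in a well) cancel in
ΔCt by construction. Concordance between platforms is sign agreement of
log₂FC (RNA-seq) with log₂ rq (qPCR), evaluated over the validated gene
panel; rq = 1 agrees only with log₂FC = 0.

## Synthetic benchmarks

The generator produces matched network + expression + qPCR data with a
planted 30-gene pathway module (defaults; all parameters configurable):

* **Network** — pathway pairs get an edge with probability 0.6 and LLS
  uniform in [2, 4]; all other pairs with probability 0.003 and LLS in
  [0.5, 1.5]. This yields a background mean degree ≈ 6 against a module
  internal degree ≈ 17, the qualitative structure of a functional network
  with a coherent biosynthetic module. Planted hubs are recorded post hoc
  as module genes whose realized degree reaches the hub threshold.
* **Expression** — log₂ FPKM = baseline + effect·[case] + noise, with
  baseline ~ N(5, 2) per gene (median FPKM ≈ 32, ~95% of genes between 2
  and 512 — typical of expressed transcripts in a leaf library, and high
  enough that planted effects are rarely erased by the FPKM floor),
  replicate noise N(0, 0.25) on the log₂ scale (log-normal FPKM, the
  simplest multiplicative noise model), three replicates per genotype.
  200 of 2,000 genes carry planted effects with |log₂FC| uniform in
  [2, 6]; 10% of them fall inside the module by default (75% in the
  recovery settings). Module DEGs are up-regulated in the case genotype —
  the direction implied by a biosynthetic module driving a
  high-metabolite phenotype — while background DEG signs are random.
* **qPCR** — Ct = 34 − log₂(FPKM) + N(0, σ); σ defaults to 0.2 cycles,
  and 0 for exact-linkage checks. The simulated reference gene is the
  most highly expressed non-differential, non-pathway gene (an actin
  analog).
* **Known-gene list** — in simulation mode the pipeline receives the
  planted *guide* subset (15 of 30 module genes) as its curated pathway
  list; the remaining members are the unknowns the method should recover.

A single integer seed drives everything; sub-streams use fixed offsets
(network: seed, expression: seed+1, qPCR: seed+2), so identical
configurations give byte-identical outputs.

*What the benchmarks do not emulate:* read-level sampling, gene-length
and library-size artifacts in FPKM, correlated (batch) noise, hub-degree
heterogeneity of real functional networks, and edge weights estimated
from the same expression data being analyzed. Passing the recovery tests
therefore demonstrates the pipeline's internal correctness and its
behavior under the planted-signal model, not performance on real tissue
libraries.

## Numerical conventions

* Zero-variance *t*-tests: *p* ∈ {0, 1} as above, never NaN.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, validated in
  the tests against exhaustive subset enumeration (N ≤ 12) to 1e-12.
* "Exact" qPCR linkage is exact up to float rounding: averaging three
  identical doubles can perturb the last ulp, so the noiseless-chain test
  asserts agreement at 1e-9 while reference-gene rq = 1 is bitwise exact.
* Edge weights and FPKM values are written with 17 significant digits so
  file round trips reproduce them exactly.
* Problem sizes in the test-suite recovery checks (10 seeds for DEG
  recovery, 20 for module recovery, 2,000 genes) keep the whole suite in
  the tens of seconds while the binomial/hypergeometric margins involved
  remain enormous relative to the thresholds being asserted.

## Known limitations

* FPKM-based fold changes with a 3-replicate *t*-test are less powerful
  and less calibrated than count-based models; the package intentionally
  reproduces the simple convention rather than improving on it.
* Hub p-values are strongly degree-dependent; comparing hubs of very
  different degree by raw *p* favors large neighborhoods. The BH column
  is provided for inspection.
* The guide score is coverage-biased: genes with many weak guide edges
  can outrank genes with one strong edge. This is inherent to the
  summed-LLS definition.
* With zero DEGs (or none in the network) the DEG-seeded and hub
  approaches return empty rankings and the pipeline reports zero
  candidates rather than failing.
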