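# Methods

`orthoconj` tests whether paralogous lineages diverge more in selective
pressure than orthologous lineages — the "ortholog conjecture" phrased in
terms of ω = dN/dS — on simulated gene families where the answer is known
by construction. This note records the models, the defaults and why, the
numerical choices, and what the simulations do and do not establish.

## Event labeling by species overlap

A rooted binary gene tree with species-annotated leaves is labeled by the
species-overlap rule: an internal node is a **duplication** iff the species
sets of its two daughter clades intersect, otherwise a **speciation**.
Duplication nodes whose descendant leaves all belong to one species are
*within-species* paralog nodes; the rest are *between-species*. The rule is
exact when no gene has been lost; gene loss can hide events and flip
labels, which is why labeling accuracy is *measured* against simulator
truth (100% at zero loss, slightly below otherwise) rather than assumed.
Non-binary nodes are rejected rather than resolved: every definition here
(two daughter lineages, Δω) presumes bifurcations. Horizontal transfer is
ignored throughout.

## Codon substitution model

Branch ω values are estimated under a Goldman–Yang-style model on the 61
sense codons of the standard nuclear code (NCBI table 1; the table id is
configurable). Instantaneous rates for single-nucleotide codon changes are

    q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous],     q_ij = 0 otherwise,

with equilibrium codon frequencies π (F3x4 from the alignment by default;
uniform available and used in oracles), transition/transversion ratio κ,
and ω multiplying nonsynonymous changes. Q is reversible with stationary
distribution π, so transition probabilities come from one symmetric
eigendecomposition per (κ, ω) and are reused across branch lengths.

**Normalization.** Q is scaled so one unit of branch length is one expected
codon substitution *at that branch's ω*. dN and dS for a branch partition
the expected flux Σ π_i q_ij t into nonsynonymous and synonymous classes
and divide by per-codon site opportunities defined from the neutral (ω = 1)
flux shares; under this convention dN/dS = ω is an exact identity, and the
dS values feeding the filters live on the familiar per-synonymous-site
scale.

## ω estimation

Estimation is two-step, per gene family:

1. **Null (uniform-ω) fit.** κ, a single ω and all branch lengths are
   fitted by maximum likelihood (Felsenstein pruning, per-node log scaling,
   gaps summed over states). The optimizer alternates coordinate sweeps
   over branch lengths — each edge's one-dimensional likelihood is cheap in
   the spectral form of Q — with bounded quasi-Newton steps on
   (log κ, log ω), until the round-to-round log-likelihood gain falls below
   1e-8 relative (max 50 rounds, one jittered restart on failure). Bounds:
   ω ∈ [1e-6, 20], κ ∈ [0.01, 100], t ∈ [1e-8, 50]. Branch-length sweeps
   use partials refreshed once per sweep; a sweep that fails to improve the
   exactly recomputed likelihood is rolled back.
2. **Free-ratios fit.** One ω per branch, with κ and branch lengths *fixed*
   at the null-fit values. This deviates from re-optimizing everything
   jointly; it is cheaper, avoids the worst identifiability problems of a
   fully free model, and starts from the null optimum so the free
   log-likelihood can only improve (asserted in tests). ω values landing on
   a bound are flagged per branch, not fatal.

Note the two root-daughter branch lengths are confounded under a
reversible model (only their sum is identifiable); per-branch estimates at
the root should be read accordingly.

A **counting estimator** cross-checks the ML route: marginal ancestral
codons are reconstructed under the null fit, and each (parent, child) pair
is scored by Nei–Gojobori-style pathway-averaged difference counts over
mutational-opportunity sites with a Jukes–Cantor correction. Mutants or
pathway steps through stop codons are excluded (stop-codon site
opportunities count as nonsynonymous so N + S = 3 per codon); saturated
branches (p ≥ 3/4) return NA with a flag. Across simulated trees the two
estimators' branch ω values rank-correlate at ρ ≈ 0.8.

## Node records and filters

Each labeled internal node yields one record: ω of its parent branch and
two daughter branches, daughter dS values, Δω = |ω_left − ω_right|, and the
signed child-minus-parent differences summarized as (Δω_p_min, Δω_p_max),
so Δω = Δω_p_max − Δω_p_min identically. Δω_p is signed because the
direction of change from the parent is the scientific question
(neofunctionalization predicts one strongly positive daughter). The root
has Δω but no Δω_p.

Node filters, applied sequentially with an audit of each rule: drop a node
if either daughter has dS > 2 (synonymous saturation), then if either has
dS < 0.01 (too little signal for a ratio), then if either daughter ω > 10
(runaway estimates; the node is dropped, not the tree). Tree-level filters
keep families with ≤ 170 tips and at least one duplication *and* one
speciation node. All thresholds are configurable; the retained *set* is
order-independent, only the audit attribution depends on the order.

## Statistics

- **Permutation test.** Speciation/duplication labels are reshuffled
  *within each tree* (preserving per-tree label counts), the statistic —
  difference in mean Δω, duplication minus speciation; difference in
  medians available — is recomputed on the pooled records, and the
  two-tailed p-value uses add-one smoothing
  p = (1 + #{|T*| ≥ |T|}) / (B + 1), B = 1000 by default. Draws matching
  |T| to within 1e-12 relative count as ties, so enumeration and Monte
  Carlo agree. Measured type-I error at α = 0.05 over 200 null replicates
  sits inside the exact binomial 95% band.
- **Hedges' g** with the small-sample correction J = 1 − 3/(4·df − 1).
- **Two-sample Kolmogorov–Smirnov** test (scipy, asymptotic p).
- **Overlap coefficient (OVL)**: Gaussian KDEs with Silverman bandwidths
  per sample on a shared 512-point grid spanning the pooled range ± 3 max
  bandwidths, trapezoidal integral of the pointwise minimum. Δω densities
  are compared on log(Δω + ε), ε = 1e-6 (Δω = 0 occurs); ε and the
  transform are reported in every result. Signed Δω_p comparisons use no
  transform.
- **Parent outliers in Δω_p.** The node filters screen runaway ω estimates
  (> 10) on daughter branches only; a node's *parent* branch can still
  carry one, and a handful of such parents dominate the parent-difference
  means (simulations show the ortholog mean Δω_p swinging from ≈ 0 to
  strongly negative through ~1% of records). Δω_p comparisons therefore
  also drop nodes whose parent ω exceeds the same cap; Δω comparisons are
  untouched. The cap is a parameter and is recorded in every report.

## Synthetic data

The generator stands in for a curated vertebrate gene-family resource; it
is a first-class, tested component, and its defaults define the study
conditions.

- **Species tree**: packaged 16-taxon vertebrate tree (5 teleosts, a frog,
  a lizard, 2 birds, 7 mammals), ultrametric with a 430-Myr root —
  realistic clade depths without any download.
- **Gene trees**: birth–death along the species tree, duplication rate
  λ_d = 0.002/Myr and loss rate λ_l = 0.001/Myr by default (≈ 2–6 surviving
  duplications per family; most families pass the tree filters). Families
  with < 2 surviving copies are redrawn. Lost lineages are pruned, so some
  true events are invisible — deliberately, as in real data.
- **Branch lengths**: time spans × a per-tree rate, log-normal around
  0.002 substitutions/codon/Myr (log-SD 0.3), so family depths vary and the
  dS filters have realistic bite.
- **Branch ω**: a multiplicative random walk — each daughter draws
  log-normally (log-SD 0.2) around its parent branch's ω, root centred on
  0.2, clamped to [0.005, 8] — echoing the strongly purifying regime of
  typical vertebrate orthologs. At true duplication nodes the scenario
  applies: *conservation* nothing, *neofunctionalization* multiplies one
  random daughter by f (default 3), *subfunctionalization* multiplies both,
  *null* ignores labels entirely (so labels are provably uninformative —
  the type-I harness). The effect persists down-tree (a shifted regime,
  not a one-branch blip), capped at 15.
- **Alignments**: forward simulation from a π-drawn root sequence, uniform
  π and κ = 2 by default, 300 codons, no indels.

**What this does not emulate**: alignment error, indels, rate variation
across sites, selection shifts unrelated to duplication, whole-genome
duplications, biased codon usage, and gene conversion. Passing tests
demonstrate that the *pipeline* recovers planted signals of this kind —
not that real vertebrate paralogs behave this way.

## Problem sizes and determinism

Default analysis sizes (50 families × 300 codons for the headline
contrast; 200 replicates for calibration harnesses; 20 seeded replicates
for parameter recovery) were chosen so each stage's sampling error is well
below the effects probed while a full run stays in the minutes range on
one core. All randomness flows from one master seed through
`numpy.random.SeedSequence` spawns (per-tree streams, per-analysis
permutation streams), so every report and output file is bit-reproducible
given (config, seed).

## Known limitations

- Free-ratios ω values on short branches are noisy and can hit bounds;
  the filters exist precisely to keep such branches out of the contrasts.
- Fixing κ and branch lengths during the free-ratios fit slightly
  understates per-branch uncertainty relative to a joint fit.
- The root's two daughter branch lengths are only jointly identifiable.
- The counting estimator conditions on a single reconstructed ancestral
  sequence and underestimates changes on long branches.
- Node ages come from simulator truth; no molecular dating of inferred
  trees is attempted.
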