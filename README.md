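# orthoconj

Do gene copies created by duplication diverge more in selective pressure
than copies separated by speciation? Under the **ortholog conjecture**,
orthologs (copies whose last common ancestor is a speciation) should
evolve more similarly than paralogs (copies born of a duplication) of
comparable age. `orthoconj` phrases the question in terms of
ω = dN/dS — the rate of nonsynonymous substitutions per nonsynonymous
site relative to synonymous substitutions per synonymous site — and tests
it end to end on simulated vertebrate-like gene families where the ground
truth is known.

The pipeline, intended for molecular evolutionists and for anyone
validating ortholog/paralog inference machinery:

1. **Simulate** gene families: birth–death gene trees inside a dated
   16-taxon vertebrate species tree, branch-specific true ω values under
   four duplication-fate scenarios (null, conservation,
   neofunctionalization, subfunctionalization), and forward-evolved codon
   alignments (Goldman–Yang-style model).
2. **Label** every internal node speciation or duplication by the
   species-overlap rule: a node is a duplication iff the species sets of
   its two daughter clades intersect.
3. **Estimate** a branch-specific ω for every branch: a uniform-ω
   maximum-likelihood fit of κ and branch lengths, then a free-ratios fit
   (one ω per branch, κ and lengths held fixed). A
   counting-based estimator (Nei–Gojobori-style, over reconstructed
   ancestral codons) serves as a fast cross-check.
4. **Summarise** each node: Δω = |ω_left − ω_right| between the daughter
   branches, and the signed parent differences Δω_p (min/max over the two
   daughters). Quality filters drop nodes with saturated (dS > 2) or
   uninformative (dS < 0.01) daughters and runaway estimates (ω > 10).
5. **Compare** orthologous vs paralogous lineages: a within-tree label
   permutation test (two-tailed, 1000 permutations), Hedges' g, a
   two-sample Kolmogorov–Smirnov test, and the overlap coefficient (OVL)
   of the two kernel-density estimates of log Δω.

See `docs/methods.md` for the model, defaults, and limitations.

## Worked example

```python
from orthoconj import PipelineConfig, ScenarioConfig, run_pipeline

cfg = PipelineConfig(
    n_trees=10, seed=11, b=500, estimator="ml",
    scenario=ScenarioConfig(name="neofunctionalization",
                            duplication_factor=3.0, n_codons=300),
)
res = run_pipeline(cfg)
d = res.report["delta_omega"]
print(f"mean dOmega paralogs  {d['mean_duplication']:.3f}")
print(f"mean dOmega orthologs {d['mean_speciation']:.3f}")
print(f"permutation p {d['permutation']['p_value']:.4g}  "
      f"Hedges g {d['hedges_g']['g']:.2f}  OVL {d['ovl']['ovl']:.2f}")
```

prints

```
mean dOmega paralogs  0.612
mean dOmega orthologs 0.259
permutation p 0.001996  Hedges g 0.64  OVL 0.61
```

With one daughter copy's ω inflated threefold after each duplication, Δω
between paralogous daughter lineages (0.61) clearly exceeds Δω between
orthologous ones (0.26); the within-tree permutation test rejects the
label-uninformative null (p ≈ 0.002), and the two Δω densities overlap at
61%. Under the `"null"` scenario the same pipeline returns uniform
p-values — labels carry no signal, and the test knows it.

The same workflow is available from the shell:

```bash
orthoconj run-all --seed 42 --n-trees 10 --estimator ml --out results/run42
```

and stage by stage (`orthoconj simulate | label | estimate | metrics |
stats`). The numbered scripts under `analysis/` run the same study as a
narrative: simulate the four scenarios, audit label recovery, estimate ω,
build and filter node records, and run the ortholog-vs-paralog
comparisons, writing tables under `results/analysis/`.

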