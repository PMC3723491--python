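# voxcoex

Spatial co-expression analysis of a designated gene set within a voxelized
brain-wide expression atlas: co-expression matrices, background comparison,
clique discovery, Monte Carlo enrichment, and anatomical localization of
clique expression.

## The problem

Gene-expression atlases such as the Allen Mouse Brain Atlas summarize *in
situ* hybridization signal as an expression energy `E(v, g)` on a grid of
brain voxels `v` for thousands of genes `g`. Given a designated gene set —
for instance, genes implicated in a disorder — two questions arise: do these
genes co-express in space more tightly than chance, and if so, *where* in
the brain do their co-expressed subgroups sit? `voxcoex` implements that
analysis end to end for anyone with gene × voxel expression energies, a
region annotation, and a gene list, and ships a synthetic-brain generator
with planted ground truth so every stage can be validated.

## The method

**Co-expression** between genes is the cosine similarity of their voxel
profiles,

    C(g, g') = Σ_v E(v,g) E(v,g') / (‖E(·,g)‖₂ ‖E(·,g')‖₂) ∈ [0, 1],

equivalent, for unit-normalized profiles ê, to the squared energy of the
difference: ‖ê − ê′‖² = 2(1 − C).

**Background comparison.** The designated set's pairwise co-expression
distribution is compared with the background's by a two-sample
Kolmogorov–Smirnov test; the co-expression value at which the set is most
over-represented above the background becomes the seed threshold ρ₀.

**Threshold graphs and cliques.** Cutting C at ρ yields a graph with an
edge wherever C ≥ ρ. Per threshold, with N_ρ(k) components of size k, the
maximum and average component sizes are M(ρ) = max{k : N_ρ(k) > 0} and
A(ρ) = Σ k·N_ρ(k) / Σ N_ρ(k); random-set envelopes show what connectivity
chance produces. A *clique* is a gene set whose every pair satisfies
C ≥ ρ. Seeds are maximal cliques among the designated genes at ρ₀
(Bron–Kerbosch); each seed is extended over the whole universe by a greedy
maximin rule at the seed's own minimum pairwise co-expression.

**Enrichment.** A clique with n genes, ng of them designated, gets a Monte
Carlo p-value: the chance that a random designated set of size G hits it in
≥ ng genes (resampled; the exact hypergeometric tail is the built-in
oracle), Bonferroni-corrected across cliques.

**Anatomy.** A clique's spatial signature is S(v) = Σ_g E(v,g)/‖E(·,g)‖₂
over members; its fit to a region ω with characteristic function χ_ω is the
cosine Φ(ω) = Σ_v S(v)χ_ω(v) / (‖S‖₂‖χ_ω‖₂) ∈ [0, 1], with a permutation
null from random same-size gene sets, plus maximal-intensity projections.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_cliques_and_enrichment.py` on the default synthetic
brain (394 genes, 1,000 voxels, 26 designated genes, two planted cliques)
prints:

```
seed threshold rho0 = 0.596
clique 1: n = 8, designated = 8, min co-expression = 0.873, p_mc = 1.00e-05 (hypergeometric oracle 1.17e-10)
clique 2: n = 6, designated = 6, min co-expression = 0.876, p_mc = 1.00e-05 (hypergeometric oracle 4.60e-08)
clique_1: Bonferroni-corrected p = 2.00e-05
clique_2: Bonferroni-corrected p = 2.00e-05
```

Both planted cliques are recovered exactly at the automatically chosen
threshold; their Monte Carlo p-values sit at the resolution floor of
100,000 draws and stay significant after correction.
`examples/04_anatomy_fitting.py` then localizes the first clique:

```
top regions by fitting score:
   CER-1 (CER): score 0.874, permutation p = 1.00e-04 (null mean 0.197)
     CER (CER): score 0.641, permutation p = 1.00e-04 (null mean 0.259)
...
ground-truth host region: CER-1
```

The planted host region ranks first, far above the null expectation for
random gene sets of the same size.

The same flow runs from the shell:

```bash
voxcoex run-all --config config.yaml --outdir out/
voxcoex report --outdir out/
```

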