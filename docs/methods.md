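# Methods

## Data model

An `ExpressionDataset` is a gene × masked-voxel matrix of nonnegative
expression energies with the integer grid coordinates of every masked
voxel. Masked voxels are kept in raster order (x fastest, then y, then z),
a pure function of the mask, so serialized artifacts are identical across
runs regardless of input file order. Zero-expression genes are retained at
load and excluded by downstream analyses with a warning. A `RegionAtlas`
carries a per-voxel integer region label (0 = unassigned), a hierarchy
table whose parent links must form a forest, and a mapping of every region
to one of 12 coarse anatomical groups (cerebral cortex, olfactory areas,
hippocampal and retrohippocampal regions, striatum, pallidum, thalamus,
hypothalamus, midbrain, pons, medulla, cerebellum). Characteristic
functions χ_ω optionally include a region's descendants, which is how
non-leaf regions acquire voxels.

Volumes travel as NRRD scalar grids through a minimal built-in
reader/writer (raw, gzip and ascii encodings, little-endian, attached data
only; the first `sizes` entry is the fastest axis, so arrays round-trip
bit-exactly). A tabular carrier (MatrixMarket matrix + TSV sidecars,
written at 17 significant digits so float64 survives) serves desk-scale
work without volumetric files.

## Replicate-consistency filter

When each gene has two acquisitions (e.g. coronal and sagittal series),
the analysis universe is the `keep_n` genes whose two profiles have the
highest Pearson correlation, ties broken by gene order. Zero-variance
profiles get correlation 0 — flagged, never NaN — so degenerate genes sort
last instead of poisoning the ranking. Pearson on the masked energies is a
deliberate choice; rank-based alternatives were left out of the core path.

## Co-expression and the CDF comparison

Cosine similarity of energy profiles is computed on unit-normalized rows;
the matrix is clipped to [0, 1], the diagonal forced to exactly 1 for
nonzero genes, and zero-profile genes get an all-zero row/column (their
diagonal is undefined; stored as 0 with a warning).

The designated set's n(n−1)/2 pairwise values are compared with a
background. The default background is every off-diagonal entry of the full
matrix except the set-vs-set pairs ("all other pairs"); a flag switches to
the full matrix, since both readings of "the other genes" are defensible.
Diagonal entries never enter (identically 1, no information).

The comparison reports the two-sample KS statistic D with its asymptotic
p-value, and two deviation locations, both computed in exact integer
arithmetic over the common denominator so ties resolve to the smallest
co-expression value:

* `argmax_coexpression` — where |CDF_set − CDF_bg| is largest (the KS
  argmax);
* `argmax_set_excess` — where CDF_bg − CDF_set is largest, i.e. the value
  above which the set is maximally over-represented.

The pipeline's automatic seed threshold uses the signed version. The two
coincide when the designated set is shifted up as a whole; they diverge
when the set is a heterogeneous mixture whose cross pairs (clique member ×
unrelated designated gene) are *weaker* than background — there the
absolute argmax sits at the low end and delineates nothing, while the
signed argmax lands just below the set's tightly co-expressed block, which
is the intended delineation threshold. This is the one place the package
deliberately refines the naive procedure; both values are always reported.

## Threshold graphs, component curves, cliques

Edges are inclusive (C ≥ ρ). Connected components come from sparse-graph
union (cross-checked in tests against a brute-force reachability closure);
component censuses N_ρ(k) give M(ρ) and A(ρ) with the conservation law
Σ k·N_ρ(k) = G asserted as a test invariant.

Seed cliques are all maximal cliques of size ≥ 2 within the designated set
at ρ₀, by Bron–Kerbosch enumeration — exhaustive is feasible because the
designated set is small (26 by default). Output order is deterministic
(members in matrix order, cliques sorted lexicographically).

Extension over the ~400–3,000-gene universe cannot use exact maximum
clique (NP-hard), so each seed grows greedily: the threshold ρ is frozen at
the seed's internal minimum pairwise co-expression, and the candidate
whose minimum co-expression to all current members is largest is admitted
while that minimum stays ≥ ρ, ties broken by gene order. An exhaustive
extension mode exists for small universes and is used in tests to confirm
the greedy recovers the true maximum clique containing the seed whenever
planted structure is separated from background by a margin ≥ 0.1. An
optional mode recomputes ρ from the extended members for sensitivity
analysis. Overlapping cliques are kept; only exact duplicate member sets
collapse.

## Enrichment

The null holds the clique fixed and randomizes the designated set: G genes
drawn uniformly without replacement from the universe. The overlap is then
exactly hypergeometric, so `hypergeometric_tail` (exact tail via the
standard log-gamma implementation) is the closed-form oracle the Monte
Carlo estimate must match within binomial error — a dual-route check kept
in the test suite. The resampled p uses the (r+1)/(n_draws+1) estimator
(never 0); the plain r/n_draws estimate is reported alongside. Draws are
vectorized (random keys, partial argsort) in memory-bounded chunks; each
clique gets an independent stream derived from the stage seed. Bonferroni
multiplies by the number of cliques tested, clamped at 1. Random-set
envelopes replay A(ρ), M(ρ) on n_sets random G-subsets and summarize
per-threshold means and quantiles.

## Anatomical fitting

S_clique sums the members' L2-unit-normalized profiles ("normalized" read
as L2, consistent with the cosine framework; zero-norm members are skipped
with a warning). The fitting score is the cosine between S and χ_ω, so it
is invariant to positive rescaling of either and equals 1 / 0 in the
proportional / disjoint limits, and √(|ω|/V) for a uniform profile.

The permutation null draws `n_perm` random gene sets of the clique's size
(random sets, not random graph-cliques — sampling true cliques uniformly
is infeasible) and scores every region with one shared set of draws, so
the per-region profile is internally consistent; p(ω) =
(1 + #{null ≥ observed}) / (1 + n_perm), one-sided for over-expression.
Null scores are computed algebraically: with unit profiles U, a draw's
score needs only Σ U·χ over its members and ‖S‖² = the draw's block sum of
the Gram matrix UUᵀ, so 100,000 permutations run in seconds without
materializing null profiles. Null mean and SD per region are reported, and
seeds plus draw counts are embedded in a JSON sidecar.

Maximal-intensity projections scatter S back to the 3-D grid (unmasked
voxels 0) and take the maximum along one axis; outputs are written as
plain-text matrices and PNG.

## Synthetic brains

The generator is the stand-in for an atlas download and defines the study
conditions; its defaults are fixed and the tests run against them.

* **Grid and regions.** 10×10×10 voxels, fully masked; 12 main-region
  blocks (3 z-slabs × 4 y-slabs), one per coarse group, each split into
  two leaf subregions along x. Labels live on leaves; main regions get
  voxels through descendants.
* **Background (380 genes).** Spatial arrangement from Gaussian-blurred
  white noise (σ = 0.6 voxels), values replaced by a shared reference
  histogram: the order statistics of a zero-clamped standard normal plus a
  uniform offset setting the flatness ratio mean·√V/‖·‖₂ to 0.7. Every
  background gene therefore has identical marginals and genes differ only
  in *where* they express. This exchangeability is essential: without it,
  per-gene sparsity acts as a connectivity main effect in the cosine
  matrix, the designated set's 325 pairs carry an effective sample size
  near 26, and the KS null is strongly anti-conservative (measured 29%
  false positives at the 0.01 level, versus ~1% after equalization). The
  flatness ratio sets the bulk co-expression level (≈ its square, median
  ≈ 0.49).
* **Planted cliques.** Two by default: 8 genes hosted in a cerebellar
  leaf and 6 in a thalamic leaf, all members designated. A clique's
  in-region template (localization 0.9 of squared energy) is shared by all
  members; each member's out-of-region spill is an *independent* field, so
  no background gene can co-express with every member through a common
  tail. Members multiply the template by per-voxel lognormal noise
  (σ = 0.2). The guaranteed expected pairwise cosine is
  exp(−σ²)·localization ≈ 0.87 against the 0.8 target; generation verifies
  feasibility in closed form up front and fails loudly if the realized
  minimum within-clique cosine misses the target by more than 0.1.
  Members are fully designated because greedy extension admits candidates
  at the seed's internal minimum: statistically exchangeable non-designated
  members would be lost in a sizeable fraction of runs, which is a property
  of the admission rule, not of the data.
* **Designated set.** The 14 planted members plus 12 random background
  genes — 26 in total, matching the size regime the method targets.
* **Paired replicates.** Each gene's latent profile times independent
  lognormal noise per replicate; a configurable fraction of genes get an
  independent second profile (the filter's targets). Returns the corrupted
  ids as ground truth.

What the generator does **not** emulate: real neuroanatomy or atlas
geometry beyond a masked grid with nested regions, point-spread or
registration artifacts, correlated background modules, or heavy-tailed
per-gene energy distributions. Passing tests therefore demonstrate that
the machinery recovers planted structure under exchangeable background
noise at realistic sizes — not that any particular biological dataset
contains such structure.

## Pipeline, determinism, problem sizes

Stages (inputs → co-expression → CDF → curves/envelope → cliques →
enrichment → anatomy) each read their inputs from, and write plain-text
artifacts to, the run directory; a manifest records the configuration,
per-stage seeds and SHA-256 digest of every output. Per-stage seeds derive
from the master seed by fixed indices (not execution order), so deleting
downstream artifacts and resuming regenerates them byte-identically, and
two full runs under one master seed have equal digests. The synthetic
spec's own seed is overridden by the derived inputs-stage seed so one
master seed controls everything.

Default resampling depths are 10,000 enrichment draws, 10,000 permutation
draws and 1,000 envelope sets in the pipeline configuration; the
acceptance script uses 100,000 draws for enrichment and permutation
p-values, the depth at which their resolution floor is 10⁻⁵-ish. The
whole default analysis runs in well under a minute on one core; test-suite
configurations scale draw counts down further where the check is about
mechanics rather than resolution.

## Numerical choices and degenerate inputs

* Cosines are clipped to [0, 1] against floating-point drift; the matrix is
  symmetrized after the outer product.
* CDF deviations use exact integer arithmetic (counts cross-multiplied),
  making the tie rule — smallest value attaining the supremum — exact.
* The KS p-value is asymptotic; at the problem sizes involved the
  alternative exact computations add nothing at the scales the analysis
  cares about (the interesting p-values are far below any resolvable
  threshold).
* Monte Carlo p-values are never 0 by construction; impossible overlap
  thresholds return the estimator floor 1/(n_draws+1).
* Zero-variance or zero-norm genes: correlation 0 in the filter, zero
  row/column in C, skipped in S_clique; errors only when nothing usable
  remains.
* Empty regions are skipped with a warning in fitting profiles, an error
  only where a caller requires nonempty.
* Greedy-extension ties (equal minimum co-expression) resolve to the
  earliest gene in matrix order; seed-clique output is sorted so every run
  and platform produces identical tables.
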