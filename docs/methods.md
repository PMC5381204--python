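# Methods

## Representation and correspondence

Everything operates on CA traces: one coordinate per residue, in chain
order, in Ångströms. Decoys of one target are assumed residue-wise
corresponding (identical length and residue numbering), so no alignment is
performed — "corresponding atoms" means equal positions in the chain. This
is the conventional reduced representation for fold-level comparison;
side-chain and backbone detail add nothing to cluster-level geometry and
are out of scope. Distances cited for decoy clustering in the literature
(pairwise RMSD, TM-score) are conventionally CA-based, which is why the
package commits to CA-only rather than all-heavy-atom input.

## Structural measures

**Euclidean metric.** `sqrt(Σᵢ [(xᵢ−xⱼ)² + (yᵢ−yⱼ)² + (zᵢ−zⱼ)²])` over
corresponding atoms, no superposition. This is the standard
squared-difference form; it equals raw RMSD × √L. (Some published
renderings of this formula typeset the squares on the coordinates rather
than on the differences, which is not a metric; the standard form is the
only self-consistent reading and is what this package computes.)

**Kabsch RMSD.** The rotation minimizing RMSD is closed-form via SVD of
the 3×3 cross-covariance of the centered point sets; the smallest singular
direction's sign is flipped when needed so the rotation is always proper
(det = +1, reflections excluded). Degenerate inputs (collinear/coplanar
points) still yield a valid proper rotation attaining the constrained
minimum. The pairwise-matrix builder batches this over all pairs
(vectorized SVD over stacked 3×3 matrices), which makes a 440-member,
80-residue matrix (~97k superpositions) a ~2 s computation.

**TM-score.** `max (1/Lₙ) Σᵢ 1/(1+(dᵢ/d₀)²)` with
`d₀ = 1.24·(Lₙ−15)^⅓ − 1.8`, floored at 0.5 Å. The normalization constant
is the standard one used by the reference TM-score implementations; using
it keeps scores comparable with published values. Full-length
correspondence (Lₐ = Lₙ) is assumed since decoys share all residues. The
maximization is the standard heuristic: Kabsch fits seeded from contiguous
fragments (full/half/quarter length), each refined by re-superposing on
the residue subset with dᵢ < d₀ (cutoff widened by 0.5 Å steps when fewer
than three residues qualify) until the subset stabilizes or 20 iterations
pass, followed by a smooth climb that iterates Kabsch weighted by the TM
integrand's gradient factor `1/(1+(d/d₀)²)²`. For chains of ≤ 20 residues,
where the d₀ floor makes the score landscape spiky, the seed set is
densified to every contiguous fragment and every atom triple; on such
instances the search matches an independent rotation-grid/translation-
enumeration oracle to ~1e-9 (tested). Exhaustive maximization is
infeasible in general; the test suite bounds the heuristic's shortfall on
small instances instead.

**Distance matrices** are dense (ensembles here are at most a few thousand
members, so O(N²) memory is acceptable) and support three metrics:
superposed RMSD (default), `1 − max(tm(i→j), tm(j→i))` (symmetrized
because the TM search is directional), and the raw Euclidean metric.

## Clustering

All four procedures operate on a distance matrix, not coordinates.

**Cluster centers are medoids.** Recomputing a K-means center as a
coordinate average is ill-defined for conformations (averaging without
mutual superposition produces nonphysical chains, and after superposition
the average is still not a decoy). The center update is therefore the
medoid — the member minimizing total within-cluster distance — which is
well defined for any dissimilarity. This is the one place where the
procedure family is genuinely under-specified in the literature this
package follows, and the medoid choice is deliberate and load-bearing:
with it, "model1" is always an actual decoy, as selection requires.

**K-means (Lloyd descent).** Alternate nearest-center assignment (ties to
the earlier center; a center always belongs to its own cluster) and
per-cluster medoid updates until the center set repeats or `max_iter`
(default 100) is reached. Because medoids are discrete, a "centers moved
less than a threshold" stopping rule degenerates to exact equality, which
is what is implemented. The objective Σᵢ d(i, center(i)) is non-increasing
by construction, and since each cluster contains its own (self-assigned)
center, clusters cannot empty; a deterministic farthest-member repair is
retained as a safeguard. Classical K-means is this descent from uniformly
drawn distinct centers; K defaults to 5 (the SPICKER maximum cluster
count) when not specified.

**K-means++ seeding.** First center uniform; each next center drawn with
probability proportional to squared distance to the nearest chosen center.
Members at distance zero can never be re-drawn while positive-mass
candidates remain; if all masses vanish (fewer distinct members than K)
the draw falls back to uniform over unchosen members and logs it.

**SPICKER-style pass.** (1) Ensembles above `representative_cap` (13000)
members are thinned to an evenly strided subset. (2) The pairwise cutoff
starts at `initial_cutoff` (8 Å) and is multiplied/divided by 1.1 until
the most populated neighborhood holds between 15% and 70% of the members,
clamped to [3.5, 12] Å, at most 20 adjustments. (3) Clusters are extracted
greedily: the member with the most neighbors becomes a center and removes
its whole neighborhood; repeat up to `max_clusters` (5). Leftovers join
the nearest center; clusters are reported by decreasing size. The defaults
mirror the published behavior of the original program, which the
literature summarizes but does not parameterize; they are exposed as
`SpickerParams`.

**SK-means.** The SPICKER pass supplies K and the initial centers (each
SPICKER cluster re-centered on its medoid), then the Lloyd descent
refines. The refined objective never exceeds the SPICKER partition's
objective under the same matrix and medoid centers.

**Model selection.** Clusters are ranked by size, ties by smaller
within-cluster mean distance, then lower center index; modelᵢ is the
medoid of the i-th ranked cluster. All tie-breaks in the package go to the
lowest index — reproducibility over elegance — and every stochastic step
consumes a caller-supplied seeded generator, so results are bit-identical
across processes.

## Evaluation

A benchmark table has one row per target (length, decoy count, best TM in
the set, model1 TM per method, random-pick baseline). The package ships
the published 56-target small-protein benchmark as a TSV fixture so the
aggregate statistics are reproducible without downloading decoy sets:
counts of targets at or above the SPICKER column (33/56 for K-means++,
42/56 for SK-means, ties counted) and column means (SPICKER 0.5745).
Recomputing the classical K-means mean from the table's 4-decimal cells
gives 0.5718 versus the published 0.5717 (computed before rounding); the
test asserts it at 1e-3. Per-target parity from re-clustering is *not* a
goal: the underlying decoy sets are an external download and the exact
SPICKER build behind the published column is unspecified.

Significance uses the equal-sample-size two-sample Student t-test with
pooled variance, 2n−2 degrees of freedom, and two-sided p-values
(sidedness is not stated in the source comparison; two-sided is the
conservative choice). The evaluator can restrict to targets with decoy
count < 520, the subgroup in which the seeded variants separate best from
the random baseline; subgroup p-values are reported, not asserted. The
random baseline is a single seeded uniform draw per target, with the seed
recorded.

## Synthetic ensembles

The generator emulates the shape of fragment-assembly decoy sets: a
handful of conformational basins with the most populated basin nearest the
native.

* **Native chain**: self-avoiding random walk, consecutive CA–CA distance
  fixed at 3.8 Å (the canonical value), non-consecutive pairs kept ≥ 3 Å,
  with a persistent step direction so chains are extended rather than
  collapsed. Placement retries are bounded; exhaustion raises a generation
  error.
* **Cluster prototypes**: each basin is an *internal* (hinge) perturbation
  of the native — the C-terminal half is rotated by the basin's rotation
  magnitude (degrees) about an axis through the mid-chain CA, plus a
  linearly ramped displacement of the basin's translation magnitude (Å).
  Internal motions are used rather than whole-body rigid transforms
  because superposed RMSD and TM-score are invariant to rigid transforms:
  rigidly displaced "clusters" would be mutually invisible to every
  distance this package clusters on. Hinge axes are taken from one random
  orthonormal triad per ensemble, so different basins deform in mutually
  orthogonal directions by construction rather than by luck.
* **Members**: prototype + i.i.d. isotropic Gaussian noise per atom
  (per-basin scale). This keeps closed-form moments — the expected
  per-atom squared deviation between two members of one basin is 6σ² —
  which the tests check directly. Members are shuffled deterministically;
  the native is returned separately and never included unless injected.

**Defaults** mirror the benchmark scale the package targets: 80 residues,
440 decoys in three basins of sizes (220, 140, 80), noise 0.5 Å per atom,
offsets (0°, 0 Å), (50°, 10 Å), (100°, 20 Å). With these settings the
realized superposed-RMSD separation between basins is 4–10× the
within-basin spread across seeds, the mean TM to native decreases strictly
with basin index, and all four methods recover the generated labels
exactly — which is what passing tests demonstrate. What the generator does
*not* model: energy-weighted sampling density, secondary-structure
content, chain-break or compactness pathologies of real decoys, and
non-Gaussian within-basin anisotropy; exact label recovery on synthetic
basins therefore shows algorithmic correctness, not expected accuracy on
real decoy sets.

## Problem sizes and runtime

The shipped tests and the reproduction script run at the benchmark's own
scale where that is cheap (440×80 ensembles: ~2 s for the RMSD matrix,
~10 s for 440 TM scores) and at reduced scale where an independent oracle
is the point (grid-search oracles at L ≤ 15; exhaustive clustering optima
at N ≤ 8, K ≤ 3 — the largest sizes where enumeration over center subsets
is still instant). Oracle resolution bounds are stated per oracle:
rotation-grid RMSD is certified to its final grid step × structure radius;
the TM oracle's bound combines the integrand's maximum slope (3√3/8)/d₀
with the polish tolerance.

## Known limitations

* CA-only; no mmCIF; no sequence alignment of non-corresponding decoys —
  inputs must be decoys of one target.
* The TM-score search is heuristic; its oracle-verified regime is small
  chains, and for long chains it relies on the same fragment-seeding
  scheme as the reference implementations.
* The SPICKER-style pass is a faithful re-implementation of the published
  *behavior*, not of the original Fortran program; numeric parity with any
  particular SPICKER build is not expected.
* Pairwise `1 − TM` matrices cost one TM search per pair and are only
  practical for small ensembles; superposed RMSD is the intended
  production metric.
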