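# Methods

This note documents the models, defaults and numerical choices behind
each stage of the cascade, what the synthetic generators do and do not
emulate, and the known limitations.

## Compound admission (chemlib)

Compounds are canonicalized with RDKit's default canonical SMILES
(stereochemistry preserved as written; the reference table carries no
stereo annotations). Whitespace inside SMILES is stripped before parsing
because tables lifted from typeset documents routinely acquire spaces
around bond symbols. Deduplication is by canonical SMILES with
first-occurrence-wins, which keeps output order deterministic and stable
under re-runs; the operation is idempotent on its own output.

The admission filter keeps records with oral bioavailability ≥ 20 % and
drug-likeness ≥ 0.18, both inclusive — the conventional TCMSP screening
thresholds. Records missing either descriptor are rejected with a
warning rather than imputed.

## Fingerprints and similarity

Defaults: Morgan radius 2 at 2048 bits for chemical-space work and 1024
bits for the ML benchmark (both widths are common practice; they are
kept as separate named defaults, `CLUSTERING_MORGAN` and `ML_MORGAN`).
Hashed torsion and atom-pair widths default to 2048 bits and are
recorded in the fingerprint objects so runs are reproducible. MACCS
fingerprints use the conventional 167-slot layout (keys 1–166, slot 0
permanently unset); we report `n_bits = 167` so the bit-index invariant
`bit < n_bits` holds, and document the 166 structural keys here rather
than special-casing the width.

Tanimoto similarity of two empty fingerprints is defined as 0 (avoiding
0/0); this is conservative in that it can never inflate similarity.
Property tests check symmetry, range, self-similarity and agreement with
both a brute-force set-arithmetic oracle and RDKit's own Tanimoto.

## Chemical-space clustering (chemspace)

The cascade is t-SNE (3 components, exact gradients) on the 0/1
fingerprint vectors with Euclidean distance (Jaccard available by
flag), Ward-linkage agglomerative clustering on the embedded
coordinates cut at *k* = 3, then per-cluster representative selection.

t-SNE requires perplexity < n. A conventional perplexity of 30 is
unrunnable for an 18-compound library, so the pipeline clamps to
min(perplexity, (n−1)/3) with a warning; the clamp keeps perplexity well
below the sample count, in line with standard guidance. Stock
scikit-learn optimizer settings (random init, `learning_rate="auto"`,
1000 iterations) shear well-separated chemotype families apart at this
scale — planted 3-family libraries were recovered in only ~2/10 seeds —
so the module defaults to PCA initialization, learning rate 10 and a
5000-iteration budget, which recovers the planted families in 10/10
seeds and is deterministic per seed. For libraries of thousands of
molecules a larger learning rate is advisable.

Representatives are similarity medoids: the member with the highest
mean Tanimoto to the other members of its cluster. The mean excludes
the candidate itself by default; including it adds a constant term and
cannot change the argmax except at exact ties (both conventions are
implemented). Ties break by input order; a singleton cluster is its own
representative. Cluster labels are renumbered 1..k by first appearance
in input order so partitions are comparable across runs.

On the bundled 18-compound reference table, the recomputed medoids of
the steroid and alkaloid clusters match the reference flags
(sitogluside, nuciferine). For the flavonoid cluster the rule selects
quercetin (mean within-cluster Tanimoto 0.444) over the flagged
kaempferol (0.412); the ordering is stable under every scheme, radius,
bit width, similarity coefficient and self-inclusion convention we
tested, and also under medoid selection in the embedded coordinates.
Chemically this is expected: quercetin shares its catechol B-ring with
three other cluster members, while kaempferol lacks it. The
corresponding acceptance check is therefore expected to disagree with
the reference flag on that one cluster, and the acceptance script
reports the honest 2/3 agreement. Similarly, re-clustering the full
table reproduces the reference partition on 17 of 18 compounds (ARI
0.867): the lone nucleoside, flagged with the steroids in the
reference, is a polyol that sits closer to the flavonoid family in any
fingerprint space; the best-seed test asserts ARI ≥ 0.85.

## Target networks (targetnet)

Gene symbols are normalized (trimmed, uppercased) before set
operations. PPI edge lists use the STRING TSV dialect; integer scores
on the 0–1000 scale are rescaled to [0, 1], and the default confidence
cutoff is 0.4 ("medium confidence"). Hub ranking is Maximal Clique
Centrality: score(v) = Σ over maximal cliques containing v of (|C|−1)!,
with score(v) = degree(v) when v's neighborhood contains no edge. Note
the acronym collision: this "MCC" is cytoHubba's clique-based
centrality, not the Matthews correlation coefficient of the ML panel.
Maximal cliques come from networkx (Bron–Kerbosch); a 5000-node ceiling
guards the exponential worst case, and the error message suggests a
degree-based fallback. Top-k ties break lexicographically by symbol for
determinism. Correctness is established against a brute-force
maximal-clique enumerator on the complete networkx graph atlas (≤ 7
nodes) plus seeded random 8-node graphs; enumerating *all* labelled
8-node graphs (2^28) is not feasible, so atlas coverage plus random
sampling stands in.

## Enrichment (enrich)

The ORA p-value is the hypergeometric upper tail P[X ≥ k] computed with
`scipy.stats.hypergeom.sf(k−1, N, K, n)`; k = 0 gives exactly 1. The
universe defaults to the union of annotated genes (the common ORA
default) and is overridable. Query genes outside the universe are
dropped with a warning. q-values are Benjamini–Hochberg (the standard
default for this analysis; step-up rule, computed via statsmodels
behind the module surface), adjusted within one annotation collection —
separately supplied term files (e.g. GO namespaces) form separate
families. Default cutoffs are p ≤ 0.01 and q ≤ 0.05. p-values are
verified against exhaustive enumeration of all C(N, n) draws for
N ≤ 12.

## Activity benchmark (activity_ml)

The split is stratified 80/20 (balanced classes make stratification the
safer reading of a plain shuffle split) and seeded. Cross-validation is
stratified 5-fold, scored by ROC AUC, over compact default grids (8
combinations per algorithm, covering trees/depth/min-samples/bootstrap
for the forest and estimators/depth/learning-rate/subsampling for the
boosted trees); `FAST_GRIDS` (one combination) serves quick runs. Test
metrics use a 0.5 probability threshold; AUC is threshold-free.
SE/SP/ACC/MCC/precision/F1/BA are computed from confusion counts in
this module and are cross-checked against raw-pair recomputation on
random confusion tables; undefined ratios (empty margin) yield NaN
rather than a silent 0. MCC with a zero denominator is defined as 0.

## Trajectory analytics (trajstats)

Kabsch superposition solves the least-squares rotation by SVD with the
determinant-sign correction, guaranteeing a proper rotation; fewer than
three non-collinear selected atoms is an error. RMSD is
mass-unweighted, computed after per-frame fitting to the reference
(frame 0 by default) on the same selection. The alignment reference for
RMSF, DCCM and PCA is the trajectory-average structure iterated twice
(fit to frame 0's mean, recompute, refit). For constructed toys with a
meaningful lab frame, `superpose=False` skips fitting — fitting
redistributes planted single-atom motion across the structure, which is
correct behavior but obscures closed-form checks.

SASA is Shrake–Rupley with a golden-spiral (Fibonacci) point lattice,
960 points per atom and a 1.4 Å probe by default (reports can be
converted to nm² by dividing by 100). A point exactly on a shared
surface (coincident or tangent inflated spheres, within 1e-6 relative
tolerance) is assigned to the lowest-index atom so the union surface is
counted once. Production MD packages often default to the LCPO
approximation instead; Shrake–Rupley was chosen because it is exact in
the sampling limit and directly oracle-checkable — agreement with an
independent implementation is within 1 % at 960 points, and
960-vs-4000-point convergence is within 2 % on random 20-atom toys.

DCCM is the normalized displacement covariance with unit diagonal
(zero-variance atoms get diagonal 1 by convention); PCA diagonalizes
the 3A×3A coordinate covariance, sorts eigenvalues descending, and
projects frames on the first two modes. Frame clustering is seeded
k-means++ (50 restarts) on aligned flattened coordinates, with the
frame nearest each centroid as representative; k ≥ F returns every
frame. Van der Waals radii and masses come from a bundled element
table (Bondi-style radii, fallback 1.7 Å / 12.011 amu), overridable
per trajectory.

## Synthetic generators (synthdata)

One global seed fans out to fixed per-stage child seeds, so a stage's
output is stable when other stages' parameters change. All generators
are byte-reproducible given a seed.

* **Compound libraries** plant up to three chemotype families —
  flavonoid, aporphine-like alkaloid, steroid — as template scaffolds
  with enumerated substituents (guaranteeing SMILES validity), sized
  3 × 6 = 18 by default to mirror a small herbal library. The draw is
  retried (bounded) until the within-family mean Morgan-Tanimoto
  exceeds the between-family mean by ≥ 0.2; typical margins are ~0.5.
  OB/DL descriptors are sampled inside the admission region.
* **Activity sets** label a molecule active iff it contains a planted
  2-substituted furan, growing random fragment chains around it;
  classes are balanced to within one and labels then flipped i.i.d. at
  the configured noise rate. Default n = 1000, noise 0 (the test bed
  varies both); by construction the Bayes accuracy is 1 − noise.
* **PPI graphs** are G(n = 60, p = 0.05) plus one planted 6-clique,
  with confidences uniform on [0.4, 1.0].
* **Gene universes** (N = 1000 default; recovery tests use N = 500)
  contain one term whose query overlap is exact, plus random
  distractor terms whose overlaps sit at the null expectation nK/N.
* **Trajectories** are a helical CA trace (≈ 3.8 Å spacing) with
  per-block isotropic Gaussian jitter, an optional hinge mode — a
  shared scalar series displacing the two blocks along their
  separation axis with opposite (or equal) sign, planting inter-block
  correlation of magnitude amp²/(amp² + 3σ²) — and optional random
  rigid rotation+translation per frame to exercise alignment. The
  displacement axis is the inter-block axis deliberately: an
  antisymmetric displacement perpendicular to it approximates a rigid
  rotation, which superposition would (correctly) remove.

What the generators do **not** emulate: real ADME value distributions,
force-field dynamics, realistic PPI degree distributions, correlated GO
term hierarchies, or assay noise structure. Passing the recovery tests
therefore demonstrates the statistical machinery is correct and
well-calibrated on data satisfying each method's assumptions — not that
the methods will behave identically on any particular experimental
dataset.

## Problem sizes

Default test and acceptance problem sizes — 18-compound libraries, 10
recovery seeds, 60-node graphs, 500-gene universes with 200 enrichment
replicates, 400-molecule activity sets, 120–2000-frame toy
trajectories of 60 atoms — were chosen as the smallest scales at which
each planted effect is statistically unambiguous, keeping the whole
suite runnable interactively on one CPU.

## Known limitations

* The clique-centrality guard refuses > 5000 nodes rather than falling
  back automatically; degree-based ranking must be chosen explicitly.
* Exact t-SNE is O(n²) per iteration; the tuned defaults target
  library-scale inputs (tens to hundreds of molecules).
* SASA is O(A² · points) per frame; per-frame series over long
  trajectories of large systems are better computed on a CA selection
  or with fewer points.
* Only binary fingerprints are implemented (no counts, no 3-D
  pharmacophores), and only text trajectory formats (multi-model PDB,
  XYZ) are read.
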