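# Methods

This note documents the models, defaults and numerical choices behind
`flniche`, and what the synthetic experiments do and do not establish.

## Synthetic data model

**Cell maps.** Background cell types are scattered uniformly over a
rectangular field (homogeneous Poisson conditioned on the requested
counts); defaults are a 2000 × 2000 µm field with a few thousand typed
centroids, chosen for desk-scale runtime. Planted pairwise attraction
follows a Thomas-process construction: each parent receives a fixed number
of offspring displaced by an isotropic Gaussian (default sd 20 µm, inside
the 5–50 µm analysis band), with points falling outside the field
resampled rather than clipped to avoid edge pile-up. Erythroblastic-island
"rosettes" place `n_satellites` satellite cells on a ring of radius
0.5–1.0 × `contact_radius` around each core; cores are inset from the
field boundary by the contact radius so every ring fits, which guarantees
a contact fraction of exactly 1 for the core type. Coordinates are
continuous 2D µm; no 3D generation (thin-section centroid maps carry no
usable z-structure).

**Expression.** Counts are gamma–Poisson (negative binomial,
var = m + αm², default α = 0.5). Per-gene baseline means are lognormal
around `nb_mean`, except signature genes, which are pinned at `nb_mean`:
marker genes are by definition detectably expressed, and pinning makes the
planted effect exactly `signature_effect` (default ×8) on a unit-baseline
gene rather than scaled by a random draw. An optional progenitor
population takes the geometric mean of two mature populations' mean
profiles before overlaying its own precursor signature, producing the
intermediate transcriptome that links mature clusters in the cluster
graph. Recovery experiments use 4 populations × 50 cells with 15 signature
genes each — a breadth typical of real cluster-defining programs.

**Cytometry.** Events are multivariate Gaussian in asinh(x/cofactor)
space (cofactor 150, the common cytometry default; configurable) and
back-transformed with x = cofactor·sinh(z) clipped at 0. Default
populations differ by +3 asinh units on their high markers with sd 0.35 —
clearly separated populations, as after gating a clean panel.

**Bulk counts.** Two groups (4 control / 6 knockout samples by default),
NB counts with planted ±`planted_lfc` log2 shifts in the second group.

**Ligand–receptor fixture.** Twelve database pairs are constructed so that
every failure mode of the chain occurs at least once, including exact
boundary cases (ligand total of 4 counts vs 5; receptor control mean of
40.0 vs 40.1). The surviving edge set is recorded by independent flag
logic in the generator, never by running the inference code.

**What passing these tests shows.** The synthetic data are idealised: no
segmentation errors, doublet optics, batch effects, ambient RNA, spectral
spillover or library-size confounding. Recovery and calibration results
therefore validate the statistical machinery, not robustness to the
artefacts of real data.

## Clustering arm

Normalisation is library-size scaling to 10⁴ counts per cell followed by
log1p; zero-count cells are dropped with a warning. Cells are projected to
at most 50 principal components (full SVD, deterministic) and connected in
a kNN graph (default k = 15, cosine metric). Neighbour sets are
self-inclusive (the shared-nearest-neighbour convention) and edges are
weighted by the Jaccard overlap of the two neighbour sets; zero-weight
edges are dropped and distance ties break by lexicographic id order so the
graph is a pure function of its input.

Communities come from greedy multi-level modularity optimisation
(Louvain-style, seeded). On the well-separated synthetic data used here
Louvain and Leiden-refined partitions agree; a final-partition check
asserts the result's modularity is at least that of the singleton
partition. Community labels are renumbered by their lexicographically
smallest member for determinism.

Marker ranking is a one-vs-rest two-sample rank-sum (Mann–Whitney) test —
the coherent reading of a "Wilcoxon" one-vs-rest cluster comparison, which
is unpaired — with tie-corrected normal approximation, exact enumeration
when both groups have ≤ 10 cells and no ties, and BH adjustment across
genes within each cluster. Constant genes get p = 1 and effect 0 by
convention.

Signature scores are plain means of per-gene z-scores (constant genes
contribute 0); no expression-bin control genes are used — simpler,
monotone-equivalent on synthetic data, and exactly testable. Cluster
selection keeps clusters whose median score exceeds the global median by
at least `margin`. Note the rule is relative: once only signature-positive
clusters remain, a positive margin empties the selection, so multi-round
designs put the decisive margin in the first round(s) and a permissive
one later. Three rounds are the default.

Cluster-graph connectivity compares observed inter-cluster edge counts to
the degree-preserving expectation D_c·D_d/(2E), capped at 1; it is 0
exactly for disconnected cluster pairs.

## SOM and consensus metaclustering

The batch SOM (default 10 × 10 grid, 20 epochs) initialises its codebook
by seeded sampling of data rows. Each epoch assigns rows to their best
matching node (Euclidean) and replaces the codebook with
neighbourhood-weighted means. The Gaussian neighbourhood is truncated at
its radius, which decays linearly from max(rows, cols)/2 to 0.5: once the
radius falls below the grid spacing the update is exactly batch k-means,
so late epochs sharpen rather than smooth, and the quantisation error
(mean squared distance to the BMU) is monitored per epoch. Nodes with no
weight in an epoch keep their codebook row.

Consensus metaclustering (default 100 resamples of 80% of the nodes)
accumulates co-assignment frequencies of average-linkage Euclidean cuts at
K, then cuts the average-linkage tree of (1 − consensus) at K. With one
resample at full subsampling this reduces exactly to a single hierarchical
cut.

## Cross-modality correlation

Per-cluster centroids (mean of log-normalised expression for scRNA, median
of asinh intensities for cytometry) are restricted to mutual markers
(≥ 3 required), translated through the shipped protein-to-gene alias table
(unmapped markers dropped with a warning), z-scored per feature across
each modality's own clusters, and compared by Spearman's ρ with
average-rank ties. "Scaled and normalised" is read as per-feature
z-scoring; per-cluster scaling is available via the `scale` flag.
Constant centroid rows yield NaN and a warning rather than a silent 0.

## Spatial statistics

All radii ship as defaults in `SpatialConfig`: interaction band 5–50 µm,
census radius 50 µm over 20 sampled centres, contact radius 6 µm
(≈ one cell diameter — "direct interaction" is operationalised as
nearest-centroid distance ≤ 6 µm), density radius 3 µm, contact sample
size 50, 1000 permutations. Pair search uses a k-d tree whose output is
asserted equal to O(n²) brute force in the test suite (n ≤ 500, 50 random
maps).

The interaction log-odds construction (ordered in-band pairs, 2×2 table,
Haldane–Anscombe correction, label-shuffle permutation p) was chosen
because it is exactly reproducible, calibrated under CSR and monotone in
co-occurrence; proprietary imaging suites do not document their estimator,
so numerical values are comparable only in sign and ordering, not
magnitude. The census and window counts are not edge-corrected, matching
uncorrected manual counting. The raster step defaults to the census
radius (overlap-free centre tiling); disc-union areas for density
enrichment are estimated by seeded Monte-Carlo (200k points, relative
error ≤ 1% at the default sizes) rather than exact geometry. The group
comparison of nearest-neighbour distances defaults to Welch's t; a
rank-based alternative is a flag.

## Ligand–receptor chain

Thresholds follow the workflow the package models: "expressed" is
operationalised as nonzero in ≥ 3 cells of the kept clusters (exposed as
`min_cells`); the count filter sums raw counts across all cells of the
kept clusters (≥ 5, inclusive); the receptor filter uses raw bulk counts
without library-size normalisation with a strict mean > 40 in the control
group (caveat: raw-count thresholds are depth-dependent). Term selection
replaces manual curation with a reproducible surrogate: hypergeometric ORA
per term, BH over terms, keep terms that are significant AND whose name
matches a hematopoiesis-related keyword (defaults: "hemato", "stem cell",
"chemotaxis", "vascul"). Each filter returns a subset of its input, so the
chain is monotone: relaxing any threshold can only grow the edge set.
Differential-expression estimation itself is out of scope; the DEG
classifier consumes an externally produced table (|log2FC| > 0.5,
BH-adjusted p < 0.1) and low-count filtering keeps a gene if any sample
reaches 11 counts (the per-sample reading; the summed reading is a flag
away in `min_count`).

## Pipeline and reproducibility

Every stage draws from a substream derived by SHA-256 from the global seed
and the stage name, so adding a stage never perturbs earlier stages'
randomness, and all seeds stay below 2³¹. Configurations are strict
(unknown keys are errors). The driver writes every intermediate table as
TSV/MatrixMarket plus a `run_log.json` with all seeds and parameters and
no wall-clock state, so identical configs yield byte-identical artifact
directories.

## Known limitations

* 2D centroid distances underestimate 3D contact; thin sections ignore
  neighbours in z.
* No edge correction in censuses and windows; fields much smaller than
  the interaction band would bias log-odds.
* The Louvain/Leiden equivalence holds on separated data; on continuous
  manifolds the refinement step can matter.
* Raw-count thresholds in the receptor filter are sequencing-depth
  dependent.
* The exact cluster count of any particular real dataset is not a target:
  resolution, k and the selection margin are free parameters that real
  analyses tune by inspection.
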