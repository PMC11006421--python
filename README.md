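# flniche

Analysis toolkit for studying how macrophage subpopulations structure the
hematopoietic niche of the fetal liver. At embryonic day ~14.5 the liver is
the main hematopoietic organ: erythroblastic-island (EI) macrophages ring
maturing erythroblasts, while other macrophage subsets sit near CD150⁺
long-term hematopoietic stem cells (LT-HSCs) and may signal to them. Testing
that picture computationally requires five different analyses that usually
live in five different tools; `flniche` implements them as one coherent,
seeded, fully testable pipeline:

1. **Signature-guided iterative clustering** of scRNA-seq counts
   (library-size log1p normalisation → PCA → shared-nearest-neighbour kNN
   graph with Jaccard weights → Louvain-style modularity communities →
   marker-signature scoring → cluster selection, repeated three rounds),
   with one-vs-rest rank-sum marker ranking and PAGA-style cluster-graph
   connectivity.
2. **SOM + consensus metaclustering** of cytometry marker intensities in
   asinh space (batch self-organising map; repeated subsampled hierarchical
   cuts of the codebook aggregated into a consensus matrix).
3. **Cross-modality correlation**: per-cluster centroids over the markers
   shared by the two panels (protein names mapped to gene symbols through a
   shipped alias table), feature-wise z-scored per modality, compared by
   Spearman's ρ.
4. **Spatial statistics** on typed cell-centroid maps: pairwise interaction
   log-odds within a 5–50 µm band with a label-permutation null,
   nearest-neighbour distances, density enrichment within 3 µm, a 50 µm
   radius census around sampled HSCs with one-way ANOVA, contact fractions
   (≤ 6 µm), raster-scan neighbourhood composition with SOM clustering,
   pixel Pearson colocalization, and two-step marker gating.
5. **Ligand–receptor inference** as a threshold chain: ligands expressed in
   the macrophage clusters → restricted to significant hematopoiesis-related
   gene-set terms (hypergeometric over-representation, BH-corrected) →
   ≥ 5 summed counts → receptors with bulk LT-HSC mean count > 40 →
   database pairs surviving both ends.

Because the raw imaging and sequencing data of such a study are not
portable, the package ships a first-class synthetic-data module
(`flniche.syndata`) that generates every input with planted ground truth:
Thomas-process spatial attraction, erythroblast "rosettes", negative-
binomial counts with planted marker signatures and a progenitor bridge,
Gaussian-mixture cytometry intensities, two-group bulk counts, and a
ligand–receptor fixture whose surviving edge set is known by construction.

## The interaction statistic

For cell types A and B, all ordered pairs (u, v) of distinct cells with
5 µm ≤ d(u, v) ≤ 50 µm are cross-tabulated into a 2×2 table of
[u ∈ A] × [v ∈ B]. The log odds ratio is

    LOR = ln( (n₁₁ · n₀₀) / (n₁₀ · n₀₁) )

with a Haldane–Anscombe +0.5 correction when any cell is empty. The null
distribution shuffles type labels over cells (positions fixed);
p = (1 + #{|LOR*| ≥ |LOR|}) / (n_perm + 1). Under complete spatial
randomness this test holds its nominal size (empirical type-I error 0.045
at α = 0.05 over 200 replicates, seed 1) and detects planted attraction
(offspring scattered N(0, 20² µm) around parents) in 50/50 replicates.

## Worked example

```bash
flniche run --config configs/demo.yaml --seed 1 --out demo_run
```

simulates a 2×2 mm centroid map (~5400 cells), a 600-cell × 600-gene count
matrix, a 1000-event cytometry panel and the bulk/ligand fixtures, then runs
all five analyses. From `demo_run/` (seed 1):

* `spatial_log_odds.tsv` — the planted mac_C ↔ HSC attraction is the
  dominant entry: LOR(mac_C, hsc) = 1.13 with permutation p = 0.002, while
  all non-planted type pairs stay near 0;
* `spatial_contact_fractions.tsv` — the planted EI-macrophage type shows
  erythroblast contact fraction 1.00 (every sampled core has an
  erythroblast within 6 µm); non-rosette macrophages 0.0–0.1;
* `scrna_clusters.tsv`, `scrna_markers.tsv` — three selection rounds
  enrich 600 sorted myeloid cells down to 95 signature-positive cells;
* `lr_edges.tsv` — the chain returns exactly the five planted
  ligand–receptor edges (e.g. `Lig01 → Rec01`), matching the fixture's
  recorded truth;
* `run_log.json` — every stage's seed and parameters; re-running the same
  config reproduces all artifacts byte for byte.

Library use mirrors the CLI:

```python
import flniche as fl

cfg = fl.SimConfig(seed=1)
cell_map, truth = fl.gen_cell_map(cfg)
res = fl.interaction_log_odds(cell_map, "mac_C", "hsc", fl.SpatialConfig(seed=0))
print(res.log_odds, res.p_value)   # 1.11, 0.001 (seed 1)
```

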