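# scmregions

Tissue-region calling, cross-sample marker discovery and interface
ligand–receptor analysis for Visium-style spatial transcriptomics, with a
bundled synthetic-cohort generator that makes every stage testable without
any data download.

## The problem

Spot-based spatial transcriptomics measures expression on a staggered
hexagonal lattice of ~55 µm capture areas, each holding a handful of cells.
After deconvolution against a single-cell reference, every spot carries a
nonnegative abundance vector over cell states. This package implements the
downstream microenvironment analysis that turns those abundances into
biology, in five steps:

1. **Region calling.** The pooled spots × cell-states abundance matrix is
   factorised by NMF at every component count k ∈ [5, 12]. For each k the
   top-contributing state of each component (argmax of its H row) is
   recorded; the chosen model is the largest k at which no cell state tops
   two components, and each spot is labeled by its highest-contributing
   component (argmax over its W row). The uniqueness rule is a parsimony
   stop: once components start sharing a dominant state, extra components
   are splitting tissue domains rather than discovering new ones.
2. **Region markers.** Within each sample, every region with ≥ 10 spots is
   compared one-vs-rest per gene (two-sided Wilcoxon rank-sum, BH within
   (sample, region); DE = log2FC ≥ 1 and p_adj < 0.05, mito/ribo genes
   excluded). Across samples a one-sided Fisher exact test asks, per
   (gene, region), whether the gene was DE more often in that region's
   tested instances than in all other regions'; BH across genes within
   region declares *region-specific markers*.
3. **Spatial structure.** Hex ring distance d = (|dq|+|dr|+|dq+dr|)/2 on
   axial coordinates q = (col−row)/2, r = row. Neighborhood enrichment
   z-scores come from permuting labels over spots (edges within 3 rings);
   spots around a focal region are *proximal* when within 3 rings of an
   adjacent pair of anchored focal spots, else *distant*; a region-pair
   interface is the set of spots anchored in their own region with ≥ 2
   partner-region spots within 3 rings (≥ 10 spots on both sides).
4. **Signature scoring.** Seurat-style module scores with bin-matched
   controls (ctrl_size = 50, n_bins = 25): mean normalized expression of the
   set genes minus the mean over controls drawn from the same
   average-expression bins. Effect sizes between regions are reported with
   a percentile star rule (★/★★/★★★ = other group's 70th/80th/90th
   percentile below the focal mean, with Welch-t p < 0.05).
5. **Ligand–receptor testing.** CellphoneDB-style permutation test per
   (sample, interface, direction): statistic = mean of (ligand mean on the
   F side, receptor mean on the G side); null = permuting the side labels
   over the union of interacting spots (n_perms = 1000, detection gate 1%,
   pairs with < 3 literature references dropped); add-one p, BH within
   (sample, interface, direction), active = p_adj < 0.05. Across samples a
   one-sided Fisher test finds pairs active specifically at one interface
   type.

The synthetic generator (`scmregions.synthetic_data`) emulates a
multi-sample prostate cohort — four sample categories (BPH / TRNA / NEADT /
CRPC-like), spatially coherent latent regions grown on the hex lattice,
per-region cell-state composition profiles, negative-binomial counts with
planted markers, signature shifts, a treatment-linked AR-like downshift, and
ligand–receptor co-expression planted at one region interface — with full
ground truth and single-seed determinism.

## Worked example

```python
from scmregions.synthetic_data import SimConfig, generate_cohort
from scmregions.region_calling import AbundanceMatrix, select_k_by_uniqueness, assign_regions

cohort, abundance, truth, gene_sets, lr_db = generate_cohort(SimConfig(seed=7))
model = select_k_by_uniqueness(AbundanceMatrix.from_frame(abundance), 5, 12, seed=7)
print(model.k)                      # 8
assignment = assign_regions(model)

from sklearn.metrics import adjusted_rand_score
import numpy as np
true = np.concatenate([truth.true_region[s.sample_id] for s in cohort])
print(round(adjusted_rand_score(true, assignment.labels), 3))   # 0.998
```

The selection trace shows why k = 8: every k ≤ 8 assigns a distinct dominant
cell state to each component, while k = 9..12 forces two components to share
one (the flag flips to False), so the largest admissible k is kept. The ARI
of 0.998 against the planted regions says the argmax labeling recovers the
simulated tissue domains almost exactly.

The full narrative lives in `analysis/` as numbered drivers
(`01_simulate_cohort.py` … `07_ligand_receptor.py`), each writing its tables
under `results/analysis/`. Running them in order on the default cohort
prints, among other things: 10–13 markers per region (10 planted), ★★★
quantile effects of ≈ +0.43 vs −0.07 for each planted signature in its
region (planted shift 0.5 on the log scale), Spearman ρ = +0.87 between the
focal-region fraction and the non-focal PMN-MDSC score, and the planted
ligand–receptor pair active in 12/12 instances of its planted interface
(enrichment q = 2.4 × 10⁻⁸) and at no other interface.

There is also a CLI for one-shot runs:

```bash
scmregions all --out run/ --seed 7        # simulate + full pipeline + manifest
scmregions simulate --out cohort/ --seed 7
scmregions call-regions --abundance cohort/abundance.tsv --out regions/ --seed 7
```

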