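#!/usr/bin/env python
"""Simulate the 12-sample Visium-like cohort used by all later steps.

Writes the cohort (MTX triplets, positions, abundance, gene sets, LR table,
ground truth) under results/analysis/cohort/.
"""

from _common import COHORT_DIR, SIM

from scmregions.synthetic_data import generate_cohort, write_cohort


def main():
    cohort, abundance, truth, gene_sets, lr_db = generate_cohort(SIM)
    out = write_cohort(COHORT_DIR, cohort, abundance, truth, gene_sets, lr_db)
    n_spots = sum(s.n_spots for s in cohort)
    print(f"wrote {len(cohort)} samples ({n_spots} spots, {SIM.n_genes} genes) to {out}")
    print(f"planted: {SIM.markers_per_region} markers/region at log2fc={SIM.marker_log2fc}, "
          f"signature shift {SIM.signature_shift}, LR pair at the region 1-2 interface")


if __name__ == "__main__":
    main()
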