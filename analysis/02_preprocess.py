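#!/usr/bin/env python
"""Apply the QC filters (genes in < 5 spots, spots with < 500 UMIs) and the
median-library log1p normalization; report what survives."""

import pandas as pd

from _common import COHORT_DIR, RESULTS

from scmregions.pipeline import load_cohort
from scmregions.st_io import filter_sample, normalize_log


def main():
    cohort, *_ = load_cohort(COHORT_DIR)
    rows = []
    for s in cohort:
        f = normalize_log(filter_sample(s))
        rows.append(
            {
                "sample_id": s.sample_id,
                "category": s.category,
                "spots_in": s.n_spots,
                "spots_kept": f.n_spots,
                "genes_in": s.n_genes,
                "genes_kept": f.n_genes,
                "median_umis": float(pd.Series(f.counts.sum(axis=1).A1).median()),
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "qc_summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
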