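#!/usr/bin/env python
"""Bin-matched gene-set scores per spot; quantile effect-size comparison of
the planted signature between its region and the rest; region-fraction vs
score Spearman correlation across samples."""

import numpy as np
import pandas as pd

from _common import RESULTS, SEED, load_preprocessed, true_to_called

from scmregions.region_calling import RegionAssignment
from scmregions.signatures import (
    fraction_score_correlation,
    quantile_effect_test,
    score_table,
)

def main():
    cohort, *_, gene_sets = load_preprocessed()
    regions = pd.read_csv(RESULTS / "regions.tsv", sep="\t")
    assignment = RegionAssignment(
        labels=regions.region.to_numpy(), spot_ids=list(regions.spot_id),
        sample_ids=list(regions.sample_id), k=int(regions.region.max()),
    )
    mapping = true_to_called()
    scores = score_table(cohort, gene_sets, seed=SEED)
    scores.to_csv(RESULTS / "scores.tsv", sep="\t", index=False)

    merged = scores.merge(
        regions, left_on=["sample_id", "spot_id"], right_on=["sample_id", "spot_id"]
    )
    print("quantile effect tests (set score, designated region vs rest):")
    designated = {name: mapping[r] for name, r in
                  {"Club-cell": 1, "PMN-MDSC": 2, "AR-like": 3}.items()}
    rows = []
    for set_name, region in designated.items():
        sub = merged[merged.set == set_name]
        res = quantile_effect_test(
            sub[sub.region == region].score, sub[sub.region != region].score
        )
        rows.append({"set": set_name, "region": region, "p": res.p,
                     "mean_in": res.mean_focal, "mean_out": res.mean_other,
                     "stars": res.stars})
        print(f"  {set_name} in region {region}: mean {res.mean_focal:+.3f} vs "
              f"{res.mean_other:+.3f}, p={res.p:.2e}, {res.stars}")
    pd.DataFrame(rows).to_csv(RESULTS / "effect_tests.tsv", sep="\t", index=False)

    pmn = next(gs for gs in gene_sets if gs.name == "PMN-MDSC")
    rho, p = fraction_score_correlation(cohort, assignment, mapping[1], pmn, seed=SEED)
    pd.DataFrame([{"set": pmn.name, "rho": rho, "p": p}]).to_csv(
        RESULTS / "fraction_score_correlation.tsv", sep="\t", index=False
    )
    print(f"\nSpearman(focal fraction, non-focal {pmn.name} score): "
          f"rho={rho:+.3f}, p={p:.3f}")


if __name__ == "__main__":
    main()
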