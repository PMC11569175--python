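#!/usr/bin/env python
"""Call tissue regions from the cell-state abundances: iterative NMF over
k = 5..12 with the top-state uniqueness stopping rule, argmax spot labels,
per-sample region fractions and category-wise fraction tests."""

from _common import RESULTS, SEED, load_preprocessed

from scmregions.region_calling import (
    AbundanceMatrix,
    assign_regions,
    compare_fractions,
    region_fractions,
    select_k_by_uniqueness,
)


def main():
    cohort, abundance, *_ = load_preprocessed()
    A = AbundanceMatrix.from_frame(abundance)
    model = select_k_by_uniqueness(A, 5, 12, seed=SEED)
    print(f"chosen n_components = {model.k}")
    print(model.trace[["k", "unique_top_states", "top_states"]].to_string(index=False))
    assignment = assign_regions(model)
    assignment.frame().to_csv(RESULTS / "regions.tsv", sep="\t", index=False)
    model.trace.to_csv(RESULTS / "selection_trace.tsv", sep="\t", index=False)
    fractions = region_fractions(assignment)
    fractions.to_csv(RESULTS / "region_fractions.tsv", sep="\t")
    tests = compare_fractions(fractions, {s.sample_id: s.category for s in cohort})
    tests.to_csv(RESULTS / "fraction_tests.tsv", sep="\t", index=False)
    kw = tests[tests.test == "kruskal"]
    print("\nKruskal-Wallis p per region (fractions across categories):")
    print(kw[["region", "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
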