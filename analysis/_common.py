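"""Shared configuration for the analysis drivers.

The cohort simulated by 01_simulate_cohort.py is the input of every later
step; each driver reloads it from disk, so the scripts can be run one by one.
"""

from pathlib import Path

from scmregions.pipeline import load_cohort
from scmregions.st_io import filter_sample, normalize_log
from scmregions.synthetic_data import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
COHORT_DIR = RESULTS / "cohort"
SEED = 7

SIM = SimConfig(seed=SEED)  # the default study-like conditions


def load_preprocessed():
    cohort, abundance, lr_db, gene_sets = load_cohort(COHORT_DIR)
    from scmregions.st_io import Cohort

    samples = [normalize_log(filter_sample(s)) for s in cohort]
    return Cohort(samples=samples), abundance, lr_db, gene_sets


def true_to_called():
    """Map planted region labels to NMF component labels by majority vote.

    Component numbering is arbitrary, so later drivers that talk about the
    planted focal region translate through this mapping.
    """
    import pandas as pd

    regions = pd.read_csv(RESULTS / "regions.tsv", sep="\t")
    truth = pd.read_csv(COHORT_DIR / "ground_truth" / "true_regions.tsv", sep="\t")
    merged = regions.merge(
        truth, left_on=["sample_id", "spot_id"], right_on=["sample_id", "barcode"]
    )
    return (
        merged.groupby("true_region")["region"]
        .agg(lambda s: s.value_counts().idxmax())
        .to_dict()
    )
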