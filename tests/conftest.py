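"""Shared fixtures: small synthetic cohorts and toy samples."""

import numpy as np
import pytest
import scipy.sparse as sp

from scmregions.st_io import STSample, filter_sample, normalize_log
from scmregions.synthetic_data import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cfg():
    """A 4-sample, 16x16-lattice, 300-gene cohort configuration."""
    return SimConfig(
        samples_per_category={"BPH": 1, "TRNA": 1, "NEADT": 1, "CRPC": 1},
        lattice_rows=16,
        lattice_cols=16,
        n_genes=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def normalized_sample(small_cohort):
    cohort, *_ = small_cohort
    return normalize_log(filter_sample(cohort.samples[0]))


def make_sample(counts, coords=None, sample_id="s1", category="TRNA", **kw):
    counts = np.asarray(counts)
    n, g = counts.shape
    if coords is None:
        rows = np.arange(n)
        coords = np.column_stack([rows, rows % 2 + 2 * (rows // 1) * 0 + rows % 2])
        # simple valid-parity coords: (i, i % 2) has even sum only if i even...
        coords = np.column_stack([rows, rows])  # row+col = 2i, always even
    return STSample(
        sample_id=sample_id,
        category=category,
        counts=sp.csr_matrix(counts),
        gene_ids=kw.pop("gene_ids", [f"g{j}" for j in range(g)]),
        spot_ids=kw.pop("spot_ids", [f"b{i}" for i in range(n)]),
        array_coords=coords,
        **kw,
    )
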