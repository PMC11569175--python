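"""Tissue-region calling from cell-state abundances by iterative NMF.

The abundance matrix (spots x cell states, pooled over samples) is factorised
with non-negative matrix factorisation at every component count k in
[k_min, k_max].  For each k the top-contributing cell state of every
component (argmax of its H row) is recorded; a k is *admissible* when no two
components share a top state, and the chosen model is the largest admissible
k.  Spots are then labeled by their highest-contributing component (argmax
over the W row).

Abundances enter the factorisation unnormalised (they are inferred cell
counts); a per-spot sum-normalisation option exists but is off by default.
Spot labels are invariant to positive row scaling anyway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from ._stats import bh_adjust, kruskal_p, rank_sum_test

logger = logging.getLogger(__name__)

UNASSIGNED = 0  # reserved label for all-zero W rows


class SelectionFailureError(RuntimeError):
    """No component count in the scanned range had all-unique top states."""

    def __init__(self, duplicates_by_k):
        self.duplicates_by_k = duplicates_by_k
        lines = ", ".join(
            f"k={k}: duplicated states {sorted(dups)}" for k, dups in duplicates_by_k.items()
        )
        super().__init__(f"no admissible component count ({lines})")


@dataclass
class AbundanceMatrix:
    """Validated NMF input: non-negative spots x cell-states values with
    per-row sample ids."""

    values: np.ndarray
    state_names: list[str]
    spot_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.state_names):
            raise ValueError("values shape does not match state_names")
        if not (len(self.spot_ids) == len(self.sample_ids) == self.values.shape[0]):
            raise ValueError("row metadata length mismatch")
        if self.values.min() < 0:
            raise ValueError("abundance values must be non-negative")
        if (self.values.sum(axis=1) == 0).any():
            raise ValueError("abundance contains all-zero spot rows")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        """From the st_io abundance table (index: barcode [, sample_id])."""
        if df.index.nlevels == 2:
            spots = [i[0] for i in df.index]
            samples = [i[1] for i in df.index]
        else:
            spots = list(df.index)
            samples = ["sample"] * len(df)
        return cls(
            values=df.to_numpy(dtype=float),
            state_names=list(df.columns),
            spot_ids=spots,
            sample_ids=samples,
        )


@dataclass
class RegionModel:
    k: int
    W: np.ndarray
    H: np.ndarray
    state_names: list[str]
    spot_ids: list[str]
    sample_ids: list[str]
    top_state_per_component: list[int]
    k_range_tried: list[int]
    uniqueness_flags: dict[int, bool]
    seed: int
    trace: pd.DataFrame = field(default=None, repr=False)


def _fit_nmf(X, k, seed, max_iter, tol):
    model = NMF(
        n_components=k,
        init="nndsvd",
        solver="cd",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    W = model.fit_transform(X)
    return W, model.components_, model.reconstruction_err_


def select_k_by_uniqueness(
    A: AbundanceMatrix,
    k_min: int = 5,
    k_max: int = 12,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> RegionModel:
    """Scan k in [k_min, k_max]; keep the largest k whose components all have
    distinct top-contributing cell states.

    Raises :class:`SelectionFailureError` (listing the duplicated states per
    k) when no k qualifies.  Deterministic given the seed and init scheme.
    """
    if k_max > len(A.state_names):
        raise ValueError("k_max cannot exceed the number of cell states")
    trace_rows = []
    fits = {}
    flags = {}
    duplicates = {}
    for k in range(k_min, k_max + 1):
        W, H, err = _fit_nmf(A.values, k, seed, max_iter, tol)
        # argmax breaks exact ties by lowest state index (np.argmax contract)
        top = [int(np.argmax(H[j])) for j in range(k)]
        seen, dups = set(), set()
        for t in top:
            (dups if t in seen else seen).add(t)
        flags[k] = not dups
        if dups:
            duplicates[k] = {A.state_names[t] for t in dups}
        fits[k] = (W, H, top)
        trace_rows.append(
            {
                "k": k,
                "unique_top_states": flags[k],
                "reconstruction_err": err,
                "top_states": ";".join(A.state_names[t] for t in top),
            }
        )
    admissible = [k for k in flags if flags[k]]
    if not admissible:
        raise SelectionFailureError(duplicates)
    k_star = max(admissible)
    W, H, top = fits[k_star]
    return RegionModel(
        k=k_star,
        W=W,
        H=H,
        state_names=list(A.state_names),
        spot_ids=list(A.spot_ids),
        sample_ids=list(A.sample_ids),
        top_state_per_component=top,
        k_range_tried=list(range(k_min, k_max + 1)),
        uniqueness_flags=flags,
        seed=seed,
        trace=pd.DataFrame(trace_rows),
    )


@dataclass
class RegionAssignment:
    """One region label (1..k, 0 = unassigned) per spot, with row metadata."""

    labels: np.ndarray
    spot_ids: list[str]
    sample_ids: list[str]
    k: int
    region_names: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"spot_id": self.spot_ids, "sample_id": self.sample_ids, "region": self.labels}
        )

    def for_sample(self, sample_id: str) -> np.ndarray:
        mask = np.asarray(self.sample_ids) == sample_id
        return self.labels[mask]


def assign_regions(model: RegionModel) -> RegionAssignment:
    """Label each spot by its highest-contributing component (argmax over W).

    Exact ties go to the lowest component index (logged); all-zero W rows get
    the reserved unassigned label 0 (warned).
    """
    W = model.W
    labels = np.argmax(W, axis=1) + 1
    row_max = W.max(axis=1)
    zero_rows = row_max == 0
    if zero_rows.any():
        logger.warning("%d spots have all-zero W rows; marked unassigned", zero_rows.sum())
        labels[zero_rows] = UNASSIGNED
    ties = (W == row_max[:, None]).sum(axis=1) > 1
    ties &= ~zero_rows
    if ties.any():
        logger.info("%d spots had tied top components; lowest index kept", ties.sum())
    return RegionAssignment(
        labels=labels,
        spot_ids=list(model.spot_ids),
        sample_ids=list(model.sample_ids),
        k=model.k,
    )


def region_fractions(assignment: RegionAssignment) -> pd.DataFrame:
    """Per-sample fraction of spots in each region (rows sum to 1; missing
    regions get 0; unassigned spots excluded from the denominator)."""
    df = assignment.frame()
    df = df[df["region"] != UNASSIGNED]
    counts = df.pivot_table(
        index="sample_id", columns="region", values="spot_id", aggfunc="count", fill_value=0
    )
    counts = counts.reindex(columns=range(1, assignment.k + 1), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def compare_fractions(fractions: pd.DataFrame, categories: dict) -> pd.DataFrame:
    """Kruskal-Wallis across categories plus all pairwise two-sided rank-sum
    tests, per region, on the per-sample fraction vectors.

    Categories with fewer than 2 samples are excluded (warned).  Returns a
    tidy table with one Kruskal-Wallis row and one row per category pair for
    every region.
    """
    cat = pd.Series({s: categories[s] for s in fractions.index})
    sizes = cat.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("categories excluded (<2 samples): %s", small)
        cat = cat[~cat.isin(small)]
    groups = sorted(cat.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 categories with >= 2 samples")
    rows = []
    for region in fractions.columns:
        by_group = {g: fractions.loc[cat[cat == g].index, region].to_numpy() for g in groups}
        rows.append(
            {
                "region": region,
                "test": "kruskal",
                "group_a": "all",
                "group_b": "all",
                "p": kruskal_p(list(by_group.values())),
            }
        )
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                _, p = rank_sum_test(by_group[ga], by_group[gb])
                rows.append(
                    {"region": region, "test": "ranksum", "group_a": ga, "group_b": gb, "p": p}
                )
    return pd.DataFrame(rows)
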