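"""Gene-set activity scoring with bin-matched controls, quantile effect-size
tests, and region-fraction vs score correlation.

Scoring follows the Seurat-style module-score recipe: genes are ranked by
their mean normalized expression across spots and cut into ``n_bins``
equal-frequency bins (ties broken by gene name); each set gene contributes
``ctrl_size`` control genes drawn from its own bin (the whole bin when it has
at most ``ctrl_size`` genes, otherwise a uniform draw without replacement);
the spot score is the mean normalized expression of the set genes minus the
mean over the pooled control draw.  No gene is excluded from the control pool
-- set genes may serve as their own controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .st_io import Cohort, GeneSet, STSample, normalize_log

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    """Per-spot scores for one gene set in one sample."""

    set_name: str
    sample_id: str
    values: np.ndarray
    n_set_genes_used: int
    ctrl_size: int
    n_bins: int
    seed: int


def _expression_bins(expr: np.ndarray, gene_ids, n_bins: int) -> list[np.ndarray]:
    """Equal-frequency bins of gene indices by mean expression (name-tiebreak)."""
    means = expr.mean(axis=0)
    order = np.lexsort((np.asarray(gene_ids, dtype=object), means))
    return [np.asarray(b) for b in np.array_split(order, n_bins)]


def score_gene_set(
    sample: STSample,
    gene_set: GeneSet,
    ctrl_size: int = 50,
    n_bins: int = 25,
    seed: int = 0,
) -> ScoreVector:
    """Bin-matched control score of one gene set on one normalized sample.

    Deterministic given the seed.  Returns an all-NaN vector (with a warning)
    when no set gene is present in the sample.
    """
    if sample.norm_expr is None:
        raise ValueError(f"{sample.sample_id}: normalize before scoring")
    expr = np.asarray(sample.norm_expr.todense())
    gene_ids = list(sample.gene_ids)
    col = {g: j for j, g in enumerate(gene_ids)}
    # canonical gene-name order so the control draw is invariant to the
    # sample's gene/spot ordering
    set_idx = [col[g] for g in sorted(gene_set.genes) if g in col]
    if not set_idx:
        logger.warning("set %s: no genes present in %s", gene_set.name, sample.sample_id)
        return ScoreVector(
            gene_set.name, sample.sample_id, np.full(sample.n_spots, np.nan),
            0, ctrl_size, n_bins, seed,
        )
    bins = _expression_bins(expr, gene_ids, n_bins)
    bin_of = np.empty(len(gene_ids), dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b
    rng = np.random.default_rng(seed)
    ctrl = []
    for g in set_idx:
        members = bins[bin_of[g]]
        if len(members) <= ctrl_size:
            ctrl.append(members)
        else:
            ctrl.append(rng.choice(members, size=ctrl_size, replace=False))
    ctrl = np.concatenate(ctrl)
    values = expr[:, set_idx].mean(axis=1) - expr[:, ctrl].mean(axis=1)
    return ScoreVector(
        gene_set.name, sample.sample_id, values, len(set_idx), ctrl_size, n_bins, seed
    )


STAR_TIERS = ((90, "***"), (80, "**"), (70, "*"))


@dataclass
class EffectTestResult:
    mean_focal: float
    mean_other: float
    t_stat: float
    p: float
    stars: str  # "ns", "*", "**" or "***"


def quantile_effect_test(scores_focal, scores_other, alpha: float = 0.05) -> EffectTestResult:
    """Welch t-test plus the percentile effect-size star rule.

    Stars require p < alpha and: *** when the other group's 90th percentile is
    below the focal mean, ** for the 80th, * for the 70th (highest satisfied
    tier; the tiers nest since percentiles are monotone).
    """
    x = np.asarray(scores_focal, float)
    y = np.asarray(scores_other, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    if not np.isfinite(p):  # zero variance in both groups
        t, p = 0.0, 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    stars = "ns"
    if p < alpha:
        for q, label in STAR_TIERS:
            if np.percentile(y, q) < x.mean():
                stars = label
                break
    return EffectTestResult(float(x.mean()), float(y.mean()), float(t), float(p), stars)


def fraction_score_correlation(
    cohort: Cohort,
    assignment,
    focal_region,
    gene_set: GeneSet,
    ctrl_size: int = 50,
    n_bins: int = 25,
    seed: int = 0,
    min_samples: int = 4,
    min_samples_expressed: int = 10,
) -> tuple[float, float]:
    """Spearman correlation between each sample's focal-region fraction and
    its mean gene-set score over non-focal spots.

    Non-focal raw counts are pooled cohort-wide, genes expressed in fewer
    than ``min_samples_expressed`` samples dropped, the pool renormalized and
    scored as one pseudo-sample, then averaged per sample.  Requires >=
    ``min_samples`` samples.  A constant score vector yields rho = 0 with a
    warning (undefined rank correlation).
    """
    shared = cohort.shared_genes()
    blocks, owners, fractions = [], [], {}
    for s in cohort:
        labels = assignment.for_sample(s.sample_id)
        fractions[s.sample_id] = float(np.mean(labels == focal_region))
        mask = labels != focal_region
        col = {g: j for j, g in enumerate(s.gene_ids)}
        counts = np.asarray(s.counts.todense())[:, [col[g] for g in shared]]
        blocks.append(counts[mask])
        owners.extend([s.sample_id] * int(mask.sum()))
    if len(cohort) < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {len(cohort)}")
    pooled = np.vstack(blocks)
    owners = np.asarray(owners, dtype=object)
    expressed_in = np.zeros(len(shared))
    for sid in fractions:
        expressed_in += (pooled[owners == sid].sum(axis=0) > 0).astype(int)
    keep = expressed_in >= min(min_samples_expressed, len(cohort))
    pooled = pooled[:, keep]
    genes = [g for g, k in zip(shared, keep) if k]
    import scipy.sparse as sp

    pseudo = STSample(
        sample_id="pooled",
        category="OTHER",
        counts=sp.csr_matrix(pooled.astype(int)),
        gene_ids=genes,
        spot_ids=[f"p{i}" for i in range(len(pooled))],
        array_coords=np.column_stack(
            [np.arange(len(pooled)), np.arange(len(pooled))]
        ),
    )
    pseudo = normalize_log(pseudo)
    scores = score_gene_set(pseudo, gene_set, ctrl_size, n_bins, seed).values
    sample_ids = sorted(fractions)
    mean_scores = np.array([scores[owners == sid].mean() for sid in sample_ids])
    frac = np.array([fractions[sid] for sid in sample_ids])
    if np.ptp(mean_scores) == 0 or np.ptp(frac) == 0:
        logger.warning("degenerate (constant) input to Spearman; rho reported as 0")
        return 0.0, 1.0
    rho, p = stats.spearmanr(frac, mean_scores)
    return float(rho), float(p)


def score_table(cohort: Cohort, gene_sets, ctrl_size=50, n_bins=25, seed=0) -> pd.DataFrame:
    """Tidy per-spot score table over all samples and sets."""
    rows = []
    for s in cohort:
        for gs in gene_sets:
            sv = score_gene_set(s, gs, ctrl_size, n_bins, seed)
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "spot_id": s.spot_ids,
                        "set": gs.name,
                        "score": sv.values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
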