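"""Region marker discovery: per-sample one-vs-rest DE, cross-sample Fisher
meta-enrichment, category-wise group DE, and gene-set overrepresentation.

Marker logic: within each sample, every region with at least
``min_region_size`` spots is compared gene-by-gene against all other spots of
that sample (two-sided Wilcoxon rank-sum, BH across genes within the
(sample, region) family); a gene is *differentially expressed* in that
instance when log2 fold change >= 1 and adjusted p < 0.05.  Across samples, a
one-sided Fisher exact test then asks, for every (gene, region), whether the
gene was DE more often in that region's instances than in all other regions'
instances; BH across genes within each region declares the region-specific
markers.  A gene may be a marker of several regions.

The fold change convention: means are taken on the linear scale (expm1 of the
log-normalized values), log2fc = log2((mean_in + eps) / (mean_out + eps)),
eps = 1e-9.

Instances dropped by the region-size floor count as *untested*, not as
non-DE: they contribute to neither margin of the Fisher table.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_greater, rank_sum_test, rank_sum_test_matrix
from .st_io import Cohort, GeneSet, STSample, is_mito_ribo

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9
DEFAULT_ALPHA = 0.05
DEFAULT_LOG2FC_MIN = 1.0


def _log2fc(expr_in, expr_out) -> np.ndarray:
    """log2 ratio of linear-scale group means of log1p-normalized values."""
    mean_in = np.expm1(expr_in).mean(axis=0)
    mean_out = np.expm1(expr_out).mean(axis=0)
    return np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))


def _dense_norm(sample: STSample) -> np.ndarray:
    if sample.norm_expr is None:
        raise ValueError(f"{sample.sample_id}: normalize before DE")
    return np.asarray(sample.norm_expr.todense())


def per_sample_de(
    sample: STSample,
    labels,
    min_region_size: int = 10,
    exclude_mito_ribo: bool = True,
    alpha: float = DEFAULT_ALPHA,
    log2fc_min: float = DEFAULT_LOG2FC_MIN,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon DE for every sufficiently large region of one sample.

    Returns a tidy table (sample_id, region, gene, log2fc, p, p_adj, is_de);
    empty (with a warning) when no region reaches the size floor.  Mito/ribo
    genes are excluded from testing by default.
    """
    labels = np.asarray(labels)
    if len(labels) != sample.n_spots:
        raise ValueError("labels length does not match sample spots")
    expr = _dense_norm(sample)
    genes = np.asarray(sample.gene_ids, dtype=object)
    if exclude_mito_ribo:
        keep = ~is_mito_ribo(sample.gene_ids)
        expr = expr[:, keep]
        genes = genes[keep]
    frames = []
    for region in np.unique(labels):
        if region == 0:
            continue
        mask = labels == region
        if mask.sum() < min_region_size or (~mask).sum() == 0:
            continue
        p = rank_sum_test_matrix(expr[mask], expr[~mask])
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample.sample_id,
                    "region": region,
                    "gene": genes,
                    "log2fc": _log2fc(expr[mask], expr[~mask]),
                    "p": p,
                    "p_adj": bh_adjust(p),
                }
            )
        )
    if not frames:
        logger.warning("%s: no region with >= %d spots", sample.sample_id, min_region_size)
        return pd.DataFrame(
            columns=["sample_id", "region", "gene", "log2fc", "p", "p_adj", "is_de"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["is_de"] = (out["log2fc"] >= log2fc_min) & (out["p_adj"] < alpha)
    return out


def region_specific_markers(tables, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Fisher meta-enrichment of DE calls across samples.

    An *instance* is a (sample, region) pair that was actually tested.  For
    gene g and region r the 2x2 table is: a = instances of r where g was DE,
    b = instances of r where g was tested but not DE, c / d = the same over
    all other regions.  One-sided (greater) Fisher p, BH across genes within
    each region; markers are fisher_p_adj < alpha.  Genes never tested in a
    region are excluded from that region's family.
    """
    de = pd.concat(list(tables), ignore_index=True)
    if de.empty:
        raise ValueError("no DE instances to meta-analyze")
    counts = (
        de.groupby(["region", "gene"], sort=True)
        .agg(n_de=("is_de", "sum"), n_tested=("is_de", "size"))
        .reset_index()
    )
    total_by_gene = counts.groupby("gene")[["n_de", "n_tested"]].sum()
    rows = []
    for rec in counts.itertuples(index=False):
        tot = total_by_gene.loc[rec.gene]
        a = int(rec.n_de)
        b = int(rec.n_tested - rec.n_de)
        c = int(tot.n_de - rec.n_de)
        d = int(tot.n_tested - rec.n_tested - c)
        rows.append(
            {
                "region": rec.region,
                "gene": rec.gene,
                "n_de_in_region": a,
                "n_tested_in_region": a + b,
                "n_de_elsewhere": c,
                "n_tested_elsewhere": c + d,
                "fisher_p": fisher_greater(a, b, c, d),
            }
        )
    out = pd.DataFrame(rows)
    out["fisher_p_adj"] = np.nan
    for region, idx in out.groupby("region").groups.items():
        out.loc[idx, "fisher_p_adj"] = bh_adjust(out.loc[idx, "fisher_p"])
    out["is_marker"] = out["fisher_p_adj"] < alpha
    return out


def marker_genes(markers: pd.DataFrame, region) -> list[str]:
    """Convenience: the marker gene list of one region."""
    sel = markers[(markers["region"] == region) & markers["is_marker"]]
    return sorted(sel["gene"])


def group_de(
    cohort: Cohort,
    assignment,
    region,
    min_group_size: int = 10,
    alpha: float = DEFAULT_ALPHA,
    log2fc_min: float = DEFAULT_LOG2FC_MIN,
) -> pd.DataFrame:
    """Pairwise DE between sample categories within one region.

    Spots of the region are pooled across samples within each category (on
    the shared gene space); every category pair with both pools >=
    ``min_group_size`` spots gets a two-sided rank-sum test per gene, BH per
    pair.  Flags genes with |log2fc| >= log2fc_min and p_adj < alpha.
    """
    shared = cohort.shared_genes()
    pools: dict[str, list[np.ndarray]] = {}
    for s in cohort:
        labels = assignment.for_sample(s.sample_id)
        mask = labels == region
        if not mask.any():
            continue
        expr = _dense_norm(s)
        col = {g: j for j, g in enumerate(s.gene_ids)}
        expr = expr[:, [col[g] for g in shared]]
        pools.setdefault(s.category, []).append(expr[mask])
    pooled = {c: np.vstack(mats) for c, mats in pools.items()}
    rows = []
    for ga, gb in combinations(sorted(pooled), 2):
        xa, xb = pooled[ga], pooled[gb]
        if len(xa) < min_group_size or len(xb) < min_group_size:
            logger.info("group pair (%s, %s) skipped: below size floor", ga, gb)
            continue
        p = rank_sum_test_matrix(xa, xb)
        frame = pd.DataFrame(
            {
                "region": region,
                "group_a": ga,
                "group_b": gb,
                "gene": shared,
                "log2fc": _log2fc(xa, xb),
                "p": p,
                "p_adj": bh_adjust(p),
            }
        )
        rows.append(frame)
    if not rows:
        return pd.DataFrame(
            columns=["region", "group_a", "group_b", "gene", "log2fc", "p", "p_adj", "is_de"]
        )
    out = pd.concat(rows, ignore_index=True)
    out["is_de"] = (out["log2fc"].abs() >= log2fc_min) & (out["p_adj"] < alpha)
    return out


def marker_set_overrepresentation(
    markers: pd.DataFrame, gene_sets, universe=None, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of gene sets among each region's
    markers, over the universe of genes tested in >= 1 instance."""
    if universe is None:
        universe = set(markers["gene"])
    universe = set(universe)
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    rows = []
    for region in sorted(markers["region"].unique()):
        mk = set(marker_genes(markers, region))
        for gs in gene_sets:
            members = set(gs.genes) & universe
            if not members:
                logger.warning("set %s has no genes in the tested universe", gs.name)
                rows.append({"region": region, "set": gs.name, "p": 1.0})
                continue
            a = len(members & mk)
            b = len(mk - members)
            c = len(members - mk)
            d = len(universe - members - mk)
            rows.append({"region": region, "set": gs.name, "p": fisher_greater(a, b, c, d)})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for region, idx in out.groupby("region").groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"])
    out["enriched"] = out["p_adj"] < alpha
    return out
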