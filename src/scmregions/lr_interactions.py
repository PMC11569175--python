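"""Ligand-receptor testing at region interfaces.

Within one sample and one region interface (the interacting spot sets from
:mod:`scmregions.spatial_graph`), a directed ligand-receptor pair is tested
with a CellphoneDB-style permutation test: the statistic is the mean of
(mean normalized ligand expression over the F-side spots, mean normalized
receptor expression over the G-side spots); the null permutes the F/G side
assignment over the union of interacting spots.  A pair is only tested when
the ligand is detected (count > 0) in more than ``threshold`` of the F-side
spots and the receptor likewise on the G side; gated-out pairs are *untested*
(no p-value), not p = 1.  p uses the add-one estimator
(1 + #{null >= observed}) / (1 + n_perms), so the smallest attainable value
is 1/(n_perms + 1).  BH runs across pairs within (sample, interface,
direction); pairs with adjusted p < 0.05 are *active*.

Across samples, interface-specific enrichment compares, for each pair, the
number of (sample, interface) instances where it was active at one interface
type against all other interface types (one-sided Fisher, BH across pairs
within interface type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_greater
from .spatial_graph import InterfaceLabels
from .st_io import LRDatabase, STSample

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.01
DEFAULT_N_PERMS = 1000
DEFAULT_MIN_REFS = 3


def filter_lr_pairs(db: LRDatabase, min_refs: int = DEFAULT_MIN_REFS) -> LRDatabase:
    """Keep pairs with at least ``min_refs`` literature references."""
    kept = [p for p in db.pairs if p[2] >= min_refs]
    if not kept:
        logger.warning("no ligand-receptor pair has >= %d references", min_refs)
    return LRDatabase(pairs=kept)


def lr_permutation_test(
    sample: STSample,
    interface: InterfaceLabels,
    ligand: str,
    receptor: str,
    threshold: float = DEFAULT_THRESHOLD,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int = 0,
) -> tuple[float | None, float, float]:
    """Permutation p for one directed pair at one interface.

    Returns ``(p, mean_ligand_f, mean_receptor_g)``; ``p`` is None when the
    expression-fraction gate fails.
    """
    res = lr_test_pairs(
        sample, interface, [(ligand, receptor)], threshold, n_perms, seed
    )
    row = res.iloc[0]
    p = None if not row["tested"] else float(row["p"])
    return p, float(row["mean_lig"]), float(row["mean_rec"])


def lr_test_pairs(
    sample: STSample,
    interface: InterfaceLabels,
    pairs,
    threshold: float = DEFAULT_THRESHOLD,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int = 0,
) -> pd.DataFrame:
    """Test many directed (ligand, receptor) pairs at one interface, sharing
    one stream of side permutations across pairs."""
    if sample.norm_expr is None:
        raise ValueError(f"{sample.sample_id}: normalize before LR testing")
    idx_f = np.flatnonzero(interface.interacting_f)
    idx_g = np.flatnonzero(interface.interacting_g)
    col = {g: j for j, g in enumerate(sample.gene_ids)}
    norm = sample.norm_expr
    counts = sample.counts
    # Canonical side order (by region repr) so that calling with (F, G,
    # ligand, receptor) and (G, F, receptor, ligand) consumes the identical
    # permutation stream and returns the identical p.
    f_first = str(interface.region_f) <= str(interface.region_g)
    side_a, side_b = (idx_f, idx_g) if f_first else (idx_g, idx_f)
    union = np.concatenate([side_a, side_b])
    n_a = len(side_a)
    lig_is_a = f_first  # ligand lives on the F side
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(union)) for _ in range(n_perms)]
    rows = []
    for ligand, receptor in pairs:
        if ligand not in col or receptor not in col:
            rows.append(
                dict(ligand=ligand, receptor=receptor, tested=False,
                     mean_lig=np.nan, mean_rec=np.nan, p=np.nan)
            )
            continue
        jl, jr = col[ligand], col[receptor]
        frac_l = float((counts[idx_f, jl] > 0).sum()) / max(1, len(idx_f))
        frac_r = float((counts[idx_g, jr] > 0).sum()) / max(1, len(idx_g))
        lig_vals = np.asarray(norm[union, jl].todense()).ravel()
        rec_vals = np.asarray(norm[union, jr].todense()).ravel()
        lig_slice = slice(0, n_a) if lig_is_a else slice(n_a, None)
        rec_slice = slice(n_a, None) if lig_is_a else slice(0, n_a)
        mean_lig = float(lig_vals[lig_slice].mean())
        mean_rec = float(rec_vals[rec_slice].mean())
        if frac_l <= threshold or frac_r <= threshold:
            rows.append(
                dict(ligand=ligand, receptor=receptor, tested=False,
                     mean_lig=mean_lig, mean_rec=mean_rec, p=np.nan)
            )
            continue
        obs = 0.5 * (mean_lig + mean_rec)
        n_ge = 0
        for perm in perms:
            null = 0.5 * (
                lig_vals[perm[lig_slice]].mean() + rec_vals[perm[rec_slice]].mean()
            )
            if null >= obs:
                n_ge += 1
        p = (1 + n_ge) / (1 + n_perms)
        rows.append(
            dict(ligand=ligand, receptor=receptor, tested=True,
                 mean_lig=mean_lig, mean_rec=mean_rec, p=p)
        )
    return pd.DataFrame(rows)


def lr_interface_results(
    samples_interfaces,
    db: LRDatabase,
    threshold: float = DEFAULT_THRESHOLD,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the permutation test over every (sample, interface) and both
    directions; BH within (sample, interface, direction).

    ``samples_interfaces`` yields ``(sample, interface)`` tuples where the
    interface already passed the spot-count floor.  Direction ``F->G`` places
    the ligand on the F side; ``G->F`` swaps the sides.
    """
    frames = []
    for i, (sample, iface) in enumerate(samples_interfaces):
        for direction in ("F->G", "G->F"):
            if direction == "F->G":
                use = iface
            else:
                use = InterfaceLabels(
                    iface.region_g, iface.region_f, iface.interacting_g, iface.interacting_f
                )
            res = lr_test_pairs(
                sample, use, [(l, r) for l, r, _ in db.pairs], threshold, n_perms,
                seed=int(np.random.default_rng([seed, i]).integers(2**31)),
            )
            res["sample_id"] = sample.sample_id
            res["region_f"] = iface.region_f
            res["region_g"] = iface.region_g
            res["direction"] = direction
            tested = res["tested"].to_numpy()
            res["p_adj"] = np.nan
            res.loc[tested, "p_adj"] = bh_adjust(res.loc[tested, "p"])
            res["active"] = res["p_adj"] < alpha
            frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "region_f", "region_g", "direction", "ligand",
                     "receptor", "tested", "mean_lig", "mean_rec", "p", "p_adj", "active"]
        )
    return pd.concat(frames, ignore_index=True)


def interface_enrichment(
    results: pd.DataFrame,
    focal_markers=None,
    focal_region=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Interface-type specificity of active pairs across samples.

    Interface type = (partner region, direction) seen from the focal region.
    When ``focal_markers`` is given, pairs are first restricted to those whose
    focal-side partner gene (the ligand for focal->other, the receptor for
    other->focal) is a focal-region marker.  For each (pair, interface type):
    a = instances active here, b = tested-not-active here, c/d = the same at
    all other interface types; one-sided Fisher, BH across pairs within type.
    """
    res = results[results["tested"]].copy()
    if res.empty:
        return pd.DataFrame(
            columns=["ligand", "receptor", "interface", "n_active_here",
                     "n_tested_here", "n_active_elsewhere", "n_tested_elsewhere",
                     "fisher_p", "fisher_p_adj", "enriched"]
        )
    if focal_region is not None:

        def iface_type(row):
            if row["region_f"] == focal_region:
                partner, direction = row["region_g"], row["direction"]
            else:
                partner = row["region_f"]
                direction = "G->F" if row["direction"] == "F->G" else "F->G"
            return f"{partner}:{direction}"

        res["interface"] = res.apply(iface_type, axis=1)
        if focal_markers is not None:
            focal_side_gene = np.where(
                ((res["region_f"] == focal_region) & (res["direction"] == "F->G"))
                | ((res["region_g"] == focal_region) & (res["direction"] == "G->F")),
                res["ligand"],
                res["receptor"],
            )
            res = res[pd.Series(focal_side_gene, index=res.index).isin(set(focal_markers))]
    else:
        res["interface"] = (
            res["region_f"].astype(str) + "-" + res["region_g"].astype(str)
            + ":" + res["direction"]
        )
    grp = (
        res.groupby(["ligand", "receptor", "interface"])
        .agg(n_active=("active", "sum"), n_tested=("active", "size"))
        .reset_index()
    )
    totals = grp.groupby(["ligand", "receptor"])[["n_active", "n_tested"]].sum()
    rows = []
    for rec in grp.itertuples(index=False):
        tot = totals.loc[(rec.ligand, rec.receptor)]
        a = int(rec.n_active)
        b = int(rec.n_tested - rec.n_active)
        c = int(tot.n_active - a)
        d = int(tot.n_tested - rec.n_tested - c)
        degenerate = rec.n_tested == tot.n_tested  # tested at a single type
        rows.append(
            {
                "ligand": rec.ligand,
                "receptor": rec.receptor,
                "interface": rec.interface,
                "n_active_here": a,
                "n_tested_here": a + b,
                "n_active_elsewhere": c,
                "n_tested_elsewhere": c + d,
                "fisher_p": fisher_greater(a, b, c, d),
                "single_type": bool(degenerate),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["ligand", "receptor", "interface", "n_active_here",
                 "n_tested_here", "n_active_elsewhere", "n_tested_elsewhere",
                 "fisher_p", "single_type"],
    )
    out["fisher_p_adj"] = np.nan
    for iface, idx in out.groupby("interface").groups.items():
        out.loc[idx, "fisher_p_adj"] = bh_adjust(out.loc[idx, "fisher_p"])
    out["enriched"] = out["fisher_p_adj"] < alpha
    return out
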