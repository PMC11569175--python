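"""Synthetic Visium-like cohorts with known ground truth.

Emulates the study conditions of a multi-sample prostate spatial
transcriptomics cohort: four sample categories (BPH-, treatment-naive-,
neoadjuvant-treated- and CRPC-like), spots on the staggered hex lattice,
per-spot cell-state abundances concentrated into spatially coherent latent
regions, negative-binomial counts with planted region markers and gene-set
shifts, and planted ligand-receptor co-expression at one region's interface.

The generative model (nothing of the sort exists upstream, so it is stated
fully here):

* regions: ``k_true`` seed spots grown by randomized BFS over the hex lattice
  (compact connected patches);
* abundance: each region has a fixed composition profile (a 0.7 bump on its
  dominant cell state plus a Dirichlet background, shared across samples);
  spots draw their region's profile with per-state log-normal jitter of
  scale ``abundance_noise_sd`` and a gamma-jittered total of
  ``cells_per_spot`` cells;
* counts: gene-wise negative binomial with variance mu + mu^2 / dispersion;
  library sizes log-normal around ``mean_umis_per_spot``; each region's
  marker genes have their mean multiplied by ``2**marker_log2fc`` inside the
  region; planted gene sets are shifted by ``exp(signature_shift)`` in their
  designated region; an "AR-like" set is scaled down genome-wide in
  NEADT/CRPC-category samples while "club-like" markers stay unchanged;
* ligand-receptor planting: for flagged pairs, ligand counts are inflated in
  source-region spots within 3 rings of the target region and receptor
  counts in target-region spots within 3 rings of the source region (the
  interface band), making the co-expression specific to that region pair.

Determinism: one master seed; each sample draws from its own substream
``default_rng([seed, category_key])`` (the key depending only on category and
index within category) and cohort-level gene assignments from
``default_rng([seed, 999983])``, so adding a sample never perturbs earlier
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .st_io import (
    Cohort,
    GeneSet,
    LRDatabase,
    STSample,
    write_abundance,
    write_gene_sets,
    write_lr_table,
    write_spot_matrix,
)
from .spatial_graph import build_hex_graph

_GENE_RNG_KEY = 999983  # fixed cohort-level substream offset


@dataclass
class SimConfig:
    """All knobs of the generator, with the default study-like conditions."""

    samples_per_category: dict = field(
        default_factory=lambda: {"BPH": 3, "TRNA": 3, "NEADT": 3, "CRPC": 3}
    )
    lattice_rows: int = 30
    lattice_cols: int = 30
    k_true: int = 8
    k_states: int = 26
    n_genes: int = 1000
    markers_per_region: int = 10
    marker_log2fc: float = 2.0
    nb_dispersion: float = 10.0
    mean_umis_per_spot: float = 3000.0
    library_log_sd: float = 0.3
    cells_per_spot: float = 20.0
    abundance_noise_sd: float = 0.3
    spatial_patch_scale: float = 1.0
    signature_genes_per_set: int = 20
    signature_shift: float = 0.5
    ar_downshift_log2fc: float = 1.0
    fraction_score_coupling: float = 2.0
    lr_interface_effect: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.k_true > self.k_states:
            raise ValueError("k_true must be <= k_states")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("lattice_rows", "lattice_cols", "k_true", "k_states", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted truth for one cohort."""

    true_region: dict  # sample_id -> np.ndarray of region labels (1..k_true)
    marker_genes: dict  # region label -> list of gene symbols
    dominant_state: dict  # region label -> state index
    gene_sets: list  # list of GeneSet
    set_shifts: dict  # (set name, region label) -> log-scale shift
    lr_planted: list  # dicts: ligand, receptor, source_region, target_region


def generate_hex_lattice(rows: int, cols: int) -> np.ndarray:
    """Staggered (row, col) grid with the 10x parity convention (row+col even)."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    r = np.repeat(np.arange(rows), cols)
    c = 2 * np.tile(np.arange(cols), rows) + (r % 2)
    return np.column_stack([r, c])


def generate_region_field(coords, k_true: int, patch_scale: float = 1.0, seed=0) -> np.ndarray:
    """Spatially coherent labeling by randomized multi-source BFS growth.

    ``patch_scale`` sets how front-like the growth is: each step pops from the
    first ``ceil(4 * patch_scale)`` entries of the growing region's frontier
    (small window = smooth compact fronts, large = ragged).  Labels are
    1..k_true; deterministic given the seed.
    """
    coords = np.asarray(coords, int)
    n = len(coords)
    if k_true > n:
        raise ValueError(f"k_true={k_true} exceeds {n} spots")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer, list)) else seed
    graph = build_hex_graph(coords, n_rings=1)
    nbrs = [graph.neighbors(i, 1) for i in range(n)]
    labels = np.zeros(n, dtype=int)
    seeds = rng.choice(n, size=k_true, replace=False)
    # regions 1 and 2 are seeded on adjacent spots so their interface (where
    # ligand-receptor co-expression is planted) exists in every sample
    if k_true >= 2:
        nbrs0 = [v for v in nbrs[seeds[0]] if v not in seeds[2:]]
        if nbrs0:
            seeds[1] = nbrs0[int(rng.integers(len(nbrs0)))]
    frontiers = []
    for lab, s in enumerate(seeds, start=1):
        labels[s] = lab
        frontiers.append([s])
    window = max(1, int(np.ceil(4 * patch_scale)))
    active = list(range(k_true))
    while active:
        r = active[rng.integers(len(active))]
        frontier = frontiers[r]
        if not frontier:
            active.remove(r)
            continue
        pos = int(rng.integers(min(window, len(frontier))))
        spot = frontier[pos]
        grown = False
        for v in nbrs[spot]:
            if labels[v] == 0:
                labels[v] = r + 1
                frontier.append(int(v))
                grown = True
        if not grown:
            frontier.pop(pos)
    # isolated unlabeled spots (disconnected lattices only): nearest seed
    if (labels == 0).any():
        from .spatial_graph import axial_coords, hex_distance

        ax = axial_coords(coords)
        for i in np.flatnonzero(labels == 0):
            d = hex_distance(ax[i][None, :], ax[seeds])
            labels[i] = 1 + int(np.argmin(d))
    return labels


#: weight of the dominant-state bump in each region's composition profile
_DOMINANT_WEIGHT = 0.7


def region_state_profiles(cfg: SimConfig) -> np.ndarray:
    """Fixed per-region cell-state composition profiles (k_true x k_states).

    Region r (1-based) is dominated by its designated state s(r) = r - 1 (an
    injective map since k_true <= k_states): profile = 0.7 on the dominant
    state plus 0.3 spread as a region-specific Dirichlet background.  Drawn
    from a cohort-level substream of the seed, so every sample shares the
    same profiles -- abundance data is then effectively rank k_true, the
    regime in which the component-uniqueness stopping rule is meaningful.
    """
    rng = np.random.default_rng([cfg.seed, _GENE_RNG_KEY + 2])
    # Background mass sits mostly on the dominant states themselves
    # (cross-contamination between regions); states that dominate nowhere are
    # rare everywhere, as in deconvolution output of a curated reference.
    bg_dom = rng.dirichlet(np.ones(cfg.k_true), size=cfg.k_true)
    background = np.zeros((cfg.k_true, cfg.k_states))
    background[:, : cfg.k_true] = 0.95 * bg_dom
    n_rest = cfg.k_states - cfg.k_true
    if n_rest:
        background[:, cfg.k_true :] = 0.05 * rng.dirichlet(np.ones(n_rest), size=cfg.k_true)
    else:
        background[:, : cfg.k_true] = bg_dom
    profiles = _DOMINANT_WEIGHT * np.eye(cfg.k_true, cfg.k_states)
    profiles += (1.0 - _DOMINANT_WEIGHT) * background
    return profiles


def generate_abundance(true_region, cfg: SimConfig, rng, profiles=None) -> np.ndarray:
    """Per-spot nonnegative cell-state abundance (spots x k_states).

    Each spot's composition is its region's profile perturbed by per-state
    log-normal jitter of scale ``abundance_noise_sd`` (0 = exact profile,
    argmax always the dominant state), renormalised and scaled to a
    gamma-jittered total of ``cells_per_spot`` cells.
    """
    labels = np.asarray(true_region)
    n = len(labels)
    if profiles is None:
        profiles = region_state_profiles(cfg)
    comp = profiles[labels - 1]
    noise = float(cfg.abundance_noise_sd)
    if noise > 0:
        comp = comp * np.exp(rng.normal(0.0, noise, size=(n, cfg.k_states)))
    comp = comp / comp.sum(axis=1, keepdims=True)
    totals = cfg.cells_per_spot * rng.gamma(shape=50.0, scale=1 / 50.0, size=n)
    return totals[:, None] * comp


@dataclass
class _GeneTable:
    """Cohort-level gene assignments shared by every sample."""

    gene_ids: list
    base_weight: np.ndarray  # relative expression, sums to 1
    marker_genes: dict  # region -> list of gene indices
    gene_sets: dict  # name -> list of gene indices
    set_region: dict  # name -> region whose spots get the signature shift
    lr_genes: tuple = (0, 1)  # (ligand_idx, receptor_idx) for the planted pair


REGION_NAMES = {1: "Club-like", 2: "Immune-like"}  # remaining regions generic


def _build_gene_table(cfg: SimConfig) -> _GeneTable:
    rng = np.random.default_rng([cfg.seed, _GENE_RNG_KEY])
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    n_marker = cfg.k_true * cfg.markers_per_region
    n_sig = 3 * cfg.signature_genes_per_set
    if n_marker + n_sig + 2 > cfg.n_genes:
        raise ValueError("n_genes too small for requested markers and signatures")
    order = rng.permutation(cfg.n_genes)
    marker_genes = {
        r: sorted(order[(r - 1) * cfg.markers_per_region : r * cfg.markers_per_region])
        for r in range(1, cfg.k_true + 1)
    }
    # Signature genes are spread across the upper 60% of the expression
    # distribution with a fixed stride: each expression bin then holds at
    # most a couple of genes of any one set, so bin-matched controls are not
    # dominated by the set itself, and counts are large enough for log1p
    # shifts to be read off cleanly.
    free = order[n_marker:]
    free_sorted = free[np.argsort(raw[free])][::-1]
    band = free_sorted[: max(n_sig + 2, int(0.6 * len(free_sorted)))]
    stride = len(band) // (n_sig + 2)
    picks = band[:: max(1, stride)][: n_sig + 2]
    sets = {}
    for i, name in enumerate(("AR-like", "Club-cell", "PMN-MDSC")):
        sets[name] = sorted(int(g) for g in picks[i::3][: cfg.signature_genes_per_set])
    set_region = {"AR-like": 3, "Club-cell": 1, "PMN-MDSC": 2}
    # dedicated ligand/receptor genes: the two left-over picks, deliberately
    # outside every signature set and marker list
    lr_genes = (int(picks[-2]), int(picks[-1]))
    return _GeneTable(
        gene_ids=gene_ids,
        base_weight=raw / raw.sum(),
        marker_genes=marker_genes,
        gene_sets=sets,
        set_region=set_region,
        lr_genes=lr_genes,
    )


def generate_counts(true_region, category: str, cfg: SimConfig, gene_table: _GeneTable, rng,
                    focal_fraction: float | None = None) -> np.ndarray:
    """Negative-binomial spot x gene counts for one sample.

    Fold effects: region markers up ``2**marker_log2fc`` inside their region;
    planted signature sets up ``exp(signature_shift)`` in their designated
    region; the AR-like set down ``2**-ar_downshift_log2fc`` genome-wide in
    NEADT/CRPC samples (club-like markers untouched); the PMN-MDSC set
    additionally scaled by ``2**(fraction_score_coupling * focal_fraction)``
    outside the focal region, coupling sample composition to signature level.
    """
    labels = np.asarray(true_region)
    n = len(labels)
    g = cfg.n_genes
    fold = np.ones((n, g))
    for r, genes in gene_table.marker_genes.items():
        fold[np.ix_(labels == r, genes)] *= 2.0**cfg.marker_log2fc
    for name, genes in gene_table.gene_sets.items():
        r = gene_table.set_region[name]
        # plant the shift in log1p space at the typical library size: the
        # per-gene count multiplier m solves log1p(m*mu) - log1p(mu) = shift,
        # so bin-matched scores recover `signature_shift` directly
        mu = cfg.mean_umis_per_spot * gene_table.base_weight[genes]
        m = (np.exp(cfg.signature_shift) * (1.0 + mu) - 1.0) / mu
        fold[np.ix_(labels == r, genes)] *= m[None, :]
    if category in ("NEADT", "CRPC"):
        fold[:, gene_table.gene_sets["AR-like"]] *= 2.0**-cfg.ar_downshift_log2fc
    if cfg.fraction_score_coupling and focal_fraction is not None:
        pmn = gene_table.gene_sets["PMN-MDSC"]
        nonfocal = labels != gene_table.set_region["Club-cell"]
        fold[np.ix_(nonfocal, pmn)] *= 2.0 ** (cfg.fraction_score_coupling * focal_fraction)
    lib = rng.lognormal(
        mean=np.log(cfg.mean_umis_per_spot) - cfg.library_log_sd**2 / 2,
        sigma=cfg.library_log_sd,
        size=n,
    )
    mu = lib[:, None] * gene_table.base_weight[None, :] * fold
    lam = rng.gamma(shape=cfg.nb_dispersion, scale=mu / cfg.nb_dispersion)
    return rng.poisson(lam)


def plant_lr_coexpression(counts, true_region, graph, lr_specs, effect: float, rng) -> np.ndarray:
    """Inflate ligand counts in source-region spots facing the target region
    and receptor counts in target-region spots within 3 rings of the source.

    Both effects are confined to the interface band (spots of one region
    within 3 rings of the other), so the planted co-expression is specific to
    that region pair's interface rather than to every interface the source
    region participates in.  ``lr_specs`` is a list of dicts with keys
    ligand_idx, receptor_idx, source_region, target_region (gene indices into
    the counts columns).  ``effect`` is the mean number of added (Poisson)
    counts per affected spot; 0 leaves counts untouched.
    """
    counts = np.asarray(counts)
    if effect == 0 or not lr_specs:
        return counts
    labels = np.asarray(true_region)
    out = counts.copy()
    within3 = graph.within(3).astype(float)
    for spec in lr_specs:
        for key in ("ligand_idx", "receptor_idx"):
            if not (0 <= spec[key] < counts.shape[1]):
                raise ValueError(f"unknown gene index {spec[key]} in lr spec")
        src = labels == spec["source_region"]
        tgt_all = labels == spec["target_region"]
        near_src = np.asarray(within3 @ src.astype(float)).ravel() > 0
        near_tgt = np.asarray(within3 @ tgt_all.astype(float)).ravel() > 0
        src_band = src & near_tgt
        tgt_band = tgt_all & near_src
        out[src_band, spec["ligand_idx"]] += rng.poisson(effect, size=int(src_band.sum()))
        out[tgt_band, spec["receptor_idx"]] += rng.poisson(effect, size=int(tgt_band.sum()))
    return out


def _sample_ids_and_categories(cfg: SimConfig):
    """(sample_id, category, substream key) triples; the key depends only on
    the category and the index within it, so adding samples elsewhere never
    perturbs existing ones."""
    cats = ("BPH", "TRNA", "NEADT", "CRPC", "MET", "OTHER")
    out = []
    for c, cat in enumerate(cats):
        for i in range(cfg.samples_per_category.get(cat, 0)):
            out.append((f"{cat}_{i + 1}", cat, 1000 * (c + 1) + i))
    return out


def generate_cohort(cfg: SimConfig):
    """Full cohort: samples, per-sample abundances, gene sets, LR table, truth.

    Returns ``(cohort, abundance, truth, gene_sets, lr_db)`` where
    ``abundance`` is a DataFrame indexed by (barcode, sample_id) over cell
    states, aligned with the concatenated spots of the cohort.
    """
    gene_table = _build_gene_table(cfg)
    coords = generate_hex_lattice(cfg.lattice_rows, cfg.lattice_cols)
    state_names = [f"state_{i:02d}" for i in range(cfg.k_states)]
    # one planted LR pair: ligand from the Club-like region toward the
    # Immune-like region's interface spots
    lig_idx, rec_idx = gene_table.lr_genes
    lr_specs = [
        {
            "ligand_idx": lig_idx,
            "receptor_idx": rec_idx,
            "source_region": 1,
            "target_region": 2,
        }
    ]
    samples = []
    abundance_frames = []
    true_region = {}
    profiles = region_state_profiles(cfg)
    for sample_id, category, stream_key in _sample_ids_and_categories(cfg):
        rng = np.random.default_rng([cfg.seed, stream_key])
        labels = generate_region_field(coords, cfg.k_true, cfg.spatial_patch_scale, rng)
        abundance = generate_abundance(labels, cfg, rng, profiles)
        focal_fraction = float(np.mean(labels == 1))
        counts = generate_counts(labels, category, cfg, gene_table, rng, focal_fraction)
        graph = build_hex_graph(coords, n_rings=3)
        counts = plant_lr_coexpression(
            counts, labels, graph, lr_specs, cfg.lr_interface_effect, rng
        )
        barcodes = [f"{sample_id}_s{i:04d}" for i in range(len(coords))]
        samples.append(
            STSample(
                sample_id=sample_id,
                category=category,
                counts=sp.csr_matrix(counts),
                gene_ids=list(gene_table.gene_ids),
                spot_ids=barcodes,
                array_coords=coords.copy(),
            )
        )
        frame = pd.DataFrame(abundance, columns=state_names)
        frame.insert(0, "sample_id", sample_id)
        frame.insert(0, "barcode", barcodes)
        abundance_frames.append(frame.set_index(["barcode", "sample_id"]))
        true_region[sample_id] = labels
    gene_sets = [
        GeneSet(name=name, genes=[gene_table.gene_ids[i] for i in idx])
        for name, idx in gene_table.gene_sets.items()
    ]
    # a set that overlaps region 1's planted markers, so marker-level
    # overrepresentation has a true positive to find
    gene_sets.append(
        GeneSet(
            name="Region1-marker-like",
            genes=[gene_table.gene_ids[i] for i in gene_table.marker_genes[1]],
        )
    )
    # LR table: the planted pair plus decoys spanning the reference-count filter
    decoy_rng = np.random.default_rng([cfg.seed, _GENE_RNG_KEY + 1])
    background = [
        i for i in range(cfg.n_genes)
        if i not in (lig_idx, rec_idx)
    ]
    decoys = decoy_rng.choice(background, size=12, replace=False)
    pairs = [(gene_table.gene_ids[lig_idx], gene_table.gene_ids[rec_idx], 9)]
    for j in range(0, 12, 2):
        pairs.append(
            (
                gene_table.gene_ids[decoys[j]],
                gene_table.gene_ids[decoys[j + 1]],
                int(decoy_rng.integers(0, 8)),
            )
        )
    lr_db = LRDatabase(pairs=pairs)
    truth = GroundTruth(
        true_region=true_region,
        marker_genes={
            r: [gene_table.gene_ids[i] for i in idx]
            for r, idx in gene_table.marker_genes.items()
        },
        dominant_state={r: r - 1 for r in range(1, cfg.k_true + 1)},
        gene_sets=gene_sets,
        set_shifts={
            (name, gene_table.set_region[name]): cfg.signature_shift
            for name in gene_table.gene_sets
        },
        lr_planted=[
            {
                "ligand": gene_table.gene_ids[lig_idx],
                "receptor": gene_table.gene_ids[rec_idx],
                "source_region": 1,
                "target_region": 2,
            }
        ],
    )
    return Cohort(samples=samples), pd.concat(abundance_frames), truth, gene_sets, lr_db


def write_cohort(out_dir, cohort: Cohort, abundance: pd.DataFrame, truth: GroundTruth,
                 gene_sets, lr_db) -> Path:
    """Write the cohort in the exact on-disk layout st_io reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        write_spot_matrix(s, out / s.sample_id)
        rows.append({"sample_id": s.sample_id, "category": s.category})
    pd.DataFrame(rows).to_csv(out / "samples.tsv", sep="\t", index=False)
    write_abundance(abundance, out / "abundance.tsv")
    write_gene_sets(gene_sets, out / "gene_sets.gmt")
    write_lr_table(lr_db, out / "lr_pairs.csv")
    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    region_rows = []
    for sid, labels in truth.true_region.items():
        for barcode, lab in zip(cohort[sid].spot_ids, labels):
            region_rows.append({"sample_id": sid, "barcode": barcode, "true_region": lab})
    pd.DataFrame(region_rows).to_csv(gt_dir / "true_regions.tsv", sep="\t", index=False)
    marker_rows = [
        {"region": r, "gene": g} for r, genes in truth.marker_genes.items() for g in genes
    ]
    pd.DataFrame(marker_rows).to_csv(gt_dir / "marker_genes.tsv", sep="\t", index=False)
    return out
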