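"""End-to-end orchestration: simulate -> preprocess -> regions -> markers ->
graph/interfaces -> scores -> ligand-receptor, with a run manifest.

Every stage writes TSV tables prefixed with a comment header carrying the
seed and a hash of the parameter set, so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import st_io, synthetic_data
from .region_calling import (
    AbundanceMatrix,
    RegionAssignment,
    assign_regions,
    compare_fractions,
    region_fractions,
    select_k_by_uniqueness,
)
from .region_markers import (
    marker_genes,
    marker_set_overrepresentation,
    per_sample_de,
    region_specific_markers,
)
from .signatures import score_table
from .spatial_graph import (
    SampleExcluded,
    annotate_interface,
    annotate_proximity,
    build_hex_graph,
    cohort_enrichment,
    neighborhood_enrichment,
)
from .lr_interactions import filter_lr_pairs, interface_enrichment, lr_interface_results

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "call_regions",
    "markers",
    "interfaces",
    "score",
    "lr",
)


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the study settings."""

    out_dir: str = "run"
    simulate: bool = True
    data_dir: str | None = None
    min_umis: int = 500
    min_spots_per_gene: int = 5
    k_min: int = 5
    k_max: int = 12
    min_region_size: int = 10
    rings: int = 3
    n_perms: int = 1000
    ctrl_size: int = 50
    n_bins: int = 25
    lr_threshold: float = 0.01
    min_refs: int = 3
    alpha: float = 0.05
    log2fc_min: float = 1.0
    focal_region: int = 1
    min_focal_spots: int = 10
    min_interface_spots: int = 10
    seed: int = 0
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def params_hash(self) -> str:
        """Hash of the analytic parameters (paths excluded)."""
        params = dataclasses.asdict(self)
        params.pop("out_dir", None)
        params.pop("data_dir", None)
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    header = f"# seed={cfg.seed} params={cfg.params_hash()}\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_cohort(data_dir) -> tuple[st_io.Cohort, pd.DataFrame, st_io.LRDatabase, list]:
    data_dir = Path(data_dir)
    samples_tbl = pd.read_csv(data_dir / "samples.tsv", sep="\t")
    samples = [
        st_io.read_spot_matrix(
            data_dir / row.sample_id / "matrix.mtx",
            data_dir / row.sample_id / "barcodes.tsv",
            data_dir / row.sample_id / "features.tsv",
            data_dir / row.sample_id / "tissue_positions.csv",
            row.sample_id,
            row.category,
        )
        for row in samples_tbl.itertuples(index=False)
    ]
    abundance = st_io.read_abundance(data_dir / "abundance.tsv")
    lr_db = st_io.read_lr_table(data_dir / "lr_pairs.csv")
    gene_sets = st_io.read_gene_sets(data_dir / "gene_sets.gmt")
    return st_io.Cohort(samples=samples), abundance, lr_db, gene_sets


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages; returns the run directory containing outputs and
    manifest.json."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "params": dataclasses.asdict(cfg),
        "params_hash": cfg.params_hash(),
        "stages": [],
    }

    def stage_done(name, t0, **info):
        manifest["stages"].append(
            {"stage": name, "seconds": round(time.time() - t0, 2), **info}
        )
        logger.info("stage %s done (%.1fs) %s", name, time.time() - t0, info)

    # --- simulate / load -------------------------------------------------
    t0 = time.time()
    if cfg.simulate:
        sim_cfg = synthetic_data.SimConfig(seed=cfg.seed, **cfg.sim)
        cohort, abundance, truth, gene_sets, lr_db = synthetic_data.generate_cohort(sim_cfg)
        data_dir = synthetic_data.write_cohort(
            out / "cohort", cohort, abundance, truth, gene_sets, lr_db
        )
        stage_done("simulate", t0, n_samples=len(cohort), data_dir=str(data_dir))
    else:
        if cfg.data_dir is None:
            raise ValueError("data_dir required when simulate is false")
        cohort, abundance, lr_db, gene_sets = load_cohort(cfg.data_dir)
        stage_done("simulate", t0, skipped=True, data_dir=str(cfg.data_dir))

    # --- preprocess ------------------------------------------------------
    t0 = time.time()
    filtered = []
    for s in cohort:
        f = st_io.filter_sample(s, cfg.min_umis, cfg.min_spots_per_gene)
        filtered.append(st_io.normalize_log(f))
    cohort = st_io.Cohort(samples=filtered)
    kept = {(sid, b) for s in cohort for sid, b in zip([s.sample_id] * s.n_spots, s.spot_ids)}
    stage_done(
        "preprocess", t0,
        spots=sum(s.n_spots for s in cohort),
        genes=[s.n_genes for s in cohort],
    )

    # --- regions ---------------------------------------------------------
    t0 = time.time()
    # abundance index is (barcode, sample_id); align to QC-surviving spots
    mask = [
        (idx[1], idx[0]) in kept if abundance.index.nlevels == 2 else True
        for idx in abundance.index
    ]
    ab = abundance[np.asarray(mask)]
    A = AbundanceMatrix.from_frame(ab)
    model = select_k_by_uniqueness(A, cfg.k_min, cfg.k_max, seed=cfg.seed)
    assignment = assign_regions(model)
    _write_table(assignment.frame(), out / "regions.tsv", cfg)
    _write_table(model.trace, out / "selection_trace.tsv", cfg)
    fractions = region_fractions(assignment)
    _write_table(fractions.reset_index(), out / "region_fractions.tsv", cfg)
    categories = {s.sample_id: s.category for s in cohort}
    try:
        _write_table(compare_fractions(fractions, categories), out / "fraction_tests.tsv", cfg)
    except ValueError as err:
        logger.warning("fraction comparison skipped: %s", err)
    stage_done("call_regions", t0, k=model.k)

    # --- markers ---------------------------------------------------------
    t0 = time.time()
    de_tables = [
        per_sample_de(
            s, assignment.for_sample(s.sample_id), cfg.min_region_size,
            alpha=cfg.alpha, log2fc_min=cfg.log2fc_min,
        )
        for s in cohort
    ]
    de_all = pd.concat(de_tables, ignore_index=True)
    _write_table(de_all, out / "de_per_sample.tsv", cfg)
    markers = region_specific_markers(de_tables, alpha=cfg.alpha)
    _write_table(markers, out / "markers.tsv", cfg)
    overrep = marker_set_overrepresentation(markers, gene_sets, alpha=cfg.alpha)
    _write_table(overrep, out / "marker_set_enrichment.tsv", cfg)
    stage_done("markers", t0, n_markers=int(markers["is_marker"].sum()))

    # --- graph / interfaces ----------------------------------------------
    t0 = time.time()
    z_mats, iface_rows, interfaces = [], [], []
    region_ids = list(range(1, model.k + 1))
    for i, s in enumerate(cohort):
        graph = build_hex_graph(s.array_coords, n_rings=cfg.rings)
        labels = assignment.for_sample(s.sample_id)
        z = neighborhood_enrichment(
            labels, graph, region_ids=region_ids, n_perms=cfg.n_perms,
            seed=int(np.random.default_rng([cfg.seed, 7, i]).integers(2**31)),
        )
        z_mats.append(z)
        try:
            status = annotate_proximity(
                labels, graph, cfg.focal_region, cfg.min_focal_spots
            )
            iface_rows.append(
                pd.DataFrame(
                    {"sample_id": s.sample_id, "spot_id": s.spot_ids, "status": status}
                )
            )
        except SampleExcluded as err:
            logger.info("%s excluded from proximity: %s", s.sample_id, err)
        for other in region_ids:
            if other == cfg.focal_region:
                continue
            try:
                iface = annotate_interface(
                    labels, graph, cfg.focal_region, other, cfg.min_interface_spots
                )
                interfaces.append((s, iface))
            except SampleExcluded:
                pass
    mean_z = cohort_enrichment(z_mats)
    _write_table(
        pd.DataFrame(mean_z, columns=[f"R{r}" for r in region_ids]).assign(
            region=[f"R{r}" for r in region_ids]
        ),
        out / "neighborhood_enrichment.tsv",
        cfg,
    )
    if iface_rows:
        _write_table(pd.concat(iface_rows, ignore_index=True), out / "proximity.tsv", cfg)
    stage_done("interfaces", t0, n_interfaces=len(interfaces))

    # --- scores ----------------------------------------------------------
    t0 = time.time()
    scores = score_table(cohort, gene_sets, cfg.ctrl_size, cfg.n_bins, seed=cfg.seed)
    _write_table(scores, out / "scores.tsv", cfg)
    stage_done("score", t0, n_sets=len(gene_sets))

    # --- ligand-receptor --------------------------------------------------
    t0 = time.time()
    db = filter_lr_pairs(lr_db, cfg.min_refs)
    lr_res = lr_interface_results(
        interfaces, db, cfg.lr_threshold, cfg.n_perms, seed=cfg.seed, alpha=cfg.alpha
    )
    _write_table(lr_res, out / "lr_results.tsv", cfg)
    focal_mk = marker_genes(markers, cfg.focal_region)
    enr = interface_enrichment(
        lr_res, focal_markers=focal_mk, focal_region=cfg.focal_region, alpha=cfg.alpha
    )
    _write_table(enr, out / "lr_interface_enrichment.tsv", cfg)
    stage_done("lr", t0, n_tested=int(lr_res["tested"].sum()) if len(lr_res) else 0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
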