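"""I/O and preprocessing for Visium-style spot-level expression data.

Reads the 10x on-disk triplet layout (MatrixMarket counts + barcode/feature
tables + a tissue-positions table), per-spot cell-state abundance tables,
GMT gene sets and ligand-receptor pair tables; applies the QC filters
(genes in < 5 spots, spots with < 500 UMIs discarded) and a median-library
log1p normalization.

Normalization note: the analysis pipeline only relies on rank-based tests and
bin-matched control scoring downstream, both insensitive to monotone per-spot
scaling, so a simple deterministic median-library-size scaling + log1p is used
as the normalization contract. It is pluggable via ``normalize_log``'s
``target`` argument.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

CATEGORIES = ("BPH", "TRNA", "NEADT", "CRPC", "MET", "OTHER")

#: default recognizer for mitochondrial / ribosomal gene symbols
MITO_RIBO_PATTERN = r"^(MT-|RPL|RPS)"


class FormatError(ValueError):
    """Inconsistent or malformed on-disk data."""


class MissingPositionError(FormatError):
    """A matrix barcode has no entry in the positions table."""


class EmptySampleError(ValueError):
    """All spots (or all genes) were removed by filtering."""


class ValidationError(ValueError):
    """Parsed data violates a declared invariant."""


@dataclass
class STSample:
    """One tissue section: raw counts plus spot geometry and metadata.

    ``counts`` is spots x genes (CSR, non-negative integers); ``norm_expr``
    is absent (None) until :func:`normalize_log` is applied.
    """

    sample_id: str
    category: str
    counts: sp.csr_matrix
    gene_ids: list[str]
    spot_ids: list[str]
    array_coords: np.ndarray  # (n_spots, 2) int: (array_row, array_col)
    in_tissue: np.ndarray | None = None
    norm_expr: sp.csr_matrix | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        n, g = self.counts.shape
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValidationError("counts shape does not match id tables")
        if len(set(self.spot_ids)) != n:
            raise ValidationError("spot_ids not unique")
        if len(set(self.gene_ids)) != g:
            self.gene_ids = _make_unique(self.gene_ids)
        self.array_coords = np.asarray(self.array_coords, dtype=int)
        if self.array_coords.shape != (n, 2):
            raise ValidationError("array_coords shape mismatch")
        if len({tuple(rc) for rc in self.array_coords}) != n:
            raise ValidationError("array_coords not unique per spot")
        if self.in_tissue is None:
            self.in_tissue = np.ones(n, dtype=bool)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, spot_mask=None, gene_mask=None) -> "STSample":
        """Row/column subset keeping all per-spot / per-gene tables aligned."""
        spot_mask = slice(None) if spot_mask is None else np.asarray(spot_mask)
        gene_mask = slice(None) if gene_mask is None else np.asarray(gene_mask)
        return STSample(
            sample_id=self.sample_id,
            category=self.category,
            counts=self.counts[spot_mask][:, gene_mask],
            gene_ids=list(np.asarray(self.gene_ids, dtype=object)[gene_mask]),
            spot_ids=list(np.asarray(self.spot_ids, dtype=object)[spot_mask]),
            array_coords=self.array_coords[spot_mask],
            in_tissue=np.asarray(self.in_tissue)[spot_mask],
            norm_expr=None
            if self.norm_expr is None
            else sp.csr_matrix(self.norm_expr)[spot_mask][:, gene_mask],
        )


@dataclass
class Cohort:
    samples: list[STSample]
    gene_policy: str = "intersection"

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample_ids not unique")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, sample_id: str) -> STSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def shared_genes(self) -> list[str]:
        gene_sets = [set(s.gene_ids) for s in self.samples]
        if self.gene_policy == "union":
            out = set().union(*gene_sets)
        else:
            out = set.intersection(*gene_sets)
        return sorted(out)


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name}: duplicate genes")


@dataclass
class LRDatabase:
    pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        keys = [(l, r) for l, r, _ in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate ligand-receptor pair")
        if any(n < 0 for _, _, n in self.pairs):
            raise ValidationError("n_references must be >= 0")

    def __len__(self):
        return len(self.pairs)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def _make_unique(names):
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}-{seen[name]}"
            logger.warning("duplicated identifier %r renamed to %r", name, new)
            out.append(new)
        else:
            seen[name] = 0
            out.append(name)
    return out


def _read_id_column(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


_POSITION_COLS = ["barcode", "in_tissue", "array_row", "array_col", "px_row", "px_col"]


def read_positions(path) -> pd.DataFrame:
    """Tissue-positions table; header is auto-detected."""
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = str(first.iloc[0, 0]).strip().lower() in ("barcode", "barcodes")
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 4:
        raise FormatError(f"positions table {path} needs >= 4 columns")
    df.columns = _POSITION_COLS[: df.shape[1]]
    return df


def read_spot_matrix(
    mtx_path, barcodes_path, features_path, positions_path, sample_id, category
) -> STSample:
    """Read one 10x-layout sample, keeping only in-tissue spots.

    The on-disk matrix may be genes x spots (10x convention) or spots x genes;
    orientation is resolved against the barcode/feature counts.  A square
    matrix is assumed to be genes x spots.
    """
    mat = sp.csr_matrix(mmread(str(mtx_path)))
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    nb, nf = len(barcodes), len(features)
    if mat.shape == (nf, nb):
        mat = sp.csr_matrix(mat.T)
    elif mat.shape != (nb, nf):
        raise FormatError(
            f"{mtx_path}: matrix shape {mat.shape} matches neither "
            f"(genes={nf}, spots={nb}) nor its transpose"
        )
    pos = read_positions(positions_path)
    pos_index = {b: i for i, b in enumerate(pos["barcode"].astype(str))}
    missing = [b for b in barcodes if b not in pos_index]
    if missing:
        raise MissingPositionError(
            f"barcode {missing[0]!r} has no entry in {positions_path}"
        )
    rows = [pos_index[b] for b in barcodes]
    in_tissue = pos["in_tissue"].to_numpy()[rows].astype(bool)
    coords = pos[["array_row", "array_col"]].to_numpy()[rows]
    keep = np.flatnonzero(in_tissue)
    return STSample(
        sample_id=sample_id,
        category=category,
        counts=mat[keep],
        gene_ids=list(features),
        spot_ids=[barcodes[i] for i in keep],
        array_coords=coords[keep],
        in_tissue=np.ones(len(keep), dtype=bool),
    )


def write_spot_matrix(sample: STSample, out_dir) -> Path:
    """Write a sample back out in the same triplet layout (genes x spots MTX)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(sample.counts.T.astype(int)))
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in sample.spot_ids))
    (out / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in sample.gene_ids)
    )
    pos = pd.DataFrame(
        {
            "barcode": sample.spot_ids,
            "in_tissue": np.asarray(sample.in_tissue).astype(int),
            "array_row": sample.array_coords[:, 0],
            "array_col": sample.array_coords[:, 1],
            "px_row": sample.array_coords[:, 0] * 100,
            "px_col": sample.array_coords[:, 1] * 100,
        }
    )
    pos.to_csv(out / "tissue_positions.csv", index=False)
    return out


def filter_sample(
    sample: STSample, min_umis: int = 500, min_spots_per_gene: int = 5
) -> STSample:
    """QC filter: drop genes in < ``min_spots_per_gene`` spots and spots with
    < ``min_umis`` total UMIs (strict "less than" on both boundaries).

    The gene filter is computed first (on the incoming matrix), then the spot
    filter, iterating to a fixed point so that the post-conditions hold
    jointly on the retained matrix; this also makes the operation idempotent.
    """
    current = sample
    while True:
        gene_keep = np.asarray(
            (current.counts > 0).sum(axis=0)
        ).ravel() >= min_spots_per_gene
        if not gene_keep.all():
            current = current.subset(gene_mask=gene_keep)
        spot_keep = np.asarray(current.counts.sum(axis=1)).ravel() >= min_umis
        if not spot_keep.any():
            raise EmptySampleError(
                f"{sample.sample_id}: no spot reaches {min_umis} UMIs after filtering"
            )
        changed = not spot_keep.all()
        if changed:
            current = current.subset(spot_mask=spot_keep)
        if gene_keep.all() and not changed:
            return current


def normalize_log(sample: STSample, target: float | None = None) -> STSample:
    """Median-library scaling + log1p.

    Each spot's counts are scaled so its total equals ``target`` (default: the
    median spot total of this sample), then log1p-transformed.  Deterministic;
    preserves the zero pattern of the counts.
    """
    totals = np.asarray(sample.counts.sum(axis=1)).ravel()
    if sample.n_spots == 0 or totals.max() == 0:
        raise EmptySampleError(f"{sample.sample_id}: nothing to normalize")
    if target is None:
        target = float(np.median(totals))
    scale = np.divide(target, totals, out=np.zeros_like(totals, float), where=totals > 0)
    norm = sp.csr_matrix(sp.diags(scale) @ sample.counts.astype(float))
    norm.data = np.log1p(norm.data)
    return replace(sample, norm_expr=norm)


def is_mito_ribo(gene_ids, pattern: str = MITO_RIBO_PATTERN) -> np.ndarray:
    """Boolean mask of mitochondrial/ribosomal symbols (prefix convention)."""
    rx = re.compile(pattern)
    return np.array([bool(rx.match(g)) for g in gene_ids])


# ---------------------------------------------------------------------------
# abundance / gene-set / LR tables


def read_abundance(path) -> pd.DataFrame:
    """Spots x cell-states abundance table (TSV with header).

    First column is the spot barcode; an optional ``sample_id`` column is kept
    as part of the index.  All state values must be non-negative.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    idx_cols = [df.columns[0]]
    if "sample_id" in df.columns[1:]:
        idx_cols.append("sample_id")
    df = df.set_index(idx_cols)
    values = df.to_numpy(dtype=float)
    if values.size and values.min() < 0:
        bad = df.columns[np.argwhere(values < 0)[0][1]]
        raise ValidationError(f"negative abundance in column {bad!r}")
    return df


def write_abundance(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_gene_sets(path) -> list[GeneSet]:
    """GMT-like file: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets = []
    with _open_text(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSet(name=parts[0], description=parts[1], genes=[g for g in parts[2:] if g]))
    return sets


def write_gene_sets(sets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def read_lr_table(path) -> LRDatabase:
    """3-column ligand / receptor / n_references table (CSV or TSV)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns (ligand, receptor, n_references)")
    df.columns = ["ligand", "receptor", "n_references"] + list(df.columns[3:])
    pairs = [
        (str(r.ligand), str(r.receptor), int(r.n_references))
        for r in df.itertuples(index=False)
    ]
    return LRDatabase(pairs=pairs)


def write_lr_table(db: LRDatabase, path) -> None:
    pd.DataFrame(db.pairs, columns=["ligand", "receptor", "n_references"]).to_csv(
        path, index=False
    )
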