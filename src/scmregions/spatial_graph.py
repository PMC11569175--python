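"""Hexagonal spot-lattice geometry, neighborhood enrichment, and interface rules.

Visium spots sit on a staggered grid where valid (array_row, array_col)
positions have even row+col parity and each interior spot has six neighbors
at ~100 um.  Ring distance is the hex shortest-path length, computed through
the axial transform q = (col - row) / 2, r = row, giving
d = (|dq| + |dr| + |dq + dr|) / 2.

Three analyses live here:

* permutation neighborhood enrichment (z-score of region-pair adjacency
  counts against label shuffles),
* proximity annotation of spots around a focal region (anchored / sporadic
  focal spots; proximal = within 3 rings of an adjacent pair of anchored
  focal spots; everything else distant),
* interface annotation between two regions (spots anchored in their own
  region with >= 2 spots of the partner region within 3 rings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

DEFAULT_N_RINGS = 3

FOCAL_ANCHORED = "focal-anchored"
FOCAL_SPORADIC = "focal-sporadic"
PROXIMAL = "proximal"
DISTANT = "distant"


class ParityError(ValueError):
    """A coordinate violates the staggered-grid parity convention."""


def axial_coords(array_coords) -> np.ndarray:
    """Map staggered (row, col) to axial hex coordinates (q, r)."""
    coords = np.asarray(array_coords, dtype=int)
    parity = (coords[:, 0] + coords[:, 1]) % 2
    if parity.any():
        bad = np.flatnonzero(parity)[0]
        raise ParityError(
            f"spot {bad} at (row, col)={tuple(coords[bad])} has odd row+col parity"
        )
    q = (coords[:, 1] - coords[:, 0]) // 2
    r = coords[:, 0]
    return np.column_stack([q, r])


def hex_distance(ax_u, ax_v) -> np.ndarray:
    """Hex ring distance between axial coordinate arrays (broadcastable)."""
    dq = np.asarray(ax_u)[..., 0] - np.asarray(ax_v)[..., 0]
    dr = np.asarray(ax_u)[..., 1] - np.asarray(ax_v)[..., 1]
    return (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2


@dataclass
class NeighborGraph:
    """Per-sample ring adjacency up to ``n_rings``.

    ``ring_adj[k]`` (k = 1..n_rings) is a boolean CSR matrix marking spot
    pairs at exactly ring distance k; ``within(k)`` unions rings 1..k.
    """

    array_coords: np.ndarray
    n_rings: int
    ring_adj: dict[int, sp.csr_matrix] = field(repr=False)

    @property
    def n_spots(self) -> int:
        return len(self.array_coords)

    def within(self, max_ring: int | None = None) -> sp.csr_matrix:
        max_ring = self.n_rings if max_ring is None else max_ring
        mats = [self.ring_adj[k] for k in range(1, max_ring + 1)]
        out = mats[0]
        for m in mats[1:]:
            out = (out + m).astype(bool)
        return sp.csr_matrix(out)

    def neighbors(self, i: int, ring: int = 1) -> np.ndarray:
        return self.ring_adj[ring][i].indices


def build_hex_graph(array_coords, n_rings: int = DEFAULT_N_RINGS) -> NeighborGraph:
    """Build ring-1..n adjacency from staggered coordinates (pairwise hex distance)."""
    ax = axial_coords(array_coords)
    d = hex_distance(ax[:, None, :], ax[None, :, :])
    ring_adj = {
        k: sp.csr_matrix(d == k, dtype=bool) for k in range(1, n_rings + 1)
    }
    return NeighborGraph(array_coords=np.asarray(array_coords, int), n_rings=n_rings, ring_adj=ring_adj)


# ---------------------------------------------------------------------------
# neighborhood enrichment


def _pair_counts(adj: sp.csr_matrix, onehot: np.ndarray) -> np.ndarray:
    # ordered-pair edge counts between labels; consistent across permutations
    return onehot.T @ (adj @ onehot)


def neighborhood_enrichment(
    labels,
    graph: NeighborGraph,
    region_ids=None,
    n_perms: int = 1000,
    max_ring: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Permutation z-scores of region-adjacency counts for one sample.

    The observed count of spot pairs (within ``max_ring`` rings, unweighted)
    joining regions i and j is compared to ``n_perms`` random relabelings of
    the same spots; z = (obs - mean_null) / sd_null, with z = 0 wherever the
    null is degenerate (sd = 0).  Rows/columns of regions absent from the
    sample are 0.
    """
    labels = np.asarray(labels)
    if region_ids is None:
        region_ids = np.unique(labels)
    region_ids = list(region_ids)
    k = len(region_ids)
    index = {r: i for i, r in enumerate(region_ids)}
    onehot = np.zeros((len(labels), k))
    for s, lab in enumerate(labels):
        if lab in index:
            onehot[s, index[lab]] = 1.0
    adj = graph.within(max_ring).astype(float)
    obs = _pair_counts(adj, onehot)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perms, k, k))
    for p in range(n_perms):
        perm = rng.permutation(len(labels))
        null[p] = _pair_counts(adj, onehot[perm])
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)
    z = np.zeros((k, k))
    ok = sd > 0
    z[ok] = (obs[ok] - mean[ok]) / sd[ok]
    present = onehot.sum(axis=0) > 0
    z[~present, :] = 0.0
    z[:, ~present] = 0.0
    return z


def cohort_enrichment(z_matrices) -> np.ndarray:
    """Dataset-wide enrichment: mean of per-sample z matrices (missing regions
    already zeroed per sample)."""
    return np.mean(np.stack(list(z_matrices)), axis=0)


# ---------------------------------------------------------------------------
# proximity / interface annotation


class SampleExcluded(Exception):
    """Sample does not meet the focal-spot (or interface) count floor."""


def _anchored_mask(labels, graph, region) -> np.ndarray:
    """Focal spots with >= 1 ring-1 neighbor of the same region."""
    focal = np.asarray(labels) == region
    ring1 = graph.ring_adj[1].astype(float)
    n_focal_nbrs = np.asarray(ring1 @ focal.astype(float)).ravel()
    return focal & (n_focal_nbrs >= 1)


def annotate_proximity(
    labels,
    graph: NeighborGraph,
    focal_region,
    min_focal_spots: int = 10,
    rule: str = "pair-adjacency",
) -> np.ndarray:
    """Classify every spot relative to a focal region.

    Focal spots are *anchored* (>= 1 ring-1 neighbor of the same region) or
    *sporadic*.  Under the default ``pair-adjacency`` rule a non-focal spot is
    *proximal* iff it lies within 3 rings of at least two anchored focal spots
    that are themselves mutually adjacent (a connected pair); the alternative
    ``any-two`` rule only requires two anchored focal spots within 3 rings.
    All remaining non-focal spots are *distant*.  Samples with fewer than
    ``min_focal_spots`` focal spots raise :class:`SampleExcluded`.
    """
    labels = np.asarray(labels)
    focal = labels == focal_region
    if focal.sum() < min_focal_spots:
        raise SampleExcluded(
            f"{int(focal.sum())} focal spots < floor {min_focal_spots}"
        )
    anchored = _anchored_mask(labels, graph, focal_region)
    within3 = graph.within(3)
    n = len(labels)
    proximal = np.zeros(n, dtype=bool)
    anchored_idx = np.flatnonzero(anchored)
    if rule == "pair-adjacency":
        ring1 = graph.ring_adj[1]
        # mark spots within 3 rings of both endpoints of an adjacent anchored pair
        sub = ring1[anchored_idx][:, anchored_idx].tocoo()
        for a, b in zip(anchored_idx[sub.row], anchored_idx[sub.col]):
            if a < b:
                near_a = np.zeros(n, bool)
                near_a[within3[a].indices] = True
                near_a[a] = True
                near_b = np.zeros(n, bool)
                near_b[within3[b].indices] = True
                near_b[b] = True
                proximal |= near_a & near_b
    elif rule == "any-two":
        count = np.asarray(within3.astype(float) @ anchored.astype(float)).ravel()
        proximal = count >= 2
    else:
        raise ValueError(f"unknown rule {rule!r}")
    status = np.where(focal, np.where(anchored, FOCAL_ANCHORED, FOCAL_SPORADIC),
                      np.where(proximal, PROXIMAL, DISTANT))
    return status


@dataclass
class InterfaceLabels:
    """Interacting spot sets for a region pair in one sample."""

    region_f: object
    region_g: object
    interacting_f: np.ndarray  # boolean over spots
    interacting_g: np.ndarray

    @property
    def n_f(self) -> int:
        return int(self.interacting_f.sum())

    @property
    def n_g(self) -> int:
        return int(self.interacting_g.sum())


def annotate_interface(
    labels,
    graph: NeighborGraph,
    region_f,
    region_g,
    min_spots: int = 10,
) -> InterfaceLabels:
    """Interface between two regions.

    A spot of F is *interacting* iff it is anchored in F (>= 1 same-region
    ring-1 neighbor) and has >= 2 region-G spots within 3 rings; symmetric for
    G.  The (sample, F-G) interface exists only if both interacting sets have
    at least ``min_spots`` spots; otherwise :class:`SampleExcluded` is raised.
    """
    labels = np.asarray(labels)
    within3 = graph.within(3).astype(float)

    def interacting(region, other):
        anchored = _anchored_mask(labels, graph, region)
        n_other = np.asarray(within3 @ (labels == other).astype(float)).ravel()
        return anchored & (n_other >= 2)

    inter_f = interacting(region_f, region_g)
    inter_g = interacting(region_g, region_f)
    if inter_f.sum() < min_spots or inter_g.sum() < min_spots:
        raise SampleExcluded(
            f"interface {region_f}-{region_g}: interacting sets "
            f"({int(inter_f.sum())}, {int(inter_g.sum())}) below floor {min_spots}"
        )
    return InterfaceLabels(region_f, region_g, inter_f, inter_g)
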