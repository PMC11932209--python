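"""Typed edge construction: primary, secondary and spatial edge sets.

Three mutually exclusive directed edge types describe one RNA structure:

* primary — backbone adjacency, both directions for every consecutive pair;
* secondary — annotated base pairs (canonical and non-canonical), both
  directions per pair;
* spatial — long-range proximity between *unpaired* nucleotides that fall
  in the same DBSCAN density cluster of C4' positions, sit 2 Å to
  2×eps apart in space and at least ``primary_dist`` apart in sequence.

Spatial candidates grow super-linearly with chain length, so the emitted
directed count is capped at ``cap_multiplier × L`` by seeded uniform
down-sampling of undirected pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .structures import BasePairSet, RNAStructure

__all__ = [
    "TypedEdgeList",
    "SpatialParams",
    "TypedGraph",
    "build_primary_edges",
    "build_secondary_edges",
    "build_spatial_edges",
    "build_graph",
]

EDGE_TYPES = ("primary", "secondary", "spatial")


@dataclass
class TypedEdgeList:
    """Ordered directed (i, j) edges of a single type."""

    edges: np.ndarray  # (E, 2) int
    edge_type: str

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.edge_type!r}")
        if len(self.edges) and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-edges are not allowed")

    def __len__(self) -> int:
        return len(self.edges)

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}


@dataclass
class SpatialParams:
    """Knobs for spatial-edge construction (lengths in Angstrom)."""

    dbscan_eps: float = 20.0
    min_samples: int = 5
    primary_dist: int = 500
    cap_multiplier: int = 4
    min_edge_len: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dbscan_eps, self.min_samples, self.primary_dist,
               self.cap_multiplier, self.min_edge_len) <= 0:
            raise ValueError("all spatial parameters must be positive")
        if self.min_edge_len >= 2 * self.dbscan_eps:
            raise ValueError("min_edge_len must be < 2*dbscan_eps")


@dataclass
class TypedGraph:
    structure: RNAStructure
    basepairs: BasePairSet
    edge_lists: dict[str, TypedEdgeList]
    node_features: object | None = field(default=None)
    edge_features: dict | None = field(default=None)

    def __post_init__(self) -> None:
        sets = [self.edge_lists[t].as_set() for t in EDGE_TYPES]
        for a in range(3):
            for b in range(a + 1, 3):
                overlap = sets[a] & sets[b]
                if overlap:
                    raise AssertionError(
                        f"edge types {EDGE_TYPES[a]}/{EDGE_TYPES[b]} overlap: "
                        f"{sorted(overlap)[:5]}"
                    )

    @property
    def L(self) -> int:
        return len(self.structure)


def build_primary_edges(L: int) -> TypedEdgeList:
    """Backbone-adjacency edges: (i, i+1) and (i+1, i) for all i."""
    if L < 2:
        return TypedEdgeList(np.empty((0, 2), dtype=int), "primary")
    i = np.arange(L - 1)
    edges = np.concatenate([np.stack([i, i + 1], 1), np.stack([i + 1, i], 1)])
    return TypedEdgeList(edges, "primary")


def build_secondary_edges(bp: BasePairSet) -> TypedEdgeList:
    """Both directions for every annotated base pair."""
    if not bp.pairs:
        return TypedEdgeList(np.empty((0, 2), dtype=int), "secondary")
    und = np.array(sorted(bp.pairs), dtype=int)
    edges = np.concatenate([und, und[:, ::-1]])
    return TypedEdgeList(edges, "secondary")


def _candidate_spatial_pairs(
    structure: RNAStructure, bp: BasePairSet, params: SpatialParams
) -> np.ndarray:
    """Undirected candidate pairs (sorted lexicographically)."""
    L = len(structure)
    paired = bp.paired_positions()
    has_c4 = structure.atom_mask[:, 1]
    free = np.array(
        [i for i in range(L) if i not in paired and has_c4[i]], dtype=int
    )
    if len(free) < params.min_samples:
        return np.empty((0, 2), dtype=int)
    xyz = structure.c4_coords[free]
    labels = DBSCAN(
        eps=params.dbscan_eps, min_samples=params.min_samples
    ).fit_predict(xyz)

    out: list[tuple[int, int]] = []
    for lab in np.unique(labels):
        if lab < 0:  # DBSCAN noise belongs to no cluster
            continue
        member_idx = np.flatnonzero(labels == lab)
        pts = xyz[member_idx]
        tree = cKDTree(pts)
        for a, b in tree.query_pairs(r=2 * params.dbscan_eps):
            i, j = int(free[member_idx[a]]), int(free[member_idx[b]])
            if i > j:
                i, j = j, i
            if j - i < params.primary_dist:
                continue
            d = np.linalg.norm(
                structure.c4_coords[i] - structure.c4_coords[j]
            )
            if params.min_edge_len <= d < 2 * params.dbscan_eps:
                out.append((i, j))
    if not out:
        return np.empty((0, 2), dtype=int)
    return np.array(sorted(set(out)), dtype=int)


def build_spatial_edges(
    structure: RNAStructure, bp: BasePairSet, params: SpatialParams | None = None
) -> TypedEdgeList:
    """DBSCAN-gated long-range edges between unpaired nucleotides.

    Candidates are restricted to same-cluster pairs with spatial distance
    in [min_edge_len, 2*eps) and sequence separation >= primary_dist; the
    directed count is capped at cap_multiplier*L via seeded uniform
    down-sampling of undirected pairs (both directions always emitted
    together, keeping the set symmetric).
    """
    params = params or SpatialParams()
    L = len(structure)
    if L < params.primary_dist:
        return TypedEdgeList(np.empty((0, 2), dtype=int), "spatial")
    und = _candidate_spatial_pairs(structure, bp, params)
    max_und = (params.cap_multiplier * L) // 2
    if len(und) > max_und:
        rng = np.random.default_rng(params.seed)
        keep = rng.choice(len(und), size=max_und, replace=False)
        und = und[np.sort(keep)]
    if not len(und):
        return TypedEdgeList(np.empty((0, 2), dtype=int), "spatial")
    edges = np.concatenate([und, und[:, ::-1]])
    return TypedEdgeList(edges, "spatial")


def build_graph(
    structure: RNAStructure,
    bp: BasePairSet,
    params: SpatialParams | None = None,
) -> TypedGraph:
    """Assemble the three typed edge lists into one graph.

    Base pairs between backbone neighbours (|i-j| == 1) would collide
    with primary edges; such annotations are extremely rare and are
    dropped from the secondary list here to keep the types disjoint.
    """
    params = params or SpatialParams()
    L = len(structure)
    bp.validate(L)
    primary = build_primary_edges(L)
    secondary = build_secondary_edges(bp)
    if len(secondary):
        sep = np.abs(secondary.edges[:, 0] - secondary.edges[:, 1])
        secondary = TypedEdgeList(secondary.edges[sep > 1], "secondary")
    if L < params.primary_dist:  # spatial edges need >= 500 nt separation
        spatial = TypedEdgeList(np.empty((0, 2), dtype=int), "spatial")
    else:
        spatial = build_spatial_edges(structure, bp, params)
    return TypedGraph(
        structure=structure,
        basepairs=bp,
        edge_lists={"primary": primary, "secondary": secondary, "spatial": spatial},
    )


def edges_to_tsv(graph: TypedGraph) -> str:
    """Dump all edges as a TSV (i, j, type, length in Angstrom)."""
    rows = ["i\tj\ttype\tlength_A"]
    xyz = graph.structure.c4_coords
    for t in EDGE_TYPES:
        for i, j in graph.edge_lists[t].edges:
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            rows.append(f"{i}\t{j}\t{t}\t{d:.3f}")
    return "\n".join(rows) + "\n"
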