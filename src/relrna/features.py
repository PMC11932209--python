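"""Geometric node and edge featurization.

Node scalars (15 per nucleotide) are the sin/cos of three inter-atom
angles and three dihedrals plus three distances, all computed from the
P/C4'/N backbone frame of the nucleotide and its sequence neighbours.
Node vectors are four unit 3-vectors (C4'->P backward/forward,
C4'->N same-residue/previous-residue).  Edge features are the unit
displacement between C4' endpoints plus the distance encoded by a bank
of Gaussian radial basis functions; all edge types share the same
featurization and no positional encodings are used.

Terms that reference a missing atom or run off a chain terminus are
zero-filled, so scalars stay dense and vectors keep their slot count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import TypedEdgeList
from .structures import RNAStructure

__all__ = ["NodeFeatureSet", "EdgeFeatureSet", "node_features", "edge_features", "rbf_encode"]

N_NODE_SCALARS = 15
N_NODE_VECTORS = 4
DEFAULT_RBF_COUNT = 16
DEFAULT_RBF_MAX = 40.0  # covers the maximal spatial edge length (2 * eps)


@dataclass
class NodeFeatureSet:
    scalars: np.ndarray  # (L, 15)
    vectors: np.ndarray  # (L, 4, 3), unit or zero


@dataclass
class EdgeFeatureSet:
    scalars: np.ndarray  # (E, rbf_count)
    vectors: np.ndarray  # (E, 1, 3), unit


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.zeros(3)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, in radians."""
    u, w = a - b, c - b
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        return np.nan
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.arccos(cosang))


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral of the p0-p1-p2-p3 chain, radians in (-pi, pi]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1)) if np.linalg.norm(b1) else n1
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    if x == 0 and y == 0:
        return np.nan
    return float(np.arctan2(y, x))


def node_features(structure: RNAStructure) -> NodeFeatureSet:
    """Per-nucleotide scalar (15) and unit-vector (4) features.

    With P_i, C_i (C4') and N_i the backbone atoms of nucleotide i:

    distances  d1=|P_i-C_i|  d2=|C_i-N_i|  d3=|C_{i+1}-C_i|
    angles     a1=ang(P_i,C_i,N_i)  a2=ang(C_{i-1},C_i,C_{i+1})
               a3=ang(N_i,C_i,C_{i+1})
    dihedrals  t1=dih(P_i,C_i,P_{i+1},C_{i+1})
               t2=dih(C_{i-1},P_i,C_i,P_{i+1})
               t3=dih(N_{i-1},C_{i-1},C_i,N_i)
    scalars  = [sin,cos](a1,a2,a3,t1,t2,t3) ++ [d1,d2,d3]
    vectors  = unit(P_i-C_i), unit(P_{i+1}-C_i), unit(N_i-C_i), unit(N_{i-1}-C_i)
    """
    L = len(structure)
    scal = np.zeros((L, N_NODE_SCALARS))
    vect = np.zeros((L, N_NODE_VECTORS, 3))
    if L == 0:
        return NodeFeatureSet(scal, vect)
    mask = structure.atom_mask

    def atom(i: int, slot: int) -> np.ndarray | None:
        if 0 <= i < L and mask[i, slot]:
            return structure.coords[i, slot]
        return None

    for i in range(L):
        P, C, N = atom(i, 0), atom(i, 1), atom(i, 2)
        Pn, Cn = atom(i + 1, 0), atom(i + 1, 1)
        Cp, Np_, Pp = atom(i - 1, 1), atom(i - 1, 2), atom(i - 1, 0)

        angles = [
            _angle(P, C, N) if P is not None and C is not None and N is not None else np.nan,
            _angle(Cp, C, Cn) if Cp is not None and C is not None and Cn is not None else np.nan,
            _angle(N, C, Cn) if N is not None and C is not None and Cn is not None else np.nan,
            _dihedral(P, C, Pn, Cn)
            if all(x is not None for x in (P, C, Pn, Cn)) else np.nan,
            _dihedral(Cp, P, C, Pn)
            if all(x is not None for x in (Cp, P, C, Pn)) else np.nan,
            _dihedral(Np_, Cp, C, N)
            if all(x is not None for x in (Np_, Cp, C, N)) else np.nan,
        ]
        for k, ang in enumerate(angles):
            if np.isfinite(ang):
                scal[i, 2 * k] = np.sin(ang)
                scal[i, 2 * k + 1] = np.cos(ang)
        dists = [
            np.linalg.norm(P - C) if P is not None and C is not None else 0.0,
            np.linalg.norm(C - N) if C is not None and N is not None else 0.0,
            np.linalg.norm(Cn - C) if Cn is not None and C is not None else 0.0,
        ]
        scal[i, 12:15] = dists

        if C is not None:
            if P is not None:
                vect[i, 0] = _unit(P - C)
            if Pn is not None:
                vect[i, 1] = _unit(Pn - C)
            if N is not None:
                vect[i, 2] = _unit(N - C)
            if Np_ is not None:
                vect[i, 3] = _unit(Np_ - C)
    return NodeFeatureSet(scal, vect)


def rbf_encode(d: float | np.ndarray, count: int = DEFAULT_RBF_COUNT,
               d_max: float = DEFAULT_RBF_MAX) -> np.ndarray:
    """Gaussian radial basis encoding of a distance.

    Centers are evenly spaced on [0, d_max]; the width equals the center
    spacing, so a distance sitting on a center scores exactly 1 there.
    """
    d = np.asarray(d, dtype=float)
    centers = np.linspace(0.0, d_max, count)
    sigma = centers[1] - centers[0]
    return np.exp(-(((d[..., None] - centers) / sigma) ** 2))


def edge_features(
    structure: RNAStructure,
    edges: TypedEdgeList,
    rbf_count: int = DEFAULT_RBF_COUNT,
    rbf_max: float = DEFAULT_RBF_MAX,
) -> EdgeFeatureSet:
    """Unit displacement x_j - x_i plus RBF-encoded C4' distance."""
    E = len(edges)
    if E == 0:
        return EdgeFeatureSet(np.zeros((0, rbf_count)), np.zeros((0, 1, 3)))
    xyz = structure.c4_coords
    i, j = edges.edges[:, 0], edges.edges[:, 1]
    disp = xyz[j] - xyz[i]
    dist = np.linalg.norm(disp, axis=1)
    if np.any(dist == 0) or np.any(~np.isfinite(dist)):
        bad = int(np.flatnonzero((dist == 0) | ~np.isfinite(dist))[0])
        raise ValueError(
            f"degenerate displacement on edge ({i[bad]},{j[bad]})"
        )
    vectors = (disp / dist[:, None])[:, None, :]
    scalars = rbf_encode(dist, rbf_count, rbf_max)
    return EdgeFeatureSet(scalars, vectors)
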