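"""Deterministic synthetic RNA 3D fixtures.

These generators produce idealized-but-plausible backbone geometry so
the whole pipeline (parsing, graph construction, featurization, model,
metrics) runs without any structure downloads:

* ``make_helix`` — an idealized A-form double helix with Watson-Crick
  consistent random sequence;
* ``make_hairpin`` — a single chain: stem plus a smooth loop arc;
* ``make_two_state`` — one sequence realized under two mutually
  exclusive pairings (a toy riboswitch, K=2);
* ``make_long_coil`` — a compact unpaired random walk long enough
  (>= 1000 nt) to produce spatial edges.

Everything is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import BasePairSet, ConformerGroup, RNAStructure

__all__ = ["HelixParams", "make_helix", "make_hairpin", "make_two_state", "make_long_coil"]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


@dataclass
class HelixParams:
    """Idealized A-form helical parameters (Angstrom / degrees)."""

    rise: float = 2.81
    twist: float = 32.7
    radius: float = 9.4
    pair_phase: float = 150.0  # angular offset of the partner strand
    seed: int = 0

    def __post_init__(self):
        if self.rise <= 0 or not (0 < self.twist < 360):
            raise ValueError("rise must be > 0 and twist in (0, 360)")


def _residue_atoms(theta: float, z: float, params: HelixParams,
                   sense: float = 1.0) -> np.ndarray:
    """P/C4'/N positions for one residue on the helical trace."""
    r = params.radius
    c4 = np.array([r * np.cos(theta), r * np.sin(theta), z])
    tp = theta - sense * np.deg2rad(10.0)
    p = np.array([(r + 1.5) * np.cos(tp), (r + 1.5) * np.sin(tp),
                  z - sense * 1.0])
    n = np.array([(r - 4.5) * np.cos(theta), (r - 4.5) * np.sin(theta), z])
    return np.stack([p, c4, n])


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU")) for _ in range(n))


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def make_helix(n_bp: int, params: HelixParams | None = None
               ) -> tuple[RNAStructure, BasePairSet]:
    """Double helix of n_bp pairs: chain position i pairs with 2*n_bp-1-i."""
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    params = params or HelixParams()
    rng = np.random.default_rng(params.seed)
    twist = np.deg2rad(params.twist)
    phase = np.deg2rad(params.pair_phase)
    coords = np.zeros((2 * n_bp, 3, 3))
    for i in range(n_bp):
        coords[i] = _residue_atoms(i * twist, i * params.rise, params, 1.0)
    for m in range(n_bp, 2 * n_bp):
        i = 2 * n_bp - 1 - m  # Watson-Crick partner on strand 1
        coords[m] = _residue_atoms(i * twist + phase, i * params.rise,
                                   params, -1.0)
    strand1 = _random_sequence(rng, n_bp)
    seq = strand1 + _revcomp(strand1)
    pairs = BasePairSet(pairs={(i, 2 * n_bp - 1 - i) for i in range(n_bp)})
    st = RNAStructure(chain_id="A", sequence=seq, coords=coords)
    return st, pairs


def _loop_arc(theta0: float, phase: float, z0: float, loop_n: int,
              params: HelixParams) -> np.ndarray:
    """C4' trace of a smooth arc closing the top of a stem."""
    r = params.radius
    out = np.zeros((loop_n, 3, 3))
    bulge = max(params.rise * loop_n / np.pi, 2.5)
    for t in range(1, loop_n + 1):
        frac = t / (loop_n + 1)
        theta = theta0 + phase * frac
        z = z0 + bulge * np.sin(np.pi * frac)
        out[t - 1] = _residue_atoms(theta, z, params, 1.0)
    return out


def make_hairpin(stem_bp: int, loop_n: int, seed: int = 0,
                 params: HelixParams | None = None, jitter: float = 0.3
                 ) -> tuple[RNAStructure, BasePairSet]:
    """Single chain of length 2*stem_bp + loop_n with pairs in the stem only.

    ``jitter`` adds seeded Gaussian coordinate noise (Angstrom) to every
    atom, emulating the coordinate heterogeneity of experimental
    structures; an ideal noise-free stem is degenerate in a way real
    data never is (every mid-stem nucleotide becomes geometrically
    identical).  Set jitter=0 for exact helical geometry."""
    if loop_n < 3:
        raise ValueError("loop_n must be >= 3 (minimal hairpin loop)")
    params = params or HelixParams(seed=seed)
    params.seed = seed
    rng = np.random.default_rng(seed)
    helix, _ = make_helix(stem_bp, params)
    L = 2 * stem_bp + loop_n
    coords = np.zeros((L, 3, 3))
    coords[:stem_bp] = helix.coords[:stem_bp]
    coords[stem_bp + loop_n:] = helix.coords[stem_bp:]
    twist = np.deg2rad(params.twist)
    theta_top = (stem_bp - 1) * twist
    z_top = (stem_bp - 1) * params.rise
    coords[stem_bp:stem_bp + loop_n] = _loop_arc(
        theta_top, np.deg2rad(params.pair_phase), z_top, loop_n, params
    )
    if jitter > 0:
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    stem = _random_sequence(rng, stem_bp)
    seq = stem + _random_sequence(rng, loop_n) + _revcomp(stem)
    pairs = BasePairSet(pairs={(i, L - 1 - i) for i in range(stem_bp)})
    return RNAStructure(chain_id="A", sequence=seq, coords=coords), pairs


def _coil_extension(start: np.ndarray, direction: np.ndarray, n: int,
                    rng: np.random.Generator, step: float = 6.0) -> np.ndarray:
    """C4'-trace random-ish coil of n residues leaving `start`."""
    out = np.zeros((n, 3, 3))
    pos = start.copy()
    d = direction / np.linalg.norm(direction)
    for k in range(n):
        jitter = rng.normal(scale=0.15, size=3)
        d = d + 0.3 * jitter
        d /= np.linalg.norm(d)
        pos = pos + step * d
        u1 = _unit_or(rng.normal(size=3))
        u2 = _unit_or(rng.normal(size=3))
        out[k, 1] = pos
        out[k, 0] = pos + 1.6 * u1
        out[k, 2] = pos + 4.0 * u2
    return out


def _unit_or(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])


def make_two_state(stem_bp: int, seed: int = 0) -> ConformerGroup:
    """Toy riboswitch: S1-loop-S2-loop-S3 with S3 == S1, so segment S2
    can pair either upstream (with S1) or downstream (with S3).  Returns
    a K=2 conformer group sharing one sequence with different pair sets
    and different coordinates."""
    loop_n = 4
    rng = np.random.default_rng(seed)
    params = HelixParams(seed=seed)
    s1 = _random_sequence(rng, stem_bp)
    s2 = _revcomp(s1)
    l1 = _random_sequence(rng, loop_n)
    l2 = _random_sequence(rng, loop_n)
    seq = s1 + l1 + s2 + l2 + s1
    n, L = stem_bp, 3 * stem_bp + 2 * loop_n

    hp, _ = make_hairpin(stem_bp, loop_n, seed=seed, params=params)
    head_len = 2 * stem_bp + loop_n

    # state 1: S1:S2 hairpin, tail (l2 + s3) coils away from the stem base
    coords1 = np.zeros((L, 3, 3))
    coords1[:head_len] = hp.coords
    tail_rng = np.random.default_rng(seed + 101)
    coords1[head_len:] = _coil_extension(
        hp.coords[head_len - 1, 1], np.array([0.5, -0.5, -1.0]),
        L - head_len, tail_rng,
    )
    pairs1 = BasePairSet(pairs={(i, head_len - 1 - i) for i in range(n)})

    # state 2: S2:S3 hairpin, head (s1 + l1) coils away; the hairpin
    # geometry is reused shifted to chain positions n+loop_n ... L-1
    coords2 = np.zeros((L, 3, 3))
    shift = n + loop_n
    coords2[shift:] = hp.coords
    head_rng = np.random.default_rng(seed + 202)
    head = _coil_extension(
        hp.coords[0, 1], np.array([-0.5, 0.5, -1.0]), shift, head_rng
    )
    coords2[:shift] = head[::-1]
    pairs2 = BasePairSet(
        pairs={(shift + i, L - 1 - i) for i in range(n)}
    )

    st1 = RNAStructure(chain_id="A", sequence=seq, coords=coords1)
    st2 = RNAStructure(chain_id="A", sequence=seq, coords=coords2)
    return ConformerGroup(sequence=seq,
                          structures=[(st1, pairs1), (st2, pairs2)])


def make_long_coil(L: int, compactness: float = 1.0, seed: int = 0
                   ) -> RNAStructure:
    """Compact confined random walk, entirely unpaired.

    The confining radius scales as L^(1/3) so the local density (hence
    the DBSCAN neighbourhood count at eps = 20 A) is roughly
    length-independent; compactness > 1 shrinks the ball."""
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    R = 20.0 * (L / (30.0 * compactness)) ** (1.0 / 3.0)
    coords = np.zeros((L, 3, 3))
    pos = np.zeros(3)
    d = _unit_or(rng.normal(size=3))
    step = 6.0
    for i in range(L):
        d = _unit_or(d + 0.8 * rng.normal(size=3))
        nxt = pos + step * d
        if np.linalg.norm(nxt) > R:  # steer back inside the ball
            d = _unit_or(-pos + 2.0 * rng.normal(size=3))
            nxt = pos + step * d
        pos = nxt
        coords[i, 1] = pos
        coords[i, 0] = pos + 1.6 * _unit_or(rng.normal(size=3))
        coords[i, 2] = pos + 4.0 * _unit_or(rng.normal(size=3))
    seq = _random_sequence(rng, L)
    return RNAStructure(chain_id="A", sequence=seq, coords=coords)
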