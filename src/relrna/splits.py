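"""Cluster-aware train/validation/test splitting of conformer groups.

Two strategies mirror common practice for structure-sequence datasets:
``seqid`` clusters sequences by identity (a greedy longest-first
CD-HIT-style scheme, 90% default threshold) and ``structsim`` consumes
structural cluster labels from an external tool (a TM-score clusterer),
with a crude internal RMSD-threshold fallback.  Whole clusters go to one
side of the split; clusters whose member groups have low intra-sequence
RMSD (structurally redundant conformers) are favoured for training, and
validation/test are filled from the high-RMSD end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.spatial.transform import Rotation

from .structures import ConformerGroup, RNAStructure

__all__ = [
    "SplitAssignment",
    "intra_sequence_rmsd",
    "superposed_rmsd",
    "cluster_by_identity",
    "cluster_by_structure_approx",
    "assign_splits",
    "read_clstr",
    "read_cluster_tsv",
]


def superposed_rmsd(a: RNAStructure, b: RNAStructure) -> float:
    """Optimal-superposition (Kabsch) RMSD over shared C4' atoms."""
    if len(a) != len(b):
        raise ValueError("structures differ in length")
    both = a.atom_mask[:, 1] & b.atom_mask[:, 1]
    if both.sum() < 3:
        raise ValueError("fewer than 3 shared C4' atoms")
    pa = a.c4_coords[both]
    pb = b.c4_coords[both]
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(len(pa)))


def intra_sequence_rmsd(group: ConformerGroup) -> float:
    """Mean pairwise superposed RMSD across the group's K structures."""
    K = group.K
    if K == 1:
        return 0.0
    vals = []
    for i in range(K):
        for j in range(i + 1, K):
            vals.append(
                superposed_rmsd(group.structures[i][0], group.structures[j][0])
            )
    return float(np.mean(vals))


def _identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    res = edlib.align(a, b, mode="NW", task="path")
    alen = sum(int(n) for n in _cigar_lengths(res["cigar"]))
    if alen == 0:
        return 1.0
    return (alen - res["editDistance"]) / alen


def _cigar_lengths(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num
            num = ""


def cluster_by_identity(sequences: list[str], threshold: float = 0.9
                        ) -> np.ndarray:
    """Greedy longest-first representative clustering (the CD-HIT scheme).

    Sequences sorted by decreasing length; each joins the first cluster
    whose representative shares >= threshold identity, else founds one.
    Returns integer labels aligned with the input order."""
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(range(len(sequences)),
                   key=lambda k: (-len(sequences[k]), k))
    labels = np.full(len(sequences), -1, dtype=int)
    reps: list[str] = []
    for k in order:
        seq = sequences[k]
        for c, rep in enumerate(reps):
            if _identity(seq, rep) >= threshold:
                labels[k] = c
                break
        else:
            labels[k] = len(reps)
            reps.append(seq)
    return labels


def cluster_by_structure_approx(structures: list[RNAStructure],
                                rmsd_threshold: float = 5.0) -> np.ndarray:
    """Approximate structural clustering by C4' RMSD to greedy
    representatives.  This is a stand-in for TM-score-based clustering
    (qTMclust): structures of different length never share a cluster and
    the metric is global RMSD, not TM-score.  Prefer loading labels
    produced by a real structural clusterer via read_cluster_tsv."""
    labels = np.full(len(structures), -1, dtype=int)
    reps: list[int] = []
    for k, st in enumerate(structures):
        for c, r in enumerate(reps):
            ref = structures[r]
            if len(ref) == len(st) and superposed_rmsd(st, ref) <= rmsd_threshold:
                labels[k] = c
                break
        else:
            labels[k] = len(reps)
            reps.append(k)
    return labels


@dataclass
class SplitAssignment:
    assignment: dict[int, str]  # group index -> train/val/test
    cluster_labels: np.ndarray
    group_rmsd: np.ndarray
    strategy: str = "seqid"
    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sizes:
            self.sizes = {
                s: sum(1 for v in self.assignment.values() if v == s)
                for s in ("train", "val", "test")
            }

    def indices(self, split: str) -> list[int]:
        return sorted(k for k, v in self.assignment.items() if v == split)


def assign_splits(
    groups: list[ConformerGroup],
    cluster_labels: np.ndarray,
    strategy: str = "seqid",
    val_n: int = 100,
    test_n: int = 100,
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole clusters to train/val/test.

    Clusters are ranked by mean intra-sequence RMSD of their member
    groups; low-RMSD clusters go to training, and val/test are filled to
    exactly val_n / test_n groups from the high-RMSD end (RMSD ties are
    broken by a seeded shuffle)."""
    n = len(groups)
    cluster_labels = np.asarray(cluster_labels)
    if len(cluster_labels) != n:
        raise ValueError("cluster label count mismatch")
    if val_n + test_n >= n:
        raise ValueError(
            f"cannot fill val+test={val_n + test_n} from {n} groups"
        )
    grp_rmsd = np.array([intra_sequence_rmsd(g) for g in groups])
    clusters: dict[int, list[int]] = {}
    for k, lab in enumerate(cluster_labels):
        clusters.setdefault(int(lab), []).append(k)
    rng = np.random.default_rng(seed)
    tiebreak = {lab: rng.random() for lab in clusters}
    ranked = sorted(
        clusters,
        key=lambda lab: (float(np.mean(grp_rmsd[clusters[lab]])), tiebreak[lab]),
    )
    assignment: dict[int, str] = {}
    need = {"test": test_n, "val": val_n}
    for lab in reversed(ranked):  # high-RMSD end first
        members = clusters[lab]
        placed = False
        for side in ("test", "val"):
            if 0 < need[side] and len(members) <= need[side]:
                for k in members:
                    assignment[k] = side
                need[side] -= len(members)
                placed = True
                break
        if not placed:
            for k in members:
                assignment[k] = "train"
    if need["test"] or need["val"]:
        raise ValueError(
            "cannot fill val/test without splitting a cluster "
            f"(missing val={need['val']}, test={need['test']})"
        )
    return SplitAssignment(
        assignment=assignment,
        cluster_labels=cluster_labels,
        group_rmsd=grp_rmsd,
        strategy=strategy,
    )


def read_clstr(text: str, names: list[str]) -> np.ndarray:
    """Parse CD-HIT .clstr output into labels aligned with `names`."""
    name_to_cluster: dict[str, int] = {}
    current = -1
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">Cluster"):
            current = int(line.split()[1])
            continue
        # e.g. "0	77nt, >seq_name... *"
        start = line.index(">") + 1
        end = line.index("...", start)
        name_to_cluster[line[start:end]] = current
    labels = np.full(len(names), -1, dtype=int)
    for k, name in enumerate(names):
        if name not in name_to_cluster:
            raise KeyError(f"sequence {name!r} absent from .clstr file")
        labels[k] = name_to_cluster[name]
    return labels


def read_cluster_tsv(text: str, names: list[str]) -> np.ndarray:
    """Read `group_id<TAB>cluster_id` labels (tool-agnostic)."""
    mapping: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"line {lineno}: expected 2 columns")
        mapping[fields[0]] = int(fields[1])
    labels = np.full(len(names), -1, dtype=int)
    for k, name in enumerate(names):
        if name not in mapping:
            raise KeyError(f"group {name!r} absent from cluster file")
        labels[k] = mapping[name]
    return labels
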