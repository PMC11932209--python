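"""The relational GVP-GNN encoder, the NAR/AR decoders, and training.

The encoder embeds node/edge features through a linear GVP, then runs
``num_layers`` relational message-passing layers per structure.  For a
conformer group with K structures the per-structure final embeddings are
averaged position-wise (multi-state pooling).  Two decoders are
available:

* NAR (one-shot): two node-wise GVPs on the pooled embedding followed
  by a linear 4-way head and softmax — positions are independent.
* AR (autoregressive, 5'->3'): each structure's embedding is decoded
  causally, conditioning position i on the letter at i-1 (ground truth
  under teacher forcing, sampled letters at design time); the final
  probability at i is the average of the per-structure probabilities.

Training minimizes masked cross-entropy of the native letters with Adam.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .features import edge_features, node_features
from .graphs import SpatialParams, TypedGraph, build_graph
from .nn.autodiff import Adam, Tensor, concat, gather_rows
from .nn.gvp import GVP, Module, RelationalLayer
from .structures import BasePairSet, ConformerGroup, RNAStructure

__all__ = [
    "ModelConfig",
    "GraphTensors",
    "RelationalDesignNet",
    "graph_tensors",
    "group_tensors",
    "train",
    "evaluate_group",
    "save_checkpoint",
    "load_checkpoint",
    "seq_to_indices",
    "indices_to_seq",
]

LETTERS = "ACGU"
START_TOKEN = 4  # AR conditioning token for position 0 and unknown letters

EDGE_TYPE_SETS = {
    "2d": ("primary", "secondary"),
    "3d": ("primary", "secondary", "spatial"),
}


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the GVP-GNN conventions."""

    num_layers: int = 2
    node_scalar: int = 128
    node_vector: int = 16
    edge_scalar: int = 32
    edge_vector: int = 1
    edge_types: str = "3d"  # "2d" = primary+secondary, "3d" = all three
    decoder: str = "nar"  # "nar" or "ar"
    dropout: float = 0.1
    lr: float = 1e-3
    seed: int = 0
    ar_embed: int = 16
    rbf_count: int = 16
    rbf_max: float = 40.0
    temperature: float = 1.0

    def __post_init__(self):
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.edge_types not in EDGE_TYPE_SETS:
            raise ValueError("edge_types must be '2d' or '3d'")
        if self.decoder not in ("nar", "ar"):
            raise ValueError("decoder must be 'nar' or 'ar'")

    @property
    def used_edge_types(self) -> tuple[str, ...]:
        return EDGE_TYPE_SETS[self.edge_types]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: v for k, v in d.items()})


def seq_to_indices(seq: str) -> np.ndarray:
    """A/C/G/U -> 0..3; N -> -1 (masked)."""
    lut = {c: k for k, c in enumerate(LETTERS)}
    return np.array([lut.get(c, -1) for c in seq], dtype=int)


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(LETTERS[k] for k in idx)


@dataclass
class GraphTensors:
    """Featurized graph ready for the network."""

    L: int
    node_s: np.ndarray  # (L, 15)
    node_v: np.ndarray  # (L, 4, 3)
    typed: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # type -> (edges, edge_scalars, edge_vectors)


def graph_tensors(
    structure: RNAStructure,
    bp: BasePairSet,
    config: ModelConfig,
    spatial: SpatialParams | None = None,
    graph: TypedGraph | None = None,
) -> GraphTensors:
    if graph is None:
        graph = build_graph(structure, bp, spatial)
    nf = node_features(structure)
    typed = {}
    for t in config.used_edge_types:
        el = graph.edge_lists[t]
        ef = edge_features(structure, el, config.rbf_count, config.rbf_max)
        typed[t] = (el.edges, ef.scalars, ef.vectors)
    return GraphTensors(L=len(structure), node_s=nf.scalars,
                        node_v=nf.vectors, typed=typed)


def group_tensors(group: ConformerGroup, config: ModelConfig,
                  spatial: SpatialParams | None = None) -> list[GraphTensors]:
    return [graph_tensors(st, bp, config, spatial) for st, bp in group.structures]


def _softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))  # detached
    e = (logits - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def _log_softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    return z - z.exp().sum(axis=-1, keepdims=True).log()


class RelationalDesignNet(Module):
    """Encoder + decoder producing per-position nucleotide probabilities."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        nd = (config.node_scalar, config.node_vector)
        ed = (config.edge_scalar, config.edge_vector)
        self.node_embed = self.add_child(
            "node_embed", GVP((15, 4), nd, rng, activation=False)
        )
        self.edge_embed = self.add_child(
            "edge_embed", GVP((config.rbf_count, 1), ed, rng, activation=False)
        )
        self.layers = [
            self.add_child(
                f"layer{l}",
                RelationalLayer(nd, ed, config.used_edge_types, rng,
                                drop_rate=config.dropout),
            )
            for l in range(config.num_layers)
        ]
        ns = config.node_scalar
        if config.decoder == "nar":
            self.dec1 = self.add_child("dec1", GVP(nd, nd, rng))
            self.dec2 = self.add_child("dec2", GVP(nd, nd, rng, activation=False))
            self.head_W = self.add_param("head_W", _small(rng, ns, 4))
            self.head_b = self.add_param("head_b", np.zeros(4))
        else:
            self.letter_embed = self.add_param(
                "letter_embed", 0.1 * rng.standard_normal((5, config.ar_embed))
            )
            self.ar_W1 = self.add_param(
                "ar_W1", _small(rng, ns + config.ar_embed, ns)
            )
            self.ar_b1 = self.add_param("ar_b1", np.zeros(ns))
            self.ar_W2 = self.add_param("ar_W2", _small(rng, ns, 4))
            self.ar_b2 = self.add_param("ar_b2", np.zeros(4))

    # -- encoder --------------------------------------------------------
    def _embed_edges(self, gt: GraphTensors):
        typed = {}
        for t, (edges, e_s, e_v) in gt.typed.items():
            es, ev = self.edge_embed(Tensor(e_s), Tensor(e_v))
            typed[t] = (edges, es, ev)
        return typed

    def encode_each(self, graphs: list[GraphTensors],
                    rng: np.random.Generator | None = None
                    ) -> list[tuple[Tensor, Tensor]]:
        """Run the encoder per structure with shared parameters."""
        if not graphs:
            raise ValueError("conformer group is empty (K=0)")
        out = []
        for gt in graphs:
            s, V = self.node_embed(Tensor(gt.node_s), Tensor(gt.node_v))
            typed = self._embed_edges(gt)
            for layer in self.layers:
                s, V = layer(s, V, typed, rng=rng)
            out.append((s, V))
        return out

    def encode(self, graphs: list[GraphTensors],
               rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Multi-state pooling: position-wise mean over the K structures."""
        per = self.encode_each(graphs, rng=rng)
        K = len(per)
        s = per[0][0]
        V = per[0][1]
        for sk, vk in per[1:]:
            s = s + sk
            V = V + vk
        return s * (1.0 / K), V * (1.0 / K)

    # -- decoders -------------------------------------------------------
    def decode_nar(self, pooled: tuple[Tensor, Tensor]) -> Tensor:
        s, V = pooled
        s, V = self.dec1(s, V)
        s, _ = self.dec2(s, V)
        logits = s @ self.head_W + self.head_b
        return _softmax(logits)

    def _ar_logits(self, s_k: Tensor, prev_idx: np.ndarray) -> Tensor:
        emb = gather_rows(self.letter_embed, prev_idx)
        h = concat([s_k, emb], axis=-1)
        h = (h @ self.ar_W1 + self.ar_b1).relu()
        return h @ self.ar_W2 + self.ar_b2

    def decode_ar_teacher(self, per_structure: list[tuple[Tensor, Tensor]],
                          teacher_idx: np.ndarray) -> Tensor:
        """Teacher-forced AR probabilities, pooled over structures."""
        L = len(teacher_idx)
        if per_structure[0][0].shape[0] != L:
            raise ValueError("teacher sequence length mismatch")
        prev = np.empty(L, dtype=int)
        prev[0] = START_TOKEN
        prev[1:] = np.where(teacher_idx[:-1] >= 0, teacher_idx[:-1], START_TOKEN)
        probs = None
        for s_k, _ in per_structure:
            p_k = _softmax(self._ar_logits(s_k, prev))
            probs = p_k if probs is None else probs + p_k
        return probs * (1.0 / len(per_structure))

    def decode_ar_sample(self, per_structure: list[tuple[Tensor, Tensor]],
                         rng: np.random.Generator,
                         temperature: float = 1.0) -> np.ndarray:
        """Design-time AR decoding: each structure follows its own
        sampled trajectory 5'->3'; probabilities are pooled per position
        after decoding.  Returns the (L, 4) pooled probability matrix."""
        K = len(per_structure)
        L = per_structure[0][0].shape[0]
        S = [sk.data for sk, _ in per_structure]
        Wl = self.letter_embed.data
        W1, b1 = self.ar_W1.data, self.ar_b1.data
        W2, b2 = self.ar_W2.data, self.ar_b2.data
        prev = np.full(K, START_TOKEN, dtype=int)
        pooled = np.zeros((L, 4))
        for i in range(L):
            rows = np.stack([S[k][i] for k in range(K)])
            h = np.concatenate([rows, Wl[prev]], axis=-1)
            h = np.maximum(h @ W1 + b1, 0.0)
            logits = (h @ W2 + b2) / max(temperature, 1e-8)
            logits -= logits.max(axis=-1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=-1, keepdims=True)
            pooled[i] = p.mean(axis=0)
            prev = np.array([rng.choice(4, p=p[k]) for k in range(K)])
        return pooled

    # -- end-to-end -----------------------------------------------------
    def forward_probs(self, graphs: list[GraphTensors],
                      teacher_idx: np.ndarray | None = None,
                      rng: np.random.Generator | None = None) -> Tensor:
        """(L, 4) probability matrix for one conformer group.

        AR mode requires a teacher sequence (use `sample` for design)."""
        if self.config.decoder == "nar":
            return self.decode_nar(self.encode(graphs, rng=rng))
        if teacher_idx is None:
            raise ValueError("AR decoding requires a teacher sequence")
        per = self.encode_each(graphs, rng=rng)
        return self.decode_ar_teacher(per, teacher_idx)

    def loss(self, graphs: list[GraphTensors], target_idx: np.ndarray,
             rng: np.random.Generator | None = None) -> Tensor:
        """Masked cross-entropy (nats/position) of the native letters."""
        if len(target_idx) != graphs[0].L:
            raise ValueError(
                f"teacher sequence length mismatch: {len(target_idx)} letters"
                f" vs {graphs[0].L} nodes"
            )
        mask = target_idx >= 0
        if not mask.any():
            raise ValueError("no unmasked positions to train on")
        if self.config.decoder == "nar":
            pooled = self.encode(graphs, rng=rng)
            s, V = self.dec1(*pooled)
            s, _ = self.dec2(s, V)
            logits = s @ self.head_W + self.head_b
        else:
            per = self.encode_each(graphs, rng=rng)
            L = len(target_idx)
            prev = np.empty(L, dtype=int)
            prev[0] = START_TOKEN
            prev[1:] = np.where(target_idx[:-1] >= 0, target_idx[:-1], START_TOKEN)
            # average per-structure probabilities, then take the log
            probs = None
            for s_k, _ in per:
                p_k = _softmax(self._ar_logits(s_k, prev))
                probs = p_k if probs is None else probs + p_k
            probs = probs * (1.0 / len(per))
            rows = np.flatnonzero(mask)
            picked = probs[(rows, target_idx[rows])]
            return -(picked.log().mean())
        logp = _log_softmax(logits)
        rows = np.flatnonzero(mask)
        picked = logp[(rows, target_idx[rows])]
        return -(picked.mean())

    def probabilities(self, group: ConformerGroup,
                      spatial: SpatialParams | None = None) -> np.ndarray:
        """Evaluation-mode (L, 4) probabilities for a conformer group."""
        graphs = group_tensors(group, self.config, spatial)
        teacher = seq_to_indices(group.sequence)
        return self.forward_probs(graphs, teacher_idx=teacher).data

    def sample(self, graphs: list[GraphTensors], n_samples: int,
               rng: np.random.Generator,
               temperature: float | None = None) -> tuple[list[str], np.ndarray]:
        """Draw designed sequences; returns (sequences, mean prob matrix)."""
        temp = self.config.temperature if temperature is None else temperature
        seqs = []
        mats = []
        if self.config.decoder == "nar":
            probs = self.decode_nar(self.encode(graphs)).data
            if temp != 1.0:
                logp = np.log(np.clip(probs, 1e-12, None)) / temp
                probs = np.exp(logp - logp.max(axis=-1, keepdims=True))
                probs /= probs.sum(axis=-1, keepdims=True)
            for _ in range(n_samples):
                idx = np.array([rng.choice(4, p=row) for row in probs])
                seqs.append(indices_to_seq(idx))
                mats.append(probs)
        else:
            per = self.encode_each(graphs)
            for _ in range(n_samples):
                pooled = self.decode_ar_sample(per, rng, temperature=temp)
                idx = np.array([rng.choice(4, p=row) for row in pooled])
                seqs.append(indices_to_seq(idx))
                mats.append(pooled)
        return seqs, np.mean(mats, axis=0)


def _small(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


# -- training ------------------------------------------------------------

def evaluate_group(net: RelationalDesignNet, group: ConformerGroup,
                   graphs: list[GraphTensors] | None = None) -> dict:
    from .metrics import accuracy, perplexity

    if graphs is None:
        graphs = group_tensors(group, net.config)
    teacher = seq_to_indices(group.sequence)
    probs = net.forward_probs(graphs, teacher_idx=teacher).data
    return {
        "perplexity": perplexity(probs, group.sequence),
        "accuracy": accuracy(probs, group.sequence),
    }


def train(
    train_groups: list[ConformerGroup],
    config: ModelConfig,
    epochs: int = 100,
    val_groups: list[ConformerGroup] | None = None,
    spatial: SpatialParams | None = None,
    net: RelationalDesignNet | None = None,
    grad_clip: float = 1.0,
) -> tuple[RelationalDesignNet, list[dict]]:
    """Fit the network; returns (net, per-epoch log).

    Graphs are featurized once up front.  Groups are visited in a
    seeded shuffled order each epoch; gradients are clipped to a global
    norm of `grad_clip`; a non-finite loss aborts with a diagnostic."""
    if not train_groups:
        raise ValueError("empty training set")
    net = net or RelationalDesignNet(config)
    params = net.parameters()
    opt = Adam(params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    cached = [group_tensors(g, config, spatial) for g in train_groups]
    targets = [seq_to_indices(g.sequence) for g in train_groups]
    val_cached = (
        [group_tensors(g, config, spatial) for g in val_groups]
        if val_groups else None
    )
    log: list[dict] = []
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(train_groups))
        total, npos = 0.0, 0
        for k in order:
            opt.zero_grad()
            loss = net.loss(cached[k], targets[k], rng=rng)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, group {k}: {loss.data}"
                )
            loss.backward()
            _clip_grad_norm(params, grad_clip)
            opt.step()
            n_unmasked = int((targets[k] >= 0).sum())
            total += float(loss.data) * n_unmasked
            npos += n_unmasked
        row = {"epoch": epoch, "train_loss": total / max(npos, 1)}
        if val_groups:
            vals = [
                evaluate_group(net, g, gt)
                for g, gt in zip(val_groups, val_cached)
            ]
            row["val_perplexity"] = float(
                np.mean([v["perplexity"] for v in vals])
            )
            row["val_accuracy"] = float(np.mean([v["accuracy"] for v in vals]))
        log.append(row)
    return net, log


def _clip_grad_norm(params, max_norm: float) -> None:
    if not max_norm:
        return
    total = np.sqrt(sum(
        float((p.grad ** 2).sum()) for p in params if p.grad is not None
    ))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(path: str, net: RelationalDesignNet) -> None:
    state = net.state_dict()
    meta = json.dumps(net.config.to_dict())
    np.savez(path, __config__=np.array(meta), **state)


def load_checkpoint(path: str) -> RelationalDesignNet:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        net = RelationalDesignNet(config)
        net.load_state_dict(
            {k: data[k] for k in data.files if k != "__config__"}
        )
    return net
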