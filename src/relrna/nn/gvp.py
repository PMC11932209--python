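"""Geometric vector perceptron (GVP) building blocks.

A GVP maintains separate scalar and 3-vector channels per node.  Vector
channels are mixed only by linear maps over the channel axis and scaled
by functions of rotation-invariant quantities (their norms and the
scalar channel), so vector outputs rotate with the input coordinates
while scalar outputs are invariant.

The relational layer runs one GVP message function per edge type,
aggregates each type over its own neighbourhood, pools the per-type
messages with learned type weights, and applies a GVP update with a
residual connection.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, channel_linear, concat, gather_rows, scatter_sum

__all__ = ["Module", "GVP", "GVPMessage", "LayerNorm", "RelationalLayer",
           "PlainGVPLayer", "dropout"]


class Module:
    """Tiny parameter container with recursive collection."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, Module] = {}

    def add_param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)[:5]}")
        for k, t in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = arr.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def dropout(t: Tensor, rate: float, rng: np.random.Generator | None,
            vector: bool = False) -> Tensor:
    """Inverted dropout; drops whole vector channels when vector=True.

    A None rng means evaluation mode (identity)."""
    if rng is None or rate <= 0:
        return t
    shape = t.shape[:-1] + (1,) if vector else t.shape
    mask = (rng.random(shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


class GVP(Module):
    """One geometric vector perceptron with vector gating.

    Maps (n, s_in) scalars + (n, v_in, 3) vectors to (n, s_out) + (n, v_out, 3).
    """

    def __init__(self, in_dims: tuple[int, int], out_dims: tuple[int, int],
                 rng: np.random.Generator, activation: bool = True):
        super().__init__()
        self.s_in, self.v_in = in_dims
        self.s_out, self.v_out = out_dims
        self.activation = activation
        self.h = max(self.v_in, self.v_out) if self.v_in else 0
        if self.v_in:
            self.Wh = self.add_param("Wh", _glorot(rng, self.v_in, self.h))
        s_tot = self.s_in + self.h
        self.Wm = self.add_param("Wm", _glorot(rng, s_tot, self.s_out))
        self.bm = self.add_param("bm", np.zeros(self.s_out))
        if self.v_out and self.v_in:
            self.Wmu = self.add_param("Wmu", _glorot(rng, self.h, self.v_out))
            self.Wg = self.add_param("Wg", _glorot(rng, self.s_out, self.v_out))
            self.bg = self.add_param("bg", np.zeros(self.v_out))

    def __call__(self, s: Tensor, V: Tensor | None) -> tuple[Tensor, Tensor]:
        n = s.shape[0]
        if self.v_in:
            Vh = channel_linear(V, self.Wh)
            s_in = concat([s, Vh.norm(axis=-1)], axis=-1)
        else:
            s_in = s
        sm = s_in @ self.Wm + self.bm
        s_out = sm.relu() if self.activation else sm
        if self.v_out and self.v_in:
            Vmu = channel_linear(Vh, self.Wmu)
            gate = (sm @ self.Wg + self.bg).sigmoid()
            V_out = Vmu * gate.reshape(n, self.v_out, 1)
        else:
            V_out = Tensor(np.zeros((n, self.v_out, 3)))
        return s_out, V_out


class GVPMessage(Module):
    """Edge message function: two stacked GVPs on (node_i, node_j, edge)."""

    def __init__(self, node_dims: tuple[int, int], edge_dims: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        ns, nv = node_dims
        es, ev = edge_dims
        self.node_dims = node_dims
        self.g1 = self.add_child(
            "g1", GVP((2 * ns + es, 2 * nv + ev), node_dims, rng)
        )
        self.g2 = self.add_child("g2", GVP(node_dims, node_dims, rng,
                                           activation=False))

    def __call__(self, s: Tensor, V: Tensor, edge_s: Tensor, edge_v: Tensor,
                 edges: np.ndarray) -> tuple[Tensor, Tensor]:
        """Per-edge messages for directed edges (i, j); i aggregates."""
        dst, src = edges[:, 0], edges[:, 1]
        s_cat = concat([gather_rows(s, dst), gather_rows(s, src), edge_s], axis=-1)
        v_cat = concat([gather_rows(V, dst), gather_rows(V, src), edge_v], axis=1)
        ms, mv = self.g1(s_cat, v_cat)
        return self.g2(ms, mv)


def _aggregate(msg_s: Tensor, msg_v: Tensor, dst: np.ndarray,
               n: int) -> tuple[Tensor, Tensor]:
    return scatter_sum(msg_s, dst, n), scatter_sum(msg_v, dst, n)


class LayerNorm(Module):
    """Scalar channel: standard layer norm with learned gain/bias.
    Vector channel: divided by the RMS of the channel norms (no learned
    parameters, preserving equivariance)."""

    def __init__(self, node_dims):
        super().__init__()
        ns, nv = node_dims
        self.gamma = self.add_param("gamma", np.ones(ns))
        self.beta = self.add_param("beta", np.zeros(ns))

    def __call__(self, s: Tensor, V: Tensor) -> tuple[Tensor, Tensor]:
        mu = s.mean(axis=-1, keepdims=True)
        var = ((s - mu) * (s - mu)).mean(axis=-1, keepdims=True)
        s_out = (s - mu) / (var + 1e-8).sqrt() * self.gamma + self.beta
        nv = V.shape[1]
        if nv:
            rms = ((V * V).sum(axis=-1).mean(axis=-1) + 1e-8).sqrt()
            V = V / rms.reshape(-1, 1, 1)
        return s_out, V


class _FeedForward(Module):
    """Node-wise feed-forward: two stacked GVPs."""

    def __init__(self, node_dims, rng):
        super().__init__()
        self.u1 = self.add_child("u1", GVP(node_dims, node_dims, rng))
        self.u2 = self.add_child("u2", GVP(node_dims, node_dims, rng,
                                           activation=False))

    def __call__(self, s, V):
        return self.u2(*self.u1(s, V))


class RelationalLayer(Module):
    """One relational message-passing layer over typed edge sets.

    Each edge type e has its own GVP message function; per-type
    aggregates are pooled as sum_e w_e * m_e with learned scalar weights
    w_e (initialized to 1).  The node update is residual: the pooled
    message is added and layer-normalized, then a node-wise GVP
    feed-forward is applied with a second residual + normalization.
    Types with no edges contribute an exact zero message.
    """

    def __init__(self, node_dims, edge_dims, edge_types: tuple[str, ...],
                 rng: np.random.Generator, drop_rate: float = 0.1):
        super().__init__()
        self.node_dims = node_dims
        self.edge_types = tuple(edge_types)
        self.drop_rate = drop_rate
        for t in self.edge_types:
            self.add_child(f"msg_{t}", GVPMessage(node_dims, edge_dims, rng))
        self.type_weights = self.add_param(
            "type_weights", np.ones(len(self.edge_types))
        )
        self.ln1 = self.add_child("ln1", LayerNorm(node_dims))
        self.ff = self.add_child("ff", _FeedForward(node_dims, rng))
        self.ln2 = self.add_child("ln2", LayerNorm(node_dims))

    def __call__(self, s: Tensor, V: Tensor,
                 typed_edges: dict[str, tuple[np.ndarray, Tensor, Tensor]],
                 rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        n = s.shape[0]
        ns, nv = self.node_dims
        m_s = Tensor(np.zeros((n, ns)))
        m_v = Tensor(np.zeros((n, nv, 3)))
        for k, t in enumerate(self.edge_types):
            if t not in typed_edges:
                continue
            edges, e_s, e_v = typed_edges[t]
            if len(edges) == 0:
                continue
            msg = self._children[f"msg_{t}"]
            ms, mv = msg(s, V, e_s, e_v, edges)
            as_, av = _aggregate(ms, mv, edges[:, 0], n)
            w = self.type_weights[k]
            m_s = m_s + as_ * w
            m_v = m_v + av * w.reshape(1, 1, 1)
        s, V = self.ln1(s + dropout(m_s, self.drop_rate, rng),
                        V + dropout(m_v, self.drop_rate, rng, vector=True))
        fs, fv = self.ff(s, V)
        return self.ln2(s + dropout(fs, self.drop_rate, rng),
                        V + dropout(fv, self.drop_rate, rng, vector=True))


class PlainGVPLayer:
    """Single-component GVP-GNN layer (untyped edges), used as the
    equivalence oracle for the relational layer.

    Shares (borrows) a message module, feed-forward and norms; its
    forward path is written independently of RelationalLayer and has no
    edge-type weighting machinery.
    """

    def __init__(self, message: GVPMessage, ff: _FeedForward,
                 ln1: LayerNorm, ln2: LayerNorm, drop_rate: float = 0.1):
        self.message = message
        self.ff = ff
        self.ln1, self.ln2 = ln1, ln2
        self.drop_rate = drop_rate

    def __call__(self, s: Tensor, V: Tensor, edges: np.ndarray,
                 edge_s: Tensor, edge_v: Tensor,
                 rng: np.random.Generator | None = None):
        n = s.shape[0]
        ns, nv = self.message.node_dims
        if len(edges):
            ms, mv = self.message(s, V, edge_s, edge_v, edges)
            m_s, m_v = _aggregate(ms, mv, edges[:, 0], n)
        else:
            m_s = Tensor(np.zeros((n, ns)))
            m_v = Tensor(np.zeros((n, nv, 3)))
        s, V = self.ln1(s + dropout(m_s, self.drop_rate, rng),
                        V + dropout(m_v, self.drop_rate, rng, vector=True))
        fs, fv = self.ff(s, V)
        return self.ln2(s + dropout(fs, self.drop_rate, rng),
                        V + dropout(fv, self.drop_rate, rng, vector=True))
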