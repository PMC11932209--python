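"""High-level modelling interface.

`RNAInverseDesign` is constructed from conformer groups (the data) plus a
`ModelConfig`; `fit()` trains the network and returns a `DesignResults`
carrying the fitted parameters, the training log, per-layer edge-type
weights and a `summary()` table, with `design()` / `evaluate()` hanging
off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import DesignOutput, SecondaryStructurePredictor
from .model import (
    ModelConfig,
    RelationalDesignNet,
    evaluate_group,
    group_tensors,
    load_checkpoint,
    save_checkpoint,
    train,
)
from .graphs import SpatialParams
from .structures import BasePairSet, ConformerGroup

__all__ = ["RNAInverseDesign", "DesignResults"]


class RNAInverseDesign:
    """Relational geometric GNN for fixed-backbone RNA sequence design.

    Parameters
    ----------
    groups : training conformer groups (K structures per sequence).
    config : model hyperparameters; defaults to `ModelConfig()`.
    val_groups : optional held-out groups logged each epoch.
    spatial : spatial-edge construction parameters.
    """

    def __init__(self, groups: list[ConformerGroup],
                 config: ModelConfig | None = None,
                 val_groups: list[ConformerGroup] | None = None,
                 spatial: SpatialParams | None = None):
        if not groups:
            raise ValueError("no training groups")
        self.groups = list(groups)
        self.config = config or ModelConfig()
        self.val_groups = val_groups
        self.spatial = spatial or SpatialParams(seed=self.config.seed)

    def fit(self, epochs: int = 100) -> "DesignResults":
        net, log = train(self.groups, self.config, epochs=epochs,
                         val_groups=self.val_groups, spatial=self.spatial)
        return DesignResults(self, net, log)


class DesignResults:
    """Fitted model: estimates, diagnostics, design and evaluation."""

    def __init__(self, model: RNAInverseDesign | None,
                 net: RelationalDesignNet, log: list[dict]):
        self.model = model
        self.net = net
        self.config = net.config
        self.log = pd.DataFrame(log) if log else pd.DataFrame()

    # -- estimates ------------------------------------------------------
    @property
    def params_(self) -> dict[str, np.ndarray]:
        return self.net.state_dict()

    @property
    def edge_type_weights_(self) -> pd.DataFrame:
        """Learned per-layer relation weights (one row per layer)."""
        rows = []
        for l, layer in enumerate(self.net.layers):
            rows.append(dict(zip(layer.edge_types,
                                 layer.type_weights.data.tolist()),
                             layer=l))
        return pd.DataFrame(rows).set_index("layer")

    # -- use ------------------------------------------------------------
    def design(self, group: ConformerGroup, n_samples: int = 16,
               seed: int = 0, temperature: float | None = None,
               reference_pairs: BasePairSet | None = None,
               predictor: SecondaryStructurePredictor | None = None
               ) -> DesignOutput:
        """Sample sequences for a template group and score them."""
        graphs = group_tensors(group, self.config,
                               self.model.spatial if self.model else None)
        rng = np.random.default_rng(seed)
        seqs, probs = self.net.sample(graphs, n_samples, rng,
                                      temperature=temperature)
        out = DesignOutput(probabilities=probs, samples=seqs,
                           reference=group.sequence)
        out.compute_metrics(reference_pairs=reference_pairs,
                            predictor=predictor)
        # perplexity/accuracy should reflect the model's conditional
        # probabilities of the native sequence, not the sampling average
        ev = evaluate_group(self.net, group, graphs)
        out.metrics.update(ev)
        return out

    def evaluate(self, group: ConformerGroup) -> dict:
        """Perplexity and accuracy of the native sequence under the model."""
        return evaluate_group(self.net, group)

    # -- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        save_checkpoint(path, self.net)

    @classmethod
    def from_checkpoint(cls, path: str) -> "DesignResults":
        return cls(None, load_checkpoint(path), [])

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        c = self.config
        lines = [
            "          RNA Inverse Design — relational GVP-GNN",
            "=" * 62,
            f"Decoder:           {c.decoder.upper():<10} Edge types:      {c.edge_types}",
            f"Encoder layers:    {c.num_layers:<10} Node width:      {c.node_scalar}s/{c.node_vector}v",
            f"Edge width:        {f'{c.edge_scalar}s/{c.edge_vector}v':<10} Dropout:         {c.dropout}",
            f"Seed:              {c.seed:<10} Learning rate:   {c.lr}",
        ]
        if self.model is not None:
            lines.append(f"Training groups:   {len(self.model.groups)}")
        if len(self.log):
            last = self.log.iloc[-1]
            lines.append(f"Epochs:            {int(last['epoch'])}")
            lines.append(f"Final train loss:  {last['train_loss']:.4f} nats/position")
            if "val_accuracy" in last:
                lines.append(
                    f"Validation:        perplexity {last['val_perplexity']:.4f},"
                    f" accuracy {last['val_accuracy']:.4f}"
                )
        lines.append("-" * 62)
        lines.append("Edge-type weights (learned, per encoder layer):")
        for l, row in self.edge_type_weights_.iterrows():
            vals = "  ".join(f"{k}={v: .4f}" for k, v in row.items())
            lines.append(f"  layer {l}: {vals}")
        lines.append("=" * 62)
        return "\n".join(lines)
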