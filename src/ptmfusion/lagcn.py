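"""Layer-attention GCN (LAGCN) link predictor for PTM-disease scoring.

The model propagates node features over the penalized heterogeneous graph
``G_pd`` through ``L`` graph-convolution layers,

    H^(l+1) = sigma(D^{-1/2} G_pd D^{-1/2} H^(l) W^(l)),

combines the layer outputs with learned scalar attention weights
``theta_l`` (initialized to 1/(l+1)), and reconstructs the association
score matrix with a bilinear decoder,

    A' = sigmoid(H_p W' H_d^T),

trained against the weighted cross-entropy in which the sparse positive
set is up-weighted by the negative/positive cardinality ratio. All
parameters are learned full-batch with Adam; gradients are analytic
(NumPy), which keeps the model dependency-free and exactly reproducible
from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import EPS, Adam, glorot, relu, sigmoid
from .datatypes import AssociationMatrix, ScoreMatrix
from .heterograph import HeteroGraph, build_input_graph, initial_embedding, sym_normalize

__all__ = [
    "LagcnConfig",
    "LayerAttentionGCN",
    "LagcnResults",
    "gcn_layer",
    "layer_attention",
    "bilinear_decode",
    "weighted_ce_loss",
]


@dataclass
class LagcnConfig:
    """Hyperparameters of the link predictor.

    ``embed_dim`` and ``n_layers`` default to the standard k=64, L=3;
    ``lr``/``epochs`` default to the grid-selected optimum (0.01, 800).
    The alternative textual preset (0.001, 400) is available through
    :meth:`preset`. ``dropout_node`` masks hidden node embeddings,
    ``dropout_edge`` randomly removes graph edges during training.
    """

    embed_dim: int = 64
    n_layers: int = 3
    lr: float = 0.01
    epochs: int = 800
    dropout_node: float = 0.6
    dropout_edge: float = 0.4
    psi: float = 6.0
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.embed_dim < 1 or self.n_layers < 1:
            raise ValueError("embed_dim and n_layers must be >= 1")
        if not (0 <= self.dropout_node < 1 and 0 <= self.dropout_edge < 1):
            raise ValueError("dropout ratios must lie in [0, 1)")
        if self.lr <= 0 or self.epochs < 1:
            raise ValueError("lr must be positive and epochs >= 1")

    @classmethod
    def preset(cls, name: str, **overrides) -> "LagcnConfig":
        presets = {
            "grid": dict(lr=0.01, epochs=800),
            "text": dict(lr=0.001, epochs=400),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        return cls(**{**presets[name], **overrides})


def initial_attention(n_layers: int) -> np.ndarray:
    """theta_l = 1/(l+1) for l = 1..L."""
    return np.array([1.0 / (l + 1) for l in range(1, n_layers + 1)])


def gcn_layer(
    h: np.ndarray,
    g: np.ndarray,
    w: np.ndarray,
    activation=relu,
) -> np.ndarray:
    """One propagation step sigma(D^{-1/2} G D^{-1/2} H W)."""
    if not (np.isfinite(h).all() and np.isfinite(g).all() and np.isfinite(w).all()):
        raise ValueError("non-finite values in gcn_layer inputs")
    if (g < 0).any():
        raise ValueError("graph matrix must be non-negative")
    return activation(sym_normalize(g) @ h @ w)


def layer_attention(
    embeddings: list[np.ndarray],
    theta: np.ndarray,
    n_p: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Attention-weighted sum of layer embeddings, split into (H_p, H_d)."""
    theta = np.asarray(theta, dtype=float)
    if len(embeddings) != theta.shape[0]:
        raise ValueError(
            f"{len(embeddings)} embeddings but {theta.shape[0]} attention weights"
        )
    shapes = {e.shape for e in embeddings}
    if len(shapes) != 1:
        raise ValueError("all layer embeddings must share one shape")
    h = sum(t * e for t, e in zip(theta, embeddings))
    return h[:n_p], h[n_p:]


def bilinear_decode(h_p: np.ndarray, h_d: np.ndarray, w_prime: np.ndarray) -> np.ndarray:
    """A' = sigmoid(H_p W' H_d^T)."""
    if h_p.shape[1] != w_prime.shape[0] or h_d.shape[1] != w_prime.shape[1]:
        raise ValueError("embedding dimensions do not match decoder matrix")
    return sigmoid(h_p @ w_prime @ h_d.T)


def weighted_ce_loss(
    scores: np.ndarray,
    positives: np.ndarray,
    negatives: np.ndarray,
) -> float:
    """Class-weighted cross-entropy over the full score matrix.

    ``positives``/``negatives`` are boolean masks over the n_p x n_d grid;
    together they must tile it exactly. The positive terms carry weight
    |T-|/|T+| to counter the extreme class imbalance, and the sum is
    scaled by 1/(P*D).
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    negatives = np.asarray(negatives, dtype=bool)
    if positives.shape != scores.shape or negatives.shape != scores.shape:
        raise ValueError("masks must match the score matrix shape")
    if (positives & negatives).any() or not (positives | negatives).all():
        raise ValueError("positive and negative sets must partition all pairs")
    n_pos = int(positives.sum())
    if n_pos == 0:
        raise ValueError("positive set is empty")
    n_neg = int(negatives.sum())
    a = np.clip(scores, EPS, 1.0 - EPS)
    weight = n_neg / n_pos
    total = weight * np.log(a[positives]).sum() + np.log(1.0 - a[negatives]).sum()
    return float(-total / scores.size)


@dataclass
class LagcnResults:
    """Fit artifacts: decoded scores, learned parameters, loss history."""

    scores: ScoreMatrix
    attention: np.ndarray
    layer_weights: list[np.ndarray]
    decoder: np.ndarray
    loss_history: np.ndarray
    config: LagcnConfig
    seed: int

    @property
    def final_loss(self) -> float:
        return float(self.loss_history[-1])

    def summary(self) -> str:
        c = self.config
        lines = [
            "Layer-Attention GCN link predictor",
            "==================================",
            f"nodes: {self.scores.values.shape[0]} proteins x "
            f"{self.scores.values.shape[1]} diseases",
            f"layers L={c.n_layers}, embed k={c.embed_dim}, psi={c.psi}",
            f"lr={c.lr}, epochs={c.epochs}, seed={self.seed}",
            f"loss: {self.loss_history[0]:.4f} -> {self.final_loss:.4f}",
            "attention weights: "
            + ", ".join(f"theta_{l + 1}={t:.4f}" for l, t in enumerate(self.attention)),
        ]
        return "\n".join(lines)


class LayerAttentionGCN:
    """Link-prediction model over a protein-disease heterogeneous graph.

    Parameters
    ----------
    hetero : HeteroGraph
        The assembled network. If its penalized input graph has not been
        built yet it is built here with ``config.psi``.
    assoc : AssociationMatrix
        The (possibly CV-masked) association matrix supplying the positive
        training set; all remaining pairs form the negative set.
    config : LagcnConfig, optional
    """

    def __init__(
        self,
        hetero: HeteroGraph,
        assoc: AssociationMatrix,
        config: LagcnConfig | None = None,
    ):
        self.config = config or LagcnConfig()
        if hetero.n_p != assoc.n_proteins or hetero.n_d != assoc.n_diseases:
            raise ValueError("association matrix inconsistent with graph dimensions")
        if hetero.g_pd is None:
            build_input_graph(hetero, psi=self.config.psi)
        self.hetero = hetero
        self.assoc = assoc
        self.h0 = initial_embedding(hetero)
        self.pos_mask = assoc.values == 1.0
        self.neg_mask = ~self.pos_mask
        if not self.pos_mask.any():
            raise ValueError("association matrix has no positive pairs")

    # -- forward/backward ------------------------------------------------

    def _forward(self, ghat: np.ndarray, params: dict, drop_masks=None):
        L = self.config.n_layers
        cache = {"msg": [], "pre": [], "out": []}
        h = self.h0
        for l in range(L):
            msg = ghat @ h
            pre = msg @ params["W"][l]
            out = relu(pre)
            if drop_masks is not None:
                out = out * drop_masks[l]
            cache["msg"].append(msg)
            cache["pre"].append(pre)
            cache["out"].append(out)
            h = out
        n_p = self.hetero.n_p
        h_final = sum(t * e for t, e in zip(params["theta"], cache["out"]))
        h_p, h_d = h_final[:n_p], h_final[n_p:]
        logits = h_p @ params["Wp"] @ h_d.T
        cache.update(h_final=h_final, h_p=h_p, h_d=h_d, logits=logits,
                     scores=sigmoid(logits))
        return cache

    def _loss_and_grads(self, ghat, params, cache, drop_masks=None):
        """Analytic gradients of the weighted cross-entropy w.r.t. all
        trainable parameters; layer gradients are routed through any
        node-dropout masks applied in the forward pass."""
        scores = cache["scores"]
        pos, neg = self.pos_mask, self.neg_mask
        weight = neg.sum() / pos.sum()
        size = scores.size
        loss = weighted_ce_loss(scores, pos, neg)
        # d loss / d logits (the EPS clamp only affects the reported value)
        g_logit = np.where(pos, -weight * (1.0 - scores), scores) / size
        h_p, h_d = cache["h_p"], cache["h_d"]
        grads = {"W": [None] * self.config.n_layers}
        grads["Wp"] = h_p.T @ g_logit @ h_d
        d_hp = g_logit @ h_d @ params["Wp"].T
        d_hd = g_logit.T @ h_p @ params["Wp"]
        d_hfinal = np.vstack([d_hp, d_hd])
        grads["theta"] = np.array(
            [float(np.sum(d_hfinal * out)) for out in cache["out"]]
        )
        d_out = [t * d_hfinal for t in params["theta"]]
        for l in range(self.config.n_layers - 1, -1, -1):
            d_act = d_out[l]
            if drop_masks is not None:
                d_act = d_act * drop_masks[l]
            d_pre = d_act * (cache["pre"][l] > 0)
            grads["W"][l] = cache["msg"][l].T @ d_pre
            if l > 0:
                d_out[l - 1] = d_out[l - 1] + ghat @ (d_pre @ params["W"][l].T)
        return loss, grads

    # -- training --------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict:
        c = self.config
        n = self.hetero.n_nodes
        dims = [n] + [c.embed_dim] * c.n_layers
        return {
            "W": [glorot(rng, dims[l], dims[l + 1]) for l in range(c.n_layers)],
            "theta": initial_attention(c.n_layers),
            "Wp": glorot(rng, c.embed_dim, c.embed_dim),
        }

    def _dropped_graph(self, rng: np.random.Generator) -> np.ndarray:
        """Symmetric random edge dropout on g_pd with inverted scaling."""
        omega = self.config.dropout_edge
        g = self.hetero.g_pd
        if omega == 0:
            return g
        n = g.shape[0]
        keep = rng.random((n, n)) >= omega
        keep = np.triu(keep)
        keep = keep | keep.T
        return g * keep / (1.0 - omega)

    def fit(self, seed: int = 0) -> LagcnResults:
        """Full-batch Adam training; deterministic given ``seed``."""
        rng = np.random.default_rng(seed)
        c = self.config
        params = self._init_params(rng)
        flat = params["W"] + [params["theta"], params["Wp"]]
        opt = Adam(flat, lr=c.lr)
        ghat_eval = sym_normalize(self.hetero.g_pd)
        phi = c.dropout_node
        losses = np.empty(c.epochs)
        n = self.hetero.n_nodes
        for epoch in range(c.epochs):
            ghat = (
                sym_normalize(self._dropped_graph(rng))
                if c.dropout_edge > 0
                else ghat_eval
            )
            if phi > 0:
                drop_masks = [
                    (rng.random((n, c.embed_dim)) >= phi) / (1.0 - phi)
                    for _ in range(c.n_layers)
                ]
            else:
                drop_masks = None
            cache = self._forward(ghat, params, drop_masks)
            loss, grads = self._loss_and_grads(ghat, params, cache, drop_masks)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={c.lr} is likely too high for this graph"
                )
            losses[epoch] = loss
            opt.step(grads["W"] + [grads["theta"], grads["Wp"]])
        cache = self._forward(ghat_eval, params, None)
        scores = np.clip(cache["scores"], EPS, 1.0 - EPS)
        return LagcnResults(
            scores=ScoreMatrix(
                scores, list(self.assoc.protein_ids), list(self.assoc.disease_ids)
            ),
            attention=params["theta"].copy(),
            layer_weights=[w.copy() for w in params["W"]],
            decoder=params["Wp"].copy(),
            loss_history=losses,
            config=replace(c),
            seed=seed,
        )
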