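"""Feature-weighted GCN (FWGCN) for disease-subtype classification.

Expression features of *shared* proteins (those also present in the
association data) are re-scaled by their PTM potentiality score ``a``
for the cohort's disease,

    p' = 2 * p * a * exp(delta * |p|),

so a score above 0.5 amplifies the protein and a score below 0.5
attenuates it; ``delta`` is a small regularization coefficient selected
on the training data. A cosine-similarity graph over samples is then
thresholded so that the mean number of retained edges per node (counting
self-connections) reaches a target ``gamma``, and a two-layer GCN is
trained transductively: test samples are appended to the graph and
classified by a forward pass of the frozen model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._nn import Adam, glorot, relu, softmax
from .datatypes import ExpressionDataset, SampleGraph, ScoreMatrix
from .heterograph import sym_normalize

__all__ = [
    "DELTA_GRID",
    "FwgcnConfig",
    "FeatureWeightedGCN",
    "FwgcnResults",
    "feature_weight",
    "cosine_adjacency",
    "select_delta",
    "train_fwgcn",
]

# Candidate regularization coefficients for the feature-weighting exponent.
DELTA_GRID = (0.0001, 0.0003, 0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0)
GAMMA_CANDIDATES = (2, 5, 10)


@dataclass
class FwgcnConfig:
    """Classifier hyperparameters.

    ``gamma`` is the target mean degree (self-loops included) of the
    cosine sample graph; ``delta`` the weighting regularizer (selected
    from :data:`DELTA_GRID` by cross-validation when not fixed).
    ``weight_mode`` chooses between the growing exponent ``exp(+d|p|)``
    (literal) and the shrinking variant ``exp(-d|p|)``.
    """

    hidden_dim: int = 64
    n_layers: int = 2
    lr: float = 0.001
    epochs: int = 400
    gamma: int = 5
    delta: float = 0.0001
    weight_mode: str = "literal"
    extension_mode: str = "batch"

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.weight_mode not in ("literal", "shrink"):
            raise ValueError("weight_mode must be 'literal' or 'shrink'")
        if self.extension_mode not in ("batch", "single"):
            raise ValueError("extension_mode must be 'batch' or 'single'")
        if self.n_layers < 2:
            raise ValueError("need at least two GCN layers")


# ---------------------------------------------------------------------------
# feature weighting


def weight_columns(
    values: np.ndarray,
    columns: np.ndarray,
    scores: np.ndarray,
    delta: float,
    mode: str = "literal",
) -> np.ndarray:
    """Apply p' = 2 p a exp(+-delta |p|) to the selected columns."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    out = values.copy()
    sign = 1.0 if mode == "literal" else -1.0
    cols = np.asarray(columns, dtype=int)
    block = out[:, cols]
    out[:, cols] = 2.0 * block * scores[None, :] * np.exp(sign * delta * np.abs(block))
    return out


def feature_weight(
    expr: ExpressionDataset,
    scores: ScoreMatrix,
    delta: float,
    mode: str = "literal",
) -> ExpressionDataset:
    """Score-weight the shared-protein columns of an expression dataset.

    Every shared protein must have a potentiality score for the dataset's
    ``disease_key``; all other columns pass through unchanged. At a score
    of 0.5 and ``delta = 0`` the transform is the identity.
    """
    if expr.disease_key is None:
        raise ValueError("expression dataset has no disease_key mapping")
    per_protein = scores.column(expr.disease_key)  # KeyError if absent
    cols = expr.shared_index
    missing = [expr.protein_ids[c] for c in cols if expr.protein_ids[c] not in per_protein]
    if missing:
        raise KeyError(f"no potentiality score for shared protein(s) {missing[:5]}")
    a = np.array([per_protein[expr.protein_ids[c]] for c in cols])
    values = weight_columns(expr.values, cols, a, delta, mode)
    return replace(expr, values=values)


# ---------------------------------------------------------------------------
# sample graph


def cosine_adjacency(features: np.ndarray, gamma: int) -> SampleGraph:
    """Thresholded cosine-similarity graph with target mean degree gamma.

    The threshold ``epsilon`` is the largest candidate value (a sorted
    unique non-negative off-diagonal cosine, or 0) for which the mean
    number of retained edges per node — self-connections included —
    reaches ``gamma``. Retained off-diagonal entries keep their cosine
    value; unit self-loops are always added. If even ``epsilon = 0``
    cannot reach ``gamma`` the graph keeps all non-negative edges and the
    achieved degree is reported with a warning.
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if gamma < 1 or gamma > n:
        raise ValueError(f"gamma must lie in [1, {n}], got {gamma}")
    norms = np.linalg.norm(x, axis=1)
    zero_rows = np.flatnonzero(norms == 0)
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} all-zero feature row(s) get self-loops only",
            stacklevel=2,
        )
    safe = np.where(norms == 0, 1.0, norms)
    xn = x / safe[:, None]
    cos = np.clip(xn @ xn.T, -1.0, 1.0)
    np.fill_diagonal(cos, 0.0)
    cos[zero_rows, :] = 0.0
    cos[:, zero_rows] = 0.0

    off = cos[~np.eye(n, dtype=bool)]
    candidates = np.unique(off[off >= 0.0])[::-1]  # descending
    if candidates.size == 0 or candidates[-1] > 0.0:
        candidates = np.append(candidates, 0.0)
    epsilon = None
    for eps in candidates:
        retained = int((off >= eps).sum())
        if (n + retained) / n >= gamma:
            epsilon = float(eps)
            break
    if epsilon is None:
        epsilon = 0.0
        achieved = (n + int((off >= 0.0).sum())) / n
        warnings.warn(
            f"target mean degree {gamma} unreachable with non-negative cosines; "
            f"achieved {achieved:.2f}",
            stacklevel=2,
        )
    g = np.where(cos >= epsilon, cos, 0.0)
    np.fill_diagonal(g, 1.0)
    g = 0.5 * (g + g.T)
    achieved = (n + int((off >= epsilon).sum())) / n
    return SampleGraph(g_pp=g, epsilon=epsilon, gamma=gamma, achieved_degree=achieved)


# ---------------------------------------------------------------------------
# the classifier


@dataclass
class FwgcnResults:
    """Trained classifier state plus training diagnostics."""

    model: "FeatureWeightedGCN"
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_history: np.ndarray
    train_graph: SampleGraph
    config: FwgcnConfig
    seed: int

    @property
    def final_loss(self) -> float:
        return float(self.loss_history[-1])

    def predict_proba_train(self) -> np.ndarray:
        ghat = sym_normalize(self.train_graph.g_pp)
        return self._forward(self.model.x_tr, ghat)

    def _forward(self, x: np.ndarray, ghat: np.ndarray) -> np.ndarray:
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = relu(ghat @ h @ w + b)
        logits = ghat @ h @ self.weights[-1] + self.biases[-1]
        return softmax(logits)

    def predict_transductive(self, x_te: np.ndarray, mode: str | None = None) -> np.ndarray:
        """Class probabilities for new samples.

        The test rows are appended to the training features, the cosine
        graph is rebuilt over the union with the training ``gamma``, and
        one forward pass of the frozen model yields their probabilities.
        ``mode='single'`` extends the graph one test sample at a time.
        """
        x_te = np.atleast_2d(np.asarray(x_te, dtype=float))
        if x_te.shape[1] != self.model.x_tr.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: test {x_te.shape[1]} vs "
                f"train {self.model.x_tr.shape[1]}"
            )
        mode = mode or self.config.extension_mode
        n_tr = self.model.x_tr.shape[0]
        if mode == "batch":
            x_all = np.vstack([self.model.x_tr, x_te])
            graph = cosine_adjacency(x_all, self.config.gamma)
            probs = self._forward(x_all, sym_normalize(graph.g_pp))
            return probs[n_tr:]
        rows = []
        for row in x_te:
            x_all = np.vstack([self.model.x_tr, row[None, :]])
            graph = cosine_adjacency(x_all, self.config.gamma)
            probs = self._forward(x_all, sym_normalize(graph.g_pp))
            rows.append(probs[-1])
        return np.vstack(rows)

    def predict(self, x_te: np.ndarray, mode: str | None = None) -> np.ndarray:
        return self.predict_transductive(x_te, mode).argmax(axis=1)

    def summary(self) -> str:
        c = self.config
        g = self.train_graph
        return "\n".join(
            [
                "Feature-weighted GCN subtype classifier",
                "=======================================",
                f"training samples: {self.model.x_tr.shape[0]}, "
                f"features: {self.model.x_tr.shape[1]}, "
                f"classes: {self.model.n_classes}",
                f"layers={c.n_layers}, hidden={c.hidden_dim}, lr={c.lr}, "
                f"epochs={c.epochs}, seed={self.seed}",
                f"sample graph: gamma={g.gamma}, epsilon={g.epsilon:.4f}, "
                f"mean degree={g.achieved_degree:.2f}",
                f"loss: {self.loss_history[0]:.4f} -> {self.final_loss:.4f}",
            ]
        )


class FeatureWeightedGCN:
    """Transductive GCN classifier over a cosine sample graph.

    Build from (already weighted) training features and labels, then call
    :meth:`fit`. Prediction for held-out samples goes through the results
    object, which freezes the trained parameters.
    """

    def __init__(
        self,
        x_tr: np.ndarray,
        y_tr: np.ndarray,
        config: FwgcnConfig | None = None,
        graph: SampleGraph | None = None,
    ):
        self.config = config or FwgcnConfig()
        self.x_tr = np.asarray(x_tr, dtype=float)
        self.y_tr = np.asarray(y_tr, dtype=int)
        if self.x_tr.ndim != 2 or self.x_tr.shape[0] != self.y_tr.shape[0]:
            raise ValueError("x_tr must be 2-D with one label per row")
        classes = np.unique(self.y_tr)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        self.n_classes = int(classes.max()) + 1
        self.graph = graph or cosine_adjacency(self.x_tr, self.config.gamma)

    @classmethod
    def from_dataset(
        cls,
        expr: ExpressionDataset,
        scores: ScoreMatrix | None = None,
        config: FwgcnConfig | None = None,
    ) -> "FeatureWeightedGCN":
        """Build from an :class:`ExpressionDataset`, optionally applying
        potentiality-score feature weighting first."""
        config = config or FwgcnConfig()
        if scores is not None:
            expr = feature_weight(expr, scores, config.delta, config.weight_mode)
        return cls(expr.values, expr.labels, config)

    def fit(self, seed: int = 0) -> FwgcnResults:
        rng = np.random.default_rng(seed)
        c = self.config
        n, d = self.x_tr.shape
        dims = [d] + [c.hidden_dim] * (c.n_layers - 1) + [self.n_classes]
        weights = [glorot(rng, dims[i], dims[i + 1]) for i in range(c.n_layers)]
        biases = [np.zeros(dims[i + 1]) for i in range(c.n_layers)]
        opt = Adam(weights + biases, lr=c.lr)
        ghat = sym_normalize(self.graph.g_pp)
        y_onehot = np.eye(self.n_classes)[self.y_tr]
        msg0 = ghat @ self.x_tr  # graph and features are fixed: precompute
        losses = np.empty(c.epochs)
        for epoch in range(c.epochs):
            # forward; msgs[i] is the propagated input ghat @ h_{i-1} to layer i
            msgs, pres = [], []
            h = self.x_tr
            for i in range(c.n_layers - 1):
                msg = msg0 if i == 0 else ghat @ h
                pre = msg @ weights[i] + biases[i]
                h = relu(pre)
                msgs.append(msg)
                pres.append(pre)
            msg_last = ghat @ h
            logits = msg_last @ weights[-1] + biases[-1]
            probs = softmax(logits)
            loss = float(
                -np.mean(np.log(np.clip(probs[np.arange(n), self.y_tr], 1e-12, None)))
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; lr={c.lr} too high?"
                )
            losses[epoch] = loss
            # backward (mean cross-entropy over labeled rows)
            d_logits = (probs - y_onehot) / n
            g_w = [None] * c.n_layers
            g_b = [None] * c.n_layers
            g_w[-1] = msg_last.T @ d_logits
            g_b[-1] = d_logits.sum(axis=0)
            d_h = ghat @ (d_logits @ weights[-1].T)
            for i in range(c.n_layers - 2, -1, -1):
                d_pre = d_h * (pres[i] > 0)
                g_w[i] = msgs[i].T @ d_pre
                g_b[i] = d_pre.sum(axis=0)
                if i > 0:
                    d_h = ghat @ (d_pre @ weights[i].T)
            opt.step(g_w + g_b)
        return FwgcnResults(
            model=self,
            weights=[w.copy() for w in weights],
            biases=[b.copy() for b in biases],
            loss_history=losses,
            train_graph=self.graph,
            config=replace(c),
            seed=seed,
        )


def train_fwgcn(
    x_tr: np.ndarray,
    y_tr: np.ndarray,
    graph: SampleGraph | None = None,
    config: FwgcnConfig | None = None,
    seed: int = 0,
) -> FwgcnResults:
    """Functional wrapper around :class:`FeatureWeightedGCN`."""
    return FeatureWeightedGCN(x_tr, y_tr, config, graph).fit(seed)


def select_delta(
    expr: ExpressionDataset,
    scores: ScoreMatrix,
    grid: tuple[float, ...] = DELTA_GRID,
    folds: int = 5,
    seed: int = 0,
    config: FwgcnConfig | None = None,
) -> float:
    """Pick the weighting regularizer delta by stratified k-fold CV.

    Each candidate weights the data, runs a stratified ``folds``-fold
    split of ``expr`` and records mean validation accuracy; the candidate
    with the highest mean wins (first in grid order on ties).
    """
    from sklearn.model_selection import StratifiedKFold

    if len(grid) == 0:
        raise ValueError("delta grid is empty")
    if len(grid) == 1:
        return float(grid[0])
    base = config or FwgcnConfig()
    best_delta, best_acc = None, -np.inf
    for delta in grid:
        cfg = replace(base, delta=float(delta))
        weighted = feature_weight(expr, scores, cfg.delta, cfg.weight_mode)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for tr_idx, va_idx in skf.split(weighted.values, weighted.labels):
            res = train_fwgcn(
                weighted.values[tr_idx], weighted.labels[tr_idx], config=cfg, seed=seed
            )
            pred = res.predict(weighted.values[va_idx])
            accs.append(float(np.mean(pred == weighted.labels[va_idx])))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc + 1e-12:
            best_acc, best_delta = mean_acc, float(delta)
    return best_delta
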