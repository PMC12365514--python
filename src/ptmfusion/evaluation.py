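"""Cross-validated evaluation and biomarker screening.

Link prediction is scored with the masked-ranking protocol: known
associations are split into five folds, the test fold's entries are set
to 0 in the association matrix *before* any similarity is computed, the
model is retrained, and the held-out positives are ranked among all
unknown candidate pairs; the AUC of that ranking (equivalently the
Mann--Whitney statistic) summarizes one fold.

Biomarker screening weights one shared protein at a time inside a
stratified k-fold loop and records the proteins whose weighting strictly
improves validation accuracy; aggregation by fold frequency yields the
biomarker ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import AssociationMatrix, ExpressionDataset, ScoreMatrix, SimilarityMatrix
from .fwgcn import FwgcnConfig, feature_weight, train_fwgcn, weight_columns
from .heterograph import build_hetero_network, build_input_graph
from .lagcn import LagcnConfig, LayerAttentionGCN
from .similarity import disease_gip, fuse_protein_similarity, protein_gip

__all__ = [
    "split_pairs",
    "ranking_auc",
    "kfold_link_auc",
    "classification_metrics",
    "weighted_cv_accuracy",
    "BiomarkerReport",
    "screen_biomarkers",
    "final_weighted_model",
    "shared_protein_sensitivity",
    "SHARED_PROTEIN_GUIDANCE",
]

# Below this many shared proteins, weighting gains are dominated by
# stochastic error and the plain GCN may do better.
SHARED_PROTEIN_GUIDANCE = 10


def split_pairs(pairs: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Shuffle (i, j) pairs and cut them into k near-equal folds."""
    pairs = np.asarray(pairs, dtype=int)
    if pairs.shape[0] < k:
        raise ValueError(f"need at least {k} positive pairs, got {pairs.shape[0]}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(pairs.shape[0])
    return [pairs[idx] for idx in np.array_split(order, k)]


def ranking_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC of ranking held-out positives above unknown candidates."""
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    if pos_scores.size == 0 or neg_scores.size == 0:
        raise ValueError("both score groups must be nonempty")
    y = np.concatenate([np.ones(pos_scores.size), np.zeros(neg_scores.size)])
    return float(roc_auc_score(y, np.concatenate([pos_scores, neg_scores])))


def kfold_link_auc(
    assoc: AssociationMatrix,
    ssp: SimilarityMatrix,
    config: LagcnConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Masked k-fold ranking AUC of the LAGCN link predictor.

    ``ssp`` is the sequence-similarity matrix for the association-side
    proteins (association-independent, so it is computed once by the
    caller). Per fold: test positives are masked to 0 in A, both GIP
    kernels are recomputed on the masked matrix, the model is retrained,
    and the test positives are ranked among all pairs unknown to the full
    dataset. Returns (mean AUC, per-fold AUCs).
    """
    config = config or LagcnConfig()
    positives = assoc.positives()
    folds = split_pairs(positives, k, seed)
    for f, fold in enumerate(folds):
        if fold.shape[0] == 0:
            raise ValueError(f"fold {f} has no test positives; too few associations")
    unknown_mask = assoc.values == 0.0
    aucs = np.empty(k)
    for f, test_pairs in enumerate(folds):
        masked = assoc.masked(test_pairs)
        sp = fuse_protein_similarity(ssp, protein_gip(masked))
        sd = disease_gip(masked)
        hetero = build_input_graph(
            build_hetero_network(masked, sp, sd), psi=config.psi
        )
        results = LayerAttentionGCN(hetero, masked, config).fit(seed=seed + f)
        scores = results.scores.values
        pos_scores = scores[test_pairs[:, 0], test_pairs[:, 1]]
        neg_scores = scores[unknown_mask]
        aucs[f] = ranking_auc(pos_scores, neg_scores)
    return float(aucs.mean()), aucs


def classification_metrics(y_true: np.ndarray, y_prob: np.ndarray) -> dict[str, float]:
    """Accuracy / F1 / AUC bundle for subtype classification.

    Binary tasks report ACC, the positive-class F1, and the AUC of the
    class-1 probability; multiclass tasks report ACC, weighted F1 and
    macro F1. A single-class truth vector makes AUC undefined (NaN).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.atleast_2d(np.asarray(y_prob, dtype=float))
    if y_prob.shape[0] != y_true.shape[0]:
        raise ValueError("y_prob must have one row per sample")
    y_pred = y_prob.argmax(axis=1)
    acc = float(np.mean(y_pred == y_true))
    n_classes = y_prob.shape[1]
    out: dict[str, float] = {"acc": acc}
    if n_classes == 2:
        out["f1"] = float(f1_score(y_true, y_pred, pos_label=1, zero_division=0))
        if np.unique(y_true).size < 2:
            out["auc"] = float("nan")
        else:
            out["auc"] = float(roc_auc_score(y_true, y_prob[:, 1]))
    else:
        out["f1_weighted"] = float(
            f1_score(y_true, y_pred, average="weighted", zero_division=0)
        )
        out["f1_macro"] = float(
            f1_score(y_true, y_pred, average="macro", zero_division=0)
        )
    return out


def _stratified_folds(labels: np.ndarray, k: int, seed: int):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(labels), labels))


def weighted_cv_accuracy(
    expr: ExpressionDataset,
    scores: ScoreMatrix | None,
    config: FwgcnConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean stratified k-fold accuracy of the (optionally weighted) GCN.

    ``scores=None`` runs the unweighted baseline. Weighting is applied to
    the whole table up front — the transform is per-entry, so this is
    identical to weighting each split separately.
    """
    config = config or FwgcnConfig()
    if scores is not None:
        expr = feature_weight(expr, scores, config.delta, config.weight_mode)
    accs = []
    for f, (tr, va) in enumerate(_stratified_folds(expr.labels, k, seed)):
        res = train_fwgcn(expr.values[tr], expr.labels[tr], config=config, seed=seed + f)
        pred = res.predict(expr.values[va])
        accs.append(float(np.mean(pred == expr.labels[va])))
    accs = np.asarray(accs)
    return float(accs.mean()), accs


@dataclass
class BiomarkerReport:
    """Per-protein fold frequency of accuracy improvement under weighting."""

    protein_ids: list[str]
    counts: np.ndarray  # occurrences across folds, 0..k
    mean_improvement: np.ndarray  # mean accuracy delta over folds
    k: int
    empty_shared: bool = False

    def ranking(self) -> list[str]:
        """Proteins ordered by frequency, ties by mean improvement then ID."""
        order = sorted(
            range(len(self.protein_ids)),
            key=lambda i: (-self.counts[i], -self.mean_improvement[i], self.protein_ids[i]),
        )
        return [self.protein_ids[i] for i in order]

    def selected(self, min_count: int = 1) -> list[str]:
        return [
            p for p, c in zip(self.protein_ids, self.counts) if c >= min_count
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "protein": self.protein_ids,
                "count": self.counts,
                "mean_improvement": self.mean_improvement,
            }
        )
        return df.sort_values(
            ["count", "mean_improvement", "protein"],
            ascending=[False, False, True],
        ).reset_index(drop=True)


def screen_biomarkers(
    expr: ExpressionDataset,
    scores: ScoreMatrix,
    config: FwgcnConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> BiomarkerReport:
    """One-protein-at-a-time weighting screen across stratified folds.

    Per fold, the unweighted GCN sets the baseline validation accuracy;
    each shared protein is then weighted alone (same training seed, so
    the comparison is paired) and counted for the fold if accuracy
    strictly improves.
    """
    config = config or FwgcnConfig()
    shared = expr.shared_index
    if shared.size == 0:
        warnings.warn("no shared proteins; screening degenerates to plain GCN")
        return BiomarkerReport([], np.array([], dtype=int), np.array([]), k, True)
    per_protein = scores.column(expr.disease_key)
    shared_ids = [expr.protein_ids[c] for c in shared]
    missing = [p for p in shared_ids if p not in per_protein]
    if missing:
        raise KeyError(f"no potentiality score for shared protein(s) {missing[:5]}")
    a_vals = np.array([per_protein[p] for p in shared_ids])
    counts = np.zeros(shared.size, dtype=int)
    improvements = np.zeros(shared.size)
    for f, (tr, va) in enumerate(_stratified_folds(expr.labels, k, seed)):
        fold_seed = seed + f
        base = train_fwgcn(
            expr.values[tr], expr.labels[tr], config=config, seed=fold_seed
        )
        base_acc = float(np.mean(base.predict(expr.values[va]) == expr.labels[va]))
        for s, col in enumerate(shared):
            weighted = weight_columns(
                expr.values,
                np.array([col]),
                a_vals[s : s + 1],
                config.delta,
                config.weight_mode,
            )
            res = train_fwgcn(
                weighted[tr], expr.labels[tr], config=config, seed=fold_seed
            )
            acc = float(np.mean(res.predict(weighted[va]) == expr.labels[va]))
            delta_acc = acc - base_acc
            improvements[s] += delta_acc
            if delta_acc > 0:
                counts[s] += 1
    return BiomarkerReport(shared_ids, counts, improvements / k, k)


def final_weighted_model(
    expr: ExpressionDataset,
    scores: ScoreMatrix,
    report: BiomarkerReport,
    config: FwgcnConfig | None = None,
    min_count: int = 1,
    seed: int = 0,
):
    """Weight the columns of all screened biomarkers and train on everything."""
    config = config or FwgcnConfig()
    selected = set(report.selected(min_count))
    cols = np.array(
        [c for c in expr.shared_index if expr.protein_ids[c] in selected], dtype=int
    )
    values = expr.values
    if cols.size:
        per_protein = scores.column(expr.disease_key)
        a_vals = np.array([per_protein[expr.protein_ids[c]] for c in cols])
        values = weight_columns(values, cols, a_vals, config.delta, config.weight_mode)
    return train_fwgcn(values, expr.labels, config=config, seed=seed)


def shared_protein_sensitivity(
    expr: ExpressionDataset,
    scores: ScoreMatrix,
    config: FwgcnConfig | None = None,
    sizes: list[int] | None = None,
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """Mean CV accuracy as the shared-protein set is randomly thinned.

    For each requested size a random subset of the shared proteins keeps
    its weighting (the rest pass through unweighted); size 0 is exactly
    the unweighted baseline. Emits a warning when the available shared
    set is at or below the guidance threshold of 10 proteins.
    """
    config = config or FwgcnConfig()
    n_shared = int(expr.shared_index.size)
    if n_shared <= SHARED_PROTEIN_GUIDANCE:
        warnings.warn(
            f"only {n_shared} shared proteins (<= {SHARED_PROTEIN_GUIDANCE}); "
            "weighting gains may be dominated by stochastic error"
        )
    if sizes is None:
        sizes = sorted({0, n_shared // 4, n_shared // 2, n_shared})
    rng = np.random.default_rng(seed)
    baseline, _ = weighted_cv_accuracy(expr, None, config, k, seed)
    rows = []
    for size in sizes:
        if not 0 <= size <= n_shared:
            raise ValueError(f"size {size} outside 0..{n_shared}")
        if size == 0:
            rows.append({"n_shared": 0, "accuracy": baseline})
            continue
        keep = rng.choice(expr.shared_index, size=size, replace=False)
        thinned = replace(expr, shared_index=np.sort(keep))
        acc, _ = weighted_cv_accuracy(thinned, scores, config, k, seed)
        rows.append({"n_shared": size, "accuracy": acc})
    df = pd.DataFrame(rows)
    df.attrs["baseline"] = baseline
    return df
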