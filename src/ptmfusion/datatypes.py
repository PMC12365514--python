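"""Core in-memory containers shared across the pipeline.

All matrices are dense :class:`numpy.ndarray`; the graphs involved stay
below a few thousand nodes, where dense linear algebra is both simpler
and faster than sparse codepaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "ScoreMatrix",
    "ExpressionDataset",
    "SampleGraph",
]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} IDs: {dupes[:5]}")
    return ids


@dataclass
class AssociationMatrix:
    """Binary protein x disease incidence matrix with ID vocabularies.

    ``values[i, j] == 1`` iff protein ``protein_ids[i]`` has a known
    (PTM-mediated) association with disease ``disease_ids[j]``.
    """

    values: np.ndarray
    protein_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.protein_ids = _check_ids(self.protein_ids, "protein")
        self.disease_ids = _check_ids(self.disease_ids, "disease")
        n_p, n_d = self.values.shape
        if n_p != len(self.protein_ids) or n_d != len(self.disease_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match ID lists "
                f"({len(self.protein_ids)}, {len(self.disease_ids)})"
            )

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    def positives(self) -> np.ndarray:
        """Indices of known associations as an (n, 2) array of (i, j)."""
        return np.argwhere(self.values == 1.0)

    def masked(self, pairs: np.ndarray) -> "AssociationMatrix":
        """Copy with the given (i, j) pairs zeroed (held-out edges)."""
        values = self.values.copy()
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        values[pairs[:, 0], pairs[:, 1]] = 0.0
        return AssociationMatrix(values, list(self.protein_ids), list(self.disease_ids))


@dataclass
class SimilarityMatrix:
    """Square symmetric non-negative kernel over proteins or diseases."""

    values: np.ndarray
    ids: list[str]
    kind: str  # "sequence" | "gip" | "fused"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("similarity matrix must be non-negative")
        if self.kind not in ("sequence", "gip", "fused"):
            raise ValueError(f"unknown similarity kind {self.kind!r}")


@dataclass
class ScoreMatrix:
    """Decoded PTM potentiality scores, entries in the open interval (0, 1)."""

    values: np.ndarray
    protein_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.disease_ids)):
            raise ValueError("score matrix shape does not match ID lists")
        if not ((self.values > 0.0) & (self.values < 1.0)).all():
            raise ValueError("scores must lie strictly in (0, 1)")

    def column(self, disease_key: str) -> dict[str, float]:
        """Per-protein score for one disease, keyed by protein ID."""
        try:
            j = self.disease_ids.index(disease_key)
        except ValueError:
            raise KeyError(
                f"disease {disease_key!r} not present in score matrix"
            ) from None
        return dict(zip(self.protein_ids, self.values[:, j]))


@dataclass
class ExpressionDataset:
    """Sample x protein expression table with subtype labels.

    ``shared_index`` marks the protein columns that also appear in the
    association data — only these are eligible for potentiality-score
    weighting. ``disease_key`` names the association-table disease this
    expression cohort is mapped to.
    """

    values: np.ndarray
    sample_ids: list[str]
    protein_ids: list[str]
    labels: np.ndarray
    shared_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    disease_key: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n_s, n_f = self.values.shape
        if n_s != len(self.sample_ids) or n_f != len(self.protein_ids):
            raise ValueError("expression shape does not match ID lists")
        if self.labels.shape != (n_s,):
            raise ValueError("one label required per sample")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        self.shared_index = np.asarray(self.shared_index, dtype=int)
        if self.shared_index.size and (
            self.shared_index.min() < 0 or self.shared_index.max() >= n_f
        ):
            raise ValueError("shared_index out of range")
        labels = np.unique(self.labels)
        if labels.size and (labels.min() < 0):
            raise ValueError("labels must be non-negative integers 0..C-1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def subset(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
        )


@dataclass
class SampleGraph:
    """Thresholded cosine-similarity graph over samples with self-loops."""

    g_pp: np.ndarray
    epsilon: float
    gamma: int
    achieved_degree: float

    def __post_init__(self) -> None:
        self.g_pp = np.asarray(self.g_pp, dtype=float)
        n = self.g_pp.shape[0]
        if self.g_pp.shape != (n, n):
            raise ValueError("sample graph must be square")
        if not np.allclose(self.g_pp, self.g_pp.T, atol=1e-9):
            raise ValueError("sample graph must be symmetric")
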