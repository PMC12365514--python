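"""Synthetic data generators mirroring the statistical structure of the
real inputs: a sparse block-structured association matrix, sequences whose
similarity tracks block membership, and an expression table in which a
subset of shared proteins carries subtype signal.

Every generator is a deterministic function of ``spec.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .datatypes import AssociationMatrix, ExpressionDataset, ScoreMatrix

__all__ = [
    "SyntheticSpec",
    "simulate_associations",
    "simulate_sequences",
    "simulate_expression",
    "truth_scores",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic study.

    Defaults mirror the scale of the real inputs at reduced size: a
    100 x 40 association matrix with 5 latent blocks (within-block edge
    density 0.6, background noise 0.02), 300 samples over 200 expression
    proteins of which 30 are shared with the association data and 15
    carry a subtype mean shift of 1.5 feature standard deviations.
    """

    n_proteins: int = 100
    n_diseases: int = 40
    n_blocks: int = 5
    within_block_density: float = 0.6
    noise_density: float = 0.02
    n_samples: int = 300
    n_subtypes: int = 2
    n_expression_proteins: int = 200
    n_shared: int = 30
    n_shared_informative: int = 15
    effect_size: float = 1.5
    seq_len_min: int = 80
    seq_len_max: int = 120
    motif_len: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_block_density", "noise_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_shared_informative > self.n_shared:
            raise ValueError("n_shared_informative cannot exceed n_shared")
        if self.n_shared > min(self.n_proteins, self.n_expression_proteins):
            raise ValueError("n_shared exceeds available proteins")
        if self.n_blocks > min(self.n_proteins, self.n_diseases):
            raise ValueError("more blocks than proteins or diseases")


def _blocks(n: int, n_blocks: int) -> np.ndarray:
    """Round-robin block assignment, contiguous groups."""
    return np.repeat(np.arange(n_blocks), -(-n // n_blocks))[:n]


def simulate_associations(spec: SyntheticSpec) -> AssociationMatrix:
    """Bipartite block model: within-block pairs link with the block
    density, off-block pairs with the background noise density."""
    rng = np.random.default_rng(spec.seed)
    pb = _blocks(spec.n_proteins, spec.n_blocks)
    db = _blocks(spec.n_diseases, spec.n_blocks)
    within = pb[:, None] == db[None, :]
    density = np.where(within, spec.within_block_density, spec.noise_density)
    values = (rng.random(density.shape) < density).astype(float)
    if values.sum() == 0:
        warnings.warn("no positives generated; bumping densities by 50%")
        bumped = replace(
            spec,
            within_block_density=min(1.0, spec.within_block_density * 1.5 + 0.05),
            noise_density=min(1.0, spec.noise_density * 1.5 + 0.01),
            seed=spec.seed + 1,
        )
        return simulate_associations(bumped)
    return AssociationMatrix(
        values,
        [f"P{i:04d}" for i in range(spec.n_proteins)],
        [f"D{j:03d}" for j in range(spec.n_diseases)],
    )


def protein_blocks(spec: SyntheticSpec) -> np.ndarray:
    """Ground-truth block labels of the association-side proteins."""
    return _blocks(spec.n_proteins, spec.n_blocks)


def simulate_sequences(spec: SyntheticSpec, assoc: AssociationMatrix) -> dict[str, str]:
    """Random residue strings with a conserved per-block motif embedded,
    so within-block pairwise similarity exceeds between-block similarity."""
    rng = np.random.default_rng(spec.seed + 1)
    pb = protein_blocks(spec)
    motifs = [
        "".join(rng.choice(AMINO_ACIDS, size=spec.motif_len))
        for _ in range(spec.n_blocks)
    ]
    records: dict[str, str] = {}
    for pid, block in zip(assoc.protein_ids, pb):
        length = int(rng.integers(spec.seq_len_min, spec.seq_len_max + 1))
        body = "".join(rng.choice(AMINO_ACIDS, size=length))
        pos = int(rng.integers(0, max(1, length - spec.motif_len)))
        records[pid] = body[:pos] + motifs[block] + body[pos + spec.motif_len :]
    return records


def _robust_scale(values: np.ndarray) -> np.ndarray:
    med = np.median(values, axis=0)
    q75, q25 = np.percentile(values, [75, 25], axis=0)
    iqr = np.where(q75 - q25 > 1e-12, q75 - q25, 1.0)
    return (values - med) / iqr


def simulate_expression(
    spec: SyntheticSpec,
    assoc: AssociationMatrix,
    disease_key: str | None = None,
) -> ExpressionDataset:
    """Gaussian expression table with subtype mean shifts on the
    informative shared proteins.

    The first ``n_shared`` association proteins become the shared columns
    (keeping their association IDs); the first ``n_shared_informative``
    of those receive per-subtype mean shifts of ``effect_size`` feature
    standard deviations. All other columns are pure noise. The table is
    robust-scaled (median/IQR per column).
    """
    rng = np.random.default_rng(spec.seed + 2)
    n, f = spec.n_samples, spec.n_expression_proteins
    labels = np.sort(rng.integers(0, spec.n_subtypes, size=n))
    # guarantee usable class sizes
    counts = np.bincount(labels, minlength=spec.n_subtypes)
    if counts.min() < 5:
        labels = np.repeat(np.arange(spec.n_subtypes), -(-n // spec.n_subtypes))[:n]
    rng.shuffle(labels)
    values = rng.normal(size=(n, f))
    shared_cols = np.arange(spec.n_shared)
    informative = shared_cols[: spec.n_shared_informative]
    C = spec.n_subtypes
    codes = np.arange(C) - (C - 1) / 2.0
    for col in informative:
        per_class = spec.effect_size * rng.permutation(codes)
        values[:, col] += per_class[labels]
    protein_ids = [
        assoc.protein_ids[c] if c < spec.n_shared else f"EXP{c:04d}" for c in range(f)
    ]
    if disease_key is None:
        disease_key = assoc.disease_ids[0]
    return ExpressionDataset(
        values=_robust_scale(values),
        sample_ids=[f"S{i:04d}" for i in range(n)],
        protein_ids=protein_ids,
        labels=labels,
        shared_index=shared_cols,
        disease_key=disease_key,
    )


def truth_scores(
    spec: SyntheticSpec,
    assoc: AssociationMatrix,
    expr: ExpressionDataset,
    high: float = 0.9,
    low: float = 0.1,
    neutral: float = 0.5,
) -> ScoreMatrix:
    """Oracle potentiality scores for the planted structure.

    Informative shared proteins score ``high`` for the expression
    cohort's disease, other shared proteins ``low``, and everything else
    ``neutral`` (the identity point of the weighting transform).
    """
    values = np.full((assoc.n_proteins, assoc.n_diseases), neutral)
    j = assoc.disease_ids.index(expr.disease_key)
    shared_ids = [expr.protein_ids[c] for c in expr.shared_index]
    informative_ids = set(shared_ids[: spec.n_shared_informative])
    for pid in shared_ids:
        i = assoc.protein_ids.index(pid)
        values[i, j] = high if pid in informative_ids else low
    return ScoreMatrix(values, list(assoc.protein_ids), list(assoc.disease_ids))
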