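"""Protein and disease similarity kernels.

Two complementary similarity views feed the heterogeneous network:

* **sequence similarity** — best local-alignment (Smith--Waterman, affine
  gaps) score for every protein pair, normalized by the global maximum of
  the score matrix;
* **Gaussian interaction profile (GIP) kernel** — a Gaussian of the
  Euclidean distance between two entities' binary association profiles,
  with the bandwidth normalized by the mean squared profile norm.

The fused protein similarity is the (weighted) elementwise sum of the two.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from Bio import Align

from .datatypes import AssociationMatrix, SimilarityMatrix

__all__ = [
    "DEFAULT_MATCH",
    "DEFAULT_MISMATCH",
    "DEFAULT_GAP_OPEN",
    "DEFAULT_GAP_EXTEND",
    "sequence_similarity",
    "gip_kernel",
    "protein_gip",
    "disease_gip",
    "fuse_protein_similarity",
]

# Local-alignment scoring scheme used throughout: a gap of length L costs
# |gap_open| + (L - 1) * |gap_extend|.
DEFAULT_MATCH = 2.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_OPEN = -0.5
DEFAULT_GAP_EXTEND = -0.1


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def local_alignment_score(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Best local-alignment score between two residue strings.

    Any pair of unequal characters — including non-standard residues such
    as ``X`` or ``U`` — scores as a mismatch rather than being rejected.
    """
    return float(_aligner(match, mismatch, gap_open, gap_extend).score(a, b))


def sequence_similarity(
    sequences: Sequence[str],
    ids: Sequence[str] | None = None,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> SimilarityMatrix:
    """Pairwise normalized local-alignment similarity matrix (SSP).

    Every pair (including each sequence with itself) is scored with the
    affine-gap Smith--Waterman algorithm; the whole matrix is then divided
    by its global maximum, so entries lie in [0, 1] and the best-scoring
    pair — in practice the self-alignment of the longest sequence — maps
    to exactly 1.

    Parameters default to match 2, mismatch -1, gap open -0.5 and gap
    extension -0.1.
    """
    sequences = [str(s) for s in sequences]
    if ids is None:
        ids = [f"P{i}" for i in range(len(sequences))]
    ids = [str(i) for i in ids]
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    for sid, seq in zip(ids, sequences):
        if len(seq) == 0:
            raise ValueError(f"empty sequence for record {sid!r}")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    n = len(sequences)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            raw[i, j] = raw[j, i] = aligner.score(sequences[i], sequences[j])
    max_score = raw.max()
    if max_score <= 0.0:
        raise ValueError("all alignment scores are <= 0; normalization undefined")
    return SimilarityMatrix(raw / max_score, ids, kind="sequence")


def gip_kernel(
    profiles: np.ndarray,
    ids: Sequence[str],
    rho_prime: float = 1.0,
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over binary profiles.

    ``K(i, j) = exp(-rho * ||I(i) - I(j)||^2)`` with the normalized
    bandwidth ``rho = rho_prime / mean_i ||I(i)||^2``. The initial
    bandwidth defaults to 1.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix (one row per entity)")
    if rho_prime <= 0:
        raise ValueError("rho_prime must be positive")
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("all interaction profiles are zero; GIP bandwidth undefined")
    rho = rho_prime / mean_sq_norm
    # ||x - y||^2 = ||x||^2 + ||y||^2 - 2 x.y, computed in one shot
    sq = np.sum(profiles**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (profiles @ profiles.T)
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-rho * d2)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)
    return SimilarityMatrix(values, list(ids), kind="gip")


def protein_gip(assoc: AssociationMatrix, rho_prime: float = 1.0) -> SimilarityMatrix:
    """GIP kernel over proteins — profiles are the rows of A."""
    return gip_kernel(assoc.values, assoc.protein_ids, rho_prime)


def disease_gip(assoc: AssociationMatrix, rho_prime: float = 1.0) -> SimilarityMatrix:
    """GIP kernel over diseases — profiles are the columns of A."""
    return gip_kernel(assoc.values.T, assoc.disease_ids, rho_prime)


def fuse_protein_similarity(
    ssp: SimilarityMatrix,
    sgp: SimilarityMatrix,
    alpha1: float = 1.0,
    alpha2: float = 1.0,
) -> SimilarityMatrix:
    """Integrated protein similarity SP = alpha1 * SSP + alpha2 * SGP."""
    if ssp.ids != sgp.ids:
        raise ValueError("similarity matrices have mismatched ID orderings")
    if ssp.values.shape != sgp.values.shape:
        raise ValueError("similarity matrices have mismatched shapes")
    return SimilarityMatrix(
        alpha1 * ssp.values + alpha2 * sgp.values, list(ssp.ids), kind="fused"
    )
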