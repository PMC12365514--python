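"""Assembly of the protein-disease heterogeneous network.

The network stacks three edge sets into one symmetric block matrix over
``n_p + n_d`` nodes: degree-normalized protein similarity (top-left),
degree-normalized disease similarity (bottom-right), and the binary
association matrix in the off-diagonal blocks::

    A_H = [ D_p^{-1/2} S_P D_p^{-1/2}    A  ]
          [ A^T    D_d^{-1/2} S_D D_d^{-1/2} ]

The model input ``G_pd`` is ``A_H`` with both similarity blocks scaled by
the factor ``psi`` (default 6), which modulates how strongly similarity
edges compete with association edges during propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AssociationMatrix, SimilarityMatrix

__all__ = [
    "HeteroGraph",
    "build_hetero_network",
    "build_input_graph",
    "initial_embedding",
    "sym_normalize",
]

DEGREE_FLOOR = 1e-12


def _normalize_block(sim: SimilarityMatrix, what: str) -> np.ndarray:
    """D^{-1/2} S D^{-1/2} with D = diag of row sums; zero rows rejected."""
    s = sim.values
    deg = s.sum(axis=1)
    zero = np.flatnonzero(deg <= 0)
    if zero.size:
        raise ValueError(
            f"zero row sum in {what} similarity for node(s) "
            f"{[sim.ids[i] for i in zero[:5]]}; normalization undefined"
        )
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return d_inv_sqrt[:, None] * s * d_inv_sqrt[None, :]


@dataclass
class HeteroGraph:
    """Heterogeneous network ``a_h``, its penalized input ``g_pd``."""

    a_h: np.ndarray
    n_p: int
    n_d: int
    g_pd: np.ndarray | None = None
    psi: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.n_p + self.n_d


def build_hetero_network(
    assoc: AssociationMatrix,
    sp: SimilarityMatrix,
    sd: SimilarityMatrix,
) -> HeteroGraph:
    """Combine associations with normalized similarities into A_H."""
    n_p, n_d = assoc.values.shape
    if sp.values.shape != (n_p, n_p):
        raise ValueError("protein similarity shape does not match association matrix")
    if sd.values.shape != (n_d, n_d):
        raise ValueError("disease similarity shape does not match association matrix")
    if sp.ids != assoc.protein_ids or sd.ids != assoc.disease_ids:
        raise ValueError("similarity ID ordering does not match association matrix")
    sp_norm = _normalize_block(sp, "protein")
    sd_norm = _normalize_block(sd, "disease")
    a = assoc.values
    a_h = np.block([[sp_norm, a], [a.T, sd_norm]])
    a_h = 0.5 * (a_h + a_h.T)  # exact symmetry against float noise
    return HeteroGraph(a_h=a_h, n_p=n_p, n_d=n_d)


def build_input_graph(hetero: HeteroGraph, psi: float = 6.0) -> HeteroGraph:
    """Fill ``g_pd``: similarity blocks of A_H scaled by psi, associations kept."""
    if psi <= 0:
        raise ValueError("psi must be positive")
    if hetero.g_pd is not None:
        raise ValueError("input graph already built; refusing to scale twice")
    n_p = hetero.n_p
    g = hetero.a_h.copy()
    g[:n_p, :n_p] *= psi
    g[n_p:, n_p:] *= psi
    hetero.g_pd = g
    hetero.psi = psi
    return hetero


def initial_embedding(hetero: HeteroGraph) -> np.ndarray:
    """Initial node features H^(0): each node's row of A_H.

    Gives every node an (n_p + n_d)-dimensional descriptor mixing its
    similarity and association edges — the standard starting embedding
    for layer-attention GCN link predictors on a single combined graph.
    """
    return hetero.a_h.copy()


def sym_normalize(g: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} G D^{-1/2} used by Eq.-style
    GCN propagation; degrees floored to avoid dividing by zero on isolated
    nodes."""
    deg = np.maximum(g.sum(axis=1), DEGREE_FLOOR)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return d_inv_sqrt[:, None] * g * d_inv_sqrt[None, :]
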