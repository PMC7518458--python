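"""Effective information and its determinism/degeneracy decomposition.

For a network of N nodes with row-stochastic out-weight vectors W_i^out, the
effective information is

    EI = H(<W_i^out>) - <H(W_i^out)>        (bits, log base 2)

where <.> averages over nodes.  The first term is the entropy of the
network-wide weight distribution; the second is the mean uncertainty a random
walker faces on a node.  Equivalently,

    determinism = log2(N) - <H(W_i^out)>
    degeneracy  = log2(N) - H(<W_i^out>)
    EI          = determinism - degeneracy

Determinism is certainty about a walker's next step (the future); degeneracy
is overlap in targeting, i.e. uncertainty about where a walker came from (the
past).  EI is bounded between 0 and log2(N) and is maximal exactly when every
node deterministically targets a unique node.  EI is also the mutual
information between a maximum-entropy intervention on node identity and the
one-step destination, which :func:`ei_via_intervention` computes directly as
a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import TransitionStructure

__all__ = [
    "out_entropy",
    "EIDecomposition",
    "effective_information",
    "ei_via_intervention",
]


def out_entropy(row: np.ndarray, tol: float = 1e-9) -> float:
    """Shannon entropy (bits) of a single out-weight probability row.

    Uses the 0*log(0) = 0 convention, so zero entries contribute nothing.
    """
    p = np.asarray(row, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("empty probability vector")
    if np.any(p < 0):
        raise ValueError("probability vector has a negative entry")
    s = p.sum()
    if abs(s - 1.0) > tol:
        raise ValueError(f"probability vector sums to {s!r}, not 1.0")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) + 0.0


def _row_entropies(M: sp.csr_matrix) -> np.ndarray:
    """Entropy in bits of every row of a sparse row-stochastic matrix."""
    data = M.data
    contrib = np.zeros_like(data)
    nz = data > 0
    contrib[nz] = -data[nz] * np.log2(data[nz])
    out = np.zeros(M.shape[0])
    np.add.at(out, np.repeat(np.arange(M.shape[0]), np.diff(M.indptr)),
              contrib)
    return out


@dataclass(frozen=True)
class EIDecomposition:
    """Effective information of a transition structure, fully decomposed.

    All quantities are in bits.  ``avg_out_entropy`` is <H(W_i^out)> and
    ``weight_dist_entropy`` is H(<W_i^out>); the remaining fields are the
    derived determinism, degeneracy and EI.
    """

    n_nodes: int
    avg_out_entropy: float
    weight_dist_entropy: float

    @property
    def determinism(self) -> float:
        return float(np.log2(self.n_nodes)) - self.avg_out_entropy

    @property
    def degeneracy(self) -> float:
        return float(np.log2(self.n_nodes)) - self.weight_dist_entropy

    @property
    def ei(self) -> float:
        return self.weight_dist_entropy - self.avg_out_entropy

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "avg_out_entropy": self.avg_out_entropy,
            "weight_dist_entropy": self.weight_dist_entropy,
            "determinism": self.determinism,
            "degeneracy": self.degeneracy,
            "ei": self.ei,
        }


def effective_information(ts: TransitionStructure) -> EIDecomposition:
    """Compute EI and its decomposition for a transition structure.

    <W_i^out> is the simple (unweighted) mean of the rows; the entropy of
    that mean minus the mean row entropy is the EI.
    """
    if ts.n_nodes < 1:
        raise ValueError("transition structure has no nodes")
    avg_row = ts.mean_out_vector()
    nz = avg_row[avg_row > 0]
    h_avg = float(-(nz * np.log2(nz)).sum()) + 0.0
    h_rows = float(_row_entropies(ts.matrix).mean()) + 0.0
    return EIDecomposition(
        n_nodes=ts.n_nodes,
        avg_out_entropy=h_rows,
        weight_dist_entropy=h_avg,
    )


def ei_via_intervention(ts: TransitionStructure) -> float:
    """EI as mutual information under a maximum-entropy perturbation.

    Place a walker on a node drawn uniformly at random (the intervention),
    take one step, and measure the mutual information I(source; destination)
    of the resulting joint distribution p(i, j) = T[i, j] / N.  This is the
    interventionist reading of EI and must agree with the entropy-difference
    formula to within numerical error.
    """
    n = ts.n_nodes
    coo = ts.matrix.tocoo()
    p_joint = coo.data / n
    p_dest = np.zeros(n)
    np.add.at(p_dest, coo.col, p_joint)
    # I(S;D) = sum_ij p(i,j) log2( p(i,j) / (p(i) p(j)) ), p(i) = 1/N
    nz = p_joint > 0
    terms = p_joint[nz] * np.log2(
        p_joint[nz] / ((1.0 / n) * p_dest[coo.col[nz]]))
    return float(terms.sum())
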