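"""Projection algorithm: the consensus vector of a fixed document set.

Given rows u_1..u_m of a document-term matrix, the consensus vector is
the unit vector phi maximizing the sum of squared projections
sum_i (u_i, phi)^2 — equivalently, the first right singular vector of
the stacked matrix. The iteration

    phi <- normalize( sum_i (u_i, phi) u_i )

is power iteration on the Gram operator X^T X; for entrywise
non-negative rows and a start vector not orthogonal to the dominant
singular subspace it converges to the first right singular vector, and
the objective ascends monotonically along the iterates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ConsensusVector",
    "ProjectionConfig",
    "DegenerateStartError",
    "objective",
    "residual",
    "iterate_once",
    "run_projection",
]


class DegenerateStartError(ValueError):
    """Start vector orthogonal to the row space: the update is zero."""


@dataclass(frozen=True)
class ProjectionConfig:
    """Stopping rule: 1 - (phi_{t+1}, phi_t) < tol, capped at max_iter."""

    tol: float = 1e-10
    max_iter: int = 500

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ConsensusVector:
    """Unit term vector summarizing a document set, with run metadata."""

    weights: np.ndarray
    iteration_count: int = 0
    converged: bool = False

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.weights))


def _as_2d(rows) -> sp.csr_matrix | np.ndarray:
    if sp.issparse(rows):
        return rows.tocsr()
    return np.atleast_2d(np.asarray(rows, dtype=float))


def _check_dims(rows, phi: np.ndarray) -> None:
    if rows.shape[1] != phi.shape[0]:
        raise ValueError(f"dimension mismatch: rows have {rows.shape[1]} terms, phi has {phi.shape[0]}")


def objective(rows, phi: np.ndarray) -> float:
    """Sum of squared projections sum_i (u_i, phi)^2."""
    rows = _as_2d(rows)
    phi = np.asarray(phi, dtype=float).ravel()
    _check_dims(rows, phi)
    s = rows @ phi
    return float(np.dot(s, s))


def residual(rows, phi: np.ndarray, chunk: int = 256) -> float:
    """Sum of squared residuals sum_i ||u_i - (u_i, phi) phi||^2.

    Computed literally (row chunks densified and the rank-one component
    subtracted), so the identity objective + residual = sum ||u_i||^2
    is an actual consequence, not a definition.
    """
    rows = _as_2d(rows)
    phi = np.asarray(phi, dtype=float).ravel()
    _check_dims(rows, phi)
    total = 0.0
    n = rows.shape[0]
    for start in range(0, n, chunk):
        block = rows[start : start + chunk]
        dense = block.toarray() if sp.issparse(block) else np.asarray(block, dtype=float)
        s = dense @ phi
        resid = dense - np.outer(s, phi)
        total += float(np.sum(resid * resid))
    return total


def iterate_once(rows, phi: np.ndarray) -> np.ndarray:
    """One power step: normalize( sum_i (u_i, phi) u_i )."""
    rows = _as_2d(rows)
    phi = np.asarray(phi, dtype=float).ravel()
    _check_dims(rows, phi)
    v = rows.T @ (rows @ phi)
    v = np.asarray(v).ravel()
    nv = np.linalg.norm(v)
    if nv == 0.0:
        raise DegenerateStartError("update vector is zero: phi is orthogonal to the row space")
    return v / nv


def _canonical_sign(phi: np.ndarray) -> np.ndarray:
    # deterministic orientation: largest-magnitude coordinate non-negative
    k = int(np.argmax(np.abs(phi)))
    return -phi if phi[k] < 0 else phi


def run_projection(rows, phi0: np.ndarray, cfg: ProjectionConfig | None = None) -> ConsensusVector:
    """Iterate to the consensus vector of a fixed document set.

    For non-negative rows with a non-negative, non-orthogonal start this
    converges to the first right singular vector of the row matrix; the
    returned vector is unit-norm with its largest-magnitude coordinate
    oriented non-negative.
    """
    cfg = cfg or ProjectionConfig()
    rows = _as_2d(rows)
    phi = np.asarray(phi0, dtype=float).ravel().copy()
    _check_dims(rows, phi)
    nrm = np.linalg.norm(phi)
    if nrm == 0.0:
        raise DegenerateStartError("start vector has zero norm")
    phi /= nrm
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        phi_new = iterate_once(rows, phi)
        if 1.0 - float(np.dot(phi_new, phi)) < cfg.tol:
            phi = phi_new
            converged = True
            break
        phi = phi_new
    return ConsensusVector(weights=_canonical_sign(phi), iteration_count=it, converged=converged)
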