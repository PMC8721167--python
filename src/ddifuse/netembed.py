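"""Topological-similarity networks via random walk with restart and PPMI.

Each similarity matrix is row-normalized into a transition matrix, diffused
by random walk with restart (RWR) from every drug simultaneously, re-weighted
entrywise by positive pointwise mutual information (PPMI), and symmetrized by
averaging with its transpose. The result is a nonnegative symmetric network
that encodes each drug's global topological context rather than its raw
pairwise similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

logger = logging.getLogger("ddifuse")


@dataclass
class DiffusionMatrix:
    """Row i is the stationary RWR distribution started from drug i."""

    values: np.ndarray
    iterations_used: int
    alpha: float
    epsilon: float


@dataclass
class PPMINetwork:
    source_name: str
    values: np.ndarray  # nonnegative, symmetric, finite
    drug_ids: tuple[str, ...] | None = None


def row_normalize(s: np.ndarray) -> np.ndarray:
    """W = D^{-1} S with D_ii = sum_j S_ij; every row of W sums to 1."""
    s = np.asarray(s, dtype=float)
    if (s < 0).any():
        raise ValueError("row_normalize requires a nonnegative matrix")
    degrees = s.sum(axis=1)
    zero = np.flatnonzero(degrees == 0)
    if zero.size:
        raise ValueError(f"zero-degree rows cannot be normalized: {zero.tolist()}")
    return s / degrees[:, None]


def rwr(
    w: np.ndarray,
    alpha: float,
    epsilon: float = 1e-9,
    max_iter: int = 1000,
) -> DiffusionMatrix:
    """Random walk with restart from every node.

    Iterates p_t = alpha * p_{t-1} W + (1 - alpha) * p_0 for all one-hot
    starts at once (a matrix iteration, identical per row) until the largest
    row L1 change drops below ``epsilon``. alpha < 1 guarantees geometric
    convergence; ``max_iter`` only catches non-finite pathologies.
    """
    w = np.asarray(w, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not np.allclose(w.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix must be row-stochastic")
    m = w.shape[0]
    restart = (1.0 - alpha) * np.eye(m)
    p = np.eye(m)
    for it in range(1, max_iter + 1):
        p_next = alpha * (p @ w) + restart
        delta = np.abs(p_next - p).sum(axis=1).max()
        p = p_next
        if delta < epsilon:
            return DiffusionMatrix(p, it, alpha, epsilon)
    raise RuntimeError(
        f"RWR did not converge within {max_iter} iterations "
        f"(residual {delta:.3e})"
    )


def ppmi(p: np.ndarray) -> np.ndarray:
    """Positive pointwise mutual information, entrywise.

    X(i,j) = max(0, log2( P(i,j) * T / (r_i * c_j) )) with T the grand sum,
    r_i the row sum and c_j the column sum; zero entries stay zero.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("PPMI requires a nonnegative matrix")
    total = p.sum()
    if total <= 0:
        raise ValueError("PPMI requires positive total mass")
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    denom = r[:, None] * c[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((p > 0) & (denom > 0), p * total / np.where(denom > 0, denom, 1.0), 0.0)
        x = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return np.maximum(x, 0.0)


def symmetrize(x: np.ndarray, source_name: str = "") -> PPMINetwork:
    """Average X with its transpose: N(i,j) = (X(i,j) + X(j,i)) / 2."""
    x = np.asarray(x, dtype=float)
    return PPMINetwork(source_name, (x + x.T) / 2.0)


def topological_similarity(
    sim: SimilarityMatrix,
    alpha: float = 0.8,
    epsilon: float = 1e-9,
) -> PPMINetwork:
    """Full chain: row-normalize -> RWR -> PPMI -> symmetrize."""
    diff = rwr(row_normalize(sim.values), alpha, epsilon)
    net = symmetrize(ppmi(diff.values), sim.source_name)
    net.drug_ids = sim.drug_ids
    logger.debug("topological network %s converged in %d iterations",
                 sim.source_name, diff.iterations_used)
    return net


def build_all_networks(
    sims: list[SimilarityMatrix], alpha: float = 0.8, epsilon: float = 1e-9
) -> list[PPMINetwork]:
    return [topological_similarity(s, alpha, epsilon) for s in sims]
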