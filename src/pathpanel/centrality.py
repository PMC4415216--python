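"""PageRank centrality of genes on the transcriptional regulatory network.

PageRank is the stationary distribution of a damped random walk: with
probability *d* the walker follows a uniformly chosen out-edge of the current
gene, with probability 1-d it teleports to a uniformly chosen gene.  Genes
pointed at by other high-scoring genes therefore score high, which is the
ranking backbone of reporter-gene prioritization.

Because the curated direction of regulatory edges is not always the direction
that best rewards importance, three direction modes are exposed:

``directed``
    walk along source -> target edges (importance flows to regulatory targets);
``reversed``
    walk along target -> source edges (rewarding upstream regulators);
``undirected``
    collapse each edge to an undirected one (the network's skeleton; default).

Multi-edges collapse to single edges before iteration (unweighted walk);
dangling genes redistribute their mass uniformly over all genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .knowledge import RegulatoryNetwork

MODES = ("directed", "reversed", "undirected")


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the residual tolerance."""

    def __init__(self, iterations: int, residual: float, tol: float) -> None:
        super().__init__(
            f"PageRank did not converge in {iterations} iterations "
            f"(L1 residual {residual:.3e} > tol {tol:.3e})"
        )
        self.iterations = iterations
        self.residual = residual


@dataclass(frozen=True)
class CentralityScores:
    """Per-gene PageRank values (sum to one) with convergence metadata."""

    scores: pd.Series  # index: gene id, values sum to 1
    damping: float
    mode: str
    iterations: int
    residual: float

    def __getitem__(self, gene: str) -> float:
        return float(self.scores[gene])

    def __contains__(self, gene: str) -> bool:
        return gene in self.scores.index

    def rank_order(self) -> list[str]:
        """Gene ids by descending score; score ties broken by gene id."""
        df = self.scores.rename("score").reset_index()
        df.columns = ["gene", "score"]
        df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
        return df["gene"].tolist()

    def to_frame(self) -> pd.DataFrame:
        order = self.rank_order()
        return pd.DataFrame(
            {
                "gene": order,
                "score": [float(self.scores[g]) for g in order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def _edge_arrays(network: RegulatoryNetwork, mode: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    nodes = sorted(network.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    pairs = {(s, t) for s, t, _ in network.edges}
    if mode == "reversed":
        pairs = {(t, s) for s, t in pairs}
    elif mode == "undirected":
        pairs = pairs | {(t, s) for s, t in pairs}
    elif mode != "directed":
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    # self-loops (if permitted at read time) are kept: the walker may stay put
    src = np.fromiter((idx[s] for s, _ in pairs), dtype=np.int64, count=len(pairs))
    tgt = np.fromiter((idx[t] for _, t in pairs), dtype=np.int64, count=len(pairs))
    return nodes, src, tgt


def pagerank(
    network: RegulatoryNetwork,
    mode: str = "undirected",
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> CentralityScores:
    """Power-iteration PageRank with uniform teleport and uniform dangling
    redistribution, to an L1 residual below ``tol``.

    Raises :class:`ConvergenceError` (carrying the last residual) if the
    residual is still above ``tol`` after ``max_iter`` iterations, and
    ``ValueError`` for an empty network or damping outside (0, 1).
    """
    if len(network) == 0:
        raise ValueError("network is empty")
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must be in (0, 1), got {damping}")

    nodes, src, tgt = _edge_arrays(network, mode)
    n = len(nodes)
    outdeg = np.bincount(src, minlength=n).astype(float)
    with np.errstate(divide="ignore"):
        inv_out = np.where(outdeg > 0, 1.0 / outdeg, 0.0)
    # column-stochastic transition restricted to non-dangling columns
    P = sparse.csr_matrix((inv_out[src], (tgt, src)), shape=(n, n))
    dangling = outdeg == 0

    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    residual = np.inf
    for it in range(1, max_iter + 1):
        x_new = damping * (P @ x + x[dangling].sum() / n) + teleport
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < tol:
            x = x / x.sum()  # remove float drift
            return CentralityScores(
                scores=pd.Series(x, index=nodes),
                damping=damping,
                mode=mode,
                iterations=it,
                residual=residual,
            )
    raise ConvergenceError(max_iter, residual, tol)
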