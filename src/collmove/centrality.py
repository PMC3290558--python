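"""Eigenvector centrality and the group centrality (centralization) index.

Centrality is computed on *received* affiliation: the score vector is the
dominant eigenvector of the transpose of the giver matrix (entry
``(k, i) = r(i, k)``), so an individual is central when it receives many
and strong ties, weighted by how central its partners are.  Because every
giver row sums to one, the received matrix is column-stochastic and its
dominant eigenvalue is exactly 1 for every constructed network.

For the continuum family the scores have a closed form: with ``n``
individuals and non-central-to-central affiliation ``r_cC``, the score
ratio is ``C : c = (n-1) * r_cC`` and the non-central score is
``1 / sqrt(((n-1) * r_cC)**2 + (n-1))`` after unit-norm scaling.  The
power iteration is checked against this closed form in the test suite.

The *centrality index* of a group is the central individual's score minus
the mean score of all others: 0 for a fully decentralized group, rising
toward 1 for a star-like group.  Two variants are exposed: ``index_exact``
on the unrounded scores, and ``index_table`` on scores first rounded to
two decimals — the convention in which the canonical continuum values
(0.85 for the star, 0 for the equal network) are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import NetworkError, SocialNetwork

__all__ = [
    "CentralityResult",
    "eigenvector_centrality",
    "centrality_index",
    "identify_central",
    "compute_centrality",
]

#: score spread below which the maximum is considered non-unique
UNIQUENESS_TOL = 1e-9


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge."""


@dataclass(frozen=True)
class CentralityResult:
    """Per-individual eigenvector scores and group-level indices."""

    scores: dict[str, float]
    central: str | None
    index_exact: float | None
    index_table: float | None
    eigenvalue: float

    def score(self, label: str) -> float:
        return self.scores[label]


def eigenvector_centrality(
    net: SocialNetwork, tol: float = 1e-12, max_iter: int = 100_000
) -> dict[str, float]:
    """Eigenvector centrality scores on received weights.

    Power iteration on ``A + I`` where ``A[k, i] = r(i, k)`` (the identity
    shift removes the period-2 oscillation of bipartite topologies such as
    the chain without changing the dominant eigenvector).  Scores are
    nonnegative and normalized to unit Euclidean norm.
    """
    if not net.is_connected():
        raise NetworkError("eigenvector centrality requires a connected network")
    a = net.weights.T
    shifted = a + np.eye(net.n)
    v = np.full(net.n, 1.0 / np.sqrt(net.n))
    for _ in range(max_iter):
        nxt = shifted @ v
        nxt /= np.linalg.norm(nxt)
        if np.linalg.norm(nxt - v) < tol * np.linalg.norm(nxt):
            v = nxt
            break
        v = nxt
    else:
        raise ConvergenceError(f"power iteration did not converge in {max_iter} steps")
    v = np.abs(v)  # Perron vector is nonnegative; fix the sign
    v /= np.linalg.norm(v)
    return {lab: float(s) for lab, s in zip(net.labels, v)}


def _dominant_eigenvalue(net: SocialNetwork, scores: dict[str, float]) -> float:
    v = np.array([scores[lab] for lab in net.labels])
    av = net.weights.T @ v
    return float(v @ av)  # Rayleigh quotient, ||v|| = 1


def centrality_index(
    scores: dict[str, float], central: str
) -> tuple[float, float]:
    """Centrality index of a group: score(C) minus mean score of the rest.

    Returns ``(index_exact, index_table)``; the table variant rounds each
    score to two decimals before differencing.
    """
    if central not in scores:
        raise NetworkError(f"unknown central individual {central!r}")
    if len(scores) < 2:
        raise NetworkError("centrality index needs at least 2 individuals")
    others = [s for lab, s in scores.items() if lab != central]
    exact = scores[central] - float(np.mean(others))
    rounded = round(scores[central], 2) - float(np.mean([round(s, 2) for s in others]))
    return exact, rounded


def identify_central(net: SocialNetwork, tol: float = UNIQUENESS_TOL) -> str | None:
    """Most central individual, or ``None`` when the maximum is not unique."""
    scores = eigenvector_centrality(net)
    vals = np.array(list(scores.values()))
    order = np.argsort(vals)[::-1]
    if len(vals) > 1 and vals[order[0]] - vals[order[1]] < tol:
        return None
    return list(scores.keys())[order[0]]


def compute_centrality(net: SocialNetwork) -> CentralityResult:
    """Scores, central individual and both index variants in one pass."""
    scores = eigenvector_centrality(net)
    central = identify_central(net)
    if central is None:
        exact = table = None
    else:
        exact, table = centrality_index(scores, central)
    return CentralityResult(
        scores=scores,
        central=central,
        index_exact=exact,
        index_table=table,
        eigenvalue=_dominant_eigenvalue(net, scores),
    )
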