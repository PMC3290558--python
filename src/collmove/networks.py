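"""Weighted social networks for the departure model.

A group of ``n`` individuals is represented by a directed, weighted
affiliation matrix ``r(i, k)``: row ``i`` is the *giver*, column ``k`` the
*receiver*, and each individual distributes a fixed unit budget of social
interaction over its group mates (every row sums to one, the diagonal is
zero).  The parameterized "continuum" family interpolates between the two
extreme group organizations:

* the **star** network — every non-central individual directs its whole
  budget to a single central individual ``C`` (extreme centralization);
* the **equal** network — every dyad carries the same weight
  ``1/(n-1)`` (extreme decentralization).

Between the two, the single parameter ``r_cC`` (the affiliation of each
non-central individual ``c`` toward ``C``) slides from 1 down to
``1/(n-1)``; whatever the network, ``C`` spreads its own budget evenly,
``r(C, c) = 1/(n-1)``.  A path-topology "chain" network and a connected
Erdős–Rényi "random" network complete the set of group organizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SocialNetwork",
    "NetworkError",
    "NetworkParseError",
    "build_continuum_network",
    "build_chain_network",
    "build_random_network",
    "read_network",
    "write_network",
    "validate_network",
]

#: tolerance on the unit row-sum (interaction budget) invariant
ROW_SUM_TOL = 1e-12


class NetworkError(ValueError):
    """Invalid network structure or construction parameters."""


class NetworkParseError(NetworkError):
    """A network file could not be parsed."""


@dataclass(frozen=True)
class SocialNetwork:
    """Directed weighted affiliation network.

    Parameters
    ----------
    labels
        Ordered individual identifiers.
    weights
        ``n x n`` matrix; entry ``(i, k)`` is the affiliation ``r(i, k)``
        *given* by individual ``i`` *to* individual ``k``.
    central
        Identifier of the central individual, or ``None`` when the network
        has no unique most-central member (e.g. the equal network).
    """

    labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    central: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] != len(self.labels):
            raise NetworkError(
                f"{len(self.labels)} labels for a {w.shape[0]}x{w.shape[1]} matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise NetworkError("duplicate individual labels")
        if self.central is not None and self.central not in self.labels:
            raise NetworkError(f"central individual {self.central!r} not in labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise NetworkError(f"unknown individual {label!r}") from None

    def weight(self, giver: str, receiver: str) -> float:
        return float(self.weights[self.index(giver), self.index(receiver)])

    def row_sums(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def is_connected(self) -> bool:
        """Connectivity through nonzero weights, direction ignored."""
        g = nx.from_numpy_array((self.weights + self.weights.T) > 0)
        return bool(nx.is_connected(g))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)

    def with_central(self, central: str | None) -> "SocialNetwork":
        return replace(self, central=central)


def validate_network(net: SocialNetwork, strict: bool = True) -> list[str]:
    """Check the structural invariants of a constructed network.

    Returns the list of violations.  With ``strict=True`` any violation
    raises :class:`NetworkError`; otherwise violations are emitted as
    warnings so that empirically derived (unnormalized) matrices can still
    be loaded and inspected.
    """
    problems: list[str] = []
    w = net.weights
    if np.any(np.diagonal(w) != 0):
        problems.append("nonzero diagonal (self-affiliation)")
    if np.any(w < 0):
        problems.append("negative weight")
    if np.any(w > 1):
        problems.append("weight above 1")
    bad_rows = np.abs(net.row_sums() - 1.0) > ROW_SUM_TOL
    if np.any(bad_rows):
        names = [net.labels[i] for i in np.flatnonzero(bad_rows)]
        problems.append(f"row sums differ from 1 for {', '.join(names)}")
    if strict and problems:
        raise NetworkError("; ".join(problems))
    for p in problems:
        warnings.warn(f"network invariant violated: {p}", stacklevel=2)
    return problems


def _default_labels(n: int) -> tuple[str, ...]:
    # central individual first, then the non-central ones
    return ("C",) + tuple(f"c{i}" for i in range(1, n))


def build_continuum_network(n: int, r_cC: float) -> SocialNetwork:
    """Network on the centralized-to-decentralized continuum.

    Each non-central individual ``c`` gives ``r_cC`` to the central
    individual ``C`` and splits the remainder evenly over the other
    ``n - 2`` non-central individuals; ``C`` gives ``1/(n-1)`` to every
    ``c``.  ``r_cC = 1`` is the star network, ``r_cC = 1/(n-1)`` the equal
    network.

    Parameters
    ----------
    n
        Group size, at least 3.
    r_cC
        Affiliation of each non-central individual toward the central one,
        in ``[1/(n-1), 1]``.
    """
    if n < 3:
        raise NetworkError(f"continuum networks need n >= 3, got n={n}")
    lo = 1.0 / (n - 1)
    if not (lo - ROW_SUM_TOL <= r_cC <= 1.0 + ROW_SUM_TOL):
        raise NetworkError(
            f"r_cC={r_cC} outside the continuum range [1/(n-1)={lo:.6g}, 1]"
        )
    r_cC = float(min(max(r_cC, lo), 1.0))
    r_cc = (1.0 - r_cC) / (n - 2)
    w = np.full((n, n), r_cc)
    w[:, 0] = r_cC  # everyone gives r_cC to C ...
    w[0, :] = lo  # ... while C spreads its budget evenly
    np.fill_diagonal(w, 0.0)
    labels = _default_labels(n)
    central = None if abs(r_cC - lo) <= ROW_SUM_TOL else "C"
    net = SocialNetwork(labels, w, central=central)
    validate_network(net)
    return net


def build_chain_network(n: int) -> SocialNetwork:
    """Path-topology network: a linear hierarchy.

    Each endpoint gives its full unit budget to its single neighbour;
    interior individuals give half to each of their two neighbours.
    """
    if n < 2:
        raise NetworkError(f"chain networks need n >= 2, got n={n}")
    w = np.zeros((n, n))
    for i in range(n):
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n]
        for j in nbrs:
            w[i, j] = 1.0 / len(nbrs)
    labels = tuple(f"i{k}" for k in range(1, n + 1))
    net = SocialNetwork(labels, w)
    validate_network(net)
    return net


def build_random_network(
    n: int, p: float = 0.5, seed: int | None = None, max_tries: int = 10_000
) -> SocialNetwork:
    """Connected Erdős–Rényi network with evenly split unit budgets.

    An undirected G(n, p) topology is resampled until connected; each
    individual then divides its budget equally among its neighbours
    (``r(i, k) = 1/degree(i)`` for each neighbour ``k``).
    """
    if n < 2:
        raise NetworkError(f"random networks need n >= 2, got n={n}")
    if not 0.0 < p <= 1.0:
        raise NetworkError(f"edge probability p={p} must be in (0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    else:  # pragma: no cover - p would have to be minuscule
        raise NetworkError(f"no connected G({n}, {p}) graph after {max_tries} tries")
    w = np.zeros((n, n))
    for i in range(n):
        deg = g.degree(i)
        for j in g.neighbors(i):
            w[i, j] = 1.0 / deg
    labels = tuple(f"i{k}" for k in range(1, n + 1))
    net = SocialNetwork(labels, w)
    validate_network(net)
    return net


# ---------------------------------------------------------------------------
# file formats
#
# Adjacency table: delimited text (tab or comma), first row and first column
# carry the labels; cell (i, k) holds r(i, k) with row i the giver.
# Edge list: three columns "giver receiver weight"; absent dyads are zero.
# ---------------------------------------------------------------------------


def write_network(
    net: SocialNetwork, path: str | Path, fmt: str = "adjacency", sep: str = "\t"
) -> None:
    """Write a network as an adjacency table or an edge list."""
    path = Path(path)
    if fmt == "adjacency":
        net.to_frame().to_csv(path, sep=sep, float_format="%.17g")
    elif fmt == "edgelist":
        rows = [
            (gi, rec, f"{net.weights[a, b]:.17g}")
            for a, gi in enumerate(net.labels)
            for b, rec in enumerate(net.labels)
            if net.weights[a, b] != 0.0
        ]
        with path.open("w") as fh:
            fh.write("giver" + sep + "receiver" + sep + "weight\n")
            for r in rows:
                fh.write(sep.join(r) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (adjacency or edgelist)")


def _sniff_sep(line: str) -> str:
    return "\t" if "\t" in line else ("," if "," in line else None)  # type: ignore[return-value]


def read_network(
    path: str | Path, fmt: str | None = None, central: str | None = None
) -> SocialNetwork:
    """Read a network from an adjacency table or weighted edge list.

    The format is sniffed from the header when ``fmt`` is not given.
    Structural invariants (row sums, diagonal) are checked with warnings
    rather than errors so that unnormalized empirical matrices load.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    sep = _sniff_sep(header) or r"\s+"
    first = [t for t in header.replace(",", "\t").split() if t]
    if fmt is None:
        fmt = "edgelist" if [t.lower() for t in first[:3]] == ["giver", "receiver", "weight"] else "adjacency"
    if fmt == "edgelist":
        df = pd.read_csv(path, sep=sep, engine="python")
        # label order follows first appearance so write/read round-trips
        labels = list(
            dict.fromkeys(
                list(df["giver"].astype(str)) + list(df["receiver"].astype(str))
            )
        )
        idx = {lab: i for i, lab in enumerate(labels)}
        w = np.zeros((len(labels), len(labels)))
        for row in df.itertuples(index=False):
            wt = float(row.weight)
            if wt < 0:
                raise NetworkParseError(
                    f"negative weight on dyad {row.giver!r} -> {row.receiver!r}"
                )
            w[idx[str(row.giver)], idx[str(row.receiver)]] = wt
        net = SocialNetwork(tuple(labels), w, central=central)
    elif fmt == "adjacency":
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
        if df.shape[0] != df.shape[1]:
            raise NetworkParseError(
                f"adjacency table is not square: {df.shape[0]} rows x {df.shape[1]} columns"
            )
        rows = [str(x) for x in df.index]
        cols = [str(x) for x in df.columns]
        if rows != cols:
            raise NetworkParseError(
                f"row labels {rows} do not match column labels {cols}"
            )
        w = df.to_numpy(dtype=float)
        neg = np.argwhere(w < 0)
        if neg.size:
            i, k = neg[0]
            raise NetworkParseError(
                f"negative weight on dyad {rows[i]!r} -> {cols[k]!r}"
            )
        net = SocialNetwork(tuple(rows), w, central=central)
    else:
        raise ValueError(f"unknown format {fmt!r} (adjacency or edgelist)")
    validate_network(net, strict=False)
    return net
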