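"""Directed mobility networks from origin-destination trip records.

The baseline mobility graph is built by averaging daily OD trip counts over a
date window, separating intra-tile trips (self-loops) from inter-tile flows,
and restricting to the largest strongly connected component (LSCC).  A
continuous- or discrete-time random walk on the resulting graph provides the
descriptors used throughout the package: the row-stochastic transition matrix
``M = D_out^+ A``, its stationary distribution ``pi`` (PageRank without
teleportation), and the random-walk Laplacian ``L = I - D_out^+ A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import linregress

from .exceptions import (
    InvalidParameterError,
    MalformedRecordsError,
    NumericalError,
    UndefinedStatisticError,
)

__all__ = [
    "FlowGraph",
    "RandomWalkModel",
    "read_flow_csv",
    "build_baseline_graph",
    "stationary_distribution",
    "pairwise_relative_asymmetry",
    "detailed_balance_deviation",
    "centrality_diagnostics",
]


@dataclass
class FlowGraph:
    """A directed, weighted mobility network.

    Attributes
    ----------
    nodes : tuple of str
        Tile identifiers in fixed (lexicographic) order.
    A : ndarray, shape (N, N)
        Non-negative inter-tile flow matrix with zero diagonal.
    intra : ndarray, shape (N,)
        Intra-tile (self-loop) flows, the diagonal of the loopful matrix
        ``A_tilde = A + diag(intra)``.
    n_dropped : int
        Nodes discarded when restricting to the LSCC.
    """

    nodes: tuple
    A: np.ndarray
    intra: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        self.nodes = tuple(str(n) for n in self.nodes)
        self.A = np.asarray(self.A, dtype=float)
        self.intra = np.asarray(self.intra, dtype=float)
        n = len(self.nodes)
        if self.A.shape != (n, n):
            raise InvalidParameterError("A must be N x N for N nodes")
        if self.intra.shape != (n,):
            raise InvalidParameterError("intra must have length N")
        if np.any(self.A < 0) or np.any(self.intra < 0):
            raise InvalidParameterError("flows must be non-negative")
        if np.any(np.diag(self.A) != 0):
            raise InvalidParameterError("A must have a zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def d_out(self) -> np.ndarray:
        """Out-strengths d_out = A 1."""
        return self.A.sum(axis=1)

    @property
    def A_tilde(self) -> np.ndarray:
        """Flow matrix including intra-tile trips on the diagonal."""
        return self.A + np.diag(self.intra)

    @property
    def total_flow(self) -> float:
        return float(self.A.sum() + self.intra.sum())

    def is_strongly_connected(self) -> bool:
        ncomp, _ = connected_components(
            sparse.csr_matrix(self.A > 0), connection="strong"
        )
        return ncomp == 1

    def to_edge_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Sparse edge-list and node-index frames (round-trip serialisation)."""
        i, j = np.nonzero(self.A)
        edges = pd.DataFrame(
            {
                "origin": [self.nodes[a] for a in i],
                "destination": [self.nodes[b] for b in j],
                "trips": self.A[i, j],
            }
        )
        nodes = pd.DataFrame(
            {"node": self.nodes, "index": range(self.n_nodes), "intra": self.intra}
        )
        return edges, nodes


@dataclass
class RandomWalkModel:
    """Random-walk descriptors of a :class:`FlowGraph`.

    ``M`` is row-stochastic, ``pi`` the unique stationary distribution
    (``pi M = pi``), ``Pi = diag(pi)`` and ``L = I - D_out^+ A`` the
    random-walk Laplacian, so ``pi L = 0``.
    """

    M: np.ndarray
    pi: np.ndarray
    L: np.ndarray
    graph: FlowGraph = field(repr=False)

    @property
    def Pi(self) -> np.ndarray:
        return np.diag(self.pi)

    @classmethod
    def from_graph(cls, graph: FlowGraph) -> "RandomWalkModel":
        d = graph.d_out
        if np.any(d <= 0):
            raise InvalidParameterError(
                "all nodes need positive out-strength (is the graph an LSCC?)"
            )
        M = graph.A / d[:, None]
        L = np.eye(graph.n_nodes) - M
        pi = stationary_distribution(graph)
        return cls(M=M, pi=pi, L=L, graph=graph)


# ---------------------------------------------------------------------------
# OD record ingestion
# ---------------------------------------------------------------------------

_REQUIRED = ("date", "origin", "destination", "trips")


def read_flow_csv(path) -> pd.DataFrame:
    """Read the OD-flow CSV dialect ``date,origin,destination,trips``.

    Malformed rows (missing fields, non-numeric or negative trips) raise
    :class:`MalformedRecordsError` listing the offending 1-based data line
    numbers.
    """
    df = pd.read_csv(path, dtype={"origin": str, "destination": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise MalformedRecordsError(f"missing columns: {missing}")
    trips = pd.to_numeric(df["trips"], errors="coerce")
    bad = trips.isna() | (trips < 0) | df["origin"].isna() | df["destination"].isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header plus 1-based
        raise MalformedRecordsError(
            f"{bad.sum()} malformed rows at lines {lines[:20]}", lines=lines
        )
    out = df.copy()
    out["trips"] = trips.astype(float)
    out["date"] = pd.to_datetime(out["date"]).dt.normalize()
    return out


def build_baseline_graph(
    flow_records: pd.DataFrame,
    date_window: tuple | Sequence | None = None,
) -> FlowGraph:
    """Average OD records over a window and restrict to the LSCC.

    Flows are averaged per ordered pair over the *days of the window*: a day
    with no record for a pair contributes zero trips to that pair's mean.
    Self-loop records become the ``intra`` vector; the inter-tile graph is
    then restricted to its largest strongly connected component (ties between
    equal-size components broken by total edge weight).

    Parameters
    ----------
    flow_records : DataFrame
        Columns ``origin, destination, trips`` and, if a window is given,
        ``date``.
    date_window : (start, end) or explicit sequence of dates, optional
        Inclusive date window.  ``None`` averages over all distinct dates
        present (or treats the table as a single snapshot if undated).
    """
    df = flow_records
    for col in ("origin", "destination", "trips"):
        if col not in df.columns:
            raise MalformedRecordsError(f"missing column {col!r}")
    if "date" in df.columns and df["date"].notna().any():
        dates = pd.to_datetime(df["date"]).dt.normalize()
        if date_window is None:
            days = pd.Index(dates.unique())
        elif isinstance(date_window, tuple) and len(date_window) == 2:
            start, end = pd.Timestamp(date_window[0]), pd.Timestamp(date_window[1])
            days = pd.Index(dates[(dates >= start) & (dates <= end)].unique())
        else:
            days = pd.DatetimeIndex([pd.Timestamp(d) for d in date_window])
        if len(days) == 0:
            raise InvalidParameterError("empty date window")
        df = df.loc[dates.isin(days)]
        n_days = len(days)
    else:
        n_days = 1
    if df.empty:
        raise InvalidParameterError("no records in window")

    # mean over window days: sum of trips / number of days in the window
    agg = (
        df.groupby(["origin", "destination"], sort=False)["trips"].sum() / n_days
    ).reset_index()
    return _graph_from_mean_flows(agg)


def _graph_from_mean_flows(agg: pd.DataFrame) -> FlowGraph:
    nodes = sorted(set(agg["origin"]).union(agg["destination"]))
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    i = agg["origin"].map(index).to_numpy()
    j = agg["destination"].map(index).to_numpy()
    w = agg["trips"].to_numpy(dtype=float)

    loop = i == j
    intra_full = np.zeros(n)
    np.add.at(intra_full, i[loop], w[loop])
    A_full = sparse.coo_matrix((w[~loop], (i[~loop], j[~loop])), shape=(n, n)).toarray()

    ncomp, comp = connected_components(
        sparse.csr_matrix(A_full > 0), connection="strong"
    )
    sizes = np.bincount(comp, minlength=ncomp)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:  # tie: keep the component carrying the most flow
        weights = [A_full[np.ix_(comp == c, comp == c)].sum() for c in best]
        keep = best[int(np.argmax(weights))]
    else:
        keep = best[0]
    mask = comp == keep
    if mask.sum() < 2 or A_full[np.ix_(mask, mask)].sum() == 0:
        raise InvalidParameterError("largest strongly connected component is empty")

    kept_nodes = [nodes[k] for k in np.flatnonzero(mask)]
    return FlowGraph(
        nodes=kept_nodes,
        A=A_full[np.ix_(mask, mask)],
        intra=intra_full[mask],
        n_dropped=int(n - mask.sum()),
    )


# ---------------------------------------------------------------------------
# random-walk descriptors
# ---------------------------------------------------------------------------


def stationary_distribution(graph: FlowGraph) -> np.ndarray:
    """Stationary distribution of the discrete random walk ``M = D_out^+ A``.

    Solved as the dense linear system ``pi (M - I) = 0`` with the
    normalisation ``sum(pi) = 1`` replacing one equation; robust to periodic
    chains where power iteration fails.
    """
    d = graph.d_out
    if np.any(d <= 0):
        raise InvalidParameterError("zero out-strength node: not an LSCC")
    M = graph.A / d[:, None]
    n = graph.n_nodes
    # (M^T - I) pi^T = 0 with last row replaced by the normalisation
    S = M.T - np.eye(n)
    S[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(S, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular stationary system: {exc}")
    resid = np.max(np.abs(pi @ M - pi))
    if resid > 1e-8 or np.any(pi < -1e-10):
        raise NumericalError(
            f"ill-conditioned stationary solve: residual {resid:.2e}, "
            f"cond {np.linalg.cond(S):.2e}"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def pairwise_relative_asymmetry(
    graph: FlowGraph, quantiles: Sequence[float] = (0.25, 0.5, 0.75)
) -> dict:
    """Pairwise relative asymmetry PRA_ij = |A_ij - A_ji| / (A_ij + A_ji).

    Defined for unordered pairs with positive total flow; PRA = 1 marks a
    one-way connection.  Returns per-pair values, requested quantiles of the
    distribution and the count of one-way pairs.
    """
    A = graph.A
    iu, ju = np.triu_indices(graph.n_nodes, k=1)
    tot = A[iu, ju] + A[ju, iu]
    sel = tot > 0
    pra = np.abs(A[iu, ju] - A[ju, iu])[sel] / tot[sel]
    pairs = {
        (graph.nodes[a], graph.nodes[b]): float(v)
        for a, b, v in zip(iu[sel], ju[sel], pra)
    }
    return {
        "pairs": pairs,
        "values": pra,
        "quantiles": {q: float(np.quantile(pra, q)) for q in quantiles}
        if pra.size
        else {},
        "n_one_way": int(np.sum(pra == 1.0)),
    }


def detailed_balance_deviation(model: RandomWalkModel) -> float:
    """Relative Frobenius deviation from detailed balance.

    Returns ``||Pi M - (Pi M)^T||_F / ||Pi M||_F``; zero iff the stationary
    chain is reversible.
    """
    PM = model.pi[:, None] * model.M
    return float(np.linalg.norm(PM - PM.T) / np.linalg.norm(PM))


def centrality_diagnostics(graph: FlowGraph, model: RandomWalkModel) -> dict:
    """R^2 of simple linear regressions pi ~ d_out and pi ~ intra."""
    if graph.n_nodes < 3:
        raise InvalidParameterError("need at least 3 nodes for a regression")
    out = {}
    for name, x in (("d_out", graph.d_out), ("intra", graph.intra)):
        if np.ptp(x) == 0:
            raise UndefinedStatisticError(f"regressor {name!r} has zero variance")
        out[f"r2_pi_{name}"] = float(linregress(x, model.pi).rvalue ** 2)
    return out
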