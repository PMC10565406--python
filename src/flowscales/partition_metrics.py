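"""Partition similarity and flow-containment statistics.

Two families of measures:

* information-theoretic partition comparison — variation of information
  (VI), joint entropy, and their ratio the normalised variation of
  information (NVI), a universal metric on partitions in [0, 1] with 0 for
  identical partitions;
* flow containment — per-community coverage ``C_k``, flow-weighted partition
  coverage ``C``, per-node containment ``NC_i`` and its average ``NC``,
  quantifying how much mobility stays inside the communities of a partition.

Entropies use natural logarithms throughout (NVI, a ratio, is base
invariant) with uniform weight per node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .exceptions import InvalidParameterError
from .mobility_graph import FlowGraph
from .partition import Partition

__all__ = [
    "ContainmentReport",
    "entropy_of_partition",
    "variation_of_information",
    "nvi",
    "containment",
    "compare_to_reference",
    "rank_sum_compare",
]


def _joint_counts(p: Partition, q: Partition) -> np.ndarray:
    """Contingency table of labels after aligning the two partitions."""
    if (p.nodes is None) != (q.nodes is None):
        raise InvalidParameterError(
            "cannot align a positional partition with a node-labelled one"
        )
    if p.nodes is not None:
        if set(p.nodes) != set(q.nodes):
            raise InvalidParameterError("partitions are on different node sets")
        qa = q.aligned_labels(p.nodes)
    else:
        if len(p) != len(q):
            raise InvalidParameterError("positional partitions differ in length")
        qa = q.labels
    pa = p.labels
    table = np.zeros((p.n_communities, q.n_communities))
    np.add.at(table, (pa, qa), 1.0)
    return table / len(p)


def _entropy(prob: np.ndarray) -> float:
    p = prob[prob > 0]
    return float(-(p * np.log(p)).sum())


def entropy_of_partition(p: Partition) -> float:
    """Shannon entropy (nats) of the community-size distribution."""
    counts = np.bincount(p.labels).astype(float)
    return _entropy(counts / counts.sum())


def variation_of_information(p: Partition, q: Partition) -> float:
    """VI(p, q) = 2 H(p, q) - H(p) - H(q), in nats."""
    joint = _joint_counts(p, q)
    h_joint = _entropy(joint.ravel())
    return 2.0 * h_joint - _entropy(joint.sum(1)) - _entropy(joint.sum(0))


def nvi(p: Partition, q: Partition) -> float:
    """Normalised variation of information VI / joint entropy, in [0, 1].

    Defined as 0 when the joint entropy vanishes (both partitions trivial).
    """
    joint = _joint_counts(p, q)
    h_joint = _entropy(joint.ravel())
    if h_joint == 0.0:
        return 0.0
    v = 2.0 * h_joint - _entropy(joint.sum(1)) - _entropy(joint.sum(0))
    return float(min(max(v / h_joint, 0.0), 1.0))


# ---------------------------------------------------------------------------
# flow containment
# ---------------------------------------------------------------------------


@dataclass
class ContainmentReport:
    """Flow-containment statistics of a partition on a mobility graph.

    ``F = H^T A_tilde H`` is the c x c lumped flow matrix (self-loops
    included), ``d_hat = F 1`` its out-strengths.  ``C_k = F_kk / d_hat_k``
    is the coverage of community k; ``C`` the d_hat-weighted average.
    ``NC_i`` is the share of node i's *inter-tile* outflow that stays in its
    community; ``NC`` the per-node average.
    """

    F: np.ndarray
    d_hat: np.ndarray
    community_coverage: np.ndarray
    coverage: float
    nodal_containment: np.ndarray
    avg_nodal_containment: float

    def community_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "community": range(len(self.d_hat)),
                "coverage": self.community_coverage,
                "out_strength": self.d_hat,
            }
        )

    def node_frame(self, nodes: Sequence[str] | None = None) -> pd.DataFrame:
        n = len(self.nodal_containment)
        return pd.DataFrame(
            {
                "node": list(nodes) if nodes is not None else list(range(n)),
                "nodal_containment": self.nodal_containment,
            }
        )


def containment(graph: FlowGraph, p: Partition) -> ContainmentReport:
    """Coverage and nodal-containment statistics of ``p`` on ``graph``.

    Coverage uses the loopful matrix ``A_tilde = A + diag(intra)``; nodal
    containment uses inter-tile flows only (``d_i = (A 1)_i``).  Nodes with
    zero inter-tile outflow are excluded from the NC average with a warning.
    """
    labels = p.aligned_labels(graph.nodes)
    H = np.zeros((graph.n_nodes, labels.max() + 1))
    H[np.arange(graph.n_nodes), labels] = 1.0

    F = H.T @ graph.A_tilde @ H
    d_hat = F.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C_k = np.where(d_hat > 0, np.diag(F) / np.where(d_hat > 0, d_hat, 1.0), 0.0)
    C = float((d_hat * C_k).sum() / d_hat.sum())

    d = graph.d_out
    internal_out = (graph.A * (labels[:, None] == labels[None, :])).sum(axis=1)
    ok = d > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} nodes with zero inter-tile outflow excluded from NC",
            stacklevel=2,
        )
    NC_i = np.zeros(graph.n_nodes)
    NC_i[ok] = internal_out[ok] / d[ok]
    NC = float(NC_i[ok].mean())
    return ContainmentReport(
        F=F,
        d_hat=d_hat,
        community_coverage=C_k,
        coverage=C,
        nodal_containment=NC_i,
        avg_nodal_containment=NC,
    )


def compare_to_reference(scan, ref: Partition) -> dict:
    """NVI between each scanned partition and a reference partition.

    Nodes of the scan absent from the reference are dropped from both sides
    (with a count), mirroring incomplete administrative coverage.  Returns
    the NVI-vs-scale curve and the best-matching scale (argmin).
    """
    if scan.nodes is None:
        raise InvalidParameterError("scan carries no node identifiers")
    if ref.nodes is None:
        raise InvalidParameterError("reference partition needs node identifiers")
    common = [n for n in scan.nodes if n in set(ref.nodes)]
    if not common:
        raise InvalidParameterError("no overlap between scan and reference nodes")
    n_dropped = len(scan.nodes) - len(common)
    ref_r = ref.restrict(common)
    keep = np.array([n in set(common) for n in scan.nodes])
    curve = []
    for part in scan.partitions:
        sub = Partition(part.labels[keep], nodes=common)
        curve.append(nvi(sub, ref_r))
    curve = np.asarray(curve)
    best = int(np.argmin(curve))
    return {
        "scales": scan.scales,
        "nvi": curve,
        "best_index": best,
        "best_scale": float(scan.scales[best]),
        "best_nvi": float(curve[best]),
        "n_dropped": n_dropped,
    }


def rank_sum_compare(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney rank-sum test between two samples.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.  If every value in both
    samples is identical the test is degenerate: p = 1 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return {"u": x.size * y.size / 2.0, "p_value": 1.0, "degenerate": True}
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return {"u": float(res.statistic), "p_value": float(res.pvalue), "degenerate": False}
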