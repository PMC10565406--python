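"""Markov-stability multiscale community detection.

The Markov stability of a partition with indicator matrix ``H`` at Markov
scale ``r`` is the trace objective

    MS(r, H) = Tr[ H^T (Pi exp(-L r) - pi^T pi) H ],

the probability that a random walker started at stationarity inside a
community is found in the same community a diffusion time ``r`` later, minus
the stationary baseline.  Small ``r`` favours fine partitions; large ``r``
coarse ones.  Scales are reported as ``s = log10(r)``.

The objective is optimised with a generalised Louvain algorithm operating
directly on the dense quality matrix ``Q(r)``; directionality of the
underlying network enters through ``L`` and ``pi``, and moves are evaluated
on the symmetrised matrix (the trace objective is invariant to
symmetrisation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .exceptions import InvalidParameterError
from .mobility_graph import RandomWalkModel
from .partition import Partition

__all__ = [
    "Partition",
    "ScaleScan",
    "quality_matrix",
    "partition_quality",
    "louvain_partition",
    "scan",
]

#: largest network handled densely; exp(-Lr) is dense regardless of A's sparsity
MAX_DENSE_NODES = 2000


def quality_matrix(model: RandomWalkModel, r: float) -> np.ndarray:
    """Quality matrix ``Q(r) = Pi exp(-L r) - pi^T pi``.

    ``r = 0`` returns the analytic limit ``Pi - pi^T pi``.  The matrix
    exponential uses scaling-and-squaring.  All entries of Q sum to zero.
    """
    if r < 0:
        raise InvalidParameterError("Markov scale r must be >= 0")
    n = model.pi.size
    if n > MAX_DENSE_NODES:
        raise InvalidParameterError(
            f"N={n} exceeds the dense-computation cap {MAX_DENSE_NODES}"
        )
    P = np.eye(n) if r == 0 else expm(-model.L * r)
    Q = model.pi[:, None] * P - np.outer(model.pi, model.pi)
    if not np.all(np.isfinite(Q)):
        raise InvalidParameterError("non-finite entries in quality matrix")
    return Q


def partition_quality(Q: np.ndarray, partition: Partition) -> float:
    """Evaluate the trace objective ``Tr[H^T Q H]`` for a partition."""
    labels = partition.labels
    same = labels[:, None] == labels[None, :]
    return float(Q[same].sum())


def _louvain_one_level(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain level on symmetric B: greedy node moves until no gain.

    Ties in gain are broken toward the incumbent community (no move), which
    guarantees termination.
    """
    n = B.shape[0]
    labels = np.arange(n)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = labels[i]
            nc = labels.max() + 1
            comm_sums = np.bincount(labels, weights=B[i], minlength=nc)
            stay = comm_sums[a] - B[i, i]
            comm_sums[a] = -np.inf
            b = int(np.argmax(comm_sums))
            if comm_sums[b] - stay > 1e-14:
                labels[i] = b
                improved = True
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def louvain_partition(
    Q: np.ndarray, seed: int | np.random.SeedSequence
) -> tuple[Partition, float]:
    """Generalised Louvain optimisation of ``Tr[H^T Q H]``.

    Alternates greedy local moves (on the symmetrised gain) with graph
    aggregation until no merge improves the objective.  Deterministic given
    ``seed`` (which only controls node sweep order).

    Returns the partition and its quality.  The single-community partition
    always has quality 0 for a quality matrix from :func:`quality_matrix`
    (its entries sum to zero), so the returned quality is non-negative there.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise InvalidParameterError("Q must be square")
    if not np.all(np.isfinite(Q)):
        raise InvalidParameterError("Q contains NaN or Inf")
    rng = np.random.default_rng(seed)
    B = (Q + Q.T) / 2.0
    n = B.shape[0]
    node_labels = np.arange(n)
    Bc = B
    while True:
        level = _louvain_one_level(Bc, rng)
        if level.max() + 1 == Bc.shape[0]:  # no merges at this level
            break
        node_labels = level[node_labels]
        H = np.zeros((Bc.shape[0], level.max() + 1))
        H[np.arange(Bc.shape[0]), level] = 1.0
        Bc = H.T @ Bc @ H
        if Bc.shape[0] == 1:
            break
    part = Partition(node_labels)
    return part, partition_quality(Q, part)


@dataclass
class ScaleScan:
    """Per-scale optimised partitions with ensemble and cross-scale NVI.

    Attributes
    ----------
    scales : ndarray
        Markov scales ``s = log10(r)``, strictly increasing.
    partitions : list of Partition
        Best-quality partition per scale.
    qualities : ndarray
        Objective value of each best partition.
    nvi_within : ndarray
        Average pairwise NVI over the optimisation ensemble per scale
        (reproducibility of the non-convex optimisation; low = robust).
    nvi_cross : ndarray
        Symmetric m x m NVI between best partitions of scale pairs
        (persistence across scales; low blocks = robust scale ranges).
    """

    scales: np.ndarray
    partitions: list
    qualities: np.ndarray
    nvi_within: np.ndarray
    nvi_cross: np.ndarray
    n_repeats: int
    seed: int
    nodes: tuple | None = None

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def n_communities(self) -> np.ndarray:
        return np.array([p.n_communities for p in self.partitions])

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "scale": self.scales,
                "quality": self.qualities,
                "n_communities": self.n_communities(),
                "nvi_within": self.nvi_within,
            }
        ).to_csv(outdir / "scales.csv", index=False)
        lab = pd.DataFrame(
            {f"s={s:.6g}": p.labels for s, p in zip(self.scales, self.partitions)}
        )
        lab.insert(
            0,
            "node",
            list(self.nodes) if self.nodes else list(range(len(self.partitions[0]))),
        )
        lab.to_csv(outdir / "partitions.csv", index=False)
        pd.DataFrame(self.nvi_cross).to_csv(outdir / "nvi_cross.csv", index=False)
        pd.DataFrame({"nvi_within": self.nvi_within}).to_csv(
            outdir / "nvi_within.csv", index=False
        )
        (outdir / "meta.json").write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "n_repeats": self.n_repeats,
                    "scales": self.scales.tolist(),
                }
            )
        )


def scan(
    model: RandomWalkModel,
    scales: Sequence[float],
    n_repeats: int = 50,
    seed: int = 0,
    max_pairs: int = 1000,
) -> ScaleScan:
    """Optimise Markov stability over a grid of scales.

    For each scale ``s`` (with ``r = 10**s``) the Louvain optimisation is
    repeated ``n_repeats`` times from distinct sub-seeds; the best-quality
    partition is kept.  ``NVI(s)`` averages pairwise NVI over the ensemble
    (all pairs when ``n_repeats <= 50``, else a seeded random subsample of
    ``max_pairs`` pairs); ``NVI(s, s')`` compares best partitions across
    scales.
    """
    from .partition_metrics import nvi  # local import: avoids a cycle

    scales = np.asarray(scales, dtype=float)
    if scales.ndim != 1 or len(scales) < 2 or np.any(np.diff(scales) <= 0):
        raise InvalidParameterError("scales must be strictly increasing, length >= 2")
    if n_repeats < 2:
        raise InvalidParameterError("n_repeats must be >= 2")

    master = np.random.SeedSequence(seed)
    scale_seeds = master.spawn(len(scales))
    pair_rng = np.random.default_rng(master.spawn(1)[0])

    best_parts, best_quals, nvi_within = [], [], []
    for s, ss in zip(scales, scale_seeds):
        Q = quality_matrix(model, 10.0**s)
        ensemble, quals = [], []
        for child in ss.spawn(n_repeats):
            p, q = louvain_partition(Q, child)
            ensemble.append(p)
            quals.append(q)
        k = int(np.argmax(quals))
        best_parts.append(ensemble[k])
        best_quals.append(quals[k])

        m = n_repeats
        if m * (m - 1) // 2 <= max_pairs:
            pairs = [(a, b) for a in range(m) for b in range(a + 1, m)]
        else:
            pairs = [
                tuple(sorted(pair_rng.choice(m, size=2, replace=False)))
                for _ in range(max_pairs)
            ]
        nvi_within.append(
            float(np.mean([nvi(ensemble[a], ensemble[b]) for a, b in pairs]))
        )

    m = len(scales)
    cross = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            cross[a, b] = cross[b, a] = nvi(best_parts[a], best_parts[b])

    return ScaleScan(
        scales=scales,
        partitions=best_parts,
        qualities=np.asarray(best_quals),
        nvi_within=np.asarray(nvi_within),
        nvi_cross=cross,
        n_repeats=n_repeats,
        seed=seed,
        nodes=model.graph.nodes,
    )
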