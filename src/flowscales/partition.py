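"""Node partitions with indicator-matrix semantics.

A :class:`Partition` assigns every node exactly one community label; labels
are normalised to a contiguous 0-based range.  Partitions may carry explicit
node identifiers (tile IDs) so that partitions defined on different node
orderings can be aligned, restricted and compared.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = ["Partition", "read_partition_csv", "write_partition_csv"]


class Partition:
    """A partition of nodes into communities.

    Parameters
    ----------
    labels : sequence of int
        Community label per node.  Labels are relabelled to the contiguous
        range ``0..c-1`` preserving first-appearance order.
    nodes : sequence of str, optional
        Node identifiers aligned with ``labels``.  When omitted the partition
        is positional (index-aligned).
    """

    __slots__ = ("labels", "nodes", "_index")

    def __init__(self, labels: Sequence[int], nodes: Sequence[str] | None = None):
        lab = np.asarray(labels)
        if lab.ndim != 1 or lab.size == 0:
            raise InvalidParameterError("labels must be a non-empty 1-D sequence")
        # contiguous 0-based relabelling, stable in order of first appearance
        _, first_idx, inv = np.unique(lab, return_index=True, return_inverse=True)
        order = np.argsort(np.argsort(first_idx))
        self.labels = order[inv].astype(np.int64)
        if nodes is not None:
            nodes = tuple(str(n) for n in nodes)
            if len(nodes) != lab.size:
                raise InvalidParameterError("nodes and labels length mismatch")
            if len(set(nodes)) != len(nodes):
                raise InvalidParameterError("duplicate node identifiers")
        self.nodes = nodes
        self._index = None if nodes is None else {n: i for i, n in enumerate(nodes)}

    # -- basic properties ---------------------------------------------------

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.labels.shape == other.labels.shape
            and bool(np.all(self.labels == other.labels))
        )

    def __repr__(self) -> str:
        return f"Partition(n={len(self)}, c={self.n_communities})"

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "Partition":
        nodes = sorted(mapping)
        return cls([mapping[n] for n in nodes], nodes=nodes)

    # -- views --------------------------------------------------------------

    def indicator(self) -> np.ndarray:
        """The N x c one-hot indicator matrix H (each row sums to 1)."""
        H = np.zeros((len(self), self.n_communities))
        H[np.arange(len(self)), self.labels] = 1.0
        return H

    def aligned_labels(self, nodes: Sequence[str]) -> np.ndarray:
        """Labels reordered to match ``nodes``; requires all nodes present."""
        if self.nodes is None:
            if len(nodes) != len(self):
                raise InvalidParameterError(
                    "positional partition length does not match node list"
                )
            return self.labels
        try:
            idx = np.array([self._index[str(n)] for n in nodes])
        except KeyError as exc:
            raise InvalidParameterError(f"node {exc.args[0]!r} missing from partition")
        return self.labels[idx]

    def restrict(self, nodes: Sequence[str]) -> "Partition":
        """Sub-partition on ``nodes`` (all must be present; order preserved)."""
        return Partition(self.aligned_labels(nodes), nodes=nodes)


def read_partition_csv(path) -> Partition:
    """Read a ``node,community`` CSV into a Partition."""
    df = pd.read_csv(path, dtype={"node": str})
    if not {"node", "community"}.issubset(df.columns):
        raise InvalidParameterError("partition CSV must have node,community columns")
    codes = pd.factorize(df["community"])[0]
    return Partition(codes, nodes=df["node"].tolist())


def write_partition_csv(partition: Partition, path) -> None:
    nodes = partition.nodes if partition.nodes is not None else range(len(partition))
    pd.DataFrame({"node": list(nodes), "community": partition.labels}).to_csv(
        path, index=False
    )
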