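"""Parcellation schemes and canonical edge indexing.

A connectome is stored as one row per subject and one column per *edge*,
where an edge is an unordered pair of parcellation regions (i < j) under a
single task condition.  All modules share the canonical upper-triangular,
row-major edge ordering defined here: (0,1), (0,2), ..., (0,n-1), (1,2), ...
Node ids are 0-based in memory and 1-based in files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ParcellationScheme:
    """Coordinate system for all edge sets.

    Parameters
    ----------
    n_nodes
        Number of regions.
    network_of
        Integer array of length ``n_nodes`` mapping region -> network id
        (0-based, contiguous).
    network_names
        Optional display names, one per network.
    """

    n_nodes: int
    network_of: np.ndarray
    network_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        net = np.asarray(self.network_of, dtype=np.intp)
        object.__setattr__(self, "network_of", net)
        if self.n_nodes < 2:
            raise ValueError("parcellation needs at least 2 nodes")
        if net.shape != (self.n_nodes,):
            raise ValueError("network_of must have one entry per node")
        if net.min() < 0:
            raise ValueError("network ids must be nonnegative")
        if not self.network_names:
            object.__setattr__(
                self,
                "network_names",
                tuple(f"N{k + 1}" for k in range(int(net.max()) + 1)),
            )

    @property
    def n_networks(self) -> int:
        return int(self.network_of.max()) + 1

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def edge_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) node arrays for every edge, in canonical order."""
        return np.triu_indices(self.n_nodes, k=1)

    def pair_to_index(self, i, j):
        """Edge position(s) of unordered node pair(s) ``(i, j)``, i != j."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        if np.any(i == j):
            raise ValueError("self-loops have no edge index")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        if np.any(lo < 0) or np.any(hi >= self.n_nodes):
            raise ValueError("node id out of range")
        n = self.n_nodes
        k = lo * (2 * n - lo - 1) // 2 + (hi - lo - 1)
        return k if k.ndim else int(k)

    def index_to_pair(self, k):
        """Inverse of :meth:`pair_to_index`."""
        k = np.asarray(k, dtype=np.int64)
        if np.any(k < 0) or np.any(k >= self.n_edges):
            raise ValueError("edge index out of range")
        ii, jj = self.edge_pairs()
        i, j = ii[k], jj[k]
        if k.ndim:
            return i, j
        return int(i), int(j)


def generate_parcellation(
    n_nodes: int, n_networks: int, seed: int = 0
) -> ParcellationScheme:
    """Deterministic synthetic parcellation with contiguous network blocks.

    Networks are contiguous runs of near-equal size (block sizes differ by at
    most one).  ``seed`` is accepted for interface symmetry with the other
    generators and recorded by callers; the construction itself is seed-free.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    if not 1 <= n_networks <= n_nodes:
        raise ValueError("require 1 <= n_networks <= n_nodes")
    blocks = np.array_split(np.arange(n_nodes), n_networks)
    network_of = np.empty(n_nodes, dtype=np.intp)
    for net_id, block in enumerate(blocks):
        network_of[block] = net_id
    return ParcellationScheme(n_nodes=n_nodes, network_of=network_of)
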