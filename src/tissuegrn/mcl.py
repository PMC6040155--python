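"""Markov Cluster Algorithm (MCL) for module detection on a ranked network.

The directed weighted network is symmetrized (undirected weight = max of the
two directed weights), self-loops are added, and the column-stochastic
transition matrix is alternately expanded (matrix squared) and inflated
(entrywise power, columns renormalized) until it stops changing.  Clusters
are read off the attractor rows of the limit matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genie3 import RankedEdgeList

__all__ = ["ModulePartition", "mcl_cluster", "filter_modules"]


@dataclass
class ModulePartition:
    """Disjoint node modules.

    ``module_of`` maps every node to a module id; ids are contiguous from 1
    and ordered by module size descending (ties by smallest member node id).
    """

    module_of: dict[str, int]
    inflation: float
    prune: float
    iterations: int
    converged: bool = True

    def __post_init__(self) -> None:
        ids = sorted(set(self.module_of.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("module ids must be contiguous from 1")

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.module_of.values():
            out[m] = out.get(m, 0) + 1
        return dict(sorted(out.items()))

    @property
    def n_modules(self) -> int:
        return len(self.sizes)

    def members(self, module_id: int) -> set[str]:
        return {n for n, m in self.module_of.items() if m == module_id}

    def to_tsv(self, path: str | Path) -> None:
        pd.Series(self.module_of, name="module_id").rename_axis("gene") \
            .sort_index().to_csv(path, sep="\t")

    def summary_json(self, path: str | Path, min_size: int = 10) -> None:
        retained, dropped = filter_modules(self, min_size)
        Path(path).write_text(json.dumps({
            "n_modules": self.n_modules,
            "n_nodes": len(self.module_of),
            "inflation": self.inflation,
            "converged": self.converged,
            "iterations": self.iterations,
            f"n_modules_gt_{min_size}": len(retained),
            f"n_modules_le_{min_size}": len(dropped),
        }, indent=2) + "\n")


def _stochastic(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl_cluster(grn: RankedEdgeList, inflation: float = 2.5,
                prune: float = 1e-5, max_iter: int = 200,
                tol: float = 1e-8, binary: bool = False) -> ModulePartition:
    """Partition the network's nodes into modules by Markov clustering.

    The adjacency is symmetrized with the max of the two directed weights
    (or binarized when ``binary``), each node receives a self-loop at its
    max incident weight, and columns are normalized.  Expansion squares the
    matrix; inflation raises entries to ``inflation`` and renormalizes;
    entries below ``prune`` are dropped after each inflation.  Iteration
    stops when the max absolute change falls below ``tol``; hitting
    ``max_iter`` first returns the last state flagged non-converged.

    Nodes claimed by several attractors go to the largest module (ties by
    module id); nodes claimed by none become singletons.
    """
    if len(grn) == 0:
        raise ValueError("network has no edges")
    nodes = sorted(set(grn.edges["regulator"]) | set(grn.edges["target"]))
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    adj = np.zeros((n, n))
    for r, t, w in grn.edges[["regulator", "target", "weight"]].itertuples(index=False):
        i, j = idx[r], idx[t]
        val = 1.0 if binary else float(w)
        adj[i, j] = max(adj[i, j], val)
        adj[j, i] = max(adj[j, i], val)
    loop = adj.max(axis=1)
    loop[loop == 0] = 1.0  # isolated node keeps a unit loop
    np.fill_diagonal(adj, loop)

    m = _stochastic(adj)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = _stochastic(np.linalg.matrix_power(prev, 2) ** inflation)
        m[m < prune] = 0.0
        m = _stochastic(m)
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")

    # attractors = rows with positive diagonal mass
    attractors = np.where(np.diag(m) > 0)[0]
    raw: list[set[int]] = [set(np.nonzero(m[a, :] > 0)[0]) | {a}
                           for a in attractors]
    # attractors sharing an *attractor* node belong to one attractor system:
    # merge those; plain nodes claimed by several systems are resolved below.
    attractor_set = set(attractors)
    merged: list[set[int]] = []
    for cluster in raw:
        overlapping = [c for c in merged if c & cluster & attractor_set]
        for c in overlapping:
            merged.remove(c)
        merged.append(set().union(cluster, *overlapping))

    assigned: dict[int, int] = {}
    order = sorted(range(len(merged)),
                   key=lambda c: (-len(merged[c]), min(merged[c])))
    for rank, c in enumerate(order):
        for node in merged[c]:
            if node not in assigned:  # larger module wins, ties by module id
                assigned[node] = rank
    next_id = len(order)
    for i in range(n):
        if i not in assigned:  # unattached node -> singleton
            assigned[i] = next_id
            next_id += 1

    # renumber contiguously 1.. by size descending, ties by smallest member
    groups: dict[int, list[int]] = {}
    for node, mod in assigned.items():
        groups.setdefault(mod, []).append(node)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    module_of = {nodes[node]: mid
                 for mid, grp in enumerate(ordered, start=1) for node in grp}
    return ModulePartition(module_of, inflation=inflation, prune=prune,
                           iterations=it, converged=converged)


def filter_modules(partition: ModulePartition, min_size: int = 10
                   ) -> tuple[list[int], list[int]]:
    """Split module ids into (retained, dropped) by size.

    A module is retained only when it has strictly more than ``min_size``
    members — "more than 10 genes" keeps sizes of 11 and up at the default.
    """
    retained = [m for m, s in partition.sizes.items() if s > min_size]
    dropped = [m for m, s in partition.sizes.items() if s <= min_size]
    return retained, dropped
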