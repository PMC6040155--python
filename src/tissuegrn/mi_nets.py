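"""Mutual-information comparator networks: CLR and MRNET.

Both methods start from a symmetric matrix of pairwise mutual information
(MI) computed with a plug-in estimator on equal-frequency discretized
expression.  CLR converts each MI value into a background-corrected z-score
pair; MRNET performs per-target maximum-relevance / minimum-redundancy
forward selection.  MI carries no direction, so both directed edges of a
pair inherit the same score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expr import ExpressionMatrix
from .genie3 import RankedEdgeList

__all__ = ["MIMatrix", "mi_matrix", "clr_network", "mrnet_network"]


@dataclass
class MIMatrix:
    """Symmetric gene x gene mutual-information matrix (nats).

    The diagonal holds each gene's plug-in entropy estimate (the
    self-information, which upper-bounds every off-diagonal entry of its
    row).
    """

    values: pd.DataFrame
    bins: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("MI matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("MI values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize into ``bins`` classes of (near-)equal occupancy.

    Ties are broken by position ('first' ranking) so every class is filled
    even for heavily tied data; a constant vector maps to a single class.
    """
    ranks = rankdata(x, method="ordinal") - 1  # 0..n-1
    return np.floor(ranks * bins / len(x)).astype(np.int64)


def _plugin_mi(bx: np.ndarray, by: np.ndarray, bins: int) -> float:
    joint = np.zeros((bins, bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz]
                                           / np.outer(px, py)[nz])))


def mi_matrix(expr: ExpressionMatrix, bins: int | None = None) -> MIMatrix:
    """Pairwise plug-in MI on equal-frequency discretized expression.

    ``bins`` defaults to ceil(sqrt(n_samples)).  Constant genes cannot be
    discretized informatively; their rows (and columns) are zeroed with a
    warning.
    """
    n = len(expr.library_ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if bins is None:
        bins = int(np.ceil(np.sqrt(n)))
    if bins < 2:
        raise ValueError("need at least 2 bins")

    genes = expr.gene_ids
    data = expr.values.to_numpy(dtype=float)
    constant = data.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s); MI rows zeroed")
    coded = np.vstack([_equal_frequency_bins(row, bins) for row in data])

    g = len(genes)
    mi = np.zeros((g, g))
    for i in range(g):
        if constant[i]:
            continue
        for j in range(i, g):
            if constant[j]:
                continue
            mi[i, j] = mi[j, i] = _plugin_mi(coded[i], coded[j], bins)
    return MIMatrix(pd.DataFrame(mi, index=genes, columns=genes), bins)


def _directed_pairs(genes: list[str], regs: list[str]):
    for r in regs:
        for g in genes:
            if g != r:
                yield r, g


def clr_network(mi: MIMatrix, regulators: Iterable[str]) -> RankedEdgeList:
    """Context-likelihood-of-relatedness scores, restricted to TF -> gene edges.

    Each MI value is z-scored against the background MI distribution of both
    of its genes (off-diagonal values of that gene's row); negative z-scores
    are clipped at zero and the edge score is sqrt(z_i^2 + z_j^2).  A
    degenerate background (zero spread) yields z = 0.
    """
    genes = mi.gene_ids
    regs = sorted(set(regulators) & set(genes))
    if not regs:
        raise ValueError("no regulator present in the MI matrix")
    vals = mi.values.to_numpy()
    g = len(genes)
    off = ~np.eye(g, dtype=bool)
    mean = np.array([vals[i, off[i]].mean() for i in range(g)])
    sd = np.array([vals[i, off[i]].std(ddof=0) for i in range(g)])

    def z(i: int, j: int) -> float:
        if sd[i] == 0:
            return 0.0
        return max((vals[i, j] - mean[i]) / sd[i], 0.0)

    idx = {g_: k for k, g_ in enumerate(genes)}
    rows = []
    for r, t in _directed_pairs(genes, regs):
        i, j = idx[r], idx[t]
        rows.append((r, t, float(np.hypot(z(i, j), z(j, i)))))
    df = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    return RankedEdgeList(df, frozenset(regs), provenance=f"clr:B={mi.bins}")


def mrnet_network(mi: MIMatrix, regulators: Iterable[str]) -> RankedEdgeList:
    """Maximum-relevance / minimum-redundancy forward selection per target.

    For each target the first regulator chosen is the one with the largest
    MI to the target (score = that MI); each subsequent regulator's score is
    its relevance minus its mean redundancy (MI) to the regulators already
    selected, and selection stops when the best remaining score is not
    positive.  TF-TF pairs are scored in both directions and both directed
    edges receive the larger of the two scores.
    """
    genes = mi.gene_ids
    regs = sorted(set(regulators) & set(genes))
    if not regs:
        raise ValueError("no regulator present in the MI matrix")
    vals = mi.values
    scores: dict[tuple[str, str], float] = {}
    for target in genes:
        cand = [r for r in regs if r != target]
        if not cand:
            continue
        relevance = vals.loc[cand, target]
        selected: list[str] = []
        remaining = set(cand)
        while remaining:
            best_r, best_s = None, 0.0
            for r in sorted(remaining):
                red = (float(np.mean([vals.loc[r, s] for s in selected]))
                       if selected else 0.0)
                s = float(relevance[r]) - red
                if s > best_s:
                    best_r, best_s = r, s
            if best_r is None:
                break
            scores[(best_r, target)] = best_s
            selected.append(best_r)
            remaining.discard(best_r)

    # direction-symmetric: TF-TF pairs take the max over both orientations
    sym: dict[tuple[str, str], float] = {}
    for (r, t), s in scores.items():
        sym[(r, t)] = max(sym.get((r, t), 0.0), s)
        if t in set(regs):
            sym[(t, r)] = max(sym.get((t, r), 0.0), s)
    rows = [(r, t, s) for (r, t), s in sym.items()]
    df = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    return RankedEdgeList(df, frozenset(regs), provenance=f"mrnet:B={mi.bins}")
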