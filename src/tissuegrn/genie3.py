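"""Directed network inference by regression-tree ensembles.

For every expressed gene, a random forest of regression trees is grown with
the declared transcription factors (TFs) as predictors; the importance of a
TF for a target is the mean, over trees, of the total variance reduction its
splits achieve, per sample.  Concatenating the per-target importances and
sorting yields a globally ranked, directed TF -> target edge list.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .expr import ExpressionMatrix

__all__ = ["GRNConfig", "RankedEdgeList", "target_importances", "infer_grn",
           "top_edges"]


@dataclass(frozen=True)
class GRNConfig:
    """Settings for tree-ensemble network inference.

    ``k_rule`` controls the number of candidate predictors examined per
    split: ``"sqrt"`` (floor of the square root of the number of candidate
    regulators — the tree-ensemble default), ``"all"``, or ``"fixed:m"``
    for an explicit integer m.
    """

    n_trees: int = 1000
    k_rule: str = "sqrt"
    seed: int = 0
    min_samples: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.k_rule not in ("sqrt", "all") and not self.k_rule.startswith("fixed:"):
            raise ValueError(f"unknown k_rule {self.k_rule!r}")

    def max_features(self, n_regulators: int) -> int:
        if self.k_rule == "sqrt":
            return max(1, int(np.sqrt(n_regulators)))
        if self.k_rule == "all":
            return n_regulators
        m = int(self.k_rule.split(":", 1)[1])
        if not 1 <= m <= n_regulators:
            raise ValueError(f"fixed K={m} outside [1, {n_regulators}]")
        return m


@dataclass
class RankedEdgeList:
    """Directed TF -> target edges with a total rank order.

    ``edges`` has columns ``regulator``, ``target``, ``weight`` and is sorted
    by weight descending with ties broken lexicographically by
    (regulator, target) for platform-stable determinism.
    """

    edges: pd.DataFrame
    tf_ids: frozenset
    tissue: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.edges
        if list(df.columns[:3]) != ["regulator", "target", "weight"]:
            raise ValueError("edge frame needs regulator/target/weight columns")
        if (df["weight"].to_numpy() < 0).any():
            raise ValueError("negative edge weights")
        if (df["regulator"] == df["target"]).any():
            raise ValueError("self-edges are not allowed")
        if not set(df["regulator"]).issubset(self.tf_ids):
            raise ValueError("regulator outside the declared TF set")
        if df.duplicated(["regulator", "target"]).any():
            raise ValueError("duplicate (regulator, target) pairs")
        self.edges = _rank_sort(df)

    def __len__(self) -> int:
        return len(self.edges)

    def top(self, k: int) -> "RankedEdgeList":
        return top_edges(self, k)

    def targets_of(self, tf: str) -> set[str]:
        df = self.edges
        return set(df.loc[df["regulator"] == tf, "target"])

    def weight_of(self, tf: str, universe: Iterable[str]) -> pd.Series:
        """Score every gene of ``universe`` by the weight of the tf -> gene
        edge, 0 when no such edge exists."""
        df = self.edges
        w = df.loc[df["regulator"] == tf].set_index("target")["weight"]
        genes = list(universe)
        return w.reindex(genes).fillna(0.0)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    def to_tsv(self, path: str | Path, header: bool = True) -> None:
        self.edges.to_csv(path, sep="\t", index=False, header=header)

    @classmethod
    def from_tsv(cls, path: str | Path, tf_ids: Iterable[str] | None = None,
                 tissue: str = "") -> "RankedEdgeList":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:3]) != ["regulator", "target", "weight"]:
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["regulator", "target", "weight"])
        tfs = frozenset(tf_ids) if tf_ids is not None else frozenset(df["regulator"])
        return cls(df, tfs, tissue=tissue)


def _rank_sort(df: pd.DataFrame) -> pd.DataFrame:
    return (df.sort_values(["weight", "regulator", "target"],
                           ascending=[False, True, True], kind="mergesort")
              .reset_index(drop=True))


def _target_seed(master_seed: int, target: str) -> int:
    """Stable per-target seed so results are independent of scheduling order."""
    digest = hashlib.sha256(target.encode()).digest()
    return (int.from_bytes(digest[:4], "big") ^ (master_seed & 0x7FFFFFFF)) % (2**31)


def target_importances(expr: ExpressionMatrix, regulators: Iterable[str],
                       target: str, config: GRNConfig) -> pd.Series:
    """Importance of each candidate regulator for one target gene.

    The target's expression is standardized to unit variance so importances
    are comparable across targets; a zero-variance target yields an all-zero
    importance map rather than an error.  The target itself (if a TF) is
    excluded from its own candidate regulators.
    """
    regs = sorted(set(regulators) & set(expr.gene_ids) - {target})
    if not regs:
        raise ValueError("no candidate regulators left for target")
    if target not in set(expr.gene_ids):
        raise ValueError(f"target {target!r} not in expression matrix")
    n = len(expr.library_ids)
    if n < config.min_samples:
        raise ValueError(f"need at least {config.min_samples} libraries")

    y = expr.values.loc[target].to_numpy(dtype=float)
    sd = y.std(ddof=0)
    if sd == 0:
        warnings.warn(f"zero-variance target {target!r}; importances all zero")
        return pd.Series(0.0, index=regs)
    y = (y - y.mean()) / sd
    x = expr.values.loc[regs].to_numpy(dtype=float).T

    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features(len(regs)),
        bootstrap=True,
        random_state=_target_seed(config.seed, target),
        n_jobs=1,
    )
    forest.fit(x, y)
    # unnormalized impurity importances = total variance reduction / n samples
    imp = np.zeros(len(regs))
    for est in forest.estimators_:
        imp += est.tree_.compute_feature_importances(normalize=False)
    imp /= config.n_trees
    return pd.Series(imp, index=regs)


def infer_grn(expr: ExpressionMatrix, regulators: Iterable[str],
              config: GRNConfig | None = None, tissue: str = "") -> RankedEdgeList:
    """Infer a globally ranked directed network from an expression matrix.

    Every gene of the matrix is modelled as a target in turn; all candidate
    (regulator, target) pairs are emitted, including zero-importance ones,
    ranked by importance descending.  Both directions between two TFs are
    scored independently.
    """
    config = config or GRNConfig()
    genes = expr.gene_ids
    if not genes or not expr.library_ids:
        raise ValueError("empty expression matrix")
    regs = sorted(set(regulators) & set(genes))
    if not regs:
        raise ValueError("no regulator is expressed")

    frames = []
    for target in genes:
        cand = [r for r in regs if r != target]
        if not cand:
            continue
        imp = target_importances(expr, regs, target, config)
        frames.append(pd.DataFrame({"regulator": imp.index,
                                    "target": target,
                                    "weight": imp.to_numpy()}))
    edges = pd.concat(frames, ignore_index=True)
    prov = hashlib.sha256(
        f"{config.n_trees}|{config.k_rule}|{config.seed}".encode()).hexdigest()[:12]
    return RankedEdgeList(edges, frozenset(regs), tissue=tissue, provenance=prov)


def top_edges(grn: RankedEdgeList, k: int) -> RankedEdgeList:
    """First ``k`` edges under the total order (weight desc, then regulator,
    target lexicographic)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(grn):
        warnings.warn(f"requested top {k} of {len(grn)} edges; returning all")
        k = len(grn)
    return RankedEdgeList(grn.edges.iloc[:k].copy(), grn.tf_ids,
                          tissue=grn.tissue, provenance=grn.provenance)
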