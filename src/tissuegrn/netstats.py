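"""Degree-centrality, cross-tissue and topology analyses of ranked networks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expr import set_overlaps
from .genie3 import RankedEdgeList, top_edges

__all__ = [
    "DegreeTable", "PowerLawFit", "LinearFit",
    "out_degrees", "degree_table", "degree_variability", "key_tfs",
    "edge_overlap", "degree_vs_expression", "powerlaw_fit",
    "neighborhood_connectivity_fit",
]


@dataclass
class DegreeTable:
    """TF x tissue out-degree counts at a stated edge cutoff."""

    degrees: pd.DataFrame  # index TF, columns tissues, int
    cutoff: int

    def __post_init__(self) -> None:
        if (self.degrees.to_numpy() < 0).any():
            raise ValueError("negative degrees")


@dataclass
class PowerLawFit:
    """Least-squares fit of log frequency against log degree."""

    exponent: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def out_degrees(grn: RankedEdgeList, k_cutoff: int,
                tf_ids: Iterable[str] | None = None) -> pd.Series:
    """Per-TF count of outgoing edges within the top ``k_cutoff`` edges.

    TFs of ``tf_ids`` (default: the network's declared TF set) with no edge
    report 0.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub = top_edges(grn, min(k_cutoff, len(grn)))
    tfs = sorted(tf_ids) if tf_ids is not None else sorted(grn.tf_ids)
    tally = sub.edges["regulator"].value_counts()
    return tally.reindex(tfs).fillna(0).astype(int)


def degree_table(networks: Mapping[str, RankedEdgeList],
                 k_cutoff: int) -> DegreeTable:
    """Assemble the TF x tissue degree table at one cutoff."""
    tfs = sorted(set().union(*(g.tf_ids for g in networks.values())))
    cols = {t: out_degrees(g, k_cutoff, tfs) for t, g in networks.items()}
    return DegreeTable(pd.DataFrame(cols), k_cutoff)


def degree_variability(table: DegreeTable, top_n: int = 100,
                       min_range: int = 500) -> pd.DataFrame:
    """Cross-tissue degree variability per TF.

    CV = (sample standard deviation / mean) x 100 across tissues.  TFs with
    mean degree 0 have an undefined CV and are excluded (flagged via the
    ``cv`` column being NaN).  The selected set is the ``top_n`` TFs by CV
    among those whose max - min degree is at least ``min_range``; for each,
    the tissue with the largest degree is reported.

    Returns a DataFrame indexed by TF with columns ``cv``, ``mean``,
    ``range``, ``max_tissue``, ``selected``.
    """
    d = table.degrees
    if d.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    cv = pd.Series(np.where(mean > 0, sd / mean * 100.0, np.nan),
                   index=d.index)
    rng = d.max(axis=1) - d.min(axis=1)
    out = pd.DataFrame({
        "cv": cv,
        "mean": mean,
        "range": rng,
        "max_tissue": d.idxmax(axis=1),
    })
    eligible = out[(out["range"] >= min_range) & out["cv"].notna()]
    chosen = set(eligible.sort_values("cv", ascending=False).index[:top_n])
    out["selected"] = [tf in chosen for tf in out.index]
    return out.sort_values("cv", ascending=False)


def key_tfs(table: DegreeTable, threshold: int = 2000
            ) -> tuple[dict[str, set[str]], dict[frozenset, int]]:
    """Key TFs per tissue (degree strictly greater than ``threshold``) plus
    the cross-tissue exact-combination sharing counts."""
    d = table.degrees
    sets = {t: set(d.index[d[t] > threshold]) for t in d.columns}
    return sets, set_overlaps(sets)


def edge_overlap(networks: Mapping[str, RankedEdgeList], k_cutoff: int
                 ) -> tuple[dict[frozenset, int], pd.DataFrame]:
    """Cross-tissue overlap of directed top-k edge sets.

    Returns (exact-combination counts over every tissue combination, the
    fully-shared edge list as a DataFrame with regulator and target columns).
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    edge_sets = {}
    for t, g in networks.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edge_sets[t] = top_edges(g, min(k_cutoff, len(g))).edge_set()
    counts = set_overlaps(edge_sets)
    shared = set.intersection(*edge_sets.values())
    shared_df = pd.DataFrame(sorted(shared), columns=["regulator", "target"])
    return counts, shared_df


def degree_vs_expression(degrees: pd.Series, expression: pd.Series) -> LinearFit:
    """Ordinary least squares of TF out-degree on TF mean expression."""
    joint = pd.concat([degrees.rename("k"), expression.rename("x")],
                      axis=1).dropna()
    if len(joint) < 3:
        raise ValueError("need at least 3 TFs with defined values")
    if joint["x"].nunique() == 1:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(joint["x"], joint["k"])
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2),
                     p_value=float(res.pvalue), n=len(joint))


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> PowerLawFit:
    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PowerLawFit(exponent=float(slope), intercept=float(intercept),
                       r_squared=min(r2, 1.0), n_points=len(x))


def powerlaw_fit(degrees: Sequence[int] | pd.Series) -> PowerLawFit:
    """Power-law fit of the out-degree distribution.

    The empirical frequency of each positive degree value is regressed on
    degree in log-log space by least squares; zero-degree nodes are excluded
    (their log is undefined).  The fitted slope estimates the power-law
    exponent (negative for a decaying distribution).
    """
    d = np.asarray(degrees, dtype=int)
    d = d[d > 0]
    values, counts = np.unique(d, return_counts=True)
    if len(values) < 3:
        raise ValueError("need at least 3 distinct positive degrees")
    freq = counts / counts.sum()
    return _loglog_fit(values.astype(float), freq)


def neighborhood_connectivity_fit(grn: RankedEdgeList,
                                  k_cutoff: int | None = None) -> PowerLawFit:
    """Power-law fit of average neighborhood connectivity against degree.

    The top-k network is treated as an undirected graph; for every degree k
    present, the mean over k-degree nodes of their neighbors' mean degree is
    computed and the (degree, connectivity) points are fitted in log-log
    space, as for the degree distribution.
    """
    sub = grn if k_cutoff is None else top_edges(grn, min(k_cutoff, len(grn)))
    g = nx.Graph()
    g.add_edges_from(zip(sub.edges["regulator"], sub.edges["target"]))
    conn = nx.average_degree_connectivity(g)
    pts = [(k, v) for k, v in conn.items() if k > 0 and v > 0]
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct degrees")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    return _loglog_fit(x, y)
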