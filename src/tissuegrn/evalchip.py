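"""Evaluation of ranked networks against ChIP-derived positive target sets.

Positive sets come either from a published target-gene list or from peak
summits assigned to genes within a fixed window (default 10 kb of the gene
span, strand-agnostic).  A TF's predicted ranking over a gene universe is
summarized by AUROC (Mann-Whitney concordance with ties counted 1/2) and
AUPR (step-wise precision-recall integration), compared against a
label-permutation baseline, and set overlaps are tested with one-tail
Fisher's exact tests.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .genie3 import RankedEdgeList, top_edges

__all__ = [
    "GeneAnnotation", "PeakSet", "PositiveTargetSet", "EvalReport",
    "assign_peak_targets", "predicted_targets", "evaluate_ranking",
    "permutation_baseline", "fisher_overlap", "size_sweep",
    "auroc_score", "aupr_score",
]


@dataclass
class GeneAnnotation:
    """Gene spans: per gene chromosome, start, end (1-based inclusive), strand."""

    table: pd.DataFrame  # index gene_id; columns chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        need = {"chrom", "start", "end", "strand"}
        if not need.issubset(t.columns):
            raise ValueError(f"annotation needs columns {sorted(need)}")
        if t.index.has_duplicates:
            raise ValueError("duplicate gene IDs in annotation")
        if (t["start"] > t["end"]).any():
            raise ValueError("gene with start > end")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gid, row in self.table.iterrows():
                attrs = f"ID={gid}"
                fh.write(f"{row.chrom}\ttissuegrn\tgene\t{row.start}\t{row.end}"
                         f"\t.\t{row.strand}\t.\t{attrs}\n")

    @classmethod
    def from_gff3(cls, path: str | Path,
                  feature: str = "gene") -> "GeneAnnotation":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != feature:
                    continue
                m = re.search(r"(?:^|;)ID=([^;]+)", f[8])
                if not m:
                    raise ValueError(f"feature without ID attribute: {line!r}")
                rows.append((m.group(1), f[0], int(f[3]), int(f[4]), f[6]))
        df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                         "strand"]).set_index("gene")
        return cls(df)


@dataclass
class PeakSet:
    """ChIP peak summits: (chrom, 0-based summit position, score)."""

    table: pd.DataFrame  # columns chrom, summit, score

    def __post_init__(self) -> None:
        if not {"chrom", "summit"}.issubset(self.table.columns):
            raise ValueError("peak table needs chrom and summit columns")
        if (self.table["summit"] < 0).any():
            raise ValueError("negative summit position")
        if "score" not in self.table.columns:
            self.table = self.table.assign(score=0.0)

    def __len__(self) -> int:
        return len(self.table)

    def to_bed(self, path: str | Path) -> None:
        """Six-column BED; each summit is a single-base half-open interval."""
        t = self.table
        bed = pd.DataFrame({
            "chrom": t["chrom"],
            "start": t["summit"].astype(int),
            "end": t["summit"].astype(int) + 1,
            "name": [f"summit_{i}" for i in range(len(t))],
            "score": t["score"],
            "strand": ".",
        })
        bed.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "PeakSet":
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = pd.DataFrame({"chrom": bed[0], "summit": bed[1].astype(int)})
        if bed.shape[1] >= 5:
            df["score"] = bed[4]
        return cls(df)


@dataclass
class PositiveTargetSet:
    """ChIP-confirmed targets of one TF within an evaluation universe."""

    tf: str
    positives: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.positives <= self.universe:
            raise ValueError("positives must be a subset of the universe")

    @classmethod
    def from_gene_list(cls, tf: str, path: str | Path,
                       universe: Iterable[str]) -> "PositiveTargetSet":
        universe = set(universe)
        with open(path) as fh:
            genes = {line.strip() for line in fh if line.strip()}
        return cls(tf, genes & universe, universe)


@dataclass
class EvalReport:
    auroc: float
    aupr: float
    random_auroc_mean: float = float("nan")
    random_aupr_mean: float = float("nan")
    n_permutations: int = 0
    n_positives: int = 0
    n_universe: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def assign_peak_targets(peaks: PeakSet, annotation: GeneAnnotation,
                        window: int = 10_000) -> set[str]:
    """Genes whose span lies within ``window`` bp of some peak summit.

    Distance is measured from the summit (0-based) to the nearest coordinate
    of the gene span (0 when the summit falls inside it); strand is ignored.
    A gene is included iff that distance is <= window for at least one summit.
    """
    hits: set[str] = set()
    ann = annotation.table
    for chrom, sub in peaks.table.groupby("chrom"):
        genes = ann[ann["chrom"] == chrom]
        if genes.empty:
            continue
        start0 = genes["start"].to_numpy() - 1  # 0-based inclusive span
        end0 = genes["end"].to_numpy() - 1
        summits = sub["summit"].to_numpy()[:, None]
        dist = np.maximum.reduce([start0[None, :] - summits,
                                  summits - end0[None, :],
                                  np.zeros((len(summits), len(genes)), int)])
        near = (dist <= window).any(axis=0)
        hits.update(genes.index[near])
    return hits


def predicted_targets(grn: RankedEdgeList, tf: str, k: int) -> set[str]:
    """Targets of ``tf`` among the top-``k`` edges; empty if the TF is absent."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub = top_edges(grn, min(k, len(grn)))
    return sub.targets_of(tf)


def auroc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance probability; tied scores count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    p = int(labels.sum())
    n = int((~labels).sum())
    if p == 0 or n == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels].sum() - p * (p + 1) / 2) / (p * n))


def aupr_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise integration.

    Thresholds sweep the distinct score values in descending order; tied
    scores enter as one block.  AUPR = sum over thresholds of
    (recall_i - recall_{i-1}) * precision_i.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    p_total = int(labels.sum())
    if p_total == 0 or (~labels).sum() == 0:
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-scores, kind="mergesort")
    s, lab = scores[order], labels[order]
    tp = np.cumsum(lab)
    k = np.arange(1, len(s) + 1)
    # block ends: last index of each run of equal scores
    block_end = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    recall = tp[block_end] / p_total
    precision = tp[block_end] / k[block_end]
    prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev) * precision))


def _score_vector(grn: RankedEdgeList, truth: PositiveTargetSet,
                  tf: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    genes = sorted(truth.universe - {tf})
    scores = grn.weight_of(tf, genes).to_numpy(dtype=float)
    labels = np.array([g in truth.positives for g in genes])
    return scores, labels, genes


def evaluate_ranking(grn: RankedEdgeList, truth: PositiveTargetSet,
                     tf: str | None = None) -> EvalReport:
    """AUROC / AUPR of the TF's predicted ranking over the universe.

    Universe genes without an edge from the TF receive score 0 and enter the
    ranking as one tied block, so every gene is rankable.
    """
    tf = tf or truth.tf
    scores, labels, _ = _score_vector(grn, truth, tf)
    return EvalReport(
        auroc=auroc_score(scores, labels),
        aupr=aupr_score(scores, labels),
        n_positives=int(labels.sum()),
        n_universe=len(labels),
    )


def permutation_baseline(grn: RankedEdgeList, truth: PositiveTargetSet,
                         tf: str | None = None, n_perm: int = 10_000,
                         seed: int = 0) -> tuple[float, float]:
    """Mean AUROC and AUPR over random label permutations.

    The gene labels of the fixed score vector are shuffled ``n_perm`` times
    (equivalently, random positive sets of the same size are drawn) and the
    two areas averaged — the expected performance of a random network of the
    same shape.
    """
    tf = tf or truth.tf
    scores, labels, _ = _score_vector(grn, truth, tf)
    rng = np.random.default_rng(seed)
    p_total = int(labels.sum())
    n = len(labels)

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    ranks = rankdata(scores)
    block_end = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    k = np.arange(1, n + 1)

    aurocs = np.empty(n_perm)
    auprs = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        lab = np.zeros(n, dtype=bool)
        lab[perm[:p_total]] = True
        aurocs[i] = (ranks[lab].sum() - p_total * (p_total + 1) / 2) \
            / (p_total * (n - p_total))
        tp = np.cumsum(lab[order])
        recall = tp[block_end] / p_total
        precision = tp[block_end] / k[block_end]
        prev = np.r_[0.0, recall[:-1]]
        auprs[i] = np.sum((recall - prev) * precision)
    return float(aurocs.mean()), float(auprs.mean())


def fisher_overlap(predicted: set, chip: set,
                   universe: set) -> tuple[np.ndarray, float, float]:
    """One-tail (enrichment) Fisher's exact test of two gene sets.

    Returns the 2x2 contingency table ``[[a, b], [c, d]]`` (a = both, b =
    predicted only, c = chip only, d = neither), the sample odds ratio
    (infinite when b*c = 0 and a*d > 0), and the hypergeometric upper-tail
    p-value P(overlap >= a).
    """
    if not universe:
        raise ValueError("empty universe")
    if not predicted <= universe or not chip <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(predicted & chip)
    b = len(predicted - chip)
    c = len(chip - predicted)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    # upper tail of Hypergeometric(N=|U|, K=|chip|, n=|predicted|) at a
    p = float(hypergeom.sf(a - 1, len(universe), len(chip), len(predicted)))
    return table, odds, min(p, 1.0)


def size_sweep(grn: RankedEdgeList, truth: PositiveTargetSet,
               tf: str | None = None,
               sizes: Sequence[int] = (100_000, 1_000_000, 10_000_000),
               ) -> dict[int, float | None]:
    """Percentage of predicted targets confirmed by the positive set, per
    network size.  Sizes with zero predictions report ``None`` (undefined)."""
    tf = tf or truth.tf
    out: dict[int, float | None] = {}
    for size in sizes:
        pred = predicted_targets(grn, tf, size) & truth.universe
        if not pred:
            warnings.warn(f"no predictions for {tf!r} at size {size}")
            out[size] = None
        else:
            out[size] = 100.0 * len(pred & truth.positives) / len(pred)
    return out
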