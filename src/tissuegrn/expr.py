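"""Expression-matrix handling: TMM/CPM normalization, expressed-gene calls,
tissue overlaps and expression-profile clustering.

The pipeline works on gene x library count matrices with a library -> tissue
map.  Counts are scaled between libraries with trimmed-mean-of-M-values (TMM)
factors, converted to counts per million (CPM) or log2(CPM + 1), and a gene is
called "expressed" in a tissue when its CPM exceeds a threshold in more than a
given fraction of that tissue's libraries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

__all__ = [
    "CountsMatrix",
    "ExpressionMatrix",
    "ExpressedSets",
    "tmm_factors",
    "to_cpm",
    "filter_expressed",
    "expressed_sets",
    "set_overlaps",
    "cluster_tissue_profiles",
]

SCALE_CPM = "CPM"
SCALE_LOG = "log2CPM1"


@dataclass
class CountsMatrix:
    """Gene x library matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene ID with one column per library.
    tissue_of
        Mapping from library ID to tissue label; must cover every column.
    """

    counts: pd.DataFrame
    tissue_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene IDs")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate library IDs")
        missing = set(self.counts.columns) - set(self.tissue_of)
        if missing:
            raise ValueError(f"libraries without tissue label: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for lib in self.counts.columns:
            seen.setdefault(self.tissue_of[lib], None)
        return list(seen)

    def libraries_of(self, tissue: str) -> list[str]:
        libs = [c for c in self.counts.columns if self.tissue_of[c] == tissue]
        if not libs:
            raise KeyError(f"unknown tissue label: {tissue!r}")
        return libs

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_tissue(self, tissue: str) -> "CountsMatrix":
        libs = self.libraries_of(tissue)
        return CountsMatrix(self.counts[libs].copy(),
                            {l: tissue for l in libs})

    # -- TSV round trip (counts: first column gene ID, header = library IDs;
    #    tissue map: two-column TSV library<TAB>tissue) -------------------
    def to_tsv(self, counts_path: str | Path, tissue_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        pd.Series(self.tissue_of, name="tissue").rename_axis("library").to_csv(
            tissue_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path,
                 tissue_path: str | Path) -> "CountsMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        tmap = pd.read_csv(tissue_path, sep="\t", index_col=0)["tissue"]
        return cls(counts, tmap.to_dict())


@dataclass
class ExpressionMatrix:
    """Gene x library matrix of normalized expression values.

    ``scale`` is either ``"CPM"`` or ``"log2CPM1"`` (log2 of CPM plus a
    pseudocount of one).
    """

    values: pd.DataFrame
    scale: str
    tissue_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_CPM, SCALE_LOG):
            raise ValueError(f"unknown scale {self.scale!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for lib in self.values.columns:
            seen.setdefault(self.tissue_of[lib], None)
        return list(seen)

    def libraries_of(self, tissue: str) -> list[str]:
        libs = [c for c in self.values.columns if self.tissue_of[c] == tissue]
        if not libs:
            raise KeyError(f"unknown tissue label: {tissue!r}")
        return libs

    def subset(self, genes: Iterable[str] | None = None,
               tissue: str | None = None) -> "ExpressionMatrix":
        df = self.values
        if tissue is not None:
            df = df[self.libraries_of(tissue)]
        if genes is not None:
            genes = [g for g in self.gene_ids if g in set(genes)]
            df = df.loc[genes]
        return ExpressionMatrix(df.copy(), self.scale,
                                {l: self.tissue_of[l] for l in df.columns})


@dataclass
class ExpressedSets:
    """Per-tissue sets of expressed genes plus the thresholds that made them."""

    sets: dict[str, set[str]]
    cpm_threshold: float
    fraction_threshold: float


def tmm_factors(counts: CountsMatrix) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per library.

    The reference library is the one whose upper-quartile CPM is closest to
    the mean upper quartile.  For every other library, per-gene log-ratios
    (M) and average log-intensities (A) are computed on genes with positive
    counts in both libraries; the 30% most extreme M values and 5% most
    extreme A values are trimmed on each side and the remaining M values
    averaged with precision (inverse delta-method variance) weights.  Factors
    are rescaled to geometric mean one.

    Raises
    ------
    ValueError
        If any library has all-zero counts.
    """
    mat = counts.counts.to_numpy(dtype=float)
    lib_sizes = mat.sum(axis=0)
    if (lib_sizes <= 0).any():
        bad = [counts.library_ids[j] for j in np.where(lib_sizes <= 0)[0]]
        raise ValueError(f"libraries with all-zero counts: {bad}")

    # reference library: upper-quartile CPM closest to the mean upper quartile
    uq = np.array([np.quantile(mat[:, j] / lib_sizes[j] * 1e6, 0.75)
                   for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(mat[:, j], lib_sizes[j],
                                   mat[:, ref], lib_sizes[ref])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.library_ids, name="tmm_factor")


def _tmm_pair(obs: np.ndarray, n_obs: float, ref: np.ndarray, n_ref: float,
              m_trim: float = 0.30, a_trim: float = 0.05) -> float:
    """Weighted trimmed mean of M values of one library against the reference."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 0.0
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) \
        + (n_ref - ref[keep]) / (n_ref * ref[keep])

    n = m.size
    m_rank = pd.Series(m).rank().to_numpy()
    a_rank = pd.Series(a).rank().to_numpy()
    lo_m, hi_m = np.floor(n * m_trim) + 1, n + 1 - (np.floor(n * m_trim) + 1)
    lo_a, hi_a = np.floor(n * a_trim) + 1, n + 1 - (np.floor(n * a_trim) + 1)
    keep2 = (m_rank >= lo_m) & (m_rank <= hi_m) \
        & (a_rank >= lo_a) & (a_rank <= hi_a)
    if keep2.sum() == 0 or not np.isfinite(m[keep2]).all():
        return 0.0
    val = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(val) if np.isfinite(val) else 0.0


def to_cpm(counts: CountsMatrix,
           factors: pd.Series | Mapping[str, float] | None = None,
           log_transform: bool = False) -> ExpressionMatrix:
    """Counts per million, optionally TMM-adjusted and log2(CPM + 1) scaled.

    ``CPM[g, j] = counts[g, j] / (library_size_j * factor_j) * 1e6``.  With
    ``factors=None`` every factor is one and each column sums to 1e6.
    """
    lib_sizes = counts.library_sizes().astype(float)
    if factors is None:
        f = pd.Series(1.0, index=counts.counts.columns)
    else:
        f = pd.Series(factors, dtype=float)
        missing = set(counts.library_ids) - set(f.index)
        if missing:
            raise ValueError(f"factors missing for libraries: {sorted(missing)}")
        f = f.reindex(counts.counts.columns)
    cpm = counts.counts / (lib_sizes * f) * 1e6
    if log_transform:
        return ExpressionMatrix(np.log2(cpm + 1.0), SCALE_LOG,
                                dict(counts.tissue_of))
    return ExpressionMatrix(cpm, SCALE_CPM, dict(counts.tissue_of))


def filter_expressed(expr: ExpressionMatrix, tissue: str,
                     cpm_threshold: float = 1.0,
                     fraction_threshold: float = 0.10,
                     rule: str = "results") -> set[str]:
    """Genes called expressed in one tissue.

    Under the default ``"results"`` rule a gene is expressed when its CPM is
    strictly greater than ``cpm_threshold`` in strictly more than
    ``fraction_threshold`` of the tissue's libraries.  The alternative
    ``"methods"`` rule instead *excludes* genes whose CPM falls below the
    threshold in more than that fraction of libraries (i.e. keeps a gene when
    the fraction of libraries with CPM < threshold is at most the cutoff);
    the two rules differ for genes in the intermediate regime.
    """
    if expr.scale != SCALE_CPM:
        raise ValueError("filter_expressed requires a CPM-scale matrix")
    libs = expr.libraries_of(tissue)
    vals = expr.values[libs]
    n = len(libs)
    if rule == "results":
        frac_above = (vals > cpm_threshold).sum(axis=1) / n
        keep = frac_above > fraction_threshold
    elif rule == "methods":
        frac_below = (vals < cpm_threshold).sum(axis=1) / n
        keep = frac_below <= fraction_threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return set(vals.index[keep])


def expressed_sets(expr: ExpressionMatrix, cpm_threshold: float = 1.0,
                   fraction_threshold: float = 0.10,
                   rule: str = "results") -> ExpressedSets:
    """Apply :func:`filter_expressed` to every tissue of the matrix."""
    sets = {t: filter_expressed(expr, t, cpm_threshold, fraction_threshold, rule)
            for t in expr.tissues}
    return ExpressedSets(sets, cpm_threshold, fraction_threshold)


def set_overlaps(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exact-combination membership counts (UpSet semantics).

    For every non-empty combination of set labels, the number of elements
    belonging to exactly those sets and no others.  Counts over all
    combinations sum to the size of the union.
    """
    labels = list(sets)
    if not labels:
        raise ValueError("at least one set required")
    out: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            out[frozenset(combo)] = 0
    for element in set().union(*sets.values()):
        member = frozenset(l for l in labels if element in sets[l])
        out[member] += 1
    return out


def cluster_tissue_profiles(expr: ExpressionMatrix, genes: Iterable[str],
                            k_groups: int = 15) -> dict[str, int]:
    """Group genes by their tissue-level expression profile.

    Per-gene expression is averaged within each tissue and z-transformed
    across tissues (mean 0, sd 1 per gene), then complete-linkage hierarchical
    clustering on Euclidean distance is cut into ``k_groups`` groups.  Genes
    whose tissue means have zero variance cannot be z-scaled; each is placed
    in its own group, appended deterministically in gene-ID order.
    """
    genes = sorted(set(genes))
    if len(genes) < k_groups:
        raise ValueError("need at least k_groups genes")
    means = pd.DataFrame(
        {t: expr.values.loc[genes, expr.libraries_of(t)].mean(axis=1)
         for t in expr.tissues})
    sd = means.std(axis=1, ddof=1)
    degenerate = sorted(means.index[(sd == 0) | sd.isna()])
    regular = [g for g in genes if g not in set(degenerate)]

    assignment: dict[str, int] = {}
    n_cluster_groups = max(k_groups - len(degenerate), 1) if regular else 0
    if regular:
        z = means.loc[regular].sub(means.loc[regular].mean(axis=1), axis=0)
        z = z.div(sd.loc[regular], axis=0)
        if len(regular) == 1:
            labels = np.array([1])
        else:
            link = sch.linkage(z.to_numpy(), method="complete",
                               metric="euclidean")
            labels = sch.fcluster(link, t=min(n_cluster_groups, len(regular)),
                                  criterion="maxclust")
        for g, lab in zip(regular, labels):
            assignment[g] = int(lab)
    next_id = max(assignment.values(), default=0) + 1
    for g in degenerate:
        assignment[g] = next_id
        next_id += 1
    return assignment
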