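"""Ground-truth simulator: multi-tissue regulatory networks, count-level
expression and ChIP-like evaluation sets.

The generator emulates the inputs of the real analysis without any
download: a designated TF subset, a directed ground-truth network per tissue
with controllable cross-tissue sharing, RNA-Seq-like counts with
library-size variation and negative-binomial noise, and ChIP-like positive
sets with peak summits placed near target genes so the peak-to-gene rule is
testable end to end.

Out-degrees are drawn from a truncated discrete power law so the simulated
networks have the heavy-tailed hub structure the topology analysis expects.
Latent abundances propagate through the network by damped fixed-point
iteration, which also resolves feedback loops.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expr import CountsMatrix
from .evalchip import GeneAnnotation, PeakSet, PositiveTargetSet

__all__ = [
    "TrueNetwork", "SimulationConfig",
    "simulate_network", "derive_tissue_networks", "simulate_latent",
    "simulate_expression", "simulate_dataset", "simulate_chip_truth",
    "make_annotation", "sample_out_degrees",
]

# fixed sub-stream codes so subsets of the simulation are independently
# reproducible from the one master seed
_STREAM_NETWORK = 1
_STREAM_TISSUES = 2
_STREAM_EXPRESSION = 3
_STREAM_CHIP = 4

_MAX_SWEEPS = 100
_DAMPING = 0.5
_LATENT_CLIP = 30.0
_FIXED_POINT_TOL = 1e-8
# cap on the L1 norm of each target's incoming effects; keeps the damped
# propagation map a contraction so feedback loops always settle within the
# sweep budget, and keeps latent variances comparable across genes
_MAX_IN_L1 = 0.6


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


@dataclass
class TrueNetwork:
    """Ground-truth signed directed regulatory network.

    Every edge runs from a TF to another gene, carries a non-zero signed
    effect, and appears at most once.
    """

    tf_ids: frozenset
    gene_ids: frozenset
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        if not self.tf_ids <= self.gene_ids:
            raise ValueError("tf_ids must be a subset of gene_ids")
        seen = set()
        for reg, tgt, eff in self.edges:
            if reg not in self.tf_ids:
                raise ValueError(f"regulator {reg!r} is not a declared TF")
            if tgt not in self.gene_ids:
                raise ValueError(f"target {tgt!r} is not a known gene")
            if reg == tgt:
                raise ValueError(f"self-edge on {reg!r}")
            if eff == 0:
                raise ValueError("zero effect")
            if (reg, tgt) in seen:
                raise ValueError(f"duplicate edge {(reg, tgt)}")
            seen.add((reg, tgt))

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.edges}

    def targets_of(self, tf: str) -> set[str]:
        if tf not in self.tf_ids:
            raise KeyError(f"{tf!r} is not a TF of this network")
        return {t for r, t, _ in self.edges if r == tf}

    def out_degrees(self) -> pd.Series:
        tally: dict[str, int] = {tf: 0 for tf in sorted(self.tf_ids)}
        for r, _, _ in self.edges:
            tally[r] += 1
        return pd.Series(tally)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.edges,
                     columns=["regulator", "target", "effect"]) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, tf_ids: Iterable[str],
                 gene_ids: Iterable[str]) -> "TrueNetwork":
        df = pd.read_csv(path, sep="\t")
        edges = [(r, t, float(e)) for r, t, e in
                 df[["regulator", "target", "effect"]].itertuples(index=False)]
        return cls(frozenset(tf_ids), frozenset(gene_ids), edges)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the whole simulation.

    Defaults describe the benchmark conditions used throughout the test
    suite: 50 TFs among 500 genes, four tissues of 200 libraries each, a
    fifth of edges shared by all tissues, power-law out-degrees averaging
    10 targets per TF, moderate propagation noise and negative-binomial
    counts at bulk-RNA-Seq-like depth.
    """

    n_tf: int = 50
    n_genes: int = 500
    n_samples_per_tissue: int = 200
    n_tissues: int = 4
    shared_edge_fraction: float = 0.2
    avg_targets_per_tf: float = 10.0
    noise_sd: float = 0.2
    link_function: str = "linear"
    dispersion: float = 0.1
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    seed: int = 0
    degree_exponent: float = 1.5
    effect_range: tuple[float, float] = (0.3, 0.9)
    activator_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.n_tf < self.n_genes:
            raise ValueError("need 0 < n_tf < n_genes")
        if min(self.n_samples_per_tissue, self.n_tissues) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.shared_edge_fraction <= 1.0:
            raise ValueError("shared_edge_fraction outside [0, 1]")
        if self.avg_targets_per_tf < 0:
            raise ValueError("avg_targets_per_tf must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.link_function not in ("linear", "sigmoid"):
            raise ValueError(f"unknown link {self.link_function!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid library_size_range")

    def tf_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_tf + 1)]

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("library_size_range", "effect_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# network topology
# ---------------------------------------------------------------------------

def _truncated_powerlaw_pmf(exponent: float, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1, dtype=float)
    pmf = k ** (-exponent)
    return pmf / pmf.sum()

def _powerlaw_mean(exponent: float, kmax: int) -> float:
    pmf = _truncated_powerlaw_pmf(exponent, kmax)
    return float(np.sum(np.arange(1, kmax + 1) * pmf))


def sample_out_degrees(rng: np.random.Generator, n_tf: int, avg: float,
                       exponent: float, max_degree: int) -> np.ndarray:
    """Heavy-tailed out-degree sample with mean approximately ``avg``.

    Degrees follow a discrete power law with the given exponent, truncated
    at ``max_degree``.  The truncation point is tightened until the
    distribution's mean matches ``avg``; if even the full support falls
    short, draws are scaled up multiplicatively with stochastic rounding
    (scaling preserves the power-law shape).
    """
    if avg == 0:
        return np.zeros(n_tf, dtype=int)
    if avg > max_degree:
        raise ValueError(
            f"avg_targets_per_tf={avg} exceeds the {max_degree} possible "
            "targets per TF")
    full_mean = _powerlaw_mean(exponent, max_degree)
    if full_mean >= avg:
        lo, hi = 1, max_degree  # mean is increasing in the truncation point
        while lo < hi:
            mid = (lo + hi) // 2
            if _powerlaw_mean(exponent, mid) < avg:
                lo = mid + 1
            else:
                hi = mid
        kmax = lo
        pmf = _truncated_powerlaw_pmf(exponent, kmax)
        return rng.choice(np.arange(1, kmax + 1), size=n_tf, p=pmf)
    # full support still below target: scale draws up, preserving exponent
    pmf = _truncated_powerlaw_pmf(exponent, max_degree)
    z = rng.choice(np.arange(1, max_degree + 1), size=n_tf, p=pmf)
    scaled = z * (avg / full_mean)
    deg = np.floor(scaled).astype(int)
    deg += rng.random(n_tf) < (scaled - np.floor(scaled))
    return np.minimum(deg, max_degree)


def simulate_network(config: SimulationConfig) -> TrueNetwork:
    """Draw a ground-truth network with power-law out-degrees.

    Each TF's targets are chosen uniformly without replacement among the
    other genes; effects have magnitude in ``effect_range`` and are positive
    (activating) with probability ``activator_fraction``.  Deterministic
    given the config seed.
    """
    rng = _rng(config.seed, _STREAM_NETWORK)
    genes = config.gene_names()
    tfs = config.tf_names()
    degrees = sample_out_degrees(rng, config.n_tf, config.avg_targets_per_tf,
                                 config.degree_exponent, config.n_genes - 1)
    edges: list[tuple[str, str, float]] = []
    gene_arr = np.array(genes)
    for tf, deg in zip(tfs, degrees):
        if deg == 0:
            continue
        pool = gene_arr[gene_arr != tf]
        targets = rng.choice(pool, size=int(deg), replace=False)
        lo, hi = config.effect_range
        mags = rng.uniform(lo, hi, size=int(deg))
        signs = np.where(rng.random(int(deg)) < config.activator_fraction,
                         1.0, -1.0)
        edges.extend((tf, str(t), float(m * s))
                     for t, m, s in zip(targets, mags, signs))
    return TrueNetwork(frozenset(tfs), frozenset(genes),
                       _cap_incoming_effects(edges))


def _cap_incoming_effects(edges: list[tuple[str, str, float]],
                          cap: float = _MAX_IN_L1
                          ) -> list[tuple[str, str, float]]:
    """Rescale each target's incoming effects so their L1 norm is <= cap."""
    totals: dict[str, float] = {}
    for _, tgt, eff in edges:
        totals[tgt] = totals.get(tgt, 0.0) + abs(eff)
    return [(reg, tgt, eff * min(1.0, cap / totals[tgt]))
            for reg, tgt, eff in edges]


def derive_tissue_networks(base: TrueNetwork,
                           config: SimulationConfig) -> list[TrueNetwork]:
    """Split a base network into per-tissue networks with shared structure.

    A fraction ``shared_edge_fraction`` of the base edges (rounded) appears
    in every tissue; each remaining edge is assigned to exactly one tissue
    chosen uniformly.  Deterministic given the config seed.
    """
    rng = _rng(config.seed, _STREAM_TISSUES)
    n_edges = len(base.edges)
    n_shared = int(round(config.shared_edge_fraction * n_edges))
    order = rng.permutation(n_edges)
    shared_idx = set(order[:n_shared].tolist())
    assignment = rng.integers(0, config.n_tissues, size=n_edges)
    nets = []
    for t in range(config.n_tissues):
        edges = [e for i, e in enumerate(base.edges)
                 if i in shared_idx or assignment[i] == t]
        nets.append(TrueNetwork(base.tf_ids, base.gene_ids, edges))
    return nets


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _link(values: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return values
    return 1.0 / (1.0 + np.exp(-values))  # logistic, centered at 0, unit scale


def simulate_latent(net: TrueNetwork, config: SimulationConfig,
                    n_samples: int | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Latent (pre-count) abundances under the network's regulation.

    Regulator-free genes get independent standard-normal baseline
    abundances per sample.  Every regulated gene's abundance is the link
    function of the weighted sum of its regulators' abundances plus
    Gaussian noise (``noise_sd``).  Feedback loops are resolved by damped
    fixed-point iteration (damping 0.5, at most 100 sweeps); failure to
    converge raises ``RuntimeError``.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_EXPRESSION)
    if n_samples is None:
        n_samples = config.n_samples_per_tissue
    genes = sorted(net.gene_ids)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    w = np.zeros((n, n))  # w[target, regulator]
    for reg, tgt, eff in net.edges:
        w[idx[tgt], idx[reg]] = eff
    regulated = w.any(axis=1)

    base = rng.standard_normal((n, n_samples))
    noise = config.noise_sd * rng.standard_normal((n, n_samples))

    x = base.copy()
    for _ in range(_MAX_SWEEPS):
        fx = base.copy()
        fx[regulated] = (_link(w @ x, config.link_function)[regulated]
                         + noise[regulated])
        new = (1 - _DAMPING) * x + _DAMPING * fx
        # measure change before clipping so a diverging iterate pinned at the
        # clip bound is still flagged as non-convergent
        delta = np.abs(new - x).max()
        x = np.clip(new, -_LATENT_CLIP, _LATENT_CLIP)
        if delta < _FIXED_POINT_TOL:
            break
    else:
        raise RuntimeError(
            f"latent fixed point did not converge in {_MAX_SWEEPS} sweeps")
    return pd.DataFrame(x, index=genes)


def simulate_expression(net: TrueNetwork, config: SimulationConfig,
                        tissue: str = "tissue1",
                        stream: int = 0) -> CountsMatrix:
    """Negative-binomial counts for one tissue network.

    Latent abundances are mapped to relative expression via exp, scaled to a
    per-library sequencing depth drawn uniformly from
    ``library_size_range``, and counts are drawn negative-binomially with
    the configured dispersion (variance = m + dispersion * m^2).
    """
    rng = _rng(config.seed, _STREAM_EXPRESSION, stream)
    latent = simulate_latent(net, config, config.n_samples_per_tissue, rng)
    rel = np.exp(latent.to_numpy())
    props = rel / rel.sum(axis=0, keepdims=True)

    lo, hi = config.library_size_range
    lib_sizes = rng.integers(lo, hi + 1, size=config.n_samples_per_tissue)
    mean = props * lib_sizes
    size = 1.0 / config.dispersion  # NB shape: var = m + m^2 / size
    counts = rng.negative_binomial(size, size / (size + mean))

    libs = [f"{tissue}_L{i + 1:04d}" for i in range(config.n_samples_per_tissue)]
    df = pd.DataFrame(counts, index=latent.index, columns=libs)
    return CountsMatrix(df, {l: tissue for l in libs})


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[TrueNetwork, list[TrueNetwork], CountsMatrix]:
    """Full study: base network, per-tissue networks, combined count matrix."""
    base = simulate_network(config)
    tissue_nets = derive_tissue_networks(base, config)
    parts = [simulate_expression(net, config, tissue=f"tissue{t + 1}",
                                 stream=t + 1)
             for t, net in enumerate(tissue_nets)]
    counts = pd.concat([p.counts for p in parts], axis=1)
    tissue_of: dict[str, str] = {}
    for p in parts:
        tissue_of.update(p.tissue_of)
    return base, tissue_nets, CountsMatrix(counts, tissue_of)


# ---------------------------------------------------------------------------
# ChIP-like truth
# ---------------------------------------------------------------------------

def make_annotation(gene_ids: Iterable[str], genes_per_chrom: int = 50,
                    gene_length: int = 2_000, gap: int = 23_000
                    ) -> GeneAnnotation:
    """Toy gene models: equal-length genes on consecutive chromosomes.

    The default gap keeps neighboring gene spans more than 20 kb apart, so
    a summit within 10 kb of one gene can never also sit within 10 kb of
    its neighbor and peak-to-gene assignment is unambiguous.
    """
    rows = []
    for i, gid in enumerate(sorted(gene_ids)):
        chrom = f"chr{i // genes_per_chrom + 1}"
        slot = i % genes_per_chrom
        start = 1 + slot * (gene_length + gap)
        strand = "+" if slot % 2 == 0 else "-"
        rows.append((gid, chrom, start, start + gene_length - 1, strand))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                     "strand"]).set_index("gene")
    return GeneAnnotation(df)


def simulate_chip_truth(net: TrueNetwork, tf: str, fnr: float, fpr: float,
                        annotation: GeneAnnotation, seed: int,
                        window: int = 10_000
                        ) -> tuple[PositiveTargetSet, PeakSet]:
    """ChIP-like positive set and peak summits for one TF.

    The positive set is the TF's true targets minus a fraction ``fnr``
    (rounded count, sampled), plus ``round(fpr * #non-targets)`` false
    genes.  One summit is emitted per positive gene, uniformly within
    ``window`` bp of the gene span (clipped at coordinate 0), so the 10 kb
    assignment rule recovers exactly the positive genes on a
    well-separated annotation.
    """
    if tf not in net.tf_ids:
        raise KeyError(f"{tf!r} is not a TF of this network")
    if not (0 <= fnr <= 1 and 0 <= fpr < 1):
        raise ValueError("fnr in [0, 1] and fpr in [0, 1) required")
    rng = _rng(seed, _STREAM_CHIP)
    truth = sorted(net.targets_of(tf))
    n_drop = int(round(fnr * len(truth)))
    dropped = set(rng.choice(truth, size=n_drop, replace=False)) if n_drop else set()
    positives = set(truth) - dropped

    non_targets = sorted(net.gene_ids - set(truth) - {tf})
    n_false = int(round(fpr * len(non_targets)))
    if n_false:
        positives |= set(rng.choice(non_targets, size=n_false, replace=False))

    ann = annotation.table
    rows = []
    for gene in sorted(positives):
        row = ann.loc[gene]
        lo = max(0, int(row.start) - 1 - window)
        hi = int(row.end) - 1 + window
        rows.append((row.chrom, int(rng.integers(lo, hi + 1)), 1000.0))
    peaks = PeakSet(pd.DataFrame(rows, columns=["chrom", "summit", "score"]))
    return (PositiveTargetSet(tf, positives, set(net.gene_ids) - {tf}),
            peaks)
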