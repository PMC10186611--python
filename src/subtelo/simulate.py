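"""Synthetic genomes, DEG sets, peak tracks and count matrices.

Every pipeline stage can be exercised without downloads: the generators
emulate the data structures behind the senescence subtelomere analysis —
a multi-chromosome genome with genes along both arms, DEG sets with a
planted excess of upregulated genes in terminal arm windows at a chosen
fold enrichment, chromatin peak tracks whose subtelomeric coverage
differs between an "enriched" arm group and the rest, and
negative-binomial count matrices in which planted upregulated DEGs are
repressed in the young condition and derepressed in the senescent one.

Enrichment is planted on the fold-enrichment statistic's own scale: the
in-window per-gene DEG probability is solved so that the *expected*
(k/s)/(M/N) equals the requested fold, which makes parameter-recovery
tests self-consistent.

All generators are deterministic given the global seed; each draws from
an independent substream so stages can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .degs import DEGSet
from .genome import (
    GeneRecord,
    GenomeAssembly,
    define_subtelomere_windows,
    distance_table,
)
from .chromatin import IntervalSet, normalize_intervals

logger = logging.getLogger("subtelo")

_STREAMS = {"genome": 1, "degs": 2, "peaks": 3, "counts": 4, "tables": 5}


class SimulationError(ValueError):
    pass


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named RNG substream derived from the global seed."""
    return np.random.default_rng([_STREAMS[name], int(seed)])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DEGSimConfig:
    """Planted DEG-set parameters.

    ``planted_fold`` is the expected first-window fold enrichment of
    upregulated genes on the planted arms (all arms when
    ``planted_arms`` is None); feasibility requires
    planted_fold x (window gene share) <= 1.
    """

    n_degs: int = 1250
    up_fraction: float = 0.8
    planted_arms: tuple[str, ...] | None = None
    planted_fold: float = 3.6
    window: int = 2_000_000


@dataclass
class PeakSimConfig:
    """Per-group subtelomeric coverage targets, as fractions in [0, 1]."""

    enriched_mean: float = 0.4
    other_mean: float = 0.2
    sd: float = 0.05
    mean_peak_length: int = 5_000


@dataclass
class CountSimConfig:
    """Negative-binomial count model (variance = mu + dispersion * mu^2).

    Planted up-DEGs have young mean ``base_mean / repression`` and
    senescent mean ``(base_mean / repression) * derepression``; planted
    down-DEGs mirror this (elevated young, divided by ``derepression``
    at senescence); all other genes keep ``base_mean`` in both
    conditions.
    """

    base_mean: float = 500.0
    dispersion: float = 0.05
    repression: float = 3.0
    derepression: float = 4.0
    n_replicates: int = 3


@dataclass
class SimulationConfig:
    """Study-scale defaults: a gene-dense 8-chromosome toy genome whose
    2 Mb arm windows each hold enough genes (~200) for per-arm
    enrichment tests to be informative at the fold enrichments the
    analysis targets, with 20,000 genes total and triplicate counts."""

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (
        30_000_000, 28_000_000, 27_000_000, 26_000_000,
        25_000_000, 24_000_000, 22_000_000, 20_000_000,
    )
    centromere_position: float = 0.45   # fraction of chromosome length
    centromere_width: float = 0.04
    n_genes: int = 20_000
    gene_length_median: int = 20_000
    gene_length_sigma: float = 0.8      # lognormal shape
    deg: DEGSimConfig = field(default_factory=DEGSimConfig)
    peaks: PeakSimConfig = field(default_factory=PeakSimConfig)
    counts: CountSimConfig = field(default_factory=CountSimConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key, sub in (("deg", DEGSimConfig), ("peaks", PeakSimConfig),
                         ("counts", CountSimConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "chromosome_lengths" in d:
            d["chromosome_lengths"] = tuple(d["chromosome_lengths"])
        if d.get("deg") and isinstance(d["deg"], DEGSimConfig) and \
                d["deg"].planted_arms is not None:
            d["deg"].planted_arms = tuple(d["deg"].planted_arms)
        return cls(**d)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> tuple[GenomeAssembly, list[GeneRecord]]:
    """Toy genome: chromosomes of the configured lengths, genes with
    uniform start positions and lognormal lengths truncated to fit."""
    rng = substream(config.seed, "genome")
    lengths = np.asarray(config.chromosome_lengths, dtype=np.int64)
    if len(lengths) == 0 or (lengths <= 0).any():
        raise SimulationError("chromosome lengths must be positive")
    total = int(lengths.sum())
    if config.n_genes > total:
        raise SimulationError(f"{config.n_genes} genes infeasible for {total} bp genome")
    names = [f"chr{i + 1}" for i in range(len(lengths))]
    centromeres = {}
    for name, length in zip(names, lengths):
        mid = int(config.centromere_position * length)
        half = int(config.centromere_width * length / 2)
        centromeres[name] = (mid - half, mid + half)
    assembly = GenomeAssembly(tuple(zip(names, (int(x) for x in lengths))), centromeres)

    # genes: chromosome chosen proportional to length, uniform starts
    chrom_idx = rng.choice(len(lengths), size=config.n_genes, p=lengths / total)
    starts = (rng.random(config.n_genes) * lengths[chrom_idx]).astype(np.int64)
    glen = rng.lognormal(np.log(config.gene_length_median),
                         config.gene_length_sigma, config.n_genes)
    glen = np.maximum(glen.astype(np.int64), 200)
    ends = np.minimum(starts + glen, lengths[chrom_idx])
    starts = np.minimum(starts, ends - 200).clip(min=0)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    order = np.lexsort((starts, chrom_idx))
    genes = [
        GeneRecord(
            f"G{rank:06d}", names[chrom_idx[i]], int(starts[i]), int(ends[i]),
            str(strands[i]), "protein_coding",
        )
        for rank, i in enumerate(order)
    ]
    return assembly, genes


# ---------------------------------------------------------------------------
# planted DEG sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEGTruth:
    """Generative ground truth returned alongside a simulated DEG set."""

    planted_arms: tuple[str, ...]
    planted_fold: float
    window: int
    p_in: float
    p_out: float
    n_window_genes: int


def generate_deg_set(
    assembly: GenomeAssembly,
    genes: Sequence[GeneRecord],
    config: SimulationConfig,
    name: str = "sim",
    rng: np.random.Generator | None = None,
    distances: pd.DataFrame | None = None,
) -> tuple[DEGSet, DEGTruth]:
    """Plant upregulated DEGs in the terminal windows of the planted arms.

    Per-gene up-DEG probabilities are ``p_in`` inside planted windows
    and ``p_out`` elsewhere, solved so that the expected total equals
    ``n_degs * up_fraction`` and the expected fold-enrichment statistic
    (k/s)/(M/N) over the planted windows equals ``planted_fold``.
    Down-DEGs are drawn uniformly from the remaining genes.
    """
    if rng is None:
        rng = substream(config.seed, "degs")
    deg_cfg = config.deg
    planted = tuple(deg_cfg.planted_arms) if deg_cfg.planted_arms else tuple(
        a for a in assembly.arms() if a not in assembly.excluded_arms
    )
    dist = distances if distances is not None else distance_table(genes, assembly)
    in_window = (
        dist["arm"].isin(planted) & (dist["distance_bp"] < deg_cfg.window)
    ).to_numpy()
    n_total = len(genes)
    m_window = int(in_window.sum())
    if m_window == 0:
        raise SimulationError("planted windows contain no genes")
    s_up = deg_cfg.n_degs * deg_cfg.up_fraction
    fold = deg_cfg.planted_fold
    share = m_window / n_total
    if fold * share > 1.0:
        raise SimulationError(
            f"planted_fold {fold} infeasible: fold x window gene share "
            f"({fold:.3g} x {share:.3g}) must be <= 1"
        )
    p_in = fold * s_up / n_total
    if p_in > 1.0:
        raise SimulationError(
            f"planted_fold {fold} infeasible: in-window probability {p_in:.3g} > 1 "
            f"(bound: fold <= {n_total / s_up:.3g})"
        )
    p_out = s_up * (1.0 - fold * share) / (n_total - m_window)

    probs = np.where(in_window, p_in, p_out)
    up_mask = rng.random(n_total) < probs
    gene_ids = np.asarray([g.gene_id for g in genes])
    up = frozenset(gene_ids[up_mask])
    n_down = int(round(deg_cfg.n_degs * (1.0 - deg_cfg.up_fraction)))
    candidates = gene_ids[~up_mask]
    down = frozenset(rng.choice(candidates, size=min(n_down, len(candidates)),
                                replace=False))
    deg_set = DEGSet(name, frozenset(gene_ids), up, down)
    truth = DEGTruth(planted, fold, deg_cfg.window, p_in, p_out, m_window)
    return deg_set, truth


def write_deseq_results(
    deg_set: DEGSet,
    path: str | Path,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> None:
    """Emit a DESeq2-style results TSV consistent with a DEG set, so
    that re-classifying the file at the same thresholds reproduces it.
    Some non-DEG rows get NA padj, mimicking independent filtering."""
    rng = substream(seed, "tables")
    rows = []
    for gene in sorted(deg_set.universe):
        if gene in deg_set.up:
            lfc = lfc_threshold + rng.exponential(1.0)
            padj = alpha * 10 ** -rng.uniform(1, 8)
        elif gene in deg_set.down:
            lfc = -(lfc_threshold + rng.exponential(1.0))
            padj = alpha * 10 ** -rng.uniform(1, 8)
        else:
            lfc = rng.normal(0.0, 0.3)
            padj = np.nan if rng.random() < 0.1 else rng.uniform(alpha, 1.0)
        rows.append((gene, 100 * rng.lognormal(1, 1), lfc, padj))
    frame = pd.DataFrame(rows, columns=["gene_id", "baseMean", "log2FoldChange", "padj"])
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# peak tracks
# ---------------------------------------------------------------------------

def generate_peak_track(
    windows,
    labels: dict,
    config: SimulationConfig,
    factor_name: str,
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """Peaks inside each subtelomere window hitting a group-dependent
    target coverage fraction (enriched vs other arm groups).

    The window's target coverage is drawn from the group's mean +/- sd
    (clipped to [0, 1]) and realised as equal-length non-overlapping
    peaks of approximately the configured mean length, placed at
    random non-overlapping offsets.
    """
    if rng is None:
        rng = substream(config.seed, "peaks")
    pk = config.peaks
    raw: list[tuple[str, int, int]] = []
    for w in windows:
        wlen = w.end - w.start
        if pk.mean_peak_length > wlen:
            raise SimulationError(
                f"mean peak length {pk.mean_peak_length} exceeds window {w.arm} ({wlen} bp)"
            )
        mean = pk.enriched_mean if labels.get(w.arm) == "enriched" else pk.other_mean
        target = float(np.clip(rng.normal(mean, pk.sd), 0.0, 1.0))
        covered = int(round(target * wlen))
        if covered <= 0:
            continue
        n_peaks = max(int(round(covered / pk.mean_peak_length)), 1)
        peak_len = covered // n_peaks
        if peak_len == 0:
            n_peaks, peak_len = 1, covered
        free = wlen - n_peaks * peak_len
        gaps = rng.random(n_peaks + 1)
        gaps = np.floor(gaps / gaps.sum() * free).astype(np.int64)
        pos = w.start
        for i in range(n_peaks):
            pos += int(gaps[i])
            raw.append((w.chrom, pos, pos + peak_len))
            pos += peak_len
    return normalize_intervals(raw, factor_name)


def write_narrowpeak(track: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        i = 0
        for chrom in track.intervals:
            for start, end in track.intervals[chrom]:
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{track.name}_{i}\t0\t.\t"
                    f"1.0\t-1\t-1\t{(end - start) // 2}\n"
                )
                i += 1


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def generate_counts(
    genes: Sequence[GeneRecord],
    deg_set: DEGSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Negative-binomial count matrix with planted de/repression.

    No-DEG genes share ``base_mean`` in both conditions; planted
    up-DEGs are repressed in young (mean / repression) and derepressed
    at senescence (x derepression); down-DEGs mirror this.  Returns the
    genes x samples matrix and a sample -> condition map.
    """
    if rng is None:
        rng = substream(config.seed, "counts")
    cc = config.counts
    if cc.n_replicates < 2:
        raise SimulationError("need >= 2 replicates per condition")
    if cc.base_mean <= 0:
        raise SimulationError("base_mean must be > 0")
    gene_ids = [g.gene_id for g in genes]
    mu_young = np.full(len(gene_ids), cc.base_mean)
    mu_sen = np.full(len(gene_ids), cc.base_mean)
    up = np.asarray([g in deg_set.up for g in gene_ids])
    down = np.asarray([g in deg_set.down for g in gene_ids])
    mu_young[up] = cc.base_mean / cc.repression
    mu_sen[up] = cc.base_mean / cc.repression * cc.derepression
    mu_young[down] = cc.base_mean * cc.repression
    mu_sen[down] = cc.base_mean * cc.repression / cc.derepression

    n_shape = 1.0 / cc.dispersion  # NB "number of failures" parameter
    samples, cols, conditions = [], [], {}
    for cond, mu in (("young", mu_young), ("senescent", mu_sen)):
        for rep in range(1, cc.n_replicates + 1):
            p = n_shape / (n_shape + mu)
            cols.append(rng.negative_binomial(n_shape, p))
            sample = f"{cond}_{rep}"
            samples.append(sample)
            conditions[sample] = cond
    matrix = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    return matrix, conditions


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------

def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in assembly.chromosomes:
            fh.write(f"{name}\t{length}\n")


def write_centromeres(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, _ in assembly.chromosomes:
            start, end = assembly.centromeres[name]
            fh.write(f"{name}\t{start}\t{end}\n")


def write_gtf(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Gene features only, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_counts(matrix: pd.DataFrame, conditions: dict,
                 counts_path: str | Path, conditions_path: str | Path) -> None:
    matrix.to_csv(counts_path, sep="\t")
    pd.Series(conditions, name="condition").rename_axis("sample").to_csv(
        conditions_path, sep="\t"
    )
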