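"""Chromatin-factor coverage over subtelomeres and DEG bodies.

Peak tracks (ChIP-seq/ATAC BED or narrowPeak) are reduced to percent
coverage of each subtelomere window (and, separately, of the union of
DEG gene bodies), correlated against the enriched/other arm grouping
with a rank point-biserial Spearman coefficient, and assembled into the
standardized (z-scored) arm x factor matrices that the cluster heatmaps
are built from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genome import GeneRecord, SubtelomereWindow

logger = logging.getLogger("subtelo")


class ChromatinError(ValueError):
    pass


# ---------------------------------------------------------------------------
# interval sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalSet:
    """One factor's peaks as sorted, merged intervals per chromosome."""

    name: str
    intervals: dict  # chrom -> (n, 2) int array, sorted, non-overlapping

    def total_length(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))


def _merge_sorted(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping or bookended intervals of a start-sorted array."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    out = [iv[0].tolist()]
    for start, end in iv[1:]:
        if start <= out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return np.asarray(out, dtype=np.int64)


def normalize_intervals(
    raw: Sequence[tuple[str, int, int]], name: str = "peaks"
) -> IntervalSet:
    """Sort and merge raw (chrom, start, end) triples into an
    :class:`IntervalSet` (bookended intervals are united)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in raw:
        if start < 0:
            raise ChromatinError(f"negative coordinate in interval ({chrom}, {start}, {end})")
        if start >= end:
            raise ChromatinError(f"empty or inverted interval ({chrom}, {start}, {end})")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged = {
        chrom: _merge_sorted(np.asarray(sorted(ivs), dtype=np.int64))
        for chrom, ivs in by_chrom.items()
    }
    return IntervalSet(name, merged)


def read_peaks(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read a BED3+/narrowPeak track (summit/score columns ignored)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ChromatinError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ChromatinError(f"{path}: line {lineno}: {exc}") from exc
    if name is None:
        name = Path(path).name.split(".")[0]
    return normalize_intervals(rows, name)


def _overlap_length(iv: np.ndarray, start: int, end: int) -> int:
    """Total bases of a merged interval array inside [start, end)."""
    if len(iv) == 0:
        return 0
    clipped = np.clip(iv, start, end)
    return int(np.maximum(clipped[:, 1] - clipped[:, 0], 0).sum())


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def window_coverage(peaks: IntervalSet, window: SubtelomereWindow) -> float:
    """Percent of a subtelomere window covered by peaks."""
    if window.end <= window.start:
        raise ChromatinError(f"zero-length window on arm {window.arm}")
    iv = peaks.intervals.get(window.chrom, np.empty((0, 2), dtype=np.int64))
    covered = _overlap_length(iv, window.start, window.end)
    return 100.0 * covered / (window.end - window.start)


def deg_gene_coverage(peaks: IntervalSet, genes: Sequence[GeneRecord]) -> float:
    """Percent of the union of gene bodies covered by peaks.

    Overlapping genes are merged first so shared bases count once.
    """
    if not genes:
        raise ChromatinError("empty gene list")
    bodies = normalize_intervals([(g.chrom, g.start, g.end) for g in genes], "genes")
    denom = bodies.total_length()
    covered = 0
    for chrom, body_iv in bodies.intervals.items():
        peak_iv = peaks.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))
        for start, end in body_iv:
            covered += _overlap_length(peak_iv, int(start), int(end))
    return 100.0 * covered / denom


def coverage_matrix(
    tracks: Sequence[IntervalSet], windows: Sequence[SubtelomereWindow]
) -> pd.DataFrame:
    """Arms x factors percent-coverage matrix."""
    data = {
        t.name: [window_coverage(t, w) for w in windows] for t in tracks
    }
    return pd.DataFrame(data, index=[w.arm for w in windows])


def read_compartment_labels(path: str | Path) -> pd.Series:
    """A/B compartment BED4 -> binary per-arm factor column (A=1, B=0).

    Rows must carry the arm identifier implicitly via coordinates; here
    the name column is the label and column 1/2 give the interval that
    is matched to arms by the caller.  The common case — one row per
    subtelomere with the arm id in an extra column — is also accepted
    (4 columns: chrom, start, end, label).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "label"], dtype={"chrom": str, "label": str},
    )
    bad = ~df["label"].isin(["A", "B"])
    if bad.any():
        raise ChromatinError(f"compartment labels must be A or B, got {df.loc[bad, 'label'].unique()}")
    return df.set_index("chrom")["label"].map({"A": 1.0, "B": 0.0})


# ---------------------------------------------------------------------------
# group association
# ---------------------------------------------------------------------------

def group_association(
    values: Mapping[str, float], labels: Mapping[str, str]
) -> tuple[float, float]:
    """Spearman rank correlation between per-arm coverage and the
    enriched/other grouping (enriched = 1, other = 0; midranks for
    ties; two-sided p via the t approximation).

    rho > 0 means higher coverage on the enriched arms.  A constant
    coverage vector has no defined rank correlation: returns (nan, nan).
    """
    arms = list(values)
    if len(arms) < 3:
        raise ChromatinError("need >= 3 arms for a rank correlation")
    has_enriched = any(labels[a] == "enriched" for a in arms)
    has_other = any(labels[a] == "other" for a in arms)
    if not (has_enriched and has_other):
        raise ChromatinError("both arm groups must be non-empty")
    x = np.asarray([values[a] for a in arms], dtype=float)
    y = np.asarray([1.0 if labels[a] == "enriched" else 0.0 for a in arms])
    if np.all(x == x[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlation_table(
    matrix: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-factor group association over a coverage matrix."""
    rows = []
    for factor in matrix.columns:
        rho, p = group_association(matrix[factor].to_dict(), labels)
        rows.append((factor, rho, p))
    return pd.DataFrame(rows, columns=["factor", "rho", "p_value"])


# ---------------------------------------------------------------------------
# matrices and clustering
# ---------------------------------------------------------------------------

def deg_proportion_matrix(per_dataset_arm_counts: pd.DataFrame) -> pd.DataFrame:
    """Datasets x arms matrix of upregulated-DEG percentages.

    Each count is divided by the dataset's total subtelomeric
    upregulated DEGs, so each row sums to 100.  Datasets with no
    subtelomeric upregulated genes are dropped with a warning.
    """
    counts = per_dataset_arm_counts.astype(float)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning(
            "dropping dataset(s) with zero subtelomeric upregulated genes: %s",
            list(counts.index[empty]),
        )
        counts = counts.loc[~empty]
        totals = totals.loc[~empty]
    return counts.div(totals, axis=0) * 100.0


def standardize_matrix(
    matrix: pd.DataFrame, axis: str = "columns"
) -> tuple[pd.DataFrame, list[str]]:
    """Column-wise z-scores (mean 0, sd 1 with the n-1 denominator,
    matching R's ``scale``); zero-variance columns become all-zero and
    are returned in the flag list."""
    if axis != "columns":
        matrix = matrix.T
    if len(matrix) < 2:
        raise ChromatinError("standardization needs >= 2 rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    flat = list(matrix.columns[sd == 0])
    sd_safe = sd.replace(0, 1.0)
    z = (matrix - mean) / sd_safe
    z[flat] = 0.0
    if axis != "columns":
        z = z.T
    return z, flat


def cluster_order(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "complete",
    axis: str = "rows",
) -> tuple[list[str], np.ndarray]:
    """Agglomerative hierarchical clustering of one axis.

    Returns the dendrogram leaf order (labels) and the scipy linkage
    matrix (merge tree with heights).  Ties break deterministically by
    input order via scipy's ordered distance handling.
    """
    data = matrix if axis == "rows" else matrix.T
    labels = list(data.index)
    if len(labels) < 2:
        raise ChromatinError("clustering needs >= 2 items")
    values = data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ChromatinError("non-finite values: standardize the matrix first")
    dist = pdist(values, metric=metric)
    tree = hierarchy.linkage(dist, method=linkage)
    leaves = hierarchy.leaves_list(tree)
    return [labels[i] for i in leaves], tree
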