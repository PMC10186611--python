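"""Differential-expression sets: DEG classification from DESeq2-style
result tables, exclusive two-set partitions (the Venn logic), and the
subtelomeric normalized-count derepression comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("subtelo")


class DEGError(ValueError):
    pass


# ---------------------------------------------------------------------------
# DEG sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEGSet:
    """Named up/down gene-id sets over a stated universe.

    The universe is every tested gene (protein-coding + pseudogenes),
    including genes whose adjusted p-value was removed by independent
    filtering — those can never be DEGs but still count toward N.
    """

    name: str
    universe: frozenset
    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise DEGError(f"{self.name}: genes both up and down: {sorted(self.up & self.down)[:3]}")
        if not (self.up | self.down) <= self.universe:
            raise DEGError(f"{self.name}: DEGs outside the universe")

    @property
    def degs(self) -> frozenset:
        return self.up | self.down

    def to_dict(self) -> dict:
        return {
            "name": self.name, "universe_size": len(self.universe),
            "up": sorted(self.up), "down": sorted(self.down),
        }


def read_deseq_results(path: str | Path) -> pd.DataFrame:
    """Read a DESeq2-style results TSV.

    Requires columns ``gene_id``, ``log2FoldChange`` and ``padj``
    (extra columns are ignored); NA/empty padj is kept as NaN.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2FoldChange", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise DEGError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def classify_degs(
    rows: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    name: str = "degs",
) -> DEGSet:
    """Threshold a results table into up/down DEG sets.

    up: padj < alpha and log2FC >= lfc_threshold;
    down: padj < alpha and log2FC <= -lfc_threshold.
    Rows with missing padj are never DEGs but stay in the universe.
    """
    if lfc_threshold < 0:
        raise DEGError("lfc_threshold must be >= 0")
    if rows["gene_id"].duplicated().any():
        dupes = rows.loc[rows["gene_id"].duplicated(), "gene_id"].tolist()
        raise DEGError(f"duplicate gene_id(s) in results table: {dupes[:3]}")
    padj = rows["padj"].to_numpy(dtype=float)
    lfc = rows["log2FoldChange"].to_numpy(dtype=float)
    sig = ~np.isnan(padj) & (padj < alpha)
    up = rows.loc[sig & (lfc >= lfc_threshold), "gene_id"]
    down = rows.loc[sig & (lfc <= -lfc_threshold), "gene_id"]
    return DEGSet(name, frozenset(rows["gene_id"]), frozenset(up), frozenset(down))


# ---------------------------------------------------------------------------
# set partitions (Venn logic)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SetPartition:
    """Exclusive partition of two DEG sets: A-only, shared, B-only."""

    only_a: frozenset
    shared: frozenset
    only_b: frozenset

    def sizes(self) -> dict:
        return {
            "only_a": len(self.only_a),
            "shared": len(self.shared),
            "only_b": len(self.only_b),
        }


def partition_sets(
    a: DEGSet, b: DEGSet, direction_strict: bool = False
) -> SetPartition:
    """Cross two DEG sets into exclusive groups.

    By default a gene is "shared" when it is a DEG in both sets
    regardless of direction; with ``direction_strict`` it must move the
    same way in both.
    """
    if a.universe != b.universe:
        logger.warning(
            "DEG sets %s and %s have different universes (%d vs %d genes): using the union",
            a.name, b.name, len(a.universe), len(b.universe),
        )
    if direction_strict:
        shared = (a.up & b.up) | (a.down & b.down)
    else:
        shared = a.degs & b.degs
    return SetPartition(
        only_a=frozenset(a.degs - shared),
        shared=frozenset(shared),
        only_b=frozenset(b.degs - shared),
    )


# ---------------------------------------------------------------------------
# subtelomeric count comparison
# ---------------------------------------------------------------------------

#: the four pairwise contrasts drawn in the derepression figure:
#: (group1, group2) of "<degclass>_<condition>" labels
DEFAULT_CONTRASTS = (
    ("up_{c1}", "up_{c2}"),
    ("down_{c1}", "down_{c2}"),
    ("up_{c1}", "nodeg_{c1}"),
    ("down_{c1}", "nodeg_{c1}"),
)


@dataclass
class GroupComparisonResult:
    """Medians/IQRs per group plus omnibus and pairwise rank tests."""

    groups: pd.DataFrame          # label, n, median, q1, q3
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame        # group1, group2, statistic, p_value
    adjustment: str = "none"

    def to_frame(self) -> pd.DataFrame:
        g = self.groups.copy()
        g["omnibus_statistic"] = self.omnibus_statistic
        g["omnibus_p"] = self.omnibus_p
        return g


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample Wilcoxon/Mann-Whitney rank-sum test (exact for small
    tie-free samples, normal approximation otherwise)."""
    res = stats.mannwhitneyu(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def subtelomeric_count_comparison(
    count_matrix: pd.DataFrame,
    condition_labels: dict,
    deg_set: DEGSet,
    distances: pd.DataFrame,
    width: int = 2_000_000,
    adjust: bool = False,
) -> GroupComparisonResult:
    """Compare normalized counts of subtelomeric genes across DEG class
    and condition.

    Genes with telomere distance < ``width`` are split into
    {no-DEG, up, down} x {condition1, condition2} groups of per-gene
    mean normalized counts.  A Kruskal-Wallis omnibus test runs over all
    non-empty groups, plus the four pairwise rank-sum contrasts of the
    derepression analysis (up young vs senescent, down young vs
    senescent, and each DEG class vs no-DEGs in the young condition).

    ``count_matrix``: genes x samples (index = gene_id);
    ``condition_labels``: sample -> condition, exactly two conditions,
    first-seen order defines (young, senescent).
    """
    conditions = list(dict.fromkeys(condition_labels.values()))
    if len(conditions) != 2:
        raise DEGError(f"need exactly 2 conditions, got {conditions}")
    c1, c2 = conditions
    missing = set(count_matrix.index) - set(distances["gene_id"])
    if missing:
        raise DEGError(f"{len(missing)} gene(s) in count matrix lack distances")

    near = distances.loc[distances["distance_bp"] < width, "gene_id"]
    sub = count_matrix.loc[count_matrix.index.intersection(near)]
    # per-gene mean of normalized counts within each condition
    means = {}
    for cond in conditions:
        samples = [s for s, c in condition_labels.items() if c == cond]
        means[cond] = sub[samples].mean(axis=1)

    def deg_class(gene: str) -> str:
        if gene in deg_set.up:
            return "up"
        if gene in deg_set.down:
            return "down"
        return "nodeg"

    classes = pd.Series([deg_class(g) for g in sub.index], index=sub.index)
    group_values: dict[str, np.ndarray] = {}
    rows = []
    for cls in ("nodeg", "up", "down"):
        for cond in conditions:
            label = f"{cls}_{cond}"
            vals = means[cond][classes == cls].to_numpy()
            group_values[label] = vals
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = float("nan")
            rows.append((label, len(vals), med, q1, q3))
    groups = pd.DataFrame(rows, columns=["label", "n", "median", "q1", "q3"])

    nonempty = [v for v in group_values.values() if len(v)]
    if len(nonempty) < 2:
        raise DEGError("omnibus test needs >= 2 non-empty groups")
    allvals = np.concatenate(nonempty)
    if np.all(allvals == allvals[0]):
        stat, p = 0.0, 1.0  # every value identical: all ties
    else:
        stat, p = stats.kruskal(*nonempty)

    pw_rows = []
    for g1_t, g2_t in DEFAULT_CONTRASTS:
        g1 = g1_t.format(c1=c1, c2=c2)
        g2 = g2_t.format(c1=c1, c2=c2)
        if len(group_values[g1]) == 0 or len(group_values[g2]) == 0:
            logger.warning("contrast %s vs %s skipped: empty group", g1, g2)
            continue
        u, pv = rank_sum_test(group_values[g1], group_values[g2])
        pw_rows.append((g1, g2, u, pv))
    pairwise = pd.DataFrame(pw_rows, columns=["group1", "group2", "statistic", "p_value"])
    adjustment = "none"
    if adjust and len(pairwise):
        from .enrichment import adjust_bh

        pairwise["p_adjusted"] = adjust_bh(pairwise["p_value"].to_numpy())
        adjustment = "benjamini-hochberg"
    return GroupComparisonResult(groups, float(stat), float(p), pairwise, adjustment)
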