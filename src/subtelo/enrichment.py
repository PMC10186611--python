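"""Hypergeometric enrichment: upper-tail p-values and fold enrichment
for telomere-distance bins, subtelomere arm windows and set overlaps.

The test asks how surprising it is that ``k`` of the ``s`` genes of
interest fall in an interval (or second set) containing ``M`` of the
``N`` genes in the genome (or universe), under sampling without
replacement:

    p = P(X >= k),   X ~ Hypergeometric(N, M, s)

Fold enrichment is the ratio of the observed to the expected proportion,

    FE = (k / s) / (M / N)

so FE = 1 is the null expectation, FE > 1 enrichment and FE < 1
depletion.  p-values are reported raw by default; Benjamini-Hochberg
adjustment is available as an opt-in for any family of tests produced
here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import SubtelomereWindow

#: below this population size the tail is summed in exact rational
#: arithmetic (math.comb); above it scipy's log-gamma implementation is
#: used.  600 keeps the exact path instantaneous while covering every
#: population size where last-ulp agreement with enumeration matters.
_EXACT_N_MAX = 600


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric enrichment test.

    ``k``: successes in the sample; ``s``: sample size (genes of
    interest); ``M``: successes in the population (genes in the
    interval / set B); ``N``: population size.  ``fold_enrichment`` is
    NaN when the interval holds no genes (M = 0).
    """

    label: str
    k: int
    s: int
    M: int
    N: int
    fold_enrichment: float
    p_value: float
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label, "k": self.k, "s": self.s, "M": self.M,
            "N": self.N, "fold_enrichment": self.fold_enrichment,
            "p_value": self.p_value, "flagged": self.flagged,
        }


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def _validate_ksmn(k: int, s: int, M: int, N: int) -> None:
    if not (0 <= M <= N and 0 <= s <= N):
        raise EnrichmentError(f"invalid hypergeometric parameters k={k} s={s} M={M} N={N}")
    if not (max(0, s + M - N) <= k <= min(s, M)):
        raise EnrichmentError(f"k={k} outside support for s={s}, M={M}, N={N}")


def hypergeom_upper_tail(k: int, s: int, M: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, M, s).

    Exact rational tail summation for small populations; scipy's
    survival function (log-gamma based, evaluated at k - 1 so the
    observed count is included in the tail) for large ones.
    """
    _validate_ksmn(k, s, M, N)
    if k <= max(0, s + M - N):
        return 1.0
    if N <= _EXACT_N_MAX:
        num = sum(math.comb(M, i) * math.comb(N - M, s - i) for i in range(k, min(s, M) + 1))
        return float(Fraction(num, math.comb(N, s)))
    return float(stats.hypergeom.sf(k - 1, N, M, s))


def hypergeom_upper_tail_vec(
    k: np.ndarray, s: np.ndarray | int, M: np.ndarray, N: np.ndarray | int
) -> np.ndarray:
    """Vectorised P(X >= k) for simulation-scale inputs (scipy path)."""
    return stats.hypergeom.sf(np.asarray(k) - 1, N, M, s)


def fold_enrichment(k: int, s: int, M: int, N: int) -> float:
    """(k/s) / (M/N); NaN when M = 0 (interval without genes)."""
    if s <= 0 or N <= 0:
        raise EnrichmentError("fold enrichment needs s > 0 and N > 0")
    if M == 0:
        return float("nan")
    return (k / s) / (M / N)


def enrichment_test(label: str, k: int, s: int, M: int, N: int,
                    alpha: float = 0.05) -> EnrichmentResult:
    """FE + upper-tail p for one interval; flagged when p < alpha and FE > 1."""
    _validate_ksmn(k, s, M, N)
    if s == 0:  # no genes of interest at all: nothing to test
        return EnrichmentResult(label, 0, 0, M, N,
                                float("nan") if M == 0 else 0.0, 1.0, False)
    fe = fold_enrichment(k, s, M, N)
    p = hypergeom_upper_tail(k, s, M, N)
    flagged = bool(p < alpha and not math.isnan(fe) and fe > 1.0)
    return EnrichmentResult(label, k, s, M, N, fe, p, flagged)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of one family of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# genomic applications
# ---------------------------------------------------------------------------

def bin_enrichment_profile(
    deg_genes: Sequence[str],
    distances: pd.DataFrame,
    bin_width: int = 2_000_000,
    max_distance: int = 15_000_000,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """DEG enrichment per telomere-distance bin.

    Bin i covers distances ``[i*w, (i+1)*w)``; within each bin
    ``k`` = DEGs, ``M`` = all genes, against ``s`` = total DEGs and
    ``N`` = total genes genome-wide.  Returns one row per bin up to
    ``max_distance``; p-values are raw unless ``adjust`` is set, in
    which case a ``p_adjusted`` column is added.
    """
    if bin_width <= 0:
        raise EnrichmentError("bin_width must be > 0")
    if distances.empty:
        raise EnrichmentError("empty gene distance table")
    deg_set = set(deg_genes)
    missing = deg_set - set(distances["gene_id"])
    if missing:
        raise EnrichmentError(
            f"{len(missing)} DEG(s) missing from the gene table, e.g. {sorted(missing)[:3]}"
        )
    n_bins = int(np.ceil(max_distance / bin_width))
    d = distances["distance_bp"].to_numpy()
    idx = d // bin_width
    is_deg = distances["gene_id"].isin(deg_set).to_numpy()
    N = len(distances)
    s = len(deg_set)
    results = []
    for i in range(n_bins):
        in_bin = idx == i
        M = int(in_bin.sum())
        k = int((in_bin & is_deg).sum())
        if M == 0:
            results.append(EnrichmentResult(f"bin_{i}", k, s, M, N, float("nan"), 1.0))
        else:
            results.append(enrichment_test(f"bin_{i}", k, s, M, N, alpha))
    frame = results_frame(results)
    frame.insert(1, "bin_start_bp", np.arange(n_bins) * bin_width)
    frame.insert(2, "bin_end_bp", (np.arange(n_bins) + 1) * bin_width)
    if adjust:
        frame["p_adjusted"] = adjust_bh(frame["p_value"].to_numpy())
    return frame


def arm_enrichment(
    deg_genes: Sequence[str],
    distances: pd.DataFrame,
    windows: Sequence[SubtelomereWindow],
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """DEG enrichment per subtelomere arm window.

    ``s`` is the genome-wide DEG count (configurable upstream by
    restricting ``deg_genes``); an arm is flagged "enriched" when
    p < alpha and FE > 1.  Windows without genes get NaN FE and are
    never flagged.
    """
    deg_set = set(deg_genes)
    is_deg = distances["gene_id"].isin(deg_set).to_numpy()
    N = len(distances)
    s = len(deg_set)
    if N == 0:
        raise EnrichmentError("empty gene distance table")
    results = []
    for w in windows:
        from .genome import genes_in_window

        mask = genes_in_window(distances, w).to_numpy()
        M = int(mask.sum())
        k = int((mask & is_deg).sum())
        if M == 0:
            results.append(EnrichmentResult(w.arm, k, s, M, N, float("nan"), 1.0))
        else:
            results.append(enrichment_test(w.arm, k, s, M, N, alpha))
    frame = results_frame(results)
    if adjust:
        frame["p_adjusted"] = adjust_bh(frame["p_value"].to_numpy())
    return frame


def overlap_enrichment(
    set_a: set, set_b: set, universe_size: int, label: str = "overlap",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Enrichment of the overlap of two gene sets in a shared universe.

    ``k = |A ∩ B|``, ``s = |A|``, ``M = |B|``; the statistic is
    symmetric in A and B.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise EnrichmentError("both sets must be non-empty")
    if universe_size < len(a | b):
        raise EnrichmentError(
            f"universe size {universe_size} smaller than |A ∪ B| = {len(a | b)}"
        )
    return enrichment_test(label, len(a & b), len(a), len(b), universe_size, alpha)
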