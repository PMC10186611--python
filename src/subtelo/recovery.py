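"""Seeded recovery and calibration experiments.

Each function plants a known signal with the synthetic-data generators,
runs the corresponding analysis exactly as the pipeline would, and
summarises how well the planted parameter is recovered (or, for null
configurations, how often the method flags anything).  These are the
quantitative checks behind the package's self-validation: parameter
recovery on the fold-enrichment scale, null calibration of the arm
flagging rate, the derepression rank-test pattern, and the planted
coverage-group correlation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import coverage_matrix, group_association
from .degs import subtelomeric_count_comparison
from .enrichment import arm_enrichment, bin_enrichment_profile, overlap_enrichment
from .genome import define_subtelomere_windows, distance_table
from .simulate import (
    SimulationConfig,
    generate_counts,
    generate_deg_set,
    generate_genome,
    generate_peak_track,
)


def _prepared(config: SimulationConfig):
    assembly, genes = generate_genome(config)
    distances = distance_table(genes, assembly)
    windows = define_subtelomere_windows(assembly, config.deg.window)
    return assembly, genes, distances, windows


def planted_fe_recovery(
    config: SimulationConfig,
    n_seeds: int = 200,
    detection_alpha: float = 1e-3,
) -> dict:
    """Recovery of a planted first-window fold enrichment.

    For each seed a fresh DEG set is planted on a fixed genome; the
    first telomere-distance bin's estimated FE and the per-arm
    detection rate (p < ``detection_alpha`` and FE > 1 on planted arms)
    are recorded.  Returns the median estimated FE, the planted value,
    and the detection power.
    """
    assembly, genes, distances, windows = _prepared(config)
    fes, detected, total_planted = [], 0, 0
    for i in range(n_seeds):
        rng = np.random.default_rng([7, config.seed, i])
        deg_set, truth = generate_deg_set(
            assembly, genes, config, rng=rng, distances=distances
        )
        profile = bin_enrichment_profile(
            sorted(deg_set.up), distances,
            bin_width=config.deg.window, max_distance=config.deg.window,
        )
        fes.append(profile.loc[0, "fold_enrichment"])
        arms = arm_enrichment(sorted(deg_set.up), distances, windows)
        planted = arms["label"].isin(truth.planted_arms)
        hit = (arms["p_value"] < detection_alpha) & (arms["fold_enrichment"] > 1)
        detected += int((planted & hit).sum())
        total_planted += int(planted.sum())
    return {
        "planted_fold": config.deg.planted_fold,
        "median_fe": float(np.median(fes)),
        "power": detected / total_planted,
        "n_seeds": n_seeds,
    }


def null_arm_flag_rate(
    config: SimulationConfig,
    n_reps: int = 1000,
    alpha: float = 0.05,
    n_degs: int = 1000,
) -> float:
    """Fraction of arm windows flagged when DEGs are uniform.

    DEGs are sampled uniformly without replacement from all genes, so
    every flag is a false positive; the hypergeometric test's
    discreteness makes the expected rate fall at or below ``alpha``.
    """
    _, genes, distances, windows = _prepared(config)
    gene_ids = distances["gene_id"].to_numpy()
    flags = tests = 0
    for i in range(n_reps):
        rng = np.random.default_rng([11, config.seed, i])
        degs = rng.choice(gene_ids, size=n_degs, replace=False)
        arms = arm_enrichment(degs, distances, windows, alpha=alpha)
        flags += int(arms["flagged"].sum())
        tests += len(arms)
    return flags / tests


def plant_overlap_sets(
    rng: np.random.Generator, universe_size: int, size_a: int, size_b: int,
    fold: float,
) -> tuple[set, set]:
    """Two gene sets whose expected overlap FE equals ``fold``.

    A is uniform; members of A enter B with probability
    ``fold * |B| / N`` and non-members with the complementary rate that
    keeps E[|B|] = size_b.
    """
    if fold * size_b > universe_size or fold * size_a > universe_size:
        raise ValueError(f"planted overlap fold {fold} infeasible for these sizes")
    ids = np.arange(universe_size)
    a = rng.choice(ids, size=size_a, replace=False)
    in_a = np.zeros(universe_size, dtype=bool)
    in_a[a] = True
    p1 = fold * size_b / universe_size
    p0 = size_b * (1 - fold * size_a / universe_size) / (universe_size - size_a)
    b_mask = rng.random(universe_size) < np.where(in_a, p1, p0)
    return set(a.tolist()), set(ids[b_mask].tolist())


def overlap_fe_recovery(
    n_seeds: int = 200,
    universe_size: int = 20_000,
    size_a: int = 1_000,
    size_b: int = 1_500,
    fold: float = 2.5,
    seed: int = 0,
) -> dict:
    """Median recovered overlap fold enrichment over planted set pairs."""
    fes = []
    for i in range(n_seeds):
        rng = np.random.default_rng([13, seed, i])
        a, b = plant_overlap_sets(rng, universe_size, size_a, size_b, fold)
        result = overlap_enrichment(a, b, universe_size)
        fes.append(result.fold_enrichment)
    return {"planted_fold": fold, "median_fe": float(np.median(fes)), "n_seeds": n_seeds}


def derepression_recovery(config: SimulationConfig, n_seeds: int = 100,
                          p_threshold: float = 1e-3) -> dict:
    """How often the planted repression/derepression pattern is seen.

    The qualitative pattern of the count comparison: subtelomeric
    up-DEGs sit below the no-DEG median in the young condition and above
    their own young median at senescence, with both rank-sum contrasts
    significant at ``p_threshold``.
    """
    assembly, genes, distances, _ = _prepared(config)
    hits = 0
    for i in range(n_seeds):
        rng = np.random.default_rng([17, config.seed, i])
        deg_set, _ = generate_deg_set(
            assembly, genes, config, rng=rng, distances=distances
        )
        counts, conditions = generate_counts(genes, deg_set, config, rng=rng)
        res = subtelomeric_count_comparison(
            counts, conditions, deg_set, distances, config.deg.window
        )
        med = res.groups.set_index("label")["median"]
        pw = res.pairwise.set_index(["group1", "group2"])["p_value"]
        pattern = (
            med["up_young"] < med["nodeg_young"]
            and med["up_senescent"] > med["up_young"]
            and pw[("up_young", "up_senescent")] < p_threshold
            and pw[("up_young", "nodeg_young")] < p_threshold
        )
        hits += bool(pattern)
    return {"pattern_rate": hits / n_seeds, "n_seeds": n_seeds}


def group_correlation_recovery(config: SimulationConfig, n_seeds: int = 200) -> dict:
    """Sign recovery of a planted coverage difference between arm groups,
    plus the permutation null of the rank correlation."""
    assembly, genes, distances, windows = _prepared(config)
    planted = tuple(config.deg.planted_arms) if config.deg.planted_arms else tuple(
        w.arm for w in windows[: len(windows) // 2]
    )
    labels = {w.arm: "enriched" if w.arm in planted else "other" for w in windows}
    positive = 0
    rhos = []
    for i in range(n_seeds):
        rng = np.random.default_rng([19, config.seed, i])
        track = generate_peak_track(windows, labels, config, "factor", rng=rng)
        cov = coverage_matrix([track], windows)["factor"].to_dict()
        rho, _ = group_association(cov, labels)
        rhos.append(rho)
        positive += rho > 0
    # permutation null on the last track's coverage vector
    arms = [w.arm for w in windows]
    values = np.asarray([cov[a] for a in arms])
    y = np.asarray([1.0 if labels[a] == "enriched" else 0.0 for a in arms])
    perm_rng = np.random.default_rng([23, config.seed])
    perm_rhos = [
        stats.spearmanr(values, perm_rng.permutation(y))[0] for _ in range(1000)
    ]
    return {
        "positive_rate": positive / n_seeds,
        "mean_rho": float(np.mean(rhos)),
        "permuted_mean_rho": float(np.mean(perm_rhos)),
        "n_seeds": n_seeds,
    }
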