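"""End-to-end orchestration: config in, TSV/JSON tables out.

A run sequences the analyses in the order the method proceeds:
telomere distances -> DEG classification -> bin and arm enrichment ->
set partition / overlap enrichment -> subtelomeric count comparison ->
chromatin coverage, correlation, proportion and z-score matrices with
cluster orderings.  Inputs come either from real files or from the
synthetic-data generators (a ``simulate`` block in the config); every
output and threshold is recorded in a JSON manifest so no silent
defaults exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromatin import (
    cluster_order,
    correlation_table,
    coverage_matrix,
    deg_proportion_matrix,
    read_peaks,
    standardize_matrix,
)
from .degs import (
    DEGSet,
    classify_degs,
    partition_sets,
    read_deseq_results,
    subtelomeric_count_comparison,
)
from .enrichment import arm_enrichment, bin_enrichment_profile, overlap_enrichment, results_frame
from .genome import (
    define_subtelomere_windows,
    distance_table,
    genes_in_window,
    load_assembly,
    load_gene_annotation,
)
from .simulate import (
    SimulationConfig,
    generate_counts,
    generate_deg_set,
    generate_genome,
    generate_peak_track,
    substream,
    write_centromeres,
    write_chrom_sizes,
    write_counts,
    write_deseq_results,
    write_gtf,
    write_narrowpeak,
)

logger = logging.getLogger("subtelo")

DEFAULT_PARAMS = {
    "anchor": "nearest_edge",
    "window": 2_000_000,
    "bin_width": 2_000_000,
    "max_distance": 15_000_000,
    "alpha": 0.05,
    "lfc_threshold": 1.0,
    "adjust_bh": False,
    "clip_at_centromere": False,
    "excluded_arms": [],
    "direction_strict": False,
    "metric": "euclidean",
    "linkage": "complete",
}

DEFAULT_FACTORS = ("CTCF", "MAZ", "RAD21", "SMC3", "H3K27me3", "H3K9me3")


class PipelineError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_deg_set_json(deg_set: DEGSet, path: Path) -> None:
    path.write_text(json.dumps(deg_set.to_dict(), indent=1) + "\n")


def simulate_inputs(sim_cfg: SimulationConfig, out_dir: Path) -> dict:
    """Materialise a full synthetic input bundle on disk in the same
    formats the real pipeline consumes; returns the path map."""
    out_dir.mkdir(parents=True, exist_ok=True)
    assembly, genes = generate_genome(sim_cfg)
    if sim_cfg.deg.planted_arms is None:
        # emulate the study's situation: only a minority of chromosome
        # ends carry the planted enrichment (every third arm here)
        sim_cfg = SimulationConfig.from_dict(sim_cfg.to_dict())
        sim_cfg.deg.planted_arms = tuple(assembly.arms()[::3])
    paths = {
        "chrom_sizes": out_dir / "genome.chrom.sizes",
        "centromeres": out_dir / "centromeres.bed",
        "annotation": out_dir / "genes.gtf",
        "results_a": out_dir / "deseq_results_a.tsv",
        "results_b": out_dir / "deseq_results_b.tsv",
        "counts": out_dir / "counts.tsv",
        "conditions": out_dir / "conditions.tsv",
        "peaks_dir": out_dir / "peaks",
    }
    write_chrom_sizes(assembly, paths["chrom_sizes"])
    write_centromeres(assembly, paths["centromeres"])
    write_gtf(genes, paths["annotation"])

    rng = substream(sim_cfg.seed, "degs")
    deg_a, truth = generate_deg_set(assembly, genes, sim_cfg, name="dataset_a", rng=rng)
    deg_b, _ = generate_deg_set(assembly, genes, sim_cfg, name="dataset_b", rng=rng)
    write_deseq_results(deg_a, paths["results_a"], seed=sim_cfg.seed)
    write_deseq_results(deg_b, paths["results_b"], seed=sim_cfg.seed + 1)

    counts, conditions = generate_counts(genes, deg_a, sim_cfg)
    write_counts(counts, conditions, paths["counts"], paths["conditions"])

    windows = define_subtelomere_windows(assembly, sim_cfg.deg.window)
    labels = {
        w.arm: "enriched" if w.arm in truth.planted_arms else "other" for w in windows
    }
    paths["peaks_dir"].mkdir(exist_ok=True)
    peak_rng = substream(sim_cfg.seed, "peaks")
    for factor in DEFAULT_FACTORS:
        track = generate_peak_track(windows, labels, sim_cfg, factor, rng=peak_rng)
        write_narrowpeak(track, paths["peaks_dir"] / f"{factor}.narrowPeak")
    manifest = {"simulation": sim_cfg.to_dict(), "planted_truth": {
        "planted_arms": list(truth.planted_arms), "planted_fold": truth.planted_fold,
        "p_in": truth.p_in, "p_out": truth.p_out,
    }}
    (out_dir / "simulation_manifest.json").write_text(json.dumps(manifest, indent=1))
    return {k: str(v) for k, v in paths.items()}


def run_full_analysis(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run every stage from a config mapping (or YAML path); returns the
    manifest (also written to ``manifest.json`` in the run directory)."""
    if not isinstance(config, dict):
        config = load_config(config)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    out = Path(out_dir or config.get("output_dir", "subtelo_run"))
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    if "simulate" in config:
        sim_block = dict(config["simulate"] or {})
        if "seed" in config:
            sim_block.setdefault("seed", config["seed"])
        sim_cfg = SimulationConfig.from_dict(sim_block)
        inputs = simulate_inputs(sim_cfg, out / "inputs")
        annotation_format = "gtf"
    else:
        inputs = dict(config.get("inputs", {}))
        annotation_format = inputs.get("annotation_format", "gtf")
        for key in ("chrom_sizes", "annotation"):
            if key not in inputs or not Path(inputs[key]).exists():
                raise PipelineError(f"missing required input file: {key} "
                                    f"({inputs.get(key, '<unset>')})")

    # -- stage 1: genome + distances ------------------------------------
    assembly = load_assembly(
        inputs["chrom_sizes"], inputs.get("centromeres"),
        excluded_arms=params["excluded_arms"],
    )
    genes = load_gene_annotation(
        inputs["annotation"], fmt=annotation_format, assembly=assembly
    )
    distances = distance_table(genes, assembly, anchor=params["anchor"])
    distances.to_csv(out / "distances.tsv", sep="\t", index=False)
    windows = define_subtelomere_windows(
        assembly, params["window"], params["clip_at_centromere"]
    )

    # -- stage 2: DEG classification ------------------------------------
    gene_ids = set(distances["gene_id"])

    def load_set(path: str, name: str) -> DEGSet:
        rows = read_deseq_results(path)
        rows = rows[rows["gene_id"].isin(gene_ids)]
        return classify_degs(rows, params["alpha"], params["lfc_threshold"], name)

    deg_a = load_set(inputs.get("results_a", inputs.get("deseq_results", "")), "dataset_a")
    deg_b = load_set(inputs["results_b"], "dataset_b") if inputs.get("results_b") else None
    write_deg_set_json(deg_a, out / "degs_a.json")
    if deg_b:
        write_deg_set_json(deg_b, out / "degs_b.json")

    # -- stage 3: bin + arm enrichment ----------------------------------
    profiles = []
    group_sets = {"a_up": deg_a.up, "a_down": deg_a.down}
    partition = None
    if deg_b:
        partition = partition_sets(deg_a, deg_b, params["direction_strict"])
        group_sets.update(
            only_a=partition.only_a, shared=partition.shared, only_b=partition.only_b
        )
    for label, ids in group_sets.items():
        if not ids:
            warnings.append(f"empty DEG group {label}: bin profile skipped")
            continue
        prof = bin_enrichment_profile(
            sorted(ids), distances, params["bin_width"], params["max_distance"],
            params["alpha"], adjust=params["adjust_bh"],
        )
        prof.insert(0, "set", label)
        profiles.append(prof)
    pd.concat(profiles, ignore_index=True).to_csv(out / "bins.tsv", sep="\t", index=False)

    arms = arm_enrichment(sorted(deg_a.up), distances, windows,
                          params["alpha"], adjust=params["adjust_bh"])
    arms.to_csv(out / "arms.tsv", sep="\t", index=False)
    enriched_arms = arms.loc[arms["flagged"], "label"].tolist()

    # -- stage 4: partition + overlap enrichment ------------------------
    if partition is not None:
        (out / "partition.json").write_text(json.dumps(partition.sizes(), indent=1))
        universe = len(deg_a.universe | deg_b.universe)
        rows = [
            overlap_enrichment(deg_a.degs, deg_b.degs, universe, "a_vs_b_all"),
            overlap_enrichment(deg_a.up, deg_b.up, universe, "a_vs_b_up")
            if deg_a.up and deg_b.up else None,
            overlap_enrichment(deg_a.down, deg_b.down, universe, "a_vs_b_down")
            if deg_a.down and deg_b.down else None,
        ]
        results_frame([r for r in rows if r is not None]).to_csv(
            out / "overlaps.tsv", sep="\t", index=False
        )

    # -- stage 5: subtelomeric count comparison -------------------------
    if inputs.get("counts"):
        counts = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
        conditions = pd.read_csv(inputs["conditions"], sep="\t", index_col=0)[
            "condition"
        ].to_dict()
        counts = counts.loc[counts.index.isin(gene_ids)]
        comparison = subtelomeric_count_comparison(
            counts, conditions, deg_a, distances, params["window"],
            adjust=params["adjust_bh"],
        )
        comparison.to_frame().to_csv(out / "counts_compare.tsv", sep="\t", index=False)
        comparison.pairwise.to_csv(out / "counts_pairwise.tsv", sep="\t", index=False)
    else:
        warnings.append("no count matrix: count comparison skipped")

    # -- stage 6: chromatin profile -------------------------------------
    if inputs.get("peaks_dir") and Path(inputs["peaks_dir"]).is_dir():
        tracks = [
            read_peaks(p) for p in sorted(Path(inputs["peaks_dir"]).glob("*"))
            if p.suffix in (".bed", ".narrowPeak", ".broadPeak")
        ]
        if tracks:
            cov = coverage_matrix(tracks, windows)
            cov.rename_axis("arm").to_csv(out / "coverage.tsv", sep="\t")
            labels = {
                w.arm: "enriched" if w.arm in enriched_arms else "other"
                for w in windows
            }
            if enriched_arms and len(enriched_arms) < len(windows):
                correlation_table(cov, labels).to_csv(
                    out / "correlation.tsv", sep="\t", index=False
                )
            else:
                warnings.append("arm grouping degenerate: correlation skipped")
            zmat, flat = standardize_matrix(cov)
            if flat:
                warnings.append(f"zero-variance factor column(s): {flat}")
            zmat.rename_axis("arm").to_csv(out / "zmatrix.tsv", sep="\t")
            order, _ = cluster_order(zmat, params["metric"], params["linkage"], "rows")
            factor_order, _ = cluster_order(zmat, params["metric"], params["linkage"], "columns")
            (out / "cluster_order.json").write_text(
                json.dumps({"arms": order, "factors": factor_order}, indent=1)
            )
    else:
        warnings.append("no peak tracks: chromatin profile skipped")

    # -- stage 7: per-dataset arm proportions ---------------------------
    datasets = {"dataset_a": deg_a} | ({"dataset_b": deg_b} if deg_b else {})
    count_rows = {}
    for name, ds in datasets.items():
        up_mask = distances["gene_id"].isin(ds.up)
        count_rows[name] = [
            int((genes_in_window(distances, w) & up_mask).sum()) for w in windows
        ]
    props = deg_proportion_matrix(
        pd.DataFrame(count_rows, index=[w.arm for w in windows]).T
    )
    props.rename_axis("dataset").to_csv(out / "proportions.tsv", sep="\t")
    if len(props) >= 2:
        ds_order, _ = cluster_order(props, params["metric"], params["linkage"], "rows")
        (out / "proportion_cluster_order.json").write_text(
            json.dumps({"datasets": ds_order}, indent=1)
        )

    # -- manifest -------------------------------------------------------
    outputs = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": config.get("seed"),
        "params": params,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "input_checksums": {
            k: _sha256(Path(v)) for k, v in inputs.items() if Path(str(v)).is_file()
        },
        "outputs": outputs,
        "output_checksums": {o: _sha256(out / o) for o in outputs},
        "enriched_arms": enriched_arms,
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
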