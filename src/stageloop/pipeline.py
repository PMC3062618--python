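"""End-to-end orchestration: design -> simulate/load -> normalize -> model ->
trajectories -> enrichment, with one seed driving every random draw.

All randomness flows from ``config.seed`` through named substreams (via
numpy SeedSequence) so individual steps can be re-run independently and two
runs with the same config are identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .design import LoopDesign, build_double_loop
from .enrichment import enrich_stage_peaks, enrichment_frame
from .models import (
    adjacent_contrasts,
    fit_gene_models,
    fit_global_normalization,
    fit_prepost,
    overall_stage_test,
    prepost_contrasts,
)
from .preprocess import (
    build_expression_matrix,
    control_threshold,
    filter_genes,
    pooled_control_signals,
)
from .simulate import SimulationParams, default_params, simulate_experiment
from .trajectories import correlation_summary, hcluster, peak_profiles, peak_summary

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Declarative run configuration (YAML-loadable, CLI-overridable)."""

    out_dir: str = "stageloop_out"
    simulate: bool = True
    n_stages: int = 40
    n_genes: int = 6857
    seed: int = 0
    alpha: float = 0.01
    ci_level: float = 0.90
    min_sep: int = 3
    span_intensity: float = 0.2
    span_spatial: float = 0.3
    split_stage: int | None = None  # default: stage 35 or n_stages - 1 if smaller
    spot_dir: str | None = None
    design_file: str | None = None
    annotation_file: str | None = None
    dye_effect: float = 0.3
    array_sd: float = 0.3
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.min_sep < 1:
            raise ValueError("min_sep must be >= 1")
        if self.split_stage is None:
            self.split_stage = min(35, self.n_stages - 1)
        if not (1 <= self.split_stage <= self.n_stages - 1):
            raise ValueError("split_stage must be in [1, n_stages - 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def substream_seed(seed: int, name: str) -> int:
    """Deterministic per-module child seed (< 2**31) derived from one root."""
    import zlib

    h = zlib.crc32(name.encode()) % (2**16)
    ss = np.random.SeedSequence([int(seed), h])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage of the analysis and write all output tables.

    Returns the manifest (also written to ``manifest.json``): the config,
    per-step counts, and timings.  Identical config + seed give identical
    counts.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__, "counts": {}}

    # --- design + data -----------------------------------------------------
    if config.simulate:
        design = build_double_loop(config.n_stages)
        params = default_params(
            design,
            n_genes=config.n_genes,
            seed=substream_seed(config.seed, "simulate"),
            dye_effect=config.dye_effect,
            array_sd=config.array_sd,
            noise_sd=config.noise_sd,
        )
        tables, truth = simulate_experiment(design, params)
        sio.write_design(design, out / "design.tsv")
        sio.write_truth(truth, out / "truth.tsv")
    else:
        if not config.design_file or not Path(config.design_file).exists():
            raise FileNotFoundError(f"design file missing: {config.design_file}")
        if not config.spot_dir or not Path(config.spot_dir).exists():
            raise FileNotFoundError(f"spot directory missing: {config.spot_dir}")
        design = sio.read_design(config.design_file)
        design.validate()
        tables = sio.read_spot_tables(config.spot_dir)
    manifest["counts"]["arrays"] = design.n_arrays
    manifest["counts"]["channels"] = len(design.channels)

    # --- preprocessing -----------------------------------------------------
    controls = pooled_control_signals(tables)
    threshold = control_threshold(controls)
    genes = filter_genes(tables, threshold)
    manifest["counts"]["genes_spotted"] = int(
        (tables[0]["control_type"] == "").sum()
    )
    manifest["counts"]["genes_retained"] = len(genes)
    manifest["threshold"] = threshold
    matrix = build_expression_matrix(
        tables,
        design,
        genes,
        span_intensity=config.span_intensity,
        span_spatial=config.span_spatial,
    )
    sio.write_expression_matrix(matrix, out / "expression_matrix.tsv")

    # --- mixed models ------------------------------------------------------
    norm = fit_global_normalization(matrix)
    fit = fit_gene_models(norm.residuals, design)
    fits_table = pd.concat(
        [fit.summary_frame(), fit.lsmeans_frame(), fit.lsmean_se_frame().add_suffix("_se")],
        axis=1,
    )
    fits_table.to_csv(out / "gene_fits.tsv", sep="\t")
    significant = overall_stage_test(fit, alpha=config.alpha)
    manifest["counts"]["significant_overall"] = len(significant)

    contrasts = adjacent_contrasts(fit)
    contrasts.to_csv(out / "adjacent_contrasts.tsv", sep="\t", index=False)
    sig_by_pair = (
        contrasts[contrasts["p"] < config.alpha].groupby("pair").size()
    )
    manifest["counts"]["significant_adjacent_any"] = int(
        contrasts[contrasts["p"] < config.alpha]["gene_id"].nunique()
    )
    manifest["counts"]["mean_significant_per_pair"] = float(
        sig_by_pair.reindex(contrasts["pair"].unique(), fill_value=0).mean()
    )

    pp_fit = fit_prepost(norm.residuals, design, split_stage=config.split_stage)
    pp = prepost_contrasts(pp_fit)
    pp.to_csv(out / "prepost_contrasts.tsv", sep="\t", index=False)
    manifest["counts"]["significant_prepost"] = int((pp["p"] < config.alpha).sum())

    # --- trajectories ------------------------------------------------------
    lsmeans = fit.lsmeans_frame()
    lsmean_se = fit.lsmean_se_frame()
    sig_any = pd.Index(
        contrasts[contrasts["p"] < config.alpha]["gene_id"].unique()
    )
    traj_genes = sig_any if len(sig_any) >= 2 else lsmeans.index
    profiles = peak_profiles(
        lsmeans.loc[traj_genes],
        lsmean_se.loc[traj_genes],
        ci_level=config.ci_level,
        min_sep=config.min_sep,
    )
    summary = peak_summary(profiles)
    summary["table"].to_csv(out / "peaks.tsv", sep="\t", index=False)
    manifest["counts"]["n_peak_histogram"] = {
        int(k): int(v) for k, v in summary["n_peak_counts"].items()
    }

    corr_genes = significant if len(significant) >= 2 else traj_genes
    corr = correlation_summary(lsmeans.loc[corr_genes], alpha=config.alpha)
    corr.r_matrix.to_csv(out / "correlations.tsv", sep="\t")
    manifest["counts"]["frac_significant_corr"] = corr.frac_significant

    gene_tree = hcluster(lsmeans.loc[traj_genes], axis="genes")
    stage_tree = hcluster(lsmeans, axis="stages")
    (out / "gene_dendrogram.newick").write_text(gene_tree.to_newick() + "\n")
    (out / "stage_dendrogram.newick").write_text(stage_tree.to_newick() + "\n")

    # --- enrichment --------------------------------------------------------
    if config.annotation_file:
        annotation = sio.read_annotation(config.annotation_file)
        results = []
        for stage in sorted(summary["table"]["primary_peak"].unique()):
            results.extend(
                enrich_stage_peaks(summary["table"], annotation, int(stage))
            )
        enrichment_frame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["counts"]["enrichment_tests"] = len(results)

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def null_calibration(
    n_genes: int = 6857,
    n_stages: int = 40,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    alpha: float = 0.01,
    *,
    spot_level: bool = True,
) -> dict:
    """Type-I calibration: simulate tau = 0 genes, count adjacent-pair hits.

    For each seed, simulates the full double loop with no stage effects
    (array and residual noise only), runs normalization and the per-gene
    model, and counts genes with contrast p < alpha per adjacent pair.
    Returns per-seed counts and the grand mean over pairs and seeds.  With
    ``spot_level=False`` channels are generated directly on the log2 scale,
    skipping the spot-table and Lowess steps (useful for quick checks).
    """
    design = build_double_loop(n_stages)
    per_seed_means = []
    counts = []
    analyzed = []
    for seed in seeds:
        if spot_level:
            params = default_params(design, n_genes=n_genes, seed=int(seed))
            tables, _ = simulate_experiment(design, params)
            threshold = control_threshold(pooled_control_signals(tables))
            genes = filter_genes(tables, threshold)
            matrix = build_expression_matrix(tables, design, genes)
        else:
            matrix = simulate_channel_matrix(design, n_genes=n_genes, seed=int(seed))
        norm = fit_global_normalization(matrix)
        fit = fit_gene_models(norm.residuals, design)
        contrasts = adjacent_contrasts(fit)
        by_pair = (
            (contrasts["p"] < alpha)
            .groupby(contrasts["pair"])
            .sum()
            .reindex(contrasts["pair"].unique(), fill_value=0)
        )
        counts.append(by_pair)
        per_seed_means.append(float(by_pair.mean()))
        analyzed.append(matrix.n_genes)
    return {
        "mean_count": float(np.mean(per_seed_means)),
        "per_seed_means": per_seed_means,
        "per_pair_counts": counts,
        "n_genes_simulated": n_genes,
        "n_genes_analyzed": analyzed,
        "alpha": alpha,
    }


def simulate_channel_matrix(
    design: LoopDesign,
    n_genes: int,
    seed: int,
    *,
    tau: np.ndarray | None = None,
    baseline_sd: float = 2.0,
    dye_effect: float = 0.3,
    array_sd: float = 0.3,
    noise_sd: float = 0.25,
):
    """Log2 channel matrix generated directly from the analysis model
    (no spot grid, bias fields or controls) — the fast path for
    calibration and power studies."""
    from .preprocess import ExpressionMatrix

    rng = np.random.default_rng(seed)
    meta = design.channel_table()
    baseline = rng.normal(9.5, baseline_sd, size=n_genes)
    if tau is None:
        tau = np.zeros((n_genes, design.n_stages))
    a = rng.normal(0.0, array_sd, size=design.n_arrays)
    a_by_id = dict(zip((arr.array_id for arr in design.arrays), a))
    cols = {}
    for _, row in meta.iterrows():
        mean = (
            baseline
            + tau[:, row["stage"] - 1]
            + (dye_effect if row["dye"] == "Cy5" else 0.0)
            + a_by_id[row["array_id"]]
        )
        cols[row["channel_id"]] = mean + rng.normal(0.0, noise_sd, size=n_genes)
    values = pd.DataFrame(
        cols, index=pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene_id")
    )
    return ExpressionMatrix(values=values, channel_meta=meta.set_index("channel_id"))
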