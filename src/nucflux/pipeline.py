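"""Orchestration of simulate → preprocess → fit → associate → report.

Each stage is a plain function over in-memory tables so it can be used
from Python; :func:`run_pipeline` chains the enabled stages, writes every
intermediate table as TSV, and produces a run report with the gene counts
at each filter step (which are non-increasing along the chain), the
global carry-over estimate, replicate concordance and variance shares.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .associations import (
    rate_feature_correlation,
    replicate_average,
    variance_contributions,
)
from .config import RunConfig
from .fitting import FitConfig, fit_dataset
from .noise import ContaminationModel, NoiseModel, estimate_contamination, fit_noise_model
from .preprocess import (
    REASON_4SU_AFFECTED,
    REASON_FRACTIONATION,
    REASON_UNCORRECTABLE_BIAS,
    capture_probability,
    correct_labeling_bias,
    fit_cutoff_model,
    flag_outliers,
    spike_normalize,
)
from .simulate import (
    SimulatedExperiment,
    SimulationConfig,
    generate_feature_annotations,
    sample_gene_parameters,
    simulate_experiment,
)

__all__ = ["RunReport", "run_pipeline", "stage_simulate", "stage_preprocess",
           "stage_error_models", "stage_fit", "stage_associate"]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    config_digest: str = ""
    counts: dict = field(default_factory=dict)
    contamination: dict = field(default_factory=dict)
    concordance: dict = field(default_factory=dict)
    variance_shares: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"config: {self.config_digest}", "", "gene counts:"]
        for k, v in self.counts.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
        lines.append("contamination (streptavidin carry-over):")
        for k, v in self.contamination.items():
            lines.append(f"  {k}: {v:.4g}" if isinstance(v, float) else f"  {k}: {v}")
        lines.append("")
        lines.append("replicate concordance (Spearman, retained genes):")
        for k, v in self.concordance.items():
            lines.append(f"  {k}: {v:.3f}")
        lines.append("")
        lines.append("variance shares of steady-state abundance:")
        for k, v in self.variance_shares.items():
            lines.append(f"  {k}: {100 * v:.1f}%")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_digest": self.config_digest,
                "counts": self.counts,
                "contamination": self.contamination,
                "concordance": self.concordance,
                "variance_shares": self.variance_shares,
            },
            indent=2,
        )


def simulation_config(cfg: RunConfig) -> SimulationConfig:
    return SimulationConfig(
        n_genes=cfg.n_genes,
        time_grid=cfg.time_grid,
        n_replicates=cfg.n_replicates,
        U=cfg.U,
        pr=cfg.pr,
        noise=cfg.noise,
        cell_cycle=cfg.cell_cycle(),
        seed=cfg.seed,
    )


def stage_simulate(cfg: RunConfig) -> tuple[SimulatedExperiment, pd.DataFrame]:
    sim_cfg = simulation_config(cfg)
    rng = sim_cfg.rng()
    truth = sample_gene_parameters(sim_cfg, rng)
    experiment = simulate_experiment(truth, sim_cfg, rng)
    features = generate_feature_annotations(truth, sim_cfg, rng)
    return experiment, features


def _effective_bins(n_points: int, n_bins: int) -> int:
    # the dispersion fit needs populated bins; cap interval count by density
    return max(3, min(n_bins, n_points // 25))


def stage_preprocess(
    expression: pd.DataFrame,
    sample_reads: pd.DataFrame,
    labeled_comparison: pd.DataFrame,
    fractionation_comparison: pd.DataFrame,
    features: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Spike normalization, outlier exclusion, labeling-bias correction.

    Returns (corrected long table, exclusion list, counts dict).
    """
    reads = sample_reads.set_index(["fraction", "replicate", "time_min"])
    expr = spike_normalize(
        expression.drop(columns=["fpkm_spikenorm"], errors="ignore"),
        reads["fly_mapped_reads"],
        reads["yeast_mapped_reads"],
    )
    counts = {"detected": expr["gene_id"].nunique()}
    exclusions: list[tuple[str, str]] = []

    for cmp_table, reason in (
        (labeled_comparison, REASON_4SU_AFFECTED),
        (fractionation_comparison, REASON_FRACTIONATION),
    ):
        x = cmp_table["log10_x"].to_numpy()
        y = cmp_table["log10_y"].to_numpy()
        model = fit_cutoff_model(x, y, n_bins=_effective_bins(len(x), cfg.n_bins))
        mask = flag_outliers(x, y, model)
        exclusions += [(g, reason) for g in cmp_table.loc[mask, "gene_id"]]

    excluded = {g for g, _ in exclusions}
    expr = expr[~expr["gene_id"].isin(excluded)]
    counts["after_4su_exclusion"] = expression["gene_id"].nunique() - len(
        {g for g, r in exclusions if r == REASON_4SU_AFFECTED}
    )
    counts["after_fractionation_exclusion"] = expr["gene_id"].nunique()

    F = pd.Series(
        capture_probability(features["Nu"].to_numpy(), cfg.pr),
        index=features["gene_id"],
    )
    g = cfg.cell_cycle().g
    corrected_rows = []
    kept_genes = set()
    total_clamped = 0
    for (gene, frac, rep), sub in expr.groupby(["gene_id", "fraction", "replicate"]):
        f_gene = float(F.get(gene, 1.0))
        if f_gene <= cfg.f_min:
            exclusions.append((gene, REASON_UNCORRECTABLE_BIAS))
            continue
        sub = sub.sort_values("time_min")
        t = sub["time_min"].to_numpy()
        x0 = float(sub["fpkm_spikenorm"].iloc[0])
        if t[0] != 0 or x0 <= 0:
            exclusions.append((gene, "missing-t0"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            corr, n_clamped = correct_labeling_bias(
                t, sub["fpkm_spikenorm"].to_numpy(), x0, f_gene, g, cfg.f_min
            )
        total_clamped += n_clamped
        kept_genes.add(gene)
        corrected_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene,
                    "fraction": frac,
                    "replicate": rep,
                    "time_min": t,
                    "abundance": corr,
                }
            )
        )
    corrected = (
        pd.concat(corrected_rows, ignore_index=True)
        if corrected_rows
        else pd.DataFrame(columns=list(io.SCHEMAS["corrected"]))
    )
    # drop genes that lost any series to an exclusion reason
    bad = {g for g, _ in exclusions}
    corrected = corrected[~corrected["gene_id"].isin(bad)]
    counts["after_bias_exclusion"] = corrected["gene_id"].nunique()
    if total_clamped:
        logger.info("%d corrected values clamped to zero", total_clamped)

    exclusion_df = pd.DataFrame(
        sorted(set(exclusions)), columns=["gene_id", "reason_code"]
    )
    return corrected, exclusion_df, counts


def stage_error_models(
    expression: pd.DataFrame,
    bulk: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[NoiseModel, ContaminationModel]:
    noise = fit_noise_model(
        expression,
        span=cfg.noise_span,
        min_points=min(100, expression["gene_id"].nunique() * 2),
    )
    contamination = estimate_contamination(
        bulk["time_min"].to_numpy(),
        bulk["abundance"].to_numpy(),
        cfg.cell_cycle().g,
        noise,
        weighting=cfg.weighting,
    )
    return noise, contamination


def stage_fit(
    corrected: pd.DataFrame, noise: NoiseModel, cfg: RunConfig
) -> tuple[pd.DataFrame, dict]:
    fit_cfg = FitConfig(r2_threshold=cfg.r2_threshold, weighting=cfg.weighting)
    return fit_dataset(corrected, cfg.cell_cycle(), noise, fit_cfg)


def stage_associate(
    results: pd.DataFrame,
    features: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    rates = replicate_average(
        results.rename(
            columns={
                "transcription_rate_fpkm_per_min": "kS",
                "export_rate_per_min": "kE",
                "decay_rate_per_min": "kD",
            }
        )[["gene_id", "kS", "kE", "kD", "retained"]]
    )
    rates = rates[(rates[["kS", "kE", "kD"]] > 0).all(axis=1)]
    if len(rates) >= 10:
        shares = variance_contributions(rates, cfg.cell_cycle().g)
    else:
        logger.warning("only %d retained genes: variance shares skipped", len(rates))
        shares = {}
    correlations = rate_feature_correlation(rates, features)
    return rates, shares, correlations


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> RunReport:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_digest=cfg.digest())
    logger.info("run config %s -> %s", cfg.digest(), out)

    experiment, features = stage_simulate(cfg)
    io.write_table(experiment.expression, out / "expression.tsv", "expression")
    io.write_table(experiment.sample_reads, out / "sample_reads.tsv", "sample_reads")
    io.write_table(experiment.bulk, out / "bulk.tsv", "bulk")
    io.write_table(
        experiment.labeled_comparison, out / "comparison_4su.tsv", "comparison"
    )
    io.write_table(
        experiment.fractionation_comparison,
        out / "comparison_fractionation.tsv",
        "comparison",
    )
    io.write_table(features, out / "features.tsv", "features")
    io.write_table(experiment.truth, out / "truth.tsv", "truth")

    corrected, exclusion_df, counts = stage_preprocess(
        experiment.expression,
        experiment.sample_reads,
        experiment.labeled_comparison,
        experiment.fractionation_comparison,
        features,
        cfg,
    )
    io.write_table(corrected, out / "corrected.tsv", "corrected")
    io.write_table(exclusion_df, out / "exclusions.tsv", "exclusions")
    report.counts.update(counts)

    noise, contamination = stage_error_models(
        experiment.expression, experiment.bulk, cfg
    )
    io.write_table(noise.to_frame(), out / "noise_model.tsv", "noise_model")
    report.contamination = {
        "U": contamination.U,
        "U_pct": 100.0 * contamination.U,
        "kT_bulk_per_min": contamination.kT_bulk,
        "loss_d": contamination.d,
    }

    results, fit_report = stage_fit(corrected, noise, cfg)
    io.write_table(results, out / "rates.tsv", "rates")
    report.counts["fitted"] = (
        int(results.loc[results["converged"], "gene_id"].nunique())
        if len(results)
        else 0
    )
    report.counts["retained"] = fit_report["n_retained"]
    report.concordance = fit_report["concordance"]

    rates, shares, correlations = stage_associate(results, features, cfg)
    io.write_table(correlations, out / "feature_correlations.tsv")
    report.variance_shares = shares

    (out / "report.txt").write_text(report.to_text())
    (out / "report.json").write_text(report.to_json())
    return report
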