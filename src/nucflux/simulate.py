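"""Ground-truthed synthetic 4sU labeling experiments.

The generator emulates the study design the analysis assumes: 6 labeling
time points (0, 30, 90, 180, 300, 450 min), nuclear and cytoplasmic
fractions, 2 biological replicates, yeast spike-in scaling, mean-dependent
over-dispersed noise, labeling escape for uridine-poor transcripts, and a
global streptavidin carry-over fraction.

Per-gene ground truth is drawn so that the quasi-steady-state balance,
the mitotic exchange rates and the turnover relation hold exactly by
construction: export and decay rate constants come from log-normal
distributions with the medians (kE = 0.83 %/min, kD = 1.40 %/min) and
5th–95th-percentile decade spans (~0.5 and ~0.9) reported for these
kinetics; total abundance W0 spans ~5 decades so that the derived
transcription rates do too.

The forward measurement model per compartment X in {N, C} is

    Xm(t) = F·Xp(t) + (1−F)·X0·e^{g t} + U·F·(X0/W0)·W4sU(t)

i.e. true pre-existing RNA, plus the (1−F) share of new RNA that escaped
labeling (algebraically equal to (1−F) of the growing compartment total),
plus the carry-over fraction U of captured new RNA, apportioned to
compartments by their quasi-steady-state shares.  Multiplicative
log-normal noise with sd = CV(mean) on the natural scale is applied
independently per replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import (
    CellCycleParams,
    KineticRates,
    SteadyState,
    unlabeled_cytoplasmic,
    unlabeled_nuclear,
    unlabeled_total,
)
from .noise import new_rna_model
from .preprocess import capture_probability

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "consistent_gene",
    "sample_gene_parameters",
    "simulate_experiment",
    "downsample_reads",
    "to_counts",
    "generate_feature_annotations",
    "plant_label_effect",
    "plant_chromatin_states",
    "sample_rates_with_variance_shares",
]

# span in decades (5th-95th pct) -> sigma of ln X
_SPAN_TO_SIGMA = math.log(10.0) / 3.2897072539029457


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic experiment."""

    n_genes: int = 500
    time_grid: tuple[float, ...] = (0.0, 30.0, 90.0, 180.0, 300.0, 450.0)
    n_replicates: int = 2
    # rate and abundance distributions (log-normal; medians and decade spans)
    kE_median: float = 0.0083
    kE_span_decades: float = 0.5
    kD_median: float = 0.0140
    kD_span_decades: float = 0.9
    W0_median: float = 30.0
    W0_span_decades: float = 5.0
    # noise CV as a function of mean abundance: min(cv_floor + cv_slope/sqrt(m), cv_max)
    cv_floor: float = 0.1
    cv_slope: float = 0.4
    cv_max: float = 0.3
    noise: bool = True
    # labeling / contamination
    U: float = 0.073
    pr: float = 0.01
    uridine_fraction: float = 0.3
    # spike-in factors drawn log-uniform in this range; yeast reads fixed
    spike_factor_range: tuple[float, float] = (0.5, 2.0)
    yeast_reads: float = 1e5
    # transcript features
    length_median: float = 2000.0
    length_sigma_log10: float = 0.45
    plant_length_effect: bool = False
    length_effect_slope: float = 0.25
    length_effect_noise_log10: float = 0.2
    # planted anomalies for the outlier-exclusion comparisons
    outlier_fraction: float = 0.02
    outlier_sigma_multiple: float = 5.0
    comparison_disp: tuple[float, float, float] = (0.05, 0.3, 1.0)
    # count-level output
    counts_per_fpkm: float = 50.0
    cell_cycle: CellCycleParams = field(default_factory=CellCycleParams)
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def cv_curve(self, m):
        m = np.clip(np.asarray(m, dtype=float), 1e-12, None)
        return np.minimum(self.cv_floor + self.cv_slope / np.sqrt(m), self.cv_max)


@dataclass
class SimulatedExperiment:
    expression: pd.DataFrame
    sample_reads: pd.DataFrame
    bulk: pd.DataFrame
    labeled_comparison: pd.DataFrame
    fractionation_comparison: pd.DataFrame
    truth: pd.DataFrame


def consistent_gene(
    kE: float, kD: float, W0: float, ccp: CellCycleParams
) -> tuple[SteadyState, KineticRates]:
    """Steady state and rates fully consistent with quasi-steady state.

    Solves the compartment-partition fixed point (kf depends on the
    partition, which depends on kf): with
    a = 2·r_nc³·(F_G1S+2·F_G2M)/D the ratio N0/C0 equals
    (kD + a + g)/(kE + kf' − a).
    """
    phase = ccp.F_G1S + 2.0 * ccp.F_G2M
    a = 2.0 * ccp.r_nc**3 * phase / ccp.D
    kf_prime = 2.0 * (phase - 2.0 * ccp.F_M) / ccp.D
    denom = kE + kf_prime - a
    if denom <= 0:
        raise ValueError("kE + kf' must exceed the mitotic influx constant")
    ratio = (kD + a + ccp.g) / denom
    C0 = W0 / (1.0 + ratio)
    N0 = W0 - C0
    ss = SteadyState(N0=N0, C0=C0)
    kf = a * W0 / C0
    kT = kD * C0 / W0
    kS = (ccp.g + kE + kf_prime) * N0 - kf * C0
    return ss, KineticRates(kS=kS, kE=kE, kD=kD, kT=kT, kf=kf, kf_prime=kf_prime)


def _lognormal(rng, median: float, span_decades: float, size: int):
    sigma = span_decades * _SPAN_TO_SIGMA
    return median * np.exp(sigma * rng.standard_normal(size))


def sample_gene_parameters(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-gene ground truth consistent with quasi-steady state.

    kE, kD and W0 are drawn log-normally; the compartment partition, the
    mitotic exchange rates, kT and kS are then solved self-consistently:
    with a = 2·r_nc³·(F_G1S+2·F_G2M)/D the partition satisfies
    N0/C0 = (kD + a·W0/C0 + g)/(kE + kf'), a fixed point with closed form
    N0/C0 = (kD + a + g)/(kE + kf' − a).
    """
    rng = rng or config.rng()
    ccp = config.cell_cycle
    n = config.n_genes
    kE = _lognormal(rng, config.kE_median, config.kE_span_decades, n)
    kD = _lognormal(rng, config.kD_median, config.kD_span_decades, n)
    W0 = _lognormal(rng, config.W0_median, config.W0_span_decades, n)

    phase = ccp.F_G1S + 2.0 * ccp.F_G2M
    a = 2.0 * ccp.r_nc**3 * phase / ccp.D
    kf_prime = 2.0 * (phase - 2.0 * ccp.F_M) / ccp.D
    denom = kE + kf_prime - a
    if np.any(denom <= 0):
        raise ValueError(
            "drawn export rates too small for a consistent steady state "
            "(kE + kf' must exceed the mitotic influx constant)"
        )
    ratio = (kD + a + ccp.g) / denom  # N0/C0
    C0 = W0 / (1.0 + ratio)
    N0 = W0 - C0
    kf = a * W0 / C0
    kT = kD * C0 / W0
    kS = (ccp.g + kE + kf_prime) * N0 - kf * C0

    length = _lognormal(
        rng, config.length_median, config.length_sigma_log10 * 3.2897, n
    )
    if config.plant_length_effect:
        # ln(length) = (1/slope)·(ln kD − ln median) + ln L0 + noise, so the
        # log-log regression of kD on length has slope ~= length_effect_slope
        ln_len = (
            math.log(config.length_median)
            + (np.log(kD) - math.log(config.kD_median)) / config.length_effect_slope
            + config.length_effect_noise_log10
            * math.log(10.0)
            * rng.standard_normal(n)
        )
        length = np.exp(ln_len)
    Nu = np.round(config.uridine_fraction * length).astype(int)
    F = capture_probability(Nu, config.pr)

    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "N0": N0,
            "C0": C0,
            "W0": W0,
            "kS": kS,
            "kE": kE,
            "kD": kD,
            "kT": kT,
            "kf": kf,
            "kf_prime": kf_prime,
            "transcript_length": length,
            "Nu": Nu,
            "F": F,
        }
    )


def _apply_noise(rng, clean, cv):
    """Multiplicative log-normal noise with natural-scale sd = cv·mean."""
    sigma = np.sqrt(np.log1p(np.asarray(cv) ** 2))
    return clean * np.exp(sigma * rng.standard_normal(np.shape(clean)) - 0.5 * sigma**2)


def simulate_experiment(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedExperiment:
    """Forward-simulate measured unlabeled abundance tables from truth."""
    rng = rng or config.rng()
    ccp = config.cell_cycle
    t = np.asarray(config.time_grid, dtype=float)
    n = len(truth)

    # noise-free measured series per compartment, gene x time
    measured = {}
    bulk_clean = np.zeros_like(t)
    for _, row in truth.iterrows():
        ss = SteadyState(N0=row["N0"], C0=row["C0"])
        rates = KineticRates(
            kS=row["kS"], kE=row["kE"], kD=row["kD"], kT=row["kT"],
            kf=row["kf"], kf_prime=row["kf_prime"],
        )
        w4su = new_rna_model(t, ss.W0, ccp.g, row["kT"])
        for frac, x0, curve in (
            ("nuclear", ss.N0, unlabeled_nuclear),
            ("cytoplasmic", ss.C0, unlabeled_cytoplasmic),
        ):
            xp = curve(t, ss, rates)
            xm = (
                row["F"] * xp
                + (1.0 - row["F"]) * x0 * np.exp(ccp.g * t)
                + config.U * row["F"] * (x0 / ss.W0) * w4su
            )
            measured[(row["gene_id"], frac)] = xm
        bulk_clean += unlabeled_total(t, ss.W0, row["kT"]) + config.U * w4su

    records = []
    sample_rows = []
    for rep in range(1, config.n_replicates + 1):
        for frac in ("nuclear", "cytoplasmic"):
            for j, tj in enumerate(t):
                factor = np.exp(
                    rng.uniform(*np.log(config.spike_factor_range))
                )
                clean = np.array(
                    [measured[(gid, frac)][j] for gid in truth["gene_id"]]
                )
                if config.noise:
                    vals = _apply_noise(rng, clean, config.cv_curve(clean))
                else:
                    vals = clean
                records.append(
                    pd.DataFrame(
                        {
                            "gene_id": truth["gene_id"].to_numpy(),
                            "fraction": frac,
                            "replicate": rep,
                            "time_min": tj,
                            "fpkm": vals / factor,
                            "fpkm_spikenorm": vals,
                        }
                    )
                )
                sample_rows.append(
                    {
                        "fraction": frac,
                        "replicate": rep,
                        "time_min": tj,
                        "fly_mapped_reads": factor * config.yeast_reads,
                        "yeast_mapped_reads": config.yeast_reads,
                    }
                )
    expression = pd.concat(records, ignore_index=True)
    sample_reads = pd.DataFrame(sample_rows)

    bulk_rows = []
    for rep in range(1, config.n_replicates + 1):
        if config.noise:
            vals = _apply_noise(rng, bulk_clean, config.cv_curve(bulk_clean))
        else:
            vals = bulk_clean
        bulk_rows.append(
            pd.DataFrame({"replicate": rep, "time_min": t, "abundance": vals})
        )
    bulk = pd.concat(bulk_rows, ignore_index=True)

    labeled_cmp = _comparison_table(rng, truth, config, "treated_4su")
    fraction_cmp = _comparison_table(rng, truth, config, "fraction_sum")
    return SimulatedExperiment(
        expression=expression,
        sample_reads=sample_reads,
        bulk=bulk,
        labeled_comparison=labeled_cmp,
        fractionation_comparison=fraction_cmp,
        truth=truth,
    )


def _comparison_table(
    rng, truth: pd.DataFrame, config: SimulationConfig, kind: str
) -> pd.DataFrame:
    """Scatter of two transcriptomes that should agree, on log10 scale.

    Dispersion around the diagonal follows m + n·e^{−p·x}; a planted
    fraction of genes receives a systematic offset of
    ``outlier_sigma_multiple`` local dispersions with random sign.
    """
    m_d, n_d, p_d = config.comparison_disp
    x = np.log10(truth["W0"].to_numpy())
    disp = m_d + n_d * np.exp(-p_d * x)
    y = x + disp * rng.standard_normal(len(x))
    planted = rng.random(len(x)) < config.outlier_fraction
    sign = rng.choice([-1.0, 1.0], size=len(x))
    y = y + planted * sign * config.outlier_sigma_multiple * disp
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"].to_numpy(),
            "log10_x": x,
            "log10_y": y,
            "comparison": kind,
            "planted_outlier": planted,
        }
    )


def to_counts(
    values: np.ndarray,
    rng: np.random.Generator,
    counts_per_fpkm: float = 50.0,
) -> np.ndarray:
    """Poisson read counts around FPKM-scaled expectations."""
    return rng.poisson(np.clip(values, 0, None) * counts_per_fpkm)


def downsample_reads(
    counts: np.ndarray,
    fraction: float = 0.25,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Binomially thin integer counts to ``fraction`` of the reads."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be integers")
    if fraction == 1.0:
        return counts.copy()
    return rng.binomial(counts, fraction)


def generate_feature_annotations(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene transcript features (lengths drawn log-normally)."""
    rng = rng or config.rng()
    n = len(truth)
    ln10 = math.log(10.0)
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"].to_numpy(),
            "transcript_length": truth["transcript_length"].to_numpy(),
            "intron_length": np.exp(
                math.log(800.0) + 0.6 * ln10 * rng.standard_normal(n)
            ),
            "utr3_length": np.exp(
                math.log(300.0) + 0.4 * ln10 * rng.standard_normal(n)
            ),
            "utr5_length": np.exp(
                math.log(150.0) + 0.3 * ln10 * rng.standard_normal(n)
            ),
            "cds_length": np.exp(
                math.log(1200.0) + 0.35 * ln10 * rng.standard_normal(n)
            ),
            "n_exons": 1 + rng.poisson(3.0, n),
            "Nu": truth["Nu"].to_numpy(),
        }
    )


def plant_label_effect(
    rates: pd.DataFrame,
    n_labeled: int,
    rate_col: str,
    fold: float,
    rng: np.random.Generator,
    label: str = "rbp",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multiply ``rate_col`` by ``fold`` for a random labeled gene set.

    Returns the modified rate table and a binary label table
    (gene_id, label, value).
    """
    out = rates.copy()
    idx = rng.choice(len(out), size=n_labeled, replace=False)
    mask = np.zeros(len(out), dtype=bool)
    mask[idx] = True
    out.loc[mask, rate_col] = out.loc[mask, rate_col] * fold
    labels = pd.DataFrame(
        {"gene_id": out["gene_id"].to_numpy(), "label": label, "value": mask.astype(int)}
    )
    return out, labels


def plant_chromatin_states(
    rates: pd.DataFrame,
    rng: np.random.Generator,
    states: tuple[str, ...] = ("YELLOW", "RED", "GREEN", "BLUE", "BLACK"),
    shifted_state: str | None = "BLUE",
    rate_col: str = "kS",
    fold: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign per-gene chromatin states, optionally shifting one state's rate."""
    out = rates.copy()
    tss = rng.choice(states, size=len(out))
    tts = rng.choice(states, size=len(out))
    if shifted_state is not None:
        out.loc[tss == shifted_state, rate_col] *= fold
    state_table = pd.DataFrame(
        {"gene_id": out["gene_id"].to_numpy(), "tss_state": tss, "tts_state": tts}
    )
    return out, state_table


def sample_rates_with_variance_shares(
    n_genes: int,
    shares: tuple[float, float, float] = (0.85, 0.05, 0.10),
    g: float = math.log(2.0) / 1440.0,
    total_log_var: float = 0.36,
    export_term_mean: float = -0.45,
    kD_median: float = 0.0140,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Rates whose generative variance shares of log C0 are known.

    log C0 decomposes additively as
    log kS + log(kE/(kE+g)) − log(kD+g); the three terms are drawn as
    independent normals with variances ``shares``·``total_log_var`` and
    inverted to rates.  The export term ln(kE/(kE+g)) must stay negative,
    so its mean is placed well below 0 (``export_term_mean``; >3 sd at
    the defaults) and draws are truncated there — the distortion is
    negligible relative to the planting tolerance.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sS, sE, sD = (math.sqrt(s * total_log_var) for s in shares)
    tS = math.log(1.0) + sS * rng.standard_normal(n_genes)
    tE = export_term_mean + sE * rng.standard_normal(n_genes)
    tE = np.minimum(tE, -1e-9)  # truncation: export ratio < 1
    muD = -math.log(kD_median + g)
    tD = muD + sD * rng.standard_normal(n_genes)

    kS = np.exp(tS)
    u = np.exp(tE)
    kE = g * u / (1.0 - u)
    kD = np.exp(-tD) - g
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "kS": kS,
            "kE": kE,
            "kD": kD,
        }
    )
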