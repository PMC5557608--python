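"""Downstream statistics on fitted kinetic rate tables.

Links the per-gene rate constants to steady-state abundance variance,
transcript features, RNA-binding-protein (RBP) target sets, and chromatin
states:

* variance decomposition — under quasi-steady state without mitotic
  exchange, log C0 = log kS + log(kE/(kE+g)) − log(kD+g); the share of
  each kinetic step in the genome-wide variance of steady-state abundance
  is its covariance with log C0 divided by var(log C0) (exactly additive).
* rank correlations between rates and transcript features, with the
  log-log regression slope.
* bound-vs-unbound group comparisons per RBP: Wilcoxon rank-sum on the
  70% highest-expressed genes, Holm–Bonferroni adjusted across RBPs.
* Pol II pausing index (TSS-window / gene-body signal ratio) and pairwise
  RBP target-set overlaps.
* chromatin-state comparisons: one-way ANOVA on log rates plus Tukey's
  honest-significant-difference test for all state pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "variance_contributions",
    "rate_feature_correlation",
    "group_rate_comparison",
    "rbp_overlap",
    "pausing_index",
    "chromatin_state_comparison",
    "replicate_average",
]

RATE_COLS = ("kS", "kE", "kD")


def replicate_average(results: pd.DataFrame, rate_cols=None) -> pd.DataFrame:
    """Geometric mean of per-replicate rate estimates for retained genes."""
    rate_cols = list(rate_cols or RATE_COLS)
    sub = results[results.get("retained", True) == True]  # noqa: E712
    logs = sub[["gene_id"] + rate_cols].copy()
    logs[rate_cols] = np.log(logs[rate_cols])
    out = np.exp(logs.groupby("gene_id")[rate_cols].mean()).reset_index()
    return out


def variance_contributions(rates: pd.DataFrame, g: float) -> dict[str, float]:
    """Covariance shares of log steady-state cytoplasmic abundance.

    Returns shares for transcription, export and decay; they sum to 1
    exactly because the log abundance is the sum of the three terms.
    """
    if len(rates) < 10:
        raise ValueError("need at least 10 genes")
    kS = rates["kS"].to_numpy(dtype=float)
    kE = rates["kE"].to_numpy(dtype=float)
    kD = rates["kD"].to_numpy(dtype=float)
    if np.any(kS <= 0) or np.any(kE <= 0) or np.any(kD <= 0):
        raise ValueError("rates must be positive")
    terms = {
        "transcription": np.log(kS),
        "export": np.log(kE / (kE + g)),
        "decay": -np.log(kD + g),
    }
    log_c0 = sum(terms.values())
    centered = log_c0 - log_c0.mean()
    var = float(centered @ centered)
    if var == 0:
        raise ValueError("zero variance of log steady-state abundance")
    return {
        name: float(centered @ (term - term.mean()) / var)
        for name, term in terms.items()
    }


def rate_feature_correlation(
    rates: pd.DataFrame,
    features: pd.DataFrame,
    rate_cols=RATE_COLS,
    feature_cols=None,
) -> pd.DataFrame:
    """Spearman rho/p and log-log OLS slope per (rate, feature) pair."""
    merged = rates.merge(features, on="gene_id")
    feature_cols = list(
        feature_cols
        or [c for c in features.columns if c not in ("gene_id", "Nu")]
    )
    rows = []
    for rc in rate_cols:
        for fc in feature_cols:
            pair = merged[[rc, fc]].dropna()
            pair = pair[(pair[rc] > 0) & (pair[fc] > 0)]
            if len(pair) < 10 or pair[fc].nunique() == 1:
                rows.append(
                    {"rate": rc, "feature": fc, "rho": np.nan, "p": np.nan,
                     "loglog_slope": np.nan, "n": len(pair),
                     "reason": "constant-or-sparse"}
                )
                continue
            rho, p = stats.spearmanr(pair[rc], pair[fc])
            slope = np.polyfit(np.log10(pair[fc]), np.log10(pair[rc]), 1)[0]
            rows.append(
                {"rate": rc, "feature": fc, "rho": float(rho), "p": float(p),
                 "loglog_slope": float(slope), "n": len(pair), "reason": ""}
            )
    return pd.DataFrame(rows)


def group_rate_comparison(
    rates: pd.DataFrame,
    labels: pd.DataFrame,
    expression: pd.Series | None = None,
    rate_cols=RATE_COLS,
    top_fraction: float = 0.7,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Bound-vs-unbound rate comparison per label set.

    ``labels`` is long-format (gene_id, label, value∈{0,1}).  Genes are
    first restricted to the ``top_fraction`` highest expressed (ranked by
    ``expression``, a gene-indexed series; defaults to kS as an
    expression proxy).  Per label set and rate, reports the log2 ratio of
    medians (bound/unbound) and a two-sided Wilcoxon rank-sum p
    (normal approximation with tie correction), Holm–Bonferroni adjusted
    across label sets within each rate.
    """
    if expression is None:
        expression = rates.set_index("gene_id")["kS"] * 1.0
    cutoff = expression.quantile(1.0 - top_fraction)
    kept = set(expression.index[expression >= cutoff])
    sub = rates[rates["gene_id"].isin(kept)].set_index("gene_id")

    rows = []
    for label, ltab in labels.groupby("label"):
        members = set(ltab.loc[ltab["value"] == 1, "gene_id"])
        bound = sub[sub.index.isin(members)]
        unbound = sub[~sub.index.isin(members)]
        if bound.empty or unbound.empty:
            continue
        for rc in rate_cols:
            b, u = bound[rc].dropna(), unbound[rc].dropna()
            stat = stats.mannwhitneyu(b, u, alternative="two-sided",
                                      method="asymptotic")
            rows.append(
                {
                    "label": label,
                    "rate": rc,
                    "n_bound": len(b),
                    "n_unbound": len(u),
                    "log2_median_ratio": float(
                        np.log2(np.median(b) / np.median(u))
                    ),
                    "p": float(stat.pvalue),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = np.nan
    for rc in rate_cols:
        mask = out["rate"] == rc
        if mask.any():
            out.loc[mask, "p_adj"] = multipletests(
                out.loc[mask, "p"], method="holm"
            )[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def rbp_overlap(set_x: set, set_y: set) -> tuple[float, float]:
    """(|X∩Y|/|X|, |X∩Y|/|Y|) — asymmetric target-set overlap."""
    if not set_x or not set_y:
        raise ValueError("overlap undefined for empty gene sets")
    inter = len(set(set_x) & set(set_y))
    return inter / len(set_x), inter / len(set_y)


def pausing_index(signal_tss_window, signal_body):
    """Pol II pausing index: TSS-window signal / gene-body signal.

    Zero body signal yields NaN (missing value).
    """
    tss = np.asarray(signal_tss_window, dtype=float)
    body = np.asarray(signal_body, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(body > 0, tss / body, np.nan)
    return out[()]


def chromatin_state_comparison(
    rates: pd.DataFrame,
    states: pd.Series,
    rate_col: str = "kS",
    alpha: float = 0.01,
    min_group: int = 10,
) -> dict:
    """ANOVA + Tukey HSD of log rates across chromatin states.

    ``states`` is a gene_id-indexed categorical series (one anchor, TSS
    or TTS).  States with fewer than ``min_group`` genes are merged into
    "other".  Returns the ANOVA p, the Tukey table, and the list of
    significant state pairs at ``alpha``.
    """
    merged = rates.set_index("gene_id").join(states.rename("state"), how="inner")
    merged = merged[merged[rate_col] > 0].dropna(subset=["state"])
    counts = merged["state"].value_counts()
    small = counts.index[counts < min_group]
    if len(small):
        warnings.warn(
            f"state(s) {list(small)} below {min_group} genes merged into 'other'",
            stacklevel=2,
        )
        merged.loc[merged["state"].isin(small), "state"] = "other"
        counts = merged["state"].value_counts()
        if counts.get("other", 0) < min_group:
            merged = merged[merged["state"] != "other"]
            counts = merged["state"].value_counts()
    groups = [
        np.log(merged.loc[merged["state"] == s, rate_col].to_numpy())
        for s in counts.index
    ]
    if len(groups) < 2:
        raise ValueError("need at least 2 states with enough genes")
    anova_p = float(stats.f_oneway(*groups).pvalue)
    tukey = pairwise_tukeyhsd(
        np.log(merged[rate_col].to_numpy()), merged["state"].to_numpy(),
        alpha=alpha,
    )
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    sig_pairs = [
        (row["group1"], row["group2"])
        for _, row in table.iterrows()
        if float(row["p-adj"]) < alpha
    ]
    return {"anova_p": anova_p, "tukey": table, "significant_pairs": sig_pairs}
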