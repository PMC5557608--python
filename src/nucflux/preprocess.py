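"""Preprocessing of abundance tables before kinetic fitting.

Three corrections are applied to per-gene FPKM tables:

1. Spike-in normalization: each sample's FPKM values are rescaled by the
   ratio of reads mapping to the experimental (fly) transcriptome to reads
   mapping to the spike-in (yeast) transcriptome, turning within-sample
   relative abundances into values comparable across time points.

2. Dispersion-based outlier exclusion: when two transcriptomes x and y
   should agree (e.g. mock vs 4sU-treated cells, or whole cells vs the sum
   of the fractions), genes far off the diagonal are excluded.  Technical
   dispersion shrinks with abundance, so the allowed deviation is modeled
   as f(x) = m + n·e^{−p·x} on log10 abundance and fitted to binned
   per-interval standard deviations; a gene is an outlier if it exceeds
   twice the fitted dispersion on either side of the diagonal.

3. 4sU labeling-bias correction: a newly made transcript escapes biotin
   capture with probability (1−pr)^Nu, where Nu is its uridine count and
   pr the per-uridine labeling probability (~0.01).  Escaped new RNA
   inflates the measured "unlabeled" signal, most severely for short
   transcripts; the correction inverts this contamination using the
   capture probability F = 1 − (1−pr)^Nu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "CutoffModel",
    "spike_normalize",
    "fit_cutoff_model",
    "flag_outliers",
    "capture_probability",
    "correct_labeling_bias",
]

REASON_UNCORRECTABLE_BIAS = "uncorrectable-bias"
REASON_4SU_AFFECTED = "4su-affected"
REASON_FRACTIONATION = "fractionation-inconsistent"


@dataclass(frozen=True)
class CutoffModel:
    """Fitted dispersion model f(x) = m + n·e^{−p·x} on log10 abundance.

    Evaluation clamps to the fitted abundance range: the exponential term
    explodes below it, and the dispersion of data never seen is better
    represented by the nearest fitted value.
    """

    m: float
    n: float
    p: float
    n_bins: int = 1000
    x_min: float = -np.inf
    x_max: float = np.inf

    def __call__(self, x):
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        return self.m + self.n * np.exp(-self.p * x)


def spike_normalize(
    abundance: pd.DataFrame,
    fly_mapped_reads: pd.Series,
    yeast_mapped_reads: pd.Series,
    fpkm_col: str = "fpkm",
    sample_cols: tuple[str, ...] = ("fraction", "replicate", "time_min"),
    out_col: str = "fpkm_spikenorm",
) -> pd.DataFrame:
    """Rescale FPKM by the per-sample fly/yeast mapped-read ratio.

    ``fly_mapped_reads`` and ``yeast_mapped_reads`` are indexed by the
    sample key (tuples over ``sample_cols``).  Returns a copy with the
    spike-normalized column filled in.
    """
    zero = yeast_mapped_reads[yeast_mapped_reads <= 0]
    if len(zero):
        raise ValueError(
            f"zero yeast spike-in reads for sample(s): {list(zero.index)}"
        )
    factor = fly_mapped_reads / yeast_mapped_reads
    out = abundance.copy()
    key = pd.MultiIndex.from_frame(out[list(sample_cols)])
    out[out_col] = out[fpkm_col].to_numpy() * factor.reindex(key).to_numpy()
    if out[out_col].isna().any():
        missing = sorted(set(key[out[out_col].isna()]))
        raise ValueError(f"no mapped-read counts for sample(s): {missing[:5]}")
    return out


def fit_cutoff_model(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 1000,
    min_bin_count: int = 5,
) -> CutoffModel:
    """Fit the abundance-dependent dispersion f(x) = m + n·e^{−p·x}.

    x and y are matched log10 abundances of two transcriptomes that are
    expected to agree.  x is divided into ``n_bins`` equal-width intervals;
    within each bin the standard deviation of the deviation from the
    diagonal (y − x) is computed, and (m, n, p) are fitted to the per-bin
    dispersions by Levenberg–Marquardt least squares with non-negativity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise ValueError("no finite (x, y) pairs to fit")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    resid = y - x
    centers, sds = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() < min_bin_count:
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        sds.append(np.std(resid[sel]))
    if len(centers) < 3:
        raise ValueError(
            f"only {len(centers)} usable bins (need >= 3); "
            "reduce n_bins or provide more data"
        )
    centers = np.array(centers)
    sds = np.array(sds)

    params = lmfit.Parameters()
    params.add("m", value=float(np.median(sds)), min=0.0)
    params.add("n", value=max(float(sds.max() - np.median(sds)), 1e-3), min=0.0)
    params.add("p", value=1.0, min=0.0)

    def residual(pars):
        f = pars["m"].value + pars["n"].value * np.exp(-pars["p"].value * centers)
        return f - sds

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError(f"cutoff-model fit failed: {result.message}")
    return CutoffModel(
        m=float(result.params["m"].value),
        n=float(result.params["n"].value),
        p=float(result.params["p"].value),
        n_bins=n_bins,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def flag_outliers(x, y, model: CutoffModel) -> np.ndarray:
    """Genes exceeding twice the technical dispersion on either side.

    Returns a boolean mask: flagged iff y > x + 2·f(x) or x > y + 2·f(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (y > x + 2.0 * model(x)) | (x > y + 2.0 * model(y))


def capture_probability(Nu, pr: float):
    """Probability F = 1 − (1−pr)^Nu that a new transcript is captured.

    Computed via expm1/log1p so large uridine counts do not underflow.
    Accepts scalar or array Nu.
    """
    if not 0.0 <= pr <= 1.0:
        raise ValueError("labeling probability pr must be in [0, 1]")
    Nu = np.asarray(Nu)
    if np.any(Nu < 0):
        raise ValueError("uridine count must be non-negative")
    if pr == 1.0:
        return np.where(Nu > 0, 1.0, 0.0)[()]
    return (-np.expm1(Nu * np.log1p(-pr)))[()]


def correct_labeling_bias(
    t: np.ndarray,
    measured: np.ndarray,
    x0: float,
    F: float,
    g: float,
    f_min: float = 0.2,
) -> tuple[np.ndarray, int]:
    """Remove escaped new RNA from a measured unlabeled series.

    The measured "unlabeled" signal contains, besides the true pre-existing
    pool Xp, the (1−F) share of new RNA that escaped labeling.  Since the
    compartment total grows as X0·e^{g t} under quasi-steady state, mass
    balance gives the exact inverse

        Xp(t) = [Xm(t) − (1−F)·X0·e^{g t}] / F

    Negative corrected values (noise-induced) are clamped to zero; the
    clamp count is returned alongside.  Genes with F <= ``f_min`` must be
    excluded upstream (the 1/F variance amplification becomes extreme).
    """
    if F <= f_min:
        raise ValueError(
            f"capture probability {F:.3f} <= {f_min}: gene uncorrectable "
            f"({REASON_UNCORRECTABLE_BIAS})"
        )
    t = np.asarray(t, dtype=float)
    measured = np.asarray(measured, dtype=float)
    corrected = (measured - (1.0 - F) * x0 * np.exp(g * t)) / F
    n_clamped = int(np.sum(corrected < 0))
    if n_clamped:
        warnings.warn(
            f"{n_clamped} corrected value(s) clamped to zero", stacklevel=2
        )
    return np.clip(corrected, 0.0, None), n_clamped
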