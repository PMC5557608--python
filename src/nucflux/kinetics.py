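"""Closed-form compartmental kinetics of nucleocytoplasmic mRNA flux.

The model describes, per gene, a nuclear pool ``N`` and a cytoplasmic pool
``C`` in an exponentially proliferating, non-synchronized cell culture.
Mature mRNA is produced in the nucleus at rate ``kS`` (spike-normalized
FPKM per minute), exported with first-order rate constant ``kE`` (1/min),
and degraded in the cytoplasm with rate constant ``kD`` (1/min).  Mitotic
nuclear-envelope breakdown redistributes transcripts between compartments;
this is modeled by effective exchange rate constants ``kf`` (cytoplasm to
nucleus, acting at telophase) and ``kf'`` (nucleus to cytoplasm, acting at
the start of M phase), derived from the cell-cycle phase structure and the
nucleus-to-cell diameter ratio.

Under quasi-steady state the per-gene pools grow as ``e^{g t}`` with the
culture proliferation rate ``g = ln 2 / D`` (doubling time ``D``), so at
label addition (t = 0) the system satisfies

    kS − (kE + kf')·N0 + kf·C0 = g·N0
    (kE + kf')·N0 − (kD + kf)·C0 = g·C0

The pre-existing (unlabeled-at-t0) pools decay with closed-form
bi-exponential curves; the total pre-existing pool decays as a single
exponential with overall turnover rate ``kT = kD·C0/W0``.

All rates are per minute and all times in minutes; conversion to hours
happens only at reporting boundaries (see :func:`half_life`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellCycleParams",
    "KineticRates",
    "SteadyState",
    "proliferation_rate",
    "mitotic_transfer_rates",
    "solve_steady_state",
    "derive_transcription_rate",
    "overall_turnover_rate",
    "unlabeled_total",
    "unlabeled_nuclear",
    "unlabeled_cytoplasmic",
    "half_life",
]

# Exponent differences closer than this are treated as the removable
# singularity of the bi-exponential solutions and evaluated by their limit.
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class CellCycleParams:
    """Cell-cycle structure of the culture.

    Parameters
    ----------
    D : float
        Doubling time in minutes (default 1440 = 24 h).
    F_G1S : float
        Fraction of the cycle spent in G1/S (cells with 1x content).
    F_G2M : float
        Fraction of the cycle spent in G2/M (cells with ~2x content).
    F_M : float
        Fraction of the cycle spent in mitosis proper (default 1/24:
        about one hour of a 24-hour cycle).
    r_nc : float
        Nucleus-to-cell diameter ratio (default 0.8, i.e. 4:5).
    """

    D: float = 1440.0
    F_G1S: float = 0.2
    F_G2M: float = 0.8
    F_M: float = 1.0 / 24.0
    r_nc: float = 0.8
    g: float = field(init=False)

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"doubling time must be positive, got {self.D}")
        if not 0 <= self.F_M <= self.F_G2M:
            raise ValueError("F_M must lie in [0, F_G2M]")
        if abs(self.F_G1S + self.F_G2M - 1.0) > 1e-9:
            raise ValueError("cell-cycle phase fractions must sum to 1")
        if not 0 < self.r_nc < 1:
            raise ValueError("nucleus-to-cell diameter ratio must be in (0, 1)")
        object.__setattr__(self, "g", proliferation_rate(self.D))


@dataclass(frozen=True)
class KineticRates:
    """First-order rate constants for one gene (all 1/min; kS in FPKM/min)."""

    kS: float
    kE: float
    kD: float
    kT: float
    kf: float
    kf_prime: float

    def __post_init__(self) -> None:
        for name in ("kE", "kD", "kT", "kf", "kf_prime"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SteadyState:
    """Compartment abundances at label addition (spike-normalized FPKM)."""

    N0: float
    C0: float

    def __post_init__(self) -> None:
        if self.N0 < 0 or self.C0 < 0:
            raise ValueError("steady-state abundances must be non-negative")

    @property
    def W0(self) -> float:
        return self.N0 + self.C0


def proliferation_rate(D: float) -> float:
    """Proliferation rate g = ln2/D (1/min) for doubling time D (min)."""
    if D <= 0:
        raise ValueError(f"doubling time must be positive, got {D}")
    return math.log(2.0) / D


def mitotic_transfer_rates(
    ccp: CellCycleParams, ss: SteadyState
) -> tuple[float, float]:
    """Effective mitotic exchange rate constants (kf, kf') in 1/min.

    During mitosis the nuclear envelope breaks down and transcripts
    redistribute by volume.  Averaged over the cycle, the cytoplasm-to-
    nucleus flux per unit cytoplasmic RNA is

        kf = 2·r_nc³·(N0 + C0)·(F_G1S + 2·F_G2M) / (D·C0)

    and the nucleus-to-cytoplasm flux per unit nuclear RNA is

        kf' = 2·(F_G1S + 2·F_G2M − 2·F_M) / D

    kf depends on the gene's compartment partition (N0+C0)/C0 and is
    computed from measured t=0 abundances, then held fixed during fitting.
    """
    if ss.C0 <= 0:
        raise ValueError("kf is undefined for zero cytoplasmic abundance")
    phase = ccp.F_G1S + 2.0 * ccp.F_G2M
    kf = 2.0 * ccp.r_nc**3 * ss.W0 * phase / (ccp.D * ss.C0)
    kf_prime = 2.0 * (phase - 2.0 * ccp.F_M) / ccp.D
    return kf, kf_prime


def solve_steady_state(
    kS: float, kE: float, kD: float, kf: float, kf_prime: float, g: float
) -> SteadyState:
    """Solve the quasi-steady-state balance for (N0, C0) given all rates.

    Solves the 2x2 linear system

        (kE + kf' + g)·N0 − kf·C0        = kS
        −(kE + kf')·N0 + (kD + kf + g)·C0 = 0
    """
    A = np.array(
        [
            [kE + kf_prime + g, -kf],
            [-(kE + kf_prime), kD + kf + g],
        ]
    )
    b = np.array([kS, 0.0])
    try:
        n0, c0 = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"singular steady-state system for rates kE={kE}, kD={kD}, "
            f"kf={kf}, kf'={kf_prime}, g={g}"
        ) from exc
    return SteadyState(N0=float(n0), C0=float(c0))


def derive_transcription_rate(
    ss: SteadyState, kE: float, kf: float, kf_prime: float, g: float
) -> float:
    """Transcription rate implied by the nuclear balance at t = 0.

    kS = (g + kE + kf')·N0 − kf·C0.  A negative value indicates t=0
    measurements inconsistent with quasi-steady state; it is returned
    as-is so the caller can flag the gene.
    """
    return (g + kE + kf_prime) * ss.N0 - kf * ss.C0


def overall_turnover_rate(kD: float, ss: SteadyState) -> float:
    """Overall turnover rate kT = kD·C0/W0 (decay acts only on cytoplasm)."""
    if ss.W0 <= 0:
        raise ValueError("turnover rate undefined for zero total abundance")
    return kD * ss.C0 / ss.W0


def unlabeled_total(t, W0: float, kT: float):
    """Pre-existing total RNA: Wp(t) = W0·e^{−kT·t}."""
    t = np.asarray(t, dtype=float)
    return W0 * np.exp(-kT * t)


def _biexponential(t, X0: float, a: float, amplitude: float, kT: float):
    """X0·e^{−a t} + amplitude/(a − kT)·(e^{−kT t} − e^{−a t}).

    The quotient has a removable singularity at a == kT, where the second
    term's limit is amplitude·t·e^{−kT t}.
    """
    t = np.asarray(t, dtype=float)
    first = X0 * np.exp(-a * t)
    if abs(a - kT) < _DEGENERATE_TOL:
        return first + amplitude * t * np.exp(-kT * t)
    return first + amplitude / (a - kT) * (np.exp(-kT * t) - np.exp(-a * t))


def unlabeled_nuclear(t, ss: SteadyState, rates: KineticRates):
    """Pre-existing nuclear RNA Np(t).

    Np(t) = N0·e^{−(kE+kf'+kf)t}
            + W0·kf/(kE+kf'+kf−kT)·(e^{−kT t} − e^{−(kE+kf'+kf)t})
    """
    a = rates.kE + rates.kf_prime + rates.kf
    return _biexponential(t, ss.N0, a, ss.W0 * rates.kf, rates.kT)


def unlabeled_cytoplasmic(t, ss: SteadyState, rates: KineticRates):
    """Pre-existing cytoplasmic RNA Cp(t).

    Cp(t) = C0·e^{−(kE+kf'+kD+kf)t}
            + W0·(kE+kf')/(kE+kf'+kD+kf−kT)·(e^{−kT t} − e^{−(kE+kf'+kD+kf)t})
    """
    a = rates.kE + rates.kf_prime + rates.kD + rates.kf
    return _biexponential(
        t, ss.C0, a, ss.W0 * (rates.kE + rates.kf_prime), rates.kT
    )


def half_life(k: float) -> float:
    """Half-life in hours for a first-order rate constant k (1/min)."""
    if k <= 0:
        raise ValueError(f"half-life undefined for non-positive rate {k}")
    return math.log(2.0) / (60.0 * k)
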