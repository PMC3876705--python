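"""Scaling-law mathematics for large parallel network simulations.

Three small estimators used to plan production runs from desk-scale
measurements:

* **Power-law memory model.**  Memory = α · N^β, fitted by ordinary least
  squares on log10-transformed (network size, memory) samples; the fit
  extrapolates the RAM needed for million-to-ten-million-cell networks.
* **Weak-scaling pool estimator.**  The process count that keeps the number
  of cells per process constant: n = N_target · n_ref / N_ref, reported
  either to the nearest integer or to two significant figures (round half
  away from zero) for headline extrapolations.
* **Amdahl serial-fraction model.**  Total CPU time across n threads,
  Total(n) = T1·(s·n + (1 − s)): a serial fraction s of the single-thread
  time is repeated on every thread (they all wait on it) while the parallel
  part's total is constant.  A least-squares line in n recovers (s, T1);
  speedup(n) = 1/(s + (1 − s)/n) is bounded by 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "PowerLawFit",
    "AmdahlFit",
    "ScalingRun",
    "fit_power_law",
    "predict_memory",
    "weak_scaling_pool",
    "fit_amdahl",
    "speedup",
    "tradeoff_curve",
    "round_two_significant",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Memory = alpha * N**beta (alpha in the units of the fitted data)."""

    alpha: float
    beta: float
    adj_r2: float
    n_points: int


@dataclass(frozen=True)
class AmdahlFit:
    """Serial fraction and single-thread time of the linear total-CPU model."""

    serial_fraction: float
    t1_seconds: float
    clipped: bool = False  # raw estimate fell outside [0, 1]


@dataclass(frozen=True)
class ScalingRun:
    """One benchmark sample: network size, pool size and times."""

    label: str
    n_neurons: int
    pool: int
    wall_seconds: float
    total_cpu_seconds: float

    def __post_init__(self) -> None:
        if self.pool < 1:
            raise ConfigurationError("pool must be >= 1")
        if self.total_cpu_seconds < self.wall_seconds:
            raise ConfigurationError("total CPU time cannot be below wall time")


def fit_power_law(sizes, memories) -> PowerLawFit:
    """OLS on (log10 N, log10 memory); alpha = 10**intercept, beta = slope.

    Requires at least three strictly positive points; the adjusted r² uses
    the standard n − 2 residual degrees of freedom of the two-parameter
    line.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(memories, dtype=float)
    if x.size != y.size:
        raise ConfigurationError("sizes and memories must have equal length")
    if x.size < 3:
        raise ConfigurationError("need at least 3 points for a power-law fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive data")
    lx, ly = np.log10(x), np.log10(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (intercept + slope * lx)
    ss_res = float(resid @ resid)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    n = x.size
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return PowerLawFit(alpha=float(10.0 ** intercept), beta=float(slope),
                       adj_r2=float(adj), n_points=n)


def predict_memory(fit: PowerLawFit, n) -> float | np.ndarray:
    """Evaluate alpha * N**beta."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("network size must be >= 1")
    out = fit.alpha * n_arr ** fit.beta
    return out if out.ndim else float(out)


def round_two_significant(x: float) -> float:
    """Round to two significant digits, half away from zero."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x))) - 1
    q = Decimal(x) / (Decimal(10) ** exp)
    return float(q.to_integral_value(rounding=ROUND_HALF_UP) * Decimal(10) ** exp)


def weak_scaling_pool(
    n_ref: float,
    pool_ref: float,
    n_target: float,
    rounding: str = "nearest_int",
) -> int:
    """Process count keeping cells per process constant.

    ``rounding='nearest_int'`` reports the nearest whole pool (tabulated
    per-size estimates); ``'two_significant'`` rounds to two significant
    figures (headline extrapolations to 10^6-10^7 cells).
    """
    if min(n_ref, pool_ref, n_target) <= 0:
        raise ValueError("all weak-scaling arguments must be positive")
    exact = n_target * pool_ref / n_ref
    if rounding == "nearest_int":
        return int(Decimal(exact).to_integral_value(rounding=ROUND_HALF_UP))
    if rounding == "two_significant":
        return int(round_two_significant(exact))
    raise ConfigurationError(f"unknown rounding mode {rounding!r}")


def fit_amdahl(threads, total_cpu_seconds) -> AmdahlFit:
    """Least squares of Total(n) = T1·(s·n + (1 − s)).

    The line's slope is T1·s and intercept T1·(1 − s), so T1 is their sum.
    The serial fraction is clipped to [0, 1] with a flag when noise pushes
    the raw estimate outside.
    """
    n = np.asarray(threads, dtype=float)
    y = np.asarray(total_cpu_seconds, dtype=float)
    if n.size != y.size:
        raise ConfigurationError("threads and times must have equal length")
    if n.size < 2 or np.unique(n).size < 2:
        raise ConfigurationError(
            "need >= 2 distinct thread counts to fit the Amdahl line")
    if np.any(n < 1):
        raise ValueError("thread counts must be >= 1")
    slope, intercept = np.polyfit(n, y, 1)
    t1 = slope + intercept
    if t1 <= 0:
        raise ConfigurationError("degenerate fit: nonpositive T1")
    s = slope / t1
    clipped = not 0.0 <= s <= 1.0
    s = float(np.clip(s, 0.0, 1.0))
    return AmdahlFit(serial_fraction=s, t1_seconds=float(t1), clipped=clipped)


def speedup(fit: AmdahlFit, n) -> float | np.ndarray:
    """Amdahl speedup 1/(s + (1 − s)/n); equals n when s = 0 and is bounded
    above by 1/s otherwise."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    s = fit.serial_fraction
    out = 1.0 / (s + (1.0 - s) / n_arr)
    return out if out.ndim else float(out)


def tradeoff_curve(
    amdahl: AmdahlFit,
    total_cores: int,
    splits,
    mpi_efficiency: float = 1.0,
    base_wall_seconds: float | None = None,
) -> pd.DataFrame:
    """Wall time across (processes, threads) splits of a fixed core budget.

    Distributed ranks scale the wall clock as 1/P, degraded by
    ``mpi_efficiency`` per doubling of P; the threads inside each rank
    contribute the Amdahl factor s + (1 − s)/T.  Every split must satisfy
    P·T = total_cores.
    """
    if not 0 < mpi_efficiency <= 1.0:
        raise ConfigurationError("mpi_efficiency must lie in (0, 1]")
    base = (base_wall_seconds if base_wall_seconds is not None
            else amdahl.t1_seconds)
    s = amdahl.serial_fraction
    rows = []
    for p, t in splits:
        if p * t != total_cores:
            raise ConfigurationError(
                f"split ({p}, {t}) does not factor {total_cores} cores")
        mpi_term = (1.0 / p) * (1.0 / mpi_efficiency) ** math.log2(p)
        wall = base * mpi_term * (s + (1.0 - s) / t)
        rows.append({"processes": p, "threads": t, "wall_seconds": wall})
    return pd.DataFrame(rows)
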