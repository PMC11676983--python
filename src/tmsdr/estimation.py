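"""Rate-constant estimation from substitution-ratio time courses.

The forward and backward rate constants (ka, kd) are estimated by nonlinear
least squares on the normalized time course r(t), whose model prediction is
the analytic progress curve of the reversible bimolecular reaction divided
by the initial invader concentration.  Optimization is performed in log10
parameter space -- the rates span well over two decades across labelling
conditions and the residual surface can be nearly flat along the dominated
direction -- with a multi-start over a log-spaced grid within the bounds.
Either parameter may instead be clamped to a fixed value (e.g. the
theoretical rate for the toehold length), in which case only the free one
is optimized.

Estimates are compared with the theoretical toehold-length-dependent rate
as unitless ratios, reported to two significant figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .conditions import DEFAULT_INITIAL, THEORETICAL_RATE_6NT
from .errors import ConfigError, DataError
from .observation_model import AggregatedCourse, SubstitutionCourse
from .reaction_model import (
    ReactionState,
    TMSDRSystem,
    ToeholdOrientation,
    closed_form_extent,
    equilibrium_extent,
    substitution_ratio,
)

__all__ = [
    "TheoreticalRateTable",
    "DEFAULT_THEORY",
    "FitOptions",
    "StartResult",
    "FitResult",
    "fit_rates",
    "ratio_to_theory",
    "round_sig",
    "build_report",
    "render_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "toehold",
    "modification",
    "ka_nM_s",
    "ka_ratio",
    "kd_nM_s",
    "kd_ratio",
    "equilibrium_substitution_pct",
    "rss",
    "converged",
]


@dataclass(frozen=True)
class TheoreticalRateTable:
    """Theoretical lumped displacement rate by toehold length (nt)."""

    rates: Dict[int, float] = field(default_factory=lambda: {6: THEORETICAL_RATE_6NT})

    def __post_init__(self) -> None:
        for length, rate in self.rates.items():
            if rate <= 0:
                raise ValueError(f"theoretical rate for {length} nt must be positive")

    def __getitem__(self, toehold_length: int) -> float:
        if toehold_length not in self.rates:
            raise ConfigError(
                f"no theoretical rate for toehold length {toehold_length} nt; "
                "supply a table entry"
            )
        return self.rates[toehold_length]


DEFAULT_THEORY = TheoreticalRateTable()


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_rates`.

    At most one of fix_ka/fix_kd may be set (nM^-1 s^-1); bounds apply to
    the free parameters.  n_starts log-grid starting points are used: a
    5x5 grid when both parameters are free.
    """

    fix_ka: Optional[float] = None
    fix_kd: Optional[float] = None
    bounds: Tuple[float, float] = (1e-8, 1.0)
    n_starts: int = 25
    weight_by_sd: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ValueError("bounds must be positive with lower < upper")
        if self.fix_ka is not None and self.fix_kd is not None:
            raise ValueError("at most one of fix_ka/fix_kd may be set")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class StartResult:
    """Diagnostics for one optimizer start."""

    ka_start: float
    kd_start: float
    ka: float
    kd: float
    rss: float
    success: bool
    message: str


@dataclass(frozen=True)
class FitResult:
    """Best-fit rate constants with per-start diagnostics.

    ratios_to_theory is (ka_hat/k_theory, kd_hat/k_theory) at full
    precision; round for display with :func:`round_sig`.
    """

    ka_hat: float
    kd_hat: float
    rss: float
    converged: bool
    n_points: int
    starts: Tuple[StartResult, ...]
    ratios_to_theory: Tuple[float, float]


def _model_ratio(
    ka: float, kd: float, initial: ReactionState, times: np.ndarray
) -> np.ndarray:
    system = TMSDRSystem(ka=ka, kd=kd)
    return closed_form_extent(system, initial, times) / initial.x1


def _coerce_course(
    data: Union[AggregatedCourse, SubstitutionCourse, Tuple[np.ndarray, np.ndarray]],
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    if isinstance(data, AggregatedCourse):
        return data.times, data.mean, data.sd
    if isinstance(data, SubstitutionCourse):
        return data.times, data.ratio, None
    times, ratio = data
    return np.asarray(times, float), np.asarray(ratio, float), None


def fit_rates(
    data: Union[AggregatedCourse, SubstitutionCourse, Tuple[np.ndarray, np.ndarray]],
    initial: ReactionState = DEFAULT_INITIAL,
    options: FitOptions = FitOptions(),
    theory: TheoreticalRateTable = DEFAULT_THEORY,
    toehold_length: int = 6,
) -> FitResult:
    """Estimate (ka, kd) by least squares on a substitution-ratio course.

    Minimizes sum_t (r_obs(t) - r_model(t; ka, kd))^2 over a multi-start
    log-grid; returns the best converged start.  With one parameter fixed
    only the free one is optimized.  If no start converges the result has
    ``converged=False`` and NaN estimates rather than raising.
    """
    times, r_obs, sd = _coerce_course(data)
    if times.size < 10:
        raise DataError(f"need >= 10 time points to fit, got {times.size}")
    if initial.x1 <= 0:
        raise ValueError("initial invader concentration must be positive")

    weights = None
    if options.weight_by_sd and sd is not None and np.all(sd > 0):
        weights = 1.0 / sd

    lo, hi = np.log10(options.bounds[0]), np.log10(options.bounds[1])
    n_free = 2 - (options.fix_ka is not None) - (options.fix_kd is not None)

    def unpack(theta: np.ndarray) -> Tuple[float, float]:
        vals = iter(10.0 ** theta)
        ka = options.fix_ka if options.fix_ka is not None else next(vals)
        kd = options.fix_kd if options.fix_kd is not None else next(vals)
        return float(ka), float(kd)

    def residuals(theta: np.ndarray) -> np.ndarray:
        ka, kd = unpack(theta)
        res = _model_ratio(ka, kd, initial, times) - r_obs
        return res * weights if weights is not None else res

    if n_free == 2:
        m = max(2, math.isqrt(options.n_starts))
        axis = np.linspace(lo, hi, m)
        starts_theta = [np.array([a, b]) for a in axis for b in axis][: options.n_starts]
    else:
        starts_theta = [np.array([v]) for v in np.linspace(lo, hi, options.n_starts)]

    start_results: List[StartResult] = []
    for theta0 in starts_theta:
        sol = least_squares(
            residuals,
            theta0,
            bounds=(np.full(n_free, lo), np.full(n_free, hi)),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
        )
        ka_fit, kd_fit = unpack(sol.x)
        ka0, kd0 = unpack(theta0)
        raw = _model_ratio(ka_fit, kd_fit, initial, times) - r_obs
        start_results.append(
            StartResult(
                ka_start=ka0,
                kd_start=kd0,
                ka=ka_fit,
                kd=kd_fit,
                rss=float(np.sum(raw**2)),
                success=bool(sol.success),
                message=str(sol.message),
            )
        )

    converged = [s for s in start_results if s.success]
    if not converged:
        return FitResult(
            ka_hat=float("nan"),
            kd_hat=float("nan"),
            rss=float("nan"),
            converged=False,
            n_points=int(times.size),
            starts=tuple(start_results),
            ratios_to_theory=(float("nan"), float("nan")),
        )
    best = min(converged, key=lambda s: s.rss)
    k_theory = theory[toehold_length]
    return FitResult(
        ka_hat=best.ka,
        kd_hat=best.kd,
        rss=best.rss,
        converged=True,
        n_points=int(times.size),
        starts=tuple(start_results),
        ratios_to_theory=(best.ka / k_theory, best.kd / k_theory),
    )


def ratio_to_theory(
    estimate: float,
    table: TheoreticalRateTable = DEFAULT_THEORY,
    toehold_length: int = 6,
) -> float:
    """Ratio of an estimated rate constant to the theoretical one.

    Full precision is returned; reports round to two significant figures
    via :func:`round_sig`.
    """
    return estimate / table[toehold_length]


def round_sig(x: float, n_sig: int = 2) -> float:
    """Round to n_sig significant figures (0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n_sig - 1))


def build_report(
    fits: Sequence[Tuple[TMSDRSystem, FitResult]],
    table: TheoreticalRateTable = DEFAULT_THEORY,
    initial: ReactionState = DEFAULT_INITIAL,
) -> pd.DataFrame:
    """Tabulate per-condition estimates, theory ratios and equilibria.

    One row per condition: the fitted rates, their ratios to theory at two
    significant figures, and the equilibrium substitution ratio the fitted
    rates predict (equal initials, nearest percent).
    """
    if not fits:
        raise DataError("need at least one fit to build a report")
    rows = []
    for system, fit in fits:
        k_theory = table[system.toehold_length]
        eq_pct = float("nan")
        if fit.converged:
            eq_system = TMSDRSystem(ka=fit.ka_hat, kd=fit.kd_hat)
            x_star = equilibrium_extent(eq_system, initial)
            eq_pct = round(100.0 * substitution_ratio(x_star, initial.x1))
        rows.append(
            {
                "toehold": "5'"
                if system.toehold_orientation is ToeholdOrientation.FIVE_PRIME
                else "3'",
                "modification": system.modification.value,
                "ka_nM_s": fit.ka_hat,
                "ka_ratio": round_sig(fit.ka_hat / k_theory),
                "kd_nM_s": fit.kd_hat,
                "kd_ratio": round_sig(fit.kd_hat / k_theory),
                "equilibrium_substitution_pct": eq_pct,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def render_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of a report table."""
    return report.to_string(index=False)
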