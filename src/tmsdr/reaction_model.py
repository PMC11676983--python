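"""Mass-action kinetics of the reversible strand displacement reaction.

The reaction is the single lumped reversible bimolecular step

    X1 + X2  <=>  X3 + X4,        v = ka*[X1][X2] - kd*[X3][X4]

where X1 is the invader strand, X2 the intact gate duplex, X3 the exchanged
gate and X4 the released strand.  Both rate constants are lumped
toehold-mediated displacement rates in nM^-1 s^-1; kd = 0 recovers the
irreversible reaction.  Because the stoichiometry is 1:1:1:1 the state is
fully described by a single extent of reaction x(t), for which the rate law
is a quadratic polynomial -- this admits a closed-form progress curve
(:func:`closed_form_extent`) that serves as an analytic oracle for the
numeric integrator (:func:`simulate`).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import SimulationError

__all__ = [
    "ToeholdOrientation",
    "Modification",
    "ReporterSpecies",
    "TMSDRSystem",
    "ReactionState",
    "Trajectory",
    "mass_action_rhs",
    "simulate",
    "closed_form_extent",
    "equilibrium_extent",
    "substitution_ratio",
]

TRAJECTORY_COLUMNS = ["time_s", "x1_nM", "x2_nM", "x3_nM", "x4_nM"]


class ToeholdOrientation(str, enum.Enum):
    """Placement of the invading toehold t1 on the gate strand X2."""

    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


class Modification(str, enum.Enum):
    """Fluorophore/quencher placement: adjacent (symmetric) or separated by
    the toehold length (asymmetric)."""

    SYMMETRIC = "symmetric"
    ASYMMETRIC = "asymmetric"


class ReporterSpecies(str, enum.Enum):
    """Species whose concentration drives the unquenched fluorescence."""

    X3 = "X3"
    X4 = "X4"


@dataclass(frozen=True)
class TMSDRSystem:
    """A reversible strand displacement construct and its rate constants.

    Parameters
    ----------
    ka, kd
        Forward / backward lumped displacement rate constants, nM^-1 s^-1.
        ``kd = 0`` denotes the irreversible reaction.
    toehold_orientation
        Whether toehold t1 sits at the 5' or 3' end of gate strand X2.
    modification
        Reporter labelling scheme (symmetric or asymmetric), metadata.
    reporter_species
        Which product species carries the unquenched fluorophore.
    toehold_length
        Toehold length in nucleotides (sets the theoretical rate scale).
    recognition_length
        Branch-migration domain length in nucleotides, metadata only.
    """

    ka: float
    kd: float
    toehold_orientation: ToeholdOrientation = ToeholdOrientation.FIVE_PRIME
    modification: Modification = Modification.SYMMETRIC
    reporter_species: ReporterSpecies = ReporterSpecies.X4
    toehold_length: int = 6
    recognition_length: int = 20

    def __post_init__(self) -> None:
        if not self.ka > 0:
            raise ValueError(f"ka must be positive, got {self.ka}")
        if self.kd < 0:
            raise ValueError(f"kd must be >= 0, got {self.kd}")
        if self.toehold_length < 1:
            raise ValueError("toehold_length must be >= 1")
        # tolerate plain strings from configs
        object.__setattr__(
            self, "toehold_orientation", ToeholdOrientation(self.toehold_orientation)
        )
        object.__setattr__(self, "modification", Modification(self.modification))
        object.__setattr__(
            self, "reporter_species", ReporterSpecies(self.reporter_species)
        )


@dataclass(frozen=True)
class ReactionState:
    """Concentrations of the four species, nM."""

    x1: float
    x2: float
    x3: float = 0.0
    x4: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3", "x4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"concentration {name}={v} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus species concentrations, one row per time point.

    Conserved quantities along any trajectory of the mass-action model:
    x1 + x3, x2 + x3 and x4 - x3 are each constant (within integrator
    tolerance).
    """

    times: np.ndarray
    states: np.ndarray  # shape (n, 4), columns x1..x4

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or states.shape != (times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")
        if times.size == 0:
            raise ValueError("trajectory must contain at least one time point")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(states < -1e-8):
            raise ValueError("trajectory contains negative concentrations")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", np.clip(states, 0.0, None))

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def x3(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def x4(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def initial_state(self) -> ReactionState:
        return ReactionState(*self.states[0])

    @property
    def final_state(self) -> ReactionState:
        return ReactionState(*self.states[-1])

    def species(self, which: ReporterSpecies) -> np.ndarray:
        return self.x3 if ReporterSpecies(which) is ReporterSpecies.X3 else self.x4

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([self.times, self.states]), columns=TRAJECTORY_COLUMNS
        )

    def to_csv(self, path: Union[str, Path, io.IOBase]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path, io.IOBase]) -> "Trajectory":
        df = pd.read_csv(path)
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory CSV missing columns {missing}")
        return cls(
            df["time_s"].to_numpy(),
            df[TRAJECTORY_COLUMNS[1:]].to_numpy(),
        )


def mass_action_rhs(state: ReactionState, system: TMSDRSystem) -> np.ndarray:
    """Instantaneous rates of change (dx1, dx2, dx3, dx4)/dt in nM/s.

    The net flux is v = ka*x1*x2 - kd*x3*x4; reactants decrease and
    products increase at rate v, so x1+x3 and x2+x3 are conserved.
    """
    arr = state.as_array() if isinstance(state, ReactionState) else np.asarray(state, float)
    if arr.shape != (4,):
        raise ValueError("state must contain four concentrations")
    if np.any(arr < 0):
        raise ValueError(f"negative concentration in state {arr}")
    x1, x2, x3, x4 = arr
    v = system.ka * x1 * x2 - system.kd * x3 * x4
    return np.array([-v, -v, v, v])


def simulate(
    system: TMSDRSystem, initial: ReactionState, times: Iterable[float]
) -> Trajectory:
    """Integrate the mass-action ODE on the given time grid.

    Uses a stiff-capable integrator (LSODA, rtol 1e-8, atol 1e-10 nM): the
    rate constants across experimental conditions span more than two orders
    of magnitude.  Raises :class:`SimulationError` with the solver message
    on integration failure.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if times[0] != 0:
        raise ValueError("time grid must start at 0")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")

    y0 = initial.as_array()
    if times.size == 1:
        return Trajectory(times, y0[None, :])

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        x1, x2, x3, x4 = y
        v = system.ka * x1 * x2 - system.kd * x3 * x4
        return (-v, -v, v, v)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y.T)


def _rate_polynomial(system: TMSDRSystem, initial: ReactionState):
    """Coefficients of dx/dt = alpha*x^2 + beta*x + gamma in the extent x."""
    a, b, c, d = initial.x1, initial.x2, initial.x3, initial.x4
    alpha = system.ka - system.kd
    beta = -(system.ka * (a + b) + system.kd * (c + d))
    gamma = system.ka * a * b - system.kd * c * d
    return alpha, beta, gamma


def equilibrium_extent(system: TMSDRSystem, initial: ReactionState) -> float:
    """Extent x* at which forward and backward fluxes balance.

    x* is the physical root of ka*(a-x)(b-x) = kd*(c+x)(d+x) with
    (a, b, c, d) the initial concentrations.  The admissible interval is
    [-min(c, d), min(a, b)] (no species may go negative); of the two
    quadratic roots the one reachable from x = 0 is returned.  For kd = 0
    this reduces to min(a, b): the irreversible reaction runs to completion.
    """
    a, b, c, d = initial.x1, initial.x2, initial.x3, initial.x4
    if a + b <= 0:
        raise ValueError("x1 + x2 must be positive")
    alpha, beta, gamma = _rate_polynomial(system, initial)
    if gamma == 0.0:
        return 0.0
    lo, hi = -min(c, d), min(a, b)
    if alpha == 0.0:
        x = -gamma / beta  # beta < 0 whenever a + b > 0
        roots = [x]
    else:
        disc = beta * beta - 4.0 * alpha * gamma
        if disc < -1e-12 * beta * beta:
            raise RuntimeError("no real equilibrium root (internal error)")
        disc = max(disc, 0.0)  # coincident roots up to rounding
        # numerically stable quadratic: beta < 0 always
        q = 0.5 * (-beta + np.sqrt(disc))
        roots = [gamma / q, q / alpha]
    tol = 1e-9 * max(1.0, a + b + c + d)
    admissible = [r for r in roots if lo - tol <= r <= hi + tol]
    # continuity from x = 0: the attractor shares the sign of gamma and is
    # the admissible root of smallest magnitude
    candidates = [r for r in admissible if r * np.sign(gamma) >= -tol]
    if not candidates:
        raise RuntimeError(
            f"no physical equilibrium root among {roots} in [{lo}, {hi}]"
        )
    x_star = min(candidates, key=abs)
    return float(np.clip(x_star, lo, hi))


def closed_form_extent(
    system: TMSDRSystem, initial: ReactionState, t: Union[float, np.ndarray]
) -> np.ndarray:
    """Analytic progress curve x(t) of the extent of reaction, nM.

    dx/dt is quadratic in x, so separation of variables and partial
    fractions give the exact solution.  With r1 the equilibrium root
    (attractor) and r2 the companion root,

        x(t) = (r1 - r2*W) / (1 - W),   W = (r1/r2) * exp(alpha*(r1-r2)*t)

    where the exponent is strictly negative, so the expression is stable
    for arbitrarily large t.  Degenerate cases (ka = kd, coincident roots)
    use their limiting closed forms rather than the generic formula.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    alpha, beta, gamma = _rate_polynomial(system, initial)
    if gamma == 0.0:
        return np.zeros_like(t)
    if alpha == 0.0:
        # ka == kd: dx/dt is linear in x
        x_eq = -gamma / beta
        return x_eq * (1.0 - np.exp(beta * t))
    disc = beta * beta - 4.0 * alpha * gamma
    if disc <= 0:
        # coincident roots: dx/dt = alpha*(x - r)^2
        r = -beta / (2.0 * alpha)
        return alpha * r * r * t / (1.0 + alpha * r * t)
    r1 = equilibrium_extent(system, initial)
    # r1 * r2 = gamma / alpha
    r2 = gamma / (alpha * r1)
    k = alpha * (r1 - r2)  # < 0: W decays, x -> r1
    with np.errstate(under="ignore"):
        w = (r1 / r2) * np.exp(k * t)
    return (r1 - r2 * w) / (1.0 - w)


def substitution_ratio(
    trajectory_or_extent: Union[Trajectory, float, np.ndarray], initial_x1: float
) -> Union[float, np.ndarray]:
    """Displaced fraction of the invader strand, in [0, 1].

    Defined as (x1_0 - x1(t)) / x1_0 -- the fraction of X1 consumed, which
    equals x4/x1_0 when products start at zero.  0 means no displacement,
    1 complete displacement.
    """
    if initial_x1 <= 0:
        raise ValueError("initial_x1 must be positive")
    if isinstance(trajectory_or_extent, Trajectory):
        extent = initial_x1 - trajectory_or_extent.x1
    else:
        extent = np.asarray(trajectory_or_extent, dtype=float)
        if np.any(extent < 0):
            raise ValueError("extent must be >= 0")
    ratio = extent / initial_x1
    return float(ratio) if np.ndim(ratio) == 0 else ratio
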