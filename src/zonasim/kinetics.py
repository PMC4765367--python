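"""Well-mixed single-hepatocyte APAP metabolism kinetics.

The model tracks five mechanistic species in a hepatocyte after an
acetaminophen (APAP) dose:

* ``P`` — intracellular APAP,
* ``S`` — the depletable sulphation co-factor pool,
* ``N`` — the reactive metabolite NAPQI formed by P450 oxidation,
* ``G`` — glutathione (GSH), the thiol that detoxifies NAPQI,
* ``T`` — the cumulative drug-protein adduct, the damage readout.

Three cumulative excretion pools (``E_sul``, ``E_gluc``, ``C_GSH``) collect
the sulphation, glucuronidation and GSH-conjugation products.  They carry no
mechanism of their own; they close the mass balance so that

    P + N + T + E_sul + E_gluc + C_GSH = P(0)

holds along every trajectory, which makes the pathway topology testable.

All reactions follow mass-action kinetics.  P450 and the glucuronidation
co-factors are assumed abundant and constant, so bioactivation (``k_450``)
and glucuronidation (``k_gluc``) are effective first-order rates.  The
protein-SH pool is treated as inexhaustible, so adduction is a first-order
NAPQI decay (``k_PSH``).  S and G turn over constitutively (production
``beta``, first-order decay ``delta``), giving drug-free baselines
``S0 = beta_S/delta_S`` and ``G0 = beta_G/delta_G``.

Units: concentrations in mM, time in hours, bimolecular rates in mM^-1 h^-1.
No measured parameter set exists for this pathway at this granularity; the
defaults used elsewhere in the package are synthetic and labelled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "RATE_CONSTANT_NAMES",
    "SPECIES",
    "RateConstants",
    "CellState",
    "InitialCondition",
    "Trajectory",
    "SolverError",
    "RateFitResult",
    "rhs",
    "simulate",
    "conservation_residual",
    "baseline_steady_state",
    "branch_fraction",
    "fit_rate_constants",
]

#: The ten kinetic parameters of the core model, in canonical order.
RATE_CONSTANT_NAMES: tuple[str, ...] = (
    "k_sul",
    "k_gluc",
    "k_450",
    "k_rev",
    "k_GSH",
    "k_PSH",
    "beta_S",
    "delta_S",
    "beta_G",
    "delta_G",
)

#: State-vector layout shared by CellState, Trajectory and the solver.
SPECIES: tuple[str, ...] = ("P", "S", "N", "G", "T", "E_sul", "E_gluc", "C_GSH")

#: Species entering the closed mass balance (S and G have independent turnover).
CONSERVED_SPECIES: tuple[str, ...] = ("P", "N", "T", "E_sul", "E_gluc", "C_GSH")


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails to produce a valid trajectory."""


@dataclass(frozen=True)
class RateConstants:
    """The ten mass-action rate constants, plus an optional adduct decay.

    Parameters marked *positional* (``k_450``, ``beta_G``, and the dose
    ``P0`` held elsewhere) vary along the sinusoid under zonation; the rest
    are shared.

    ``delta_T`` is an optional eleventh parameter describing downstream
    processing of the adduct pool.  It defaults to zero, in which case ``T``
    is a cumulative total and the model has exactly ten rate constants; a
    non-zero value breaks the mass-balance identity (by design) and is
    excluded from the ten-constant count.
    """

    k_sul: float = 0.2      # mM^-1 h^-1, bimolecular sulphation
    k_gluc: float = 0.4     # h^-1, effective first-order glucuronidation
    k_450: float = 0.3      # h^-1, effective first-order P450 bioactivation (positional)
    k_rev: float = 0.02     # h^-1, NAPQI -> APAP breakdown
    k_GSH: float = 10.0     # mM^-1 h^-1, bimolecular NAPQI-GSH conjugation
    k_PSH: float = 0.1      # h^-1, first-order NAPQI-protein adduction
    beta_S: float = 0.05    # mM h^-1, constitutive sulphation-cofactor production
    delta_S: float = 0.1    # h^-1, sulphation-cofactor decay
    beta_G: float = 0.5     # mM h^-1, constitutive GSH production (positional)
    delta_G: float = 0.1    # h^-1, GSH decay
    delta_T: float = 0.0    # h^-1, optional adduct decay (off by default)

    def __post_init__(self) -> None:
        for name in RATE_CONSTANT_NAMES + ("delta_T",):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"rate constant {name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"rate constant {name!r} must be >= 0, got {value!r}")
        if self.delta_S <= 0 or self.delta_G <= 0:
            raise ValueError(
                "delta_S and delta_G must be > 0 so the beta/delta baselines are finite"
            )

    @property
    def names(self) -> tuple[str, ...]:
        """Names of the active rate constants (ten when delta_T == 0)."""
        if self.delta_T == 0.0:
            return RATE_CONSTANT_NAMES
        return RATE_CONSTANT_NAMES + ("delta_T",)

    def replace(self, **kwargs: float) -> "RateConstants":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CellState:
    """Concentrations of the five model species and three bookkeeping pools."""

    P: float
    S: float
    N: float
    G: float
    T: float
    E_sul: float = 0.0
    E_gluc: float = 0.0
    C_GSH: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        return cls(**{s: float(v) for s, v in zip(SPECIES, y)})


@dataclass(frozen=True)
class InitialCondition:
    """Dosing state: APAP at ``P0``, co-factors at their drug-free baselines.

    ``S0``/``G0`` may be overridden (e.g. a GSH-depleted cell); by default
    they are the analytic steady states ``beta_S/delta_S`` and
    ``beta_G/delta_G`` of the drug-free turnover equations.
    """

    P0: float
    S0: float | None = None
    G0: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.P0) or self.P0 < 0:
            raise ValueError(f"P0 must be finite and >= 0, got {self.P0!r}")

    def state(self, params: RateConstants) -> CellState:
        s0, g0 = baseline_steady_state(params)
        return CellState(
            P=self.P0,
            S=self.S0 if self.S0 is not None else s0,
            N=0.0,
            G=self.G0 if self.G0 is not None else g0,
            T=0.0,
        )


@dataclass
class Trajectory:
    """Integrated time course: times, an (n_times, 8) state matrix, provenance."""

    times: np.ndarray
    states: np.ndarray
    params: RateConstants
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(SPECIES)):
            raise ValueError(
                f"states must have shape (n_times, {len(SPECIES)}), got {self.states.shape}"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def species(self, name: str) -> np.ndarray:
        """Time series for one species column, by name."""
        if name not in SPECIES:
            raise KeyError(f"unknown species {name!r}; expected one of {SPECIES}")
        return self.states[:, SPECIES.index(name)]

    @property
    def initial(self) -> CellState:
        return CellState.from_array(self.states[0])

    @property
    def terminal(self) -> CellState:
        return CellState.from_array(self.states[-1])

    def to_frame(self):
        """Return the trajectory as a pandas DataFrame (time + species columns)."""
        import pandas as pd

        data = {"time": self.times}
        data.update({s: self.states[:, i] for i, s in enumerate(SPECIES)})
        return pd.DataFrame(data)


def _rhs_array(y: np.ndarray, p: RateConstants) -> np.ndarray:
    """Mass-action right-hand side on the raw 8-vector [P,S,N,G,T,Es,Eg,Cg]."""
    P, S, N, G, T = y[0], y[1], y[2], y[3], y[4]
    sul = p.k_sul * S * P
    gluc = p.k_gluc * P
    act = p.k_450 * P
    rev = p.k_rev * N
    conj = p.k_GSH * G * N
    adduct = p.k_PSH * N
    return np.array(
        [
            -sul - gluc - act + rev,                 # dP
            p.beta_S - p.delta_S * S - sul,          # dS
            act - rev - conj - adduct,               # dN
            p.beta_G - p.delta_G * G - conj,         # dG
            adduct - p.delta_T * T,                  # dT
            sul,                                     # dE_sul
            gluc,                                    # dE_gluc
            conj,                                    # dC_GSH
        ]
    )


def _jac_array(y: np.ndarray, p: RateConstants) -> np.ndarray:
    """Analytic Jacobian of the right-hand side (for the implicit solvers)."""
    P, S, N, G = y[0], y[1], y[2], y[3]
    J = np.zeros((8, 8))
    # dP row
    J[0, 0] = -p.k_sul * S - p.k_gluc - p.k_450
    J[0, 1] = -p.k_sul * P
    J[0, 2] = p.k_rev
    # dS row
    J[1, 0] = -p.k_sul * S
    J[1, 1] = -p.delta_S - p.k_sul * P
    # dN row
    J[2, 0] = p.k_450
    J[2, 2] = -p.k_rev - p.k_GSH * G - p.k_PSH
    J[2, 3] = -p.k_GSH * N
    # dG row
    J[3, 2] = -p.k_GSH * G
    J[3, 3] = -p.delta_G - p.k_GSH * N
    # dT row
    J[4, 2] = p.k_PSH
    J[4, 4] = -p.delta_T
    # cumulative pools
    J[5, 0] = p.k_sul * S
    J[5, 1] = p.k_sul * P
    J[6, 0] = p.k_gluc
    J[7, 2] = p.k_GSH * G
    J[7, 3] = p.k_GSH * N
    return J


def rhs(state: CellState, params: RateConstants) -> CellState:
    """Evaluate the instantaneous rate of change of every state component.

    Rejects negative state components (a sign of solver misuse) and
    non-finite parameters.  Returns the derivative packaged as a
    :class:`CellState` whose fields are per-hour rates.
    """
    y = state.as_array()
    if np.any(y < 0):
        bad = [s for s, v in zip(SPECIES, y) if v < 0]
        raise ValueError(f"negative state component(s): {bad}")
    return CellState.from_array(_rhs_array(y, params))


def baseline_steady_state(params: RateConstants) -> tuple[float, float]:
    """Drug-free steady state ``(S0, G0) = (beta_S/delta_S, beta_G/delta_G)``.

    These are the fixed points of the constitutive turnover equations when
    no APAP is present; a healthy hepatocyte sits at this baseline.
    """
    if params.delta_S <= 0 or params.delta_G <= 0:
        raise ValueError("baseline requires delta_S > 0 and delta_G > 0")
    return params.beta_S / params.delta_S, params.beta_G / params.delta_G


def branch_fraction(state: CellState, params: RateConstants) -> float:
    """Instantaneous fraction of NAPQI consumption routed to protein adducts.

    ``k_PSH / (k_PSH + k_GSH * G)`` — near 0 while GSH is plentiful
    (detoxification dominates) and rising to 1 as GSH is exhausted, the
    branch switch that makes high APAP doses hepatotoxic.  The reversible
    breakdown back to APAP is not consumption and is excluded.
    """
    denom = params.k_PSH + params.k_GSH * state.G
    if denom <= 0:
        raise ValueError("branch fraction undefined: k_PSH + k_GSH*G must be > 0")
    return params.k_PSH / denom


def simulate(
    init: InitialCondition | CellState,
    params: RateConstants,
    t_end: float,
    output_grid: Sequence[float] | np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the metabolism ODEs from ``t=0`` to ``t_end``.

    A stiff-capable method with tight tolerances is the default: GSH
    conjugation can be orders of magnitude faster than co-factor turnover.
    Deterministic given identical inputs.

    Parameters
    ----------
    init
        Either an :class:`InitialCondition` (baselines derived from
        ``params``) or an explicit :class:`CellState`.
    output_grid
        Times at which to report the state; defaults to 201 evenly spaced
        points on [0, t_end].  Must lie within [0, t_end] and include
        strictly increasing values starting at 0.

    Raises
    ------
    SolverError
        If the integrator fails; the message carries the solver diagnostics.
    """
    if not (t_end > 0):
        raise ValueError(f"t_end must be > 0, got {t_end!r}")
    y0 = init.state(params).as_array() if isinstance(init, InitialCondition) else init.as_array()
    if np.any(y0 < 0):
        raise ValueError("initial state has negative components")

    if output_grid is None:
        grid = np.linspace(0.0, t_end, 201)
    else:
        grid = np.asarray(output_grid, dtype=float)
        if grid.size < 2 or grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
            raise ValueError("output_grid must be strictly increasing and start at 0")
        if grid[-1] > t_end:
            raise ValueError("output_grid must lie within [0, t_end]")

    jac = None if method == "LSODA" else (lambda t, y: _jac_array(y, params))
    sol = solve_ivp(
        lambda t, y: _rhs_array(y, params),
        (0.0, float(t_end)),
        y0,
        method=method,
        t_eval=grid,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        raise SolverError(
            f"ODE integration failed (method={method}, rtol={rtol}, atol={atol}): {sol.message}"
        )
    meta = {
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "n_rhs_evaluations": int(sol.nfev),
        "message": sol.message,
    }
    return Trajectory(times=sol.t, states=sol.y.T, params=params, solver_meta=meta)


def conservation_residual(traj: Trajectory) -> np.ndarray:
    """Per-time absolute residual of the drug mass balance.

    Every APAP molecule ends up in exactly one of P, N, T, E_sul, E_gluc or
    C_GSH, so their sum must equal its value at t=0 along the whole
    trajectory.  Returns ``|sum(t) - sum(0)|`` per output time; the maximum
    is the usual summary.  Only meaningful when ``delta_T == 0`` (an adduct
    decay term deliberately opens the balance).
    """
    idx = [SPECIES.index(s) for s in CONSERVED_SPECIES]
    total = traj.states[:, idx].sum(axis=1)
    return np.abs(total - total[0])


@dataclass
class RateFitResult:
    """Outcome of a rate-constant fit: estimates, misfit, and diagnostics."""

    params: RateConstants
    free_names: tuple[str, ...]
    cost: float
    residual_norm: float
    success: bool
    identifiable: bool
    message: str

    def relative_errors(self, truth: RateConstants) -> dict[str, float]:
        """Relative error of each fitted constant against a known truth."""
        out = {}
        for name in self.free_names:
            true_val = getattr(truth, name)
            est = getattr(self.params, name)
            out[name] = abs(est - true_val) / abs(true_val) if true_val != 0 else abs(est)
        return out


def fit_rate_constants(
    times: np.ndarray,
    observed: np.ndarray,
    init: InitialCondition,
    start: RateConstants,
    free_params: Iterable[str],
    *,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    species: Sequence[str] = SPECIES,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> RateFitResult:
    """Estimate a subset of rate constants from an observed trajectory.

    Trust-region nonlinear least squares on log10-transformed parameters
    (which enforces positivity and equalises scales across constants
    spanning decades).  The residual is the model-minus-data misfit over
    the named ``species`` columns, normalised per species by its observed
    dynamic range so no single concentration scale dominates.

    Non-identifiability is reported, not papered over: an unexcited
    trajectory (``P0 == 0`` or data flat at baseline) is flagged before any
    optimisation, and a rank-deficient Jacobian at the solution flags the
    estimates as unidentifiable afterwards.

    Parameters
    ----------
    times, observed
        Observation grid and an ``(n_times, len(species))`` data matrix.
    start
        Full parameter set supplying both the starting point for the free
        constants and the fixed values of the others.
    free_params
        Names of the constants to estimate (non-empty subset of the ten).
    bounds
        Optional per-name (lower, upper) bounds; default is a factor of
        1e4 either side of the start value.
    """
    free = tuple(free_params)
    if not free:
        raise ValueError("free_params must be a non-empty subset of the rate constants")
    unknown = set(free) - set(RATE_CONSTANT_NAMES)
    if unknown:
        raise ValueError(f"unknown rate constant name(s): {sorted(unknown)}")
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=float)
    col_idx = [SPECIES.index(s) for s in species]
    if observed.shape != (times.size, len(col_idx)):
        raise ValueError("observed must have shape (n_times, len(species))")

    # Excitation check: without drug (or with flat data) the reaction
    # constants have no signature in the trajectory.
    span = observed.max(axis=0) - observed.min(axis=0)
    scale = np.where(span > 0, span, 1.0)
    excited = init.P0 > 0 and np.any(span > 1e-12 * np.maximum(observed.max(axis=0), 1.0))
    if not excited:
        return RateFitResult(
            params=start,
            free_names=free,
            cost=float("nan"),
            residual_norm=float("nan"),
            success=False,
            identifiable=False,
            message="trajectory carries no excitation (P0 == 0 or flat data); "
            "reaction constants are not identifiable",
        )

    x0 = np.log10([getattr(start, n) for n in free])
    if bounds is None:
        lo = x0 - 4.0
        hi = x0 + 4.0
    else:
        lo = np.array([np.log10(bounds[n][0]) for n in free])
        hi = np.array([np.log10(bounds[n][1]) for n in free])

    grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    keep = slice(1, None) if times[0] != 0.0 else slice(None)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = start.replace(**{n: 10.0 ** v for n, v in zip(free, x)})
        try:
            traj = simulate(init, p, t_end=float(grid[-1]), output_grid=grid,
                            rtol=rtol, atol=atol)
        except SolverError:
            return np.full(observed.size, 1e6)
        model = traj.states[keep][:, col_idx]
        return ((model - observed) / scale).ravel()

    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac")
    fitted = start.replace(**{n: 10.0 ** v for n, v in zip(free, res.x)})

    # Identifiability: singular values of the Jacobian at the optimum.
    sv = np.linalg.svd(res.jac, compute_uv=False)
    identifiable = bool(sv.size and sv[0] > 0 and sv[-1] / sv[0] > 1e-8)

    return RateFitResult(
        params=fitted,
        free_names=free,
        cost=float(res.cost),
        residual_norm=float(np.linalg.norm(res.fun)),
        success=bool(res.success),
        identifiable=identifiable,
        message=res.message,
    )
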