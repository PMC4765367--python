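"""Synthetic parameter sets, noisy trajectories and dose-response tables.

No measured rate constants exist for the cell model at this granularity, so
all fixture data in this package are synthetic: parameter sets are sampled
log-uniformly around the package defaults, and observation noise is
multiplicative Gaussian.  Everything is driven by a single seeded
:class:`numpy.random.Generator` stream, so identical specs reproduce
byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .doseresponse import HillParams, hill_curve
from .kinetics import (
    RATE_CONSTANT_NAMES,
    InitialCondition,
    RateConstants,
    Trajectory,
    conservation_residual,
    simulate,
)

__all__ = [
    "DEFAULT_RANGES",
    "FixtureSpec",
    "TrajectoryFixture",
    "DoseResponseFixture",
    "sample_rate_constants",
    "generate_fixtures",
    "generate_dose_response_table",
]


def _default_ranges() -> dict[str, tuple[float, float]]:
    """Log-uniform sampling ranges: one decade either side of the defaults."""
    base = RateConstants()
    return {name: (getattr(base, name) / 10.0, getattr(base, name) * 10.0)
            for name in RATE_CONSTANT_NAMES}


DEFAULT_RANGES: dict[str, tuple[float, float]] = _default_ranges()


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible batch of synthetic fixtures."""

    n_replicates: int = 5
    noise_level: float = 0.01       # multiplicative Gaussian sigma
    seed: int = 0
    P0: float = 10.0                # mM
    t_end: float = 24.0             # h
    n_times: int = 61
    ranges: dict = field(default_factory=_default_ranges)

    def __post_init__(self) -> None:
        if self.n_replicates < 0:
            raise ValueError("n_replicates must be >= 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        for name, (lo, hi) in self.ranges.items():
            if name not in RATE_CONSTANT_NAMES:
                raise ValueError(f"unknown rate constant in ranges: {name!r}")
            if not (0 < lo <= hi):
                raise ValueError(f"range for {name!r} must satisfy 0 < lo <= hi")


@dataclass
class TrajectoryFixture:
    """One synthetic observation set: truth, clean trajectory, noisy data."""

    params: RateConstants
    init: InitialCondition
    trajectory: Trajectory        # noiseless reference
    noisy_states: np.ndarray      # same shape as trajectory.states
    max_conservation_residual: float


@dataclass
class DoseResponseFixture:
    """A synthetic noisy survival table generated from known Hill parameters."""

    hill: HillParams
    doses: np.ndarray
    survival_true: np.ndarray
    survival_noisy: np.ndarray


def sample_rate_constants(
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> RateConstants:
    """Draw one parameter set, each constant log-uniform within its range."""
    ranges = DEFAULT_RANGES if ranges is None else ranges
    values = {}
    for name in RATE_CONSTANT_NAMES:  # fixed order: reproducibility
        lo, hi = ranges.get(name, DEFAULT_RANGES[name])
        values[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return RateConstants(**values)


def generate_fixtures(spec: FixtureSpec) -> list[TrajectoryFixture]:
    """Generate ``n_replicates`` noisy synthetic trajectories.

    Each replicate samples a parameter set, integrates the clean trajectory,
    verifies the drug mass balance before noise injection, then applies
    multiplicative Gaussian noise ``x * (1 + sigma * eps)`` clipped at zero.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.linspace(0.0, spec.t_end, spec.n_times)
    fixtures: list[TrajectoryFixture] = []
    for _ in range(spec.n_replicates):
        params = sample_rate_constants(rng, spec.ranges)
        init = InitialCondition(P0=spec.P0)
        traj = simulate(init, params, spec.t_end, output_grid=grid)
        residual = float(conservation_residual(traj).max())
        noise = 1.0 + spec.noise_level * rng.standard_normal(traj.states.shape)
        noisy = np.clip(traj.states * noise, 0.0, None)
        fixtures.append(
            TrajectoryFixture(
                params=params,
                init=init,
                trajectory=traj,
                noisy_states=noisy,
                max_conservation_residual=residual,
            )
        )
    return fixtures


def generate_dose_response_table(
    hill: HillParams,
    doses: np.ndarray,
    noise_level: float,
    rng: np.random.Generator,
) -> DoseResponseFixture:
    """Synthetic survival-vs-dose table from known Hill parameters plus noise.

    Survival is the descending 4PL evaluated on the dose grid, perturbed by
    multiplicative Gaussian noise and clipped to [0, 1].
    """
    doses = np.asarray(doses, dtype=float)
    true = np.asarray(hill_curve(doses, hill, increasing=False))
    noisy = np.clip(true * (1.0 + noise_level * rng.standard_normal(true.shape)), 0.0, 1.0)
    return DoseResponseFixture(hill=hill, doses=doses, survival_true=true, survival_noisy=noisy)
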