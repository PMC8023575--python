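"""Overdamped Langevin (Brownian) dynamics on 1D model potentials.

The engine integrates the Euler–Maruyama discretization

    z <- z - (D/kT) * dV/dz * dt + sqrt(2 D dt) * xi,   xi ~ N(0, 1),

optionally with soft-wall confinement: half-harmonic restraints
``0.5*k*(z - edge)^2`` acting only beyond the lower/upper cell edge, the
same confinement used for per-cell milestoning sampling.  An unbiased
variant with a reflecting boundary collects first-passage times as the
brute-force kinetic oracle.

Hot loops are compiled with numba; every stochastic entry point takes an
explicit integer seed and is bitwise reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import DEFAULT_TEMPERATURE, kT
from .core import CellTrajectory
from .errors import InvalidArgumentError, UnstableIntegrationError
from .potentials import PotentialModel

__all__ = [
    "Confinement",
    "LateralRestraint",
    "SimulationSpec",
    "FirstPassageResult",
    "evaluate_wall_force",
    "simulate_confined",
    "simulate_unbiased_fpt",
]


@dataclass(frozen=True)
class Confinement:
    """Soft-wall cell confinement: half-harmonic restraints at both edges."""

    lower_edge: float
    upper_edge: float
    wall_k: float = 100.0

    def __post_init__(self):
        if not self.lower_edge < self.upper_edge:
            raise InvalidArgumentError("lower_edge must be below upper_edge")
        if self.wall_k < 0:
            raise InvalidArgumentError("wall_k must be nonnegative")


@dataclass(frozen=True)
class LateralRestraint:
    """Flat-bottom cylindrical restraint metadata (radius in angstrom).

    In a 1D run the lateral degree of freedom is not simulated; the
    restraint is recorded for provenance only.
    """

    radius: float = 10.0
    force_k: float = 100.0


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one Brownian-dynamics run.

    ``D`` is the diffusion coefficient (A^2/ps), ``dt`` the time step (ps).
    With confinement set, a warning is issued when the RMS step
    ``sqrt(2 D dt)`` is not small compared to the cell width.
    """

    potential: PotentialModel
    n_steps: int
    seed: int
    D: float = 0.1
    temperature: float = DEFAULT_TEMPERATURE
    dt: float = 0.001
    confinement: Confinement | None = None
    lateral_restraint: LateralRestraint | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if self.D <= 0:
            raise InvalidArgumentError("D must be positive")
        if self.n_steps <= 0:
            raise InvalidArgumentError("n_steps must be positive")
        if self.confinement is not None:
            width = self.confinement.upper_edge - self.confinement.lower_edge
            if math.sqrt(2 * self.D * self.dt) >= width:
                warnings.warn(
                    "RMS displacement per step exceeds the cell width; "
                    "reduce dt for meaningful confined sampling",
                    RuntimeWarning,
                    stacklevel=2,
                )


def evaluate_wall_force(z, lower_edge: float, upper_edge: float, wall_k: float):
    """Force (kcal/(mol A)) of the half-harmonic walls at ``z`` (vectorized).

    Zero inside ``[lower_edge, upper_edge]``; beyond the violated edge the
    restoring force is ``-wall_k * (z - edge)``, pointing back into the cell.
    """
    if not lower_edge < upper_edge:
        raise InvalidArgumentError("lower_edge must be below upper_edge")
    if wall_k < 0:
        raise InvalidArgumentError("wall_k must be nonnegative")
    z = np.asarray(z, dtype=float)
    force = np.zeros_like(z)
    above = z > upper_edge
    below = z < lower_edge
    force = np.where(above, -wall_k * (z - upper_edge), force)
    force = np.where(below, -wall_k * (z - lower_edge), force)
    if force.ndim == 0:
        return float(force)
    return force


@njit(cache=True)
def _force(z, amps, centers, widths, kh, hc):
    """-dV/dz of the Gaussian-mixture + harmonic potential."""
    f = -kh * (z - hc)
    for i in range(amps.size):
        d = z - centers[i]
        w2 = widths[i] * widths[i]
        f += amps[i] * d / w2 * np.exp(-0.5 * d * d / w2)
    return f


@njit(cache=True)
def _run_confined(
    z0, n_steps, dt, D, kt, amps, centers, widths, kh, hc, lower, upper, wall_k, seed
):
    np.random.seed(seed)
    out = np.empty(n_steps)
    mob = D * dt / kt
    noise = np.sqrt(2.0 * D * dt)
    z = z0
    for t in range(n_steps):
        f = _force(z, amps, centers, widths, kh, hc)
        if z > upper:
            f += -wall_k * (z - upper)
        elif z < lower:
            f += -wall_k * (z - lower)
        z = z + mob * f + noise * np.random.normal()
        out[t] = z
        if not np.isfinite(z) or abs(z) > 1e8:
            return out[: t + 1], False
    return out, True


@njit(cache=True)
def _run_fpt(
    z0, reflecting, absorbing, n_replicas, max_steps, dt, D, kt,
    amps, centers, widths, kh, hc, seed,
):
    np.random.seed(seed)
    times = np.empty(n_replicas)
    censored = np.zeros(n_replicas, dtype=np.bool_)
    mob = D * dt / kt
    noise = np.sqrt(2.0 * D * dt)
    upward = absorbing > z0
    for r in range(n_replicas):
        z = z0
        steps = 0
        done = False
        while steps < max_steps:
            f = _force(z, amps, centers, widths, kh, hc)
            z = z + mob * f + noise * np.random.normal()
            steps += 1
            if upward:
                if z < reflecting:
                    z = 2.0 * reflecting - z
                if z >= absorbing:
                    done = True
                    break
            else:
                if z > reflecting:
                    z = 2.0 * reflecting - z
                if z <= absorbing:
                    done = True
                    break
        times[r] = steps * dt
        censored[r] = not done
    return times, censored


def simulate_confined(spec: SimulationSpec, cell_index: int = 0) -> CellTrajectory:
    """Run a soft-wall confined Brownian trajectory in one cell.

    The walk starts at the cell center; every step is recorded.  Returns a
    :class:`CellTrajectory` whose ``out_of_cell_fraction`` attribute reports
    the fraction of samples beyond the cell edges (those are excluded from
    the milestoning statistics downstream).
    """
    if spec.confinement is None:
        raise InvalidArgumentError("simulate_confined requires spec.confinement")
    conf = spec.confinement
    amps, centers, widths = spec.potential.arrays()
    z0 = 0.5 * (conf.lower_edge + conf.upper_edge)
    samples, ok = _run_confined(
        z0,
        spec.n_steps,
        spec.dt,
        spec.D,
        kT(spec.temperature),
        amps,
        centers,
        widths,
        spec.potential.harmonic_k,
        spec.potential.harmonic_center,
        conf.lower_edge,
        conf.upper_edge,
        conf.wall_k,
        spec.seed,
    )
    if not ok:
        raise UnstableIntegrationError(
            f"confined run diverged after {samples.size} steps; reduce dt "
            f"(dt={spec.dt} ps, wall_k={conf.wall_k})"
        )
    traj = CellTrajectory(
        cell_index=cell_index,
        samples=samples,
        dt=spec.dt,
        wall_k=conf.wall_k,
        lower_edge=conf.lower_edge,
        upper_edge=conf.upper_edge,
        seed=spec.seed,
    )
    inside = (samples >= conf.lower_edge) & (samples <= conf.upper_edge)
    traj.out_of_cell_fraction = 1.0 - float(inside.mean())
    return traj


@dataclass
class FirstPassageResult:
    """First-passage times of unbiased replicas (ps).

    ``times`` holds one entry per replica; censored replicas (step budget
    exhausted before absorption) are excluded from ``mean``/``sem`` and
    counted in ``n_censored``.
    """

    times: np.ndarray
    censored: np.ndarray

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def uncensored_times(self) -> np.ndarray:
        return self.times[~self.censored]

    @property
    def mean(self) -> float:
        return float(self.uncensored_times.mean())

    @property
    def sem(self) -> float:
        t = self.uncensored_times
        return float(t.std(ddof=1) / np.sqrt(t.size))


def simulate_unbiased_fpt(
    spec: SimulationSpec,
    start: float,
    absorbing: float,
    n_replicas: int,
    seed: int | None = None,
    max_steps: int = 50_000_000,
    reflecting: float | None = None,
) -> FirstPassageResult:
    """Brute-force first-passage sampling on the unbiased potential.

    Each replica starts at ``start`` and runs until it first crosses
    ``absorbing``; the interval end opposite to the absorbing position is
    reflecting (position mirroring, which preserves the equilibrium density
    of overdamped dynamics).  Replicas exceeding ``max_steps`` are returned
    as censored samples.
    """
    if start == absorbing:
        raise InvalidArgumentError("start must differ from the absorbing position")
    if n_replicas <= 0:
        raise InvalidArgumentError("n_replicas must be positive")
    pot = spec.potential
    if reflecting is None:
        reflecting = pot.z_min if absorbing > start else pot.z_max
    amps, centers, widths = pot.arrays()
    times, censored = _run_fpt(
        float(start),
        float(reflecting),
        float(absorbing),
        int(n_replicas),
        int(max_steps),
        spec.dt,
        spec.D,
        kT(spec.temperature),
        amps,
        centers,
        widths,
        pot.harmonic_k,
        pot.harmonic_center,
        int(spec.seed if seed is None else seed),
    )
    result = FirstPassageResult(times=times, censored=censored)
    if result.n_censored:
        warnings.warn(
            f"{result.n_censored}/{n_replicas} first-passage replicas were "
            f"censored at {max_steps} steps",
            RuntimeWarning,
            stacklevel=2,
        )
    return result
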