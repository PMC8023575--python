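"""Markovian milestoning estimators on a 1D Voronoi tessellation.

Workflow: per-cell confined trajectories -> :func:`track_crossings` ->
:func:`aggregate_escape_rates` + :func:`solve_stationary` (cell equilibrium
probabilities from flux balance) -> :func:`free_energy_profile` ->
:func:`global_milestone_statistics` -> :func:`rate_matrix` -> :func:`mfpt`.

The estimator follows soft-wall Voronoi tessellated Markovian milestoning:
every cell is sampled by a trajectory confined with half-harmonic walls at
its edges; trajectory portions transiently outside the cell are excluded
from the statistics.  The milestone bookkeeping in each cell records, for
milestones i, j bounding that cell,

* ``N_ij``  — number of i -> j transitions (milestone j crossed while i was
  the last crossed milestone),
* ``R_i``   — total in-cell time during which milestone i was the last
  crossed one,
* ``T``     — total in-cell time carrying a milestone label.

Cell probabilities ``pi`` come from a balance equation: the net probability
flux in and out of each cell is zero, with cell-to-cell attempted-crossing
rates ``k[a,b] = (edge crossings from a toward b) / (time spent inside a)``.
Cell free energies are ``F = -kB*T*ln(pi)``; global milestone statistics are
the pi-weighted sums ``N_ij = sum_a pi_a N_ij^a/T_a`` and
``R_i = sum_a pi_a R_i^a/T_a``; the milestone rate matrix is
``q_ij = N_ij/R_i`` and mean first passage times to a target milestone solve
``sum_j q_ij tau_j = -1`` with ``tau[target] = 0``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components

from .constants import DEFAULT_TEMPERATURE, KB_KCAL_MOL_K
from .errors import (
    DegenerateSamplingError,
    InconsistentStatisticsError,
    InvalidArgumentError,
    NoUniqueSolutionError,
    UnreachableMilestoneError,
)
from .tessellation import Tessellation

__all__ = [
    "CellTrajectory",
    "CellStatistics",
    "MilestoningModel",
    "MFPTResult",
    "track_crossings",
    "aggregate_escape_rates",
    "solve_stationary",
    "free_energy_profile",
    "global_milestone_statistics",
    "rate_matrix",
    "mfpt",
]


@dataclass
class CellTrajectory:
    """A confined scalar collective-variable time series for one cell.

    Attributes
    ----------
    cell_index
        Index of the Voronoi cell the trajectory was confined to.
    samples
        Ordered CV values (angstrom), one per time step.
    dt
        Time between samples (ps).
    wall_k
        Half-harmonic wall force constant, kcal/(mol A^2).
    lower_edge, upper_edge
        Cell boundaries (angstrom) where the walls act.
    seed
        RNG seed the trajectory was generated with, if any (provenance).
    out_of_cell_fraction
        Fraction of samples beyond the cell edges (filled by the engine).
    """

    cell_index: int
    samples: np.ndarray
    dt: float
    wall_k: float
    lower_edge: float
    upper_edge: float
    seed: int | None = None
    out_of_cell_fraction: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvalidArgumentError("trajectory samples must be a non-empty 1D array")
        if self.dt <= 0:
            raise InvalidArgumentError(f"dt must be positive, got {self.dt}")
        if not self.lower_edge < self.upper_edge:
            raise InvalidArgumentError(
                f"lower_edge ({self.lower_edge}) must be below upper_edge ({self.upper_edge})"
            )

    @property
    def duration(self) -> float:
        """Total simulated time (ps)."""
        return self.samples.size * self.dt

    def split_halves(self) -> tuple["CellTrajectory", "CellTrajectory"]:
        """First/second half, for block convergence diagnostics."""
        mid = self.samples.size // 2
        if mid == 0 or mid == self.samples.size:
            raise InvalidArgumentError("trajectory too short to split in halves")
        mk = lambda s: CellTrajectory(
            self.cell_index, s, self.dt, self.wall_k,
            self.lower_edge, self.upper_edge, self.seed,
        )
        return mk(self.samples[:mid]), mk(self.samples[mid:])


@dataclass
class CellStatistics:
    """Milestone bookkeeping extracted from one cell's confined sampling.

    ``N_alpha[i, j]`` counts i -> j milestone transitions observed in the
    cell (global milestone indices; nonzero only for the cell's own edges).
    ``R_alpha[i]`` is the in-cell time during which milestone i was the last
    crossed (ps) and ``T_alpha`` their total (labelled in-cell time).
    ``occupancy_time`` is the total in-cell time including the unlabelled
    burn-in before the first crossing; it is the denominator of the
    cell-to-cell escape rates.  ``boundary_crossings`` counts in-cell ->
    out-of-cell crossings of the (lower, upper) cell boundary.
    """

    cell_index: int
    N_alpha: np.ndarray
    R_alpha: np.ndarray
    T_alpha: float
    occupancy_time: float
    boundary_crossings: np.ndarray
    out_of_cell_fraction: float = 0.0

    def __post_init__(self):
        self.N_alpha = np.asarray(self.N_alpha, dtype=float)
        self.R_alpha = np.asarray(self.R_alpha, dtype=float)
        self.boundary_crossings = np.asarray(self.boundary_crossings, dtype=float)
        if (self.N_alpha < 0).any() or (self.R_alpha < 0).any():
            raise InvalidArgumentError("counts and residence times must be >= 0")
        if self.R_alpha.sum() > self.T_alpha * (1 + 1e-9) + 1e-9:
            raise InvalidArgumentError("sum of residence times exceeds labelled time")

    def __add__(self, other: "CellStatistics") -> "CellStatistics":
        """Pool statistics of two runs confined to the same cell."""
        if other.cell_index != self.cell_index:
            raise InvalidArgumentError("can only pool statistics of the same cell")

        def total_duration(s):  # occupancy is the in-cell part of the run
            return s.occupancy_time / (1 - s.out_of_cell_fraction) if s.out_of_cell_fraction < 1 else 0.0

        dur = total_duration(self) + total_duration(other)
        frac = 1 - (self.occupancy_time + other.occupancy_time) / dur if dur > 0 else 0.0
        return CellStatistics(
            self.cell_index,
            self.N_alpha + other.N_alpha,
            self.R_alpha + other.R_alpha,
            self.T_alpha + other.T_alpha,
            self.occupancy_time + other.occupancy_time,
            self.boundary_crossings + other.boundary_crossings,
            max(frac, 0.0),
        )


def _sides(z: np.ndarray, edge: float) -> np.ndarray | None:
    """Which side of ``edge`` each sample is on (+1/-1), with samples exactly
    on the edge attributed to the side they came from (tie-break toward no
    crossing).  Returns None when the series never leaves the edge."""
    s = np.sign(z - edge).astype(np.int8)
    nz = s != 0
    if not nz.any():
        return None
    if nz.all():
        return s
    idx = np.arange(s.size)
    last = np.maximum.accumulate(np.where(nz, idx, -1))
    first = idx[nz][0]
    filled = s[np.where(last >= 0, last, first)]
    return filled


def track_crossings(traj: CellTrajectory, tess: Tessellation) -> CellStatistics:
    """Extract milestone statistics from one confined cell trajectory.

    A last-crossed-milestone label is maintained along the series: a strict
    sign change of ``(z - edge)`` between consecutive samples records a
    crossing of that edge; a crossing of milestone j while the label is
    i != j increments ``N[i, j]``.  Every in-cell sample carrying a label
    adds ``dt`` to the label's residence time and to ``T_alpha``; samples
    outside the cell, and samples before the first crossing, contribute no
    residence time.  In-cell -> out-of-cell crossings of either cell
    boundary are tallied separately for the flux-balance estimator (burn-in
    included there).
    """
    a = traj.cell_index
    lo_b, hi_b = tess.cell_bounds(a)
    if not (np.isclose(traj.lower_edge, lo_b) and np.isclose(traj.upper_edge, hi_b)):
        raise InvalidArgumentError(
            f"trajectory edges ({traj.lower_edge}, {traj.upper_edge}) do not match "
            f"tessellation cell {a} bounds ({lo_b}, {hi_b})"
        )
    z = traj.samples
    n = z.size
    n_mil = tess.milestone_count
    lo_mil, hi_mil = tess.cell_milestones(a)

    # crossing events per boundary: step t means "between samples t and t+1"
    events = {}  # boundary -> (times, direction out?)
    sides = {}
    for key, edge in (("lower", traj.lower_edge), ("upper", traj.upper_edge)):
        s = _sides(z, edge)
        sides[key] = s
        if s is None:
            events[key] = np.empty(0, dtype=int)
        else:
            events[key] = np.nonzero(s[:-1] != s[1:])[0]

    # a single step jumping across both edges: keep only the final edge
    both = np.intersect1d(events["lower"], events["upper"])
    if both.size:
        warnings.warn(
            f"cell {a}: {both.size} step(s) jumped across both cell edges; "
            "only the final edge is counted as crossed — consider reducing dt",
            RuntimeWarning,
            stacklevel=2,
        )
        ended_high = z[both + 1] > traj.upper_edge
        drop_from_upper = both[~ended_high]
        drop_from_lower = both[ended_high]
        events["upper"] = np.setdiff1d(events["upper"], drop_from_upper)
        events["lower"] = np.setdiff1d(events["lower"], drop_from_lower)

    # merge events in time order
    ev_t = np.concatenate([events["lower"], events["upper"]])
    ev_side = np.concatenate(
        [np.zeros(events["lower"].size, dtype=int), np.ones(events["upper"].size, dtype=int)]
    )
    order = np.argsort(ev_t, kind="stable")
    ev_t, ev_side = ev_t[order], ev_side[order]

    N = np.zeros((n_mil, n_mil))
    label = -1
    mil_of_side = {0: lo_mil, 1: hi_mil}
    change_t, change_lab = [], []
    for t, side in zip(ev_t, ev_side):
        m = mil_of_side[int(side)]
        if m is None:
            continue  # terminal wall: confinement boundary, not a milestone
        if label >= 0 and label != m:
            N[label, m] += 1
        if label != m:
            change_t.append(t + 1)  # label applies from the landing sample on
            change_lab.append(m)
        label = m

    # forward-fill the label over samples
    label_arr = np.full(n, -1, dtype=int)
    if change_t:
        ct = np.asarray(change_t)
        cl = np.asarray(change_lab)
        pos = np.searchsorted(ct, np.arange(n), side="right") - 1
        label_arr = np.where(pos >= 0, cl[np.maximum(pos, 0)], -1)

    in_cell = (z >= traj.lower_edge) & (z <= traj.upper_edge)
    labelled = in_cell & (label_arr >= 0)
    if labelled.any():
        R = np.bincount(label_arr[labelled], minlength=n_mil).astype(float) * traj.dt
    else:
        R = np.zeros(n_mil)
    T = float(labelled.sum()) * traj.dt
    occupancy = float(in_cell.sum()) * traj.dt

    # outward boundary crossings (in-cell side -> out-of-cell side)
    bc = np.zeros(2)
    for k, key in enumerate(("lower", "upper")):
        s = sides[key]
        if s is None:
            continue
        t_ev = events[key]
        if t_ev.size == 0:
            continue
        outward = s[t_ev + 1] == (-1 if key == "lower" else 1)
        bc[k] = float(np.count_nonzero(outward))

    return CellStatistics(
        cell_index=a,
        N_alpha=N,
        R_alpha=R,
        T_alpha=T,
        occupancy_time=occupancy,
        boundary_crossings=bc,
        out_of_cell_fraction=1.0 - in_cell.mean(),
    )


def aggregate_escape_rates(
    stats: Sequence[CellStatistics], tess: Tessellation
) -> np.ndarray:
    """Cell-to-cell attempted-escape rate matrix ``K`` (ps^-1).

    ``K[a, b]`` is the number of in-cell -> out-of-cell crossings of the
    edge shared by cells a and b, observed in cell a's confined run, divided
    by the time the run spent inside cell a.  Zero for non-adjacent cells.
    """
    M = tess.cell_count
    if len(stats) != M:
        raise InvalidArgumentError(
            f"need one CellStatistics per cell ({M}), got {len(stats)}"
        )
    by_cell = {s.cell_index: s for s in stats}
    if set(by_cell) != set(range(M)):
        raise InvalidArgumentError("cell statistics indices must cover every cell once")
    K = np.zeros((M, M))
    for a in range(M):
        s = by_cell[a]
        if s.occupancy_time <= 0:
            raise DegenerateSamplingError(
                f"cell {a} has zero in-cell sampling time"
            )
        if a > 0:
            K[a, a - 1] = s.boundary_crossings[0] / s.occupancy_time
        if a < M - 1:
            K[a, a + 1] = s.boundary_crossings[1] / s.occupancy_time
    return K


def solve_stationary(K_cells: np.ndarray) -> np.ndarray:
    """Equilibrium cell probabilities from the flux-balance equation.

    Solves ``sum_b pi_b K[b, a] = pi_a sum_b K[a, b]`` for every cell a,
    i.e. the stationary distribution of the continuous-time chain with
    generator ``G = K - diag(rowsums)``, normalized to sum to one.  The
    solution is unique when the cell graph is connected; otherwise a
    :class:`NoUniqueSolutionError` lists the components.
    """
    K = np.asarray(K_cells, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InvalidArgumentError("K_cells must be a square matrix")
    M = K.shape[0]
    off = K.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any():
        raise InvalidArgumentError("off-diagonal rates must be nonnegative")

    adj = csr_matrix(off > 0)
    ncomp, labels = connected_components(adj, directed=True, connection="strong")
    if ncomp > 1:
        comps = [np.nonzero(labels == c)[0].tolist() for c in range(ncomp)]
        raise NoUniqueSolutionError(
            f"cell graph is disconnected into {ncomp} components: {comps}",
            components=comps,
        )

    G = off - np.diag(off.sum(axis=1))
    A = G.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(M)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.where(np.abs(pi) < 1e-14, 0.0, pi)
    if (pi < 0).any():
        raise NoUniqueSolutionError("balance equation produced negative probabilities")
    return pi / pi.sum()


def free_energy_profile(
    pi: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    anchor: bool = False,
) -> np.ndarray:
    """Cell free energies ``F = -kB*T*ln(pi)`` in kcal/mol.

    Cells with ``pi == 0`` are unsampled: their free energy is reported as
    NaN and a warning names them rather than returning an infinite number.
    With ``anchor=True`` the profile minimum is shifted to zero.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or pi.size == 0:
        raise InvalidArgumentError("pi must be a non-empty vector")
    if (pi < 0).any():
        raise InvalidArgumentError("probabilities must be nonnegative")
    if not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise InvalidArgumentError("pi must be normalized to 1")
    zero = pi == 0
    if zero.any():
        warnings.warn(
            f"unsampled cells (pi = 0) reported as NaN: {np.nonzero(zero)[0].tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        F = np.where(zero, np.nan, -KB_KCAL_MOL_K * temperature * np.log(np.where(zero, 1.0, pi)))
    if anchor:
        F = F - np.nanmin(F)
    return F


def global_milestone_statistics(
    stats: Sequence[CellStatistics], pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pi-weighted global milestone statistics.

    ``N[i, j] = sum_a pi_a * N_ij^a / T_a`` and
    ``R[i]   = sum_a pi_a * R_i^a  / T_a``; cells with zero weight or zero
    labelled time contribute nothing (the latter raise a warning when their
    weight is positive).  Milestones never visited keep ``R[i] = 0``.
    """
    pi = np.asarray(pi, dtype=float)
    if len(stats) != pi.size:
        raise InvalidArgumentError(
            f"pi has {pi.size} entries but there are {len(stats)} cell statistics"
        )
    n_mil = stats[0].R_alpha.size
    N = np.zeros((n_mil, n_mil))
    R = np.zeros(n_mil)
    for s, w in zip(stats, pi):
        if w == 0:
            continue
        if s.T_alpha <= 0:
            warnings.warn(
                f"cell {s.cell_index} has positive weight but no labelled time; "
                "it contributes nothing to the milestone statistics",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        N += w * s.N_alpha / s.T_alpha
        R += w * s.R_alpha / s.T_alpha
    return N, R


def rate_matrix(N: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Milestone rate matrix ``q_ij = N_ij / R_i`` (ps^-1), as a generator.

    Off-diagonal entries are the transition rates; the diagonal is set to
    ``q_ii = -sum_{j != i} q_ij`` so rows sum to zero.  Milestones with
    outgoing transitions but zero residence time are inconsistent.
    """
    N = np.asarray(N, dtype=float)
    R = np.asarray(R, dtype=float)
    n = R.size
    if N.shape != (n, n):
        raise InvalidArgumentError("N must be square and match R's length")
    q = np.zeros((n, n))
    for i in range(n):
        row = N[i].copy()
        row[i] = 0.0
        if row.sum() > 0 and R[i] <= 0:
            raise InconsistentStatisticsError(
                f"milestone {i} has transitions but zero residence time"
            )
        if R[i] > 0:
            q[i] = row / R[i]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@dataclass
class MFPTResult:
    """Mean first passage times to one target milestone.

    ``tau[i]`` is the MFPT from milestone i to ``target_milestone`` (ps);
    ``tau[target_milestone] = 0`` by definition.  Milestones treated as
    additionally absorbing also carry zero.
    """

    target_milestone: int
    tau: np.ndarray
    absorbing: tuple[int, ...] = ()


def mfpt(
    q: np.ndarray,
    target: int,
    absorbing: Iterable[int] = (),
) -> MFPTResult:
    """Solve the first-passage linear system for the rate matrix ``q``.

    The system ``sum_j q_ij tau_j = -1`` is solved over all milestones with
    the target's row and column removed (``tau[target] = 0``); the target
    may sit at either end of the chain, so both inward and outward passages
    can be computed.  By default the opposite terminal milestone is
    reflecting (nothing beyond it); indices in ``absorbing`` are instead
    treated as additional absorbing states with zero passage time.
    """
    q = np.asarray(q, dtype=float)
    n = q.shape[0]
    if q.ndim != 2 or q.shape[1] != n:
        raise InvalidArgumentError("q must be square")
    if not 0 <= target < n:
        raise InvalidArgumentError(f"target milestone {target} outside 0..{n - 1}")
    removed = {target, *absorbing}
    keep = np.array(sorted(set(range(n)) - removed), dtype=int)
    tau = np.zeros(n)
    if keep.size == 0:
        return MFPTResult(target, tau, tuple(sorted(set(absorbing))))

    # every kept milestone must reach an absorbing one through the q>0 graph
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    reach = csr_matrix((off > 0).T)  # reversed edges: search from targets
    seen = set()
    for t in removed:
        order = breadth_first_order(reach, int(t), directed=True, return_predecessors=False)
        seen.update(int(i) for i in np.atleast_1d(order))
    missing = [int(i) for i in keep if int(i) not in seen]
    if missing:
        raise UnreachableMilestoneError(
            f"milestones {missing} cannot reach the target {target}"
        )

    Q = q[np.ix_(keep, keep)]
    try:
        t_sub = np.linalg.solve(Q, -np.ones(keep.size))
    except np.linalg.LinAlgError as exc:
        raise UnreachableMilestoneError(
            f"singular first-passage system for target {target}: {exc}"
        ) from exc
    if not np.all(np.isfinite(t_sub)) or (t_sub < -1e-9).any():
        raise UnreachableMilestoneError(
            f"first-passage system for target {target} yielded invalid times"
        )
    tau[keep] = np.maximum(t_sub, 0.0)
    return MFPTResult(target, tau, tuple(sorted(set(absorbing) - {target})))


@dataclass
class MilestoningModel:
    """Complete milestoning solution for one tessellated system."""

    tessellation: Tessellation
    pi: np.ndarray
    F: np.ndarray
    N: np.ndarray
    R: np.ndarray
    q: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    kB: float = KB_KCAL_MOL_K

    @classmethod
    def from_cell_statistics(
        cls,
        stats: Sequence[CellStatistics],
        tess: Tessellation,
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "MilestoningModel":
        K = aggregate_escape_rates(stats, tess)
        pi = solve_stationary(K)
        F = free_energy_profile(pi, temperature)
        ordered = sorted(stats, key=lambda s: s.cell_index)
        N, R = global_milestone_statistics(ordered, pi)
        q = rate_matrix(N, R)
        return cls(tess, pi, F, N, R, q, temperature)

    def anchored_F(self) -> np.ndarray:
        return self.F - np.nanmin(self.F)

    def mfpt(self, target: int | str = "last", absorbing: Iterable[int] = ()) -> MFPTResult:
        n = self.tessellation.milestone_count
        if target == "last":
            target = n - 1
        elif target == "first":
            target = 0
        return mfpt(self.q, int(target), absorbing)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tessellation": self.tessellation.to_dict(),
            "pi": self.pi.tolist(),
            "F_kcal_mol": self.F.tolist(),
            "N": self.N.tolist(),
            "R": self.R.tolist(),
            "q_per_ps": self.q.tolist(),
            "temperature_K": self.temperature,
            "kB_kcal_mol_K": self.kB,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MilestoningModel":
        return cls(
            Tessellation.from_dict(d["tessellation"]),
            np.asarray(d["pi"], dtype=float),
            np.asarray(d["F_kcal_mol"], dtype=float),
            np.asarray(d["N"], dtype=float),
            np.asarray(d["R"], dtype=float),
            np.asarray(d["q_per_ps"], dtype=float),
            float(d["temperature_K"]),
            float(d.get("kB_kcal_mol_K", KB_KCAL_MOL_K)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "MilestoningModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
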