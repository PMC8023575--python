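"""Analytic 1D model potentials for the permeation coordinate.

Every potential is a sum of Gaussian bumps/wells plus an optional harmonic
term, evaluated on a stated interval.  The factory functions build the
scenario shapes used throughout the package:

* ``flat``                     — free diffusion, the null model;
* ``harmonic``                 — a single well (equipartition checks);
* ``single_barrier``           — one Gaussian peak, emulating a permeation
  profile dominated by a single hydrophobic constriction (the wild-type-like
  scenario; default peak 15 kcal/mol);
* ``double_well``              — two wells separated by a barrier;
* ``dual_barrier_with_well``   — two peaks with an intermediate well, the
  mutant-like scenario (default main peak 8 kcal/mol).

The shapes are package-defined parameterized scenarios, not fits to any
particular simulated profile.  Each factory calibrates an overall scale by
dense scan so that the *stated* barrier height equals ``max V - min V`` on
the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "PotentialModel",
    "flat",
    "harmonic",
    "single_barrier",
    "double_well",
    "dual_barrier_with_well",
    "from_spec",
]


@dataclass(frozen=True)
class PotentialModel:
    """V(z) = 0.5*k_h*(z - c_h)^2 + sum_i A_i exp(-(z - c_i)^2 / (2 w_i^2)).

    ``z_min``/``z_max`` state the interval the model is meant for; energies
    in kcal/mol, lengths in angstrom.
    """

    kind: str
    z_min: float
    z_max: float
    gauss_amps: tuple[float, ...] = ()
    gauss_centers: tuple[float, ...] = ()
    gauss_widths: tuple[float, ...] = ()
    harmonic_k: float = 0.0
    harmonic_center: float = 0.0

    def __post_init__(self):
        if not self.z_min < self.z_max:
            raise InvalidArgumentError("z_min must be below z_max")
        n = len(self.gauss_amps)
        if len(self.gauss_centers) != n or len(self.gauss_widths) != n:
            raise InvalidArgumentError("Gaussian parameter tuples must have equal length")
        if any(w <= 0 for w in self.gauss_widths):
            raise InvalidArgumentError("Gaussian widths must be positive")

    def energy(self, z):
        """V(z), kcal/mol (vectorized)."""
        z = np.asarray(z, dtype=float)
        v = 0.5 * self.harmonic_k * (z - self.harmonic_center) ** 2
        for a, c, w in zip(self.gauss_amps, self.gauss_centers, self.gauss_widths):
            v = v + a * np.exp(-0.5 * ((z - c) / w) ** 2)
        return v

    def gradient(self, z):
        """dV/dz, kcal/(mol A) (vectorized)."""
        z = np.asarray(z, dtype=float)
        g = self.harmonic_k * (z - self.harmonic_center)
        for a, c, w in zip(self.gauss_amps, self.gauss_centers, self.gauss_widths):
            g = g + a * (-(z - c) / w**2) * np.exp(-0.5 * ((z - c) / w) ** 2)
        return g

    def barrier_height(self, n_scan: int = 20001) -> float:
        """max V - min V on the interval, by dense scan."""
        zz = np.linspace(self.z_min, self.z_max, n_scan)
        v = self.energy(zz)
        return float(v.max() - v.min())

    def arrays(self):
        """(amps, centers, widths) as float arrays, for the numba kernels."""
        return (
            np.asarray(self.gauss_amps, dtype=float),
            np.asarray(self.gauss_centers, dtype=float),
            np.asarray(self.gauss_widths, dtype=float),
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "z_min": self.z_min,
            "z_max": self.z_max,
            "gauss_amps": list(self.gauss_amps),
            "gauss_centers": list(self.gauss_centers),
            "gauss_widths": list(self.gauss_widths),
            "harmonic_k": self.harmonic_k,
            "harmonic_center": self.harmonic_center,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PotentialModel":
        return cls(
            kind=d["kind"],
            z_min=float(d["z_min"]),
            z_max=float(d["z_max"]),
            gauss_amps=tuple(d.get("gauss_amps", ())),
            gauss_centers=tuple(d.get("gauss_centers", ())),
            gauss_widths=tuple(d.get("gauss_widths", ())),
            harmonic_k=float(d.get("harmonic_k", 0.0)),
            harmonic_center=float(d.get("harmonic_center", 0.0)),
        )


def _calibrated(pot: PotentialModel, stated: float) -> PotentialModel:
    """Rescale the Gaussian amplitudes so the scanned barrier equals ``stated``."""
    actual = pot.barrier_height()
    if actual <= 0:
        raise InvalidArgumentError("potential has no barrier to calibrate")
    scale = stated / actual
    return PotentialModel(
        pot.kind,
        pot.z_min,
        pot.z_max,
        tuple(a * scale for a in pot.gauss_amps),
        pot.gauss_centers,
        pot.gauss_widths,
        pot.harmonic_k,
        pot.harmonic_center,
    )


def flat(z_min: float = 0.0, z_max: float = 10.0) -> PotentialModel:
    """V = 0 on [z_min, z_max]."""
    return PotentialModel("flat", z_min, z_max)


def harmonic(k: float, center: float | None = None, z_min: float = 0.0, z_max: float = 10.0) -> PotentialModel:
    """Single harmonic well with spring constant ``k`` kcal/(mol A^2)."""
    if k <= 0:
        raise InvalidArgumentError("spring constant must be positive")
    c = 0.5 * (z_min + z_max) if center is None else center
    return PotentialModel("harmonic", z_min, z_max, harmonic_k=k, harmonic_center=c)


def single_barrier(
    height: float = 15.0,
    z_min: float = 0.0,
    z_max: float = 10.0,
    center: float | None = None,
    width: float | None = None,
) -> PotentialModel:
    """One Gaussian peak of the stated ``height`` on a flat background."""
    if height <= 0:
        raise InvalidArgumentError("barrier height must be positive")
    span = z_max - z_min
    c = 0.5 * (z_min + z_max) if center is None else center
    w = 0.1 * span if width is None else width
    pot = PotentialModel("single_barrier", z_min, z_max, (height,), (c,), (w,))
    return _calibrated(pot, height)


def double_well(
    barrier: float = 3.0,
    z_min: float = 0.0,
    z_max: float = 10.0,
    well_separation_frac: float = 0.4,
    width: float | None = None,
) -> PotentialModel:
    """Two Gaussian wells; the stated ``barrier`` is max V - min V.

    The wells sit symmetrically about the interval midpoint; between them
    the potential returns to the flat baseline, which is the barrier top.
    """
    if barrier <= 0:
        raise InvalidArgumentError("barrier must be positive")
    span = z_max - z_min
    mid = 0.5 * (z_min + z_max)
    half_sep = 0.5 * well_separation_frac * span
    w = 0.1 * span if width is None else width
    pot = PotentialModel(
        "double_well",
        z_min,
        z_max,
        (-barrier, -barrier),
        (mid - half_sep, mid + half_sep),
        (w, w),
    )
    return _calibrated(pot, barrier)


def dual_barrier_with_well(
    main_height: float = 8.0,
    z_min: float = 0.0,
    z_max: float = 10.0,
    secondary_frac: float = 0.6,
    well_frac: float = 0.25,
    width: float | None = None,
) -> PotentialModel:
    """Two peaks with an intermediate well (mutant-like scenario).

    ``main_height`` is the stated overall barrier (max V - min V); the
    secondary peak reaches ``secondary_frac`` of the main one and the
    intermediate well dips ``well_frac`` of it below the baseline.
    """
    if main_height <= 0:
        raise InvalidArgumentError("main barrier height must be positive")
    if not 0 < secondary_frac < 1:
        raise InvalidArgumentError("secondary_frac must lie in (0, 1)")
    span = z_max - z_min
    mid = 0.5 * (z_min + z_max)
    w = 0.08 * span if width is None else width
    c1 = z_min + 0.35 * span
    c2 = z_min + 0.65 * span
    pot = PotentialModel(
        "dual_barrier_with_well",
        z_min,
        z_max,
        (main_height, -well_frac * main_height, secondary_frac * main_height),
        (c1, mid, c2),
        (w, w, w),
    )
    return _calibrated(pot, main_height)


_FACTORIES = {
    "flat": flat,
    "harmonic": harmonic,
    "single_barrier": single_barrier,
    "double_well": double_well,
    "dual_barrier_with_well": dual_barrier_with_well,
}


def from_spec(name: str, **params) -> PotentialModel:
    """Build a potential by factory name with keyword parameters (CLI entry)."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown potential {name!r}; choose from {sorted(_FACTORIES)}"
        ) from None
    return factory(**params)
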