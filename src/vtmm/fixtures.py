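"""Synthetic labelled-frame generator for the structural observables.

Builds frames with *planted* ground truth: a known number of waters inside
and outside the axial slab and the HCS sphere, a known Gaussian axial water
cloud, a known heavy-atom coordination shell around a sodium ion, and a
protein scaffold carrying the registered distance-pair residues.  The
planted values are emitted alongside the frames so tests can make exact
assertions.  All frames are synthetic stand-ins for MD trajectories, not
derived from any deposited structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidArgumentError
from .structure import AxisSpec, Frame, FrameSeries

__all__ = ["FixtureSpec", "make_fixture_frames", "rigid_transform_copy"]

_GROUP_ATOM = {
    "water": ("OH2", "TIP3"),
    "protein": ("CA", "ALA"),
    "lipid": ("C21", "POPC"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative plan of what each synthetic frame plants.

    The slab/sphere water counts refer to the axial interval
    ``hcs ± slab_half_width`` and to the ball of ``sphere_radius`` around
    the HCS point.  ``coordination`` maps group -> (atoms inside the
    cutoff, atoms outside); ``gaussian_cloud = (n, mean, sigma)`` plants an
    axial Gaussian water cloud.  ``total_waters``, when given, caps the
    overall number of planted waters (an infeasible cap is rejected).
    """

    n_frames: int = 1
    slab_in: int = 0
    slab_out: int = 0
    slab_half_width: float = 5.0
    sphere_in: int = 0
    sphere_out: int = 0
    sphere_radius: float = 5.0
    gaussian_cloud: tuple[int, float, float] | None = None
    coordination: dict | None = None
    coordination_cutoff: float = 3.0
    total_waters: int | None = None
    jitter: float = 0.3

    def planted_waters(self) -> int:
        n = self.slab_in + self.slab_out + self.sphere_in + self.sphere_out
        if self.gaussian_cloud is not None:
            n += self.gaussian_cloud[0]
        if self.coordination:
            n += sum(self.coordination.get("water", (0, 0)))
        return n

    def validate(self) -> None:
        for val in (self.slab_in, self.slab_out, self.sphere_in, self.sphere_out):
            if val < 0:
                raise InvalidArgumentError("planted counts must be nonnegative")
        if self.n_frames < 1:
            raise InvalidArgumentError("need at least one frame")
        if self.total_waters is not None and self.total_waters < self.planted_waters():
            raise InvalidArgumentError(
                f"total_waters={self.total_waters} is less than the "
                f"{self.planted_waters()} planted waters (infeasible spec)"
            )
        if self.coordination:
            unknown = set(self.coordination) - {"water", "protein", "lipid"}
            if unknown:
                raise InvalidArgumentError(f"unknown coordination groups {sorted(unknown)}")


def _water_rows(atoms, xyz_list, positions):
    name, resname = _GROUP_ATOM["water"]
    for pos in positions:
        atoms.append((name, resname, "water"))
        xyz_list.append(pos)


def make_fixture_frames(
    spec: FixtureSpec, seed: int, axis: AxisSpec | None = None
) -> FrameSeries:
    """Generate frames per ``spec`` with their planted ground truth.

    The returned series carries ``ground_truth`` with per-observable planted
    values: ``slab_count``, ``sphere_count``, ``coordination`` (per group),
    ``gaussian_mean`` and the ion id.  Ground truth is bookkept from the
    planted coordinates at construction time, independently of the counting
    operations under test.
    """
    spec.validate()
    axis = axis or AxisSpec(hcs_center=0.0)
    if axis.hcs_center is None:
        raise InvalidArgumentError("fixture axis needs hcs_center")
    rng = np.random.default_rng(seed)
    hcs = axis.hcs_point()
    u = axis.direction
    # two unit vectors orthogonal to the axis
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, trial)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    frames = []
    truth_frames = []
    ion_id = None
    for _ in range(spec.n_frames):
        atoms: list[tuple[str, str, str]] = []
        xyz: list[np.ndarray] = []
        truth = {}

        far = 6.0 * max(spec.slab_half_width, spec.sphere_radius, 5.0)

        # axial-slab waters: inside at |s| < half_width, outside well beyond,
        # both pushed off-axis so they stay out of the HCS sphere
        lateral = spec.sphere_radius + 3.0
        for _k in range(spec.slab_in):
            s = rng.uniform(-0.9, 0.9) * spec.slab_half_width
            r = lateral + rng.uniform(0, 2)
            ang = rng.uniform(0, 2 * np.pi)
            _water_rows(atoms, xyz, [hcs + s * u + r * (np.cos(ang) * e1 + np.sin(ang) * e2)])
        for _k in range(spec.slab_out):
            s = np.sign(rng.standard_normal() or 1.0) * (
                spec.slab_half_width + 1.0 + rng.uniform(0, far)
            )
            _water_rows(atoms, xyz, [hcs + s * u + lateral * e1])

        # sphere waters: inside strictly within the ball and within the slab
        # span only incidentally; outside at > radius but inside nothing else
        for _k in range(spec.sphere_in):
            r = rng.uniform(0.1, 0.9) * spec.sphere_radius
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            _water_rows(atoms, xyz, [hcs + r * v])
        for _k in range(spec.sphere_out):
            r = spec.sphere_radius * rng.uniform(1.2, 2.0)
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            _water_rows(atoms, xyz, [hcs + r * v])

        if spec.gaussian_cloud is not None:
            n, mean, sigma = spec.gaussian_cloud
            ss = rng.normal(mean, sigma, size=n)
            rr = lateral + rng.uniform(0, 2, size=n)
            aa = rng.uniform(0, 2 * np.pi, size=n)
            for s, r, ang in zip(ss, rr, aa):
                _water_rows(
                    atoms, xyz, [hcs + s * u + r * (np.cos(ang) * e1 + np.sin(ang) * e2)]
                )
            truth["gaussian_mean"] = float(mean)
            truth["gaussian_samples"] = ss

        # coordination shell around an ion placed far from all water regions
        if spec.coordination:
            # far along the axis, so shell waters never leak into slab/sphere
            ion_pos = hcs + (far + 20.0) * u
            atoms.append(("NA", "SOD", "ion"))
            xyz.append(ion_pos)
            coord_truth = {}
            for group, (n_in, n_out) in spec.coordination.items():
                name, resname = _GROUP_ATOM[group]
                for _k in range(n_in):
                    r = spec.coordination_cutoff * rng.uniform(0.4, 0.95)
                    v = rng.standard_normal(3)
                    v /= np.linalg.norm(v)
                    atoms.append((name, resname, group))
                    xyz.append(ion_pos + r * v)
                for _k in range(n_out):
                    r = spec.coordination_cutoff * rng.uniform(1.15, 2.5)
                    v = rng.standard_normal(3)
                    v /= np.linalg.norm(v)
                    atoms.append((name, resname, group))
                    xyz.append(ion_pos + r * v)
                coord_truth[group] = n_in
            coord_truth["total"] = sum(
                v for k, v in coord_truth.items() if k != "total"
            )
            truth["coordination"] = coord_truth

        n_atoms = len(atoms)
        names = np.array([a[0] for a in atoms], dtype=object)
        resnames = np.array([a[1] for a in atoms], dtype=object)
        groups = np.array([a[2] for a in atoms], dtype=object)
        resids = np.arange(1, n_atoms + 1)
        ids = np.arange(1, n_atoms + 1)
        frame = Frame(
            ids=ids,
            names=names,
            resnames=resnames,
            resids=resids,
            groups=groups,
            xyz=np.array(xyz),
        )
        if spec.coordination:
            ion_id = int(ids[np.nonzero(groups == "ion")[0][0]])
            truth["ion_id"] = ion_id
        truth["slab_count"] = _planted_slab_count(frame, axis, spec.slab_half_width)
        truth["sphere_count"] = _planted_sphere_count(frame, hcs, spec.sphere_radius)
        frames.append(frame)
        truth_frames.append(truth)

    return FrameSeries(frames, ground_truth={"frames": truth_frames, "axis": axis})


def _planted_slab_count(frame, axis, half_width):
    # fixture-side bookkeeping: plain loop arithmetic, kept separate from
    # the vectorized counting operations under test
    count = 0
    for i in range(frame.n_atoms):
        if frame.groups[i] == "water" and str(frame.names[i]).strip()[:1].upper() == "O":
            s = float(np.dot(frame.xyz[i] - axis.origin, axis.direction))
            if abs(s - axis.hcs_center) <= half_width:
                count += 1
    return count


def _planted_sphere_count(frame, center, radius):
    count = 0
    for i in range(frame.n_atoms):
        if frame.groups[i] == "water" and str(frame.names[i]).strip()[:1].upper() == "O":
            d = float(np.linalg.norm(frame.xyz[i] - center))
            if d <= radius:
                count += 1
    return count


def rigid_transform_copy(frame: Frame, seed: int, translation_scale: float = 5.0) -> Frame:
    """A copy of ``frame`` under a random rigid rotation + translation."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(2**31)))
    shift = rng.normal(scale=translation_scale, size=3)
    return Frame(
        ids=frame.ids.copy(),
        names=frame.names.copy(),
        resnames=frame.resnames.copy(),
        resids=frame.resids.copy(),
        groups=frame.groups.copy(),
        xyz=rot.apply(frame.xyz) + shift,
        box=None,
        time=frame.time,
    )
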