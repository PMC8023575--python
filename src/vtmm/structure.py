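"""Trajectory observables for voltage-sensor hydration and coordination.

Operates on labelled coordinate frames (atom name, residue, group tag among
water/protein/lipid/ion): water occupancy of an axial slab or a sphere
around the hydrophobic constriction site (HCS), axial water-density
profiles, ion coordination by group within the first solvation shell,
named residue-pair distances (the d1–d4 salt-bridge set and the cd1–cd5
cross-distance set), and backbone RMSD after optimal superposition.

Conventions: the axial coordinate increases from the extracellular to the
intracellular space; closed intervals and closed balls (a distance exactly
at the cutoff counts); water molecules are located by their oxygen atom;
hydrogens are recognized by the leading character of the whitespace-
normalized atom name; minimum-image distances are used when the frame
carries an orthorhombic box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import InvalidArgumentError, SelectionError

__all__ = [
    "GROUP_TAGS",
    "Frame",
    "FrameSeries",
    "AxisSpec",
    "DensityProfile",
    "AtomSelector",
    "DISTANCE_REGISTRY",
    "water_count_axis",
    "water_count_sphere",
    "axial_density_profile",
    "coordination",
    "pair_distance",
    "named_distance",
    "backbone_rmsd",
]

GROUP_TAGS = ("water", "protein", "lipid", "ion")


@dataclass
class Frame:
    """One labelled coordinate frame.

    ``groups`` entries must come from :data:`GROUP_TAGS`; ``box`` is an
    optional orthorhombic periodic box (three lengths, angstrom).
    """

    ids: np.ndarray
    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    groups: np.ndarray
    xyz: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.groups = np.asarray(self.groups, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = self.ids.size
        if self.xyz.shape != (n, 3):
            raise InvalidArgumentError("xyz must have shape (n_atoms, 3)")
        if len(np.unique(self.ids)) != n:
            raise InvalidArgumentError("atom ids must be unique")
        if not np.all(np.isfinite(self.xyz)):
            raise InvalidArgumentError("coordinates must be finite")
        bad = set(self.groups) - set(GROUP_TAGS)
        if bad:
            raise InvalidArgumentError(f"unknown group tags {sorted(bad)}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or (self.box <= 0).any():
                raise InvalidArgumentError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return self.ids.size

    def normalized_names(self) -> np.ndarray:
        return np.array([str(x).strip() for x in self.names], dtype=object)

    def is_hydrogen(self) -> np.ndarray:
        """Hydrogen flag by leading character of the normalized atom name."""
        return np.array(
            [str(x).strip()[:1].upper() == "H" for x in self.names], dtype=bool
        )

    def water_oxygen_mask(self) -> np.ndarray:
        names = self.normalized_names()
        is_ox = np.array([n[:1].upper() == "O" for n in names], dtype=bool)
        return (self.groups == "water") & is_ox

    def displacements(self, point: np.ndarray, mask=None) -> np.ndarray:
        """Vectors from ``point`` to the (masked) atoms, minimum-image if boxed."""
        xyz = self.xyz if mask is None else self.xyz[mask]
        d = xyz - np.asarray(point, dtype=float)
        if self.box is not None:
            d = d - self.box * np.round(d / self.box)
        return d


@dataclass
class FrameSeries:
    """An ordered list of frames sharing one atom layout."""

    frames: list
    ground_truth: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass
class AxisSpec:
    """The permeation axis of the voltage sensor.

    The axial coordinate of an atom is its projection
    ``s = (r - origin) . direction`` and increases from the extracellular to
    the intracellular space.  ``hcs_center`` locates the hydrophobic
    constriction along the axis; it must be supplied by the user (the HCS
    is defined by the V103/F137/V175 constriction residues, whose axial
    position depends on the structure at hand).
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    hcs_center: float | None = None
    orientation: str = "extracellular_to_intracellular"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if norm == 0:
            raise InvalidArgumentError("axis direction must be nonzero")
        self.direction = self.direction / norm

    def axial_coordinate(self, xyz: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(xyz) - self.origin) @ self.direction

    def hcs_point(self) -> np.ndarray:
        if self.hcs_center is None:
            raise InvalidArgumentError("AxisSpec.hcs_center is not set")
        return self.origin + self.hcs_center * self.direction


@dataclass
class DensityProfile:
    """Mean per-bin water counts along the axis, averaged over frames."""

    bin_edges: np.ndarray
    mean_counts: np.ndarray
    n_frames: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mean_counts = np.asarray(self.mean_counts, dtype=float)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise InvalidArgumentError("bin edges must be strictly increasing")
        if self.mean_counts.size != self.bin_edges.size - 1:
            raise InvalidArgumentError("need one count per bin")


# ---------------------------------------------------------------------------
# water occupancy


def water_count_axis(frame: Frame, axis: AxisSpec, half_width: float = 5.0) -> int:
    """Water oxygens whose axial coordinate lies within ``hcs_center ±
    half_width`` (closed interval; the default is the 10-angstrom slab
    centered on the constriction)."""
    if axis.hcs_center is None:
        raise InvalidArgumentError("AxisSpec.hcs_center must be set for slab counting")
    mask = frame.water_oxygen_mask()
    if not mask.any():
        warnings.warn("frame contains no water oxygens", RuntimeWarning, stacklevel=2)
        return 0
    s = axis.axial_coordinate(frame.xyz[mask])
    return int(np.count_nonzero(np.abs(s - axis.hcs_center) <= half_width))


def water_count_sphere(frame: Frame, center, radius: float = 5.0) -> int:
    """Water oxygens within the closed ball of ``radius`` around ``center``."""
    if radius <= 0:
        raise InvalidArgumentError("radius must be positive")
    mask = frame.water_oxygen_mask()
    if not mask.any():
        warnings.warn("frame contains no water oxygens", RuntimeWarning, stacklevel=2)
        return 0
    d = np.linalg.norm(frame.displacements(center, mask), axis=1)
    return int(np.count_nonzero(d <= radius))


def axial_density_profile(
    frames: Iterable[Frame],
    axis: AxisSpec,
    bin_width: float,
    span: tuple[float, float] | None = None,
) -> DensityProfile:
    """Per-bin water counts along the axis, averaged over frames.

    ``span`` defaults to the bin-width grid covering every water in every
    frame, so the per-frame bin sums equal the frames' water totals.
    """
    frames = list(frames)
    if not frames:
        raise InvalidArgumentError("need at least one frame")
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be positive")
    coords = []
    for fr in frames:
        mask = fr.water_oxygen_mask()
        coords.append(axis.axial_coordinate(fr.xyz[mask]) if mask.any() else np.empty(0))
    if span is None:
        allc = np.concatenate([c for c in coords if c.size] or [np.zeros(1)])
        lo = np.floor(allc.min() / bin_width) * bin_width
        hi = np.ceil(allc.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = span
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for c in coords:
        h, _ = np.histogram(c, bins=edges)
        counts += h
    return DensityProfile(edges, counts / len(frames), len(frames))


# ---------------------------------------------------------------------------
# ion coordination


def coordination(frame: Frame, ion_id, cutoff: float = 3.0) -> dict:
    """Heavy-atom coordination of one ion within its first solvation shell.

    Counts water, protein and lipid heavy atoms (hydrogens excluded by atom
    name) whose minimum-image distance from the ion is <= ``cutoff``
    (default 3 angstrom); ``total`` is the sum over the three groups.
    """
    where = np.nonzero(frame.ids == ion_id)[0]
    if where.size != 1:
        raise InvalidArgumentError(f"ion id {ion_id!r} matched {where.size} atoms")
    ion_idx = int(where[0])
    center = frame.xyz[ion_idx]
    heavy = ~frame.is_hydrogen()
    heavy[ion_idx] = False
    out = {}
    for group in ("water", "protein", "lipid"):
        mask = heavy & (frame.groups == group)
        if mask.any():
            d = np.linalg.norm(frame.displacements(center, mask), axis=1)
            out[group] = int(np.count_nonzero(d <= cutoff))
        else:
            out[group] = 0
    out["total"] = out["water"] + out["protein"] + out["lipid"]
    return out


# ---------------------------------------------------------------------------
# named pair distances


@dataclass(frozen=True)
class AtomSelector:
    """Selects exactly one atom by residue number, atom name and optionally
    residue name."""

    resid: int
    name: str
    resname: str | None = None

    def resolve(self, frame: Frame) -> int:
        names = frame.normalized_names()
        mask = (frame.resids == self.resid) & (names == self.name.strip())
        if self.resname is not None:
            mask &= frame.resnames == self.resname
        idx = np.nonzero(mask)[0]
        if idx.size != 1:
            matches = [
                (int(frame.resids[i]), str(frame.resnames[i]), str(names[i]))
                for i in idx
            ]
            raise SelectionError(
                f"selector {self} matched {idx.size} atoms (need exactly 1)",
                matches=matches,
            )
        return int(idx[0])


#: Salt-bridge (d1–d4) and cross-distance (cd1–cd5) registry.  The d-series
#: uses the last side-chain carbon of each residue so side-chain rotations of
#: the charged groups are tolerated; the cd-series uses the C-alpha atoms of
#: facing residues on opposite helices.  Helix membership in the values.
DISTANCE_REGISTRY = {
    "d1": (AtomSelector(207, "CZ"), AtomSelector(130, "CD"), ("S4", "S2")),
    "d2": (AtomSelector(204, "CD"), AtomSelector(130, "CD"), ("S4", "S2")),
    "d3": (AtomSelector(210, "CZ"), AtomSelector(140, "CD"), ("S4", "S2")),
    "d4": (AtomSelector(213, "CZ"), AtomSelector(172, "CG"), ("S4", "S3")),
    "cd1": (AtomSelector(99, "CA"), AtomSelector(172, "CA"), ("S1", "S3")),
    "cd2": (AtomSelector(103, "CA"), AtomSelector(175, "CA"), ("S1", "S3")),
    "cd3": (AtomSelector(110, "CA"), AtomSelector(182, "CA"), ("S1", "S3")),
    "cd4": (AtomSelector(141, "CA"), AtomSelector(211, "CA"), ("S2", "S4")),
    "cd5": (AtomSelector(134, "CA"), AtomSelector(203, "CA"), ("S2", "S4")),
}


def pair_distance(frame: Frame, selector_a: AtomSelector, selector_b: AtomSelector) -> float:
    """Euclidean (minimum-image, if boxed) distance between two single atoms."""
    ia = selector_a.resolve(frame)
    ib = selector_b.resolve(frame)
    d = frame.xyz[ib] - frame.xyz[ia]
    if frame.box is not None:
        d = d - frame.box * np.round(d / frame.box)
    return float(np.linalg.norm(d))


def named_distance(frame: Frame, name: str) -> float:
    """One of the registered d1–d4 / cd1–cd5 distances."""
    try:
        sel_a, sel_b, _helices = DISTANCE_REGISTRY[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown distance {name!r}; registry has {sorted(DISTANCE_REGISTRY)}"
        ) from None
    return pair_distance(frame, sel_a, sel_b)


# ---------------------------------------------------------------------------
# backbone RMSD


def _resolve_selection(frame: Frame, selection) -> np.ndarray:
    if selection is None:
        idx = np.nonzero(frame.groups == "protein")[0]
    elif isinstance(selection, np.ndarray) and selection.dtype == bool:
        idx = np.nonzero(selection)[0]
    else:
        idx = np.array([s.resolve(frame) for s in selection], dtype=int)
    if idx.size == 0:
        raise InvalidArgumentError("selection resolved to no atoms")
    return idx


def backbone_rmsd(frame: Frame, reference: Frame, selection=None, superpose: bool = True) -> float:
    """RMSD (angstrom) of a selection after optimal rigid-body superposition.

    ``selection`` may be ``None`` (all protein atoms), a boolean mask, or a
    sequence of :class:`AtomSelector`; it must resolve to identically
    ordered atom lists in both frames.  With ``superpose=False`` the raw
    (no-fit) RMSD is returned.
    """
    import MDAnalysis.analysis.rms as mda_rms

    ia = _resolve_selection(frame, selection)
    ib = _resolve_selection(reference, selection)
    if ia.size != ib.size:
        raise InvalidArgumentError(
            f"selection sizes differ: {ia.size} vs {ib.size} atoms"
        )
    names_a = frame.normalized_names()[ia]
    names_b = reference.normalized_names()[ib]
    if not (np.all(names_a == names_b) and np.all(frame.resids[ia] == reference.resids[ib])):
        raise InvalidArgumentError("selections resolve to different atom lists")
    a = frame.xyz[ia]
    b = reference.xyz[ib]
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    value = float(mda_rms.rmsd(a, b, center=True, superposition=True))
    if np.isnan(value):
        # degenerate geometries (e.g. collinear selections) can defeat the
        # quaternion superposition; fall back to an explicit Kabsch fit
        from scipy.spatial.transform import Rotation

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(bc, ac)
        value = float(np.sqrt(np.mean(np.sum((rot.apply(ac) - bc) ** 2, axis=1))))
    return value
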