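"""Readers turning coordinate files into labelled :class:`~vtmm.structure.Frame`s.

PDB (ATOM/HETATM records, CRYST1 box, multi-MODEL) and multi-frame XYZ are
parsed with MDAnalysis; atoms are tagged water/protein/lipid/ion by
configurable residue-name tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure import Frame, FrameSeries

__all__ = ["GroupRules", "read_pdb_frames", "read_xyz_frames"]

_WATER_RESNAMES = {"HOH", "TIP3", "TIP4", "WAT", "SOL", "SPC", "H2O"}
_ION_RESNAMES = {"NA", "SOD", "CL", "CLA", "K", "POT", "MG", "CA2", "CAL", "ZN"}
_LIPID_RESNAMES = {
    "POPC", "POPE", "POPG", "POPS", "POPI", "DPPC", "DOPC", "DMPC",
    "CHL1", "PIP2", "SAPI", "PSM",
}


@dataclass(frozen=True)
class GroupRules:
    """Residue-name tables mapping residues to group tags.

    Residues matching none of the tables default to ``protein``.
    """

    water: frozenset = frozenset(_WATER_RESNAMES)
    ion: frozenset = frozenset(_ION_RESNAMES)
    lipid: frozenset = frozenset(_LIPID_RESNAMES)

    def tag(self, resname: str) -> str:
        r = resname.strip().upper()
        if r in self.water:
            return "water"
        if r in self.ion:
            return "ion"
        if r in self.lipid:
            return "lipid"
        return "protein"


def _universe_to_frames(universe, rules: GroupRules) -> FrameSeries:
    atoms = universe.atoms
    names = np.array([str(n) for n in atoms.names], dtype=object)
    try:
        resnames = np.array([str(r) for r in atoms.resnames], dtype=object)
    except Exception:  # XYZ carries no residue information
        resnames = np.array(["UNK"] * len(atoms), dtype=object)
    try:
        resids = np.asarray(atoms.resids, dtype=int)
    except Exception:
        resids = np.ones(len(atoms), dtype=int)
    groups = np.array([rules.tag(r) for r in resnames], dtype=object)
    ids = np.arange(1, len(atoms) + 1)

    frames = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no dt information.*")
        for ts in universe.trajectory:
            box = None
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = np.asarray(ts.dimensions[:3], dtype=float)
            frames.append(
                Frame(
                    ids=ids.copy(),
                    names=names.copy(),
                    resnames=resnames.copy(),
                    resids=resids.copy(),
                    groups=groups.copy(),
                    xyz=np.asarray(ts.positions, dtype=float).copy(),
                    box=box,
                    time=float(getattr(ts, "time", 0.0) or 0.0),
                )
            )
    return FrameSeries(frames)


def read_pdb_frames(path, rules: GroupRules | None = None) -> FrameSeries:
    """Read a (multi-MODEL) PDB file into labelled frames."""
    import MDAnalysis as mda

    rules = rules or GroupRules()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign guessing warnings from the reader
        u = mda.Universe(str(path))
    series = _universe_to_frames(u, rules)
    # PDB carries author atom ids and residue numbering; keep them
    try:
        ids = np.asarray(u.atoms.ids, dtype=int)
        if len(np.unique(ids)) == len(ids):
            for fr in series.frames:
                fr.ids = ids.copy()
    except Exception:
        pass
    return series


def read_xyz_frames(path, rules: GroupRules | None = None,
                    name_groups: dict | None = None) -> FrameSeries:
    """Read a multi-frame XYZ file.

    XYZ has no residue records, so every atom defaults to ``protein``
    unless ``name_groups`` maps element/atom names to group tags
    (e.g. ``{"O": "water", "NA": "ion"}``).
    """
    import MDAnalysis as mda

    rules = rules or GroupRules()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    series = _universe_to_frames(u, rules)
    if name_groups:
        lut = {k.strip().upper(): v for k, v in name_groups.items()}
        for fr in series.frames:
            fr.groups = np.array(
                [lut.get(str(n).strip().upper(), "protein") for n in fr.names],
                dtype=object,
            )
    return series
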