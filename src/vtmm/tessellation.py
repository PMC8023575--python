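"""Voronoi tessellation of a 1D reaction coordinate.

A set of ordered centers ``z_1 < z_2 < ... < z_M`` on the permeation axis
defines M Voronoi cells; in one dimension each internal cell boundary (the
*milestone*) is simply the midpoint between adjacent centers.  Milestone k
separates cells k and k+1 (0-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class Tessellation:
    """Ordered 1D Voronoi cells along the permeation axis.

    Parameters
    ----------
    centers
        Strictly increasing cell centers (angstrom).  The internal edges —
        the milestones — are the midpoints of adjacent centers.  The outer
        boundaries of the terminal cells are placed symmetrically, so every
        cell has a well-defined ``(lower, upper)`` support for the soft-wall
        confinement.
    """

    centers: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size < 2:
            raise InvalidArgumentError(
                "a tessellation needs at least 2 cell centers (one milestone)"
            )
        if not np.all(np.diff(centers) > 0):
            raise InvalidArgumentError("cell centers must be strictly increasing")
        if not np.all(np.isfinite(centers)):
            raise InvalidArgumentError("cell centers must be finite")
        object.__setattr__(self, "centers", centers)

    # -- basic geometry ----------------------------------------------------

    @property
    def cell_count(self) -> int:
        return self.centers.size

    @property
    def edges(self) -> np.ndarray:
        """Internal cell boundaries (milestone positions), length M-1."""
        return 0.5 * (self.centers[:-1] + self.centers[1:])

    @property
    def milestone_count(self) -> int:
        return self.cell_count - 1

    @property
    def lower_bound(self) -> float:
        """Outer boundary of the first cell (mirror of its upper edge)."""
        return float(self.centers[0] - (self.edges[0] - self.centers[0]))

    @property
    def upper_bound(self) -> float:
        """Outer boundary of the last cell (mirror of its lower edge)."""
        return float(self.centers[-1] + (self.centers[-1] - self.edges[-1]))

    def cell_bounds(self, index: int) -> tuple[float, float]:
        """Full (lower, upper) support of cell ``index`` including the
        outer walls of the terminal cells."""
        self._check_index(index)
        edges = self.edges
        lo = self.lower_bound if index == 0 else float(edges[index - 1])
        hi = self.upper_bound if index == self.cell_count - 1 else float(edges[index])
        return lo, hi

    def cell_milestones(self, index: int) -> tuple[int | None, int | None]:
        """Global milestone ids at the (lower, upper) boundary of a cell.

        Terminal cells have ``None`` on their outer side: the domain wall
        there confines the trajectory but is not a milestone.
        """
        self._check_index(index)
        lower = index - 1 if index > 0 else None
        upper = index if index < self.cell_count - 1 else None
        return lower, upper

    def widths(self) -> np.ndarray:
        bounds = np.concatenate(([self.lower_bound], self.edges, [self.upper_bound]))
        return np.diff(bounds)

    def _check_index(self, index: int) -> None:
        if not 0 <= index < self.cell_count:
            raise InvalidArgumentError(
                f"cell index {index} outside 0..{self.cell_count - 1}"
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {"centers": self.centers.tolist()}

    @classmethod
    def from_dict(cls, data: dict) -> "Tessellation":
        return cls(np.asarray(data["centers"], dtype=float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Tessellation":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_uniform_tessellation(origin: float, width: float, count: int) -> Tessellation:
    """Uniform grid of ``count`` cells of equal ``width`` starting at ``origin``.

    Cell k spans ``[origin + k*width, origin + (k+1)*width]``; its center sits
    at the midpoint, so the internal edges land on the grid lines.
    """
    if width <= 0:
        raise InvalidArgumentError(f"cell width must be positive, got {width}")
    if count < 2:
        raise InvalidArgumentError(
            f"milestoning needs at least 2 cells, got {count}"
        )
    centers = origin + width * (np.arange(count) + 0.5)
    return Tessellation(centers)
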