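"""File dialects: per-cell CV time series (CSV + JSON sidecar) and result
tables (TSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CellTrajectory, MFPTResult, MilestoningModel
from .errors import InvalidArgumentError
from .tessellation import Tessellation

__all__ = [
    "write_cell_trajectory",
    "read_cell_trajectory",
    "pmf_table",
    "mfpt_table",
    "write_pmf_table",
    "write_mfpt_table",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_cell_trajectory(traj: CellTrajectory, csv_path) -> None:
    """Write one cell's time series as CSV (time_ps, z_angstrom) plus a JSON
    sidecar with the cell metadata."""
    csv_path = Path(csv_path)
    t = np.arange(1, traj.samples.size + 1) * traj.dt
    pd.DataFrame({"time_ps": t, "z_angstrom": traj.samples}).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    meta = {
        "cell_index": traj.cell_index,
        "lower_edge": traj.lower_edge,
        "upper_edge": traj.upper_edge,
        "wall_k": traj.wall_k,
        "dt": traj.dt,
        "seed": traj.seed,
    }
    with open(_sidecar_path(csv_path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_cell_trajectory(csv_path) -> CellTrajectory:
    """Read a CSV + sidecar pair written by :func:`write_cell_trajectory`."""
    csv_path = Path(csv_path)
    side = _sidecar_path(csv_path)
    if not side.exists():
        raise InvalidArgumentError(f"missing sidecar {side} for {csv_path}")
    with open(side) as fh:
        meta = json.load(fh)
    df = pd.read_csv(csv_path)
    for col in ("time_ps", "z_angstrom"):
        if col not in df.columns:
            raise InvalidArgumentError(f"{csv_path} lacks required column {col!r}")
    return CellTrajectory(
        cell_index=int(meta["cell_index"]),
        samples=df["z_angstrom"].to_numpy(),
        dt=float(meta["dt"]),
        wall_k=float(meta["wall_k"]),
        lower_edge=float(meta["lower_edge"]),
        upper_edge=float(meta["upper_edge"]),
        seed=meta.get("seed"),
    )


def pmf_table(model: MilestoningModel) -> pd.DataFrame:
    """Per-cell equilibrium table: cell_index, center_A, pi, F_kcal_mol."""
    return pd.DataFrame(
        {
            "cell_index": np.arange(model.tessellation.cell_count),
            "center_A": model.tessellation.centers,
            "pi": model.pi,
            "F_kcal_mol": model.F,
        }
    )


def mfpt_table(result: MFPTResult, tess: Tessellation) -> pd.DataFrame:
    """Per-milestone MFPT table: milestone_index, position_A, tau_ps."""
    return pd.DataFrame(
        {
            "milestone_index": np.arange(tess.milestone_count),
            "position_A": tess.edges,
            "tau_ps": result.tau,
        }
    )


def write_pmf_table(model: MilestoningModel, path) -> None:
    pmf_table(model).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_mfpt_table(result: MFPTResult, tess: Tessellation, path) -> None:
    mfpt_table(result, tess).to_csv(path, sep="\t", index=False, float_format="%.10g")
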