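"""End-to-end scenario runner: tessellate, sample every cell, solve the
milestoning model, and compare two scenarios the way a wild-type-versus-
mutant permeation study would (barrier difference and MFPT ratio).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .constants import DEFAULT_TEMPERATURE
from .core import (
    CellStatistics,
    CellTrajectory,
    MFPTResult,
    MilestoningModel,
    track_crossings,
)
from .dynamics import Confinement, SimulationSpec, simulate_confined
from .errors import InvalidArgumentError
from .io import mfpt_table, pmf_table
from .potentials import PotentialModel, from_spec
from .tessellation import Tessellation, build_uniform_tessellation

__all__ = ["ScenarioConfig", "ScenarioReport", "ScenarioComparison",
           "run_scenario", "compare_scenarios", "cell_seed"]


def cell_seed(base_seed: int, cell_index: int, replica: int = 0) -> int:
    """Deterministic per-cell, per-replica child seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(cell_index, replica))
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


@dataclass(frozen=True)
class ScenarioConfig:
    """One milestoning scenario on a model potential.

    The tessellation is a uniform grid over the potential's interval with
    ``n_cells`` cells.  ``seeds`` lists independent replicas per cell whose
    statistics are pooled.  ``target`` selects the MFPT target milestone:
    ``"last"`` (intracellular end, the default, matching an inward current),
    ``"first"``, or an explicit index.
    """

    name: str
    potential: PotentialModel
    n_cells: int = 20
    n_steps: int = 500_000
    dt: float = 0.001
    D: float = 0.1
    wall_k: float = 100.0
    temperature: float = DEFAULT_TEMPERATURE
    seeds: tuple[int, ...] = (1,)
    target: int | str = "last"

    def __post_init__(self):
        if self.n_cells < 2:
            raise InvalidArgumentError("need at least 2 cells")
        if not self.seeds:
            raise InvalidArgumentError("seeds must be non-empty")

    def tessellation(self) -> Tessellation:
        width = (self.potential.z_max - self.potential.z_min) / self.n_cells
        return build_uniform_tessellation(self.potential.z_min, width, self.n_cells)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "potential": self.potential.to_dict(),
            "n_cells": self.n_cells,
            "n_steps": self.n_steps,
            "dt": self.dt,
            "D": self.D,
            "wall_k": self.wall_k,
            "temperature": self.temperature,
            "seeds": list(self.seeds),
            "target": self.target,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        pot = d["potential"]
        if "kind" in pot and "gauss_amps" in pot:
            potential = PotentialModel.from_dict(pot)
        else:  # factory-style spec: {"kind": ..., other factory kwargs}
            kind = pot["kind"]
            params = {k: v for k, v in pot.items() if k != "kind"}
            potential = from_spec(kind, **params)
        return cls(
            name=d["name"],
            potential=potential,
            n_cells=int(d.get("n_cells", 20)),
            n_steps=int(d.get("n_steps", 500_000)),
            dt=float(d.get("dt", 0.001)),
            D=float(d.get("D", 0.1)),
            wall_k=float(d.get("wall_k", 100.0)),
            temperature=float(d.get("temperature", DEFAULT_TEMPERATURE)),
            seeds=tuple(int(s) for s in d.get("seeds", (1,))),
            target=d.get("target", "last"),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ScenarioReport:
    """Everything one scenario run produced, with provenance."""

    config: ScenarioConfig
    tessellation: Tessellation
    model: MilestoningModel
    mfpt: MFPTResult
    out_of_cell_fractions: np.ndarray
    convergence: dict

    @property
    def anchored_F(self) -> np.ndarray:
        return self.model.anchored_F()

    @property
    def peak_F(self) -> float:
        """Main barrier height: maximum of the minimum-anchored profile."""
        return float(np.nanmax(self.anchored_F))

    @property
    def mfpt_first_to_target(self) -> float:
        start = 0 if self.mfpt.target_milestone != 0 else self.tessellation.milestone_count - 1
        return float(self.mfpt.tau[start])

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pmf_table(self.model).to_csv(out / "pmf.tsv", sep="\t", index=False,
                                     float_format="%.10g")
        mfpt_table(self.mfpt, self.tessellation).to_csv(
            out / "mfpt.tsv", sep="\t", index=False, float_format="%.10g"
        )
        self.model.to_json(out / "model.json")
        diag = {
            "scenario": self.config.name,
            "seeds": list(self.config.seeds),
            "target_milestone": int(self.mfpt.target_milestone),
            "peak_F_kcal_mol": self.peak_F,
            "mfpt_first_to_target_ps": self.mfpt_first_to_target,
            "out_of_cell_fractions": [float(x) for x in self.out_of_cell_fractions],
            "convergence": self.convergence,
        }
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True)


def _statistics_for(trajs, tess) -> list[CellStatistics]:
    pooled: dict[int, CellStatistics] = {}
    for traj in trajs:
        s = track_crossings(traj, tess)
        pooled[s.cell_index] = pooled[s.cell_index] + s if s.cell_index in pooled else s
    return [pooled[a] for a in sorted(pooled)]


def _convergence(trajs, tess, config) -> dict:
    """Block diagnostic: first vs second half of every cell trajectory."""
    halves = ([], [])
    for traj in trajs:
        h1, h2 = traj.split_halves()
        halves[0].append(h1)
        halves[1].append(h2)
    out = {}
    try:
        models = [
            MilestoningModel.from_cell_statistics(
                _statistics_for(h, tess), tess, config.temperature
            )
            for h in halves
        ]
        dF = np.nanmax(np.abs(models[0].anchored_F() - models[1].anchored_F()))
        out["max_abs_dF_kcal_mol"] = float(dF)
        taus = [m.mfpt(config.target).tau for m in models]
        start = 0 if config.target != "first" else tess.milestone_count - 1
        t0, t1 = taus[0][start], taus[1][start]
        out["mfpt_rel_change"] = float(abs(t0 - t1) / max(t0, t1)) if max(t0, t1) > 0 else 0.0
    except Exception as exc:  # diagnostics must not kill the run
        out["error"] = f"{type(exc).__name__}: {exc}"
    return out


def run_scenario(config: ScenarioConfig, diagnostics: bool = True) -> ScenarioReport:
    """Sample every cell, solve the milestoning model, compute the MFPT.

    Deterministic for fixed ``config.seeds``: per-cell engine seeds are
    derived from them with a counter-based sequence, so a rerun is
    bit-identical.
    """
    tess = config.tessellation()
    trajs: list[CellTrajectory] = []
    for a in range(tess.cell_count):
        lo, hi = tess.cell_bounds(a)
        for r, base in enumerate(config.seeds):
            spec = SimulationSpec(
                potential=config.potential,
                n_steps=config.n_steps,
                seed=cell_seed(base, a, r),
                D=config.D,
                temperature=config.temperature,
                dt=config.dt,
                confinement=Confinement(lo, hi, config.wall_k),
            )
            trajs.append(simulate_confined(spec, cell_index=a))

    stats = _statistics_for(trajs, tess)
    model = MilestoningModel.from_cell_statistics(stats, tess, config.temperature)
    result = model.mfpt(config.target)
    oof = np.array([s.out_of_cell_fraction for s in stats])
    conv = _convergence(trajs, tess, config) if diagnostics else {}
    return ScenarioReport(config, tess, model, result, oof, conv)


@dataclass
class ScenarioComparison:
    """Barrier difference and MFPT ratio between two scenario reports."""

    name_a: str
    name_b: str
    delta_peak_F: float
    mfpt_ratio: float

    @property
    def log10_mfpt_ratio(self) -> float:
        return float(np.log10(self.mfpt_ratio))

    @property
    def orders_of_magnitude(self) -> float:
        return abs(self.log10_mfpt_ratio)


def compare_scenarios(report_a: ScenarioReport, report_b: ScenarioReport) -> ScenarioComparison:
    """Peak-aligned barrier difference and first-to-target MFPT ratio (A/B)."""
    ta, tb = report_a.tessellation, report_b.tessellation
    if ta.cell_count != tb.cell_count or not np.allclose(ta.centers, tb.centers):
        raise InvalidArgumentError("scenario reports use different tessellations")
    return ScenarioComparison(
        name_a=report_a.config.name,
        name_b=report_b.config.name,
        delta_peak_F=report_a.peak_F - report_b.peak_F,
        mfpt_ratio=report_a.mfpt_first_to_target / report_b.mfpt_first_to_target,
    )
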