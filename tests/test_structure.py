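"""Hydration, coordination, distance and RMSD observables, each checked
against an independent brute-force re-scan of the planted fixtures."""

import math

import numpy as np
import pytest

from vtmm import (
    AtomSelector,
    AxisSpec,
    Frame,
    axial_density_profile,
    backbone_rmsd,
    coordination,
    named_distance,
    pair_distance,
    water_count_axis,
    water_count_sphere,
)
from vtmm.errors import InvalidArgumentError, SelectionError
from vtmm.fixtures import FixtureSpec, make_fixture_frames, rigid_transform_copy
from vtmm.structure import DISTANCE_REGISTRY


# -- independent brute-force oracles (plain python loops) -------------------

def brute_slab(frame, axis, half_width):
    n = 0
    for i in range(frame.n_atoms):
        if frame.groups[i] != "water" or not str(frame.names[i]).strip().upper().startswith("O"):
            continue
        s = sum((frame.xyz[i][k] - axis.origin[k]) * axis.direction[k] for k in range(3))
        if abs(s - axis.hcs_center) <= half_width:
            n += 1
    return n


def brute_sphere(frame, center, radius):
    n = 0
    for i in range(frame.n_atoms):
        if frame.groups[i] != "water" or not str(frame.names[i]).strip().upper().startswith("O"):
            continue
        if math.dist(frame.xyz[i], center) <= radius:
            n += 1
    return n


def brute_coordination(frame, ion_id, cutoff):
    ion = [i for i in range(frame.n_atoms) if frame.ids[i] == ion_id][0]
    out = {"water": 0, "protein": 0, "lipid": 0}
    for i in range(frame.n_atoms):
        if i == ion:
            continue
        name = str(frame.names[i]).strip()
        if name[:1].upper() == "H":
            continue
        g = frame.groups[i]
        if g in out and math.dist(frame.xyz[i], frame.xyz[ion]) <= cutoff:
            out[g] += 1
    out["total"] = sum(out.values())
    return out


def simple_frame(names, groups, xyz, resids=None, resnames=None):
    n = len(names)
    return Frame(
        ids=np.arange(1, n + 1),
        names=np.array(names, dtype=object),
        resnames=np.array(resnames or ["UNK"] * n, dtype=object),
        resids=np.array(resids or range(1, n + 1)),
        groups=np.array(groups, dtype=object),
        xyz=np.asarray(xyz, float),
    )


class TestSlabCount:
    def test_planted_seven_in_three_out(self, axis_z):
        series = make_fixture_frames(FixtureSpec(slab_in=7, slab_out=3), seed=1, axis=axis_z)
        frame = series[0]
        assert water_count_axis(frame, axis_z, 5.0) == 7
        assert series.ground_truth["frames"][0]["slab_count"] == 7

    def test_degenerate_zero_half_width(self, axis_z):
        series = make_fixture_frames(FixtureSpec(slab_in=5), seed=2, axis=axis_z)
        assert water_count_axis(series[0], axis_z, 0.0) == 0

    def test_no_waters_warns_and_returns_zero(self, axis_z):
        frame = simple_frame(["CA"], ["protein"], [[0.0, 0.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="no water"):
            assert water_count_axis(frame, axis_z, 5.0) == 0


class TestSphereCount:
    def test_dry_core_regime_returns_planted_count(self, axis_z):
        # a nearly dry constriction sphere: six waters or fewer
        series = make_fixture_frames(FixtureSpec(sphere_in=6, sphere_out=8), seed=3, axis=axis_z)
        assert water_count_sphere(series[0], axis_z.hcs_point(), 5.0) == 6

    def test_water_exactly_at_radius_is_counted(self, axis_z):
        frame = simple_frame(["OH2"], ["water"], [[5.0, 0.0, 0.0]])
        assert water_count_sphere(frame, np.zeros(3), 5.0) == 1

    def test_slab_and_sphere_agree_for_on_axis_waters(self, axis_z):
        xyz = [[0, 0, z] for z in (-3.0, -1.0, 0.5, 2.0)]
        frame = simple_frame(["OH2"] * 4, ["water"] * 4, xyz)
        assert water_count_axis(frame, axis_z, 5.0) == water_count_sphere(
            frame, axis_z.hcs_point(), 5.0
        )


class TestRandomizedFixturesMatchBruteForce:
    @pytest.mark.parametrize("seed", range(12))
    def test_all_counting_operations(self, seed, axis_z):
        rng = np.random.default_rng(1000 + seed)
        spec = FixtureSpec(
            slab_in=int(rng.integers(0, 12)),
            slab_out=int(rng.integers(0, 12)),
            sphere_in=int(rng.integers(0, 9)),
            sphere_out=int(rng.integers(0, 9)),
            coordination={
                "water": (int(rng.integers(0, 7)), int(rng.integers(0, 5))),
                "protein": (int(rng.integers(0, 5)), int(rng.integers(0, 5))),
                "lipid": (int(rng.integers(0, 3)), int(rng.integers(0, 3))),
            },
        )
        series = make_fixture_frames(spec, seed=seed, axis=axis_z)
        frame = series[0]
        truth = series.ground_truth["frames"][0]

        assert water_count_axis(frame, axis_z, 5.0) == brute_slab(frame, axis_z, 5.0)
        assert water_count_axis(frame, axis_z, 5.0) == truth["slab_count"]
        got_sphere = water_count_sphere(frame, axis_z.hcs_point(), 5.0)
        assert got_sphere == brute_sphere(frame, axis_z.hcs_point(), 5.0)
        assert got_sphere == truth["sphere_count"] == spec.sphere_in

        got = coordination(frame, truth["ion_id"], 3.0)
        assert got == brute_coordination(frame, truth["ion_id"], 3.0)
        for group in ("water", "protein", "lipid"):
            assert got[group] == truth["coordination"][group]
        assert got["total"] == got["water"] + got["protein"] + got["lipid"]


class TestCoordination:
    def test_planted_shell_partition(self, axis_z):
        series = make_fixture_frames(
            FixtureSpec(coordination={"water": (4, 2)}), seed=9, axis=axis_z
        )
        frame = series[0]
        ion = series.ground_truth["frames"][0]["ion_id"]
        got = coordination(frame, ion, 3.0)
        assert got["water"] == 4
        assert got["total"] == 4

    def test_hydrogens_excluded_by_name(self):
        frame = simple_frame(
            ["NA", "OH2", "H1", "H2"],
            ["ion", "water", "water", "water"],
            [[0, 0, 0], [2, 0, 0], [2.2, 0, 0], [2.4, 0, 0]],
        )
        got = coordination(frame, 1, 3.0)
        assert got["water"] == 1 and got["total"] == 1

    def test_missing_ion_rejected(self):
        frame = simple_frame(["OH2"], ["water"], [[0, 0, 0]])
        with pytest.raises(InvalidArgumentError):
            coordination(frame, 99, 3.0)


class TestPairDistances:
    def test_three_four_five_triangle(self):
        frame = simple_frame(["CA", "CB"], ["protein"] * 2, [[0, 0, 0], [3, 4, 0]])
        d = pair_distance(frame, AtomSelector(1, "CA"), AtomSelector(2, "CB"))
        assert d == pytest.approx(5.0)

    def test_distance_symmetric(self):
        frame = simple_frame(["CA", "CB"], ["protein"] * 2, [[1, 2, 3], [4, 6, 8]])
        a, b = AtomSelector(1, "CA"), AtomSelector(2, "CB")
        assert pair_distance(frame, a, b) == pair_distance(frame, b, a)

    def test_registry_d1_resolves_salt_bridge_atoms(self):
        sel_a, sel_b, helices = DISTANCE_REGISTRY["d1"]
        assert (sel_a.resid, sel_a.name) == (207, "CZ")
        assert (sel_b.resid, sel_b.name) == (130, "CD")
        assert helices == ("S4", "S2")

    def test_registry_covers_all_named_pairs(self):
        assert set(DISTANCE_REGISTRY) == {
            "d1", "d2", "d3", "d4", "cd1", "cd2", "cd3", "cd4", "cd5"
        }
        # the d-series ends on side-chain carbons, the cd-series on CA
        for name in ("cd1", "cd2", "cd3", "cd4", "cd5"):
            a, b, _ = DISTANCE_REGISTRY[name]
            assert a.name == "CA" and b.name == "CA"

    def test_named_distance_on_scaffold(self):
        frame = simple_frame(
            ["CZ", "CD"], ["protein"] * 2, [[0, 0, 0], [0, 0, 7.5]],
            resids=[207, 130], resnames=["ARG", "GLU"],
        )
        assert named_distance(frame, "d1") == pytest.approx(7.5)

    def test_ambiguous_selector_lists_matches(self):
        frame = simple_frame(
            ["CA", "CA"], ["protein"] * 2, [[0, 0, 0], [1, 0, 0]], resids=[7, 7]
        )
        with pytest.raises(SelectionError) as err:
            AtomSelector(7, "CA").resolve(frame)
        assert len(err.value.matches) == 2

    def test_minimum_image_convention_with_box(self):
        frame = simple_frame(["CA", "CB"], ["protein"] * 2, [[0.5, 0, 0], [9.5, 0, 0]])
        frame.box = np.array([10.0, 10.0, 10.0])
        d = pair_distance(frame, AtomSelector(1, "CA"), AtomSelector(2, "CB"))
        assert d == pytest.approx(1.0)


class TestRMSD:
    def scaffold(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 12
        return simple_frame(
            ["CA"] * n, ["protein"] * n, rng.normal(scale=4.0, size=(n, 3))
        )

    def test_frame_vs_itself_is_zero(self):
        frame = self.scaffold()
        assert backbone_rmsd(frame, frame) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_transform_removed_by_fitting(self):
        frame = self.scaffold()
        moved = rigid_transform_copy(frame, seed=4)
        assert backbone_rmsd(moved, frame) == pytest.approx(0.0, abs=1e-6)
        assert backbone_rmsd(moved, frame, superpose=False) > 1.0

    def test_fitted_never_exceeds_unfitted(self):
        rng = np.random.default_rng(8)
        a = self.scaffold(1)
        b = self.scaffold(1)
        b.xyz = b.xyz + rng.normal(scale=0.5, size=b.xyz.shape)
        assert backbone_rmsd(a, b) <= backbone_rmsd(a, b, superpose=False) + 1e-12

    def test_two_atom_toy_matches_hand_value_and_grid_search(self):
        # bonds of length 2 and 4 along x: after centering, the optimal
        # superposition leaves each atom 1 A from its partner -> RMSD 1
        a = simple_frame(["CA", "CB"], ["protein"] * 2, [[-1, 0, 0], [1, 0, 0]])
        b = simple_frame(["CA", "CB"], ["protein"] * 2, [[-2, 0, 0], [2, 0, 0]])
        got = backbone_rmsd(a, b)
        assert got == pytest.approx(1.0, abs=1e-6)
        # independent oracle: exhaustive in-plane rotation grid
        best = np.inf
        for theta in np.linspace(0, 2 * np.pi, 3601):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            rot = a.xyz @ R.T
            best = min(best, np.sqrt(np.mean(np.sum((rot - b.xyz) ** 2, axis=1))))
        assert got == pytest.approx(best, abs=1e-6)

    def test_mismatched_atom_lists_rejected(self):
        a = self.scaffold()
        b = simple_frame(["CB"] * 12, ["protein"] * 12, a.xyz)
        with pytest.raises(InvalidArgumentError):
            backbone_rmsd(a, b)


class TestDensityProfile:
    def test_gaussian_cloud_peaks_at_planted_mean(self, axis_z):
        series = make_fixture_frames(
            FixtureSpec(n_frames=5, gaussian_cloud=(200, 2.0, 1.5)), seed=12, axis=axis_z
        )
        profile = axial_density_profile(list(series), axis_z, bin_width=1.0)
        centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
        assert abs(centers[np.argmax(profile.mean_counts)] - 2.0) <= 1.0

    def test_identical_frames_equal_single_frame_histogram(self, axis_z):
        one = make_fixture_frames(FixtureSpec(slab_in=9, slab_out=4), seed=5, axis=axis_z)[0]
        frames = [one] * 210
        p210 = axial_density_profile(frames, axis_z, bin_width=2.0)
        p1 = axial_density_profile([one], axis_z, bin_width=2.0)
        assert p210.n_frames == 210
        assert np.array_equal(p210.mean_counts, p1.mean_counts)

    def test_profile_mass_conservation(self, axis_z):
        series = make_fixture_frames(
            FixtureSpec(n_frames=3, gaussian_cloud=(50, 0.0, 2.0)), seed=6, axis=axis_z
        )
        frames = list(series)
        profile = axial_density_profile(frames, axis_z, bin_width=0.5)
        total_mean = np.mean([f.water_oxygen_mask().sum() for f in frames])
        assert profile.mean_counts.sum() == pytest.approx(total_mean)

    def test_empty_input_rejected(self, axis_z):
        with pytest.raises(InvalidArgumentError):
            axial_density_profile([], axis_z, 1.0)


class TestFixtureGenerator:
    def test_same_seed_same_frames(self, axis_z):
        spec = FixtureSpec(slab_in=3, sphere_in=2, coordination={"water": (2, 1)})
        a = make_fixture_frames(spec, seed=7, axis=axis_z)
        b = make_fixture_frames(spec, seed=7, axis=axis_z)
        assert np.array_equal(a[0].xyz, b[0].xyz)

    def test_infeasible_total_rejected(self, axis_z):
        with pytest.raises(InvalidArgumentError, match="infeasible"):
            make_fixture_frames(
                FixtureSpec(sphere_in=6, total_waters=3), seed=1, axis=axis_z
            )
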