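"""Pose readers, receptor-frame RMSD, grouping, and the decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mutscape import synthetic as syn
from mutscape.errors import (
    ComparisonError,
    CorrespondenceError,
    DegenerateInputError,
    FormatError,
)
from mutscape.landscape import (
    LandscapePoint,
    LigandPose,
    PoseEnsemble,
    build_landscape,
    cluster_groups,
    compare_mutant,
    ligand_rmsd,
    read_docking_log,
    read_pose_set,
    representative,
)


def pose(coords, energy=0.0, run_id=0, labels=None):
    coords = np.asarray(coords, dtype=float)
    labels = labels or tuple(f"C{i + 1}" for i in range(len(coords)))
    return LigandPose(tuple(labels), coords, energy, run_id)


class TestDockingLogReader:
    def test_round_trip_through_writer(self, tmp_path, small_ensemble):
        ensemble, _ = small_ensemble
        sub = PoseEnsemble(
            ensemble.variant_id, ensemble.ligand_name,
            ensemble.poses[:3], ensemble.reference,
        )
        paths = syn.write_fixtures(tmp_path, ensemble=sub)
        back = read_docking_log(paths["dlg"])
        assert len(back) == 3
        for orig, rd in zip(sub.poses, back):
            assert rd.run_id == orig.run_id
            assert rd.energy == pytest.approx(orig.energy, abs=5e-3)
            assert np.allclose(rd.coords, orig.coords, atol=1e-3)

    def test_missing_energy_line_names_the_run(self, tmp_path, small_ensemble):
        ensemble, _ = small_ensemble
        sub = PoseEnsemble(
            ensemble.variant_id, ensemble.ligand_name,
            ensemble.poses[:1], ensemble.reference,
        )
        paths = syn.write_fixtures(tmp_path, ensemble=sub)
        lines = [
            line for line in paths["dlg"].read_text().splitlines()
            if "Free Energy" not in line
        ]
        bad = tmp_path / "bad.dlg"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match=f"run {sub.poses[0].run_id}"):
            read_docking_log(bad)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.dlg"
        path.write_text("")
        with pytest.raises(FormatError):
            read_docking_log(path)

    def test_truncated_block(self, tmp_path, small_ensemble):
        ensemble, _ = small_ensemble
        sub = PoseEnsemble(
            ensemble.variant_id, ensemble.ligand_name,
            ensemble.poses[:1], ensemble.reference,
        )
        paths = syn.write_fixtures(tmp_path, ensemble=sub)
        lines = paths["dlg"].read_text().splitlines()
        trunc = tmp_path / "trunc.dlg"
        trunc.write_text("\n".join(line for line in lines if "ENDMDL" not in line) + "\n")
        with pytest.raises(FormatError, match="truncated"):
            read_docking_log(trunc)


class TestPoseSetReader:
    def test_pdb_plus_tsv(self, tmp_path, small_ensemble):
        ensemble, _ = small_ensemble
        paths = syn.write_fixtures(tmp_path, ensemble=ensemble)
        back = read_pose_set(paths["poses_pdb"], paths["energies"])
        assert len(back) == len(ensemble.poses)
        assert np.allclose(back[0].coords, ensemble.poses[0].coords, atol=1e-3)

    def test_count_mismatch(self, tmp_path, small_ensemble):
        ensemble, _ = small_ensemble
        paths = syn.write_fixtures(tmp_path, ensemble=ensemble)
        truncated = tmp_path / "fewer.tsv"
        lines = paths["energies"].read_text().splitlines()
        truncated.write_text("\n".join(lines[:-5]) + "\n")
        with pytest.raises(FormatError, match="models"):
            read_pose_set(paths["poses_pdb"], truncated)


class TestLigandRmsd:
    def test_identity_is_zero(self, mock_ligand):
        assert ligand_rmsd(mock_ligand, mock_ligand) == 0.0

    def test_uniform_translation(self, mock_ligand):
        shifted = pose(mock_ligand.coords + np.array([3.0, 0.0, 0.0]),
                       labels=mock_ligand.atom_labels)
        assert ligand_rmsd(shifted, mock_ligand) == pytest.approx(3.0)

    def test_formula_on_known_deviations(self):
        ref = pose([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        dev = pose([[0, 0, 0], [1, 0, 0], [2, 3, 0]])  # deviations 0, 0, 3
        assert ligand_rmsd(dev, ref) == pytest.approx(np.sqrt(3.0))

    def test_label_mismatch(self):
        a = pose([[0, 0, 0]], labels=("C1",))
        b = pose([[0, 0, 0]], labels=("N1",))
        with pytest.raises(CorrespondenceError):
            ligand_rmsd(a, b)

    def test_matching_is_by_label_not_order(self, rng):
        coords = rng.normal(0, 3, (6, 3))
        a = pose(coords)
        perm = rng.permutation(6)
        b = pose(coords[perm], labels=tuple(f"C{i + 1}" for i in perm))
        assert ligand_rmsd(b, a) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        arrays(float, (3, 5, 3), elements=st.floats(-50, 50, allow_nan=False))
    )
    def test_metric_axioms(self, xyz):
        a, b, c = (pose(xyz[i], run_id=i) for i in range(3))
        dab, dba = ligand_rmsd(a, b), ligand_rmsd(b, a)
        assert dab >= 0
        assert dab == pytest.approx(dba, abs=1e-9)
        assert ligand_rmsd(a, a) == 0.0
        assert dab <= ligand_rmsd(a, c) + ligand_rmsd(c, b) + 1e-9


class TestBuildLandscape:
    def test_point_per_pose_in_order(self, small_ensemble):
        ensemble, _ = small_ensemble
        points = build_landscape(ensemble)
        assert len(points) == len(ensemble.poses)
        assert [p.pose.run_id for p in points] == [
            p.run_id for p in ensemble.poses
        ]

    def test_reference_only_ensemble_has_zero_rmsd(self, mock_ligand):
        ensemble = PoseEnsemble(
            "wt", "lig",
            tuple(
                LigandPose(mock_ligand.atom_labels, mock_ligand.coords, -5.0, i)
                for i in range(1, 4)
            ),
            mock_ligand,
        )
        assert all(p.rmsd == 0.0 for p in build_landscape(ensemble))


class TestRepresentative:
    def test_lowest_energy_wins(self):
        pts = [
            LandscapePoint(1.0, -6.1, pose([[0, 0, 0]], -6.1, 1)),
            LandscapePoint(2.0, -7.3, pose([[0, 0, 0]], -7.3, 2)),
            LandscapePoint(3.0, -5.0, pose([[0, 0, 0]], -5.0, 3)),
        ]
        assert representative(pts).energy == -7.3

    def test_tie_breaks_on_lower_rmsd_then_run_id(self):
        pts = [
            LandscapePoint(1.2, -7.3, pose([[0, 0, 0]], -7.3, 1)),
            LandscapePoint(0.8, -7.3, pose([[0, 0, 0]], -7.3, 2)),
            LandscapePoint(0.8, -7.3, pose([[0, 0, 0]], -7.3, 9)),
        ]
        rep = representative(pts)
        assert rep.rmsd == 0.8 and rep.pose.run_id == 2

    def test_matches_bruteforce_argmin(self, rng):
        pts = [
            LandscapePoint(float(r), float(e), pose([[0, 0, 0]], float(e), i))
            for i, (r, e) in enumerate(zip(rng.random(100), rng.normal(-6, 1, 100)))
        ]
        brute = min(pts, key=lambda p: (p.energy, p.rmsd, p.pose.run_id))
        assert representative(pts) is brute

    def test_empty_group(self):
        with pytest.raises(ValueError):
            representative([])


class TestClusterGroups:
    def test_planted_modes_recovered_and_flip_labelled_iv(self, small_ensemble):
        ensemble, modes = small_ensemble
        points = build_landscape(ensemble)
        groups = cluster_groups(points)
        label_of = {id(p): g.label for g in groups.groups for p in g.members}
        # memberships must match the planted modes exactly at tight noise
        by_mode = {}
        for p, m in zip(points, modes):
            by_mode.setdefault(m, set()).add(label_of[id(p)])
        assert all(len(v) == 1 for v in by_mode.values())
        assert by_mode[3] == {"IV"}
        assert groups.n_points == len(points)

    def test_group_energies_descend_i_to_iii(self, small_ensemble):
        ensemble, _ = small_ensemble
        groups = cluster_groups(build_landscape(ensemble))
        e = {g.label: g.representative.energy for g in groups.groups}
        assert e["I"] > e["II"] > e["III"]

    def test_k1_returns_global_minimum(self, small_ensemble):
        ensemble, _ = small_ensemble
        points = build_landscape(ensemble)
        groups = cluster_groups(points, k=1)
        assert len(groups.groups) == 1
        assert groups.groups[0].representative.energy == min(
            p.energy for p in points
        )

    def test_empty_flip_mode_with_k3_gives_no_iv(self):
        cfg = syn.SyntheticEnsembleConfig(
            n_poses=300,
            mode_weights=(0.4, 0.3, 0.3, 0.0),  # flip mode planted empty
            seed=3,
        )
        ensemble, _ = syn.sample_ensemble(cfg)
        groups = cluster_groups(build_landscape(ensemble), k=3)
        assert sorted(g.label for g in groups.groups) == ["I", "II", "III"]

    def test_representative_energy_bounds_members(self, small_ensemble):
        ensemble, _ = small_ensemble
        for g in cluster_groups(build_landscape(ensemble)).groups:
            assert all(p.energy >= g.representative.energy for p in g.members)

    def test_degenerate_rmsd_values(self, mock_ligand):
        points = [
            LandscapePoint(1.0, -5.0, pose([[0, 0, 0]], -5.0, i)) for i in range(10)
        ]
        with pytest.raises(DegenerateInputError):
            cluster_groups(points, k=4)


class TestCompareMutant:
    def _groups_with_shift(self, shift, seed=0):
        cfg = syn.SyntheticEnsembleConfig(n_poses=400, seed=seed)
        ensemble, _ = syn.sample_ensemble(cfg, effect=shift)
        return cluster_groups(build_landscape(ensemble))

    def test_lower_group_iii_energy_is_beneficial(self):
        wt = self._groups_with_shift(None, seed=1)
        mut = self._groups_with_shift(-1.2, seed=2)
        comp = compare_mutant(wt, mut)
        assert comp.verdict == "beneficial"
        assert comp.delta_e_iii < -0.5

    def test_higher_group_iii_energy_is_detrimental(self):
        wt = self._groups_with_shift(None, seed=1)
        mut = self._groups_with_shift(+0.9, seed=3)
        assert compare_mutant(wt, mut).verdict == "detrimental"

    def test_self_comparison_is_neutral(self):
        wt = self._groups_with_shift(None, seed=4)
        comp = compare_mutant(wt, wt)
        assert comp.delta_e_iii == 0.0 and comp.verdict == "neutral"

    def test_missing_group_iii(self, small_ensemble):
        ensemble, _ = small_ensemble
        groups = cluster_groups(build_landscape(ensemble))
        only_iv = type(groups)(
            groups=tuple(g for g in groups.groups if g.label == "IV"),
            flip_threshold=groups.flip_threshold,
        )
        with pytest.raises(ComparisonError):
            compare_mutant(groups, only_iv)

    def test_antisymmetry_about_wild_type_at_zero_epsilon(self):
        wt = self._groups_with_shift(None, seed=5)
        mut = self._groups_with_shift(-0.8, seed=6)
        comp = compare_mutant(wt, mut, epsilon=0.0)
        mirrored = compare_mutant(mut, wt, epsilon=0.0)
        assert mirrored.delta_e_iii == pytest.approx(-comp.delta_e_iii)
        assert {comp.verdict, mirrored.verdict} == {"beneficial", "detrimental"}
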