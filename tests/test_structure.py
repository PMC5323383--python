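"""PDB parsing, active-site geometry, and the candidate screen."""

import numpy as np
import pytest

from mutscape.errors import FormatError, ReferenceMappingError
from mutscape.selection import CandidateSite, CandidateSiteSet
from mutscape.structure import (
    ActiveSiteDefinition,
    AtomRecord,
    ScreenThresholds,
    StructureModel,
    hbond_network_member,
    min_distance_to_active_site,
    read_structure,
    screen_candidates,
)
from mutscape.synthetic import CandidatePlan, make_toy_receptor

PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       3.000   1.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       4.458   1.000   0.000  1.00  0.00           C
ATOM      5  N   SER A   3       6.000   2.000   0.000  1.00  0.00           N
ATOM      6  CA  SER A   3       7.458   2.000   0.000  1.00  0.00           C
HETATM    7  C1  LIG A  10      10.000   5.000   0.000  1.00  0.00           C
END
"""

PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ENDMDL
END
"""


def model_from(atoms):
    return StructureModel(atoms=tuple(atoms))


class TestReadStructure:
    def test_small_fixture(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(PDB_3RES)
        model = read_structure(path)
        assert len(model.atoms) == 7
        assert len(model.ligand_atoms) == 1
        assert {a.residue_number for a in model.atoms} == {1, 2, 3, 10}

    def test_first_model_only(self, tmp_path):
        path = tmp_path / "mm.pdb"
        path.write_text(PDB_TWO_MODELS)
        model = read_structure(path)
        assert len(model.atoms) == 2
        assert model.atoms[0].coord == (0.0, 0.0, 0.0)

    def test_insertion_code_rejected(self, tmp_path):
        path = tmp_path / "ins.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1A      0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        with pytest.raises(FormatError):
            read_structure(path)


class TestMinDistance:
    def test_three_four_five_triangle(self):
        model = model_from([
            AtomRecord("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            AtomRecord("A", 9, "GLY", "CA", "C", (3.0, 4.0, 0.0)),
        ])
        active = ActiveSiteDefinition(catalytic_residues=(("A", 9),))
        assert min_distance_to_active_site(model, ("A", 1), active) == pytest.approx(5.0)

    def test_catalytic_residue_distance_to_itself_is_zero(self):
        model = model_from([
            AtomRecord("A", 9, "GLY", "CA", "C", (3.0, 4.0, 0.0)),
            AtomRecord("A", 9, "GLY", "CB", "C", (4.0, 4.0, 0.0)),
        ])
        active = ActiveSiteDefinition(catalytic_residues=(("A", 9),))
        assert min_distance_to_active_site(model, ("A", 9), active) == 0.0

    def test_absent_residue(self):
        model = model_from([AtomRecord("A", 1, "ALA", "CA", "C", (0, 0, 0))])
        active = ActiveSiteDefinition(catalytic_residues=(("A", 1),))
        with pytest.raises(ReferenceMappingError):
            min_distance_to_active_site(model, ("A", 99), active)

    def test_matches_all_pairs_bruteforce(self, rng):
        atoms = [
            AtomRecord("A", 1, "ALA", f"X{i}", "C", tuple(rng.normal(0, 8, 3)))
            for i in range(25)
        ] + [
            AtomRecord("A", 2, "GLY", f"Y{i}", "C", tuple(rng.normal(0, 8, 3)))
            for i in range(25)
        ]
        model = model_from(atoms)
        active = ActiveSiteDefinition(catalytic_residues=(("A", 2),))
        got = min_distance_to_active_site(model, ("A", 1), active)
        brute = min(
            np.linalg.norm(np.subtract(a.coord, b.coord))
            for a in atoms if a.residue_number == 1
            for b in atoms if b.residue_number == 2
        )
        assert got == pytest.approx(brute, abs=1e-12)


class TestHbondNetwork:
    def _model(self, og_distance):
        return model_from([
            AtomRecord("A", 50, "GLU", "OE1", "O", (0.0, 0.0, 0.0)),
            AtomRecord("A", 50, "GLU", "CD", "C", (0.0, 0.0, 1.3)),
            AtomRecord("A", 7, "SER", "CA", "C", (og_distance, 0.0, 2.0)),
            AtomRecord("A", 7, "SER", "OG", "O", (og_distance, 0.0, 0.0)),
        ])

    def test_polar_contact_within_cutoff(self):
        model = self._model(2.8)
        active = ActiveSiteDefinition(catalytic_residues=(("A", 50),))
        member, partners = hbond_network_member(model, ("A", 7), active)
        assert member
        assert partners == ["A/50/OE1"]

    def test_distant_pair_is_not_a_member(self):
        model = self._model(5.0)
        active = ActiveSiteDefinition(catalytic_residues=(("A", 50),))
        member, partners = hbond_network_member(model, ("A", 7), active)
        assert not member and partners == []

    def test_partner_list_matches_enumeration(self, rng):
        # several planted polar contacts; enumerate expected partners directly
        catalytic = [
            AtomRecord("A", 50, "GLU", "OE1", "O", (0.0, 0.0, 0.0)),
            AtomRecord("A", 50, "GLU", "OE2", "O", (2.0, 0.0, 0.0)),
            AtomRecord("A", 50, "GLU", "N", "N", (8.0, 8.0, 8.0)),
        ]
        site = [
            AtomRecord("A", 7, "ASN", "OD1", "O", (1.0, 0.5, 0.0)),
            AtomRecord("A", 7, "ASN", "ND2", "N", (1.0, -3.0, 0.0)),
        ]
        model = model_from(catalytic + site)
        active = ActiveSiteDefinition(catalytic_residues=(("A", 50),))
        member, partners = hbond_network_member(model, ("A", 7), active)
        expected = sorted({
            f"{c.chain}/{c.residue_number}/{c.atom_name}"
            for s in site for c in catalytic
            if np.linalg.norm(np.subtract(s.coord, c.coord)) <= 3.5
        })
        assert member and partners == expected


class TestScreenCandidates:
    def test_planted_pass_and_fail(self):
        plans = (
            [CandidatePlan(p, near=True) for p in (101, 102, 103, 104)]
            + [CandidatePlan(p, near=False) for p in (105, 106, 107, 108)]
            + [CandidatePlan(p, near=True, hbonded=True) for p in (109, 110)]
        )
        model, active = make_toy_receptor(plans, seed=11)
        candidates = CandidateSiteSet(sites=tuple(
            CandidateSite(p.ref_position, "A", "SSP") for p in plans
        ) + (CandidateSite(200, "A", "PSD"),))  # 200 is unmodeled
        report = screen_candidates(model, candidates, active)
        verdicts = {r.ref_position: r.verdict for r in report.rows}
        assert [p for p, v in sorted(verdicts.items()) if v == "retain"] == [
            101, 102, 103, 104,
        ]
        unmodeled = next(r for r in report.rows if r.ref_position == 200)
        assert unmodeled.verdict == "drop" and unmodeled.reason == "unmodeled"

    def test_loosening_cutoff_never_shrinks_retained_set(self):
        plans = [CandidatePlan(100 + i, near=bool(i % 2)) for i in range(8)]
        model, active = make_toy_receptor(plans, seed=2)
        candidates = CandidateSiteSet(sites=tuple(
            CandidateSite(p.ref_position, "A", "SSP") for p in plans
        ))
        previous: set[int] = set()
        for cutoff in (3.0, 7.0, 12.0, 30.0):
            report = screen_candidates(
                model, candidates, active,
                ScreenThresholds(distance_cutoff=cutoff),
            )
            retained = {r.ref_position for r in report.retained}
            assert previous <= retained
            previous = retained

    def test_verdicts_are_pure_functions_of_metrics(self):
        plans = [
            CandidatePlan(101, near=True),
            CandidatePlan(102, near=False),
            CandidatePlan(103, near=True, hbonded=True),
        ]
        model, active = make_toy_receptor(plans, seed=3)
        candidates = CandidateSiteSet(sites=tuple(
            CandidateSite(p.ref_position, "A", "SSP") for p in plans
        ))
        thresholds = ScreenThresholds()
        report = screen_candidates(model, candidates, active, thresholds)
        for row in report.rows:
            rederived = (
                "retain"
                if row.min_distance is not None
                and row.min_distance <= thresholds.distance_cutoff
                and not (row.hbond_network_member and thresholds.protect_network)
                else "drop"
            )
            assert row.verdict == rederived

    def test_protect_network_off_retains_hbonded_site(self):
        plans = [CandidatePlan(101, near=True, hbonded=True)]
        model, active = make_toy_receptor(plans, seed=4)
        candidates = CandidateSiteSet(
            sites=(CandidateSite(101, "A", "SSP"),)
        )
        on = screen_candidates(model, candidates, active, ScreenThresholds())
        off = screen_candidates(
            model, candidates, active, ScreenThresholds(protect_network=False)
        )
        assert on.rows[0].verdict == "drop"
        assert off.rows[0].verdict == "retain"
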