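"""Structure-based screening of candidate mutation sites.

Candidate sites from sequence analysis are kept only when they sit close
enough to the active site to influence catalysis, and dropped when their
side chains hydrogen-bond directly into the catalytic network (mutating a
network member risks destroying the hydrogen-bonding geometry the reaction
depends on). The two criteria turn an otherwise manual structural
inspection into an explicit, reproducible rule:

* proximity: any heavy atom of the candidate residue within
  ``distance_cutoff`` (default 10 Å) of any heavy atom of the catalytic
  residues or of the reference ligand;
* network membership: any side-chain N/O of the candidate within
  ``hbond_distance`` (default 3.5 Å) of an N/O of a catalytic residue or a
  ligand N/O. A donor–H…acceptor angle check (default >= 120°) applies only
  when the model contains hydrogens; crystal-resolution and homology models
  usually do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from scipy.spatial.distance import cdist

from .errors import FormatError, ReferenceMappingError
from .landscape import LigandPose
from .selection import CandidateSiteSet

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

DEFAULT_DISTANCE_CUTOFF = 10.0
DEFAULT_HBOND_DISTANCE = 3.5
DEFAULT_HBOND_ANGLE = 120.0


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    coord: tuple[float, float, float]
    is_hetero: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class StructureModel:
    """A flat atom list parsed from the first MODEL of a PDB file."""

    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        keys = [(a.chain, a.residue_number, a.atom_name) for a in self.atoms]
        if len(keys) != len(set(keys)):
            raise FormatError("duplicate (chain, residue, atom) records in model")
        for a in self.atoms:
            if not all(np.isfinite(a.coord)):
                raise FormatError(f"non-finite coordinate for atom {a.atom_name}")

    @property
    def ligand_atoms(self) -> tuple[AtomRecord, ...]:
        return tuple(a for a in self.atoms if a.is_hetero)

    def residue_atoms(self, chain: str, residue_number: int) -> tuple[AtomRecord, ...]:
        out = tuple(
            a
            for a in self.atoms
            if a.chain == chain and a.residue_number == residue_number
        )
        if not out:
            raise ReferenceMappingError(
                f"residue {chain}/{residue_number} absent from model"
            )
        return out

    def has_residue(self, chain: str, residue_number: int) -> bool:
        return any(
            a.chain == chain and a.residue_number == residue_number for a in self.atoms
        )

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen


@dataclass(frozen=True)
class ActiveSiteDefinition:
    """Catalytic residues (chain, residue number) plus an optional bound ligand."""

    catalytic_residues: tuple[tuple[str, int], ...]
    reference_ligand: Optional[LigandPose] = None

    def __post_init__(self) -> None:
        if not self.catalytic_residues and self.reference_ligand is None:
            raise ValueError("active site definition is empty")


@dataclass(frozen=True)
class ScreenRow:
    ref_position: int
    wt_residue: str
    origin: str
    min_distance: Optional[float]
    hbond_network_member: Optional[bool]
    hbond_partners: tuple[str, ...]
    verdict: str  # "retain" | "drop"
    reason: str


@dataclass(frozen=True)
class ScreenThresholds:
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF
    hbond_distance: float = DEFAULT_HBOND_DISTANCE
    hbond_angle: float = DEFAULT_HBOND_ANGLE
    protect_network: bool = True


@dataclass(frozen=True)
class ScreenReport:
    rows: tuple[ScreenRow, ...]
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)

    @property
    def retained(self) -> list[ScreenRow]:
        return [r for r in self.rows if r.verdict == "retain"]


def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Only the first MODEL is used when several are present; HETATM records
    are flagged as ligand atoms; insertion codes are rejected.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("model", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no MODEL found")
    atoms: list[AtomRecord] = []
    for chain in models[0]:
        for residue in chain:
            hetflag, resnum, icode = residue.id
            if icode.strip():
                raise FormatError(
                    f"{path}: insertion code {icode!r} at residue {resnum} "
                    "is not supported"
                )
            for atom in residue:
                x, y, z = (float(v) for v in atom.coord)
                atoms.append(
                    AtomRecord(
                        chain=chain.id,
                        residue_number=int(resnum),
                        residue_name=residue.resname.strip(),
                        atom_name=atom.get_name(),
                        element=(atom.element or "").strip().upper() or "X",
                        coord=(x, y, z),
                        is_hetero=bool(hetflag.strip()),
                    )
                )
    if not atoms:
        raise FormatError(f"{path}: no atoms parsed")
    return StructureModel(atoms=tuple(atoms))


def _active_site_coords(
    model: StructureModel, active: ActiveSiteDefinition
) -> np.ndarray:
    coords = []
    for chain, resnum in active.catalytic_residues:
        coords.extend(
            a.coord for a in model.residue_atoms(chain, resnum) if a.is_heavy
        )
    if active.reference_ligand is not None:
        coords.extend(map(tuple, active.reference_ligand.coords))
    return np.asarray(coords, dtype=float)


def min_distance_to_active_site(
    model: StructureModel,
    site: tuple[str, int],
    active: ActiveSiteDefinition,
) -> float:
    """Minimum heavy-atom distance (Å) from a residue to the active site.

    A residue listed among the catalytic residues trivially returns 0.0.
    """
    site_coords = np.asarray(
        [a.coord for a in model.residue_atoms(*site) if a.is_heavy], dtype=float
    )
    active_coords = _active_site_coords(model, active)
    if site_coords.size == 0 or active_coords.size == 0:
        raise ReferenceMappingError("no heavy atoms to measure distances between")
    return float(cdist(site_coords, active_coords).min())


def _polar_side_chain_atoms(atoms: tuple[AtomRecord, ...]) -> list[AtomRecord]:
    return [
        a
        for a in atoms
        if a.element in ("N", "O") and a.atom_name not in BACKBONE_ATOMS
    ]


def _attached_hydrogens(
    model: StructureModel, donor: AtomRecord, bond_cutoff: float = 1.3
) -> list[AtomRecord]:
    near = model.residue_atoms(donor.chain, donor.residue_number)
    out = []
    for a in near:
        if a.element != "H":
            continue
        d = np.linalg.norm(np.subtract(a.coord, donor.coord))
        if d <= bond_cutoff:
            out.append(a)
    return out


def hbond_network_member(
    model: StructureModel,
    site: tuple[str, int],
    active: ActiveSiteDefinition,
    dist_cutoff: float = DEFAULT_HBOND_DISTANCE,
    angle_cutoff: float = DEFAULT_HBOND_ANGLE,
) -> tuple[bool, list[str]]:
    """Does the residue's side chain hydrogen-bond into the catalytic network?

    Heavy-atom criterion: a side-chain N/O of the site within ``dist_cutoff``
    of an N/O of a catalytic residue or a ligand N/O. When the model carries
    hydrogens on the site atom, at least one donor–H…acceptor angle must also
    reach ``angle_cutoff``. Returns the flag and a partner list like
    ``["A/190/ND1"]``.
    """
    donors = _polar_side_chain_atoms(model.residue_atoms(*site))
    acceptors: list[AtomRecord] = []
    for chain, resnum in active.catalytic_residues:
        if (chain, resnum) == site:
            continue
        acceptors.extend(
            a
            for a in model.residue_atoms(chain, resnum)
            if a.element in ("N", "O")
        )
    lig_coords: list[tuple[str, np.ndarray]] = []
    if active.reference_ligand is not None:
        lig = active.reference_ligand
        for label, coord in zip(lig.atom_labels, lig.coords):
            if label[0] in ("N", "O"):
                lig_coords.append((f"ligand/{label}", np.asarray(coord)))
    partners: list[str] = []
    for donor in donors:
        hydrogens = _attached_hydrogens(model, donor)
        candidates = [
            (f"{a.chain}/{a.residue_number}/{a.atom_name}", np.asarray(a.coord))
            for a in acceptors
        ] + lig_coords
        for tag, coord in candidates:
            d = float(np.linalg.norm(np.subtract(coord, donor.coord)))
            if d > dist_cutoff:
                continue
            if hydrogens and not _angle_ok(donor, hydrogens, coord, angle_cutoff):
                continue
            partners.append(tag)
    return (len(partners) > 0, sorted(set(partners)))


def _angle_ok(
    donor: AtomRecord,
    hydrogens: list[AtomRecord],
    acceptor_coord: np.ndarray,
    angle_cutoff: float,
) -> bool:
    for h in hydrogens:
        v1 = np.subtract(donor.coord, h.coord)
        v2 = acceptor_coord - np.asarray(h.coord)
        cosang = float(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        )
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if angle >= angle_cutoff:
            return True
    return False


def screen_candidates(
    model: StructureModel,
    candidates: CandidateSiteSet,
    active: ActiveSiteDefinition,
    thresholds: ScreenThresholds = ScreenThresholds(),
    chain: Optional[str] = None,
) -> ScreenReport:
    """Apply the proximity and network-protection criteria to every candidate.

    Verdict rule: retain iff the residue lies within ``distance_cutoff`` of
    the active site and (when ``protect_network`` is on) its side chain is
    not a hydrogen-bond partner of the catalytic network. Candidates absent
    from the model are listed with verdict "drop", reason "unmodeled".
    """
    chain = chain or model.chains[0]
    rows: list[ScreenRow] = []
    for cand in candidates.sites:
        site = (chain, cand.ref_position)
        if not model.has_residue(*site):
            rows.append(
                ScreenRow(
                    ref_position=cand.ref_position,
                    wt_residue=cand.wt_residue,
                    origin=cand.origin,
                    min_distance=None,
                    hbond_network_member=None,
                    hbond_partners=(),
                    verdict="drop",
                    reason="unmodeled",
                )
            )
            continue
        dist = min_distance_to_active_site(model, site, active)
        member, partners = hbond_network_member(
            model, site, active, thresholds.hbond_distance, thresholds.hbond_angle
        )
        if dist > thresholds.distance_cutoff:
            verdict, reason = "drop", f"{dist:.1f} Å from active site"
        elif member and thresholds.protect_network:
            verdict, reason = "drop", "side chain in catalytic H-bond network"
        else:
            verdict, reason = "retain", "near active site, network-safe"
        rows.append(
            ScreenRow(
                ref_position=cand.ref_position,
                wt_residue=cand.wt_residue,
                origin=cand.origin,
                min_distance=dist,
                hbond_network_member=member,
                hbond_partners=tuple(partners),
                verdict=verdict,
                reason=reason,
            )
        )
    return ScreenReport(rows=tuple(rows), thresholds=thresholds)


def write_screen_report(report: ScreenReport, path: str | Path) -> None:
    lines = [
        "ref_position\twt_residue\torigin\tmin_distance\thbond_network_member"
        "\tverdict\treason"
    ]
    for r in report.rows:
        dist = "" if r.min_distance is None else f"{r.min_distance:.3f}"
        member = "" if r.hbond_network_member is None else str(r.hbond_network_member)
        lines.append(
            f"{r.ref_position}\t{r.wt_residue}\t{r.origin}\t{dist}\t{member}"
            f"\t{r.verdict}\t{r.reason}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
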