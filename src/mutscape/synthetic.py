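"""Synthetic inputs for every pipeline stage.

Every consumable the pipeline reads — two-group MSAs with planted
subfamily-specific positions, positive-selection tables with planted
positive sites, toy receptor structures, and docking-pose ensembles with
planted RMSD-group structure — can be generated here with known ground
truth, so each stage and the end-to-end decision rule can be tested without
any external downloads.

The ensemble generator mirrors the structure of a real docking landscape:
a rigid mock ligand is perturbed from the reference (product) pose into
several RMSD modes — three near-product modes plus one flipped-orientation
mode beyond the group-IV threshold — and per-mode Gaussian binding energies
honour the empirical ordering E(I) > E(II) > E(III), with group IV between
II and III. A per-mutant shift of the group-III energy mean encodes the
planted beneficial/neutral/detrimental effect.

All generators take explicit seeds and are reproducible: the same seed
yields byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alignment import SubfamilyAlignment
from .errors import ConfigError
from .landscape import LigandPose, PoseEnsemble
from .selection import SiteEntry, SiteSelectionTable
from .structure import ActiveSiteDefinition, AtomRecord, StructureModel

AA = "ACDEFGHIKLMNPQRSTVWY"

# Planted group-III shifts (kcal/mol) whose signs encode the known
# activity outcomes of the six classic test mutants: negative = more
# active, ~0 = unchanged, positive = less active.
DEFAULT_MUTANT_EFFECTS: dict[str, float] = {
    "I197P": -1.5,
    "R110A": -1.2,
    "E107D": 0.0,
    "E107Q": +0.8,
    "R110E": +0.6,
    "R110H": +1.0,
}


# ---------------------------------------------------------------------------
# MSA generator


@dataclass(frozen=True)
class SyntheticMSAConfig:
    """Planted two-group alignment: 2×7 sequences of length 220 by default,
    with 9 subfamily-specific columns, mirroring the scale of a small
    isomerase family alignment."""

    n_per_group: int = 7
    length: int = 220
    n_ssp: int = 9
    n_conserved: int = 120
    noise_rate: float = 0.05
    gap_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ssp + self.n_conserved > self.length:
            raise ConfigError("n_ssp + n_conserved exceeds alignment length")
        for name in ("noise_rate", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_per_group < 2:
            raise ConfigError("each group needs at least 2 sequences")


def make_subfamily_msa(
    cfg: SyntheticMSAConfig,
) -> tuple[SubfamilyAlignment, list[int]]:
    """Generate a two-group alignment with planted SSP columns.

    Returns the alignment and the sorted 1-based planted SSP columns.
    SSP columns carry residue *a* in group 1 and *b* ≠ *a* in group 2 with
    zero within-group noise; conserved columns carry one residue everywhere;
    the remaining background columns start from a shared residue and are
    substituted per cell at ``noise_rate`` and gapped at ``gap_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_seq = 2 * cfg.n_per_group
    cols = rng.permutation(cfg.length)
    ssp_cols = np.sort(cols[: cfg.n_ssp])
    conserved_cols = np.sort(cols[cfg.n_ssp: cfg.n_ssp + cfg.n_conserved])
    background = np.sort(cols[cfg.n_ssp + cfg.n_conserved:])

    matrix = np.empty((n_seq, cfg.length), dtype="<U1")
    aa = np.array(list(AA))
    for col in conserved_cols:
        matrix[:, col] = rng.choice(aa)
    for col in ssp_cols:
        a, b = rng.choice(aa, size=2, replace=False)
        matrix[: cfg.n_per_group, col] = a
        matrix[cfg.n_per_group:, col] = b
    for col in background:
        base = rng.choice(aa)
        column = np.full(n_seq, base, dtype="<U1")
        flip = rng.random(n_seq) < cfg.noise_rate
        column[flip] = rng.choice(aa, size=int(flip.sum()))
        gap = rng.random(n_seq) < cfg.gap_rate
        column[gap] = "-"
        matrix[:, col] = column

    ids = [f"g1_s{i + 1}" for i in range(cfg.n_per_group)] + [
        f"g2_s{i + 1}" for i in range(cfg.n_per_group)
    ]
    rows = {sid: "".join(matrix[i]) for i, sid in enumerate(ids)}
    group_of = {sid: 1 if sid.startswith("g1") else 2 for sid in ids}
    aln = SubfamilyAlignment(rows=rows, group_of=group_of, reference_id=ids[0])
    return aln, [int(c) + 1 for c in ssp_cols]


# ---------------------------------------------------------------------------
# Selection-table generator


def make_selection_table(
    positions: list[int],
    positives: set[int],
    high: float = 0.95,
    low: float = 0.5,
    seed: int = 0,
    wt_map: Optional[dict[int, str]] = None,
) -> tuple[SiteSelectionTable, set[int]]:
    """Planted posterior table: positives ~ U(high, 1], the rest ~ U[0, low).

    Thresholding at any value in [low, high] recovers exactly the planted
    positives, by construction. Returns the table and the planted set.
    """
    if high <= low:
        raise ValueError(f"high ({high}) must exceed low ({low})")
    if not set(positives) <= set(positions):
        raise ValueError("positives must be a subset of positions")
    rng = np.random.default_rng(seed)
    entries = []
    for pos in sorted(positions):
        if pos in positives:
            posterior = float(rng.uniform(high, 1.0))
            posterior = min(np.nextafter(posterior, 1.0), 1.0) if posterior == high else posterior
        else:
            posterior = float(rng.uniform(0.0, low))
        wt = wt_map[pos] if wt_map else str(rng.choice(list(AA)))
        entries.append(SiteEntry(pos, wt, posterior))
    return (
        SiteSelectionTable(entries=tuple(entries), method_tag="synthetic planted"),
        set(positives),
    )


# ---------------------------------------------------------------------------
# Mock ligand and pose ensembles


def make_mock_ligand(n_atoms: int = 12, length: float = 12.0) -> LigandPose:
    """A rigid planar zig-zag of labelled heavy atoms.

    Atoms are spaced evenly along the x axis over ``length`` Å with
    alternating ±0.5 Å y offsets, centred at the origin of the toy receptor
    frame, so the maximum inter-atom distance is ≈ ``length``.
    """
    if n_atoms < 3:
        raise ValueError("mock ligand needs at least 3 atoms")
    if length <= 0:
        raise ValueError("length must be positive")
    x = np.linspace(-length / 2.0, length / 2.0, n_atoms)
    y = 0.5 * np.where(np.arange(n_atoms) % 2 == 0, 1.0, -1.0)
    coords = np.column_stack([x, y, np.zeros(n_atoms)])
    coords -= coords.mean(axis=0)
    labels = tuple(f"C{i + 1}" for i in range(n_atoms))
    return LigandPose(atom_labels=labels, coords=coords, energy=0.0, run_id=0)


def flip_pose(pose: LigandPose) -> LigandPose:
    """180° rotation about the y axis through the centroid (x→−x, z→−z).

    For an extended ligand this produces the opposite-orientation geometry
    of a group-IV pose: each atom moves by twice its distance from the flip
    axis, so a ligand spanning ≥ 10 Å lands at RMSD > 6 Å from the original.
    """
    c = pose.centroid
    rel = pose.coords - c
    flipped = rel * np.array([-1.0, 1.0, -1.0]) + c
    return LigandPose(pose.atom_labels, flipped, pose.energy, pose.run_id)


@dataclass(frozen=True)
class SyntheticEnsembleConfig:
    """Planted docking landscape: 2,000 poses in four RMSD modes.

    Modes 1–3 are near-product perturbations at 0.5, 1.8 and 3.5 Å; mode 4
    is the flipped orientation near 7.5 Å. Energy means (−5.5, −6.5, −7.5,
    −7.0 kcal/mol) encode the canonical ordering I > II > III with the flip
    mode between II and III. ``energy_sd`` is the within-mode spread;
    ``rmsd_rel_sd`` the relative jitter of each pose's target RMSD.
    """

    n_poses: int = 2000
    ligand_atoms: int = 12
    ligand_length: float = 10.0
    mode_rmsd_centers: tuple[float, ...] = (0.5, 1.8, 3.5, 7.5)
    mode_weights: tuple[float, ...] = (0.30, 0.25, 0.25, 0.20)
    energy_means: tuple[float, ...] = (-5.5, -6.5, -7.5, -7.0)
    energy_sd: float = 0.1
    rmsd_rel_sd: float = 0.05
    flip_mode_index: int = 3
    group_iii_mode_index: int = 2
    flip_threshold: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.mode_rmsd_centers)
        if len(self.mode_weights) != k or len(self.energy_means) != k:
            raise ConfigError("mode centers, weights and energy means must align")
        if abs(sum(self.mode_weights) - 1.0) > 1e-9:
            raise ConfigError("mode weights must sum to 1")
        if not 0 <= self.flip_mode_index < k:
            raise ConfigError("flip_mode_index out of range")
        if self.n_poses < 1:
            raise ConfigError("n_poses must be >= 1")
        if self.energy_sd <= 0 or self.rmsd_rel_sd < 0:
            raise ConfigError("energy_sd must be > 0 and rmsd_rel_sd >= 0")


def _batch_rotations(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices for unit axes (n,3) and angles (n,)."""
    n = len(angles)
    kx, ky, kz = axes[:, 0], axes[:, 1], axes[:, 2]
    zero = np.zeros(n)
    K = np.stack(
        [
            np.stack([zero, -kz, ky], axis=1),
            np.stack([kz, zero, -kx], axis=1),
            np.stack([-ky, kx, zero], axis=1),
        ],
        axis=1,
    )
    eye = np.eye(3)[None, :, :]
    s = np.sin(angles)[:, None, None]
    c = (1.0 - np.cos(angles))[:, None, None]
    return eye + s * K + c * (K @ K)


def _rotation_rmsd(rel: np.ndarray, R: np.ndarray) -> np.ndarray:
    """RMSD induced by rotating centred coords *rel* (m,3) by each R (n,3,3)."""
    rotated = np.einsum("nij,mj->nmi", R, rel)
    d = rotated - rel[None, :, :]
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))


def _random_units(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_ensemble(
    cfg: SyntheticEnsembleConfig,
    reference: Optional[LigandPose] = None,
    effect: Optional[float] = None,
    variant_id: str = "wild-type",
) -> tuple[PoseEnsemble, np.ndarray]:
    """Draw a pose ensemble with planted mode structure.

    Each pose's target RMSD is its mode centre jittered by
    ``rmsd_rel_sd``; the pose is built as a small random rotation about the
    centroid (capped below the target) plus a random-direction translation
    sized so the realised RMSD hits the target exactly. Flip-mode poses
    start from the 180° flipped geometry, whose intrinsic RMSD sets a floor.
    Energies are Gaussian per mode; ``effect`` shifts the group-III mode
    mean (the planted mutant effect). Returns the ensemble and the per-pose
    true mode indices (aligned with pose order).
    """
    rng = np.random.default_rng(cfg.seed)
    if reference is None:
        reference = make_mock_ligand(cfg.ligand_atoms, cfg.ligand_length)
    rel = reference.coords - reference.centroid
    flip_floor = float(
        np.sqrt(np.mean(np.sum((flip_pose(reference).coords - reference.coords) ** 2, axis=1)))
    )
    for i, center in enumerate(cfg.mode_rmsd_centers):
        if center <= 0:
            raise ConfigError("mode rmsd centers must be positive")
        if i == cfg.flip_mode_index and center < flip_floor:
            raise ConfigError(
                f"flip mode centre {center} Å below the ligand's intrinsic "
                f"flip rmsd {flip_floor:.2f} Å — use a longer centre or a "
                "shorter ligand"
            )

    counts = rng.multinomial(cfg.n_poses, cfg.mode_weights)
    all_coords: list[np.ndarray] = []
    all_modes: list[int] = []
    energies: list[np.ndarray] = []
    for mode, n in enumerate(counts):
        if n == 0:
            continue
        center = cfg.mode_rmsd_centers[mode]
        targets = center * (1.0 + rng.normal(0.0, cfg.rmsd_rel_sd, size=n))
        targets = np.clip(targets, 0.05, None)
        if mode == cfg.flip_mode_index:
            base = flip_pose(reference).coords
            base_rel = base - base.mean(axis=0)
            targets = np.maximum(targets, flip_floor)
            # translate the flipped pose to reach the target exactly
            extra = np.sqrt(np.maximum(targets**2 - flip_floor**2, 0.0))
            dirs = _random_units(rng, n)
            coords = base[None, :, :] + (extra[:, None] * dirs)[:, None, :]
        else:
            axes = _random_units(rng, n)
            angles = rng.uniform(0.0, np.pi / 6.0, size=n)
            R = _batch_rotations(axes, angles)
            r_rot = _rotation_rmsd(rel, R)
            # cap the rotational contribution at 90% of the target
            scale = np.minimum(1.0, 0.9 * targets / np.maximum(r_rot, 1e-12))
            R = _batch_rotations(axes, angles * scale)
            r_rot = _rotation_rmsd(rel, R)
            trans = np.sqrt(np.maximum(targets**2 - r_rot**2, 0.0))
            dirs = _random_units(rng, n)
            rotated = np.einsum("nij,mj->nmi", R, rel) + reference.centroid
            coords = rotated + (trans[:, None] * dirs)[:, None, :]
        mean = cfg.energy_means[mode]
        if effect is not None and mode == cfg.group_iii_mode_index:
            mean += effect
        energies.append(rng.normal(mean, cfg.energy_sd, size=n))
        all_coords.append(coords)
        all_modes.extend([mode] * n)

    coords = np.concatenate(all_coords, axis=0)
    energy = np.concatenate(energies)
    modes = np.asarray(all_modes)
    order = rng.permutation(len(modes))
    poses = tuple(
        LigandPose(
            atom_labels=reference.atom_labels,
            coords=coords[j],
            energy=float(energy[j]),
            run_id=i + 1,
        )
        for i, j in enumerate(order)
    )
    ensemble = PoseEnsemble(
        variant_id=variant_id,
        ligand_name="mock-substrate",
        poses=poses,
        reference=reference,
    )
    return ensemble, modes[order]


# ---------------------------------------------------------------------------
# Toy receptor generator


@dataclass(frozen=True)
class CandidatePlan:
    """Placement plan for one candidate residue in the toy receptor."""

    ref_position: int
    wt_residue: str = "A"
    origin: str = "SSP"
    near: bool = True       # within the proximity cutoff of the active site
    hbonded: bool = False   # side-chain N/O placed at H-bond range


def make_toy_receptor(
    plans: list[CandidatePlan],
    near_distance: float = 6.0,
    far_distance: float = 25.0,
    seed: int = 0,
) -> tuple[StructureModel, ActiveSiteDefinition]:
    """A minimal receptor with one catalytic residue and planted candidates.

    The catalytic residue (chain A, residue 50) sits at the origin with a
    polar OE1 atom. Each planned candidate is placed ``near_distance`` or
    ``far_distance`` Å away; when ``hbonded``, its side-chain OG atom is
    put 2.8 Å from the catalytic OE1.
    """
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = [
        AtomRecord("A", 50, "GLU", "CA", "C", (0.0, 0.0, 1.5)),
        AtomRecord("A", 50, "GLU", "CD", "C", (0.0, 0.0, 0.5)),
        AtomRecord("A", 50, "GLU", "OE1", "O", (0.0, 0.0, 0.0)),
    ]
    for plan in plans:
        d = near_distance if plan.near else far_distance
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        base = d * u
        atoms.append(
            AtomRecord("A", plan.ref_position, "ALA", "CA", "C", tuple(base))
        )
        atoms.append(
            AtomRecord(
                "A", plan.ref_position, "ALA", "CB", "C", tuple(base + [0.0, 0.0, 1.5])
            )
        )
        if plan.hbonded:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            atoms.append(
                AtomRecord("A", plan.ref_position, "SER", "OG", "O", tuple(2.8 * v))
            )
    model = StructureModel(atoms=tuple(atoms))
    active = ActiveSiteDefinition(catalytic_residues=(("A", 50),))
    return model, active


def write_structure_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a toy receptor model as a PDB file the reader can parse back."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        record = "HETATM" if a.is_hetero else "ATOM  "
        lines.append(
            f"{record}{i:>5} {a.atom_name:<4}{a.residue_name:>4} "
            f"{a.chain}{a.residue_number:>4}    "
            f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
            f"  1.00  0.00          {a.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Fixture writers (formats the readers consume)


def write_alignment_fasta(aln: SubfamilyAlignment, path: str | Path) -> None:
    lines = []
    for sid, row in aln.rows.items():
        lines.append(f">{sid}")
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def write_groups_tsv(aln: SubfamilyAlignment, path: str | Path) -> None:
    lines = [f"{sid}\t{aln.group_of[sid]}" for sid in aln.rows]
    Path(path).write_text("\n".join(lines) + "\n")


def write_selection_tsv(table: SiteSelectionTable, path: str | Path) -> None:
    lines = ["ref_position\twt_residue\tposterior"]
    lines += [
        f"{e.ref_position}\t{e.wt_residue}\t{e.posterior:.6f}" for e in table.entries
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_atom_line(
    serial: int, name: str, resname: str, resnum: int, xyz: np.ndarray, element: str
) -> str:
    return (
        f"HETATM{serial:>5} {name:<4}{resname:>4} A{resnum:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2}"
    )


def write_reference_pdb(pose: LigandPose, path: str | Path) -> None:
    lines = []
    for i, (label, xyz) in enumerate(zip(pose.atom_labels, pose.coords), start=1):
        lines.append(_pdb_atom_line(i, label, "LIG", 1, xyz, label[0]))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pose_pdb(poses: list[LigandPose], path: str | Path) -> None:
    """Multi-MODEL PDB of ligand poses (coordinates only)."""
    if not poses:
        raise ValueError("refusing to write an empty pose set")
    lines = []
    for m, pose in enumerate(poses, start=1):
        lines.append(f"MODEL     {m:>4}")
        for i, (label, xyz) in enumerate(zip(pose.atom_labels, pose.coords), start=1):
            lines.append(_pdb_atom_line(i, label, "LIG", 1, xyz, label[0]))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_energy_tsv(poses: list[LigandPose], path: str | Path) -> None:
    lines = ["model\tenergy"]
    lines += [f"{p.run_id}\t{p.energy:.6f}" for p in poses]
    Path(path).write_text("\n".join(lines) + "\n")


def write_dlg(ensemble: PoseEnsemble, path: str | Path) -> None:
    """Write poses in the DLG docking-log dialect the reader consumes."""
    if not ensemble.poses:
        raise ValueError("refusing to write an empty ensemble")
    lines = [
        "# synthetic docking log",
        f"# variant: {ensemble.variant_id}",
    ]
    for pose in ensemble.poses:
        lines.append(f"DOCKED: MODEL     {pose.run_id:>4}")
        lines.append(f"DOCKED: USER    Run = {pose.run_id}")
        lines.append(
            "DOCKED: USER    Estimated Free Energy of Binding    = "
            f"{pose.energy:+8.2f} kcal/mol"
        )
        for i, (label, xyz) in enumerate(zip(pose.atom_labels, pose.coords), start=1):
            lines.append(
                "DOCKED: "
                + _pdb_atom_line(i, label, "LIG", 1, xyz, label[0]).replace(
                    "HETATM", "ATOM  ", 1
                )
            )
        lines.append("DOCKED: ENDMDL")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixtures(
    out_dir: str | Path,
    ensemble: Optional[PoseEnsemble] = None,
    alignment: Optional[SubfamilyAlignment] = None,
    table: Optional[SiteSelectionTable] = None,
) -> dict[str, Path]:
    """Write whichever inputs are given into *out_dir*; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if alignment is not None:
        written["alignment"] = out / "alignment.fasta"
        write_alignment_fasta(alignment, written["alignment"])
        written["groups"] = out / "groups.tsv"
        write_groups_tsv(alignment, written["groups"])
    if table is not None:
        written["selection"] = out / "selection.tsv"
        write_selection_tsv(table, written["selection"])
    if ensemble is not None:
        tag = ensemble.variant_id.replace(" ", "_")
        written["dlg"] = out / f"{tag}.dlg"
        write_dlg(ensemble, written["dlg"])
        written["poses_pdb"] = out / f"{tag}_poses.pdb"
        write_pose_pdb(list(ensemble.poses), written["poses_pdb"])
        written["energies"] = out / f"{tag}_energies.tsv"
        write_energy_tsv(list(ensemble.poses), written["energies"])
        written["reference"] = out / "reference_pose.pdb"
        write_reference_pdb(ensemble.reference, written["reference"])
    return written
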