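"""RMSD–binding-energy landscapes of docking-pose ensembles.

The central object is an ensemble of ligand binding poses docked into one
receptor variant, each pose carrying an estimated binding free energy
(kcal/mol). Every pose is compared to a reference product pose by
receptor-frame RMSD — matched heavy atoms, **no superposition** — so the
RMSD axis measures how far a docked substrate sits from the productive
orientation inside the fixed active site. Plotting energy against that RMSD
yields a landscape that typically resolves into discrete groups:

* near-product groups, labelled I, II, III in strictly descending
  representative energy (I = the high-energy initial encounter mode,
  III = the lowest-energy, transition-like mode);
* a flipped-orientation group IV whose representative RMSD exceeds a flip
  threshold (default 6.0 Å).

The decision rule compares the group-III representative energies of a
mutant and the wild type: a mutation that lowers that energy beyond a noise
margin ε is predicted beneficial for activity, one that raises it is
predicted detrimental, anything inside ±ε is neutral.

Grouping is a one-dimensional k-means on the RMSD axis with deterministic
quantile initialisation, so repeated runs give identical landscapes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ComparisonError,
    CorrespondenceError,
    DegenerateInputError,
    FormatError,
)

DEFAULT_K = 4
DEFAULT_FLIP_THRESHOLD = 6.0
DEFAULT_EPSILON = 0.5

_ROMAN_NEAR = ["I", "II", "III", "V", "VI", "VII", "VIII"]  # IV reserved for flips


@dataclass(frozen=True)
class LigandPose:
    """One ligand pose in the fixed receptor frame.

    ``atom_labels`` are heavy-atom names; ``coords`` is an (n, 3) array in Å;
    ``energy`` is the estimated binding free energy in kcal/mol.
    """

    atom_labels: tuple[str, ...]
    coords: np.ndarray
    energy: float
    run_id: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(self.atom_labels), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.atom_labels)} atom labels"
            )
        if len(set(self.atom_labels)) != len(self.atom_labels):
            raise ValueError("atom labels must be unique")
        if not np.all(np.isfinite(coords)) or not np.isfinite(self.energy):
            raise ValueError("coordinates and energy must be finite")

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass(frozen=True)
class PoseEnsemble:
    """All docking poses for one receptor variant plus the reference pose."""

    variant_id: str
    ligand_name: str
    poses: tuple[LigandPose, ...]
    reference: LigandPose

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("ensemble must contain at least one pose")
        ref_labels = set(self.reference.atom_labels)
        for pose in self.poses:
            if set(pose.atom_labels) != ref_labels:
                raise CorrespondenceError(
                    f"pose run {pose.run_id} labels differ from the reference"
                )


@dataclass(frozen=True)
class LandscapePoint:
    rmsd: float
    energy: float
    pose: LigandPose

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


@dataclass(frozen=True)
class LandscapeGroup:
    label: str
    members: tuple[LandscapePoint, ...]
    representative: LandscapePoint
    rmsd_range: tuple[float, float]


@dataclass(frozen=True)
class LandscapeGroups:
    groups: tuple[LandscapeGroup, ...]
    flip_threshold: float = DEFAULT_FLIP_THRESHOLD

    def by_label(self, label: str) -> Optional[LandscapeGroup]:
        for g in self.groups:
            if g.label == label:
                return g
        return None

    @property
    def n_points(self) -> int:
        return sum(len(g.members) for g in self.groups)


@dataclass(frozen=True)
class MutantComparison:
    """Group-III energy difference (mutant − wild type) and its verdict."""

    delta_e_iii: float
    verdict: str  # "beneficial" | "detrimental" | "neutral"
    epsilon: float = DEFAULT_EPSILON


# ---------------------------------------------------------------------------
# Readers


_DLG_ENERGY = re.compile(
    r"Estimated Free Energy of Binding\s*=\s*([+-]?\d+(?:\.\d+)?)"
)
_DLG_RUN = re.compile(r"Run\s*=?\s*(\d+)")


def _parse_pdb_atom_line(line: str) -> Optional[tuple[str, str, np.ndarray]]:
    """(atom name, element, xyz) from a PDB-style ATOM/HETATM line, else None."""
    if not (line.startswith("ATOM") or line.startswith("HETATM")):
        return None
    try:
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparsable ATOM record: {line.rstrip()!r}") from exc
    element = line[76:78].strip().upper()
    if not element:
        element = "".join(c for c in name if c.isalpha())[:1].upper()
    return name, element, np.array([x, y, z])


def read_docking_log(path: str | Path) -> list[LigandPose]:
    """Parse an AutoDock DLG docking log into heavy-atom ligand poses.

    Each docked run is the block of ``DOCKED:`` lines between ``MODEL`` and
    ``ENDMDL``; the run's energy comes from its ``Estimated Free Energy of
    Binding`` USER line. Hydrogens are discarded.
    """
    text = Path(path).read_text()
    poses: list[LigandPose] = []
    in_block = False
    labels: list[str] = []
    coords: list[np.ndarray] = []
    energy: Optional[float] = None
    run_id: Optional[int] = None
    n_blocks = 0
    for raw in text.splitlines():
        if not raw.startswith("DOCKED:"):
            continue
        line = raw[len("DOCKED:"):].lstrip()
        if line.startswith("MODEL"):
            if in_block:
                raise FormatError(f"{path}: truncated block before run {n_blocks + 1}")
            in_block = True
            n_blocks += 1
            labels, coords, energy = [], [], None
            parts = line.split()
            run_id = int(parts[1]) if len(parts) > 1 and parts[1].isdigit() else n_blocks
        elif line.startswith("ENDMDL"):
            if not in_block:
                raise FormatError(f"{path}: ENDMDL without MODEL")
            if energy is None:
                raise FormatError(f"{path}: run {run_id} lacks its energy line")
            if not labels:
                raise FormatError(f"{path}: run {run_id} has no atoms")
            poses.append(
                LigandPose(
                    atom_labels=tuple(labels),
                    coords=np.vstack(coords),
                    energy=energy,
                    run_id=int(run_id),
                )
            )
            in_block = False
        elif in_block and line.startswith("USER"):
            m = _DLG_ENERGY.search(line)
            if m:
                energy = float(m.group(1))
            m = _DLG_RUN.search(line)
            if m:
                run_id = int(m.group(1))
        elif in_block:
            parsed = _parse_pdb_atom_line(line)
            if parsed is not None:
                name, element, xyz = parsed
                if element != "H":
                    labels.append(name)
                    coords.append(xyz)
    if in_block:
        raise FormatError(f"{path}: truncated block at run {run_id}")
    if not poses:
        raise FormatError(f"{path}: no docked runs found")
    return poses


def _read_multimodel_pdb(path: str | Path) -> list[tuple[tuple[str, ...], np.ndarray]]:
    """Atom labels + heavy-atom coordinates per MODEL of a pose PDB file."""
    models: list[tuple[tuple[str, ...], np.ndarray]] = []
    labels: list[str] = []
    coords: list[np.ndarray] = []
    in_model = False
    saw_model_card = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("MODEL"):
            saw_model_card = True
            in_model = True
            labels, coords = [], []
        elif line.startswith("ENDMDL"):
            if labels:
                models.append((tuple(labels), np.vstack(coords)))
            in_model = False
        elif line.startswith(("ATOM", "HETATM")) and (in_model or not saw_model_card):
            name, element, xyz = _parse_pdb_atom_line(line)
            if element != "H":
                labels.append(name)
                coords.append(xyz)
    if not saw_model_card and labels:
        models.append((tuple(labels), np.vstack(coords)))
    if not models:
        raise FormatError(f"{path}: no coordinate models found")
    return models


def read_pose_set(coords_path: str | Path, energies_path: str | Path) -> list[LigandPose]:
    """Read poses from a multi-MODEL PDB plus a (model, energy) TSV."""
    models = _read_multimodel_pdb(coords_path)
    energies: list[tuple[int, float]] = []
    for lineno, line in enumerate(Path(energies_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and not parts[0].lstrip("+-").isdigit():
            continue  # header
        if len(parts) < 2:
            raise FormatError(f"{energies_path}:{lineno}: expected 'model energy'")
        energies.append((int(parts[0]), float(parts[1])))
    if len(models) != len(energies):
        raise FormatError(
            f"{coords_path}: {len(models)} models but "
            f"{len(energies)} energy rows in {energies_path}"
        )
    ref_labels = models[0][0]
    poses = []
    for (labels, coords), (run_id, energy) in zip(models, energies):
        if set(labels) != set(ref_labels):
            raise FormatError(f"{coords_path}: inconsistent atom labels across models")
        poses.append(LigandPose(labels, coords, energy, run_id))
    return poses


def read_reference_pose(path: str | Path) -> LigandPose:
    """Read a single-MODEL PDB as the reference (product) pose; energy 0."""
    models = _read_multimodel_pdb(path)
    labels, coords = models[0]
    return LigandPose(labels, coords, energy=0.0, run_id=0)


# ---------------------------------------------------------------------------
# Core computations


def ligand_rmsd(pose: LigandPose, reference: LigandPose) -> float:
    """Receptor-frame RMSD between matched heavy atoms, without superposition.

    sqrt of the mean squared Euclidean deviation over atoms matched by
    label. Both poses must carry identical label sets; no fitting is done
    because both live in the same receptor coordinate frame.
    """
    if set(pose.atom_labels) != set(reference.atom_labels):
        raise CorrespondenceError(
            "atom label sets differ: "
            f"{sorted(set(pose.atom_labels) ^ set(reference.atom_labels))}"
        )
    if pose.atom_labels == reference.atom_labels:
        a = pose.coords
    else:
        order = {lab: i for i, lab in enumerate(pose.atom_labels)}
        a = pose.coords[[order[lab] for lab in reference.atom_labels]]
    diff = a - reference.coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def build_landscape(ensemble: PoseEnsemble) -> list[LandscapePoint]:
    """One (rmsd, energy) point per pose, order preserved."""
    return [
        LandscapePoint(ligand_rmsd(p, ensemble.reference), p.energy, p)
        for p in ensemble.poses
    ]


def representative(members: Sequence[LandscapePoint]) -> LandscapePoint:
    """Lowest-energy member; ties broken by lower rmsd, then lower run id."""
    if not members:
        raise ValueError("cannot take the representative of an empty group")
    return min(members, key=lambda p: (p.energy, p.rmsd, p.pose.run_id))


def _kmeans_1d(values: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D k-means: centers start at evenly spaced quantiles."""
    sorted_vals = np.sort(values)
    centers = np.quantile(sorted_vals, (np.arange(k) + 0.5) / k)
    assign = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        new_assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for j in range(k):
            sel = values[assign == j]
            if sel.size:
                centers[j] = sel.mean()
    return assign


def cluster_groups(
    points: Sequence[LandscapePoint],
    k: int = DEFAULT_K,
    flip_threshold: float = DEFAULT_FLIP_THRESHOLD,
    seed: Optional[int] = None,
) -> LandscapeGroups:
    """Cluster landscape points into k groups along the RMSD axis.

    One-dimensional k-means with deterministic quantile initialisation (the
    ``seed`` is accepted for interface symmetry and provenance; the
    procedure itself is deterministic). Clusters whose representative RMSD
    exceeds ``flip_threshold`` are labelled IV (flipped orientation); the
    remaining clusters are labelled I, II, III in strictly descending
    representative energy.
    """
    rmsds = np.array([p.rmsd for p in points], dtype=float)
    if len(np.unique(rmsds)) < k:
        raise DegenerateInputError(
            f"only {len(np.unique(rmsds))} distinct rmsd values; "
            f"choose k <= that (k={k} requested)"
        )
    assign = _kmeans_1d(rmsds, k)
    clusters: list[list[LandscapePoint]] = [[] for _ in range(k)]
    for p, j in zip(points, assign):
        clusters[j].append(p)
    clusters = [c for c in clusters if c]
    reps = [representative(c) for c in clusters]
    flip = [(c, r) for c, r in zip(clusters, reps) if r.rmsd > flip_threshold]
    near = [(c, r) for c, r in zip(clusters, reps) if r.rmsd <= flip_threshold]
    near.sort(key=lambda cr: -cr[1].energy)
    groups: list[LandscapeGroup] = []
    for i, (members, rep) in enumerate(near):
        label = _ROMAN_NEAR[i] if i < len(_ROMAN_NEAR) else f"N{i + 1}"
        groups.append(_make_group(label, members, rep))
    flip.sort(key=lambda cr: cr[1].rmsd)
    for i, (members, rep) in enumerate(flip):
        label = "IV" if i == 0 else "IV" + "bcdefg"[i - 1]
        groups.append(_make_group(label, members, rep))
    return LandscapeGroups(groups=tuple(groups), flip_threshold=flip_threshold)


def _make_group(
    label: str, members: list[LandscapePoint], rep: LandscapePoint
) -> LandscapeGroup:
    rmsds = [p.rmsd for p in members]
    return LandscapeGroup(
        label=label,
        members=tuple(members),
        representative=rep,
        rmsd_range=(min(rmsds), max(rmsds)),
    )


def compare_mutant(
    wt: LandscapeGroups,
    mut: LandscapeGroups,
    epsilon: float = DEFAULT_EPSILON,
) -> MutantComparison:
    """Apply the group-III decision rule.

    delta_e_iii = mutant group-III representative energy − wild type's.
    Verdict: beneficial when delta < −ε, detrimental when delta > +ε,
    neutral otherwise.
    """
    wt_iii = wt.by_label("III")
    mut_iii = mut.by_label("III")
    if wt_iii is None or mut_iii is None:
        missing = [name for name, g in (("wild-type", wt_iii), ("mutant", mut_iii)) if g is None]
        raise ComparisonError(f"group III missing in: {', '.join(missing)}")
    delta = mut_iii.representative.energy - wt_iii.representative.energy
    if delta < -epsilon:
        verdict = "beneficial"
    elif delta > epsilon:
        verdict = "detrimental"
    else:
        verdict = "neutral"
    return MutantComparison(delta_e_iii=delta, verdict=verdict, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Writers


def write_landscape_tsv(
    points: Sequence[LandscapePoint],
    groups: Optional[LandscapeGroups],
    path: str | Path,
) -> None:
    label_of: dict[int, str] = {}
    if groups is not None:
        for g in groups.groups:
            for p in g.members:
                label_of[id(p)] = g.label
    lines = ["run_id\trmsd\tenergy\tgroup"]
    for p in points:
        lines.append(
            f"{p.pose.run_id}\t{p.rmsd:.4f}\t{p.energy:.4f}\t{label_of.get(id(p), '')}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def groups_to_json(groups: LandscapeGroups) -> dict:
    return {
        "flip_threshold": groups.flip_threshold,
        "groups": [
            {
                "label": g.label,
                "size": len(g.members),
                "rmsd_range": list(g.rmsd_range),
                "representative": {
                    "run_id": g.representative.pose.run_id,
                    "rmsd": g.representative.rmsd,
                    "energy": g.representative.energy,
                },
            }
            for g in groups.groups
        ],
    }


def write_groups_json(groups: LandscapeGroups, path: str | Path) -> None:
    Path(path).write_text(json.dumps(groups_to_json(groups), indent=2) + "\n")


def write_comparison_json(comparison: MutantComparison, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "delta_e_iii": comparison.delta_e_iii,
                "verdict": comparison.verdict,
                "epsilon": comparison.epsilon,
            },
            indent=2,
        )
        + "\n"
    )


def plot_landscape(
    points: Sequence[LandscapePoint],
    groups: Optional[LandscapeGroups],
    path: str | Path,
    title: str = "",
) -> None:
    """Scatter plot of the RMSD–energy landscape, coloured by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if groups is None:
        ax.scatter([p.rmsd for p in points], [p.energy for p in points], s=4)
    else:
        for g in groups.groups:
            ax.scatter(
                [p.rmsd for p in g.members],
                [p.energy for p in g.members],
                s=4,
                label=f"group {g.label}",
            )
            ax.scatter(
                [g.representative.rmsd],
                [g.representative.energy],
                marker="*",
                s=120,
                edgecolor="black",
                linewidths=0.5,
                zorder=3,
            )
        ax.legend(fontsize=8)
    ax.set_xlabel("RMSD to product pose (Å)")
    ax.set_ylabel("binding energy (kcal/mol)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
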