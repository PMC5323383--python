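"""End-to-end orchestration: sites → screen → panel → landscapes → ranking.

The pipeline mirrors the mutation-design workflow: candidate sites come
from subfamily-specific positions and positively selected sites, are
screened against the receptor structure, expanded into physicochemical
mutation panels, and finally judged by the group-III docking-landscape
rule, producing a ranked report of predicted mutant effects.

Stages are driven by which blocks the config contains, so a landscape-only
run (candidate sites given directly, or only pose ensembles provided) is a
valid configuration. Every intermediate artifact is written to the run
directory; a resolved copy of the config and digests of every input file
are recorded so a report can always be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import alignment as aln_mod
from . import landscape as ls
from . import panel as panel_mod
from . import selection as sel_mod
from . import structure as struct_mod
from .errors import ConfigError, MutscapeError

log = logging.getLogger("mutscape.pipeline")


class PipelineStageError(MutscapeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RankingEntry:
    mutation: str
    origin: str
    delta_e_iii: Optional[float]
    verdict: str
    rank: int


@dataclass(frozen=True)
class RankingReport:
    entries: tuple[RankingEntry, ...]
    epsilon: float
    metadata: dict[str, Any] = field(default_factory=dict)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_config(config: dict) -> None:
    """Fail fast on structurally invalid configs, before any stage runs."""
    if not isinstance(config, dict) or not config:
        raise ConfigError("config is empty")
    known = {
        "seed", "alignment", "selection", "candidates", "screen",
        "panel", "landscape", "epsilon",
    }
    unknown = set(config) - known
    if unknown:
        raise ConfigError(f"unknown config blocks: {sorted(unknown)}")
    if "alignment" in config:
        blk = config["alignment"]
        for key in ("path", "groups", "reference_id"):
            if key not in blk:
                raise ConfigError(f"alignment block missing {key!r}")
    if "selection" in config and "path" not in config["selection"]:
        raise ConfigError("selection block missing 'path'")
    if "screen" in config:
        blk = config["screen"]
        if "model" not in blk or "active_site" not in blk:
            raise ConfigError("screen block needs 'model' and 'active_site'")
    if "landscape" in config:
        blk = config["landscape"]
        if "reference" not in blk:
            raise ConfigError("landscape block missing the reference pose")
        if "wild_type" not in blk:
            raise ConfigError("landscape block missing the wild-type ensemble")
        if "variants" not in blk or not blk["variants"]:
            raise ConfigError("landscape block lists no variants to compare")
        for name, spec in list(blk["variants"].items()) + [("wild_type", blk["wild_type"])]:
            if "dlg" not in spec and "poses" not in spec:
                raise ConfigError(
                    f"variant {name!r} needs a 'dlg' or 'poses' input"
                )
            if "poses" in spec and "energies" not in spec:
                raise ConfigError(f"variant {name!r} has poses but no energies")


def _load_poses(spec: dict, digests: dict[str, str]) -> list[ls.LigandPose]:
    if "dlg" in spec:
        digests[str(spec["dlg"])] = _digest(spec["dlg"])
        return ls.read_docking_log(spec["dlg"])
    digests[str(spec["poses"])] = _digest(spec["poses"])
    digests[str(spec["energies"])] = _digest(spec["energies"])
    return ls.read_pose_set(spec["poses"], spec["energies"])


def run_pipeline(
    config: dict,
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> RankingReport:
    """Run the configured stages and write every artifact under *out_dir*.

    Returns the ranking report (also written as report.tsv / report.json).
    Deterministic given the config and seed; the resolved config, seed and
    input digests are stored in the report metadata.
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else int(config.get("seed", 0))
    digests: dict[str, str] = {}
    resolved = dict(config, seed=seed)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))

    candidates: Optional[sel_mod.CandidateSiteSet] = None
    ssp_positions: list[int] = []
    psd_positions: list[int] = []
    wt_map: dict[int, str] = {}

    # --- sequence stages -------------------------------------------------
    if "alignment" in config:
        blk = config["alignment"]
        try:
            digests[str(blk["path"])] = _digest(blk["path"])
            aln = aln_mod.read_alignment(
                blk["path"], blk.get("format", "fasta"), blk["groups"],
                blk["reference_id"],
            )
            records = aln_mod.detect_ssps(
                aln,
                blk.get("min_conservation", aln_mod.DEFAULT_MIN_CONSERVATION),
                blk.get("max_gap_fraction", aln_mod.DEFAULT_MAX_GAP_FRACTION),
            )
        except MutscapeError as exc:
            raise PipelineStageError("ssp", str(exc)) from exc
        aln_mod.write_ssp_report(records, out / "ssp.tsv", out / "ssp.json")
        ssp_positions = [r.ref_position for r in records if r.ref_position]
        wt_map = sel_mod.wt_map_from_sequence(aln.reference_sequence)
        log.info("ssp: %d subfamily-specific positions", len(records))

    if "selection" in config:
        blk = config["selection"]
        try:
            digests[str(blk["path"])] = _digest(blk["path"])
            table = sel_mod.read_selection_table(blk["path"], blk.get("dialect", "tsv"))
            selected = sel_mod.select_positive_sites(
                table, blk.get("threshold", sel_mod.DEFAULT_POSTERIOR_THRESHOLD)
            )
        except MutscapeError as exc:
            raise PipelineStageError("psd", str(exc)) from exc
        psd_positions = [pos for pos, _ in selected]
        for pos, wt in selected:
            wt_map.setdefault(pos, wt)
        log.info("psd: %d positively selected sites", len(psd_positions))

    if "candidates" in config:
        try:
            digests[str(config["candidates"]["path"])] = _digest(
                config["candidates"]["path"]
            )
            candidates = sel_mod.read_candidates_tsv(config["candidates"]["path"])
        except MutscapeError as exc:
            raise PipelineStageError("merge", str(exc)) from exc
    elif ssp_positions or psd_positions:
        try:
            candidates = sel_mod.merge_candidates(ssp_positions, psd_positions, wt_map)
        except MutscapeError as exc:
            raise PipelineStageError("merge", str(exc)) from exc
    if candidates is not None:
        sel_mod.write_candidates_tsv(candidates, out / "candidates.tsv")
        log.info("merge: %d candidate sites", len(candidates.sites))

    # --- structural screen ------------------------------------------------
    retained = candidates
    if "screen" in config and candidates is not None:
        blk = config["screen"]
        try:
            digests[str(blk["model"])] = _digest(blk["model"])
            model = struct_mod.read_structure(blk["model"])
            ref_ligand = None
            if blk["active_site"].get("reference_ligand"):
                ref_ligand = ls.read_reference_pose(
                    blk["active_site"]["reference_ligand"]
                )
            active = struct_mod.ActiveSiteDefinition(
                catalytic_residues=tuple(
                    (str(c), int(n)) for c, n in blk["active_site"]["residues"]
                ),
                reference_ligand=ref_ligand,
            )
            thresholds = struct_mod.ScreenThresholds(
                distance_cutoff=blk.get(
                    "distance_cutoff", struct_mod.DEFAULT_DISTANCE_CUTOFF
                ),
                hbond_distance=blk.get(
                    "hbond_distance", struct_mod.DEFAULT_HBOND_DISTANCE
                ),
                hbond_angle=blk.get("hbond_angle", struct_mod.DEFAULT_HBOND_ANGLE),
                protect_network=blk.get("protect_network", True),
            )
            report = struct_mod.screen_candidates(
                model, candidates, active, thresholds, blk.get("chain")
            )
        except MutscapeError as exc:
            raise PipelineStageError("screen", str(exc)) from exc
        struct_mod.write_screen_report(report, out / "screen.tsv")
        retained = sel_mod.CandidateSiteSet(
            sites=tuple(
                sel_mod.CandidateSite(r.ref_position, r.wt_residue, r.origin)
                for r in report.retained
            )
        )
        log.info("screen: retained %d of %d sites",
                 len(report.retained), len(report.rows))

    # --- mutation panel ---------------------------------------------------
    origin_of: dict[str, str] = {}
    if "panel" in config and retained is not None:
        blk = config["panel"] or {}
        loop_sites = set(blk.get("loop_sites", []))
        panel: list[panel_mod.MutationSpec] = []
        try:
            for site in retained.sites:
                muts = panel_mod.enumerate_mutations(
                    site.ref_position, site.wt_residue,
                    is_loop=site.ref_position in loop_sites,
                )
                panel.extend(muts)
                for m in muts:
                    origin_of[m.name] = site.origin
        except ValueError as exc:
            raise PipelineStageError("panel", str(exc)) from exc
        panel_mod.write_panel_tsv(panel, out / "panel.tsv")
        log.info("panel: %d mutations across %d sites",
                 len(panel), len(retained.sites))

    # --- landscapes and decision rule ------------------------------------
    entries: list[RankingEntry] = []
    epsilon = float(
        config.get("landscape", {}).get("epsilon", ls.DEFAULT_EPSILON)
    )
    if "landscape" in config:
        blk = config["landscape"]
        k = int(blk.get("k", ls.DEFAULT_K))
        flip = float(blk.get("flip_threshold", ls.DEFAULT_FLIP_THRESHOLD))
        try:
            digests[str(blk["reference"])] = _digest(blk["reference"])
            reference = ls.read_reference_pose(blk["reference"])
            wt_poses = _load_poses(blk["wild_type"], digests)
            wt_ensemble = ls.PoseEnsemble(
                "wild-type", blk.get("ligand_name", "substrate"),
                tuple(wt_poses), reference,
            )
            wt_points = ls.build_landscape(wt_ensemble)
            wt_groups = ls.cluster_groups(wt_points, k, flip, seed)
        except MutscapeError as exc:
            raise PipelineStageError("landscape", f"wild-type: {exc}") from exc
        ls.write_landscape_tsv(wt_points, wt_groups, out / "wild-type_landscape.tsv")
        ls.write_groups_json(wt_groups, out / "wild-type_groups.json")

        comparisons: dict[str, ls.MutantComparison] = {}
        for name, spec in blk["variants"].items():
            try:
                poses = _load_poses(spec, digests)
                ensemble = ls.PoseEnsemble(
                    name, blk.get("ligand_name", "substrate"), tuple(poses), reference
                )
                points = ls.build_landscape(ensemble)
                groups = ls.cluster_groups(points, k, flip, seed)
                comparisons[name] = ls.compare_mutant(wt_groups, groups, epsilon)
            except MutscapeError as exc:
                raise PipelineStageError("landscape", f"{name}: {exc}") from exc
            ls.write_landscape_tsv(points, groups, out / f"{name}_landscape.tsv")
            ls.write_groups_json(groups, out / f"{name}_groups.json")
            ls.write_comparison_json(comparisons[name], out / f"{name}_comparison.json")
        ranked = sorted(
            comparisons.items(), key=lambda kv: (kv[1].delta_e_iii, kv[0])
        )
        for rank, (name, comp) in enumerate(ranked, start=1):
            entries.append(
                RankingEntry(
                    mutation=name,
                    origin=origin_of.get(name, ""),
                    delta_e_iii=comp.delta_e_iii,
                    verdict=comp.verdict,
                    rank=rank,
                )
            )

    report = RankingReport(
        entries=tuple(entries),
        epsilon=epsilon,
        metadata={
            "seed": seed,
            "config_hash": _config_hash(resolved),
            "input_digests": digests,
        },
    )
    _write_report(report, out)
    return report


def _write_report(report: RankingReport, out: Path) -> None:
    lines = ["rank\tmutation\torigin\tdelta_e_iii\tverdict"]
    for e in report.entries:
        delta = "" if e.delta_e_iii is None else f"{e.delta_e_iii:.4f}"
        lines.append(f"{e.rank}\t{e.mutation}\t{e.origin}\t{delta}\t{e.verdict}")
    (out / "report.tsv").write_text("\n".join(lines) + "\n")
    payload = {
        "epsilon": report.epsilon,
        "metadata": report.metadata,
        "entries": [
            {
                "rank": e.rank,
                "mutation": e.mutation,
                "origin": e.origin,
                "delta_e_iii": e.delta_e_iii,
                "verdict": e.verdict,
            }
            for e in report.entries
        ],
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2) + "\n")


def load_config(path: str | Path) -> dict:
    try:
        config = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(config, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return config
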