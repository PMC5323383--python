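"""Positive-selection site tables and candidate-site merging.

Branch-site codon models (run externally with codeml or similar) emit a
per-site Bayes-empirical-Bayes posterior probability that the site evolves
under positive selection (dN/dS > 1). This module only *consumes* such
output — either the "Positively selected sites" text block of a codeml main
result file, or a plain three-column TSV — thresholds it into a site list,
and merges that list with subfamily-specific positions into the candidate
set for mutagenesis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .errors import FormatError, ReferenceMappingError

DEFAULT_POSTERIOR_THRESHOLD = 0.95

_BEB_HEADER = re.compile(r"Positively selected sites", re.IGNORECASE)
_BEB_ROW = re.compile(r"^\s*(\d+)\s+([A-Z\*])\s+(\d+(?:\.\d+)?)(\*{0,2})\s*")


@dataclass(frozen=True)
class SiteEntry:
    ref_position: int
    wt_residue: str
    posterior: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError(
                f"posterior {self.posterior} at site {self.ref_position} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class SiteSelectionTable:
    """Per-site positive-selection posteriors in reference numbering."""

    entries: tuple[SiteEntry, ...]
    method_tag: str = "branch-site BEB"

    def __post_init__(self) -> None:
        positions = [e.ref_position for e in self.entries]
        if len(positions) != len(set(positions)):
            dupes = sorted({p for p in positions if positions.count(p) > 1})
            raise FormatError(f"duplicate site positions: {dupes}")
        object.__setattr__(
            self, "entries", tuple(sorted(self.entries, key=lambda e: e.ref_position))
        )

    def posterior_of(self, position: int) -> Optional[float]:
        for e in self.entries:
            if e.ref_position == position:
                return e.posterior
        return None


@dataclass(frozen=True)
class CandidateSite:
    ref_position: int
    wt_residue: str
    origin: str  # "SSP", "PSD" or "both"


@dataclass(frozen=True)
class CandidateSiteSet:
    sites: tuple[CandidateSite, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        positions = [s.ref_position for s in self.sites]
        if len(positions) != len(set(positions)):
            raise ValueError("candidate positions must be unique")
        object.__setattr__(
            self, "sites", tuple(sorted(self.sites, key=lambda s: s.ref_position))
        )

    @property
    def positions(self) -> list[int]:
        return [s.ref_position for s in self.sites]


def _parse_tsv(text: str, path: str | Path) -> list[SiteEntry]:
    entries = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 'position residue posterior'")
        if lineno == 1 and not parts[0].isdigit():
            continue  # header row
        try:
            pos = int(parts[0])
            posterior = float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        entries.append(SiteEntry(pos, parts[1], posterior))
    return entries


def _parse_beb_block(text: str, path: str | Path) -> list[SiteEntry]:
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if _BEB_HEADER.search(line):
            start = i + 1
            break
    if start is None:
        raise FormatError(f"{path}: no 'Positively selected sites' block found")
    entries = []
    seen_rows = False
    for line in lines[start:]:
        m = _BEB_ROW.match(line)
        if m:
            seen_rows = True
            entries.append(SiteEntry(int(m.group(1)), m.group(2), float(m.group(3))))
        elif seen_rows and line.strip() == "":
            break  # end of the block
    if not entries:
        raise FormatError(f"{path}: empty 'Positively selected sites' block")
    return entries


def read_selection_table(path: str | Path, dialect: str = "tsv") -> SiteSelectionTable:
    """Read a per-site posterior table.

    ``dialect`` is ``"tsv"`` (columns: position, residue, posterior) or
    ``"beb_block"`` (the "Positively selected sites" section of a codeml
    main output file, with optional significance stars after the posterior).
    """
    text = Path(path).read_text()
    if dialect == "tsv":
        entries = _parse_tsv(text, path)
        tag = "tsv"
    elif dialect == "beb_block":
        entries = _parse_beb_block(text, path)
        tag = "branch-site BEB"
    else:
        raise ValueError(f"dialect must be 'tsv' or 'beb_block', got {dialect!r}")
    return SiteSelectionTable(entries=tuple(entries), method_tag=tag)


def select_positive_sites(
    table: SiteSelectionTable,
    threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
) -> list[tuple[int, str]]:
    """Sites whose posterior strictly exceeds *threshold*, sorted by position."""
    return [
        (e.ref_position, e.wt_residue)
        for e in table.entries
        if e.posterior > threshold
    ]


def wt_map_from_sequence(sequence: str) -> dict[int, str]:
    """1-based position → residue map from an ungapped reference sequence."""
    return {i: aa for i, aa in enumerate(sequence, start=1)}


def merge_candidates(
    ssp_sites: Iterable[int],
    psd_sites: Iterable[int],
    wt_map: Mapping[int, str],
) -> CandidateSiteSet:
    """Union of SSP and positively selected positions with origin tags.

    The result size obeys inclusion–exclusion: |SSP| + |PSD| − |overlap|.
    Every position must resolve in ``wt_map`` (reference numbering).
    """
    ssp = set(ssp_sites)
    psd = set(psd_sites)
    unknown = sorted((ssp | psd) - set(wt_map))
    if unknown:
        raise ReferenceMappingError(
            f"positions absent from the reference sequence: {unknown}"
        )
    sites = []
    for pos in sorted(ssp | psd):
        origin = "both" if pos in ssp and pos in psd else ("SSP" if pos in ssp else "PSD")
        sites.append(CandidateSite(pos, wt_map[pos], origin))
    return CandidateSiteSet(sites=tuple(sites))


def write_candidates_tsv(candidates: CandidateSiteSet, path: str | Path) -> None:
    lines = ["ref_position\twt_residue\torigin"]
    lines += [f"{s.ref_position}\t{s.wt_residue}\t{s.origin}" for s in candidates.sites]
    Path(path).write_text("\n".join(lines) + "\n")


def read_candidates_tsv(path: str | Path) -> CandidateSiteSet:
    sites = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("ref_position"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
        sites.append(CandidateSite(int(parts[0]), parts[1], parts[2]))
    return CandidateSiteSet(sites=tuple(sites))
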