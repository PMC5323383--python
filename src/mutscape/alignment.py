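"""Two-group protein alignments and subfamily-specific position (SSP) detection.

A subfamily-specific position is an alignment column whose residue is
conserved within each of two subfamily groups but differs between them.
Such columns are classic candidates for function-switching mutations:
in the chalcone isomerase family, for example, they separate the
legume-specific type-II enzymes from the ubiquitous type-I enzymes.

Positions are reported both as 1-based alignment columns and, where the
reference sequence is ungapped at the column, as 1-based positions in the
reference sequence (the numbering used for naming mutations like E107D).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import AlignIO

from .errors import FormatError, LabelError, ReferenceMappingError

GAP = "-"
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_MIN_CONSERVATION = 1.0
DEFAULT_MAX_GAP_FRACTION = 0.2


@dataclass(frozen=True)
class SubfamilyAlignment:
    """An aligned sequence set split into exactly two subfamily groups.

    Parameters
    ----------
    rows
        Mapping of sequence id to its aligned string (insertion order is
        the order sequences were read).
    group_of
        Mapping of sequence id to its group label, 1 or 2.
    reference_id
        Id of the sequence whose ungapped numbering is used for reporting.
    """

    rows: dict[str, str]
    group_of: dict[str, int]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no sequences")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise FormatError(f"aligned rows have unequal lengths: {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise FormatError("alignment length must be >= 1")
        missing = set(self.rows) - set(self.group_of)
        if missing:
            raise LabelError(f"sequences missing a group label: {sorted(missing)}")
        bad = {g for g in self.group_of.values() if g not in (1, 2)}
        if bad:
            raise LabelError(f"group labels must be 1 or 2, got {sorted(bad)}")
        for g in (1, 2):
            if len(self.members(g)) < 2:
                raise LabelError(f"group {g} has fewer than 2 members")
        if self.reference_id not in self.rows:
            raise ReferenceMappingError(
                f"reference sequence {self.reference_id!r} not in alignment"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def members(self, group: int) -> list[str]:
        return [sid for sid in self.rows if self.group_of.get(sid) == group]

    def column(self, col: int, ids: Optional[Iterable[str]] = None) -> list[str]:
        """Residues of 1-based column *col*, optionally restricted to *ids*."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        ids = list(ids) if ids is not None else list(self.rows)
        return [self.rows[sid][col - 1] for sid in ids]

    @property
    def reference_sequence(self) -> str:
        """The reference row with gaps removed."""
        return self.rows[self.reference_id].replace(GAP, "")


@dataclass(frozen=True)
class SSPRecord:
    """One subfamily-specific position.

    ``ref_position`` is None when the reference sequence is gapped at the
    column, in which case only the alignment column locates the site.
    """

    column: int
    ref_position: Optional[int]
    group1_residue: str
    group2_residue: str

    def __post_init__(self) -> None:
        if self.group1_residue == self.group2_residue:
            raise ValueError("SSP requires differing group residues")


def _read_groups(path: str | Path) -> dict[str, int]:
    groups: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'id<TAB>group', got {line!r}")
        sid, grp = parts
        try:
            groups[sid] = int(grp)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: group must be an integer") from exc
    return groups


def read_alignment(
    path: str | Path,
    fmt: str,
    groups_path: str | Path,
    reference_id: str,
) -> SubfamilyAlignment:
    """Read an aligned FASTA or Clustal file plus a two-column group TSV.

    Raises
    ------
    FormatError
        If the file cannot be parsed or rows have unequal lengths.
    LabelError
        If any sequence lacks a group assignment.
    ReferenceMappingError
        If ``reference_id`` is absent from the alignment.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"format must be 'fasta' or 'clustal', got {fmt!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    if len(rows) != len(aln):
        raise FormatError(f"duplicate sequence ids in {path}")
    groups = _read_groups(groups_path)
    missing = [sid for sid in rows if sid not in groups]
    if missing:
        raise LabelError(f"sequences missing from groups file: {missing}")
    return SubfamilyAlignment(
        rows=rows,
        group_of={sid: groups[sid] for sid in rows},
        reference_id=reference_id,
    )


def column_consensus(
    residues: list[str],
    min_conservation: float,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> Optional[str]:
    """Consensus letter of one column slice, or None.

    Returns the amino-acid letter whose frequency among non-gap entries is at
    least ``min_conservation``; None when no letter qualifies or when the gap
    fraction of the slice exceeds ``max_gap_fraction``. Ties at equal counts
    resolve to the alphabetically first letter (only reachable when
    ``min_conservation`` <= 0.5).
    """
    if not residues:
        raise ValueError("column_consensus requires a non-empty residue list")
    n_gap = sum(1 for r in residues if r == GAP)
    if n_gap / len(residues) > max_gap_fraction:
        return None
    non_gap = [r for r in residues if r != GAP]
    if not non_gap:
        return None
    counts = Counter(non_gap)
    best = min(counts, key=lambda r: (-counts[r], r))
    if counts[best] / len(non_gap) >= min_conservation:
        return best
    return None


def map_to_reference(aln: SubfamilyAlignment, column: int) -> Optional[int]:
    """Map a 1-based alignment column to a 1-based reference position.

    Counts non-gap reference characters up to and including the column;
    returns None when the reference row holds a gap there.
    """
    if not 1 <= column <= aln.length:
        raise IndexError(f"column {column} out of range 1..{aln.length}")
    ref = aln.rows[aln.reference_id]
    if ref[column - 1] == GAP:
        return None
    return column - ref[:column].count(GAP)


def detect_ssps(
    aln: SubfamilyAlignment,
    min_conservation: float = DEFAULT_MIN_CONSERVATION,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> list[SSPRecord]:
    """Scan every column for subfamily-specific positions.

    A column qualifies when both group consensuses exist (at the given
    conservation and gap thresholds, applied per group) and differ. Records
    are sorted by column; reference positions are filled in where the
    reference sequence is ungapped.
    """
    g1 = aln.members(1)
    g2 = aln.members(2)
    out: list[SSPRecord] = []
    for col in range(1, aln.length + 1):
        c1 = column_consensus(aln.column(col, g1), min_conservation, max_gap_fraction)
        c2 = column_consensus(aln.column(col, g2), min_conservation, max_gap_fraction)
        if c1 is not None and c2 is not None and c1 != c2:
            out.append(
                SSPRecord(
                    column=col,
                    ref_position=map_to_reference(aln, col),
                    group1_residue=c1,
                    group2_residue=c2,
                )
            )
    return out


def write_ssp_report(records: list[SSPRecord], tsv_path: str | Path,
                     json_path: Optional[str | Path] = None) -> None:
    """Write SSP records as TSV (and optionally JSON)."""
    lines = ["column\tref_position\tgroup1_residue\tgroup2_residue"]
    for r in records:
        ref = "" if r.ref_position is None else str(r.ref_position)
        lines.append(f"{r.column}\t{ref}\t{r.group1_residue}\t{r.group2_residue}")
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    if json_path is not None:
        payload = [
            {
                "column": r.column,
                "ref_position": r.ref_position,
                "group1_residue": r.group1_residue,
                "group2_residue": r.group2_residue,
            }
            for r in records
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
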