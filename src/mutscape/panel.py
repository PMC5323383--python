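"""Physicochemical mutation panels for retained sites.

For each retained site the panel proposes one representative substitution
per side-chain class — non-polar, aromatic, non-charged polar, basic
(alkaline) and acidic — plus proline for sites on a loop, where a backbone
rigidification can reshape the active-site entrance. When the wild type
already belongs to a class, the class contributes its within-class
alternate instead (an Asp at a Glu site, an Asn at a Gln site, ...), so a
conservative same-class swap is always tested rather than skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

AA_CLASSES: dict[str, frozenset[str]] = {
    "non-polar": frozenset("AVLIMG"),
    "aromatic": frozenset("FYW"),
    "polar": frozenset("STNQC"),
    "basic": frozenset("KRH"),
    "acidic": frozenset("DE"),
    "proline": frozenset("P"),
}

# Preference order per class: the first member differing from the wild type
# is used. Orders chosen so the conventional representative comes first
# (Ala, Phe, Gln, His, Glu) and the within-class alternate second.
DEFAULT_PREFERENCES: dict[str, tuple[str, ...]] = {
    "non-polar": ("A", "G", "V"),
    "aromatic": ("F", "Y", "W"),
    "polar": ("Q", "N", "S"),
    "basic": ("H", "K", "R"),
    "acidic": ("E", "D"),
}

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MutationSpec:
    ref_position: int
    wt_residue: str
    mutant_residue: str
    class_tag: str

    def __post_init__(self) -> None:
        if self.mutant_residue == self.wt_residue:
            raise ValueError("mutant residue equals wild type")
        for aa in (self.wt_residue, self.mutant_residue):
            if aa not in STANDARD_AA:
                raise ValueError(f"non-standard residue {aa!r}")

    @property
    def name(self) -> str:
        """Conventional mutation string, e.g. 'I197P'."""
        return f"{self.wt_residue}{self.ref_position}{self.mutant_residue}"


@dataclass(frozen=True)
class PanelConfig:
    preferences: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PREFERENCES)
    )


def enumerate_mutations(
    site: int,
    wt: str,
    is_loop: bool = False,
    config: PanelConfig = PanelConfig(),
) -> list[MutationSpec]:
    """One substitution per physicochemical class, plus proline on loops.

    Raises ``ValueError`` for a non-standard wild-type residue. A proline
    wild type gets no proline entry (there is no within-class alternate).
    """
    if wt not in STANDARD_AA:
        raise ValueError(f"non-standard wild-type residue {wt!r}")
    panel: list[MutationSpec] = []
    for class_tag, prefs in config.preferences.items():
        mutant = next((aa for aa in prefs if aa != wt), None)
        if mutant is None:
            continue
        panel.append(MutationSpec(site, wt, mutant, class_tag))
    if is_loop and wt != "P":
        panel.append(MutationSpec(site, wt, "P", "proline"))
    return panel


def write_panel_tsv(panel: list[MutationSpec], path: str | Path) -> None:
    lines = ["ref_position\twt_residue\tmutant_residue\tclass_tag\tmutation"]
    lines += [
        f"{m.ref_position}\t{m.wt_residue}\t{m.mutant_residue}\t{m.class_tag}\t{m.name}"
        for m in panel
    ]
    Path(path).write_text("\n".join(lines) + "\n")
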