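"""Amino-acid chemistry tables shared by every stage of the screen.

The table bundles four things the pipeline needs about residue types:
whether a residue counts as hydrophobic, how big its side chain is
(Zamyatnin mean residue volumes, used as the size proxy for the
"small side chain" criterion), per-element van der Waals radii for
occupancy grids and clash checks, and the ideal-geometry templates used
to graft side chains onto an existing backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# Bondi-style van der Waals radii, Angstrom. Heavy-atom values are the ones
# that matter: hydrogens are excluded from occupancy grids by default.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.70

AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Common non-standard residues mapped to their standard parent.
NONSTANDARD_PARENT = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",
    "PYL": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "MLY": "LYS",
    "CSO": "CYS",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}

# Mean residue volumes (Zamyatnin-style), Angstrom^3. Used as the residue
# size scale: the sensitive-residue filter keeps residues at or below the
# candidate threshold, and mutation targets must be strictly larger than
# the wild type on this scale.
RESIDUE_VOLUME: dict[str, float] = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}

# Default hydrophobic set. Deliberately broader than a Kyte-Doolittle > 0
# cut: Pro and Tyr behave as hydrophobic packing partners in loop context
# (e.g. the Val/Pro/Tyr neighbours that stabilise a buried Ala position),
# so they are included alongside the aliphatic and aromatic residues.
HYDROPHOBIC_DEFAULT = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "TYR", "CYS"}
)

# Large hydrophobic residues offered as cavity-filling mutation targets.
LARGE_HYDROPHOBIC_TARGETS = ("PHE", "TYR", "TRP", "MET")


@dataclass(frozen=True)
class AminoAcidTable:
    """Residue-type chemistry used across the screen.

    All fields are overridable so a config file can redefine e.g. the
    hydrophobic set without touching code.
    """

    hydrophobic: frozenset[str] = HYDROPHOBIC_DEFAULT
    volumes: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_VOLUME))
    vdw: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    default_vdw: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        missing = [aa for aa in AA3 if aa not in self.volumes]
        if missing:
            raise ValueError(f"volume table missing residues: {missing}")
        bad = [aa for aa, v in self.volumes.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive residue volumes: {bad}")

    def is_hydrophobic(self, name3: str) -> bool:
        name3 = NONSTANDARD_PARENT.get(name3, name3)
        return name3 in self.hydrophobic

    def volume(self, name3: str) -> float:
        name3 = NONSTANDARD_PARENT.get(name3, name3)
        return self.volumes[name3]

    def vdw_radius(self, element: str) -> float:
        return self.vdw.get(element.upper(), self.default_vdw)

    def with_hydrophobic(self, names: set[str] | frozenset[str]) -> "AminoAcidTable":
        return replace(self, hydrophobic=frozenset(names))


DEFAULT_TABLE = AminoAcidTable()


def standard_parent(name3: str) -> str | None:
    """Standard three-letter parent of a residue name, or None."""
    if name3 in THREE_TO_ONE:
        return name3
    return NONSTANDARD_PARENT.get(name3)
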