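"""Structure data model and PDB input/output.

The in-memory model is deliberately small: chains of residues of atoms,
with author numbering preserved end-to-end so a report can say "Ala99"
exactly as a structural biologist would. Parsing and serialization are
delegated to gemmi; this module owns altloc filtering, water/hetero
separation, and van der Waals radius assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .chem import (
    DEFAULT_TABLE,
    THREE_TO_ONE,
    WATER_NAMES,
    AminoAcidTable,
    standard_parent,
)

log = logging.getLogger(__name__)


class StructureInputError(ValueError):
    """Unreadable file or file without usable ATOM records."""


class EmptyModelError(StructureInputError):
    """File parsed but contains zero amino-acid residues."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    position: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float = 1.70

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.vdw_radius > 0:
            raise ValueError(f"non-positive vdw radius for atom {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    icode: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)
    is_hydrophobic: bool = False
    sidechain_volume: float = 0.0
    is_standard: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.icode)

    @property
    def one_letter(self) -> str:
        parent = standard_parent(self.name3)
        return THREE_TO_ONE.get(parent, "X") if parent else "X"

    @property
    def label(self) -> str:
        """Human-readable label, e.g. 'A/Ala99'."""
        name = self.name3.capitalize()
        return f"{self.chain_id}/{name}{self.seq_number}{self.icode}".rstrip()

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class StructureModel:
    identifier: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    hetero: list[Residue] = field(default_factory=list)
    waters: list[Residue] = field(default_factory=list)
    source_path: str = ""

    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        for residues in self.chains.values():
            out.extend(residues)
        return out

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def find_residue(self, chain_id: str, seq_number: int, icode: str = "") -> Residue | None:
        for res in self.chains.get(chain_id, []):
            if res.seq_number == seq_number and res.icode == icode:
                return res
        return None

    def heavy_atom_arrays(
        self, include_hetero: bool = False
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[Residue, Atom]]]:
        """Coordinates (N,3), vdw radii (N,) and owner refs for heavy atoms."""
        refs: list[tuple[Residue, Atom]] = []
        pool = list(self.residues())
        if include_hetero:
            pool.extend(self.hetero)
        for res in pool:
            for atom in res.heavy_atoms():
                refs.append((res, atom))
        if not refs:
            return np.zeros((0, 3)), np.zeros(0), refs
        coords = np.array([a.position for _, a in refs])
        radii = np.array([a.vdw_radius for _, a in refs])
        return coords, radii, refs

    def copy(self) -> "StructureModel":
        new = StructureModel(self.identifier, {}, [], [], self.source_path)
        for cid, residues in self.chains.items():
            new.chains[cid] = [
                Residue(
                    r.chain_id, r.seq_number, r.icode, r.name3,
                    [Atom(a.serial, a.name, a.element, a.position.copy(),
                          a.occupancy, a.altloc, a.vdw_radius) for a in r.atoms],
                    r.is_hydrophobic, r.sidechain_volume, r.is_standard,
                )
                for r in residues
            ]
        new.hetero = list(self.hetero)
        new.waters = list(self.waters)
        return new

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transformed copy (used by invariance tests)."""
        new = self.copy()
        for res in new.residues():
            for atom in res.atoms:
                atom.position = rotation @ atom.position + translation
        return new


def _annotate_residue(res: Residue, table: AminoAcidTable) -> None:
    parent = standard_parent(res.name3)
    if parent is None:
        res.is_standard = False
        res.is_hydrophobic = False
        res.sidechain_volume = table.volumes.get("ALA", 88.6)
        log.warning("non-standard residue %s treated as non-hydrophobic", res.label)
    else:
        res.is_standard = res.name3 == parent
        res.is_hydrophobic = table.is_hydrophobic(parent)
        res.sidechain_volume = table.volume(parent)


def _select_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per atom name: highest occupancy, first wins ties."""
    by_name: dict[str, Atom] = {}
    for atom in raw_atoms:
        prev = by_name.get(atom.name)
        if prev is None or atom.occupancy > prev.occupancy + 1e-12:
            by_name[atom.name] = atom
    return list(by_name.values())


def parse_pdb(
    path: str,
    table: AminoAcidTable = DEFAULT_TABLE,
    chain: str | None = None,
    identifier: str | None = None,
) -> StructureModel:
    """Read a PDB file into a StructureModel.

    Only the first MODEL of multi-model files is used. Alternate
    locations are collapsed to a single copy per atom name (highest
    occupancy, positional first on ties). Waters and hetero compounds
    are kept on side lists, never in the polymer chains.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureInputError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureInputError(f"no models in {path}")
    st.setup_entities()
    gmodel = st[0]

    model = StructureModel(
        identifier=identifier or (st.name or "model").lower(),
        source_path=str(path),
    )
    unknown_elements: set[str] = set()
    for gchain in gmodel:
        cid = gchain.name
        if chain is not None and cid != chain:
            continue
        for gres in gchain:
            raw: list[Atom] = []
            for ga in gres:
                element = ga.element.name if ga.element else ""
                if not element:
                    element = "".join(c for c in ga.name if c.isalpha())[:1] or "C"
                if element.upper() not in table.vdw:
                    unknown_elements.add(element)
                raw.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=element,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                        vdw_radius=table.vdw_radius(element),
                    )
                )
            res = Residue(
                chain_id=cid,
                seq_number=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                name3=gres.name.strip().upper(),
                atoms=_select_altlocs(raw),
            )
            if res.name3 in WATER_NAMES:
                model.waters.append(res)
            elif standard_parent(res.name3) is None and gres.het_flag == "H":
                model.hetero.append(res)
            else:
                _annotate_residue(res, table)
                model.chains.setdefault(cid, []).append(res)
    if unknown_elements:
        warnings.warn(
            f"unknown elements {sorted(unknown_elements)} assigned default "
            f"vdw radius {table.default_vdw} A",
            stacklevel=2,
        )
    for cid in model.chains:
        model.chains[cid].sort(key=lambda r: (r.seq_number, r.icode))
    if model.n_residues() == 0:
        raise EmptyModelError(f"no amino-acid residues in {path}")
    return model


def write_pdb(model: StructureModel, path: str) -> None:
    """Serialize a StructureModel to PDB via gemmi."""
    st = gemmi.Structure()
    st.name = model.identifier
    gmodel = gemmi.Model("1")
    for cid, residues in model.chains.items():
        gchain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name3
            gres.seqid = gemmi.SeqId(res.seq_number, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\x00"
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    doc_path = str(path)
    st.write_pdb(doc_path)
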