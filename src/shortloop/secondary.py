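"""Secondary-structure assignment from backbone hydrogen-bond energies.

A minimal DSSP-style assigner sufficient to separate loops from regular
structure: backbone N-H...O=C hydrogen bonds are scored with the
Kabsch-Sander electrostatic model, two consecutive i -> i+4 turns make a
helix, and isolated or laddered bridges make strand. Everything else is
coil. Finer DSSP classes (3-10 helix, turns, bends) are deliberately
collapsed: the screen only needs loop-vs-regular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure import Residue, StructureModel

log = logging.getLogger(__name__)

NO_BOND = float("inf")
# Kabsch-Sander: E = q1*q2*f*(1/rON + 1/rCH - 1/rOH - 1/rCN), kcal/mol
KS_FACTOR = 0.084 * 332.0
BOND_ENERGY_CUTOFF = -0.5  # kcal/mol; bond recorded iff E < cutoff
NO_DISTANCE_CUTOFF = 5.2  # Angstrom N..O shortcut: farther pairs never bond


@dataclass(frozen=True)
class BackboneHBond:
    donor: tuple[str, int, str]  # residue key of the N-H side
    acceptor: tuple[str, int, str]  # residue key of the C=O side
    energy: float  # kcal/mol


@dataclass
class SSAssignment:
    """Per-residue helix/strand/coil states plus the H-bond evidence."""

    states: dict[tuple[str, int, str], str] = field(default_factory=dict)
    evidence: dict[tuple[str, int, str], list[BackboneHBond]] = field(default_factory=dict)

    def state(self, residue: Residue) -> str:
        return self.states.get(residue.key, "C")

    def chain_string(self, model: StructureModel, chain_id: str) -> str:
        return "".join(self.state(r) for r in model.chains.get(chain_id, []))


def build_amide_hydrogen(residue: Residue, prev_residue: Residue | None) -> np.ndarray | None:
    """Amide H position: 1.0 A from N along unit(C_prev - O_prev).

    A deposited hydrogen named H/HN wins; the first residue of a chain
    and proline have no usable donor.
    """
    deposited = residue.atom("H") or residue.atom("HN")
    if deposited is not None:
        return deposited.position
    if residue.name3 == "PRO" or prev_residue is None:
        return None
    n = residue.atom("N")
    c_prev = prev_residue.atom("C")
    o_prev = prev_residue.atom("O")
    if n is None or c_prev is None or o_prev is None:
        return None
    v = c_prev.position - o_prev.position
    norm = np.linalg.norm(v)
    if norm < 1e-6:
        log.warning("%s: degenerate C=O geometry in predecessor; donor disabled",
                    residue.label)
        return None
    return n.position + v / norm


def hbond_energy(
    donor: Residue,
    acceptor: Residue,
    h_position: np.ndarray | None,
) -> float:
    """Kabsch-Sander electrostatic H-bond energy, kcal/mol.

    Returns the no-bond sentinel (+inf) for missing atoms, proline
    donors, self pairs, or N..O beyond the distance shortcut.
    """
    if donor.key == acceptor.key or h_position is None:
        return NO_BOND
    n = donor.atom("N")
    c = acceptor.atom("C")
    o = acceptor.atom("O")
    if n is None or c is None or o is None:
        return NO_BOND
    r_on = np.linalg.norm(o.position - n.position)
    if r_on > NO_DISTANCE_CUTOFF:
        return NO_BOND
    r_ch = np.linalg.norm(c.position - h_position)
    r_oh = np.linalg.norm(o.position - h_position)
    r_cn = np.linalg.norm(c.position - n.position)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-3:
        return NO_BOND
    return KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _chain_hbonds(model: StructureModel) -> dict[tuple, dict[tuple, float]]:
    """All backbone H-bonds as donor_key -> {acceptor_key: energy}."""
    residues: list[Residue] = []
    prev_of: dict[tuple, Residue | None] = {}
    for chain in model.chains.values():
        for i, res in enumerate(chain):
            residues.append(res)
            prev = chain[i - 1] if i > 0 else None
            # a sequence gap breaks the peptide bond; no donor H then
            if prev is not None and res.seq_number - prev.seq_number > 1:
                prev = None
            prev_of[res.key] = prev

    acceptors = [r for r in residues if r.atom("C") is not None and r.atom("O") is not None]
    if not acceptors:
        return {}
    from scipy.spatial import cKDTree

    o_coords = np.array([r.atom("O").position for r in acceptors])
    tree = cKDTree(o_coords)

    bonds: dict[tuple, dict[tuple, float]] = {}
    for donor in residues:
        h = build_amide_hydrogen(donor, prev_of[donor.key])
        n = donor.atom("N")
        if h is None or n is None:
            continue
        for j in tree.query_ball_point(n.position, NO_DISTANCE_CUTOFF):
            acceptor = acceptors[j]
            e = hbond_energy(donor, acceptor, h)
            if e < BOND_ENERGY_CUTOFF:
                bonds.setdefault(donor.key, {})[acceptor.key] = e
    return bonds


def assign_secondary_structure(model: StructureModel) -> SSAssignment:
    """Assign H/E/C per residue.

    Helix: two consecutive i -> i+4 turns (N-H of residue i+4 bonded to
    C=O of residue i) mark residues i+1..i+4. Strand: Kabsch-Sander
    parallel/antiparallel bridge patterns between residues at least
    three apart in sequence (or in different chains). Helix evidence
    wins where both patterns apply. Residues without backbone atoms stay
    coil. Deterministic.
    """
    bonds = _chain_hbonds(model)

    def hb(donor_key: tuple | None, acceptor_key: tuple | None) -> bool:
        if donor_key is None or acceptor_key is None:
            return False
        return acceptor_key in bonds.get(donor_key, set())

    assignment = SSAssignment()
    energies: dict[tuple, list[BackboneHBond]] = {}
    for dk, acs in bonds.items():
        for ak, e in acs.items():
            hbnd = BackboneHBond(dk, ak, e)
            energies.setdefault(dk, []).append(hbnd)
            energies.setdefault(ak, []).append(hbnd)
    assignment.evidence = energies

    all_keys: list[tuple] = []
    chain_arrays: dict[str, list[tuple]] = {}
    for cid, chain in model.chains.items():
        keys = [r.key for r in chain]
        chain_arrays[cid] = keys
        all_keys.extend(keys)
    states = {k: "C" for k in all_keys}

    def key_at(keys: list[tuple], i: int) -> tuple | None:
        if 0 <= i < len(keys):
            return keys[i]
        return None

    # helices: consecutive 4-turns
    for keys in chain_arrays.values():
        turn4 = [hb(key_at(keys, i + 4), key_at(keys, i)) for i in range(len(keys))]
        for i in range(len(keys) - 1):
            if turn4[i] and turn4[i + 1]:
                for j in range(i + 1, min(i + 5, len(keys))):
                    states[keys[j]] = "H"

    # strands: bridge patterns between all residue pairs
    flat: list[tuple[str, int, tuple]] = []
    for cid, keys in chain_arrays.items():
        for i, k in enumerate(keys):
            flat.append((cid, i, k))
    index_of = {k: (cid, i) for cid, i, k in flat}

    def nb(key: tuple | None, delta: int) -> tuple | None:
        if key is None or key not in index_of:
            return None
        cid, i = index_of[key]
        return key_at(chain_arrays[cid], i + delta)

    bridge_partners: set[tuple] = set()
    candidate_pairs: set[tuple[tuple, tuple]] = set()
    for dk, acs in bonds.items():
        for ak in acs:
            for a in (dk, nb(dk, -1), nb(dk, 1)):
                for b in (ak, nb(ak, -1), nb(ak, 1)):
                    if a is not None and b is not None:
                        candidate_pairs.add((a, b))
    for i_key, j_key in candidate_pairs:
        cid_i, i = index_of[i_key]
        cid_j, j = index_of[j_key]
        if cid_i == cid_j and abs(i - j) < 3:
            continue
        parallel = (hb(j_key, nb(i_key, -1)) and hb(nb(i_key, 1), j_key)) or (
            hb(i_key, nb(j_key, -1)) and hb(nb(j_key, 1), i_key)
        )
        antiparallel = (hb(j_key, i_key) and hb(i_key, j_key)) or (
            hb(nb(j_key, 1), nb(i_key, -1)) and hb(nb(i_key, 1), nb(j_key, -1))
        )
        if parallel or antiparallel:
            bridge_partners.add(i_key)
            bridge_partners.add(j_key)
    for k in bridge_partners:
        if states[k] == "C":  # helix wins ties
            states[k] = "E"

    assignment.states = states
    return assignment
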