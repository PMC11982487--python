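"""Side-chain grafting with ideal templates and a hard-sphere clash count.

A mutation is modelled by keeping the residue's backbone fixed, placing
the target residue's ideal side-chain geometry (Chemical Component
Dictionary templates, via biotite) onto that backbone, and scanning a
small rotamer grid of chi torsions. The rotamer with the fewest
hard-sphere clashes against the rest of the model wins. No energies,
no minimization: the screen only needs a steric feasibility signal and
mutant coordinates good enough for a voxel-grid volume estimate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .chem import DEFAULT_TABLE, AminoAcidTable
from .geometry import dihedral
from .structure import Atom, Residue, StructureModel

log = logging.getLogger(__name__)

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# Heavy-atom chi torsion definitions (standard conventions).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

AROMATIC_CHI2 = {"PHE", "TYR", "TRP", "HIS"}


class GraftError(ValueError):
    """Backbone incomplete or target residue cannot be templated."""


@dataclass(frozen=True)
class GraftResult:
    model: StructureModel
    residue: Residue
    chis: tuple[float, ...]
    clash_count: int
    feasible: bool


@lru_cache(maxsize=32)
def _template(name3: str):
    """Ideal heavy-atom template for a residue type.

    Returns (names, elements, coords (n,3), rotating_sets) where
    rotating_sets[k] is the index set moved by chi_{k+1}.
    """
    import biotite.structure.info as binfo

    try:
        arr = binfo.residue(name3)
    except KeyError as exc:
        raise GraftError(f"no template for residue type {name3}") from exc
    if arr is None or arr.bonds is None:
        raise GraftError(f"no template geometry for {name3}")
    heavy = np.flatnonzero((arr.element != "H") & (arr.atom_name != "OXT"))
    names = [str(arr.atom_name[i]) for i in heavy]
    elements = [str(arr.element[i]) for i in heavy]
    coords = np.asarray(arr.coord[heavy], dtype=float)
    idx_of = {n: k for k, n in enumerate(names)}

    # adjacency among kept heavy atoms
    adj: dict[int, set[int]] = {k: set() for k in range(len(names))}
    full_index = {int(i): k for k, i in enumerate(heavy)}
    for a, b, _ in arr.bonds.as_array():
        if int(a) in full_index and int(b) in full_index:
            ka, kb = full_index[int(a)], full_index[int(b)]
            adj[ka].add(kb)
            adj[kb].add(ka)

    rotating_sets: list[frozenset[int]] = []
    for (_, b, c, _) in CHI_ATOMS.get(name3, []):
        kb, kc = idx_of[b], idx_of[c]
        # component containing c when the b-c bond is removed
        seen = {kb, kc}
        stack = [kc]
        comp = set()
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    stack.append(nb)
        rotating_sets.append(frozenset(comp))
    return names, elements, coords, rotating_sets


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t with R@mobile + t ~ target (least squares)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


def _rotate_about_axis(
    coords: np.ndarray, idx: list[int], p0: np.ndarray, p1: np.ndarray, angle_deg: float
) -> None:
    axis = p1 - p0
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    k = axis
    pts = coords[idx] - p0
    coords[idx] = (
        pts * np.cos(theta)
        + np.cross(k, pts) * np.sin(theta)
        + np.outer(pts @ k, k) * (1 - np.cos(theta))
    ) + p0


def default_chi_grid(name3: str) -> list[tuple[float, ...]]:
    """Small exhaustive rotamer grid: staggered chi1, common chi2/chi3 values."""
    n_chi = len(CHI_ATOMS.get(name3, []))
    if n_chi == 0:
        return [()]
    axes: list[tuple[float, ...]] = [(-60.0, 60.0, 180.0)]
    if n_chi >= 2:
        axes.append((-90.0, 90.0) if name3 in AROMATIC_CHI2 else (-60.0, 60.0, 180.0))
    if n_chi >= 3:
        axes.append((-60.0, 60.0, 180.0))
    # chis beyond 3 held at 180 (extended)
    grid = [tuple(c) + (180.0,) * (n_chi - len(axes)) for c in itertools.product(*axes)]
    return grid


def build_sidechain_coords(
    residue: Residue, target_aa: str, chis: tuple[float, ...] = ()
) -> tuple[list[str], list[str], np.ndarray]:
    """Ideal side-chain heavy atoms (CB outward) placed on the residue backbone.

    The template is superimposed on the residue's N/CA/C atoms; chi
    torsions are then set to the requested values.
    """
    n, ca, c = residue.atom("N"), residue.atom("CA"), residue.atom("C")
    if n is None or ca is None or c is None:
        raise GraftError(f"{residue.label}: backbone N/CA/C incomplete")
    names, elements, tcoords, rotating = _template(target_aa)
    idx_of = {nm: k for k, nm in enumerate(names)}
    mobile = np.array([tcoords[idx_of["N"]], tcoords[idx_of["CA"]], tcoords[idx_of["C"]]])
    target = np.array([n.position, ca.position, c.position])
    r, t = _kabsch(mobile, target)
    coords = tcoords @ r.T + t

    chi_defs = CHI_ATOMS.get(target_aa, [])
    for k, chi in enumerate(chis[: len(chi_defs)]):
        a, b, cc, d = (idx_of[x] for x in chi_defs[k])
        current = dihedral(coords[a], coords[b], coords[cc], coords[d])
        _rotate_about_axis(coords, sorted(rotating[k]), coords[b], coords[cc], chi - current)

    side = [k for k, nm in enumerate(names) if nm not in BACKBONE_NAMES]
    return (
        [names[k] for k in side],
        [elements[k] for k in side],
        coords[side],
    )


def count_clashes(
    sidechain_coords: np.ndarray,
    sidechain_radii: np.ndarray,
    env_tree: cKDTree,
    env_radii: np.ndarray,
    clash_factor: float = 0.7,
) -> int:
    """Hard-sphere clash count: pairs with center distance < factor*(r1+r2)."""
    if len(sidechain_coords) == 0 or env_tree.n == 0:
        return 0
    cutoff = clash_factor * (sidechain_radii.max() + env_radii.max())
    clashes = 0
    for coord, rad in zip(sidechain_coords, sidechain_radii):
        for j in env_tree.query_ball_point(coord, cutoff):
            d = np.linalg.norm(coord - env_tree.data[j])
            if d < clash_factor * (rad + env_radii[j]):
                clashes += 1
    return clashes


def graft_side_chain(
    model: StructureModel,
    residue: Residue,
    target_aa: str,
    chi_grid: list[tuple[float, ...]] | None = None,
    clash_factor: float = 0.7,
    clash_cap: int = 10,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> GraftResult:
    """Mutate one residue to target_aa on a copy of the model.

    Scans the chi grid, keeps the rotamer with the fewest clashes
    (first in grid order on ties), and flags the graft infeasible if
    even the best rotamer exceeds clash_cap clashes. Deterministic.
    """
    if chi_grid is None:
        chi_grid = default_chi_grid(target_aa)

    # environment: every heavy atom except the mutated residue's own
    env: list[Atom] = []
    for res in list(model.residues()) + model.hetero:
        if res.key == residue.key:
            continue
        env.extend(res.heavy_atoms())
    if env:
        env_tree = cKDTree(np.array([a.position for a in env]))
        env_radii = np.array([a.vdw_radius for a in env])
    else:
        env_tree = cKDTree(np.zeros((1, 3)) + 1e6)
        env_radii = np.array([0.0])

    best: tuple[int, int, tuple[float, ...], list[str], list[str], np.ndarray] | None = None
    for gi, chis in enumerate(chi_grid):
        names, elements, coords = build_sidechain_coords(residue, target_aa, chis)
        radii = np.array([table.vdw_radius(e) for e in elements])
        clashes = count_clashes(coords, radii, env_tree, env_radii, clash_factor)
        if best is None or clashes < best[0]:
            best = (clashes, gi, tuple(chis), names, elements, coords)
        if clashes == 0:
            break  # grid order is the tie-break; first zero-clash rotamer wins
    assert best is not None
    clash_count, _, chis, names, elements, coords = best
    feasible = clash_count <= clash_cap
    if not feasible:
        log.warning(
            "%s -> %s: best rotamer has %d clashes (cap %d); flagged infeasible",
            residue.label, target_aa, clash_count, clash_cap,
        )

    mutant = model.copy()
    mres = mutant.find_residue(*residue.key)
    assert mres is not None
    backbone = [a for a in mres.atoms if a.name in BACKBONE_NAMES and not a.is_hydrogen]
    serial = max((a.serial for a in backbone), default=0)
    new_atoms = list(backbone)
    for nm, el, pos in zip(names, elements, coords):
        serial += 1
        new_atoms.append(
            Atom(serial, nm, el, pos, occupancy=1.0, vdw_radius=table.vdw_radius(el))
        )
    mres.atoms = new_atoms
    mres.name3 = target_aa
    mres.is_hydrophobic = table.is_hydrophobic(target_aa)
    mres.sidechain_volume = table.volume(target_aa)
    return GraftResult(mutant, mres, chis, clash_count, feasible)
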