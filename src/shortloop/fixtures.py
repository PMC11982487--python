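"""Synthetic structures with known ground truth.

Every stage of the screen is testable without downloading real
structures: an ideal alpha-helix exercises secondary-structure
assignment, a helix-loop-helix peptide exercises loop segmentation and
hydrophobic runs, a hollow pseudo-atom shell encloses a void of
analytically known probe-accessible volume for the cavity detector, and
the cavity-pocket fixture combines a short loop, hydrophobic
neighbours, a small central residue and an adjacent engineered cavity
so the full sensitive-residue screen fires end to end.

Fixtures are geometric test objects, not physical protein decoys; all
generation is deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .chem import DEFAULT_TABLE, ONE_TO_THREE, AminoAcidTable
from .geometry import fibonacci_sphere, place_atom
from .sidechains import build_sidechain_coords, default_chi_grid
from .structure import Atom, Residue, StructureModel

# ideal peptide geometry, Angstrom / degrees
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
HELIX_PHI, HELIX_PSI = -57.0, -47.0

# fixed "random-coil" torsion cycle used for designed loop linkers
COIL_TORSIONS = [(-120.0, 135.0), (-140.0, 155.0), (-110.0, 140.0),
                 (-130.0, 125.0), (-100.0, 145.0)]
COIL_ENTRY_PSI = 150.0


def _build_peptide(
    sequence: str,
    torsions: list[tuple[float, float]],
    chain_id: str = "A",
    identifier: str = "peptide",
    table: AminoAcidTable = DEFAULT_TABLE,
    start_number: int = 1,
) -> StructureModel:
    """Backbone from (phi, psi) per residue (omega fixed 180), ideal bonds.

    Side chains beyond CB are placed from ideal templates with a fixed
    g- chi1 / extended higher-chi rotamer.
    """
    n = len(sequence)
    assert len(torsions) == n
    ncap = np.zeros((n, 3))
    cacap = np.zeros((n, 3))
    ccap = np.zeros((n, 3))
    ncap[0] = (0.0, 0.0, 0.0)
    cacap[0] = (B_N_CA, 0.0, 0.0)
    a = np.radians(180.0 - A_N_CA_C)
    ccap[0] = cacap[0] + B_CA_C * np.array([np.cos(a), np.sin(a), 0.0])
    for i in range(1, n):
        psi_prev = torsions[i - 1][1]
        ncap[i] = place_atom(ncap[i - 1], cacap[i - 1], ccap[i - 1], B_C_N, A_CA_C_N, psi_prev)
        cacap[i] = place_atom(cacap[i - 1], ccap[i - 1], ncap[i], B_N_CA, A_C_N_CA, 180.0)
        ccap[i] = place_atom(ccap[i - 1], ncap[i], cacap[i], B_CA_C, A_N_CA_C, torsions[i][0])

    model = StructureModel(identifier=identifier)
    residues: list[Residue] = []
    serial = 0
    for i, one in enumerate(sequence):
        name3 = ONE_TO_THREE[one.upper()]
        res = Residue(chain_id, start_number + i, "", name3)
        o_pos = place_atom(ncap[i], cacap[i], ccap[i], B_C_O, A_CA_C_O, torsions[i][1] + 180.0)
        for nm, el, pos in (
            ("N", "N", ncap[i]), ("CA", "C", cacap[i]), ("C", "C", ccap[i]), ("O", "O", o_pos)
        ):
            serial += 1
            res.atoms.append(Atom(serial, nm, el, pos, vdw_radius=table.vdw_radius(el)))
        if name3 != "GLY":
            chis = tuple(-60.0 if k == 0 else 180.0
                         for k in range(len(default_chi_grid(name3)[0])))
            names, elements, coords = build_sidechain_coords(res, name3, chis)
            for nm, el, pos in zip(names, elements, coords):
                serial += 1
                res.atoms.append(Atom(serial, nm, el, pos, vdw_radius=table.vdw_radius(el)))
        res.is_hydrophobic = table.is_hydrophobic(name3)
        res.sidechain_volume = table.volume(name3)
        residues.append(res)
    model.chains[chain_id] = residues
    return model


def make_ideal_helix(
    n_residues: int,
    sequence: str | None = None,
    identifier: str = "ideal_helix",
) -> StructureModel:
    """Ideal alpha-helix (phi -57, psi -47, omega 180), poly-Ala by default."""
    if n_residues < 4:
        raise ValueError("helix needs at least 4 residues")
    seq = sequence if sequence is not None else "A" * n_residues
    if len(seq) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    torsions = [(HELIX_PHI, HELIX_PSI)] * n_residues
    return _build_peptide(seq, torsions, identifier=identifier)


def make_extended_chain(n_residues: int, sequence: str | None = None) -> StructureModel:
    """Fully extended single strand (no bridge partner, so assigned coil)."""
    seq = sequence if sequence is not None else "A" * n_residues
    torsions = [(-135.0, 135.0)] * n_residues
    return _build_peptide(seq, torsions, identifier="extended_chain")


def make_helix_loop_helix(
    helix_len: int = 12,
    loop_sequence: str = "NVPAYS",
    loop_torsions: list[tuple[float, float]] | None = None,
    identifier: str = "helix_loop_helix",
    helix_char: str = "A",
) -> StructureModel:
    """Two ideal helices joined by a designed coil linker.

    The torsion pattern is arranged so the coil state run produced by
    the assigner coincides exactly with the designed loop residues: the
    psi of the last left-helix residue and the phi of the last loop
    residue take coil values, which breaks the helical hydrogen-bond
    chain precisely at the designed boundaries.
    """
    loop_len = len(loop_sequence)
    if not 1 <= loop_len <= 15:
        raise ValueError("loop length must be 1-15")
    if loop_torsions is not None and len(loop_torsions) != loop_len:
        raise ValueError(f"need {loop_len} (phi, psi) pairs")
    if loop_torsions is None:
        loop_torsions = [COIL_TORSIONS[i % len(COIL_TORSIONS)] for i in range(loop_len)]

    seq = helix_char * helix_len + loop_sequence + helix_char * helix_len
    torsions = [(HELIX_PHI, HELIX_PSI)] * len(seq)
    s = helix_len  # first designed loop index
    if loop_len >= 3:
        # First loop residue keeps a helical phi but a coil psi: that breaks
        # the last incoming 4-turn, so helix states stop at residue s-1.
        # The last loop residue takes a coil phi but a helical psi, so the
        # outgoing turn ladder restarts at the first right-helix residue.
        torsions[s] = (HELIX_PHI, loop_torsions[0][1])
        for k in range(1, loop_len - 1):
            torsions[s + k] = loop_torsions[k]
        torsions[s + loop_len - 1] = (loop_torsions[-1][0], HELIX_PSI)
    else:
        for k in range(loop_len):
            torsions[s + k] = loop_torsions[k]
    return _build_peptide(seq, torsions, identifier=identifier)


def _shell_points(center: np.ndarray, radius: float, gap_max: float,
                  vdw: float = 1.70) -> np.ndarray:
    """Fibonacci-lattice pseudo-atom centers on a sphere.

    gap_max is the largest allowed surface-to-surface distance between
    neighbouring atoms; the point count is chosen so that even the
    holes between atom triples are too narrow for the water probe.
    """
    spacing = gap_max + 2.0 * vdw
    n = max(8, int(np.ceil(4.0 * np.pi * radius**2 / (0.5 * np.sqrt(3.0) * spacing**2))))
    # Densify until the largest hole clearance sits a full 1.0 A below the
    # water-probe reach (vdw + 1.4 A). The margin keeps the occupied slab
    # around the shell surface thicker than a voxel step on any practical
    # grid, so discretized paths cannot slip through pinholes; Fibonacci
    # lattices are not perfectly hexagonal, so the area-based estimate
    # alone is not enough.
    target = vdw + 1.4 - 1.0
    probe_surface = fibonacci_sphere(20000)
    for _ in range(20):
        points = center + radius * fibonacci_sphere(n)
        tree = cKDTree(points)
        dmin, _ = tree.query(center + radius * probe_surface, k=1)
        if dmin.max() <= target:
            return points
        n = int(n * 1.25) + 1
    raise ValueError("could not seal shell within iteration budget")


def _check_shell_sealed(points: np.ndarray, center: np.ndarray, radius: float,
                        probe: float = 1.4, vdw: float = 1.70) -> None:
    """Every point of the shell sphere must be overlapped by some atom's
    probe-inflated sphere, else the probe could slip through a hole."""
    surface = center + radius * fibonacci_sphere(20000)
    tree = cKDTree(points)
    dmin, _ = tree.query(surface, k=1)
    if dmin.max() >= vdw + probe:
        raise ValueError(
            f"shell has holes of clearance {dmin.max():.2f} A >= {vdw + probe:.2f} A; "
            "reduce gap_max"
        )


def _pseudo_residues(
    points: np.ndarray, chain_id: str, table: AminoAcidTable, start_serial: int = 10000
) -> list[Residue]:
    residues = []
    for i, pos in enumerate(points):
        res = Residue(chain_id, i + 1, "", "GLY")
        res.atoms.append(
            Atom(start_serial + i, "CA", "C", pos, vdw_radius=table.vdw_radius("C"))
        )
        res.is_hydrophobic = table.is_hydrophobic("GLY")
        res.sidechain_volume = table.volume("GLY")
        residues.append(res)
    return residues


def make_hollow_shell(
    inner_radius: float,
    gap_max: float = 1.5,
    aperture_deg: float | None = None,
    center: np.ndarray | None = None,
    identifier: str = "hollow_shell",
    table: AminoAcidTable = DEFAULT_TABLE,
) -> StructureModel:
    """Pseudo-atom sphere shell enclosing a void of known volume.

    Carbon-typed single-atom glycine 'residues' sit on a sphere of
    radius inner_radius + vdw(C), so the inner van der Waals surface is
    at inner_radius and the water-probe-accessible void is a ball of
    radius about inner_radius - probe_in. With aperture_deg set, atoms
    within that polar angle of +z are removed, opening the void to bulk
    solvent (a negative control: no cavity should be reported).
    """
    if inner_radius < 3.0:
        raise ValueError("inner_radius must be >= 3 A")
    if not 0 < gap_max < 2.8:
        raise ValueError("gap_max must be in (0, 2.8) A: twice the water probe radius")
    vdw = table.vdw_radius("C")
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    radius = inner_radius + vdw
    points = _shell_points(c, radius, gap_max, vdw)
    if aperture_deg is not None:
        axis = np.array([0.0, 0.0, 1.0])
        cosang = (points - c) @ axis / radius
        points = points[cosang < np.cos(np.radians(aperture_deg))]
    else:
        _check_shell_sealed(points, c, radius, vdw=vdw)
    model = StructureModel(identifier=identifier)
    model.chains["X"] = _pseudo_residues(points, "X", table)
    return model


def shell_probe_accessible_volume_mc(
    model: StructureModel,
    center: np.ndarray,
    outer_radius: float,
    probe: float = 1.4,
    n_points: int = 1_000_000,
    seed: int = 20240901,
) -> float:
    """Monte-Carlo oracle for the probe-accessible interior of a shell.

    Samples points uniformly in the cube circumscribing the shell and
    counts those inside the shell sphere and at least (vdw + probe)
    from every atom. Independent of the voxel-grid path.
    """
    coords, radii, _ = model.heavy_atom_arrays()
    tree = cKDTree(coords)
    rng = np.random.default_rng(seed)
    half = outer_radius
    pts = center + rng.uniform(-half, half, size=(n_points, 3))
    inside = np.linalg.norm(pts - center, axis=1) <= outer_radius
    pts = pts[inside]
    dmin, idx = tree.query(pts, k=1)
    free = dmin >= radii[idx] + probe
    frac = free.sum() / n_points
    return float(frac * (2 * half) ** 3)


def make_cavity_pocket(
    helix_len: int = 12,
    loop_sequence: str = "SVAVS",
    inner_radius: float = 5.0,
    hole_radius: float = 4.8,
    plug_offset: float = 0.8,
    identifier: str = "cavity_pocket",
    table: AminoAcidTable = DEFAULT_TABLE,
) -> StructureModel:
    """Helix-loop-helix with an engineered buried cavity at the loop centre.

    Serine helices flank the loop, so the centre residue (Ala in the
    default SVAVS sequence) is the only position with hydrophobic
    sequence neighbours on both sides. A sealed pseudo-atom shell with
    a wide mouth sits directly against that residue: the residue's own
    beta carbon plugs the mouth, so the water probe cannot slip in or
    out, yet a large hydrophobic side chain grafted at the position
    grows straight through the mouth into the void. The mouth is aimed
    along the tip of the first TRP rotamer of the default chi grid --
    the rotamer the graft scan visits first -- so the screen finds
    exactly one sensitive residue with a zero-clash, cavity-filling
    proposal by construction.
    """
    model = make_helix_loop_helix(
        helix_len, loop_sequence, identifier=identifier, helix_char="S"
    )
    chain = model.chains["A"]
    centre_res = chain[helix_len + len(loop_sequence) // 2]
    cb = centre_res.atom("CB")
    if cb is None:
        raise ValueError("pocket centre residue needs CB")

    aim_chis = default_chi_grid("TRP")[0]
    _, _, coords = build_sidechain_coords(centre_res, "TRP", aim_chis)
    tip = coords[np.argmax(np.linalg.norm(coords - cb.position, axis=1))]
    u = (tip - cb.position) / np.linalg.norm(tip - cb.position)

    vdw = table.vdw_radius("C")
    shell_radius = inner_radius + vdw
    if not hole_radius < shell_radius:
        raise ValueError("hole_radius must be smaller than the shell radius")
    # mouth plane sits plug_offset inside the residue's CB position
    axial = np.sqrt(shell_radius**2 - hole_radius**2)
    centre = cb.position + (axial + plug_offset) * u
    points = _shell_points(centre, shell_radius, gap_max=1.5, vdw=vdw)
    to_res = -u
    cosang = (points - centre) @ to_res / shell_radius
    theta_ring = np.arcsin(min(0.999, hole_radius / shell_radius))
    cut = np.degrees(theta_ring) + 6.0
    points = points[cosang < np.cos(np.radians(cut))]
    # explicit ring of atoms defining the mouth edge
    e1 = np.cross(to_res, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(to_res, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(to_res, e1)
    n_ring = max(8, int(np.ceil(2 * np.pi * hole_radius / 2.0)))
    ring = [
        centre
        + shell_radius * np.cos(theta_ring) * to_res
        + shell_radius * np.sin(theta_ring)
        * (np.cos(2 * np.pi * k / n_ring) * e1 + np.sin(2 * np.pi * k / n_ring) * e2)
        for k in range(n_ring)
    ]
    points = np.vstack([points, np.array(ring)])
    model.chains["X"] = _pseudo_residues(points, "X", table)
    return model
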