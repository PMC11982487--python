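"""Internal-cavity detection on a voxel grid with a dual-probe method.

The method follows the grid-and-dual-probe family of cavity detectors:
a small (water-sized) probe defines the space accessible to solvent
molecules, a large probe defines bulk solvent. Grid voxels that the
small probe can occupy but that the large probe cannot reach from the
box boundary are cavity voxels; 6-connected components of them are the
cavities, with volume = voxel count x spacing^3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .structure import Residue, StructureModel

log = logging.getLogger(__name__)


class ResolutionError(ValueError):
    """Grid would exceed the voxel budget; increase spacing."""


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid parameters.

    spacing 0.6 A, probe_in 1.4 A (water) and probe_out 4.0 A mirror
    the defaults of the dual-probe grid tools commonly used for this
    job; padding must exceed probe_out so bulk solvent surrounds the
    molecule inside the box.
    """

    spacing: float = 0.6
    probe_in: float = 1.4
    probe_out: float = 4.0
    padding: float | None = None
    voxel_budget: int = 400_000_000

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if not (self.probe_out > self.probe_in > 0):
            raise ValueError("need probe_out > probe_in > 0")

    @property
    def pad(self) -> float:
        return self.padding if self.padding is not None else self.probe_out + 2 * self.spacing


@dataclass
class Grid:
    origin: np.ndarray
    shape: tuple[int, int, int]
    spacing: float

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(indices, dtype=float) + 0.5) * self.spacing


@dataclass
class Cavity:
    id: int
    voxels: np.ndarray  # (n, 3) integer grid indices
    centers: np.ndarray  # (n, 3) voxel centers, A (real space)
    volume: float  # A^3
    centroid: np.ndarray  # (3,) A
    lining_residues: set[tuple[str, int, str]] = field(default_factory=set)
    lining_labels: list[str] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def _make_grid(coords: np.ndarray, radii: np.ndarray, grid: GridSpec) -> Grid:
    lo = (coords - radii[:, None]).min(axis=0) - grid.pad
    hi = (coords + radii[:, None]).max(axis=0) + grid.pad
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / grid.spacing)) + 1 for k in range(3))
    n = shape[0] * shape[1] * shape[2]
    if n > grid.voxel_budget:
        raise ResolutionError(
            f"grid of {n} voxels exceeds budget {grid.voxel_budget}; "
            f"increase spacing (currently {grid.spacing} A)"
        )
    return Grid(lo, shape, grid.spacing)


def _occupancy(coords: np.ndarray, radii: np.ndarray, g: Grid, probe: float) -> np.ndarray:
    """Boolean mask: voxel center within (vdw + probe) of any atom."""
    occ = np.zeros(g.shape, dtype=bool)
    s = g.spacing
    nx, ny, nz = g.shape
    for pos, rad in zip(coords, radii):
        r = rad + probe
        cmin = np.maximum(np.floor((pos - r - g.origin) / s - 0.5).astype(int), 0)
        cmax = np.minimum(
            np.ceil((pos + r - g.origin) / s - 0.5).astype(int), np.array([nx, ny, nz]) - 1
        )
        if np.any(cmin > cmax):
            continue
        ax = (np.arange(cmin[0], cmax[0] + 1) + 0.5) * s + g.origin[0] - pos[0]
        ay = (np.arange(cmin[1], cmax[1] + 1) + 0.5) * s + g.origin[1] - pos[1]
        az = (np.arange(cmin[2], cmax[2] + 1) + 0.5) * s + g.origin[2] - pos[2]
        d2 = ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
        ball = d2 < r * r
        occ[cmin[0] : cmax[0] + 1, cmin[1] : cmax[1] + 1, cmin[2] : cmax[2] + 1] |= ball
    return occ


def voxelize(
    model: StructureModel,
    grid: GridSpec,
    probe: float,
    include_hetero: bool = False,
) -> tuple[np.ndarray, Grid]:
    """Probe-inflated van der Waals occupancy mask for a model."""
    coords, radii, _ = model.heavy_atom_arrays(include_hetero=include_hetero)
    if len(coords) == 0:
        raise ValueError("model has no heavy atoms")
    g = _make_grid(coords, radii, grid)
    return _occupancy(coords, radii, g, probe), g


_FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)  # 6-neighbourhood


def _boundary_connected(free: np.ndarray) -> np.ndarray:
    """Subset of a free-space mask reachable from the box boundary."""
    labels, n = ndimage.label(free, structure=_FACE_CONNECTIVITY)
    if n == 0:
        return np.zeros_like(free)
    boundary_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            boundary_labels.update(np.unique(face[face > 0]).tolist())
    if not boundary_labels:
        return np.zeros_like(free)
    return np.isin(labels, sorted(boundary_labels))


def detect_cavities(
    model: StructureModel,
    grid: GridSpec = GridSpec(),
    min_volume: float = 5.0,
    contact_distance: float = 5.0,
    include_hetero: bool = False,
) -> list[Cavity]:
    """Detect internal cavities and their lining residues.

    Pipeline: occupancy masks for both probes; bulk solvent = the
    large-probe-free region connected to the box boundary, swept by the
    large probe radius; cavities = small-probe-free voxels outside the
    swept region, split into 6-connected components, filtered by
    min_volume. Components whose lining would be empty (no residue
    within contact_distance) are suppressed. Deterministic; cavities
    are ordered by decreasing volume.
    """
    coords, radii, refs = model.heavy_atom_arrays(include_hetero=include_hetero)
    if len(coords) == 0:
        return []
    g = _make_grid(coords, radii, grid)
    occ_in = _occupancy(coords, radii, g, grid.probe_in)
    occ_out = _occupancy(coords, radii, g, grid.probe_out)

    bulk_seed = _boundary_connected(~occ_out)
    # sweep: every point within probe_out of an allowed large-probe center
    if bulk_seed.any():
        dist = ndimage.distance_transform_edt(
            ~bulk_seed, sampling=(grid.spacing,) * 3
        )
        swept = dist <= grid.probe_out + 1e-9
    else:
        swept = np.zeros_like(bulk_seed)

    cavity_mask = ~occ_in & ~swept
    labels, n = ndimage.label(cavity_mask, structure=_FACE_CONNECTIVITY)
    cavities: list[Cavity] = []
    voxel_vol = grid.spacing**3
    for comp in range(1, n + 1):
        idx = np.argwhere(labels == comp)
        volume = len(idx) * voxel_vol
        if volume < min_volume:
            continue
        centers = g.voxel_centers(idx)
        lining = lining_residues(centers, model, contact_distance, include_hetero)
        if not lining:
            log.warning(
                "cavity of %.1f A^3 has no residue within %.1f A; suppressed",
                volume, contact_distance,
            )
            continue
        cavities.append(
            Cavity(
                id=0,
                voxels=idx,
                centers=centers,
                volume=volume,
                centroid=centers.mean(axis=0),
                lining_residues={r.key for r in lining},
                lining_labels=sorted(r.label for r in lining),
            )
        )
    cavities.sort(key=lambda c: (-c.volume, tuple(np.round(c.centroid, 3))))
    for i, cav in enumerate(cavities):
        cav.id = i + 1
    return cavities


def lining_residues(
    voxel_centers: np.ndarray,
    model: StructureModel,
    contact_distance: float = 5.0,
    include_hetero: bool = False,
) -> list[Residue]:
    """Residues with any heavy atom within contact_distance of a cavity voxel."""
    from scipy.spatial import cKDTree

    coords, _, refs = model.heavy_atom_arrays(include_hetero=include_hetero)
    if len(coords) == 0 or len(voxel_centers) == 0:
        return []
    tree = cKDTree(voxel_centers)
    dmin, _ = tree.query(coords, k=1)
    out: dict[tuple, Residue] = {}
    for (res, _atom), d in zip(refs, dmin):
        if d <= contact_distance and res.key not in out:
            out[res.key] = res
    return list(out.values())


def total_cavity_volume(cavities: list[Cavity]) -> float:
    return float(sum(c.volume for c in cavities))


def cavities_near(
    cavities: list[Cavity],
    reference: Cavity,
    grid: GridSpec,
) -> list[Cavity]:
    """Cavities intersecting the reference's bounding box dilated by probe_in.

    Used to re-measure 'the same' cavity after a mutation, where filling
    may have shrunk, split, or shifted it; works across grids because
    voxel centers are compared in real space.
    """
    if len(reference.centers) == 0:
        return []
    pad = grid.probe_in
    lo = reference.centers.min(axis=0) - pad
    hi = reference.centers.max(axis=0) + pad
    out = []
    for cav in cavities:
        inside = np.all((cav.centers >= lo) & (cav.centers <= hi), axis=1)
        if inside.any():
            out.append(cav)
    return out
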