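"""Sensitive-residue identification and cavity-filling mutation proposals.

A sensitive residue is a small-side-chain position inside a retained
short loop, with hydrophobic residues on both sequence sides, lining an
internal cavity of meaningful size. Such positions are rigid (short
loop, hydrophobic context) yet destabilizing (they leave a void), so
flexibility-based screens miss them. The proposed fix is mutation to a
large hydrophobic residue (Phe/Tyr/Trp/Met by default) that fills the
cavity; each proposal carries a hard-sphere rotamer graft, its clash
count, and a voxel-grid re-estimate of the residual cavity volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cavities import Cavity, GridSpec, cavities_near, detect_cavities
from .chem import DEFAULT_TABLE, LARGE_HYDROPHOBIC_TARGETS, AminoAcidTable
from .loops import HydrophobicRun, LoopSegment
from .sidechains import GraftResult, graft_side_chain
from .structure import Residue, StructureModel

log = logging.getLogger(__name__)


@dataclass
class SensitiveResidue:
    residue: Residue
    loop: LoopSegment
    cavity: Cavity
    cavity_volume: float  # A^3
    left_hydrophobic: bool
    right_hydrophobic: bool
    sidechain_volume: float  # A^3
    rank_score: float  # cavity_volume / sidechain_volume, dimensionless

    @property
    def label(self) -> str:
        return self.residue.label


@dataclass
class MutationProposal:
    sensitive: SensitiveResidue
    target_aa: str
    chis: tuple[float, ...]
    clash_count: int
    feasible: bool
    mutant_cavity_volume: float  # A^3
    delta_volume: float  # wild-type minus mutant, A^3
    external_ddg: float | None = None  # kcal/mol, annotation only
    mutant_model: StructureModel | None = field(default=None, repr=False)

    @property
    def name(self) -> str:
        wt = self.sensitive.residue.one_letter
        num = self.sensitive.residue.seq_number
        from .chem import THREE_TO_ONE

        return f"{wt}{num}{THREE_TO_ONE[self.target_aa]}"


def _sequence_neighbors(
    model: StructureModel, residue: Residue
) -> tuple[Residue | None, Residue | None]:
    chain = model.chains[residue.chain_id]
    idx = next(i for i, r in enumerate(chain) if r.key == residue.key)
    left = chain[idx - 1] if idx > 0 else None
    right = chain[idx + 1] if idx + 1 < len(chain) else None
    return left, right


def candidate_sensitive_residues(
    model: StructureModel,
    short_loops: list[LoopSegment],
    runs: dict[str, list[HydrophobicRun]],
    cavities: list[Cavity],
    max_sidechain_volume: float = 140.0,
    min_cavity_volume: float = 100.0,
    table: AminoAcidTable = DEFAULT_TABLE,
) -> list[SensitiveResidue]:
    """Flag sensitive residues.

    Criteria: (a) member of a retained short loop; (b) hydrophobic
    immediate sequence neighbours on both sides; (c) own side-chain
    volume at most max_sidechain_volume; (d) in the lining of a cavity
    of at least min_cavity_volume. Results are ranked by
    cavity_volume / sidechain_volume, descending (large void behind a
    small residue first).
    """
    big_cavities = [c for c in cavities if c.volume >= min_cavity_volume]
    out: list[SensitiveResidue] = []
    for loop in short_loops:
        for res in loop.residues:
            if res.sidechain_volume > max_sidechain_volume:
                continue
            left, right = _sequence_neighbors(model, res)
            lh = left is not None and table.is_hydrophobic(left.name3)
            rh = right is not None and table.is_hydrophobic(right.name3)
            if not (lh and rh):
                continue
            lined = [c for c in big_cavities if res.key in c.lining_residues]
            if not lined:
                continue
            cavity = max(lined, key=lambda c: c.volume)
            out.append(
                SensitiveResidue(
                    residue=res,
                    loop=loop,
                    cavity=cavity,
                    cavity_volume=cavity.volume,
                    left_hydrophobic=lh,
                    right_hydrophobic=rh,
                    sidechain_volume=res.sidechain_volume,
                    rank_score=cavity.volume / res.sidechain_volume,
                )
            )
    out.sort(key=lambda s: -s.rank_score)
    return out


def estimate_mutant_cavity(
    mutant: StructureModel,
    original_cavity: Cavity,
    grid: GridSpec,
    min_volume: float = 5.0,
    contact_distance: float = 5.0,
) -> float:
    """Residual volume of the original cavity after a mutation.

    Re-runs cavity detection on the mutated model and sums the volumes
    of cavities intersecting the original cavity's probe_in-dilated
    bounding region; 0 if the cavity is gone.
    """
    mut_cavities = detect_cavities(
        mutant, grid, min_volume=min_volume, contact_distance=contact_distance
    )
    near = cavities_near(mut_cavities, original_cavity, grid)
    return float(sum(c.volume for c in near))


def propose_mutations(
    model: StructureModel,
    sr: SensitiveResidue,
    grid: GridSpec = GridSpec(),
    targets: tuple[str, ...] = LARGE_HYDROPHOBIC_TARGETS,
    clash_factor: float = 0.7,
    clash_cap: int = 10,
    table: AminoAcidTable = DEFAULT_TABLE,
    keep_models: bool = True,
) -> list[MutationProposal]:
    """One proposal per target strictly larger than the wild-type side chain.

    Each proposal grafts the best rotamer, counts clashes, and
    re-measures the cavity on the mutant. Sorted by (clash_count,
    mutant_cavity_volume) ascending, so the cleanest, most-filling
    mutation comes first. Deterministic.
    """
    wt_vol = sr.sidechain_volume
    proposals: list[MutationProposal] = []
    for target in targets:
        if not table.is_hydrophobic(target):
            raise ValueError(f"target {target} is not in the hydrophobic table")
        if target == sr.residue.name3:
            log.info("%s: wild type already %s; skipped", sr.label, target)
            continue
        if table.volume(target) <= wt_vol:
            continue
        graft: GraftResult = graft_side_chain(
            model, sr.residue, target,
            clash_factor=clash_factor, clash_cap=clash_cap, table=table,
        )
        mut_vol = estimate_mutant_cavity(graft.model, sr.cavity, grid)
        proposals.append(
            MutationProposal(
                sensitive=sr,
                target_aa=target,
                chis=graft.chis,
                clash_count=graft.clash_count,
                feasible=graft.feasible,
                mutant_cavity_volume=mut_vol,
                delta_volume=sr.cavity_volume - mut_vol,
                mutant_model=graft.model if keep_models else None,
            )
        )
    proposals.sort(key=lambda p: (p.clash_count, p.mutant_cavity_volume))
    return proposals


def annotate_ddg(
    proposals: list[MutationProposal], ddg_table_path: str
) -> list[MutationProposal]:
    """Join externally computed stability scores onto proposals.

    Expects a TSV with columns chain, resnum, wt_aa, mut_aa,
    ddg_kcal_mol, using the convention ddG = dG(mutant) - dG(wild-type):
    negative values indicate predicted stabilization. The values are
    annotations from an external engine, never computed here.
    """
    df = pd.read_csv(ddg_table_path, sep="\t", dtype={"chain": str})
    required = {"chain", "resnum", "wt_aa", "mut_aa", "ddg_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ddG table missing columns: {sorted(missing)}")
    lookup = {
        (str(r.chain), int(r.resnum), str(r.wt_aa).upper(), str(r.mut_aa).upper()):
        float(r.ddg_kcal_mol)
        for r in df.itertuples()
    }
    from .chem import THREE_TO_ONE

    for p in proposals:
        res = p.sensitive.residue
        key = (
            res.chain_id,
            res.seq_number,
            res.one_letter,
            THREE_TO_ONE[p.target_aa],
        )
        if key in lookup:
            p.external_ddg = lookup[key]
    return proposals
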