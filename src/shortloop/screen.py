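"""Orchestration of the full short-loop screen.

run_screen executes the stage chain parse -> secondary structure ->
loops -> hydrophobic runs -> cavities -> sensitive residues ->
mutation proposals on one structure and packages everything into a
serializable report; batch_screen maps it over a directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cavities import Cavity, detect_cavities
from .config import ScreenConfig
from .design import (
    MutationProposal,
    SensitiveResidue,
    annotate_ddg,
    candidate_sensitive_residues,
    propose_mutations,
)
from .loops import HydrophobicRun, LoopSegment, annotate_hydrophobic_runs, find_short_loops, segment_loops
from .secondary import SSAssignment, assign_secondary_structure
from .structure import StructureModel, parse_pdb

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class BatchError(RuntimeError):
    pass


@dataclass
class ScreenResult:
    """Live objects produced by one screen run (report + references)."""

    model: StructureModel
    ss: SSAssignment
    loops: list[LoopSegment]
    short_loops: list[LoopSegment]
    runs: dict[str, list[HydrophobicRun]]
    cavities: list[Cavity]
    sensitive: list[SensitiveResidue]
    proposals: dict[str, list[MutationProposal]]
    config: ScreenConfig
    timings: dict[str, float] = field(default_factory=dict)

    def report(self, include_timings: bool = True) -> dict:
        """JSON-serializable report; every proposal is traceable to its
        sensitive residue, loop and cavity by label/id."""
        rep = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "tool_version": __version__,
            "identifier": self.model.identifier,
            "source_path": self.model.source_path,
            "config": self.config.to_dict(),
            "n_residues": self.model.n_residues(),
            "secondary_structure": {
                cid: self.ss.chain_string(self.model, cid) for cid in self.model.chains
            },
            "loops": [
                {
                    "label": lp.label,
                    "chain": lp.chain_id,
                    "start": lp.start.seq_number,
                    "end": lp.end.seq_number,
                    "length": lp.length,
                    "sequence": lp.sequence(),
                    "terminal": lp.is_terminal,
                    "left_flank": list(lp.left_flank) if lp.left_flank else None,
                    "right_flank": list(lp.right_flank) if lp.right_flank else None,
                }
                for lp in self.loops
            ],
            "short_loops": [lp.label for lp in self.short_loops],
            "hydrophobic_runs": {
                label: [
                    {
                        "sequence": run.sequence(),
                        "start": run.residues[0].seq_number,
                        "end": run.residues[-1].seq_number,
                    }
                    for run in runs
                ]
                for label, runs in self.runs.items()
            },
            "cavities": [
                {
                    "id": c.id,
                    "volume_A3": round(c.volume, 3),
                    "centroid": [round(float(x), 3) for x in c.centroid],
                    "n_voxels": c.n_voxels,
                    "lining": c.lining_labels,
                }
                for c in self.cavities
            ],
            "sensitive_residues": [
                {
                    "residue": sr.label,
                    "loop": sr.loop.label,
                    "cavity_id": sr.cavity.id,
                    "cavity_volume_A3": round(sr.cavity_volume, 3),
                    "sidechain_volume_A3": round(sr.sidechain_volume, 1),
                    "rank_score": round(sr.rank_score, 4),
                }
                for sr in self.sensitive
            ],
            "proposals": {
                label: [
                    {
                        "mutation": p.name,
                        "target": p.target_aa,
                        "chis_deg": list(p.chis),
                        "clash_count": p.clash_count,
                        "feasible": p.feasible,
                        "mutant_cavity_volume_A3": round(p.mutant_cavity_volume, 3),
                        "delta_volume_A3": round(p.delta_volume, 3),
                        "external_ddg_kcal_mol": p.external_ddg,
                    }
                    for p in props
                ]
                for label, props in self.proposals.items()
            },
        }
        if include_timings:
            rep["timings_s"] = {k: round(v, 3) for k, v in self.timings.items()}
        return rep


def _ss_from_override(model: StructureModel, path: str) -> SSAssignment:
    """Load a precomputed assignment: lines of '<chain_id> <HEC string>'."""
    ss = SSAssignment()
    strings: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cid, _, s = line.partition(" ")
        strings[cid] = s.strip().upper()
    for cid, residues in model.chains.items():
        s = strings.get(cid, "")
        if len(s) != len(residues):
            raise ValueError(
                f"ss override for chain {cid}: {len(s)} states for "
                f"{len(residues)} residues"
            )
        if set(s) - set("HEC"):
            raise ValueError(f"ss override for chain {cid}: alphabet is HEC")
        for res, state in zip(residues, s):
            ss.states[res.key] = state
    return ss


def screen_model(model: StructureModel, config: ScreenConfig | None = None) -> ScreenResult:
    """Run the screen on an already-loaded model."""
    config = config or ScreenConfig()
    table = config.table()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.ss_override:
        ss = _ss_from_override(model, config.ss_override)
    else:
        ss = assign_secondary_structure(model)
    timings["secondary_structure"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    loops = segment_loops(model, ss)
    short = find_short_loops(
        loops,
        min_len=config.loop_min_len,
        max_len=config.loop_max_len,
        require_both_flanks=config.require_both_flanks,
        min_flank_len=config.min_flank_len,
    )
    runs = {
        lp.label: annotate_hydrophobic_runs(model, lp, table, config.flank_extension)
        for lp in short
    }
    timings["loops"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cavities = detect_cavities(
        model,
        config.grid(),
        min_volume=config.min_volume,
        contact_distance=config.contact_distance,
        include_hetero=config.include_hetero,
    )
    timings["cavities"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sensitive = candidate_sensitive_residues(
        model, short, runs, cavities,
        max_sidechain_volume=config.max_sidechain_volume,
        min_cavity_volume=config.min_cavity_volume,
        table=table,
    )
    proposals: dict[str, list[MutationProposal]] = {}
    for sr in sensitive:
        try:
            proposals[sr.label] = propose_mutations(
                model, sr,
                grid=config.grid(),
                targets=tuple(config.targets),
                clash_factor=config.clash_factor,
                clash_cap=config.clash_cap,
                table=table,
            )
        except Exception as exc:  # graft failures leave a partial report
            log.error("proposals for %s failed: %s", sr.label, exc)
            proposals[sr.label] = []
    timings["design"] = time.perf_counter() - t0

    return ScreenResult(
        model=model, ss=ss, loops=loops, short_loops=short, runs=runs,
        cavities=cavities, sensitive=sensitive, proposals=proposals,
        config=config, timings=timings,
    )


def run_screen(
    pdb_path: str,
    config: ScreenConfig | None = None,
    ddg_table: str | None = None,
) -> ScreenResult:
    """Parse a PDB file and run the full screen on it."""
    config = config or ScreenConfig()
    model = parse_pdb(pdb_path, table=config.table(), chain=config.chain)
    result = screen_model(model, config)
    if ddg_table:
        for props in result.proposals.values():
            annotate_ddg(props, ddg_table)
    return result


def summary_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """One row per sensitive residue with its best proposal."""
    rows = []
    for res in results:
        for sr in res.sensitive:
            props = res.proposals.get(sr.label, [])
            best = props[0] if props else None
            rows.append(
                {
                    "model": res.model.identifier,
                    "residue": sr.label,
                    "loop": sr.loop.label,
                    "loop_sequence": sr.loop.sequence(),
                    "cavity_volume_A3": round(sr.cavity_volume, 3),
                    "sidechain_volume_A3": round(sr.sidechain_volume, 1),
                    "rank_score": round(sr.rank_score, 4),
                    "best_mutation": best.name if best else "",
                    "best_clash_count": best.clash_count if best else "",
                    "best_mutant_cavity_A3": round(best.mutant_cavity_volume, 3)
                    if best else "",
                    "best_delta_volume_A3": round(best.delta_volume, 3) if best else "",
                }
            )
    columns = [
        "model", "residue", "loop", "loop_sequence", "cavity_volume_A3",
        "sidechain_volume_A3", "rank_score", "best_mutation",
        "best_clash_count", "best_mutant_cavity_A3", "best_delta_volume_A3",
    ]
    return pd.DataFrame(rows, columns=columns)


def batch_screen(
    directory: str,
    config: ScreenConfig | None = None,
) -> tuple[list[ScreenResult], pd.DataFrame, list[tuple[str, str]]]:
    """Screen every .pdb file in a directory.

    Returns (results, summary table, failures); per-file failures are
    logged and collected, never fatal. Raises BatchError when no file
    can be processed at all.
    """
    paths = sorted(Path(directory).glob("*.pdb"))
    if not paths:
        raise BatchError(f"no .pdb files in {directory}")
    results: list[ScreenResult] = []
    failures: list[tuple[str, str]] = []
    for path in paths:
        try:
            results.append(run_screen(str(path), config))
        except Exception as exc:
            log.error("screen failed for %s: %s", path, exc)
            failures.append((str(path), str(exc)))
    if not results:
        raise BatchError(f"no parseable .pdb files in {directory}")
    return results, summary_frame(results), failures


def write_report(result: ScreenResult, path: str, include_timings: bool = True) -> None:
    Path(path).write_text(json.dumps(result.report(include_timings), indent=2) + "\n")
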