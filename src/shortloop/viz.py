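"""Visualization script output (.pml command dialect).

Mirrors the convention of the screen's visual workflow: loop regions
red, hydrophobic residues yellow, cavities as blue pseudoatom spheres,
sensitive residues labelled.
"""

from __future__ import annotations

from pathlib import Path

from .screen import ScreenResult


def _sel_residues(labelled: list) -> str:
    parts = [f"(chain {r.chain_id} and resi {r.seq_number})" for r in labelled]
    return " or ".join(parts) if parts else "none"


def write_visualization_script(result: ScreenResult, path: str) -> None:
    """Write a .pml script for the screened model.

    Colors every loop segment red and every hydrophobic residue yellow,
    places one blue sphere pseudoatom per cavity (at the centroid, with
    a subsample of voxel spheres), and labels sensitive residues.
    """
    model = result.model
    lines: list[str] = [
        f"# short-loop screen visualization for {model.identifier}",
        f"load {model.source_path or model.identifier + '.pdb'}, mol" if model.source_path
        else "# load your structure as object 'mol' first",
        "hide everything, mol",
        "show cartoon, mol",
        "color grey80, mol",
    ]
    hydrophobic = [r for r in model.residues() if r.is_hydrophobic]
    if hydrophobic:
        lines.append(f"select hydrophobic, mol and ({_sel_residues(hydrophobic)})")
        lines.append("color yellow, hydrophobic")
    loop_res = [r for lp in result.loops for r in lp.residues]
    if loop_res:
        lines.append(f"select loops, mol and ({_sel_residues(loop_res)})")
        lines.append("color red, loops")
    for cav in result.cavities:
        obj = f"cavity_{cav.id}"
        cx, cy, cz = (float(v) for v in cav.centroid)
        lines.append(
            f"pseudoatom {obj}, pos=[{cx:.3f}, {cy:.3f}, {cz:.3f}], vdw=1.5"
        )
        # a sparse subsample of voxel centers to sketch the cavity shape
        step = max(1, len(cav.centers) // 30)
        for k, (x, y, z) in enumerate(cav.centers[::step]):
            lines.append(
                f"pseudoatom {obj}, pos=[{x:.3f}, {y:.3f}, {z:.3f}], vdw=0.6"
            )
        lines.append(f"show spheres, {obj}")
        lines.append(f"color blue, {obj}")
    for sr in result.sensitive:
        r = sr.residue
        lines.append(
            f'label mol and chain {r.chain_id} and resi {r.seq_number} and name CA, '
            f'"{r.name3.capitalize()}{r.seq_number}"'
        )
    lines.append("bg_color white")
    Path(path).write_text("\n".join(lines) + "\n")
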