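"""Loop segmentation and hydrophobic-run annotation.

Coil residues are partitioned into maximal runs (loops); short loops of
roughly 5-7 residues flanked by regular secondary structure on both
sides are the regions this screen targets, and within (and just around)
them we record maximal stretches of consecutive hydrophobic residues.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import DEFAULT_TABLE, AminoAcidTable
from .secondary import SSAssignment
from .structure import Residue, StructureModel


class ConfigError(ValueError):
    pass


@dataclass
class LoopSegment:
    chain_id: str
    residues: list[Residue]  # contiguous coil run, inclusive
    left_flank: tuple[str, int] | None  # (state, length) or None at chain end
    right_flank: tuple[str, int] | None

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> Residue:
        return self.residues[0]

    @property
    def end(self) -> Residue:
        return self.residues[-1]

    @property
    def is_terminal(self) -> bool:
        return self.left_flank is None or self.right_flank is None

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.start.seq_number}-{self.end.seq_number}"

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class HydrophobicRun:
    loop: LoopSegment
    residues: list[Residue]  # maximal consecutive hydrophobic stretch

    @property
    def length(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


def segment_loops(model: StructureModel, ss: SSAssignment) -> list[LoopSegment]:
    """Maximal coil runs per chain, ordered by chain then position.

    Terminal runs (touching a chain end) carry a single flank; internal
    runs carry the state and length of both adjacent regular elements.
    """
    loops: list[LoopSegment] = []
    for cid in model.chains:
        chain = model.chains[cid]
        states = [ss.state(r) for r in chain]
        runs: list[tuple[int, int, str]] = []  # start, end inclusive, state
        i = 0
        while i < len(states):
            j = i
            while j + 1 < len(states) and states[j + 1] == states[i]:
                j += 1
            runs.append((i, j, states[i]))
            i = j + 1
        for k, (a, b, state) in enumerate(runs):
            if state != "C":
                continue
            left = None
            if k > 0:
                la, lb, ls = runs[k - 1]
                left = (ls, lb - la + 1)
            right = None
            if k + 1 < len(runs):
                ra, rb, rs = runs[k + 1]
                right = (rs, rb - ra + 1)
            loops.append(LoopSegment(cid, chain[a : b + 1], left, right))
    return loops


def find_short_loops(
    loops: list[LoopSegment],
    min_len: int = 5,
    max_len: int = 7,
    require_both_flanks: bool = True,
    min_flank_len: int = 3,
) -> list[LoopSegment]:
    """Filter loops to the short-loop band with regular flanks.

    The 5-7 residue default band reflects the loop sizes this strategy
    targets; both bounds are soft and configurable.
    """
    if min_len > max_len:
        raise ConfigError(f"min_len {min_len} > max_len {max_len}")
    out = []
    for loop in loops:
        if not (min_len <= loop.length <= max_len):
            continue
        if require_both_flanks:
            if loop.left_flank is None or loop.right_flank is None:
                continue
            if loop.left_flank[1] < min_flank_len or loop.right_flank[1] < min_flank_len:
                continue
        out.append(loop)
    return out


def _loop_window(
    model: StructureModel, loop: LoopSegment, flank_extension: int
) -> list[Residue]:
    """Loop residues plus up to flank_extension residues on each side."""
    chain = model.chains[loop.chain_id]
    idx = {r.key: i for i, r in enumerate(chain)}
    a = idx[loop.start.key]
    b = idx[loop.end.key]
    return chain[max(0, a - flank_extension) : min(len(chain), b + flank_extension + 1)]


def annotate_hydrophobic_runs(
    model: StructureModel,
    loop: LoopSegment,
    table: AminoAcidTable = DEFAULT_TABLE,
    flank_extension: int = 2,
) -> list[HydrophobicRun]:
    """Maximal consecutive-hydrophobic runs in the loop's window.

    Runs may extend into the flanking regular elements by up to
    flank_extension residues, because the hydrophobic context of a loop
    often includes flank-adjacent residues; runs that never touch the
    loop itself are dropped.
    """
    window = _loop_window(model, loop, flank_extension)
    loop_keys = {r.key for r in loop.residues}
    runs: list[HydrophobicRun] = []
    current: list[Residue] = []
    for res in window + [None]:  # type: ignore[list-item]
        if res is not None and table.is_hydrophobic(res.name3):
            current.append(res)
        else:
            if current and any(r.key in loop_keys for r in current):
                runs.append(HydrophobicRun(loop, current))
            current = []
    return runs
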