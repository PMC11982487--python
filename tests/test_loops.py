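"""Loop segmentation, short-loop filtering and hydrophobic runs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortloop.fixtures import make_extended_chain, make_helix_loop_helix, make_ideal_helix
from shortloop.loops import (
    ConfigError,
    annotate_hydrophobic_runs,
    find_short_loops,
    segment_loops,
)
from shortloop.secondary import SSAssignment, assign_secondary_structure


def _ss_from_string(model, states: str) -> SSAssignment:
    ss = SSAssignment()
    for res, s in zip(model.chains["A"], states):
        ss.states[res.key] = s
    return ss


def test_state_string_segmentation():
    model = make_extended_chain(14)
    ss = _ss_from_string(model, "HHHHCCCCCCEEEE")
    loops = segment_loops(model, ss)
    assert len(loops) == 1
    lp = loops[0]
    assert (lp.start.seq_number, lp.end.seq_number) == (5, 10)
    assert lp.left_flank == ("H", 4)
    assert lp.right_flank == ("E", 4)
    assert not lp.is_terminal


def test_all_helix_has_no_loops():
    model = make_extended_chain(10)
    ss = _ss_from_string(model, "H" * 10)
    assert segment_loops(model, ss) == []


def test_terminal_runs_flagged():
    model = make_extended_chain(10)
    ss = _ss_from_string(model, "CCHHHHHHCC")
    loops = segment_loops(model, ss)
    assert len(loops) == 2
    assert all(lp.is_terminal for lp in loops)


def test_loops_partition_coil_residues(hlh_nvpays):
    ss = assign_secondary_structure(hlh_nvpays)
    loops = segment_loops(hlh_nvpays, ss)
    coil = {r.key for r in hlh_nvpays.residues() if ss.state(r) == "C"}
    in_loops = [r.key for lp in loops for r in lp.residues]
    assert set(in_loops) == coil
    assert len(in_loops) == len(set(in_loops))


def test_band_filter():
    model = make_extended_chain(40)
    # three internal loops of lengths 3, 6, 12
    states = "HHHH" + "CCC" + "HHHH" + "CCCCCC" + "HHHH" + "C" * 12 + "HHHH" + "CCC"
    ss = _ss_from_string(model, states[:40])
    loops = segment_loops(model, ss)
    short = find_short_loops(loops, 5, 7)
    assert [lp.length for lp in short] == [6]


def test_flank_requirement():
    model = make_extended_chain(13)
    ss = _ss_from_string(model, "HHCCCCCHHHHHH")  # left flank too short
    loops = segment_loops(model, ss)
    assert find_short_loops(loops, 5, 7, require_both_flanks=True) == []
    assert len(find_short_loops(loops, 5, 7, require_both_flanks=False)) == 1


def test_invalid_band_rejected():
    with pytest.raises(ConfigError):
        find_short_loops([], min_len=7, max_len=5)


@settings(deadline=None, max_examples=30)
@given(
    lo1=st.integers(3, 7), hi1=st.integers(5, 9),
    shrink=st.integers(0, 2),
)
def test_band_filter_monotone(lo1, hi1, shrink):
    """Shrinking the band never adds loops."""
    if lo1 > hi1:
        lo1, hi1 = hi1, lo1
    lo2, hi2 = lo1 + shrink, hi1 - shrink
    if lo2 > hi2:
        lo2 = hi2 = (lo1 + hi1) // 2
    model = make_extended_chain(40)
    states = ("HHHH" + "CCCCC" + "HHHH" + "CCCCCCC" + "HHHH" + "CCCC" + "HHHH" * 3)[:40]
    ss = _ss_from_string(model, states)
    loops = segment_loops(model, ss)
    wide = {lp.label for lp in find_short_loops(loops, lo1, hi1)}
    narrow = {lp.label for lp in find_short_loops(loops, lo2, hi2)}
    assert narrow <= wide


def test_nvpays_loop_has_vpay_run(hlh_nvpays):
    ss = assign_secondary_structure(hlh_nvpays)
    short = find_short_loops(segment_loops(hlh_nvpays, ss))
    assert len(short) == 1
    runs = annotate_hydrophobic_runs(hlh_nvpays, short[0])
    assert "VPAY" in [r.sequence() for r in runs]


def test_all_ser_loop_has_no_runs():
    model = make_helix_loop_helix(12, "SSSSS", helix_char="S")
    ss = assign_secondary_structure(model)
    loops = segment_loops(model, ss)
    for lp in loops:
        assert annotate_hydrophobic_runs(model, lp) == []


def test_runs_are_maximal(pocket_result):
    model = pocket_result.model
    for runs in pocket_result.runs.values():
        for run in runs:
            chain = model.chains[run.residues[0].chain_id]
            idx = {r.key: i for i, r in enumerate(chain)}
            a, b = idx[run.residues[0].key], idx[run.residues[-1].key]
            if a > 0:
                assert not chain[a - 1].is_hydrophobic
            if b + 1 < len(chain):
                assert not chain[b + 1].is_hydrophobic


def test_all_helix_model_yields_no_loops(helix20):
    ss = assign_secondary_structure(helix20)
    loops = segment_loops(helix20, ss)
    # only the short terminal caps can be coil, and they are terminal
    assert all(lp.is_terminal for lp in loops)
    assert find_short_loops(loops) == []
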