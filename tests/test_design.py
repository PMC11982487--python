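"""Sensitive-residue criteria, rotamer grafting and mutation proposals."""

import numpy as np
import pytest

from shortloop.cavities import GridSpec, detect_cavities
from shortloop.design import (
    annotate_ddg,
    candidate_sensitive_residues,
    estimate_mutant_cavity,
    propose_mutations,
)
from shortloop.fixtures import make_extended_chain, make_ideal_helix
from shortloop.sidechains import GraftError, default_chi_grid, graft_side_chain
from shortloop.structure import Residue


def test_identity_graft_reproduces_cb(hlh_nvpays):
    res = hlh_nvpays.chains["A"][5]  # a helix alanine
    original_cb = res.atom("CB").position.copy()
    graft = graft_side_chain(hlh_nvpays, res, "ALA")
    new_cb = graft.residue.atom("CB").position
    assert np.linalg.norm(new_cb - original_cb) < 0.05


def test_graft_in_isolated_peptide_has_no_clashes():
    model = make_extended_chain(3)
    res = model.chains["A"][1]
    for target in ("PHE", "TYR", "TRP", "MET"):
        graft = graft_side_chain(model, res, target)
        assert graft.clash_count == 0
        assert graft.feasible
        assert graft.residue.name3 == target


def test_graft_requires_backbone():
    model = make_extended_chain(3)
    bad = Residue("A", 9, "", "ALA")
    model.chains["A"].append(bad)
    with pytest.raises(GraftError):
        graft_side_chain(model, bad, "PHE")


def test_graft_on_glycine_builds_cb():
    model = make_extended_chain(3, "GGG")
    res = model.chains["A"][1]
    assert res.atom("CB") is None
    graft = graft_side_chain(model, res, "PHE")
    assert graft.residue.atom("CB") is not None


def test_chi_grid_sizes():
    assert len(default_chi_grid("ALA")) == 1
    assert len(default_chi_grid("PHE")) == 6
    assert len(default_chi_grid("MET")) == 27


def test_pocket_flags_exactly_one_sensitive_residue(pocket_result):
    assert [sr.label for sr in pocket_result.sensitive] == ["A/Ala15"]
    sr = pocket_result.sensitive[0]
    assert sr.left_hydrophobic and sr.right_hydrophobic
    assert sr.cavity_volume >= 100.0
    assert sr.residue.key in sr.cavity.lining_residues
    assert sr.rank_score == pytest.approx(sr.cavity_volume / sr.sidechain_volume)


def test_no_cavity_means_no_sensitive_residue(pocket_result):
    model = pocket_result.model
    srs = candidate_sensitive_residues(
        model, pocket_result.short_loops, pocket_result.runs, [],
    )
    assert srs == []


def test_alanine_site_gets_four_proposals(pocket_result):
    props = pocket_result.proposals["A/Ala15"]
    assert sorted(p.target_aa for p in props) == ["MET", "PHE", "TRP", "TYR"]


def test_tryptophan_wild_type_gets_no_proposals(pocket_result):
    import dataclasses

    sr = dataclasses.replace(
        pocket_result.sensitive[0],
        residue=Residue("A", 1, "", "TRP"),
        sidechain_volume=227.8,
    )
    assert propose_mutations(pocket_result.model, sr) == []


def test_proposals_sorted_and_filling(pocket_result):
    props = pocket_result.proposals["A/Ala15"]
    keys = [(p.clash_count, p.mutant_cavity_volume) for p in props]
    assert keys == sorted(keys)
    wt = pocket_result.sensitive[0].cavity_volume
    grid = GridSpec()
    tol = 2 * grid.spacing**3 * pocket_result.sensitive[0].cavity.n_voxels ** (2 / 3)
    for p in props:
        assert p.delta_volume == pytest.approx(wt - p.mutant_cavity_volume)
        if p.clash_count == 0:
            # filling monotonicity: adding atoms cannot grow the cavity
            assert p.mutant_cavity_volume <= wt + tol


def test_best_proposal_fills_cavity(pocket_result):
    best = pocket_result.proposals["A/Ala15"][0]
    assert best.clash_count == 0
    assert best.mutant_cavity_volume < pocket_result.sensitive[0].cavity_volume


def test_mutation_far_from_cavity_leaves_volume_unchanged(pocket_result):
    model = pocket_result.model
    far_res = model.chains["A"][-2]  # helix end, ~20 A from the pocket
    graft = graft_side_chain(model, far_res, "PHE")
    sr = pocket_result.sensitive[0]
    vol = estimate_mutant_cavity(graft.model, sr.cavity, GridSpec())
    assert vol == pytest.approx(sr.cavity_volume, rel=0.05)


def test_rank_order_is_by_cavity_per_sidechain_volume(pocket_result):
    scores = [sr.rank_score for sr in pocket_result.sensitive]
    assert scores == sorted(scores, reverse=True)
    assert all(s > 0 for s in scores)


def test_proposals_deterministic(pocket_result):
    sr = pocket_result.sensitive[0]
    again = propose_mutations(pocket_result.model, sr, grid=GridSpec())
    assert [(p.name, p.chis, p.clash_count, p.mutant_cavity_volume) for p in again] == [
        (p.name, p.chis, p.clash_count, p.mutant_cavity_volume)
        for p in pocket_result.proposals["A/Ala15"]
    ]


def test_ddg_annotation_join(tmp_path, pocket_result):
    table = tmp_path / "ddg.tsv"
    table.write_text(
        "chain\tresnum\twt_aa\tmut_aa\tddg_kcal_mol\n"
        "A\t15\tA\tW\t-1.8\n"
        "A\t15\tA\tF\t-0.9\n"
    )
    props = [p for p in pocket_result.proposals["A/Ala15"]]
    annotate_ddg(props, str(table))
    by_name = {p.name: p.external_ddg for p in props}
    assert by_name["A15W"] == pytest.approx(-1.8)
    assert by_name["A15F"] == pytest.approx(-0.9)
    assert by_name["A15Y"] is None


def test_ddg_table_schema_checked(tmp_path, pocket_result):
    bad = tmp_path / "bad.tsv"
    bad.write_text("chain\tresnum\n")
    with pytest.raises(ValueError):
        annotate_ddg([], str(bad))


def test_max_sidechain_volume_threshold(pocket_result):
    srs = candidate_sensitive_residues(
        pocket_result.model,
        pocket_result.short_loops,
        pocket_result.runs,
        pocket_result.cavities,
        max_sidechain_volume=80.0,  # below alanine's 88.6
    )
    assert srs == []
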