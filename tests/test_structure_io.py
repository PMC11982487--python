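"""PDB parsing, altloc policy, round-trip fidelity and chemistry tables."""

import numpy as np
import pytest

from shortloop.chem import DEFAULT_TABLE
from shortloop.structure import (
    EmptyModelError,
    StructureInputError,
    parse_pdb,
    write_pdb,
)

TRIPEPTIDE = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.729   6.768  -4.123  1.00  0.00           C
ATOM      4  O   ALA A   1       9.580   7.101  -4.429  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.868   4.630  -4.717  1.00  0.00           C
ATOM      6  N   ALA A   2      11.255   7.012  -2.920  1.00  0.00           N
ATOM      7  CA  ALA A   2      10.503   7.660  -1.842  1.00  0.00           C
ATOM      8  C   ALA A   2      10.213   9.125  -2.180  1.00  0.00           C
ATOM      9  O   ALA A   2      11.066   9.818  -2.739  1.00  0.00           O
ATOM     10  CB  ALA A   2      11.281   7.576  -0.529  1.00  0.00           C
ATOM     11  N   ALA A   3       9.005   9.579  -1.845  1.00  0.00           N
ATOM     12  CA  ALA A   3       8.581  10.966  -2.083  1.00  0.00           C
ATOM     13  C   ALA A   3       8.730  11.351  -3.558  1.00  0.00           C
ATOM     14  O   ALA A   3       8.316  12.444  -3.946  1.00  0.00           O
ATOM     15  CB  ALA A   3       7.133  11.155  -1.623  1.00  0.00           C
TER
END
"""

ALTLOC_PAIR = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB ASER A   1       2.000  -0.800   1.200  0.60  0.00           C
ATOM      6  CB BSER A   1       2.100  -0.700   1.100  0.40  0.00           C
ATOM      7  OG ASER A   1       3.400  -0.900   1.200  0.60  0.00           O
ATOM      8  OG BSER A   1       3.500  -0.800   1.100  0.40  0.00           O
TER
END
"""

MSE_LINE = """\
HETATM    1  N   MSE A   1       0.000   0.000   0.000  1.00  0.00           N
HETATM    2  CA  MSE A   1       1.458   0.000   0.000  1.00  0.00           C
HETATM    3  C   MSE A   1       2.000   1.400   0.000  1.00  0.00           C
HETATM    4  O   MSE A   1       1.300   2.400   0.000  1.00  0.00           O
TER
END
"""


def test_parse_minimal_tripeptide(tmp_path):
    path = tmp_path / "tri.pdb"
    path.write_text(TRIPEPTIDE)
    model = parse_pdb(str(path))
    assert list(model.chains) == ["A"]
    residues = model.chains["A"]
    assert len(residues) == 3
    assert all(len(r.heavy_atoms()) == 5 for r in residues)
    assert all(r.name3 == "ALA" and r.is_hydrophobic for r in residues)
    assert [r.seq_number for r in residues] == [1, 2, 3]


def test_altloc_keeps_highest_occupancy(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(ALTLOC_PAIR)
    model = parse_pdb(str(path))
    res = model.chains["A"][0]
    # one CB and one OG kept, the 0.60-occupancy copies
    cb = [a for a in res.atoms if a.name == "CB"]
    og = [a for a in res.atoms if a.name == "OG"]
    assert len(cb) == 1 and len(og) == 1
    assert cb[0].occupancy == pytest.approx(0.60)
    assert np.allclose(cb[0].position, [2.000, -0.800, 1.200])


def test_roundtrip_preserves_structure(tmp_path, hlh_nvpays):
    p1 = tmp_path / "a.pdb"
    p2 = tmp_path / "b.pdb"
    write_pdb(hlh_nvpays, str(p1))
    model = parse_pdb(str(p1))
    write_pdb(model, str(p2))
    again = parse_pdb(str(p2))
    assert again.n_residues() == hlh_nvpays.n_residues()
    for r1, r2 in zip(model.residues(), again.residues()):
        assert (r1.name3, r1.seq_number, r1.icode) == (r2.name3, r2.seq_number, r2.icode)
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
        for a1, a2 in zip(r1.atoms, r2.atoms):
            assert np.allclose(a1.position, a2.position, atol=1.5e-3)


def test_chain_ordering_monotone(tmp_path, pocket_model):
    path = tmp_path / "pocket.pdb"
    write_pdb(pocket_model, str(path))
    model = parse_pdb(str(path))
    for residues in model.chains.values():
        keys = [(r.seq_number, r.icode) for r in residues]
        assert keys == sorted(keys)


def test_nonstandard_residue_mapped_to_parent(tmp_path):
    path = tmp_path / "mse.pdb"
    path.write_text(MSE_LINE)
    model = parse_pdb(str(path))
    res = model.chains["A"][0]
    assert res.name3 == "MSE"
    assert not res.is_standard
    # selenomethionine inherits methionine chemistry
    assert res.is_hydrophobic
    assert res.sidechain_volume == pytest.approx(DEFAULT_TABLE.volume("MET"))


def test_empty_and_unreadable_files(tmp_path):
    empty = tmp_path / "empty.pdb"
    empty.write_text("HEADER only\nEND\n")
    with pytest.raises((EmptyModelError, StructureInputError)):
        parse_pdb(str(empty))
    with pytest.raises(StructureInputError):
        parse_pdb(str(tmp_path / "missing.pdb"))


def test_waters_kept_out_of_chains(tmp_path):
    path = tmp_path / "wat.pdb"
    path.write_text(
        TRIPEPTIDE.replace(
            "TER\nEND\n",
            "TER\nHETATM   16  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O\nEND\n",
        )
    )
    model = parse_pdb(str(path))
    assert model.n_residues() == 3
    assert len(model.waters) == 1


def test_chain_filter(tmp_path, pocket_model):
    path = tmp_path / "pocket.pdb"
    write_pdb(pocket_model, str(path))
    model = parse_pdb(str(path), chain="A")
    assert list(model.chains) == ["A"]
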