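"""End-to-end orchestration, batching, reports, config and CLI plumbing."""

import json

import pytest
from click.testing import CliRunner

from shortloop.cli import main
from shortloop.config import ConfigError, ScreenConfig
from shortloop.screen import BatchError, batch_screen, run_screen, screen_model, summary_frame
from shortloop.viz import write_visualization_script


def test_all_helix_report_is_empty(helix20):
    result = screen_model(helix20, ScreenConfig())
    assert result.short_loops == []
    assert result.sensitive == []
    assert result.proposals == {}


def test_pocket_screen_finds_the_design(pocket_result):
    assert len(pocket_result.sensitive) == 1
    props = pocket_result.proposals["A/Ala15"]
    assert len(props) >= 1
    assert props[0].clash_count == 0


def test_report_traceability(pocket_result):
    rep = pocket_result.report()
    loops = {lp["label"] for lp in rep["loops"]}
    cavity_ids = {c["id"] for c in rep["cavities"]}
    for sr in rep["sensitive_residues"]:
        assert sr["loop"] in loops
        assert sr["cavity_id"] in cavity_ids
        assert sr["residue"] in rep["proposals"]


def test_report_json_roundtrip(pocket_result):
    rep = pocket_result.report(include_timings=False)
    assert json.loads(json.dumps(rep)) == rep


def test_batch_over_fixture_directory(fixture_dir):
    results, summary, failures = batch_screen(str(fixture_dir))
    assert len(results) == 3
    assert failures == []
    assert len(summary) == sum(len(r.sensitive) for r in results)


def test_batch_determinism(fixture_dir):
    _, s1, _ = batch_screen(str(fixture_dir))
    _, s2, _ = batch_screen(str(fixture_dir))
    assert s1.to_csv(sep="\t", index=False) == s2.to_csv(sep="\t", index=False)


def test_batch_partial_failure(fixture_dir, tmp_path):
    import shutil

    d = tmp_path / "mixed"
    d.mkdir()
    shutil.copy(fixture_dir / "helix.pdb", d / "ok.pdb")
    (d / "corrupt.pdb").write_text("this is not a pdb file\n")
    results, _, failures = batch_screen(str(d))
    assert len(results) == 1
    assert len(failures) == 1


def test_batch_empty_directory(tmp_path):
    with pytest.raises(BatchError):
        batch_screen(str(tmp_path))


def test_config_rejects_unknown_keys():
    with pytest.raises(ConfigError):
        ScreenConfig.from_dict({"probe_inn": 1.4})
    with pytest.raises(ConfigError):
        ScreenConfig(loop_min_len=8, loop_max_len=5)


def test_config_yaml_roundtrip(tmp_path):
    cfg = ScreenConfig(loop_min_len=4, spacing=0.8)
    path = tmp_path / "cfg.yaml"
    path.write_text(cfg.to_yaml())
    again = ScreenConfig.from_yaml(str(path))
    assert again == cfg


def test_ss_override(fixture_dir, tmp_path, helix20):
    override = tmp_path / "ss.txt"
    override.write_text("A " + "H" * 8 + "C" * 6 + "H" * 6 + "\n")
    cfg = ScreenConfig(ss_override=str(override))
    result = run_screen(str(fixture_dir / "helix.pdb"), cfg)
    assert len(result.loops) == 1
    assert result.loops[0].length == 6


def test_ss_override_length_mismatch(fixture_dir, tmp_path):
    override = tmp_path / "ss.txt"
    override.write_text("A HHHC\n")
    cfg = ScreenConfig(ss_override=str(override))
    with pytest.raises(ValueError):
        run_screen(str(fixture_dir / "helix.pdb"), cfg)


def test_visualization_script_contents(tmp_path, pocket_result, helix20):
    path = tmp_path / "pocket.pml"
    write_visualization_script(pocket_result, str(path))
    text = path.read_text()
    assert text.count("pseudoatom cavity_1,") >= 1
    assert "color yellow, hydrophobic" in text
    assert "color red, loops" in text
    assert "Ala15" in text

    from shortloop.screen import screen_model
    from shortloop.config import ScreenConfig

    empty = screen_model(helix20, ScreenConfig())
    path2 = tmp_path / "helix.pml"
    write_visualization_script(empty, str(path2))
    assert "pseudoatom" not in path2.read_text()


def test_cli_scan_and_batch(tmp_path, fixture_dir):
    runner = CliRunner()
    out = tmp_path / "out"
    res = runner.invoke(
        main, ["scan", str(fixture_dir / "pocket.pdb"), "--out", str(out), "--pml"]
    )
    assert res.exit_code == 0, res.output
    assert (out / "pocket.report.json").exists()
    assert (out / "pocket.pml").exists()
    assert "sensitive residue" in res.output

    res = runner.invoke(main, ["batch", str(fixture_dir), "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "summary.tsv").exists()

    res = runner.invoke(main, ["config", "show"])
    assert res.exit_code == 0
    assert "probe_in" in res.output


def test_cli_fixture_writer(tmp_path):
    runner = CliRunner()
    path = tmp_path / "helix.pdb"
    res = runner.invoke(
        main, ["fixtures", "make", "ideal_helix", "--n-residues", "8", "--out", str(path)]
    )
    assert res.exit_code == 0, res.output
    from shortloop.structure import parse_pdb

    assert parse_pdb(str(path)).n_residues() == 8


def test_summary_frame_columns(pocket_result):
    df = summary_frame([pocket_result])
    assert list(df["residue"]) == ["A/Ala15"]
    assert df.loc[0, "best_mutation"] == "A15W"
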