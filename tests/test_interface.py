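import json

import pytest
from click.testing import CliRunner

from hemoloop import damage_index, write_field_csv
from hemoloop.interface import load_config, main, read_field
from hemoloop.synthetic_data import generate_pump_like_field, generate_uniform_field

Q_LPM = 5.0
Q = Q_LPM / 60000.0


@pytest.fixture
def runner():
    return CliRunner()


def write_pump_field(path, seed, scale=400.0):
    f = generate_pump_like_field(seed, 200, Q=Q, dissipation_scale=scale,
                                 label=f"pump{seed}")
    write_field_csv(f, path)
    return f


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("constants: [HO, Ding-PAI]\nout_dir: runs/x\nseed: 7\n")
        cfg = load_config(p)
        assert [c.name for c in cfg.constants] == ["HO", "Ding-PAI"]
        assert cfg.seed == 7

    def test_inline_constants_accepted(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "constants:\n"
            "  - {name: custom, C: 2.0e-4, alpha: 2.0, beta: 0.7, damage_kind: HI}\n"
        )
        cfg = load_config(p)
        assert cfg.constants[0].name == "custom"


class TestDamageCommand:
    def test_uniform_spec_matches_closed_form(self, runner, tmp_path):
        res = runner.invoke(main, [
            "damage", "--tau", "50", "--volume", "2e-5", "--flow", "5",
            "--constants", "HO", "--out", str(tmp_path),
        ])
        assert res.exit_code == 0, res.output
        report = json.loads((tmp_path / "damage_report.json").read_text())
        d = report["per_model"]["HO"]["D"]
        assert d == pytest.approx(
            damage_index(50.0, 2e-5 / Q, __import__("hemoloop").HO), rel=1e-10
        )
        assert (tmp_path / "manifest.json").exists()

    def test_zero_field_reports_zero(self, runner, tmp_path):
        res = runner.invoke(main, [
            "damage", "--tau", "0", "--out", str(tmp_path),
        ])
        assert res.exit_code == 0
        report = json.loads((tmp_path / "damage_report.json").read_text())
        assert all(m["D"] == 0.0 for m in report["per_model"].values())

    def test_field_file_input(self, runner, tmp_path):
        f, _ = generate_uniform_field(60.0, 2e-5, Q, label="file-field")
        path = tmp_path / "field.csv"
        write_field_csv(f, path)
        res = runner.invoke(main, [
            "damage", "--field", str(path), "--out", str(tmp_path / "out"),
        ])
        assert res.exit_code == 0
        report = json.loads((tmp_path / "out" / "damage_report.json").read_text())
        assert report["field"]["label"] == "file-field"

    def test_malformed_field_file_nonzero_exit(self, runner, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("volume,eps_vis\n1e-6,1.0\n")  # no Q header
        res = runner.invoke(main, ["damage", "--field", str(bad)])
        assert res.exit_code != 0
        assert "malformed" in res.output

    def test_missing_eps_turb_warns(self, tmp_path, caplog):
        p = tmp_path / "f.csv"
        p.write_text("# Q = 8e-5\nvolume,eps_vis\n1e-6,10.0\n")
        import logging

        with caplog.at_level(logging.WARNING, logger="hemoloop"):
            read_field(p)
        assert any("eps_turb" in r.message for r in caplog.records)


class TestLoopCompare:
    def test_report_structure_and_symmetry(self, runner, tmp_path):
        pa, pb, pv = (tmp_path / n for n in ("a.csv", "b.csv", "v.csv"))
        write_pump_field(pa, seed=1, scale=600.0)
        write_pump_field(pb, seed=2, scale=300.0)
        write_pump_field(pv, seed=3, scale=200.0)
        out1, out2 = tmp_path / "o1", tmp_path / "o2"
        r1 = runner.invoke(main, [
            "loop-compare", "--pump-a", str(pa), "--pump-b", str(pb),
            "--valve", str(pv), "--out", str(out1),
        ])
        assert r1.exit_code == 0, r1.output
        rep1 = json.loads((out1 / "loop_compare.json").read_text())
        assert rep1["R_HI_pump_a"]["sd"] >= 0
        # swapping A and B inverts eta and leaves R unchanged
        r2 = runner.invoke(main, [
            "loop-compare", "--pump-a", str(pb), "--pump-b", str(pa),
            "--valve", str(pv), "--out", str(out2),
        ])
        rep2 = json.loads((out2 / "loop_compare.json").read_text())
        for name in rep1["per_model"]:
            e1, e2 = rep1["per_model"][name], rep2["per_model"][name]
            assert e1["eta_p"] * e2["eta_p"] == pytest.approx(1.0, rel=1e-10)
            assert e1["R"]["pump_a"] == pytest.approx(e2["R"]["pump_b"], rel=1e-12)
            # delta reproduces the footnote formula from its own etas
            from hemoloop import attenuation_delta

            assert e1["delta_percent"] == pytest.approx(
                100 * attenuation_delta(e1["eta_p"], e1["eta_pv"]), rel=1e-12
            )

    def test_identical_pumps_delta_undefined(self, runner, tmp_path):
        pa, pv = tmp_path / "a.csv", tmp_path / "v.csv"
        write_pump_field(pa, seed=1)
        write_pump_field(pv, seed=3)
        out = tmp_path / "o"
        res = runner.invoke(main, [
            "loop-compare", "--pump-a", str(pa), "--pump-b", str(pa),
            "--valve", str(pv), "--out", str(out),
        ])
        assert res.exit_code == 0
        rep = json.loads((out / "loop_compare.json").read_text())
        for entry in rep["per_model"].values():
            assert entry["eta_p"] == 1.0
            assert entry["delta_percent"] is None

    def test_inconsistent_flow_rejected(self, runner, tmp_path):
        pa, pb, pv = (tmp_path / n for n in ("a.csv", "b.csv", "v.csv"))
        write_pump_field(pa, seed=1)
        write_pump_field(pb, seed=2)
        f = generate_pump_like_field(3, 100, Q=2 * Q)
        write_field_csv(f, pv)
        res = runner.invoke(main, [
            "loop-compare", "--pump-a", str(pa), "--pump-b", str(pb),
            "--valve", str(pv),
        ])
        assert res.exit_code != 0
        assert "flow rates differ" in res.output


class TestThroatSizeCommand:
    def test_sizing_run_end_to_end(self, runner, tmp_path):
        res = runner.invoke(main, [
            "throat-size", "--head", "150", "--flow", "5", "--out", str(tmp_path),
        ])
        assert res.exit_code == 0, res.output
        report = json.loads((tmp_path / "throat_size.json").read_text())
        assert report["final_rel_err"] <= 0.0075
        assert (tmp_path / "throat.stl").exists()
        assert (tmp_path / "iterations.csv").exists()

    def test_impossible_target_fails_cleanly(self, runner, tmp_path):
        res = runner.invoke(main, [
            "throat-size", "--head", "1e-3", "--flow", "5", "--out", str(tmp_path),
        ])
        assert res.exit_code != 0
        assert "achievable" in res.output

    def test_rerun_is_deterministic(self, runner, tmp_path):
        o1, o2 = tmp_path / "r1", tmp_path / "r2"
        for o in (o1, o2):
            res = runner.invoke(main, [
                "throat-size", "--head", "120", "--flow", "4.5", "--out", str(o),
            ])
            assert res.exit_code == 0
        assert (o1 / "throat.stl").read_bytes() == (o2 / "throat.stl").read_bytes()
        assert (o1 / "throat_size.json").read_text() == (
            o2 / "throat_size.json"
        ).read_text()


class TestSynthAndFixtures:
    def test_synth_writes_both_dialects(self, runner, tmp_path):
        res = runner.invoke(main, [
            "synth", "--kind", "pump-like", "--seed", "5", "--n-cells", "100",
            "--out", str(tmp_path),
        ])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "pump-like.csv").exists()
        assert (tmp_path / "pump-like.vtu").exists()
        f1 = read_field(tmp_path / "pump-like.csv")
        f2 = read_field(tmp_path / "pump-like.vtu")
        assert f1.total_power == f2.total_power

    def test_fixtures_csv(self, runner, tmp_path):
        out = tmp_path / "fix.csv"
        res = runner.invoke(main, ["fixtures", "--out", str(out)])
        assert res.exit_code == 0
        import pandas as pd

        frame = pd.read_csv(out)
        assert len(frame) == 8
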