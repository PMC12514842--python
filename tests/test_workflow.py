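import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from conftest import LOOP_SHIFT_ATOMS, SHIFT_DIRECTION
from triadgeo.cli import main
from triadgeo.errors import ValidationError
from triadgeo.fixtures import (
    EnsembleSpec,
    FixtureSpec,
    make_ensemble,
    make_toy_hydrolase,
    write_fixture_pair,
)
from triadgeo.structure_io import write_pdb
from triadgeo.workflow import (
    builtin_config_path,
    load_site_config,
    run_compare,
    run_ensemble,
    run_panel,
)

TOY_CONFIG = {
    "name": "toy",
    "accessions": [],
    "triad": {
        "ser": {"res_name": "SER", "seq": 14},
        "his": {"res_name": "HIS", "seq": 25},
        "asp": {"res_name": "ASP", "seq": 28},
    },
    "oxyanion_donors": [
        {"res_name": "GLY", "seq": 10, "atom": "N"},
        {"res_name": "HIS", "seq": 13, "atom": "N"},
    ],
    "distal_donor_index": 0,
    "oxyanion_loop": {"start": 9, "end": 12},
    "his_loop": {"start": 23, "end": 26},
    "core": [{"start": 1, "end": 8}, {"start": 15, "end": 22}],
    "ligand": {"res_name": "LIG", "seq": 99, "atoms": ["C1", "O1", "N1"]},
    "measure_atoms": [
        {"res_name": "GLY", "seq": 10, "atom": "N"},
        {"res_name": "GLY", "seq": 10, "atom": "CA"},
        {"res_name": "HIS", "seq": 25, "atom": "CA"},
    ],
    "contacts": [
        {
            "label": "donor-to-donor",
            "a": {"res_name": "GLY", "seq": 10, "atom": "N"},
            "b": {"res_name": "HIS", "seq": 13, "atom": "N"},
        }
    ],
}


@pytest.fixture()
def toy_config_path(tmp_path):
    path = tmp_path / "toy_site.yaml"
    path.write_text(yaml.safe_dump(TOY_CONFIG))
    return path


@pytest.fixture()
def pair_paths(tmp_path):
    spec = FixtureSpec(
        seed=23, planted_loop_shift=(LOOP_SHIFT_ATOMS, 0.75 * SHIFT_DIRECTION)
    )
    return write_fixture_pair(tmp_path / "pair", spec)


class TestSiteConfig:
    def test_load_toy_config(self, toy_config_path):
        config = load_site_config(toy_config_path)
        assert config.site.ser.seq_num == 14
        assert config.site.distal_donor == (config.site.oxyanion_donors[0])
        assert config.site.ligand.res_name == "LIG"
        assert len(config.measure_atoms) == 3
        assert config.digest

    def test_builtin_configs_parse(self):
        for name in ("apeh", "ache", "dpp4"):
            config = load_site_config(builtin_config_path(name))
            assert config.site.core, name

    def test_apeh_config_matches_published_numbering(self):
        config = load_site_config(builtin_config_path("apeh"))
        site = config.site
        assert (site.ser.res_name, site.ser.seq_num) == ("SER", 587)
        assert (site.his.res_name, site.his.seq_num) == ("HIS", 707)
        assert (site.asp.res_name, site.asp.seq_num) == ("ASP", 675)
        donor_spec, donor_atom = site.distal_donor
        assert (donor_spec.seq_num, donor_atom) == (509, "N")
        assert (site.oxyanion_loop.start, site.oxyanion_loop.end) == (508, 511)

    def test_dpp4_sidechain_donor(self):
        config = load_site_config(builtin_config_path("dpp4"))
        donor_spec, donor_atom = config.site.distal_donor
        assert donor_spec.res_name == "TYR"
        assert donor_atom == "OH"

    def test_missing_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"name": "x"}))
        with pytest.raises(ValidationError, match="triad"):
            load_site_config(path)

    def test_unknown_builtin(self):
        with pytest.raises(ValidationError, match="available"):
            builtin_config_path("nope")


class TestRunCompare:
    def test_reproduces_planted_shift(self, pair_paths, toy_config_path, tmp_path):
        apo_path, holo_path, truth_path = pair_paths
        config = load_site_config(toy_config_path)
        report = run_compare(apo_path, holo_path, config, tmp_path / "out")
        shifts = {
            (r["residue"], r["atom"]): r for r in report["shift_report"]["shifts"]
        }
        row = shifts[("GLY10", "N")]
        assert row["mean"] == pytest.approx(0.75, abs=5e-3)
        assert row["direction"] == "toward"
        assert (tmp_path / "out" / "compare.json").exists()
        assert (tmp_path / "out" / "shifts.csv").exists()

    def test_self_comparison_zero(self, pair_paths, toy_config_path, tmp_path):
        apo_path, _, _ = pair_paths
        config = load_site_config(toy_config_path)
        report = run_compare(apo_path, apo_path, config, tmp_path / "out")
        for row in report["shift_report"]["shifts"]:
            assert row["mean"] == pytest.approx(0.0, abs=1e-9)
            assert row["direction"] == "n/a"

    def test_provenance_embedded(self, pair_paths, toy_config_path, tmp_path):
        apo_path, holo_path, _ = pair_paths
        config = load_site_config(toy_config_path)
        report = run_compare(apo_path, holo_path, config, tmp_path / "out")
        prov = report["provenance"]
        assert prov["version"]
        assert prov["config_hash"] == config.digest
        assert len(prov["inputs"]) == 2
        assert report["policies"]["altloc"].startswith("highest occupancy")


class TestRunPanel:
    def _manifest(self, tmp_path, toy_config_path, n=2, break_last=False):
        entries = []
        for i in range(n):
            spec = FixtureSpec(
                seed=30 + i,
                planted_loop_shift=(LOOP_SHIFT_ATOMS, (0.2 + 0.2 * i) * SHIFT_DIRECTION),
            )
            apo, holo, _ = write_fixture_pair(tmp_path / f"pair{i}", spec)
            entries.append(
                {
                    "label": f"pair{i}",
                    "apo": str(apo),
                    "holo": str(holo),
                    "site": str(toy_config_path),
                }
            )
        if break_last:
            entries[-1]["holo"] = str(tmp_path / "missing.pdb")
        return {"entries": entries}

    def test_panel_csv(self, tmp_path, toy_config_path):
        manifest = self._manifest(tmp_path, toy_config_path)
        summary = run_panel(manifest, tmp_path / "out")
        assert summary["n_rows"] == 2
        import pandas as pd

        frame = pd.read_csv(tmp_path / "out" / "deltas.csv")
        assert list(frame["label"]) == ["pair0", "pair1"]

    def test_row_failure_isolated(self, tmp_path, toy_config_path):
        manifest = self._manifest(tmp_path, toy_config_path, n=3, break_last=True)
        summary = run_panel(manifest, tmp_path / "out")
        assert summary["n_rows"] == 2
        assert len(summary["failures"]) == 1
        assert summary["failures"][0]["label"] == "pair2"

    def test_duplicate_labels_rejected_before_compute(self, tmp_path, toy_config_path):
        manifest = self._manifest(tmp_path, toy_config_path)
        manifest["entries"][1]["label"] = manifest["entries"][0]["label"]
        with pytest.raises(ValidationError, match="duplicate"):
            run_panel(manifest, tmp_path / "out")

    def test_empty_manifest(self, tmp_path):
        with pytest.raises(ValidationError):
            run_panel({"entries": []}, tmp_path / "out")


class TestRunEnsemble:
    def _write_ensemble(self, tmp_path, n_frames=20, open_fraction=0.5):
        spec = FixtureSpec(
            seed=31,
            n_chains=1,
            ensemble=EnsembleSpec(n_frames=n_frames, open_fraction=open_fraction),
        )
        ens, truth = make_ensemble(spec)
        path = tmp_path / "ens.pdb"
        write_pdb(ens.frames, path)
        return path, truth

    def test_two_state_outputs(self, tmp_path, toy_config_path):
        path, truth = self._write_ensemble(tmp_path)
        config = load_site_config(toy_config_path)
        result = run_ensemble(path, config, tmp_path / "out")
        assert result["clusters"]["n_clusters"] == 2
        fit = json.loads((tmp_path / "out" / "mixture_fit.json").read_text())
        assert (tmp_path / "out" / "sasa_series.csv").exists()
        lo, hi = sorted([truth["sasa_closed"], truth["sasa_open"]])
        if "means" in fit:
            assert abs(fit["means"][0] - lo) < 2.0
            assert abs(fit["means"][1] - hi) < 2.0

    def test_single_frame_usage_error(self, tmp_path, toy_config_path):
        model, _ = make_toy_hydrolase(FixtureSpec(seed=1, n_chains=1))
        path = tmp_path / "one.pdb"
        write_pdb(model, path)
        config = load_site_config(toy_config_path)
        with pytest.raises(ValidationError):
            run_ensemble(path, config, tmp_path / "out")

    def test_constant_ensemble_degenerate_flag(self, tmp_path, toy_config_path):
        model, _ = make_toy_hydrolase(FixtureSpec(seed=1, n_chains=1))
        path = tmp_path / "const.pdb"
        write_pdb([model.copy() for _ in range(60)], path)
        config = load_site_config(toy_config_path)
        result = run_ensemble(path, config, tmp_path / "out")
        assert result["clusters"]["n_clusters"] == 1
        assert result["fit"]["degenerate"] is True


class TestCli:
    def test_compare_command(self, pair_paths, toy_config_path, tmp_path):
        apo_path, holo_path, _ = pair_paths
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "compare", str(apo_path), str(holo_path),
                "--site", str(toy_config_path), "--out", str(tmp_path / "out"),
            ],
        )
        assert result.exit_code == 0, result.output
        assert "GLY10:N" in result.output
        assert "toward" in result.output

    def test_compare_bad_site_exits_nonzero(self, pair_paths, tmp_path):
        apo_path, holo_path, _ = pair_paths
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["compare", str(apo_path), str(holo_path), "--site", "nope",
             "--out", str(tmp_path / "o")],
        )
        assert result.exit_code == 2
        assert "error" in result.output

    def test_fixtures_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["fixtures", "--seed", "4", "--out", str(tmp_path / "fx")]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "fx" / "apo.pdb").exists()
        assert (tmp_path / "fx" / "truth.json").exists()

    def test_fixtures_ensemble_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["fixtures", "--seed", "4", "--kind", "ensemble", "--n-frames", "6",
             "--out", str(tmp_path / "fx")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "fx" / "ensemble.pdb").exists()

    def test_sasa_command(self, pair_paths, toy_config_path, tmp_path):
        apo_path, _, _ = pair_paths
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["sasa", str(apo_path), "--site", str(toy_config_path),
             "--out", str(tmp_path / "s")],
        )
        assert result.exit_code == 0, result.output
        doc = json.loads((tmp_path / "s" / "sasa_summary.json").read_text())
        assert doc["ser_sidechain_sasa"] > 0
        assert doc["params"]["probe_radius"] == 1.4

    def test_panel_command(self, tmp_path, toy_config_path):
        spec = FixtureSpec(
            seed=40, planted_loop_shift=(LOOP_SHIFT_ATOMS, 0.3 * SHIFT_DIRECTION)
        )
        apo, holo, _ = write_fixture_pair(tmp_path / "p0", spec)
        manifest = {
            "entries": [
                {"label": "p0", "apo": str(apo), "holo": str(holo),
                 "site": str(toy_config_path)}
            ]
        }
        mpath = tmp_path / "manifest.yaml"
        mpath.write_text(yaml.safe_dump(manifest))
        runner = CliRunner()
        result = runner.invoke(
            main, ["panel", str(mpath), "--out", str(tmp_path / "out")]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "deltas.csv").exists()

    def test_ensemble_command(self, tmp_path, toy_config_path):
        spec = FixtureSpec(seed=41, n_chains=1, ensemble=EnsembleSpec(n_frames=10))
        ens, _ = make_ensemble(spec)
        path = tmp_path / "e.pdb"
        write_pdb(ens.frames, path)
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["ensemble", str(path), "--site", str(toy_config_path),
             "--out", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "clusters.json").exists()
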