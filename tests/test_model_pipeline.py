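"""RohStudy/RohStudyResults front end, pipeline orchestration and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from rohscan import RohStudy, RunConfig, run_pipeline
from rohscan.cli import main as cli_main
from rohscan.pipeline import PipelineError
from rohscan.qc import QcThresholds
from rohscan.roh import RohParams
from rohscan.simulate import SimConfig, simulate_panel

GENOME = tuple((str(i + 1), 120_000_000) for i in range(4))


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(
        n_individuals=30,
        chromosomes=GENOME,
        target_f=0.05,
        genotype_error_rate=0.001,
        missing_rate=0.01,
        seed=19,
    )
    return cfg, *simulate_panel(cfg)


@pytest.fixture(scope="module")
def fitted(sim):
    cfg, panel, truth = sim
    study = RohStudy(panel, chrom_lengths=dict(cfg.chromosomes))
    return study.fit()


class TestModel:
    def test_tables_present_and_consistent(self, fitted):
        assert fitted.n_segments == len(fitted.segments) > 0
        assert set(fitted.segments.columns) == {
            "individual_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"
        }
        assert len(fitted.profiles) == fitted.panel.n_individuals
        assert len(fitted.correlations) == 15
        assert len(fitted.incidence) == fitted.panel.n_snps
        assert fitted.class_summary["n_segments"].iloc[-1] == fitted.n_segments

    def test_headline_statistics_recomputable_from_tables(self, fitted):
        # no hidden state: every headline number re-derives from the TSVs
        assert fitted.mn_roh == pytest.approx(
            len(fitted.segments) / fitted.panel.n_individuals
        )
        assert fitted.mean_total_length_mb == pytest.approx(
            fitted.segments["length_bp"].sum() / 1e6 / fitted.panel.n_individuals
        )
        assert fitted.mean_f_roh == pytest.approx(fitted.profiles["f_roh"].mean())

    def test_fit_is_deterministic(self, sim):
        cfg, panel, _ = sim
        a = RohStudy(panel).fit()
        b = RohStudy(panel).fit()
        pd.testing.assert_frame_equal(a.segments, b.segments)
        pd.testing.assert_frame_equal(a.profiles, b.profiles)

    def test_summary_mentions_key_quantities(self, fitted):
        text = fitted.summary()
        assert "minimum SNPs per run" in text
        assert "F_ROH" in text and "F_HOM" in text
        assert str(fitted.n_segments) in text

    def test_save_reports_schema(self, fitted, tmp_path):
        paths = fitted.save_reports(tmp_path)
        names = {p.name for p in paths}
        assert {
            "roh_segments.tsv", "roh_class_summary.tsv", "chromosome_summary.tsv",
            "inbreeding.tsv", "correlations.tsv", "islands.tsv", "islands.bed",
            "snp_incidence.tsv",
        } <= names
        seg = pd.read_csv(tmp_path / "roh_segments.tsv", sep="\t")
        assert len(seg) == fitted.n_segments
        inb = pd.read_csv(tmp_path / "inbreeding.tsv", sep="\t")
        assert list(inb.columns) == [
            "individual_id", "f_hom", "f_roh",
            "f_roh_1_5", "f_roh_5_10", "f_roh_10_20", "f_roh_gt20",
        ]

    def test_plots_render(self, fitted):
        import matplotlib

        matplotlib.use("Agg")
        assert fitted.plot_chromosome_roh() is not None
        assert fitted.plot_incidence() is not None
        assert fitted.plot_inbreeding_distribution() is not None


class TestPipeline:
    def _write_inputs(self, sim, tmp_path):
        from rohscan import io as rio

        cfg, panel, _ = sim
        rio.write_ped_map(panel, tmp_path / "d.ped", tmp_path / "d.map")
        with open(tmp_path / "chroms.tsv", "w") as fh:
            for c, l in cfg.chromosomes:
                fh.write(f"{c}\t{l}\n")
        return tmp_path / "d.ped", tmp_path / "d.map", tmp_path / "chroms.tsv"

    def test_end_to_end_and_manifest_determinism(self, sim, tmp_path):
        ped, map_, chroms = self._write_inputs(sim, tmp_path)
        config = RunConfig(
            ped=str(ped), map=str(map_), chrom_lengths=str(chroms),
            out_dir=str(tmp_path / "run1"),
        )
        results = run_pipeline(config)
        out1 = tmp_path / "run1"
        for name in ("roh_segments.tsv", "inbreeding.tsv", "manifest.json", "summary.txt"):
            assert (out1 / name).exists()
        manifest = json.loads((out1 / "manifest.json").read_text())
        assert manifest["row_counts"]["segments"] == len(results.segments)
        assert manifest["min_roh_snps"] == results.min_roh_snps

        config2 = RunConfig(
            ped=str(ped), map=str(map_), chrom_lengths=str(chroms),
            out_dir=str(tmp_path / "run2"),
        )
        run_pipeline(config2)
        m1 = json.loads((out1 / "manifest.json").read_text())
        m2 = json.loads((tmp_path / "run2" / "manifest.json").read_text())
        assert m1 == m2
        assert (out1 / "roh_segments.tsv").read_text() == (
            tmp_path / "run2" / "roh_segments.tsv"
        ).read_text()

    def test_yaml_roundtrip(self, sim, tmp_path):
        ped, map_, chroms = self._write_inputs(sim, tmp_path)
        cfg_yaml = {
            "ped": str(ped),
            "map": str(map_),
            "chrom_lengths": str(chroms),
            "out_dir": str(tmp_path / "runy"),
            "qc": {"min_maf": 0.01},
            "roh": {"window_snps": 50, "min_snps_override": 40},
        }
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg_yaml))
        config = RunConfig.from_yaml(path)
        assert config.qc.min_maf == 0.01
        assert config.roh.min_snps_override == 40
        results = run_pipeline(config)
        assert results.min_roh_snps == 40

    def test_missing_path_fails_before_compute(self, tmp_path):
        config = RunConfig(ped="absent.ped", map="absent.map", out_dir=str(tmp_path))
        with pytest.raises(PipelineError, match="does not exist"):
            run_pipeline(config)
        assert not (tmp_path / "manifest.json").exists()

    def test_stage_failure_writes_marker(self, sim, tmp_path):
        ped, map_, _ = self._write_inputs(sim, tmp_path)
        config = RunConfig(
            ped=str(ped), map=str(map_), out_dir=str(tmp_path / "bad"),
            qc=QcThresholds(min_maf=0.9),  # removes everything
        )
        with pytest.raises(PipelineError, match="stage 'fit'"):
            run_pipeline(config)
        assert (tmp_path / "bad" / "FAILED").exists()


class TestCli:
    def test_version(self):
        result = CliRunner().invoke(cli_main, ["--version"])
        assert result.exit_code == 0 and "rohscan" in result.output

    def test_stagewise_chain(self, tmp_path):
        runner = CliRunner()
        sim_cfg = {
            "n_individuals": 15,
            "chromosomes": [["1", 120_000_000], ["2", 120_000_000]],
            "target_f": 0.06,
            "seed": 4,
        }
        (tmp_path / "sim.yaml").write_text(yaml.safe_dump(sim_cfg))
        r = runner.invoke(
            cli_main,
            ["simulate", "--out", str(tmp_path / "panel"), "--config",
             str(tmp_path / "sim.yaml")],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "panel.ped").exists()
        assert (tmp_path / "panel_truth_tracts.tsv").exists()

        r = runner.invoke(
            cli_main,
            ["qc", "--ped", str(tmp_path / "panel.ped"), "--map",
             str(tmp_path / "panel.map"), "--out", str(tmp_path / "clean")],
        )
        assert r.exit_code == 0, r.output

        r = runner.invoke(
            cli_main,
            ["detect", "--ped", str(tmp_path / "clean.ped"), "--map",
             str(tmp_path / "clean.map"), "--out", str(tmp_path / "segments.tsv")],
        )
        assert r.exit_code == 0, r.output
        segments = pd.read_csv(tmp_path / "segments.tsv", sep="\t")
        assert len(segments) > 0

        r = runner.invoke(
            cli_main,
            ["summarize", "--segments", str(tmp_path / "segments.tsv"),
             "--chrom-lengths", str(tmp_path / "panel_chrom_lengths.tsv"),
             "--n-individuals", "15", "--out-dir", str(tmp_path / "sums")],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "sums" / "roh_class_summary.tsv").exists()

        r = runner.invoke(
            cli_main,
            ["inbreeding", "--ped", str(tmp_path / "clean.ped"), "--map",
             str(tmp_path / "clean.map"), "--segments", str(tmp_path / "segments.tsv"),
             "--out-dir", str(tmp_path / "inb")],
        )
        assert r.exit_code == 0, r.output
        prof = pd.read_csv(tmp_path / "inb" / "inbreeding.tsv", sep="\t")
        assert len(prof) == 15

        r = runner.invoke(
            cli_main,
            ["islands", "--ped", str(tmp_path / "clean.ped"), "--map",
             str(tmp_path / "clean.map"), "--segments", str(tmp_path / "segments.tsv"),
             "--out-dir", str(tmp_path / "isl")],
        )
        assert r.exit_code == 0, r.output
        islands = pd.read_csv(tmp_path / "isl" / "islands.tsv", sep="\t")

        gff = tmp_path / "genes.gff3"
        lines = ["##gff-version 3"]
        for c, l in (("1", 120_000_000), ("2", 120_000_000)):
            for k in range(0, l, 5_000_000):
                lines.append(
                    f"{c}\tsrc\tgene\t{k + 1}\t{k + 100_000}\t.\t+\t.\t"
                    f"ID=gene-{c}-{k};Name=G{c}_{k}"
                )
        gff.write_text("\n".join(lines) + "\n")
        r = runner.invoke(
            cli_main,
            ["annotate", "--islands", str(tmp_path / "isl" / "islands.tsv"),
             "--genes", str(gff), "--out", str(tmp_path / "annotated.tsv")],
        )
        assert r.exit_code == 0, r.output
        annotated = pd.read_csv(tmp_path / "annotated.tsv", sep="\t")
        assert "n_genes" in annotated.columns and len(annotated) == len(islands)

    def test_run_subcommand(self, tmp_path):
        runner = CliRunner()
        cfg = SimConfig(
            n_individuals=12, chromosomes=GENOME, target_f=0.05, seed=23
        )
        panel, _ = simulate_panel(cfg)
        from rohscan import io as rio

        rio.write_ped_map(panel, tmp_path / "d.ped", tmp_path / "d.map")
        run_cfg = {
            "ped": str(tmp_path / "d.ped"),
            "map": str(tmp_path / "d.map"),
            "out_dir": str(tmp_path / "out"),
        }
        (tmp_path / "cfg.yaml").write_text(yaml.safe_dump(run_cfg))
        r = runner.invoke(cli_main, ["run", "--config", str(tmp_path / "cfg.yaml")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "manifest.json").exists()
        assert "segments" in r.output
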