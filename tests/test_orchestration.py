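"""End-to-end pipeline, report determinism, CLI and deposit adapter."""

import math

import numpy as np
import pytest
from click.testing import CliRunner

from navassess import (
    AdapterError,
    build_report,
    import_deposited,
    jaccard_similarity,
    magnitude_series,
    read_cohort,
    run_pipeline,
    score_sus,
    summarize_errors,
    trials_to_frame,
    write_cohort,
)
from navassess.cli import load_config, main
from navassess.synthetic_cohort import CohortConfig, reference_config


@pytest.fixture(scope="module")
def report():
    return run_pipeline(synthetic=True, config=reference_config())


class TestRunPipeline:
    def test_synthetic_run_is_byte_identical(self, tmp_path):
        cfg = reference_config()
        run_pipeline(synthetic=True, config=cfg, out_dir=tmp_path / "a")
        run_pipeline(synthetic=True, config=cfg, out_dir=tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b and files_a
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert not (tmp_path / "a.partial").exists()

    def test_fixture_contract_and_dropout_logged(self, report):
        assert "ingest: 11 sessions, 22 questionnaire responses" in report.log[1]
        dropout_lines = [l for l in report.log if l.startswith("dropout")]
        assert any("P06" in l for l in dropout_lines)
        assert report.error_table["n_trials"].sum() == 176

    def test_requires_an_input_source(self):
        from navassess import InputError

        with pytest.raises(InputError):
            run_pipeline()

    def test_file_input_equals_synthetic_input(self, tmp_path, cohort):
        sessions, quests = cohort
        write_cohort(sessions, quests, tmp_path / "logs")
        from_files = run_pipeline(input_dir=tmp_path / "logs")
        direct = build_report(sessions, quests)
        assert from_files.error_table.equals(direct.error_table)
        assert from_files.sus_scores.equals(direct.sus_scores)


class TestNoRecomputationDrift:
    """Every report number equals the corresponding direct operation call."""

    def test_sus_means_match_direct_scoring(self, report, questionnaires):
        for cond in ("immersive", "semi_immersive"):
            scores = [score_sus(q.items).value for q in questionnaires
                      if q.instrument == "SUS" and q.condition == cond]
            row = report.sus_scores[report.sus_scores["condition"] == cond].iloc[0]
            assert row["mean"] == pytest.approx(np.mean(scores))
            assert row["n"] == len(scores)

    def test_error_table_matches_summarize_errors(self, report, sessions):
        direct = summarize_errors(trials_to_frame([t for s in sessions for t in s.trials]))
        assert report.error_table.equals(direct)

    def test_jaccard_matches_direct_computation(self, report, sessions):
        s = sessions[0]
        j = jaccard_similarity(
            magnitude_series(s.encoding_trace), magnitude_series(s.recall_trace)
        )
        cond = s.condition
        # recompute the per-condition mean from direct per-session values
        vals = [
            jaccard_similarity(magnitude_series(x.encoding_trace),
                               magnitude_series(x.recall_trace))
            for x in sessions if x.condition == cond
        ]
        assert j in vals
        row = report.jaccard_summary[report.jaccard_summary["condition"] == cond].iloc[0]
        assert row["mean"] == pytest.approx(np.mean(vals))

    def test_density_grids_conserve_counts(self, report, sessions):
        for cond, grid in report.density_grids.items():
            n = sum(
                len(tr) for s in sessions if s.condition == cond
                for tr in (s.encoding_trace, s.recall_trace) if tr is not None
            )
            assert grid.total == n


class TestRayleighThroughPipeline:
    def test_error_cells_near_rayleigh_mean(self):
        """sigma=10 everywhere -> every cell mean within 3 SE of 10*sqrt(pi/2)."""
        cfg = CohortConfig(
            n_participants=30, dropout_pattern=("both",) * 30,
            displacement_sigma=10.0,
            encoding_duration={"immersive": (0.05, 0.0), "semi_immersive": (0.05, 0.0)},
            recall_duration={"immersive": (0.05, 0.0), "semi_immersive": (0.05, 0.0)},
            seed=23,
        )
        report = run_pipeline(synthetic=True, config=cfg)
        target = 10.0 * math.sqrt(math.pi / 2.0)
        for _, row in report.error_table.iterrows():
            se = row["sd_r"] / math.sqrt(row["n_trials"])
            assert abs(row["mean_r"] - target) < 3 * se


class TestImportDeposited:
    def test_empty_directory_is_adapter_error(self, tmp_path):
        with pytest.raises(AdapterError, match="none"):
            import_deposited(tmp_path)

    def test_unknown_layout_lists_files(self, tmp_path):
        (tmp_path / "mystery.xlsx").write_text("x")
        with pytest.raises(AdapterError, match="mystery.xlsx"):
            import_deposited(tmp_path)

    def test_own_format_falls_back_to_reader(self, tmp_path, cohort):
        sessions, quests = cohort
        write_cohort(sessions, quests, tmp_path)
        s2, q2 = import_deposited(tmp_path)
        assert {s.key for s in s2} == {s.key for s in sessions}
        assert len(q2) == len(quests)


class TestCli:
    def test_simulate_then_run_and_score(self, tmp_path):
        runner = CliRunner()
        cfgfile = tmp_path / "cohort.cfg"
        cfgfile.write_text(
            "seed = 7\n"
            "encoding_duration.immersive = 0.2, 0.0\n"
            "encoding_duration.semi_immersive = 0.2, 0.0\n"
            "recall_duration.immersive = 0.2, 0.0\n"
            "recall_duration.semi_immersive = 0.2, 0.0\n"
        )
        out = tmp_path / "logs"
        r = runner.invoke(main, ["simulate", "--config", str(cfgfile), "--out", str(out)])
        assert r.exit_code == 0, r.output
        sessions, quests = read_cohort(out)
        assert len(sessions) == 11 and len(quests) == 22

        rep = tmp_path / "report"
        r = runner.invoke(main, ["run", "--input", str(out), "--out", str(rep)])
        assert r.exit_code == 0, r.output
        assert (rep / "summary.txt").exists()
        assert (rep / "error_table.csv").exists()

        r = runner.invoke(main, ["score", "--input", str(out)])
        assert r.exit_code == 0, r.output
        assert "SUS" in r.output

    def test_seed_flag_overrides_config(self, tmp_path):
        cfg = load_config_with_seed(tmp_path, 3)
        assert cfg.seed == 3

    def test_run_rejects_ambiguous_source(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(main, ["run", "--out", str(tmp_path / "x")])
        assert r.exit_code != 0

    def test_config_parser_round_trip(self, tmp_path):
        cfgfile = tmp_path / "c.cfg"
        cfgfile.write_text(
            "# comment\n"
            "n_participants = 3\n"
            "dropout_pattern = both, both, none\n"
            "displacement_sigma.allocentric.immersive = 9.5\n"
            "motion.volatility = 0.2\n"
            "questionnaire.SUS.immersive = 50, 10\n"
        )
        cfg = load_config(cfgfile)
        assert cfg.n_participants == 3
        assert cfg.dropout_pattern == ("both", "both", "none")
        assert cfg.sigma_for("allocentric", "immersive") == 9.5
        assert cfg.motion_model.volatility == 0.2
        assert cfg.questionnaire_targets[("SUS", "immersive")] == (50.0, 10.0)

    def test_config_parser_rejects_unknown_key(self, tmp_path):
        from navassess import ConfigError

        cfgfile = tmp_path / "c.cfg"
        cfgfile.write_text("banana = 1\n")
        with pytest.raises(ConfigError, match="banana"):
            load_config(cfgfile)


def load_config_with_seed(tmp_path, seed):
    from navassess.cli import _cfg_from

    cfgfile = tmp_path / "s.cfg"
    cfgfile.write_text("seed = 99\n")
    return _cfg_from(cfgfile, seed)
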