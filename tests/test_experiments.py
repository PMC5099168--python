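"""Experiment protocols: training, novelty switch, distance sweep, and the
command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import olfnet
from olfnet.cli import main as cli_main
from olfnet.experiments import (
    ExperimentConfig,
    classify_mode,
    run_distance_sweep,
    run_novelty_switch,
    run_session,
    run_training_protocol,
    sweep_summary,
    switch_distance,
)


class TestClassifier:
    def test_low_m_high_rate_is_recall(self):
        assert classify_mode(0.3, 9.0, 0.95, 4.0, 0.3, 9.0) == "recall"

    def test_high_m_low_rate_is_learning(self):
        assert classify_mode(0.9, 4.5, 0.95, 4.0, 0.3, 9.0) == "learning"

    def test_mixed_evidence_defaults_to_learning(self):
        assert classify_mode(0.3, 3.0, 0.95, 4.0, 0.3, 9.0) == "learning"


class TestConfig:
    def test_invalid_durations_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(session_ms=0.0)
        with pytest.raises(ValueError):
            ExperimentConfig(n_sessions=0)


class TestNoveltySwitch:
    def test_trained_probe_recalls_and_novel_probe_learns(self, trained_state):
        net = trained_state["net"]
        odor = trained_state["odor"]
        cfg = ExperimentConfig(seed=11)
        net.W = trained_state["weights"].copy()
        naive_ref = (trained_state["sessions"][0].mean_m(),
                     trained_state["sessions"][0].mean_rate("Pyr"))
        recall_probe = run_session(net, odor, cfg, label="recall")
        recall_ref = (recall_probe.m_mean, recall_probe.rates["Pyr"])

        net.W = trained_state["weights"].copy()
        res = run_novelty_switch(cfg, net, odor, odor, naive_ref, recall_ref)
        assert res.mode == "recall"

        # single far probes sit near the classifier midpoint, so the
        # novel-odor claim is checked on statistics averaged over probes:
        # dissimilar odors must raise modulation and lower the rate relative
        # to the trained-odor probe, and the averaged state must classify
        # as learning
        m_vals, r_vals = [], []
        for k in (7, 8, 9):
            novel = olfnet.morph_odor(odor, 1.0, rng=k)
            net.W = trained_state["weights"].copy()
            res = run_novelty_switch(cfg, net, odor, novel, naive_ref, recall_ref)
            m_vals.append(res.sessions[0].m_mean)
            r_vals.append(res.sessions[0].rates["Pyr"])
        assert np.mean(m_vals) > recall_ref[0]
        assert np.mean(r_vals) < recall_ref[1]
        assert classify_mode(np.mean(m_vals), np.mean(r_vals),
                             *naive_ref, *recall_ref) == "learning"
        net.W = trained_state["weights"].copy()

    def test_untrained_network_stays_in_learning_mode(self):
        cfg = ExperimentConfig(seed=21)
        net = olfnet.build_network(seed=21)
        odor = olfnet.generate_odor(31)
        # references from a separately trained sibling network
        trained = olfnet.build_network(seed=22)
        for _ in range(9):
            run_session(trained, odor, cfg)
        recall_probe = run_session(trained, odor, cfg)
        naive = run_session(olfnet.build_network(seed=23), odor, cfg)
        res = run_novelty_switch(
            cfg, net, odor, odor,
            (naive.m_mean, naive.rates["Pyr"]),
            (recall_probe.m_mean, recall_probe.rates["Pyr"]),
        )
        assert res.mode == "learning"


class TestTrainingProtocol:
    @pytest.fixture(scope="class")
    def results(self):
        """Three independent protocol runs; trend assertions use the mean
        trajectory (single runs are noisy at 100 units / 1 s sessions)."""
        return [run_training_protocol(ExperimentConfig(seed=s, coherence_pairs=50))
                for s in (33, 34, 35)]

    @staticmethod
    def mean_over(results, field, group=None):
        out = []
        for i in range(11):
            vals = [getattr(r.sessions[i], field)[group] if group
                    else getattr(r.sessions[i], field) for r in results]
            out.append(np.mean(vals))
        return out

    def test_session_structure(self, results):
        labels = [s.label for s in results[0].sessions]
        assert labels[:9] == [f"train{k}" for k in range(1, 10)]
        assert labels[9:] == ["probe_trained", "probe_novel"]

    def test_pyramidal_rate_grows_with_training(self, results):
        rates = self.mean_over(results, "rates", "Pyr")
        assert rates[8] > rates[0]

    def test_cholinergic_activity_falls_with_familiarity(self, results):
        ac = self.mean_over(results, "rates", "Ac")
        m = self.mean_over(results, "m_mean")
        assert ac[8] < ac[0]     # familiarity suppresses cholinergic firing
        assert m[8] < m[0]       # and with it the modulation level

    def test_novel_probe_rebounds_toward_baseline(self, results):
        m = self.mean_over(results, "m_mean")
        assert m[10] > m[9]      # novel odor restores modulation vs recall

    def test_weight_mass_grows(self, results):
        n = 100
        initial_mean = 0.02 * n * (n - 1)
        assert all(r.weights_sum > initial_mean for r in results)

    def test_frame_export(self, results):
        frame = results[0].session_frame()
        assert {"session", "label", "M", "rate_Pyr"} <= set(frame.columns)
        assert len(frame) == 11


class TestDistanceSweep:
    @pytest.fixture(scope="class")
    def sweep(self):
        cfg = ExperimentConfig(seed=55, n_repeats=4,
                               sweep_fractions=(0.0, 0.5, 1.0),
                               coherence_pairs=0)
        return run_distance_sweep(cfg)

    def test_tidy_table_shape(self, sweep):
        assert len(sweep) == 4 * 3
        assert {"repeat", "fraction", "distance", "M", "rate_Pyr", "mode"} <= set(sweep.columns)

    def test_distance_axis_is_monotone_in_fraction(self, sweep):
        s = sweep_summary(sweep)
        d = s.sort_values("fraction")["distance"].to_numpy()
        assert np.all(np.diff(d) > 0)

    def test_modulation_rises_with_distance(self, sweep):
        s = sweep_summary(sweep).sort_values("distance")
        assert s["M"].iloc[-1] > s["M"].iloc[0]

    def test_trained_probe_is_recall_for_majority(self, sweep):
        s = sweep_summary(sweep)
        assert s[s["fraction"] == 0.0]["learning_share"].iloc[0] < 0.5

    def test_switch_distance_found(self, sweep):
        d = switch_distance(sweep)
        assert 0.0 < d <= 1.0

    def test_full_repeat_determinism(self):
        cfg = ExperimentConfig(seed=77, n_repeats=1, sweep_fractions=(0.0, 1.0),
                               coherence_pairs=0)
        t1 = run_distance_sweep(cfg)
        t2 = run_distance_sweep(cfg)
        assert t1.equals(t2)


class TestCli:
    def test_simulate_writes_raster_and_metrics(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "simulate", "--seed", "1", "--out", str(tmp_path), "--duration", "200",
        ])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "metrics.json").exists()
        assert (tmp_path / "raster_Pyr.csv").exists()
        meta = json.loads((tmp_path / "run_metadata.json").read_text())
        assert meta["seed"] == 1

    def test_calibrate_emits_constants_and_curve(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "calibrate", "--seed", "2", "--out", str(tmp_path),
            "--duration", "600",
        ])
        assert res.exit_code == 0, res.output
        fitted = json.loads((tmp_path / "calibration.json").read_text())
        assert fitted["gain"] > 0
        assert 0 < fitted["Y_half"] < 1
        assert (tmp_path / "m_of_a.csv").exists()
        assert (tmp_path / "calibrated_config.yaml").exists()

    def test_gen_odors_writes_pool(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "gen-odors", "--seed", "3", "--out", str(tmp_path), "--n", "5",
        ])
        assert res.exit_code == 0, res.output
        rows = np.loadtxt(tmp_path / "odors.csv", delimiter=",")
        assert rows.shape == (5, 100)

    def test_switch_command_classifies(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "switch", "--seed", "4", "--out", str(tmp_path),
            "--probe-fraction", "1.0", "--sessions", "3",
        ])
        assert res.exit_code == 0, res.output
        payload = json.loads((tmp_path / "switch.json").read_text())
        assert payload["mode"] in ("learning", "recall")
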