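"""The reporter-expression statistic and derived scores."""

import numpy as np
import pandas as pd
import pytest

import fmdsbr
from fmdsbr.scoring import ScoringError


def _table(channel_values: dict, cocktail="none", sample_id="t"):
    return fmdsbr.EventTable(pd.DataFrame(channel_values), sample_id=sample_id,
                             cocktail=cocktail)


def _hand_tables(panel):
    """Damaged sample with (200 positives @ MFI 1500) BFP and (1000 @ 2000)
    AmCyan; undamaged with (800 @ 3000) and (1000 @ 2000). Hand arithmetic:
    X = 0.15, Y = 1.2, score 12.5%."""
    n = 2000

    def build(bfp_n, bfp_mfi, amcyan_n, amcyan_mfi, cocktail):
        cols = {ch: np.zeros(n) for ch in panel.channel_names}
        cols["VL1"][:bfp_n] = bfp_mfi
        cols["VL2"][:amcyan_n] = amcyan_mfi
        # keep other reporters' channels populated so all pathways score
        cols["BL1"][:bfp_n] = bfp_mfi
        cols["YL1"][:bfp_n] = bfp_mfi
        return _table(cols, cocktail=cocktail)

    damaged = build(200, 1500, 1000, 2000, "damaged")
    undamaged = build(800, 3000, 1000, 2000, "undamaged")
    gates = fmdsbr.GateSet({ch: 10.0 for ch in panel.channel_names})
    return damaged, undamaged, gates


class TestReporterExpression:
    def test_self_comparison_is_exactly_100(self, panel):
        truth = fmdsbr.SimulationTruth(n_events=10_000, seed=33)
        und, _ = fmdsbr.simulate_sample(truth, panel, "undamaged")
        gates = fmdsbr.GateSet({ch: 100.0 for ch in panel.channel_names})
        for score in fmdsbr.reporter_expression(und, und, panel, gates):
            assert score.percent_expression == 100.0
            assert score.x_value == score.y_value

    def test_hand_arithmetic_case(self, panel):
        damaged, undamaged, gates = _hand_tables(panel)
        scores = {s.pathway: s for s in
                  fmdsbr.reporter_expression(damaged, undamaged, panel, gates)}
        nhej = scores["NHEJ"]
        assert nhej.x_value == pytest.approx(0.15, abs=1e-12)
        assert nhej.y_value == pytest.approx(1.2, abs=1e-12)
        assert nhej.percent_expression == pytest.approx(12.5, abs=1e-9)
        assert nhej.counts_and_mfi["reporter_damaged"] == (200, 1500.0)
        assert nhej.counts_and_mfi["control_undamaged"] == (1000, 2000.0)

    def test_channel_rescaling_cancels(self, panel):
        """Multiplying one channel by a gain factor in both samples (with the
        control-derived gate rescaled accordingly) leaves scores unchanged."""
        damaged, undamaged, gates = _hand_tables(panel)
        base = {s.pathway: s.percent_expression
                for s in fmdsbr.reporter_expression(damaged, undamaged, panel, gates)}
        factor = 37.5
        dam2 = _table({ch: damaged.data[ch] * (factor if ch == "VL1" else 1)
                       for ch in panel.channel_names}, "damaged")
        und2 = _table({ch: undamaged.data[ch] * (factor if ch == "VL1" else 1)
                       for ch in panel.channel_names}, "undamaged")
        gates2 = fmdsbr.GateSet(
            {ch: gates[ch] * (factor if ch == "VL1" else 1) for ch in panel.channel_names}
        )
        for s in fmdsbr.reporter_expression(dam2, und2, panel, gates2):
            assert s.percent_expression == pytest.approx(base[s.pathway], rel=1e-9)

    def test_control_channel_rescaling_cancels(self, panel):
        damaged, undamaged, gates = _hand_tables(panel)
        base = {s.pathway: s.percent_expression
                for s in fmdsbr.reporter_expression(damaged, undamaged, panel, gates)}
        factor = 0.2
        dam2 = _table({ch: damaged.data[ch] * (factor if ch == "VL2" else 1)
                       for ch in panel.channel_names}, "damaged")
        und2 = _table({ch: undamaged.data[ch] * (factor if ch == "VL2" else 1)
                       for ch in panel.channel_names}, "undamaged")
        gates2 = fmdsbr.GateSet(
            {ch: gates[ch] * (factor if ch == "VL2" else 1) for ch in panel.channel_names}
        )
        for s in fmdsbr.reporter_expression(dam2, und2, panel, gates2):
            assert s.percent_expression == pytest.approx(base[s.pathway], rel=1e-9)

    def test_zero_control_count_is_loud(self, panel):
        damaged, undamaged, _ = _hand_tables(panel)
        gates = fmdsbr.GateSet({ch: 1e9 if ch == "VL2" else 10.0
                                for ch in panel.channel_names})
        with pytest.raises(ScoringError, match="AmCyan"):
            fmdsbr.reporter_expression(damaged, undamaged, panel, gates)

    def test_zero_y_flags_undefined_score(self, panel):
        damaged, undamaged, gates = _hand_tables(panel)
        # empty the undamaged BFP channel: Y = 0 for NHEJ
        data = undamaged.data.copy()
        data["VL1"] = 0.0
        und2 = fmdsbr.EventTable(data, cocktail="undamaged")
        scores = {s.pathway: s for s in
                  fmdsbr.reporter_expression(damaged, und2, panel, gates)}
        assert not scores["NHEJ"].defined
        assert scores["MMEJ"].defined

    def test_simulated_hr_recovery(self, matched_panel):
        """Repair efficiency 1.5% at n = 100,000 recovers 1.5 ± 0.3 percent."""
        truth = fmdsbr.SimulationTruth(n_events=100_000, seed=8)
        dam, _ = fmdsbr.simulate_sample(truth, matched_panel, "damaged")
        und, _ = fmdsbr.simulate_sample(truth, matched_panel, "undamaged")
        neg = fmdsbr.simulate_single_color_controls(truth, matched_panel)["negative"]
        spill = truth.spillover
        gates = fmdsbr.fit_gates(
            fmdsbr.compensate(neg, spill),
            sorted(set(matched_panel.fluorophore_channels.values())),
        )
        scores = {s.pathway: s for s in fmdsbr.reporter_expression(
            fmdsbr.compensate(dam, spill), fmdsbr.compensate(und, spill),
            matched_panel, gates)}
        assert scores["HR"].percent_expression == pytest.approx(1.5, abs=0.3)


class TestNormalizeToControl:
    def test_identical_replicates_give_fold_one(self):
        ns = fmdsbr.normalize_to_control([1.2, 1.4, 1.0], [1.2, 1.4, 1.0])
        assert ns.fold_change == 1.0

    def test_parental_vs_resistant_hr_ratio(self):
        """HR of 1.5% in the resistant line over 0.71% parental: fold 2.11."""
        ns = fmdsbr.normalize_to_control([1.5], [0.71], "resistant", "parental")
        assert ns.fold_change == pytest.approx(2.11, abs=0.005)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ScoringError, match="control mean"):
            fmdsbr.normalize_to_control([1.0], [0.0])

    def test_mismatched_pathways_rejected(self, panel):
        a = fmdsbr.ReporterScore("HR", 1.0, 0.01, 1.0, {})
        b = fmdsbr.ReporterScore("NHEJ", 10.0, 0.1, 1.0, {})
        with pytest.raises(ScoringError, match="mismatch"):
            fmdsbr.normalize_to_control([a], [b])


class TestSceReporterPercent:
    def test_count_arithmetic(self):
        table = _table({
            "BL1": np.concatenate([np.full(50, 5000.0), np.zeros(950)]),
            "VL1": np.concatenate([np.full(200, 5000.0), np.zeros(800)]),
        })
        assert fmdsbr.sce_reporter_percent(table, 100.0, 100.0) == 25.0

    def test_sample_equal_to_background_is_zero(self):
        table = _table({
            "BL1": np.concatenate([np.full(10, 5000.0), np.zeros(90)]),
            "VL1": np.concatenate([np.full(50, 5000.0), np.zeros(50)]),
        })
        assert fmdsbr.sce_reporter_percent(table, 100.0, 100.0, background=table) == 0.0

    def test_zero_bfp_positive_is_error(self):
        table = _table({"BL1": np.full(10, 5000.0), "VL1": np.zeros(10)})
        with pytest.raises(ScoringError, match="BFP"):
            fmdsbr.sce_reporter_percent(table, 100.0, 100.0)

    def test_generative_model_recovery(self):
        """Conversion probability 0.05 recovers a ~5% normalized signal."""
        sample, _ = fmdsbr.simulate_sce_reporter(
            0.05, 0.5, background_rate=0.0, n_events=100_000, seed=14
        )
        value = fmdsbr.sce_reporter_percent(sample, 500.0, 500.0)
        assert value == pytest.approx(5.0, rel=0.15)


class TestMarkerFractionByPhase:
    def _phases(self, labels):
        return fmdsbr.PhaseLabels(np.asarray(labels, dtype=object),
                                  (1.0, 2.0, 3.0, 4.0))

    def test_all_below_threshold(self):
        table = _table({"RL1": np.full(100, 1.0)})
        phases = self._phases(["G1"] * 100)
        mf = fmdsbr.marker_fraction_by_phase(table, "RL1", 100.0, phases)
        assert mf.overall_fraction == 0.0
        assert mf.per_phase["G1"] == 0.0

    def test_g2m_fraction_hand_case(self):
        marker = np.concatenate([np.full(30, 500.0), np.zeros(70), np.zeros(50)])
        table = _table({"RL1": marker})
        phases = self._phases(["G2M"] * 100 + ["G1"] * 50)
        mf = fmdsbr.marker_fraction_by_phase(table, "RL1", 100.0, phases)
        assert mf.per_phase["G2M"] == pytest.approx(0.30)
        assert mf.counts["G2M"] == (30, 100)

    def test_empty_phase_flagged_missing(self):
        table = _table({"RL1": np.zeros(10)})
        phases = self._phases(["G1"] * 10)
        mf = fmdsbr.marker_fraction_by_phase(table, "RL1", 1.0, phases)
        assert np.isnan(mf.per_phase["S"])

    def test_phase_dependent_recovery(self):
        """Per-phase positivity (0.05, 0.4, 0.6) recovered within ±0.03 at
        n = 50,000 using gated (not truth) phase labels."""
        truth = fmdsbr.CellCycleTruth(
            marker_positive_prob={"G1": 0.05, "S": 0.4, "G2M": 0.6},
            n_events=50_000, seed=6,
        )
        table, _ = fmdsbr.simulate_cell_cycle_sample(truth)
        phases = fmdsbr.gate_cell_cycle(table, truth.dna_channel)
        threshold = float(np.exp(truth.marker_mu_neg + 3.1 * truth.marker_sigma))
        mf = fmdsbr.marker_fraction_by_phase(table, truth.marker_channel,
                                             threshold, phases)
        assert mf.per_phase["G1"] == pytest.approx(0.05, abs=0.03)
        assert mf.per_phase["S"] == pytest.approx(0.40, abs=0.03)
        assert mf.per_phase["G2M"] == pytest.approx(0.60, abs=0.03)
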