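"""Tests of index computation, deltas, the stress rule and parameter estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from behaviordyn.physio import (
    BASELINE,
    MEDIA_CONDITIONS,
    TASK_CONDITION,
    StressRuleConfig,
    apply_stress_rule,
    compute_deltas,
    eeg_asymmetry,
    emg_rms,
    estimate_parameters,
    hrv_frequency_domain,
    hrv_time_domain,
    respiration_features,
    threshold_sweep,
)
from behaviordyn.cohort import CohortSpec, generate_index_table, generate_nn_series


class TestHRVTimeDomain:
    def test_constant_series(self):
        res = hrv_time_domain([800, 800, 800, 800])
        assert (res.avnn, res.sdnn, res.rmssd, res.pnn50) == (800.0, 0.0, 0.0, 0.0)

    def test_alternating_series_hand_values(self):
        res = hrv_time_domain([800, 860, 800, 860])
        assert res.pnn50 == 100.0  # all three diffs have magnitude 60 > 50
        assert res.rmssd == pytest.approx(60.0)

    def test_against_brute_force_loop_oracle(self, rng):
        for _ in range(200):
            nn = rng.uniform(400, 1200, size=int(rng.integers(2, 40)))
            res = hrv_time_domain(nn)
            mean = sum(nn) / len(nn)
            sd = math.sqrt(sum((x - mean) ** 2 for x in nn) / (len(nn) - 1))
            diffs = [nn[i + 1] - nn[i] for i in range(len(nn) - 1)]
            rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
            pnn50 = 100.0 * sum(1 for d in diffs if abs(d) > 50) / len(diffs)
            assert res.avnn == pytest.approx(mean, abs=1e-9)
            assert res.sdnn == pytest.approx(sd, abs=1e-9)
            assert res.rmssd == pytest.approx(rmssd, abs=1e-9)
            assert res.pnn50 == pytest.approx(pnn50, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hrv_time_domain([800])


class TestHRVFrequencyDomain:
    def test_lf_tone_dominates(self):
        nn = generate_nn_series(300, 800, lf_amp_ms=50, hf_amp_ms=0, noise_sd_ms=0, seed=1)
        assert hrv_frequency_domain(nn).lf_hf > 10

    def test_hf_tone_dominates(self):
        nn = generate_nn_series(300, 800, lf_amp_ms=0, hf_amp_ms=50, noise_sd_ms=0, seed=1)
        assert hrv_frequency_domain(nn).lf_hf < 0.1

    def test_normalized_units_sum_to_hundred(self):
        nn = generate_nn_series(300, 800, lf_amp_ms=40, hf_amp_ms=30, noise_sd_ms=0, seed=2)
        sp = hrv_frequency_domain(nn)
        assert sp.lf_nu + sp.hf_nu == pytest.approx(100.0, abs=5.0)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            hrv_frequency_domain([800] * 20)


class TestSignalFeatures:
    def test_emg_rms_zero_and_constant(self):
        assert np.all(emg_rms(np.zeros(100), 10) == 0.0)
        assert np.allclose(emg_rms(np.full(100, -3.0), 10), 3.0)

    def test_emg_rms_of_sine(self):
        x = np.sin(2 * np.pi * np.arange(1000) / 100)
        assert emg_rms(x, 100) == pytest.approx(1 / math.sqrt(2), rel=0.01)

    def test_emg_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            emg_rms(np.zeros(10), 11)

    @pytest.mark.parametrize("freq, period", [(0.25, 4.0), (0.2, 5.0)])
    def test_respiration_sinusoid(self, freq, period):
        fs = 20.0
        t = np.arange(0, 60, 1 / fs)
        res = respiration_features(np.sin(2 * np.pi * freq * t), fs)
        assert res.depth == pytest.approx(2.0, rel=0.01)
        assert res.period == pytest.approx(period, rel=0.02)
        assert res.rate == pytest.approx(60.0 / period, rel=0.02)

    def test_flat_signal_has_undefined_rate(self):
        res = respiration_features(np.zeros(100), 10.0)
        assert res.depth == 0.0 and math.isnan(res.rate)

    @pytest.mark.parametrize(
        "right, left, expected", [(5, 5, 0.0), (2, 1, 1 / 3), (1, 0, 1.0)]
    )
    def test_eeg_asymmetry(self, right, left, expected):
        assert eeg_asymmetry(right, left) == pytest.approx(expected)

    def test_eeg_asymmetry_both_zero(self):
        with pytest.raises(ValueError):
            eeg_asymmetry(0.0, 0.0)


def _mini_table(rows):
    return pd.DataFrame(rows, columns=["subject", "group", "condition", "index", "value"])


class TestDeltas:
    def test_relative_change(self):
        table = _mini_table(
            [
                ("s1", "g", BASELINE, "SDNN", 10.0),
                ("s1", "g", "VR", "SDNN", 15.0),
                ("s1", "g", "AUDIO", "SDNN", 10.0),
            ]
        )
        deltas = compute_deltas(table).set_index("condition")["delta"]
        assert deltas["VR"] == pytest.approx(0.5)
        assert deltas["AUDIO"] == 0.0

    def test_self_report_raw_difference(self):
        table = _mini_table(
            [
                ("s1", "g", BASELINE, "SUS", 3.0),
                ("s1", "g", "VR", "SUS", 4.5),
            ]
        )
        assert compute_deltas(table)["delta"].iloc[0] == pytest.approx(1.5)

    def test_zero_baseline_flagged_missing(self):
        table = _mini_table(
            [
                ("s1", "g", BASELINE, "SDNN", 0.0),
                ("s1", "g", "VR", "SDNN", 10.0),
            ]
        )
        out = compute_deltas(table)
        assert bool(out["missing"].iloc[0]) and math.isnan(out["delta"].iloc[0])

    def test_missing_baseline_rejected(self):
        table = _mini_table([("s1", "g", "VR", "SDNN", 10.0)])
        with pytest.raises(ValueError, match="Baseline"):
            compute_deltas(table)


def _delta_frame(values, condition="VR", subject="s1", group="g"):
    return pd.DataFrame(
        [
            {"subject": subject, "group": group, "condition": condition,
             "index": idx, "delta": v, "missing": False}
            for idx, v in values.items()
        ]
    )


class TestStressRule:
    def test_all_zero_not_flagged(self):
        deltas = _delta_frame({i: 0.0 for i in ("EMG-Z", "SC_Mean", "SDNN", "PMQ_Anxiety")})
        out = apply_stress_rule(deltas, StressRuleConfig(st=0.2))
        assert not out["flagged"].iloc[0]

    def test_self_report_clause(self):
        deltas = _delta_frame({"PMQ_Anxiety": 0.3, "SDNN": 0.0})
        out = apply_stress_rule(deltas, StressRuleConfig(st=0.2))
        assert out["flagged"].iloc[0] and "self_report" in out["clauses"].iloc[0]

    def test_facial_block_requires_electrodermal_gate(self):
        flagged = apply_stress_rule(
            _delta_frame({"EMG-CS": 0.3, "SC_Mean": 0.5}), StressRuleConfig(st=0.2)
        )
        assert flagged["flagged"].iloc[0]
        assert "facial_electrodermal" in flagged["clauses"].iloc[0]
        gated = apply_stress_rule(
            _delta_frame({"EMG-CS": 0.3, "SC_Mean": 0.1}), StressRuleConfig(st=0.2)
        )
        assert not gated["flagged"].iloc[0]

    def test_single_autonomic_shift_triggers(self):
        out = apply_stress_rule(_delta_frame({"rMSSD": -0.4}), StressRuleConfig(st=0.2))
        assert out["flagged"].iloc[0] and "autonomic" in out["clauses"].iloc[0]

    def test_combination_block_counts_eeg(self):
        # EEG shifts alone cannot fire the autonomic block but two of them
        # satisfy the default couple in the combination block.
        out = apply_stress_rule(
            _delta_frame({"Alpha": -0.5, "Beta": 0.5}), StressRuleConfig(st=0.2)
        )
        assert out["flagged"].iloc[0] and out["clauses"].iloc[0] == "combination"

    def test_sus_clause_switchable(self):
        deltas = _delta_frame({"SUS": 0.05})
        assert apply_stress_rule(deltas, StressRuleConfig(st=0.2))["flagged"].iloc[0]
        assert not apply_stress_rule(
            deltas, StressRuleConfig(st=0.2, include_sus=False)
        )["flagged"].iloc[0]

    def test_missing_values_never_trigger(self):
        deltas = _delta_frame({"rMSSD": np.nan, "SDNN": np.nan})
        out = apply_stress_rule(deltas, StressRuleConfig(st=0.2))
        assert not out["flagged"].iloc[0]

    def test_flag_monotone_in_threshold(self):
        """Raising ST can only shrink the flagged set (presence clause off)."""
        table, _ = generate_index_table(CohortSpec(seed=77))
        deltas = compute_deltas(table)
        cfg = StressRuleConfig(include_sus=False)
        prev = None
        for st_val in (0.05, 0.15, 0.3, 0.6):
            from dataclasses import replace

            flags = apply_stress_rule(deltas, replace(cfg, st=st_val))
            cur = set(map(tuple, flags[flags["flagged"]][["subject", "condition"]].values))
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestEstimation:
    def _flags(self, flag_map):
        rows = []
        for subject, flagged in flag_map.items():
            for cond in (*MEDIA_CONDITIONS, TASK_CONDITION):
                rows.append(
                    {"subject": subject, "group": "g", "condition": cond,
                     "flagged": flagged, "clauses": ""}
                )
        return pd.DataFrame(rows)

    def test_nobody_flagged(self):
        res = estimate_parameters(self._flags({f"s{i}": False for i in range(5)}))
        assert res.params("g") == (0.0, 0.0)

    def test_everyone_flagged(self):
        res = estimate_parameters(self._flags({f"s{i}": True for i in range(5)}))
        assert res.params("g") == (1.0, 1.0)

    def test_proportion(self):
        flag_map = {f"s{i}": i < 4 for i in range(10)}
        res = estimate_parameters(self._flags(flag_map))
        assert res.params("g")[0] == pytest.approx(0.4)

    def test_missing_condition_rejected(self):
        flags = self._flags({"s1": True})
        with pytest.raises(ValueError):
            estimate_parameters(flags[flags["condition"] != TASK_CONDITION])


class TestThresholdSweep:
    def test_monotone_non_increasing(self):
        table, _ = generate_index_table(CohortSpec(seed=11))
        sweep = threshold_sweep(
            table, [0.05, 0.1, 0.2, 0.4, 0.7, 1.0], StressRuleConfig(include_sus=False)
        )
        for _, sub in sweep.groupby("group"):
            assert np.all(np.diff(sub["adoption_fraction"]) <= 1e-12)
            assert np.all(np.diff(sub["imitation_effectiveness"]) <= 1e-12)
            # hardest threshold attains the grid minimum
            assert sub["adoption_fraction"].iloc[-1] == sub["adoption_fraction"].min()

    def test_parameters_bounded(self):
        table, _ = generate_index_table(CohortSpec(seed=12))
        sweep = threshold_sweep(table, np.linspace(0.0, 1.0, 6))
        vals = sweep[["adoption_fraction", "imitation_effectiveness"]]
        assert ((vals >= 0) & (vals <= 1)).all().all()

    def test_plateau_recovers_responder_share(self):
        """Half the cohort responds with large effects: curves plateau near 0.5."""
        spec = CohortSpec(
            n_subjects={"g": 40},
            responder_prob={"g": 0.5},
            effect_size=0.5,
            noise_sd=0.05,
            seed=13,
        )
        table, truth = generate_index_table(spec)
        sweep = threshold_sweep(table, [0.2, 0.3], StressRuleConfig(include_sus=False))
        realized = truth.realized().set_index("group").loc["g", "adoption_fraction"]
        for _, row in sweep.iterrows():
            assert row["adoption_fraction"] == pytest.approx(realized, abs=0.1)

    def test_empty_grid_rejected(self):
        table, _ = generate_index_table(CohortSpec(seed=1))
        with pytest.raises(ValueError):
            threshold_sweep(table, [])
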