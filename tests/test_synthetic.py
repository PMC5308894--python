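"""Synthetic patch-clamp datasets: fidelity, determinism, paradigms."""

import numpy as np
import pytest

from cav3sim import Boltzmann
from cav3sim.fitting import recovery_ratio
from cav3sim.synthetic import (
    APWaveform,
    SyntheticConfig,
    default_burst_waveform,
    make_ap_clamp_dataset,
    make_recovery_dataset,
    make_ssi_dataset,
    make_train_dataset,
    write_dataset,
)


class TestSSIDataset:
    @pytest.mark.parametrize("stim,expected", [("stim1", -72.4), ("stim40", -81.1)])
    def test_noiseless_fit_recovers_printed_midpoint(self, clean_config, stim, expected):
        _, df = make_ssi_dataset(clean_config, stim_index=stim)
        res = Boltzmann(df["v_cond"].to_numpy(), df["p2_norm"].to_numpy()).fit()
        assert res.converged
        assert res.v_half == pytest.approx(expected, abs=1.0)

    def test_seeded_runs_are_byte_identical(self):
        cfg = SyntheticConfig(n_cells=2, seed=7, sample_dt=0.2)
        _, a = make_ssi_dataset(cfg)
        _, b = make_ssi_dataset(cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_averaging_cells_shrinks_midpoint_spread(self):
        # across fixed seeds, means over 5 cells scatter less than single cells
        singles, means = [], []
        for seed in (11, 12, 13):
            _, df1 = make_ssi_dataset(SyntheticConfig(n_cells=1, seed=seed, sample_dt=0.2))
            singles.append(Boltzmann(df1["v_cond"].to_numpy(),
                                     df1["p2_norm"].to_numpy()).fit().v_half)
            _, df5 = make_ssi_dataset(SyntheticConfig(n_cells=5, seed=seed, sample_dt=0.2))
            vh = [Boltzmann(g["v_cond"].to_numpy(), g["p2_norm"].to_numpy()).fit().v_half
                  for _, g in df5.groupby("cell")]
            means.append(np.mean(vh))
        assert np.std(means) < np.std(singles)


class TestTrainDataset:
    def test_egta_train_declines(self, clean_config):
        _, df = make_train_dataset(clean_config, n_sweeps=60)
        amps = df["amp"].to_numpy()
        assert amps[-1] < amps[1]  # slow Ca2+-driven decline beyond settling
        assert df["s"].iloc[-1] > 0.01

    def test_higher_frequency_not_supported_beyond_pulse(self, clean_config):
        with pytest.raises(ValueError):
            make_train_dataset(clean_config, freq=2.5)


class TestRecoveryDataset:
    def test_no_shift_means_no_recovery_gain(self, clean_config):
        _, summary = make_recovery_dataset(clean_config, force_s=0.0, recovery_s=30.0)
        assert summary["recovery_ratio"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_full_shift_recovery_ratio_near_availability_gain(self, clean_config):
        # at -70 mV the resting/shifted availability ratio (~4) dominates
        cfg = clean_config.model_copy(update={"attenuation_alpha": 0.0})
        _, summary = make_recovery_dataset(cfg, force_s=1.0)
        assert 3.5 < summary["recovery_ratio"].iloc[0] < 5.5

    def test_deterministic_under_fixed_seed(self):
        cfg = SyntheticConfig(n_cells=2, seed=3, sample_dt=0.2)
        _, s1 = make_recovery_dataset(cfg, force_s=1.0, recovery_s=20.0)
        _, s2 = make_recovery_dataset(cfg, force_s=1.0, recovery_s=20.0)
        assert s1.to_csv(index=False) == s2.to_csv(index=False)


class TestAPClamp:
    def test_waveform_shape(self):
        w = default_burst_waveform()
        t, v = w.sample(0.1)
        assert len(w.spike_times) == 13
        assert np.all(np.diff(w.spike_times) > 0)
        assert v.min() >= -100.0 and v.max() <= w.spike_peak_v + 1e-9
        assert len(t) == len(v)

    def test_waveform_needs_a_spike(self):
        with pytest.raises(ValueError):
            APWaveform(n_spikes=0)

    def test_spike_facilitation_and_burst_decay(self, clean_config):
        cfg = clean_config.model_copy(update={"sample_dt": 0.05})
        _, spikes, _ = make_ap_clamp_dataset(cfg, n_repeats=2)
        first = spikes[spikes["repeat"] == 0].set_index("spike")["amp"]
        # Ca-independent facilitation early in the burst, decay by its end
        assert first[4] / first[1] > 1.0
        assert first[13] / first[1] < 1.0

    def test_bapta_total_current_decline_below_15_percent(self, clean_config):
        cfg = clean_config.model_copy(update={"buffer": "bapta", "sample_dt": 0.1})
        _, _, aucs = make_ap_clamp_dataset(cfg, n_repeats=40)
        last = aucs[aucs["repeat"] == aucs["repeat"].max()]
        decline = 100.0 * (1.0 - float(last["auc_norm"].mean()))
        assert decline < 15.0

    def test_facilitation_is_buffer_independent(self, clean_config):
        ratios = {}
        for buf in ("egta", "bapta"):
            cfg = clean_config.model_copy(update={"buffer": buf, "sample_dt": 0.05})
            _, spikes, _ = make_ap_clamp_dataset(cfg, n_repeats=1)
            first = spikes[spikes["repeat"] == 0].set_index("spike")["amp"]
            ratios[buf] = first[4] / first[1]
        assert ratios["egta"] == pytest.approx(ratios["bapta"], rel=0.05)


def test_write_dataset_manifest(tmp_path, clean_config):
    traces, df = make_ssi_dataset(
        clean_config, v_cond=np.arange(-130.0, -39.9, 15.0), conditioning_ms=500.0
    )
    out = write_dataset(tmp_path / "ds", traces[:2], {"ssi": df}, clean_config,
                        {"paradigm": "ssi"})
    assert (out / "manifest.json").exists()
    assert (out / "ssi.csv").exists()
    assert (out / "trace_0000.csv").exists()
    assert (out / "trace_0000.json").exists()
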