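"""Schedule constraints, template shape, signal model, artifact injection."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p300decode import (
    ErpTemplateParams,
    SimulationConfig,
    erp_template,
    extract_epochs,
    inject_artifacts,
    make_schedule,
    simulate_session,
)
from p300decode.simulate import FLASH_PERIOD_S, rounds_per_block


class TestSchedule:
    def test_flash_counts_match_oddball_identity(self):
        cfg = SimulationConfig(n_symbols=5, min_target_flashes=280, seed=0)
        events, _ = make_schedule(cfg)
        assert (events["label"] == "target").sum() == 280
        assert (events["label"] == "nontarget").sum() == 1120

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        n_symbols=st.integers(4, 9),
        min_target=st.integers(1, 60),
        seed=st.integers(0, 2**20),
    )
    def test_schedule_constraints(self, n_symbols, min_target, seed):
        """No-repeat, equal per-symbol counts per block, exact spacing."""
        cfg = SimulationConfig(
            n_symbols=n_symbols, min_target_flashes=min_target, seed=seed
        )
        events, targets = make_schedule(cfg)
        step = round(FLASH_PERIOD_S * cfg.sampling_rate)
        total_targets = 0
        for b, grp in events[events["phase"] == "stimulation"].groupby("block_id"):
            idx = grp["stimulus_index"].to_numpy()
            assert not np.any(idx[1:] == idx[:-1])
            counts = np.bincount(idx, minlength=n_symbols)
            assert counts.min() == counts.max() == rounds_per_block(cfg)
            assert np.all(np.diff(grp["onset_sample"].to_numpy()) == step)
            assert set(grp.loc[grp["label"] == "target", "stimulus_index"]) <= {
                targets[b]
            }
            total_targets += (grp["label"] == "target").sum()
        assert total_targets >= min_target

    def test_target_choice_uniform(self):
        """Block targets drawn uniformly over symbols (binomial CI)."""
        cfg = SimulationConfig(n_symbols=4, min_target_flashes=1)
        hits = []
        for seed in range(2000):
            _, targets = make_schedule(cfg, seed=seed)
            hits.append(targets[0])
        counts = np.bincount(hits, minlength=4)
        p = 0.25
        ci = 2.81 * np.sqrt(p * (1 - p) * 2000)  # ~99.5% per-cell band
        assert np.all(np.abs(counts - 2000 * p) < ci)

    def test_too_few_symbols_rejected(self):
        with pytest.raises(ValueError, match="n_symbols"):
            SimulationConfig(n_symbols=1)


class TestErpTemplate:
    def test_zero_gain_gives_zero_waveform(self):
        params = ErpTemplateParams(channel_gains={"Pz": 0.0})
        assert np.all(erp_template(params, "SF", "Pz") == 0)

    def test_cf_exceeds_sf_at_posterior_channel(self):
        params = ErpTemplateParams()
        t = np.arange(256) / 256.0
        win = (t >= 0.3) & (t <= 0.4)
        cf = erp_template(params, "CF", "Pz")[win].max()
        sf = erp_template(params, "SF", "Pz")[win].max()
        assert cf > sf
        # frontal channels condition-independent
        np.testing.assert_array_equal(
            erp_template(params, "CF", "Fz"), erp_template(params, "SF", "Fz")
        )

    def test_area_matches_gaussian_closed_form(self):
        params = ErpTemplateParams()
        wave = erp_template(params, "SF", "Pz", sampling_rate=256.0)
        area = wave.sum() / 256.0
        sigma_s = params.peak_width_ms / 1000.0
        gain = params.gain("Pz", "SF")
        expected = (
            gain
            * (params.neg_peak_amplitude_uV + params.pos_peak_amplitude_uV)
            * sigma_s
            * np.sqrt(2 * np.pi)
        )
        assert area == pytest.approx(expected, rel=1e-6)

    def test_latency_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="latency"):
            erp_template(
                ErpTemplateParams(pos_peak_latency_ms=1200.0), "SF", "Pz"
            )


class TestSimulateSession:
    def test_noiseless_session_recovers_template(self):
        cfg = SimulationConfig(
            n_symbols=9, min_target_flashes=30, noise_std=0.0,
            ssvep_amplitude=0.0, seed=4,
        )
        rec = simulate_session(cfg)
        template = erp_template(cfg.erp_params, cfg.condition, "Pz")
        epochs = extract_epochs(rec, window=(0.0, 1.0))
        targets = rec.labelled_events.reset_index(drop=True)
        onsets = targets["onset_sample"].to_numpy()
        t_onsets = onsets[targets["label"] == "target"]
        pz = epochs.channel_names.index("Pz")
        # only windows free of any neighbouring target template are exact
        found = 0
        for row in np.flatnonzero(targets["label"].to_numpy() == "target"):
            onset = onsets[row]
            others = t_onsets[t_onsets != onset]
            if np.any(np.abs(others - onset) < 256):
                continue
            np.testing.assert_allclose(epochs.data[row, :, pz], template, atol=1e-12)
            found += 1
        assert found > 0

    def test_same_seed_reproduces_signals(self):
        cfg = SimulationConfig(min_target_flashes=20, seed=77)
        a = simulate_session(cfg)
        b = simulate_session(cfg)
        np.testing.assert_array_equal(a.signals, b.signals)

    def test_epoch_average_converges_to_template(self):
        """Across-target average converges to the template (LLN).

        Neighbouring target templates leak a small noise-independent
        bias into the average, so the noise contribution is isolated by
        differencing the squared residuals of two noise levels:
        rmse(sigma)^2 = bias^2 + sigma^2 / n_target.
        """
        sq = {}
        n_targets = {}
        for noise in (3.0, 6.0):
            cfg = SimulationConfig(
                n_symbols=4, min_target_flashes=200, noise_std=noise,
                noise_model="white", ssvep_amplitude=0.0, seed=15,
            )
            rec = simulate_session(cfg)
            epochs = extract_epochs(rec, window=(0.0, 1.0))
            pz = epochs.channel_names.index("Pz")
            avg = epochs.data[epochs.is_target, :, pz].mean(axis=0)
            template = erp_template(cfg.erp_params, cfg.condition, "Pz")
            sq[noise] = np.mean((avg - template) ** 2)
            n_targets[noise] = int(epochs.is_target.sum())
        n = n_targets[3.0]
        observed = np.sqrt((sq[6.0] - sq[3.0]) / 3.0)  # isolates sigma_1/sqrt(n)
        assert observed == pytest.approx(3.0 / np.sqrt(n), rel=0.25)


class TestInjectArtifacts:
    def test_zero_rate_leaves_recording_unchanged(self, small_recording):
        out, truth = inject_artifacts(small_recording, 0.0, seed=1)
        np.testing.assert_array_equal(out.signals, small_recording.signals)
        assert len(truth) == 0

    def test_rate_one_p2p_kind_trips_every_epoch(self):
        cfg = SimulationConfig(n_symbols=4, min_target_flashes=20, seed=30)
        rec = simulate_session(cfg)
        out, truth = inject_artifacts(rec, 1.0, seed=2, kinds=("p2p",))
        epochs = extract_epochs(out)
        p2p = epochs.data.max(axis=1) - epochs.data.min(axis=1)
        contaminated = truth["flash_index"].to_numpy()
        assert np.all(p2p[contaminated].max(axis=1) > 200.0)

    def test_contamination_count_binomial(self):
        cfg = SimulationConfig(n_symbols=5, min_target_flashes=200, seed=31)
        rec = simulate_session(cfg)
        _, truth = inject_artifacts(rec, 0.1, seed=3)
        n = len(rec.labelled_events)
        # 99% binomial interval around n * 0.1
        half = 2.576 * np.sqrt(n * 0.1 * 0.9)
        assert abs(len(truth) - 0.1 * n) < half

    def test_rate_out_of_range_rejected(self, small_recording):
        with pytest.raises(ValueError, match="artifact_rate"):
            inject_artifacts(small_recording, 1.5)
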