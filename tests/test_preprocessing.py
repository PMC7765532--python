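"""Epoching conventions, exclusion criteria, FIR filtering, ERP averaging."""

import numpy as np
import pytest

from p300decode import (
    ContinuousRecording,
    SimulationConfig,
    bandpass_epochs,
    compute_erp,
    extract_epochs,
    make_events,
    reject_artifacts,
    simulate_session,
)
from p300decode.preprocessing import CleanEpochSet, EpochSet, band_power_ratio

FS = 256.0


def epochs_from(data, labels=None):
    data = np.asarray(data, dtype=float)
    nt, ns, ne = data.shape
    if labels is None:
        labels = np.array(["target"] * (nt // 2) + ["nontarget"] * (nt - nt // 2))
    times = (np.arange(ns) - 51) / FS
    return EpochSet(
        data=data,
        labels=np.asarray(labels),
        times=times,
        channel_names=tuple(f"ch{i}" for i in range(ne)),
        sampling_rate=FS,
    )


class TestExtractEpochs:
    def test_epoch_window_convention(self):
        ev = make_events([1000], [0], ["target"], [0])
        rec = ContinuousRecording(signals=np.zeros((8, 2000)), events=ev)
        rec.signals[:, 1000] = 7.0  # value at the stimulus onset
        epochs = extract_epochs(rec)
        assert epochs.data.shape == (1, 307, 8)
        assert epochs.times[51] == 0.0
        assert np.all(epochs.data[0, 51, :] == 7.0)

    def test_boundary_event_skipped_with_log(self, caplog):
        ev = make_events([10, 1000], [0, 1], ["target", "nontarget"], [0, 0])
        rec = ContinuousRecording(signals=np.zeros((8, 2000)), events=ev)
        with caplog.at_level("WARNING"):
            epochs = extract_epochs(rec)
        assert epochs.n_epochs == 1
        assert "skipped 1" in caplog.text

    def test_full_session_epoch_count(self):
        cfg = SimulationConfig(n_symbols=5, min_target_flashes=40, seed=12)
        rec = simulate_session(cfg)
        epochs = extract_epochs(rec)
        assert epochs.n_epochs == 200
        assert epochs.is_target.sum() == 40

    def test_no_events_is_an_error(self):
        rec = ContinuousRecording(signals=np.zeros((8, 100)))
        with pytest.raises(ValueError, match="no extractable epochs"):
            extract_epochs(rec)


class TestRejectArtifacts:
    def test_constant_epoch_kept(self):
        clean = reject_artifacts(epochs_from(np.zeros((4, 307, 2))))
        assert clean.n_epochs == 4
        assert clean.report["kept"].all()

    def test_step_over_200uV_rejected_by_p2p(self):
        data = np.zeros((2, 307, 2))
        data[1, 150:, 0] = 201.0
        clean = reject_artifacts(epochs_from(data))
        rep = clean.report
        assert rep.loc[0, "kept"] and not rep.loc[1, "kept"]
        assert rep.loc[1, "p2p"]

    def test_threshold_is_strict(self):
        data = np.zeros((1, 307, 1))
        data[0, ::2, 0] = 0.0
        data[0, 0, 0] = 200.0  # peak-to-peak exactly 200: not rejected
        rep = reject_artifacts(epochs_from(data)).report
        assert not rep.loc[0, "p2p"]

    def test_high_std_rejected(self, rng):
        data = np.zeros((1, 307, 1))
        data[0, :, 0] = rng.choice([-90.0, 90.0], size=307)  # std ~ 90
        rep = reject_artifacts(epochs_from(data)).report
        assert rep.loc[0, "std"] and not rep.loc[0, "kept"]

    def test_pure_30hz_tone_rejected_by_band_ratio(self):
        t = np.arange(307) / FS
        data = 20.0 * np.sin(2 * np.pi * 30.0 * t)[None, :, None]
        ratio = band_power_ratio(data, FS)
        assert ratio[0, 0] > 0.9  # analytically 1 for a pure tone in-band
        rep = reject_artifacts(epochs_from(data)).report
        assert rep.loc[0, "ratio"] and not rep.loc[0, "kept"]

    def test_rejection_is_per_epoch_pure(self, rng):
        data = rng.standard_normal((20, 307, 3)) * 30
        rep1 = reject_artifacts(epochs_from(data)).report
        perm = rng.permutation(20)
        rep2 = reject_artifacts(epochs_from(data[perm])).report
        np.testing.assert_array_equal(
            rep1["kept"].to_numpy()[perm], rep2["kept"].to_numpy()
        )

    def test_rejected_epochs_trip_at_least_one_criterion(self):
        cfg = SimulationConfig(min_target_flashes=60, seed=5, artifact_rate=0.2)
        rec = simulate_session(cfg)
        rep = reject_artifacts(extract_epochs(rec)).report
        rejected = rep[~rep["kept"]]
        assert (rejected[["p2p", "std", "ratio"]].any(axis=1)).all()
        kept = rep[rep["kept"]]
        assert not kept[["p2p", "std", "ratio"]].any(axis=1).any()


class TestBandpass:
    def probe(self, freq, amp=1.0):
        t = np.arange(307) / FS
        data = amp * np.sin(2 * np.pi * freq * t)[None, :, None]
        clean = CleanEpochSet(
            data=data,
            labels=np.array(["target"]),
            times=(np.arange(307) - 51) / FS,
            channel_names=("Pz",),
            sampling_rate=FS,
            report=None,
            filtered=False,
        )
        out = bandpass_epochs(clean)
        # measure in the central half, clear of edge effects
        return out.data[0, 77:230, 0]

    def test_passband_tone_preserved(self):
        out = self.probe(8.0)
        assert np.abs(out).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated_30db(self):
        out = self.probe(30.0)
        assert 20 * np.log10(np.abs(out).max()) < -30.0

    def test_dc_removed(self):
        data = np.full((1, 307, 1), 5.0)
        clean = CleanEpochSet(
            data=data, labels=np.array(["target"]),
            times=(np.arange(307) - 51) / FS, channel_names=("Pz",),
            sampling_rate=FS, report=None, filtered=False,
        )
        out = bandpass_epochs(clean)
        assert np.abs(out.data[0, 77:230, 0]).max() < 0.05

    def test_filter_identical_across_channels_and_epochs(self, rng):
        data = rng.standard_normal((3, 307, 1))
        stacked = np.concatenate([data, data], axis=2)  # same signal, 2 channels
        clean = CleanEpochSet(
            data=stacked, labels=np.array(["target"] * 3),
            times=(np.arange(307) - 51) / FS, channel_names=("a", "b"),
            sampling_rate=FS, report=None, filtered=False,
        )
        out = bandpass_epochs(clean)
        np.testing.assert_allclose(out.data[..., 0], out.data[..., 1], atol=1e-12)


class TestComputeErp:
    def test_identical_epochs_average_to_themselves(self, rng):
        one = rng.standard_normal((307, 2))
        data = np.repeat(one[None], 6, axis=0)
        erp = compute_erp(
            CleanEpochSet(
                data=data,
                labels=np.array(["target"] * 3 + ["nontarget"] * 3),
                times=(np.arange(307) - 51) / FS,
                channel_names=("a", "b"), sampling_rate=FS,
                report=None, filtered=True,
            )
        )
        np.testing.assert_allclose(erp.target, one)
        np.testing.assert_allclose(erp.nontarget, one)

    def test_missing_condition_is_an_error(self):
        clean = CleanEpochSet(
            data=np.zeros((3, 307, 1)), labels=np.array(["target"] * 3),
            times=(np.arange(307) - 51) / FS, channel_names=("a",),
            sampling_rate=FS, report=None, filtered=True,
        )
        with pytest.raises(ValueError, match="per condition"):
            compute_erp(clean)

    def test_label_permutation_erps_converge(self, rng):
        """With labels shuffled, target and non-target means coincide
        up to sampling error that shrinks with the epoch count."""
        data = rng.standard_normal((400, 307, 1))
        labels = np.array(["target"] * 200 + ["nontarget"] * 200)
        rng.shuffle(labels)
        erp = compute_erp(
            CleanEpochSet(
                data=data, labels=labels, times=(np.arange(307) - 51) / FS,
                channel_names=("a",), sampling_rate=FS, report=None, filtered=True,
            )
        )
        gap = np.abs(erp.target - erp.nontarget).mean()
        assert gap < 4.0 / np.sqrt(200)
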