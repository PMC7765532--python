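"""Epoch extraction, artifact rejection, band-pass filtering, ERP averaging.

The preparation chain is: extract stimulus-locked epochs from -0.2 to
1.0 s, discard epochs where any channel exceeds any of three amplitude /
variance / high-frequency criteria (rejection runs on the raw, unfiltered
epochs), band-pass the survivors 4-14 Hz with a linear-phase FIR filter,
and average per condition to obtain the ERP waveforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ContinuousRecording

logger = logging.getLogger(__name__)

#: Epoch window relative to stimulus onset, seconds (half-open).
DEFAULT_WINDOW = (-0.2, 1.0)

#: Exclusion thresholds: peak-to-peak (uV), standard deviation (uV),
#: band-power ratio [20-40] Hz / [4-40] Hz.  All strict inequalities.
P2P_THRESHOLD_UV = 200.0
STD_THRESHOLD_UV = 50.0
RATIO_THRESHOLD = 0.5

CRITERIA = ("p2p", "std", "ratio")


@dataclass
class EpochSet:
    """Labelled stimulus-locked epochs.

    data has shape (n_epochs, n_samples, n_channels) in microvolts;
    times is the within-epoch time axis in seconds (0 = stimulus onset).
    """

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    channel_names: tuple
    sampling_rate: float

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def is_target(self) -> np.ndarray:
        return np.asarray(self.labels) == "target"


@dataclass
class CleanEpochSet(EpochSet):
    """Epochs surviving artifact rejection, plus the rejection report.

    ``report`` has one row per input epoch with columns ``kept`` and one
    boolean column per criterion; ``filtered`` records whether the 4-14
    Hz band-pass has been applied (downstream feature extraction
    requires it).
    """

    report: pd.DataFrame = None
    filtered: bool = False


@dataclass
class ErpWaveform:
    """Per-channel average waveform for target and non-target epochs."""

    target: np.ndarray  # (n_samples, n_channels)
    nontarget: np.ndarray
    n_target: int
    n_nontarget: int
    times: np.ndarray
    channel_names: tuple
    sampling_rate: float

    def waveform(self, condition: str) -> np.ndarray:
        if condition not in ("target", "nontarget"):
            raise ValueError(f"unknown condition {condition!r}")
        return self.target if condition == "target" else self.nontarget


def extract_epochs(
    recording: ContinuousRecording, window=DEFAULT_WINDOW
) -> EpochSet:
    """Extract labelled stimulus-locked epochs.

    The window is half-open: ``round(-window[0]*fs)`` samples before and
    ``round(window[1]*fs)`` samples from the onset (307 samples at
    256 Hz for the default window, onset at sample index 51).  Events
    whose window falls outside the recording are skipped with a logged
    count; zero extractable epochs is an error.
    """
    fs = recording.sampling_rate
    pre = round(-window[0] * fs)
    post = round(window[1] * fs)
    if pre < 0 or post <= 0:
        raise ValueError("window must include the stimulus onset")
    events = recording.labelled_events
    onsets = events["onset_sample"].to_numpy()
    labels = events["label"].to_numpy()

    ok = (onsets - pre >= 0) & (onsets + post <= recording.n_samples)
    skipped = int((~ok).sum())
    if skipped:
        logger.warning("skipped %d events with out-of-bounds windows", skipped)
    if not ok.any():
        raise ValueError("no extractable epochs")

    idx = onsets[ok][:, None] + np.arange(-pre, post)[None, :]
    data = recording.signals[:, idx]  # (n_ch, n_epochs, n_samples)
    data = np.ascontiguousarray(np.moveaxis(data, 0, 2))
    times = np.arange(-pre, post) / fs
    return EpochSet(
        data=data,
        labels=labels[ok],
        times=times,
        channel_names=recording.channel_names,
        sampling_rate=fs,
    )


def band_power_ratio(
    data: np.ndarray, sampling_rate: float, num_band=(20.0, 40.0), den_band=(4.0, 40.0)
) -> np.ndarray:
    """Welch band-power ratio per epoch and channel.

    data: (n_epochs, n_samples, n_channels).  Hann window, segment
    length min(n_samples, 256), 50% overlap; band power by trapezoidal
    integration over the frequency bins.  A zero denominator yields 0
    (a constant epoch is not a high-frequency artifact).
    """
    ns = data.shape[1]
    nperseg = min(ns, 256)
    if ns < 8:
        raise ValueError("epoch too short for a PSD estimate")
    freqs, psd = sps.welch(
        data, fs=sampling_rate, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, axis=1,
    )
    def bp(lo, hi):
        m = (freqs >= lo) & (freqs <= hi)
        return np.trapezoid(psd[:, m, :], freqs[m], axis=1)
    num = bp(*num_band)
    den = bp(*den_band)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return ratio


def reject_artifacts(epochs: EpochSet) -> CleanEpochSet:
    """Apply the three exclusion criteria to raw (unfiltered) epochs.

    An epoch is discarded if on any channel (i) peak-to-peak amplitude
    exceeds 200 uV, (ii) sample standard deviation exceeds 50 uV, or
    (iii) the [20-40]/[4-40] Hz band-power ratio exceeds 0.5 (all
    strict).  The report records, per input epoch, which criteria
    tripped.
    """
    x = epochs.data
    p2p = x.max(axis=1) - x.min(axis=1)  # (n_epochs, n_channels)
    std = x.std(axis=1, ddof=1)
    ratio = band_power_ratio(x, epochs.sampling_rate)

    trip_p2p = (p2p > P2P_THRESHOLD_UV).any(axis=1)
    trip_std = (std > STD_THRESHOLD_UV).any(axis=1)
    trip_ratio = (ratio > RATIO_THRESHOLD).any(axis=1)
    rejected = trip_p2p | trip_std | trip_ratio

    report = pd.DataFrame(
        {
            "kept": ~rejected,
            "p2p": trip_p2p,
            "std": trip_std,
            "ratio": trip_ratio,
            "label": epochs.labels,
        }
    )
    keep = ~rejected
    return CleanEpochSet(
        data=epochs.data[keep],
        labels=epochs.labels[keep],
        times=epochs.times,
        channel_names=epochs.channel_names,
        sampling_rate=epochs.sampling_rate,
        report=report,
        filtered=False,
    )


def design_bandpass(
    sampling_rate: float,
    low: float = 4.0,
    high: float = 14.0,
    transition: float = 2.0,
) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase FIR band-pass taps.

    Order ~ 3.3 * fs / transition width, forced odd so the group delay
    is an integer number of samples.
    """
    numtaps = int(np.ceil(3.3 * sampling_rate / transition))
    numtaps += 1 - numtaps % 2
    return sps.firwin(
        numtaps, [low, high], pass_zero=False, window="hamming", fs=sampling_rate
    )


def bandpass_epochs(
    clean: CleanEpochSet, low: float = 4.0, high: float = 14.0,
    transition: float = 2.0,
) -> CleanEpochSet:
    """Zero-phase 4-14 Hz FIR band-pass, identical across channels.

    The linear-phase filter is applied forward on reflection-padded
    epochs and the group delay compensated by shifting, so filtered
    epochs stay aligned with the stimulus.
    """
    taps = design_bandpass(clean.sampling_rate, low, high, transition)
    delay = (len(taps) - 1) // 2
    pad = len(taps)
    x = np.pad(clean.data, ((0, 0), (pad, pad), (0, 0)), mode="reflect")
    y = sps.lfilter(taps, 1.0, x, axis=1)
    ns = clean.data.shape[1]
    out = y[:, pad + delay : pad + delay + ns, :]
    return replace(clean, data=np.ascontiguousarray(out), filtered=True)


def compute_erp(clean: CleanEpochSet, baseline: bool = False) -> ErpWaveform:
    """Across-epochs average per channel, separately per condition.

    With ``baseline=True`` the mean over the pre-stimulus interval is
    subtracted per channel and condition (for display and statistics;
    the classification path relies on the 4 Hz high-pass edge instead).
    """
    is_t = clean.is_target
    if is_t.sum() == 0 or (~is_t).sum() == 0:
        raise ValueError("need at least one kept epoch per condition")
    erp_t = clean.data[is_t].mean(axis=0)
    erp_n = clean.data[~is_t].mean(axis=0)
    if baseline:
        pre = clean.times < 0
        erp_t = erp_t - erp_t[pre].mean(axis=0, keepdims=True)
        erp_n = erp_n - erp_n[pre].mean(axis=0, keepdims=True)
    return ErpWaveform(
        target=erp_t,
        nontarget=erp_n,
        n_target=int(is_t.sum()),
        n_nontarget=int((~is_t).sum()),
        times=clean.times,
        channel_names=clean.channel_names,
        sampling_rate=clean.sampling_rate,
    )
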