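"""Protocol-faithful synthetic oddball sessions with known ground truth.

Emulates a single-option visual oddball protocol: blocks of
fixation (2 s) / target presentation (2 s) / preparation (1 s) /
stimulation (~30 s of 75 ms flashes separated by 75 ms gaps) / rest (5 s),
repeated until the attended symbol has flashed at least
``min_target_flashes`` times.  Within a block every symbol flashes
equally often (complete shuffled rounds), no two consecutive flashes show
the same symbol, and the attended symbol is drawn uniformly per block.

The signal model is: background noise (1/f by default) + a steady-state
visual response at the flash rate during stimulation + a stereotyped
event-related template (negative deflection around 200-300 ms, positive
P300-like peak around 300-400 ms) added at every target flash, with
larger posterior amplitudes for the cartoon-face (CF) condition than for
the standard flash (SF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import DEFAULT_CHANNELS, ContinuousRecording, make_events

#: Channels where the visual P300 response dominates and where the CF
#: condition boosts amplitudes.
POSTERIOR_CHANNELS = ("P3", "Pz", "P4", "PO7", "PO8", "Oz")

#: Flash period: 75 ms highlight + 75 ms gap.
FLASH_PERIOD_S = 0.150

#: Nominal steady-state visual response frequency (one cycle per flash
#: period).  Simulation uses the exact on-grid rate fs / round(0.150 fs)
#: so the response stays phase-locked to the flashes.
SSVEP_FREQ_HZ = 1.0 / FLASH_PERIOD_S

_PHASE_DURATIONS_S = {
    "fixation": 2.0,
    "target_presentation": 2.0,
    "preparation": 1.0,
    "rest": 5.0,
}


def _default_channel_gains() -> dict:
    # Posterior dominance of the visual P300; frontal/central weaker.
    return {
        "Fz": 0.5,
        "Cz": 0.7,
        "P3": 0.9,
        "Pz": 1.0,
        "P4": 0.9,
        "PO7": 0.8,
        "PO8": 0.8,
        "Oz": 0.8,
    }


@dataclass
class ErpTemplateParams:
    """Shape of the simulated event-related response.

    The template is the sum of a negative and a positive Gaussian
    deflection.  ``peak_width_ms`` is the Gaussian standard deviation.
    ``channel_gains`` scales the template per channel and
    ``cf_posterior_gain`` multiplies posterior channels in the CF
    condition (frontal/central channels are condition-independent).
    """

    neg_peak_latency_ms: float = 250.0
    neg_peak_amplitude_uV: float = -4.0
    pos_peak_latency_ms: float = 350.0
    pos_peak_amplitude_uV: float = 6.0
    peak_width_ms: float = 45.0
    channel_gains: dict = field(default_factory=_default_channel_gains)
    cf_posterior_gain: float = 1.4

    def gain(self, channel: str, condition: str) -> float:
        g = self.channel_gains.get(channel, 1.0)
        if condition == "CF" and channel in POSTERIOR_CHANNELS:
            g *= self.cf_posterior_gain
        return g


@dataclass
class SimulationConfig:
    """Conditions of one simulated oddball session.

    noise_std is the total RMS of the background noise per channel in
    microvolts; ssvep_amplitude is the peak amplitude of the steady-state
    response at the flash rate (scaled by the same per-channel gains as
    the ERP); artifact_rate is the per-flash probability of contaminating
    the flash-aligned window with a high-amplitude transient.
    """

    n_symbols: int = 5
    condition: str = "SF"
    min_target_flashes: int = 280
    flash_on_ms: float = 75.0
    flash_off_ms: float = 75.0
    sampling_rate: float = 256.0
    erp_params: ErpTemplateParams = field(default_factory=ErpTemplateParams)
    noise_std: float = 12.0
    noise_model: str = "pink"  # "pink" | "white" | "ar1"
    noise_exponent: float = 1.5  # PSD ~ 1/f**exponent for the pink model
    ssvep_amplitude: float = 1.5
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.n_symbols:
            raise ValueError("n_symbols must be >= 2 (no-repeat needs >= 2 symbols)")
        if self.min_target_flashes < 1:
            raise ValueError("min_target_flashes must be >= 1")
        period = self.flash_on_ms + self.flash_off_ms
        if abs(period - 1000 * FLASH_PERIOD_S) > 1e-9:
            raise ValueError("flash period (on + off) must be 150 ms")
        if self.noise_model not in ("pink", "white", "ar1"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def rounds_per_block(config: SimulationConfig) -> int:
    """Stimulation rounds per ~30 s block (one target flash per round)."""
    return max(1, round(30.0 / (FLASH_PERIOD_S * config.n_symbols)))


def _no_repeat_rounds(n_symbols: int, n_rounds: int, rng) -> np.ndarray:
    """Concatenated shuffled rounds with no equal adjacent symbols.

    Each round is one permutation of all symbols (blockwise counts are
    exactly equal by construction); a round is re-drawn while its first
    element equals the previous round's last element.
    """
    out = np.empty(n_symbols * n_rounds, dtype=np.int64)
    prev_last = -1
    for r in range(n_rounds):
        perm = rng.permutation(n_symbols)
        while perm[0] == prev_last:
            perm = rng.permutation(n_symbols)
        out[r * n_symbols : (r + 1) * n_symbols] = perm
        prev_last = perm[-1]
    return out


def make_schedule(config: SimulationConfig, seed: int | None = None):
    """Build the event stream for one session.

    Returns ``(events, block_targets)``: an event table containing phase
    markers and labelled stimulation flashes at one flash period spacing,
    and the attended symbol of each block.  Blocks are appended until the
    total number of target flashes reaches ``config.min_target_flashes``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    step = round(FLASH_PERIOD_S * fs)
    n_rounds = rounds_per_block(config)
    n_blocks = -(-config.min_target_flashes // n_rounds)  # ceil

    onsets, stim_idx, labels, blocks, phases = [], [], [], [], []
    block_targets = []
    cursor = 0
    for b in range(n_blocks):
        target = int(rng.integers(config.n_symbols))
        block_targets.append(target)
        for phase in ("fixation", "target_presentation", "preparation"):
            onsets.append(cursor)
            stim_idx.append(-1)
            labels.append("n/a")
            blocks.append(b)
            phases.append(phase)
            cursor += round(_PHASE_DURATIONS_S[phase] * fs)
        seq = _no_repeat_rounds(config.n_symbols, n_rounds, rng)
        for k, sym in enumerate(seq):
            onsets.append(cursor + k * step)
            stim_idx.append(int(sym))
            labels.append("target" if sym == target else "nontarget")
            blocks.append(b)
            phases.append("stimulation")
        cursor += len(seq) * step
        onsets.append(cursor)
        stim_idx.append(-1)
        labels.append("n/a")
        blocks.append(b)
        phases.append("rest")
        cursor += round(_PHASE_DURATIONS_S["rest"] * fs)

    events = make_events(onsets, stim_idx, labels, blocks, phase=phases)
    return events, block_targets


def erp_template(
    params: ErpTemplateParams,
    condition: str,
    channel: str,
    sampling_rate: float = 256.0,
) -> np.ndarray:
    """Event-related template on [0, 1.0) s for one channel/condition.

    Sum of a negative and a positive Gaussian deflection at the
    configured latencies, scaled by the per-channel/per-condition gain.
    """
    for lat in (params.neg_peak_latency_ms, params.pos_peak_latency_ms):
        if not 0.0 <= lat <= 1000.0:
            raise ValueError(f"peak latency {lat} ms outside [0, 1000] ms")
    n = round(1.0 * sampling_rate)
    t_ms = np.arange(n) / sampling_rate * 1000.0
    sig = params.peak_width_ms
    wave = params.neg_peak_amplitude_uV * np.exp(
        -0.5 * ((t_ms - params.neg_peak_latency_ms) / sig) ** 2
    ) + params.pos_peak_amplitude_uV * np.exp(
        -0.5 * ((t_ms - params.pos_peak_latency_ms) / sig) ** 2
    )
    return params.gain(channel, condition) * wave


def _background_noise(config: SimulationConfig, n_samples: int, rng) -> np.ndarray:
    """(n_channels, n_samples) background noise at RMS ``noise_std``."""
    n_ch = len(DEFAULT_CHANNELS)
    if config.noise_std == 0:
        return np.zeros((n_ch, n_samples))
    if config.noise_model == "white":
        return rng.standard_normal((n_ch, n_samples)) * config.noise_std
    if config.noise_model == "ar1":
        # AR(1) surrogate with lag-1 correlation 0.95, scaled to noise_std.
        phi = 0.95
        eps = rng.standard_normal((n_ch, n_samples))
        out = np.empty_like(eps)
        out[:, 0] = eps[:, 0] / np.sqrt(1 - phi**2)
        for t in range(1, n_samples):
            out[:, t] = phi * out[:, t - 1] + eps[:, t]
        out *= np.sqrt(1 - phi**2)
        return out * config.noise_std
    # pink: FFT-shaped 1/f**exponent power spectrum, flat below 1 Hz
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / config.sampling_rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 1.0) ** (-config.noise_exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    spec = (
        rng.standard_normal((n_ch, len(freqs)))
        + 1j * rng.standard_normal((n_ch, len(freqs)))
    ) * shape
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = noise.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return noise / rms * config.noise_std


def simulate_session(config: SimulationConfig) -> ContinuousRecording:
    """Simulate one continuous oddball session.

    Signal = background noise + steady-state sinusoid at the flash rate
    during stimulation phases + the ERP template added at every target
    flash onset.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    events, _ = make_schedule(config, seed=config.seed)
    fs = config.sampling_rate
    step = round(FLASH_PERIOD_S * fs)
    tail = round(1.0 * fs) + round(_PHASE_DURATIONS_S["rest"] * fs)
    n_samples = int(events["onset_sample"].max()) + tail

    signals = _background_noise(config, n_samples, rng)

    gains = np.array(
        [config.erp_params.gain(ch, config.condition) for ch in DEFAULT_CHANNELS]
    )
    base_gains = np.array(
        [config.erp_params.channel_gains.get(ch, 1.0) for ch in DEFAULT_CHANNELS]
    )

    if config.ssvep_amplitude:
        ssvep_freq = fs / step  # exact flash rate on the sample grid
        flashes = events[events["phase"] == "stimulation"]
        for _, grp in flashes.groupby("block_id", sort=False):
            start = int(grp["onset_sample"].iloc[0])
            stop = int(grp["onset_sample"].iloc[-1]) + step
            t = np.arange(stop - start) / fs
            ssvep = config.ssvep_amplitude * np.sin(2 * np.pi * ssvep_freq * t)
            signals[:, start:stop] += base_gains[:, None] * ssvep[None, :]

    # one base template; per-channel gain applied on insertion
    base = ErpTemplateParams(**{**config.erp_params.__dict__, "channel_gains": {}})
    template = erp_template(base, config.condition, "", sampling_rate=fs)
    # erp_template applies no channel gain for an unknown channel name, and
    # the condition boost only acts through gain(); reapply per channel:
    n_tpl = len(template)
    targets = events[events["label"] == "target"]["onset_sample"].to_numpy()
    for onset in targets:
        sl = slice(onset, min(onset + n_tpl, n_samples))
        signals[:, sl] += gains[:, None] * template[None, : sl.stop - sl.start]

    rec = ContinuousRecording(
        signals=signals,
        channel_names=DEFAULT_CHANNELS,
        sampling_rate=fs,
        events=events,
        condition=config.condition,
        n_symbols=config.n_symbols,
    )
    if config.artifact_rate > 0:
        rec, _ = inject_artifacts(rec, config.artifact_rate, seed=config.seed + 1)
    return rec


# --- artifact injection -----------------------------------------------------

#: Flash-aligned contamination window, matching the epoching window.
_ARTIFACT_WINDOW_S = (-0.2, 1.0)


def _artifact_waveform(kind: str, n: int, fs: float, rng) -> np.ndarray:
    """One contamination transient engineered to trip one exclusion rule.

    ``p2p``  : eye-blink-like 80 ms half-sine bump, 220 uV (peak-to-peak
               > 200 uV; std ~ 40 uV; low-frequency).
    ``std``  : 8-12 Hz oscillation, 80 uV amplitude (std ~ 57 uV > 50;
               peak-to-peak 160 uV; negligible 20-40 Hz power).
    ``ratio``: 20-40 Hz oscillation, 40 uV amplitude (band-power ratio
               [20-40]/[4-40] well above 0.5; std ~ 28 uV; p2p 80 uV).
    """
    out = np.zeros(n)
    t = np.arange(n) / fs
    if kind == "p2p":
        width = round(0.080 * fs)
        start = rng.integers(0, n - width)
        out[start : start + width] = 220.0 * np.sin(
            np.pi * np.arange(width) / width
        )
    elif kind == "std":
        f = rng.uniform(8.0, 12.0)
        out = 80.0 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    elif kind == "ratio":
        f = rng.uniform(25.0, 35.0)
        out = 40.0 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return out


def inject_artifacts(
    recording: ContinuousRecording,
    artifact_rate: float,
    seed: int = 0,
    flash_indices=None,
    kinds=("p2p", "std", "ratio"),
):
    """Contaminate flash-aligned windows of a recording.

    Each considered labelled flash is independently contaminated with
    probability ``artifact_rate``; the contamination is one of three
    transients, each engineered to trip one of the epoch exclusion
    criteria (peak-to-peak, standard deviation, high-frequency band-power
    ratio) on one randomly chosen channel.

    Because consecutive flashes are 150 ms apart while the flash-aligned
    window is 1.2 s long, an artifact also lies inside the windows of
    neighbouring flashes; pass ``flash_indices`` restricted to flashes
    spaced at least one window apart when per-epoch ground truth must be
    exact.

    Returns ``(recording, ground_truth)`` where ground_truth is a
    DataFrame with columns ``flash_index`` (position among labelled
    events), ``criterion`` and ``channel``.
    """
    if not 0.0 <= artifact_rate <= 1.0:
        raise ValueError("artifact_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labelled = recording.labelled_events.reset_index(drop=True)
    if flash_indices is None:
        flash_indices = np.arange(len(labelled))
    flash_indices = np.asarray(flash_indices)

    signals = recording.signals.copy()
    fs = recording.sampling_rate
    pre = round(-_ARTIFACT_WINDOW_S[0] * fs)
    post = round(_ARTIFACT_WINDOW_S[1] * fs)
    n_win = pre + post

    rows = []
    hit = rng.random(len(flash_indices)) < artifact_rate
    for fi, h in zip(flash_indices, hit):
        if not h:
            continue
        kind = kinds[rng.integers(len(kinds))]
        chan = int(rng.integers(recording.n_channels))
        onset = int(labelled.loc[fi, "onset_sample"])
        start = onset - pre
        if start < 0 or start + n_win > recording.n_samples:
            continue
        signals[chan, start : start + n_win] += _artifact_waveform(
            kind, n_win, fs, rng
        )
        rows.append({"flash_index": int(fi), "criterion": kind, "channel": chan})

    out = ContinuousRecording(
        signals=signals,
        channel_names=recording.channel_names,
        sampling_rate=fs,
        events=recording.events,
        subject=recording.subject,
        session=recording.session,
        condition=recording.condition,
        n_symbols=recording.n_symbols,
    )
    return out, pd.DataFrame(rows, columns=["flash_index", "criterion", "channel"])


def sf_cf_pair(config: SimulationConfig, seed: int | None = None):
    """Matched SF/CF sessions differing only in condition (and seed offset)."""
    if seed is None:
        seed = config.seed
    sf = replace(config, condition="SF", seed=seed)
    cf = replace(config, condition="CF", seed=seed + 10_000)
    return simulate_session(sf), simulate_session(cf)
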