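"""Session containers and a BIDS-flavoured on-disk layout.

A session is one continuous multichannel EEG recording plus a stimulus
event stream.  On disk a session is laid out the BIDS way
(``sub-*/ses-*/eeg/``) with the signal in BrainVision format
(text header ``.vhdr``, text marker file ``.vmrk``, binary float32
``.eeg``), events in ``*_events.tsv`` and channel metadata in
``*_channels.tsv`` plus a JSON sidecar.  Synthetic and real sessions
flow through the same interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standard montage for P300 recordings (10-20 positions).
DEFAULT_CHANNELS = ("Fz", "Cz", "P3", "Pz", "P4", "PO7", "PO8", "Oz")

#: Columns of the event table.
EVENT_COLUMNS = ("onset_sample", "stimulus_index", "label", "block_id", "phase")

#: Phases of one oddball block.  Only ``stimulation``-phase flash events
#: carry a target/non-target label.
PHASES = ("fixation", "target_presentation", "preparation", "stimulation", "rest")


class ValidationError(ValueError):
    """A recording or event table violates one of its invariants."""


def make_events(
    onset_sample,
    stimulus_index,
    label,
    block_id,
    phase="stimulation",
) -> pd.DataFrame:
    """Assemble an event table (one row per event, onset in samples)."""
    df = pd.DataFrame(
        {
            "onset_sample": np.asarray(onset_sample, dtype=np.int64),
            "stimulus_index": np.asarray(stimulus_index, dtype=np.int64),
            "label": label,
            "block_id": np.asarray(block_id, dtype=np.int64),
            "phase": phase,
        }
    )
    return df


def validate_events(events: pd.DataFrame, n_samples: int | None = None) -> None:
    """Check the event-table invariants, raising ValidationError on failure.

    Checks: onsets strictly increasing within a block, no two consecutive
    stimulation flashes in a block share a stimulus index ("no-repeat"),
    and onsets inside ``[0, n_samples)`` when the signal length is given.
    """
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise ValidationError(f"events missing column {col!r}")
    if len(events) == 0:
        return
    if n_samples is not None:
        onsets = events["onset_sample"].to_numpy()
        if onsets.min() < 0 or onsets.max() >= n_samples:
            raise ValidationError("event onsets outside [0, n_samples)")
    for block, grp in events.groupby("block_id", sort=False):
        onsets = grp["onset_sample"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValidationError(f"onsets not increasing in block {block}")
        flashes = grp[grp["phase"] == "stimulation"]
        idx = flashes["stimulus_index"].to_numpy()
        if len(idx) > 1 and np.any(idx[1:] == idx[:-1]):
            raise ValidationError(f"no-repeat violated in block {block}")


@dataclass
class ContinuousRecording:
    """One session of continuous EEG plus its event stream.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    channel_names : sequence of str
        One name per signal row.
    sampling_rate : float
        Sampling frequency in Hz.
    events : pandas.DataFrame
        Event table with columns ``onset_sample, stimulus_index, label,
        block_id, phase``.  Labels are ``"target"``/``"nontarget"`` for
        stimulation flashes and ``"n/a"`` elsewhere.
    subject, session : str
        BIDS-style entity labels (e.g. ``"01"``).
    condition : str
        Stimulation condition tag, ``"SF"`` (standard flash) or ``"CF"``
        (cartoon face).
    n_symbols : int
        Number of symbols on the virtual display (4-9).
    """

    signals: np.ndarray
    channel_names: tuple = DEFAULT_CHANNELS
    sampling_rate: float = 256.0
    events: pd.DataFrame = field(default_factory=lambda: make_events([], [], [], []))
    subject: str = "01"
    session: str = "01"
    condition: str = "SF"
    n_symbols: int = 5

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.channel_names = tuple(self.channel_names)
        self.validate()

    def validate(self) -> None:
        if self.signals.shape[0] != len(self.channel_names):
            raise ValidationError(
                "channel count mismatch: "
                f"{self.signals.shape[0]} signal rows, "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        validate_events(self.events, n_samples=self.signals.shape[1])

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def labelled_events(self) -> pd.DataFrame:
        """Stimulation flashes carrying a target/non-target label."""
        mask = self.events["label"].isin(["target", "nontarget"])
        return self.events[mask]


def _basename(rec: ContinuousRecording) -> str:
    return (
        f"sub-{rec.subject}_ses-{rec.session}"
        f"_task-oddball_acq-{rec.condition}{rec.n_symbols}"
    )


def _write_brainvision(rec: ContinuousRecording, eeg_dir: Path, base: str) -> list[Path]:
    """Write a minimal BrainVision triplet (.vhdr/.vmrk text, float32 .eeg).

    Multiplexed IEEE float32 binary, one unit scale (resolution 1 uV), as
    read back by ``mne.io.read_raw_brainvision``.
    """
    vhdr = eeg_dir / f"{base}_eeg.vhdr"
    vmrk = eeg_dir / f"{base}_eeg.vmrk"
    dat = eeg_dir / f"{base}_eeg.eeg"
    sampling_interval_us = 1e6 / rec.sampling_rate
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={dat.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "BrainVision Data Exchange Marker File Version 1.0\n\n"
        "[Common Infos]\n"
        f"DataFile={dat.name}\n\n"
        "[Marker Infos]\n"
        f"Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    rec.signals.T.astype("<f4").tofile(dat)
    return [vhdr, vmrk, dat]


def write_session(rec: ContinuousRecording, root) -> list[Path]:
    """Write one session under ``root`` in the BIDS-flavoured layout.

    Creates ``sub-XX/ses-YY/eeg/`` containing the BrainVision signal
    triplet, ``*_channels.tsv``, ``*_events.tsv`` (onsets in seconds, 6
    decimals) and a JSON sidecar with condition and symbol count.
    Round-trips losslessly up to float32 sample quantization.
    """
    rec.validate()
    root = Path(root)
    eeg_dir = root / f"sub-{rec.subject}" / f"ses-{rec.session}" / "eeg"
    eeg_dir.mkdir(parents=True, exist_ok=True)
    base = _basename(rec)
    paths = _write_brainvision(rec, eeg_dir, base)

    chan = pd.DataFrame(
        {"name": list(rec.channel_names), "type": "EEG", "units": "uV"}
    )
    chan_path = eeg_dir / f"{base}_channels.tsv"
    chan.to_csv(chan_path, sep="\t", index=False)
    paths.append(chan_path)

    ev = rec.events
    events_tsv = pd.DataFrame(
        {
            "onset": (ev["onset_sample"] / rec.sampling_rate).map(
                lambda t: f"{t:.6f}"
            ),
            "duration": 0.075,
            "trial_type": ev["label"],
            "stimulus_index": ev["stimulus_index"],
            "block_id": ev["block_id"],
            "phase": ev["phase"],
        }
    )
    ev_path = eeg_dir / f"{base}_events.tsv"
    events_tsv.to_csv(ev_path, sep="\t", index=False)
    paths.append(ev_path)

    sidecar = {
        "TaskName": "oddball",
        "SamplingFrequency": rec.sampling_rate,
        "EEGChannelCount": rec.n_channels,
        "Condition": rec.condition,
        "NSymbols": rec.n_symbols,
    }
    json_path = eeg_dir / f"{base}_eeg.json"
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n", encoding="utf-8")
    paths.append(json_path)
    return paths


def read_session(
    root, subject: str, session: str, condition: str, n_symbols: int | None = None
) -> ContinuousRecording:
    """Read one session written by :func:`write_session`.

    Malformed event rows (unknown ``trial_type``) are dropped with a
    logged count.  Raises ``FileNotFoundError`` for missing files and
    :class:`ValidationError` on a channel-count mismatch between the
    signal file and ``channels.tsv``.
    """
    import mne

    root = Path(root)
    eeg_dir = root / f"sub-{subject}" / f"ses-{session}" / "eeg"
    if n_symbols is None:
        pattern = f"sub-{subject}_ses-{session}_task-oddball_acq-{condition}*_eeg.vhdr"
        matches = sorted(eeg_dir.glob(pattern))
        if not matches:
            raise FileNotFoundError(f"no session matching {pattern} in {eeg_dir}")
        vhdr = matches[0]
        base = vhdr.name[: -len("_eeg.vhdr")]
    else:
        base = (
            f"sub-{subject}_ses-{session}_task-oddball_acq-{condition}{n_symbols}"
        )
        vhdr = eeg_dir / f"{base}_eeg.vhdr"
        if not vhdr.exists():
            raise FileNotFoundError(vhdr)

    raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    signals = raw.get_data() * 1e6  # mne loads volts; sessions are in uV
    fs = raw.info["sfreq"]

    chan = pd.read_csv(eeg_dir / f"{base}_channels.tsv", sep="\t")
    if len(chan) != signals.shape[0]:
        raise ValidationError(
            f"channel count mismatch: {signals.shape[0]} in signal file, "
            f"{len(chan)} in channels.tsv"
        )

    sidecar = json.loads((eeg_dir / f"{base}_eeg.json").read_text(encoding="utf-8"))

    ev = pd.read_csv(
        eeg_dir / f"{base}_events.tsv", sep="\t", na_filter=False, dtype=str
    )
    valid_types = {"target", "nontarget", "n/a"}
    bad = ~ev["trial_type"].isin(valid_types)
    if bad.any():
        logger.warning("dropping %d event rows with unknown trial_type", bad.sum())
        ev = ev[~bad]
    onset_sample = np.rint(ev["onset"].astype(float) * fs).astype(np.int64)
    events = make_events(
        onset_sample,
        ev["stimulus_index"].astype(int),
        ev["trial_type"].to_numpy(),
        ev["block_id"].astype(int),
        phase=ev["phase"].to_numpy(),
    )
    return ContinuousRecording(
        signals=signals,
        channel_names=tuple(chan["name"]),
        sampling_rate=fs,
        events=events,
        subject=subject,
        session=session,
        condition=sidecar.get("Condition", condition),
        n_symbols=int(sidecar.get("NSymbols", n_symbols or 0)),
    )
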