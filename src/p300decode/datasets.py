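"""Published reference accuracy tables bundled with the package.

These TSVs hold the per-participant balanced-accuracy summaries
published with the 19-participant, 3-session single-option oddball
study whose raw EEG is deposited as OpenNeuro dataset ds003190 (8
channels, 256 Hz, standard-flash vs cartoon-face stimulation, 4-9
symbols).  They serve as worked-example inputs for the aggregation
operations; the raw recordings themselves are not bundled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("p300decode.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_condition_accuracy() -> pd.DataFrame:
    """Per-participant mean ± sd balanced accuracy for the two
    stimulation conditions (CF = cartoon face, SF = standard flash),
    averaged over three sessions.  Indexed by participant."""
    return _read("condition_accuracy.tsv").set_index("participant")


def load_symbol_accuracy() -> pd.DataFrame:
    """Per-participant mean ± sd balanced accuracy for 4-9 displayed
    symbols, averaged over three sessions.  Indexed by participant."""
    return _read("symbol_accuracy.tsv").set_index("participant")


def load_condition_transfer() -> pd.DataFrame:
    """Across-participants accuracy rates for training on one
    stimulation condition and testing on the other (diagonal rows are
    the same-condition cross-validation results).  Long format:
    train, test, class (target/nontarget/total), mean, sd."""
    return _read("condition_transfer.tsv")


def load_symbol_transfer() -> pd.DataFrame:
    """Across-participants accuracy rates for training on one symbol
    count and testing on another (diagonal rows are same-count
    cross-validation results).  Long format like
    :func:`load_condition_transfer` with integer train/test counts."""
    return _read("symbol_transfer.tsv")
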