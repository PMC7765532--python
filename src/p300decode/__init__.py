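"""Single-trial P300 target/non-target decoding.

Simulation of single-option visual oddball EEG sessions, epoch cleaning,
CCA spatial-filter features, shrinkage LDA with stepwise selection, and
balanced-accuracy evaluation with permutation chance levels.
"""

from .cca import (
    CcaModel,
    SpatialFilter,
    TrimmedEpochs,
    cca,
    extract_features,
    fit_spatial_filter,
    trim_decimate,
)
from .classification import (
    LdaModel,
    SelectionResult,
    balanced_accuracy,
    fit_lda,
    predict,
    stepwise_select,
)
from .datasets import (
    load_condition_accuracy,
    load_condition_transfer,
    load_symbol_accuracy,
    load_symbol_transfer,
)
from .erp_stats import SignificanceMask, erp_snr, kde_significance, peak_amplitude
from .evaluation import (
    AccuracyResult,
    AccuracyTable,
    CrossValResult,
    P300Decoder,
    PermutationResult,
    aggregate_sessions,
    aggregate_table,
    crossval,
    permutation_test,
    rank_tests,
    transfer_eval,
)
from .io import (
    ContinuousRecording,
    ValidationError,
    make_events,
    read_session,
    write_session,
)
from .preprocessing import (
    CleanEpochSet,
    EpochSet,
    ErpWaveform,
    bandpass_epochs,
    compute_erp,
    extract_epochs,
    reject_artifacts,
)
from .simulate import (
    ErpTemplateParams,
    SimulationConfig,
    erp_template,
    inject_artifacts,
    make_schedule,
    simulate_session,
)

__version__ = "0.1.0"


def preprocess(recording, window=(-0.2, 1.0)):
    """Convenience chain: epochs -> rejection -> band-pass -> trim/decimate.

    Returns ``(trimmed, clean)`` where ``trimmed`` feeds the decoder and
    ``clean`` (band-passed) feeds ERP averaging.
    """
    epochs = extract_epochs(recording, window=window)
    clean = reject_artifacts(epochs)
    clean = bandpass_epochs(clean)
    return trim_decimate(clean), clean


__all__ = [name for name in dir() if not name.startswith("_")]
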