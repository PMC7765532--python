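"""Evaluation: cross-validation, permutation chance levels, transfer,
rank tests, and accuracy-table aggregation.

All accuracies are balanced: CAtotal = 0.5 (CAtarget + CAnontarget),
with CAtarget the true-positive (target) rate and CAnontarget the
true-negative rate, so the 1 : (n_symbols - 1) class imbalance does not
inflate performance.  Cross-validation refits the whole chain — CCA
spatial filter, stepwise selection, shrinkage LDA — on the training
folds only.  Chance levels come from a permutation test that reruns the
full cross-validated chain on label-shuffled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold

from .cca import N_FILTERS, TrimmedEpochs, extract_features, fit_spatial_filter
from .classification import (
    LdaModel,
    _as_target_mask,
    balanced_accuracy,
    fit_lda,
    predict,
    stepwise_select,
)


@dataclass
class AccuracyResult:
    """Balanced-accuracy triple: target rate, non-target rate, total."""

    ca_target: float
    ca_nontarget: float
    n_target: int
    n_nontarget: int

    @property
    def ca_total(self) -> float:
        return 0.5 * (self.ca_target + self.ca_nontarget)


@dataclass
class CrossValResult:
    """Fold-mean accuracies plus the per-fold results."""

    mean: AccuracyResult
    folds: list


@dataclass
class PermutationResult:
    observed: float
    m: int
    null: np.ndarray
    p_value: float

    @property
    def above_chance(self) -> bool:
        return self.p_value < 0.05


def _score(true_mask, pred_mask) -> AccuracyResult:
    t = np.asarray(true_mask)
    p = np.asarray(pred_mask)
    return AccuracyResult(
        ca_target=float((p & t).sum() / max(t.sum(), 1)),
        ca_nontarget=float((~p & ~t).sum() / max((~t).sum(), 1)),
        n_target=int(t.sum()),
        n_nontarget=int((~t).sum()),
    )


@dataclass
class P300Decoder:
    """The full single-trial decoding chain on trimmed epochs.

    fit() learns the CCA spatial filter from the training target epochs,
    extracts concatenated projections as features, optionally runs
    stepwise selection, and fits the shrinkage LDA.
    """

    n_filters: int = N_FILTERS
    stepwise: bool = True
    seed: int = 0
    tol: float = 0.01
    max_features: int | None = 30
    filter_: object = None
    model_: LdaModel = None

    def fit(self, trimmed: TrimmedEpochs) -> "P300Decoder":
        self.filter_ = fit_spatial_filter(trimmed, n_filters=self.n_filters)
        X, labels = extract_features(trimmed, self.filter_)
        if self.stepwise:
            sel = stepwise_select(
                X, labels, tol=self.tol, seed=self.seed,
                max_features=self.max_features,
            )
            self.model_ = sel.model
        else:
            self.model_ = fit_lda(X, labels)
        return self

    def predict(self, trimmed: TrimmedEpochs):
        X, _ = extract_features(trimmed, self.filter_)
        return predict(self.model_, X)

    def evaluate(self, trimmed: TrimmedEpochs) -> AccuracyResult:
        labels, _ = self.predict(trimmed)
        return _score(trimmed.is_target, labels == "target")


def crossval(
    data,
    labels=None,
    k: int = 5,
    seed: int = 0,
    n_filters: int = N_FILTERS,
    stepwise: bool = True,
    max_features: int | None = 30,
) -> CrossValResult:
    """Stratified k-fold cross-validated balanced accuracy.

    ``data`` is either a :class:`TrimmedEpochs` (full chain: spatial
    filter + optional stepwise + LDA refit per fold) or a 2-D feature
    matrix with ``labels`` (LDA, optionally with stepwise selection,
    per fold).  Stratification guarantees both classes in every fold.
    Deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(data, TrimmedEpochs):
        tmask = data.is_target
    else:
        data = np.asarray(data, dtype=float)
        tmask = _as_target_mask(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(np.zeros(len(tmask)), tmask):
        if isinstance(data, TrimmedEpochs):
            dec = P300Decoder(
                n_filters=n_filters, stepwise=stepwise, seed=seed,
                max_features=max_features,
            ).fit(data.subset(tr))
            folds.append(dec.evaluate(data.subset(te)))
        else:
            lab = np.where(tmask, "target", "nontarget")
            if stepwise:
                sel = stepwise_select(
                    data[tr], lab[tr], seed=seed, max_features=max_features
                )
                model = sel.model
            else:
                model = fit_lda(data[tr], lab[tr])
            pred, _ = predict(model, data[te])
            folds.append(_score(tmask[te], pred == "target"))
    mean = AccuracyResult(
        ca_target=float(np.mean([f.ca_target for f in folds])),
        ca_nontarget=float(np.mean([f.ca_nontarget for f in folds])),
        n_target=int(sum(f.n_target for f in folds)),
        n_nontarget=int(sum(f.n_nontarget for f in folds)),
    )
    return CrossValResult(mean=mean, folds=folds)


def permutation_test(
    data, labels=None, m: int = 200, seed: int = 0, **cv_kwargs
) -> PermutationResult:
    """Permutation chance level for the cross-validated balanced accuracy.

    The full cross-validated chain (including any feature selection) is
    rerun on ``m`` label permutations, keeping the null exchangeable;
    p = (1 + #{null >= observed}) / (m + 1).  Requires m >= 19 so the
    resolution reaches 0.05.
    """
    if m < 19:
        raise ValueError("m must be >= 19 for 0.05 resolution")
    rng = np.random.default_rng(seed)
    if isinstance(data, TrimmedEpochs):
        labels_arr = np.asarray(data.labels)
    else:
        labels_arr = np.asarray(labels)
    observed = crossval(data, labels_arr, seed=seed, **cv_kwargs).mean.ca_total
    null = np.empty(m)
    for i in range(m):
        perm = rng.permutation(labels_arr)
        if isinstance(data, TrimmedEpochs):
            pdata = TrimmedEpochs(
                data=data.data, labels=perm, times=data.times,
                channel_names=data.channel_names,
                sampling_rate=data.sampling_rate,
            )
            null[i] = crossval(pdata, seed=seed, **cv_kwargs).mean.ca_total
        else:
            null[i] = crossval(data, perm, seed=seed, **cv_kwargs).mean.ca_total
    p = (1.0 + float((null >= observed).sum())) / (m + 1.0)
    return PermutationResult(observed=observed, m=m, null=null, p_value=p)


def transfer_eval(
    train: TrimmedEpochs,
    test: TrimmedEpochs,
    n_filters: int = N_FILTERS,
    stepwise: bool = True,
    seed: int = 0,
    max_features: int | None = 30,
) -> AccuracyResult:
    """Train the full chain on one dataset, evaluate once on another.

    Supports the condition-swap design (train SF, test CF and vice
    versa) and the symbol-count grid.  Datasets must share the montage.
    """
    if tuple(train.channel_names) != tuple(test.channel_names):
        raise ValueError("montage mismatch between train and test datasets")
    if train.sampling_rate != test.sampling_rate:
        raise ValueError("sampling-rate mismatch between train and test datasets")
    dec = P300Decoder(
        n_filters=n_filters, stepwise=stepwise, seed=seed,
        max_features=max_features,
    ).fit(train)
    return dec.evaluate(test)


def rank_tests(groups, paired: bool = False):
    """Nonparametric comparison of accuracy distributions.

    Two unpaired groups -> Wilcoxon rank-sum; two paired groups ->
    Wilcoxon signed-rank; more than two -> Kruskal-Wallis.  Returns
    ``(statistic, p_value, test_name)`` with two-sided p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if len(groups) == 2:
        if paired:
            if len(groups[0]) != len(groups[1]):
                raise ValueError("paired groups must have equal length")
            res = sstats.wilcoxon(groups[0], groups[1])
            return float(res.statistic), float(res.pvalue), "wilcoxon-signed-rank"
        res = sstats.ranksums(groups[0], groups[1])
        return float(res.statistic), float(res.pvalue), "wilcoxon-rank-sum"
    res = sstats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue), "kruskal-wallis"


def round3(x) -> float:
    """Half-away-from-zero rounding to 3 decimals (display convention)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) * 1000 + 0.5) / 1000


@dataclass
class AccuracyTable:
    """Participant x condition table of balanced accuracies.

    ``cells`` is a DataFrame (rows = participants, columns = conditions
    or symbol counts); every aggregation is recomputed from the cells.
    """

    cells: pd.DataFrame
    sd: pd.DataFrame = None
    flags: dict = field(default_factory=dict)

    def column_means(self) -> pd.Series:
        return self.cells.mean(axis=0)

    def column_sds(self) -> pd.Series:
        if len(self.cells) < 2:
            self.flags["sd_undefined"] = True
            return pd.Series(0.0, index=self.cells.columns)
        return self.cells.std(axis=0, ddof=1)

    def column_medians(self) -> pd.Series:
        return self.cells.median(axis=0)

    def compare_columns(self, a, b):
        """Rows where column a exceeds column b: count and percentage."""
        wins = (self.cells[a] > self.cells[b]).sum()
        return int(wins), float(100.0 * wins / len(self.cells))

    def column_mean_extremes(self):
        """(max, min, difference) of the column means."""
        means = self.column_means()
        return float(means.max()), float(means.min()), float(means.max() - means.min())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.column_means(),
                "sd": self.column_sds(),
                "median": self.column_medians(),
            }
        )

    def to_tsv(self, path) -> None:
        out = self.cells.copy()
        out.loc["Average"] = self.column_means()
        out.map(lambda v: f"{round3(v):.3f}").to_csv(path, sep="\t")


def aggregate_sessions(df: pd.DataFrame) -> AccuracyTable:
    """Aggregate per-session rows to per-participant means ± sd.

    ``df`` is indexed by (participant, session) with one column per
    condition; returns an AccuracyTable of participant means with the
    matching sd table.
    """
    mean = df.groupby(level=0).mean()
    sd = df.groupby(level=0).std(ddof=1)
    return AccuracyTable(cells=mean, sd=sd)


def aggregate_table(cells: pd.DataFrame) -> AccuracyTable:
    """Wrap per-participant accuracy cells for aggregation and reporting."""
    table = AccuracyTable(cells=cells.copy())
    if len(cells) == 1:
        table.flags["sd_undefined"] = True
    return table
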