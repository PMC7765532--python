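"""CCA spatial filtering for single-trial ERP feature extraction.

Canonical correlation analysis finds weight vectors wp, wq maximizing
corr(P wp, Q wq).  Writing Cpp, Cqq for the auto-covariances and Cpq for
the cross-covariance, wp solves the generalized eigenproblem

    (Cpq Cqq^-1 Cqp) wp = rho^2 Cpp wp,

and wq follows as Cqq^-1 Cqp wp (up to scale).  The spatial filter is
learned by stacking the target epochs row-wise into X' and the
replicated target average into Xbar' (same shape) and running CCA
between them: the leading wp directions are the channel combinations
whose single-trial projections best correlate with the average evoked
response.  Epochs are first trimmed to [0, 0.8) s and decimated by 4
(plain subsampling; the preceding 4-14 Hz band-pass makes this
alias-free), and each epoch's projection onto the first ``n_filters``
directions is concatenated column-major into the feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .preprocessing import CleanEpochSet

#: Number of spatial filters retained by default.
N_FILTERS = 3


@dataclass
class TrimmedEpochs:
    """Epochs trimmed to [0, 0.8) s and decimated by 4.

    data: (n_epochs, n_samples_reduced, n_channels); 51 samples at a
    256 Hz acquisition rate.
    """

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    channel_names: tuple
    sampling_rate: float  # effective rate after decimation

    @property
    def is_target(self) -> np.ndarray:
        return np.asarray(self.labels) == "target"

    def subset(self, indices) -> "TrimmedEpochs":
        return TrimmedEpochs(
            data=self.data[indices],
            labels=np.asarray(self.labels)[indices],
            times=self.times,
            channel_names=self.channel_names,
            sampling_rate=self.sampling_rate,
        )


@dataclass
class CcaModel:
    """All canonical pairs of one CCA fit, sorted by descending rho."""

    Wp: np.ndarray
    Wq: np.ndarray
    rho: np.ndarray
    T: int
    N: int
    M: int
    Cpp: np.ndarray
    Cqq: np.ndarray
    Cpq: np.ndarray


@dataclass
class SpatialFilter:
    """Channels -> components projection learned from target epochs.

    weights is (n_channels, n_filters), columns unit-norm, ordered by
    descending canonical correlation, sign fixed so the filtered target
    average's largest-magnitude sample is positive.
    """

    weights: np.ndarray
    rho: np.ndarray
    n_samples: int  # reduced sample count the filter was trained on
    channel_names: tuple
    metadata: dict

    @property
    def n_filters(self) -> int:
        return self.weights.shape[1]


def trim_decimate(
    clean: CleanEpochSet, t_max: float = 0.8, factor: int = 4
) -> TrimmedEpochs:
    """Keep samples with t in [0, t_max), then every ``factor``-th.

    Refuses unfiltered epochs: plain subsampling is only alias-free
    because the 4-14 Hz band-pass has already been applied.
    """
    if not clean.filtered:
        raise ValueError("epochs must be band-pass filtered before decimation")
    nd = int(round(t_max * clean.sampling_rate)) // factor  # 51 at 256 Hz
    idx = np.flatnonzero(clean.times >= 0)[::factor][:nd]
    return TrimmedEpochs(
        data=np.ascontiguousarray(clean.data[:, idx, :]),
        labels=clean.labels,
        times=clean.times[idx],
        channel_names=clean.channel_names,
        sampling_rate=clean.sampling_rate / factor,
    )


def cca(P: np.ndarray, Q: np.ndarray, ridge: float = 1e-8) -> CcaModel:
    """Canonical correlation analysis via the generalized eigenproblem.

    Columns are mean-centred internally.  The auto-covariance diagonals
    receive a ridge ``ridge * trace / dim`` for numerical stability (the
    replicated-average construction makes one side rank-deficient by
    design).  Returns all eigenpairs sorted by descending canonical
    correlation.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    T, N = P.shape
    Tq, M = Q.shape
    if T != Tq:
        raise ValueError("P and Q must have the same number of observations")
    if T <= max(N, M):
        raise ValueError("underdetermined CCA: need T > max(N, M)")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    Cpp = Pc.T @ Pc / (T - 1)
    Cqq = Qc.T @ Qc / (T - 1)
    Cpq = Pc.T @ Qc / (T - 1)
    Cpp_r = Cpp + ridge * (np.trace(Cpp) / N) * np.eye(N)
    Cqq_r = Cqq + ridge * (np.trace(Cqq) / M) * np.eye(M)

    A = Cpq @ scipy.linalg.solve(Cqq_r, Cpq.T, assume_a="pos")
    A = 0.5 * (A + A.T)
    evals, Wp = scipy.linalg.eigh(A, Cpp_r)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    Wp = Wp[:, order]
    rho = np.sqrt(np.clip(evals, 0.0, None))

    Wq = scipy.linalg.solve(Cqq_r, Cpq.T @ Wp, assume_a="pos")
    norms = np.linalg.norm(Wq, axis=0)
    norms[norms == 0] = 1.0
    Wq = Wq / norms
    return CcaModel(Wp=Wp, Wq=Wq, rho=rho, T=T, N=N, M=M, Cpp=Cpp, Cqq=Cqq, Cpq=Cpq)


def fit_spatial_filter(
    trimmed: TrimmedEpochs, n_filters: int = N_FILTERS
) -> SpatialFilter:
    """Learn the CCA spatial filter from the target epochs.

    Target epochs are stacked row-wise into X' ((n_target * n_samples) x
    n_channels) and the replicated target average into Xbar' of the same
    shape; CCA between the two yields the filter columns (leading wp
    eigenvectors, unit-norm, sign fixed on the filtered average).
    """
    tmask = trimmed.is_target
    n_target = int(tmask.sum())
    if n_target < 2:
        raise ValueError("need at least 2 target epochs to fit the spatial filter")
    target = trimmed.data[tmask]  # (n_target, nd, ne)
    xbar = target.mean(axis=0)  # (nd, ne)
    nd, ne = xbar.shape
    X = target.reshape(n_target * nd, ne)
    Xbar = np.tile(xbar, (n_target, 1))
    model = cca(X, Xbar)
    W = model.Wp[:, :n_filters].copy()
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W /= norms
    proj = xbar @ W  # (nd, n_filters)
    for k in range(W.shape[1]):
        peak = proj[np.argmax(np.abs(proj[:, k])), k]
        if peak < 0:
            W[:, k] = -W[:, k]
    return SpatialFilter(
        weights=W,
        rho=model.rho[:n_filters],
        n_samples=nd,
        channel_names=trimmed.channel_names,
        metadata={"n_target": n_target},
    )


def extract_features(trimmed: TrimmedEpochs, filt: SpatialFilter):
    """Project epochs through the spatial filter and flatten to vectors.

    Per epoch: Xsf = X W (n_samples x n_filters), concatenated
    column-major into a vector of length n_samples * n_filters (153 at
    the defaults).  Returns ``(features, labels)``.
    """
    nd = trimmed.data.shape[1]
    if nd != filt.n_samples:
        raise ValueError(
            f"sample-count mismatch: epochs have {nd}, filter expects "
            f"{filt.n_samples}"
        )
    if trimmed.data.shape[2] != filt.weights.shape[0]:
        raise ValueError("channel-count mismatch between epochs and filter")
    proj = trimmed.data @ filt.weights  # (nt, nd, nsf)
    feats = np.transpose(proj, (0, 2, 1)).reshape(trimmed.data.shape[0], -1)
    return np.ascontiguousarray(feats), np.asarray(trimmed.labels)
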