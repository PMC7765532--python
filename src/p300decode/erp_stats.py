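"""ERP significance and summary metrics.

The significance test treats the pre-stimulus samples of the averaged
ERP as draws from the baseline distribution: a Gaussian-kernel density
estimate (Silverman bandwidth) of those samples yields a baseline CDF,
and each post-stimulus sample is flagged positive (negative) when it
falls above the 1 - alpha/2 (below the alpha/2) baseline quantile —
a two-tailed test at level alpha per channel and time sample, with no
multiple-comparison correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import gaussian_kde

from .preprocessing import ErpWaveform


@dataclass
class SignificanceMask:
    """Per channel x post-stimulus sample significance flags.

    flags is (n_post_samples, n_channels) with values +1 (above the
    upper baseline quantile), -1 (below the lower), 0 otherwise.
    """

    flags: np.ndarray
    times: np.ndarray
    alpha: float
    channel_names: tuple

    def flagged_fraction(self) -> float:
        return float((self.flags != 0).mean())


def _baseline_cdf(pre: np.ndarray, values: np.ndarray, grid_size: int = 512):
    """CDF of the KDE fitted to ``pre``, evaluated at ``values``."""
    kde = gaussian_kde(pre, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    lo = pre.min() - 5 * bw
    hi = pre.max() + 5 * bw
    grid = np.linspace(lo, hi, grid_size)
    pdf = kde(grid)
    cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    return np.interp(values, grid, cdf, left=0.0, right=1.0)


def kde_significance(
    erp: ErpWaveform, condition: str = "target", alpha: float = 0.05
) -> SignificanceMask:
    """Two-tailed KDE test of post-stimulus ERP values against baseline.

    For each channel, a Gaussian-kernel KDE is fitted to the channel's
    pre-stimulus ERP samples; post-stimulus samples with baseline CDF
    above 1 - alpha/2 are flagged +1 and below alpha/2 are flagged -1.
    The test is invariant to adding a constant to the whole waveform.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    wave = erp.waveform(condition)
    pre_mask = erp.times < 0
    post_mask = ~pre_mask
    if pre_mask.sum() < 20:
        raise ValueError("need at least 20 pre-stimulus samples")
    n_post = int(post_mask.sum())
    flags = np.zeros((n_post, wave.shape[1]), dtype=np.int8)
    for c in range(wave.shape[1]):
        cdf = _baseline_cdf(wave[pre_mask, c], wave[post_mask, c])
        flags[cdf > 1 - alpha / 2, c] = 1
        flags[cdf < alpha / 2, c] = -1
    return SignificanceMask(
        flags=flags,
        times=erp.times[post_mask],
        alpha=alpha,
        channel_names=erp.channel_names,
    )


def peak_amplitude(
    erp: ErpWaveform,
    window=(0.2, 0.6),
    polarity: int = 1,
    condition: str = "target",
) -> np.ndarray:
    """Per-channel extremum of the ERP within a post-stimulus window.

    polarity +1 returns the maximum, -1 the minimum; among ties the
    earliest-latency sample is reported.
    """
    mask = (erp.times >= window[0]) & (erp.times <= window[1])
    if not mask.any():
        raise ValueError("empty peak window")
    wave = erp.waveform(condition)[mask]
    return wave.max(axis=0) if polarity >= 0 else wave.min(axis=0)


def erp_snr(erp: ErpWaveform, window=(0.0, 0.8)) -> np.ndarray:
    """Target vs non-target mean-square ratio per channel, in dB.

    10*log10( mean-square of the target ERP in the window / mean-square
    of the non-target ERP ).  This is a summary metric defined by this
    package, not a standard quantity.  Zero non-target power yields +inf
    with a warning.
    """
    mask = (erp.times >= window[0]) & (erp.times <= window[1])
    if not mask.any():
        raise ValueError("empty SNR window")
    ms_t = (erp.target[mask] ** 2).mean(axis=0)
    ms_n = (erp.nontarget[mask] ** 2).mean(axis=0)
    out = np.full_like(ms_t, np.inf)
    nz = ms_n > 0
    out[nz] = 10.0 * np.log10(ms_t[nz] / ms_n[nz])
    if (~nz).any():
        warnings.warn("zero non-target power in SNR window; reporting +inf")
    return out
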