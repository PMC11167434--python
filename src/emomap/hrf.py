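"""Canonical haemodynamic response function and block-design regressors.

The double-gamma HRF used here (response peak at 6 s, undershoot at 16 s,
peak-to-undershoot ratio 6) is the de-facto standard impulse response for
block-design BOLD models.  Both the synthetic-run generator and the GLM design
builder call :func:`condition_regressor`, so in the noiseless limit the fitted
betas recover planted amplitudes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist


@dataclass(frozen=True)
class HRFParams:
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 32.0


DEFAULT_HRF = HRFParams()

HRF_MODELS = {"double_gamma": DEFAULT_HRF}


def double_gamma_hrf(t: np.ndarray, params: HRFParams = DEFAULT_HRF) -> np.ndarray:
    """Sample the canonical double-gamma HRF at times ``t`` (seconds).

    The response is normalised to unit peak so that a planted block amplitude
    of ``beta`` yields a regressor with plateau approximately ``beta``.
    """
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, params.peak_delay_s / params.peak_dispersion, scale=params.peak_dispersion)
    under = gamma_dist.pdf(
        t, params.undershoot_delay_s / params.undershoot_dispersion, scale=params.undershoot_dispersion
    )
    h = peak - under / params.peak_undershoot_ratio
    h[t < 0] = 0.0
    peak_val = h.max()
    if peak_val > 0:
        h = h / peak_val
    return h


def condition_regressor(
    onsets_s: np.ndarray,
    durations_s: np.ndarray,
    n_volumes: int,
    tr_s: float,
    params: HRFParams = DEFAULT_HRF,
    oversample: int = 16,
) -> np.ndarray:
    """Boxcar-convolved-with-HRF regressor sampled at frame-onset times.

    The boxcar is built on a microtime grid of ``tr_s / oversample`` seconds,
    convolved with the HRF sampled on the same grid, and read out at
    t = 0, TR, 2 TR, ...
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    dt = tr_s / oversample
    n_fine = n_volumes * oversample
    box = np.zeros(n_fine)
    for onset, dur in zip(np.atleast_1d(onsets_s), np.atleast_1d(durations_s)):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + dur) / dt))
        box[i0 : min(i1, n_fine)] = 1.0
    t_hrf = np.arange(0.0, params.duration_s + dt, dt)
    h = double_gamma_hrf(t_hrf, params)
    conv = np.convolve(box, h)[:n_fine] * dt
    # unit-plateau normalisation: a long block converges to sum(h) * dt
    plateau = h.sum() * dt
    if plateau > 0:
        conv = conv / plateau
    return conv[::oversample]
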