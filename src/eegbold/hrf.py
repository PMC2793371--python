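"""Informed hemodynamic basis: canonical double-gamma HRF plus temporal and
dispersion derivatives, and regressor convolution/downsampling to scan rate.

The canonical response is the conventional difference of two gamma densities
(response peak ~5 s, undershoot peaking later, undershoot ratio 1/6, 32 s
support).  The temporal derivative is the finite difference under a 1 s
onset shift, so its coefficient absorbs peak responses roughly one second
earlier or later than usual; the dispersion derivative is the finite
difference under a small perturbation of the peak dispersion and absorbs
variations in response width.  Both derivatives are orthogonalised against
the canonical kernel so the canonical coefficient keeps its interpretation;
F-tests over the triplet are unaffected by the orthogonalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

#: Double-gamma parameters: (response delay, undershoot delay, response
#: dispersion, undershoot dispersion, undershoot ratio, kernel length s).
HRF_PARAMS = {
    "delay_response": 6.0,
    "delay_undershoot": 16.0,
    "dispersion_response": 1.0,
    "dispersion_undershoot": 1.0,
    "undershoot_ratio": 6.0,
    "length": 32.0,
}


def _double_gamma(
    t: np.ndarray,
    delay_r: float = 6.0,
    delay_u: float = 16.0,
    disp_r: float = 1.0,
    disp_u: float = 1.0,
    ratio: float = 6.0,
    onset: float = 0.0,
) -> np.ndarray:
    ts = t - onset
    peak = gamma_dist.pdf(ts, a=delay_r / disp_r, scale=disp_r)
    under = gamma_dist.pdf(ts, a=delay_u / disp_u, scale=disp_u)
    h = peak - under / ratio
    h[ts < 0] = 0.0
    return h


@dataclass
class HRFBasis:
    """Canonical HRF with temporal and dispersion derivatives on a dt grid."""

    dt: float
    canonical: np.ndarray
    temporal_derivative: np.ndarray
    dispersion_derivative: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        for k in (self.canonical, self.temporal_derivative, self.dispersion_derivative):
            if not np.all(np.isfinite(k)):
                raise ValueError("basis kernels must be finite")
        if self.canonical[np.argmax(np.abs(self.canonical))] <= 0:
            raise ValueError("canonical kernel peak must be positive")

    @property
    def kernels(self) -> list[np.ndarray]:
        return [self.canonical, self.temporal_derivative, self.dispersion_derivative]

    @property
    def kernel_names(self) -> list[str]:
        return ["hrf", "tderiv", "dderiv"]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.canonical.size) * self.dt


def canonical_hrf_basis(dt: float) -> HRFBasis:
    """Informed basis set sampled every ``dt`` seconds over 32 s.

    The temporal derivative is (canonical - canonical shifted 1 s later)
    divided by the 1 s shift; the dispersion derivative is the finite
    difference under a 1% perturbation of the response dispersion.  Each
    derivative is then orthogonalised against the canonical kernel.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = HRF_PARAMS
    t = np.arange(0.0, p["length"], dt)
    canon = _double_gamma(
        t, p["delay_response"], p["delay_undershoot"],
        p["dispersion_response"], p["dispersion_undershoot"], p["undershoot_ratio"],
    )
    shifted = _double_gamma(
        t, p["delay_response"], p["delay_undershoot"],
        p["dispersion_response"], p["dispersion_undershoot"], p["undershoot_ratio"],
        onset=1.0,
    )
    tderiv = (canon - shifted) / 1.0
    ddisp = 0.01
    perturbed = _double_gamma(
        t, p["delay_response"], p["delay_undershoot"],
        p["dispersion_response"] * (1.0 + ddisp), p["dispersion_undershoot"],
        p["undershoot_ratio"],
    )
    dderiv = (canon - perturbed) / ddisp

    def orth(v: np.ndarray, against: np.ndarray) -> np.ndarray:
        return v - against * (against @ v) / (against @ against)

    tderiv = orth(tderiv, canon)
    dderiv = orth(dderiv, canon)
    return HRFBasis(
        dt=dt,
        canonical=canon,
        temporal_derivative=tderiv,
        dispersion_derivative=dderiv,
        params=dict(p),
    )


def convolve_downsample_series(
    q: np.ndarray,
    kernel: np.ndarray,
    feature_rate: float,
    kernel_dt: float,
    TR: float,
    n_scans: int,
) -> np.ndarray:
    """Causal convolution of one series with one kernel, sampled mid-TR.

    The kernel is resampled onto the feature-rate grid, convolved causally
    with the series (dt-weighted, so the result approximates the continuous
    convolution integral), and read out at acquisition times
    t_k = (k + 1/2) TR — the middle-slice reference of a slice-time corrected
    acquisition.  The series is extended backwards with its initial value
    for one kernel length: EEG features are ongoing signals, so assuming the
    pre-session state equals the first sample avoids a spurious session-onset
    transient (a constant input maps to a constant output everywhere).
    """
    dt = 1.0 / feature_rate
    kt = np.arange(kernel.size) * kernel_dt
    grid = np.arange(0.0, kt[-1] + dt, dt)
    k = np.interp(grid, kt, kernel)
    n_pad = k.size
    padded = np.concatenate([np.full(n_pad, q[0]), q])
    conv = fftconvolve(padded, k)[n_pad : n_pad + q.size] * dt
    t_scan = (np.arange(n_scans) + 0.5) * TR
    idx = np.round(t_scan * feature_rate).astype(int)
    if idx[-1] >= q.size:
        raise ValueError("regressor shorter than the scan protocol")
    return conv[idx]


def convolve_and_downsample(
    q, basis: HRFBasis, TR: float, n_scans: int
) -> tuple[np.ndarray, list[str]]:
    """Expand a RegressorSet through the 3-kernel basis at scan rate.

    Returns (n_scans x 3*n_regressors matrix, column names); columns are
    mean-centered.  Column order: for each input column, canonical, temporal
    derivative, dispersion derivative.
    """
    rate = q.sampling_rate
    if rate < 1.0 / TR:
        raise ValueError("feature rate must be at least the scan rate")
    cols = []
    names = []
    for name, series in q.columns.items():
        if series.size < int(round(n_scans * TR * rate)) - 1:
            raise ValueError("regressor shorter than the scan protocol")
        for kname, kernel in zip(basis.kernel_names, basis.kernels):
            c = convolve_downsample_series(series, kernel, rate, basis.dt, TR, n_scans)
            cols.append(c - c.mean())
            names.append(f"{q.model_label}:{name}:{kname}")
    return np.column_stack(cols), names
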