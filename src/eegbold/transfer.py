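"""Transfer functions mapping EEG spectral power to BOLD predictors.

Each transfer function turns the Morlet power matrix P(f, t) (or the raw
multichannel amplitude, for the global field power) into one or more
regressor time series at the EEG feature rate:

* Total Power (TP):        q_TP(t)    = sum_f P(f, t)
* Frequency Response (FR): q_FR(t; b) = sum_{f in b} P(f, t), one column
                           per band b (3-, 5- and 8-band presets)
* Heuristic (RMSF):        q_RMSF(t)  = sqrt( sum_f f^2 Ptilde(f, t) )
* u-Heuristic (uRMSF):     q_uRMSF(t) = sqrt( sum_f f^2 P(f, t) )
* l-Heuristic (MSF):       q_MSF(t)   = sum_f f^2 Ptilde(f, t)
* Mean Frequency (MF):     q_MF(t)    = sum_f f  Ptilde(f, t)
* Global Field Power (GFP) from the electrode amplitudes directly.

Ptilde is the column-normalised spectrum (each time point's power divided by
its total), so RMSF/MSF/MF are moments of a per-time-point frequency
distribution and are invariant to overall power scaling, whereas TP and
uRMSF scale with power — the frequency-dependence-versus-amplitude
distinction the model comparison is designed to test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import TimeFrequencyPower

MODEL_LABELS = ("TP", "FR3", "FR5", "FR8", "RMSF", "uRMSF", "MSF", "MF", "GFP")


@dataclass(frozen=True)
class BandSpec:
    """Inclusive integer frequency band [f_min, f_max] in Hz."""

    name: str
    f_min: float
    f_max: float

    def __post_init__(self) -> None:
        if not (1 <= self.f_min <= self.f_max <= 40):
            raise ValueError("band bounds must satisfy 1 <= f_min <= f_max <= 40")


#: Three-band preset: low, alpha, high.  The upper band starts at 15 Hz; its
#: one-bin overlap with the alpha band keeps TP outside the exact linear span
#: of the three bands.
FR3_BANDS = (
    BandSpec("low", 1, 7),
    BandSpec("alpha", 8, 15),
    BandSpec("high", 15, 40),
)

#: Five-band preset on the integer grid, shared endpoints assigned to the
#: lower band so the bands partition 1-40 Hz.
FR5_BANDS = (
    BandSpec("delta", 1, 4),
    BandSpec("theta", 5, 8),
    BandSpec("alpha", 9, 13),
    BandSpec("beta", 14, 30),
    BandSpec("low_gamma", 31, 40),
)

#: Eight 5 Hz bands spanning 1-40 Hz.
FR8_BANDS = tuple(
    BandSpec(f"band_{lo}_{lo + 4}", lo, lo + 4) for lo in range(1, 40, 5)
)

#: Single-band presets for the one-band Frequency Response comparisons.
ALPHA_BAND = (BandSpec("alpha", 8, 15),)
BETA_GAMMA_BAND = (BandSpec("beta_gamma", 15, 40),)

BAND_PRESETS: dict[str, tuple[BandSpec, ...]] = {
    "FR3": FR3_BANDS,
    "FR5": FR5_BANDS,
    "FR8": FR8_BANDS,
}


@dataclass
class NormalizedSpectrum:
    """Column-normalised power spectrum Ptilde: every time column sums to 1."""

    ptilde: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ptilde < 0) or np.any(self.ptilde > 1 + 1e-9):
            raise ValueError("normalised spectrum entries must lie in [0, 1]")


@dataclass
class RegressorSet:
    """Named transfer-function time series at the feature rate.

    ``columns`` is an ordered mapping of column name -> 1-D series; all
    columns share ``times``.  Scalar models carry one column; FR3/FR5/FR8
    carry one per band.
    """

    model_label: str
    columns: dict[str, np.ndarray]
    times: np.ndarray
    bands: tuple[BandSpec, ...] | None = None

    def __post_init__(self) -> None:
        if self.model_label not in MODEL_LABELS:
            raise ValueError(f"unknown model label {self.model_label!r}")
        n = self.times.size
        for name, col in self.columns.items():
            if col.shape != (n,):
                raise ValueError(f"column {name!r} does not share the time base")

    @property
    def n_regressors(self) -> int:
        return len(self.columns)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])

    def as_matrix(self) -> np.ndarray:
        """Columns stacked as n_t x n_regressors."""
        return np.column_stack(list(self.columns.values()))


def normalize_spectrum(P: TimeFrequencyPower) -> NormalizedSpectrum:
    """Divide each time column of P by its total power over frequencies.

    Zero-total columns (impossible on realistic data once broadband noise is
    present) are mapped to the uniform distribution 1/n_f with a warning.
    """
    totals = P.power.sum(axis=0)
    zero = totals <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-total-power columns set to uniform",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, totals)
    ptilde = P.power / safe
    if np.any(zero):
        ptilde[:, zero] = 1.0 / P.freqs.size
    return NormalizedSpectrum(ptilde=ptilde, freqs=P.freqs, times=P.times)


def total_power(P: TimeFrequencyPower) -> RegressorSet:
    """Total Power: sum of spectral power over the full analysis grid."""
    return RegressorSet(
        model_label="TP",
        columns={"TP": P.power.sum(axis=0)},
        times=P.times,
    )


def band_power(
    P: TimeFrequencyPower,
    bands: tuple[BandSpec, ...],
    model_label: str = "FR3",
) -> RegressorSet:
    """Frequency Response regressors: per-band power sums."""
    cols: dict[str, np.ndarray] = {}
    for band in bands:
        if band.f_min < P.freqs[0] or band.f_max > P.freqs[-1]:
            raise ValueError(f"band {band.name} outside the frequency grid")
        sel = (P.freqs >= band.f_min) & (P.freqs <= band.f_max)
        cols[band.name] = P.power[sel].sum(axis=0)
    return RegressorSet(model_label=model_label, columns=cols, times=P.times, bands=bands)


def rmsf(ptilde: NormalizedSpectrum) -> RegressorSet:
    """Heuristic: root-mean-square frequency of the normalised spectrum."""
    q = np.sqrt(np.einsum("f,ft->t", ptilde.freqs**2, ptilde.ptilde))
    return RegressorSet(model_label="RMSF", columns={"RMSF": q}, times=ptilde.times)


def u_rmsf(P: TimeFrequencyPower) -> RegressorSet:
    """Un-normalised Heuristic: sqrt of the f^2-weighted raw power sum."""
    q = np.sqrt(np.einsum("f,ft->t", P.freqs**2, P.power))
    return RegressorSet(model_label="uRMSF", columns={"uRMSF": q}, times=P.times)


def msf(ptilde: NormalizedSpectrum) -> RegressorSet:
    """Linear Heuristic: mean-square frequency (RMSF without the root)."""
    q = np.einsum("f,ft->t", ptilde.freqs**2, ptilde.ptilde)
    return RegressorSet(model_label="MSF", columns={"MSF": q}, times=ptilde.times)


def mean_frequency(ptilde: NormalizedSpectrum) -> RegressorSet:
    """Mean frequency (spectral centroid) of the normalised spectrum."""
    q = np.einsum("f,ft->t", ptilde.freqs, ptilde.ptilde)
    return RegressorSet(model_label="MF", columns={"MF": q}, times=ptilde.times)


def gfp_regressor(gfp: np.ndarray, sampling_rate: float) -> RegressorSet:
    """Wrap a global-field-power series as a transfer-function regressor."""
    times = np.arange(gfp.size) / sampling_rate
    return RegressorSet(model_label="GFP", columns={"GFP": np.asarray(gfp, float)}, times=times)


def build_regressors(
    label: str,
    P: TimeFrequencyPower,
    gfp: np.ndarray | None = None,
    normalized_bands: bool = False,
) -> RegressorSet:
    """Build the regressor set for one model label from the power matrix.

    ``normalized_bands`` builds the FR variants from the normalised spectrum
    instead of raw power (used in the non-linearity comparisons).
    """
    if label == "TP":
        return total_power(P)
    if label in BAND_PRESETS:
        if normalized_bands:
            pt = normalize_spectrum(P)
            Pn = TimeFrequencyPower(
                power=pt.ptilde, freqs=pt.freqs, times=pt.times,
                wavelet_factor=P.wavelet_factor,
            )
            return band_power(Pn, BAND_PRESETS[label], model_label=label)
        return band_power(P, BAND_PRESETS[label], model_label=label)
    if label == "RMSF":
        return rmsf(normalize_spectrum(P))
    if label == "uRMSF":
        return u_rmsf(P)
    if label == "MSF":
        return msf(normalize_spectrum(P))
    if label == "MF":
        return mean_frequency(normalize_spectrum(P))
    if label == "GFP":
        if gfp is None:
            raise ValueError("GFP model requires the global-field-power series")
        return gfp_regressor(gfp, 1.0 / float(P.times[1] - P.times[0]))
    raise ValueError(f"unknown model label {label!r}")
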