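"""EEG feature extraction: principal scalp series, Morlet time-frequency
power, global field power, and steady-state visual evoked responses.

The multichannel recording is reduced to a single representative "scalp"
series by projection onto the leading spatial eigenvector of the data
(computed by SVD), the data-driven analogue of averaging over posterior
electrodes.  Its time-varying spectrum is obtained by convolution with
complex Morlet wavelets

    G(f, t) = A exp(-t^2 / 2 sigma_t^2) exp(2 i pi f t),

with A = (sigma_t sqrt(pi))^(-1/2), sigma_t = 1/(2 pi sigma_f),
sigma_f = f / R and wavelet factor R = 7; the power is the squared modulus
of the convolution, P(f, t) = |G(f, .) * y(t)|^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

DEFAULT_WAVELET_FACTOR: float = 7.0

#: Default analysis grid: 1-40 Hz inclusive, 1 Hz steps.
DEFAULT_FREQS: np.ndarray = np.arange(1.0, 41.0)


@dataclass
class EEGRecording:
    """Multichannel EEG with protocol annotations.

    ``data`` is electrodes x samples in microvolts.  ``annotations`` is a
    list of ``(onset_seconds, condition, frequency)`` block annotations.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    annotations: list[tuple[float, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be electrodes x samples")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 electrodes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in EEG data")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match electrode count")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def drop_channels(self, labels: list[str]) -> "EEGRecording":
        """Recording without the named channels (e.g. eye-blink leads Fp1/Fp2)."""
        keep = [i for i, l in enumerate(self.channel_labels) if l not in labels]
        if len(keep) < 2:
            raise ValueError("cannot drop channels below 2 electrodes")
        return EEGRecording(
            data=self.data[keep],
            sampling_rate=self.sampling_rate,
            channel_labels=[self.channel_labels[i] for i in keep],
            annotations=list(self.annotations),
        )


@dataclass
class ScalpSeries:
    """Representative scalp series: projection onto the first spatial eigenvector."""

    series: np.ndarray
    eigenvector: np.ndarray
    variance_explained: float
    sampling_rate: float

    def __post_init__(self) -> None:
        if not np.isclose(np.linalg.norm(self.eigenvector), 1.0):
            raise ValueError("eigenvector must have unit norm")
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-12:
            raise ValueError("variance_explained must lie in [0, 1]")


@dataclass
class TimeFrequencyPower:
    """Morlet wavelet power matrix P(f, t).

    ``power`` is n_f x n_t (non-negative), ``freqs`` the strictly increasing
    frequency grid in Hz, ``times`` in seconds.  ``edge_mask`` flags, per
    frequency, samples within 3 sigma_t(f) of either boundary where the
    zero-padded convolution is biased; flagged samples are retained in the
    matrix (downstream HRF convolution and high-pass filtering dominate any
    edge bias) but excluded from interior time averages.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    wavelet_factor: float = DEFAULT_WAVELET_FACTOR
    edge_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError("power must be n_f x n_t")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])

    def interior_mean(self) -> np.ndarray:
        """Time-averaged power per frequency, excluding edge-flagged samples."""
        if self.edge_mask is None:
            return self.power.mean(axis=1)
        out = np.empty(self.freqs.size)
        for i in range(self.freqs.size):
            ok = ~self.edge_mask[i]
            out[i] = self.power[i, ok].mean() if ok.any() else self.power[i].mean()
        return out


def principal_projection(rec: EEGRecording) -> ScalpSeries:
    """Project the recording onto its first principal spatial eigenvector.

    Electrode rows are mean-centered over time before the SVD so that the
    explained-variance fraction is a true variance fraction.  The sign of the
    eigenvector is fixed so its largest-magnitude loading is positive.
    """
    Y = rec.data - rec.data.mean(axis=1, keepdims=True)
    if not np.any(Y):
        raise ValueError("degenerate input: EEG data has zero variance")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    u1 = U[:, 0]
    if u1[np.argmax(np.abs(u1))] < 0:
        u1 = -u1
    series = u1 @ Y
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return ScalpSeries(
        series=series,
        eigenvector=u1,
        variance_explained=var_explained,
        sampling_rate=rec.sampling_rate,
    )


def morlet_wavelet(f: float, rate: float, R: float = DEFAULT_WAVELET_FACTOR) -> np.ndarray:
    """Complex Morlet kernel at frequency `f`, sampled at `rate`, +/- 5 sigma_t."""
    sigma_f = f / R
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(5.0 * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    A = (sigma_t * np.sqrt(np.pi)) ** (-0.5)
    return A * np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f * t)


def morlet_power(
    series: ScalpSeries | np.ndarray,
    freqs: np.ndarray | None = None,
    R: float = DEFAULT_WAVELET_FACTOR,
    sampling_rate: float | None = None,
) -> TimeFrequencyPower:
    """Time-varying power |G(f,.) * y|^2 on the analysis frequency grid.

    Accepts a :class:`ScalpSeries` or a plain array (then ``sampling_rate``
    is required).  The convolution is zero-padded and aligned to the input
    time base; per-frequency edge regions within 3 sigma_t of either boundary
    are flagged in ``edge_mask``.
    """
    if isinstance(series, ScalpSeries):
        y = np.asarray(series.series, dtype=float)
        rate = series.sampling_rate
    else:
        y = np.asarray(series, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a plain array")
        rate = float(sampling_rate)
    freqs = DEFAULT_FREQS.copy() if freqs is None else np.asarray(freqs, dtype=float)
    nyquist = rate / 2.0
    if np.any(freqs <= 0) or np.any(freqs >= nyquist):
        raise ValueError("frequencies must lie strictly inside (0, Nyquist)")
    n = y.size
    power = np.empty((freqs.size, n))
    edge = np.zeros((freqs.size, n), dtype=bool)
    idx = np.arange(n)
    for i, f in enumerate(freqs):
        G = morlet_wavelet(f, rate, R)
        conv = fftconvolve(y.astype(complex), G, mode="same")
        power[i] = np.abs(conv) ** 2
        sigma_t = R / (2.0 * np.pi * f)
        n_edge = int(np.ceil(3.0 * sigma_t * rate))
        edge[i] = (idx < n_edge) | (idx >= n - n_edge)
    times = np.arange(n) / rate
    return TimeFrequencyPower(
        power=power, freqs=freqs, times=times, wavelet_factor=R, edge_mask=edge
    )


def global_field_power(rec: EEGRecording) -> np.ndarray:
    """Global field power: per-sample RMS deviation of the electrode
    potentials from their instantaneous cross-electrode mean.

    Reference-free: adding any common offset per time point leaves it
    unchanged.
    """
    if rec.n_electrodes < 2:
        raise ValueError("GFP requires at least 2 electrodes")
    dev = rec.data - rec.data.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(dev**2, axis=0))


@dataclass
class SSVERResult:
    """Steady-state visual evoked responses, one averaged epoch per condition."""

    conditions: list[float]
    epochs: dict[float, np.ndarray]
    spectra: dict[float, TimeFrequencyPower]
    window: float
    sampling_rate: float

    def peak_frequency(self, condition: float) -> float:
        """Frequency of maximal time-averaged power for one flicker condition."""
        spec = self.spectra[condition]
        return float(spec.freqs[np.argmax(spec.power.mean(axis=1))])

    def peak_power(self, condition: float) -> float:
        """Maximal time-averaged power across the grid for one condition."""
        return float(self.spectra[condition].power.mean(axis=1).max())


def compute_ssver(
    rec: EEGRecording,
    channel: str,
    window: float = 0.5,
    freqs: np.ndarray | None = None,
    R: float = DEFAULT_WAVELET_FACTOR,
) -> SSVERResult:
    """Steady-state responses by epoching one channel post-stimulus.

    For every task block at flicker frequency f, epochs of length ``window``
    are extracted time-locked to each checkerboard reversal (reversals occur
    at 2f, so phase-locked activity at the reversal frequency and its
    harmonics survives averaging while ongoing activity cancels).  Epochs are
    averaged across all reversals and blocks of a condition, and the spectrum
    of the averaged epoch is computed with the same Morlet decomposition as
    the main analysis.
    """
    from .protocol import SCANS_PER_BLOCK  # local import to avoid cycle

    if channel not in rec.channel_labels:
        raise ValueError(f"unknown channel {channel!r}")
    sig = rec.data[rec.channel_labels.index(channel)]
    rate = rec.sampling_rate
    n_win = int(round(window * rate))

    blocks: dict[float, list[tuple[float, float]]] = {}
    onsets = [a for a in rec.annotations if a[1] == "task"]
    if not onsets:
        raise ValueError("recording has no task-block annotations")
    block_dur = None
    rests = sorted(a[0] for a in rec.annotations)
    if len(rests) >= 2:
        block_dur = rests[1] - rests[0]
    if block_dur is None:
        block_dur = rec.n_samples / rate
    if window > block_dur:
        raise ValueError("window exceeds the inter-stimulus (block) interval")
    for onset, _, f in onsets:
        blocks.setdefault(f, []).append((onset, onset + block_dur))

    conditions = sorted(blocks)
    epochs: dict[float, np.ndarray] = {}
    spectra: dict[float, TimeFrequencyPower] = {}
    for f in conditions:
        acc = np.zeros(n_win)
        count = 0
        reversal_period = 1.0 / (2.0 * f)
        for onset, offset in blocks[f]:
            t = onset
            while t + window <= offset:
                i0 = int(round(t * rate))
                if i0 + n_win <= rec.n_samples:
                    acc += sig[i0 : i0 + n_win]
                    count += 1
                t += reversal_period
        avg = acc / max(count, 1)
        epochs[f] = avg
        spectra[f] = morlet_power(avg, freqs=freqs, R=R, sampling_rate=rate)
    return SSVERResult(
        conditions=conditions,
        epochs=epochs,
        spectra=spectra,
        window=window,
        sampling_rate=rate,
    )
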