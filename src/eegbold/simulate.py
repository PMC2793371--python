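"""Synthetic simultaneous EEG-fMRI generator with known ground-truth
neurovascular coupling.

The EEG simulator emulates the statistical structure the analysis assumes:
steady-state entrainment at the second harmonic of the flicker frequency
with an inverted-U amplitude profile peaking near 7.5 Hz, posterior alpha
whose amplitude drops during task blocks, and broadband 1/f noise.  The
signal components are projected through a single posterior-weighted
topography vector; noise is spatially white, so the first spatial
eigenvector of the data recovers the signal topography.

The BOLD simulator drives active voxels with a chosen ground-truth transfer
function applied to the simulated EEG features, convolved with the canonical
HRF and downsampled to scan rate, plus AR(1) noise and slow polynomial
drift; inactive voxels carry noise and drift only.  All randomness is
reproducible from the parameter seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .features import EEGRecording, TimeFrequencyPower
from .hrf import HRFBasis, convolve_downsample_series
from .protocol import FLICKER_FREQUENCIES, StimulusProtocol
from .transfer import MODEL_LABELS, RegressorSet, build_regressors

#: 29 scalp positions (10/20 extension), posterior channels last.
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "O2",
]

#: SSVER amplitude (microvolt) vs flicker frequency: piecewise-linear
#: inverted U peaking at 7.5 Hz, near zero above 15 Hz.
DEFAULT_SSVER_CURVE = {
    2.0: 1.5, 3.75: 2.5, 5.0: 3.5, 6.0: 4.2, 7.5: 5.0,
    10.0: 3.5, 15.0: 1.2, 30.0: 0.3,
}


def posterior_topography(channels: list[str] | None = None) -> np.ndarray:
    """Unit-norm spatial loading concentrated on posterior (O/PO/P) leads."""
    channels = DEFAULT_CHANNELS if channels is None else channels
    w = []
    for c in channels:
        if c.startswith("O"):
            w.append(1.0)
        elif c.startswith("PO"):
            w.append(0.8)
        elif c.startswith("P") or c.startswith("CP"):
            w.append(0.5)
        else:
            w.append(0.1)
    v = np.asarray(w)
    return v / np.linalg.norm(v)


def substreams(master_seed: int) -> dict[str, int]:
    """Named independent seeds derived from one master seed.

    Lets the block order, the EEG noise and the BOLD noise be varied
    independently while staying reproducible from a single integer.
    """
    state = np.random.SeedSequence(master_seed).generate_state(3)
    names = ("block-order", "eeg-noise", "bold-noise")
    return {n: int(s) & 0x7FFFFFFF for n, s in zip(names, state)}


@dataclass
class EEGSimParams:
    """Parameters of the EEG forward model (amplitudes in microvolt)."""

    n_electrodes: int = 29
    ssver_amplitude_curve: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_SSVER_CURVE)
    )
    alpha_power_rest: float = 20.0
    alpha_power_task: float = 8.0
    alpha_frequency: float = 10.0
    one_over_f_exponent: float = 1.0
    sensor_topography: np.ndarray | None = None
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_power_rest < 0 or self.alpha_power_task < 0:
            raise ValueError("alpha powers must be non-negative")
        if any(a < 0 for a in self.ssver_amplitude_curve.values()):
            raise ValueError("SSVER amplitudes must be non-negative")
        if self.sensor_topography is not None:
            v = np.asarray(self.sensor_topography, float)
            if not np.isclose(np.linalg.norm(v), 1.0):
                raise ValueError("sensor_topography must have unit norm")
            self.sensor_topography = v


@dataclass
class BOLDSimParams:
    """Parameters of the BOLD forward model (arbitrary units)."""

    ground_truth_model: str = "RMSF"
    coupling_gain: float = 3.0
    n_voxels: int = 200
    active_voxels: np.ndarray | None = None
    ar1_coefficient: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    standardize_regressor: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ground_truth_model not in MODEL_LABELS:
            raise ValueError(f"unknown ground-truth model {self.ground_truth_model!r}")
        if not 0 <= abs(self.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1")
        if self.active_voxels is None:
            self.active_voxels = np.arange(max(1, self.n_voxels // 10))
        self.active_voxels = np.asarray(self.active_voxels, dtype=int)
        if self.active_voxels.min() < 0 or self.active_voxels.max() >= self.n_voxels:
            raise ValueError("active_voxels must lie within [0, n_voxels)")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery of the simulated coupling."""

    ground_truth_model: str
    regressor: np.ndarray
    active_voxels: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        self.regressor = np.asarray(self.regressor, float)


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, rate: float, exponent: float
) -> np.ndarray:
    """Unit-sd noise per channel with power spectrum proportional to 1/f^exponent."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    shaped = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def ssver_amplitude(curve: dict[float, float], f: float) -> float:
    """Piecewise-linear interpolation of the amplitude curve at flicker f."""
    fs = np.array(sorted(curve))
    amps = np.array([curve[k] for k in fs])
    return float(np.interp(f, fs, amps))


def simulate_eeg(protocol: StimulusProtocol, params: EEGSimParams) -> EEGRecording:
    """Simulate the multichannel EEG for one session.

    During a task block at flicker frequency f the topography carries a
    sinusoid at the reversal frequency 2f (phase-locked to block onset) with
    amplitude from the inverted-U curve; the alpha component switches
    between its rest and task amplitudes; 1/f-shaped noise is added
    independently per channel.
    """
    rate = protocol.eeg_rate
    max_response = 2.0 * max(
        [f for _, f in protocol.block_order if f > 0], default=0.0
    )
    if rate < 2.0 * max_response:
        raise ValueError(
            f"eeg_rate {rate} Hz aliases the {max_response} Hz steady-state response"
        )
    n = protocol.n_eeg_samples
    t = np.arange(n) / rate
    channels = DEFAULT_CHANNELS[: params.n_electrodes]
    if len(channels) < params.n_electrodes:
        channels = channels + [f"ch{i}" for i in range(len(channels), params.n_electrodes)]
    topo = (
        posterior_topography(channels)
        if params.sensor_topography is None
        else params.sensor_topography
    )
    if topo.size != params.n_electrodes:
        raise ValueError("topography length must match electrode count")

    rng = np.random.default_rng(params.seed)
    alpha_phase = rng.uniform(0.0, 2.0 * np.pi)

    ssver = np.zeros(n)
    for onset, offset, f in protocol.task_blocks():
        amp = ssver_amplitude(params.ssver_amplitude_curve, f)
        sel = (t >= onset) & (t < offset)
        ssver[sel] = amp * np.sin(2.0 * np.pi * (2.0 * f) * (t[sel] - onset))

    task = protocol.task_boxcar(rate)[:n]
    alpha_amp = np.where(
        task > 0,
        np.sqrt(2.0 * params.alpha_power_task),
        np.sqrt(2.0 * params.alpha_power_rest),
    )
    alpha = alpha_amp * np.sin(2.0 * np.pi * params.alpha_frequency * t + alpha_phase)

    data = topo[:, None] * (ssver + alpha)[None, :]
    if params.noise_sd > 0:
        data = data + params.noise_sd * _one_over_f_noise(
            rng, params.n_electrodes, n, rate, params.one_over_f_exponent
        )
    annotations = [
        (float(onset), cond, float(f))
        for onset, (cond, f) in zip(protocol.block_onsets(), protocol.block_order)
    ]
    return EEGRecording(
        data=data, sampling_rate=rate, channel_labels=channels, annotations=annotations
    )


def _band_forward_weights(n_bands: int) -> np.ndarray:
    """Fixed alternating band weights for Frequency-Response ground truth."""
    j = np.arange(n_bands)
    return (-1.0) ** (j + 1) * (1.0 + 0.5 * j)


def _ground_truth_regressor(
    label: str,
    tfr: TimeFrequencyPower,
    gfp: np.ndarray | None,
    basis: HRFBasis,
    TR: float,
    n_scans: int,
    standardize: bool,
) -> np.ndarray:
    q = build_regressors(label, tfr, gfp=gfp)
    rate = q.sampling_rate
    cols = []
    for series in q.columns.values():
        c = convolve_downsample_series(
            series, basis.canonical, rate, basis.dt, TR, n_scans
        )
        cols.append(c)
    if len(cols) == 1:
        z = cols[0]
    else:
        # frequency-dependent combination: standardize bands before weighting
        w = _band_forward_weights(len(cols))
        stacked = np.column_stack([(c - c.mean()) / (c.std() or 1.0) for c in cols])
        z = stacked @ w
    if standardize:
        sd = z.std()
        z = (z - z.mean()) / (sd if sd > 0 else 1.0)
    return z


def simulate_bold(
    tfr: TimeFrequencyPower,
    gfp: np.ndarray | None,
    protocol: StimulusProtocol,
    params: BOLDSimParams,
    basis: HRFBasis,
):
    """Simulate the BOLD dataset for one session with known coupling.

    Active voxels receive ``coupling_gain`` times the ground-truth regressor
    (the chosen transfer function of the supplied EEG features, convolved
    with the canonical HRF and sampled mid-TR); every voxel receives
    stationary AR(1) noise and a random second-order polynomial drift.
    Returns ``(BOLDDataset, SyntheticGroundTruth)``; the ground truth records
    the final scan-rate regressor and all parameters.

    Noise, drift and motion draws do not depend on ``coupling_gain``, so
    runs differing only in gain share their noise realisation seed-for-seed.
    """
    from .design import BOLDDataset  # local import to avoid cycle

    duration = tfr.times[-1] + (tfr.times[1] - tfr.times[0])
    if duration + 1e-6 < protocol.duration:
        raise ValueError("feature time base does not cover the full protocol")
    n_scans = protocol.n_scans
    TR = protocol.TR
    rng = np.random.default_rng(params.seed)

    # noise first, independent of the coupling model/gain
    rho = params.ar1_coefficient
    eps = rng.standard_normal((n_scans, params.n_voxels))
    eps *= params.noise_sd * np.sqrt(1.0 - rho**2)
    eps[0] /= np.sqrt(1.0 - rho**2)
    noise = lfilter([1.0], [1.0, -rho], eps, axis=0)

    x = np.linspace(-1.0, 1.0, n_scans)
    leg = np.column_stack([x, 1.5 * x**2 - 0.5])
    drift_coef = rng.standard_normal((2, params.n_voxels)) * params.drift_amplitude
    drift = leg @ drift_coef

    steps = rng.standard_normal((n_scans, 6)) * 0.02
    motion = lfilter([1.0], [1.0, -0.95], steps, axis=0)

    z = _ground_truth_regressor(
        params.ground_truth_model, tfr, gfp, basis, TR, n_scans,
        params.standardize_regressor,
    )
    Y = noise + drift
    Y[:, params.active_voxels] += params.coupling_gain * z[:, None]

    bold = BOLDDataset(Y=Y, TR=TR, motion=[motion])
    truth = SyntheticGroundTruth(
        ground_truth_model=params.ground_truth_model,
        regressor=z,
        active_voxels=params.active_voxels.copy(),
        params={
            "coupling_gain": params.coupling_gain,
            "n_voxels": params.n_voxels,
            "ar1_coefficient": rho,
            "noise_sd": params.noise_sd,
            "drift_amplitude": params.drift_amplitude,
            "standardize_regressor": params.standardize_regressor,
            "seed": params.seed,
            "n_scans": n_scans,
            "TR": TR,
        },
    )
    return bold, truth
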