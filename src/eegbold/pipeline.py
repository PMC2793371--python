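"""End-to-end orchestration: simulate -> features -> transfer functions ->
design -> model comparison, with cached intermediates and a run manifest.

Every stage reads its inputs from, and writes its outputs to, one output
directory; intermediates are flat ``.npy`` arrays with JSON sidecars, so any
stage can be re-run in isolation and reproduces its outputs bit-exactly from
the cached inputs.  The manifest records the configuration snapshot, all
derived seeds, the package version and a checksum for every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .design import BOLDDataset, assemble_design
from .features import (
    EEGRecording,
    TimeFrequencyPower,
    compute_ssver,
    global_field_power,
    morlet_power,
    principal_projection,
)
from .glm import activation_mask, compare_models
from .hrf import canonical_hrf_basis
from .protocol import StimulusProtocol, generate_protocol
from .simulate import BOLDSimParams, EEGSimParams, simulate_bold, simulate_eeg, substreams
from .transfer import build_regressors

logger = logging.getLogger("eegbold")

DEFAULT_CONFIG = {
    "n_task_blocks": 30,
    "TR": 3.06,
    "eeg_rate": 250.0,
    "wavelet_factor": 7.0,
    "freq_min": 1.0,
    "freq_max": 40.0,
    "freq_step": 1.0,
    "highpass_cutoff": 128.0,
    "hrf_dt": 0.1,
    "models": ["TP", "FR3", "RMSF"],
    "mode": "shared",
    "mask_alpha": 0.05,
    "thresholds": {"p05_fwe": 0.05, "p001_uncorrected": 0.001},
    "ground_truth_model": "RMSF",
    "coupling_gain": 3.0,
    "n_voxels": 200,
    "ar1_coefficient": 0.3,
    "bold_noise_sd": 1.0,
    "drift_amplitude": 1.0,
    "eeg_noise_sd": 0.5,
}

REQUIRED_KEYS = ("n_task_blocks", "TR", "models", "mode")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seeds: dict
    version: str
    checksums: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "version": self.version,
            "checksums": self.checksums,
        }


def validate_config(config: dict) -> dict:
    """Fill defaults; raise naming any required key that is missing/None."""
    merged = dict(DEFAULT_CONFIG)
    merged.update(config or {})
    for key in REQUIRED_KEYS:
        if merged.get(key) is None:
            raise ValueError(f"missing required config key: {key!r}")
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _freqs(config: dict) -> np.ndarray:
    return np.arange(
        config["freq_min"], config["freq_max"] + config["freq_step"] / 2,
        config["freq_step"],
    )


def _save(out: Path, name: str, array: np.ndarray, sidecar: dict) -> None:
    np.save(out / f"{name}.npy", array)
    (out / f"{name}.json").write_text(json.dumps(sidecar, indent=1))


def stage_simulate(config: dict, seed: int, out: Path) -> None:
    """Generate the protocol, the EEG session and the coupled BOLD dataset."""
    seeds = substreams(seed)
    protocol = generate_protocol(
        config["n_task_blocks"], TR=config["TR"], seed=seeds["block-order"],
        eeg_rate=config["eeg_rate"],
    )
    eeg_params = EEGSimParams(seed=seeds["eeg-noise"], noise_sd=config["eeg_noise_sd"])
    rec = simulate_eeg(protocol, eeg_params)

    # features of the simulated EEG drive the forward BOLD model
    scalp = principal_projection(rec)
    tfr = morlet_power(scalp, freqs=_freqs(config), R=config["wavelet_factor"])
    gfp = global_field_power(rec)
    basis = canonical_hrf_basis(config["hrf_dt"])
    bold_params = BOLDSimParams(
        ground_truth_model=config["ground_truth_model"],
        coupling_gain=config["coupling_gain"],
        n_voxels=config["n_voxels"],
        ar1_coefficient=config["ar1_coefficient"],
        noise_sd=config["bold_noise_sd"],
        drift_amplitude=config["drift_amplitude"],
        seed=seeds["bold-noise"],
    )
    bold, truth = simulate_bold(tfr, gfp, protocol, bold_params, basis)

    (out / "protocol.json").write_text(json.dumps(protocol.to_dict(), indent=1))
    _save(out, "eeg", rec.data, {
        "sampling_rate": rec.sampling_rate,
        "channel_labels": rec.channel_labels,
        "annotations": rec.annotations,
        "units": "microvolt",
    })
    _save(out, "bold", bold.Y, {"TR": bold.TR, "units": "a.u."})
    _save(out, "motion", bold.motion[0], {"columns": 6})
    (out / "ground_truth.json").write_text(json.dumps({
        "ground_truth_model": truth.ground_truth_model,
        "regressor": truth.regressor.tolist(),
        "active_voxels": truth.active_voxels.tolist(),
        "params": truth.params,
        "seeds": seeds,
    }, indent=1))


def _load_recording(out: Path) -> EEGRecording:
    side = json.loads((out / "eeg.json").read_text())
    return EEGRecording(
        data=np.load(out / "eeg.npy"),
        sampling_rate=side["sampling_rate"],
        channel_labels=side["channel_labels"],
        annotations=[(a[0], a[1], a[2]) for a in side["annotations"]],
    )


def _load_bold(out: Path) -> BOLDDataset:
    side = json.loads((out / "bold.json").read_text())
    return BOLDDataset(
        Y=np.load(out / "bold.npy"), TR=side["TR"], motion=[np.load(out / "motion.npy")]
    )


def _load_tfr(out: Path, config: dict) -> TimeFrequencyPower:
    side = json.loads((out / "tfr.json").read_text())
    return TimeFrequencyPower(
        power=np.load(out / "tfr.npy"),
        freqs=np.asarray(side["freqs"]),
        times=np.asarray(side["times"]),
        wavelet_factor=side["wavelet_factor"],
    )


def stage_features(config: dict, out: Path) -> None:
    """Scalp projection, Morlet power, GFP and SSVER spectra of the EEG."""
    rec = _load_recording(out)
    scalp = principal_projection(rec)
    tfr = morlet_power(scalp, freqs=_freqs(config), R=config["wavelet_factor"])
    gfp = global_field_power(rec)
    _save(out, "tfr", tfr.power, {
        "freqs": tfr.freqs.tolist(),
        "times": tfr.times.tolist(),
        "wavelet_factor": tfr.wavelet_factor,
    })
    _save(out, "gfp", gfp, {"sampling_rate": rec.sampling_rate})
    _save(out, "scalp_series", scalp.series, {
        "eigenvector": scalp.eigenvector.tolist(),
        "variance_explained": scalp.variance_explained,
        "channel_labels": rec.channel_labels,
    })
    posterior = [c for c in ("O2", "O1", "PO4", "PO3", "Pz") if c in rec.channel_labels]
    if posterior:
        ssver = compute_ssver(rec, posterior[0])
        (out / "ssver.json").write_text(json.dumps({
            "channel": posterior[0],
            "conditions": ssver.conditions,
            "peak_frequency": {str(c): ssver.peak_frequency(c) for c in ssver.conditions},
            "peak_power": {str(c): ssver.peak_power(c) for c in ssver.conditions},
        }, indent=1))


def stage_transfer(config: dict, out: Path) -> None:
    """Build every requested transfer-function regressor at feature rate."""
    tfr = _load_tfr(out, config)
    gfp = np.load(out / "gfp.npy")
    meta = {}
    mats = {}
    for label in config["models"]:
        q = build_regressors(label, tfr, gfp=gfp)
        mats[label] = q.as_matrix()
        meta[label] = list(q.columns.keys())
    stacked = np.column_stack([mats[l] for l in config["models"]])
    _save(out, "regressors", stacked, {
        "models": {l: meta[l] for l in config["models"]},
        "sampling_rate": 1.0 / float(tfr.times[1] - tfr.times[0]),
    })


def _load_models(config: dict, out: Path):
    tfr = _load_tfr(out, config)
    gfp = np.load(out / "gfp.npy")
    return [build_regressors(l, tfr, gfp=gfp) for l in config["models"]]


def stage_design(config: dict, out: Path) -> None:
    """Assemble the partitioned design matrix for the configured models."""
    bold = _load_bold(out)
    basis = canonical_hrf_basis(config["hrf_dt"])
    models = _load_models(config, out)
    dm = assemble_design(models, bold, basis, config["highpass_cutoff"])
    _save(out, "design", dm.X, {
        "column_labels": dm.column_labels,
        "partition": {l: v.tolist() for l, v in dm.partition.items()},
        "confound_columns": dm.confound_columns.tolist(),
        "highpass_cutoff": dm.highpass_cutoff,
        "TR": dm.TR,
    })


def stage_compare(config: dict, out: Path) -> None:
    """Activation mask, model comparison and the thresholded report."""
    bold = _load_bold(out)
    protocol = StimulusProtocol.from_dict(
        json.loads((out / "protocol.json").read_text())
    )
    basis = canonical_hrf_basis(config["hrf_dt"])
    models = _load_models(config, out)
    mask = activation_mask(
        bold, protocol, basis, alpha=config["mask_alpha"],
        highpass_cutoff=config["highpass_cutoff"],
    )
    report = compare_models(
        bold, models, basis, mode=config["mode"], mask=mask,
        thresholds=config["thresholds"], highpass_cutoff=config["highpass_cutoff"],
    )
    _save(out, "mask", mask.astype(int), {"alpha": config["mask_alpha"]})
    fmaps = np.column_stack([report.f_results[l].F for l in report.model_labels])
    _save(out, "fmaps", fmaps, {"models": report.model_labels})
    df = report.to_dataframe()
    df.to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps({
        "mode": report.mode,
        "models": report.model_labels,
        "thresholds": report.thresholds,
        "summaries": {
            l: {
                region: {
                    thr: {"n_vox": s.n_vox, "F_max": s.F_max, "peak_voxel": s.peak_voxel}
                    for thr, s in by_thr.items()
                }
                for region, by_thr in report.summaries[l].items()
            }
            for l in report.model_labels
        },
    }, indent=1))


STAGES = {
    "simulate": stage_simulate,
    "features": stage_features,
    "transfer": stage_transfer,
    "design": stage_design,
    "compare": stage_compare,
}

STAGE_ORDER = ("simulate", "features", "transfer", "design", "compare")


def run_stage(name: str, config: dict, seed: int, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage %s -> %s", name, out)
    try:
        if name == "simulate":
            stage_simulate(config, seed, out)
        else:
            STAGES[name](config, out)
    except Exception as exc:
        inputs = sorted(p.name for p in out.iterdir() if p.is_file())
        raise RuntimeError(
            f"stage {name!r} failed ({exc}); inputs present: {inputs}"
        ) from exc


def run_pipeline(config: dict | None, seed: int, out_dir: str | Path) -> RunManifest:
    """Run every stage in order and write ``manifest.json``.

    Deterministic: the same (config, seed) pair reproduces every output file
    byte-for-byte, hence an identical manifest.
    """
    config = validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in STAGE_ORDER:
        run_stage(name, config, seed, out)
    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=config, seeds=substreams(seed), version=__version__, checksums=checksums
    )
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest
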