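"""Reusable study procedures: model-recovery replicates, null calibration,
and steady-state second-harmonic verification on simulated sessions.

These are the package's standard simulation experiments at desk scale:
single sessions of 15.3 s task / 15.3 s rest blocks, EEG at 250 Hz reduced
to the 1-40 Hz Morlet spectrum, BOLD at TR = 3.06 s with a known coupling
law, and the shared-design three-way comparison between Total Power, the
3-band Frequency Response model and the Heuristic (RMSF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import global_field_power, morlet_power, principal_projection
from .glm import activation_mask, compare_models, f_contrast, fit_glm
from .design import assemble_design
from .hrf import HRFBasis, canonical_hrf_basis
from .protocol import generate_protocol
from .simulate import BOLDSimParams, EEGSimParams, simulate_bold, simulate_eeg, substreams
from .transfer import build_regressors


@dataclass
class SessionFeatures:
    """One simulated session reduced to its analysis features."""

    protocol: object
    recording: object
    scalp: object
    tfr: object
    gfp: np.ndarray


def simulate_session_features(
    master_seed: int,
    n_task_blocks: int = 30,
    eeg_params: EEGSimParams | None = None,
) -> SessionFeatures:
    """Simulate one EEG session and extract scalp series, spectrum and GFP."""
    seeds = substreams(master_seed)
    protocol = generate_protocol(n_task_blocks, seed=seeds["block-order"])
    if eeg_params is None:
        eeg_params = EEGSimParams(seed=seeds["eeg-noise"])
    rec = simulate_eeg(protocol, eeg_params)
    scalp = principal_projection(rec)
    tfr = morlet_power(scalp)
    gfp = global_field_power(rec)
    return SessionFeatures(
        protocol=protocol, recording=rec, scalp=scalp, tfr=tfr, gfp=gfp
    )


def recovery_replicate(
    sess: SessionFeatures,
    truth_label: str,
    basis: HRFBasis,
    bold_seed: int,
    n_voxels: int = 200,
    coupling_gain: float = 3.0,
    model_labels: tuple[str, ...] = ("TP", "FR3", "RMSF"),
) -> dict:
    """One recovery run: simulate BOLD under `truth_label`, run the shared
    three-way comparison within the activation mask, report the ranking."""
    params = BOLDSimParams(
        ground_truth_model=truth_label,
        coupling_gain=coupling_gain,
        n_voxels=n_voxels,
        seed=bold_seed,
    )
    bold, truth = simulate_bold(sess.tfr, sess.gfp, sess.protocol, params, basis)
    mask = activation_mask(bold, sess.protocol, basis)
    models = [build_regressors(l, sess.tfr, gfp=sess.gfp) for l in model_labels]
    report = compare_models(bold, models, basis, mode="shared", mask=mask)
    fmax = {l: report.f_max_within(l) for l in model_labels}
    winner = max(fmax, key=fmax.get)
    return {
        "truth": truth_label,
        "winner": winner,
        "f_max_within": fmax,
        "mask_size": int(mask.sum()),
        "mask_recall": float(mask[truth.active_voxels].mean()),
        "report": report,
    }


def recovery_experiment(
    master_seed: int = 0,
    n_replicates: int = 10,
    truth_labels: tuple[str, ...] = ("TP", "FR3", "RMSF"),
    n_task_blocks: int = 30,
    n_voxels: int = 200,
    coupling_gain: float = 3.0,
) -> dict[str, list[dict]]:
    """Seeded model-recovery matrix.

    For every replicate one EEG session is simulated and, for each candidate
    ground-truth coupling law, a BOLD dataset is generated from it and the
    shared three-way comparison is asked to identify the generator by the
    maximal within-mask F.  Returns per-truth lists of replicate results.
    """
    basis = canonical_hrf_basis(0.1)
    results: dict[str, list[dict]] = {l: [] for l in truth_labels}
    root = np.random.SeedSequence(master_seed)
    rep_seeds = [int(s) & 0x7FFFFFFF for s in root.generate_state(n_replicates)]
    for rep, seed in enumerate(rep_seeds):
        sess = simulate_session_features(seed, n_task_blocks=n_task_blocks)
        bold_seed = substreams(seed)["bold-noise"]
        for label in truth_labels:
            results[label].append(
                recovery_replicate(
                    sess, label, basis, bold_seed,
                    n_voxels=n_voxels, coupling_gain=coupling_gain,
                )
            )
    return results


def recovery_rates(results: dict[str, list[dict]]) -> dict[str, float]:
    """Fraction of replicates in which the generator ranked first."""
    return {
        label: float(np.mean([r["winner"] == label for r in reps]))
        for label, reps in results.items()
    }


def null_false_positive_rate(
    master_seed: int = 0,
    n_voxels: int = 2000,
    n_task_blocks: int = 8,
    alpha: float = 0.05,
    tested_model: str = "RMSF",
) -> dict:
    """Type-I calibration of the extra-sum-of-squares F-test.

    BOLD is pure white noise (no coupling, no drift, no serial correlation);
    the three-way shared design is fitted and the tested model's triplet is
    F-tested per voxel at ``alpha`` (uncorrected).  Under a calibrated test
    the suprathreshold fraction is binomial(n_voxels, alpha).
    """
    sess = simulate_session_features(master_seed, n_task_blocks=n_task_blocks)
    basis = canonical_hrf_basis(0.1)
    params = BOLDSimParams(
        coupling_gain=0.0,
        n_voxels=n_voxels,
        ar1_coefficient=0.0,
        drift_amplitude=0.0,
        seed=substreams(master_seed)["bold-noise"],
    )
    bold, _ = simulate_bold(sess.tfr, sess.gfp, sess.protocol, params, basis)
    models = [build_regressors(l, sess.tfr) for l in ("TP", "FR3", "RMSF")]
    dm = assemble_design(models, bold, basis)
    fit = fit_glm(bold, dm)
    fr = f_contrast(fit, dm.partition[tested_model])
    n_pos = int(np.sum(fr.p_uncorrected < alpha))
    return {
        "n_voxels": n_voxels,
        "n_positive": n_pos,
        "rate": n_pos / n_voxels,
        "alpha": alpha,
        "df": fr.df,
    }
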