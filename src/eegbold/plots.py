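"""Figure-style summaries: regressor traces, SSVER spectra, topography."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .features import SSVERResult
from .transfer import RegressorSet


def plot_regressor_traces(models: list[RegressorSet], scan_columns=None, path=None):
    """Stacked traces of the transfer-function regressors over time."""
    fig, axes = plt.subplots(len(models), 1, figsize=(9, 2.2 * len(models)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, m in zip(axes, models):
        for name, col in m.columns.items():
            ax.plot(m.times, col, lw=0.6, label=name)
        ax.set_ylabel(m.model_label)
        ax.legend(fontsize=7, loc="upper right")
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_ssver_spectra(ssver: SSVERResult, path=None):
    """Time-averaged SSVER power per flicker condition with its peak marked."""
    n = len(ssver.conditions)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.6), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, cond in zip(axes, ssver.conditions):
        spec = ssver.spectra[cond]
        mean = spec.power.mean(axis=1)
        ax.plot(spec.freqs, mean, lw=0.8)
        ax.axvline(2 * cond, color="r", ls=":", lw=0.8)
        ax.set_title(f"{cond:g} Hz", fontsize=8)
        ax.set_xlabel("f (Hz)")
    axes[0].set_ylabel("power (a.u.)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_topography(eigenvector: np.ndarray, channel_labels: list[str], path=None):
    """Bar chart of the first spatial eigenvector's per-electrode loading."""
    fig, ax = plt.subplots(figsize=(9, 2.8))
    ax.bar(range(len(channel_labels)), eigenvector)
    ax.set_xticks(range(len(channel_labels)))
    ax.set_xticklabels(channel_labels, rotation=90, fontsize=7)
    ax.set_ylabel("loading")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
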