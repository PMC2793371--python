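"""Design-matrix assembly: high-pass filtering, session-wise partitioned
designs, and the parameter bookkeeping n_P = n_R x n_BF + n_C per session.

Every transfer-function regressor column is expanded through the 3-kernel
informed basis (n_BF = 3); each session contributes 7 confounds (6 motion
parameters and 1 session mean).  Sessions are block-concatenated with
session-specific columns throughout, the fixed-effects arrangement for a
multi-session analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hrf import HRFBasis, convolve_and_downsample
from .transfer import RegressorSet

#: Regressor-of-interest count per model label (n_R in the bookkeeping).
N_REGRESSORS = {
    "TP": 1, "FR3": 3, "FR5": 5, "FR8": 8,
    "RMSF": 1, "uRMSF": 1, "MSF": 1, "MF": 1, "GFP": 1,
}

N_BASIS_FUNCTIONS = 3
N_CONFOUNDS_PER_SESSION = 7  # 6 motion + 1 mean
DEFAULT_HIGHPASS_CUTOFF = 128.0


@dataclass
class BOLDDataset:
    """BOLD data as scans x voxels with per-session motion confounds.

    ``session_ids`` must be contiguous runs (all scans of a session
    adjacent).  ``motion`` holds one (n_scans_session x 6) array per session.
    ``mask`` optionally restricts analyses to a voxel subset (boolean or
    index array over voxels).
    """

    Y: np.ndarray
    TR: float
    session_ids: np.ndarray | None = None
    motion: list[np.ndarray] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be scans x voxels")
        if self.session_ids is None:
            self.session_ids = np.zeros(self.Y.shape[0], dtype=int)
        self.session_ids = np.asarray(self.session_ids)
        if self.session_ids.size != self.Y.shape[0]:
            raise ValueError("session_ids length must match scan count")
        ids = self.session_ids
        changes = np.flatnonzero(np.diff(ids)) + 1
        runs = [ids[0]] + [ids[i] for i in changes]
        if len(runs) != len(set(runs)):
            raise ValueError("session ids must be contiguous")
        if self.motion is not None:
            if len(self.motion) != self.n_sessions:
                raise ValueError("need one motion array per session")
            for m, n in zip(self.motion, self.scans_per_session()):
                if m.shape != (n, 6):
                    raise ValueError("motion must be n_scans_session x 6")

    @property
    def n_scans(self) -> int:
        return self.Y.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.Y.shape[1]

    @property
    def sessions(self) -> list:
        seen: list = []
        for s in self.session_ids:
            if s not in seen:
                seen.append(s)
        return seen

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def scans_per_session(self) -> list[int]:
        return [int(np.sum(self.session_ids == s)) for s in self.sessions]

    def mask_indices(self) -> np.ndarray:
        if self.mask is None:
            return np.arange(self.n_voxels)
        m = np.asarray(self.mask)
        if m.dtype == bool:
            return np.flatnonzero(m)
        return m


@dataclass
class DesignMatrix:
    """Partitioned design: interest columns per model plus confounds.

    ``partition`` maps model_label -> global column indices of that model's
    regressors of interest (all sessions); ``confound_columns`` indexes the
    motion and session-mean columns.
    """

    X: np.ndarray
    column_labels: list[str]
    partition: dict[str, np.ndarray]
    confound_columns: np.ndarray
    session_boundaries: list[int]
    TR: float
    highpass_cutoff: float | None = None

    def __post_init__(self) -> None:
        claimed = np.concatenate(
            [v for v in self.partition.values()] + [self.confound_columns]
        )
        if sorted(claimed.tolist()) != list(range(self.X.shape[1])):
            raise ValueError("every column must belong to exactly one partition entry")

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def parameter_count(model_labels: Sequence[str], n_sessions: int = 1) -> int:
    """Total estimated parameters: (sum n_R) x 3 + 7 per session, summed."""
    n_r = sum(N_REGRESSORS[l] for l in model_labels)
    return (n_r * N_BASIS_FUNCTIONS + N_CONFOUNDS_PER_SESSION) * n_sessions


def dct_highpass_basis(n_scans: int, TR: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine set spanning all components with period > cutoff.

    Columns are the DCT-II cosines c_k(n) = cos(pi k (2n+1) / (2N)) for
    k = 0 .. K with K = floor(2 N TR / cutoff); the k = 0 (constant) column
    is included so filtering also removes the mean.
    """
    K = int(np.floor(2.0 * n_scans * TR / cutoff))
    n = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_scans)) for k in range(K + 1)]
    return np.column_stack(cols)


def highpass(
    series_matrix: np.ndarray, TR: float, cutoff: float = DEFAULT_HIGHPASS_CUTOFF
) -> np.ndarray:
    """Residual-forming high-pass: project out slow discrete cosines.

    Applied identically to the BOLD data and the design columns of interest,
    so the GLM is exact under the filtered model.  Accepts a 1-D series or a
    scans x columns matrix.
    """
    x = np.asarray(series_matrix, dtype=float)
    flat = x.ndim == 1
    if flat:
        x = x[:, None]
    C = dct_highpass_basis(x.shape[0], TR, cutoff)
    coef, *_ = np.linalg.lstsq(C, x, rcond=None)
    out = x - C @ coef
    return out[:, 0] if flat else out


def assemble_design(
    models: Sequence[RegressorSet] | Sequence[Sequence[RegressorSet]],
    bold: BOLDDataset,
    basis: HRFBasis,
    highpass_cutoff: float | None = DEFAULT_HIGHPASS_CUTOFF,
) -> DesignMatrix:
    """Assemble the partitioned, session-concatenated design matrix.

    ``models`` is either one list of RegressorSets (single-session data) or
    one list per session.  Per session, each model's regressor columns are
    basis-expanded (3 columns each), high-pass filtered and mean-centered;
    the 6 motion confounds enter unfiltered and uncentered and a constant
    column absorbs the session mean.  Sessions are block-diagonal: a
    session's columns are zero outside its scans.
    """
    n_sessions = bold.n_sessions
    if models and isinstance(models[0], RegressorSet):
        models_by_session = [list(models)] * n_sessions  # type: ignore[list-item]
    else:
        models_by_session = [list(m) for m in models]  # type: ignore[union-attr]
    if len(models_by_session) != n_sessions:
        raise ValueError("need one model list per session")
    labels0 = [m.model_label for m in models_by_session[0]]
    if len(set(labels0)) != len(labels0):
        raise ValueError("duplicate model labels in the design")
    for mlist in models_by_session:
        if [m.model_label for m in mlist] != labels0:
            raise ValueError("sessions must share the same model list")
    if bold.motion is None:
        raise ValueError("BOLDDataset must carry motion confounds (6 per session)")

    scans = bold.scans_per_session()
    n_total = bold.n_scans
    blocks_interest: list[tuple[str, int, np.ndarray, list[str]]] = []
    blocks_confound: list[tuple[int, np.ndarray, list[str]]] = []
    offset = 0
    for s_idx, (mlist, n_s) in enumerate(zip(models_by_session, scans)):
        for m in mlist:
            Xm, names = convolve_and_downsample(m, basis, bold.TR, n_s)
            if highpass_cutoff is not None:
                Xm = highpass(Xm, bold.TR, highpass_cutoff)
            blocks_interest.append(
                (m.model_label, offset, Xm, [f"s{s_idx}:{n}" for n in names])
            )
        conf = np.column_stack([bold.motion[s_idx], np.ones(n_s)])
        cnames = [f"s{s_idx}:motion{j}" for j in range(6)] + [f"s{s_idx}:mean"]
        blocks_confound.append((offset, conf, cnames))
        offset += n_s

    n_cols = sum(b[2].shape[1] for b in blocks_interest) + sum(
        b[1].shape[1] for b in blocks_confound
    )
    X = np.zeros((n_total, n_cols))
    column_labels: list[str] = []
    partition: dict[str, list[int]] = {l: [] for l in labels0}
    confound_cols: list[int] = []
    col = 0
    for label, row0, Xm, names in blocks_interest:
        X[row0 : row0 + Xm.shape[0], col : col + Xm.shape[1]] = Xm
        partition[label].extend(range(col, col + Xm.shape[1]))
        column_labels.extend(names)
        col += Xm.shape[1]
    for row0, conf, cnames in blocks_confound:
        X[row0 : row0 + conf.shape[0], col : col + conf.shape[1]] = conf
        confound_cols.extend(range(col, col + conf.shape[1]))
        column_labels.extend(cnames)
        col += conf.shape[1]

    expected = parameter_count(labels0, n_sessions)
    if n_cols != expected:
        raise AssertionError(
            f"column bookkeeping violated: {n_cols} columns, expected {expected}"
        )
    boundaries = list(np.cumsum(scans)[:-1])
    return DesignMatrix(
        X=X,
        column_labels=column_labels,
        partition={l: np.array(v) for l, v in partition.items()},
        confound_columns=np.array(confound_cols),
        session_boundaries=boundaries,
        TR=bold.TR,
        highpass_cutoff=highpass_cutoff,
    )
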