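"""Mass-univariate GLM fitting, extra-sum-of-squares F-contrasts, and the
model-comparison reports.

A single ordinary-least-squares fit per voxel provides the residual sum of
squares; the unique contribution of a model's regressor set is tested with
the extra-sum-of-squares F statistic

    F = [ (RSS_reduced - RSS_full) / df_1 ] / [ RSS_full / df_2 ],

computed here in its algebraically equivalent contrast form
(C beta)' [C (X'X)^+ C']^+ (C beta) so no reduced model is ever refitted.
In "separate" mode each model is tested in its own design (marginal
variance); in "shared" mode all models enter one design and each model's F
reflects variance it uniquely explains.  Family-wise error control across
voxels uses Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    BOLDDataset,
    DesignMatrix,
    assemble_design,
    dct_highpass_basis,
    highpass,
)
from .hrf import HRFBasis, convolve_downsample_series
from .protocol import StimulusProtocol
from .transfer import RegressorSet


@dataclass
class GLMResult:
    """Per-voxel OLS fit against a partitioned design."""

    beta: np.ndarray
    residual_ss: np.ndarray
    df_residual: int
    design: DesignMatrix
    rank: int
    xtx_pinv: np.ndarray
    ar1_rho: float | None = None
    #: (whitened) filtered data and design, kept so rank-deficient contrasts
    #: can fall back to an explicit reduced-model refit
    Y_filtered: np.ndarray | None = None
    X_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.df_residual <= 0:
            raise ValueError("no residual degrees of freedom")


@dataclass
class FComparisonResult:
    """F-contrast over a column set, with uncorrected and Bonferroni p."""

    F: np.ndarray
    df: tuple[int, int]
    p_uncorrected: np.ndarray
    p_bonferroni: np.ndarray
    columns: np.ndarray


@dataclass
class RegionSummary:
    """Suprathreshold bookkeeping for one model in one region/threshold."""

    n_vox: int
    F_max: float
    peak_voxel: int | None


@dataclass
class ComparisonReport:
    """Per-model F-maps and thresholded summaries, within/outside a mask."""

    mode: str
    model_labels: list[str]
    f_results: dict[str, FComparisonResult]
    summaries: dict[str, dict[str, dict[str, RegionSummary]]]
    mask: np.ndarray | None
    thresholds: dict[str, float]

    def f_max_within(self, label: str, threshold_name: str = "p001_uncorrected") -> float:
        return self.summaries[label]["within"][threshold_name].F_max

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label in self.model_labels:
            for region, by_thr in self.summaries[label].items():
                for thr, s in by_thr.items():
                    rows.append(
                        {
                            "model": label,
                            "location": region,
                            "threshold": thr,
                            "n_vox": s.n_vox,
                            "F_max": s.F_max,
                            "peak_voxel": s.peak_voxel,
                        }
                    )
        return pd.DataFrame(rows)


def _ar1_whiten(M: np.ndarray, rho: float) -> np.ndarray:
    out = M.astype(float).copy()
    out[1:] = M[1:] - rho * M[:-1]
    out[0] = M[0] * np.sqrt(1.0 - rho**2)
    return out


def fit_glm(
    bold: BOLDDataset | np.ndarray,
    X: DesignMatrix,
    ar1_prewhiten: bool = False,
) -> GLMResult:
    """Ordinary least squares per voxel.

    The BOLD data are high-pass filtered with the design's cutoff before
    fitting (the interest columns were filtered at assembly).  If the design
    is rank deficient the pseudo-inverse solution is used and the residual
    degrees of freedom are reduced to n_scans - rank(X).  Optional global
    AR(1) prewhitening estimates a single pooled lag-1 coefficient from the
    OLS residuals and refits on whitened data.
    """
    Y = bold.Y if isinstance(bold, BOLDDataset) else np.asarray(bold, float)
    if Y.shape[0] != X.X.shape[0]:
        raise ValueError("scan count mismatch between data and design")
    filter_basis = None
    if X.highpass_cutoff is not None:
        bounds = [0] + list(X.session_boundaries) + [Y.shape[0]]
        Yf = np.empty_like(Y, dtype=float)
        blocks = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            Yf[a:b] = highpass(Y[a:b], X.TR, X.highpass_cutoff)
            blocks.append((a, b, dct_highpass_basis(b - a, X.TR, X.highpass_cutoff)))
        Y = Yf
        filter_basis = np.zeros((Y.shape[0], sum(c.shape[1] for _, _, c in blocks)))
        col = 0
        for a, b, c in blocks:
            filter_basis[a:b, col : col + c.shape[1]] = c
            col += c.shape[1]
    Xm = X.X

    def _ols(Xm: np.ndarray, Y: np.ndarray):
        rank = int(np.linalg.matrix_rank(Xm))
        pinv = np.linalg.pinv(Xm)
        beta = pinv @ Y
        resid = Y - Xm @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        return beta, rss, rank, resid

    beta, rss, rank, resid = _ols(Xm, Y)
    rho = None
    if ar1_prewhiten:
        num = np.sum(resid[1:] * resid[:-1])
        den = np.sum(resid**2)
        rho = float(num / den) if den > 0 else 0.0
        Xw = _ar1_whiten(Xm, rho)
        Yw = _ar1_whiten(Y, rho)
        beta, rss, rank, _ = _ols(Xw, Yw)
        Xm = Xw
    # dof spent by the high-pass projection (components outside span(X),
    # e.g. the per-session DC is already absorbed by the session mean)
    extra = 0
    if filter_basis is not None:
        rank_aug = int(np.linalg.matrix_rank(np.column_stack([X.X, filter_basis])))
        extra = rank_aug - int(np.linalg.matrix_rank(X.X))
    df_resid = Y.shape[0] - rank - extra
    if ar1_prewhiten:
        Y = _ar1_whiten(Y, rho)
    return GLMResult(
        beta=beta,
        residual_ss=rss,
        df_residual=df_resid,
        design=X,
        rank=rank,
        xtx_pinv=np.linalg.pinv(Xm.T @ Xm),
        ar1_rho=rho,
        Y_filtered=Y,
        X_used=Xm,
    )


def f_contrast(fit: GLMResult, columns: np.ndarray | Sequence[int]) -> FComparisonResult:
    """Extra-sum-of-squares F for the given design columns.

    Equivalent (to numerical precision) to refitting the model without the
    tested columns and comparing residual sums of squares; the numerator
    degrees of freedom are rank-adjusted when the tested set is collinear
    with the rest of the design.
    """
    cols = np.asarray(columns, dtype=int)
    if cols.size == 0:
        raise ValueError("empty contrast column set")
    if np.intersect1d(cols, fit.design.confound_columns).size:
        raise ValueError("tested set overlaps confound columns")
    if fit.rank < fit.design.X.shape[1]:
        # rank-deficient design: selection contrasts need not be estimable,
        # so compute the extra sum of squares by explicit reduced refit
        Xm, Y = fit.X_used, fit.Y_filtered
        keep = np.setdiff1d(np.arange(Xm.shape[1]), cols)
        Xr = Xm[:, keep]
        br = np.linalg.pinv(Xr) @ Y
        rss_r = np.einsum("ij,ij->j", Y - Xr @ br, Y - Xr @ br)
        ess = np.maximum(rss_r - fit.residual_ss, 0.0)
        df1 = fit.rank - int(np.linalg.matrix_rank(Xr))
        df1 = max(df1, 1)
    else:
        C = np.zeros((cols.size, fit.design.X.shape[1]))
        C[np.arange(cols.size), cols] = 1.0
        M = C @ fit.xtx_pinv @ C.T
        Minv = np.linalg.pinv(M)
        df1 = int(np.linalg.matrix_rank(M))
        cb = C @ fit.beta
        ess = np.einsum("iv,ij,jv->v", cb, Minv, cb)
        ess = np.maximum(ess, 0.0)
    df2 = fit.df_residual
    mse = fit.residual_ss / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(mse > 0, (ess / df1) / mse, 0.0)
    p_unc = stats.f.sf(F, df1, df2)
    n_vox = F.size
    p_bonf = np.minimum(1.0, p_unc * n_vox)
    return FComparisonResult(
        F=F, df=(df1, df2), p_uncorrected=p_unc, p_bonferroni=p_bonf, columns=cols
    )


def _summarise(
    fr: FComparisonResult, voxels: np.ndarray, use_bonferroni: bool, alpha: float
) -> RegionSummary:
    if voxels.size == 0:
        return RegionSummary(n_vox=0, F_max=float("nan"), peak_voxel=None)
    p = fr.p_bonferroni if use_bonferroni else fr.p_uncorrected
    supra = voxels[p[voxels] < alpha]
    Fv = fr.F[voxels]
    peak_local = int(np.argmax(Fv))  # lowest index wins ties via argmax
    return RegionSummary(
        n_vox=int(supra.size),
        F_max=float(Fv[peak_local]),
        peak_voxel=int(voxels[peak_local]),
    )


DEFAULT_THRESHOLDS = {"p05_fwe": 0.05, "p001_uncorrected": 0.001}


def compare_models(
    bold: BOLDDataset,
    models: Sequence[RegressorSet] | Sequence[Sequence[RegressorSet]],
    basis: HRFBasis,
    mode: str = "shared",
    mask: np.ndarray | None = None,
    thresholds: dict[str, float] | None = None,
    highpass_cutoff: float | None = 128.0,
    ar1_prewhiten: bool = False,
) -> ComparisonReport:
    """Run the transfer-function comparison and produce the summary report.

    ``mode="separate"`` fits one design per model and tests each model's
    triplet alone (marginal variance); ``mode="shared"`` places all models in
    one design so each model's F-contrast tests the variance it uniquely
    explains.  The report gives the suprathreshold voxel count, the maximal
    F and its location, within and outside the mask, at a Bonferroni
    family-wise threshold ("p05_fwe") and an uncorrected one
    ("p001_uncorrected").
    """
    if mode not in ("separate", "shared"):
        raise ValueError("mode must be 'separate' or 'shared'")
    if not len(models) or (not isinstance(models[0], RegressorSet) and not len(models[0])):
        raise ValueError("empty model list")
    flat = isinstance(models[0], RegressorSet)
    labels = (
        [m.model_label for m in models]  # type: ignore[union-attr]
        if flat
        else [m.model_label for m in models[0]]
    )
    if not labels:
        raise ValueError("empty model list")
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)

    f_results: dict[str, FComparisonResult] = {}
    if mode == "shared":
        X = assemble_design(models, bold, basis, highpass_cutoff)
        fit = fit_glm(bold, X, ar1_prewhiten=ar1_prewhiten)
        for label in labels:
            f_results[label] = f_contrast(fit, X.partition[label])
    else:
        for i, label in enumerate(labels):
            sub = [models[i]] if flat else [[mm[i]] for mm in models]  # type: ignore[index]
            X = assemble_design(sub, bold, basis, highpass_cutoff)
            fit = fit_glm(bold, X, ar1_prewhiten=ar1_prewhiten)
            f_results[label] = f_contrast(fit, X.partition[label])

    all_vox = np.arange(bold.n_voxels)
    if mask is None:
        within = all_vox
        outside = np.array([], dtype=int)
    else:
        m = np.asarray(mask)
        within = np.flatnonzero(m) if m.dtype == bool else m
        outside = np.setdiff1d(all_vox, within)

    summaries: dict[str, dict[str, dict[str, RegionSummary]]] = {}
    for label in labels:
        fr = f_results[label]
        summaries[label] = {}
        for region, voxels in (("within", within), ("outside", outside)):
            summaries[label][region] = {}
            for tname, alpha in thresholds.items():
                use_bonf = "fwe" in tname
                summaries[label][region][tname] = _summarise(fr, voxels, use_bonf, alpha)
    return ComparisonReport(
        mode=mode,
        model_labels=labels,
        f_results=f_results,
        summaries=summaries,
        mask=None if mask is None else within,
        thresholds=thresholds,
    )


def activation_mask(
    bold: BOLDDataset,
    protocols: StimulusProtocol | Sequence[StimulusProtocol],
    basis: HRFBasis,
    alpha: float = 0.05,
    highpass_cutoff: float | None = 128.0,
) -> np.ndarray:
    """Voxels significantly responsive to the stimulus-onset model.

    Builds per-condition boxcar regressors from the protocol (one per
    flicker frequency present), expands them through the basis triplet, adds
    the session confounds, and thresholds the F-test over all stimulus
    columns at Bonferroni-corrected ``alpha``.  This is the only analysis in
    which stimulus-onset regressors are used; the returned boolean mask is
    the BOLD activation mask restricting the model-comparison reports.
    """
    if np.ndim(protocols) == 0:
        protocols = [protocols] * bold.n_sessions  # type: ignore[list-item]
    protocols = list(protocols)
    if len(protocols) != bold.n_sessions:
        raise ValueError("need one protocol per session")
    if bold.motion is None:
        raise ValueError("BOLDDataset must carry motion confounds")

    boxcar_rate = 16.0 / bold.TR  # fine grid; HRF convolution anti-aliases
    scans = bold.scans_per_session()
    interest_blocks = []
    for proto, n_s in zip(protocols, scans):
        freqs = sorted({f for _, _, f in proto.task_blocks()})
        cols = []
        for f in freqs:
            box = proto.condition_boxcar(f, boxcar_rate)
            for kernel in basis.kernels:
                c = convolve_downsample_series(
                    box, kernel, boxcar_rate, basis.dt, bold.TR, n_s
                )
                cols.append(c - c.mean())
        Xs = np.column_stack(cols)
        if highpass_cutoff is not None:
            Xs = highpass(Xs, bold.TR, highpass_cutoff)
        interest_blocks.append(Xs)

    n_interest = sum(b.shape[1] for b in interest_blocks)
    n_conf = 7 * bold.n_sessions
    X = np.zeros((bold.n_scans, n_interest + n_conf))
    labels = []
    row = col = 0
    for s_idx, (b, n_s) in enumerate(zip(interest_blocks, scans)):
        X[row : row + n_s, col : col + b.shape[1]] = b
        labels += [f"s{s_idx}:stim{j}" for j in range(b.shape[1])]
        row += n_s
        col += b.shape[1]
    row = 0
    conf_cols = []
    for s_idx, n_s in enumerate(scans):
        conf = np.column_stack([bold.motion[s_idx], np.ones(n_s)])
        X[row : row + n_s, col : col + 7] = conf
        conf_cols += list(range(col, col + 7))
        labels += [f"s{s_idx}:motion{j}" for j in range(6)] + [f"s{s_idx}:mean"]
        row += n_s
        col += 7

    dm = DesignMatrix(
        X=X,
        column_labels=labels,
        partition={"stimulus": np.arange(n_interest)},
        confound_columns=np.array(conf_cols),
        session_boundaries=list(np.cumsum(scans)[:-1]),
        TR=bold.TR,
        highpass_cutoff=highpass_cutoff,
    )
    fit = fit_glm(bold, dm)
    fr = f_contrast(fit, dm.partition["stimulus"])
    return fr.p_bonferroni < alpha
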