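"""Per-cell-type RNA-content (cell size) estimation.

Two complementary estimators are provided. When the reference carries ERCC
spike-ins, absolute per-cell RNA content is measured directly: endogenous
counts are scaled by each cell's spike-in upper quartile (the spike-ins
were added in equal amounts to every cell, so their level tracks purely
technical capture differences), summed, and averaged within each type.

Without spike-ins, a three-stage residual-driven procedure estimates
relative sizes from the mixture itself: (1) screen for types whose
signature column rank-correlates with the residual of a uniform-size fit,
(2) validate each flagged type by checking that scaling its coefficient
improves reconstruction, (3) jointly tune a shared scaling strength over
the validated set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import CellSizeVector, DeconvolutionFit, SignatureMatrix
from .core import _as_series, irls_deconvolve, select_beta_and_cap

logger = logging.getLogger(__name__)

TAU_SCREEN = 0.25
MIN_PROP = 0.05
LAMBDA_GRID_VALIDATE = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
LAMBDA_GRID_JOINT = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
C_FLOOR = 0.05


@dataclass
class SizeDiagnostics:
    """Trace of the three-stage computational size estimation."""

    rho: pd.Series
    flagged: list = field(default_factory=list)
    validated: list = field(default_factory=list)
    lambda_star: Optional[float] = None
    baseline_score: float = np.nan
    final_score: float = np.nan
    tau_screen: float = TAU_SCREEN


def ercc_cell_sizes(ref) -> CellSizeVector:
    """Absolute RNA content per type from ERCC spike-ins.

    Per cell, endogenous counts are divided by the 75th percentile (type-7)
    of that cell's spike-in counts; the cell's absolute content is the sum
    of the normalized endogenous counts, and c_j is the mean content over
    the cells of type j. Cells with a zero spike-in upper quartile are
    dropped (count logged); a type losing every cell raises.
    """
    spike, _ = ref.spikeins()
    if spike.shape[0] < 1:
        raise ValueError("reference has no spike-in rows")
    endo, _ = ref.endogenous()
    uq = np.quantile(spike.astype(float), 0.75, axis=0)
    keep = uq > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d cells with zero spike-in upper quartile", n_dropped)
    content = endo[:, keep].sum(axis=0) / uq[keep]
    types_kept = ref.cell_types[keep]
    c = {}
    for ct in ref.type_names:
        vals = content[types_kept == ct]
        if len(vals) == 0:
            raise ValueError(f"all cells of type {ct!r} had zero spike-in counts")
        c[ct] = float(vals.mean())
    return CellSizeVector(
        c=pd.Series(c, index=ref.type_names),
        method="ercc",
        per_cell_content=pd.Series(content),
    )


def scale_factor(rho_j: float, rho_max: float, tau_screen: float, lam: float) -> float:
    """Exponential-saturation scaling 1 + lam * (1 - exp(-2 (rho-tau)/(rho_max-tau))).

    Equals 1 at rho_j = tau or lam = 0 and saturates at 1 + lam(1 - e^-2)
    when rho_j = rho_max. Negative rho (a type the uniform fit
    underestimates) yields a factor below 1, floored at 0.05 to stay
    positive.
    """
    if rho_max <= tau_screen:
        raise ValueError("rho_max must exceed the screening threshold")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    f = 1.0 + lam * (1.0 - np.exp(-2.0 * (rho_j - tau_screen) / (rho_max - tau_screen)))
    return float(max(f, C_FLOOR))


def screen(
    y,
    S: SignatureMatrix,
    fit0: DeconvolutionFit,
    tau_screen: float = TAU_SCREEN,
    min_prop: float = MIN_PROP,
) -> SizeDiagnostics:
    """Stage 1: flag types whose signature correlates with the residual.

    ``fit0`` must come from a uniform-size deconvolution. The residual
    R = Y - S X̂ is rank-correlated with each signature column; types with
    |rho_j| above ``tau_screen`` and an initial proportion above
    ``min_prop`` are flagged as potentially misestimated.
    """
    yv = _as_series(y, S.genes).to_numpy(dtype=float)
    Sarr = S.values.to_numpy(dtype=float)
    x0 = fit0.proportions.reindex(S.cell_type_names).to_numpy(dtype=float)
    resid = yv - Sarr @ x0
    # a residual at floating-point noise level carries no rank information
    negligible = np.linalg.norm(resid) <= 1e-9 * np.linalg.norm(yv)
    rho = {}
    for k, ct in enumerate(S.cell_type_names):
        if negligible or np.ptp(resid) == 0 or np.ptp(Sarr[:, k]) == 0:
            rho[ct] = 0.0
        else:
            r = spearmanr(resid, Sarr[:, k]).statistic
            rho[ct] = float(r) if np.isfinite(r) else 0.0
    rho_s = pd.Series(rho, index=S.cell_type_names)
    flagged = [
        ct
        for ct in S.cell_type_names
        if abs(rho_s[ct]) > tau_screen and fit0.proportions[ct] > min_prop
    ]
    return SizeDiagnostics(
        rho=rho_s,
        flagged=flagged,
        baseline_score=fit0.score,
        tau_screen=tau_screen,
    )


def _rho_max(diag: SizeDiagnostics) -> float:
    vals = diag.rho.loc[diag.flagged]
    m = float(vals.max())
    if m > diag.tau_screen:
        return m
    # all flagged correlations negative: use the magnitude so the
    # saturation scale stays positive while negative rho shrinks c below 1
    return float(vals.abs().max())


def _sizes_from(
    diag: SizeDiagnostics,
    members: list,
    lam: float,
    cell_types: list,
) -> CellSizeVector:
    rmax = _rho_max(diag)
    c = pd.Series(1.0, index=cell_types)
    for ct in members:
        c[ct] = scale_factor(diag.rho[ct], rmax, diag.tau_screen, lam)
    method = "uniform" if lam == 0 or not members else "computational"
    if np.allclose(c.to_numpy(), 1.0):
        method = "uniform"
    return CellSizeVector(c=c, method=method)


def validate(
    y,
    S: SignatureMatrix,
    diag: SizeDiagnostics,
    core_opts: Optional[dict] = None,
) -> SizeDiagnostics:
    """Stage 2: retain flagged types whose lone adjustment helps.

    For each flagged type alone, the coefficient grid over lambda is
    rescored; the type survives iff some lambda strictly improves the
    reconstruction Spearman over the uniform-size baseline. Beta is
    re-selected at each lambda — altering c changes which weighting
    regime fits best, so holding the baseline's beta would conflate
    weighting misfit with size misfit.
    """
    core_opts = dict(core_opts or {})
    enable_cap = core_opts.pop("enable_cap", False)
    validated = []
    for ct in diag.flagged:
        for lam in LAMBDA_GRID_VALIDATE:
            c = _sizes_from(diag, [ct], lam, S.cell_type_names)
            fit = select_beta_and_cap(y, S, c, enable_cap=enable_cap, **core_opts)
            if fit.score > diag.baseline_score:
                validated.append(ct)
                break
    diag.validated = validated
    return diag


def joint_optimize(
    y,
    S: SignatureMatrix,
    diag: SizeDiagnostics,
    core_opts: Optional[dict] = None,
) -> CellSizeVector:
    """Stage 3: shared-lambda grid search over the validated set.

    lambda = 0 reproduces uniform sizes, so the selected fit never scores
    below the baseline. Ties keep the smaller lambda. Beta is re-selected
    at each lambda, as in Stage 2.
    """
    core_opts = dict(core_opts or {})
    enable_cap = core_opts.pop("enable_cap", False)
    if not diag.validated:
        diag.lambda_star = 0.0
        diag.final_score = diag.baseline_score
        return CellSizeVector.uniform(S.cell_type_names)
    best_lam, best_score, best_c = 0.0, -np.inf, None
    for lam in LAMBDA_GRID_JOINT:
        c = _sizes_from(diag, diag.validated, lam, S.cell_type_names)
        fit = select_beta_and_cap(y, S, c, enable_cap=enable_cap, **core_opts)
        if fit.score > best_score:
            best_lam, best_score, best_c = lam, fit.score, c
    diag.lambda_star = best_lam
    diag.final_score = best_score
    assert best_c is not None
    return CellSizeVector(c=best_c.c, method="computational")


def computational_cell_sizes(
    y,
    S: SignatureMatrix,
    core_opts: Optional[dict] = None,
    enable_cap: bool = False,
) -> tuple[CellSizeVector, SizeDiagnostics]:
    """Full three-stage computational size estimation for one mixture.

    Deconvolves at uniform sizes (beta and, optionally, the weight cap
    selected by reconstruction score), screens the residual, then runs
    validation and joint optimization with beta re-selected at each
    candidate coefficient vector.
    """
    core_opts = dict(core_opts or {})
    uniform = CellSizeVector.uniform(S.cell_type_names)
    fit0 = select_beta_and_cap(y, S, uniform, enable_cap=enable_cap, **core_opts)
    stage_opts = dict(core_opts)
    stage_opts["enable_cap"] = enable_cap
    diag = screen(y, S, fit0)
    if diag.flagged:
        diag = validate(y, S, diag, stage_opts)
    c = joint_optimize(y, S, diag, stage_opts)
    logger.info(
        "computational sizes: flagged=%s validated=%s lambda*=%s score %.4f -> %.4f",
        diag.flagged,
        diag.validated,
        diag.lambda_star,
        diag.baseline_score,
        diag.final_score,
    )
    return c, diag


def pooled_cell_sizes(
    mixtures: pd.DataFrame,
    S: SignatureMatrix,
    core_opts: Optional[dict] = None,
    enable_cap: bool = False,
) -> tuple[CellSizeVector, SizeDiagnostics]:
    """Cohort-level variant: diagnostics averaged across mixtures.

    Residual correlations, initial proportions and reconstruction scores
    are averaged over the columns of ``mixtures`` before the flagging,
    validation and joint-optimization rules are applied once for the whole
    cohort.
    """
    core_opts = dict(core_opts or {})
    uniform = CellSizeVector.uniform(S.cell_type_names)
    shared = S.genes.intersection(mixtures.index)
    from .core import _restrict_genes

    Ssub = _restrict_genes(S, shared)
    fits = []
    diags = []
    for col in mixtures.columns:
        fit0 = select_beta_and_cap(
            mixtures.loc[shared, col], Ssub, uniform, enable_cap=enable_cap, **core_opts
        )
        fits.append(fit0)
        diags.append(screen(mixtures.loc[shared, col], Ssub, fit0))
    rho = pd.concat([d.rho for d in diags], axis=1).mean(axis=1)
    props = pd.concat([f.proportions for f in fits], axis=1).mean(axis=1)
    baseline = float(np.mean([f.score for f in fits]))
    pooled = SizeDiagnostics(
        rho=rho,
        flagged=[
            ct
            for ct in Ssub.cell_type_names
            if abs(rho[ct]) > TAU_SCREEN and props[ct] > MIN_PROP
        ],
        baseline_score=baseline,
    )

    def cohort_score(c: CellSizeVector, beta, tau_q) -> float:
        scores = []
        for col in mixtures.columns:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = irls_deconvolve(
                    mixtures.loc[shared, col], Ssub, c, beta=beta, tau_q=tau_q, **core_opts
                )
            scores.append(fit.score)
        return float(np.mean(scores))

    beta0, tau0 = fits[0].beta, fits[0].cap_quantile
    validated = []
    for ct in pooled.flagged:
        for lam in LAMBDA_GRID_VALIDATE:
            c = _sizes_from(pooled, [ct], lam, Ssub.cell_type_names)
            if cohort_score(c, beta0, tau0) > baseline:
                validated.append(ct)
                break
    pooled.validated = validated
    if not validated:
        pooled.lambda_star = 0.0
        pooled.final_score = baseline
        return CellSizeVector.uniform(Ssub.cell_type_names), pooled
    best_lam, best_score, best_c = 0.0, -np.inf, None
    for lam in LAMBDA_GRID_JOINT:
        c = _sizes_from(pooled, validated, lam, Ssub.cell_type_names)
        s = cohort_score(c, beta0, tau0)
        if s > best_score:
            best_lam, best_score, best_c = lam, s, c
    pooled.lambda_star = best_lam
    pooled.final_score = best_score
    assert best_c is not None
    return CellSizeVector(c=best_c.c, method="computational"), pooled
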