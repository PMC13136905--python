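"""Iteratively reweighted least-squares deconvolution engine.

The mixture model is

    y_i = sum_j c_j x_j s_ij + eps_i,   x_j >= 0,  sum_j x_j = 1,

where ``S`` holds CP10K marker-gene profiles for K cell types, ``c_j`` are
per-type RNA-content (cell size) coefficients and ``x_j`` the cell-number
fractions being estimated. Fitting minimizes a per-gene weighted squared
error. Weights are seeded through the sectional-linear property of marker
genes — on a type's exclusive markers, log y_i = u_j + log s_ij with
u_j = log(c_j x_j) — and refreshed each iteration from the current
reconstruction until the proportion vector stabilizes.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import spearmanr

from .containers import CP10K, CellSizeVector, DeconvolutionFit, MixtureProfile, SignatureMatrix

logger = logging.getLogger(__name__)

BETA_GRID = (0.0, 0.5, 1.0)
CAP_GRID = tuple(np.round(np.arange(0.01, 1.001, 0.01), 2))
DEFAULT_EPS = 1e-8
DEFAULT_MAX_ITER = 100
DEFAULT_CONV_TOL = 0.01
DEFAULT_MIN_MARKERS = 3


def normalize_cp10k(raw):
    """Scale each column (or a single vector) to sum to 10^4.

    Idempotent; accepts numpy arrays, Series or DataFrames. Raises on an
    all-zero column, which cannot be placed on the CP10K scale.
    """
    if isinstance(raw, pd.DataFrame):
        totals = raw.sum(axis=0)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"all-zero column(s): {bad}")
        return raw * (CP10K / totals)
    if isinstance(raw, pd.Series):
        total = float(raw.sum())
        if total <= 0:
            raise ValueError("all-zero vector cannot be CP10K-normalized")
        return raw * (CP10K / total)
    arr = np.asarray(raw, dtype=float)
    if arr.ndim == 1:
        total = arr.sum()
        if total <= 0:
            raise ValueError("all-zero vector cannot be CP10K-normalized")
        return arr * (CP10K / total)
    totals = arr.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("all-zero column cannot be CP10K-normalized")
    return arr * (CP10K / totals)


def _as_series(y, genes: pd.Index) -> pd.Series:
    if isinstance(y, MixtureProfile):
        y = y.values
    if isinstance(y, pd.Series):
        return y.reindex(genes)
    arr = np.asarray(y, dtype=float)
    if arr.shape[0] != len(genes):
        raise ValueError("mixture length does not match signature genes")
    return pd.Series(arr, index=genes)


def fit_disturbance_terms(
    y,
    S: SignatureMatrix,
    min_markers: int = DEFAULT_MIN_MARKERS,
) -> pd.Series:
    """Estimate the per-type disturbance terms u_j = log(c_j x_j).

    For each cell type the slope-1 log-log regression of the mixture on the
    type's marker column reduces to an intercept: the mean of
    log(y_i) - log(s_ij) over markers positive in both vectors. Types with
    fewer than ``min_markers`` usable markers receive u_j = -inf, i.e. an
    initial RNA share of zero.
    """
    yv = _as_series(y, S.genes)
    u = {}
    for ct in S.cell_type_names:
        genes = [g for g in S.marker_sets[ct] if g in yv.index]
        ys = yv.loc[genes].to_numpy(dtype=float)
        ss = S.values.loc[genes, ct].to_numpy(dtype=float)
        ok = (ys > 0) & (ss > 0)
        if ok.sum() < min_markers:
            warnings.warn(
                f"cell type {ct!r} has {int(ok.sum())} usable markers "
                f"(< {min_markers}); initialized as absent",
                stacklevel=2,
            )
            u[ct] = -np.inf
        else:
            u[ct] = float(np.mean(np.log(ys[ok]) - np.log(ss[ok])))
    return pd.Series(u, index=S.cell_type_names, dtype=float)


def initial_mixture(u: pd.Series, S: SignatureMatrix) -> tuple[pd.Series, pd.Series]:
    """Softmax the disturbance terms into RNA-content shares delta_j and
    form the initial reconstruction t_i = sum_j delta_j s_ij.

    Returns ``(delta, y_star)``.
    """
    uv = u.reindex(S.cell_type_names).to_numpy(dtype=float)
    if np.all(np.isneginf(uv)):
        raise ValueError("all disturbance terms are -inf; no type is usable")
    shifted = uv - np.max(uv[np.isfinite(uv)])
    e = np.where(np.isneginf(shifted), 0.0, np.exp(shifted))
    delta = e / e.sum()
    y_star = S.values.to_numpy(dtype=float) @ delta
    return (
        pd.Series(delta, index=S.cell_type_names),
        pd.Series(y_star, index=S.genes),
    )


def compute_weights(
    y: np.ndarray,
    t: np.ndarray,
    beta: float,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Adaptive gene weights w_i = 1 / (|y_i - t_i|^beta * t_i^(1-beta))^2.

    ``beta`` balances the residual magnitude against the expression level:
    beta=1 down-weights poorly fit genes, beta=0 down-weights highly
    expressed genes. Both factors are floored at ``eps`` so weights stay
    finite at an exact fit.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    resid = np.maximum(np.abs(y - t), eps)
    level = np.maximum(t, eps)
    return 1.0 / (resid**beta * level ** (1.0 - beta)) ** 2


def cap_weights(w: np.ndarray, tau_q: float) -> np.ndarray:
    """Cap weights at their empirical ``tau_q`` quantile (type-7)."""
    w = np.asarray(w, dtype=float)
    q = np.quantile(w, tau_q)
    return np.minimum(w, q)


def _constrained_wls(A: np.ndarray, b: np.ndarray, a: np.ndarray) -> np.ndarray:
    """min ||A z - b||^2 s.t. z >= 0, a.z = 1.

    Solved by non-negative least squares with the equality appended as a
    heavily weighted row, then polished to machine precision by solving
    the equality-constrained KKT system on the detected active set.
    """
    mu = 1e3 * max(np.linalg.norm(b), np.linalg.norm(A), 1.0)
    A_aug = np.vstack([A, mu * a[None, :]])
    b_aug = np.concatenate([b, [mu]])
    z, _ = nnls(A_aug, b_aug)
    support = z > 0
    if support.any():
        Ap = A[:, support]
        ap = a[support]
        k = int(support.sum())
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = Ap.T @ Ap
        kkt[:k, k] = ap
        kkt[k, :k] = ap
        rhs = np.concatenate([Ap.T @ b, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
            zp = sol[:k]
            if (zp >= 0).all():
                z = np.zeros_like(z)
                z[support] = zp
        except np.linalg.LinAlgError:
            pass
    return z


def solve_weighted(
    y,
    S: SignatureMatrix,
    c,
    w: np.ndarray,
) -> pd.Series:
    """Weighted constrained least squares for the proportions.

    Minimizes sum_i w_i (y_i - sum_j c_j x_j s_ij)^2 subject to x >= 0 and
    sum x = 1. The problem is solved in z_j = c_j x_j, where the simplex
    constraint on x becomes sum_j z_j / c_j = 1, and mapped back via
    x_j = (z_j / c_j) / sum_k (z_k / c_k).
    """
    yv = _as_series(y, S.genes).to_numpy(dtype=float)
    cv = c.aligned(S.cell_type_names) if isinstance(c, CellSizeVector) else np.asarray(c, float)
    sw = np.sqrt(np.asarray(w, dtype=float))
    A = S.values.to_numpy(dtype=float) * sw[:, None]
    b = yv * sw
    # z = 0 solves the unconstrained cone fit iff the gradient there is
    # non-positive: the mixture carries no signal along any column
    if (A.T @ b <= 0).all():
        raise ValueError("mixture orthogonal to signature: all-zero solution")
    z = _constrained_wls(A, b, 1.0 / cv)
    if z.sum() <= 0:
        raise ValueError("mixture orthogonal to signature: all-zero solution")
    x = z / cv
    x = x / x.sum()
    return pd.Series(x, index=S.cell_type_names)


def irls_deconvolve(
    y,
    S: SignatureMatrix,
    c: Optional[CellSizeVector] = None,
    beta: float = 0.5,
    tau_q: Optional[float] = None,
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
    conv_tol: float = DEFAULT_CONV_TOL,
    min_markers: int = DEFAULT_MIN_MARKERS,
    calibrate_scale: bool = False,
) -> DeconvolutionFit:
    """Run the IRLS loop for one mixture at a fixed beta (and optional cap).

    The reconstruction target t_i = sum_j c_j x_j s_ij is refreshed each
    iteration from the current proportions. Iteration stops when the L2
    change of the proportion vector drops to ``conv_tol`` or ``max_iter``
    is reached. ``c`` is used exactly as given; callers working with
    absolute (e.g. spike-in derived) sizes should rescale them to mean one
    first so the reconstruction stays on the CP10K scale of y.

    ``calibrate_scale`` rescales y so the sum-to-one constraint is
    attainable without shape distortion. Use it for relative-abundance
    (library-size-normalized) mixtures, whose overall scale is arbitrary;
    leave it off for intensity-calibrated mixtures (e.g. spike-in
    normalized bulk), where the deviation between the mixture's scale and
    the c-weighted signature combination is real signal.
    """
    if c is None:
        c = CellSizeVector.uniform(S.cell_type_names)
    yv = _as_series(y, S.genes)
    yarr = yv.to_numpy(dtype=float)
    cv = c.aligned(S.cell_type_names)
    K = len(S.cell_type_names)
    Sarr = S.values.to_numpy(dtype=float)
    if calibrate_scale and K > 1:
        z0, _ = nnls(Sarr, yarr)
        denom = float((z0 / cv).sum())
        if denom > 0:
            yarr = yarr / denom
            yv = pd.Series(yarr, index=yv.index)

    if K == 1:
        x = pd.Series([1.0], index=S.cell_type_names)
        recon = pd.Series(Sarr[:, 0] * cv[0], index=S.genes)
        return DeconvolutionFit(
            proportions=x,
            weights=np.ones(len(yv)),
            beta=beta,
            reconstruction=recon,
            n_iter=1,
            converged=True,
            score=_spearman(recon.to_numpy(), yarr),
        )

    u = fit_disturbance_terms(yv, S, min_markers=min_markers)
    delta, y_star = initial_mixture(u, S)
    w = compute_weights(yarr, y_star.to_numpy(), beta, eps)
    w_used = cap_weights(w, tau_q) if tau_q is not None else w
    x = solve_weighted(yv, S, cv, w_used).to_numpy()

    converged = False
    n_iter = 1
    for n_iter in range(2, max_iter + 1):
        t = Sarr @ (cv * x)
        w = compute_weights(yarr, t, beta, eps)
        w_used = cap_weights(w, tau_q) if tau_q is not None else w
        x_new = solve_weighted(yv, S, cv, w_used).to_numpy()
        if np.linalg.norm(x_new - x) <= conv_tol:
            x = x_new
            converged = True
            break
        x = x_new
    if not converged:
        warnings.warn(
            "IRLS did not converge within "
            f"{max_iter} iterations (beta={beta}, tau_q={tau_q})",
            stacklevel=2,
        )
    recon = pd.Series(Sarr @ (cv * x), index=S.genes)
    fit = DeconvolutionFit(
        proportions=pd.Series(x, index=S.cell_type_names),
        weights=w,
        capped_weights=w_used if tau_q is not None else None,
        beta=beta,
        cap_quantile=tau_q,
        reconstruction=recon,
        n_iter=n_iter,
        converged=converged,
        score=_spearman(recon.to_numpy(), yarr),
        delta=delta,
    )
    return fit


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    rho = spearmanr(a, b).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def select_beta_and_cap(
    y,
    S: SignatureMatrix,
    c: Optional[CellSizeVector] = None,
    enable_cap: bool = False,
    betas: Sequence[float] = BETA_GRID,
    cap_grid: Iterable[float] = CAP_GRID,
    **irls_opts,
) -> DeconvolutionFit:
    """Grid-search beta (and, for high technical variation, the weight cap).

    Runs the IRLS fit for each beta in {0, 0.5, 1}; when ``enable_cap`` is
    set, additionally caps weights at every quantile tau in {0.01..1.00}.
    Returns the fit whose reconstruction best rank-correlates with the
    observed mixture; ties prefer larger beta, then larger tau.
    """
    best: Optional[DeconvolutionFit] = None
    best_key = None
    for beta in betas:
        taus: list[Optional[float]] = [None]
        if enable_cap:
            taus += list(cap_grid)
        for tau in taus:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = irls_deconvolve(y, S, c, beta=beta, tau_q=tau, **irls_opts)
            # uncapped == tau=1 cap; rank it above the grid on exact ties
            key = (fit.score, beta, 1.01 if tau is None else tau)
            if best_key is None or key > best_key:
                best, best_key = fit, key
    assert best is not None
    logger.info(
        "mixture fit: beta=%s tau=%s iters=%d score=%.4f",
        best.beta,
        best.cap_quantile,
        best.n_iter,
        best.score,
    )
    return best


def deconvolve_mixtures(
    mixtures: pd.DataFrame,
    S: SignatureMatrix,
    c: Optional[CellSizeVector] = None,
    enable_cap: bool = False,
    beta: Optional[float] = None,
    **irls_opts,
) -> tuple[pd.DataFrame, list[DeconvolutionFit]]:
    """Deconvolve every column of a genes x samples CP10K matrix.

    Columns are restricted to the signature's marker genes; a supplied
    cell-size vector is rescaled to mean one. Returns a samples x
    cell-types proportion table plus per-sample fits.
    """
    if c is not None:
        c = c.relative()
    irls_opts.setdefault("calibrate_scale", True)
    shared = S.genes.intersection(mixtures.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between mixtures and signature")
    Ssub = _restrict_genes(S, shared)
    rows = []
    fits = []
    for sample in mixtures.columns:
        yv = mixtures.loc[shared, sample]
        if beta is None:
            fit = select_beta_and_cap(yv, Ssub, c, enable_cap=enable_cap, **irls_opts)
        else:
            fit = irls_deconvolve(yv, Ssub, c, beta=beta, **irls_opts)
        rows.append(fit.proportions.rename(sample))
        fits.append(fit)
    return pd.DataFrame(rows), fits


def _restrict_genes(S: SignatureMatrix, genes: pd.Index) -> SignatureMatrix:
    keep = [g for g in S.genes if g in set(genes)]
    return SignatureMatrix(
        values=S.values.loc[keep],
        marker_sets={
            ct: [g for g in gs if g in set(keep)] for ct, gs in S.marker_sets.items()
        },
        top_n=S.top_n,
    )
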