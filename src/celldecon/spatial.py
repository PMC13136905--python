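"""Per-spot cell-type enrichment and enrichment-gated spot deconvolution.

A spatial spot typically holds a handful of cells, so most cell types are
absent from any given spot. Before deconvolving, each spot is screened
with a marker-based Z-score test (in the PAGE family): marker fold changes
against a per-gene background are averaged per type, standardized against
the spot's all-gene fold-change distribution, and scaled by the square
root of the number of expressed markers. Types passing any of three
criteria (positive Z, top Z in the spot, positive spot-standardized Z)
form the spot's enriched set; the regression for that spot then only sees
the signature columns of enriched types.

Prevalent types — highly and uniformly expressed across the tissue — use
the 25th percentile rather than the mean as the fold-change reference,
since their fold change against the mean hovers near one everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import CellSizeVector, SignatureMatrix
from .core import normalize_cp10k, select_beta_and_cap

logger = logging.getLogger(__name__)

PREVALENT_REL_TOL = 0.1


@dataclass
class SpotMatrix:
    """Genes x spots expression with per-spot grid coordinates."""

    values: pd.DataFrame
    coords: pd.DataFrame  # index = spot id, columns x, y

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("spot expression must be non-negative")
        if self.coords.duplicated().any():
            raise ValueError("spot coordinates must be unique")

    @property
    def spot_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class SpotEnrichment:
    """Per-spot enrichment statistics."""

    fold_changes: pd.DataFrame  # genes x spots
    gene_refs: pd.Series  # per-gene reference statistic used
    abs_scores: pd.DataFrame  # types x spots
    rel_scores: pd.DataFrame
    prevalent: pd.Series  # per-type bool
    z: pd.DataFrame  # types x spots
    n_expr: pd.DataFrame  # types x spots marker counts
    enriched: dict  # spot id -> list of types


def _marker_view(S: SignatureMatrix, genes: pd.Index) -> dict[str, list[str]]:
    present = set(genes)
    out = {}
    for ct, ms in S.marker_sets.items():
        found = [g for g in ms if g in present]
        if not found:
            raise ValueError(f"no markers of type {ct!r} present in the spot matrix")
        out[ct] = found
    return out


def spot_scores(
    spots: SpotMatrix, S: SignatureMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute and relative marker scores per (type, spot).

    Absolute: mean marker expression in the spot. Relative: mean of the
    marker's fold change against its cross-spot mean (genes with zero mean
    dropped).
    """
    Y = spots.values
    markers = _marker_view(S, Y.index)
    gene_means = Y.mean(axis=1)
    abs_rows, rel_rows = {}, {}
    for ct, ms in markers.items():
        sub = Y.loc[ms]
        abs_rows[ct] = sub.mean(axis=0)
        nonzero = [g for g in ms if gene_means[g] > 0]
        rel_rows[ct] = (
            sub.loc[nonzero].div(gene_means[nonzero], axis=0).mean(axis=0)
            if nonzero
            else pd.Series(np.nan, index=Y.columns)
        )
    return pd.DataFrame(abs_rows).T, pd.DataFrame(rel_rows).T


def prevalent_types(
    abs_scores: pd.DataFrame,
    rel_scores: pd.DataFrame,
    tol: float = PREVALENT_REL_TOL,
) -> pd.Series:
    """Flag types that are both abundant and uniformly expressed.

    A type is prevalent iff its median absolute score exceeds the 75th
    percentile of all absolute-score entries and its median relative score
    lies within ``tol`` of one.
    """
    global_q75 = np.quantile(abs_scores.to_numpy().ravel(), 0.75)
    med_abs = abs_scores.median(axis=1)
    med_rel = rel_scores.median(axis=1)
    return (med_abs > global_q75) & ((med_rel - 1.0).abs() <= tol)


def spot_fold_changes(
    spots: SpotMatrix,
    prevalent: pd.Series,
    S: SignatureMatrix,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene fold changes with a mixed reference.

    Markers of prevalent types are referenced to their 25th percentile
    across spots (type-7); every other gene to its mean. Genes with a zero
    reference are dropped from the fold-change matrix (logged).
    Returns ``(fold_changes, gene_refs)`` where gene_refs records the
    reference statistic used per retained gene.
    """
    Y = spots.values
    markers = _marker_view(S, Y.index)
    q1_genes: set = set()
    for ct, flag in prevalent.items():
        if flag and ct in markers:
            q1_genes |= set(markers[ct])
    refs = Y.mean(axis=1).copy()
    if q1_genes:
        q1 = Y.quantile(0.25, axis=1)
        idx = [g for g in Y.index if g in q1_genes]
        refs.loc[idx] = q1.loc[idx]
    keep = refs > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d genes with a zero fold-change reference", n_dropped)
    F = Y.loc[keep].div(refs[keep], axis=0)
    return F, refs[keep]


def spot_zscores(
    fold_changes: pd.DataFrame,
    S: SignatureMatrix,
    spots: SpotMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-average Z-scores per (type, spot).

    Z_j(s) = (f_j(s) - mu(s)) * sqrt(n_j) / sigma(s), where f_j averages
    the fold changes of type-j markers expressed (Y > 0) in the spot, n_j
    counts them, and mu, sigma are the mean and sample (n-1) standard
    deviation of the spot's fold changes over all genes. Types with no
    expressed marker get Z = -inf and can only enter a spot through the
    argmax criterion.
    """
    F = fold_changes
    markers = _marker_view(S, F.index)
    mu = F.mean(axis=0)
    sigma = F.std(axis=0, ddof=1)
    z_rows, n_rows = {}, {}
    for ct, ms in markers.items():
        expressed = (spots.values.loc[ms, F.columns] > 0) & True
        Fm = F.loc[ms]
        n_j = expressed.sum(axis=0)
        f_j = Fm.where(expressed).sum(axis=0) / n_j.replace(0, np.nan)
        z = (f_j - mu) * np.sqrt(n_j) / sigma
        z[n_j == 0] = -np.inf
        z_rows[ct] = z
        n_rows[ct] = n_j
    z = pd.DataFrame(z_rows).T
    n_expr = pd.DataFrame(n_rows).T
    zero_sd = sigma == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} spot(s) have zero fold-change dispersion; "
            "their Z-scores are set to 0",
            stacklevel=2,
        )
        z.loc[:, zero_sd] = 0.0
    return z, n_expr


def enriched_types(z: pd.DataFrame) -> dict:
    """Union of the three per-spot enrichment criteria.

    (1) Z > 0; (2) the spot's highest Z (ties all included); (3) positive
    Z after per-spot standardization to zero mean and unit variance.
    Criterion (2) guarantees every spot a non-empty set.
    """
    out = {}
    for spot in z.columns:
        zs = z[spot]
        chosen = set(zs.index[zs > 0])
        finite = zs[np.isfinite(zs)]
        top_pool = finite if len(finite) else zs
        top = top_pool.max()
        chosen |= set(top_pool.index[top_pool == top])
        if len(finite) > 1 and finite.std(ddof=1) > 0:
            std = (finite - finite.mean()) / finite.std(ddof=1)
            chosen |= set(std.index[std > 0])
        out[spot] = sorted(chosen)
    return out


def analyze_spots(spots: SpotMatrix, S: SignatureMatrix) -> SpotEnrichment:
    """Run the full enrichment pipeline for a spot matrix."""
    norm = SpotMatrix(values=normalize_cp10k(spots.values), coords=spots.coords)
    abs_s, rel_s = spot_scores(norm, S)
    prev = prevalent_types(abs_s, rel_s)
    F, refs = spot_fold_changes(norm, prev, S)
    z, n_expr = spot_zscores(F, S, norm)
    enr = enriched_types(z)
    return SpotEnrichment(
        fold_changes=F,
        gene_refs=refs,
        abs_scores=abs_s,
        rel_scores=rel_s,
        prevalent=prev,
        z=z,
        n_expr=n_expr,
        enriched=enr,
    )


def deconvolve_spots(
    spots: SpotMatrix,
    S: SignatureMatrix,
    c: Optional[CellSizeVector] = None,
    enrichment: Optional[SpotEnrichment] = None,
    enable_cap: bool = False,
    **irls_opts,
) -> tuple[pd.DataFrame, SpotEnrichment]:
    """Deconvolve each spot against its enriched types only.

    Spots are CP10K-normalized, enrichment is computed (or reused), and
    each spot's regression sees only the signature columns of its enriched
    types; all other types receive exactly zero. A spot enriched for a
    single type gets proportion one. Spots that fail to fit are reported
    at warning level and filled with NaN rather than aborting the run.

    Cell-size correction is off by default for spatial runs; pass ``c`` to
    enable it.
    """
    enr = enrichment if enrichment is not None else analyze_spots(spots, S)
    if c is not None:
        c = c.relative()
    irls_opts.setdefault("calibrate_scale", True)
    shared = S.genes.intersection(spots.values.index)
    norm = normalize_cp10k(spots.values)
    out = pd.DataFrame(
        0.0, index=S.cell_type_names, columns=spots.values.columns
    )
    for spot in spots.values.columns:
        types = enr.enriched[spot]
        if len(types) == 1:
            out.loc[types[0], spot] = 1.0
            continue
        sub = S.restrict_types(types)
        sub_genes = sub.genes.intersection(shared)
        from .core import _restrict_genes

        sub = _restrict_genes(sub, sub_genes)
        csub = None
        if c is not None:
            csub = CellSizeVector(c=c.c.loc[types], method=c.method)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = select_beta_and_cap(
                    norm.loc[sub.genes, spot], sub, csub, enable_cap=enable_cap, **irls_opts
                )
        except ValueError as exc:
            logger.warning("spot %s failed to deconvolve: %s", spot, exc)
            out.loc[:, spot] = np.nan
            continue
        out.loc[types, spot] = fit.proportions.reindex(types).to_numpy()
    return out, enr
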