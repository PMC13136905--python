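"""Signature-matrix construction from an annotated single-cell reference.

A full pseudobulk profile (genes x types, CP10K) is truncated to ranked
marker genes found by one-vs-rest Wilcoxon rank-sum tests, producing a
family of candidate signature matrices (top 50/100/150/200 markers per
type by default). The candidate whose deconvolution reconstructs the
observed mixtures best — highest Spearman correlation between inferred and
observed marker expression — is kept.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu

from .containers import (
    CP10K,
    CellSizeVector,
    FullSignature,
    MixtureProfile,
    ReferenceCounts,
    SignatureMatrix,
)
from .core import _restrict_genes, normalize_cp10k, select_beta_and_cap

logger = logging.getLogger(__name__)

DEFAULT_N_GRID = (50, 100, 150, 200)


def pseudobulk_by_type(ref: ReferenceCounts) -> FullSignature:
    """Sum counts of all cells of each type, then CP10K-normalize columns.

    Spike-in rows are excluded. A type whose cells contribute zero total
    counts cannot be normalized and raises.
    """
    counts, genes = ref.endogenous()
    cols = {}
    for ct in ref.type_names:
        total = counts[:, ref.cell_types == ct].sum(axis=1).astype(float)
        if total.sum() <= 0:
            raise ValueError(f"cell type {ct!r} has zero total counts")
        cols[ct] = total * (CP10K / total.sum())
    return FullSignature(values=pd.DataFrame(cols, index=genes))


def find_markers(
    ref: ReferenceCounts,
    alpha: float = 0.01,
    lfc_min: float = 0.25,
    adjust: bool = True,
) -> pd.DataFrame:
    """One-vs-rest marker genes per cell type.

    Per-cell expression is CP10K-normalized then log1p-transformed; each
    gene is tested per type with a two-sided Wilcoxon rank-sum test against
    all other cells. Kept genes satisfy
    log2((mean CP10K in type + 1) / (mean CP10K in rest + 1)) >= ``lfc_min``
    and (BH-adjusted, unless ``adjust`` is False) p < ``alpha``; within a
    type rows are sorted by ascending p-value, ties broken by descending
    fold change then gene id.

    Returns a table with columns cell_type, gene, rank, p_value, p_adj,
    log2fc.
    """
    counts, genes = ref.endogenous()
    cp10k = normalize_cp10k(counts.astype(float))
    logx = np.log1p(cp10k)

    frames = []
    for ct in ref.type_names:
        mask = ref.cell_types == ct
        if mask.sum() < 2:
            raise ValueError(f"cell type {ct!r} has fewer than 2 cells")
        a = logx[:, mask]
        b = logx[:, ~mask]
        res = mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals = np.nan_to_num(pvals, nan=1.0)
        padj = false_discovery_control(pvals, method="bh")
        lfc = np.log2(
            (cp10k[:, mask].mean(axis=1) + 1.0) / (cp10k[:, ~mask].mean(axis=1) + 1.0)
        )
        crit_p = padj if adjust else pvals
        keep = (lfc >= lfc_min) & (crit_p < alpha)
        if not keep.any():
            raise ValueError(f"cell type {ct!r} yielded zero marker genes")
        tab = pd.DataFrame(
            {
                "cell_type": ct,
                "gene": genes[keep],
                "p_value": pvals[keep],
                "p_adj": padj[keep],
                "log2fc": lfc[keep],
            }
        ).sort_values(
            ["p_value", "log2fc", "gene"], ascending=[True, False, True]
        )
        tab["rank"] = np.arange(1, len(tab) + 1)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    logger.info(
        "markers: %s", {ct: int((out.cell_type == ct).sum()) for ct in ref.type_names}
    )
    return out


def permutation_false_positives(
    ref: ReferenceCounts,
    rng: np.random.Generator,
    alpha: float = 0.01,
    lfc_min: float = 0.25,
    adjust: bool = False,
) -> float:
    """Mean markers-per-type found after randomly permuting cell labels.

    A calibration helper: under the null of exchangeable labels the raw-p
    marker count per type should not exceed alpha * G on average.
    """
    permuted = ReferenceCounts(
        counts=ref.counts,
        gene_ids=ref.gene_ids,
        cell_types=rng.permutation(ref.cell_types),
        sample_ids=ref.sample_ids,
        ercc_mask=ref.ercc_mask,
    )
    try:
        tab = find_markers(permuted, alpha=alpha, lfc_min=lfc_min, adjust=adjust)
    except ValueError:
        return 0.0
    counts = tab.groupby("cell_type").size()
    return float(counts.reindex(permuted.type_names, fill_value=0).mean())


def build_candidates(
    full: FullSignature,
    markers: pd.DataFrame,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
) -> list[SignatureMatrix]:
    """One candidate signature per N: union of per-type top-N markers.

    N is capped at the number of markers available for a type. A gene
    ranking as a top marker for several types keeps a single matrix row but
    is recorded in each type's marker set.
    """
    if len(n_grid) == 0:
        raise ValueError("n_grid must not be empty")
    cell_types = full.cell_type_names
    out = []
    for n in n_grid:
        marker_sets: dict[str, list[str]] = {}
        for ct in cell_types:
            sub = markers[markers.cell_type == ct].sort_values("rank")
            marker_sets[ct] = sub.gene.head(n).tolist()
        union = set().union(*marker_sets.values())
        rows = [g for g in full.values.index if g in union]
        out.append(
            SignatureMatrix(
                values=full.values.loc[rows],
                marker_sets=marker_sets,
                top_n=int(n),
            )
        )
    return out


def select_signature(
    candidates: list[SignatureMatrix],
    mixtures: Iterable[MixtureProfile],
    sizes: Optional[CellSizeVector] = None,
    enable_cap: bool = False,
    **irls_opts,
) -> SignatureMatrix:
    """Pick the candidate whose deconvolution reconstructs mixtures best.

    Each candidate is run through the full deconvolver on every mixture;
    its score is the mean per-mixture Spearman correlation between inferred
    and observed marker-gene expression. Ties favour the smaller N.
    """
    if not candidates:
        raise ValueError("no candidate signatures supplied")
    mixtures = list(mixtures)
    best = None
    best_key = None
    any_ok = False
    for cand in candidates:
        scores = []
        for mix in mixtures:
            shared = cand.genes.intersection(mix.values.index)
            if len(shared) < 2:
                continue
            sub = _restrict_genes(cand, shared)
            try:
                fit = select_beta_and_cap(
                    mix.values.loc[shared], sub, sizes, enable_cap=enable_cap, **irls_opts
                )
            except ValueError:
                continue
            scores.append(fit.score)
        if not scores:
            continue
        any_ok = True
        mean_score = float(np.mean(scores))
        n = cand.top_n if cand.top_n is not None else len(cand.genes)
        key = (mean_score, -n)
        logger.info("candidate N=%s: mean score %.4f", cand.top_n, mean_score)
        if best_key is None or key > best_key:
            best, best_key = cand, key
    if not any_ok:
        raise ValueError("every candidate signature failed to deconvolve")
    return best
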