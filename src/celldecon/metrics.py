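"""Evaluation metrics and gene-set alignment helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


@dataclass
class EvalMetrics:
    """Agreement between true and estimated proportion matrices.

    Pearson R over all entries, root mean squared deviation, and mean
    absolute deviation. RMSD >= mAD always, with equality iff all absolute
    errors are equal.
    """

    pearson_r: float
    rmsd: float
    mad: float


def evaluate(truth: pd.DataFrame, est: pd.DataFrame) -> EvalMetrics:
    """Score an estimated proportions matrix against the truth.

    Rows are mixtures, columns cell types; ``est`` is aligned to
    ``truth``'s labels and must cover them.
    """
    missing_rows = truth.index.difference(est.index)
    missing_cols = truth.columns.difference(est.columns)
    if len(missing_rows) or len(missing_cols):
        raise ValueError(
            f"estimate is missing rows {list(missing_rows)} "
            f"and columns {list(missing_cols)}"
        )
    a = truth.to_numpy(dtype=float).ravel()
    b = est.loc[truth.index, truth.columns].to_numpy(dtype=float).ravel()
    err = b - a
    r = float(pearsonr(a, b).statistic) if np.ptp(a) > 0 and np.ptp(b) > 0 else np.nan
    return EvalMetrics(
        pearson_r=r,
        rmsd=float(np.sqrt(np.mean(err**2))),
        mad=float(np.mean(np.abs(err))),
    )


def align_genes(a, b):
    """Restrict two gene-indexed objects to their shared genes, same order.

    Accepts Series or DataFrames indexed by gene (case-sensitive exact
    match). Returns ``(a_shared, b_shared, dropped)`` where dropped maps
    each input to its genes absent from the other.
    """
    ia, ib = a.index, b.index
    shared = ia.intersection(ib)
    if len(shared) == 0:
        raise ValueError("no shared gene identifiers between the two inputs")
    dropped = {"a": list(ia.difference(ib)), "b": list(ib.difference(ia))}
    return a.loc[shared], b.loc[shared], dropped
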