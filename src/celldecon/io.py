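"""Readers and writers for the package's on-disk formats.

Count matrices come in as 10x-style MTX triplets (matrix.mtx,
features.tsv, barcodes.tsv) or dense gene x cell TSVs; annotations,
signatures, proportions and coordinates are tab-separated UTF-8 tables
with a header row. Floats are written with 10 significant digits so
writer/reader round trips are stable to 1e-12 relative.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ReferenceCounts, SignatureMatrix

PathLike = Union[str, Path]
FLOAT_FMT = "%.10g"


def read_counts_mtx(directory: PathLike) -> tuple[pd.Index, pd.Index, np.ndarray]:
    """Read a 10x MTX triplet; returns (gene_ids, barcodes, genes x cells)."""
    d = Path(directory)
    mat = scipy.io.mmread(d / "matrix.mtx")
    genes = pd.read_csv(d / "features.tsv", sep="\t", header=None).iloc[:, 0]
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None).iloc[:, 0]
    dense = np.asarray(scipy.sparse.csr_matrix(mat).todense())
    return pd.Index(genes), pd.Index(barcodes), dense


def write_counts_mtx(
    directory: PathLike,
    counts: np.ndarray,
    gene_ids: pd.Index,
    barcodes: pd.Index,
) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), scipy.sparse.coo_matrix(counts))
    pd.Series(gene_ids).to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(barcodes).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)


def read_matrix_tsv(path: PathLike) -> pd.DataFrame:
    """Dense matrix TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_reference(
    counts_path: PathLike,
    annot_path: PathLike,
    ercc_prefix: str = "ERCC-",
) -> ReferenceCounts:
    """Load a reference from MTX dir or dense TSV plus an annotation TSV.

    The annotation table needs columns cell_id, cell_type, sample_id; its
    rows are matched to count columns by cell id. Gene rows whose id
    starts with ``ercc_prefix`` are flagged as spike-ins.
    """
    p = Path(counts_path)
    if p.is_dir():
        genes, barcodes, dense = read_counts_mtx(p)
        mat = pd.DataFrame(dense, index=genes, columns=barcodes)
    else:
        mat = read_matrix_tsv(p)
    annot = pd.read_csv(annot_path, sep="\t", dtype=str)
    required = {"cell_id", "cell_type", "sample_id"}
    if not required <= set(annot.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    annot = annot.set_index("cell_id").reindex(mat.columns)
    if annot.cell_type.isna().any():
        bad = list(annot.index[annot.cell_type.isna()][:5])
        raise ValueError(f"cells missing annotation, e.g. {bad}")
    return ReferenceCounts(
        counts=mat.to_numpy(),
        gene_ids=mat.index,
        cell_types=annot.cell_type.to_numpy(),
        sample_ids=annot.sample_id.to_numpy(),
        ercc_mask=np.asarray(mat.index.str.startswith(ercc_prefix)),
    )


def write_signature(S: SignatureMatrix, path: PathLike, markers_path: Optional[PathLike] = None) -> None:
    """Write a signature matrix TSV plus a marker-membership sidecar."""
    write_matrix_tsv(S.values, path)
    if markers_path is not None:
        rows = []
        for ct, genes in S.marker_sets.items():
            for rank, g in enumerate(genes, start=1):
                rows.append({"gene": g, "cell_type": ct, "rank": rank})
        pd.DataFrame(rows).to_csv(markers_path, sep="\t", index=False)


def read_signature(path: PathLike, markers_path: Optional[PathLike] = None) -> SignatureMatrix:
    values = read_matrix_tsv(path)
    if markers_path is not None:
        tab = pd.read_csv(markers_path, sep="\t")
        marker_sets = {
            ct: sub.sort_values("rank").gene.tolist()
            for ct, sub in tab.groupby("cell_type")
        }
        for ct in values.columns:
            marker_sets.setdefault(ct, [])
    else:
        # fall back to attributing each row to its max-expression column
        marker_sets = {ct: [] for ct in values.columns}
        for g, row in values.iterrows():
            marker_sets[row.idxmax()].append(g)
    return SignatureMatrix(values=values, marker_sets=marker_sets)


def read_coords(path: PathLike) -> pd.DataFrame:
    """Spot coordinate TSV with columns spot_id, x, y."""
    tab = pd.read_csv(path, sep="\t")
    if not {"spot_id", "x", "y"} <= set(tab.columns):
        raise ValueError("coordinates table must have columns spot_id, x, y")
    return tab.set_index("spot_id")[["x", "y"]].astype(float)


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (np.ndarray, pd.Series)):
        return list(x)
    raise TypeError(f"cannot serialize {type(x)}")
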