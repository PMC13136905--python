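"""Synthetic single-cell references, bulk mixtures and spatial spots.

Every generator is seeded and returns ground truth alongside the data, so
recovery of proportions, markers and cell sizes can be scored exactly.

The count model is deliberately minimal: each cell draws Poisson counts
around a per-type expected profile scaled by that type's true RNA content
and a per-cell log-normal capture efficiency. This is the smallest model
that exhibits the two effects the deconvolution engine targets — per-type
RNA-content differences and per-cell technical capture variation — while
staying honest about what it omits (no ambient RNA, no barcode artifacts,
no platform-specific chemistry).

Spike-in rows receive a fixed expected total per cell scaled only by the
capture efficiency, encoding the assumption that equal amounts of
spike-in RNA are added to every cell.

Bulk mixtures are linear combinations of the per-type expected profiles,
weighted by proportion times RNA content, with optional per-gene
log-normal measurement noise and an optional size-coupled capture
saturation: with ``saturation`` = s, marker genes of a type whose content
is c_j appear (c_j / min_k c_k)^s-fold inflated in the mixture relative to
the single-cell reference. This emulates the cross-source inconsistency of
highly expressed markers of large cells (library saturation compresses
them in single-cell profiles); it is the signal the residual-driven
computational size estimator feeds on, and it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import CP10K, ReferenceCounts
from .core import normalize_cp10k
from .spatial import SpotMatrix

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic reference generator.

    Defaults describe a small but realistic droplet-style experiment:
    a few hundred genes, tens of cells per type, ~8x overexpression of
    planted markers, 30% log-normal capture noise.
    """

    n_types: int = 3
    n_genes: int = 500
    n_ercc: int = 0
    cells_per_type: int = 50
    content: Optional[Sequence[float]] = None  # per-type true RNA content
    marker_frac: float = 0.05
    marker_strength: float = 8.0
    capture_noise_sd: float = 0.3
    base_counts: float = 2000.0  # expected endogenous total at content 1
    ercc_counts: float = 500.0  # expected spike-in total per cell
    n_samples: int = 3
    seed: int = 0

    type_names: list = field(init=False)

    def __post_init__(self) -> None:
        if self.content is None:
            self.content = [1.0] * self.n_types
        self.content = list(self.content)
        if len(self.content) != self.n_types:
            raise ValueError("content must have one entry per type")
        if min(self.content) <= 0:
            raise ValueError("content must be positive")
        self.type_names = [f"type{j}" for j in range(self.n_types)]


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic dataset."""

    profiles: Optional[pd.DataFrame] = None  # genes x types expected CP10K
    markers: Optional[dict] = None  # type -> planted marker genes
    content: Optional[pd.Series] = None  # true RNA content per type
    proportions: Optional[pd.DataFrame] = None  # mixtures x types


def make_reference(cfg: SyntheticConfig) -> tuple[ReferenceCounts, SyntheticTruth]:
    """Generate an annotated single-cell count matrix with known structure.

    Each type's expected profile is a shared log-normal baseline with a
    disjoint block of planted markers multiplied by ``marker_strength``.
    Cell totals scale with the type's RNA content; spike-ins do not.
    """
    rng = _rng(cfg.seed)
    G, K = cfg.n_genes, cfg.n_types
    genes = pd.Index([f"g{i:04d}" for i in range(G)])
    base = rng.lognormal(mean=0.0, sigma=1.0, size=G)

    n_mark = max(1, int(round(cfg.marker_frac * G)))
    order = rng.permutation(G)
    markers = {}
    profiles = np.empty((G, K))
    for j, ct in enumerate(cfg.type_names):
        idx = order[j * n_mark : (j + 1) * n_mark]
        markers[ct] = sorted(genes[idx])
        p = base.copy()
        p[idx] *= cfg.marker_strength
        profiles[:, j] = p / p.sum()

    n_cells = K * cfg.cells_per_type
    cell_types = np.repeat(cfg.type_names, cfg.cells_per_type)
    capture = rng.lognormal(mean=0.0, sigma=cfg.capture_noise_sd, size=n_cells)
    counts = np.empty((G, n_cells), dtype=np.int64)
    for i in range(n_cells):
        j = cfg.type_names.index(cell_types[i])
        lam = profiles[:, j] * cfg.base_counts * cfg.content[j] * capture[i]
        counts[:, i] = rng.poisson(lam)

    gene_ids = genes
    ercc_mask = np.zeros(G, dtype=bool)
    if cfg.n_ercc > 0:
        ercc_genes = pd.Index([f"ERCC-{i:05d}" for i in range(cfg.n_ercc)])
        spike_profile = rng.lognormal(mean=0.0, sigma=0.5, size=cfg.n_ercc)
        spike_profile /= spike_profile.sum()
        spike = np.empty((cfg.n_ercc, n_cells), dtype=np.int64)
        for i in range(n_cells):
            spike[:, i] = rng.poisson(spike_profile * cfg.ercc_counts * capture[i])
        counts = np.vstack([counts, spike])
        gene_ids = genes.append(ercc_genes)
        ercc_mask = np.concatenate([ercc_mask, np.ones(cfg.n_ercc, dtype=bool)])

    sample_ids = rng.integers(0, cfg.n_samples, size=n_cells)
    ref = ReferenceCounts(
        counts=counts,
        gene_ids=gene_ids,
        cell_types=cell_types,
        sample_ids=np.array([f"s{k}" for k in sample_ids]),
        ercc_mask=ercc_mask,
    )
    truth = SyntheticTruth(
        profiles=pd.DataFrame(profiles * CP10K, index=genes, columns=cfg.type_names),
        markers=markers,
        content=pd.Series(cfg.content, index=cfg.type_names, dtype=float),
    )
    return ref, truth


def make_bulk(
    truth: SyntheticTruth,
    proportions: pd.DataFrame,
    noise_sd: float = 0.0,
    saturation: float = 0.0,
    scale: str = "cp10k",
    seed: RngLike = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Bulk mixtures from known cell-number proportions.

    Each mixture is sum_j x_j c_j p_j over the true type profiles, with
    per-gene log-normal noise of ``noise_sd`` on the log scale.
    ``saturation`` applies the size-coupled marker inflation described in
    the module docstring. Rows of ``proportions`` are mixtures; the
    returned truth carries both x and the content vector, so corrected and
    uncorrected fits are testable.

    ``scale`` controls the overall intensity of each mixture:

    - ``"cp10k"`` — every mixture renormalized to total 10^4, the ordinary
      relative-abundance convention of library-size-normalized bulk data;
    - ``"content"`` — each mixture's total is 10^4 * sum_j x_j c_j,
      emulating intensity-calibrated measurements (e.g. spike-in
      normalized bulk) whose overall signal tracks the average RNA content
      per cell. Only on this scale does a single mixture carry enough
      information for the residual-driven cell-size estimator to separate
      content from composition.
    """
    rng = _rng(seed)
    P = truth.profiles.to_numpy(dtype=float)
    types = list(truth.profiles.columns)
    c = truth.content.reindex(types).to_numpy(dtype=float)
    X = proportions[types].to_numpy(dtype=float)
    if (X < 0).any() or not np.allclose(X.sum(axis=1), 1.0):
        raise ValueError("proportions must lie on the simplex")

    boost = np.ones_like(P)
    if saturation > 0:
        rel = c / c.min()
        for j, ct in enumerate(types):
            idx = truth.profiles.index.get_indexer(truth.markers[ct])
            boost[idx, j] = rel[j] ** saturation

    if scale not in {"cp10k", "content"}:
        raise ValueError(f"unknown scale {scale!r}")
    cols = {}
    for m, row in enumerate(X):
        mix = (P * boost) @ (row * c)
        if noise_sd > 0:
            mix = mix * rng.lognormal(mean=0.0, sigma=noise_sd, size=mix.shape)
        cols[f"mix{m}"] = mix
    mixtures = pd.DataFrame(cols, index=truth.profiles.index)
    if scale == "cp10k":
        mixtures = normalize_cp10k(mixtures)
    out_truth = SyntheticTruth(
        profiles=truth.profiles,
        markers=truth.markers,
        content=truth.content,
        proportions=pd.DataFrame(X, index=list(cols), columns=types),
    )
    return mixtures, out_truth


def pseudobulk_from_sc(
    ref: ReferenceCounts,
    n_boot: int = 1,
    resample: bool = True,
    seed: RngLike = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Artificial bulk profiles by summing single-cell counts per sample.

    For each bootstrap replicate and sample, cells are resampled with
    replacement to the sample's original size (or taken as-is when
    ``resample`` is off) and their endogenous counts summed. The true
    proportion of type j is its resampled cell count over the total.
    """
    import warnings

    rng = _rng(seed)
    counts, genes = ref.endogenous()
    samples = sorted(pd.unique(ref.sample_ids))
    types = ref.type_names
    cols = {}
    rows = {}
    for rep in range(n_boot):
        for s in samples:
            idx = np.flatnonzero(ref.sample_ids == s)
            if len(idx) == 0:
                warnings.warn(f"sample {s!r} has no cells; skipped", stacklevel=2)
                continue
            chosen = rng.choice(idx, size=len(idx), replace=True) if resample else idx
            name = s if n_boot == 1 else f"{s}.rep{rep}"
            cols[name] = counts[:, chosen].sum(axis=1)
            labels = ref.cell_types[chosen]
            rows[name] = [float((labels == ct).sum()) / len(chosen) for ct in types]
    mixtures = pd.DataFrame(cols, index=genes)
    truth = SyntheticTruth(
        proportions=pd.DataFrame.from_dict(rows, orient="index", columns=types)
    )
    return mixtures, truth


def make_spatial(
    ref: ReferenceCounts,
    grid: tuple[int, int] = (10, 10),
    cells_per_spot: int = 10,
    pattern: str = "random",
    depth: Optional[int] = None,
    seed: RngLike = 0,
) -> tuple[SpotMatrix, SyntheticTruth]:
    """Gridded synthetic spots with known per-spot composition.

    Patterns: ``pure`` (each spot holds one type), ``layered`` (horizontal
    bands of one type each, emulating cortical layers), ``random``
    (per-spot Dirichlet type mix, multinomial cell draw). Spot counts are
    sums of real cell count vectors drawn from the reference; ``depth``,
    when given, multinomially downsamples each spot to that total count,
    emulating the shallow capture of spot-based platforms. The truth is
    the realized per-spot type fraction.
    """
    if pattern not in {"layered", "random", "pure"}:
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = _rng(seed)
    counts, genes = ref.endogenous()
    types = ref.type_names
    K = len(types)
    cells_by_type = {ct: np.flatnonzero(ref.cell_types == ct) for ct in types}
    rows_n, cols_n = grid
    spot_ids = []
    coords = []
    values = {}
    fractions = {}
    for r in range(rows_n):
        for q in range(cols_n):
            sid = f"spot_{r}_{q}"
            spot_ids.append(sid)
            coords.append((float(q), float(r)))
            if pattern == "pure":
                j = rng.integers(0, K)
                n_per_type = np.zeros(K, dtype=int)
                n_per_type[j] = cells_per_spot
            elif pattern == "layered":
                j = min(r * K // rows_n, K - 1)
                n_per_type = np.zeros(K, dtype=int)
                n_per_type[j] = cells_per_spot
            else:
                probs = rng.dirichlet(np.ones(K))
                n_per_type = rng.multinomial(cells_per_spot, probs)
            vec = np.zeros(counts.shape[0], dtype=np.int64)
            for j, ct in enumerate(types):
                if n_per_type[j] == 0:
                    continue
                chosen = rng.choice(cells_by_type[ct], size=n_per_type[j], replace=True)
                vec += counts[:, chosen].sum(axis=1)
            if depth is not None and vec.sum() > depth:
                vec = rng.multinomial(depth, vec / vec.sum())
            values[sid] = vec
            fractions[sid] = n_per_type / cells_per_spot
    spots = SpotMatrix(
        values=pd.DataFrame(values, index=genes),
        coords=pd.DataFrame(coords, index=pd.Index(spot_ids), columns=["x", "y"]),
    )
    truth = SyntheticTruth(
        proportions=pd.DataFrame.from_dict(fractions, orient="index", columns=types)
    )
    return spots, truth
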