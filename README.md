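# celldecon

Cell-size-aware cell-type deconvolution of bulk and spatial transcriptomes
from single-cell references.

## The problem

Bulk RNA-seq, microarray and spot-based spatial transcriptomics measure
mixtures of cells. Estimating the *cell-number* composition of such a
mixture from a single-cell reference is confounded by two effects most
deconvolution methods ignore:

1. **Cell size.** A cell type with r-fold more RNA per cell contributes
   r-fold more reads per cell. Methods that fit relative expression
   therefore return *RNA shares*, not cell fractions, and systematically
   overestimate large cells (think hepatocytes vs lymphocytes, or HEK vs
   Jurkat cells).
2. **Cross-source technical variation.** The reference and the mixture are
   usually measured on different platforms, so no gene is perfectly
   consistent between the two, and highly expressed genes dominate naive
   least squares.

## The model

A mixture profile Y (CP10K-normalized, restricted to N marker genes) is
modeled as

    y_i = Σ_j c_j x_j s_ij + ε_i,   x_j ≥ 0,  Σ_j x_j = 1,

where S is the N × K marker-gene signature built from the reference,
c_j is the RNA-content ("cell size") coefficient of type j, and x are the
cell-number fractions. Fitting is iteratively reweighted least squares:

- **Initialization by sectional linearity.** On a type's exclusive
  markers, log y_i = u_j + log s_ij with u_j = log(c_j x_j); the
  intercepts u_j, estimated per type by slope-1 regression, softmax into
  RNA-content shares δ_j and an initial reconstruction t = Sδ.
- **Adaptive gene weights** w_i = 1 / (|y_i − t_i|^β · t_i^(1−β))², with
  β ∈ {0, ½, 1} chosen per mixture to maximize the Spearman correlation
  between the reconstruction and the observed mixture. For
  high-technical-variation settings (e.g. microarray mixtures against an
  RNA-seq reference) an optional cap clips weights at a quantile q, with
  the quantile likewise selected by reconstruction score.
- **Constrained weighted solve** in z_j = c_j x_j with the sum-to-one
  constraint enforced inside the optimization, iterated until the
  proportion vector stabilizes (‖ΔX‖₂ ≤ 0.01).

Cell sizes come from ERCC spike-ins when the reference has them (per-cell
absolute RNA content = endogenous counts over the spike-in upper
quartile, averaged per type), or from a three-stage residual-driven
procedure (screen types whose signature rank-correlates with the
uniform-size residual → validate each by reconstruction improvement →
jointly tune a shared scaling strength λ).

For spatial data, each spot is first screened with marker-based Z-scores
(fold changes against per-gene backgrounds, 25th-percentile reference for
prevalent types); only the enriched types enter that spot's regression.

## Worked example

Two cell types with a true 4× RNA-content difference, an ERCC-bearing
synthetic reference, and three bulk mixtures with known composition:

```python
import pandas as pd
from celldecon.simulate import SyntheticConfig, make_reference, make_bulk
from celldecon.reference import pseudobulk_by_type, find_markers, build_candidates
from celldecon.core import deconvolve_mixtures
from celldecon.sizes import ercc_cell_sizes
from celldecon.metrics import evaluate

cfg = SyntheticConfig(n_types=2, n_ercc=20, content=[4.0, 1.0], seed=0)
ref, truth = make_reference(cfg)

signature = build_candidates(pseudobulk_by_type(ref), find_markers(ref), [50])[0]
proportions = pd.DataFrame([[0.5, 0.5], [0.3, 0.7], [0.7, 0.3]],
                           columns=cfg.type_names)
mixtures, bulk_truth = make_bulk(truth, proportions, noise_sd=0.05, seed=1)

sizes = ercc_cell_sizes(ref)
print("estimated cell-size ratio:", round(sizes.c["type0"] / sizes.c["type1"], 2))

uncorrected, _ = deconvolve_mixtures(mixtures, signature)
corrected, _ = deconvolve_mixtures(mixtures, signature, sizes)
for name, est in [("uncorrected", uncorrected), ("corrected", corrected)]:
    m = evaluate(bulk_truth.proportions.set_axis(est.index), est)
    print(f"{name}: R={m.pearson_r:.3f} RMSD={m.rmsd:.3f} mAD={m.mad:.3f}")
```

Output:

```
estimated cell-size ratio: 3.9
uncorrected: R=0.359 RMSD=0.281 mAD=0.274
corrected: R=0.997 RMSD=0.014 mAD=0.012
```

The uncorrected fit returns RNA shares — a 50/50 mixture is reported as
roughly 80/20 because type0 cells carry 4× the RNA — while supplying the
spike-in-estimated sizes recovers the true cell-number fractions.

The same pipeline is available from the shell:

```
celldecon simulate reference --n-ercc 20 --content 4,1 --out-dir ref/
celldecon build-signature --ref-counts ref/ --ref-annot ref/annotations.tsv \
    --mixtures mixtures.tsv --out sig.tsv --markers-out markers.tsv
celldecon cell-sizes ercc --ref-counts ref/ --ref-annot ref/annotations.tsv --out sizes.tsv
celldecon deconvolve --mixtures mixtures.tsv --signature sig.tsv \
    --markers markers.tsv --cell-sizes file:sizes.tsv --out props.tsv
celldecon deconvolve-spatial --spots spots.tsv --coords coords.tsv \
    --signature sig.tsv --out spot_props.tsv
```

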