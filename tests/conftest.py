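import numpy as np
import pandas as pd
import pytest

from celldecon import ReferenceCounts, SignatureMatrix
from celldecon.reference import build_candidates, find_markers, pseudobulk_by_type
from celldecon.simulate import SyntheticConfig, make_reference


@pytest.fixture(scope="session")
def small_ref():
    """Three-type reference with planted markers, 400 genes, 40 cells/type."""
    cfg = SyntheticConfig(n_types=3, n_genes=400, cells_per_type=40, seed=11)
    ref, truth = make_reference(cfg)
    return ref, truth


@pytest.fixture(scope="session")
def small_signature(small_ref):
    ref, _ = small_ref
    full = pseudobulk_by_type(ref)
    markers = find_markers(ref)
    return build_candidates(full, markers, [25])[0]


def toy_signature(K=2, n_per_type=3, scale=100.0, seed=None):
    """Tiny block-diagonal-ish signature with disjoint marker sets."""
    rng = np.random.default_rng(0 if seed is None else seed)
    genes = [f"g{i}" for i in range(K * n_per_type)]
    vals = np.full((K * n_per_type, K), 1.0)
    marker_sets = {}
    for j in range(K):
        rows = slice(j * n_per_type, (j + 1) * n_per_type)
        vals[rows, j] = scale * (1 + rng.random(n_per_type))
        marker_sets[f"t{j}"] = genes[rows]
    return SignatureMatrix(
        values=pd.DataFrame(vals, index=genes, columns=[f"t{j}" for j in range(K)]),
        marker_sets=marker_sets,
    )
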