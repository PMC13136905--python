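"""Spot enrichment scores, Z-statistics and enrichment-gated deconvolution."""

import numpy as np
import pandas as pd
import pytest

from celldecon.spatial import (
    SpotMatrix,
    analyze_spots,
    deconvolve_spots,
    enriched_types,
    prevalent_types,
    spot_fold_changes,
    spot_scores,
    spot_zscores,
)
from celldecon.simulate import SyntheticConfig, make_reference, make_spatial
from celldecon.reference import build_candidates, find_markers, pseudobulk_by_type

from conftest import toy_signature


def grid_spots(values: pd.DataFrame) -> SpotMatrix:
    n = values.shape[1]
    coords = pd.DataFrame(
        {"x": np.arange(n, dtype=float), "y": np.zeros(n)}, index=values.columns
    )
    return SpotMatrix(values=values, coords=coords)


class TestScores:
    def test_uniform_gene_gives_unit_relative_score(self):
        S = toy_signature(K=2, n_per_type=1)
        vals = pd.DataFrame(
            [[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]],
            index=S.genes,
            columns=["s0", "s1", "s2"],
        )
        abs_s, rel_s = spot_scores(grid_spots(vals), S)
        np.testing.assert_allclose(rel_s.loc["t0"], 1.0)

    def test_absolute_score_is_marker_mean(self):
        S = toy_signature(K=2, n_per_type=2)
        vals = pd.DataFrame(
            [[10.0], [30.0], [0.0], [0.0]], index=S.genes, columns=["s0"]
        )
        abs_s, _ = spot_scores(grid_spots(vals), S)
        assert abs_s.loc["t0", "s0"] == pytest.approx(20.0)

    def test_relative_scores_hand_division(self):
        S = toy_signature(K=2, n_per_type=1)
        vals = pd.DataFrame(
            [[2.0, 4.0, 6.0], [1.0, 1.0, 1.0]],
            index=S.genes,
            columns=["s0", "s1", "s2"],
        )
        _, rel_s = spot_scores(grid_spots(vals), S)
        np.testing.assert_allclose(rel_s.loc["t0"], [0.5, 1.0, 1.5])

    def test_missing_markers_error(self):
        S = toy_signature(K=2, n_per_type=1)
        vals = pd.DataFrame([[1.0, 2.0]], index=[S.genes[0]], columns=["s0", "s1"])
        with pytest.raises(ValueError, match="no markers"):
            spot_scores(grid_spots(vals), S)


class TestPrevalence:
    def test_single_type_never_prevalent(self):
        abs_s = pd.DataFrame([[5.0, 5.0, 5.0]], index=["t0"])
        rel_s = pd.DataFrame([[1.0, 1.0, 1.0]], index=["t0"])
        assert not prevalent_types(abs_s, rel_s).any()

    def test_inconsistent_type_not_prevalent(self):
        abs_s = pd.DataFrame([[9.0, 9.0], [1.0, 1.0]], index=["t0", "t1"])
        rel_s = pd.DataFrame([[1.5, 1.5], [1.0, 1.0]], index=["t0", "t1"])
        flags = prevalent_types(abs_s, rel_s)
        assert not flags["t0"]

    def test_ubiquitous_high_type_flagged(self):
        abs_s = pd.DataFrame(
            [[9.0, 10.0, 9.5, 8.9], [1.0, 2.0, 1.5, 1.0]], index=["t0", "t1"]
        )
        rel_s = pd.DataFrame(
            [[1.0, 1.01, 0.99, 1.0], [0.5, 2.0, 1.5, 0.2]], index=["t0", "t1"]
        )
        flags = prevalent_types(abs_s, rel_s)
        assert flags["t0"] and not flags["t1"]


class TestFoldChanges:
    def test_mean_reference(self):
        S = toy_signature(K=2, n_per_type=1)
        vals = pd.DataFrame(
            [np.arange(1.0, 6.0), np.ones(5)],
            index=S.genes,
            columns=[f"s{i}" for i in range(5)],
        )
        prev = pd.Series(False, index=S.cell_type_names)
        F, refs = spot_fold_changes(grid_spots(vals), prev, S)
        assert F.loc[S.genes[0], "s2"] == pytest.approx(1.0)

    def test_q1_reference_for_prevalent(self):
        S = toy_signature(K=2, n_per_type=1)
        vals = pd.DataFrame(
            [np.arange(1.0, 6.0), np.ones(5)],
            index=S.genes,
            columns=[f"s{i}" for i in range(5)],
        )
        prev = pd.Series([True, False], index=S.cell_type_names)
        F, refs = spot_fold_changes(grid_spots(vals), prev, S)
        # Q1 of (1..5) is 2 (type-7); spot s2 has value 3
        assert F.loc[S.genes[0], "s2"] == pytest.approx(1.5)

    def test_constant_gene_unit_fold_change(self):
        S = toy_signature(K=2, n_per_type=1)
        vals = pd.DataFrame(
            [np.full(4, 7.0), np.arange(1.0, 5.0)],
            index=S.genes,
            columns=[f"s{i}" for i in range(4)],
        )
        prev = pd.Series(False, index=S.cell_type_names)
        F, _ = spot_fold_changes(grid_spots(vals), prev, S)
        np.testing.assert_allclose(F.loc[S.genes[0]], 1.0)


class TestZScores:
    def _setup(self):
        # 4 genes; type t0 has single marker g0
        genes = ["g0", "g1", "g2", "g3"]
        S_vals = pd.DataFrame(
            {"t0": [50.0, 1, 1, 1], "t1": [1, 50.0, 50.0, 50.0]}, index=genes
        )
        from celldecon.containers import SignatureMatrix

        S = SignatureMatrix(
            values=S_vals, marker_sets={"t0": ["g0"], "t1": ["g1", "g2", "g3"]}
        )
        F = pd.DataFrame({"s0": [3.0, 1.0, 2.0, 2.0]}, index=genes)
        spots = grid_spots(pd.DataFrame({"s0": [5.0, 5.0, 5.0, 5.0]}, index=genes))
        return S, F, spots

    def test_hand_computed_z(self):
        S, F, spots = self._setup()
        z, n = spot_zscores(F, S, spots)
        # mu=2, sd=sqrt(2/3), f_t0=3, n=1 -> Z = 1/0.8165
        assert z.loc["t0", "s0"] == pytest.approx(1.0 / np.sqrt(2.0 / 3.0), rel=1e-6)
        assert n.loc["t0", "s0"] == 1

    def test_zero_centered_type(self):
        S, F, spots = self._setup()
        # with g0 = 5/3 the spot mean equals f_t0, so Z = 0 for any n
        F.loc[:, "s0"] = [5.0 / 3.0, 1.0, 2.0, 2.0]
        z, _ = spot_zscores(F, S, spots)
        assert z.loc["t0", "s0"] == pytest.approx(0.0, abs=1e-12)

    def test_sqrt_n_scaling(self):
        genes = [f"g{i}" for i in range(12)]
        from celldecon.containers import SignatureMatrix

        S1 = SignatureMatrix(
            values=pd.DataFrame({"t0": np.ones(12), "t1": np.ones(12)}, index=genes),
            marker_sets={"t0": ["g0"], "t1": genes[4:]},
        )
        S4 = SignatureMatrix(
            values=S1.values, marker_sets={"t0": genes[:4], "t1": genes[4:]}
        )
        F = pd.DataFrame({"s0": [3.0] * 4 + [1.0, 2.0] * 4}, index=genes)
        spots = grid_spots(pd.DataFrame({"s0": np.full(12, 5.0)}, index=genes))
        z1, _ = spot_zscores(F, S1, spots)
        z4, _ = spot_zscores(F, S4, spots)
        assert z4.loc["t0", "s0"] == pytest.approx(2 * z1.loc["t0", "s0"])

    def test_unexpressed_marker_gives_neg_inf(self):
        S, F, spots = self._setup()
        spots.values.loc["g0", "s0"] = 0.0
        z, n = spot_zscores(F, S, spots)
        assert np.isneginf(z.loc["t0", "s0"])
        assert n.loc["t0", "s0"] == 0


class TestEnrichedSets:
    def test_clear_winner(self):
        z = pd.DataFrame({"s0": [1.0, -1.0]}, index=["t0", "t1"])
        assert enriched_types(z)["s0"] == ["t0"]

    def test_all_negative_keeps_argmax(self):
        z = pd.DataFrame({"s0": [-3.0, -1.0, -2.0]}, index=["t0", "t1", "t2"])
        enr = enriched_types(z)["s0"]
        assert "t1" in enr and len(enr) >= 1

    def test_tied_argmax_includes_both(self):
        z = pd.DataFrame({"s0": [2.0, 2.0]}, index=["t0", "t1"])
        assert enriched_types(z)["s0"] == ["t0", "t1"]


@pytest.fixture(scope="module")
def spatial_world():
    cfg = SyntheticConfig(n_types=4, n_genes=400, cells_per_type=40, seed=3)
    ref, truth = make_reference(cfg)
    S = build_candidates(pseudobulk_by_type(ref), find_markers(ref), [25])[0]
    return ref, S


class TestSpotDeconvolution:
    def test_pure_spots_assigned_correctly(self, spatial_world):
        ref, S = spatial_world
        spots, truth = make_spatial(ref, (5, 8), cells_per_spot=8, pattern="pure", seed=7)
        props, enr = deconvolve_spots(spots, S)
        for s in truth.proportions.index:
            assert props[s].idxmax() == truth.proportions.loc[s].idxmax()

    def test_columns_on_simplex_and_gating(self, spatial_world):
        ref, S = spatial_world
        spots, truth = make_spatial(
            ref, (4, 6), cells_per_spot=10, pattern="random", seed=8
        )
        props, enr = deconvolve_spots(spots, S)
        np.testing.assert_allclose(props.sum(axis=0), 1.0, atol=1e-8)
        for s in props.columns:
            assert enr.enriched[s], "every spot must have an enriched type"
            for ct in props.index:
                if ct not in enr.enriched[s]:
                    assert props.loc[ct, s] == 0.0

    def test_constant_genes_leave_enrichment_unchanged(self, spatial_world):
        ref, S = spatial_world
        spots, _ = make_spatial(ref, (5, 10), cells_per_spot=8, pattern="random", seed=9)
        enr1 = analyze_spots(spots, S)
        padded = spots.values.copy()
        for i in range(5):
            padded.loc[f"const{i}"] = 50.0
        enr2 = analyze_spots(SpotMatrix(values=padded, coords=spots.coords), S)
        assert enr1.enriched == enr2.enriched

    def test_fully_enriched_spot_matches_ungated(self, spatial_world):
        ref, S = spatial_world
        spots, _ = make_spatial(ref, (3, 4), cells_per_spot=10, pattern="random", seed=10)
        from celldecon.core import deconvolve_mixtures, normalize_cp10k
        from celldecon.spatial import SpotEnrichment

        enr = analyze_spots(spots, S)
        sid = spots.values.columns[0]
        enr.enriched[sid] = list(S.cell_type_names)  # force full set
        props, _ = deconvolve_spots(spots, S, enrichment=enr)
        ungated, _ = deconvolve_mixtures(
            normalize_cp10k(spots.values[[sid]]), S
        )
        np.testing.assert_allclose(
            props[sid].to_numpy(), ungated.loc[sid].to_numpy(), atol=1e-8
        )
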