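"""Landscape pattern metrics against hand counts and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from ecocoupling.grid import CategoricalGrid
from ecocoupling import landmetrics as lm

from oracles import bf_metrics


class TestPatches:
    def test_uniform_square_is_one_patch(self, code):
        cat = CategoricalGrid(codes=np.full((2, 2), code["forest"]))
        ps = lm.label_patches(cat)
        assert len(ps.patches) == 1
        assert ps.patches.area.iloc[0] == 4
        assert ps.patches.perimeter.iloc[0] == 8

    def test_diagonal_pair_connectivity(self, code):
        codes = np.full((2, 2), code["grassland"])
        codes[0, 0] = codes[1, 1] = code["forest"]
        cat = CategoricalGrid(codes=codes)
        forest8 = lm.label_patches(cat, connectivity=8).patches
        forest4 = lm.label_patches(cat, connectivity=4).patches
        n8 = (forest8.code == code["forest"]).sum()
        n4 = (forest4.code == code["forest"]).sum()
        assert (n8, n4) == (1, 2)

    def test_ring_perimeter_counts_inner_and_outer_edges(self, ring_grid, code):
        ps = lm.label_patches(ring_grid)
        forest = ps.patches[ps.patches.code == code["forest"]]
        assert forest.perimeter.iloc[0] == 16  # 12 outer + 4 inner

    def test_areas_conserve_unmasked_cell_count(self, random_landscape_factory):
        cat = random_landscape_factory(7)
        ps = lm.label_patches(cat)
        assert ps.patches.area.sum() == (~cat.nodata_mask).sum()

    def test_fully_masked_raises(self, code):
        cat = CategoricalGrid(codes=np.full((2, 2), code["forest"]),
                              nodata_mask=np.ones((2, 2), bool))
        with pytest.raises(lm.EmptyLandscapeError):
            lm.label_patches(cat)


class TestScalarMetrics:
    @pytest.mark.parametrize("p, expected", [
        ([0.5, 0.5], np.log(2)),
        ([1.0], 0.0),
        ([0.25] * 4, np.log(4)),
    ])
    def test_shdi(self, p, expected):
        assert lm.shdi(p) == pytest.approx(expected)

    def test_shei_values(self):
        assert lm.shei([0.25] * 4) == pytest.approx(1.0)
        assert lm.shei([1.0]) == 0.0
        expected = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1)) / np.log(2)
        assert lm.shei([0.9, 0.1]) == pytest.approx(expected)

    def test_division_closed_forms(self, code):
        cat = CategoricalGrid(codes=np.full((4, 4), code["forest"]))
        ps = lm.label_patches(cat)
        assert lm.division(ps, 16) == pytest.approx(0.0)
        # 4 equal patches of 4 cells in a 16-cell landscape -> 1 - 4*(1/16)
        quad = np.empty((4, 4), dtype=int)
        quad[:2, :2], quad[:2, 2:] = code["forest"], code["grassland"]
        quad[2:, :2], quad[2:, 2:] = code["farmland"], code["water"]
        ps4 = lm.label_patches(CategoricalGrid(codes=quad))
        assert lm.division(ps4, 16) == pytest.approx(0.75)

    def test_frac_am_hand_values(self, code):
        square = CategoricalGrid(codes=np.full((3, 3), code["forest"]))
        assert lm.frac_am(lm.label_patches(square)) == pytest.approx(1.0)
        single = CategoricalGrid(codes=np.array([[code["forest"]]]))
        assert lm.frac_am(lm.label_patches(single)) == pytest.approx(1.0)
        # 1x8 forest strip beside an unrelated 4x4 block: weighted average of
        # 2 ln 4.5 / ln 8 (strip) and 1.0 (square)
        strip = CategoricalGrid(codes=np.full((1, 8), code["forest"]))
        got = lm.frac_am(lm.label_patches(strip))
        assert got == pytest.approx(2 * np.log(4.5) / np.log(8))

    def test_iji_hand_values(self):
        assert lm.iji({(1, 2): 5, (1, 3): 5, (2, 3): 5}, 3) == pytest.approx(100.0)
        assert lm.iji({(1, 2): 7}, 3) == pytest.approx(0.0)
        e = {(1, 2): 2, (1, 3): 1, (2, 3): 1}
        expected = 100 * (-(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))) / np.log(3)
        assert lm.iji(e, 3) == pytest.approx(expected)
        assert np.isnan(lm.iji({(1, 2): 3}, 2))

    def test_contag_conventions(self, code, checkerboard8):
        assert lm.contag([1.0], np.array([[10]]), 1) == 100.0
        met = lm.landscape_metrics(checkerboard8)
        # two fully interleaved classes: no like-class adjacency at all,
        # q = 1/2 on the off-diagonal, hence exactly 50
        assert met["contag"] == pytest.approx(50.0)
        assert 0 <= met["contag"] <= 100


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(50))
    def test_random_8x8_landscapes_match_brute_force(
            self, seed, random_landscape_factory):
        cat = random_landscape_factory(seed, n_classes=4)
        got = lm.landscape_metrics(cat)
        want = bf_metrics(cat.codes)
        for key in ("shdi", "shei", "division", "frac_am", "contag"):
            assert got[key] == pytest.approx(want[key], abs=1e-9), key
        if np.isnan(want["iji"]):
            assert np.isnan(got["iji"])
        else:
            assert got["iji"] == pytest.approx(want["iji"], abs=1e-9)

    def test_metrics_invariant_under_code_relabeling(
            self, random_landscape_factory):
        cat = random_landscape_factory(11, n_classes=3)
        relabeled = CategoricalGrid(codes=7 - cat.codes)  # 1,2,3 -> 6,5,4
        a = lm.landscape_metrics(cat)
        b = lm.landscape_metrics(relabeled)
        for key in ("shdi", "shei", "division", "iji", "contag", "frac_am"):
            assert a[key] == pytest.approx(b[key], nan_ok=True)

    def test_masked_cells_are_excluded(self, code):
        codes = np.full((4, 4), code["forest"])
        codes[:, 2:] = code["grassland"]
        mask = np.zeros((4, 4), bool)
        mask[:, 3] = True
        cat = CategoricalGrid(codes=codes, nodata_mask=mask)
        got = lm.landscape_metrics(cat)
        want = bf_metrics(codes, valid=~mask)
        assert got["shdi"] == pytest.approx(want["shdi"], abs=1e-12)
        assert got["contag"] == pytest.approx(want["contag"], abs=1e-9)


class TestUnitMetrics:
    def test_uniform_unit_degenerate_values(self, code):
        cat = CategoricalGrid(codes=np.full((4, 4), code["forest"]))
        rec = lm.unit_metrics(cat, 4).iloc[0]
        assert rec.shdi == 0 and rec.contag == 100 and rec.division == 0
        assert np.isnan(rec.iji)

    def test_disjoint_identical_units_get_identical_records(self, code):
        block = np.array([[code["forest"], code["grassland"]],
                          [code["grassland"], code["water"]]])
        cat = CategoricalGrid(codes=np.tile(block, (1, 2)))
        recs = lm.unit_metrics(cat, 2)
        a, b = recs.iloc[0], recs.iloc[1]
        for key in lm.METRIC_COLUMNS:
            assert a[key] == pytest.approx(b[key], nan_ok=True)

    def test_worked_6x6_fixture_matches_oracle(self, random_landscape_factory):
        cat = random_landscape_factory(5, shape=(6, 6), n_classes=3)
        rec = lm.unit_metrics(cat, 6).iloc[0]
        want = bf_metrics(cat.codes)
        for key in lm.METRIC_COLUMNS:
            got = rec[key]
            if isinstance(want[key], float) and np.isnan(want[key]):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want[key], abs=1e-9), key


class TestOrganizationIndex:
    def _records(self, values):
        df = pd.DataFrame(values, columns=lm.METRIC_COLUMNS)
        df.insert(0, "unit_id", range(len(df)))
        return df

    def test_extreme_units_hit_bounds(self):
        rng = np.random.default_rng(0)
        mid = rng.uniform(0.2, 0.8, size=(5, 6))
        rec = self._records(np.vstack([np.zeros(6), mid, np.ones(6)]))
        out = lm.organization_index(rec)
        assert out.eo.iloc[0] == pytest.approx(0.0, abs=5e-4)
        assert out.eo.iloc[-1] == pytest.approx(1.0, abs=5e-4)
        assert ((out.eo >= 0) & (out.eo <= 1)).all()

    def test_flat_weights_sum_to_one(self):
        assert lm.OrganizationWeights().flat_vector().sum() == pytest.approx(
            1.0, abs=5e-4)

    def test_nested_mode_double_applies_group_weights(self):
        # The grouped (published) form re-scales each group by its
        # coefficient, so a unit maximal in everything lands well below 1.
        rec = self._records(np.vstack([np.zeros(6), np.ones(6)]))
        nested = lm.organization_index(
            rec, lm.OrganizationWeights(mode="nested"))
        flat = lm.organization_index(rec)
        w = lm.OrganizationWeights()
        expected_top = (w.w_connectivity * (w.w_shdi + w.w_shei)
                        + w.w_heterogeneity * (w.w_division + w.w_iji + w.w_contag)
                        + w.w_shape * w.w_frac)
        assert nested.eo.iloc[1] == pytest.approx(expected_top)
        assert flat.eo.iloc[1] == pytest.approx(1.0, abs=5e-4)

    def test_constant_metric_normalizes_to_half(self):
        vals = np.random.default_rng(1).uniform(size=(4, 6))
        vals[:, 0] = 0.7  # constant shdi column
        out = lm.organization_index(self._records(vals))
        assert (out["shdi_norm"] == 0.5).all()

    def test_missing_metric_imputed_with_median(self):
        vals = np.random.default_rng(2).uniform(size=(5, 6))
        rec = self._records(vals)
        rec.loc[2, "iji"] = np.nan
        out = lm.organization_index(rec)
        others = out.loc[out.index != 2, "iji_norm"]
        assert out.loc[2, "iji_norm"] == pytest.approx(others.median())
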