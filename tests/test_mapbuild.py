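"""Segmentation, spatial features (ND/NDR), splitting and normalization."""

import numpy as np
import pandas as pd
import pytest

from nanovote.mapbuild import (
    NanomechMap,
    build_pixel_table,
    cell_center,
    compute_nd,
    compute_ndr,
    fit_normalizer,
    read_pixel_table,
    segment_cell,
    split_by_cell,
    write_pixel_table,
)


def _map_from_morpho(morpho, label="M0", cell_id="c0", valid=None):
    zeros = np.zeros_like(morpho, dtype=float)
    return NanomechMap(
        channels={"Adh": zeros + 0.3, "MechH": zeros + 300.0,
                  "MechL": zeros + 150.0, "Morpho": morpho.astype(float)},
        valid=valid, label=label, cell_id=cell_id,
    )


def _disc_morpho(grid=20, center=(10, 10), radius=6, height=4000.0):
    rr, cc = np.mgrid[0:grid, 0:grid]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return np.where(d2 <= radius**2, height, 0.0)


class TestSegmentation:
    def test_single_disc_is_recovered(self):
        morpho = _disc_morpho()
        mask = segment_cell(_map_from_morpho(morpho))
        assert np.array_equal(mask, morpho > 0)

    def test_all_substrate_fails(self):
        with pytest.raises(ValueError):
            segment_cell(_map_from_morpho(np.zeros((10, 10))))

    def test_largest_component_wins(self):
        morpho = np.zeros((30, 30))
        morpho[2:4, 2:4] = 3000.0       # 4 px blob
        morpho[10:25, 10:25] = 3000.0   # 225 px blob
        mask = segment_cell(_map_from_morpho(morpho))
        assert mask[12, 12] and not mask[2, 2]
        assert mask.sum() == 225

    def test_invalid_pixels_are_excluded(self):
        morpho = _disc_morpho()
        valid = np.ones_like(morpho, dtype=bool)
        valid[10, 10] = False
        mask = segment_cell(_map_from_morpho(morpho, valid=valid))
        assert not mask[10, 10]


class TestCellCenter:
    def test_single_pixel(self):
        morpho = np.zeros((10, 10))
        morpho[5, 7] = 1000.0
        nmap = _map_from_morpho(morpho)
        assert cell_center(nmap, morpho > 0) == (5.0, 7.0)

    def test_two_pixel_weighted_mean(self):
        morpho = np.zeros((4, 4))
        morpho[0, 0] = 1.0
        morpho[0, 1] = 3.0
        nmap = _map_from_morpho(morpho)
        row, col = cell_center(nmap, morpho > 0)
        assert (row, col) == (0.0, 0.75)

    def test_uniform_square_gives_geometric_centroid(self):
        morpho = np.zeros((12, 12))
        morpho[2:7, 3:8] = 500.0
        row, col = cell_center(_map_from_morpho(morpho), morpho > 0)
        assert (row, col) == (4.0, 5.0)


class TestNdNdr:
    def test_farthest_pixel_has_nd_one(self):
        morpho = _disc_morpho()
        mask = morpho > 0
        nd = compute_nd(mask, (10.0, 10.0))
        assert nd.max() == pytest.approx(1.0)

    def test_half_distance_gives_half_nd(self):
        mask = np.zeros((11, 11), dtype=bool)
        mask[5, 5] = mask[5, 7] = mask[5, 9] = True  # distances 0, 2, 4
        nd = compute_nd(mask, (5.0, 5.0))
        assert sorted(nd) == pytest.approx([0.0, 0.5, 1.0])

    def test_single_pixel_cell_nd_zero_ndr_one(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert compute_nd(mask, (2.0, 2.0)) == pytest.approx([0.0])
        assert compute_ndr(mask, (2.0, 2.0)) == pytest.approx([1.0])

    def test_ndr_multiset_is_exactly_k_over_n(self):
        morpho = _disc_morpho(radius=5)
        mask = morpho > 0
        n = int(mask.sum())
        ndr = compute_ndr(mask, cell_center(_map_from_morpho(morpho), mask))
        assert sorted(ndr) == pytest.approx([k / n for k in range(1, n + 1)])

    def test_nd_ndr_rank_consistent(self, rng):
        # random mask: ordering by ND must equal ordering by NDR when
        # distances are distinct
        mask = rng.random((15, 15)) < 0.4
        mask[7, 7] = True
        center = (7.0 + rng.random() * 0.01, 7.0 + rng.random() * 0.01)
        nd = compute_nd(mask, center)
        ndr = compute_ndr(mask, center)
        assert len(set(np.round(nd, 12))) == len(nd)  # distinct distances
        assert np.array_equal(np.argsort(nd), np.argsort(ndr))

    def test_rotation_by_90_degrees_preserves_nd(self):
        morpho = _disc_morpho(center=(8, 11), radius=5)
        morpho[4, 9] = 6000.0  # break symmetry
        mask = morpho > 0
        center = cell_center(_map_from_morpho(morpho), mask)
        nd = compute_nd(mask, center)

        morpho_r = np.rot90(morpho)
        mask_r = morpho_r > 0
        center_r = cell_center(_map_from_morpho(morpho_r), mask_r)
        nd_r = compute_nd(mask_r, center_r)
        assert sorted(nd_r) == pytest.approx(sorted(nd))

        ndr = compute_ndr(mask, center)
        ndr_r = compute_ndr(mask_r, center_r)
        assert sorted(ndr_r) == pytest.approx(sorted(ndr))


class TestPixelTable:
    def test_record_count_is_sum_of_mask_sizes(self):
        maps = [
            _map_from_morpho(_disc_morpho(radius=r), cell_id=f"c{r}")
            for r in (4, 5, 6)
        ]
        for m in maps:
            m.mask = segment_cell(m)
        table = build_pixel_table(maps)
        assert len(table) == sum(m.mask.sum() for m in maps)
        assert set(table["cell_id"]) == {"c4", "c5", "c6"}

    def test_empty_input_gives_empty_table(self):
        table = build_pixel_table([])
        assert len(table) == 0
        assert "Category" in table.columns

    def test_flagged_pixels_reduce_the_count(self):
        morpho = _disc_morpho()
        clean = _map_from_morpho(morpho)
        clean.mask = segment_cell(clean)
        n_clean = len(build_pixel_table([clean]))

        valid = np.ones_like(morpho, dtype=bool)
        flagged_rows = [(10, 10), (10, 11), (9, 10), (11, 10), (10, 9)]
        for r, c in flagged_rows:
            valid[r, c] = False
        dirty = _map_from_morpho(morpho, valid=valid)
        dirty.mask = segment_cell(dirty)
        assert len(build_pixel_table([dirty])) == n_clean - len(flagged_rows)

    def test_round_trip_preserves_six_significant_digits(self, tmp_path, rng):
        nmap = _map_from_morpho(_disc_morpho())
        nmap.channels["MechL"] += rng.random(nmap.grid_shape) * 100
        nmap.mask = segment_cell(nmap)
        table = build_pixel_table([nmap])
        path = tmp_path / "table.csv"
        write_pixel_table(table, path, provenance=True)
        back = read_pixel_table(path)
        for col in ("Adh", "MechH", "MechL", "Morpho", "ND", "NDR"):
            np.testing.assert_allclose(back[col], table[col], rtol=1e-6)
        assert (back["Category"] == table["Category"]).all()


class TestSplit:
    def test_ten_cells_split_6_2_2(self):
        ids = [f"c{i}" for i in range(10)]
        train, val, test = split_by_cell(ids, seed=1)
        assert (len(train), len(val), len(test)) == (6, 2, 2)

    def test_same_seed_same_split(self):
        ids = [f"c{i}" for i in range(17)]
        assert split_by_cell(ids, seed=9) == split_by_cell(ids, seed=9)

    def test_partition_property(self):
        ids = [f"c{i}" for i in range(90)]
        train, val, test = split_by_cell(ids, seed=4)
        assert sorted(train + val + test) == sorted(ids)
        assert not (set(train) & set(val) | set(train) & set(test)
                    | set(val) & set(test))

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError):
            split_by_cell(["a", "b"], seed=0)


class TestNormalizer:
    def _table(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            rng.uniform(1.0, 9.0, size=(40, 6)),
            columns=["Adh", "MechH", "MechL", "Morpho", "ND", "NDR"],
        )
        frame["Category"] = "M0"
        return frame

    def test_training_extremes_map_to_plus_minus_one(self):
        table = self._table()
        norm = fit_normalizer(table)
        out = norm.transform(table)
        for col in ("Adh", "MechH", "MechL", "Morpho", "ND", "NDR"):
            assert out[col].min() == pytest.approx(-1.0)
            assert out[col].max() == pytest.approx(1.0)

    def test_midpoint_maps_to_zero(self):
        table = self._table()
        norm = fit_normalizer(table)
        mid = table.iloc[:1].copy()
        for col in norm.minima:
            mid[col] = (norm.minima[col] + norm.maxima[col]) / 2.0
        assert np.allclose(norm.transform(mid)[list(norm.minima)], 0.0)

    def test_out_of_range_values_extrapolate_unclipped(self):
        table = self._table()
        norm = fit_normalizer(table)
        probe_row = table.iloc[:1].copy()
        probe_row["Adh"] = norm.maxima["Adh"] + 1.0
        assert norm.transform(probe_row)["Adh"].iloc[0] > 1.0

    def test_constant_feature_error_names_it(self):
        table = self._table()
        table["NDR"] = 0.5
        with pytest.raises(ValueError, match="NDR"):
            fit_normalizer(table)

    def test_json_round_trip(self):
        from nanovote.mapbuild import Normalizer

        norm = fit_normalizer(self._table())
        back = Normalizer.from_json(norm.to_json())
        assert back.minima == norm.minima and back.maxima == norm.maxima
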