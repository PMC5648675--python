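import numpy as np
import pytest

import chromaderm as cd
from chromaderm.tem_morphometrics import (
    DEFAULT_CLASS_MAP as CM,
    IRIDOPHORE_CLASSES,
    LabeledMicrograph,
    depth_profile,
    extract_transects,
    median_iridophore_proportion,
    morphometry_table,
    platelet_area_fraction,
)
from conftest import random_label_mask


def make_band_mask(band_rows=None, h=60, w=50, px=0.5, epi=4):
    """Dermis of collagen with an optional full-width iridophore row band."""
    labels = np.full((h, w), CM["xanthophore_or_collagen"], dtype=np.uint8)
    labels[:epi, :] = CM["epidermis"]
    if band_rows is not None:
        labels[band_rows[0]:band_rows[1], :] = CM["iridophore"]
    return LabeledMicrograph(labels=labels, pixel_size_um=px,
                             epidermis_boundary=np.full(w, epi, dtype=int))


def brute_force_transects(mask, depth_um=15.0, spacing_um=5.0):
    """Pure-python per-pixel transect counting, independent of the library path."""
    px = mask.pixel_size_um
    depth_px = int(round(depth_um / px))
    step = max(int(round(spacing_um / px)), 1)
    irid_codes = {mask.class_map[n] for n in IRIDOPHORE_CLASSES}
    bg = mask.class_map["background"]
    out = {}
    for x in range(0, mask.labels.shape[1], step):
        b = mask.epidermis_boundary[x]
        if b < 0 or b + depth_px > mask.labels.shape[0]:
            continue
        hit_bg = False
        count = 0
        for r in range(b, b + depth_px):
            v = int(mask.labels[r, x])
            if v == bg:
                hit_bg = True
                break
            if v in irid_codes:
                count += 1
        if not hit_bg:
            out[x] = count / depth_px
    return out


class TestTransects:
    def test_full_band_gives_proportion_one(self):
        # iridophore occupies the whole 15-um window below the epidermis
        m = make_band_mask(band_rows=(4, 34))  # 30 rows * 0.5 um = 15 um
        tr = extract_transects(m)
        assert np.allclose(tr.proportions, 1.0)

    def test_no_iridophores_gives_zero(self):
        tr = extract_transects(make_band_mask(None))
        assert np.allclose(tr.proportions, 0.0)

    def test_matches_brute_force_on_random_masks(self):
        for seed in range(5):
            m = random_label_mask(seed)
            tr = extract_transects(m)
            oracle = brute_force_transects(m)
            assert set(tr.columns_px.tolist()) == set(oracle)
            for x, p in zip(tr.columns_px, tr.proportions):
                assert p == oracle[x]

    def test_partial_depth_transects_dropped(self):
        m = make_band_mask(None, h=20)  # only 8 um below the epidermis
        with pytest.raises(ValueError, match="no valid transect"):
            extract_transects(m)

    def test_pixel_size_invariance_under_integer_upscale(self):
        m = random_label_mask(3)
        tr = extract_transects(m)
        up = LabeledMicrograph(labels=np.kron(m.labels, np.ones((2, 2), np.uint8)),
                               pixel_size_um=m.pixel_size_um / 2,
                               epidermis_boundary=np.repeat(
                                   m.epidermis_boundary * 2, 2))
        tr2 = extract_transects(up)
        # same physical transect positions, identical proportions
        assert np.allclose(tr2.positions_um, tr.positions_um)
        assert np.array_equal(tr2.proportions, tr.proportions)


class TestMedian:
    def test_odd_count(self):
        tr = cd.TransectSet(np.arange(3), np.arange(3) * 5.0,
                            np.array([0.2, 0.4, 0.6]), 15.0, 5.0)
        assert median_iridophore_proportion(tr) == 0.4

    def test_even_count_mean_of_central_pair(self):
        tr = cd.TransectSet(np.arange(2), np.arange(2) * 5.0,
                            np.array([0.2, 0.4]), 15.0, 5.0)
        assert median_iridophore_proportion(tr) == pytest.approx(0.3)

    def test_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(9)
        props = rng.uniform(0, 1, size=25)
        tr = cd.TransectSet(np.arange(25), np.arange(25) * 5.0, props, 15.0, 5.0)
        s = sorted(props)
        assert median_iridophore_proportion(tr) == s[12]

    def test_empty_set_rejected(self):
        tr = cd.TransectSet(np.array([], int), np.array([]), np.array([]),
                            15.0, 5.0)
        with pytest.raises(ValueError):
            median_iridophore_proportion(tr)


class TestDepthProfile:
    def test_band_construction(self):
        # full-width band at 6-9 um below the epidermis
        m = make_band_mask(band_rows=(4 + 12, 4 + 18))  # rows in px, 0.5 um/px
        prof = depth_profile(m)
        inside = (prof["depth_um"] >= 6.25) & (prof["depth_um"] <= 8.75)
        assert np.allclose(prof.loc[inside, "prevalence"], 1.0)
        assert np.allclose(prof.loc[~inside, "prevalence"], 0.0)
        assert 6.0 <= prof.attrs["peak_depth_um"] <= 9.0

    def test_empty_mask_profile(self):
        prof = depth_profile(make_band_mask(None))
        assert np.allclose(prof["prevalence"], 0.0)
        assert np.isnan(prof.attrs["peak_depth_um"])

    def test_matches_brute_force_at_random_depths(self):
        m = random_label_mask(11)
        prof = depth_profile(m)
        oracle_cols = sorted(brute_force_transects(m))
        irid_codes = {m.class_map[n] for n in IRIDOPHORE_CLASSES}
        rng = np.random.default_rng(0)
        for k in rng.integers(0, len(prof), size=10):
            hits = sum(int(m.labels[m.epidermis_boundary[x] + k, x]) in irid_codes
                       for x in oracle_cols)
            assert prof["prevalence"].iloc[int(k)] == hits / len(oracle_cols)
        assert prof["prevalence"].between(0, 1).all()


class TestPlateletPlots:
    def test_pure_platelet_plot_is_one(self):
        labels = np.full((40, 40), CM["platelet"], dtype=np.uint8)
        m = LabeledMicrograph(labels=labels, pixel_size_um=0.1,
                              epidermis_boundary=np.zeros(40, int))
        grid, med = platelet_area_fraction(m, plot_size_um=1.0, n_plots=4, seed=0)
        assert med == 1.0
        assert np.allclose(grid.fractions, 1.0)

    def test_half_platelet_half_cytoplasm(self):
        # one 10x10 px iridophore block, left half platelet: any plot
        # spanning the block is exactly half platelet
        labels = np.full((10, 10), CM["iridophore"], dtype=np.uint8)
        labels[:, :5] = CM["platelet"]
        m = LabeledMicrograph(labels=labels, pixel_size_um=0.1,
                              epidermis_boundary=np.zeros(10, int))
        grid, med = platelet_area_fraction(m, plot_size_um=1.0, n_plots=1, seed=0)
        assert med == pytest.approx(0.5)

    def test_holes_count_as_platelet(self):
        labels = np.full((10, 10), CM["iridophore"], dtype=np.uint8)
        labels[:, :3] = CM["platelet"]
        labels[:, 3:5] = CM["platelet_hole"]
        m = LabeledMicrograph(labels=labels, pixel_size_um=0.1,
                              epidermis_boundary=np.zeros(10, int))
        _, med = platelet_area_fraction(m, plot_size_um=1.0, n_plots=1, seed=0)
        assert med == pytest.approx(0.5)

    def test_plots_nonoverlapping_and_inside_iridophores(self, small_micrograph):
        m = small_micrograph["micrograph"]
        grid, _ = platelet_area_fraction(m, n_plots=20, seed=4)
        s = grid.plot_size_px
        inside = np.isin(m.labels, m.codes(IRIDOPHORE_CLASSES))
        for i, (r, c) in enumerate(grid.top_left_px):
            assert inside[r:r + s, c:c + s].all()
            for r2, c2 in grid.top_left_px[i + 1:]:
                assert abs(r - r2) >= s or abs(c - c2) >= s

    def test_warns_when_fewer_plots_fit(self):
        labels = np.full((12, 12), CM["cytoplasm"], dtype=np.uint8)
        labels[1:11, 1:11] = CM["iridophore"]
        m = LabeledMicrograph(labels=labels, pixel_size_um=0.1,
                              epidermis_boundary=np.zeros(12, int))
        with pytest.warns(UserWarning, match="requested plots"):
            platelet_area_fraction(m, plot_size_um=1.0, n_plots=100, seed=0)

    def test_no_room_for_plot_rejected(self):
        labels = np.full((10, 10), CM["cytoplasm"], dtype=np.uint8)
        m = LabeledMicrograph(labels=labels, pixel_size_um=0.1,
                              epidermis_boundary=np.zeros(10, int))
        with pytest.raises(ValueError):
            platelet_area_fraction(m, plot_size_um=1.0, n_plots=5, seed=0)


class TestMorphometryTable:
    @staticmethod
    def _sample(i, color="orange", n_tr=20):
        tr = cd.TransectSet(np.arange(n_tr), np.arange(n_tr) * 5.0,
                            np.linspace(0, 1, n_tr), 15.0, 5.0)
        pg = cd.PlotGrid(np.zeros((25, 2), int), 10, 1.0,
                         np.linspace(0.2, 0.6, 25))
        return {"id": f"L{i:02d}", "skin_color": color, "transects": tr,
                "plots": pg}

    def test_study_sized_table(self):
        # 24 samples over 13 individuals (7 orange, 8 yellow, 4 dark gray,
        # 5 cream), ids reused where individuals contributed several samples
        colors = (["orange"] * 7 + ["yellow"] * 8 + ["dark_gray"] * 4
                  + ["cream"] * 5)
        samples = [self._sample(i % 13, c) for i, c in enumerate(colors)]
        df = morphometry_table(samples)
        assert len(df) == 24
        assert df["id"].nunique() == 13

    def test_single_sample_single_row(self):
        assert len(morphometry_table([self._sample(1)])) == 1

    def test_transect_counts_in_study_range(self, small_micrograph):
        tr = cd.extract_transects(small_micrograph["micrograph"])
        grid, _ = platelet_area_fraction(small_micrograph["micrograph"],
                                         n_plots=25, seed=0)
        df = morphometry_table([{"id": "L01", "skin_color": "yellow",
                                 "transects": tr, "plots": grid}])
        assert 1 <= df["n_transects"].iloc[0] <= 36

    def test_missing_id_rejected(self):
        s = self._sample(1)
        s["id"] = None
        with pytest.raises(ValueError, match="ID"):
            morphometry_table([s])

    def test_unknown_color_rejected(self):
        s = self._sample(1, color="blue")
        with pytest.raises(ValueError, match="skin color"):
            morphometry_table([s])
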