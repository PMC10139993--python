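"""Synthetic cell images and their quantification."""

import numpy as np
import pytest

from simpull.imagequant import (
    CellMeasurement,
    SegmentationParams,
    localization_ratio,
    measure_image,
    quantify_granules,
    segment_cells_and_nuclei,
    summarize_cells,
)
from simpull.synthetic import (
    CellSpec,
    GranuleSpec,
    SyntheticImageSpec,
    simulate_cell_image,
    write_image,
)


def one_cell_spec(f=0.5, granules=(), noise_sd=0.0, seed=0):
    cell = CellSpec(center=(64, 64), nuclear_signal_fraction=f, granules=granules)
    return SyntheticImageSpec(shape=(128, 128), cells=(cell,), noise_sd=noise_sd, seed=seed)


class TestGenerator:
    def test_all_signal_nuclear_when_fraction_one(self):
        img = simulate_cell_image(one_cell_spec(f=1.0))
        gfp = img.gfp_channel - img.spec.background_offset
        outside_nucleus = gfp[(img.nucleus_labels == 0)]
        assert np.allclose(outside_nucleus, 0.0)

    def test_analytic_granule_area(self):
        g = GranuleSpec(center=(64, 74), radius=5)
        img = simulate_cell_image(one_cell_spec(granules=(g,)))
        assert img.granule_areas_um2[1][0] == pytest.approx(np.pi * 1.25**2)

    def test_integrated_signal_split_matches_fraction(self):
        img = simulate_cell_image(one_cell_spec(f=0.5))
        gfp = img.gfp_channel - img.spec.background_offset
        nuc = gfp[img.nucleus_labels == 1].sum()
        tot = gfp[img.cell_labels == 1].sum()
        assert nuc / tot == pytest.approx(0.5, abs=1e-9)
        assert img.nuclear_fractions[1] == pytest.approx(0.5, abs=1e-9)

    def test_total_intensity_conserved(self):
        img = simulate_cell_image(one_cell_spec(f=0.3))
        gfp = img.gfp_channel - img.spec.background_offset
        assert gfp.sum() == pytest.approx(2.0e6, rel=1e-9)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            CellSpec(center=(64, 64), nucleus_axes=(40, 40))  # nucleus > cell
        with pytest.raises(ValueError):
            CellSpec(center=(64, 64), granules=(GranuleSpec(center=(5, 5), radius=3),))
        with pytest.raises(ValueError):
            GranuleSpec(center=(0, 0), radius=0)

    def test_same_seed_bit_identical(self):
        a = simulate_cell_image(one_cell_spec(noise_sd=5.0, seed=4))
        b = simulate_cell_image(one_cell_spec(noise_sd=5.0, seed=4))
        assert np.array_equal(a.gfp_channel, b.gfp_channel)

    def test_tiff_roundtrip(self, tmp_path):
        import tifffile

        img = simulate_cell_image(one_cell_spec(noise_sd=5.0))
        paths = write_image(img, tmp_path)
        stack = tifffile.imread(paths["image"])
        assert stack.shape == (2, 128, 128)
        assert stack.dtype == np.uint16
        labels = tifffile.imread(paths["cell_labels"])
        assert np.array_equal(labels > 0, img.cell_labels > 0)


class TestSegmentation:
    def test_three_separated_cells_found(self):
        cells = tuple(
            CellSpec(center=c, nuclear_signal_fraction=0.5)
            for c in ((50, 50), (50, 160), (160, 105))
        )
        spec = SyntheticImageSpec(shape=(220, 220), cells=cells, noise_sd=5.0, seed=1)
        img = simulate_cell_image(spec)
        cell_l, nuc_l = segment_cells_and_nuclei(img.nuclear_channel, img.gfp_channel)
        assert cell_l.max() == 3 and nuc_l.max() == 3
        for lab in (1, 2, 3):
            assert np.all(cell_l[nuc_l == lab] == lab)  # nucleus inside its cell

    def test_blank_image_yields_no_cells(self):
        blank = np.full((64, 64), 100.0)
        cell_l, nuc_l = segment_cells_and_nuclei(blank, blank)
        assert cell_l.max() == 0 and nuc_l.max() == 0

    def test_mask_recovery_jaccard(self):
        # noise at 2% of the mean within-cell signal
        img = simulate_cell_image(one_cell_spec(f=0.5, noise_sd=19.0, seed=2))
        cell_l, nuc_l = segment_cells_and_nuclei(img.nuclear_channel, img.gfp_channel)
        for rec, truth in ((cell_l == 1, img.cell_labels == 1), (nuc_l == 1, img.nucleus_labels == 1)):
            jac = (rec & truth).sum() / (rec | truth).sum()
            assert jac >= 0.9

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            segment_cells_and_nuclei(np.ones((10, 10)), np.ones((12, 12)))


class TestLocalization:
    def test_all_nuclear_gives_fraction_one(self):
        img = simulate_cell_image(one_cell_spec(f=1.0))
        m = localization_ratio(
            img.cell_labels == 1, img.nucleus_labels == 1, img.gfp_channel
        )
        assert m.nuclear_fraction == pytest.approx(1.0, abs=1e-6)
        assert m.cytosolic_fraction == pytest.approx(0.0, abs=1e-6)

    def test_half_nuclear_recovered_noiseless(self):
        img = simulate_cell_image(one_cell_spec(f=0.5))
        m = localization_ratio(
            img.cell_labels == 1, img.nucleus_labels == 1, img.gfp_channel
        )
        assert m.nuclear_fraction == pytest.approx(0.5, abs=0.02)

    def test_fractions_sum_to_one(self):
        for f in (0.2, 0.5, 0.8):
            img = simulate_cell_image(one_cell_spec(f=f, noise_sd=10.0, seed=3))
            for m in measure_image(img.nuclear_channel, img.gfp_channel):
                assert m.nuclear_fraction + m.cytosolic_fraction == pytest.approx(1.0, abs=1e-6)

    def test_zero_signal_flagged_undefined(self):
        gfp = np.zeros((40, 40))
        cmask = np.zeros((40, 40), bool)
        cmask[10:20, 10:20] = True
        nmask = np.zeros_like(cmask)
        nmask[12:16, 12:16] = True
        m = localization_ratio(cmask, nmask, gfp)
        assert m.undefined

    def test_nucleus_must_be_inside_cell(self):
        cmask = np.zeros((20, 20), bool)
        cmask[:10] = True
        nmask = ~cmask
        with pytest.raises(ValueError):
            localization_ratio(cmask, nmask, np.ones((20, 20)))


class TestGranules:
    def test_uniform_cell_has_no_granules(self):
        img = simulate_cell_image(one_cell_spec(f=0.5, noise_sd=10.0, seed=5))
        areas, has = quantify_granules(
            img.cell_labels == 1, img.gfp_channel, nucleus_mask=img.nucleus_labels == 1
        )
        assert areas == [] and not has

    def test_single_disk_area_within_15pct(self):
        g = GranuleSpec(center=(64, 78), radius=5, amplification=10)
        img = simulate_cell_image(one_cell_spec(granules=(g,), noise_sd=5.0, seed=6))
        areas, has = quantify_granules(
            img.cell_labels == 1, img.gfp_channel, nucleus_mask=img.nucleus_labels == 1
        )
        assert has and len(areas) == 1
        assert areas[0] == pytest.approx(np.pi * 1.25**2, rel=0.15)

    def test_two_disjoint_granules_counted(self):
        gs = (
            GranuleSpec(center=(54, 76), radius=4),
            GranuleSpec(center=(76, 68), radius=4),
        )
        img = simulate_cell_image(one_cell_spec(granules=gs, noise_sd=5.0, seed=7))
        areas, _ = quantify_granules(
            img.cell_labels == 1, img.gfp_channel, nucleus_mask=img.nucleus_labels == 1
        )
        assert len(areas) == 2

    def test_area_invariant_to_intensity_rescaling(self):
        g = GranuleSpec(center=(64, 78), radius=5)
        img = simulate_cell_image(one_cell_spec(granules=(g,), noise_sd=2.0, seed=8))
        a1, _ = quantify_granules(img.cell_labels == 1, img.gfp_channel,
                                  nucleus_mask=img.nucleus_labels == 1)
        a2, _ = quantify_granules(img.cell_labels == 1, img.gfp_channel * 7.5,
                                  nucleus_mask=img.nucleus_labels == 1)
        assert a1 == a2

    def test_nuclear_concentration_is_not_a_granule(self):
        # nuclear/cytosolic intensity ratio ~16 at f=0.8 must not trip detection
        img = simulate_cell_image(one_cell_spec(f=0.8, noise_sd=10.0, seed=9))
        _, has = quantify_granules(
            img.cell_labels == 1, img.gfp_channel, nucleus_mask=img.nucleus_labels == 1
        )
        assert not has


class TestSummaries:
    def test_granule_positive_percentage(self):
        ms = [
            CellMeasurement(cell_id=i, nuclear_fraction=0.5, cytosolic_fraction=0.5,
                            granule_areas=(2.0,) if i < 4 else (), has_granules=i < 4)
            for i in range(10)
        ]
        table = summarize_cells(ms)
        assert table.loc[0, "pct_granule_positive"] == pytest.approx(40.0)
        assert table.loc[0, "n_cells"] == 10

    def test_identical_cells_have_zero_sem(self):
        ms = [
            CellMeasurement(cell_id=i, nuclear_fraction=0.6, cytosolic_fraction=0.4)
            for i in range(5)
        ]
        table = summarize_cells(ms)
        assert table.loc[0, "sem_nuclear_fraction"] == pytest.approx(0.0)

    def test_grouping_splits_rows(self):
        ms = [
            CellMeasurement(cell_id=i, nuclear_fraction=0.5, cytosolic_fraction=0.5)
            for i in range(4)
        ]
        table = summarize_cells(ms, grouping={0: "wt", 1: "wt", 2: "mut", 3: "mut"})
        assert set(table["group"]) == {"wt", "mut"}

    def test_known_granule_positive_rate_recovered(self):
        rng = np.random.default_rng(10)
        ms = []
        n, rate = 200, 0.30
        for i in range(n):
            positive = rng.random() < rate
            g = GranuleSpec(center=(64, 76), radius=4) if positive else None
            spec = one_cell_spec(granules=(g,) if g else (), noise_sd=10.0,
                                 seed=int(rng.integers(2**31)))
            img = simulate_cell_image(spec)
            cm = measure_image(img.nuclear_channel, img.gfp_channel)
            assert len(cm) == 1
            ms.append(cm[0])
        table = summarize_cells(ms)
        observed = table.loc[0, "pct_granule_positive"] / 100.0
        assert abs(observed - rate) < 1.96 * np.sqrt(rate * (1 - rate) / n) + 0.02
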