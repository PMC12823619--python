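"""TPEF preprocessing and Aggregation Index metrics."""

import numpy as np
import pytest

from senometrix import tpef
from senometrix.containers import CellLabelMask
from senometrix.synthetic import TpefSimConfig, simulate_tpef_image


def brute_force_median(img, r, c, window=3):
    half = window // 2
    padded = np.pad(img, half, mode="edge")
    block = padded[r : r + window, c : c + window]
    return float(np.median(sorted(block.ravel())))


class TestRemoveOutliers:
    def test_single_bright_outlier_on_constant(self):
        img = np.full((15, 15), 2.0)
        img[7, 7] = 200.0
        out = tpef.remove_outliers(img)
        assert out[7, 7] == 2.0
        mask = np.ones_like(img, dtype=bool)
        mask[7, 7] = False
        assert np.array_equal(out[mask], img[mask])

    def test_dark_outlier_removed_too(self):
        img = np.full((15, 15), 5.0)
        img[3, 4] = 0.0
        out = tpef.remove_outliers(img)
        assert out[3, 4] == 5.0

    def test_identity_on_clean_image(self, rng):
        # smooth field: no pixel satisfies the outlier criterion
        x = np.linspace(0, 2 * np.pi, 40)
        img = 1.5 + np.sin(x)[:, None] * np.cos(x)[None, :]
        assert np.array_equal(tpef.remove_outliers(img), img)

    def test_flagged_set_and_replacement_match_oracle(self, rng):
        x = np.linspace(0, 3 * np.pi, 60)
        img = 2.0 + np.sin(x)[:, None] * np.cos(x)[None, :]
        positions = [(10, 10), (25, 40), (44, 7), (50, 50)]
        for i, (r, c) in enumerate(positions):
            img[r, c] = 100.0 if i % 2 == 0 else -50.0
        flags = tpef.detect_outliers(img)
        expected = np.zeros_like(flags)
        for r, c in positions:
            expected[r, c] = True
        assert np.array_equal(flags, expected)
        out = tpef.remove_outliers(img)
        for r, c in positions:
            assert out[r, c] == pytest.approx(brute_force_median(img, r, c))

    def test_idempotent(self):
        img = np.full((20, 20), 1.0)
        for r, c in [(5, 5), (12, 3), (17, 17)]:
            img[r, c] = 99.0
        once = tpef.remove_outliers(img)
        assert np.array_equal(tpef.remove_outliers(once), once)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            tpef.remove_outliers(np.ones((5, 5)), window=4)


class TestDeskew:
    @staticmethod
    def smooth_field(h=40, w=64):
        x = np.linspace(0, 4 * np.pi, w)
        y = np.linspace(0, 2 * np.pi, h)
        return 1 + np.sin(x)[None, :] * (1.2 + np.cos(y))[:, None]

    @pytest.mark.parametrize("shift", [-5, -3, 0, 3, 5])
    def test_injected_shift_recovered_and_inverted(self, shift):
        base = self.smooth_field()
        distorted = base.copy()
        distorted[1::2] = np.roll(distorted[1::2], shift, axis=1)
        res = tpef.deskew_serpentine(distorted, max_shift=8)
        assert res.shift == -shift
        assert np.array_equal(res.image, base)
        assert not res.degenerate

    def test_roundtrip_is_bit_exact(self):
        rng = np.random.default_rng(0)
        img = rng.random((30, 48))
        res = tpef.deskew_serpentine(img, max_shift=5)
        redone = res.image.copy()
        redone[1::2] = np.roll(redone[1::2], -res.shift, axis=1)
        assert np.array_equal(redone, img)

    def test_constant_image_degenerate(self):
        res = tpef.deskew_serpentine(np.full((10, 40), 3.0), max_shift=5)
        assert res.shift == 0
        assert res.degenerate

    def test_tie_breaks_toward_small_then_negative(self):
        # columns periodic with period 2 and odd rows offset by 1:
        # shifts -1 and +1 align equally well; the negative one wins
        row = np.tile([0.0, 1.0], 20)
        img = np.vstack([row, np.roll(row, 1)] * 5)
        res = tpef.deskew_serpentine(img, max_shift=4)
        assert res.shift == -1


class TestThresholdAndMetrics:
    def test_uniform_cell_above_threshold(self, square_cell_mask):
        img = np.full((20, 20), 0.30)
        rec = tpef.cell_records(img, square_cell_mask)
        assert rec.loc[0, "area_fraction_pct"] == 100.0
        assert rec.loc[0, "flag"] == ""

    def test_uniform_cell_below_threshold_flagged(self, square_cell_mask):
        img = np.full((20, 20), 0.10)
        rec = tpef.cell_records(img, square_cell_mask)
        assert rec.loc[0, "flag"] == "no_signal"
        assert np.isnan(rec.loc[0, "aggregation_index"])

    def test_half_covered_cell(self, square_cell_mask):
        img = np.full((20, 20), 0.20)
        img[:10] = 0.30  # upper half of the 10x10 cell box
        rec = tpef.cell_records(img, square_cell_mask)
        assert rec.loc[0, "area_fraction_pct"] == pytest.approx(50.0)

    def test_max_tpef_definition(self):
        assert tpef.max_tpef(np.arange(1.0, 11.0)) == 10.0
        assert tpef.max_tpef(np.full(25, 3.3)) == pytest.approx(3.3)

    def test_max_tpef_matches_sort_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 500))
            v = rng.gamma(2.0, 1.0, n)
            k = int(np.ceil(0.1 * n))
            assert tpef.max_tpef(v) == pytest.approx(np.mean(np.sort(v)[-k:]))

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError):
            tpef.max_tpef(np.ones(5))

    @pytest.mark.parametrize("mt, frac, ai", [(1.0, 50.0, 0.02), (0.8, 100.0, 0.008)])
    def test_aggregation_index_arithmetic(self, mt, frac, ai):
        assert tpef.aggregation_index(mt, frac) == pytest.approx(ai)

    def test_zero_fraction_undefined(self):
        with pytest.raises(ValueError):
            tpef.aggregation_index(1.0, 0.0)


class TestAggregationInvariances:
    @staticmethod
    def records_for(img, labels):
        return tpef.cell_records(img, CellLabelMask(labels))

    def test_invariant_under_relabeling_and_translation(self):
        img = np.zeros((30, 30))
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[2:12, 2:12] = 1
        labels[16:26, 16:26] = 2
        img[labels > 0] = 0.3
        img[4, 4] = img[18, 18] = 2.0
        rec = self.records_for(img, labels)
        swapped = np.where(labels == 1, 2, np.where(labels == 2, 1, 0)).astype(np.int32)
        rec_swapped = self.records_for(img, swapped)
        assert sorted(rec["aggregation_index"]) == pytest.approx(
            sorted(rec_swapped["aggregation_index"])
        )
        rec_shift = self.records_for(np.roll(img, (3, 3), (0, 1)),
                                     np.roll(labels, (3, 3), (0, 1)))
        assert rec["aggregation_index"].tolist() == pytest.approx(
            rec_shift["aggregation_index"].tolist()
        )

    def test_not_invariant_under_intensity_rescaling(self):
        # the 0.25 a.u. threshold is absolute: doubling intensity changes
        # both the covered area and the max signal
        img = np.zeros((20, 20))
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        img[5:15, 5:15] = np.linspace(0.1, 0.6, 100).reshape(10, 10)
        rec1 = self.records_for(img, labels)
        rec2 = self.records_for(2 * img, labels)
        assert rec2.loc[0, "area_fraction_pct"] > rec1.loc[0, "area_fraction_pct"]
        assert rec2.loc[0, "max_tpef"] == pytest.approx(2 * rec1.loc[0, "max_tpef"])


class TestPipeline:
    def test_identical_groups_give_p_one(self, noiseless_tpef_cfg):
        image, mask, _ = simulate_tpef_image(noiseless_tpef_cfg)
        records, comps, _ = tpef.run_tpef_pipeline(
            [(image, mask, "a"), (image, mask, "b")]
        )
        assert (comps["p_two_sided"] == 1.0).all()

    def test_aggregated_vs_dispersed_significant(self):
        specs = []
        for agg, group, seed in [(1.0, "aggregated", 21), (0.2, "dispersed", 22)]:
            cfg = TpefSimConfig(image_size=(420, 420), n_cells=20,
                                aggregation=agg, seed=seed)
            img, mask, _ = simulate_tpef_image(cfg)
            specs.append((img, mask, group))
        records, comps, log = tpef.run_tpef_pipeline(specs)
        ai = comps[comps["metric"] == "aggregation_index"].iloc[0]
        assert ai["p_two_sided"] < 0.01
        med = records.groupby("group")["aggregation_index"].median()
        assert med["aggregated"] > med["dispersed"]

    def test_processing_order_logged(self, noiseless_tpef_cfg):
        image, mask, _ = simulate_tpef_image(noiseless_tpef_cfg)
        _, _, log = tpef.run_tpef_pipeline([(image, mask, "a"), (image, mask, "b")])
        img0 = [line for line in log if line.startswith("image 0")]
        assert "remove_outliers" in img0[0]
        assert "deskew" in img0[1]
        assert "threshold" in img0[2]


def test_segment_cells_recovers_simulated_count():
    cfg = TpefSimConfig(image_size=(200, 200), n_cells=4, aggregation=0.0,
                        background_sd=0.0, n_outliers=0, serpentine_shift=0,
                        seed=30)
    image, mask, _ = simulate_tpef_image(cfg)
    seg = tpef.segment_cells(image["tpef"])
    assert seg.n_cells == mask.n_cells
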