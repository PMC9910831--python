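"""Tests of segmentation, translocation-ratio measurement and responder calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from ifnfate.imaging import (
    CellMeasurement,
    SisterCriteria,
    SyntheticImageConfig,
    call_responders,
    find_sister_pairs,
    generate_image_set,
    measurements_to_frame,
    segment_and_measure,
    transfection_stats,
)


def _meas(cell_id, ratio, x=0.0, y=0.0, rho=np.nan):
    return CellMeasurement(
        cell_id=cell_id,
        x_um=x,
        y_um=y,
        nucleus_median_cfp=1000.0 * ratio,
        cytoplasm_median_cfp=1000.0,
        rhodamine_mean=rho,
        total_cfp_mean=1000.0,
    )


class TestSegmentAndMeasure:
    def test_six_cell_fixture_roundtrip(self):
        """Six planted cells are recovered with centroids within one cell
        radius of truth."""
        config = SyntheticImageConfig(
            width=400, height=400, n_cells=6, responder_fraction=0.5, seed=21
        )
        imgs = generate_image_set(config)
        ms = segment_and_measure(imgs.hoechst, imgs.cfp, imgs.rhodamine, imgs.um_per_px)
        assert len(ms) == 6
        truth_xy = imgs.truth[["x_um", "y_um"]].to_numpy()
        meas_xy = np.array([[m.x_um, m.y_um] for m in ms])
        d, _ = cKDTree(truth_xy).query(meas_xy)
        assert (d < config.cell_radius_um).all()

    def test_noiseless_planted_ratio_recovered(self):
        config = SyntheticImageConfig(
            width=400,
            height=400,
            n_cells=6,
            responder_fraction=1.0,
            responder_ratio_mean=1.25,
            responder_ratio_sd=0.0,
            irf7_heterogeneity_cv=0.0,
            background=0.0,
            read_noise_sd=0.0,
            seed=22,
        )
        imgs = generate_image_set(config)
        ms = segment_and_measure(imgs.hoechst, imgs.cfp, um_per_px=imgs.um_per_px)
        for m in ms:
            assert m.translocation_ratio == pytest.approx(1.25, abs=0.01)

    def test_blank_image_yields_empty_list(self):
        blank = np.zeros((64, 64))
        assert segment_and_measure(blank, blank) == []

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            segment_and_measure(np.zeros((10, 10)), np.zeros((12, 12)))

    def test_segmentation_count_error_below_two_percent(self, default_image_set):
        s = default_image_set
        ms = segment_and_measure(s.hoechst, s.cfp, s.rhodamine, s.um_per_px)
        assert abs(len(ms) - 500) / 500 <= 0.02

    def test_ratio_scale_invariance(self, default_image_set):
        """Multiplying the CFP channel by a constant leaves ratios unchanged."""
        s = default_image_set
        ms1 = segment_and_measure(s.hoechst, s.cfp.astype(float), um_per_px=s.um_per_px)
        ms2 = segment_and_measure(
            s.hoechst, 3.0 * s.cfp.astype(float), um_per_px=s.um_per_px
        )
        r1 = {m.cell_id: m.translocation_ratio for m in ms1}
        r2 = {m.cell_id: m.translocation_ratio for m in ms2}
        assert r1.keys() == r2.keys()
        for k in r1:
            assert r1[k] == pytest.approx(r2[k], rel=1e-9)


class TestCallResponders:
    def test_threshold_is_strict_greater(self):
        calls, fraction = call_responders(
            [_meas(1, 1.0), _meas(2, 1.1), _meas(3, 1.8)], ratio_threshold=1.3
        )
        assert [c.is_responder for c in calls] == [False, False, True]
        assert fraction == pytest.approx(1 / 3)

    def test_identity_ratio_never_a_responder(self):
        calls, _ = call_responders([_meas(1, 1.0)], ratio_threshold=1.0)
        assert not calls[0].is_responder

    def test_empty_input_reports_missing_fraction(self):
        calls, fraction = call_responders([])
        assert calls == [] and fraction is None

    def test_planted_fraction_recovery_within_one_point(self):
        """Called responder fraction on >=500-cell synthetic fields stays
        within one percentage point of the planted 2.2%."""
        for seed in (1, 2, 3):
            imgs = generate_image_set(SyntheticImageConfig(seed=seed))
            ms = segment_and_measure(
                imgs.hoechst, imgs.cfp, imgs.rhodamine, imgs.um_per_px
            )
            _, fraction = call_responders(ms, ratio_threshold=1.3)
            planted = imgs.truth["is_responder"].mean()
            assert abs(fraction - planted) <= 0.01


class TestTransfection:
    def test_threshold_is_max_of_controls(self):
        controls = [_meas(i, 1.0, rho=v) for i, v in enumerate([10.0, 12.0, 15.0])]
        sample = [_meas(i, 1.0, rho=v) for i, v in enumerate([14.0, 20.0, 30.0])]
        stats = transfection_stats(sample, controls)
        assert stats.threshold == 15.0
        assert stats.efficiency == pytest.approx(2 / 3)

    def test_all_below_threshold(self):
        controls = [_meas(1, 1.0, rho=50.0)]
        sample = [_meas(2, 1.0, rho=10.0), _meas(3, 1.0, rho=20.0)]
        assert transfection_stats(sample, controls).efficiency == 0.0

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            transfection_stats([_meas(1, 1.0, rho=1.0)], [])

    def test_planted_transfection_recovery(self, default_image_set):
        s = default_image_set
        ms = segment_and_measure(s.hoechst, s.cfp, s.rhodamine, s.um_per_px)
        ctrl_imgs = generate_image_set(
            SyntheticImageConfig(n_cells=100, transfected_fraction=0.0, seed=33)
        )
        ctrl = segment_and_measure(
            ctrl_imgs.hoechst, ctrl_imgs.cfp, ctrl_imgs.rhodamine, ctrl_imgs.um_per_px
        )
        stats = transfection_stats(ms, ctrl)
        assert stats.efficiency == pytest.approx(0.9, abs=0.03)


class TestSisterPairs:
    def _cells(self, rows):
        return pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "is_responder"])

    def test_close_pair_with_clear_corridor(self):
        cells = self._cells([(1, 0, 0, True), (2, 200, 0, True), (3, 100, 100, False)])
        res = find_sister_pairs(cells)
        assert len(res.pairs) == 1
        assert res.percent_responding_sisters == 100.0

    def test_distance_cap_excludes_far_pair(self):
        cells = self._cells([(1, 0, 0, True), (2, 400, 0, True)])
        assert find_sister_pairs(cells).pairs == ()

    def test_two_intervening_nonresponders_block_pair(self):
        cells = self._cells(
            [
                (1, 0, 0, True),
                (2, 250, 0, True),
                (3, 100, 0, False),
                (4, 150, 0, False),
            ]
        )
        res = find_sister_pairs(cells)
        assert res.pairs == ()
        assert res.percent_responding_sisters == 0.0

    def test_one_intervening_nonresponder_allowed(self):
        cells = self._cells([(1, 0, 0, True), (2, 250, 0, True), (3, 120, 0, False)])
        assert len(find_sister_pairs(cells).pairs) == 1

    def test_nonresponder_outside_corridor_ignored(self):
        crit = SisterCriteria(corridor_width_um=28.0)
        cells = self._cells(
            [
                (1, 0, 0, True),
                (2, 250, 0, True),
                (3, 100, 50.0, False),  # 50 um off-axis > half-width
                (4, 150, -40.0, False),
            ]
        )
        assert len(find_sister_pairs(cells, crit).pairs) == 1

    def test_greedy_pairing_no_double_counting(self):
        # three clustered responders: only one pair retained (closest)
        cells = self._cells(
            [(1, 0, 0, True), (2, 50, 0, True), (3, 120, 0, True)]
        )
        res = find_sister_pairs(cells)
        assert len(res.pairs) == 1
        assert {res.pairs[0][0], res.pairs[0][1]} == {1, 2}
        assert res.percent_responding_sisters == pytest.approx(100 * 2 / 3)

    def test_planted_pairs_recovered_from_synthetic_field(self):
        config = SyntheticImageConfig(
            n_cells=150, responder_fraction=0.2, sister_pair_fraction=0.6, seed=7
        )
        imgs = generate_image_set(config)
        cells = imgs.truth.rename(columns={"is_responder": "is_responder"})[
            ["cell_id", "x_um", "y_um", "is_responder"]
        ]
        res = find_sister_pairs(cells)
        n_planted_pairs = int(imgs.truth["pair_id"].max())
        assert len(res.pairs) >= n_planted_pairs  # planted duos all pairable


def test_measurements_to_frame_columns():
    ms = [_meas(1, 1.5, rho=10.0)]
    calls, _ = call_responders(ms, 1.3)
    frame = measurements_to_frame(ms, calls)
    assert {"cell_id", "x_um", "y_um", "ratio", "is_responder"} <= set(frame.columns)
    assert bool(frame.loc[0, "is_responder"])
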