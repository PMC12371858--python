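"""Voxel-wise mapping, T2' maps, ROI medians and interval summaries."""

import numpy as np
import pytest

from tvfmap import (
    CompartmentSet,
    LayerTimeCourse,
    MultiEchoImage,
    ParametricMap,
    ROILabels,
    compose_signal,
    fid_echo_amplitudes,
    get_preset,
    interval_summary,
    map_voxelwise,
    roi_median,
    t2prime_map,
)


def _uniform_image(protocol, decay, shape=(6, 5), mask=None):
    data = np.broadcast_to(decay, shape + (decay.size,)).copy()
    return MultiEchoImage(data=data, protocol=protocol, mask=mask)


class TestMapVoxelwise:
    def test_uniform_t2_image_gives_constant_map(self, short_te):
        te = short_te.echo_times_ms
        image = _uniform_image(short_te, np.exp(-te / 40.0))
        maps = map_voxelwise(image, "mono_t2")
        assert np.allclose(maps["t2"].values, 40.0, atol=1e-3)
        assert maps["t2"].valid.all()

    def test_uniform_tvf_image(self, short_te):
        sig = compose_signal(CompartmentSet.two_pool(42.6, 35.0, 150.0), short_te)
        image = _uniform_image(short_te, sig.amplitude)
        maps = map_voxelwise(image, "biexp_tvf")
        assert np.allclose(maps["tvf"].values, 42.6, atol=1e-3)
        assert np.allclose(maps["t2_short"].values, 35.0, atol=0.05)

    def test_t2star_on_mge(self):
        mge = get_preset("mge")
        image = _uniform_image(mge, fid_echo_amplitudes(12.0, mge))
        maps = map_voxelwise(image, "mono_t2star")
        assert np.allclose(maps["t2star"].values, 12.0, atol=1e-3)

    def test_out_of_mask_voxels_invalid(self, short_te):
        te = short_te.echo_times_ms
        mask = np.zeros((6, 5), dtype=bool)
        mask[2:4, 1:3] = True
        image = _uniform_image(short_te, np.exp(-te / 40.0), mask=mask)
        maps = map_voxelwise(image, "mono_t2")
        assert maps["t2"].valid.sum() == mask.sum()
        assert np.isnan(maps["t2"].values[~mask]).all()

    def test_model_protocol_mismatch_rejected(self, short_te):
        te = short_te.echo_times_ms
        image = _uniform_image(short_te, np.exp(-te / 40.0))
        with pytest.raises(ValueError):
            map_voxelwise(image, "mono_t2star")
        mge = get_preset("mge")
        with pytest.raises(ValueError):
            map_voxelwise(_uniform_image(mge, fid_echo_amplitudes(12.0, mge)), "biexp_tvf")

    def test_mapping_commutes_with_voxel_permutation(self, short_te, rng):
        te = short_te.echo_times_ms
        data = np.exp(-te[None, None, :] / rng.uniform(20, 120, size=(4, 4, 1)))
        data += rng.normal(0, 0.002, size=data.shape)
        image = MultiEchoImage(data=data, protocol=short_te)
        t2 = map_voxelwise(image, "mono_t2")["t2"].values
        perm = rng.permutation(16)
        shuffled = data.reshape(16, -1)[perm].reshape(4, 4, -1)
        t2_shuffled = map_voxelwise(MultiEchoImage(data=shuffled, protocol=short_te),
                                    "mono_t2")["t2"].values
        assert np.allclose(t2.reshape(16)[perm], t2_shuffled.reshape(16), atol=1e-9)

    def test_echo_dimension_must_match_protocol(self, short_te):
        with pytest.raises(ValueError):
            MultiEchoImage(data=np.ones((4, 4, 5)), protocol=short_te)


class TestT2PrimeMap:
    def test_constant_maps(self):
        t2 = ParametricMap(np.full((3, 3), 50.0), np.ones((3, 3), bool), "ms")
        t2s = ParametricMap(np.full((3, 3), 10.0), np.ones((3, 3), bool), "ms")
        result = t2prime_map(t2, t2s)
        assert np.allclose(result.values, 12.5)

    def test_nonphysical_voxels_marked_invalid(self):
        t2 = ParametricMap(np.array([[50.0, 30.0]]), np.ones((1, 2), bool), "ms")
        t2s = ParametricMap(np.array([[10.0, 35.0]]), np.ones((1, 2), bool), "ms")
        result = t2prime_map(t2, t2s)
        assert result.valid[0, 0] and not result.valid[0, 1]
        assert np.isnan(result.values[0, 1])

    def test_roundtrip_recovers_t2star(self, rng):
        t2_vals = rng.uniform(30, 120, size=(4, 4))
        t2s_vals = t2_vals * rng.uniform(0.2, 0.8, size=(4, 4))
        valid = np.ones((4, 4), bool)
        tp = t2prime_map(ParametricMap(t2_vals, valid, "ms"),
                         ParametricMap(t2s_vals, valid, "ms"))
        recon = 1.0 / (1.0 / t2_vals + 1.0 / tp.values)
        assert np.allclose(recon, t2s_vals, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        a = ParametricMap(np.ones((2, 2)), np.ones((2, 2), bool), "ms")
        b = ParametricMap(np.ones((3, 2)), np.ones((3, 2), bool), "ms")
        with pytest.raises(ValueError):
            t2prime_map(a, b)


class TestROIMedian:
    def test_single_label_median(self):
        values = np.array([[1.0, 2.0, 3.0, 0.0]])
        valid = np.array([[True, True, True, False]])
        labels = ROILabels(np.array([[1, 1, 1, 0]], dtype=np.int16))
        med = roi_median(ParametricMap(values, valid, "ms"), labels)
        assert med["cortex"] == 2.0
        assert np.isnan(med["outer_medulla"]) and np.isnan(med["inner_medulla"])

    def test_invalid_only_label_is_missing(self):
        values = np.array([[5.0, 5.0]])
        valid = np.array([[False, False]])
        labels = ROILabels(np.array([[2, 2]], dtype=np.int16))
        assert np.isnan(roi_median(ParametricMap(values, valid, "ms"), labels)["outer_medulla"])

    def test_median_invariant_under_region_duplication(self):
        vals = np.array([[1.0, 5.0, 9.0]])
        valid = np.ones((1, 3), bool)
        labels = ROILabels(np.full((1, 3), 3, dtype=np.int16))
        m1 = roi_median(ParametricMap(vals, valid, "ms"), labels)["inner_medulla"]
        vals2 = np.tile(vals, (2, 1))
        labels2 = ROILabels(np.full((2, 3), 3, dtype=np.int16))
        m2 = roi_median(ParametricMap(vals2, np.ones((2, 3), bool), "ms"), labels2)["inner_medulla"]
        assert m1 == m2

    def test_label_values_validated(self):
        with pytest.raises(ValueError):
            ROILabels(np.array([[7]], dtype=np.int16))


class TestIntervalSummary:
    def _tc(self, series_by_layer):
        return LayerTimeCourse(values=series_by_layer, baseline_idx=(0, 1, 2),
                               interval1_idx=(3, 4, 5, 6), interval2_idx=(7, 8, 9))

    def test_flat_series_gives_zero_change(self):
        tc = self._tc({"cortex": np.full(10, 30.0)})
        out = interval_summary(tc)["cortex"]
        assert out["interval1_mean_relative_change_percent"] == pytest.approx(0.0)
        assert out["interval2_mean_relative_change_percent"] == pytest.approx(0.0)

    def test_constructed_step_reproduces_percent_change(self):
        series = np.concatenate([np.full(3, 30.0), np.full(4, 39.33), np.full(3, 30.0)])
        out = interval_summary(self._tc({"cortex": series}))["cortex"]
        assert out["baseline_mean"] == pytest.approx(30.0)
        assert out["interval1_mean_relative_change_percent"] == pytest.approx(31.1, abs=0.01)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            interval_summary(self._tc({"cortex": np.concatenate([[0.0, 30.0, 30.0], np.ones(7)])}))

    def test_overlapping_index_sets_rejected(self):
        with pytest.raises(ValueError):
            LayerTimeCourse(values={"cortex": np.ones(10)}, baseline_idx=(0, 1),
                            interval1_idx=(1, 2), interval2_idx=(3,))
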