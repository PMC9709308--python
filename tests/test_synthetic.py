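import numpy as np
import pytest
from scipy.spatial.distance import cdist

from binloc.features import (BinauralCues, FeatureConfig,
                             assemble_measurement, extract_measurement,
                             resolve_bins)
from binloc.synthetic import (SceneConfig, corrupt_and_average,
                              generate_dataset, head_template,
                              reduced_training_subset, render_waveform)


def _template_vec(az, el, head, cfg):
    ild, ipd = head_template(az, el, head, cfg)
    cues = BinauralCues(ild_avg=ild, ipd_avg=np.exp(1j * ipd))
    return assemble_measurement(cues, cfg).values


class TestTemplates:
    def test_median_plane_symmetry(self, head, desk_cfg):
        ild, ipd = head_template(0.0, 0.0, head, desk_cfg)
        assert head.itd_seconds(0.0) == 0.0
        assert np.allclose(ipd, 0.0)
        freqs = desk_cfg.bin_freqs_hz
        far = np.abs(freqs - head.notch_center_hz) > 6 * head.notch_width_hz
        assert np.allclose(ild[far], 0.0, atol=1e-5)
        assert ild.min() < -0.5 * head.notch_depth_db  # notch present

    def test_left_right_mirror_of_azimuth_component(self, head, desk_cfg):
        for el in (-30.0, 0.0, 25.0):
            base_ild, _ = head_template(0.0, el, head, desk_cfg)
            pos_ild, pos_ipd = head_template(40.0, el, head, desk_cfg)
            neg_ild, neg_ipd = head_template(-40.0, el, head, desk_cfg)
            assert np.allclose(pos_ild - base_ild, -(neg_ild - base_ild))
            assert np.allclose(pos_ipd, -neg_ipd)

    def test_nearby_directions_are_closer(self, head, desk_cfg):
        for el in (-45.0, 0.0, 45.0):
            for base in np.arange(-90.0, 51.0, 20.0):
                near = np.linalg.norm(
                    _template_vec(base, el, head, desk_cfg)
                    - _template_vec(base + 2, el, head, desk_cfg))
                far = np.linalg.norm(
                    _template_vec(base, el, head, desk_cfg)
                    - _template_vec(base + 40, el, head, desk_cfg))
                assert near < far

    @pytest.mark.parametrize("axis", ["azimuth", "elevation"])
    def test_distance_monotone_along_grid_axis(self, head, desk_cfg, axis):
        """Template distance grows with separation walking outward along a
        grid axis (tolerance covers bin-sampling ripple of the notch)."""
        azs = np.arange(-90.0, 91.0, 15.0)
        els = np.arange(-45.0, 46.0, 15.0)
        outer, inner = (els, azs) if axis == "azimuth" else (azs, els)
        for fixed in outer:
            if axis == "azimuth":
                vecs = [_template_vec(v, fixed, head, desk_cfg) for v in azs]
            else:
                vecs = [_template_vec(fixed, v, head, desk_cfg) for v in els]
            n = len(vecs)
            for start in range(n):
                for sign in (1, -1):
                    seq = [np.linalg.norm(vecs[start] - vecs[j])
                           for j in range(start, n if sign > 0 else -1, sign)]
                    assert np.all(np.diff(seq) > -1e-2)


class TestCorruption:
    def test_clean_limit_recovers_template(self, head, desk_cfg):
        rng = np.random.default_rng(0)
        ild, ipd = head_template(30.0, 10.0, head, desk_cfg)
        cues = corrupt_and_average((ild, ipd), np.inf, 0.0, 5, rng,
                                   dft_size=desk_cfg.dft_size)
        assert np.allclose(cues.ild_avg, ild, atol=1e-10)
        assert np.allclose(np.angle(cues.ipd_avg), ipd, atol=1e-10)

    def test_reverberation_disperses_phasors(self, head, desk_cfg):
        rng = np.random.default_rng(1)
        tpl = head_template(30.0, 10.0, head, desk_cfg)
        cues = corrupt_and_average(tpl, np.inf, 0.6, 30, rng,
                                   dft_size=desk_cfg.dft_size)
        assert np.mean(np.abs(cues.ipd_avg)) < 1.0 - 1e-3

    def test_seeded_draws_identical(self, head, desk_cfg):
        tpl = head_template(-20.0, 0.0, head, desk_cfg)
        a = corrupt_and_average(tpl, 10.0, 0.4, 8,
                                np.random.default_rng(7),
                                dft_size=desk_cfg.dft_size)
        b = corrupt_and_average(tpl, 10.0, 0.4, 8,
                                np.random.default_rng(7),
                                dft_size=desk_cfg.dft_size)
        assert np.array_equal(a.ild_avg, b.ild_avg)
        assert np.array_equal(a.ipd_avg, b.ipd_avg)


class TestDatasets:
    def test_grid_cardinality_and_split(self):
        scene = SceneConfig(snr_db=np.inf, reverb_strength=0.0)
        ds = generate_dataset(scene)
        n = ds.train_features.shape[0] + ds.val_features.shape[0]
        assert n == 37 * 19 == 703
        assert ds.train_features.shape[0] == round(0.7 * 703)
        assert ds.test_features.shape[0] == 703

    def test_front_direction_cartesian_convention(self):
        scene = SceneConfig(azimuths_deg=(0.0,), elevations_deg=(0.0,),
                            snr_db=np.inf, reverb_strength=0.0)
        ds = generate_dataset(scene)
        row = ds.test_labels.iloc[0]
        assert np.allclose([row.x_m, row.y_m, row.z_m], [1.0, 0.0, 0.0])

    def test_regeneration_bit_identical(self):
        scene = SceneConfig(azimuths_deg=(-30.0, 0.0, 30.0),
                            elevations_deg=(0.0,), repeats=2,
                            condition_seed=5)
        d1, d2 = generate_dataset(scene), generate_dataset(scene)
        assert np.array_equal(d1.train_features, d2.train_features)
        assert np.array_equal(d1.test_features, d2.test_features)

    def test_clean_one_nn_identifiability(self, clean_coarse_ds):
        """On clean data every test vector's raw-space nearest neighbor in
        the full generated pool carries the exact grid label."""
        ds = clean_coarse_ds
        pool = np.vstack([ds.train_features, ds.val_features])
        az = np.concatenate([ds.train_labels["azimuth_deg"],
                             ds.val_labels["azimuth_deg"]])
        el = np.concatenate([ds.train_labels["elevation_deg"],
                             ds.val_labels["elevation_deg"]])
        nn = cdist(ds.test_features, pool).argmin(axis=1)
        assert np.array_equal(az[nn], ds.test_labels["azimuth_deg"])
        assert np.array_equal(el[nn], ds.test_labels["elevation_deg"])

    def test_reverberation_breaks_raw_neighborhoods(self, clean_coarse_ds,
                                                    reverb_coarse_ds):
        def mean_nn_error(ds):
            az = ds.train_labels["azimuth_deg"].to_numpy()
            nn = cdist(ds.test_features, ds.train_features).argmin(axis=1)
            return np.abs(az[nn]
                          - ds.test_labels["azimuth_deg"].to_numpy()).mean()

        assert mean_nn_error(reverb_coarse_ds) > mean_nn_error(clean_coarse_ds)

    def test_reduced_subset(self, clean_coarse_ds):
        ds = clean_coarse_ds
        full = reduced_training_subset(ds, 1.0, 0)
        assert full.train_features.shape == ds.train_features.shape
        n = ds.train_features.shape[0]
        sub = reduced_training_subset(ds, 0.1, 0)
        assert sub.train_features.shape[0] == round(0.1 * n)
        other = reduced_training_subset(ds, 0.1, 1)
        assert not np.array_equal(sub.train_features, other.train_features)
        assert sub.train_features.shape == other.train_features.shape

    def test_invalid_fraction_raises(self, clean_coarse_ds):
        with pytest.raises(ValueError):
            reduced_training_subset(clean_coarse_ds, 0.0, 0)


class TestWaveformRendering:
    def test_rendered_cues_follow_template(self, head):
        cfg = FeatureConfig(dft_size=256)
        rng = np.random.default_rng(0)
        wave = render_waveform(60.0, 0.0, head, cfg, duration_s=1.0, rng=rng)
        vec = extract_measurement(wave, cfg).values
        ild, ipd = head_template(60.0, 0.0, head, cfg)
        k1, k2, _, _, _ = resolve_bins(cfg)
        ild_block = vec[: k2 - k1]
        ref = ild[k1:k2]
        # windowing leakage blurs exact levels; demand strong agreement
        assert np.corrcoef(ild_block, ref)[0, 1] > 0.95
        assert abs(ild_block.mean() - ref.mean()) < 1.5
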