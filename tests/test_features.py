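import numpy as np
import pytest

from statedetect import (
    BANDS,
    CHANNELS_38,
    ROI_15,
    BandScheme,
    ConnectivityIndexConfig,
    EpochedRecording,
    FeatureTable,
    ROIMap,
    compute_all_features,
    compute_band_roi_psd,
    compute_connectivity_index,
    compute_pairwise_sync,
    compute_psd_ratios,
    region_pair_features,
)

SFREQ = 500.0


def _epochs(data):
    data = np.asarray(data, dtype=float)
    return EpochedRecording(
        data, 1.0, SFREQ, [f"ch{i}" for i in range(data.shape[1])], np.arange(data.shape[0])
    )


def _epochs38(n_epochs, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n_epochs, 38, 500))
    return EpochedRecording(data, 1.0, SFREQ, list(CHANNELS_38), np.arange(n_epochs))


@pytest.fixture(scope="module")
def full_tables():
    """Full feature recipe on the standard montage (white-noise epochs)."""
    return compute_all_features(_epochs38(8), include_pairs=True)


class TestMontage:
    def test_roi_map_covers_38_channels(self):
        covered = sorted({ch for chs in ROI_15.values() for ch in chs})
        assert covered == sorted(CHANNELS_38)
        assert len(ROI_15) == 15

    def test_band_edges(self):
        assert BANDS["delta"] == (0.9, 4.0)
        assert BANDS["gamma"] == (25.0, 40.0)
        # half-open membership: 8 Hz belongs to alpha, not theta
        masks = BandScheme().masks(np.array([1.0, 4.0, 8.0, 14.0, 25.0, 40.0]))
        assert masks["alpha"].tolist() == [False, False, True, False, False, False]
        assert masks["gamma"].tolist() == [False, False, False, False, True, True]


class TestColumnCounts:
    """Structural counts for the standard 38-channel / 15-region montage."""

    def test_psd_75(self, full_tables):
        assert full_tables["psd"].n_features == 5 * 15 == 75

    def test_ratios_240(self, full_tables):
        assert full_tables["ratios"].n_features == 16 * 15 == 240

    def test_indices_per_measure(self, full_tables):
        # 3 thresholds x 5 bands x 15 regions
        assert full_tables["coh_index"].n_features == 3 * 5 * 15 == 225
        assert full_tables["plv_index"].n_features == 225

    def test_sda_input_total(self, full_tables):
        assert full_tables["sda_input"].n_features == 75 + 240 + 2 * 225 == 765

    def test_region_pairs_525_each(self, full_tables):
        pairs = full_tables["region_pairs"]
        assert pairs.select(kind="coherence").n_features == 5 * 105 == 525
        assert pairs.select(kind="plv").n_features == 525

    def test_analysis_total(self, full_tables):
        assert full_tables["analysis"].n_features == 765 + 2 * 525 == 1815

    def test_channel_pair_count(self):
        ep = _epochs38(5)
        coh = compute_pairwise_sync(ep, cfg=ConnectivityIndexConfig(measure="coherence"))
        assert coh.n_features == 5 * (38 * 37 // 2) == 3515


class TestPSD:
    def test_pure_sinusoid_lands_in_alpha(self, small_rois):
        t = np.arange(500) / SFREQ
        sig = np.sin(2 * np.pi * 10 * t)
        data = np.tile(sig, (3, 4, 1))
        psd = compute_band_roi_psd(_epochs(data), rois=small_rois)
        for region in ("front", "back"):
            sub = psd.select(region=region)
            by_band = {b: sub.select(band=b).values.mean() for b in BANDS}
            assert max(by_band, key=by_band.get) == "alpha"

    def test_white_noise_flat_spectrum(self, small_rois):
        # Band powers of white noise are flat per Hz: band means agree
        # within multitaper bias across >= 100 epochs.
        rng = np.random.default_rng(7)
        data = rng.normal(size=(120, 4, 500))
        psd = compute_band_roi_psd(_epochs(data), rois=small_rois)
        means = np.array([psd.select(band=b).values.mean() for b in BANDS])
        assert means.max() / means.min() < 1.35

    def test_scaling_moves_power_quadratically(self, small_rois):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(4, 4, 500))
        p1 = compute_band_roi_psd(_epochs(data), rois=small_rois)
        p2 = compute_band_roi_psd(_epochs(3.0 * data), rois=small_rois)
        np.testing.assert_allclose(p2.values, 9.0 * p1.values, rtol=1e-8)

    def test_nyquist_guard(self, small_rois):
        data = np.random.default_rng(0).normal(size=(2, 4, 60))
        ep = EpochedRecording(data, 1.0, 60.0, [f"ch{i}" for i in range(4)], np.arange(2))
        with pytest.raises(ValueError, match="Nyquist"):
            compute_band_roi_psd(ep, rois=small_rois)


class TestRatios:
    def _psd_table(self, powers):
        """One-region psd table with given per-band powers (single epoch)."""
        from conftest import make_table

        bands = list(BANDS)
        return make_table(
            np.array([powers], dtype=float),
            kind="psd",
            bands=bands,
            regions=["r"] * 5,
        )

    def test_simple_ratio(self):
        t = self._psd_table([2.0, 4.0, 1.0, 1.0, 1.0])  # delta=2, theta=4
        ratios = compute_psd_ratios(t)
        assert ratios.column("ratio:theta/delta:r")[0] == pytest.approx(2.0)

    def test_equal_powers_symmetry(self):
        t = self._psd_table([3.0] * 5)
        ratios = compute_psd_ratios(t)
        assert ratios.column("ratio:alpha/theta:r")[0] == pytest.approx(1.0)
        assert ratios.column("ratio:gamma/(alpha+beta):r")[0] == pytest.approx(0.5)
        assert ratios.column("ratio:beta/(delta+theta):r")[0] == pytest.approx(0.5)

    def test_nonpositive_power_rejected(self):
        t = self._psd_table([2.0, 0.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="positive"):
            compute_psd_ratios(t)

    def test_ratio_invariance_under_common_scaling(self, small_rois):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(3, 4, 500))
        r1 = compute_psd_ratios(compute_band_roi_psd(_epochs(data), rois=small_rois))
        r2 = compute_psd_ratios(compute_band_roi_psd(_epochs(2.5 * data), rois=small_rois))
        np.testing.assert_allclose(r1.values, r2.values, rtol=1e-8)


class TestSync:
    def test_identical_channels_full_sync(self, small_rois):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 1, 500))
        data = np.tile(base, (1, 4, 1))  # every channel an exact copy
        ep = _epochs(data)
        for measure in ("coherence", "plv"):
            sync = compute_pairwise_sync(ep, cfg=ConnectivityIndexConfig(measure=measure))
            np.testing.assert_allclose(sync.values, 1.0, atol=1e-9)

    def test_independent_noise_null_levels(self):
        # Window-limited bias with n_seg = window_epochs * n_tapers = 35
        # independent segments: coherence null ~ 1/n_seg = 0.029, PLV null
        # ~ sqrt(pi/(4 n_seg)) = 0.15.  Check the Monte-Carlo means land
        # near the analytic values.
        rng = np.random.default_rng(4)
        data = rng.normal(size=(200, 2, 500))
        ep = _epochs(data)
        coh = compute_pairwise_sync(ep, cfg=ConnectivityIndexConfig(measure="coherence"))
        assert abs(coh.values.mean() - 1 / 35) < 0.02
        plv = compute_pairwise_sync(ep, cfg=ConnectivityIndexConfig(measure="plv"))
        assert abs(plv.values.mean() - np.sqrt(np.pi / (4 * 35))) < 0.04

    def test_values_in_unit_interval(self, small_rois):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(10, 4, 500))
        for measure in ("coherence", "plv"):
            sync = compute_pairwise_sync(_epochs(data), cfg=ConnectivityIndexConfig(measure=measure))
            assert sync.values.min() >= 0.0 and sync.values.max() <= 1.0 + 1e-12

    def test_silent_channel_rejected(self):
        data = np.random.default_rng(0).normal(size=(6, 3, 500))
        data[:, 1] = 0.0
        with pytest.raises(ValueError, match="zero power"):
            compute_pairwise_sync(_epochs(data))


class TestConnectivityIndex:
    def _sync_table(self, pair_vals, channels=("c1", "c2", "c3")):
        from conftest import make_table

        pairs = [f"{channels[0]}|{channels[1]}", f"{channels[0]}|{channels[2]}", f"{channels[1]}|{channels[2]}"]
        return make_table(
            np.array([pair_vals]), kind="coherence", bands=["alpha"] * 3, regions=pairs
        )

    def test_brute_force_counts(self):
        # coherences (1,2)=0.8, (1,3)=0.5, (2,3)=0.75 at P=0.7 -> counts 1, 2, 1
        sync = self._sync_table([0.8, 0.5, 0.75])
        rois = ROIMap({"r1": ["c1"], "r2": ["c2"], "r3": ["c3"]})
        cfg = ConnectivityIndexConfig(thresholds=(0.7,))
        idx = compute_connectivity_index(sync, cfg, rois, channel_names=["c1", "c2", "c3"])
        assert idx.column("coh_index:P0.7:alpha:r1")[0] == 1
        assert idx.column("coh_index:P0.7:alpha:r2")[0] == 2
        assert idx.column("coh_index:P0.7:alpha:r3")[0] == 1

    def test_all_below_threshold(self):
        sync = self._sync_table([0.5, 0.4, 0.3])
        rois = ROIMap({"all": ["c1", "c2", "c3"]})
        cfg = ConnectivityIndexConfig(thresholds=(0.9,))
        idx = compute_connectivity_index(sync, cfg, rois, channel_names=["c1", "c2", "c3"])
        np.testing.assert_array_equal(idx.values, 0.0)

    def test_monotone_in_threshold(self, small_rois, small_channels):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(12, 4, 500))
        sync = compute_pairwise_sync(_epochs(data))
        cfg = ConnectivityIndexConfig(thresholds=(0.3, 0.5, 0.7))
        idx = compute_connectivity_index(sync, cfg, small_rois, channel_names=list(small_channels))
        by_thr = [idx.select(threshold=p).values for p in (0.3, 0.5, 0.7)]
        assert (by_thr[0] >= by_thr[1]).all() and (by_thr[1] >= by_thr[2]).all()


class TestRegionPairs:
    def test_singleton_regions_identity(self):
        from conftest import make_table

        sync = make_table(np.array([[0.4]]), kind="plv", bands=["alpha"], regions=["a|b"])
        rois = ROIMap({"ra": ["a"], "rb": ["b"]})
        rp = region_pair_features(sync, rois)
        assert rp.values[0, 0] == pytest.approx(0.4)

    def test_constant_pairs_mean(self, small_rois, small_channels):
        from conftest import make_table

        pairs = [f"{a}|{b}" for i, a in enumerate(small_channels) for b in small_channels[i + 1:]]
        sync = make_table(
            np.full((2, len(pairs)), 0.77), kind="coherence",
            bands=["alpha"] * len(pairs), regions=pairs,
        )
        rp = region_pair_features(sync, small_rois)
        np.testing.assert_allclose(rp.values, 0.77)


class TestFeatureTableIO:
    def test_csv_roundtrip(self, tmp_path, small_rois):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(4, 4, 500))
        tabs = compute_all_features(_epochs(data), rois=small_rois, include_pairs=False)
        path = tmp_path / "feat.csv"
        tabs["sda_input"].to_csv(path)
        back = FeatureTable.from_csv(path)
        np.testing.assert_allclose(back.values, tabs["sda_input"].values, rtol=1e-12)
        assert back.names == tabs["sda_input"].names
        assert list(back.meta["kind"]) == list(tabs["sda_input"].meta["kind"])
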