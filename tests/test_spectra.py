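import numpy as np
import pandas as pd
import pytest

from specphos.spectra import (
    SpectraError, SpectrumSet, WavelengthGrid, average_replicates,
    exclude_noisy_band, read_spectra, standardize, within_spectrum_correlation,
    write_spectra,
)


def _write_csv(tmp_path, wavelengths, rows, name="toy.csv", meta=None):
    path = tmp_path / name
    cols = [f"R{w:g}" for w in wavelengths]
    df = pd.DataFrame(rows, columns=cols)
    n = len(df)
    meta = meta or {}
    df.insert(0, "sample_id", meta.get("sample_id", [f"s{i}" for i in range(n)]))
    df.insert(1, "accession_id", meta.get("accession_id", [f"a{i}" for i in range(n)]))
    df.insert(2, "treatment", meta.get("treatment", ["P100"] * n))
    df.insert(3, "block", 1)
    df.insert(4, "replicate", meta.get("replicate", [0] * n))
    df.to_csv(path, index=False)
    return path


class TestWavelengthGrid:
    def test_device_grid_has_206_channels(self):
        assert len(WavelengthGrid(380, 790, 2)) == 206

    @pytest.mark.parametrize("start,stop,step", [
        (380, 790, 0), (790, 380, 2), (380, 791, 2),
    ])
    def test_invalid_grids_rejected(self, start, stop, step):
        with pytest.raises(SpectraError):
            WavelengthGrid(start, stop, step)

    def test_index_of_off_grid_wavelength(self):
        with pytest.raises(SpectraError):
            WavelengthGrid().index_of(421)


class TestReadSpectra:
    def test_round_trip_two_records(self, tmp_path):
        wl = WavelengthGrid().wavelengths
        path = _write_csv(tmp_path, wl, np.full((2, 206), 0.3))
        sset = read_spectra(path, WavelengthGrid())
        assert len(sset) == 2
        assert sset.reflectance.shape == (2, 206)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("sample_id,R420\n")
        with pytest.raises(SpectraError, match="no records"):
            read_spectra(path)

    def test_grid_mismatch_errors(self, tmp_path):
        wl5 = np.arange(380, 791, 5)
        path = _write_csv(tmp_path, wl5, np.full((2, len(wl5)), 0.3))
        with pytest.raises(SpectraError, match="mismatch"):
            read_spectra(path, WavelengthGrid(380, 790, 2))

    def test_duplicate_sample_replicate_errors(self, tmp_path):
        wl = WavelengthGrid().wavelengths
        path = _write_csv(tmp_path, wl, np.full((2, 206), 0.3),
                          meta={"sample_id": ["s1", "s1"], "replicate": [1, 1]})
        with pytest.raises(SpectraError, match="duplicate"):
            read_spectra(path)

    def test_percent_scale_autodetected(self, tmp_path):
        wl = WavelengthGrid().wavelengths
        path = _write_csv(tmp_path, wl, np.full((2, 206), 30.0))
        sset = read_spectra(path)
        assert np.allclose(sset.reflectance, 0.30)


class TestAverageReplicates:
    def test_channelwise_mean(self, toy_set):
        df = toy_set.data.copy()
        df["sample_id"] = "same"
        df.loc[0, toy_set.grid.columns()] = 0.2
        df.loc[1, toy_set.grid.columns()] = 0.4
        df["replicate"] = [1, 2]
        merged = average_replicates(SpectrumSet(toy_set.grid, df))
        assert len(merged) == 1
        assert np.allclose(merged.reflectance, 0.3)

    def test_one_record_per_sample(self, small_panel):
        averaged = average_replicates(small_panel.spectra)
        n_samples = small_panel.spectra.data["sample_id"].nunique()
        assert len(averaged) == n_samples

    def test_idempotent(self, small_panel):
        once = average_replicates(small_panel.spectra)
        twice = average_replicates(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestExcludeNoisyBand:
    def test_186_channels_remain(self, toy_set):
        trimmed = exclude_noisy_band(toy_set)
        assert len(trimmed.grid) == 186
        assert trimmed.grid.start == 420 and trimmed.grid.stop == 790

    def test_full_range_is_identity(self, toy_set):
        same = exclude_noisy_band(toy_set, 380, 790)
        assert np.allclose(same.reflectance, toy_set.reflectance)

    def test_empty_range_errors(self, toy_set):
        with pytest.raises(SpectraError):
            exclude_noisy_band(toy_set, 700, 500)

    def test_commutes_with_replicate_averaging(self, small_panel):
        a = exclude_noisy_band(average_replicates(small_panel.spectra))
        b = average_replicates(exclude_noisy_band(small_panel.spectra))
        assert np.allclose(a.reflectance, b.reflectance)


class TestStandardize:
    def test_train_set_centered_and_scaled(self, small_panel):
        std, stats = standardize(small_panel.spectra)
        z = std.reflectance
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0) - 1).max() < 1e-9

    def test_single_record_zero_variance_errors(self, toy_set):
        one = SpectrumSet(toy_set.grid, toy_set.data.iloc[:1])
        with pytest.raises(SpectraError, match="zero-variance"):
            standardize(one)

    def test_apply_set_uses_train_statistics(self, small_panel):
        self_std, _ = standardize(small_panel.spectra)
        applied, _ = standardize(small_panel.spectra, small_panel.spectra)
        assert np.allclose(self_std.reflectance, applied.reflectance)

    def test_double_standardization_is_identity(self, small_panel):
        once, _ = standardize(small_panel.spectra)
        twice, _ = standardize(once)
        assert np.abs(once.reflectance - twice.reflectance).max() < 1e-9


class TestWithinSpectrumCorrelation:
    def test_perfect_monotone_pair(self, small_panel):
        sset = average_replicates(small_panel.spectra)
        data = sset.data.copy()
        cols = sset.grid.columns()
        data[cols[1]] = 2.0 * data[cols[0]]
        corr = within_spectrum_correlation(SpectrumSet(sset.grid, data))
        wl = sset.grid.wavelengths
        assert corr.loc[wl[0], wl[1]] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, small_panel):
        corr = within_spectrum_correlation(
            average_replicates(small_panel.spectra)).to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.min() >= -1 - 1e-12 and corr.max() <= 1 + 1e-12

    def test_too_few_records_error(self, toy_set):
        with pytest.raises(SpectraError):
            within_spectrum_correlation(toy_set)

    def test_vis_nir_block_structure(self, small_panel):
        """VIS channels correlate among themselves more than with NIR."""
        sset = exclude_noisy_band(average_replicates(small_panel.spectra))
        corr = within_spectrum_correlation(sset)
        wl = sset.grid.wavelengths
        vis = (wl >= 430) & (wl <= 720)
        nir = wl >= 730
        within_vis = corr.to_numpy()[np.ix_(vis, vis)]
        cross = corr.to_numpy()[np.ix_(vis, nir)]
        assert np.median(within_vis) > np.median(cross)


def test_write_read_round_trip(tmp_path, small_panel):
    path = tmp_path / "out.csv"
    write_spectra(small_panel.spectra, path)
    back = read_spectra(path, small_panel.spectra.grid)
    assert np.allclose(back.reflectance, small_panel.spectra.reflectance)
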