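import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adulterspec.spectra_core import (AbsorbanceDomainError, RawMeasurement,
                                      SpectraDataset, SpectraError,
                                      SpectraParseError, Spectrum,
                                      WavelengthGrid, average_replicate_scans,
                                      compute_absorbance, default_grid,
                                      read_spectra_csv, write_spectra_csv)


@pytest.fixture
def tiny_grid():
    return WavelengthGrid(np.linspace(400.0, 700.0, 10))


class TestWavelengthGrid:
    def test_default_instrument_grid(self):
        g = default_grid()
        assert len(g) == 2068
        assert g.values[0] == 200.0 and g.values[-1] == 1100.0

    @pytest.mark.parametrize("values", [
        [500.0],                       # too short
        [500.0, 500.0, 600.0],         # not strictly increasing
        [600.0, 500.0],                # descending
        [50.0, 600.0],                 # below 100 nm
        [500.0, np.inf],               # non-finite
    ])
    def test_invalid_grids_rejected(self, values):
        with pytest.raises(SpectraError):
            WavelengthGrid(np.array(values))

    def test_band_masks_partition_grid(self):
        g = default_grid(500)
        uv, vis, nir = g.band_masks()
        assert np.all(uv.astype(int) + vis.astype(int) + nir.astype(int) == 1)
        assert g.values[uv].max() < 400 <= g.values[vis].min()
        assert g.values[vis].max() <= 780 < g.values[nir].min()


class TestComputeAbsorbance:
    def test_sample_equals_reference_gives_zero(self, tiny_grid):
        n = len(tiny_grid)
        m = RawMeasurement(tiny_grid, np.full(n, 900.0), np.full(n, 100.0),
                           np.full(n, 900.0))
        np.testing.assert_allclose(compute_absorbance(m).absorbance, 0.0)

    @pytest.mark.parametrize("transmittance,expected", [(0.1, 1.0), (0.01, 2.0)])
    def test_log10_closed_forms(self, tiny_grid, transmittance, expected):
        n = len(tiny_grid)
        dark, ref = np.full(n, 50.0), np.full(n, 1050.0)
        sample = dark + transmittance * (ref - dark)
        m = RawMeasurement(tiny_grid, sample, dark, ref)
        np.testing.assert_allclose(compute_absorbance(m).absorbance, expected,
                                   atol=1e-12)

    def test_nonpositive_transmittance_identifies_wavelengths(self, tiny_grid):
        n = len(tiny_grid)
        sample = np.full(n, 500.0)
        sample[3] = 80.0  # below dark
        with pytest.raises(AbsorbanceDomainError) as exc:
            compute_absorbance(RawMeasurement(tiny_grid, sample,
                                              np.full(n, 100.0),
                                              np.full(n, 900.0)))
        assert tiny_grid.values[3] in exc.value.wavelengths_nm

    def test_nonpositive_reference_rejected_at_construction(self, tiny_grid):
        n = len(tiny_grid)
        with pytest.raises(AbsorbanceDomainError):
            RawMeasurement(tiny_grid, np.full(n, 500.0), np.full(n, 100.0),
                           np.full(n, 100.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_monotone_decreasing_in_sample_intensity(self, seed):
        """Raising S at fixed D, R lowers absorbance everywhere."""
        rng = np.random.default_rng(seed)
        g = WavelengthGrid(np.linspace(300, 900, 15))
        dark = rng.uniform(10, 50, 15)
        ref = dark + rng.uniform(100, 1000, 15)
        s1 = dark + rng.uniform(1, 500, 15)
        s2 = s1 + rng.uniform(0.1, 100, 15)
        a1 = compute_absorbance(RawMeasurement(g, s1, dark, ref)).absorbance
        a2 = compute_absorbance(RawMeasurement(g, s2, dark, ref)).absorbance
        assert np.all(a2 < a1)


class TestAverageReplicateScans:
    def test_three_identical_scans_reproduce_spectrum(self, tiny_grid):
        s = Spectrum(tiny_grid, np.linspace(0, 1, len(tiny_grid)))
        out = average_replicate_scans([s, s, s])
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_elementwise_mean(self, tiny_grid):
        scans = [Spectrum(tiny_grid, np.full(len(tiny_grid), v))
                 for v in (0.0, 1.0, 2.0)]
        np.testing.assert_allclose(average_replicate_scans(scans).absorbance, 1.0)

    def test_single_scan_warns_but_succeeds(self, tiny_grid):
        s = Spectrum(tiny_grid, np.ones(len(tiny_grid)))
        with pytest.warns(UserWarning, match="expected 3"):
            out = average_replicate_scans([s])
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_grid_mismatch_rejected(self, tiny_grid):
        other = WavelengthGrid(np.linspace(401.0, 701.0, 10))
        with pytest.raises(SpectraError):
            average_replicate_scans([Spectrum(tiny_grid, np.ones(10)),
                                     Spectrum(other, np.ones(10))] * 2)


class TestDatasetValidation:
    def test_fraction_outside_unit_interval_rejected(self, tiny_grid):
        with pytest.raises(SpectraError, match=r"\[0, 1\]"):
            SpectraDataset(tiny_grid, np.zeros((2, 10)), [0.5, 1.5],
                           ["soybean", "soybean"], [0, 1])

    def test_nan_rejected(self, tiny_grid):
        X = np.zeros((2, 10))
        X[0, 0] = np.nan
        with pytest.raises(SpectraError):
            SpectraDataset(tiny_grid, X, [0.1, 0.2], ["corn", "corn"], [0, 1])


class TestCsvRoundTrip:
    @pytest.fixture
    def dataset(self, tiny_grid):
        rng = np.random.default_rng(3)
        return SpectraDataset(tiny_grid, rng.uniform(0, 2, (5, 10)),
                              [0.0, 0.1, 0.5, 0.9, 1.0],
                              ["none", "corn", "corn", "corn", "corn"],
                              [0, 0, 1, 2, 3])

    def test_round_trip_preserves_everything(self, dataset, tmp_path):
        sp, md = tmp_path / "s.csv", tmp_path / "m.csv"
        write_spectra_csv(dataset, sp, md)
        back = read_spectra_csv(sp, md)
        np.testing.assert_allclose(back.X, dataset.X, atol=1e-12)
        np.testing.assert_array_equal(back.grid.values, dataset.grid.values)
        np.testing.assert_array_equal(back.y, dataset.y)
        np.testing.assert_array_equal(back.adulterant, dataset.adulterant)
        np.testing.assert_array_equal(back.replicate_id, dataset.replicate_id)

    def test_write_read_write_is_byte_stable(self, dataset, tmp_path):
        s1, m1 = tmp_path / "s1.csv", tmp_path / "m1.csv"
        s2, m2 = tmp_path / "s2.csv", tmp_path / "m2.csv"
        write_spectra_csv(dataset, s1, m1)
        write_spectra_csv(read_spectra_csv(s1, m1), s2, m2)
        assert s1.read_bytes() == s2.read_bytes()
        assert m1.read_bytes() == m2.read_bytes()

    def test_full_resolution_file_has_2068_grid_points(self, tmp_path):
        from adulterspec.spectra_core import default_grid
        g = default_grid()
        ds = SpectraDataset(g, np.zeros((2, 2068)), [0.1, 0.2],
                            ["peanut", "peanut"], [0, 1])
        write_spectra_csv(ds, tmp_path / "s.csv", tmp_path / "m.csv")
        back = read_spectra_csv(tmp_path / "s.csv", tmp_path / "m.csv")
        assert len(back.grid) == 2068

    def test_bad_fraction_in_metadata_rejected(self, dataset, tmp_path):
        sp, md = tmp_path / "s.csv", tmp_path / "m.csv"
        write_spectra_csv(dataset, sp, md)
        text = md.read_text().replace("0.10000000000000001", "1.5")
        md.write_text(text)
        with pytest.raises(SpectraParseError, match="outside"):
            read_spectra_csv(sp, md)

    def test_missing_wavelength_column_rejected(self, dataset, tmp_path):
        sp, md = tmp_path / "s.csv", tmp_path / "m.csv"
        write_spectra_csv(dataset, sp, md)
        sp.write_text(sp.read_text().replace("wavelength_nm", "wl"))
        with pytest.raises(SpectraParseError, match="wavelength_nm"):
            read_spectra_csv(sp, md)

    def test_non_numeric_cell_rejected_with_line_number(self, dataset, tmp_path):
        sp, md = tmp_path / "s.csv", tmp_path / "m.csv"
        write_spectra_csv(dataset, sp, md)
        lines = sp.read_text().splitlines()
        parts = lines[4].split(",")
        parts[2] = "oops"
        lines[4] = ",".join(parts)
        sp.write_text("\n".join(lines) + "\n")
        with pytest.raises(SpectraParseError, match="line 5"):
            read_spectra_csv(sp, md)
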