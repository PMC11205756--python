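"""Spectrum container, IO, blank correction and interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algadens.spectra import (
    SpectraSet,
    Spectrum,
    SpectrumError,
    average_replicates,
    blank_correct,
    od_at,
    read_spectrum,
    regrid,
    restrict_range,
)

WL = np.arange(300.0, 320.0)


def make(values, **kw):
    return Spectrum(WL, np.asarray(values, dtype=float), **kw)


class TestSpectrumInvariants:
    def test_grid_must_be_strictly_increasing(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([300.0, 300.0, 301.0]), np.zeros(3))
        with pytest.raises(SpectrumError):
            Spectrum(np.array([302.0, 301.0, 300.0]), np.zeros(3))

    def test_lengths_must_match(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([300.0, 301.0]), np.zeros(3))

    def test_non_finite_rejected(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([300.0, 301.0]), np.array([0.1, np.nan]))

    def test_negative_absorbance_allowed(self):
        s = make(np.full(WL.size, -0.01))
        assert s.absorbance.min() == -0.01


class TestReadSpectrum:
    def test_csv_round_trip(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,absorbance\n300,0.1\n301,0.2\n302,0.3\n")
        s = read_spectrum(p)
        assert len(s) == 3
        assert s.absorbance[1] == 0.2

    def test_descending_rows_are_sorted(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,absorbance\n302,0.3\n301,0.2\n300,0.1\n")
        s = read_spectrum(p)
        np.testing.assert_array_equal(s.wavelengths, [300, 301, 302])
        np.testing.assert_array_equal(s.absorbance, [0.1, 0.2, 0.3])

    def test_duplicate_wavelength_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,absorbance\n440,0.3\n440,0.2\n441,0.1\n")
        with pytest.raises(SpectrumError, match="duplicate"):
            read_spectrum(p)

    @pytest.mark.parametrize(
        "body", ["wl,absorbance\n300,0.1\n", "wavelength_nm,absorbance\n300,abc\n"]
    )
    def test_bad_columns_or_cells(self, tmp_path, body):
        p = tmp_path / "s.csv"
        p.write_text(body)
        with pytest.raises(SpectrumError):
            read_spectrum(p)


class TestAverageAndBlank:
    def test_mean_of_identical_inputs_is_identity(self):
        s = make(np.linspace(0, 1, WL.size))
        avg = average_replicates([s, s])
        np.testing.assert_allclose(avg.absorbance, s.absorbance)

    def test_pointwise_mean(self):
        a = make(np.full(WL.size, 0.2))
        b = make(np.full(WL.size, 0.4))
        assert od_at(average_replicates([a, b]), 310.0) == pytest.approx(0.3)

    def test_empty_input_rejected(self):
        with pytest.raises(SpectrumError):
            average_replicates([])

    def test_mismatched_grids_rejected(self):
        a = make(np.zeros(WL.size))
        b = Spectrum(WL + 0.5, np.zeros(WL.size))
        with pytest.raises(SpectrumError):
            average_replicates([a, b])

    def test_blank_corrected_flag_requires_all_inputs(self):
        a = make(np.zeros(WL.size), blank_corrected=True)
        b = make(np.zeros(WL.size), blank_corrected=False)
        assert not average_replicates([a, b]).blank_corrected
        assert average_replicates([a, a]).blank_corrected

    def test_self_subtraction_gives_zero(self):
        b = make(np.linspace(0.1, 0.5, WL.size))
        out = blank_correct(b, b)
        np.testing.assert_array_equal(out.absorbance, 0.0)
        assert out.blank_corrected

    def test_constant_shift(self):
        s = make(np.full(WL.size, 0.5))
        b = make(np.full(WL.size, 0.1))
        np.testing.assert_allclose(blank_correct(s, b).absorbance, 0.4)

    def test_double_correction_rejected(self):
        s = make(np.full(WL.size, 0.5))
        b = make(np.full(WL.size, 0.1))
        once = blank_correct(s, b)
        with pytest.raises(SpectrumError, match="already"):
            blank_correct(once, b)

    def test_grid_mismatch_rejected(self):
        s = make(np.zeros(WL.size))
        b = Spectrum(WL[:-1], np.zeros(WL.size - 1))
        with pytest.raises(SpectrumError):
            blank_correct(s, b)

    @given(st.lists(st.floats(-1, 4), min_size=WL.size, max_size=WL.size))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_zero_blank_is_identity(self, values):
        s = make(values)
        zero = make(np.zeros(WL.size))
        np.testing.assert_array_equal(
            blank_correct(s, zero).absorbance, s.absorbance
        )


class TestRestrictAndQuery:
    def test_restrict_drops_uv_tail(self):
        wl = np.arange(190.0, 1101.0)
        s = Spectrum(wl, np.zeros(wl.size))
        out = restrict_range(s, 300, 1100)
        assert out.wavelengths[0] == 300
        assert out.wavelengths[-1] == 1100

    def test_restrict_covering_all_is_noop_and_idempotent(self):
        s = make(np.linspace(0, 1, WL.size))
        once = restrict_range(s, 250, 400)
        np.testing.assert_array_equal(once.wavelengths, s.wavelengths)
        twice = restrict_range(restrict_range(s, 305, 315), 305, 315)
        np.testing.assert_array_equal(
            twice.wavelengths, restrict_range(s, 305, 315).wavelengths
        )

    def test_empty_restriction_rejected(self):
        s = make(np.zeros(WL.size))
        with pytest.raises(SpectrumError):
            restrict_range(s, 2000, 3000)

    def test_od_at_grid_point_and_midpoint(self):
        values = np.zeros(WL.size)
        values[10], values[11] = 0.2, 0.4
        s = make(values)
        assert od_at(s, WL[10]) == 0.2
        assert od_at(s, WL[10] + 0.5) == pytest.approx(0.3)

    def test_od_at_outside_span_rejected(self):
        s = make(np.zeros(WL.size))
        with pytest.raises(SpectrumError):
            od_at(s, 120.0)

    def test_regrid_interpolates_linearly(self):
        s = make(np.linspace(0, 1, WL.size))
        out = regrid(s, np.arange(305.0, 315.0, 0.5))
        np.testing.assert_allclose(
            out.absorbance, np.interp(out.wavelengths, WL, s.absorbance)
        )


class TestSpectraSet:
    def test_common_grid_and_corrected_average(self):
        wl_a = np.arange(300.0, 321.0)
        wl_b = np.arange(299.5, 321.5)
        spectra = {
            (1, 0): Spectrum(wl_a, np.full(wl_a.size, 0.5)),
            (1, 1): Spectrum(wl_b, np.full(wl_b.size, 0.7)),
        }
        blank = Spectrum(wl_a, np.full(wl_a.size, 0.1))
        ss = SpectraSet(spectra=spectra, blank=blank)
        corrected = ss.corrected(1)
        assert corrected.blank_corrected
        np.testing.assert_allclose(corrected.absorbance, 0.5)

    def test_disjoint_spans_rejected(self):
        a = Spectrum(np.arange(300.0, 310.0), np.zeros(10))
        b = Spectrum(np.arange(400.0, 410.0), np.zeros(10))
        with pytest.raises(SpectrumError):
            SpectraSet(spectra={(1, 0): a}, blank=b)
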