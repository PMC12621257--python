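"""File IO, unit conversion and conditioning of spectra and structures."""

import numpy as np
import pytest
from scipy.integrate import trapezoid

import benchkit as bk
from benchkit.constants import DEFAULT_SPACING_EV, HC_EV_NM
from benchkit.errors import (
    DegenerateSpectrumError,
    InputError,
    MetalAmbiguityError,
    SpectrumParseError,
    WindowError,
    XYZFormatError,
)


class TestReadXYSpectrum:
    def test_parses_two_columns(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("# header\n200 0.5\n300, 1.0\n")
        raw = bk.read_xy_spectrum(p)
        assert len(raw) == 2
        np.testing.assert_allclose(raw.abscissa, [200, 300])
        np.testing.assert_allclose(raw.intensity, [0.5, 1.0])

    def test_sorts_out_of_order_rows(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("300 1.0\n200 0.5\n")
        raw = bk.read_xy_spectrum(p)
        np.testing.assert_allclose(raw.abscissa, [200, 300])
        np.testing.assert_allclose(raw.intensity, [0.5, 1.0])

    def test_averages_duplicate_abscissa(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("200 0.4\n200 0.6\n300 1.0\n")
        raw = bk.read_xy_spectrum(p)
        np.testing.assert_allclose(raw.abscissa, [200, 300])
        np.testing.assert_allclose(raw.intensity, [0.5, 1.0])

    def test_non_numeric_row_reports_line_number(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("200 0.5\nfoo bar\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            bk.read_xy_spectrum(p)

    def test_single_point_rejected(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("200 0.5\n")
        with pytest.raises(InputError):
            bk.read_xy_spectrum(p)


class TestWavelengthToEnergy:
    def test_energy_values(self):
        raw = bk.RawSpectrum([200.0, 354.0], [1.0, 1.0])
        conv = bk.wavelength_to_energy(raw)
        # hc/354 = 3.502 eV, hc/200 = 6.199 eV, ascending in energy
        np.testing.assert_allclose(conv.abscissa, [HC_EV_NM / 354, HC_EV_NM / 200])
        assert conv.abscissa[0] == pytest.approx(3.502, abs=5e-4)
        assert conv.abscissa[1] == pytest.approx(6.199, abs=5e-4)

    def test_jacobian_preserves_band_area(self):
        # flat I(lambda)=c on [l1,l2] must carry area c*(l2-l1) into the energy domain
        lam = np.linspace(250.0, 500.0, 4001)
        c = 0.7
        conv = bk.wavelength_to_energy(bk.RawSpectrum(lam, np.full_like(lam, c)))
        area = trapezoid(conv.intensity, conv.abscissa)
        assert area == pytest.approx(c * 250.0, rel=1e-6)

    def test_round_trip_reproduces_abscissa(self):
        lam = np.linspace(210.0, 830.0, 311)
        raw = bk.RawSpectrum(lam, np.random.default_rng(0).uniform(0.1, 1, lam.size))
        back = bk.energy_to_wavelength(bk.wavelength_to_energy(raw))
        np.testing.assert_allclose(back.abscissa, lam, rtol=1e-9)
        np.testing.assert_allclose(back.intensity, raw.intensity, rtol=1e-9)

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(InputError):
            bk.wavelength_to_energy(bk.RawSpectrum([-1.0, 200.0], [1.0, 1.0]))


class TestCondition:
    def test_default_spacing_is_100_wavenumbers(self):
        assert DEFAULT_SPACING_EV == pytest.approx(0.012398, abs=1e-6)

    def test_identity_on_uniform_noiseless_input(self):
        e = np.arange(2.0, 4.0, 0.01)
        y = np.exp(-0.5 * ((e - 3.0) / 0.3) ** 2)
        raw = bk.RawSpectrum(e, y, domain="energy")
        spec = bk.condition(raw, window=(2.0, 3.99), spacing=0.01, smoothing=None)
        np.testing.assert_allclose(spec.intensities, y[: len(spec)] / y.max(), atol=1e-12)

    def test_max_normalized(self):
        e = np.linspace(1.0, 5.0, 200)
        raw = bk.RawSpectrum(e, 2.7 * np.exp(-((e - 3) ** 2)), domain="energy")
        spec = bk.condition(raw, window=(1.5, 4.5))
        assert spec.intensities.max() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_on_own_output(self):
        e = np.linspace(1.0, 5.0, 400)
        rng = np.random.default_rng(2)
        raw = bk.RawSpectrum(e, np.abs(np.sin(e)) + 0.1 * rng.uniform(size=e.size), domain="energy")
        first = bk.condition(raw, window=(1.5, 4.5), spacing=0.01, smoothing=None)
        again = bk.condition(
            bk.RawSpectrum(first.energies, first.intensities, domain="energy"),
            window=(1.5, 4.5), spacing=0.01, smoothing=None,
        )
        np.testing.assert_allclose(again.intensities, first.intensities, atol=1e-12)

    def test_window_outside_data_rejected(self):
        raw = bk.RawSpectrum([2.0, 3.0, 4.0], [0.1, 1.0, 0.2], domain="energy")
        with pytest.raises(WindowError):
            bk.condition(raw, window=(1.0, 4.0))

    def test_all_zero_degenerate(self):
        raw = bk.RawSpectrum([2.0, 3.0, 4.0], [0.0, 0.0, 0.0], domain="energy")
        with pytest.raises(DegenerateSpectrumError):
            bk.condition(raw, window=(2.5, 3.5), smoothing=None)

    def test_negative_values_clipped(self):
        e = np.linspace(2.0, 4.0, 50)
        y = np.sin(6 * e)  # dips below zero
        spec = bk.condition(bk.RawSpectrum(e, y, domain="energy"), window=(2.2, 3.8), smoothing=None)
        assert (spec.intensities >= 0).all()


class TestReadStickSpectrum:
    def test_forty_rows(self, tmp_path):
        rng = np.random.default_rng(4)
        p = tmp_path / "sticks.txt"
        rows = "\n".join(f"{e:.4f} {f:.4f}" for e, f in
                         zip(rng.uniform(1.4, 6.2, 40), rng.uniform(0, 1, 40)))
        p.write_text(rows + "\n")
        sticks = bk.read_stick_spectrum(p)
        assert len(sticks) == 40
        assert np.all(np.diff(sticks.energies) >= 0)

    def test_zero_strength_usable_flag(self, tmp_path):
        p = tmp_path / "sticks.txt"
        p.write_text("3.0 0.0\n")
        sticks = bk.read_stick_spectrum(p)
        assert len(sticks) == 1 and not sticks.usable

    def test_descending_rows_sorted(self, tmp_path):
        p = tmp_path / "sticks.txt"
        p.write_text("5.0 0.2\n3.0 0.8\n")
        sticks = bk.read_stick_spectrum(p)
        np.testing.assert_allclose(sticks.energies, [3.0, 5.0])
        np.testing.assert_allclose(sticks.strengths, [0.8, 0.2])

    @pytest.mark.parametrize("row", ["3.0 -0.1", "-1.0 0.5", "0.0 0.5"])
    def test_invalid_rows_rejected(self, tmp_path, row):
        p = tmp_path / "sticks.txt"
        p.write_text(row + "\n")
        with pytest.raises(SpectrumParseError):
            bk.read_stick_spectrum(p)


class TestReadXYZ:
    def test_metal_autodetected(self, tmp_path):
        p = tmp_path / "m.xyz"
        p.write_text("3\ncomment\nN 0 0 1\nFe 0 0 0\nN 0 0 -1\n")
        s = bk.read_xyz(p)
        assert s.metal_index == 1 and s.metal == "Fe"

    def test_count_mismatch(self, tmp_path):
        p = tmp_path / "m.xyz"
        p.write_text("5\ncomment\nFe 0 0 0\nN 0 0 1\nN 0 1 0\nN 1 0 0\n")
        with pytest.raises(XYZFormatError):
            bk.read_xyz(p)

    def test_two_metals_ambiguous(self, tmp_path):
        p = tmp_path / "m.xyz"
        p.write_text("3\ncomment\nFe 0 0 0\nFe 0 0 2\nN 0 0 1\n")
        with pytest.raises(MetalAmbiguityError):
            bk.read_xyz(p)
        s = bk.read_xyz(p, metal_index=0)
        assert s.metal_index == 0

    def test_round_trip(self, tmp_path, octahedron):
        p = tmp_path / "t.xyz"
        bk.write_xyz(octahedron, p)
        back = bk.read_xyz(p)
        assert back.elements == octahedron.elements
        np.testing.assert_allclose(back.coords, octahedron.coords, atol=1e-7)
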