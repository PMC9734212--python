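import numpy as np
import pytest

import beechroma as bc
from beechroma import hexagon
from beechroma.hexagon import (
    HexLocus, NonSpectralError, dominant_wavelength, excitation_from_catch,
    hex_coords, hex_distance, spectral_locus, spectral_purity,
)
from beechroma.spectra import SpectralCurve

from _oracles import sp_oracle

SQRT3_2 = np.sqrt(3.0) / 2.0


class TestCoordinates:
    def test_centre(self):
        loc = hex_coords((0.5, 0.5, 0.5))
        assert loc.x == pytest.approx(0.0, abs=1e-12)
        assert loc.y == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("E,expected", [
        ((0.0, 0.0, 1.0), (SQRT3_2, -0.5)),
        ((1.0, 0.0, 0.0), (-SQRT3_2, -0.5)),
        ((0.0, 1.0, 0.0), (0.0, 1.0)),
    ])
    def test_vertices(self, E, expected):
        loc = hex_coords(E)
        assert (loc.x, loc.y) == pytest.approx(expected)
        assert loc.distance == pytest.approx(1.0)

    def test_distance_is_a_metric(self):
        rng = np.random.default_rng(3)
        pts = [HexLocus(*rng.uniform(-1, 1, 2)) for _ in range(30)]
        for a, b, c in zip(pts, pts[1:], pts[2:]):
            assert hex_distance(a, a) == 0.0
            assert hex_distance(a, b) == pytest.approx(hex_distance(b, a))
            assert hex_distance(a, c) <= hex_distance(a, b) + hex_distance(b, c) + 1e-12

    def test_excitation_transform(self):
        assert excitation_from_catch(3.0) == pytest.approx(0.75)
        assert excitation_from_catch(0.0) == 0.0


class TestContext:
    def test_background_is_adapted_to_centre(self, context):
        E = bc.excitations(context.background, context).E
        np.testing.assert_allclose(E, 0.5, atol=1e-9)

    def test_doubling_illuminant_halves_gains(self, context):
        doubled = bc.make_context(context.illuminant.scaled(2.0),
                                  context.background, context.receptors)
        np.testing.assert_allclose(doubled.von_kries_R,
                                   context.von_kries_R / 2.0, rtol=1e-12)

    def test_zero_background_rejected(self, context):
        zero = SpectralCurve(context.grid, np.zeros(context.grid.size),
                             "reflectance")
        with pytest.raises(ValueError, match="von Kries"):
            bc.make_context(context.illuminant, zero, context.receptors)

    def test_zero_stimulus_gives_zero_excitation(self, context):
        zero = SpectralCurve(context.grid, np.zeros(context.grid.size),
                             "reflectance")
        E = bc.excitations(zero, context)
        np.testing.assert_array_equal(E.P, 0.0)
        np.testing.assert_array_equal(E.E, 0.0)

    def test_excitation_monotone_in_stimulus_scale(self, context,
                                                   random_reflectances):
        for curve in random_reflectances[:10]:
            half = SpectralCurve(curve.wavelengths, 0.5 * curve.values,
                                 "reflectance")
            assert np.all(bc.excitations(curve, context).E
                          >= bc.excitations(half, context).E)


class TestSpectralLocus:
    def test_chromatic_wavelengths_off_centre(self, locus_table):
        sel = (locus_table.wavelength >= 350) & (locus_table.wavelength <= 600)
        dist = np.hypot(locus_table.xy[sel, 0], locus_table.xy[sel, 1])
        assert np.all(dist > 0.0)

    @pytest.mark.parametrize("lam", [360.0, 440.0, 560.0])
    def test_max_distance_dominates_any_fixed_flux(self, context, locus_table, lam):
        i = int(np.searchsorted(locus_table.wavelength, lam))
        d_max = np.hypot(*locus_table.xy[i])
        # brute-force flux scan over six decades
        for q in np.logspace(-3, 3, 25):
            d_q = hexagon._mono_locus(context, lam, q).distance
            assert d_q <= d_max + 1e-9

    def test_deterministic(self, context, locus_table):
        again = spectral_locus(bc.make_context(
            context.illuminant, context.background, context.receptors))
        np.testing.assert_array_equal(again.xy, locus_table.xy)

    def test_fixed_flux_mode_requires_flux(self, context):
        with pytest.raises(ValueError, match="flux"):
            spectral_locus(context, mode="fixed_flux")


class TestDominantWavelength:
    def test_self_intersection_at_table_point(self, locus_table):
        i = int(np.searchsorted(locus_table.wavelength, 440.0))
        loc = HexLocus(*locus_table.xy[i])
        dw = dominant_wavelength(locus_table, loc)
        assert dw.flag == "spectral"
        assert dw.lambda_d == pytest.approx(440.0, abs=1e-6)

    def test_origin_is_achromatic(self, locus_table):
        assert dominant_wavelength(locus_table, HexLocus(0.0, 0.0)).flag \
            == "achromatic"

    def test_bee_purple_sector_flagged(self, locus_table):
        # geometric construction: the ray bisecting the directions of the
        # two locus endpoints points into the purple sector
        ends = [locus_table.xy[0], locus_table.xy[-1]]
        dirs = [p / np.linalg.norm(p) for p in ends]
        bisector = dirs[0] + dirs[1]
        bisector /= np.linalg.norm(bisector)
        loc = HexLocus(*(0.3 * bisector))
        assert dominant_wavelength(locus_table, loc).flag == "non_spectral"
        with pytest.raises(NonSpectralError):
            spectral_purity(loc, locus_table)
        # the endpoint-line denominator is opt-in and positive
        sp = spectral_purity(loc, locus_table, nonspectral_purple_line=True)
        assert sp > 0.0


class TestSpectralPurity:
    def test_background_has_zero_purity(self, context, locus_table):
        m = bc.compute_metrics(context.background, context, locus_table)
        assert m.spectral_purity == 0.0
        assert m.colour_contrast == pytest.approx(0.0, abs=1e-9)

    def test_monochromatic_stimulus_has_unit_purity(self, locus_table):
        for lam in (380.0, 440.0, 530.0):
            i = int(np.searchsorted(locus_table.wavelength, lam))
            loc = HexLocus(*locus_table.xy[i])
            assert spectral_purity(loc, locus_table) == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_independent_ray_oracle(self, context, locus_table,
                                                random_reflectances):
        checked = 0
        for curve in random_reflectances:
            m = bc.compute_metrics(curve, context, locus_table)
            if m.flag != "spectral":
                continue
            assert m.spectral_purity == pytest.approx(
                sp_oracle(m.locus, locus_table), abs=1e-6)
            checked += 1
        assert checked >= 40

    def test_invariant_under_illuminant_rescaling(self, context, locus_table,
                                                  random_reflectances):
        bright = bc.make_context(context.illuminant.scaled(10.0),
                                 context.background, context.receptors)
        bright_table = spectral_locus(bright)
        for curve in random_reflectances[:10]:
            a = bc.compute_metrics(curve, context, locus_table)
            b = bc.compute_metrics(curve, bright, bright_table)
            if a.flag == "spectral":
                assert b.spectral_purity == pytest.approx(a.spectral_purity,
                                                          abs=1e-9)

    def test_proportional_to_colour_contrast_at_fixed_hue(self, locus_table):
        # loci along one chromatic ray share lambda_d exactly, so the
        # SP : contrast ratio is a constant (1 / locus distance)
        direction = np.array([0.2, 0.35])
        direction /= np.linalg.norm(direction)
        ratios = []
        for r in (0.05, 0.15, 0.3, 0.45):
            loc = HexLocus(*(r * direction))
            ratios.append(spectral_purity(loc, locus_table) / loc.distance)
        assert np.ptp(ratios) < 1e-9


class TestScalarMetrics:
    @pytest.mark.parametrize("E,expected", [
        ((0.5, 0.5, 0.5), 0.5), ((0.2, 0.4, 0.6), 0.4), ((0.0, 0.0, 0.0), 0.0)])
    def test_intensity(self, E, expected):
        assert bc.intensity(E) == pytest.approx(expected)

    @pytest.mark.parametrize("eg,expected", [(0.5, 0.0), (0.75, 0.25), (0.0, -0.5)])
    def test_green_contrast(self, eg, expected):
        assert bc.green_contrast((0.3, 0.3, eg)) == pytest.approx(expected)


class TestMetricsTable:
    def test_background_row_is_neutral(self, context, locus_table):
        m = bc.metrics_table([context.background], context, locus_table)[0]
        assert m.flag == "achromatic"
        assert m.spectral_purity == 0.0
        assert m.intensity == pytest.approx(0.5, abs=1e-9)
        assert m.green_contrast == pytest.approx(0.0, abs=1e-9)
        assert m.colour_contrast == pytest.approx(0.0, abs=1e-9)

    def test_batch_equals_per_stimulus_and_respects_order(
            self, context, locus_table, random_reflectances):
        stimuli = random_reflectances[:6]
        batch = bc.metrics_table(stimuli, context, locus_table)
        singles = [bc.compute_metrics(s, context, locus_table) for s in stimuli]
        assert [m.name for m in batch] == [s.name for s in stimuli]
        for b, s in zip(batch, singles):
            assert b.name == s.name
            assert np.array_equal(b.excitations.E, s.excitations.E)
            assert b.spectral_purity == s.spectral_purity
            assert b.lambda_d == s.lambda_d
        rev = bc.metrics_table(stimuli[::-1], context, locus_table)
        assert [m.name for m in rev] == [m.name for m in batch][::-1]


class TestValidateSeries:
    def _metrics(self, sps, iis, lams):
        out = []
        for sp, ii, lam in zip(sps, iis, lams):
            E = hexagon.ReceptorExcitations.from_catches(np.ones(3))
            out.append(hexagon.ColourMetrics(
                name="", excitations=E, locus=HexLocus(0.1, 0.1),
                colour_contrast=0.14, lambda_d=lam, flag="spectral",
                spectral_purity=sp, intensity=ii, green_contrast=0.0))
        return out

    def test_good_purity_series_passes(self):
        m = self._metrics([0.1, 0.2, 0.3, 0.4], [0.45] * 4, [440.0] * 4)
        assert bc.validate_series(m, "purity").passed

    def test_intensity_spread_fails_hold_criterion(self):
        m = self._metrics([0.1, 0.2, 0.3, 0.4], [0.40, 0.45, 0.50, 0.55],
                          [440.0] * 4)
        rep = bc.validate_series(m, "purity")
        assert not rep.hold_ok and rep.hue_ok and rep.monotone_ok

    def test_hue_drift_fails(self):
        m = self._metrics([0.1, 0.2, 0.3, 0.4], [0.45] * 4,
                          [430.0, 440.0, 450.0, 460.0])
        assert not bc.validate_series(m, "purity").hue_ok

    def test_nonmonotone_fails(self):
        m = self._metrics([0.1, 0.3, 0.2, 0.4], [0.45] * 4, [440.0] * 4)
        assert not bc.validate_series(m, "purity").monotone_ok
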