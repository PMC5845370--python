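"""Geometry loading, resampling, curvature and the cranial extension."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinalwave.errors import GeometryError, InsufficientDataError, OrderingError
from spinalwave.geometry import (
    CenterlineSample,
    compute_curvature,
    extend_cranially,
    load_centerline_table,
    resample_profile,
    write_centerline_table,
)
from spinalwave.synth import builtin_fixture


def table(text: str):
    return load_centerline_table(io.StringIO(text))


HEADER = "x_mm,y_mm,r_syrinx_mm,r_cord_mm,r_sas_mm,r_eds_mm\n"


class TestLoader:
    def test_fixture_shape_and_first_station(self, fixture_samples):
        assert len(fixture_samples) == 13
        first = fixture_samples[0]
        assert first.r_cord_mm == 4.5
        assert first.r_sas_mm == 6.4
        assert first.r_syrinx_mm == 2.2

    def test_caudal_stations_lack_syrinx(self, fixture_samples):
        by_x = {s.x_mm: s for s in fixture_samples}
        assert by_x[325].r_syrinx_mm is None
        assert by_x[335].r_syrinx_mm is None
        # the caudal-most printed row also ends the cord radius column
        assert by_x[335].r_cord_mm is None
        assert by_x[335].r_sas_mm == 3.8

    def test_two_row_straight_table_accepted(self):
        samples = table(HEADER + "0,0,,4,5,6\n100,0,,4,5,6\n")
        assert len(samples) == 2
        assert samples[0].r_syrinx_mm is None

    def test_non_monotone_x_is_ordering_error(self):
        with pytest.raises(OrderingError, match="strictly increasing"):
            table(HEADER + "0,0,,4,5,6\n100,0,,4,5,6\n50,0,,4,5,6\n")

    def test_nesting_violation_names_station(self):
        with pytest.raises(GeometryError, match="x = 100"):
            table(HEADER + "0,0,,4,5,6\n100,0,,5.5,5,6\n")

    def test_missing_column_rejected(self):
        with pytest.raises(GeometryError, match="lacks columns"):
            table("x_mm,y_mm\n0,0\n")

    def test_dash_sentinels_mean_absent(self):
        samples = table(HEADER + "0,0,-,4,5,6\n100,0,–,4,5,6\n")
        assert all(s.r_syrinx_mm is None for s in samples)


radii = st.tuples(
    st.floats(0.5, 2.5), st.floats(0.3, 2.0), st.floats(0.3, 2.0),
    st.floats(0.1, 1.5),
)


@st.composite
def valid_tables(draw, smooth=False):
    """Random nested-radius tables; ``smooth`` keeps station-to-station radius
    changes small enough that cubic interpolation cannot overshoot nesting."""
    n = draw(st.integers(3, 8))
    xs = np.cumsum([draw(st.floats(10.0, 40.0)) for _ in range(n)])
    base = draw(radii) if smooth else None
    out = []
    for x in xs:
        if smooth:
            rs, d1, d2, d3 = base
            jit = draw(st.floats(-0.02, 0.02))
            rs = rs + jit
        else:
            rs, d1, d2, d3 = draw(radii)
        y = draw(st.floats(-30.0, 10.0)) if not smooth else draw(st.floats(-5.0, 5.0))
        out.append(CenterlineSample(float(x), y, rs, rs + d1, rs + d1 + d2,
                                    rs + d1 + d2 + d3))
    return out


class TestRoundTrip:
    @settings(max_examples=25, deadline=None)
    @given(valid_tables())
    def test_write_then_load_preserves_radii(self, samples):
        buf = io.StringIO()
        write_centerline_table(samples, buf)
        buf.seek(0)
        back = load_centerline_table(buf)
        for a, b in zip(samples, back):
            for f in ("x_mm", "y_mm", "r_syrinx_mm", "r_cord_mm",
                      "r_sas_mm", "r_eds_mm"):
                va, vb = getattr(a, f), getattr(b, f)
                assert vb == pytest.approx(va, rel=1e-6)

    @settings(max_examples=15, deadline=None)
    @given(valid_tables(smooth=True))
    def test_resampled_stations_keep_nesting(self, samples):
        prof = resample_profile(samples, 2e-3)
        inside = prof.has_syrinx
        assert np.all(prof.r_syrinx[inside] < prof.r_cord[inside])
        assert np.all(prof.r_cord < prof.r_sas)
        assert np.all(prof.r_sas <= prof.r_eds + 1e-12)


class TestResample:
    def test_fixture_station_count_and_extent(self, fixture_samples):
        prof = resample_profile(fixture_samples, 1e-3)
        assert prof.n_stations >= 336
        assert prof.xy[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert prof.xy[-1, 0] == pytest.approx(0.335, abs=1.5e-3)

    def test_collinear_samples_give_exact_arc_length(self):
        samples = table(HEADER + "0,0,,4,5,6\n100,0,,4,5,6\n")
        prof = resample_profile(samples, 1e-3)
        assert prof.arc_length == pytest.approx(0.100, abs=1e-12)

    def test_circular_arc_length_matches_closed_form(self):
        # stations on a circle of radius 100 mm spanning 60 degrees
        R = 100.0
        th = np.linspace(-np.pi / 6, np.pi / 6, 9)
        x = R * np.sin(th)
        y = R * (np.cos(th) - 1.0)
        rows = "".join(f"{xi - x[0]:.6f},{yi:.6f},,4,5,6\n" for xi, yi in zip(x, y))
        prof = resample_profile(table(HEADER + rows), 1e-3)
        expected = R * 1e-3 * (np.pi / 3)
        assert prof.arc_length == pytest.approx(expected, rel=5e-3)

    def test_too_coarse_ds_rejected(self, fixture_samples):
        with pytest.raises(GeometryError, match="half the smallest"):
            resample_profile(fixture_samples, 20e-3)

    def test_area_partition_identity(self, profile):
        # cord annulus + syrinx disc reassemble the full cord disc
        disc = np.pi * profile.r_cord**2
        assert np.allclose(profile.A_cord + profile.A_syrinx, disc, rtol=1e-3)

    def test_arc_length_at_least_chord(self, profile):
        chord = np.linalg.norm(profile.xy[-1] - profile.xy[0])
        assert profile.arc_length >= chord - 1e-12

    def test_refinement_stability(self, fixture_samples):
        p1 = resample_profile(fixture_samples, 1e-3)
        p2 = resample_profile(fixture_samples, 0.5e-3)
        assert abs(p2.arc_length - p1.arc_length) / p1.arc_length < 5e-3
        i1 = np.trapezoid(np.abs(p1.kappa), p1.s)
        i2 = np.trapezoid(np.abs(p2.kappa), p2.s)
        assert abs(i2 - i1) / i1 < 5e-3


class TestCurvature:
    def test_straight_profile_has_zero_curvature(self):
        samples = table(HEADER + "0,0,,4,5,6\n50,0,,4,5,6\n100,0,,4,5,6\n")
        prof = resample_profile(samples, 1e-3)
        assert np.allclose(prof.kappa, 0.0, atol=1e-9)

    def test_circle_curvature_is_inverse_radius(self):
        R = 100.0
        th = np.linspace(-np.pi / 8, np.pi / 8, 15)
        x = R * np.sin(th)
        y = R * (np.cos(th) - 1.0)
        rows = "".join(f"{xi - x[0]:.6f},{yi:.6f},,4,5,6\n" for xi, yi in zip(x, y))
        prof = resample_profile(table(HEADER + rows), 1e-3)
        interior = slice(5, -5)
        assert np.abs(prof.kappa[interior]) == pytest.approx(10.0, rel=1e-2)

    def test_fixture_has_cranial_cervical_flexure(self, fixture_samples):
        prof = resample_profile(fixture_samples, 1e-3)
        x_mm = prof.xy[:, 0] * 1e3
        window = (x_mm >= 10) & (x_mm <= 50)
        k = np.abs(prof.kappa)
        # a local curvature maximum inside the cranial cervical window
        assert k[window].max() > 1.5 * np.median(k)
        jmax = np.argmax(np.where(window, k, 0.0))
        assert 0 < jmax < prof.n_stations - 1

    def test_too_few_stations_rejected(self, profile):
        from dataclasses import replace
        tiny = replace(profile, s=profile.s[:2], xy=profile.xy[:2],
                       r_syrinx=profile.r_syrinx[:2], r_cord=profile.r_cord[:2],
                       r_sas=profile.r_sas[:2], r_eds=profile.r_eds[:2],
                       kappa=profile.kappa[:2], has_syrinx=profile.has_syrinx[:2])
        with pytest.raises(InsufficientDataError):
            compute_curvature(tiny)


class TestExtension:
    def test_zero_length_is_identity(self, fixture_samples):
        prof = resample_profile(fixture_samples, 1e-3)
        assert extend_cranially(prof, 0.0) is prof

    def test_fifteen_mm_extends_arc_exactly(self, fixture_samples):
        prof = resample_profile(fixture_samples, 1e-3)
        ext = extend_cranially(prof, 15e-3)
        assert ext.arc_length - prof.arc_length == pytest.approx(15e-3, abs=1e-12)
        assert ext.extension_length == pytest.approx(15e-3, abs=1e-12)

    def test_extension_extrudes_cranial_section(self, fixture_samples):
        prof = resample_profile(fixture_samples, 1e-3)
        ext = extend_cranially(prof, 15e-3)
        assert np.allclose(ext.A_sas[:15], prof.A_sas[0])
        assert np.allclose(ext.kappa[:15], 0.0)
        # original cranial end addressable at s = extension_length
        j = ext.station_nearest(ext.extension_length)
        assert ext.r_cord[j] == pytest.approx(prof.r_cord[0])

    def test_negative_length_rejected(self, profile):
        with pytest.raises(GeometryError):
            extend_cranially(profile, -1e-3)


def test_fixture_round_trips_through_resampling():
    """Radii of the resampled grid match the table at the station locations."""
    samples = builtin_fixture()
    prof = resample_profile(samples, 1e-3)
    for s in samples[:-1]:  # caudal-most cord radius is filled, skip it
        j = int(np.argmin(np.abs(prof.xy[:, 0] - s.x_mm * 1e-3)))
        assert prof.r_cord[j] * 1e3 == pytest.approx(s.r_cord_mm, abs=0.05)
        assert prof.r_sas[j] * 1e3 == pytest.approx(s.r_sas_mm, abs=0.05)
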