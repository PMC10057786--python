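"""NBR computation, stack statistics and geospatial covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, MultiLineString

from peatsense.raster import GridGeoref, Raster
from peatsense.remote_sensing import (SceneStack, distance_to_line,
                                      extract_at_sites, nbr, normality_check,
                                      read_geojson_lines, stack_stats,
                                      write_geojson_lines)

GEOREF = GridGeoref(0.0, 100.0, 10.0, -10.0)


def make_stack(nbr_series, shape=(4, 4)):
    """Stack whose every pixel carries the given NBR series."""
    n = len(nbr_series)
    nbr_arr = np.tile(np.asarray(nbr_series)[:, None, None], (1, *shape))
    total = 0.5
    nir = total * (1 + nbr_arr) / 2
    return SceneStack(years=list(range(2000, 2000 + n)), nir=nir,
                      swir2=total - nir, georef=GEOREF, crs="EPSG:32647")


@pytest.mark.parametrize("nir_v,swir_v,expected", [
    (0.3, 0.3, 0.0),
    (0.4, 0.0, 1.0),
    (0.5, 0.1, 2 / 3),
])
def test_nbr_values(nir_v, swir_v, expected):
    assert nbr(nir_v, swir_v) == pytest.approx(expected)


def test_nbr_zero_denominator_is_nodata():
    assert np.isnan(nbr(0.0, 0.0))


@given(a=st.floats(0.001, 1.0), b=st.floats(0.001, 1.0))
@settings(max_examples=100, deadline=None)
def test_nbr_bounded_and_antisymmetric(a, b):
    v = nbr(a, b)
    assert -1.0 <= v <= 1.0
    assert v == pytest.approx(-nbr(b, a))


def test_stack_stats_two_point_series():
    prod = stack_stats(make_stack([0.2, 0.4]))
    assert np.allclose(prod.nbr_mean, 0.3)
    assert np.allclose(prod.nbr_sd, np.sqrt(((0.2 - 0.3) ** 2 + (0.4 - 0.3) ** 2) / 1))


def test_stack_stats_constant_series_has_zero_sd():
    prod = stack_stats(make_stack([0.5, 0.5, 0.5]))
    assert np.allclose(prod.nbr_sd, 0.0)


def test_stack_stats_matches_per_pixel_loop(rng):
    """Oracle equivalence: vectorised stats equal a brute-force pixel loop."""
    n_years, nrow, ncol = 5, 6, 7
    nir = rng.uniform(0.1, 0.6, (n_years, nrow, ncol))
    swir2 = rng.uniform(0.05, 0.4, (n_years, nrow, ncol))
    nir[2, 1, 1] = np.nan  # one nodata pixel-year
    stack = SceneStack(years=list(range(n_years)), nir=nir, swir2=swir2,
                       georef=GEOREF)
    prod = stack_stats(stack)
    for r in range(nrow):
        for c in range(ncol):
            series = []
            for t in range(n_years):
                a, b = nir[t, r, c], swir2[t, r, c]
                if np.isfinite(a) and np.isfinite(b) and a + b > 0:
                    series.append((a - b) / (a + b))
            assert prod.nbr_mean[r, c] == pytest.approx(np.mean(series))
            assert prod.nbr_sd[r, c] == pytest.approx(np.std(series, ddof=1))


def test_stack_stats_nodata_year_reduces_n():
    nir = np.full((3, 2, 2), 0.4)
    swir2 = np.full((3, 2, 2), 0.1)
    nir[0, 0, 0] = np.nan
    prod = stack_stats(SceneStack(years=[1, 2, 3], nir=nir, swir2=swir2, georef=GEOREF))
    assert prod.nbr_mean[0, 0] == pytest.approx(0.6)  # over the 2 valid years
    # a single-valid-year pixel would get NaN sd
    nir[:2, 1, 1] = np.nan
    prod = stack_stats(SceneStack(years=[1, 2, 3], nir=nir, swir2=swir2, georef=GEOREF))
    assert np.isnan(prod.nbr_sd[1, 1])


def test_empty_stack_rejected():
    with pytest.raises(ValueError):
        stack_stats(SceneStack(years=[], nir=np.empty((0, 2, 2)),
                               swir2=np.empty((0, 2, 2)), georef=GEOREF))


def test_normality_check_calibration_and_power(rng):
    n_series, n_years = 300, 50
    # Gaussian series: ~5% rejections
    nbr_g = np.clip(rng.normal(0.4, 0.05, (n_years, 20, 15)), -0.9, 0.9)
    total = 0.5
    stack = SceneStack(years=list(range(n_years)), nir=total * (1 + nbr_g) / 2,
                       swir2=total * (1 - nbr_g) / 2, georef=GEOREF)
    rep = normality_check(stack, sample_size=n_series, seed=1)
    frac = rep["reject_05"].mean()
    assert frac < 0.12
    # heavily skewed series: high power
    nbr_e = np.clip(rng.exponential(0.15, (n_years, 20, 15)) - 0.5, -0.9, 0.9)
    stack_e = SceneStack(years=list(range(n_years)), nir=total * (1 + nbr_e) / 2,
                         swir2=total * (1 - nbr_e) / 2, georef=GEOREF)
    rep_e = normality_check(stack_e, sample_size=n_series, seed=1)
    assert rep_e["reject_05"].mean() > 0.5


def test_normality_check_flags_constant_series():
    stack = make_stack([0.5, 0.5, 0.5, 0.5])
    rep = normality_check(stack, sample_size=5, seed=0)
    assert rep["undefined"].all()


def test_extract_at_pixel_centers_and_nearest_cell():
    raster = np.indices((10, 10)).sum(axis=0) % 2.0  # checkerboard
    g = GridGeoref(0.0, 100.0, 10.0, -10.0)
    x, y = g.pixel_center(3, 4)
    sites = pd.DataFrame({"site_id": ["a", "b"],
                          "x": [x, x + 4.0],   # +0.4 pixel nudge stays in cell
                          "y": [y, y - 4.0]})
    vals = extract_at_sites(raster, g, sites)
    assert vals[0] == raster[3, 4]
    assert vals[1] == raster[3, 4]


def test_extract_constant_raster():
    raster = np.full((5, 5), 7.5)
    sites = pd.DataFrame({"site_id": ["s1"], "x": [25.0], "y": [75.0]})
    assert extract_at_sites(raster, GEOREF, sites)[0] == 7.5


def test_extract_outside_bounds_names_site():
    raster = np.zeros((5, 5))
    sites = pd.DataFrame({"site_id": ["wayout"], "x": [1e6], "y": [0.0]})
    with pytest.raises(ValueError, match="wayout"):
        extract_at_sites(raster, GEOREF, sites)


@pytest.mark.parametrize("pt,expected", [
    ((5.0, 0.0), 0.0),
    ((3.0, 4.0), 4.0),
    ((-2.0, 3.0), np.sqrt(13)),
])
def test_distance_to_segment(pt, expected):
    line = LineString([(0, 0), (10, 0)])
    assert distance_to_line(pt, line, crs="EPSG:32647") == pytest.approx(expected)


def test_distance_matches_densified_brute_force(rng):
    line = MultiLineString([[(0, 0), (10, 5), (12, -3)], [(20, 20), (25, 18)]])
    dense = []
    for geom in line.geoms:
        for (x0, y0), (x1, y1) in zip(geom.coords[:-1], geom.coords[1:]):
            t = np.linspace(0, 1, 20001)
            dense.append(np.column_stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)]))
    dense = np.vstack(dense)
    for _ in range(20):
        p = rng.uniform(-5, 30, 2)
        brute = np.min(np.hypot(dense[:, 0] - p[0], dense[:, 1] - p[1]))
        assert distance_to_line(tuple(p), line) == pytest.approx(brute, rel=1e-6, abs=1e-6)


def test_geographic_crs_rejected():
    with pytest.raises(ValueError, match="geographic"):
        distance_to_line((0, 0), LineString([(0, 0), (1, 1)]), crs="EPSG:4326")


def test_raster_and_geojson_round_trip(tmp_path):
    r = Raster(np.arange(12.0).reshape(3, 4), GEOREF, crs="EPSG:32647")
    path = str(tmp_path / "x.tif")
    r.write(path)
    back = Raster.read(path)
    assert np.allclose(back.data, r.data)
    assert back.georef == r.georef and back.crs == r.crs

    lines = [LineString([(0, 0), (5, 5)]), LineString([(1, 0), (1, 9)])]
    gpath = str(tmp_path / "lines.geojson")
    write_geojson_lines(lines, gpath, crs="EPSG:32647")
    merged = read_geojson_lines(gpath)
    assert merged.length == pytest.approx(sum(l.length for l in lines))
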