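"""Mollweide grid, range rasterization, competition indices, realm labels."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon, box

from nichetime import rangegrid as rg
from nichetime.activity import classify_table
from nichetime.synthdata import paper_fixture


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_mollweide_origin_and_pole():
    x, y = rg.mollweide_project(0.0, 0.0)
    assert (x, y) == (pytest.approx(0.0, abs=1e-9), pytest.approx(0.0, abs=1e-9))
    x, y = rg.mollweide_project(0.0, 90.0)
    assert x == pytest.approx(0.0, abs=1e-9)
    assert y == pytest.approx(np.sqrt(2.0) * rg.EARTH_RADIUS_KM, abs=1e-6)


def test_mollweide_roundtrip(rng):
    lon = rng.uniform(-179.9, 179.9, 500)
    lat = rng.uniform(-89.9, 89.9, 500)
    x, y = rg.mollweide_project(lon, lat)
    lon2, lat2 = rg.mollweide_inverse(x, y)
    assert np.nanmax(np.abs(lon2 - lon)) < 1e-6
    assert np.nanmax(np.abs(lat2 - lat)) < 1e-6


def test_mollweide_inverse_outside_ellipse_is_nan():
    lon, lat = rg.mollweide_inverse(3e4, 1e4)
    assert np.isnan(lon) and np.isnan(lat)


def test_mollweide_equal_area_property(rng):
    """Jacobian of small quads matches the spherical patch area to 0.1%."""
    R = rg.EARTH_RADIUS_KM
    for _ in range(50):
        lon = rng.uniform(-170, 170)
        lat = rng.uniform(-80, 80)
        d = 0.01  # degrees
        lons = np.array([lon, lon + d, lon + d, lon])
        lats = np.array([lat, lat, lat + d, lat + d])
        x, y = rg.mollweide_project(lons, lats)
        area_proj = Polygon(zip(x, y)).area
        area_sphere = (R ** 2 * np.radians(d)
                       * (np.sin(np.radians(lat + d)) - np.sin(np.radians(lat))))
        assert area_proj == pytest.approx(area_sphere, rel=1e-3)


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def test_build_grid_small_boxes():
    four = rg.build_grid(rg.GridSpec(cell_size_km=112.5,
                                     bounds=(0, 0, 225, 225)))
    assert len(four) == 4
    one = rg.build_grid(rg.GridSpec(cell_size_km=112.5, bounds=(0, 0, 50, 50)))
    assert len(one) == 1
    with pytest.raises(ValueError, match="degenerate"):
        rg.build_grid(rg.GridSpec(bounds=(0, 0, -10, 10)))


def test_global_grid_cell_count_matches_area():
    """Retained-cell count ~ sphere area / cell area (equal-area projection),
    and retention equals the centroid-in-ellipse rule exactly."""
    spec = rg.GridSpec(cell_size_km=112.5)
    grid = rg.build_grid(spec)
    R = spec.radius_km
    expected = 4 * np.pi * R ** 2 / spec.cell_size_km ** 2
    assert abs(len(grid) - expected) / expected < 0.05
    # geometry oracle: a centroid is kept iff inside the map ellipse
    a, b = 2 * np.sqrt(2) * R, np.sqrt(2) * R
    inside = (grid["x"] / a) ** 2 + (grid["y"] / b) ** 2 <= 1 + 1e-9
    assert inside.all()


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _small_grid():
    return rg.build_grid(rg.GridSpec(cell_size_km=112.5,
                                     bounds=(-450, -450, 450, 450)))


def _lonlat_box(x0, y0, x1, y1):
    xs = np.array([x0, x1, x1, x0])
    ys = np.array([y0, y0, y1, y1])
    lon, lat = rg.mollweide_inverse(xs, ys)
    return Polygon(zip(lon, lat))


def test_rasterize_cell_congruent_polygon():
    grid = _small_grid()
    # shrink slightly so projection curvature cannot leak into neighbours
    poly = _lonlat_box(2, 2, 110, 110)
    hits = rg.rasterize_range(poly, grid)
    spec = grid.attrs["spec"]
    assert len(hits) == 1
    cid = hits.pop()
    assert 0 <= grid.loc[cid, "x"] <= 112.5 and 0 <= grid.loc[cid, "y"] <= 112.5


def test_rasterize_two_by_two():
    grid = _small_grid()
    poly = _lonlat_box(-60, -60, 60, 60)  # spans the four central cells
    assert len(rg.rasterize_range(poly, grid)) == 4


def test_rasterize_monotone_under_growth(rng):
    grid = _small_grid()
    for _ in range(10):
        cx, cy = rng.uniform(-250, 250, 2)
        small = shapely.Point(cx, cy).buffer(float(rng.uniform(30, 120)))
        big = shapely.Point(cx, cy).buffer(small.bounds[2] - cx + 100)
        to_ll = lambda p: shapely.transform(
            p, lambda c: np.column_stack(rg.mollweide_inverse(c[:, 0], c[:, 1])))
        h_small = rg.rasterize_range(to_ll(small), grid)
        h_big = rg.rasterize_range(to_ll(big), grid)
        assert h_small <= h_big


def test_rasterize_against_fine_lattice_oracle(rng):
    """Overlap predicate agrees with 10x-finer point-in-polygon membership up
    to slivers thinner than the fine lattice."""
    grid = _small_grid()
    spec = grid.attrs["spec"]
    s = spec.cell_size_km
    x0, y0 = grid.attrs["origin"]
    for _ in range(12):
        cx, cy = rng.uniform(-250, 250, 2)
        disc = shapely.Point(cx, cy).buffer(float(rng.uniform(80, 260)), 64)
        lonlat = shapely.transform(
            disc, lambda c: np.column_stack(rg.mollweide_inverse(c[:, 0], c[:, 1])))
        hits = rg.rasterize_range(lonlat, grid)
        # oracle: project and test a 10x10 sub-lattice of every grid cell
        from nichetime.rangegrid import _project_polygon

        ppoly = _project_polygon(lonlat, spec.radius_km)
        shapely.prepare(ppoly)
        oracle = set()
        for cid, row in grid.iterrows():
            xs = row["x"] - s / 2 + (np.arange(10) + 0.5) * s / 10
            ys = row["y"] - s / 2 + (np.arange(10) + 0.5) * s / 10
            XX, YY = np.meshgrid(xs, ys)
            pts = shapely.points(XX.ravel(), YY.ravel())
            if shapely.intersects(ppoly, pts).any():
                oracle.add(cid)
        assert oracle <= hits
        for cid in hits - oracle:  # only slivers below lattice resolution
            row = grid.loc[cid]
            cell = box(row["x"] - s / 2, row["y"] - s / 2,
                       row["x"] + s / 2, row["y"] + s / 2)
            assert ppoly.intersection(cell).area < (s / 10) ** 2 * 4


def test_rasterize_empty_polygon_rejected():
    grid = _small_grid()
    with pytest.raises(ValueError):
        rg.rasterize_range(Polygon(), grid)


def test_min_fraction_filter():
    grid = _small_grid()
    poly = _lonlat_box(2, 2, 170, 110)  # covers one cell + half a neighbour
    assert len(rg.rasterize_range(poly, grid)) == 2
    assert len(rg.rasterize_range(poly, grid, min_fraction=0.9)) == 1


# ---------------------------------------------------------------------------
# competition indices and shifter richness
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def classified():
    return classify_table(paper_fixture())


def _mini_table():
    return classify_table(pd.DataFrame([
        {"species_id": "a1", "order": "Accipitriformes", "day": 1, "twilight": 0,
         "night": 0, "body_length_cm": 50.0},
        {"species_id": "a2", "order": "Accipitriformes", "day": 1, "twilight": 1,
         "night": 0, "body_length_cm": 25.0},
        {"species_id": "s1", "order": "Strigiformes", "day": 0, "twilight": 0,
         "night": 1, "body_length_cm": 40.0},
        {"species_id": "s2", "order": "Strigiformes", "day": 2, "twilight": 0,
         "night": 1, "body_length_cm": 20.0},
        {"species_id": "f1", "order": "Falconiformes", "day": 1, "twilight": 0,
         "night": 0, "body_length_cm": 35.0},
    ]))


def test_competition_indices_counts():
    tab = _mini_table()
    species = {"a1", "a2", "s1", "s2", "f1"}
    expl, interf = rg.competition_indices(species, tab, "Accipitriformes")
    assert (expl, interf) == (5, 3)  # a1, a2, f1 have day class 1
    expl, interf = rg.competition_indices(species, tab, "Strigiformes")
    assert (expl, interf) == (5, 2)  # s1, s2 have night class 1


def test_competition_occasional_use_excluded():
    tab = _mini_table()
    # s2 uses the day only occasionally (class 2): not a day-interference source
    _, interf = rg.competition_indices({"a1", "s2"}, tab, "Accipitriformes")
    assert interf == 1


def test_competition_size_threshold():
    tab = _mini_table()
    expl, interf = rg.competition_indices({"a1", "a2", "s1", "s2", "f1"}, tab,
                                          "Strigiformes", size_threshold_cm=30.0)
    assert (expl, interf) == (3, 1)  # only a1, s1, f1 remain; s1 night-active


def test_competition_unknown_order():
    with pytest.raises(ValueError, match="unknown focal order"):
        rg.competition_indices({"a1"}, _mini_table(), "Falconiformes")


def test_timeshifter_richness_zero_vs_missing():
    tab = _mini_table()
    assert rg.timeshifter_richness({"a1", "a2"}, tab, "Accipitriformes") == 1
    assert rg.timeshifter_richness({"a1"}, tab, "Accipitriformes") == 0
    assert np.isnan(rg.timeshifter_richness({"s1"}, tab, "Accipitriformes"))
    # small-owl model: cell with only a large owl is missing, not zero
    assert np.isnan(rg.timeshifter_richness({"s1"}, tab, "Strigiformes",
                                            subgroup="small"))
    assert rg.timeshifter_richness({"s2"}, tab, "Strigiformes",
                                   subgroup="small") == 1


# ---------------------------------------------------------------------------
# realms and migratory filter
# ---------------------------------------------------------------------------

def test_assign_realms_mapping_and_polygons():
    grid = _small_grid()
    mapping = pd.Series("west", index=grid.index)
    mapping[grid["lon"] >= 0] = "east"
    out = rg.assign_realms(grid, mapping)
    assert set(out["realm"]) == {"west", "east"}
    assert out["realm"].value_counts().sum() == len(grid)
    # polygon mode via centroid containment
    west = box(-180, -90, 0, 90)
    east = box(0, -90, 180.0001, 90)
    out2 = rg.assign_realms(grid, {"west": west, "east": east})
    boundary = out2["lon"] == 0  # boundary cells take the first covering realm
    assert (out2.loc[~boundary, "realm"] == out.loc[~boundary, "realm"]).all()
    with pytest.raises(ValueError, match="not covered"):
        rg.assign_realms(grid, {"west": box(-180, -90, -1, 90)})


def test_filter_migratory(classified):
    out = rg.filter_migratory(classified, exclude=False)
    assert out is classified
    out = rg.filter_migratory(classified, exclude=True)
    assert len(out) == 396 - 48
    all_mig = classified.copy()
    all_mig["migratory"] = True
    with pytest.warns(UserWarning, match="all species"):
        assert len(rg.filter_migratory(all_mig, exclude=True)) == 0


# ---------------------------------------------------------------------------
# assemblage table invariants
# ---------------------------------------------------------------------------

def test_assemblage_table_invariants(rng):
    from nichetime.synthdata import SyntheticScenario, simulate_world

    world = simulate_world(SyntheticScenario(
        seed=31, n_accipitriformes=30, n_strigiformes=40, n_falconiformes=8,
        window_km=700.0))
    tab = world.assemblage
    assert (tab["richness_day_active"] <= tab["richness_total"]).all()
    assert (tab["richness_night_active"] <= tab["richness_total"]).all()
    assert (tab["richness_night_active_large"]
            <= tab["richness_night_active"]).all()
    ts = tab["ts_strigiformes"].dropna()
    assert (ts <= tab.loc[ts.index, "n_strigiformes"]).all()
    sub = tab[["ts_strigiformes_small", "n_strigiformes_small"]].dropna()
    assert (sub["ts_strigiformes_small"] <= sub["n_strigiformes_small"]).all()
    # membership order must not matter
    shuffled = world.membership.sample(frac=1.0, random_state=1)
    tab2 = rg.build_assemblage_table(world.grid, shuffled, world.classified)
    pd.testing.assert_frame_equal(tab.drop(columns=["day_length", "night_length"]),
                                  tab2)
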