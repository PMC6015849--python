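"""Equal-area analysis grid, range rasterization and competition indices.

Assemblages are the cells of a square grid (default 112.5 x 112.5 km) laid on
a spherical Mollweide projection. A species belongs to the assemblage of every
cell its breeding-range polygon overlaps. Per assemblage, exploitation
competition pressure is the total avian-predator richness; interference
competition pressure is the richness of species frequently active (class 1)
in the focal order's typical period (day for Accipitriformes, night for
Strigiformes), optionally restricted to competitors above a body-size
threshold (used for large owls, > 30 cm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import box, shape
from shapely.ops import unary_union

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "mollweide_project",
    "mollweide_inverse",
    "build_grid",
    "rasterize_range",
    "rasterize_ranges",
    "competition_indices",
    "timeshifter_richness",
    "assign_realms",
    "filter_migratory",
    "build_assemblage_table",
    "read_ranges_geojson",
]

EARTH_RADIUS_KM = 6371.007  # authalic sphere radius


def mollweide_project(lon, lat, radius: float = EARTH_RADIUS_KM):
    """Forward spherical Mollweide: degrees -> km.

    Solves the auxiliary angle theta from 2*theta + sin(2*theta) = pi*sin(lat)
    by Newton iteration to 1e-10.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam = np.radians(lon)
    phi = np.radians(lat)
    theta = np.arcsin(np.clip(2 * phi / np.pi, -1, 1))  # decent start
    target = np.pi * np.sin(phi)
    for _ in range(100):
        f = 2 * theta + np.sin(2 * theta) - target
        fp = 2 + 2 * np.cos(2 * theta)
        step = np.where(np.abs(fp) > 1e-14, f / np.where(fp == 0, 1, fp), 0.0)
        theta = theta - step
        if np.max(np.abs(f)) < 1e-12:
            break
    # poles: fp -> 0; theta -> +-pi/2 exactly
    theta = np.where(np.isclose(np.abs(phi), np.pi / 2), np.sign(phi) * np.pi / 2,
                     theta)
    x = radius * (2.0 * np.sqrt(2.0) / np.pi) * lam * np.cos(theta)
    y = radius * np.sqrt(2.0) * np.sin(theta)
    return x, y


def mollweide_inverse(x, y, radius: float = EARTH_RADIUS_KM):
    """Inverse spherical Mollweide: km -> degrees. Points outside the map
    ellipse return NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sin_theta = y / (radius * np.sqrt(2.0))
    bad = np.abs(sin_theta) > 1.0 + 1e-12
    sin_theta = np.clip(sin_theta, -1.0, 1.0)
    theta = np.arcsin(sin_theta)
    sin_phi = (2 * theta + np.sin(2 * theta)) / np.pi
    bad |= np.abs(sin_phi) > 1.0 + 1e-9
    phi = np.arcsin(np.clip(sin_phi, -1.0, 1.0))
    cos_theta = np.cos(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.pi * x / (radius * 2.0 * np.sqrt(2.0) * cos_theta)
    lam = np.where(cos_theta < 1e-12, 0.0, lam)
    bad |= np.abs(lam) > np.pi + 1e-9
    lon = np.degrees(lam)
    lat = np.degrees(phi)
    lon = np.where(bad, np.nan, lon)
    lat = np.where(bad, np.nan, lat)
    return lon, lat


@dataclass
class GridSpec:
    """Square tiling of (a window of) the Mollweide plane.

    ``bounds`` is the projected bounding box (xmin, ymin, xmax, ymax) in km;
    ``None`` means the whole map. Cells are retained when their centroid
    inverts to a valid longitude/latitude.
    """

    cell_size_km: float = 112.5
    radius_km: float = EARTH_RADIUS_KM
    bounds: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    def full_bounds(self) -> tuple[float, float, float, float]:
        if self.bounds is not None:
            xmin, ymin, xmax, ymax = self.bounds
            if xmax <= xmin or ymax <= ymin:
                raise ValueError("degenerate bounding box")
            return self.bounds
        xmax = self.radius_km * 2.0 * np.sqrt(2.0)
        ymax = self.radius_km * np.sqrt(2.0)
        return (-xmax, -ymax, xmax, ymax)


def build_grid(spec: GridSpec) -> pd.DataFrame:
    """Cells of the grid: cell_id, row/col, projected centroid (x, y km) and
    geographic centroid (lon, lat). Cells whose centroid falls outside the
    Mollweide ellipse are dropped."""
    xmin, ymin, xmax, ymax = spec.full_bounds()
    s = spec.cell_size_km
    ncol = max(int(np.ceil((xmax - xmin) / s - 1e-9)), 1)
    nrow = max(int(np.ceil((ymax - ymin) / s - 1e-9)), 1)
    cols, rows = np.meshgrid(np.arange(ncol), np.arange(nrow))
    cols = cols.ravel()
    rows = rows.ravel()
    cx = xmin + (cols + 0.5) * s
    cy = ymin + (rows + 0.5) * s
    lon, lat = mollweide_inverse(cx, cy, spec.radius_km)
    ok = ~(np.isnan(lon) | np.isnan(lat))
    df = pd.DataFrame({
        "cell_id": rows[ok] * ncol + cols[ok],
        "row": rows[ok], "col": cols[ok],
        "x": cx[ok], "y": cy[ok], "lon": lon[ok], "lat": lat[ok],
    }).set_index("cell_id")
    df.attrs["spec"] = spec
    df.attrs["origin"] = (xmin, ymin)
    df.attrs["shape"] = (nrow, ncol)
    return df


def _project_polygon(poly, radius: float, densify_km: float | None = None):
    """Project a lon/lat polygon to the Mollweide plane, densifying edges so
    straight projected edges track the true projected boundary."""
    if poly.is_empty:
        raise ValueError("empty polygon")
    if densify_km is None:
        densify_km = 25.0
    # densify in degrees: ~1 degree ~ 111 km
    step_deg = max(densify_km / 111.0, 1e-3)
    poly = shapely.segmentize(poly, step_deg)

    def tx(geom):
        return shapely.transform(
            geom,
            lambda coords: np.column_stack(
                mollweide_project(coords[:, 0], coords[:, 1], radius)),
        )

    return tx(poly)


def _wrap_lonlat(poly):
    """Normalize a polygon whose longitudes run outside [-180, 180] by
    splitting it at the antimeridian."""
    xmin, _, xmax, _ = poly.bounds
    if xmin >= -180.0 and xmax <= 180.0:
        return poly
    world = box(-180, -90, 180, 90)
    pieces = []
    for shift in (-360.0, 0.0, 360.0):
        moved = shapely.affinity.translate(poly, xoff=shift) if shift else poly
        clipped = moved.intersection(world)
        if not clipped.is_empty:
            pieces.append(clipped)
    return unary_union(pieces)


def rasterize_range(range_polygon, grid: pd.DataFrame,
                    min_fraction: float = 0.0) -> set[int]:
    """Cells of ``grid`` whose square intersects the projected range polygon.

    Any overlap counts (boundary touch included) unless ``min_fraction`` > 0,
    in which case at least that fraction of the cell area must be covered.
    """
    if range_polygon is None or range_polygon.is_empty:
        raise ValueError("empty or invalid range polygon")
    spec: GridSpec = grid.attrs["spec"]
    xmin0, ymin0 = grid.attrs["origin"]
    s = spec.cell_size_km
    poly = _wrap_lonlat(range_polygon)
    ppoly = _project_polygon(poly, spec.radius_km)
    pxmin, pymin, pxmax, pymax = ppoly.bounds
    c0 = int(np.floor((pxmin - xmin0) / s))
    c1 = int(np.floor((pxmax - xmin0) / s))
    r0 = int(np.floor((pymin - ymin0) / s))
    r1 = int(np.floor((pymax - ymin0) / s))
    nrow, ncol = grid.attrs["shape"]
    hits: set[int] = set()
    index = grid.index
    shapely.prepare(ppoly)
    for r in range(max(r0, 0), min(r1, nrow - 1) + 1):
        for c in range(max(c0, 0), min(c1, ncol - 1) + 1):
            cid = r * ncol + c
            if cid not in index:
                continue
            cell_geom = box(xmin0 + c * s, ymin0 + r * s,
                            xmin0 + (c + 1) * s, ymin0 + (r + 1) * s)
            if not ppoly.intersects(cell_geom):
                continue
            if min_fraction > 0:
                frac = ppoly.intersection(cell_geom).area / (s * s)
                if frac < min_fraction:
                    continue
            hits.add(int(cid))
    return hits


def rasterize_ranges(ranges: dict, grid: pd.DataFrame,
                     min_fraction: float = 0.0) -> pd.DataFrame:
    """Long membership table (cell_id, species_id) for a species->polygon map."""
    recs = []
    for sp, poly in ranges.items():
        for cid in sorted(rasterize_range(poly, grid, min_fraction)):
            recs.append((cid, sp))
    return pd.DataFrame(recs, columns=["cell_id", "species_id"])


# ---------------------------------------------------------------------------
# assemblage-level quantities
# ---------------------------------------------------------------------------

_TYPICAL_PERIOD = {"Accipitriformes": "day", "Strigiformes": "night"}


def competition_indices(cell_species, classified: pd.DataFrame, focal_order: str,
                        size_threshold_cm: float | None = None,
                        exclude: str | None = None) -> tuple[int, int]:
    """(exploitation, interference) pressure for one assemblage.

    ``cell_species`` is the species set of the cell; ``classified`` the
    species table (needs order, day/night classes and body_length_cm).
    Exploitation = total predator richness (all orders, any activity).
    Interference = species of any order with class 1 in the focal order's
    typical period; with ``size_threshold_cm`` both counts keep only
    competitors strictly larger than the threshold. ``exclude`` optionally
    drops one (focal) species from the counts.
    """
    if focal_order not in _TYPICAL_PERIOD:
        raise ValueError(f"unknown focal order {focal_order!r}")
    sub = classified[classified["species_id"].isin(set(cell_species))]
    if exclude is not None:
        sub = sub[sub["species_id"] != exclude]
    if size_threshold_cm is not None:
        sub = sub[sub["body_length_cm"] > size_threshold_cm]
    period = _TYPICAL_PERIOD[focal_order]
    exploitation = int(len(sub))
    interference = int((sub[period] == 1).sum())
    return exploitation, interference


def timeshifter_richness(cell_species, classified: pd.DataFrame, order: str,
                         subgroup: str = "all",
                         size_threshold_cm: float = 30.0) -> float:
    """Time-shifter count for one assemblage, or NaN when undefined.

    The count is zero only when the order (or, for the small/large owl
    subgroups, the subgroup) is represented in the cell at all; otherwise the
    cell is excluded (NaN) from the corresponding model.
    """
    sub = classified[(classified["species_id"].isin(set(cell_species)))
                     & (classified["order"] == order)]
    if subgroup == "all":
        base = sub
    elif subgroup == "small":
        base = sub[sub["body_length_cm"] < size_threshold_cm]
    elif subgroup == "large":
        base = sub[sub["body_length_cm"] >= size_threshold_cm]
    else:
        raise ValueError("subgroup must be 'all', 'small' or 'large'")
    if base.empty:
        return float("nan")
    return float(base["shifter"].fillna(False).sum())


def assign_realms(cells: pd.DataFrame, realm_partition) -> pd.DataFrame:
    """Attach a ``realm`` column to the cell table.

    ``realm_partition`` is either a mapping/Series cell_id -> realm label or
    a dict realm_label -> lon/lat polygon; polygon assignment uses the cell's
    geographic centroid. Every retained cell must be covered.
    """
    df = cells.copy()
    if isinstance(realm_partition, (dict,)) and realm_partition and \
            hasattr(next(iter(realm_partition.values())), "contains"):
        labels = pd.Series(index=df.index, dtype=object)
        pts = shapely.points(df["lon"].to_numpy(), df["lat"].to_numpy())
        for name, poly in realm_partition.items():
            inside = shapely.intersects(poly, pts)
            labels[inside & labels.isna().to_numpy()] = name
        if labels.isna().any():
            n = int(labels.isna().sum())
            raise ValueError(f"{n} cells not covered by any realm polygon")
        df["realm"] = labels
    else:
        mapping = pd.Series(realm_partition)
        missing = df.index.difference(mapping.index)
        if len(missing):
            raise ValueError(f"{len(missing)} cells without realm label")
        df["realm"] = mapping.reindex(df.index)
    return df


def filter_migratory(profiles: pd.DataFrame, exclude: bool = False) -> pd.DataFrame:
    """Optionally drop migratory species (sensitivity analysis)."""
    if not exclude:
        return profiles
    out = profiles[~profiles["migratory"].astype(bool)].copy()
    if out.empty:
        import warnings

        warnings.warn("all species are migratory: empty table after filtering",
                      stacklevel=2)
    return out


def build_assemblage_table(grid: pd.DataFrame, membership: pd.DataFrame,
                           classified: pd.DataFrame,
                           size_threshold_cm: float = 30.0) -> pd.DataFrame:
    """Per-cell richness and competition columns for the four focal models.

    Joins the membership table against the classified species table and
    produces, for every grid cell with at least one species: total richness,
    day-/night-active class-1 richness (and the >threshold night-active
    variant for the large-owl model), and time-shifter richness for
    Accipitriformes, all/small/large Strigiformes with the zero-vs-missing
    rule of :func:`timeshifter_richness`.
    """
    cls = classified.set_index("species_id")
    m = membership.copy()
    for col_src, col in (("order", "order"), ("day", "day"), ("night", "night"),
                         ("body_length_cm", "size"), ("shifter", "shifter")):
        m[col] = cls[col_src].reindex(m["species_id"]).to_numpy()
    m["shifter"] = m["shifter"].astype("boolean").fillna(False).astype(bool)
    m["large"] = m["size"] > size_threshold_cm
    m["small_owl"] = (m["order"] == "Strigiformes") & (m["size"] < size_threshold_cm)
    m["large_owl"] = (m["order"] == "Strigiformes") & (m["size"] >= size_threshold_cm)

    g = m.groupby("cell_id")
    out = pd.DataFrame({
        "richness_total": g.size(),
        "richness_day_active": g.apply(lambda s: int((s["day"] == 1).sum()),
                                       include_groups=False),
        "richness_night_active": g.apply(lambda s: int((s["night"] == 1).sum()),
                                         include_groups=False),
        "richness_night_active_large": g.apply(
            lambda s: int(((s["night"] == 1) & s["large"]).sum()),
            include_groups=False),
        "richness_total_large": g.apply(lambda s: int(s["large"].sum()),
                                        include_groups=False),
        "n_accipitriformes": g.apply(
            lambda s: int((s["order"] == "Accipitriformes").sum()),
            include_groups=False),
        "n_strigiformes": g.apply(lambda s: int((s["order"] == "Strigiformes").sum()),
                                  include_groups=False),
        "n_strigiformes_small": g.apply(lambda s: int(s["small_owl"].sum()),
                                        include_groups=False),
        "n_strigiformes_large": g.apply(lambda s: int(s["large_owl"].sum()),
                                        include_groups=False),
        "ts_acc_raw": g.apply(
            lambda s: int((s["shifter"] & (s["order"] == "Accipitriformes")).sum()),
            include_groups=False),
        "ts_strig_raw": g.apply(
            lambda s: int((s["shifter"] & (s["order"] == "Strigiformes")).sum()),
            include_groups=False),
        "ts_strig_small_raw": g.apply(lambda s: int((s["shifter"] & s["small_owl"]).sum()),
                                      include_groups=False),
        "ts_strig_large_raw": g.apply(lambda s: int((s["shifter"] & s["large_owl"]).sum()),
                                      include_groups=False),
    })
    # zero only where the order/subgroup occurs; else missing
    out["ts_accipitriformes"] = out["ts_acc_raw"].where(out["n_accipitriformes"] > 0)
    out["ts_strigiformes"] = out["ts_strig_raw"].where(out["n_strigiformes"] > 0)
    out["ts_strigiformes_small"] = out["ts_strig_small_raw"].where(
        out["n_strigiformes_small"] > 0)
    out["ts_strigiformes_large"] = out["ts_strig_large_raw"].where(
        out["n_strigiformes_large"] > 0)
    out = out.drop(columns=["ts_acc_raw", "ts_strig_raw", "ts_strig_small_raw",
                            "ts_strig_large_raw"])
    cols = grid[["x", "y", "lon", "lat"] + (["realm"] if "realm" in grid else [])]
    return cols.join(out, how="inner")


def read_ranges_geojson(path) -> dict:
    """Read a GeoJSON FeatureCollection of breeding ranges keyed by the
    ``species_id`` feature property."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = {}
    for feat in gj["features"]:
        sp = feat.get("properties", {}).get("species_id")
        if sp is None:
            raise ValueError("feature without species_id property")
        out[str(sp)] = _wrap_lonlat(shape(feat["geometry"]))
    return out
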