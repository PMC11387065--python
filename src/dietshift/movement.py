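"""GPS movement windows, trajectory buffers and habitat-use summaries.

Because dietary DNA integrates roughly the last three days of foraging,
each faecal sample is paired with the collared animal's GPS fixes from the
72 h before sampling. The fix sequence is buffered into a use polygon
(400 m by default) and summarized against 30 m elevation and land-cover
grids: mean elevation, area occupied (km^2), habitat richness (number of
cover classes used) and per-class proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point

from .community import bray_curtis
from .rasters import Raster


class MissingWindowError(ValueError):
    """No GPS fixes fall in the 72 h window before the sampling event."""


@dataclass
class TrackWindow:
    """Ordered GPS fixes of one animal within a pre-sampling window."""

    animal_id: str
    fixes: pd.DataFrame  # columns: timestamp (datetime64), x, y (metres)

    def __post_init__(self):
        t = self.fixes["timestamp"]
        if len(self.fixes) == 0:
            raise MissingWindowError(f"no fixes for {self.animal_id}")
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


@dataclass
class UsePolygon:
    """Buffered trajectory polygon with its area in km^2."""

    geometry: shapely.Geometry
    area_km2: float
    window_id: str


@dataclass
class HabitatSummary:
    """Raster summary of one use polygon."""

    mean_elevation: float
    area_km2: float
    habitat_richness: int
    proportions: pd.Series  # per cover class, sums to 1

    def as_series(self) -> pd.Series:
        out = pd.Series(
            {
                "mean_elevation": self.mean_elevation,
                "area_km2": self.area_km2,
                "habitat_richness": self.habitat_richness,
            }
        )
        props = self.proportions.rename(lambda c: f"prop_{c}")
        return pd.concat([out, props])


def window_fixes(
    fix_table: pd.DataFrame,
    sample_time,
    window_h: float = 72.0,
    animal_id: str | None = None,
) -> TrackWindow:
    """Fixes of one animal in the ``window_h`` hours before ``sample_time``.

    ``fix_table`` needs columns ``animal_id``, ``timestamp``, ``x``, ``y``.
    Raises :class:`MissingWindowError` when no fix falls in the window
    (such samples are excluded from spatial analyses).
    """
    df = fix_table.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if animal_id is not None:
        df = df[df["animal_id"] == animal_id]
    else:
        ids = df["animal_id"].unique()
        if len(ids) != 1:
            raise ValueError("multiple animals in fix table; pass animal_id")
        animal_id = ids[0]
    t1 = pd.to_datetime(sample_time)
    t0 = t1 - pd.Timedelta(hours=window_h)
    win = df[(df["timestamp"] >= t0) & (df["timestamp"] <= t1)].sort_values("timestamp")
    if len(win) == 0:
        raise MissingWindowError(
            f"no fixes for {animal_id} in the {window_h} h before {t1}"
        )
    return TrackWindow(animal_id=str(animal_id), fixes=win.reset_index(drop=True))


def buffer_trajectory(window: TrackWindow, buffer_m: float = 400.0) -> UsePolygon:
    """Dilate the time-ordered fix polyline by ``buffer_m`` (round joins).

    A single-fix window yields a disc. Area is reported in km^2.
    """
    xy = window.fixes[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates in track")
    if len(xy) == 1 or np.allclose(xy, xy[0]):
        geom = Point(xy[0]).buffer(buffer_m, quad_segs=64)
    else:
        geom = LineString(xy).buffer(buffer_m, quad_segs=64)
    return UsePolygon(
        geometry=geom, area_km2=geom.area / 1e6, window_id=window.animal_id
    )


def summarize_habitat(
    polygon: UsePolygon, elevation: Raster, cover: Raster
) -> HabitatSummary:
    """Zonal summary of a use polygon over aligned elevation/cover grids.

    Cells belong to the polygon when their centre lies inside it; the
    rasterized area, mean elevation, habitat richness and cover-class
    proportions are computed over member cells.
    """
    if not elevation.aligned_with(cover):
        raise ValueError("elevation and cover rasters are not aligned")
    X, Y = elevation.cell_centres()
    inside = shapely.contains_xy(polygon.geometry, X.ravel(), Y.ravel()).reshape(X.shape)
    n = int(inside.sum())
    if n == 0:
        raise ValueError("polygon covers no raster cell centres")
    elev = float(elevation.values[inside].mean())
    classes, counts = np.unique(cover.values[inside], return_counts=True)
    props = pd.Series(counts / n, index=[_class_label(c) for c in classes])
    area = n * elevation.cellsize**2 / 1e6
    return HabitatSummary(
        mean_elevation=elev,
        area_km2=area,
        habitat_richness=int(len(classes)),
        proportions=props,
    )


def _class_label(c):
    if isinstance(c, (int, np.integer)):
        return int(c)
    f = float(c)
    return int(f) if f.is_integer() else f


def habitat_dissimilarity(summaries: dict[str, HabitatSummary]):
    """Bray-Curtis dissimilarity of land-cover proportion vectors."""
    props = pd.DataFrame(
        {k: s.proportions for k, s in summaries.items()}
    ).T.fillna(0.0)
    return bray_curtis(props.values, labels=list(props.index))


def read_fixes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_fixes_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, sep="\t", index=False)
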