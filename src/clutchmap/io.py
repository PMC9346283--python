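"""Localisation-table and nucleus-ROI handling.

Localisation tables are plain :class:`pandas.DataFrame` objects with the
canonical per-blink columns ``frame, x, y, intensity, uncertainty, sigma``
(nm / photons).  Files are read and written in the ThunderSTORM CSV dialect
(``"id","frame","x [nm]", ...``) or a minimal ``frame,x,y`` dialect.

A :class:`NucleusROI` wraps the manually-segmented (here: synthetic) nuclear
outline as a simple closed polygon in nm, with the 16 nm reconstruction pixel
grid used for "all possible locations" statistics.  A :class:`BlinkMap` binds
in-nucleus blink coordinates to their ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "CANONICAL_COLUMNS",
    "THUNDERSTORM_HEADER",
    "NucleusROI",
    "BlinkMap",
    "read_localisations",
    "write_localisations",
    "filter_localisations",
    "clip_to_nucleus",
    "rasterise",
    "write_tiff",
    "read_roi_csv",
    "write_roi_csv",
    "DialectError",
    "MalformedRowError",
]

CANONICAL_COLUMNS = ["frame", "x", "y", "intensity", "uncertainty", "sigma"]

#: ThunderSTORM CSV export header (nm / photon units).
THUNDERSTORM_HEADER = [
    "id",
    "frame",
    "x [nm]",
    "y [nm]",
    "sigma [nm]",
    "intensity [photon]",
    "uncertainty [nm]",
]

_TS_TO_CANON = {
    "frame": "frame",
    "x [nm]": "x",
    "y [nm]": "y",
    "sigma [nm]": "sigma",
    "intensity [photon]": "intensity",
    "uncertainty [nm]": "uncertainty",
}


class DialectError(ValueError):
    """Raised when a localisation file header matches no known dialect."""


class MalformedRowError(ValueError):
    """Raised for a non-numeric cell; carries the 1-based file line number."""


@dataclass(frozen=True)
class NucleusROI:
    """A nucleus outline: simple closed polygon in nm.

    Parameters
    ----------
    vertices
        ``(n, 2)`` array of polygon vertices in nm, ordered, not repeating
        the first vertex at the end.
    pixel_size
        Reconstruction pixel size in nm (default 16, matching the 16 nm/pixel
        super-resolution reconstruction the outline was drawn on).
    """

    vertices: np.ndarray
    pixel_size: float = 16.0
    _polygon: Polygon = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("ROI needs an (n>=3, 2) vertex array")
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("ROI polygon must be simple with positive area")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area(self) -> float:
        """Polygon area in nm² (shoelace value)."""
        return self._polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self._polygon.bounds

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Closed-set point-in-polygon test (boundary points count as inside)."""
        return shapely.intersects_xy(self._polygon, np.asarray(x), np.asarray(y))

    def boundary_distance(self, xy: np.ndarray) -> np.ndarray:
        """Euclidean distance from each point to the nearest polygon edge (nm)."""
        pts = shapely.points(np.asarray(xy, dtype=float))
        return shapely.distance(pts, self._polygon.exterior)

    def interior_grid(self) -> np.ndarray:
        """Centres of the ``pixel_size`` pixels whose centre lies in the nucleus.

        The grid origin is the ROI bounding-box minimum, matching the pixel
        convention of :func:`rasterise`.  These grid points realise the
        "all possible locations" reference set for periphery statistics.
        """
        x0, y0, x1, y1 = self.bounds
        p = self.pixel_size
        xs = x0 + (np.arange(int(np.floor((x1 - x0) / p)) + 1) + 0.5) * p
        ys = y0 + (np.arange(int(np.floor((y1 - y0) / p)) + 1) + 0.5) * p
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        gx, gy = gx.ravel(), gy.ravel()
        keep = self.contains(gx, gy)
        if not keep.any():
            raise ValueError("ROI too small: no interior grid point at this pixel size")
        return np.column_stack([gx[keep], gy[keep]])

    def grid_boundary_stats(self) -> tuple[float, float]:
        """Mean and SD of boundary distance over the interior pixel grid."""
        d = self.boundary_distance(self.interior_grid())
        return float(d.mean()), float(d.std())


@dataclass
class BlinkMap:
    """In-nucleus blink coordinates bound to one :class:`NucleusROI`."""

    xy: np.ndarray
    roi: NucleusROI
    frames: Optional[np.ndarray] = None

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=int)
            if len(self.frames) != len(self.xy):
                raise ValueError("frames and coordinates length mismatch")

    def __len__(self) -> int:
        return len(self.xy)

    @property
    def global_density(self) -> float:
        """Blinks per nm² of nuclear area."""
        return len(self.xy) / self.roi.area


# ---------------------------------------------------------------------------
# localisation tables
# ---------------------------------------------------------------------------

def read_localisations(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a localisation table, normalising columns to nm/photons.

    Parameters
    ----------
    path
        CSV file in the ThunderSTORM dialect or a minimal ``frame,x,y`` one.
    dialect
        ``"thunderstorm"``, ``"minimal"`` or None to sniff from the header.

    Returns
    -------
    DataFrame with canonical columns; unknown extra columns are preserved,
    row order is kept as in the file.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    header = [c.strip().strip('"') for c in raw.columns]
    raw.columns = header

    if dialect is None:
        if set(_TS_TO_CANON) <= set(header):
            dialect = "thunderstorm"
        elif {"frame", "x", "y"} <= set(header):
            dialect = "minimal"
        else:
            raise DialectError(
                f"{path.name}: header {header!r} matches neither the ThunderSTORM "
                "dialect nor the minimal frame,x,y dialect"
            )

    if dialect == "thunderstorm":
        rename = _TS_TO_CANON
        numeric = list(_TS_TO_CANON)
    elif dialect == "minimal":
        rename = {c: c for c in ("frame", "x", "y")}
        numeric = ["frame", "x", "y"]
    else:
        raise DialectError(f"unknown dialect {dialect!r}")

    for col in numeric:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            # +2: 1-based plus the header line
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise MalformedRowError(
                f"{path.name}, line {line}: non-numeric value "
                f"{raw[col].iloc[line - 2]!r} in column {col!r}"
            )
        raw[col] = converted
    table = raw.rename(columns=rename)
    table["frame"] = table["frame"].astype(int)
    # canonical columns first, extras preserved after
    extras = [c for c in table.columns if c not in CANONICAL_COLUMNS]
    cols = [c for c in CANONICAL_COLUMNS if c in table.columns] + extras
    return table[cols]


def write_localisations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localisation table in the ThunderSTORM CSV dialect."""
    out = pd.DataFrame(
        {
            "id": np.arange(1, len(table) + 1),
            "frame": table["frame"].astype(int).to_numpy(),
            "x [nm]": table["x"].to_numpy(),
            "y [nm]": table["y"].to_numpy(),
            "sigma [nm]": table.get("sigma", pd.Series(np.zeros(len(table)))).to_numpy(),
            "intensity [photon]": table.get(
                "intensity", pd.Series(np.zeros(len(table)))
            ).to_numpy(),
            "uncertainty [nm]": table.get(
                "uncertainty", pd.Series(np.zeros(len(table)))
            ).to_numpy(),
        }
    )
    out.to_csv(path, index=False, float_format="%.4f")


def filter_localisations(
    table: pd.DataFrame,
    intensity_min: float = 300.0,
    intensity_max: float = 5000.0,
    max_uncertainty: float = 35.0,
    max_sigma: float = 200.0,
) -> pd.DataFrame:
    """Quality-filter blinks on photon count, precision and PSF width.

    Defaults are the standard dSTORM post-processing cuts: intensity within
    [300, 5000] photons, localisation uncertainty ≤ 35 nm, fitted PSF sigma
    ≤ 200 nm.  All bounds are inclusive; row order is preserved.
    """
    if intensity_min > intensity_max:
        raise ValueError("intensity_min must be <= intensity_max")
    if min(intensity_min, max_uncertainty, max_sigma) <= 0:
        raise ValueError("thresholds must be positive")
    if table.empty:
        return table.copy()
    keep = (
        (table["intensity"] >= intensity_min)
        & (table["intensity"] <= intensity_max)
        & (table["uncertainty"] <= max_uncertainty)
        & (table["sigma"] <= max_sigma)
    )
    return table.loc[keep].copy()


def clip_to_nucleus(table: pd.DataFrame, roi: NucleusROI) -> BlinkMap:
    """Discard blinks outside the nucleus; bind survivors to the ROI.

    Points exactly on the polygon boundary are kept (closed-set convention).
    """
    if table.empty:
        warnings.warn("no blinks survive nucleus clipping", stacklevel=2)
        return BlinkMap(np.empty((0, 2)), roi, frames=np.empty(0, dtype=int))
    inside = roi.contains(table["x"].to_numpy(), table["y"].to_numpy())
    kept = table.loc[inside]
    if kept.empty:
        warnings.warn("no blinks survive nucleus clipping", stacklevel=2)
    frames = kept["frame"].to_numpy() if "frame" in kept else None
    return BlinkMap(kept[["x", "y"]].to_numpy(), roi, frames=frames)


def rasterise(blinks: BlinkMap, pixel_size: float = 16.0) -> np.ndarray:
    """Bin blinks into a 2-D count image at ``pixel_size`` nm/pixel.

    Pixel ``(i, j)`` covers the half-open square
    ``[x0 + i*p, x0 + (i+1)*p) × [y0 + j*p, y0 + (j+1)*p)`` with the origin at
    the ROI bounding-box minimum.  The image sum equals the blink count.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    x0, y0, x1, y1 = blinks.roi.bounds
    nx = int(np.floor((x1 - x0) / pixel_size)) + 1
    ny = int(np.floor((y1 - y0) / pixel_size)) + 1
    img = np.zeros((nx, ny), dtype=np.uint16)
    if len(blinks) == 0:
        return img
    ix = np.floor((blinks.xy[:, 0] - x0) / pixel_size).astype(int)
    iy = np.floor((blinks.xy[:, 1] - y0) / pixel_size).astype(int)
    # blinks exactly on the bbox max edge land one past the last full pixel
    nx = max(nx, ix.max() + 1)
    ny = max(ny, iy.max() + 1)
    img = np.zeros((nx, ny), dtype=np.uint16)
    np.add.at(img, (ix, iy), 1)
    return img


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write a count image as 16-bit TIFF (diagnostic reconstruction)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))


# ---------------------------------------------------------------------------
# ROI persistence
# ---------------------------------------------------------------------------

def write_roi_csv(roi: NucleusROI, path: str | Path) -> None:
    """Write the ROI as a plain ``x,y`` vertex list (nm)."""
    pd.DataFrame(roi.vertices, columns=["x", "y"]).to_csv(path, index=False)


def read_roi_csv(path: str | Path, pixel_size: float = 16.0) -> NucleusROI:
    df = pd.read_csv(path)
    return NucleusROI(df[["x", "y"]].to_numpy(), pixel_size=pixel_size)
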