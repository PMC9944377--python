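"""Witelson parcellation and the 92-ROI sampling template.

The midsagittal corpus callosum is divided along its antero-posterior (AP)
axis into six macro-regions — rostrum/genu, rostral body, anterior midbody,
posterior midbody, isthmus and splenium — by cutting the AP bounding-box
extent of the binary mask at five configurable fractions.  On top of the
parcellated mask a sampling template of 92 tiling squares (by default 46 AP
columns x 2 dorsoventral rows) is constructed; each square carries an
inscribed circular ROI in which intensities are later averaged.  Because
columns are defined as fractions of the individual AP extent and rows as
fractions of the local dorsoventral thickness, the template adapts to
callosal size and can be compared across subjects.

Conventions
-----------
* Arrays are indexed ``[row, column]``; columns run along the AP axis and
  rows along the dorsoventral axis (row 0 = dorsal).
* Pixel ``(r, c)`` occupies the half-open cell ``[r, r+1) x [c, c+1)`` in
  continuous coordinates; its centre is ``(r + 0.5, c + 0.5)``.
* A pixel belongs to the AP interval its *centre* falls in; intervals are
  half-open and anterior-closed, so a pixel centred exactly on a boundary
  fraction goes to the posterior region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, DataError

#: Witelson macro-regions, anterior to posterior.  The rostrum is merged
#: with the genu, matching the common six-region reading of the scheme.
WITELSON_REGIONS: tuple[str, ...] = (
    "rostrum_genu",
    "rostral_body",
    "anterior_midbody",
    "posterior_midbody",
    "isthmus",
    "splenium",
)

#: Default AP boundary fractions.  Witelson's geometric cuts are at 1/3,
#: 1/2, 2/3 and 4/5 of the AP length; the rostrum/genu vs rostral-body
#: split inside the anterior third is set at 1/6 by convention.
DEFAULT_FRACTIONS: tuple[float, ...] = (1 / 6, 1 / 3, 1 / 2, 2 / 3, 4 / 5)

#: ROIs in the default template (46 AP columns x 2 dorsoventral rows).
N_ROIS: int = 92


@dataclass(frozen=True)
class CallosalMask:
    """Binary midsagittal callosal mask.

    Parameters
    ----------
    pixels
        2-D boolean array, ``[dorsoventral, antero-posterior]``.
    spacing
        ``(mm/px along AP, mm/px dorsoventral)``.
    anterior_at_left
        If True (default) column 0 is the anterior end.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    anterior_at_left: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise DataError(f"mask must be 2-D, got shape {px.shape}")
        if not px.any():
            raise DataError("mask is empty")
        # 4-connectivity: the template assumes one contiguous arch
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        _, n_comp = ndimage.label(px, structure=structure)
        if n_comp != 1:
            raise DataError(
                f"mask must have exactly one 4-connected component, found {n_comp}"
            )
        if min(self.spacing) <= 0:
            raise DataError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "pixels", px)

    @property
    def ap_bounds(self) -> tuple[int, int]:
        """Half-open column interval ``[lo, hi)`` of the foreground."""
        cols = np.flatnonzero(self.pixels.any(axis=0))
        return int(cols[0]), int(cols[-1]) + 1

    @property
    def ap_extent(self) -> int:
        lo, hi = self.ap_bounds
        return hi - lo

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    def ap_coordinate(self, columns: np.ndarray) -> np.ndarray:
        """Normalised AP coordinate in [0, 1] of pixel centres in `columns`.

        0 is the anterior tip of the bounding box, 1 the posterior tip.
        """
        lo, hi = self.ap_bounds
        u = (np.asarray(columns, dtype=float) - lo + 0.5) / (hi - lo)
        if not self.anterior_at_left:
            u = 1.0 - u
        return u


@dataclass(frozen=True)
class RegionLabelMap:
    """Witelson region labels over a mask.

    ``labels`` holds 0 for background and ``1..6`` for the regions in
    :data:`WITELSON_REGIONS` order (anterior to posterior).
    """

    labels: np.ndarray
    fractions: tuple[float, ...]
    mask: CallosalMask

    @property
    def region_names(self) -> tuple[str, ...]:
        return WITELSON_REGIONS

    def region_pixel_counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == i + 1).sum())
            for i, name in enumerate(WITELSON_REGIONS)
        }


def _validate_fractions(fractions: Sequence[float]) -> tuple[float, ...]:
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 5:
        raise ConfigError(f"need 5 boundary fractions, got {len(fr)}")
    if not all(0.0 < f < 1.0 for f in fr):
        raise ConfigError(f"fractions must lie in (0, 1), got {fr}")
    if not all(a < b for a, b in zip(fr, fr[1:])):
        raise ConfigError(f"fractions must be strictly increasing, got {fr}")
    return fr


def parcellate_witelson(
    mask: CallosalMask,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> RegionLabelMap:
    """Assign every mask pixel to one of the six Witelson macro-regions.

    The AP extent is the mask's bounding box along the anterior axis; a
    pixel's region is determined solely by the normalised AP coordinate of
    its centre against the five boundary fractions (half-open,
    anterior-closed intervals: a centre exactly on a boundary goes
    posterior).

    Raises
    ------
    ConfigError
        If the fractions are not 5 strictly increasing values in (0, 1).
    DataError
        If the mask is degenerate (AP extent < 6 px) or any region would
        be empty.
    """
    fr = _validate_fractions(fractions)
    if mask.ap_extent < 6:
        raise DataError(
            f"mask AP extent {mask.ap_extent} px is too small to carry six regions"
        )
    labels = np.zeros(mask.pixels.shape, dtype=np.int8)
    rows, cols = np.nonzero(mask.pixels)
    u = mask.ap_coordinate(cols)
    # searchsorted(side='right'): u == fraction lands in the posterior region
    labels[rows, cols] = np.searchsorted(fr, u, side="right") + 1
    lmap = RegionLabelMap(labels=labels, fractions=fr, mask=mask)
    empty = [n for n, c in lmap.region_pixel_counts().items() if c == 0]
    if empty:
        raise DataError(f"regions {empty} are empty on this mask")
    return lmap


@dataclass(frozen=True)
class GridSpec:
    """Layout of the sampling template.

    ``columns * rows`` must equal 92, the ROI count of the template;
    ``circle_ratio`` is the inscribed-circle diameter as a fraction of the
    shorter square side.
    """

    columns: int = 46
    rows: int = 2
    circle_ratio: float = 0.8

    def __post_init__(self) -> None:
        if self.columns * self.rows != N_ROIS:
            raise ConfigError(
                f"grid {self.columns}x{self.rows} has {self.columns * self.rows} "
                f"cells; the template requires exactly {N_ROIS}"
            )
        if not 0.0 < self.circle_ratio <= 1.0:
            raise ConfigError(f"circle_ratio must be in (0, 1], got {self.circle_ratio}")


@dataclass(frozen=True)
class Roi:
    """One circular ROI and its enclosing square (continuous pixel coords)."""

    index: int  # 1-based, anterior->posterior, dorsal before ventral
    cx: float
    cy: float
    radius: float
    x0: float
    x1: float
    y0: float
    y1: float
    region: str
    column: int  # 0-based AP column
    row: int  # 0 = dorsal, increasing ventrally


@dataclass(frozen=True)
class RoiTemplate:
    """The 92-circle / 92-square sampling template bound to one mask."""

    rois: tuple[Roi, ...]
    grid: GridSpec
    fractions: tuple[float, ...]
    mask: Optional[CallosalMask] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.rois)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "roi_index": r.index,
                    "cx": r.cx,
                    "cy": r.cy,
                    "radius": r.radius,
                    "x0": r.x0,
                    "x1": r.x1,
                    "y0": r.y0,
                    "y1": r.y1,
                    "region": r.region,
                    "column": r.column,
                    "row": r.row,
                }
                for r in self.rois
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: GridSpec | None = None) -> "RoiTemplate":
        """Rebuild a template from its CSV/DataFrame form (mask not restored)."""
        rois = tuple(
            Roi(
                index=int(row.roi_index),
                cx=float(row.cx),
                cy=float(row.cy),
                radius=float(row.radius),
                x0=float(row.x0),
                x1=float(row.x1),
                y0=float(row.y0),
                y1=float(row.y1),
                region=str(row.region),
                column=int(row.column),
                row=int(row.row),
            )
            for row in df.itertuples()
        )
        if len(rois) != N_ROIS:
            raise DataError(f"template frame has {len(rois)} ROIs, expected {N_ROIS}")
        return cls(rois=rois, grid=grid or GridSpec(), fractions=DEFAULT_FRACTIONS)


def build_roi_template(
    label_map: RegionLabelMap,
    grid: GridSpec = GridSpec(),
) -> RoiTemplate:
    """Construct the 92-ROI template on a parcellated mask.

    The AP bounding-box extent is split into ``grid.columns`` equal-width
    columns; within each column the local dorsoventral extent of the mask
    is split into ``grid.rows`` equal rows.  Each resulting square carries
    an inscribed circle of radius ``circle_ratio * min(side) / 2`` centred
    in the square.  ROIs are ordered anterior to posterior, dorsal row
    before ventral row within a column, and each is labelled by the
    Witelson region of its circle centre.

    Raises
    ------
    DataError
        If some column contains no mask pixels (the mask is not a
        contiguous arch spanning its bounding box), a circle radius falls
        below 1 px, or a circle centre lies outside the mask.
    """
    mask = label_map.mask
    lo, hi = mask.ap_bounds
    extent = hi - lo
    col_width = extent / grid.columns
    px = mask.pixels
    labels = label_map.labels

    # AP column of each pixel column, by pixel-centre position
    cols = np.arange(lo, hi)
    col_idx = np.minimum(
        ((cols - lo + 0.5) / col_width).astype(int), grid.columns - 1
    )

    rois: list[Roi] = []
    index = 1
    for i in range(grid.columns):
        ap_cols = cols[col_idx == i]
        if ap_cols.size == 0 or not px[:, ap_cols].any():
            raise DataError(f"AP column {i} contains no mask pixels")
        x0 = lo + i * col_width
        x1 = lo + (i + 1) * col_width
        # local dorsoventral extent, measured at the column's central pixel
        # column: on a steep arch the union extent over the whole column can
        # include rows present only at one edge, which would push the circle
        # centres outside the mask
        centre_col = min(int((x0 + x1) / 2.0), hi - 1)
        rr = np.flatnonzero(px[:, centre_col])
        if rr.size == 0:
            rr = np.flatnonzero(px[:, ap_cols].any(axis=1))
        y_lo, y_hi = float(rr[0]), float(rr[-1] + 1)
        row_height = (y_hi - y_lo) / grid.rows
        radius = grid.circle_ratio * min(col_width, row_height) / 2.0
        if radius < 1.0:
            raise DataError(
                f"circle radius {radius:.2f} px < 1 px in column {i}: "
                "mask resolution too low for this grid"
            )
        for j in range(grid.rows):
            y0 = y_lo + j * row_height
            y1 = y_lo + (j + 1) * row_height
            cx = (x0 + x1) / 2.0
            cy = (y0 + y1) / 2.0
            lab = int(labels[int(cy), int(cx)])
            if lab == 0:
                raise DataError(
                    f"circle centre of ROI {index} (column {i}, row {j}) "
                    "lies outside the mask"
                )
            rois.append(
                Roi(
                    index=index,
                    cx=cx,
                    cy=cy,
                    radius=radius,
                    x0=x0,
                    x1=x1,
                    y0=y0,
                    y1=y1,
                    region=WITELSON_REGIONS[lab - 1],
                    column=i,
                    row=j,
                )
            )
            index += 1
    return RoiTemplate(
        rois=tuple(rois), grid=grid, fractions=label_map.fractions, mask=mask
    )
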