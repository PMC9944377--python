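"""Parasagittal slice extraction and ROI sampling.

Volumetric maps (T1w/T2w, QSM, MWF) are reduced to a single 2-D sagittal
field by averaging the two parasagittal slices at +/- ``offset_mm`` (default
4 mm) from the midline, then sampled with the same 92-ROI template as the
histology: per ROI, the mean over pixels whose centres fall strictly
inside the circle.  For cross-modality display and comparison, each
modality's 92-ROI vector can be rescaled onto the arbitrary 1-7 units used
for the histological maps; the rescale is affine per vector, so Pearson
correlations are unaffected by it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .geometry import CallosalMask, RoiTemplate

log = logging.getLogger(__name__)

RAW_UNITS = "raw"
RESCALED_UNITS = "rescaled_1_7"

#: Column order of the tidy RoiSampleTable frame.
TABLE_COLUMNS = ("modality", "sample", "roi_index", "region", "value", "n_pixels")


@dataclass(frozen=True)
class ModalityMap:
    """A named 2-D or 3-D intensity field with voxel spacing in mm.

    For 3-D data the first axis is sagittal by default and
    ``midsagittal_index`` names the midline slice.
    """

    name: str
    data: np.ndarray
    spacing: tuple[float, ...]
    midsagittal_index: int | None = None
    sagittal_axis: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim not in (2, 3):
            raise DataError(f"map {self.name!r} must be 2-D or 3-D, got {d.ndim}-D")
        if len(self.spacing) != d.ndim:
            raise DataError(
                f"map {self.name!r}: spacing {self.spacing} does not match "
                f"{d.ndim}-D data"
            )
        if min(self.spacing) <= 0:
            raise DataError(f"map {self.name!r}: spacing must be positive")
        if d.ndim == 3 and self.midsagittal_index is None:
            raise DataError(f"3-D map {self.name!r} needs a midsagittal_index")
        object.__setattr__(self, "data", d)


def extract_parasagittal_average(
    vol: ModalityMap, offset_mm: float = 4.0
) -> ModalityMap:
    """Average the two sagittal slices at +/- `offset_mm` from the midline.

    The slice offset in voxels is ``round(offset_mm / sagittal spacing)``;
    a warning is logged when the rounding error exceeds 25% of the
    spacing.  With ``offset_mm=0`` the midsagittal slice itself is
    returned.
    """
    if vol.data.ndim != 3:
        raise DataError(f"map {vol.name!r} is not volumetric")
    sp = vol.spacing[vol.sagittal_axis]
    k = int(round(offset_mm / sp))
    if abs(offset_mm - k * sp) > 0.25 * sp:
        log.warning(
            "offset %.2f mm rounds to %d slices of %.2f mm (error %.2f mm)",
            offset_mm, k, sp, abs(offset_mm - k * sp),
        )
    mid = vol.midsagittal_index
    n = vol.data.shape[vol.sagittal_axis]
    lo, hi = mid - k, mid + k
    if lo < 0 or hi >= n:
        raise DataError(
            f"map {vol.name!r}: slices {lo} and {hi} out of bounds for "
            f"{n} sagittal slices"
        )
    sl_lo = np.take(vol.data, lo, axis=vol.sagittal_axis)
    sl_hi = np.take(vol.data, hi, axis=vol.sagittal_axis)
    spacing2d = tuple(
        s for i, s in enumerate(vol.spacing) if i != vol.sagittal_axis
    )
    return ModalityMap(
        name=vol.name, data=(sl_lo + sl_hi) / 2.0, spacing=spacing2d
    )


def sample_rois(
    map2d: np.ndarray | ModalityMap,
    template: RoiTemplate,
    mask: CallosalMask | None = None,
    statistic: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a 2-D map over the 92 circular ROIs.

    Per ROI the ``statistic`` ("mean" or "median") is taken over pixels
    whose centres lie strictly inside the circle; the value is attributed
    to the whole enclosing square for rendering purposes.  If a mask is
    given (or the template carries one), sampling is restricted to mask
    foreground; NaN pixels are always excluded.

    Returns
    -------
    values, counts
        Two length-92 arrays: the ROI statistic and the pixel count used.

    Raises
    ------
    DataError
        If the map does not match the template's mask shape, or some
        circle contains no pixels (the error names the ROI index).
    """
    data = map2d.data if isinstance(map2d, ModalityMap) else np.asarray(map2d, float)
    if data.ndim != 2:
        raise DataError(f"sample_rois needs a 2-D map, got {data.ndim}-D")
    if mask is None:
        mask = template.mask
    if mask is not None and data.shape != mask.pixels.shape:
        raise DataError(
            f"map shape {data.shape} does not match mask shape {mask.pixels.shape}"
        )
    if statistic not in ("mean", "median"):
        raise DataError(f"unknown statistic {statistic!r}")
    h, w = data.shape
    values = np.empty(len(template))
    counts = np.empty(len(template), dtype=int)
    for k, roi in enumerate(template.rois):
        c0 = max(int(np.floor(roi.cx - roi.radius)), 0)
        c1 = min(int(np.ceil(roi.cx + roi.radius)) + 1, w)
        r0 = max(int(np.floor(roi.cy - roi.radius)), 0)
        r1 = min(int(np.ceil(roi.cy + roi.radius)) + 1, h)
        if c1 <= c0 or r1 <= r0:
            raise DataError(f"ROI {roi.index} lies outside the map")
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = (rr + 0.5 - roi.cy) ** 2 + (cc + 0.5 - roi.cx) ** 2 < roi.radius**2
        if mask is not None:
            inside &= mask.pixels[r0:r1, c0:c1]
        vals = data[r0:r1, c0:c1][inside]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise DataError(f"ROI {roi.index} contains no sampleable pixels")
        values[k] = np.mean(vals) if statistic == "mean" else np.median(vals)
        counts[k] = vals.size
    return values, counts


@dataclass(frozen=True)
class RoiSampleTable:
    """Tidy modality x sample x ROI table of sampled intensities.

    ``data`` has columns modality, sample, roi_index, region, value,
    n_pixels; ``units_state`` flags whether values are raw modality units
    or the arbitrary 1-7 scale.
    """

    data: pd.DataFrame
    units_state: str = RAW_UNITS

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise DataError(f"RoiSampleTable missing columns {sorted(missing)}")
        if self.units_state not in (RAW_UNITS, RESCALED_UNITS):
            raise DataError(f"unknown units_state {self.units_state!r}")

    @classmethod
    def from_arrays(
        cls,
        modality: str,
        sample: str | int,
        template: RoiTemplate,
        values: np.ndarray,
        counts: np.ndarray,
        units_state: str = RAW_UNITS,
    ) -> "RoiSampleTable":
        df = pd.DataFrame(
            {
                "modality": modality,
                "sample": str(sample),
                "roi_index": [r.index for r in template.rois],
                "region": [r.region for r in template.rois],
                "value": np.asarray(values, float),
                "n_pixels": np.asarray(counts, int),
            }
        )
        return cls(data=df, units_state=units_state)

    @staticmethod
    def concat(tables: list["RoiSampleTable"]) -> "RoiSampleTable":
        states = {t.units_state for t in tables}
        if len(states) != 1:
            raise DataError(f"cannot concatenate tables with mixed units {states}")
        return RoiSampleTable(
            data=pd.concat([t.data for t in tables], ignore_index=True),
            units_state=states.pop(),
        )

    @property
    def modalities(self) -> list[str]:
        return list(dict.fromkeys(self.data["modality"]))

    def samples(self, modality: str) -> list[str]:
        sub = self.data[self.data["modality"] == modality]
        return list(dict.fromkeys(sub["sample"]))

    def matrix(self, modality: str) -> np.ndarray:
        """(n_samples, n_rois) value matrix for one modality."""
        sub = self.data[self.data["modality"] == modality]
        if sub.empty:
            raise DataError(f"modality {modality!r} not in table")
        piv = sub.pivot(index="sample", columns="roi_index", values="value")
        piv = piv.loc[self.samples(modality)]
        return piv.to_numpy()

    def vector(self, modality: str) -> np.ndarray:
        """92-ROI vector for one modality, averaged across its samples."""
        return self.matrix(modality).mean(axis=0)

    def regions(self, modality: str) -> np.ndarray:
        sub = self.data[self.data["modality"] == modality]
        one = sub[sub["sample"] == self.samples(modality)[0]]
        return one.sort_values("roi_index")["region"].to_numpy()

    def n_rois(self) -> int:
        return self.data["roi_index"].nunique()


def rescale_to_units(table: RoiSampleTable) -> RoiSampleTable:
    """Min-max rescale each modality's ROI values onto [1, 7].

    One affine map per modality, over all of its samples jointly, so that
    averaging across samples commutes with the rescale and every Pearson
    correlation between (sample-averaged) ROI vectors is unchanged.
    Applying the rescale twice is idempotent.

    Raises
    ------
    DataError
        If some modality's values are constant (zero intensity range).
    """
    df = table.data.copy()
    for mod, idx in df.groupby("modality").groups.items():
        v = df.loc[idx, "value"].to_numpy()
        rng = v.max() - v.min()
        if rng == 0:
            raise DataError(
                f"modality {mod!r} has a constant ROI table; "
                "cannot rescale a zero range to 1-7"
            )
        df.loc[idx, "value"] = 1.0 + 6.0 * (v - v.min()) / rng
    return RoiSampleTable(data=df, units_state=RESCALED_UNITS)
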