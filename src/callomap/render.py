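"""ROI-based colour-coded map rendering.

Each ROI's sampled value (on the 1-7 scale) is extended from the circle
to its enclosing square and painted with the seven-bin purple-to-dark-red
palette used for the per-pixel density maps, reproducing the
template-resolution myelin maps of the source protocol.  Region
boundaries of the Witelson parcellation are drawn as thin dark lines.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError
from .geometry import N_ROIS, RoiTemplate
from .histology import DENSITY_COLORS, DENSITY_MAX, DENSITY_MIN, density_bin

_BOUNDARY_COLOR = (40, 40, 40)


def render_roi_map(template: RoiTemplate, values: np.ndarray) -> np.ndarray:
    """Render a 92-vector of 1-7 values as a colour-coded ROI map.

    Returns an 8-bit RGB image the size of the template's mask (or of the
    template bounding box if the template carries no mask), white
    background, each square filled with its value's colour bin and the
    five Witelson boundaries overdrawn.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (N_ROIS,):
        raise DataError(f"expected {N_ROIS} values, got shape {values.shape}")
    if values.min() < DENSITY_MIN - 1e-9 or values.max() > DENSITY_MAX + 1e-9:
        raise DataError(
            f"values must lie in [1, 7], got range ({values.min()}, {values.max()})"
        )
    if template.mask is not None:
        h, w = template.mask.pixels.shape
    else:
        h = int(np.ceil(max(r.y1 for r in template.rois))) + 1
        w = int(np.ceil(max(r.x1 for r in template.rois))) + 1
    out = np.full((h, w, 3), 255, dtype=np.uint8)
    palette = np.array(DENSITY_COLORS, dtype=np.uint8)
    bins = density_bin(values)
    for roi, b in zip(template.rois, bins):
        x0, x1 = int(round(roi.x0)), int(round(roi.x1))
        y0, y1 = int(round(roi.y0)), int(round(roi.y1))
        out[y0:y1, x0:x1] = palette[b]
    # Witelson boundaries: vertical lines at the fraction cuts
    lo = min(r.x0 for r in template.rois)
    hi = max(r.x1 for r in template.rois)
    for f in template.fractions:
        xb = int(round(lo + f * (hi - lo)))
        col = out[:, xb : xb + 1, :]
        painted = (col != 255).any(axis=2)
        col[painted] = _BOUNDARY_COLOR
    return out
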