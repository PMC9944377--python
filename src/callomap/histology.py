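"""Luxol-fast-blue optical density on the 1-7 myelin scale.

LFB binds myelin lipoproteins, so on a digitised section darker blue means
denser myelin.  The quantification here converts the RGB section to a
single 256-level grey image, inverts it into an optical-density proxy
``d = 255 - grey`` (darker stain = larger d), and rescales the full
intensity range linearly onto an arbitrary 1-7 scale with 1 = lowest and
7 = highest myelin density.  For display the 1-7 range is binned into
seven colours from purple (lowest) to dark red (highest); for statistics
the continuous values are kept, since correlations over 92 ROIs need more
than seven distinct levels.

The inversion is a straight linear rescale of the camera intensity range,
not a logarithmic transmittance OD; a ``-log10`` variant is available via
``od_log=True`` for workflows that prefer true optical density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .geometry import CallosalMask

#: Rec. 709 luminance weights for the RGB -> grey conversion.
REC709_WEIGHTS: tuple[float, float, float] = (0.2126, 0.7152, 0.0722)

#: Bounds of the myelin-density scale.
DENSITY_MIN: float = 1.0
DENSITY_MAX: float = 7.0

#: Seven display colours, lowest to highest density:
#: purple, blue, cyan, green, yellow, orange, dark red.
DENSITY_COLORS: tuple[tuple[int, int, int], ...] = (
    (84, 0, 153),
    (13, 59, 222),
    (0, 187, 212),
    (76, 175, 80),
    (255, 235, 59),
    (255, 152, 0),
    (139, 0, 0),
)


@dataclass(frozen=True)
class GreySection:
    """Single-channel 256-level version of an RGB section."""

    grey: np.ndarray  # float, integer-valued, in [0, 255]
    provenance: str = ""
    conversion: str = "rec709"


@dataclass(frozen=True)
class MyelinDensityMap:
    """Per-pixel myelin density on the 1-7 scale; NaN outside the mask."""

    density: np.ndarray
    higher_is_more_myelin: bool = True


def rgb_to_grey(
    image: np.ndarray, weights: str = "rec709", provenance: str = ""
) -> GreySection:
    """Convert an 8-bit RGB section to a single 256-grey-level image.

    ``weights='rec709'`` uses the Rec. 709 luminance
    ``0.2126 R + 0.7152 G + 0.0722 B``; ``weights='mean'`` uses the plain
    channel mean.  Values are rounded half-to-even.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise DataError(f"expected an RGB image (H, W, 3), got shape {img.shape}")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.floating) or img.min() < 0 or img.max() > 255:
            raise DataError(
                f"expected 8-bit RGB values in [0, 255], got dtype {img.dtype}"
            )
    rgb = img[..., :3].astype(float)
    if weights == "rec709":
        w = np.array(REC709_WEIGHTS)
    elif weights == "mean":
        w = np.full(3, 1.0 / 3.0)
    else:
        raise ConfigError(f"unknown grey conversion {weights!r}")
    grey = np.rint(rgb @ w)
    return GreySection(grey=grey, provenance=provenance, conversion=weights)


def grey_to_density(
    grey: GreySection,
    mask: CallosalMask,
    calibration: tuple[float, float] | None = None,
    od_log: bool = False,
) -> MyelinDensityMap:
    """Map grey levels to the 1-7 myelin-density scale inside the mask.

    The optical-density proxy is ``d = 255 - grey`` (darker stain = more
    myelin), mapped linearly so that grey 255 -> density 1 and grey 0 ->
    density 7.  By default the fixed full 0-255 range is used — appropriate
    when all sections share one light calibration — so densities are
    comparable across sections.  Passing ``calibration=(d_min, d_max)``
    min-max normalises the proxy to those bounds instead (values clipped).
    With ``od_log=True`` the proxy is ``-log10((grey + 1) / 256)``,
    min-max normalised over the mask unless a calibration is given.
    """
    g = grey.grey
    if g.shape != mask.pixels.shape:
        raise DataError(
            f"grey section shape {g.shape} does not match mask shape "
            f"{mask.pixels.shape}"
        )
    if od_log:
        d = -np.log10((g + 1.0) / 256.0)
        if calibration is None:
            fg = d[mask.pixels]
            calibration = (float(fg.min()), float(fg.max()))
    else:
        d = 255.0 - g
        if calibration is None:
            calibration = (0.0, 255.0)
    d_min, d_max = calibration
    if d_max <= d_min:
        raise DataError(f"degenerate calibration range ({d_min}, {d_max})")
    frac = np.clip((d - d_min) / (d_max - d_min), 0.0, 1.0)
    density = DENSITY_MIN + (DENSITY_MAX - DENSITY_MIN) * frac
    density = np.where(mask.pixels, density, np.nan)
    return MyelinDensityMap(density=density)


def density_bin(values: np.ndarray) -> np.ndarray:
    """0-based bin index of 1-7 density values among the seven colour bins.

    Bin edges sit at ``1 + 6k/7`` for k = 0..7; the top edge is closed so
    density 7 falls in the last bin.
    """
    v = np.asarray(values, dtype=float)
    return np.clip(((v - DENSITY_MIN) * 7 / 6).astype(int), 0, 6)


def render_density_colormap(density: MyelinDensityMap) -> np.ndarray:
    """Render a density map as an 8-bit RGB image, white background.

    Foreground pixels are coloured by their bin among the seven discrete
    colours of :data:`DENSITY_COLORS`.
    """
    d = density.density
    fg = ~np.isnan(d)
    vals = d[fg]
    if vals.size and (vals.min() < DENSITY_MIN - 1e-9 or vals.max() > DENSITY_MAX + 1e-9):
        raise DataError(
            f"density values outside [1, 7]: range ({vals.min()}, {vals.max()})"
        )
    out = np.full(d.shape + (3,), 255, dtype=np.uint8)
    palette = np.array(DENSITY_COLORS, dtype=np.uint8)
    out[fg] = palette[density_bin(vals)]
    return out
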