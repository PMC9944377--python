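"""Synthetic callosal phantoms with known ground truth.

The study design this package implements — histological LFB optical
density compared with volumetric MRI myelin maps over a shared 92-ROI
callosal template — is exercised here on fully synthetic data: an
arch-shaped midsagittal mask (half-annulus with genu- and splenium-like
end bulbs), per-modality antero-posterior (AP) intensity profiles, RGB
"stained section" renderings for histology-type modalities, three-slice
sagittal volumes for MRI-type modalities, additive Gaussian noise, and a
smooth per-sample profile perturbation that emulates biological
variability between specimens.  Every dataset carries a noise-free
per-ROI truth table, so recovery of known correlation structure and of
known between-sample variability can be tested end to end.

The default ``paper_pattern_profiles`` encode the qualitative AP patterns
reported for the three modalities: LFB myelin density low anteriorly and
high posteriorly with a small uptick in the most anterior genu; T1w/T2w
highest in the rostrum/genu, low in the posterior midbody, partially
recovering in the superior splenium; MWF relatively high in the anterior
genu, lower in the anterior body, high from the posterior midbody through
the splenium.  These shapes make T1w/T2w anticorrelated with LFB while
MWF correlates positively with it.

Only AP topology is modelled.  The arch is not an anatomically realistic
corpus callosum, the volumes contain no MR physics, and the noise is
additive Gaussian truncated to the valid intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .geometry import (
    CallosalMask,
    GridSpec,
    RegionLabelMap,
    RoiTemplate,
    build_roi_template,
    parcellate_witelson,
)
from .sampling import ModalityMap, RoiSampleTable, sample_rois

SECTION = "section"  # histology-type modality: RGB stained section
VOLUME = "volume"  # MRI-type modality: 3-slice sagittal volume

#: Channel multipliers giving the rendered stain a fixed blue-dominant
#: hue; luminance stays linear in the underlying grey level.
_STAIN_HUE = np.array([0.88, 0.96, 1.0])


@dataclass(frozen=True)
class Profile:
    """Piecewise-linear intensity profile over the normalised AP axis.

    ``knots_u`` must start at 0, end at 1 and be strictly increasing;
    values must be strictly positive (intensities on an arbitrary
    positive scale; for section-type modalities they are myelin fractions
    in (0, 1]).
    """

    knots_u: tuple[float, ...]
    knots_v: tuple[float, ...]

    def __post_init__(self) -> None:
        u = np.asarray(self.knots_u, float)
        v = np.asarray(self.knots_v, float)
        if u.size != v.size or u.size < 2:
            raise ConfigError("profile needs matching u/v knots, at least 2")
        if u[0] != 0.0 or u[-1] != 1.0 or not np.all(np.diff(u) > 0):
            raise ConfigError("profile knots_u must increase strictly from 0 to 1")
        if not np.all(v > 0):
            raise ConfigError("profile values must be strictly positive")

    def __call__(self, u: np.ndarray) -> np.ndarray:
        return np.interp(u, self.knots_u, self.knots_v)

    @property
    def value_range(self) -> float:
        v = np.asarray(self.knots_v, float)
        return float(v.max() - v.min())


@dataclass(frozen=True)
class ShapeParams:
    """Geometry of the phantom arch, in pixels.

    The arch is a half annulus of AP length ``arch_length`` and base
    thickness ``thickness``, thickened at its ends by Gaussian bulbs: the
    posterior (splenium-like) bulb by factor ``splenium_bulb`` and the
    anterior (genu-like) bulb by ``genu_bulb``, each with angular width
    ``bulb_width`` radians.  ``margin`` pads the raster.
    """

    arch_length: int = 320
    thickness: float = 36.0
    genu_bulb: float = 0.55
    splenium_bulb: float = 0.85
    bulb_width: float = 0.45
    margin: int = 6

    def __post_init__(self) -> None:
        if self.arch_length < 200:
            raise ConfigError(
                f"arch_length {self.arch_length} < 200 px: the 46-column grid "
                "needs at least ~4 px per column"
            )
        if self.thickness < 8:
            raise ConfigError(f"thickness {self.thickness} px too thin for two rows")
        if self.genu_bulb < 0 or self.splenium_bulb < 0 or self.bulb_width <= 0:
            raise ConfigError("bulb factors must be >= 0 and bulb_width > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic dataset.

    ``profiles`` maps modality name -> AP profile; ``kinds`` marks each
    modality as ``"section"`` (RGB histology) or ``"volume"`` (3-slice
    sagittal volume).  ``noise_sd`` and ``sample_jitter_sd`` may be a
    single float applied to every modality or a per-modality mapping,
    both in the absolute units of that modality's profile: ``noise_sd``
    is pixelwise additive noise, ``sample_jitter_sd`` the marginal SD of
    the smooth per-sample profile perturbation.
    """

    shape: ShapeParams = field(default_factory=ShapeParams)
    profiles: Mapping[str, Profile] = field(default_factory=dict)
    kinds: Mapping[str, str] = field(default_factory=dict)
    noise_sd: float | Mapping[str, float] = 0.0
    sample_jitter_sd: float | Mapping[str, float] = 0.0
    n_samples: int = 3
    seed: int = 0
    in_plane_spacing_mm: float = 1.0
    sagittal_spacing_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError(f"n_samples must be >= 1, got {self.n_samples}")
        for name in self.profiles:
            kind = self.kinds.get(name, VOLUME)
            if kind not in (SECTION, VOLUME):
                raise ConfigError(f"modality {name!r}: unknown kind {kind!r}")
            if kind == SECTION and max(self.profiles[name].knots_v) > 1.0:
                raise ConfigError(
                    f"section modality {name!r}: profile values are myelin "
                    "fractions and must lie in (0, 1]"
                )
        for per in (self.noise_sd, self.sample_jitter_sd):
            if isinstance(per, Mapping):
                unknown = set(per) - set(self.profiles)
                if unknown:
                    raise ConfigError(f"noise/jitter for unknown modalities {unknown}")
                if any(v < 0 for v in per.values()):
                    raise ConfigError("noise/jitter SDs must be >= 0")
            elif per < 0:
                raise ConfigError("noise/jitter SDs must be >= 0")

    def noise_for(self, modality: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(modality, 0.0))
        return float(self.noise_sd)

    def jitter_for(self, modality: str) -> float:
        if isinstance(self.sample_jitter_sd, Mapping):
            return float(self.sample_jitter_sd.get(modality, 0.0))
        return float(self.sample_jitter_sd)

    def to_dict(self) -> dict:
        return {
            "shape": {
                "arch_length": self.shape.arch_length,
                "thickness": self.shape.thickness,
                "genu_bulb": self.shape.genu_bulb,
                "splenium_bulb": self.shape.splenium_bulb,
                "bulb_width": self.shape.bulb_width,
                "margin": self.shape.margin,
            },
            "profiles": {
                m: {"knots_u": list(p.knots_u), "knots_v": list(p.knots_v)}
                for m, p in self.profiles.items()
            },
            "kinds": dict(self.kinds),
            "noise_sd": dict(self.noise_sd)
            if isinstance(self.noise_sd, Mapping)
            else self.noise_sd,
            "sample_jitter_sd": dict(self.sample_jitter_sd)
            if isinstance(self.sample_jitter_sd, Mapping)
            else self.sample_jitter_sd,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "in_plane_spacing_mm": self.in_plane_spacing_mm,
            "sagittal_spacing_mm": self.sagittal_spacing_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        try:
            shape = ShapeParams(**d.get("shape", {}))
            profiles = {
                m: Profile(tuple(p["knots_u"]), tuple(p["knots_v"]))
                for m, p in d.get("profiles", {}).items()
            }
            return cls(
                shape=shape,
                profiles=profiles,
                kinds=dict(d.get("kinds", {})),
                noise_sd=d.get("noise_sd", 0.0),
                sample_jitter_sd=d.get("sample_jitter_sd", 0.0),
                n_samples=int(d.get("n_samples", 3)),
                seed=int(d.get("seed", 0)),
                in_plane_spacing_mm=float(d.get("in_plane_spacing_mm", 1.0)),
                sagittal_spacing_mm=float(d.get("sagittal_spacing_mm", 4.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid phantom spec: {exc}") from exc


def paper_pattern_profiles() -> tuple[dict[str, Profile], dict[str, str]]:
    """Profiles encoding the reported AP patterns of the three modalities.

    Returns the ``(profiles, kinds)`` pair for a PhantomSpec.  LFB is a
    section-type modality on the myelin-fraction scale; T1w/T2w and MWF
    are volume-type on their native arbitrary scales.
    """
    profiles = {
        # low anterior (dip past the genu), rising to a high splenium
        "LFB": Profile(
            (0.0, 0.08, 0.22, 0.45, 0.70, 0.85, 1.0),
            (0.40, 0.44, 0.32, 0.42, 0.58, 0.70, 0.72),
        ),
        # high rostrum/genu, low posterior midbody, partial recovery in
        # the superior splenium
        "T1w/T2w": Profile(
            (0.0, 0.15, 0.35, 0.55, 0.75, 0.90, 1.0),
            (2.20, 2.10, 1.80, 1.55, 1.55, 1.70, 1.75),
        ),
        # high anterior genu, dip in the anterior body, high from the
        # posterior midbody through the splenium
        "MWF": Profile(
            (0.0, 0.10, 0.30, 0.50, 0.65, 0.85, 1.0),
            (0.125, 0.135, 0.090, 0.100, 0.145, 0.150, 0.145),
        ),
    }
    kinds = {"LFB": SECTION, "T1w/T2w": VOLUME, "MWF": VOLUME}
    return profiles, kinds


def default_spec(
    n_samples: int = 3, seed: int = 0, arch_length: int = 320
) -> PhantomSpec:
    """Paper-pattern phantom: 3 histology samples, 2 volumetric maps.

    Noise and jitter SDs default to roughly 5% and 10% of each profile's
    range respectively — small pixel noise on top of a visible
    between-sample biological variability.
    """
    profiles, kinds = paper_pattern_profiles()
    noise = {m: 0.05 * p.value_range for m, p in profiles.items()}
    jitter = {m: 0.10 * p.value_range for m, p in profiles.items()}
    return PhantomSpec(
        shape=ShapeParams(arch_length=arch_length),
        profiles=profiles,
        kinds=kinds,
        noise_sd=noise,
        sample_jitter_sd=jitter,
        n_samples=n_samples,
        seed=seed,
    )


def generate_mask(spec: PhantomSpec) -> CallosalMask:
    """Rasterise the phantom arch as a binary midsagittal mask.

    The arch is a half annulus opening downwards (concave-down), with the
    anterior (genu-like) end at the left image edge and the posterior
    (splenium-like) bulb at the right.  Deterministic given the spec.
    """
    s = spec.shape
    theta_probe = np.linspace(0.0, np.pi, 721)

    def thick(theta: np.ndarray) -> np.ndarray:
        return s.thickness * (
            1.0
            + s.genu_bulb * np.exp(-(((theta - np.pi) / s.bulb_width) ** 2))
            + s.splenium_bulb * np.exp(-((theta / s.bulb_width) ** 2))
        )

    t_ant = float(thick(np.array([np.pi]))[0])
    t_post = float(thick(np.array([0.0]))[0])
    # inner boundary is a fixed circle of radius r_in; the thickness profile
    # (including the end bulbs) grows outward only, which keeps every AP
    # column's cross-section a single vertical interval
    r_in = (s.arch_length - t_ant - t_post) / 2.0
    if r_in <= s.thickness:
        raise ConfigError("arch_length too short for this thickness/bulb setting")
    r_out_max = r_in + float(thick(theta_probe).max())
    cx = s.margin + r_in + t_ant
    cy = float(np.ceil(r_out_max)) + s.margin
    width = s.arch_length + 2 * s.margin
    height = int(np.ceil(cy)) + s.margin

    rr, cc = np.mgrid[0:height, 0:width]
    dx = cc + 0.5 - cx
    dy = cy - (rr + 0.5)
    rho = np.hypot(dx, dy)
    theta = np.arctan2(np.maximum(dy, 0.0), dx)
    fg = (dy >= 0) & (rho >= r_in) & (rho <= r_in + thick(theta))
    return CallosalMask(
        pixels=fg,
        spacing=(spec.in_plane_spacing_mm, spec.in_plane_spacing_mm),
    )


def _ap_field(mask: CallosalMask) -> np.ndarray:
    """Per-pixel normalised AP coordinate (NaN outside the mask)."""
    h, w = mask.pixels.shape
    u_cols = mask.ap_coordinate(np.arange(w))
    u = np.broadcast_to(u_cols, (h, w)).copy()
    u[~mask.pixels] = np.nan
    return u


def _sample_jitter(
    rng: np.random.Generator, sd: float, length_scale: float = 0.25, k: int = 12
):
    """Smooth random AP perturbation with exact marginal SD ``sd``.

    Random-Fourier-feature draw from a squared-exponential Gaussian
    process: ``sd * sqrt(2/k) * sum_j cos(w_j u + phi_j)`` with
    ``w_j ~ N(0, 1/length_scale^2)`` and uniform phases.  For every AP
    position the marginal variance is exactly ``sd**2``.
    """
    w = rng.normal(0.0, 1.0 / length_scale, size=k)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=k)
    amp = sd * np.sqrt(2.0 / k)

    def jitter(u: np.ndarray) -> np.ndarray:
        return amp * np.cos(np.multiply.outer(u, w) + phi).sum(axis=-1)

    return jitter


def render_section(myelin_fraction: np.ndarray, mask: CallosalMask) -> np.ndarray:
    """Render a myelin-fraction field as an 8-bit RGB "LFB section".

    Grey level ``g = 255 - round(fraction * 255)`` (more myelin = darker),
    tinted with a fixed blue-dominant hue so the rendered luminance stays
    a linear function of the underlying grey; background is white.
    """
    f = np.clip(myelin_fraction, 0.0, 1.0)
    g = 255.0 - np.rint(f * 255.0)
    rgb = np.rint(g[..., None] * _STAIN_HUE).astype(np.uint8)
    out = np.full(mask.pixels.shape + (3,), 255, dtype=np.uint8)
    out[mask.pixels] = rgb[mask.pixels]
    return out


@dataclass(frozen=True)
class PhantomDataset:
    """One generated phantom: mask, template, images and ground truth.

    ``truth_table`` holds noise-free per-ROI means of each sample's
    (jittered) profile in raw modality units; ``sections`` maps
    section-type modality name -> list of RGB arrays (one per sample);
    ``volumes`` maps volume-type modality name -> list of 3-slice
    :class:`~callomap.sampling.ModalityMap` (one per sample).
    """

    spec: PhantomSpec
    mask: CallosalMask
    label_map: RegionLabelMap
    template: RoiTemplate
    truth_table: RoiSampleTable
    sections: dict[str, list[np.ndarray]]
    volumes: dict[str, list[ModalityMap]]

    def truth_vector(self, modality: str) -> np.ndarray:
        """Noise-free 92-ROI truth, averaged across samples."""
        return self.truth_table.vector(modality)


def generate_modality_images(
    mask: CallosalMask,
    spec: PhantomSpec,
    template: RoiTemplate | None = None,
    grid: GridSpec = GridSpec(),
) -> PhantomDataset:
    """Generate all modality images plus the noise-free truth table.

    For each modality and sample the intensity field is
    ``profile(AP) + jitter_sample(AP)`` inside the mask; section-type
    modalities are rendered as RGB stains, volume-type as three sagittal
    slices (-offset, midline, +offset, all sharing the truth field) with
    independent pixel noise per slice and background 0.  Noise is
    truncated to the valid range ([0, 1] for sections, >= 0 for volumes).
    A precomputed template may be passed to skip re-parcellation.
    """
    if not spec.profiles:
        raise ConfigError("phantom spec defines no modality profiles")
    if template is None:
        label_map = parcellate_witelson(mask)
        template = build_roi_template(label_map, grid)
    else:
        label_map = parcellate_witelson(mask, template.fractions)
    rng = np.random.default_rng(spec.seed)
    u = _ap_field(mask)
    fgmask = mask.pixels

    truth_parts: list[RoiSampleTable] = []
    sections: dict[str, list[np.ndarray]] = {}
    volumes: dict[str, list[ModalityMap]] = {}
    for name, profile in spec.profiles.items():
        kind = spec.kinds.get(name, VOLUME)
        noise_sd = spec.noise_for(name)
        jitter_sd = spec.jitter_for(name)
        outs: list = []
        for i in range(spec.n_samples):
            jitter = _sample_jitter(rng, jitter_sd) if jitter_sd > 0 else None
            field = profile(u)
            if jitter is not None:
                field = field + jitter(u)
            # noise-free per-ROI truth, raw units
            vals, counts = sample_rois(field, template, mask=mask)
            truth_parts.append(
                RoiSampleTable.from_arrays(name, f"sample{i + 1}", template, vals, counts)
            )
            if kind == SECTION:
                noisy = np.where(fgmask, field, 0.0)
                if noise_sd > 0:
                    noisy = noisy + rng.normal(0.0, noise_sd, size=noisy.shape)
                outs.append(render_section(np.clip(noisy, 0.0, 1.0), mask))
            else:
                truth2d = np.where(fgmask, field, 0.0)
                slices = []
                for _ in range(3):
                    sl = truth2d.copy()
                    if noise_sd > 0:
                        sl = sl + rng.normal(0.0, noise_sd, size=sl.shape)
                        sl = np.clip(sl, 0.0, None)
                    sl = np.where(fgmask, sl, 0.0)
                    slices.append(sl)
                vol = np.stack(slices)  # order: -offset, midline, +offset
                outs.append(
                    ModalityMap(
                        name=name,
                        data=vol,
                        spacing=(
                            spec.sagittal_spacing_mm,
                            spec.in_plane_spacing_mm,
                            spec.in_plane_spacing_mm,
                        ),
                        midsagittal_index=1,
                    )
                )
        if kind == SECTION:
            sections[name] = outs
        else:
            volumes[name] = outs
    truth = RoiSampleTable.concat(truth_parts)
    return PhantomDataset(
        spec=spec,
        mask=mask,
        label_map=label_map,
        template=template,
        truth_table=truth,
        sections=sections,
        volumes=volumes,
    )


def generate(spec: PhantomSpec, grid: GridSpec = GridSpec()) -> PhantomDataset:
    """Convenience wrapper: mask + images in one call."""
    return generate_modality_images(generate_mask(spec), spec, grid=grid)


def make_correlated_profiles(
    rho: float,
    seed: int,
    n_columns: int = 46,
    base: float = 0.5,
    amplitude: float = 0.12,
) -> tuple[Profile, Profile]:
    """Two smooth profiles whose per-column values correlate at ``rho``.

    Draws two independent smooth random functions, evaluates them at the
    AP column centres, orthonormalises the second against the first, and
    mixes them as ``rho * z1 + sqrt(1 - rho^2) * w`` so the column-centre
    values of the returned piecewise-linear profiles have sample
    correlation exactly ``rho`` (both rows of a template column share an
    AP coordinate, so the 92-ROI truth correlation matches up to
    rasterisation error).  Values are centred on ``base`` with SD
    ``amplitude``, suitable for section- and volume-type modalities.
    """
    if not -1.0 <= rho <= 1.0:
        raise ConfigError(f"rho must be in [-1, 1], got {rho}")
    rng = np.random.default_rng(seed)
    uc = (np.arange(n_columns) + 0.5) / n_columns

    def smooth_standardised() -> np.ndarray:
        f = _sample_jitter(rng, 1.0)(uc)
        sd = f.std()
        while sd < 1e-6:  # pathological flat draw; redraw
            f = _sample_jitter(rng, 1.0)(uc)
            sd = f.std()
        return (f - f.mean()) / sd

    z1 = smooth_standardised()
    g = smooth_standardised()
    w = g - (g @ z1) / (z1 @ z1) * z1
    w_sd = w.std()
    while w_sd < 1e-6:
        g = smooth_standardised()
        w = g - (g @ z1) / (z1 @ z1) * z1
        w_sd = w.std()
    w = (w - w.mean()) / w_sd
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * w

    def to_profile(z: np.ndarray) -> Profile:
        v = np.clip(base + amplitude * z, 0.02, None)
        knots_u = np.concatenate(([0.0], uc, [1.0]))
        knots_v = np.concatenate(([v[0]], v, [v[-1]]))
        return Profile(tuple(knots_u), tuple(knots_v))

    return to_profile(z1), to_profile(z2)
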