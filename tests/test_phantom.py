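"""Synthetic phantom: geometry, determinism, ground truth, noise model."""

import numpy as np
import pytest
from scipy import ndimage

from callomap import (
    ConfigError,
    PhantomSpec,
    Profile,
    ShapeParams,
    correlate_all,
    default_spec,
    generate_mask,
    generate_modality_images,
    grey_to_density,
    make_correlated_profiles,
    paper_pattern_profiles,
    rescale_to_units,
    rgb_to_grey,
    sample_phantom_dataset,
)
from callomap.phantom import SECTION, VOLUME


def _volume_spec(profile, mask_spec=None, **kwargs):
    return PhantomSpec(
        shape=(mask_spec or ShapeParams()),
        profiles={"X": profile},
        kinds={"X": VOLUME},
        **kwargs,
    )


class TestMask:
    def test_single_connected_component(self, phantom_mask):
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        _, n = ndimage.label(phantom_mask.pixels, structure=structure)
        assert n == 1

    def test_deterministic(self):
        spec = default_spec(seed=3)
        m1 = generate_mask(spec)
        m2 = generate_mask(spec)
        assert (m1.pixels == m2.pixels).all()

    @pytest.mark.parametrize("arch_length", [240, 300])
    def test_bounding_box_matches_arch_length(self, arch_length):
        spec = default_spec(arch_length=arch_length)
        mask = generate_mask(spec)
        assert abs(mask.ap_extent - arch_length) <= 2

    def test_concave_down_with_end_bulbs(self, phantom_mask):
        px = phantom_mask.pixels
        col_heights = px.sum(axis=0)
        cols = np.flatnonzero(col_heights)
        n = cols.size
        mid = (cols[0] + cols[-1]) // 2
        # the crown (top of the arch) is thin; the descending limbs a bit in
        # from the tips span much more of the column vertically
        assert col_heights[cols[n // 20]] > col_heights[mid]
        assert col_heights[cols[-n // 20]] > col_heights[mid]
        # posterior (splenium) bulb carries more tissue than the anterior
        quarter = n // 4
        assert px[:, cols[-quarter]:].sum() > px[:, : cols[quarter]].sum()
        # crown touches the top of the raster: concave-down arch
        assert px.any(axis=1).argmax() < px.shape[0] // 4

    def test_too_short_arch_rejected(self):
        with pytest.raises(ConfigError):
            ShapeParams(arch_length=150)


class TestModalityImages:
    def test_zero_noise_constant_profile(self, phantom_mask):
        spec = _volume_spec(Profile((0.0, 1.0), (3.0, 3.0)), noise_sd=0.0, n_samples=1)
        ds = generate_modality_images(phantom_mask, spec)
        vol = ds.volumes["X"][0]
        assert (vol.data[:, phantom_mask.pixels] == 3.0).all()
        assert (vol.data[:, ~phantom_mask.pixels] == 0.0).all()
        np.testing.assert_allclose(ds.truth_table.vector("X"), 3.0)

    def test_monotone_profile_monotone_truth(self, phantom_mask):
        spec = _volume_spec(Profile((0.0, 1.0), (1.0, 5.0)), noise_sd=0.0, n_samples=1)
        ds = generate_modality_images(phantom_mask, spec)
        dorsal = ds.truth_table.vector("X")[::2]  # one value per AP column
        assert (np.diff(dorsal) > 0).all()

    def test_identical_profiles_give_r_one(self, phantom_mask):
        p = Profile((0.0, 0.5, 1.0), (1.0, 4.0, 2.0))
        spec = PhantomSpec(
            profiles={"A": p, "B": p},
            kinds={"A": VOLUME, "B": VOLUME},
            noise_sd=0.0,
            n_samples=1,
        )
        ds = generate_modality_images(phantom_mask, spec)
        table = rescale_to_units(sample_phantom_dataset(ds))
        assert correlate_all(table, [("A", "B")])[0].r == pytest.approx(1.0, abs=1e-12)

    def test_dataset_deterministic(self, phantom_mask):
        spec = default_spec(seed=9)
        d1 = generate_modality_images(phantom_mask, spec)
        d2 = generate_modality_images(phantom_mask, spec)
        for name in d1.sections:
            for a, b in zip(d1.sections[name], d2.sections[name]):
                assert (a == b).all()
        for name in d1.volumes:
            for a, b in zip(d1.volumes[name], d2.volumes[name]):
                assert (a.data == b.data).all()
        assert d1.truth_table.data.equals(d2.truth_table.data)

    def test_truth_covers_template_rois(self, phantom_dataset):
        tt = phantom_dataset.truth_table
        roi_ids = {r.index for r in phantom_dataset.template.rois}
        for mod in tt.modalities:
            sub = tt.data[tt.data["modality"] == mod]
            for _, grp in sub.groupby("sample"):
                assert set(grp["roi_index"]) == roi_ids

    def test_volume_layout(self, phantom_dataset):
        vol = phantom_dataset.volumes["T1w/T2w"][0]
        assert vol.data.shape[0] == 3
        assert vol.midsagittal_index == 1
        assert vol.spacing[0] == 4.0

    def test_section_darker_where_more_myelin(self, phantom_mask):
        spec = PhantomSpec(
            profiles={"LFB": Profile((0.0, 1.0), (0.2, 0.9))},
            kinds={"LFB": SECTION},
            noise_sd=0.0,
            n_samples=1,
        )
        ds = generate_modality_images(phantom_mask, spec)
        rgb = ds.sections["LFB"][0]
        grey = rgb_to_grey(rgb).grey
        lo, hi = phantom_mask.ap_bounds
        anterior = grey[:, lo : lo + 20][phantom_mask.pixels[:, lo : lo + 20]]
        posterior = grey[:, hi - 20 : hi][phantom_mask.pixels[:, hi - 20 : hi]]
        assert posterior.mean() < anterior.mean()  # more myelin = darker
        assert (rgb[~phantom_mask.pixels] == 255).all()

    def test_density_recovers_profile_ordering(self, phantom_mask):
        """Full histology chain: rendered stain -> grey -> 1-7 density
        correlates almost perfectly with the generating profile."""
        spec = PhantomSpec(
            profiles={"LFB": Profile((0.0, 1.0), (0.1, 0.9))},
            kinds={"LFB": SECTION},
            noise_sd=0.0,
            n_samples=1,
        )
        ds = generate_modality_images(phantom_mask, spec)
        dens = grey_to_density(rgb_to_grey(ds.sections["LFB"][0]), phantom_mask)
        fg = phantom_mask.pixels
        u = np.tile(
            phantom_mask.ap_coordinate(np.arange(fg.shape[1])), (fg.shape[0], 1)
        )
        r = np.corrcoef(dens.density[fg], u[fg])[0, 1]
        assert r > 0.999

    def test_jitter_varies_between_samples(self, phantom_mask):
        spec = _volume_spec(
            Profile((0.0, 1.0), (2.0, 5.0)),
            noise_sd=0.0,
            sample_jitter_sd=0.4,
            n_samples=3,
        )
        ds = generate_modality_images(phantom_mask, spec)
        m = ds.truth_table.matrix("X")
        assert not np.allclose(m[0], m[1])


class TestSpecValidation:
    def test_section_profile_must_be_fraction(self):
        with pytest.raises(ConfigError):
            PhantomSpec(
                profiles={"LFB": Profile((0.0, 1.0), (0.5, 3.0))},
                kinds={"LFB": SECTION},
            )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            PhantomSpec(
                profiles={"X": Profile((0.0, 1.0), (1.0, 2.0))},
                kinds={"X": "spectrum"},
            )

    def test_nonpositive_profile_rejected(self):
        with pytest.raises(ConfigError):
            Profile((0.0, 1.0), (0.0, 2.0))

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            _volume_spec(Profile((0.0, 1.0), (1.0, 2.0)), noise_sd=-0.1)

    def test_zero_samples_rejected(self):
        with pytest.raises(ConfigError):
            _volume_spec(Profile((0.0, 1.0), (1.0, 2.0)), n_samples=0)

    def test_roundtrip_through_dict(self):
        spec = default_spec(seed=5)
        assert PhantomSpec.from_dict(spec.to_dict()).to_dict() == spec.to_dict()


class TestCorrelatedProfiles:
    @pytest.mark.parametrize("rho", [-0.8, 0.0, 0.8])
    def test_column_centre_correlation_is_rho(self, rho):
        p1, p2 = make_correlated_profiles(rho, seed=17)
        uc = (np.arange(46) + 0.5) / 46
        r = np.corrcoef(p1(uc), p2(uc))[0, 1]
        assert r == pytest.approx(rho, abs=1e-9)

    def test_profiles_positive(self):
        p1, p2 = make_correlated_profiles(-0.8, seed=2)
        u = np.linspace(0, 1, 200)
        assert (p1(u) > 0).all() and (p2(u) > 0).all()

    def test_paper_pattern_sign_structure_noise_free(self, phantom_mask):
        """The figure-pattern profiles reproduce the reported sign structure:
        T1w/T2w anticorrelated with LFB, MWF positively correlated with LFB,
        T1w/T2w weakly anticorrelated with MWF."""
        profiles, kinds = paper_pattern_profiles()
        spec = PhantomSpec(profiles=profiles, kinds=kinds, noise_sd=0.0, n_samples=1)
        tt = generate_modality_images(phantom_mask, spec).truth_table

        def r(a, b):
            return np.corrcoef(tt.vector(a), tt.vector(b))[0, 1]

        assert r("T1w/T2w", "LFB") < 0
        assert r("MWF", "LFB") > 0
        assert r("T1w/T2w", "MWF") < 0
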