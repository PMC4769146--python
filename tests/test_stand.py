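"""Diameter-class scheme, allometries, and patch-level structure summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from firesev import (
    DiameterClassScheme,
    PatchStructure,
    Species,
    SpeciesAllometry,
    class_attributes,
    patch_summary,
    quadratic_mean_diameter,
    structure_label,
)
from conftest import random_patch


class TestQuadraticMeanDiameter:
    @pytest.mark.parametrize(
        "lower, upper, expected",
        [(9, 11, 10.0167), (1, 3, 2.0817), (29, 31, 30.0056)],
    )
    def test_frozen_values(self, lower, upper, expected):
        assert quadratic_mean_diameter(lower, upper) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("lower, upper", [(3, 3), (5, 3), (-1, 3)])
    def test_rejects_bad_bounds(self, lower, upper):
        with pytest.raises(ValueError):
            quadratic_mean_diameter(lower, upper)

    @given(
        lower=st.floats(0.0, 50.0),
        width=st.floats(0.1, 10.0),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_is_rms_of_uniform_density(self, lower, width):
        """QMD is the RMS diameter of a uniform density, strictly inside the class."""
        upper = lower + width
        qmd = quadratic_mean_diameter(lower, upper)
        assert lower < qmd < upper
        rms = math.sqrt(quad(lambda x: x**2, lower, upper)[0] / width)
        assert qmd == pytest.approx(rms, rel=1e-9)


class TestAllometry:
    def test_height_frozen(self, spruce_allometry, pine_allometry):
        assert spruce_allometry.height(10.0166) == pytest.approx(9.503, abs=1e-3)
        assert pine_allometry.height(10.0166) == pytest.approx(10.224, abs=1e-3)

    def test_crown_ratio_frozen(self, spruce_allometry):
        assert spruce_allometry.crown_ratio(10.0, 20.0) == pytest.approx(0.6138, abs=1e-3)

    def test_crown_ratio_clamped(self, spruce_allometry):
        cr = spruce_allometry.crown_ratio(np.array([0.01, 30.0]), 500.0)
        assert np.all(cr >= spruce_allometry.cr_min)
        assert np.all(cr <= 1.0)

    def test_crown_biomass_frozen(self, spruce_allometry, pine_allometry):
        assert spruce_allometry.crown_biomass(10.0) == pytest.approx(3.800, abs=1e-3)
        assert pine_allometry.crown_biomass(10.0) == pytest.approx(4.115, abs=2e-3)

    def test_bark_thickness(self, spruce_allometry, pine_allometry):
        assert spruce_allometry.bark_thickness(10.0) == pytest.approx(0.8128)
        assert pine_allometry.bark_thickness(10.0) == pytest.approx(1.016)

    def test_species_mismatch_rejected(self, scheme, pine_allometry):
        patch = PatchStructure(Species.BLACK_SPRUCE, np.ones(15, dtype=int))
        with pytest.raises(ValueError):
            class_attributes(scheme, patch, pine_allometry)


class TestScheme:
    def test_default_bounds(self, scheme):
        assert len(scheme.class_bounds) == 15
        assert scheme.class_bounds[0] == (1.0, 3.0)
        assert scheme.class_bounds[-1] == (29.0, 31.0)

    def test_rejects_wrong_span(self):
        bad = tuple((3.0 + 2 * i, 5.0 + 2 * i) for i in range(15))
        with pytest.raises(ValueError):
            DiameterClassScheme(class_bounds=bad)


class TestPatchSummary:
    def test_single_class_weighted_means(self, scheme):
        """One class, H=10, CR=0.6: canopy base 4 m and canopy length 6 m."""
        counts = np.zeros(15, dtype=int)
        counts[4] = 1  # 9-11 cm class, QMD ~10: spruce height ~9.5
        patch = PatchStructure(Species.BLACK_SPRUCE, counts)
        attrs = class_attributes(scheme, patch)
        summary = patch_summary(patch, attrs)
        a = attrs[4]
        assert summary.cbh == pytest.approx(a.height * (1 - a.crown_ratio))
        assert summary.cl == pytest.approx(a.height * a.crown_ratio)
        assert summary.cbh + summary.cl == pytest.approx(a.height)

    def test_swdi_extremes(self, scheme):
        uniform = PatchStructure(Species.BLACK_SPRUCE, np.full(15, 7, dtype=int))
        attrs = class_attributes(scheme, uniform)
        assert patch_summary(uniform, attrs).swdi == pytest.approx(math.log(15))
        single = PatchStructure(Species.BLACK_SPRUCE, np.eye(15, dtype=int)[3] * 50)
        attrs = class_attributes(scheme, single)
        assert patch_summary(single, attrs).swdi == 0.0

    def test_swdi_maximal_only_when_uniform(self, scheme, rng):
        for _ in range(20):
            patch = random_patch(rng)
            attrs = class_attributes(scheme, patch)
            swdi = patch_summary(patch, attrs).swdi
            assert 0.0 <= swdi <= math.log(15) + 1e-12
            if len(set(patch.counts)) > 1:
                assert swdi < math.log(15)

    def test_height_partitions_into_base_and_crown(self, scheme, rng):
        patch = random_patch(rng)
        for a in class_attributes(scheme, patch):
            assert a.crown_base + a.crown_length == pytest.approx(a.height)
            assert a.qmd == pytest.approx(a.qmd)
            assert a.fuel_mass == pytest.approx(a.crown_biomass * a.count)

    def test_count_scaling_invariance(self, scheme, rng):
        """Intensive summaries are invariant to scaling all counts; extensive
        ones scale linearly.  Class crown geometry is held fixed: the
        crown-ratio model depends on stand basal area, so re-deriving
        attributes at triple density legitimately shifts crown ratios."""
        from dataclasses import replace

        patch = random_patch(rng)
        attrs = class_attributes(scheme, patch)
        s1 = patch_summary(patch, attrs)
        scaled = patch.scaled(3)
        attrs3 = [
            replace(a, count=3 * a.count, fuel_mass=3 * a.fuel_mass) for a in attrs
        ]
        s3 = patch_summary(scaled, attrs3)
        for name in ("cbh", "cl", "swdi", "pct_class10", "pct_class14"):
            assert getattr(s3, name) == pytest.approx(getattr(s1, name), rel=1e-9)
        # CBD is fuel load over depth, so it scales with density like CFL
        assert s3.cbd == pytest.approx(3 * s1.cbd, rel=1e-9)
        assert s3.cfl == pytest.approx(3 * s1.cfl, rel=1e-9)
        assert s3.basal_area == pytest.approx(3 * s1.basal_area, rel=1e-9)
        assert s3.total_density == 3 * s1.total_density

    def test_empty_patch_rejected(self, scheme):
        with pytest.raises(ValueError):
            patch = PatchStructure(Species.JACK_PINE, np.zeros(15, dtype=int))
            patch_summary(patch, class_attributes(scheme, patch))


def test_structure_label_bands():
    """SWDI in the 1.8-2.4 band labels an uneven-sized stand; 1.2-1.7 even."""
    for v in (1.8, 2.0, 2.4):
        assert structure_label(v) == "uneven"
    for v in (1.2, 1.5, 1.7):
        assert structure_label(v) == "even"
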