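"""Crown scorch, mortality logistic, binomial kills and the severity statistic."""

import numpy as np
import pytest

from firesev import (
    FireOutcome,
    PatchStructure,
    Species,
    apply_fire,
    class_attributes,
    crown_scorch,
    expected_severity,
    mortality_probability,
    severity_class,
)
from conftest import random_patch


def _outcome(sh, crowned=False, intensity=500.0):
    return FireOutcome(
        crowned=crowned, intensity_initial=intensity, intensity_used=intensity,
        scorch_height=sh,
    )


class TestCrownScorch:
    def test_scorch_above_tree_top_scorches_whole_crown(self):
        cls, cs = crown_scorch(12.0, height=10.0, crown_ratio=0.6)
        assert cls == pytest.approx(6.0)
        assert cs == 100.0

    def test_scorch_below_crown_base(self):
        cls, cs = crown_scorch(3.0, height=10.0, crown_ratio=0.6)
        assert cls == 0.0 and cs == 0.0

    def test_partial_scorch(self):
        cls, cs = crown_scorch(7.0, height=10.0, crown_ratio=0.6)
        assert cls == pytest.approx(3.0)
        assert cs == pytest.approx(50.0)

    def test_cs_never_exceeds_100(self, rng):
        for _ in range(200):
            h = rng.uniform(1, 25)
            cr = rng.uniform(0.01, 1.0)
            sh = rng.uniform(0, 40)
            _, cs = crown_scorch(sh, h, cr)
            assert 0.0 <= cs <= 100.0


class TestMortalityProbability:
    @pytest.mark.parametrize(
        "bt, cs, expected",
        [
            (0.0, 0.0, 0.8744),
            (0.0, 100.0, 0.99932),
            (1.0, 50.0, 0.7726),
            (100.0, 0.0, 0.01243),  # very thick bark: asymptotic survival
        ],
    )
    def test_frozen_values(self, bt, cs, expected):
        assert mortality_probability(bt, cs) == pytest.approx(expected, abs=1e-4)

    def test_monotone_in_scorch_and_bark(self):
        cs = np.linspace(0, 100, 21)
        m = mortality_probability(1.0, cs)
        assert np.all(np.diff(m) > 0)
        bt = np.linspace(0, 5, 21)
        m = mortality_probability(bt, 50.0)
        assert np.all(np.diff(m) < 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            mortality_probability(-1.0, 50.0)
        with pytest.raises(ValueError):
            mortality_probability(1.0, 120.0)


class TestSeverityClass:
    @pytest.mark.parametrize(
        "s, expected",
        [(0.0, "low"), (24.99, "low"), (25.0, "moderate"), (50.0, "moderate"),
         (75.0, "moderate"), (75.01, "high"), (100.0, "high")],
    )
    def test_boundaries_inclusive_to_moderate(self, s, expected):
        assert severity_class(s) == expected


class TestApplyFire:
    def test_no_scorch_no_mortality_flag_gives_zero_severity(self, scheme):
        counts = np.zeros(15, dtype=int)
        counts[5] = 200
        patch = PatchStructure(Species.BLACK_SPRUCE, counts)
        attrs = class_attributes(scheme, patch)
        result = apply_fire(patch, attrs, _outcome(sh=0.01), rng=0,
                            no_scorch_no_mortality=True)
        assert result.severity == 0.0
        assert result.severity_class == "low"
        assert result.ba_after == result.ba_before

    def test_binomial_kill_rate_single_class(self, scheme):
        """With one class the severity is the killed fraction; at n=10000 it
        sits within 3 binomial standard errors of the class mortality."""
        counts = np.zeros(15, dtype=int)
        counts[7] = 10_000
        patch = PatchStructure(Species.BLACK_SPRUCE, counts)
        attrs = class_attributes(scheme, patch)
        a = attrs[7]
        # pick a scorch height giving an interior mortality probability
        outcome = _outcome(sh=a.crown_base + 0.5 * a.crown_length)
        m = float(apply_fire(patch, attrs, outcome, rng=1).mortality[7])
        assert 0.05 < m < 0.95
        result = apply_fire(patch, attrs, outcome, rng=2)
        se = np.sqrt(m * (1 - m) / 10_000)
        assert result.severity / 100.0 == pytest.approx(m, abs=3 * se)

    def test_expectation_identity(self, scheme, rng):
        """Monte-Carlo mean of S matches 100 sum(ba_i n_i M_i)/BA."""
        patch = random_patch(rng, species=Species.JACK_PINE)
        attrs = class_attributes(scheme, patch)
        outcome = _outcome(sh=6.0)
        expected = expected_severity(patch, attrs, outcome)
        reps = 1500
        sims = np.array(
            [apply_fire(patch, attrs, outcome, rng=int(s)).severity
             for s in range(reps)]
        )
        se = sims.std(ddof=1) / np.sqrt(reps)
        assert sims.mean() == pytest.approx(expected, abs=3 * max(se, 1e-6))

    def test_killed_bounded_by_counts_and_ba_decreases(self, scheme, rng):
        for _ in range(20):
            patch = random_patch(rng)
            attrs = class_attributes(scheme, patch)
            result = apply_fire(patch, attrs, _outcome(sh=rng.uniform(0, 25)), rng=rng)
            assert np.all(result.killed <= patch.counts)
            assert result.ba_after <= result.ba_before + 1e-12
            assert 0.0 <= result.severity <= 100.0

    def test_reproducible_given_seed(self, scheme, rng):
        patch = random_patch(rng)
        attrs = class_attributes(scheme, patch)
        r1 = apply_fire(patch, attrs, _outcome(sh=8.0), rng=42)
        r2 = apply_fire(patch, attrs, _outcome(sh=8.0), rng=42)
        np.testing.assert_array_equal(r1.killed, r2.killed)
        assert r1.severity == r2.severity
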