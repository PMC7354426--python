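import math

import numpy as np
import pytest

from conftest import make_state, random_two_foot_scenario
from spiderstat.cage_geometry import Subject, attachment_from_polar, cord_state
from spiderstat.errors import InvalidInputError, PerturbationRangeWarning
from spiderstat.statics import (
    GRAVITY,
    Force3,
    Stance,
    classify_foot_load,
    foot_reactions,
    perturb_tension,
    resolve_cog,
    summarize,
)


def oracle_reactions(subject, cog_resultant, stance):
    """Independent 2-unknown moment-balance solve (matrix route)."""
    F = cog_resultant.as_array()
    net = subject.mass * GRAVITY - F[2]
    A = np.array([[1.0, 1.0], [stance.left[1], stance.right[1]]])
    lz, rz = np.linalg.solve(A, np.array([net, subject.cog_height * F[1]]))
    wl, wr = lz / net, rz / net
    return (
        np.array([-F[0] * wl, -F[1] * wl, lz]),
        np.array([-F[0] * wr, -F[1] * wr, rz]),
    )


class TestResolveCog:
    def test_four_symmetric_cords_sum_vertically(self, adult, adult_thick):
        elong = 100 * 0.250 / adult_thick.spec.rest_length
        states = [
            cord_state(attachment_from_polar(adult, 45.0, elong, az, adult_thick))
            for az in (45.0, 135.0, 225.0, 315.0)
        ]
        res, frac = resolve_cog(adult, states)
        assert frac == pytest.approx(0.15, abs=0.01)
        assert res.x == pytest.approx(0.0, abs=1e-9)
        assert res.y == pytest.approx(0.0, abs=1e-9)

    def test_child_case_fraction(self, child, child_thin):
        elong = 100 * 0.100 / child_thin.spec.rest_length
        states = [
            cord_state(attachment_from_polar(child, 10.0, elong, az, child_thin))
            for az in (45.0, 135.0, 225.0, 315.0)
        ]
        _, frac = resolve_cog(child, states)
        assert frac == pytest.approx(0.16, abs=0.01)

    def test_zero_tension_identity(self, adult):
        states = [make_state((0.2, 0.3, 0.9), 0.0)]
        res, frac = resolve_cog(adult, states)
        assert (res.x, res.y, res.z) == (0.0, 0.0, 0.0)
        assert frac == 0.0

    def test_equals_naive_loop_sum(self, adult):
        rng = np.random.default_rng(11)
        states = [make_state(rng.normal(size=3), rng.uniform(0, 60)) for _ in range(5)]
        res, _ = resolve_cog(adult, states)
        naive = np.zeros(3)
        for s in states:
            naive += s.tension * np.asarray(s.direction)
        assert res.as_array() == pytest.approx(naive, abs=0.0)

    def test_empty_rejected(self, adult):
        with pytest.raises(InvalidInputError):
            resolve_cog(adult, [])

    def test_monotone_in_each_tension(self, adult):
        rng = np.random.default_rng(5)
        states = [make_state(rng.normal(size=3), rng.uniform(0, 40)) for _ in range(4)]
        _, base = resolve_cog(adult, states)
        for i, s in enumerate(states):
            bumped = list(states)
            bumped[i] = make_state(s.direction, s.tension + 10.0)
            _, frac = resolve_cog(adult, bumped)
            sign = np.sign(s.direction[2])
            assert (frac - base) * sign >= 0 or s.direction[2] == 0


class TestFootReactions:
    def test_symmetric_split(self, adult):
        F = Force3(0.0, 0.0, 110.0)
        left, right, lift = foot_reactions(adult, F, Stance.symmetric(0.3))
        expected = (adult.mass * GRAVITY - 110.0) / 2
        assert not lift
        assert left.z == pytest.approx(expected, rel=1e-12)
        assert right.z == pytest.approx(expected, rel=1e-12)

    def test_matches_independent_moment_oracle(self, adult):
        rng = np.random.default_rng(17)
        for _ in range(50):
            subject, states, stance = random_two_foot_scenario(rng)
            res, _ = resolve_cog(subject, states)
            left, right, lift = foot_reactions(subject, res, stance)
            assert not lift
            ol, orr = oracle_reactions(subject, res, stance)
            w = subject.mass * GRAVITY
            assert left.as_array() == pytest.approx(ol, abs=1e-9 * w)
            assert right.as_array() == pytest.approx(orr, abs=1e-9 * w)

    def test_equilibrium_closure(self, adult):
        rng = np.random.default_rng(29)
        for _ in range(200):
            subject, states, stance = random_two_foot_scenario(rng)
            res, _ = resolve_cog(subject, states)
            left, right, _ = foot_reactions(subject, res, stance)
            total = (
                res.as_array()
                + np.array([0.0, 0.0, -subject.mass * GRAVITY])
                + left.as_array()
                + right.as_array()
            )
            assert np.abs(total).max() <= 1e-9 * subject.mass * GRAVITY

    def test_mirror_symmetry_is_exact(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            subject, states, stance = random_two_foot_scenario(rng)
            res, _ = resolve_cog(subject, states)
            left, right, _ = foot_reactions(subject, res, stance)
            mirrored = Force3(res.x, -res.y, res.z)
            m_stance = Stance(
                left=(stance.right[0], -stance.right[1]),
                right=(stance.left[0], -stance.left[1]),
            )
            ml, mr, _ = foot_reactions(subject, mirrored, m_stance)
            # bitwise: mirror swaps feet and negates Y
            assert (ml.x, ml.y, ml.z) == (right.x, -right.y, right.z)
            assert (mr.x, mr.y, mr.z) == (left.x, -left.y, left.z)

    def test_full_suspension_lifts_off(self, adult):
        F = Force3(0.0, 0.0, adult.mass * GRAVITY)
        left, right, lift = foot_reactions(adult, F, Stance.symmetric())
        assert lift
        assert left.as_array() == pytest.approx(np.zeros(3))
        assert right.as_array() == pytest.approx(np.zeros(3))

    def test_single_foot_takes_everything(self, adult):
        F = Force3(5.0, -3.0, 100.0)
        left, right, lift = foot_reactions(
            adult, F, Stance(left=None, right=(0.0, -0.1))
        )
        assert not lift
        assert left.as_array() == pytest.approx(np.zeros(3))
        assert right.z == pytest.approx(adult.mass * GRAVITY - 100.0)
        assert right.x == -5.0 and right.y == 3.0

    def test_lateral_pull_loads_the_near_foot(self, adult):
        # pulling the waist toward the subject's left (+Y) shifts load left
        F = Force3(0.0, 40.0, 0.0)
        left, right, _ = foot_reactions(adult, F, Stance.symmetric(0.3))
        assert left.z > right.z


class TestClassifyFootLoad:
    @pytest.mark.parametrize(
        "force,heel,toe",
        [
            (Force3(0, 0, 12.0), "unweighted", "neutral"),
            (Force3(0, -3.0, -5.0), "loaded", "load_away"),
            (Force3(0, 0, 0), "neutral", "neutral"),
            (Force3(1.0, 2.0, 0.5), "unweighted", "load_toward"),
        ],
    )
    def test_sign_rules(self, force, heel, toe):
        assert classify_foot_load(force) == (heel, toe)


class TestPerturbTension:
    def _child_states(self, child, child_thin):
        elong = 100 * 0.100 / child_thin.spec.rest_length
        return [
            cord_state(attachment_from_polar(child, 10.0, elong, az, child_thin))
            for az in (45.0, 135.0, 225.0, 315.0)
        ]

    def test_identity(self, child, child_thin):
        states = self._child_states(child, child_thin)
        assert perturb_tension(states, 1.0) == states

    @pytest.mark.parametrize("factor", [0.8, 1.2])
    def test_unweighting_scales_linearly(self, child, child_thin, factor):
        states = self._child_states(child, child_thin)
        _, base = resolve_cog(child, states)
        _, scaled = resolve_cog(child, perturb_tension(states, factor))
        assert scaled == pytest.approx(factor * base, rel=1e-12)
        # the worked child case: 0.16 +/- tolerance scales to 0.128 / 0.192
        assert scaled == pytest.approx(0.16 * factor, abs=0.01 * factor)

    def test_out_of_band_factor_warns_but_applies(self, child, child_thin):
        states = self._child_states(child, child_thin)
        with pytest.warns(PerturbationRangeWarning):
            out = perturb_tension(states, 1.5)
        assert out[0].tension == pytest.approx(1.5 * states[0].tension)

    def test_negative_factor_rejected(self, child, child_thin):
        with pytest.raises(InvalidInputError):
            perturb_tension(self._child_states(child, child_thin), -0.1)


class TestSummarize:
    def test_symmetric_unweighting_summary(self, adult, adult_thick):
        elong = 100 * 0.250 / adult_thick.spec.rest_length
        states = [
            cord_state(attachment_from_polar(adult, 45.0, elong, az, adult_thick))
            for az in (45.0, 135.0, 225.0, 315.0)
        ]
        s = summarize(adult, states, Stance.symmetric(0.3))
        assert not s.lift_off
        assert s.left_foot.z == s.right_foot.z
        assert s.left_heel == s.right_heel == "unweighted"

    def test_loading_cords_load_the_heel(self, adult, adult_thick):
        states = [
            cord_state(attachment_from_polar(adult, -30.0, 30.0, az, adult_thick))
            for az in (45.0, 135.0, 225.0, 315.0)
        ]
        s = summarize(adult, states, Stance.symmetric(0.3))
        assert s.unweighting_fraction < 0
        assert s.left_heel == s.right_heel == "loaded"
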