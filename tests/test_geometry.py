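import math

import numpy as np
import pytest

from buccalsim.geometry import (
    AnatomyParams,
    GeneralizedState,
    GeometryError,
    Point2,
    element_length,
    hinge_point_x,
    i2_tangency_angles,
    overlap_delta,
    radular_cusp,
    safe_tangent_point,
    tangent_point,
)


def brute_force_tangent(center, R, anchor, n=2_000_000):
    """Independent oracle: scan circle points for the tangency condition
    |(p - anchor) . (p - center)| = 0, then apply posterior (min-x) choice."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    px = center.x + R * np.cos(th)
    py = center.y + R * np.sin(th)
    dot = (px - anchor.x) * (px - center.x) + (py - anchor.y) * (py - center.y)
    # tangency: radius perpendicular to the anchor->point chord
    idx = np.argsort(np.abs(dot))[:40]
    cands = sorted(zip(px[idx], py[idx]))
    return cands[0]


class TestTangentPoint:
    def test_example_vertical_anchor(self):
        # center (0,0), R=1, anchor (0,2): posterior tangent is (-sqrt(3)/2, 1/2)
        p = tangent_point(Point2(0, 0), 1.0, Point2(0, 2))
        assert p.x == pytest.approx(-math.sqrt(3) / 2, abs=1e-12)
        assert p.y == pytest.approx(0.5, abs=1e-12)

    def test_example_matches_brute_force(self):
        bx, by = brute_force_tangent(Point2(0, 0), 1.0, Point2(0, 2))
        p = tangent_point(Point2(0, 0), 1.0, Point2(0, 2))
        assert p.x == pytest.approx(bx, abs=1e-4)  # oracle limited by grid
        assert p.y == pytest.approx(by, abs=1e-4)

    def test_anchor_on_circle(self):
        p = tangent_point(Point2(0, 0), 1.0, Point2(0, 1))
        assert (p.x, p.y) == pytest.approx((0.0, 1.0), abs=1e-9)

    def test_translation_invariance(self):
        p0 = tangent_point(Point2(0, 0), 1.0, Point2(0, 2))
        p1 = tangent_point(Point2(3, -2), 1.0, Point2(3, 0))
        assert p1.x == pytest.approx(p0.x + 3, abs=1e-12)
        assert p1.y == pytest.approx(p0.y - 2, abs=1e-12)

    def test_anchor_inside_raises(self):
        with pytest.raises(GeometryError):
            tangent_point(Point2(0, 0), 1.0, Point2(0.2, 0.1))

    def test_horizontal_anchor_singular_branch(self):
        # anchor on the center's horizontal: y-recovery divides by zero,
        # handled by the rotated-frame fallback
        p = tangent_point(Point2(0, 0), 1.0, Point2(2, 0))
        assert math.hypot(p.x, p.y) == pytest.approx(1.0, abs=1e-10)
        assert (p.x - 2) * p.x + p.y * p.y == pytest.approx(0.0, abs=1e-10)

    def test_random_configurations_tangency(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            c = Point2(*rng.uniform(-3, 3, 2))
            R = rng.uniform(0.2, 2.0)
            # anchor strictly outside
            ang = rng.uniform(0, 2 * np.pi)
            d = R * rng.uniform(1.01, 4.0)
            a = Point2(c.x + d * np.cos(ang), c.y + d * np.sin(ang))
            p = tangent_point(c, R, a)
            assert math.hypot(p.x - c.x, p.y - c.y) == pytest.approx(R, abs=1e-10)
            dot = (p.x - a.x) * (p.x - c.x) + (p.y - a.y) * (p.y - c.y)
            assert abs(dot) < 1e-8

    def test_safe_projection_of_shallow_penetration(self):
        # anchor just inside the circle is projected, not fatal
        p = safe_tangent_point(Point2(0, 0), 1.0, Point2(0.95, 0.0))
        assert math.hypot(p.x, p.y) == pytest.approx(1.0, abs=1e-9)

    def test_safe_rejects_deep_penetration(self):
        with pytest.raises(GeometryError):
            safe_tangent_point(Point2(0, 0), 1.0, Point2(0.3, 0.0))


@pytest.fixture
def anat():
    return AnatomyParams()


def state(anat, x_h=0.0, x_d=1.0, x_v=1.0, x_g=0.1, theta_g=0.0):
    return GeneralizedState.from_coords(x_h, x_d, x_v, x_g, theta_g, anat)


class TestTangencyAngles:
    def test_symmetric_configuration(self):
        # mirror-image groove points about the horizontal through the center
        anat = AnatomyParams(theta_H=1.5 * math.pi, H_lumen=2.0)
        gs = state(anat, x_g=0.0, theta_g=0.0)  # center at (0, 1): grooves at +-1
        a_d, a_v = i2_tangency_angles(gs, anat)
        assert a_v == pytest.approx(-a_d, abs=1e-9)

    def test_matches_tangent_point_example(self):
        anat = AnatomyParams(theta_H=0.5 * math.pi, H_lumen=2.0)
        # theta chosen so y_g = -sin(pi/2) = -1: dorsal groove (0, 2) is at
        # distance 3 above the center (0, -1)
        gs = GeneralizedState.from_coords(0.0, 0.0, 0.0, 0.0, 0.0, anat)
        a_d, _ = i2_tangency_angles(gs, anat)
        expect = tangent_point(Point2(0, -1), 1.0, Point2(0, 2))
        assert a_d == pytest.approx(math.atan2(expect.y + 1, expect.x), abs=1e-9)


class TestElementLength:
    def test_e6_collinear(self, anat):
        gs = state(anat)
        # place E6 anchor on the midline level with the midpoint
        anat2 = AnatomyParams(
            H_lumen=anat.H_lumen,
            e6_anchor_rel_head=Point2(-2.0, 0.5 * anat.H_lumen),
        )
        mid_x = 0.5 * (gs.x_d + gs.x_v)
        assert element_length("E6", gs, anat2) == pytest.approx(mid_x + 2.0)

    def test_hinge_zero(self, anat):
        gs = state(anat, theta_g=0.0)
        gs.x_v = hinge_point_x(gs, anat)
        assert element_length("hinge", gs, anat) == pytest.approx(0.0, abs=1e-12)

    def test_i1_lengths_horizontal(self, anat):
        gs = state(anat, x_h=0.5, x_d=1.2, x_v=0.8)
        assert element_length("I1d", gs, anat) == pytest.approx(0.5 + anat.L_head - 1.2)
        assert element_length("I1v", gs, anat) == pytest.approx(0.5 + anat.L_head - 0.8)

    def test_unknown_element(self, anat):
        with pytest.raises(KeyError):
            element_length("I99", state(anat), anat)

    def test_i2_continuity_under_perturbation(self, anat):
        rng = np.random.default_rng(7)
        gs0 = state(anat, x_g=0.4)
        L0 = element_length("I2", gs0, anat)
        for _ in range(200):
            eps = rng.normal(0, 1e-6, 3)
            gs = state(
                anat, x_g=0.4 + eps[0], x_d=1.0 + eps[1], x_v=1.0 + eps[2]
            )
            assert abs(element_length("I2", gs, anat) - L0) < 1e-4

    def test_i2_reduces_to_arc_when_anchors_on_circle(self, anat):
        # both groove points exactly on the circle: chords vanish
        a = AnatomyParams(theta_H=1.5 * math.pi, H_lumen=2.0)
        gs = GeneralizedState.from_coords(0.0, 0.0, 0.0, 0.0, 0.0, a)
        # grooves at (0, 2) and (0, 0); center (0, 1): both on the circle
        L = element_length("I2", gs, a)
        assert L == pytest.approx(a.R * math.pi, rel=1e-6)


class TestOverlapAndCusp:
    def test_overlap_examples(self, anat):
        gs = state(anat, x_g=0.0, x_d=1.0, x_v=1.0)
        assert overlap_delta(gs, anat) == pytest.approx(0.0)
        gs = state(anat, x_g=1.0, x_d=0.0, x_v=0.0)
        assert overlap_delta(gs, anat) == pytest.approx(2.0)

    def test_overlap_translation_invariance(self, anat):
        gs1 = state(anat, x_g=0.3, x_d=1.1, x_v=0.9)
        gs2 = state(anat, x_g=0.3 + 5, x_d=1.1 + 5, x_v=0.9 + 5)
        assert overlap_delta(gs1, anat) == pytest.approx(overlap_delta(gs2, anat))

    def test_cusp_at_zero_relative_angle(self):
        anat = AnatomyParams(theta_H=1.5 * math.pi, theta_f=0.6)
        gs = GeneralizedState.from_coords(0, 0, 0, 0.0, 0.6, anat)
        c = radular_cusp(gs, anat)
        assert c.x == pytest.approx(gs.x_g + anat.R)
        assert c.y == pytest.approx(gs.y_g, abs=1e-12)

    def test_cusp_quarter_turn(self):
        anat = AnatomyParams(theta_f=0.0)
        gs = GeneralizedState.from_coords(0, 0, 0, 0.2, 0.5 * math.pi, anat)
        c = radular_cusp(gs, anat)
        assert c.x == pytest.approx(gs.x_g, abs=1e-12)
        assert c.y == pytest.approx(gs.y_g + anat.R)

    def test_cusp_distance_and_rigid_rotation(self, anat):
        rng = np.random.default_rng(3)
        for _ in range(100):
            th = rng.uniform(-1, 1)
            phi = rng.uniform(-0.5, 0.5)
            gs = state(anat, theta_g=th)
            c = radular_cusp(gs, anat)
            assert math.hypot(c.x - gs.x_g, c.y - gs.y_g) == pytest.approx(anat.R)
            # rotating theta_g by phi rotates the cusp by phi about the center
            gs2 = GeneralizedState(gs.x_h, gs.x_d, gs.x_v, gs.x_g, th + phi, gs.y_g)
            c2 = radular_cusp(gs2, anat)
            a1 = math.atan2(c.y - gs.y_g, c.x - gs.x_g)
            a2 = math.atan2(c2.y - gs.y_g, c2.x - gs.x_g)
            assert (a2 - a1 - phi) % (2 * math.pi) == pytest.approx(0.0, abs=1e-9) or (
                (a2 - a1 - phi) % (2 * math.pi)
            ) == pytest.approx(2 * math.pi, abs=1e-9)


class TestInvariants:
    def test_pin_slot_reconstruction(self, anat):
        rng = np.random.default_rng(11)
        for _ in range(100):
            th = rng.uniform(-1, 1)
            gs = state(anat, theta_g=th)
            assert gs.constraint_residual(anat) == pytest.approx(0.0, abs=1e-12)

    def test_anatomy_validation(self):
        with pytest.raises(ValueError):
            AnatomyParams(R=-1.0)
        with pytest.raises(ValueError):
            AnatomyParams(H_lumen=0.0)
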