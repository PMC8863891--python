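"""Jaw-opening kinematics and strain-limited gape detection."""

import math

import numpy as np
import pytest

from dryskull.forces import MuscleName
from dryskull.gape import (
    GapeModelError,
    JawModel,
    MuscleCylinder,
    StrainLimits,
    cylinder_strain,
    find_gape_limits,
    jaw_clearance,
    rotate_about_axis,
)
from dryskull.synthetic import (
    SyntheticTaxonSpec,
    make_planar_gape_model,
    make_taxon,
    planar_crossing_angle,
    planar_strain_closed_form,
)


def rodrigues(p, a, b, theta_deg):
    """Independent rotation oracle: explicit Rodrigues rotation formula."""
    p, a, b = (np.asarray(x, float) for x in (p, a, b))
    k = (b - a) / np.linalg.norm(b - a)
    v = p - a
    t = math.radians(theta_deg)
    vrot = v * math.cos(t) + np.cross(k, v) * math.sin(t) + k * np.dot(k, v) * (1 - math.cos(t))
    return a + vrot


class TestRotation:
    def test_zero_angle_is_identity(self):
        p = np.array([3.0, 4.0, 5.0])
        out = rotate_about_axis(p, (0, 0, 0), (0, 1, 0), 0.0)
        assert np.allclose(out, p, atol=1e-12)

    def test_point_on_axis_unmoved(self):
        out = rotate_about_axis((1, 7, 1), (1, 0, 1), (1, 10, 1), 123.4)
        assert np.allclose(out, (1, 7, 1), atol=1e-12)

    def test_matches_rodrigues_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            p = rng.uniform(-100, 100, 3)
            a = rng.uniform(-100, 100, 3)
            b = a + rng.uniform(-10, 10, 3)
            if np.linalg.norm(b - a) < 1e-6:
                continue
            theta = rng.uniform(-180, 180)
            got = rotate_about_axis(p, a, b, theta)
            want = rodrigues(p, a, b, theta)
            assert np.linalg.norm(got - want) < 1e-9

    def test_degenerate_axis_rejected(self):
        with pytest.raises(GapeModelError, match="axis"):
            rotate_about_axis((1, 2, 3), (0, 0, 0), (0, 0, 0), 10.0)


class TestStrain:
    def test_unity_at_resting_gape(self):
        model = make_planar_gape_model(40.0, 30.0, 60.0, resting_gape=5.0)
        strains = cylinder_strain(model, 5.0)
        assert all(s == 1.0 for s in strains.values())

    def test_planar_law_of_cosines(self):
        r_o, r_i, phi0, rest = 35.0, 25.0, 50.0, 5.0
        model = make_planar_gape_model(r_o, r_i, phi0, resting_gape=rest)
        for theta in np.arange(rest, 90.0, 2.5):
            got = cylinder_strain(model, float(theta))["mAMES1"]
            want = planar_strain_closed_form(r_o, r_i, phi0, rest, float(theta))
            assert got == pytest.approx(want, abs=1e-9)

    def test_monotone_nondecreasing_while_angle_opens(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            r_o = rng.uniform(10, 60)
            r_i = rng.uniform(10, 60)
            phi0 = rng.uniform(20, 120)
            model = make_planar_gape_model(r_o, r_i, phi0, resting_gape=5.0)
            # strain grows while the enclosed angle stays below 180 degrees
            thetas = np.arange(5.0, 5.0 + (175.0 - phi0), 1.0)
            strains = [cylinder_strain(model, float(t))["mAMES1"] for t in thetas]
            assert all(b >= a - 1e-12 for a, b in zip(strains, strains[1:]))

    def test_mandible_rigidity(self):
        # distances between two mandible-fixed points survive rotation
        rng = np.random.default_rng(1)
        a, b = rng.uniform(-50, 50, 3), rng.uniform(-50, 50, 3)
        ja, jb = np.array([0.0, -30, 0]), np.array([0.0, 30, 0])
        for theta in (1.0, 17.5, 60.0):
            ra = rotate_about_axis(a, ja, jb, theta)
            rb = rotate_about_axis(b, ja, jb, theta)
            assert abs(np.linalg.norm(ra - rb) - np.linalg.norm(a - b)) < 1e-9


class TestGapeLimits:
    def test_degenerate_optimal_limit_hits_resting_gape(self):
        model = make_planar_gape_model(40.0, 30.0, 60.0, resting_gape=5.0)
        res = find_gape_limits(model, StrainLimits(optimal=1.0, maximum=1.7))
        assert res.theta_optimal == 5.0

    def test_crossings_match_closed_form_inversion(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            r_o = rng.uniform(15, 60)
            r_i = rng.uniform(15, 60)
            phi0 = rng.uniform(25, 110)
            model = make_planar_gape_model(r_o, r_i, phi0, resting_gape=5.0)
            res = find_gape_limits(model)
            for strain, got in ((1.3, res.theta_optimal), (1.7, res.theta_maximum)):
                exact = planar_crossing_angle(r_o, r_i, phi0, 5.0, strain)
                if exact is None or exact > 180.0:
                    assert got is None
                else:
                    # first grid point at/above the exact crossing
                    assert got is not None
                    assert exact - 0.5 < got <= exact + 0.5
                    assert got >= exact - 1e-9

    def test_maximum_never_precedes_optimal(self):
        for seed in range(5):
            tax = make_taxon(SyntheticTaxonSpec(seed=seed))
            res = find_gape_limits(tax.model)
            if res.theta_optimal is not None and res.theta_maximum is not None:
                assert res.theta_maximum >= res.theta_optimal

    def test_step_halving_stability(self):
        model = make_planar_gape_model(45.0, 28.0, 55.0, resting_gape=5.0, step=0.5)
        coarse = find_gape_limits(model)
        model.step = 0.25
        fine = find_gape_limits(model)
        assert abs(fine.theta_optimal - coarse.theta_optimal) <= 0.5
        assert abs(fine.theta_maximum - coarse.theta_maximum) <= 0.5

    def test_limit_angles_lie_on_the_step_grid(self):
        model = make_planar_gape_model(40.0, 30.0, 60.0, resting_gape=5.0, step=0.5)
        res = find_gape_limits(model)
        for theta in (res.theta_optimal, res.theta_maximum):
            assert (theta - model.resting_gape) / model.step == pytest.approx(
                round((theta - model.resting_gape) / model.step), abs=1e-9
            )

    def test_open_ended_when_strain_limit_unreachable(self):
        # tiny insertion radius: the cylinder can never stretch 30%
        model = make_planar_gape_model(40.0, 1.0, 60.0, resting_gape=5.0)
        res = find_gape_limits(model)
        assert res.open_ended
        assert res.theta_maximum is None
        assert res.max_scanned >= 179.5

    def test_no_adductors_rejected(self):
        model = make_planar_gape_model(40.0, 30.0, 60.0)
        model.adductors = []
        with pytest.raises(GapeModelError, match="adductor"):
            find_gape_limits(model)

    def test_depressor_shortens_and_factors_exceed_one(self):
        tax = make_taxon(SyntheticTaxonSpec(seed=12))
        res = find_gape_limits(tax.model)
        assert res.theta_maximum is not None
        dep = tax.model.depressor.id
        trace = res.strain_trace[dep]
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))  # mDM shortens
        f_opt, f_rest = res.depressor_factors
        assert f_rest >= f_opt >= 1.0  # longest at rest, shortest at max gape

    def test_constraining_cylinder_reported(self):
        model = make_planar_gape_model(40.0, 30.0, 60.0)
        res = find_gape_limits(model)
        assert res.constraining_optimal == ["mAMES1"]
        assert res.constraining_maximum == ["mAMES1"]


class TestJawClearance:
    def test_coincident_points_closed(self):
        model = make_planar_gape_model(40.0, 30.0, 60.0)
        assert jaw_clearance(model, 0.0, (55, 0, 0), (55, 0, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_chord_length_oracle(self):
        model = make_planar_gape_model(40.0, 30.0, 60.0)
        r = 72.0
        for theta in (5.0, 20.0, 45.0, 90.0):
            got = jaw_clearance(model, theta, (r, 0, 0), (r, 0, 0))
            assert got == pytest.approx(2 * r * math.sin(math.radians(theta / 2)), abs=1e-9)

    def test_monotone_on_first_quadrant(self):
        model = make_planar_gape_model(40.0, 30.0, 60.0)
        vals = [jaw_clearance(model, t, (60, 0, 0), (60, 0, 5)) for t in np.arange(0, 90.5, 5.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestModelValidation:
    def test_coincident_joints_rejected(self):
        with pytest.raises(GapeModelError, match="distinct"):
            JawModel(
                joint_left=(0, 0, 0), joint_right=(0, 0, 0),
                adductors=[MuscleCylinder(MuscleName.mAMES, 1, (0, 0, 10), (10, 0, 0))],
            )

    def test_ambiguous_opening_sense_rejected(self):
        # insertion diametrically opposite the origin: both senses shorten
        with pytest.raises(ValueError, match="non-adductor|ambiguous"):
            make_planar_gape_model(40.0, 30.0, 180.0)

    def test_strain_limits_ordering_enforced(self):
        with pytest.raises(ValueError):
            StrainLimits(optimal=1.8, maximum=1.7)
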