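"""Required torques, inner static optimization, and maximum resistible load."""

import numpy as np
import pytest

from anthroneck import (
    default_load_case,
    evaluate_strengths,
    max_resistible_load,
    moment_arm_matrix,
    required_joint_torques,
    static_muscle_optimization,
)
from anthroneck.model import GRAVITY
from anthroneck.strength import LoadCase, MODES


class TestRequiredTorques:
    def test_zero_load_no_gravity_is_zero(self, male_model):
        tau = required_joint_torques(
            male_model, default_load_case("flexion", 0.0), include_gravity=False
        )
        assert np.allclose(tau, 0.0)

    def test_single_hinge_lever_arithmetic(self, single_hinge):
        # 100 N horizontal force at a landmark 0.15 m above the hinge
        tau = required_joint_torques(
            single_hinge.model, default_load_case("flexion", 100.0),
            include_gravity=False,
        )
        assert abs(tau[1]) == pytest.approx(15.0, abs=1e-12)
        assert np.allclose(tau[[0, 2]], 0.0, atol=1e-12)

    def test_matches_free_body_oracle(self, male_model):
        load = default_load_case("extension", 200.0)
        tau = required_joint_torques(male_model, load, include_gravity=True)
        point = male_model.world_landmark("opisthocranion")
        force = load.direction * load.magnitude
        for ji, joint in enumerate(male_model.joints):
            m = np.cross(point - joint.center, force)
            for seg_name in male_model.distal_segments(joint):
                seg = male_model.segments[seg_name]
                w = np.array([0.0, 0.0, -seg.mass * GRAVITY])
                m = m + np.cross(seg.origin + seg.com - joint.center, w)
            assert np.allclose(tau[3 * ji : 3 * ji + 3], joint.dof_axes @ (-m), atol=1e-12)

    def test_pure_moment_mode_is_uniform_over_joints(self, male_model):
        tau = required_joint_torques(
            male_model, default_load_case("axial_rotation", 5.0),
            include_gravity=False,
        )
        z_components = tau.reshape(8, 3)[:, 2]
        assert np.allclose(z_components, -5.0, atol=1e-12)

    def test_non_skull_landmark_rejected(self, male_model):
        bad = LoadCase(mode="flexion", landmark="C7",
                       direction=np.array([1.0, 0, 0]), magnitude=10.0)
        with pytest.raises(ValueError, match="skull"):
            required_joint_torques(male_model, bad)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            LoadCase(mode="flexion", landmark="forehead",
                     direction=np.array([1.0, 1.0, 0.0]), magnitude=1.0)


class TestInnerOptimization:
    def test_zero_target_gives_zero_forces(self, male_model, male_moment_arms):
        sol = static_muscle_optimization(
            male_model, np.zeros(24), moment_arms=male_moment_arms
        )
        assert np.allclose(sol.forces, 0.0)
        assert sol.js == pytest.approx(0.0, abs=1e-15)

    def test_scalar_closed_form_oracle(self, single_hinge):
        # one muscle, one effective DOF: argmin (f/F)^2 + w (r f - tau)^2
        model = single_hinge.model
        arms = moment_arm_matrix(model)
        f_cap, r, w = 100.0, arms[0, 1], 100.0
        for tau_y in (0.5, 1.5, 2.9, 3.5, 10.0):
            target = np.zeros(3)
            target[1] = tau_y
            sol = static_muscle_optimization(model, target, w_tau=w, moment_arms=arms)
            f_star = np.clip(w * r * tau_y / (1.0 / f_cap**2 + w * r**2), 0.0, f_cap)
            assert sol.forces[0] == pytest.approx(f_star, abs=1e-6)

    def test_twin_muscles_share_equally(self, twin_muscle):
        model = twin_muscle.model
        arms = moment_arm_matrix(model)
        target = np.zeros(3)
        target[1] = 2.0
        sol = static_muscle_optimization(model, target, moment_arms=arms)
        assert sol.forces[0] == pytest.approx(sol.forces[1], abs=1e-9)
        assert sol.forces[0] > 1.0

    def test_kkt_stationarity(self, male_model, male_moment_arms):
        fmax = male_model.f_max_vector()
        tau = required_joint_torques(male_model, default_load_case("flexion", 100.0))
        sol = static_muscle_optimization(male_model, tau, moment_arms=male_moment_arms)
        assert sol.converged
        m = male_moment_arms.T
        grad = 2 * sol.forces / fmax**2 + 2 * 100.0 * (m.T @ sol.residual)
        free = (sol.forces > 1e-9) & (sol.forces < fmax - 1e-9)
        scale = 2 * 100.0 * np.abs(tau).max()
        assert np.max(np.abs(grad[free])) / scale < 1e-8
        # bound muscles must push in the descent direction
        assert np.all(grad[sol.forces <= 1e-9] >= -1e-6 * scale)
        assert np.all(grad[sol.forces >= fmax - 1e-9] <= 1e-6 * scale)

    def test_resolve_is_deterministic(self, male_model, male_moment_arms):
        tau = required_joint_torques(male_model, default_load_case("extension", 254.0))
        a = static_muscle_optimization(male_model, tau, moment_arms=male_moment_arms)
        b = static_muscle_optimization(male_model, tau, moment_arms=male_moment_arms)
        assert np.array_equal(a.forces, b.forces)


class TestMaxResistibleLoad:
    def test_powerless_model_resists_nothing(self, single_hinge):
        # gravity off: a muscle with no force capacity holds no load at all
        v = max_resistible_load(
            single_hinge.model, "flexion", include_gravity=False,
            residual_tolerance=1e-6, f_max=np.array([0.0]),
        )
        assert v == 0.0

    def test_unsupported_gravity_warns_and_reports_zero(self, single_hinge):
        # move the head COM off the hinge so gravity demands torque the
        # powerless muscle cannot produce
        model = single_hinge.model.copy()
        model.segments["skull"].com = np.array([0.05, 0.0, 0.05])
        with pytest.warns(UserWarning, match="zero load"):
            v = max_resistible_load(
                model, "flexion", include_gravity=True, f_max=np.array([0.0])
            )
        assert v == 0.0

    def test_single_hinge_analytic_strength(self, single_hinge):
        v = max_resistible_load(
            single_hinge.model, "flexion", include_gravity=False,
            residual_tolerance=single_hinge.analytic["residual_tolerance"],
        )
        assert v == pytest.approx(single_hinge.analytic["strength"], abs=0.5)

    def test_doubling_forces_doubles_strength(self, single_hinge):
        model = single_hinge.model
        tol = single_hinge.analytic["residual_tolerance"]
        v1 = max_resistible_load(model, "flexion", include_gravity=False,
                                 residual_tolerance=tol)
        v2 = max_resistible_load(model, "flexion", include_gravity=False,
                                 residual_tolerance=tol,
                                 f_max=np.array([200.0]))
        assert v2 == pytest.approx(2 * v1, abs=1.0)

    def test_strength_monotone_in_fmax(self, male_model, male_moment_arms):
        base = male_model.f_max_vector()
        v0 = max_resistible_load(male_model, "flexion", moment_arms=male_moment_arms)
        for bump in (1.2, 1.5, 2.0):
            v = max_resistible_load(
                male_model, "flexion", moment_arms=male_moment_arms, f_max=base * bump
            )
            assert v >= v0 - 1e-9
            v0 = v

    def test_all_modes_positive_for_default_model(self, male_model, male_moment_arms):
        res = evaluate_strengths(male_model, moment_arms=male_moment_arms)
        assert set(res.magnitudes) == set(MODES)
        for v in res.magnitudes.values():
            assert v > 0
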