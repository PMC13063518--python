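"""Forward-dynamics simulator: bite plane, excitation response, IC
reduction, tracking QP, contact quadrature, integration, and task runs."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from tmjmech.constitutive import ElasticFoundationParams, HillMuscleParams, ef_pressure
from tmjmech.core import InvalidInputError
from tmjmech import simulator as sim
from tmjmech import synthetic


# ---------------------------------------------------------------------------
# independent QP oracle: exact active-set enumeration. For each of the 3^n
# lower/free/upper patterns, solve the equality-constrained stationarity
# system and keep the pattern whose solution satisfies primal feasibility
# and the KKT sign conditions; exact for a strictly convex box QP.

def qp_enumerate(h, target, a_prev, w, ub):
    import itertools

    h = np.atleast_2d(np.asarray(h, float))
    n = h.shape[1]
    q = w.w_c * (h.T @ h) + (w.w_a + w.w_d) * np.eye(n)
    lin = -w.w_c * h.T @ np.atleast_1d(target) - w.w_d * a_prev
    for pattern in itertools.product((0, 1, 2), repeat=n):
        a = np.zeros(n)
        free = [i for i, p in enumerate(pattern) if p == 1]
        for i, p in enumerate(pattern):
            if p == 2:
                a[i] = ub[i]
        if free:
            rhs = -lin[free] - q[np.ix_(free, [i for i, p in enumerate(pattern)
                                               if p == 2])] @ ub[[i for i, p in
                                                                  enumerate(pattern) if p == 2]]
            a[free] = np.linalg.solve(q[np.ix_(free, free)], rhs)
            if np.any(a[free] < -1e-12) or np.any(a[free] > ub[free] + 1e-12):
                continue
        grad = q @ a + lin
        ok = True
        for i, p in enumerate(pattern):
            if p == 0 and grad[i] < -1e-9:
                ok = False
            if p == 2 and grad[i] > 1e-9:
                ok = False
        if ok:
            return np.clip(a, 0.0, ub)
    raise AssertionError("no KKT-consistent active set found")


def qp_objective(h, target, a_prev, w, a):
    h = np.atleast_2d(np.asarray(h, float))
    r = np.atleast_1d(target) - h @ a
    return (0.5 * w.w_c * r @ r + 0.5 * w.w_a * a @ a
            + 0.5 * w.w_d * (a - a_prev) @ (a - a_prev))


class TestBitePlane:
    def test_horizontal_plane_superior_normal(self):
        plane = sim.build_bite_plane([-1, 0, 0], [1, 0, 0], [0, 2, 0])
        assert np.allclose(plane.normal, [0, 0, 1])

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(3, 3))
        shift = np.array([3.0, -1.0, 7.0])
        p1 = sim.build_bite_plane(*pts)
        p2 = sim.build_bite_plane(*(pts + shift))
        assert np.allclose(p1.normal, p2.normal, atol=1e-12)

    def test_landmarks_on_plane(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(3, 3)) * 20
            plane = sim.build_bite_plane(*pts)
            resid = (plane.landmarks - plane.point) @ plane.normal
            assert np.abs(resid).max() < 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(InvalidInputError):
            sim.build_bite_plane([0, 0, 0], [1, 0, 0], [2, 0, 0])


class TestExcitationResponse:
    def test_vertical_muscle_through_bite_point_transmits_fully(self, toy_model):
        # a muscle pulling straight up at the task premolar produces exactly
        # its maximal force as bite output
        prem = toy_model.bite_points["left_premolar"]
        muscles = []
        for m in toy_model.muscles:
            if m.name == "left_masseter_superficial":
                origin = prem + np.array([0.0, 0.0, 60.0])
                m = replace(m, origin=origin, insertion=prem.copy(),
                            params=HillMuscleParams(m.params.max_isometric_force, 60.0))
            muscles.append(m)
        model = replace(toy_model, muscles=tuple(muscles), gravity=False)
        h = sim.excitation_response(model, sim.RigidBodyState.rest(model))
        j = [m.name for m in model.active_muscles].index("left_masseter_superficial")
        assert h[0, j] == pytest.approx(190.0, rel=1e-9)

    def test_linear_in_muscle_strength(self, toy_model):
        state = sim.RigidBodyState.rest(toy_model)
        h1 = sim.excitation_response(toy_model, state)
        stronger = synthetic.gen_toy_mandible(
            muscle_strengths={"masseter_superficial": 380.0})
        h2 = sim.excitation_response(stronger, sim.RigidBodyState.rest(stronger))
        names = [m.name for m in toy_model.active_muscles]
        j = names.index("left_masseter_superficial")
        assert h2[0, j] == pytest.approx(2 * h1[0, j], rel=1e-9)
        k = names.index("left_temporalis_anterior")
        assert h2[0, k] == pytest.approx(h1[0, k], rel=1e-9)


class TestICReduction:
    def test_unit_ratio_sums_columns(self):
        col, ub = sim.combine_pair_columns(np.array([3.0]), np.array([5.0]), 1.0)
        assert col[0] == 8.0 and ub == 1.0

    def test_ratio_two_example(self):
        col, ub = sim.combine_pair_columns(np.array([3.0]), np.array([5.0]), 2.0)
        assert col[0] == 11.0 and ub == 0.5

    def test_expansion_stays_in_bounds(self, toy_model, rng):
        h = rng.normal(size=(1, 12))
        for r_t, r_m in [(1.52, 1.43), (3.0, 0.2), (1.0, 1.0)]:
            h_red, template = sim.impose_ic_ratios(
                h, toy_model, {"temporalis": r_t, "masseter": r_m})
            u = rng.uniform(0, 1, size=template.upper_bounds.size) * template.upper_bounds
            a = replace(template, values=u).expanded
            assert np.all(a >= 0) and np.all(a <= 1)

    def test_reduced_matrix_consistent_with_expansion(self, toy_model, rng):
        h = rng.normal(size=(1, 12))
        h_red, template = sim.impose_ic_ratios(
            h, toy_model, {"temporalis": 1.7, "masseter": 0.8})
        u = rng.uniform(0, 0.3, size=template.upper_bounds.size)
        assert float((h_red @ u).item()) == pytest.approx(
            float((h @ (template.expansion @ u)).item()))

    def test_nonpositive_ratio_rejected(self, toy_model):
        with pytest.raises(InvalidInputError):
            sim.impose_ic_ratios(np.ones((1, 12)), toy_model, {"temporalis": 0.0})


class TestTrackingQP:
    W = sim.TrackingWeights()

    def test_scalar_closed_form(self):
        w = sim.TrackingWeights(w_c=1.0, w_a=0.0, w_d=0.0)
        for h, c in [(10.0, 5.0), (10.0, 25.0), (4.0, -3.0)]:
            a = sim.solve_tracking_step(np.array([[h]]), c, np.zeros(1), w,
                                        np.ones(1))
            assert a[0] == pytest.approx(np.clip(c / h, 0.0, 1.0), abs=1e-12)

    def test_zero_target_zero_solution(self):
        a = sim.solve_tracking_step(np.ones((1, 4)), 0.0, np.zeros(4), self.W,
                                    np.ones(4))
        assert np.allclose(a, 0.0, atol=1e-12)

    def test_matches_coordinate_descent_oracle(self, rng):
        for _ in range(20):
            h = rng.uniform(-20, 150, size=(1, 4))
            c = rng.uniform(0, 120)
            a_prev = rng.uniform(0, 1, 4)
            ub = np.ones(4)
            a = sim.solve_tracking_step(h, c, a_prev, self.W, ub)
            b = qp_enumerate(h, c, a_prev, self.W, ub)
            assert np.abs(a - b).max() < 1e-3
            assert abs(qp_objective(h, c, a_prev, self.W, a)
                       - qp_objective(h, c, a_prev, self.W, b)) < 1e-9

    def test_kkt_residual_small(self, rng):
        h = rng.uniform(0, 100, size=(1, 6))
        a_prev = rng.uniform(0, 1, 6)
        a = sim.solve_tracking_step(h, 40.0, a_prev, self.W, np.ones(6))
        assert sim.tracking_kkt_residual(h, 40.0, a_prev, self.W,
                                         np.ones(6), a) < 1e-8

    def test_invariant_to_column_ordering(self, rng):
        h = rng.uniform(0, 100, size=(1, 5))
        perm = rng.permutation(5)
        a = sim.solve_tracking_step(h, 30.0, np.zeros(5), self.W, np.ones(5))
        b = sim.solve_tracking_step(h[:, perm], 30.0, np.zeros(5), self.W,
                                    np.ones(5))
        assert np.abs(a[perm] - b).max() < 1e-8


class TestJointContact:
    def test_no_contact_zero(self, toy_model):
        state = sim.RigidBodyState.rest(toy_model)
        # at rest the condyles just touch: zero force
        forces = sim.joint_contact_force(toy_model, state)
        assert np.allclose(forces["left"], 0.0) and np.allclose(forces["right"], 0.0)

    def test_quadrature_against_scipy_integral(self):
        site = sim.JointSite(side="left", sphere_center=np.zeros(3), sphere_radius=8.0,
                             socket_center=np.zeros(3), socket_radius=8.5,
                             ef=ElasticFoundationParams())
        for e in [0.55, 0.62, 0.7]:
            got = sim._ef_socket_force(e, site)
            r, rs = 8.0, 8.5

            def integrand(u):
                rho = np.sqrt(e * e + r * r + 2 * e * r * u)
                return ef_pressure(max(rho - rs, 0.0), site.ef) * (e + r * u) / rho

            cos_max = (rs * rs - e * e - r * r) / (2 * e * r)
            expect = 2 * np.pi * r * r * quad(integrand, cos_max, 1.0, limit=200)[0]
            assert got == pytest.approx(expect, rel=2e-4)

    def test_linear_in_modulus(self):
        base = ElasticFoundationParams()
        stiff = ElasticFoundationParams(elastic_modulus=2 * base.elastic_modulus)
        s1 = sim.JointSite("left", np.zeros(3), 8.0, np.zeros(3), 8.5, base)
        s2 = sim.JointSite("left", np.zeros(3), 8.0, np.zeros(3), 8.5, stiff)
        assert sim._ef_socket_force(0.6, s2) == pytest.approx(
            2 * sim._ef_socket_force(0.6, s1), rel=1e-12)


class TestStep:
    def test_rest_state_with_no_forces_stays(self, toy_model):
        model = replace(toy_model, gravity=False)
        state = sim.RigidBodyState.rest(model)
        out = sim.step(model, state, np.zeros(12), 1e-3)
        assert np.allclose(out.x, state.x, atol=1e-15)
        assert np.allclose(out.v, 0.0, atol=1e-12)

    def test_constraint_residual_under_load(self, toy_model, force_curve_50):
        model = replace(toy_model, gravity=False)
        asm = sim._Assembled(model)
        state = sim.RigidBodyState.rest(model)
        a = np.full(12, 0.1)
        worst = 0.0
        for _ in range(100):
            state = sim.step(model, state, a, 1e-3, asm)
            _, e = asm.constraint_matrix(state)
            worst = max(worst, np.abs(e).max())
        assert worst < 1e-8 * 1e-3  # 1e-8 mm, in meters

    def test_energy_conservation_ballistic_tumble(self, toy_model):
        """Gravity-only tumble through sim.step: energy drift < 1% over 0.25 s.

        Ballistic variant: damping off, ligaments slack, no passive muscle
        curve, joint sockets widened so no contact engages.
        """
        from tmjmech.constitutive import LigamentParams

        no_passive = HillMuscleParams(
            max_isometric_force=1.0, optimal_length=50.0,
            passive_curve=lambda l_norm: np.zeros_like(np.asarray(l_norm)))
        muscles = tuple(replace(m, params=no_passive) for m in toy_model.muscles)
        ligaments = tuple(
            replace(l, params=LigamentParams(0.0, l.params.initial_length, 0.0))
            for l in toy_model.ligaments)
        sites = tuple(replace(s, socket_radius=s.sphere_radius + 5000.0)
                      for s in toy_model.joint_sites)
        model = replace(toy_model, damping=(0.0, 0.0), muscles=muscles,
                        ligaments=ligaments, joint_sites=sites)
        state = sim.RigidBodyState(
            x=np.array([0.0, 0.04, 0.25]), rot=np.eye(3),
            v=np.array([0.1, 0.2, 0.3]), w=np.array([2.0, -1.0, 1.5]))
        asm = sim._Assembled(model)
        i_body = np.diag(model.inertia_diag)

        def energy(s):
            i_w = s.rot @ i_body @ s.rot.T
            return (0.5 * model.mass * s.v @ s.v + 0.5 * s.w @ i_w @ s.w
                    + model.mass * 9.81 * s.x[2])

        e0 = energy(state)
        for _ in range(250):
            state = sim.step(model, state, np.zeros(12), 1e-3, asm,
                             constrained=False)
        assert abs(energy(state) - e0) / abs(e0) < 0.01


class TestSimulateTask:
    def test_tracks_target_on_symmetric_task(self, coupled_symmetric_result):
        res = coupled_symmetric_result
        assert res.terminal_bite_force == pytest.approx(50.0, abs=1.0)
        assert not res.saturated

    def test_ic_ratio_exact_at_every_step(self, toy_model, force_curve_50):
        res = sim.simulate_task(toy_model, force_curve_50,
                                {"temporalis": 2.0, "masseter": 2.0})
        names = list(res.muscle_names)
        for stem in ("temporalis_anterior", "temporalis_middle",
                     "temporalis_posterior", "masseter_superficial",
                     "masseter_deep"):
            ipsi = res.activations[:, names.index(f"left_{stem}")]
            contra = res.activations[:, names.index(f"right_{stem}")]
            assert np.abs(ipsi - 2.0 * contra).max() < 1e-12

    def test_zero_target_keeps_activations_at_noise_floor(self, toy_model):
        model = replace(toy_model, gravity=False)
        curve = synthetic.ramp_hold_curve(0.0)
        res = sim.simulate_task(model, curve, {"temporalis": 1.0, "masseter": 1.0})
        assert np.abs(res.activations).max() <= 1e-6

    def test_terminal_static_equilibrium(self, class1_left_result):
        force_res, torque_res = class1_left_result.equilibrium_residual
        assert force_res < 1e-3      # N
        assert torque_res < 1e-3     # N mm

    def test_deterministic(self, toy_model, force_curve_50):
        r1 = sim.simulate_task(toy_model, force_curve_50,
                               {"temporalis": 1.3, "masseter": 1.1})
        r2 = sim.simulate_task(toy_model, force_curve_50,
                               {"temporalis": 1.3, "masseter": 1.1})
        assert np.array_equal(r1.activations, r2.activations)
        assert np.array_equal(r1.bite_force, r2.bite_force)
        assert np.array_equal(r1.joint_force_left, r2.joint_force_left)

    def test_saturation_flagged_not_raised(self, toy_model):
        weak = synthetic.gen_toy_mandible(muscle_strengths={
            k: 4.0 for k in synthetic.DEFAULT_MUSCLE_STRENGTHS})
        curve = synthetic.ramp_hold_curve(80.0)
        res = sim.simulate_task(weak, curve, {"temporalis": 1.0, "masseter": 1.0})
        assert res.saturated


class TestStaticOracle:
    def test_terminal_state_matches_independent_statics(self):
        """The simulated clench must land on the closed-form static solution.

        Sagittally symmetric single-equivalent-muscle model (six identical
        co-located strands per side). The oracle solves the anterior
        force balance against the elastic-foundation socket by bracketed
        root finding (scipy.integrate for the cap integral) and the
        out-of-plane reactions by the overdetermined 6-equation balance,
        independently of the simulator's projection and KKT machinery.
        """
        base = synthetic.gen_toy_mandible(gravity=False)
        muscles = []
        for m in base.muscles:
            sx = -1.0 if m.side == "left" else 1.0
            origin = np.array([sx * 25.0, 34.0, 42.0])
            insertion = np.array([sx * 25.0, 20.0, -6.0])
            muscles.append(replace(
                m, origin=origin, insertion=insertion,
                params=HillMuscleParams(100.0, float(np.linalg.norm(origin - insertion)))))
        model = replace(base, muscles=tuple(muscles))
        curve = synthetic.ramp_hold_curve(40.0)
        res = sim.simulate_task(model, curve, {"temporalis": 1.0, "masseter": 1.0,
                                               "medial_pterygoid": 1.0})
        a = res.activations[-1]

        # muscle forces evaluated at the reported terminal configuration
        from tmjmech.constitutive import hill_static_force
        term = res.terminal_state
        f_total = np.zeros(3)
        ins_pts, f_each = [], []
        for j, m in enumerate(model.active_muscles):
            ins = term.body_to_world_mm(m.insertion, model)
            d = m.origin - ins
            length = np.linalg.norm(d)
            f = hill_static_force(a[j], length, m.params) * d / length
            f_total += f
            ins_pts.append(ins)
            f_each.append(f)

        # oracle joint force: anterior balance 2 J e_y/|e| = F_y at the seat
        site = model.joint_sites[0]
        clearance = site.socket_radius - site.sphere_radius
        e0 = site.sphere_center - site.socket_center

        def socket_force(e_norm):
            r, rs = site.sphere_radius, site.socket_radius
            if e_norm <= clearance:
                return 0.0
            cos_max = (rs * rs - e_norm * e_norm - r * r) / (2 * e_norm * r)

            def integrand(u):
                rho = np.sqrt(e_norm ** 2 + r * r + 2 * e_norm * r * u)
                return ef_pressure(max(rho - rs, 0.0), site.ef) * \
                    (e_norm + r * u) / rho

            return 2 * np.pi * site.sphere_radius ** 2 * \
                quad(integrand, cos_max, 1.0, limit=200)[0]

        def residual(dy):
            e = e0 + np.array([0.0, dy, 0.0])
            e_norm = np.linalg.norm(e)
            return 2 * socket_force(e_norm) * e[1] / e_norm - f_total[1]

        dy = brentq(residual, 0.0, 0.4, xtol=1e-12)
        e = e0 + np.array([0.0, dy, 0.0])
        j_oracle = socket_force(np.linalg.norm(e))
        j_sim = np.linalg.norm(res.terminal_joint_force("left"))
        assert j_sim == pytest.approx(j_oracle, rel=0.02)

        # oracle bite force: full 6-equation static balance at the terminal
        # configuration for the three normal reactions (consistent at
        # equilibrium, so plain least squares recovers them)
        plane = sim.build_bite_plane(model.bite_points["left_premolar"],
                                     model.bite_points["right_premolar"],
                                     model.bite_points["incisor"])
        n = plane.normal
        com = term.x / 1e-3  # terminal COM, mm
        w6 = np.zeros(6)
        w6[:3] = f_total
        for p, f in zip(ins_pts, f_each):
            w6[3:] += np.cross(p - com, f)
        for site_k in model.joint_sites:
            center = term.body_to_world_mm(site_k.sphere_center, model)
            e_k = center - site_k.socket_center
            f_k = -socket_force(np.linalg.norm(e_k)) * e_k / np.linalg.norm(e_k)
            w6[:3] += f_k
            w6[3:] += np.cross(center - com, f_k)
        g = np.zeros((3, 6))
        for i, p_body in enumerate([model.bite_points["left_premolar"],
                                    model.bite_points["right_premolar"],
                                    model.bite_points["incisor"]]):
            p = term.body_to_world_mm(p_body, model)
            g[i, :3] = n
            g[i, 3:] = np.cross(p - com, n)
        lam, *_ = np.linalg.lstsq(g.T, -w6, rcond=None)
        assert -lam[0] == pytest.approx(res.terminal_bite_force, rel=0.02)


class TestSummarize:
    def test_percentage_arithmetic(self, class1_left_result):
        out = sim.summarize_joint_loading(class1_left_result)
        jl = np.linalg.norm(class1_left_result.terminal_joint_force("left"))
        expect = round(100 * jl / class1_left_result.terminal_bite_force, 1)
        assert out["left"] == pytest.approx(expect, abs=0.05)

    def test_symmetric_model_balanced_loading(self, coupled_symmetric_result):
        out = sim.summarize_joint_loading(coupled_symmetric_result)
        assert abs(out["left"] - out["right"]) < 0.5

    def test_contralateral_exceeds_ipsilateral(self, class1_left_result):
        out = sim.summarize_joint_loading(class1_left_result)
        ipsi, contra = out["left"], out["right"]
        assert contra > ipsi

    def test_zero_bite_rejected(self, class1_left_result):
        broken = replace(class1_left_result,
                         bite_force=np.zeros_like(class1_left_result.bite_force))
        with pytest.raises(InvalidInputError):
            sim.summarize_joint_loading(broken)
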