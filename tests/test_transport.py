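"""Particle equation of motion, wall rules, and deposition accounting."""
import numpy as np
import pytest

import aerodep as ad
from aerodep import constants as C
from aerodep.transport import DepositionResult

from conftest import pich_sedimentation_de


class TestDrag:
    def test_stokes_limit_is_inverse_relaxation_time(self):
        """F_D -> 18 mu / (rho_p d_p^2) = 1/tau as Re_p -> 0."""
        spec = ad.ParticleSpec.from_microns(10.0)
        expected = 18.0 * C.AIR_VISCOSITY / (1000.0 * (1e-5) ** 2)
        assert float(ad.drag_factor(0.0, spec)) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(3.285e3, rel=1e-3)

    def test_schiller_naumann_at_re_one(self):
        """C_D Re_p / 24 = 1 + 0.15 = 1.15 at Re_p = 1."""
        spec = ad.ParticleSpec.from_microns(10.0)
        u_rel = C.AIR_VISCOSITY / (C.AIR_DENSITY * spec.d_p)  # Re_p = 1
        ratio = float(ad.drag_factor(u_rel, spec)
                      / ad.drag_factor(0.0, spec))
        assert ratio == pytest.approx(1.15, rel=1e-12)

    def test_drag_monotone_in_relative_speed(self):
        spec = ad.ParticleSpec.from_microns(5.0)
        speeds = np.linspace(0, 5, 20)
        fd = ad.drag_factor(speeds, spec)
        assert np.all(np.diff(fd) > 0)


class TestStepParticle:
    def test_velocity_relaxation_in_still_air(self):
        """With u = 0 and gravity off, speed decays as exp(-t/tau)."""
        spec = ad.ParticleSpec.from_microns(10.0, g=np.zeros(3),
                                            drag_law="stokes")
        tau = spec.relaxation_time()
        v = np.array([[1.0, 0.0, 0.0]])
        x = np.zeros((1, 3))
        x, v = ad.step_particle(x, v, None, spec, 2.0 * tau,
                                u=np.zeros((1, 3)), fluid_rho=0.0)
        assert v[0, 0] == pytest.approx(np.exp(-2.0), rel=1e-12)

    def test_equilibrium_with_flow(self):
        """A particle moving with the fluid and no gravity stays put."""
        spec = ad.ParticleSpec.from_microns(5.0, g=np.zeros(3))
        u = np.array([[0.3, -0.1, 0.2]])
        x, v = ad.step_particle(np.zeros((1, 3)), u.copy(), None, spec,
                                1e-3, u=u)
        assert np.allclose(v, u, rtol=1e-14, atol=0)

    @pytest.mark.parametrize("d_um", [1.0, 5.0, 10.0, 30.0])
    def test_terminal_settling_velocity(self, d_um):
        """Stokes-drag settling reaches rho_p d_p^2 g / (18 mu) exactly."""
        spec = ad.ParticleSpec.from_microns(d_um, drag_law="stokes")
        tau = spec.relaxation_time()
        x = np.zeros((1, 3))
        v = np.zeros((1, 3))
        for _ in range(40):  # 40 tau: fully relaxed
            x, v = ad.step_particle(x, v, None, spec, tau,
                                    u=np.zeros((1, 3)), fluid_rho=0.0)
        v_s = ad.stokes_settling_velocity(d_um * 1e-6)
        assert -v[0, 2] == pytest.approx(v_s, rel=1e-6)


class TestRunSimulation:
    def test_count_conservation_and_determinism(self, default_mesh, field_18):
        inj = ad.InjectionSpec(n_particles=500, seed=11)
        p = ad.ParticleSpec.from_microns(10.0)
        r1 = ad.run_simulation(default_mesh, field_18, p, inj)
        r2 = ad.run_simulation(default_mesh, field_18, p, inj)
        assert r1.n_region == r2.n_region
        assert r1.n_escaped == r2.n_escaped
        assert sum(r1.n_region.values()) + r1.n_escaped + r1.n_lost \
            == r1.n_injected

    def test_tracer_particles_escape(self, default_mesh, field_18):
        """Inertia-free tracers follow streamlines: DE stays below 5%."""
        res = ad.run_simulation(
            default_mesh, field_18, ad.ParticleSpec.from_microns(0.01),
            ad.InjectionSpec(n_particles=2000, seed=2))
        assert res.de_total <= 5.0
        assert res.n_lost == 0

    def test_de_bounds_and_additivity(self, default_mesh, field_45):
        res = ad.run_simulation(
            default_mesh, field_45, ad.ParticleSpec.from_microns(15.0),
            ad.InjectionSpec(n_particles=1000, seed=3))
        des = res.de_region
        assert all(0.0 <= v <= 100.0 for v in des.values())
        assert res.de_total == pytest.approx(sum(des.values()), abs=1e-12)

    def test_impaction_increases_with_flow(self, default_mesh, field_18,
                                           field_45):
        """10 um particles impact more at 45 than at 18 L/min (same seed)."""
        p = ad.ParticleSpec.from_microns(10.0)
        inj = ad.InjectionSpec(n_particles=2000, seed=5)
        de18 = ad.run_simulation(default_mesh, field_18, p, inj).de_total
        de45 = ad.run_simulation(default_mesh, field_45, p, inj).de_total
        assert de45 > de18

    def test_tube_reflects_not_traps(self, default_mesh, field_18):
        """No particle is ever recorded as deposited in the TUBE region."""
        res = ad.run_simulation(
            default_mesh, field_18, ad.ParticleSpec.from_microns(20.0),
            ad.InjectionSpec(n_particles=1000, seed=6))
        assert res.n_region.get("TUBE", 0) == 0

    def test_expiratory_run_and_injection_consistency(self, default_mesh,
                                                      field_18):
        rev = field_18.reverse()
        p = ad.ParticleSpec.from_microns(10.0)
        with pytest.raises(ValueError):
            ad.run_simulation(default_mesh, rev, p,
                              ad.InjectionSpec(n_particles=10, end="inlet"))
        res = ad.run_simulation(
            default_mesh, rev, p,
            ad.InjectionSpec(n_particles=500, end="outlet", seed=8))
        assert res.direction == "expiratory"
        assert res.n_injected == 500
        assert res.n_lost == 0

    def test_injection_positions_inside_opening(self, default_mesh, field_18):
        from aerodep.transport import _sample_opening
        rng = np.random.default_rng(0)
        x, s = _sample_opening(field_18, ad.InjectionSpec(n_particles=300),
                               rng)
        rho = field_18.centerline.normalized_radius(x, s)
        assert np.all(rho < 1.0)

    def test_sedimentation_matches_closed_form(self):
        """Horizontal Poiseuille tube: DE agrees with the analytic
        gravitational-deposition curve within 2 binomial SE (n = 10,000)."""
        R, L, d_um, n = 0.005, 0.25, 10.0, 10_000
        v_s = ad.stokes_settling_velocity(d_um * 1e-6)
        kappa = 0.05
        ubar = 3.0 * v_s * L / (8.0 * R * kappa)
        tube = ad.straight_tube_mesh(R, L)
        f = ad.continuity_flow(
            tube, ad.FlowSpec(flow_lpm=ubar * np.pi * R * R * 60000.0,
                              profile="parabolic"))
        res = ad.run_simulation(
            tube, f, ad.ParticleSpec.from_microns(d_um),
            ad.InjectionSpec(n_particles=n, profile="flux_weighted", seed=1))
        expected = pich_sedimentation_de(kappa)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(res.de_total / 100.0 - expected) <= 2.0 * se


class TestConvergence:
    def test_identical_ensembles_agree_exactly(self, default_mesh, field_18):
        delta = ad.convergence_check(default_mesh, field_18,
                                     ad.ParticleSpec.from_microns(10.0),
                                     n_small=400, n_large=400, seed=4)
        assert delta == 0.0

    def test_ensemble_size_convergence(self, default_mesh, field_45):
        """|DE(n1) - DE(n2)| bounded by 3 binomial SE."""
        p = ad.ParticleSpec.from_microns(10.0)
        n1, n2 = 2000, 8000
        delta = ad.convergence_check(default_mesh, field_45, p,
                                     n_small=n1, n_large=n2, seed=4)
        de = ad.run_simulation(
            default_mesh, field_45, p,
            ad.InjectionSpec(n_particles=n2, seed=4)).de_total / 100.0
        se = 100.0 * np.sqrt(de * (1 - de) * (1.0 / n1 + 1.0 / n2))
        assert delta <= 3.0 * se


def test_result_conservation_enforced():
    with pytest.raises(ValueError):
        DepositionResult(n_injected=100, n_region={"MOUTH": 10},
                         n_escaped=80, n_lost=5, d_um=1.0, flow_lpm=18.0,
                         direction="inspiratory")
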