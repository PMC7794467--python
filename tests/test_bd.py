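"""Brownian-dynamics engine: charges, screened-Coulomb energetics,
Ermak–McCammon propagation and encounter recording."""

import math

import numpy as np
import pytest

from cypet import bd
from cypet import synthetic as syn
from cypet.structure import RigidTransform
from cypet.synthetic import build_structure

PARAMS = bd.BDParameters(seed=7)


def point_body(charge, name="Q"):
    s = build_structure([(name, "C", "UNK", 1, "A", (0.0, 0.0, 0.0))])
    return bd.RigidBodyModel.from_structure(s, charges=[charge])


class TestAssignCharges:
    @staticmethod
    def tripeptide():
        rows = [
            ("N", "N", "ASP", 1, "A", (0, 0, 0)), ("CA", "C", "ASP", 1, "A", (1.5, 0, 0)),
            ("C", "C", "ASP", 1, "A", (2, 1, 0)), ("O", "O", "ASP", 1, "A", (1.6, 2, 0)),
            ("OD1", "O", "ASP", 1, "A", (1, -1, 0)), ("OD2", "O", "ASP", 1, "A", (2, -1, 0)),
            ("N", "N", "GLY", 2, "A", (3, 1, 0)), ("CA", "C", "GLY", 2, "A", (4, 1, 0)),
            ("C", "C", "GLY", 2, "A", (5, 2, 0)), ("O", "O", "GLY", 2, "A", (5, 3, 0)),
            ("N", "N", "LYS", 3, "A", (6, 2, 0)), ("CA", "C", "LYS", 3, "A", (7, 2, 0)),
            ("NZ", "N", "LYS", 3, "A", (8, 3, 0)), ("C", "C", "LYS", 3, "A", (8, 1, 0)),
            ("O", "O", "LYS", 3, "A", (8, 0, 0)), ("OXT", "O", "LYS", 3, "A", (9, 1, 0)),
        ]
        return build_structure(rows)

    def test_asp_gly_lys_free_termini_net_zero(self):
        q = bd.assign_charges(self.tripeptide())
        assert q.sum() == pytest.approx(0.0)  # +1 (Nterm) -1 (Asp) +1 (Lys) -1 (Cterm)

    def test_all_gly_capped_all_zero(self):
        rows = []
        for i in range(1, 6):
            rows += [("N", "N", "GLY", i, "A", (i, 0, 0)),
                     ("CA", "C", "GLY", i, "A", (i, 1, 0)),
                     ("C", "C", "GLY", i, "A", (i, 2, 0)),
                     ("O", "O", "GLY", i, "A", (i, 3, 0))]
        q = bd.assign_charges(build_structure(rows), cap_termini=True)
        assert np.all(q == 0.0)

    def test_unknown_residue_warns_zero(self):
        s = build_structure([("XX", "C", "XYZ", 1, "A", (0, 0, 0))])
        with pytest.warns(UserWarning, match="XYZ"):
            q = bd.assign_charges(s)
        assert np.all(q == 0.0)

    def test_net_charge_matches_per_residue_recount(self):
        """Net charge equals an independent residue-level recount."""
        s = self.tripeptide()
        q = bd.assign_charges(s)
        expected = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1}
        per_res = sum(expected.get(r, 0) for r in
                      dict.fromkeys(zip(s.chain, s.res_id, s.res_name)).keys()
                      for r in [r[2]])
        net = per_res + 1 - 1  # free N- and C-termini
        assert q.sum() == pytest.approx(net)

    def test_cofactor_charges(self):
        rows = [("O1A", "O", "HEM", 900, "A", (0, 0, 0)),
                ("O2A", "O", "HEM", 900, "A", (1, 0, 0)),
                ("O1D", "O", "HEM", 900, "A", (2, 0, 0)),
                ("O2D", "O", "HEM", 900, "A", (3, 0, 0)),
                ("P", "P", "FMN", 901, "B", (5, 0, 0))]
        q = bd.assign_charges(build_structure(rows))
        assert q.sum() == pytest.approx(-3.0)  # two propionates + one phosphate


class TestInteractionEnergy:
    def test_unit_charges_at_debye_length_closed_form(self):
        """Opposite unit charges one Debye length apart at 0.15 M, ε = 78."""
        lam = bd.debye_length(0.15, 298.0, 78.0)
        u = bd.interaction_energy(point_body(1.0), point_body(-1.0),
                                  RigidTransform(translation=(lam, 0, 0)), PARAMS)
        closed = -332.0637130741707 * math.exp(-1.0) / (78.0 * lam)
        assert u == pytest.approx(closed, rel=1e-6)

    def test_beyond_cutoff_zero(self):
        u = bd.interaction_energy(point_body(1.0), point_body(-1.0),
                                  RigidTransform(translation=(150.0, 0, 0)), PARAMS)
        assert u == 0.0

    def test_exchange_symmetry(self, rng, toy_pair):
        pose = RigidTransform.random(rng, translation=(0, 8, 30))
        u_ab = bd.interaction_energy(toy_pair.body_a, toy_pair.body_b, pose, PARAMS)
        u_ba = bd.interaction_energy(toy_pair.body_b, toy_pair.body_a,
                                     pose.inverse(), PARAMS)
        assert u_ab == pytest.approx(u_ba, rel=1e-9)
        assert u_ab != 0.0

    def test_coincident_charges_error(self):
        with pytest.raises(ValueError):
            bd.interaction_energy(point_body(1.0), point_body(1.0),
                                  RigidTransform(), PARAMS)

    def test_energy_invariant_under_joint_transform(self, rng, toy_pair):
        """Moving both bodies rigidly together leaves the energy unchanged:
        the pair energy depends only on the relative pose."""
        rel = RigidTransform.random(rng, translation=(0, 5, 29))
        u1 = bd.interaction_energy(toy_pair.body_a, toy_pair.body_b, rel, PARAMS)
        world = RigidTransform.random(rng, translation=rng.normal(size=3) * 50)
        u2 = bd.interaction_energy(toy_pair.body_a, toy_pair.body_b,
                                   world.inverse().compose(world.compose(rel)), PARAMS)
        assert u1 == pytest.approx(u2, rel=1e-9)


class TestPropagation:
    def test_zero_force_no_noise_pose_unchanged(self, toy_pair):
        p0 = RigidTransform(translation=(100, 0, 0))
        p1 = bd.bd_step(p0, np.zeros(3), np.zeros(3), toy_pair.body_b, PARAMS,
                        dt=1.0, rng=np.random.default_rng(0), noise=False)
        np.testing.assert_allclose(p1.translation, p0.translation)
        np.testing.assert_allclose(p1.quat, p0.quat)

    def test_deterministic_drift_velocity(self, toy_pair):
        """With noise off, drift per step is exactly (D_t/kT)·F·Δt."""
        body = toy_pair.body_b
        force = np.array([3.0, -1.0, 0.5])
        dt = 2.0
        p1 = bd.bd_step(RigidTransform(translation=(200, 0, 0)), force, np.zeros(3),
                        body, PARAMS, dt, np.random.default_rng(0), noise=False)
        np.testing.assert_allclose(p1.translation - [200, 0, 0],
                                   body.d_t / PARAMS.kt * force * dt, rtol=1e-12)

    def test_free_diffusion_msd(self, toy_pair):
        """Per-step MSD over seeded free diffusion matches 6·D_t·Δt within 5%."""
        body = toy_pair.body_b
        rng = np.random.default_rng(42)
        pose = RigidTransform(translation=(0.0, 0.0, 0.0))
        acc, n, dt = 0.0, 4000, 1.0
        for _ in range(n):
            new = bd.bd_step(pose, np.zeros(3), np.zeros(3), body, PARAMS, dt, rng)
            acc += np.sum((new.translation - pose.translation) ** 2)
            pose = new
        assert acc / n / (6 * body.d_t * dt) == pytest.approx(1.0, abs=0.05)

    def test_harmonic_well_boltzmann_variance(self, toy_pair):
        """A bead in a harmonic test potential samples variance kT/k within 5%."""
        body = toy_pair.body_b
        k = 1.0  # kcal/mol/Å²
        rng = np.random.default_rng(2024)
        x = np.zeros(3)
        samples = []
        pose = RigidTransform()
        for i in range(60_000):
            pose = bd.bd_step(RigidTransform(pose.quat, x), -k * x, np.zeros(3),
                              body, PARAMS, dt=1.0, rng=rng)
            x = pose.translation
            if i > 2000:
                samples.append(x.copy())
        var = np.var(np.asarray(samples), axis=0).mean()
        assert var == pytest.approx(PARAMS.kt / k, rel=0.05)

    def test_non_finite_force_rejected(self, toy_pair):
        with pytest.raises(ValueError):
            bd.bd_step(RigidTransform(), np.array([np.nan, 0, 0]), np.zeros(3),
                       toy_pair.body_b, PARAMS, 1.0, np.random.default_rng(0))

    def test_trajectory_loop_matches_bd_step(self, toy_pair):
        """The inlined trajectory propagation reproduces bd_step step-for-step
        for a shared generator (no forces, no overlaps)."""
        body_b = syn.make_toy_redox_pair(seed=0).body_b
        body_b.charges[:] = 0.0
        body_b.charged = np.flatnonzero(body_b.charges)
        params = syn.toy_bd_params(seed=0, n_trajectories=1, max_steps=40)
        rng1 = np.random.default_rng(99)
        rng2 = np.random.default_rng(99)
        bd.run_trajectory(toy_pair.body_a, body_b, params, rng1)
        # replay: same start-pose draws, then bd_step with the same stream
        u = rng2.standard_normal(3)
        u /= np.linalg.norm(u)
        from scipy.spatial.transform import Rotation
        pose = RigidTransform(Rotation.random(rng=rng2).as_quat(),
                              params.b_radius * u)
        for _ in range(params.max_steps):
            if np.linalg.norm(pose.translation) >= params.q_radius:
                break
            dt = params.dt_far if np.linalg.norm(pose.translation) > params.dt_switch \
                else params.dt_near
            pose = bd.bd_step(pose, np.zeros(3), np.zeros(3), body_b, params, dt, rng2)
        # both generators consumed identical draws -> identical stream position
        assert rng1.standard_normal() == rng2.standard_normal()


class TestToyPairEnergetics:
    def test_patch_to_patch_beats_averted(self, toy_pair):
        """Facing patches attract more strongly than averted patches."""
        contact = toy_pair.metadata["radius_a"] + toy_pair.metadata["radius_b"] + 3.0
        facing = RigidTransform.from_rotvec([np.pi, 0, 0], translation=(0, 0, contact))
        averted = RigidTransform(translation=(0, 0, -contact))
        u_face = bd.interaction_energy(toy_pair.body_a, toy_pair.body_b, facing, PARAMS)
        u_avert = bd.interaction_energy(toy_pair.body_a, toy_pair.body_b, averted, PARAMS)
        assert u_face < u_avert
        assert u_face < 0

    def test_zeroed_charges_zero_energy(self, rng):
        pair = syn.make_toy_redox_pair(seed=3)
        pair.body_b.charges[:] = 0.0
        pair.body_b.charged = np.flatnonzero(pair.body_b.charges)
        pose = RigidTransform.random(rng, translation=(0, 0, 30))
        assert bd.interaction_energy(pair.body_a, pair.body_b, pose, PARAMS) == 0.0


class TestDockingContracts:
    def test_records_satisfy_constraints_strictly(self, toy_pair):
        # hot start just outside contact so encounters actually occur
        params = syn.toy_bd_params(seed=5, n_trajectories=6, max_steps=2000,
                                   b_radius=32.0, q_radius=60.0)
        enc = bd.run_docking(toy_pair.body_a, toy_pair.body_b, params)
        assert len(enc.records) > 0
        for r in enc.records:
            assert r.d_fe_n5 < params.d_fe_n5_max
            assert r.d_domain < params.d_domain_max
            assert np.isfinite(r.energy)

    def test_single_trajectory_equals_docking_with_n1(self, toy_pair):
        params = syn.toy_bd_params(seed=11, n_trajectories=1, max_steps=1500)
        enc = bd.run_docking(toy_pair.body_a, toy_pair.body_b, params)
        ss = np.random.SeedSequence(params.seed).spawn(1)[0]
        direct = bd.run_trajectory(toy_pair.body_a, toy_pair.body_b, params,
                                   np.random.default_rng(ss), 0)
        assert len(enc.records) == len(direct)
        for a, b in zip(enc.records, direct):
            np.testing.assert_array_equal(a.pose.translation, b.pose.translation)

    def test_seed_reproducibility(self, toy_pair):
        params = syn.toy_bd_params(seed=21, n_trajectories=4, max_steps=1500)
        e1 = bd.run_docking(toy_pair.body_a, toy_pair.body_b, params)
        e2 = bd.run_docking(toy_pair.body_a, toy_pair.body_b, params)
        assert len(e1) == len(e2)
        for a, b in zip(e1.records, e2.records):
            assert a.energy == b.energy
            np.testing.assert_array_equal(a.pose.quat, b.pose.quat)

    def test_doubling_trajectories_is_superset(self, toy_pair):
        p4 = syn.toy_bd_params(seed=5, n_trajectories=4, max_steps=1500)
        p8 = syn.toy_bd_params(seed=5, n_trajectories=8, max_steps=1500)
        e4 = bd.run_docking(toy_pair.body_a, toy_pair.body_b, p4)
        e8 = bd.run_docking(toy_pair.body_a, toy_pair.body_b, p8)
        key = lambda r: (r.trajectory, r.step)
        assert set(map(key, e4.records)) <= set(map(key, e8.records))

    def test_zero_records_warns_not_errors(self, toy_pair):
        params = syn.toy_bd_params(seed=0, n_trajectories=1, max_steps=5)
        with pytest.warns(UserWarning, match="zero encounter"):
            enc = bd.run_docking(toy_pair.body_a, toy_pair.body_b, params)
        assert len(enc) == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            bd.BDParameters(b_radius=500, q_radius=400)
        with pytest.raises(ValueError):
            bd.BDParameters(d_fe_n5_max=-1)
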