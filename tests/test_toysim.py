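"""Toy steered Brownian-dynamics engine: physics and determinism checks."""

import numpy as np
import pytest

from smdfan.errors import ConfigurationError
from smdfan.smdparse import parse_namd_smd_log
from smdfan.structure import read_pdb, write_pdb
from smdfan.toysim import (Bond, SMDProtocol, ToyModel,
                           make_anisotropic_complex, run_toy_smd, smd_force)


def free_bead_model(temperature=0.0, gamma=5.0):
    return ToyModel(
        positions=np.zeros((1, 3)),
        masses=np.array([12.0]),
        gamma=np.array([gamma]),
        bonds=[],
        temperature=temperature,
        fixed_idx=np.array([], dtype=int),
        pulled_idx=np.array([0]),
    )


def bonded_pair_model(k_b=5.0, r0=3.0, ext=2.0, temperature=0.0):
    """Fixed bead at origin, pulled bead at +z r0, one breakable bond."""
    return ToyModel(
        positions=np.array([[0, 0, 0.0], [0, 0, r0]]),
        masses=np.full(2, 12.0),
        gamma=np.full(2, 5.0),
        bonds=[Bond(0, 1, k=k_b, r0=r0, breakable=True, r_break=r0 + ext)],
        temperature=temperature,
        fixed_idx=np.array([0]),
        pulled_idx=np.array([1]),
    )


class TestSmdForce:
    def test_zero_extension(self):
        proto = SMDProtocol(direction=[0, 0, 1], k_spring=1.0, v_pull=1.0,
                            dt=0.01, n_steps=10)
        f, fvec = smd_force(0.0, np.zeros(3), np.zeros(3), proto)
        assert f == 0.0 and np.allclose(fvec, 0.0)

    def test_linear_law(self):
        proto = SMDProtocol(direction=[0, 0, 1], k_spring=1.0, v_pull=1.0,
                            dt=0.01, n_steps=10)
        f, fvec = smd_force(10.0, np.array([0, 0, 4.0]), np.zeros(3), proto)
        assert f == pytest.approx(6.0)
        assert np.allclose(fvec, [0, 0, 6.0])

    def test_matches_formula_on_random_inputs(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            d = rng.normal(size=3); d /= np.linalg.norm(d)
            proto = SMDProtocol(direction=d,
                                k_spring=float(rng.uniform(0.5, 50)),
                                v_pull=float(rng.uniform(0.01, 2)),
                                dt=0.01, n_steps=10)
            t = float(rng.uniform(0, 100))
            com = rng.normal(size=3)
            com0 = rng.normal(size=3)
            f, fvec = smd_force(t, com, com0, proto)
            expected = proto.k_spring * (proto.v_pull * t - (com - com0) @ d)
            assert f == pytest.approx(expected, rel=1e-12)
            assert np.allclose(fvec, expected * d, rtol=1e-12)


class TestFreeBead:
    def test_terminal_drag_force(self):
        """T=0 free bead: projected force -> gamma * v after the transient."""
        gamma, v, k = 5.0, 0.5, 10.0
        model = free_bead_model(gamma=gamma)
        proto = SMDProtocol(direction=[0, 0, 1], k_spring=k, v_pull=v,
                            dt=0.002, n_steps=20_000, log_stride=100)
        run = run_toy_smd(model, proto)
        tau = gamma / k  # relaxation time, ps
        late = run.times > 20 * tau
        assert np.allclose(run.forces_pn[late], gamma * v, rtol=0.01)

    def test_matches_closed_form_trajectory(self):
        """T=0: r(t) = vt - (gamma v / k)(1 - exp(-kt/gamma))."""
        gamma, v, k = 5.0, 0.5, 10.0
        model = free_bead_model(gamma=gamma)
        proto = SMDProtocol(direction=[0, 0, 1], k_spring=k, v_pull=v,
                            dt=0.0005, n_steps=40_000, log_stride=200)
        run = run_toy_smd(model, proto)
        t = run.times
        expected = v * t - (gamma * v / k) * (1 - np.exp(-k * t / gamma))
        z = run.com_positions[:, 2]
        assert np.allclose(z[1:], expected[1:], atol=2e-4 * max(1, expected[-1]))


class TestDeterminismAndLog:
    def test_identical_seeds_identical_bytes(self):
        model, _ = make_anisotropic_complex(seed=0)
        proto = SMDProtocol(direction=[0, 0, 1], k_spring=20.0, v_pull=0.5,
                            dt=0.005, n_steps=500, seed=7, log_stride=10)
        r1 = run_toy_smd(model, proto)
        r2 = run_toy_smd(model, proto)
        assert r1.log_text == r2.log_text
        for f1, f2 in zip(r1.frames, r2.frames):
            assert np.array_equal(f1, f2)

    def test_different_seed_differs(self):
        model, _ = make_anisotropic_complex(seed=0)
        mk = lambda s: SMDProtocol(direction=[0, 0, 1], k_spring=20.0,
                                   v_pull=0.5, dt=0.005, n_steps=500,
                                   seed=s, log_stride=10)
        assert run_toy_smd(model, mk(1)).log_text != \
            run_toy_smd(model, mk(2)).log_text

    def test_log_parses_into_matching_trace(self, tmp_path):
        model = free_bead_model()
        proto = SMDProtocol(direction=[0, 0, 1], k_spring=10.0, v_pull=0.5,
                            dt=0.002, n_steps=2000, log_stride=50)
        run = run_toy_smd(model, proto)
        p = tmp_path / "smd.log"
        p.write_text(run.log_text)
        tr = parse_namd_smd_log(p, timestep=proto.dt * 1000, direction=[0, 0, 1])
        assert len(tr) == len(run.times)
        assert np.allclose(tr.time, run.times, rtol=1e-9)
        assert np.allclose(tr.force, run.forces_pn, rtol=1e-6)


class TestBondBreaking:
    def test_quasistatic_rupture_force(self):
        """Slow pulling: F_max ~ k_b (r_break - r0), oracle at 10x finer dt/v."""
        k_b, ext = 5.0, 2.0
        model = bonded_pair_model(k_b=k_b, ext=ext)
        base = dict(direction=[0, 0, 1], k_spring=50.0, log_stride=20)
        proto = SMDProtocol(dt=0.004, v_pull=0.1, n_steps=10_000, **base)
        fine = SMDProtocol(dt=0.0004, v_pull=0.01, n_steps=1_000_000, **base)
        f_base = run_toy_smd(model, proto).forces_pn.max()
        f_fine = run_toy_smd(model, fine).forces_pn.max()
        assert f_base == pytest.approx(k_b * ext, rel=0.05)
        assert f_base == pytest.approx(f_fine, rel=0.05)

    def test_breaking_is_irreversible(self):
        model = bonded_pair_model(k_b=5.0, ext=1.0)
        proto = SMDProtocol(direction=[0, 0, 1], k_spring=50.0, v_pull=0.2,
                            dt=0.004, n_steps=10_000, log_stride=10)
        run = run_toy_smd(model, proto)
        assert run.broken_bonds == [0]
        # after the break the bond never pulls back: force returns to the
        # drag plateau and the bead keeps moving with the anchor
        late = run.forces_pn[-10:]
        gamma_v = model.gamma[1] * proto.v_pull
        assert np.allclose(late, gamma_v, rtol=0.05)

    def test_work_exceeds_stored_elastic_energy(self):
        """T=0, no breaking: spring work >= elastic energy stored."""
        model = bonded_pair_model(k_b=5.0, ext=50.0)  # effectively unbreakable
        proto = SMDProtocol(direction=[0, 0, 1], k_spring=50.0, v_pull=0.1,
                            dt=0.002, n_steps=20_000, log_stride=10)
        run = run_toy_smd(model, proto)
        work = np.trapezoid(run.forces_pn * proto.v_pull,
                            run.times)  # pN * A = 1e-21 J units
        z = run.com_positions[-1, 2] - run.com_positions[0, 2]
        elastic = 0.5 * 5.0 * z**2
        assert work >= elastic * (1 - 1e-6)

    def test_fixed_beads_never_move(self):
        model = bonded_pair_model(temperature=300.0)
        proto = SMDProtocol(direction=[0, 0, 1], k_spring=10.0, v_pull=0.5,
                            dt=0.002, n_steps=1000, seed=3, log_stride=100)
        run = run_toy_smd(model, proto)
        for frame in run.frames:
            assert np.array_equal(frame[0], model.positions[0])


class TestValidation:
    def test_bad_bond_rejected(self):
        with pytest.raises(ConfigurationError):
            Bond(0, 1, k=1.0, r0=3.0, breakable=True, r_break=2.0)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            ToyModel(positions=np.zeros((2, 3)), masses=np.ones(2),
                     gamma=np.ones(2), bonds=[], temperature=0.0,
                     fixed_idx=np.array([0]), pulled_idx=np.array([0, 1]))


class TestAnisotropicComplex:
    def test_structure_round_trips(self, tmp_path, toy_complex):
        _, structure = toy_complex
        p = tmp_path / "toy.pdb"
        write_pdb(structure, p)
        back = read_pdb(p)
        assert len(back) == len(structure)
        for a, b in zip(structure.atoms, back.atoms):
            assert (a.x, a.y, a.z) == (b.x, b.y, b.z)
            assert (a.chain, a.resseq, a.name) == (b.chain, b.resseq, b.name)

    def test_two_clusters_define_axis(self, toy_complex):
        from smdfan.structure import principal_axis
        model, structure = toy_complex
        ax = principal_axis(structure, list(model.fixed_idx),
                            list(model.pulled_idx))
        assert np.linalg.norm(ax) == pytest.approx(1.0, abs=1e-12)
        assert abs(ax[2]) > 0.99  # clusters separated along z

    def test_interface_bonds_are_breakable(self, toy_complex):
        model, _ = toy_complex
        pulled = set(model.pulled_idx.tolist())
        interface = [b for b in model.bonds
                     if (b.i in pulled) != (b.j in pulled)]
        assert interface and all(b.breakable for b in interface)
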