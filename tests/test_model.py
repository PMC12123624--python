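"""Energy-model checks: exactness, symmetry, locality, derivatives.

Oracles: finite differences (forces, stress, smoothness), explicit
neighbor loops (atomic basis), dense tensor contraction (product basis),
and both-sides evaluation under random rotations (equivariance).
"""

import numpy as np
import pytest

from empff import model as M
from empff import so3
from empff.graph import AtomicConfiguration
from empff.synthetic import DEFAULT_E0
from conftest import random_rotation


def random_cluster(rng, n=10, box=4.0, elements=(1, 8)):
    return AtomicConfiguration(rng.choice(elements, n),
                               rng.uniform(0, box, (n, 3)))


class TestConfigAndParameters:
    def test_presets_reproduce_published_hyperparameters(self):
        expected = {"S": (4.5, 96, 0), "M": (5.0, 128, 1),
                    "L": (5.0, 192, 2), "24M": (6.0, 128, 1)}
        for name, (r_cut, k, L) in expected.items():
            cfg = M.ModelConfig.from_preset(name, elements=(1,),
                                            e0={1: 0.0})
            assert (cfg.r_cut, cfg.n_channels, cfg.L_max) == (r_cut, k, L)
            assert cfg.n_layers == 2
            assert cfg.nu == 3

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="valid presets"):
            M.ModelConfig.from_preset("XXL", elements=(1,), e0={1: 0.0})

    def test_nu_and_layers_are_fixed(self):
        with pytest.raises(ValueError, match="nu"):
            M.ModelConfig(elements=(1,), e0=(0.0,), nu=2)
        with pytest.raises(ValueError, match="two layers"):
            M.ModelConfig(elements=(1,), e0=(0.0,), n_layers=3)

    def test_parameter_flatten_roundtrip(self, tiny_config, tiny_params):
        vec = tiny_params.flatten()
        back = tiny_params.unflatten(vec)
        for k in tiny_params.arrays:
            assert np.array_equal(back[k], tiny_params[k])

    def test_serialization_roundtrip_bit_exact(self, tmp_path, tiny_config,
                                               tiny_params):
        calc = M.Calculator(tiny_config, tiny_params)
        path = tmp_path / "model.npz"
        calc.save(path)
        loaded = M.Calculator.load(path)
        assert loaded.model_config == tiny_config
        for k in tiny_params.arrays:
            assert np.array_equal(loaded.params[k], tiny_params[k])


class TestEmbedding:
    def test_same_element_same_row_and_position_independent(self, tiny_config,
                                                            tiny_params):
        h = M.embed_elements([8, 1, 8], tiny_params, tiny_config)
        assert np.array_equal(h[0], h[2])
        assert h.shape == (3, tiny_config.n_channels, 1)

    def test_one_hot_weights_give_indicator(self):
        cfg = M.ModelConfig.from_preset("tiny", elements=(1, 8),
                                        e0=DEFAULT_E0, n_channels=2)
        params = M.init_parameters(cfg, seed=0)
        params["emb"] = np.eye(2)
        h = M.embed_elements([1, 8], params, cfg)
        assert np.allclose(h[:, :, 0], np.eye(2))

    def test_unknown_element_named_in_error(self, tiny_config, tiny_params):
        with pytest.raises(ValueError, match="92"):
            M.embed_elements([92], tiny_params, tiny_config)


class TestRadialFeatures:
    def test_vanishes_exactly_at_cutoff(self, tiny_config, tiny_params):
        R = M.radial_features([tiny_config.r_cut], tiny_params, tiny_config)
        assert np.all(R == 0.0)

    def test_first_derivative_vanishes_at_cutoff(self, tiny_config,
                                                 tiny_params):
        r = tiny_config.r_cut - 1e-6
        R1 = M.radial_features([r], tiny_params, tiny_config)
        R2 = M.radial_features([r - 1e-6], tiny_params, tiny_config)
        slope = np.abs(R1 - R2).max() / 1e-6
        assert slope <= 1e-4

    def test_continuity_at_random_radii(self, tiny_config, tiny_params, rng):
        r = rng.uniform(0.5, tiny_config.r_cut - 0.1, 10)
        a = M.radial_features(r, tiny_params, tiny_config)
        b = M.radial_features(r + 1e-6, tiny_params, tiny_config)
        assert np.abs(a - b).max() <= 1e-4

    def test_beyond_cutoff_rejected(self, tiny_config, tiny_params):
        with pytest.raises(ValueError, match="r_cut"):
            M.radial_features([tiny_config.r_cut + 0.1], tiny_params,
                              tiny_config)


class TestOneParticleBasis:
    def test_scalar_neighbors_give_harmonic_profile(self, tiny_config,
                                                    tiny_params, rng):
        # with h restricted to l2=0 every φ column of degree l3 is
        # proportional to Y_l3 of the edge direction
        r_vecs = rng.standard_normal((4, 3))
        k = tiny_config.n_channels
        h = np.zeros((4, k, 1))
        h[:, :, 0] = 1.0
        Rv = np.ones((4, len(M._Tables(tiny_config).edge_paths[0]), k))
        phi = M.one_particle_basis(h, r_vecs, Rv, tiny_config, layer=0)
        Y = so3.real_spherical_harmonics(
            r_vecs / np.linalg.norm(r_vecs, axis=1, keepdims=True),
            tiny_config.l_max_ang)
        # layer-0 paths are (l,0,l); φ columns reproduce scaled harmonics
        tb = M._Tables(tiny_config)
        col = 0
        for (l1, l2, l3) in tb.edge_paths[0]:
            width = 2 * l3 + 1
            block = phi[:, 0, col:col + width]
            ratio = block / Y[:, so3.lm_slice(l3)]
            assert np.ptp(ratio) < 1e-10
            col += width

    def test_zero_radial_weights_zero_phi(self, tiny_config, tiny_params,
                                          rng):
        r_vecs = rng.standard_normal((3, 3))
        h = rng.standard_normal((3, tiny_config.n_channels, 1))
        Rv = np.zeros((3, len(M._Tables(tiny_config).edge_paths[0]),
                       tiny_config.n_channels))
        phi = M.one_particle_basis(h, r_vecs, Rv, tiny_config, layer=0)
        assert np.all(phi == 0.0)

    def test_rotational_equivariance_of_phi(self, tiny_config, tiny_params,
                                            rng):
        tb = M._Tables(tiny_config)
        r_vecs = rng.standard_normal((5, 3))
        k = tiny_config.n_channels
        h = np.zeros((5, k, 1))
        h[:, :, 0] = rng.standard_normal((5, k))
        Rv = rng.standard_normal((5, len(tb.edge_paths[0]), k))
        phi = M.one_particle_basis(h, r_vecs, Rv, tiny_config, layer=0)
        R = random_rotation(rng)
        phi_rot = M.one_particle_basis(h, r_vecs @ R.T, Rv, tiny_config,
                                       layer=0)
        col = 0
        for (l1, l2, l3) in tb.edge_paths[0]:
            width = 2 * l3 + 1
            D = so3.wigner_d_real(R, l3)
            assert np.abs(phi_rot[:, :, col:col + width]
                          - phi[:, :, col:col + width] @ D.T).max() < 1e-10
            col += width


class TestAtomicBasis:
    def test_no_neighbors_gives_zero(self, tiny_config, tiny_params):
        c = AtomicConfiguration([1, 8], [[0, 0, 0], [40, 0, 0]])
        _, states = M.total_energy(tiny_params, c, tiny_config,
                                   return_state=True)
        assert np.all(states[0].A == 0.0)
        assert np.all(states[1].A == 0.0)

    def test_coincident_neighbors_double_contribution(self, tiny_config,
                                                      tiny_params, rng):
        tb = M._Tables(tiny_config)
        k = tiny_config.n_channels
        phi = rng.standard_normal((1, k, tb.edge[0]["ncol"]))
        idx1 = np.array([0])
        A1 = M.pooled_atomic_basis(phi, idx1, 1, tiny_params, tiny_config, 0)
        phi2 = np.vstack([phi, phi])
        A2 = M.pooled_atomic_basis(phi2, np.array([0, 0]), 1, tiny_params,
                                   tiny_config, 0)
        assert np.allclose(A2, 2.0 * A1, atol=1e-12)

    def test_matches_naive_neighbor_loop(self, tiny_config, tiny_params,
                                         rng):
        # 5 edges onto one atom: fused pooled basis vs per-edge accumulation
        tb = M._Tables(tiny_config)
        k = tiny_config.n_channels
        phi = rng.standard_normal((5, k, tb.edge[0]["ncol"]))
        idx = np.zeros(5, dtype=int)
        A = M.pooled_atomic_basis(phi, idx, 1, tiny_params, tiny_config, 0)
        acc = np.zeros_like(A)
        for e in range(5):
            acc += M.pooled_atomic_basis(phi[e:e + 1], np.array([0]), 1,
                                         tiny_params, tiny_config, 0)
        assert np.abs(A - acc).max() < 1e-12


class TestProductBasis:
    def test_zero_A_zero_B(self, tiny_config):
        scheme = so3.build_coupling_scheme(tiny_config.l_max_ang, 3, 1)
        out = M.symmetric_product_basis(np.zeros(so3.num_lm(1)), scheme)
        assert all(np.all(v == 0) for _, v in out)

    def test_nu1_block_equals_A(self, tiny_config, rng):
        scheme = so3.build_coupling_scheme(1, 3, 1)
        A = rng.standard_normal(4)
        for p, v in M.symmetric_product_basis(A, scheme):
            if p.nu == 1:
                assert np.array_equal(v, A[so3.lm_slice(p.L)])

    def test_scaling_degree_per_block(self, rng):
        scheme = so3.build_coupling_scheme(1, 3, 0)
        A = rng.standard_normal(4)
        for p, v in M.symmetric_product_basis(A, scheme):
            _, v2 = [(q, w) for q, w in
                     M.symmetric_product_basis(2.0 * A, scheme)
                     if q is p][0]
            assert np.allclose(v2, 2.0 ** p.nu * v, atol=1e-12)

    def test_evaluator_B_matches_dense_triple_oracle(self, tiny_config,
                                                     tiny_params, rng):
        # the fused evaluator's ν=3 block against brute-force dense
        # contraction of A with explicitly composed coupling tensors
        c = random_cluster(rng, n=6)
        ev = M.Evaluator(tiny_config)
        cache = ev.forward(tiny_params, c)
        lc = cache["layer0"]
        A = lc["A"]
        pr = ev.tables.prod[0]
        for q, path in enumerate(ev.tables.schemes[0].paths):
            if path.nu != 3:
                continue
            nu, c0, w = pr["qcols"][q]
            got = lc["B3"][:, :, c0:c0 + w]
            l12 = path.intermediates[0]
            C12 = so3._cg_array(path.ls[0], path.ls[1], l12)
            C3 = so3._cg_array(l12, path.ls[2], path.L)
            dense = np.einsum("abx,xcM,nka,nkb,nkc->nkM", C12, C3,
                              A[:, :, so3.lm_slice(path.ls[0])],
                              A[:, :, so3.lm_slice(path.ls[1])],
                              A[:, :, so3.lm_slice(path.ls[2])])
            assert np.abs(got - dense).max() < 1e-10


class TestMessageAndUpdate:
    def test_zero_messages_give_linear_residual_map(self, tiny_config,
                                                    tiny_params, rng):
        params = tiny_params.copy()
        params["msg1"] = np.zeros_like(params["msg1"])
        k = tiny_config.n_channels
        h1 = rng.standard_normal((3, k, 4))
        z_idx = np.array([0, 1, 0])
        B_list = M.symmetric_product_basis(
            rng.standard_normal((3, k, 4)),
            so3.build_coupling_scheme(1, 3, 0))
        h2 = M.message_and_update(B_list, h1, z_idx, params, tiny_config, 1)
        # reduces to h2 = res·h1 (a fixed linear image of h1)
        expected = np.einsum("nkc,ncM->nkM", params["res1"][z_idx, 0],
                             h1[:, :, :1])
        assert np.allclose(h2[:, :, :1], expected, atol=1e-12)

    def test_isolated_atom_first_layer_features_vanish(self, tiny_config,
                                                       tiny_params):
        c = AtomicConfiguration([8], [[0, 0, 0]])
        _, states = M.total_energy(tiny_params, c, tiny_config,
                                   return_state=True)
        assert np.all(states[0].h_out == 0.0)   # no residual at layer 0
        assert np.all(states[1].h_out == 0.0)

    def test_update_equivariance(self, tiny_config, tiny_params, rng):
        c = random_cluster(rng, n=8)
        ev = M.Evaluator(tiny_config)
        h1 = ev.forward(tiny_params, c)["layer0"]["h_out"]
        R = random_rotation(rng)
        c2 = AtomicConfiguration(c.species, c.positions @ R.T)
        h1_rot = ev.forward(tiny_params, c2)["layer0"]["h_out"]
        assert np.abs(h1_rot - so3.rotate_features(h1, R)).max() < 1e-10


class TestReadoutAndTotalEnergy:
    def test_isolated_atoms_get_exactly_e0(self, tiny_config, tiny_params):
        c = AtomicConfiguration([1, 8, 1],
                                [[0, 0, 0], [50, 0, 0], [100, 0, 0]])
        res = M.total_energy(tiny_params, c, tiny_config)
        e0 = dict(zip(tiny_config.elements, tiny_config.e0))
        assert np.array_equal(res.site_energies, [e0[1], e0[8], e0[1]])
        assert res.energy == float(np.sum(res.site_energies))

    def test_zero_readout_weights_give_e0_anywhere(self, tiny_config,
                                                   tiny_params, rng):
        params = tiny_params.copy()
        params["ro1"] = np.zeros_like(params["ro1"])
        params["ro2_W2"] = np.zeros_like(params["ro2_W2"])
        c = random_cluster(rng)
        res = M.total_energy(params, c, tiny_config)
        e0 = dict(zip(tiny_config.elements, tiny_config.e0))
        expected = [e0[int(z)] for z in c.species]
        assert np.allclose(res.site_energies, expected, atol=1e-12)

    def test_symmetric_dimer_site_energies_equal(self, tiny_config,
                                                 tiny_params):
        c = AtomicConfiguration([8, 8], [[0, 0, 0], [1.5, 0, 0]])
        res = M.total_energy(tiny_params, c, tiny_config)
        assert abs(res.site_energies[0] - res.site_energies[1]) < 1e-12

    def test_total_is_sum_of_sites(self, tiny_config, tiny_params, rng):
        res = M.total_energy(tiny_params, random_cluster(rng), tiny_config)
        assert res.energy == pytest.approx(res.site_energies.sum(), abs=1e-10)

    def test_invariance_20_random_rototranslations_permutations(
            self, tiny_config, tiny_params, rng):
        c = random_cluster(rng)
        e0 = M.total_energy(tiny_params, c, tiny_config).energy
        for _ in range(20):
            R = random_rotation(rng)
            t = rng.uniform(-5, 5, 3)
            perm = rng.permutation(c.n_atoms)
            c2 = AtomicConfiguration(c.species[perm],
                                     c.positions[perm] @ R.T + t)
            e2 = M.total_energy(tiny_params, c2, tiny_config).energy
            assert abs(e2 - e0) <= 1e-10 * max(1.0, abs(e0))

    def test_extensivity_of_separated_fragments(self, tiny_config,
                                                tiny_params, rng):
        a = random_cluster(rng, n=5)
        b = random_cluster(rng, n=6)
        b2 = AtomicConfiguration(b.species, b.positions + 50.0)
        ab = AtomicConfiguration(np.concatenate([a.species, b2.species]),
                                 np.vstack([a.positions, b2.positions]))
        ea = M.total_energy(tiny_params, a, tiny_config).energy
        eb = M.total_energy(tiny_params, b2, tiny_config).energy
        eab = M.total_energy(tiny_params, ab, tiny_config).energy
        assert abs(eab - ea - eb) < 1e-10 * max(1.0, abs(eab))

    def test_smooth_across_cutoff(self, tiny_config, tiny_params):
        # E is C¹ as a pair distance crosses r_cut
        rc = tiny_config.r_cut

        def e_of(d):
            c = AtomicConfiguration([1, 8], [[0, 0, 0], [d, 0, 0]])
            return M.total_energy(tiny_params, c, tiny_config).energy

        h = 1e-5
        slope_in = (e_of(rc - h) - e_of(rc - 3 * h)) / (2 * h)
        slope_out = (e_of(rc + 3 * h) - e_of(rc + h)) / (2 * h)
        assert abs(e_of(rc + h) - e_of(rc - h)) < 1e-8
        assert abs(slope_in - slope_out) < 1e-4


class TestLocality:
    def test_site_energy_unaffected_beyond_twice_cutoff(self):
        # zero reference energies keep the floating-point noise floor of
        # the site energy near 1e-16 eV so tiny envelope-suppressed
        # signals close to 2·r_cut remain resolvable
        tiny_config = M.ModelConfig.from_preset(
            "tiny", elements=(1, 8), e0={1: 0.0, 8: 0.0})
        tiny_params = M.init_parameters(tiny_config, seed=0)
        rc = tiny_config.r_cut
        # chain of atoms (with a relay just inside r_cut) so influence can
        # hop: atom 0 ← relay ← probe covers distances up to 2·r_cut
        xs = np.concatenate([np.arange(0.0, rc, 1.4), [rc - 0.05]])
        n = len(xs)
        pos = np.zeros((n, 3))
        pos[:, 0] = xs
        species = [8] + [1] * (n - 1)

        def site0(probe_x, probe_y):
            probe = np.array([[probe_x, probe_y, 0.0]])
            c = AtomicConfiguration(species + [8], np.vstack([pos, probe]))
            return M.total_energy(tiny_params, c, tiny_config).site_energies[0]

        # below 2·r_cut the probe influences atom 0 through the relay;
        # beyond 2·r_cut there is no two-hop path, so the change is exactly
        # zero (not merely small)
        assert abs(site0(2 * rc - 0.5, 0.0) - site0(2 * rc - 0.5, 0.4)) > 1e-12
        for d in (2 * rc + 0.05, 2.2 * rc, 3.0 * rc):
            assert site0(d, 0.0) - site0(d, 0.4) == 0.0


class TestForcesAndStress:
    def test_homonuclear_dimer_forces_along_bond(self, tiny_config,
                                                 tiny_params):
        c = AtomicConfiguration([8, 8], [[0, 0, 0], [1.5, 0, 0]])
        res = M.forces_and_stress(tiny_params, c, tiny_config)
        assert np.allclose(res.forces[0], -res.forces[1], atol=1e-12)
        assert np.abs(res.forces[:, 1:]).max() < 1e-12

    def test_forces_match_central_differences(self, tiny_config, tiny_params,
                                              rng):
        c = random_cluster(rng)
        res = M.forces_and_stress(tiny_params, c, tiny_config)
        h = 1e-4
        scale = np.abs(res.forces).max()
        for i in range(c.n_atoms):
            for a in range(3):
                pp, pm = c.positions.copy(), c.positions.copy()
                pp[i, a] += h
                pm[i, a] -= h
                ep = M.total_energy(tiny_params,
                                    AtomicConfiguration(c.species, pp),
                                    tiny_config).energy
                em = M.total_energy(tiny_params,
                                    AtomicConfiguration(c.species, pm),
                                    tiny_config).energy
                fd = -(ep - em) / (2 * h)
                assert abs(fd - res.forces[i, a]) <= 1e-5 * max(1.0, scale)

    def test_zero_net_force_and_torque(self, tiny_config, tiny_params, rng):
        c = random_cluster(rng)
        res = M.forces_and_stress(tiny_params, c, tiny_config)
        assert np.abs(res.forces.sum(axis=0)).max() < 1e-9
        torque = np.cross(c.positions, res.forces).sum(axis=0)
        assert np.abs(torque).max() < 1e-9

    def test_force_equivariance(self, tiny_config, tiny_params, rng):
        c = random_cluster(rng)
        res = M.forces_and_stress(tiny_params, c, tiny_config)
        R = random_rotation(rng)
        c2 = AtomicConfiguration(c.species, c.positions @ R.T)
        res2 = M.forces_and_stress(tiny_params, c2, tiny_config)
        assert np.abs(res2.forces - res.forces @ R.T).max() <= 1e-8

    def test_stress_matches_finite_strain(self, tiny_config, tiny_params,
                                          rng):
        pos = rng.uniform(0, 5.0, (8, 3))
        cell = np.eye(3) * 5.5
        spec = rng.choice([1, 8], 8)
        c = AtomicConfiguration(spec, pos, cell=cell, pbc=(True,) * 3)
        res = M.forces_and_stress(tiny_params, c, tiny_config)
        eps = 1e-5
        V = c.volume
        fd = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                for sgn in (1, -1):
                    e = np.zeros((3, 3))
                    e[a, b] = sgn * eps
                    F = np.eye(3) + e
                    c2 = AtomicConfiguration(spec, pos @ F.T, cell=cell @ F.T,
                                             pbc=(True,) * 3)
                    fd[a, b] += sgn * M.total_energy(
                        tiny_params, c2, tiny_config).energy
        fd /= (2 * eps * V)
        assert np.abs(0.5 * (fd + fd.T) - res.stress).max() <= 1e-6

    def test_stress_requires_periodicity(self, tiny_config, tiny_params,
                                         rng):
        with pytest.raises(ValueError, match="periodic"):
            M.forces_and_stress(tiny_params, random_cluster(rng),
                                tiny_config, stress=True)


class TestBodyOrder:
    def test_triple_block_scales_cubically(self, rng):
        # log-log slope of the ν=3 block norm under uniform scaling of A
        scheme = so3.build_coupling_scheme(1, 3, 0)
        A = rng.standard_normal(4)
        lams = np.array([0.5, 1.0, 2.0, 4.0])
        norms = []
        for lam in lams:
            out = so3.contract_symmetric(lam * A, scheme, nu=3)
            norms.append(np.sqrt(sum(float(v @ v) for _, v in out)))
        slope = np.polyfit(np.log(lams), np.log(norms), 1)[0]
        assert slope == pytest.approx(3.0, abs=1e-6)
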