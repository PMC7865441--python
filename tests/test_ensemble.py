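"""Hard-sphere ensemble generator: geometry, sterics, sampling, trends."""

import numpy as np
import pytest

from dsekit.ensemble import (ALPHA_WINDOW, PPII_WINDOW, SimConfig,
                             allowed_fraction, build_chain, clash_check,
                             rama_allowed_mask, run_ensemble, sample_conformer,
                             tripeptide_allowed)
from dsekit.ensemble import (_build_batch, _clash_free_batch, _draw_dihedrals,
                             _kernel_args)


def dihedral(p0, p1, p2, p3):
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    v = (p0 - p1) - np.dot(p0 - p1, b1) * b1
    w = (p3 - p2) - np.dot(p3 - p2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


class TestBuildChain:
    def test_dihedrals_are_realized_exactly(self):
        phi, psi = [0, -75, -120], [145, 145, 120]
        coords, atoms = build_chain(phi, psi)
        idx = {a: i for i, a in enumerate(atoms)}
        assert dihedral(coords[idx[(0, "C")]], coords[idx[(1, "N")]],
                        coords[idx[(1, "CA")]], coords[idx[(1, "C")]]) == \
            pytest.approx(-75.0, abs=1e-9)
        assert dihedral(coords[idx[(0, "N")]], coords[idx[(0, "CA")]],
                        coords[idx[(0, "C")]], coords[idx[(1, "N")]]) == \
            pytest.approx(145.0, abs=1e-9)
        assert abs(dihedral(coords[idx[(0, "CA")]], coords[idx[(0, "C")]],
                            coords[idx[(1, "N")]], coords[idx[(1, "CA")]])) == \
            pytest.approx(180.0, abs=1e-9)

    def test_peptide_bond_length(self):
        coords, atoms = build_chain([0, -75], [145, 145])
        idx = {a: i for i, a in enumerate(atoms)}
        bond = np.linalg.norm(coords[idx[(1, "N")]] - coords[idx[(0, "C")]])
        assert bond == pytest.approx(1.33, abs=0.01)

    def test_homogeneous_dihedrals_give_screw_symmetry(self):
        n = 10
        coords, atoms = build_chain([-75.0] * n, [145.0] * n)
        idx = {a: i for i, a in enumerate(atoms)}
        ca = np.array([coords[idx[(i, "CA")]] for i in range(n)])
        rises = [np.linalg.norm(ca[i + 3] - ca[i]) for i in range(n - 3)]
        assert np.ptp(rises) < 1e-8

    def test_rebuild_reproduces_coordinates(self):
        conf = sample_conformer(8, config=SimConfig(s_ppii=0.3, seed=3))
        rebuilt, _ = build_chain(conf.phi, conf.psi, conf.omega)
        assert np.allclose(rebuilt, conf.coords, atol=1e-6)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            build_chain([0, -75], [145])

    def test_glycine_has_no_cb_proline_no_amide_h(self):
        _, atoms = build_chain([0, -75, -75], [145, 145, 145], sequence="GAP")
        names = {(r, n) for r, n in atoms}
        assert (0, "CB") not in names
        assert (2, "H") not in names
        assert (1, "CB") in names and (1, "H") in names


class TestClashCheck:
    def test_disallowed_origin(self):
        coords, _ = build_chain([-75, 0, -75], [145, 0, 145])
        ok, pair = clash_check(coords, "AAA")
        assert not ok and pair is not None

    def test_allowed_extended_point(self):
        coords, _ = build_chain([-75, -90, -75], [145, 90, 145])
        ok, pair = clash_check(coords, "AAA")
        assert ok and pair is None

    def test_two_residue_chain_passes(self):
        coords, _ = build_chain([0, -90], [130, 90])
        assert clash_check(coords, "AA")[0]

    def test_central_admissibility_matches_worked_examples(self):
        assert not tripeptide_allowed(0.0, 0.0)[0]
        assert tripeptide_allowed(-90.0, 90.0)[0]

    def test_ideal_basin_helices_are_clash_free(self):
        for phi, psi in ((-75.0, 145.0), (-64.0, -41.0)):
            coords, _ = build_chain([phi] * 12, [psi] * 12)
            assert clash_check(coords, "A" * 12)[0], (phi, psi)


class TestAllowedRegion:
    def test_allowed_fraction_brackets_the_hard_sphere_rate(self):
        frac = allowed_fraction(n_draws=4000, seed=2)
        assert 0.01 <= frac <= 0.06

    def test_mask_contains_both_windows(self):
        mask = rama_allowed_mask(SimConfig())
        grid = 5.0
        for window in (PPII_WINDOW, ALPHA_WINDOW):
            i = int((window.phi_min + 180) / grid)
            j = int((window.psi_min + 180) / grid)
            assert mask[i:i + 4, j:j + 4].all()

    def test_mask_excludes_origin(self):
        mask = rama_allowed_mask(SimConfig())
        assert not mask[36, 36]  # cell covering (0..5, 0..5)


class TestSampling:
    def test_full_bias_lands_in_window(self):
        conf = sample_conformer(12, config=SimConfig(s_ppii=1.0, seed=1))
        assert PPII_WINDOW.contains(conf.phi, conf.psi).all()

    def test_seeded_reproducibility(self):
        a = sample_conformer(10, config=SimConfig(s_ppii=0.4, seed=7))
        b = sample_conformer(10, config=SimConfig(s_ppii=0.4, seed=7))
        assert np.array_equal(a.coords, b.coords)

    def test_bias_budget_validated(self):
        with pytest.raises(ValueError):
            SimConfig(s_ppii=0.7, s_alpha=0.5)

    def test_l_is_max_ca_distance_and_rigid_invariant(self):
        conf = sample_conformer(10, config=SimConfig(seed=5))
        ca = np.array([conf.coords[i] for i, (r, n) in enumerate(conf.atoms)
                       if n == "CA"])
        direct = max(np.linalg.norm(a - b) for a in ca for b in ca)
        assert conf.l == pytest.approx(direct)
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = ca @ q.T + np.array([5.0, -3.0, 11.0])
        rotated = max(np.linalg.norm(a - b) for a in moved for b in moved)
        assert rotated == pytest.approx(direct)

    def test_kernel_matches_numpy_reference(self):
        """The accelerated chain builder makes the same accept/reject
        decisions as the vectorized numpy steric filter."""
        from dsekit._fastsim import chain_batch
        cfg = SimConfig(s_ppii=0.3, s_alpha=0.2, seed=9)
        rng = np.random.default_rng(21)
        seq = "A" * 12
        phi, psi, om = _draw_dihedrals(rng, 300, 12, seq, cfg)
        coords = _build_batch(phi, psi, om, seq, cfg.geometry)
        ok_ref = _clash_free_batch(coords, seq, cfg)
        args = _kernel_args(seq, cfg)
        ok = np.zeros(300, dtype=np.bool_)
        l = np.zeros(300)
        chain_batch(phi, psi, om, *args, np.zeros((args[0].shape[0], 3)),
                    ok, l)
        assert np.array_equal(ok, ok_ref)

    def test_cis_proline_rate(self):
        cfg = SimConfig(cis_pro_rate=0.5, seed=3)
        rng = np.random.default_rng(3)
        _, _, om = _draw_dihedrals(rng, 400, 4, "APAP", cfg)
        assert (om[:, [0, 2]] == 180.0).all()
        cis_rate = (om[:, [1, 3]] == 0.0).mean()
        assert 0.4 < cis_rate < 0.6


class TestEnsembles:
    def test_seeded_mean_reproducible(self):
        a = run_ensemble(10, SimConfig(seed=5), stop=200)
        b = run_ensemble(10, SimConfig(seed=5), stop=200)
        assert a.mean_l == b.mean_l
        assert a.rh == a.mean_l / 2.0

    def test_ppii_bias_expands_the_coil(self):
        means = {}
        for s in (0.0, 0.4, 0.8):
            means[s] = run_ensemble(16, SimConfig(s_ppii=s, seed=11),
                                    stop=400).mean_l
        assert means[0.8] > means[0.4] > means[0.0]

    def test_realized_fraction_tracks_applied_bias(self):
        summary = run_ensemble(16, SimConfig(s_ppii=0.4, seed=13), stop=300)
        assert summary.realized_f_ppii >= 0.8 * 0.4
        assert summary.realized_f_ppii <= 1.0

    def test_alpha_bias_response_is_non_monotone_without_ppii(self):
        """Modest helix sampling compacts the chain; near-exclusive helix
        sampling produces rod-like, elongated states."""
        means = [run_ensemble(40, SimConfig(s_alpha=s, seed=17),
                              stop=150).mean_l
                 for s in (0.0, 0.5, 1.0)]
        assert means[1] < means[0]
        assert means[2] > means[1]

    def test_convergence_rule(self):
        summary = run_ensemble(8, SimConfig(seed=19), stop="auto")
        assert summary.converged
        assert summary.n_states >= 1000

    def test_invalid_stop(self):
        with pytest.raises(ValueError):
            run_ensemble(8, SimConfig(seed=1), stop=0)
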