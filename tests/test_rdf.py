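"""Radial distribution functions: normalisation, conservation, null models."""

import numpy as np
import pytest

from micellekit import rdf_from_com, rdf_site_site
from micellekit.synthetic import MicelleSpec, build_micelle, ideal_gas_box

from .oracles import count_pairs_in_range


def gas_traj(make_point_traj, n, box, seed=0, n_frames=1):
    frames = np.stack([ideal_gas_box(n, box, seed=seed + k).coords
                       for k in range(n_frames)])
    return make_point_traj(frames, np.broadcast_to(np.asarray(box, float), (3,)))


class TestSiteSite:
    def test_single_pair_lands_in_its_bin(self, make_point_traj):
        coords = np.array([[1.0, 1.0, 1.0], [1.3, 1.0, 1.0]])
        traj = make_point_traj(coords, (8.0,) * 3)
        res = rdf_site_site(traj, [0], [1], bin_width=0.02, r_max=2.0,
                            exclude_same_molecule=False)
        nz = np.nonzero(res.counts)[0]
        assert len(nz) == 1
        assert res.bin_centers[nz[0]] == pytest.approx(0.31, abs=0.011)

    def test_ideal_gas_is_unity(self, make_point_traj):
        """Uncorrelated particles: g within 3 Poisson SE of 1 on 0.5-3 nm."""
        n, box = 5000, 8.0
        traj = gas_traj(make_point_traj, n, box, seed=42)
        res = rdf_site_site(traj, np.arange(n), np.arange(n), bin_width=0.05,
                            r_max=3.5, exclude_same_molecule=False)
        sel = (res.bin_centers >= 0.5) & (res.bin_centers <= 3.0)
        expected = res.counts[sel] / res.g[sel]          # N_A rho_B V_shell
        # ordered counts double each independent pair: SE is sqrt(2)/sqrt(counts)
        se = np.sqrt(2.0 / expected)                     # Poisson, in g units
        assert np.all(np.abs(res.g[sel] - 1.0) < 3.0 * se)
        assert abs(res.g[sel].mean() - 1.0) < 3.0 * se.mean() / np.sqrt(sel.sum())

    def test_pair_count_conservation_vs_oracle(self, make_point_traj, rng):
        """Total histogram counts equal the O(N^2) in-range enumeration."""
        for seed in (1, 2, 3):
            n, box = 120, 4.0
            traj = gas_traj(make_point_traj, n, box, seed=seed, n_frames=2)
            res = rdf_site_site(traj, np.arange(n), np.arange(n), bin_width=0.1,
                                r_max=1.9, exclude_same_molecule=False)
            oracle = 0
            for fr in traj.frames:
                oracle += count_pairs_in_range(
                    fr.coords, fr.coords, fr.box, res.r_max,
                    idx_a=np.arange(n), idx_b=np.arange(n), ordered=True)
            assert int(res.counts.sum()) == oracle

    def test_distinct_selection_conservation(self, make_point_traj):
        n, box = 100, 4.0
        traj = gas_traj(make_point_traj, n, box, seed=9)
        sel_a, sel_b = np.arange(40), np.arange(40, 100)
        res = rdf_site_site(traj, sel_a, sel_b, bin_width=0.1, r_max=1.9,
                            exclude_same_molecule=False)
        fr = traj.frames[0]
        oracle = count_pairs_in_range(fr.coords[sel_a], fr.coords[sel_b],
                                      fr.box, res.r_max)
        assert int(res.counts.sum()) == oracle

    def test_same_molecule_pairs_excluded(self, make_point_traj):
        coords = np.array([[1.0, 1, 1], [1.2, 1, 1], [3.0, 1, 1], [3.2, 1, 1]])
        traj = make_point_traj(coords, (8.0,) * 3, mol_ids=[1, 1, 2, 2])
        res_ex = rdf_site_site(traj, np.arange(4), np.arange(4), bin_width=0.05,
                               r_max=3.0, exclude_same_molecule=True)
        res_in = rdf_site_site(traj, np.arange(4), np.arange(4), bin_width=0.05,
                               r_max=3.0, exclude_same_molecule=False)
        # the two 0.2 nm intra-molecular contacts drop out (4 ordered pairs)
        assert int(res_in.counts.sum()) - int(res_ex.counts.sum()) == 4

    def test_bin_width_preserves_neighbor_count(self, make_point_traj):
        """Integral rho 4 pi r^2 g dr (cumulative neighbours) is bin-width stable."""
        n, box = 800, 5.0
        traj = gas_traj(make_point_traj, n, box, seed=17)
        fine = rdf_site_site(traj, np.arange(n), np.arange(n), bin_width=0.02,
                             r_max=2.0, exclude_same_molecule=False)
        coarse = rdf_site_site(traj, np.arange(n), np.arange(n), bin_width=0.04,
                               r_max=2.0, exclude_same_molecule=False)
        # identical raw information, different binning
        assert int(fine.counts.sum()) == int(coarse.counts.sum())
        rho = n / box ** 3
        for res in (fine, coarse):
            integral = np.sum(rho * 4 * np.pi * res.bin_centers ** 2
                              * res.g * res.bin_width)
            direct = res.counts.sum() / n
            assert integral == pytest.approx(direct, rel=0.01)

    def test_translation_and_order_invariance(self, make_point_traj, rng):
        n, box = 60, 4.0
        base = ideal_gas_box(n, box, seed=23).coords
        t0 = make_point_traj(base, (box,) * 3)
        t1 = make_point_traj(np.mod(base + [1.7, -0.9, 2.3], box), (box,) * 3)
        perm = rng.permutation(n)
        r0 = rdf_site_site(t0, np.arange(n), np.arange(n), bin_width=0.1, r_max=1.9,
                           exclude_same_molecule=False)
        r1 = rdf_site_site(t1, np.arange(n), np.arange(n), bin_width=0.1, r_max=1.9,
                           exclude_same_molecule=False)
        r2 = rdf_site_site(t0, perm, perm, bin_width=0.1, r_max=1.9,
                           exclude_same_molecule=False)
        np.testing.assert_allclose(r1.g, r0.g, atol=1e-9)
        np.testing.assert_allclose(r2.g, r0.g, atol=1e-9)

    def test_errors(self, make_point_traj):
        traj = gas_traj(make_point_traj, 10, 4.0)
        with pytest.raises(ValueError):
            rdf_site_site(traj, np.arange(10), np.arange(10), r_max=3.0)
        with pytest.raises(ValueError):
            rdf_site_site(traj, [], np.arange(10))


class TestFromCom:
    def test_fixed_radius_shell(self, make_point_traj):
        """Targets all at distance d from a point micelle: one occupied bin."""
        rng = np.random.default_rng(3)
        u = rng.normal(size=(50, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], 1.53 * u]) + 4.0
        traj = make_point_traj(coords, (8.0,) * 3)
        res = rdf_from_com(traj, [0], np.arange(1, 51), bin_width=0.02, r_max=3.0)
        nz = np.nonzero(res.counts)[0]
        assert len(nz) == 1
        assert res.bin_centers[nz[0]] == pytest.approx(1.53, abs=0.011)

    def test_uniform_targets_reach_unity(self, make_point_traj, sphere_micelle):
        """Far from the micelle COM, uniform solvent gives g -> 1."""
        box = 12.0
        rng = np.random.default_rng(8)
        n_solv = 30000
        mic = sphere_micelle.frames[0].coords - sphere_micelle.frames[0].box / 2 + box / 2
        solvent = rng.uniform(0, box, size=(n_solv, 3))
        coords = np.vstack([mic, solvent])
        n_mic = mic.shape[0]
        traj = make_point_traj(coords, (box,) * 3,
                               masses=np.r_[sphere_micelle.masses(), np.ones(n_solv)])
        res = rdf_from_com(traj, np.arange(n_mic),
                           np.arange(n_mic, n_mic + n_solv),
                           bin_width=0.1, r_max=5.5)
        far = res.bin_centers > 4.0
        assert res.g[far].mean() == pytest.approx(1.0, abs=0.03)

    def test_generated_tails_inside_heads(self, sphere_micelle):
        """Terminal tail atoms peak closer to the COM than head atoms."""
        mic = sphere_micelle.select(species="Surf")
        heads = sphere_micelle.select(atom_name="S1")
        tails = sphere_micelle.select(atom_name="C12")
        g_h = rdf_from_com(sphere_micelle, mic, heads, bin_width=0.05, r_max=2.5)
        g_t = rdf_from_com(sphere_micelle, mic, tails, bin_width=0.05, r_max=2.5)
        peak_h = g_h.bin_centers[np.argmax(g_h.g)]
        peak_t = g_t.bin_centers[np.argmax(g_t.g)]
        assert peak_t < peak_h

    def test_count_conservation(self, make_point_traj):
        n, box = 200, 6.0
        traj = gas_traj(make_point_traj, n, box, seed=31)
        res = rdf_from_com(traj, [0], np.arange(1, n), bin_width=0.05, r_max=2.9)
        fr = traj.frames[0]
        oracle = count_pairs_in_range(fr.coords[[0]], fr.coords[1:], fr.box,
                                      res.r_max)
        assert int(res.counts.sum()) == oracle
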