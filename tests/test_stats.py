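"""Statistics harvesting: codebook, collectors, clustering, radii."""

import numpy as np
import pytest

from briq import chem, stats
from briq import fixtures as fx
from briq.structure import BaseResidue, RnaStructure


def _min_nn_angle_deg(vectors):
    dots = vectors @ vectors.T
    np.fill_diagonal(dots, -1.0)
    return np.degrees(np.arccos(np.clip(dots.max(axis=1), -1, 1))).min()


class TestSphereCodebook:
    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            stats.generate_sphere_codebook(2, seed=0)

    def test_four_points_form_tetrahedron(self):
        v = stats.generate_sphere_codebook(4, seed=0).vectors
        angles = np.degrees(np.arccos(np.clip(
            (v @ v.T)[np.triu_indices(4, 1)], -1, 1
        )))
        assert np.allclose(angles, 109.4712, atol=2.0)

    def test_six_points_form_octahedron(self):
        v = stats.generate_sphere_codebook(6, seed=0).vectors
        angles = np.degrees(np.arccos(np.clip(
            (v @ v.T)[np.triu_indices(6, 1)], -1, 1
        )))
        # octahedron: 12 right angles, 3 antipodal pairs
        assert np.sum(np.abs(angles - 90.0) < 2.0) == 12
        assert np.sum(angles > 178.0) == 3

    def test_annealed_energy_beats_random(self, rng):
        n = 64
        opt = stats.generate_sphere_codebook(n, seed=0).vectors
        rand = rng.normal(size=(n, 3))
        rand /= np.linalg.norm(rand, axis=1, keepdims=True)
        assert stats.codebook_energy(opt) < stats.codebook_energy(rand)

    def test_large_codebook_packing_density(self):
        """Minimal nearest-neighbour angle of the 2000-point codebook
        within [0.8, 1.2] of the uniform-packing estimate."""
        v = stats.generate_sphere_codebook(2000, seed=0).vectors
        ideal = np.degrees(2.0 / np.sqrt(2000 / np.pi))
        assert 0.8 * ideal <= _min_nn_angle_deg(v) <= 1.2 * ideal

    def test_nearest_lookup(self):
        cb = stats.generate_sphere_codebook(32, seed=0)
        for k in (0, 7, 31):
            assert cb.nearest(cb.vectors[k]) == k


class TestPairCollection:
    def test_counts_match_brute_force(self, gc_helix):
        lib = stats.collect_pair_observations([gc_helix])
        frames = [r.frame() for r in gc_helix]
        expected = 0
        for i in range(len(frames)):
            for j in range(len(frames)):
                if i == j:
                    continue
                d = np.linalg.norm(frames[j].origin - frames[i].origin)
                if d <= stats.PAIR_RANGE:
                    expected += 1
        assert len(lib) == expected

    def test_both_directions_recorded(self, gc_helix):
        lib = stats.collect_pair_observations([gc_helix])
        obs = lib.get("CG", "1")
        directions = {(o.base_i, o.base_j) for o in obs}
        assert directions == {("G", "C"), ("C", "G")}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            stats.collect_pair_observations([])

    def test_isolated_nucleotide_gives_empty_library(self):
        nt = chem.ideal_nucleotide("A")
        res = BaseResidue("A", 1, "A", dict(nt))
        lib = stats.collect_pair_observations(
            [RnaStructure([res], "single")]
        )
        assert len(lib) == 0

    def test_distant_pair_outside_range_cut(self):
        nt = dict(chem.ideal_nucleotide("A"))
        res1 = BaseResidue("A", 1, "A", nt)
        res2 = BaseResidue("B", 1, "A",
                           {k: v + np.array([20.0, 0, 0])
                            for k, v in nt.items()})
        lib = stats.collect_pair_observations(
            [RnaStructure([res1, res2], "far")]
        )
        assert len(lib) == 0

    def test_separation_classes(self, gc_helix):
        lib = stats.collect_pair_observations([gc_helix])
        for (ptype, sep), obs in lib.groups.items():
            assert sep in stats.SEP_CLASSES
        # stacked neighbours are separation 1; cross-strand pairs 2+
        assert len(lib.get("CG", "1")) > 0
        assert len(lib.get("CG", "2+")) > 0


class TestPolarCollection:
    def test_single_oxygen_above_base_plane(self):
        """One oxygen at a hand-chosen point: the recorded pseudo-atom
        distances must equal direct computation."""
        nt = dict(chem.ideal_nucleotide("G"))
        res = BaseResidue("A", 1, "G", nt)
        frame = res.frame()
        oxy_pos = frame.to_global(np.array([2.0, 1.0, 3.0]))
        other = BaseResidue("A", 5, "U", {
            "O2'": oxy_pos, "C2'": oxy_pos + np.array([1.4, 0, 0]),
        })
        lib = stats.collect_polar_observations(
            [RnaStructure([res, other], "toy")]
        )
        obs = [o for o in lib.base_oxygen.get(("G", "O2'"), [])]
        assert len(obs) == 1
        expected = np.linalg.norm(
            frame.pseudo_atoms() - oxy_pos[None], axis=1
        )
        assert np.allclose(obs[0].distances, expected, atol=1e-10)

    def test_out_of_range_oxygen_ignored(self):
        nt = dict(chem.ideal_nucleotide("G"))
        res = BaseResidue("A", 1, "G", nt)
        far = res.frame().to_global(np.array([0.0, 0.0, 30.0]))
        other = BaseResidue("A", 5, "U", {
            "O2'": far, "C2'": far + np.array([1.4, 0, 0]),
        })
        lib = stats.collect_polar_observations(
            [RnaStructure([res, other], "toy")]
        )
        assert ("G", "O2'") not in lib.base_oxygen

    def test_oo_distances_match_brute_force(self, gc_helix):
        lib = stats.collect_polar_observations([gc_helix])
        obs = lib.oxygen_oxygen.get("O2'-OP", [])
        assert obs, "ideal helix should show O2'-OP contacts"
        # verify one observation against direct recomputation
        res = {(r.chain_id, r.index): r for r in gc_helix}
        found = False
        for (ca, ra) in res:
            a = res[(ca, ra)]
            for (cb, rb) in res:
                b = res[(cb, rb)]
                if (ca, ra) >= (cb, rb):
                    continue
                d = np.linalg.norm(a.atoms["O2'"] - b.atoms["OP1"])
                if d <= stats.OXYGEN_OXYGEN_RANGE:
                    cfg = stats.oo_configuration(
                        a.atoms["C2'"], a.atoms["O2'"],
                        b.atoms["OP1"], b.atoms["P"],
                    )
                    match = [
                        o for o in obs
                        if np.allclose(o.distances, cfg, atol=1e-9)
                    ]
                    assert match
                    found = True
        assert found


class TestRotamersAndTorsions:
    def test_single_residue_corpus(self):
        nt = dict(chem.ideal_nucleotide("C"))
        res = BaseResidue("A", 1, "C", nt)
        lib = stats.collect_rotamers([RnaStructure([res], "one")])
        rots = lib.get("C")
        assert len(rots) == 1
        assert rots[0].weight == 1.0
        assert rots[0].atoms_local.shape == (8, 3)

    def test_helix_sugars_are_c3_endo(self, gc_helix):
        lib = stats.collect_rotamers([gc_helix])
        for bt in ("G", "C"):
            for rot in lib.get(bt):
                assert stats.nu_region(rot.nu) == 0

    def test_conditional_tables_normalised(self, corpus):
        structures, _ = corpus
        samples = stats.collect_torsion_samples(structures)
        tables = stats.build_torsion_tables(samples)
        assert np.allclose(tables.p_ez_nu.sum(axis=(1, 2)), 1.0)
        assert np.allclose(tables.p_a_zb.sum(axis=2), 1.0)
        assert np.allclose(tables.p_bg_nu.sum(axis=(1, 2)), 1.0)
        assert np.all(tables.p_ez_nu > 0)

    def test_chain_break_terminates_triples(self, tetraloop):
        broken = tetraloop.copy()
        # displace one phosphate far away: the step must be dropped
        broken.residues[4].atoms["P"] += np.array([50.0, 0.0, 0.0])
        n_ok = len(stats.collect_torsion_samples([tetraloop]).rows)
        n_broken = len(stats.collect_torsion_samples([broken]).rows)
        assert n_broken == n_ok - 1


class TestClashRadii:
    def test_percentile_oracle(self):
        values = [3.0 + 0.1 * k for k in range(20)]
        assert stats.percentile_r0(values) == pytest.approx(3.0)

    def test_unobserved_pair_uses_element_ceiling(self, table_set):
        assert table_set.clash.r0("ZZZ.O9", "QQQ.N9") == pytest.approx(
            stats.ELEMENT_R0_CAP[("N", "O")]
        )

    def test_bonded_neighbours_excluded(self, gc_helix):
        table = stats.estimate_r0([gc_helix])
        # P-OP1 is covalent (1.5 A); an estimate from nonbonded pairs
        # can never sit at covalent range
        assert table.r0("P", "OP") > 2.0

    def test_radii_positive_and_capped(self, table_set):
        for (ta, tb), r0 in table_set.clash.isotropic.items():
            assert r0 > 0
            assert table_set.clash.r0(ta, tb) <= \
                stats.element_r0_cap(ta, tb) + 1e-12


class TestOrientationClustering:
    @pytest.fixture(scope="class")
    def library(self, corpus):
        structures, annotations = corpus
        return stats.collect_pair_observations(structures[:4],
                                               annotations[:4])

    def test_too_few_observations_suggests_smaller_k(self, library):
        with pytest.raises(ValueError, match="use k"):
            stats.cluster_orientations(library, "CG", "2+", k=10 ** 6)

    def test_distinct_configurations_zero_objective(self):
        from briq.geometry import RelativeOrientation
        modes = [
            (RelativeOrientation(4.0 + k, 20.0 * k,
                                 np.array([0.0, 0, 1.0]),
                                 np.array([0.0, 1.0, 0])), 1.0 / 4, 0.0)
            for k in range(4)
        ]
        lib = stats.PairLibrary()
        for mode, _, _ in modes:
            single = fx.synthetic_pair_library("A", "U", [(mode, 1.0, 0.0)],
                                               1, seed=0)
            for o in single.all_observations():
                lib.add(o)
        cset = stats.cluster_orientations(lib, "AU", "2+", k=4, seed=0)
        assert cset.objective == pytest.approx(0.0, abs=1e-9)

    def test_planted_clusters_recovered(self):
        from briq.geometry import RelativeOrientation
        m1 = RelativeOrientation(4.0, 10.0, np.array([0.0, 0, 1.0]),
                                 np.array([0.0, 1.0, 0]))
        m2 = RelativeOrientation(12.0, -60.0, np.array([1.0, 0, 0.0]),
                                 np.array([0.0, 0, 1.0]))
        lib = fx.synthetic_pair_library(
            "A", "U", [(m1, 0.5, 0.05), (m2, 0.5, 0.05)], 200, seed=3
        )
        cset = stats.cluster_orientations(lib, "AU", "2+", k=2, seed=0)
        from briq.energy_bb import configuration_from_orientation
        centers = cset.center_dmats
        for mode in (m1, m2):
            target = configuration_from_orientation(
                "A", "U", mode
            ).dmat
            dists = [np.sqrt(np.mean((c - target) ** 2)) for c in centers]
            assert min(dists) < 0.3

    def test_objective_beats_random_assignment(self, library, rng):
        obs = library.get("CG", "2+")
        cset = stats.cluster_orientations(library, "CG", "2+",
                                          k=min(20, len(obs)), seed=0)
        dmats = np.array([o.canonical_dmat() for o in obs])
        idx = rng.choice(len(dmats), size=cset.k, replace=False)
        rand_obj = np.sqrt(np.mean([
            min(np.sqrt(np.mean((d - dmats[c]) ** 2)) for c in idx) ** 2
            for d in dmats
        ]))
        assert cset.objective <= rand_obj + 1e-12


class TestMoveSets:
    def test_move_set_size_and_relaxation(self, corpus):
        structures, annotations = corpus
        lib = stats.collect_pair_observations(structures, annotations)
        ms = stats.build_move_set(lib, "wc-pair", seed=0, relax=True)
        assert ms.size == 3600
        assert ms.n_reps == 60
        with pytest.raises(ValueError, match="relax"):
            stats.build_move_set(lib, "wc-pair", seed=0, relax=False)

    def test_unknown_context_rejected(self, corpus):
        structures, annotations = corpus
        lib = stats.collect_pair_observations(structures[:1],
                                              annotations[:1])
        with pytest.raises(ValueError):
            stats.build_move_set(lib, "nwc-pair", seed=0, relax=True)
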