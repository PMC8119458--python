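"""Base-base kernel density, QM reweighting and the sparse 6D table."""

import numpy as np
import pytest

from briq import fixtures as fx
from briq import stats
from briq.energy_bb import (
    EnergyTable6D,
    build_bb_table,
    cell_center_orientation,
    cell_of,
    configuration_from_orientation,
    density_f,
    ebb_lookup,
    kernel_h,
    qm_weights,
)
from briq.geometry import RelativeOrientation


class TestKernel:
    @pytest.mark.parametrize("d,expected", [
        (0.10, 1.0),
        (0.15, 1.0),
        (0.25, np.exp(-0.5)),
        (0.35, np.exp(-2.0)),
    ])
    def test_values(self, d, expected):
        assert kernel_h(d) == pytest.approx(expected, rel=1e-12)

    def test_continuous_at_flat_top_edge(self):
        assert kernel_h(0.15 + 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            kernel_h(-0.1)


class TestDensity:
    def test_empty_library_is_zero(self):
        assert density_f(np.zeros((4, 4)), np.empty((0, 4, 4))) == 0.0

    def test_self_density_is_one(self, rng):
        d = np.abs(rng.normal(size=(4, 4)))
        assert density_f(d, d[None]) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        dmats = np.abs(rng.normal(loc=5.0, size=(100, 4, 4)))
        weights = rng.uniform(0.5, 2.0, size=100)
        query = np.abs(rng.normal(loc=5.0, size=(4, 4)))
        expected = 0.0
        for w, m in zip(weights, dmats):
            dd = np.sqrt(np.mean((query - m) ** 2))
            expected += w * (1.0 if dd <= 0.15
                             else np.exp(-0.5 * ((dd - 0.15) / 0.1) ** 2))
        assert density_f(query, dmats, weights) == pytest.approx(
            expected, abs=1e-10
        )


class TestQmWeights:
    @pytest.fixture(scope="class")
    def clustered_library(self):
        m1 = RelativeOrientation(5.0, 30.0, np.array([0.0, 0, 1.0]),
                                 np.array([0.0, 1.0, 0]))
        m2 = RelativeOrientation(11.0, -40.0, np.array([1.0, 0, 0.0]),
                                 np.array([0.0, 0, 1.0]))
        lib = fx.synthetic_pair_library(
            "G", "C", [(m1, 0.5, 0.05), (m2, 0.5, 0.05)], 120, seed=4
        )
        cset = stats.cluster_orientations(lib, "CG", "2+", k=2, seed=0)
        return lib, cset

    def test_zero_energy_unit_density_gives_unit_weight(
            self, clustered_library):
        lib, cset = clustered_library
        obs = lib.get("CG", "2+")
        qm = stats.QMTable({"CG": np.zeros(2)})
        w = qm_weights(obs, cset, qm)
        dmats = np.array([o.canonical_dmat() for o in obs])
        f0 = density_f(cset.center_dmats[cset.nearest_center(
            obs[0].canonical_dmat()
        )], dmats)
        assert w[0] == pytest.approx(1.0 / f0)

    def test_more_negative_qm_energy_raises_weight(self, clustered_library):
        lib, cset = clustered_library
        obs = lib.get("CG", "2+")
        w1 = qm_weights(obs, cset, stats.QMTable({"CG": np.zeros(2)}))
        w2 = qm_weights(obs, cset,
                        stats.QMTable({"CG": -4.32 * np.ones(2)}))
        assert np.all(w2 > w1)
        assert np.allclose(w2 / w1, np.e)

    def test_size_mismatch_rejected(self, clustered_library):
        lib, cset = clustered_library
        with pytest.raises(ValueError, match="size"):
            qm_weights(lib.get("CG", "2+"), cset,
                       stats.QMTable({"CG": np.zeros(5)}))


class TestTableBuild:
    def test_fixture_table_minima_and_sign(self, table_set):
        for (ptype, sep), table in table_set.bb.items():
            if table.n_stored() == 0:
                continue
            target = -8.0 if sep == "2+" else -4.0
            assert table.min_value() == pytest.approx(target, abs=1e-9)
            assert max(
                v for plane in table.cells.values()
                for v in plane.values()
            ) <= 0.0

    def test_planted_mode_is_table_argmin(self, table_set):
        # r chosen inside a radial bin (6.1 -> bin 20, center 6.15)
        mode = RelativeOrientation(6.1, 45.0, np.array([0.0, 0, 1.0]),
                                   np.array([1.0, 0, 0.0]))
        lib = fx.synthetic_pair_library("A", "U", [(mode, 1.0, 0.08)],
                                        400, seed=5)
        table = build_bb_table(lib, "AU", "2+", table_set.codebook)
        best_cell, best_val = None, 0.0
        for (idij, idji), plane in table.cells.items():
            for (ir, iw), v in plane.items():
                if v < best_val:
                    best_val, best_cell = v, (ir, iw, idij, idji)
        assert best_val == pytest.approx(-8.0, abs=1e-9)
        # the argmin cell's representative configuration sits within a
        # cell diagonal (DDM) of the generative mode
        from briq.geometry import ddm_matrices
        rep = cell_center_orientation(best_cell, table_set.codebook)
        rep_cfg = configuration_from_orientation("A", "U", rep)
        mode_cfg = configuration_from_orientation("A", "U", mode)
        assert ddm_matrices(rep_cfg.dmat, mode_cfg.dmat) < 0.8

    def test_empty_library_gives_empty_table(self, table_set):
        table = build_bb_table(stats.PairLibrary(), "AU", "1",
                               table_set.codebook)
        assert table.n_stored() == 0

    def test_mode_depth_recovery_after_normalisation(self, table_set):
        """With uniform weights and a 9:1 two-mode library, the
        negative-log density recovers the relative mode depths (ln 9)
        after f_ref normalisation, which cancels in the difference."""
        m1 = RelativeOrientation(5.0, 30.0, np.array([0.0, 0, 1.0]),
                                 np.array([0.0, 1.0, 0]))
        m2 = RelativeOrientation(11.0, -40.0, np.array([1.0, 0, 0.0]),
                                 np.array([0.0, 0, 1.0]))
        lib = fx.synthetic_pair_library(
            "A", "U", [(m1, 0.9, 0.04), (m2, 0.1, 0.04)], 4000, seed=6
        )
        dmats = np.array([o.canonical_dmat() for o in lib.get("AU", "2+")])
        f1 = density_f(configuration_from_orientation("A", "U", m1).dmat,
                       dmats)
        f2 = density_f(configuration_from_orientation("A", "U", m2).dmat,
                       dmats)
        assert -np.log(f2 / f1) == pytest.approx(np.log(9.0), abs=0.1)


class TestLookup:
    @pytest.fixture(scope="class")
    def table(self, table_set):
        return table_set.bb[("CG", "2+")], table_set.codebook

    def test_grid_node_consistency(self, table):
        table6d, codebook = table
        (idij, idji), plane = next(iter(table6d.cells.items()))
        (ir, iw), value = next(iter(plane.items()))
        rel = cell_center_orientation((ir, iw, idij, idji), codebook)
        got = table6d.lookup(rel, codebook)
        assert got == pytest.approx(value, abs=1e-9)

    def test_out_of_range_returns_zero(self, table):
        table6d, codebook = table
        rel = RelativeOrientation(20.0, 0.0, codebook.vectors[0],
                                  codebook.vectors[1])
        assert table6d.lookup(rel, codebook) == 0.0

    def test_radial_midpoint_interpolates_linearly(self, table_set):
        codebook = table_set.codebook
        table = EnergyTable6D("A", "U", "2+", len(codebook))
        table.store((10, 5, 3, 4), -2.0)
        table.store((11, 5, 3, 4), -4.0)
        rel_mid = cell_center_orientation((10, 5, 3, 4), codebook)
        rel_mid = RelativeOrientation(rel_mid.r + 0.15, rel_mid.omega,
                                      rel_mid.dir_ij, rel_mid.dir_ji)
        assert table.lookup(rel_mid, codebook) == pytest.approx(-3.0)

    def test_lookup_continuous_in_r(self, table):
        table6d, codebook = table
        (idij, idji), plane = next(iter(table6d.cells.items()))
        (ir, iw), _ = next(iter(plane.items()))
        base = cell_center_orientation((ir, iw, idij, idji), codebook)
        values = [
            table6d.lookup(
                RelativeOrientation(base.r + dr, base.omega,
                                    base.dir_ij, base.dir_ji), codebook
            )
            for dr in np.linspace(-0.01, 0.01, 9)
        ]
        assert np.max(np.abs(np.diff(values))) < 0.1

    def test_order_canonicalisation(self, table_set):
        """Looking up an ordered (G,C) observation equals looking up the
        swapped (C,G) observation in the same canonical table."""
        helix = fx.ideal_helix("GCGCGCGC")
        f1 = helix.residues[0].frame()
        f2 = helix.residues[15].frame()
        from briq.geometry import relative_orientation
        table = table_set.bb[("CG", "2+")]
        e_gc = ebb_lookup(table, relative_orientation(f1, f2),
                          table_set.codebook, "G", "C")
        e_cg = ebb_lookup(table, relative_orientation(f2, f1),
                          table_set.codebook, "C", "G")
        assert e_gc == pytest.approx(e_cg, abs=1e-9)
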