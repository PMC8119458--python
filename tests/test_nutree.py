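"""NuTree construction, moves, phosphate closure, annealing."""

import numpy as np
import pytest

from briq import chem, nutree, stats
from briq import fixtures as fx
from briq.energy_local import RotamerEnergy, internal_energy_batch
from briq.geometry import superpose_rmsd
from briq.pairing import PairingAnnotation, PairingError
from briq.scoring import Scorer
from briq.structure import BaseResidue, RnaStructure


class TestTreeConstruction:
    def test_gcaa_tetraloop_example(self, tetraloop, tetraloop_annotation):
        """The canonical 8-mer: G0 C1 G2 C3 A4 A5 G6 C7 with WC pairs
        (0,7),(1,6) and the non-WC pair (2,5) yields the documented
        edge typing; 4-5 stays connected only through its phosphate."""
        tree = nutree.build_nutree(tetraloop_annotation, tetraloop)
        typed = {(e.parent, e.child): e.edge_type for e in tree.edges}
        assert typed[(0, 1)] == "wc-nb-53"
        assert typed[(1, 2)] == "nwc-nb"
        assert typed[(2, 3)] == "loop-nb-53"
        assert typed[(3, 4)] == "loop-nb-53"
        assert typed[(0, 7)] == "wc-pair"
        assert typed[(1, 6)] == "wc-pair"
        assert typed[(2, 5)] == "nwc-pair"
        assert (4, 5) not in typed and (5, 4) not in typed
        assert len(tree.edges) == 7

    def test_unpaired_trimer_is_a_chain_of_loop_edges(self):
        ann = PairingAnnotation("AAA")
        tree = nutree.build_nutree(ann)
        assert [e.edge_type for e in tree.edges] == ["loop-nb-53"] * 2

    def test_pseudoknot_keeps_both_pair_edges(self):
        # two crossing WC pairs on an 8-mer
        ann = PairingAnnotation("GGAACCUU",
                                wc_pairs=[(0, 4), (2, 6)])
        tree = nutree.build_nutree(ann)
        types = [(e.parent, e.child, e.edge_type) for e in tree.edges]
        pair_edges = [t for t in types if t[2] == "wc-pair"]
        assert {frozenset(t[:2]) for t in pair_edges} == {
            frozenset({0, 4}), frozenset({2, 6})
        }
        # spanning tree over 8 nodes: exactly 7 edges, connected
        assert len(tree.edges) == 7
        assert tree.subtree(tree.root) == set(range(8))

    def test_conflicting_pairing_rejected(self):
        with pytest.raises(PairingError):
            PairingAnnotation("GGCC", [(0, 3), (1, 3)])

    def test_root_anchors_longest_helix(self, tetraloop_annotation):
        tree = nutree.build_nutree(tetraloop_annotation)
        assert tree.root == 0

    def test_edge_counts_for_step_formula(self, tetraloop,
                                          tetraloop_annotation):
        tree = nutree.build_nutree(tetraloop_annotation, tetraloop)
        assert tree.edge_counts() == {"wc": 3, "nwc": 2, "other": 2}


class TestMoveSets:
    def test_exactly_3600_leaves(self, table_set):
        for edge_type, ms in table_set.move_sets.items():
            assert ms.size == 3600

    def test_planted_modes_reach_top_level(self):
        from briq.geometry import RelativeOrientation
        m1 = RelativeOrientation(4.5, 20.0, np.array([0.0, 0, 1.0]),
                                 np.array([0.0, 1.0, 0]))
        m2 = RelativeOrientation(12.0, -90.0, np.array([1.0, 0, 0.0]),
                                 np.array([0.0, 0, 1.0]))
        lib = fx.synthetic_pair_library(
            "G", "C", [(m1, 0.5, 0.05), (m2, 0.5, 0.05)], 400, seed=8
        )
        for o in lib.all_observations():
            o.context = "wc-pair"
        ms = stats.build_move_set(lib, "wc-pair", seed=0, relax=True)
        probes = stats._MOVE_METRIC_POINTS
        top = np.array([t.apply(probes) for t in ms.representatives])
        from briq.geometry import BaseFrame, reconstruct_frame
        identity = BaseFrame(np.zeros(3), np.eye(3))
        for mode in (m1, m2):
            frame = reconstruct_frame(identity, mode)
            target = frame.as_transform().apply(probes)
            d = np.sqrt(np.mean(np.sum((top - target[None]) ** 2,
                                       axis=-1), axis=-1))
            assert d.min() < 0.5


@pytest.fixture()
def state(tetraloop, tetraloop_annotation, table_set):
    tree = nutree.build_nutree(tetraloop_annotation, tetraloop)
    return nutree.RefinementState(tetraloop, tree, table_set)


class TestMoves:
    def test_node_move_locality(self, state, rng):
        before = {
            k: state.structure.residues[k].copy()
            for k in range(state.n)
        }
        move = state.propose_node_rotamer(3, rng)
        move.commit()
        # only residues 3 (ribose) and 4 (its phosphate group) change
        for k in range(state.n):
            res = state.structure.residues[k]
            for name, coord in res.atoms.items():
                if k == 3 and name in chem.RIBOSE_ATOMS:
                    continue
                if k in (3, 4) and name in chem.PHOSPHATE_ATOMS:
                    continue
                assert np.array_equal(coord, before[k].atoms[name]), \
                    (k, name)

    def test_node_jitter_moves_rigidly(self, state, rng):
        before = state.structure.residues[2].copy()
        move = state.propose_node_jitter(2, rng)
        move.commit()
        after = state.structure.residues[2]
        names = [n for n in before.atoms if n not in chem.PHOSPHATE_ATOMS]
        a = np.array([before.atoms[n] for n in names])
        b = np.array([after.atoms[n] for n in names])
        assert superpose_rmsd(a, b) < 1e-9
        shift = np.linalg.norm(b - a, axis=1).max()
        assert 0.0 < shift < 0.5

    def test_edge_move_subtree_rigidity(self, state, rng):
        tree = state.tree
        edge = next(e for e in tree.edges if e.edge_type == "nwc-pair")
        moved = tree.subtree(edge.child)
        before = {
            k: np.array([state.structure.residues[k].atoms[n]
                         for n in sorted(state.structure.residues[k].atoms)
                         if n not in chem.PHOSPHATE_ATOMS])
            for k in moved
        }
        move = state.propose_edge_move(edge, rng, global_move=True)
        move.commit()
        after = {
            k: np.array([state.structure.residues[k].atoms[n]
                         for n in sorted(state.structure.residues[k].atoms)
                         if n not in chem.PHOSPHATE_ATOMS])
            for k in moved
        }
        all_before = np.vstack([before[k] for k in sorted(moved)])
        all_after = np.vstack([after[k] for k in sorted(moved)])
        assert superpose_rmsd(all_before, all_after) < 1e-9

    def test_jump_edge_has_no_global_moves(self, table_set):
        nt = dict(chem.ideal_nucleotide("A"))
        far = {k: v + np.array([30.0, 0, 0]) for k, v in nt.items()}
        struct = RnaStructure([
            BaseResidue("A", 1, "A", nt), BaseResidue("B", 1, "A", far),
        ])
        ann = PairingAnnotation("AA")
        tree = nutree.build_nutree(ann, struct)
        assert tree.edges[0].edge_type == nutree.JUMP
        st = nutree.RefinementState(struct, tree, table_set)
        with pytest.raises(ValueError, match="jump"):
            st.propose_edge_move(tree.edges[0], np.random.default_rng(0),
                                 global_move=True)

    def test_incremental_matches_full_recompute(self, state, table_set,
                                                rng):
        """1000 random moves: incremental delta-E equals the difference
        of full recomputations to 1e-6."""
        scorer = Scorer(table_set)
        worst = 0.0
        n_checked = 0
        for it in range(1000):
            r = rng.uniform()
            if r < 0.35:
                move = state.propose_node_rotamer(
                    int(rng.integers(state.n)), rng
                )
            elif r < 0.7:
                move = state.propose_node_jitter(
                    int(rng.integers(state.n)), rng
                )
            else:
                edge = state.tree.edges[
                    int(rng.integers(len(state.tree.edges)))
                ]
                use_global = (edge.edge_type in table_set.move_sets
                              and rng.uniform() < 0.5)
                move = state.propose_edge_move(edge, rng, use_global)
            if move is None:
                continue
            de = move.delta_energy()
            before = state.total()
            move.commit()
            worst = max(worst, abs((state.total() - before) - de))
            n_checked += 1
            if it % 200 == 0:
                full = scorer.score(state.structure, state.weights).total
                worst = max(worst, abs(full - state.total()))
        assert n_checked > 900
        assert worst < 1e-6


class TestPhosphateClosure:
    def test_exactly_125_evaluations(self, gc_helix, table_set):
        rebuild = nutree.rebuild_phosphate(
            gc_helix.residues[0], gc_helix.residues[1], table_set
        )
        assert rebuild.n_evaluations == 125

    def test_helix_phosphate_rebuilt_close_to_fixture(self, gc_helix,
                                                      table_set):
        a, b = gc_helix.residues[2], gc_helix.residues[3]
        rebuild = nutree.rebuild_phosphate(a, b, table_set)
        assert not rebuild.failed
        assert np.linalg.norm(
            rebuild.atoms["P"] - b.atoms["P"]
        ) < 0.3

    def test_near_exhaustive_optimality(self, table_set, rng):
        """Hierarchical search vs the exhaustive 1-degree grid (129,600
        evaluations) on move-scale ribose displacements: within 5% for
        at least 19 of 20 placements and never more than 15% above."""
        helix = fx.ideal_helix("GCGCGCGC")
        grid_e, grid_z = np.meshgrid(
            np.arange(-180.0, 180.0, 1.0), np.arange(-180.0, 180.0, 1.0)
        )
        eps_all = grid_e.ravel()
        zeta_all = grid_z.ravel()
        ratios = []
        for trial in range(20):
            i = int(rng.integers(7))
            a = helix.residues[i].copy()
            b = helix.residues[i + 1].copy()
            shift = rng.normal(scale=0.2, size=3)
            for name in b.atoms:
                b.atoms[name] = b.atoms[name] + shift
            rebuild = nutree.rebuild_phosphate(a, b, table_set)
            exhaustive = internal_energy_batch(
                a.atoms, b.atoms, eps_all, zeta_all, table_set.torsion
            ).min()
            ratios.append(rebuild.energy / exhaustive)
        ratios = np.array(ratios)
        assert np.sum(ratios <= 1.05 + 1e-9) >= 19
        assert ratios.max() <= 1.15

    def test_unreachable_closure_flagged(self, gc_helix, table_set):
        a = gc_helix.residues[0].copy()
        b = gc_helix.residues[1].copy()
        for name in b.atoms:
            b.atoms[name] = b.atoms[name] + np.array([20.0, 0, 0])
        rebuild = nutree.rebuild_phosphate(a, b, table_set)
        assert rebuild.failed
        assert rebuild.energy > nutree.CLOSURE_PENALTY


class TestAnnealing:
    def test_schedule_temperatures_and_steps(self):
        sched = nutree.AnnealSchedule.prediction()
        temps = sched.temperatures()
        assert temps[0] == 2.5
        assert temps[-1] >= 0.01
        assert all(b == pytest.approx(a * 0.95)
                   for a, b in zip(temps[:-1], temps[1:]))
        counts = {"wc": 3, "nwc": 2, "other": 2}
        assert nutree.AnnealSchedule.refinement().steps_per_round(counts) \
            == 400 * 3 + 2000 * 2 + 4000 * 2

    def test_weight_ramp_range(self):
        sched = nutree.AnnealSchedule.refinement()
        n = len(sched.temperatures())
        ws = [sched.ramp_weight(i, n) for i in range(n)]
        assert ws[0] == pytest.approx(0.05)
        assert ws[-1] == pytest.approx(1.0)
        assert np.all(np.diff(ws) >= 0)

    def test_zero_temperature_limit_is_greedy(self, state, rng):
        """As T -> 0 the Metropolis rule accepts only non-increasing
        moves, so the running energy is monotone non-increasing."""
        temp = 1e-9
        totals = [state.total()]
        for _ in range(60):
            move = state.propose_node_jitter(int(rng.integers(state.n)),
                                             rng)
            if move is None:
                continue
            de = move.delta_energy()
            if de <= 0 or rng.uniform() < np.exp(-de / temp):
                move.commit()
                totals.append(state.total())
        assert len(totals) > 1
        assert np.all(np.diff(totals) <= 1e-9)

    def test_deterministic_trajectory(self, tetraloop,
                                      tetraloop_annotation, table_set):
        sched = nutree.AnnealSchedule.refinement(steps_scale=0.0002)
        tree = nutree.build_nutree(tetraloop_annotation, tetraloop)
        r1 = nutree.anneal(tetraloop, tree, table_set, sched, seed=11)
        r2 = nutree.anneal(tetraloop, tree, table_set, sched, seed=11)
        assert r1.best_energy == r2.best_energy
        assert np.array_equal(r1.best_structure.coords(),
                              r2.best_structure.coords())

    def test_two_state_boltzmann_occupancy(self, table_set):
        """Fixed-temperature Metropolis over a two-rotamer system
        reproduces the Boltzmann occupancy ratio within 3 sigma."""
        nt = dict(chem.ideal_nucleotide("A"))
        far = {k: v + np.array([40.0, 0, 0]) for k, v in nt.items()}
        struct = RnaStructure([
            BaseResidue("A", 1, "A", nt), BaseResidue("B", 1, "A", far),
        ])
        ann = PairingAnnotation("AA")
        tree = nutree.build_nutree(ann, struct)

        import copy
        tables = copy.copy(table_set)
        a_loc = np.array([chem.ideal_nucleotide("A")[n]
                          for n in chem.RIBOSE_ATOMS])
        b_loc = a_loc.copy()
        b_loc[chem.RIBOSE_ATOMS.index("O2'")] += np.array([0.0, 0.0, 1.5])
        tables.rotamers = dict(table_set.rotamers)
        tables.rotamers["A"] = RotamerEnergy(
            "A", np.array([a_loc, b_loc]), np.array([0.7, 0.3])
        )
        st = nutree.RefinementState(struct, tree, tables)
        rng = np.random.default_rng(17)

        # measure the two state energies exactly
        def set_state(which):
            sample = tables.rotamers["A"].samples[which]
            frame = st.views[0].frame
            res = st.structure.residues[0].copy()
            for name, local in zip(chem.RIBOSE_ATOMS, sample):
                res.atoms[name] = frame.to_global(local)
            mv = nutree.Move(st, {0: res}, set(), {0}, set())
            mv.commit()

        set_state(0)
        e0 = st.total()
        set_state(1)
        e1 = st.total()
        set_state(0)
        temp = 1.0
        ratio = np.exp(-(e1 - e0) / temp)
        p1 = ratio / (1.0 + ratio)

        def which_state():
            o2 = st.structure.residues[0].atoms["O2'"]
            frame = st.views[0].frame
            d0 = np.linalg.norm(
                frame.to_global(tables.rotamers["A"].samples[0][
                    chem.RIBOSE_ATOMS.index("O2'")]) - o2
            )
            return 0 if d0 < 0.5 else 1

        # drive the chain through the sampler's own moves and delta-E
        n_steps = 1500
        occ1 = 0
        for _ in range(n_steps):
            move = st.propose_node_rotamer(0, rng)
            de = move.delta_energy()
            if de <= 0 or rng.uniform() < np.exp(-de / temp):
                move.commit()
            occ1 += which_state()
        sigma = np.sqrt(p1 * (1 - p1) / n_steps)
        assert abs(occ1 / n_steps - p1) < 3 * sigma

    def test_refinement_reduces_energy_of_decoy(
            self, tetraloop, tetraloop_annotation, table_set):
        decoy = fx.perturb_structure(tetraloop, 1.0, seed=42)
        tree = nutree.build_nutree(tetraloop_annotation, decoy)
        sched = nutree.AnnealSchedule.refinement(steps_scale=0.0008)
        scorer = Scorer(table_set)
        start = scorer.score(decoy).total
        result = nutree.anneal(decoy, tree, table_set, sched, seed=5)
        assert result.best_energy < start
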