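"""Clash, rotamer, internal energies and whole-structure assembly."""

import numpy as np
import pytest

from briq import chem, stats
from briq import fixtures as fx
from briq.energy_local import (
    ClashParams,
    RotamerEnergy,
    eclash,
    erot,
    etorsion,
    internal_energy_batch,
    softened_harmonic,
    step_internal_energy,
)
from briq.scoring import EnergyWeights, ResidueView, Scorer
from briq.structure import BaseResidue, RnaStructure


class TestClash:
    R0 = 3.0

    def test_zero_beyond_radius(self):
        assert eclash(self.R0 + 0.1, self.R0) == 0.0

    def test_plateau_value(self):
        # (k_clash * 0.4)^4 with k_clash = 3
        assert eclash(self.R0 - 0.2, self.R0) == pytest.approx(1.2 ** 4)
        assert 1.2 ** 4 == pytest.approx(2.0736)

    def test_linear_branch_joins_plateau_continuously(self):
        eps = 1e-9
        below = eclash(self.R0 - 0.4 - eps, self.R0)
        plateau = eclash(self.R0 - 0.4 + eps, self.R0)
        assert abs(below - plateau) < 1e-6

    def test_monotone_nonincreasing(self):
        ds = np.linspace(0.05, self.R0 + 1.0, 300)
        es = [eclash(float(d), self.R0) for d in ds]
        assert np.all(np.diff(es) <= 1e-12)

    def test_k_clash_range_enforced(self):
        with pytest.raises(ValueError):
            ClashParams(k_clash=7.0)
        for k in (2.0, 3.5, 5.0):
            ClashParams(k_clash=k)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            eclash(0.0, self.R0)


class TestSoftenedHarmonic:
    @pytest.mark.parametrize("u,expected", [
        (0.0, 0.0), (1.0, 1.0), (1.5, 2.0), (-1.0, 1.0), (-2.0, 3.0),
    ])
    def test_values(self, u, expected):
        assert softened_harmonic(u) == pytest.approx(expected)

    def test_slope_continuity_at_one(self):
        h = 1e-7
        left = (softened_harmonic(1.0) - softened_harmonic(1.0 - h)) / h
        right = (softened_harmonic(1.0 + h) - softened_harmonic(1.0)) / h
        assert left == pytest.approx(2.0, abs=1e-5)
        assert right == pytest.approx(2.0, abs=1e-5)


class TestRotamerEnergy:
    def _two_state(self, w_dense=0.9):
        a = np.array(
            [chem.ideal_nucleotide("A")[n] for n in chem.RIBOSE_ATOMS]
        )
        b = a + np.array([3.0, 0.0, 0.0])
        return RotamerEnergy("A", np.array([a, b]),
                             np.array([w_dense, 1.0 - w_dense])), a, b

    def test_densest_conformer_scores_zero(self):
        energy, a, b = self._two_state()
        assert erot(a, energy) == pytest.approx(0.0, abs=1e-9)

    def test_nonnegative_everywhere(self, rng):
        energy, a, b = self._two_state()
        for _ in range(20):
            x = a + rng.normal(scale=0.3, size=a.shape)
            assert erot(x, energy) >= 0.0

    def test_weight_ratio_gives_log_gap(self):
        """9:1 two-conformer library: energy gap ln 9 in the
        narrow-kernel (well-separated modes) limit."""
        energy, a, b = self._two_state(w_dense=0.9)
        gap = erot(b, energy) - erot(a, energy)
        assert gap == pytest.approx(np.log(9.0), abs=1e-6)


class TestTorsionEnergy:
    def test_uniform_tables_are_flat(self):
        uniform = stats.TorsionTables(
            np.full((2, 36, 36), 1.0 / 36 ** 2),
            np.full((36, 36, 36), 1.0 / 36),
            np.full((2, 36, 36), 1.0 / 36 ** 2),
        )
        vals = {
            etorsion((-35.0, eps, zeta, -68.0, 178.0, 54.0, -35.0), uniform)
            for eps in (-150.0, 10.0, 120.0)
            for zeta in (-70.0, 30.0)
        }
        assert len(vals) == 1

    def test_helix_step_is_the_conditional_mode(self, corpus):
        structures, _ = corpus
        helix = structures[0]
        samples = stats.collect_torsion_samples([helix])
        tables = stats.build_torsion_tables(samples)
        (nu_i, eps, zeta, alpha, beta, gamma, nu_ip1) = samples.rows[0]
        region = stats.nu_region(nu_i)
        slice_ez = tables.p_ez_nu[region]
        assert slice_ez[stats.torsion_bin(eps), stats.torsion_bin(zeta)] \
            == slice_ez.max()

    def test_smoothing_keeps_everything_finite(self, table_set, rng):
        for _ in range(50):
            angles = tuple(rng.uniform(-180, 180, size=7))
            assert np.isfinite(etorsion(angles, table_set.torsion))


class TestStepInternal:
    def test_native_step_near_torsion_baseline(self, table_set, gc_helix):
        """The ideal helix has relaxed bond/angle terms, so its step
        energy is dominated by the (smoothed) torsion baseline."""
        e = step_internal_energy(gc_helix.residues[0],
                                 gc_helix.residues[1], table_set.torsion)
        assert np.isfinite(e)
        # bond/angle contributions at ideal geometry are tiny
        from briq.energy_local import ebond
        bl = np.linalg.norm(
            gc_helix.residues[1].atoms["O5'"]
            - gc_helix.residues[1].atoms["C5'"]
        )
        assert ebond(float(bl)) < 0.05

    def test_batch_evaluator_matches_direct(self, table_set, gc_helix):
        """Placing the phosphate at its own observed eps/zeta via the
        batch evaluator reproduces the directly measured step energy."""
        from briq.geometry import dihedral

        a = gc_helix.residues[0]
        b = gc_helix.residues[1].copy()
        eps = dihedral(a.atoms["C2'"], a.atoms["C3'"], a.atoms["O3'"],
                       b.atoms["P"])
        zeta = dihedral(a.atoms["C3'"], a.atoms["O3'"], b.atoms["P"],
                        b.atoms["O5'"])
        group = chem.place_phosphate_group(a.atoms, b.atoms["C5'"],
                                           eps, zeta)
        for name, coord in group.items():
            b.atoms[name] = coord
        direct = step_internal_energy(a, b, table_set.torsion)
        batch = float(internal_energy_batch(
            a.atoms, b.atoms, [eps], [zeta], table_set.torsion
        )[0])
        assert batch == pytest.approx(direct, abs=1e-6)


class TestTotalEnergy:
    def test_single_nucleotide_terms(self, table_set):
        nt = dict(chem.ideal_nucleotide("A"))
        struct = RnaStructure([BaseResidue("A", 1, "A", nt)], "one")
        out = Scorer(table_set).score(struct)
        assert out.e_bb == 0.0
        assert out.e_bo == 0.0
        assert out.e_oo == 0.0
        assert out.e_internal == 0.0
        assert out.e_rot >= 0.0
        assert out.e_clash >= 0.0

    def test_distant_nucleotides_do_not_interact(self, table_set):
        nt = dict(chem.ideal_nucleotide("A"))
        far = {k: v + np.array([40.0, 0, 0]) for k, v in nt.items()}
        struct = RnaStructure([
            BaseResidue("A", 1, "A", nt), BaseResidue("B", 1, "A", far),
        ], "pair")
        scorer = Scorer(table_set)
        combined = scorer.score(struct)
        lone = scorer.score(RnaStructure([BaseResidue("A", 1, "A", nt)]))
        assert combined.e_bb == 0.0
        assert combined.e_bo == 0.0
        assert combined.e_oo == 0.0
        assert combined.e_rot == pytest.approx(2 * lone.e_rot)

    def test_total_equals_term_resummation(self, table_set, tetraloop):
        """Bookkeeping oracle: the breakdown equals an independent
        re-summation of per-pair and per-residue terms."""
        scorer = Scorer(table_set)
        out = scorer.score(tetraloop)
        views = [ResidueView(r) for r in tetraloop.residues]
        n = len(views)
        total = 0.0
        for i in range(n):
            total += scorer.rot_term(views[i])
            total += scorer.self_clash(views[i])
            for j in range(i + 1, n):
                part = scorer.pair_interaction(views[i], views[j])
                total += part.e_bb + part.e_bo + part.e_oo + part.e_clash
        for i in range(n - 1):
            total += scorer.internal_term(tetraloop.residues[i],
                                          tetraloop.residues[i + 1])
        assert out.total == pytest.approx(total, abs=1e-9)

    def test_weights_scale_clash_and_internal_only(self, table_set,
                                                   tetraloop):
        scorer = Scorer(table_set)
        full = scorer.score(tetraloop, EnergyWeights(1.0, 1.0))
        damped = scorer.score(tetraloop, EnergyWeights(0.05, 0.05))
        assert damped.e_bb == pytest.approx(full.e_bb)
        assert damped.e_clash == pytest.approx(0.05 * full.e_clash)
        assert damped.e_internal == pytest.approx(0.05 * full.e_internal)
        assert damped.e_rot == pytest.approx(full.e_rot)

    def test_breakdown_total_is_sum_of_parts(self, table_set, tetraloop):
        out = Scorer(table_set).score(tetraloop)
        parts = (out.e_bb + out.e_bo + out.e_oo + out.e_rot
                 + out.e_internal + out.e_clash)
        assert out.total == pytest.approx(parts, abs=1e-12)
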