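"""Total-energy assembly over a structure.

The total score is a sum of six families: base-base, base-oxygen,
oxygen-oxygen, ribose rotamer, internal (phosphate linkage) and clash.
Interactions decompose exactly over residue pairs, which is what makes
incremental Monte Carlo updates possible: the sampler recomputes
``pair_interaction`` only for residue pairs whose relative geometry a
move changed, plus the per-residue and per-step terms it touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import chem, energy_polar, stats
from .energy_bb import R_MAX, ebb_lookup
from .energy_local import (
    ClashParams,
    eclash,
    erot,
    step_internal_energy,
)
from .geometry import relative_orientation
from .structure import BaseResidue, RnaStructure

#: residue-pair gate: beyond this C1'-C1' distance no term can be nonzero
RESIDUE_PAIR_GATE = 22.0
#: atom-pair gate for clash evaluation (no r0 exceeds it)
CLASH_GATE = 4.0

#: cross-junction atom pairs within 3 covalent bonds (O3'(i)-P(i+1) link)
_JUNCTION_EXEMPT = frozenset({
    ("O3'", "P"), ("C3'", "P"), ("O3'", "O5'"), ("O3'", "OP1"),
    ("O3'", "OP2"), ("C2'", "P"), ("C4'", "P"), ("C3'", "O5'"),
    ("C3'", "OP1"), ("C3'", "OP2"), ("O3'", "C5'"),
})


@lru_cache(maxsize=None)
def _intra_residue_clash_pairs(base_type: str) -> tuple:
    """Atom-name pairs within one residue more than 3 bonds apart."""
    graph = chem.residue_bond_graph(base_type)
    names = sorted(graph)
    out = []
    for i, a in enumerate(names):
        dist = {a: 0}
        frontier = [a]
        for depth in range(1, stats.BOND_SEPARATION_EXEMPT + 1):
            nxt = []
            for node in frontier:
                for nb in graph.get(node, ()):
                    if nb not in dist:
                        dist[nb] = depth
                        nxt.append(nb)
            frontier = nxt
        for b in names[i + 1:]:
            if b not in dist:
                out.append((a, b))
    return tuple(out)


@dataclass
class EnergyWeights:
    """Term weights; clash and internal are ramped during annealing."""

    clash: float = 1.0
    internal: float = 1.0


@dataclass
class EnergyBreakdown:
    e_bb: float = 0.0
    e_bo: float = 0.0
    e_oo: float = 0.0
    e_rot: float = 0.0
    e_internal: float = 0.0
    e_clash: float = 0.0

    @property
    def total(self) -> float:
        return (self.e_bb + self.e_bo + self.e_oo + self.e_rot
                + self.e_internal + self.e_clash)

    def as_dict(self) -> dict[str, float]:
        return {
            "E_bb": self.e_bb, "E_bo": self.e_bo, "E_oo": self.e_oo,
            "E_rot": self.e_rot, "E_internal": self.e_internal,
            "E_clash": self.e_clash, "total": self.total,
        }


#: oxygen type codes for fast pair-class lookup
_OXY_CODE = {"OP": 0, "O2'": 1, "O3'": 2, "O4'": 3, "O5'": 4}
_OO_CLASS_BY_CODE = {
    (0, 0): "OP-OP", (0, 1): "O2'-OP", (1, 0): "O2'-OP", (1, 1): "O2'-O2'",
}


class ResidueView:
    """Geometry caches for one residue used by the pairwise terms."""

    __slots__ = ("res", "frame", "pseudo", "atom_names", "atom_xyz",
                 "atom_types", "heavy_xyz", "polar_xyz", "oxy_names",
                 "oxy_types", "oxy_codes", "oxy_xyz", "oxy_parent_xyz",
                 "ribose_local", "intra_pairs", "base_flags")

    def __init__(self, res: BaseResidue):
        self.res = res
        try:
            self.frame = res.frame()
        except Exception:  # noqa: BLE001 - frameless residues still clash
            self.frame = None
        self.pseudo = self.frame.pseudo_atoms() if self.frame else None
        self.atom_names = list(res.atoms)
        self.atom_xyz = np.array([res.atoms[n] for n in self.atom_names])
        self.atom_types = [chem.atom_type(res.base_type, n)
                           for n in self.atom_names]
        self.base_flags = [chem.is_base_atom(res.base_type, n)
                           for n in self.atom_names]
        heavy = [res.atoms[n] for n in chem.BASE_HEAVY_ATOMS[res.base_type]
                 if n in res.atoms]
        self.heavy_xyz = np.array(heavy) if heavy else np.zeros((0, 3))
        polar = [res.atoms[n] for n in chem.BASE_POLAR_ATOMS[res.base_type]
                 if n in res.atoms]
        self.polar_xyz = np.array(polar) if polar else np.zeros((0, 3))
        self.oxy_names, self.oxy_types, self.oxy_codes = [], [], []
        oxy, par = [], []
        for name, parent in stats.OXYGEN_PARENT.items():
            if name in res.atoms and parent in res.atoms:
                otype = stats.oxygen_type(name)
                self.oxy_names.append(name)
                self.oxy_types.append(otype)
                self.oxy_codes.append(_OXY_CODE[otype])
                oxy.append(res.atoms[name])
                par.append(res.atoms[parent])
        self.oxy_xyz = np.array(oxy) if oxy else np.zeros((0, 3))
        self.oxy_parent_xyz = np.array(par) if par else np.zeros((0, 3))
        if all(a in res.atoms for a in chem.RIBOSE_ATOMS) and self.frame:
            self.ribose_local = np.array(
                [self.frame.to_local(res.atoms[a])
                 for a in chem.RIBOSE_ATOMS]
            )
        else:
            self.ribose_local = None
        name_idx = {n: k for k, n in enumerate(self.atom_names)}
        self.intra_pairs = [
            (name_idx[a], name_idx[b])
            for a, b in _intra_residue_clash_pairs(res.base_type)
            if a in name_idx and b in name_idx
        ]


def _cdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


class Scorer:
    """Scores structures against a built :class:`~briq.tables.TableSet`."""

    def __init__(self, tables, clash_params: ClashParams = ClashParams()):
        self.tables = tables
        self.clash_params = clash_params
        self._r0_cache: dict[tuple[str, str], float] = {}

    # -- pairwise ----------------------------------------------------------

    def bb_term(self, vi: ResidueView, vj: ResidueView) -> float:
        if vi.frame is None or vj.frame is None:
            return 0.0
        d = vj.frame.origin - vi.frame.origin
        r = math.sqrt(float(d @ d))
        if r >= R_MAX or r < 1e-6:
            return 0.0
        sep = _sep_class(vi.res, vj.res)
        table = self.tables.bb_table(vi.res.base_type, vj.res.base_type, sep)
        if table is None:
            return 0.0
        rel = relative_orientation(vi.frame, vj.frame)
        return ebb_lookup(table, rel, self.tables.codebook,
                          vi.res.base_type, vj.res.base_type)

    def bo_terms(self, vi: ResidueView, vj: ResidueView) -> float:
        """Base of i against the oxygens of j, plus the reverse."""
        total = 0.0
        polar_tables = self.tables.polar.base_oxygen
        for va, vb in ((vi, vj), (vj, vi)):
            if va.frame is None or len(vb.oxy_xyz) == 0:
                continue
            d_heavy = _cdist(va.heavy_xyz, vb.oxy_xyz)
            d_min = d_heavy.min(axis=0)
            mask = d_min <= stats.BASE_OXYGEN_RANGE
            if not mask.any():
                continue
            d_polar = _cdist(va.polar_xyz, vb.oxy_xyz)
            nearest = np.argmin(d_polar, axis=0)
            pk = va.polar_xyz[nearest]
            v1 = pk - vb.oxy_xyz
            v2 = vb.oxy_parent_xyz - vb.oxy_xyz
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            thetas = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            d_pseudo = _cdist(vb.oxy_xyz, va.pseudo)
            bt = va.res.base_type
            for k in np.where(mask)[0]:
                table = polar_tables.get((bt, vb.oxy_types[k]))
                if table is None:
                    continue
                s = energy_polar.angle_score_s(float(thetas[k]),
                                               table.theta_range)
                if s == 0.0:
                    continue
                w = energy_polar.decay_weight(
                    float(d_min[k]), energy_polar.BO_DECAY_MIDPOINT,
                    energy_polar.BO_DECAY_RATE,
                )
                if w < 1e-12:
                    continue
                total += w * s * table.raw_energy(d_pseudo[k])
        return total

    def oo_terms(self, vi: ResidueView, vj: ResidueView) -> float:
        if len(vi.oxy_xyz) == 0 or len(vj.oxy_xyz) == 0:
            return 0.0
        dmat = _cdist(vi.oxy_xyz, vj.oxy_xyz)
        total = 0.0
        oo_tables = self.tables.polar.oxygen_oxygen
        for a, b in zip(*np.where(dmat <= stats.OXYGEN_OXYGEN_RANGE)):
            cls = _OO_CLASS_BY_CODE.get((vi.oxy_codes[a], vj.oxy_codes[b]))
            if cls is None:
                continue
            table = oo_tables.get(cls)
            if table is None:
                continue
            d = float(dmat[a, b])
            w = energy_polar.decay_weight(
                d, energy_polar.OO_DECAY_MIDPOINT, energy_polar.OO_DECAY_RATE
            )
            if w < 1e-12:
                continue
            ta, tb = vi.oxy_types[a], vj.oxy_types[b]
            if ta <= tb:
                cfg = stats.oo_configuration(
                    vi.oxy_parent_xyz[a], vi.oxy_xyz[a],
                    vj.oxy_xyz[b], vj.oxy_parent_xyz[b],
                )
            else:
                cfg = stats.oo_configuration(
                    vj.oxy_parent_xyz[b], vj.oxy_xyz[b],
                    vi.oxy_xyz[a], vi.oxy_parent_xyz[a],
                )
            total += w * table.raw_energy(cfg)
        return total

    def clash_term(self, vi: ResidueView, vj: ResidueView) -> float:
        adjacent = (
            vi.res.chain_id == vj.res.chain_id
            and abs(vi.res.index - vj.res.index) == 1
        )
        lo_is_i = vi.res.index <= vj.res.index
        dmat = _cdist(vi.atom_xyz, vj.atom_xyz)
        total = 0.0
        for a, b in zip(*np.where(dmat < CLASH_GATE)):
            if adjacent:
                na, nb = vi.atom_names[a], vj.atom_names[b]
                pair = (na, nb) if lo_is_i else (nb, na)
                if pair in _JUNCTION_EXEMPT:
                    continue
            r0 = self._pair_r0(vi, a, vj, b)
            d = float(dmat[a, b])
            if d < r0:
                total += eclash(d, r0, self.clash_params)
        return total

    def _iso_r0(self, ta: str, tb: str) -> float:
        key = (ta, tb)
        cached = self._r0_cache.get(key)
        if cached is None:
            cached = self.tables.clash.r0(ta, tb)
            self._r0_cache[key] = cached
            self._r0_cache[(tb, ta)] = cached
        return cached

    def _pair_r0(self, vi: ResidueView, a: int, vj: ResidueView, b: int) -> float:
        ta, tb = vi.atom_types[a], vj.atom_types[b]
        oriented = self.tables.clash.oriented
        if vi.base_flags[a] and vi.frame is not None \
                and (ta, tb) in oriented:
            local = vi.frame.to_local(vj.atom_xyz[b])
            cell = (int(math.floor(local[0])), int(math.floor(local[1])),
                    int(math.floor(local[2])))
            return self.tables.clash.r0(ta, tb, cell)
        if vj.base_flags[b] and vj.frame is not None \
                and (tb, ta) in oriented:
            local = vj.frame.to_local(vi.atom_xyz[a])
            cell = (int(math.floor(local[0])), int(math.floor(local[1])),
                    int(math.floor(local[2])))
            return self.tables.clash.r0(tb, ta, cell)
        return self._iso_r0(ta, tb)

    def pair_interaction(self, vi: ResidueView, vj: ResidueView
                         ) -> EnergyBreakdown:
        out = EnergyBreakdown()
        if vi.frame is not None and vj.frame is not None:
            d = vj.frame.origin - vi.frame.origin
            if math.sqrt(float(d @ d)) > RESIDUE_PAIR_GATE:
                return out
        out.e_bb = self.bb_term(vi, vj)
        out.e_bo = self.bo_terms(vi, vj)
        out.e_oo = self.oo_terms(vi, vj)
        out.e_clash = self.clash_term(vi, vj)
        return out

    # -- per-residue / per-step -------------------------------------------

    def rot_term(self, vi: ResidueView) -> float:
        if vi.ribose_local is None:
            return 0.0
        energy = self.tables.rotamers.get(vi.res.base_type)
        if energy is None:
            raise ValueError(
                f"no rotamer table for base type {vi.res.base_type}"
            )
        return erot(vi.ribose_local, energy)

    def self_clash(self, vi: ResidueView) -> float:
        total = 0.0
        xyz = vi.atom_xyz
        for (ia, ib) in vi.intra_pairs:
            delta = xyz[ia] - xyz[ib]
            d = math.sqrt(float(delta @ delta))
            if d >= CLASH_GATE:
                continue
            r0 = self._pair_r0(vi, ia, vi, ib)
            if d < r0:
                total += eclash(d, r0, self.clash_params)
        return total

    def internal_term(self, res_i: BaseResidue, res_ip1: BaseResidue) -> float:
        if self.tables.torsion is None:
            raise ValueError("torsion tables missing")
        return step_internal_energy(res_i, res_ip1, self.tables.torsion)

    # -- totals ------------------------------------------------------------

    def score(self, structure: RnaStructure,
              weights: EnergyWeights = EnergyWeights()) -> EnergyBreakdown:
        views = [ResidueView(r) for r in structure.residues]
        out = EnergyBreakdown()
        n = len(views)
        for i in range(n):
            out.e_rot += self.rot_term(views[i])
            out.e_clash += self.self_clash(views[i])
            for j in range(i + 1, n):
                part = self.pair_interaction(views[i], views[j])
                out.e_bb += part.e_bb
                out.e_bo += part.e_bo
                out.e_oo += part.e_oo
                out.e_clash += part.e_clash
        for i in range(n - 1):
            a, b = structure.residues[i], structure.residues[i + 1]
            if a.chain_id == b.chain_id and b.index == a.index + 1:
                out.e_internal += self.internal_term(a, b)
        out.e_clash *= weights.clash
        out.e_internal *= weights.internal
        return out


def _sep_class(ri: BaseResidue, rj: BaseResidue) -> str:
    if ri.chain_id != rj.chain_id:
        return "2+"
    d = abs(ri.index - rj.index)
    return "1" if d == 1 else ("2" if d == 2 else "2+")
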