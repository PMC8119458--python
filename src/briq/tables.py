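"""Assembly and serialization of the full table set.

`build_all_tables` runs every statistics collector over a corpus and
produces a :class:`TableSet` — everything scoring and sampling need:
the sphere codebook, base-base 6D tables per pair type and separation
class, base-oxygen/oxygen-oxygen KDE tables, rotamer densities, coupled
torsion tables, clash radii, the epsilon-zeta phosphate grid and the
edge move sets.  Table sets serialize to a single versioned HDF5
archive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import energy_bb, energy_polar, stats
from .energy_local import RotamerEnergy, build_rotamer_energies
from .energy_polar import (
    AngleRange,
    BaseOxygenTable,
    OxygenOxygenTable,
    PolarTables,
    build_polar_tables,
)
from .geometry import RigidTransform
from .stats import (
    ClashTable,
    MoveSet,
    PhosphateGrid,
    QMTable,
    SphereCodebook,
    TorsionTables,
)

log = logging.getLogger(__name__)

ARCHIVE_VERSION = "1"


@dataclass
class TableSet:
    codebook: SphereCodebook
    bb: dict[tuple[str, str], energy_bb.EnergyTable6D] = field(
        default_factory=dict
    )
    polar: PolarTables = field(default_factory=PolarTables)
    rotamers: dict[str, RotamerEnergy] = field(default_factory=dict)
    torsion: TorsionTables | None = None
    clash: ClashTable = field(default_factory=ClashTable)
    phosgrid: PhosphateGrid | None = None
    move_sets: dict[str, MoveSet] = field(default_factory=dict)

    def bb_table(self, base_i: str, base_j: str, sep: str):
        return self.bb.get(energy_bb.pair_key(base_i, base_j, sep))


def build_all_tables(
    corpus,
    annotations=None,
    seed: int = 0,
    codebook_size: int = 2000,
    n_clusters: int = 80,
    qm: QMTable | None = None,
    with_move_sets: bool = True,
    scaling: energy_bb.ScalingConfig = energy_bb.ScalingConfig(),
) -> TableSet:
    """Run all collectors over ``corpus`` and build every table.

    When no QM table is supplied a synthetic stand-in is generated from
    the orientation clusters (see :func:`briq.fixtures.toy_qm_table`).
    ``n_clusters`` is capped at the available observation count per pair
    type (with a log message) so small corpora remain buildable.
    """
    from .fixtures import toy_qm_table  # deferred: fixtures imports stats

    codebook = stats.generate_sphere_codebook(codebook_size, seed)
    pair_lib = stats.collect_pair_observations(corpus, annotations)

    clusters: dict[str, stats.OrientationClusterSet] = {}
    for (ptype, sep), obs in pair_lib.groups.items():
        if sep != "2+" or not obs:
            continue
        k = min(n_clusters, len(obs))
        if k < n_clusters:
            log.info("pair type %s: only %d observations, using %d clusters",
                     ptype, len(obs), k)
        clusters[ptype] = stats.cluster_orientations(
            pair_lib, ptype, sep, k=k, seed=seed
        )
    if qm is None:
        qm = toy_qm_table(clusters)

    tables = TableSet(codebook=codebook)
    for (ptype, sep) in pair_lib.groups:
        tables.bb[(ptype, sep)] = energy_bb.build_bb_table(
            pair_lib, ptype, sep, codebook,
            clusters=clusters.get(ptype), qm=qm, scaling=scaling,
        )

    polar_lib = stats.collect_polar_observations(corpus)
    tables.polar = build_polar_tables(polar_lib)

    rot_lib = stats.collect_rotamers(corpus)
    tables.rotamers = build_rotamer_energies(rot_lib)

    torsion_samples = stats.collect_torsion_samples(corpus)
    tables.torsion = stats.build_torsion_tables(torsion_samples)
    tables.phosgrid = stats.build_phosphate_grid(torsion_samples, seed=seed)

    tables.clash = stats.estimate_r0(corpus)

    if with_move_sets:
        for edge_type in stats.EDGE_TYPES:
            try:
                tables.move_sets[edge_type] = stats.build_move_set(
                    pair_lib, edge_type, seed=seed, relax=True
                )
            except ValueError as exc:
                log.warning("move set %s not built: %s", edge_type, exc)
    return tables


# ---------------------------------------------------------------------------
# HDF5 archive

def save_tables(tables: TableSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = ARCHIVE_VERSION
        f.create_dataset("codebook", data=tables.codebook.vectors)
        g = f.create_group("bb")
        for (ptype, sep), table in tables.bb.items():
            rows = []
            for (idij, idji), plane in table.cells.items():
                for (ir, iw), v in plane.items():
                    rows.append((ir, iw, idij, idji, v))
            sub = g.create_group(f"{ptype}_{sep.replace('+', 'p')}")
            sub.attrs["base_i"] = table.base_i
            sub.attrs["base_j"] = table.base_j
            sub.attrs["sep"] = sep
            sub.create_dataset(
                "cells", data=np.array(rows) if rows else np.zeros((0, 5))
            )
        g = f.create_group("bo")
        for (bt, ot), table in tables.polar.base_oxygen.items():
            sub = g.create_group(f"{bt}_{ot.replace(chr(39), 'p')}")
            sub.attrs["base_type"] = bt
            sub.attrs["oxy_type"] = ot
            sub.attrs["f_ref"] = table.f_ref
            sub.attrs["theta"] = [table.theta_range.lower,
                                  table.theta_range.median,
                                  table.theta_range.upper]
            sub.create_dataset("samples", data=table.samples)
        g = f.create_group("oo")
        for cls, table in tables.polar.oxygen_oxygen.items():
            sub = g.create_group(cls.replace("'", "p"))
            sub.attrs["pair_class"] = cls
            sub.attrs["f_ref"] = table.f_ref
            sub.create_dataset("samples", data=table.samples)
        g = f.create_group("rot")
        for bt, en in tables.rotamers.items():
            sub = g.create_group(bt)
            sub.create_dataset("samples", data=en.samples)
            sub.create_dataset("weights", data=en.weights)
            sub.attrs["f_max"] = en.f_max
        if tables.torsion is not None:
            g = f.create_group("torsion")
            g.create_dataset("p_ez_nu", data=tables.torsion.p_ez_nu)
            g.create_dataset("p_a_zb", data=tables.torsion.p_a_zb)
            g.create_dataset("p_bg_nu", data=tables.torsion.p_bg_nu)
        g = f.create_group("clash")
        keys = sorted(tables.clash.isotropic)
        g.create_dataset("iso_keys", data=np.array(
            [f"{a}|{b}" for a, b in keys], dtype=h5py.string_dtype()
        ))
        g.create_dataset("iso_vals", data=np.array(
            [tables.clash.isotropic[k] for k in keys]
        ))
        g.attrs["fallback"] = tables.clash.fallback
        og = g.create_group("oriented")
        for i, ((ta, tb), grid) in enumerate(sorted(
                tables.clash.oriented.items())):
            sub = og.create_group(str(i))
            sub.attrs["type_a"] = ta
            sub.attrs["type_b"] = tb
            cells = sorted(grid)
            sub.create_dataset("cells", data=np.array(cells))
            sub.create_dataset("vals", data=np.array(
                [grid[c] for c in cells]
            ))
        if tables.phosgrid is not None:
            g = f.create_group("phosgrid")
            g.create_dataset("reps", data=tables.phosgrid.reps)
            g.create_dataset("subreps", data=tables.phosgrid.subreps)
        g = f.create_group("moves")
        for edge_type, ms in tables.move_sets.items():
            arr = np.zeros((ms.n_reps, len(ms.transforms[0]), 3, 4))
            for i, sub in enumerate(ms.transforms):
                for j, t in enumerate(sub):
                    arr[i, j, :, :3] = t.rotation
                    arr[i, j, :, 3] = t.translation
            g.create_dataset(edge_type, data=arr)


def load_tables(path) -> TableSet:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version != ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {version!r}")
        tables = TableSet(codebook=SphereCodebook(f["codebook"][()]))
        for name, sub in f["bb"].items():
            table = energy_bb.EnergyTable6D(
                str(sub.attrs["base_i"]), str(sub.attrs["base_j"]),
                str(sub.attrs["sep"]), len(tables.codebook),
            )
            for row in sub["cells"][()]:
                ir, iw, idij, idji, v = row
                table.cells.setdefault(
                    (int(idij), int(idji)), {}
                )[(int(ir), int(iw))] = float(v)
            ptype = str(sub.attrs["base_i"]) + str(sub.attrs["base_j"])
            tables.bb[(ptype, str(sub.attrs["sep"]))] = table
        for name, sub in f["bo"].items():
            lo, med, hi = sub.attrs["theta"]
            table = BaseOxygenTable(
                str(sub.attrs["base_type"]), str(sub.attrs["oxy_type"]),
                sub["samples"][()], float(sub.attrs["f_ref"]),
                AngleRange(float(lo), float(med), float(hi)),
            )
            tables.polar.base_oxygen[(table.base_type, table.oxy_type)] = table
        for name, sub in f["oo"].items():
            table = OxygenOxygenTable(
                str(sub.attrs["pair_class"]), sub["samples"][()],
                float(sub.attrs["f_ref"]),
            )
            tables.polar.oxygen_oxygen[table.pair_class] = table
        for bt, sub in f["rot"].items():
            tables.rotamers[bt] = RotamerEnergy(
                bt, sub["samples"][()], sub["weights"][()],
                f_max=float(sub.attrs["f_max"]),
            )
        if "torsion" in f:
            tables.torsion = TorsionTables(
                f["torsion/p_ez_nu"][()], f["torsion/p_a_zb"][()],
                f["torsion/p_bg_nu"][()],
            )
        g = f["clash"]
        tables.clash = ClashTable(fallback=float(g.attrs["fallback"]))
        for key, val in zip(g["iso_keys"][()], g["iso_vals"][()]):
            a, b = key.decode().split("|")
            tables.clash.isotropic[(a, b)] = float(val)
        for name, sub in g["oriented"].items():
            grid = {
                tuple(int(x) for x in cell): float(v)
                for cell, v in zip(sub["cells"][()], sub["vals"][()])
            }
            tables.clash.oriented[
                (str(sub.attrs["type_a"]), str(sub.attrs["type_b"]))
            ] = grid
        if "phosgrid" in f:
            tables.phosgrid = PhosphateGrid(
                f["phosgrid/reps"][()], f["phosgrid/subreps"][()]
            )
        for edge_type, ds in f["moves"].items():
            arr = ds[()]
            transforms = [
                [RigidTransform(arr[i, j, :, :3], arr[i, j, :, 3])
                 for j in range(arr.shape[1])]
                for i in range(arr.shape[0])
            ]
            tables.move_sets[edge_type] = MoveSet(edge_type, transforms)
    return tables
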