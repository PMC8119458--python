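"""Six-dimensional base-base statistical energy.

The orientation density of one base around another is a kernel sum over
corpus observations in DDM space, with a flat-top radial-basis kernel
(weight 1 within 0.15 Angstrom, Gaussian of width 0.1 beyond).  For
non-local pairs (sequence separation > 2) each observation is
reweighted by a tabulated quantum-chemistry interaction energy of its
nearest orientation-cluster center, which suppresses orientations that
are common only through indirect contacts.  The energy is the negative
log density scaled so the table minimum hits a fixed target (-8 for
non-local pairs, -4 for local), with repulsive (positive) values
clipped to zero.

Energies are tabulated on a sparse 6D grid -- 0.3 A radial bins, 8 deg
twist bins and a sphere codebook for the two direction vectors -- and
looked up by bilinear interpolation in (r, omega) with nearest-codebook
resolution of the directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    BaseFrame,
    PairConfiguration,
    RelativeOrientation,
    ddm_many,
    pair_configuration,
    reconstruct_frame,
)
from .stats import (
    OrientationClusterSet,
    PairLibrary,
    PairObservation,
    QMTable,
    SphereCodebook,
    canonical_pair_type,
)

log = logging.getLogger(__name__)

#: kernel: flat top radius / Gaussian width / same-orientation threshold
KERNEL_FLAT_TOP = 0.15
KERNEL_WIDTH = 0.1

#: table geometry
R_MAX = 15.0
R_BIN = 0.3
N_R_BINS = 50
OMEGA_BIN = 8.0
N_OMEGA_BINS = 45

#: density floor for the QM-weight denominator
DENSITY_FLOOR = 1e-6


@dataclass(frozen=True)
class ScalingConfig:
    """Energy-scale targets: table minima after normalisation."""

    target_nonlocal: float = -8.0
    target_local: float = -4.0
    qm_scale: float = 4.32

    def target(self, sep: str) -> float:
        return self.target_nonlocal if sep == "2+" else self.target_local


def kernel_h(d) -> np.ndarray | float:
    """Flat-top Gaussian kernel: 1 for d <= 0.15, Gaussian tail beyond."""
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("kernel distance must be non-negative")
    out = np.where(
        d <= KERNEL_FLAT_TOP,
        1.0,
        np.exp(-0.5 * ((d - KERNEL_FLAT_TOP) / KERNEL_WIDTH) ** 2),
    )
    return float(out) if out.ndim == 0 else out


def density_f(
    dmat: np.ndarray,
    obs_dmats: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted kernel density at one configuration.

    ``obs_dmats`` is the (n,4,4) stack of observation cross-distance
    matrices in the same base order as ``dmat``; unit weights give the
    plain (unweighted) density.
    """
    if len(obs_dmats) == 0:
        return 0.0
    h = kernel_h(ddm_many(dmat, obs_dmats))
    if weights is None:
        return float(np.sum(h))
    return float(np.sum(np.asarray(weights, float) * h))


def qm_weights(
    obs: list[PairObservation],
    clusters: OrientationClusterSet,
    qm: QMTable,
    scaling: ScalingConfig = ScalingConfig(),
) -> np.ndarray:
    """Per-observation reweighting factor w = exp(-E_QM(c)/s) / f(c),
    where c is the observation's nearest cluster center and f(c) the
    unweighted density at that center."""
    energies = qm.get(clusters.pair_type)
    if energies is None:
        raise ValueError(f"no QM energies for pair type {clusters.pair_type}")
    if len(energies) != clusters.k:
        raise ValueError("QM table size does not match cluster count")
    dmats = np.array([o.canonical_dmat() for o in obs])
    center_density = np.array([
        max(density_f(c, dmats), DENSITY_FLOOR)
        for c in clusters.center_dmats
    ])
    nearest = np.array([clusters.nearest_center(d) for d in dmats])
    return np.exp(-energies[nearest] / scaling.qm_scale) / \
        center_density[nearest]


# ---------------------------------------------------------------------------
# the sparse 6D table

def r_bin_index(r: float) -> int:
    return int(r / R_BIN)


def omega_bin_index(omega: float) -> int:
    return int(((omega + 180.0) % 360.0) // OMEGA_BIN) % N_OMEGA_BINS


def cell_of(rel: RelativeOrientation, codebook: SphereCodebook):
    return (
        r_bin_index(rel.r),
        omega_bin_index(rel.omega),
        codebook.nearest(rel.dir_ij),
        codebook.nearest(rel.dir_ji),
    )


def cell_center_orientation(cell, codebook: SphereCodebook) -> RelativeOrientation:
    ir, iw, idij, idji = cell
    omega = -180.0 + (iw + 0.5) * OMEGA_BIN
    omega = (omega + 180.0) % 360.0 - 180.0
    return RelativeOrientation(
        r=(ir + 0.5) * R_BIN,
        omega=omega,
        dir_ij=codebook.vectors[idij],
        dir_ji=codebook.vectors[idji],
    )


def configuration_from_orientation(
    base_i: str, base_j: str, rel: RelativeOrientation, sep: str = "2+"
) -> PairConfiguration:
    identity = BaseFrame(np.zeros(3), np.eye(3))
    frame_j = reconstruct_frame(identity, rel)
    return pair_configuration(base_i, identity, base_j, frame_j, sep)


@dataclass
class EnergyTable6D:
    """Sparse base-base energy table for one (ordered pair type, sep).

    Only negative energies are stored; any absent cell reads as zero.
    ``cells`` maps (direction-cell pair) -> {(r bin, omega bin): value},
    which keeps the (r, omega) plane of each direction pair together for
    bilinear interpolation.
    """

    base_i: str
    base_j: str
    sep: str
    codebook_size: int
    cells: dict[tuple[int, int], dict[tuple[int, int], float]] = field(
        default_factory=dict
    )

    def store(self, cell, value: float) -> None:
        if value >= 0.0:
            return
        ir, iw, idij, idji = cell
        self.cells.setdefault((idij, idji), {})[(ir, iw)] = float(value)

    def raw_value(self, cell) -> float:
        ir, iw, idij, idji = cell
        return self.cells.get((idij, idji), {}).get((ir, iw), 0.0)

    def min_value(self) -> float:
        values = [v for plane in self.cells.values() for v in plane.values()]
        return min(values) if values else 0.0

    def n_stored(self) -> int:
        return sum(len(p) for p in self.cells.values())

    def lookup(self, rel: RelativeOrientation, codebook: SphereCodebook) -> float:
        """Bilinear interpolation in (r, omega) at the nearest codebook
        cells for the two directions; zero beyond the radial range."""
        if rel.r >= R_MAX:
            return 0.0
        key = (codebook.nearest(rel.dir_ij), codebook.nearest(rel.dir_ji))
        plane = self.cells.get(key)
        if not plane:
            return 0.0
        # fractional bin coordinates relative to cell centers
        fr = rel.r / R_BIN - 0.5
        fw = ((rel.omega + 180.0) % 360.0) / OMEGA_BIN - 0.5
        ir0 = int(np.floor(fr))
        iw0 = int(np.floor(fw))
        tr = fr - ir0
        tw = fw - iw0
        total = 0.0
        for dr, wr in ((0, 1.0 - tr), (1, tr)):
            ir = ir0 + dr
            if ir < 0 or ir >= N_R_BINS:
                continue
            for dw, ww in ((0, 1.0 - tw), (1, tw)):
                iw = (iw0 + dw) % N_OMEGA_BINS
                total += wr * ww * plane.get((ir, iw), 0.0)
        return total


def build_bb_table(
    library: PairLibrary,
    pair_type: str,
    sep: str,
    codebook: SphereCodebook,
    clusters: OrientationClusterSet | None = None,
    qm: QMTable | None = None,
    scaling: ScalingConfig = ScalingConfig(),
    neighbor_shells: int = 2,
) -> EnergyTable6D:
    """Tabulate E = -ln f'(x)/f_ref over the populated region of the grid.

    QM reweighting (``clusters`` + ``qm``) applies only to the non-local
    class.  The density is evaluated at the representative configuration
    of every cell occupied by an observation plus ``neighbor_shells``
    surrounding (r, omega) bins; cells further out carry negligible
    kernel mass and clip to zero anyway.  f_ref is chosen so the table
    minimum equals the configured target exactly.
    """
    base_i, base_j = sorted((pair_type[0], pair_type[1]))
    table = EnergyTable6D(base_i, base_j, sep, len(codebook))
    obs = [o for o in library.get(pair_type, sep)]
    if not obs:
        log.warning("no observations for %s/%s: empty table", pair_type, sep)
        return table
    dmats = np.array([o.canonical_dmat() for o in obs])
    if sep == "2+" and clusters is not None and qm is not None:
        weights = qm_weights(obs, clusters, qm, scaling)
    else:
        weights = np.ones(len(obs))

    # canonical orientations: swap observation direction if needed
    cells: set[tuple[int, int, int, int]] = set()
    for o in obs:
        rel = o.rel if o.base_i <= o.base_j else _swap_orientation(o.rel)
        c = cell_of(rel, codebook)
        for dr in range(-neighbor_shells, neighbor_shells + 1):
            ir = c[0] + dr
            if ir < 0 or ir >= N_R_BINS:
                continue
            for dw in range(-neighbor_shells, neighbor_shells + 1):
                iw = (c[1] + dw) % N_OMEGA_BINS
                cells.add((ir, iw, c[2], c[3]))

    raw: dict[tuple, float] = {}
    for cell in cells:
        rel = cell_center_orientation(cell, codebook)
        cfg = configuration_from_orientation(base_i, base_j, rel, sep)
        raw[cell] = density_f(cfg.dmat, dmats, weights)
    fmax = max(raw.values())
    if fmax <= 0:
        return table
    # f_ref scales the lowest energy (= deepest density) to the target
    f_ref = fmax * np.exp(scaling.target(sep))
    for cell, f in raw.items():
        if f <= 0:
            continue
        e0 = -np.log(f / f_ref)
        table.store(cell, min(e0, 0.0))
    return table


def _swap_orientation(rel: RelativeOrientation) -> RelativeOrientation:
    # exchanging the two bases swaps the direction vectors; the twist
    # omega is invariant (both the angle order and the axis flip)
    return RelativeOrientation(
        r=rel.r, omega=rel.omega, dir_ij=rel.dir_ji, dir_ji=rel.dir_ij,
    )


def ebb_lookup(
    table: EnergyTable6D,
    rel: RelativeOrientation,
    codebook: SphereCodebook,
    base_i: str | None = None,
    base_j: str | None = None,
) -> float:
    """Energy of one ordered base pair; callers pass the observation's
    base order and the orientation is canonicalised to the table's."""
    if base_i is not None and base_j is not None and base_i > base_j:
        rel = _swap_orientation(rel)
    return table.lookup(rel, codebook)


def pair_key(base_i: str, base_j: str, sep: str) -> tuple[str, str]:
    return (canonical_pair_type(base_i, base_j), sep)
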