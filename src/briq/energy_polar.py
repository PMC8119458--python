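"""Orientation-dependent hydrogen-bond energies involving backbone oxygens.

Two families of terms:

* base-oxygen: a main-chain oxygen (OP, O2', O3', O4', O5') near a base
  is described by its distances to the base's four pseudo-atoms; the
  energy is a negative-log kernel density over that 4-distance
  representation, gated by a logistic distance decay (midpoint 3.7 A)
  and by a quadratic angular score of the angle at the oxygen between
  its covalent parent and the nearest base N/O atom.  Unlike the
  base-base term the log-ratio is not clipped at zero: repulsion is
  attenuated by the gates instead.

* oxygen-oxygen: hydrogen bonds between O2'/OP oxygens, described by
  the six pairwise distances of the four defining atoms (each oxygen
  plus its covalent parent), gated by a logistic decay with midpoint
  3.3 A.

Both tables store the un-gated -ln f(x)/f_ref, with f_ref chosen so the
stored minimum equals the configured target exactly; the gates are
applied at query time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stats import (
    BaseOxygenObservation,
    OxygenOxygenObservation,
    PolarLibrary,
    OXYGEN_TYPES,
    OO_CLASSES,
)

log = logging.getLogger(__name__)

BO_KERNEL_WIDTH = 0.16
OO_KERNEL_WIDTH = 0.1

BO_DECAY_MIDPOINT = 3.7
BO_DECAY_RATE = 0.08
OO_DECAY_MIDPOINT = 3.3
OO_DECAY_RATE = 0.07

BO_TARGET = -3.0
OO_TARGETS = {"O2'-O2'": -3.0, "O2'-OP": -2.0, "OP-OP": -1.5}

#: cap on the repulsive (positive) log-ratio: far outside the observed
#: density the KDE tail would otherwise diverge; the cap keeps unfamiliar
#: geometry penalised at the scale of the deepest attractive wells
RAW_ENERGY_CAP = 3.0

#: angular-range trimming fraction per tail
THETA_TRIM = 0.03
#: polar-atom distance cut for harvesting gating angles
THETA_HARVEST_DISTANCE = 3.5


@dataclass(frozen=True)
class AngleRange:
    """Gating-angle bounds: zero score outside [lower, upper], one at
    the median."""

    lower: float
    median: float
    upper: float

    def __post_init__(self):
        if not (self.lower < self.median < self.upper):
            raise ValueError("need lower < median < upper")


def angle_range_from_samples(thetas: np.ndarray) -> AngleRange:
    """Empirical range after trimming 3% from each tail."""
    thetas = np.asarray(thetas, float)
    lo = float(np.quantile(thetas, THETA_TRIM))
    hi = float(np.quantile(thetas, 1.0 - THETA_TRIM))
    med = float(np.median(thetas))
    if not (lo < med < hi):
        # degenerate (near-constant) sample: widen symmetrically
        med = 0.5 * (lo + hi)
        lo, hi = med - 1.0, med + 1.0
    return AngleRange(lo, med, hi)


def angle_score_s(theta: float, rng: AngleRange) -> float:
    """Quadratic bump: 1 at the median, 0 at/outside the bounds."""
    if theta <= rng.lower or theta >= rng.upper:
        return 0.0
    if theta <= rng.median:
        return 1.0 - ((theta - rng.median) / (rng.lower - rng.median)) ** 2
    return 1.0 - ((theta - rng.median) / (rng.upper - rng.median)) ** 2


def decay_weight(d: float, midpoint: float, rate: float) -> float:
    """Logistic step ~1 below the midpoint, ~0 above: 1 - 1/(1+e^((m-d)/k))."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    x = (midpoint - d) / rate
    # numerically safe logistic
    if x >= 0:
        return 1.0 - 1.0 / (1.0 + np.exp(x) if x < 700 else np.inf)
    e = np.exp(x)
    return 1.0 - 1.0 / (1.0 + e)


def gaussian_kde_sum(query: np.ndarray, samples: np.ndarray,
                     width: float) -> float:
    """Sum of Gaussian kernels over the RMS distance between feature
    vectors (the 'RMSD' of the reduced-distance representations)."""
    if len(samples) == 0:
        return 0.0
    diff = samples - query[None, :]
    d = np.sqrt(np.mean(diff * diff, axis=1))
    return float(np.sum(np.exp(-0.5 * (d / width) ** 2)))


@dataclass
class BaseOxygenTable:
    """KDE reference data for one (base type, oxygen type)."""

    base_type: str
    oxy_type: str
    samples: np.ndarray          # (n, 4) pseudo-atom distances
    f_ref: float
    theta_range: AngleRange

    def raw_energy(self, distances: np.ndarray) -> float:
        f = gaussian_kde_sum(np.asarray(distances, float), self.samples,
                             BO_KERNEL_WIDTH)
        if f <= 0.0:
            return RAW_ENERGY_CAP
        return min(float(-np.log(f / self.f_ref)), RAW_ENERGY_CAP)


@dataclass
class OxygenOxygenTable:
    pair_class: str
    samples: np.ndarray          # (n, 6) pairwise distances
    f_ref: float

    def raw_energy(self, distances: np.ndarray) -> float:
        f = gaussian_kde_sum(np.asarray(distances, float), self.samples,
                             OO_KERNEL_WIDTH)
        if f <= 0.0:
            return RAW_ENERGY_CAP
        return min(float(-np.log(f / self.f_ref)), RAW_ENERGY_CAP)


@dataclass
class PolarTables:
    base_oxygen: dict[tuple[str, str], BaseOxygenTable] = field(
        default_factory=dict
    )
    oxygen_oxygen: dict[str, OxygenOxygenTable] = field(default_factory=dict)


def build_bo_table(base_type: str, oxy_type: str,
                   obs: list[BaseOxygenObservation]) -> BaseOxygenTable:
    samples = np.array([o.distances for o in obs])
    fvals = np.array([
        gaussian_kde_sum(s, samples, BO_KERNEL_WIDTH) for s in samples
    ])
    f_ref = float(fvals.max()) * np.exp(BO_TARGET)
    thetas = np.array([
        o.theta for o in obs if o.polar_distance <= THETA_HARVEST_DISTANCE
    ])
    if len(thetas) < 5:
        thetas = np.array([o.theta for o in obs])
    return BaseOxygenTable(base_type, oxy_type, samples, f_ref,
                           angle_range_from_samples(thetas))


def build_oo_table(pair_class: str,
                   obs: list[OxygenOxygenObservation]) -> OxygenOxygenTable:
    samples = np.array([o.distances for o in obs])
    fvals = np.array([
        gaussian_kde_sum(s, samples, OO_KERNEL_WIDTH) for s in samples
    ])
    f_ref = float(fvals.max()) * np.exp(OO_TARGETS[pair_class])
    return OxygenOxygenTable(pair_class, samples, f_ref)


def build_polar_tables(library: PolarLibrary) -> PolarTables:
    tables = PolarTables()
    for (bt, ot), obs in library.base_oxygen.items():
        if ot not in OXYGEN_TYPES:
            raise ValueError(f"unknown oxygen type {ot!r}")
        if obs:
            tables.base_oxygen[(bt, ot)] = build_bo_table(bt, ot, obs)
    for cls, obs in library.oxygen_oxygen.items():
        if cls not in OO_CLASSES:
            raise ValueError(f"unknown oxygen pair class {cls!r}")
        if obs:
            tables.oxygen_oxygen[cls] = build_oo_table(cls, obs)
    return tables


def ebo(contact: BaseOxygenObservation, tables: PolarTables) -> float:
    """Base-oxygen energy: -w_bo(d_min) * s(theta) * ln f(x)/f_ref."""
    if contact.oxy_type not in OXYGEN_TYPES:
        raise ValueError(f"unknown oxygen type {contact.oxy_type!r}")
    table = tables.base_oxygen.get((contact.base_type, contact.oxy_type))
    if table is None:
        return 0.0
    s = angle_score_s(contact.theta, table.theta_range)
    if s == 0.0:
        return 0.0
    w = decay_weight(contact.d_min, BO_DECAY_MIDPOINT, BO_DECAY_RATE)
    if w < 1e-12:
        return 0.0
    return w * s * table.raw_energy(contact.distances)


def eoo(contact: OxygenOxygenObservation, tables: PolarTables) -> float:
    """Oxygen-oxygen energy: -w_oo(d) * ln f(x)/f_ref."""
    if contact.pair_class not in OO_CLASSES:
        raise ValueError(f"unknown oxygen pair class {contact.pair_class!r}")
    table = tables.oxygen_oxygen.get(contact.pair_class)
    if table is None:
        return 0.0
    w = decay_weight(contact.d_oo, OO_DECAY_MIDPOINT, OO_DECAY_RATE)
    if w < 1e-12:
        return 0.0
    return w * table.raw_energy(contact.distances)
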