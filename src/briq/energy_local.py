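"""Clash, ribose-rotamer and internal (bond/angle/torsion) energies.

The clash term is the printed piecewise form: zero beyond the
statistical minimum-approach radius r0, a constant plateau of
(k_clash*0.4)^4 within 0.4 A below r0, and a linear ramp of slope
-4*(k_clash*0.4)^3 below that.  As printed the term steps from the
plateau to zero at r0 (the restraint acts as a flat penalty shelf with
a hard onset); the linear branch joins the plateau continuously at
r0 - 0.4.

The rotamer term scores a ribose conformer against a weighted kernel
density over library conformers, all expressed in the base-local frame
(RMS atom distance, no superposition needed).  The internal term keeps
the single flexible O5'-C5' linkage and its two flanking angles near
database averages with softened harmonics, plus coupled backbone
torsion statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import (
    RotamerLibrary,
    TorsionTables,
    backbone_step_angles,
)
from .chem import C5_O5_BOND

K_CLASH_DEFAULT = 3.0
CLASH_SHELL = 0.4

K_BOND = 5.0
MEAN_C5_O5 = C5_O5_BOND            # 1.422 A
K_ANGLE = 0.1
MEAN_THETA_POC = 120.7
MEAN_THETA_OCC = 111.1

ROTAMER_KERNEL_WIDTH = 0.15


@dataclass(frozen=True)
class ClashParams:
    k_clash: float = K_CLASH_DEFAULT
    shell: float = CLASH_SHELL

    def __post_init__(self):
        if not (2.0 <= self.k_clash <= 5.0):
            raise ValueError("k_clash supported in [2, 5]")


def eclash(d: float, r0: float, params: ClashParams = ClashParams()) -> float:
    """Piecewise clash penalty (>= 0, non-increasing in d)."""
    if d <= 0:
        raise ValueError("distance must be positive")
    if d >= r0:
        return 0.0
    plateau = (params.k_clash * params.shell) ** 4
    if d > r0 - params.shell:
        return plateau
    slope = 4.0 * (params.k_clash * params.shell) ** 3
    return plateau + slope * (r0 - params.shell - d)


def softened_harmonic(u: float) -> float:
    """u^2 within |u|<=1, continued linearly (C1) outside."""
    if u < -1.0:
        return -2.0 * u - 1.0
    if u > 1.0:
        return 2.0 * u - 1.0
    return u * u


@dataclass
class RotamerEnergy:
    """Kernel-density rotamer score for one base type."""

    base_type: str
    samples: np.ndarray      # (n, 8, 3) ribose atoms in the base frame
    weights: np.ndarray      # (n,)
    f_max: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        self.weights = np.asarray(self.weights, float)
        if self.f_max == 0.0:
            self.f_max = max(
                self.density(s) for s in self.samples
            )

    def density(self, atoms_local: np.ndarray) -> float:
        diff = self.samples - np.asarray(atoms_local, float)[None]
        d = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
        return float(np.sum(
            self.weights * np.exp(-0.5 * (d / ROTAMER_KERNEL_WIDTH) ** 2)
        ))


def erot(atoms_local: np.ndarray, energy: RotamerEnergy) -> float:
    """-ln f(x)/f_max, clipped at zero (f_max is taken over the library
    conformers, so tiny negative excursions between modes are clipped)."""
    f = energy.density(atoms_local)
    if f <= 0.0:
        return 50.0  # far outside the library support
    return max(0.0, float(-np.log(f / energy.f_max)))


def build_rotamer_energies(library: RotamerLibrary) -> dict[str, RotamerEnergy]:
    out = {}
    for base_type, rots in library.rotamers.items():
        if not rots:
            continue
        out[base_type] = RotamerEnergy(
            base_type,
            np.array([r.atoms_local for r in rots]),
            np.array([r.weight for r in rots]),
        )
    return out


@dataclass(frozen=True)
class InternalParams:
    k_bond: float = K_BOND
    mean_bond: float = MEAN_C5_O5
    k_angle: float = K_ANGLE
    mean_theta_poc: float = MEAN_THETA_POC
    mean_theta_occ: float = MEAN_THETA_OCC


def ebond(bond_length: float, params: InternalParams = InternalParams()) -> float:
    return softened_harmonic(params.k_bond * (bond_length - params.mean_bond))


def eangle_poc(theta: float, params: InternalParams = InternalParams()) -> float:
    return softened_harmonic(params.k_angle * (theta - params.mean_theta_poc))


def eangle_occ(theta: float, params: InternalParams = InternalParams()) -> float:
    return softened_harmonic(params.k_angle * (theta - params.mean_theta_occ))


def etorsion(step_angles: tuple, tables: TorsionTables) -> float:
    """Sum of the three coupled-torsion terms of one backbone step."""
    (nu_i, eps, zeta, alpha, beta, gamma, nu_ip1) = step_angles
    return tables.energy(nu_i, eps, zeta, alpha, beta, gamma, nu_ip1)


# -- vectorised building blocks (shared with the phosphate search) -----------

def nerf_batch(d, a, b, bond, angle_deg, torsion_deg):
    """Vectorised NeRF placement; d/a/b broadcast against the torsions."""
    d = np.atleast_2d(d)
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    tor = np.atleast_1d(np.radians(torsion_deg))
    ang = np.radians(angle_deg)
    ba = a - b
    ba = ba / np.linalg.norm(ba, axis=1, keepdims=True)
    ncr = np.cross(a - b, d - a)
    ncr = ncr / np.linalg.norm(ncr, axis=1, keepdims=True)
    m = np.cross(ncr, ba)
    x = np.cos(ang)
    y = np.sin(ang) * np.cos(tor)
    z = -np.sin(ang) * np.sin(tor)
    return b + bond * (x * ba + y[:, None] * m + z[:, None] * ncr)


def dihedral_batch(p0, p1, p2, p3):
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=1, keepdims=True) * b1
    ang = np.degrees(np.arctan2(
        np.sum(np.cross(b1, v) * w, axis=1), np.sum(v * w, axis=1)
    ))
    return (ang + 180.0) % 360.0 - 180.0


def angle_batch(a, b, c):
    u = a - b
    v = c - b
    cosang = np.sum(u * v, axis=1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def soft_harm_batch(u):
    return np.where(np.abs(u) <= 1.0, u * u, 2.0 * np.abs(u) - 1.0)


def internal_energy_batch(res_i_atoms, res_ip1_atoms, eps, zeta,
                          torsion_tables: TorsionTables | None,
                          params: InternalParams = InternalParams()):
    """Internal energy of candidate (eps, zeta) phosphate placements,
    with residue i+1's sugar fixed; used by the closure search."""
    from .chem import (C3_O3_P_ANGLE, C5_O5_BOND, O3P_BOND, O3_P_O5_ANGLE,
                       P_O5_BOND)
    from .stats import (N_TORSION_BINS, TORSION_BIN_DEG, nu_region,
                        ribose_improper)

    a = res_i_atoms
    b = res_ip1_atoms
    eps = np.asarray(eps, float)
    zeta = np.asarray(zeta, float)
    n = len(eps)
    c2 = np.broadcast_to(a["C2'"], (n, 3))
    c3 = np.broadcast_to(a["C3'"], (n, 3))
    o3 = np.broadcast_to(a["O3'"], (n, 3))
    p = nerf_batch(c2, c3, o3, O3P_BOND, C3_O3_P_ANGLE, eps)
    o5 = nerf_batch(c3, o3, p, P_O5_BOND, O3_P_O5_ANGLE, zeta)
    c5 = np.broadcast_to(b["C5'"], (n, 3))
    c4 = np.broadcast_to(b["C4'"], (n, 3))
    o4 = np.broadcast_to(b["O4'"], (n, 3))
    bl = np.linalg.norm(o5 - c5, axis=1)
    e = soft_harm_batch(params.k_bond * (bl - params.mean_bond))
    e = e + soft_harm_batch(params.k_angle * (
        angle_batch(p, o5, c5) - params.mean_theta_poc))
    e = e + soft_harm_batch(params.k_angle * (
        angle_batch(o5, c5, c4) - params.mean_theta_occ))
    if torsion_tables is not None:
        nu_i = ribose_improper(a)
        nu_ip1 = ribose_improper(b)
        alpha = dihedral_batch(o3, p, o5, c5)
        beta = dihedral_batch(p, o5, c5, c4)
        gamma = dihedral_batch(o5, c5, c4, o4)

        def tb(angles):
            return (((angles + 180.0) % 360.0) // TORSION_BIN_DEG
                    ).astype(int) % N_TORSION_BINS

        e = e - np.log(torsion_tables.p_ez_nu[nu_region(nu_i), tb(eps),
                                              tb(zeta)])
        e = e - np.log(torsion_tables.p_a_zb[tb(zeta), tb(beta), tb(alpha)])
        e = e - np.log(torsion_tables.p_bg_nu[nu_region(nu_ip1), tb(beta),
                                              tb(gamma)])
    return e


def step_internal_energy(res_i, res_ip1, tables: TorsionTables,
                         params: InternalParams = InternalParams()) -> float:
    """Full internal energy of the phosphate linking residues i, i+1."""
    from .geometry import angle_between, dihedral

    a, b = res_i.atoms, res_ip1.atoms
    needed = ("P", "O5'", "C5'", "C4'")
    if any(x not in b for x in needed):
        return 0.0
    e = ebond(float(np.linalg.norm(b["O5'"] - b["C5'"])), params)
    e += eangle_poc(angle_between(b["P"], b["O5'"], b["C5'"]), params)
    e += eangle_occ(angle_between(b["O5'"], b["C5'"], b["C4'"]), params)
    angles = backbone_step_angles(res_i, res_ip1)
    if angles is not None:
        e += etorsion(angles, tables)
    return e


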