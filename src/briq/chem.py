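"""Chemical reference data for standard ribonucleotides.

Ideal covalent geometry is taken from the chemical component dictionary
bundled with biotite and converted into two reusable templates:

* per-base-type rigid base templates expressed in the base-local frame
  (used to rebuild base atoms from a frame during sampling), and
* an idealized ribonucleotide unit with a C3'-endo sugar and A-form
  backbone torsions (used by the synthetic-structure generators and by
  phosphate reconstruction).

The bundled dictionary's ideal sugar happens to sit near O4'-endo, so the
ribose ring is re-built here at pseudorotation phase 18 deg (C3'-endo,
amplitude 39 deg) from the dictionary's bond lengths and angles; the
exocyclic substituents are re-attached with the dictionary's two
flanking-angle values, which preserves the D-ribose stereochemistry
independently of pucker.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .geometry import (
    BaseFrame,
    angle_between,
    dihedral,
    frame_from_atoms,
    unit,
    _axis_angle,
)

BASE_TYPES = ("A", "C", "G", "U")

BASE_HEAVY_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "U": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"],
}

#: donor/acceptor base atoms considered for base-oxygen hydrogen bonds
BASE_POLAR_ATOMS = {
    "A": ["N6", "N7", "N1", "N3"],
    "G": ["O6", "N7", "N1", "N2", "N3"],
    "C": ["O2", "N3", "N4"],
    "U": ["O2", "N3", "O4"],
}

RIBOSE_ATOMS = ["C1'", "C2'", "C3'", "C4'", "O4'", "O2'", "O3'", "C5'"]
PHOSPHATE_ATOMS = ["P", "OP1", "OP2", "O5'"]

#: intra-residue covalent bonds (by atom name); the inter-residue bond is
#: O3'(i)-P(i+1)
_RIBOSE_BONDS = [
    ("C1'", "C2'"), ("C2'", "C3'"), ("C3'", "C4'"), ("C4'", "O4'"),
    ("O4'", "C1'"), ("C2'", "O2'"), ("C3'", "O3'"), ("C4'", "C5'"),
    ("C5'", "O5'"), ("O5'", "P"), ("P", "OP1"), ("P", "OP2"),
]
_BASE_BONDS = {
    "A": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"), ("C6", "N6"),
          ("C6", "N1"), ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"),
          ("C4", "N9"), ("C1'", "N9")],
    "G": [("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C6"), ("C6", "O6"),
          ("C6", "N1"), ("N1", "C2"), ("C2", "N2"), ("C2", "N3"), ("N3", "C4"),
          ("C4", "C5"), ("C4", "N9"), ("C1'", "N9")],
    "C": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"), ("C4", "N4"),
          ("C4", "C5"), ("C5", "C6"), ("C6", "N1"), ("C1'", "N1")],
    "U": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"), ("C4", "O4"),
          ("C4", "C5"), ("C5", "C6"), ("C6", "N1"), ("C1'", "N1")],
}

#: A-form backbone torsion targets (degrees), standard fiber-diffraction
#: values; used only to build idealized units, not harvested statistics.
AFORM_TORSIONS = {
    "alpha": -68.0, "beta": 178.0, "gamma": 54.0,
    "epsilon": -153.0, "zeta": -71.0, "chi": -158.0,
}
AFORM_TWIST = 32.7     # degrees per base step
AFORM_RISE = 2.81      # Angstrom per base step

#: joint geometry across the O3'(i)-P(i+1) linkage
O3P_BOND = 1.607
C3_O3_P_ANGLE = 119.7
O3_P_O5_ANGLE = 104.0


def glycosidic_nitrogen(base_type: str) -> str:
    return "N9" if base_type in ("A", "G") else "N1"


@lru_cache(maxsize=None)
def _ccd_coords(base_type: str) -> dict[str, np.ndarray]:
    import biotite.structure.info as info

    res = info.residue(base_type)
    return {
        name: res.coord[i].astype(float)
        for i, name in enumerate(res.atom_name)
        if res.element[i] != "H"
    }


@lru_cache(maxsize=None)
def base_template(base_type: str) -> dict[str, np.ndarray]:
    """Base heavy atoms in base-local coordinates (frame at identity)."""
    ccd = _ccd_coords(base_type)
    n, c = ("N9", "C4") if base_type in ("A", "G") else ("N1", "C2")
    frame = frame_from_atoms(ccd["C1'"], ccd[n], ccd[c])
    out = {
        name: frame.to_local(ccd[name]) for name in BASE_HEAVY_ATOMS[base_type]
    }
    for v in out.values():
        v.setflags(write=False)
    return out


def base_atoms_global(base_type: str, frame: BaseFrame) -> dict[str, np.ndarray]:
    return {
        name: frame.to_global(pos)
        for name, pos in base_template(base_type).items()
    }


def nerf_place(
    d: np.ndarray, a: np.ndarray, b: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom X bonded to b with angle(a,b,X) and torsion(d,a,b,X)."""
    ba = unit(a - b)
    n = unit(np.cross(a - b, d - a))
    m = np.cross(n, ba)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    local = bond * np.array(
        [np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return b + local[0] * ba + local[1] * m + local[2] * n


def _substituent_direction(
    host: np.ndarray, nb1: np.ndarray, nb2: np.ndarray,
    ang1: float, ang2: float, sign: float,
) -> np.ndarray:
    """Unit direction for a substituent on a ring atom, given the two
    flanking bond angles and the chirality sign of det[nb1-h, nb2-h, x]."""
    e1, e2 = unit(nb1 - host), unit(nb2 - host)
    n = unit(np.cross(e1, e2))
    c1, c2 = np.cos(np.radians(ang1)), np.cos(np.radians(ang2))
    g = float(np.dot(e1, e2))
    # solve x = p*e1 + q*e2 + s*n with x.e1=c1, x.e2=c2, |x|=1
    det = 1.0 - g * g
    p = (c1 - g * c2) / det
    q = (c2 - g * c1) / det
    rad = 1.0 - (p * p + q * q + 2 * p * q * g)
    s = np.sqrt(max(rad, 0.0)) * (1.0 if sign >= 0 else -1.0)
    return p * e1 + q * e2 + s * n


def _build_ribose_ring(base_type: str, phase_deg: float = 18.0,
                       amplitude_deg: float = 39.0) -> dict[str, np.ndarray]:
    """Five-membered ring at the requested pseudorotation state, using the
    dictionary's bond lengths/angles; closed by least squares."""
    ccd = _ccd_coords(base_type)
    ring = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    bonds = [float(np.linalg.norm(ccd[ring[i]] - ccd[ring[(i + 1) % 5]]))
             for i in range(5)]
    angles = [angle_between(ccd[ring[(i - 1) % 5]], ccd[ring[i]],
                            ccd[ring[(i + 1) % 5]]) for i in range(5)]
    # endocyclic torsions nu_j = tau_m * cos(P + 144*(j-2));
    # nu0 = C4'-O4'-C1'-C2', nu1 = O4'-C1'-C2'-C3', ...
    nus = [amplitude_deg * np.cos(np.radians(phase_deg + 144.0 * (j - 2)))
           for j in range(5)]

    def torsion_quad(j):
        return [ring[(j + 3) % 5], ring[(j + 4) % 5],
                ring[j % 5], ring[(j + 1) % 5]]

    # initial guess: flat pentagon
    th = 2 * np.pi * np.arange(5) / 5
    x0 = np.column_stack([1.2 * np.cos(th), 1.2 * np.sin(th),
                          0.05 * np.arange(5)]).ravel()

    def residuals(x):
        pts = {name: x[3 * i: 3 * i + 3] for i, name in enumerate(ring)}
        res = []
        for i in range(5):
            res.append(np.linalg.norm(pts[ring[i]] - pts[ring[(i + 1) % 5]])
                       - bonds[i])
        for i in range(5):
            res.append(0.03 * (angle_between(pts[ring[(i - 1) % 5]],
                                             pts[ring[i]],
                                             pts[ring[(i + 1) % 5]])
                               - angles[i]))
        for j in range(5):
            quad = torsion_quad(j)
            res.append(0.02 * (dihedral(*[pts[q] for q in quad]) - nus[j]))
        return res

    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14)
    return {name: sol.x[3 * i: 3 * i + 3].copy() for i, name in enumerate(ring)}


@lru_cache(maxsize=None)
def ideal_nucleotide(base_type: str) -> dict[str, np.ndarray]:
    """Idealized ribonucleotide (heavy atoms, C3'-endo, A-form torsions)
    expressed in the base-local frame of its own base.

    Includes the 5' phosphate group (P, OP1, OP2, O5') of the same
    residue.  All four base types share identical sugar/backbone
    coordinates in their own base frames up to the purine/pyrimidine
    glycosidic geometry.
    """
    ccd = _ccd_coords(base_type)
    atoms = _build_ribose_ring(base_type)

    def attach(name, host, nb1, nb2):
        b = float(np.linalg.norm(ccd[name] - ccd[host]))
        a1 = angle_between(ccd[nb1], ccd[host], ccd[name])
        a2 = angle_between(ccd[nb2], ccd[host], ccd[name])
        sgn = float(np.linalg.det(np.column_stack([
            ccd[nb1] - ccd[host], ccd[nb2] - ccd[host], ccd[name] - ccd[host]
        ])))
        atoms[name] = atoms[host] + b * _substituent_direction(
            atoms[host], atoms[nb1], atoms[nb2], a1, a2, sgn
        )

    nglyc = glycosidic_nitrogen(base_type)
    attach("O2'", "C2'", "C1'", "C3'")
    attach("O3'", "C3'", "C2'", "C4'")
    attach("C5'", "C4'", "C3'", "O4'")
    attach(nglyc, "C1'", "O4'", "C2'")

    # backbone continues 5'-ward with A-form torsions
    # equilibrium backbone angles (database means), not the CCD ideal
    # conformer's values, so the unit scores relaxed internal terms
    atoms["O5'"] = nerf_place(
        atoms["C3'"], atoms["C4'"], atoms["C5'"],
        float(np.linalg.norm(ccd["O5'"] - ccd["C5'"])), 111.1,
        AFORM_TORSIONS["gamma"],
    )
    atoms["P"] = nerf_place(
        atoms["C4'"], atoms["C5'"], atoms["O5'"],
        float(np.linalg.norm(ccd["P"] - ccd["O5'"])), 120.7,
        AFORM_TORSIONS["beta"],
    )
    for op, tor_off in (("OP1", None), ("OP2", None)):
        atoms[op] = nerf_place(
            atoms["C5'"], atoms["O5'"], atoms["P"],
            float(np.linalg.norm(ccd[op] - ccd["P"])),
            angle_between(ccd["O5'"], ccd["P"], ccd[op]),
            dihedral(ccd["C5'"], ccd["O5'"], ccd["P"], ccd[op]),
        )

    # base: rigid template rolled about the glycosidic bond to the A-form chi
    tmpl = base_template(base_type)
    nb_dir = unit(atoms[nglyc] - atoms["C1'"])
    axes = _frame_axes_with_x(nb_dir)
    placed = {n: atoms["C1'"] + axes @ p for n, p in tmpl.items()}
    c_ref = "C4" if base_type in ("A", "G") else "C2"
    chi_now = dihedral(atoms["O4'"], atoms["C1'"], placed[nglyc], placed[c_ref])
    roll = _axis_angle(nb_dir, AFORM_TORSIONS["chi"] - chi_now)
    for n, p in placed.items():
        atoms[n] = atoms["C1'"] + roll @ (p - atoms["C1'"])

    # re-express everything in the base frame defined by the placed base
    nref, cref = ("N9", "C4") if base_type in ("A", "G") else ("N1", "C2")
    frame = frame_from_atoms(atoms["C1'"], atoms[nref], atoms[cref])
    out = {n: frame.to_local(p) for n, p in atoms.items()}
    for v in out.values():
        v.setflags(write=False)
    return out


def _frame_axes_with_x(x: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal axes with the given x column (arbitrary roll)."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(x, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    z = unit(np.cross(x, ref))
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


@lru_cache(maxsize=None)
def residue_bond_graph(base_type: str) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in _RIBOSE_BONDS + _BASE_BONDS[base_type]:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def atom_type(base_type: str, atom_name: str) -> str:
    """Coarse atom type used for clash statistics.

    OP1/OP2 merge into OP; backbone atoms are typed by name alone; base
    atoms carry the base type so orientation-dependent radii can be
    resolved in the base frame.
    """
    if atom_name in ("OP1", "OP2", "OP3"):
        return "OP"
    if atom_name in RIBOSE_ATOMS or atom_name in ("P", "O5'"):
        return atom_name
    return f"{base_type}.{atom_name}"


def is_base_atom(base_type: str, atom_name: str) -> bool:
    return atom_name in BASE_HEAVY_ATOMS.get(base_type, ())


#: O5'-C5' equilibrium bond length (Angstrom) -- the deliberately
#: flexible linkage used when inserting a phosphate between two riboses
C5_O5_BOND = 1.422
P_O5_BOND = 1.593
P_O5_O3_ANGLE = O3_P_O5_ANGLE


@lru_cache(maxsize=None)
def _op_internal_geometry() -> dict[str, tuple[float, float, float]]:
    """(bond, angle O5'-P-OP, torsion C5'-O5'-P-OP) for OP1/OP2."""
    ccd = _ccd_coords("A")
    out = {}
    for op in ("OP1", "OP2"):
        out[op] = (
            float(np.linalg.norm(ccd[op] - ccd["P"])),
            angle_between(ccd["O5'"], ccd["P"], ccd[op]),
            dihedral(ccd["C5'"], ccd["O5'"], ccd["P"], ccd[op]),
        )
    return out


def place_phosphate_group(
    sugar_i: dict[str, np.ndarray],
    c5_next: np.ndarray,
    eps: float,
    zeta: float,
) -> dict[str, np.ndarray]:
    """Place P, O5', OP1, OP2 of residue i+1 between two riboses.

    The phosphate hangs off the 3' side of ribose i, positioned by the
    torsions eps (C2'-C3'-O3'-P) and zeta (C3'-O3'-P-O5') at ideal bond
    lengths/angles; only the O5'-C5' linkage to ribose i+1 is left
    flexible.  ``c5_next`` is used solely as the torsion reference for
    the OP oxygens.
    """
    p = nerf_place(sugar_i["C2'"], sugar_i["C3'"], sugar_i["O3'"],
                   O3P_BOND, C3_O3_P_ANGLE, eps)
    o5 = nerf_place(sugar_i["C3'"], sugar_i["O3'"], p,
                    P_O5_BOND, O3_P_O5_ANGLE, zeta)
    out = {"P": p, "O5'": o5}
    for op, (bond, ang, tor) in _op_internal_geometry().items():
        out[op] = nerf_place(c5_next, o5, p, bond, ang, tor)
    return out


#: canonical Watson-Crick hydrogen-bond heavy-atom pairs and standard
#: lengths (Angstrom): (purine/first-base atom, partner atom, distance)
WC_HBONDS = {
    ("G", "C"): [("O6", "N4", 2.91), ("N1", "N3", 2.95), ("N2", "O2", 2.86)],
    ("A", "U"): [("N6", "O4", 2.95), ("N1", "N3", 2.82)],
    ("G", "U"): [("O6", "N3", 2.83), ("N1", "O2", 2.79)],
}


def wc_partner(base_type: str) -> str:
    return {"A": "U", "U": "A", "G": "C", "C": "G"}[base_type]
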