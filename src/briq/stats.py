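"""Harvesting interaction statistics from a corpus of RNA structures.

All knowledge-based terms of the energy model are estimated from plain
coordinate files: base-pair orientations (grouped by sequence
separation), base-oxygen and oxygen-oxygen contacts, ribose rotamers,
coupled backbone-torsion distributions, minimum-approach (clash) radii,
and the epsilon-zeta grid used to rebuild phosphates.  The collectors
are deliberately simple O(n^2) scans; corpora are assumed to be curated
by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import chem
from .geometry import (
    BaseFrame,
    RelativeOrientation,
    RigidTransform,
    dihedral,
    ddm_many,
    pair_configuration,
    relative_orientation,
)
from .structure import RnaStructure

log = logging.getLogger(__name__)

SEP_CLASSES = ("1", "2", "2+")
PAIR_TYPES = ("AA", "AC", "AG", "AU", "CC", "CG", "CU", "GG", "GU", "UU")

#: interaction range cut-offs (Angstrom)
PAIR_RANGE = 15.0
BASE_OXYGEN_RANGE = 6.0
OXYGEN_OXYGEN_RANGE = 5.0

OXYGEN_TYPES = ("OP", "O2'", "O3'", "O4'", "O5'")
OO_CLASSES = ("O2'-O2'", "O2'-OP", "OP-OP")

#: covalent parent used to define the hydrogen-bond gating angle
OXYGEN_PARENT = {"OP1": "P", "OP2": "P", "O2'": "C2'", "O3'": "C3'",
                 "O4'": "C4'", "O5'": "C5'"}


def canonical_pair_type(base_i: str, base_j: str) -> str:
    return base_i + base_j if base_i <= base_j else base_j + base_i


def oxygen_type(atom_name: str) -> str | None:
    if atom_name in ("OP1", "OP2"):
        return "OP"
    if atom_name in ("O2'", "O3'", "O4'", "O5'"):
        return atom_name
    return None


# ---------------------------------------------------------------------------
# sphere codebook

@dataclass
class SphereCodebook:
    """Near-uniform set of unit vectors discretising direction space."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, float)

    def __len__(self) -> int:
        return len(self.vectors)

    def nearest(self, v: np.ndarray) -> int:
        return int(np.argmax(self.vectors @ np.asarray(v, float)))

    def nearest_many(self, vs: np.ndarray) -> np.ndarray:
        return np.argmax(np.asarray(vs, float) @ self.vectors.T, axis=1)


def codebook_energy(vectors: np.ndarray) -> float:
    """Total 1/d^2 repulsion energy of a point set on the sphere."""
    d2 = np.sum(
        (vectors[:, None, :] - vectors[None, :, :]) ** 2, axis=-1
    )
    iu = np.triu_indices(len(vectors), k=1)
    return float(np.sum(1.0 / d2[iu]))


def _repulsion_gradient(vectors: np.ndarray) -> np.ndarray:
    diff = vectors[:, None, :] - vectors[None, :, :]
    d2 = np.sum(diff * diff, axis=-1)
    np.fill_diagonal(d2, np.inf)
    # dE/dx_i of sum 1/d^2 = -2 (x_i - x_j) / d^4
    return -2.0 * np.sum(diff / (d2 ** 2)[:, :, None], axis=1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([
        np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def generate_sphere_codebook(n: int, seed: int = 0) -> SphereCodebook:
    """Distribute ``n`` unit vectors by annealed minimisation of pairwise
    1/d^2 repulsion: a seeded random perturbation of a spiral start,
    stochastic descent with a cooled noise temperature, then a noiseless
    polish.  Deterministic for a fixed seed."""
    if n < 4:
        raise ValueError("sphere codebook needs at least 4 points")
    rng = np.random.default_rng(seed)
    spacing = 2.0 / np.sqrt(n / np.pi)   # uniform-packing angle estimate
    v = _fibonacci_sphere(n) + 0.3 * spacing * rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.15 * spacing
    temp = 0.2 * spacing
    iters = 40 if n >= 200 else 300

    def descend(v, noise):
        g = _repulsion_gradient(v)
        g -= np.sum(g * v, axis=1, keepdims=True) * v
        gn = np.linalg.norm(g, axis=1, keepdims=True)
        v = v - step * g / np.maximum(gn, 1e-12)
        if noise > 0:
            v = v + noise * rng.normal(size=v.shape)
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    for _ in range(iters):
        v = descend(v, temp)
        temp *= 0.85
        step *= 0.95

    # noiseless polish: quasi-Newton descent on the repulsion energy of
    # the normalised coordinates
    from scipy.optimize import minimize

    def fun(x):
        pts = x.reshape(n, 3)
        norms = np.linalg.norm(pts, axis=1, keepdims=True)
        u = pts / norms
        diff = u[:, None, :] - u[None, :, :]
        d2 = np.sum(diff * diff, axis=-1)
        np.fill_diagonal(d2, np.inf)
        energy = 0.5 * np.sum(1.0 / d2)
        g_u = -2.0 * np.sum(diff / (d2 ** 2)[:, :, None], axis=1)
        g = (g_u - np.sum(g_u * u, axis=1, keepdims=True) * u) / norms
        return energy, g.ravel()

    res = minimize(fun, v.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 200 if n >= 200 else 2000,
                            "ftol": 1e-12, "gtol": 1e-8})
    v = res.x.reshape(n, 3)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return SphereCodebook(v)


# ---------------------------------------------------------------------------
# pair observations

@dataclass
class PairObservation:
    """One ordered base-base placement harvested from a structure."""

    base_i: str
    base_j: str
    rel: RelativeOrientation
    dmat: np.ndarray
    sep: str
    source: str = ""
    context: str | None = None          # edge-class tag when annotated
    transform: RigidTransform | None = None  # frame_i^-1 o frame_j

    def canonical_dmat(self) -> np.ndarray:
        """Cross-distance matrix with base types in alphabetical order
        (the matrix of the swapped pair is the transpose)."""
        return self.dmat if self.base_i <= self.base_j else self.dmat.T


@dataclass
class PairLibrary:
    """Pair observations grouped by unordered pair type and separation."""

    groups: dict[tuple[str, str], list[PairObservation]] = field(
        default_factory=dict
    )

    def add(self, obs: PairObservation) -> None:
        key = (canonical_pair_type(obs.base_i, obs.base_j), obs.sep)
        self.groups.setdefault(key, []).append(obs)

    def get(self, pair_type: str, sep: str) -> list[PairObservation]:
        return self.groups.get((pair_type, sep), [])

    def all_observations(self) -> list[PairObservation]:
        return [o for g in self.groups.values() for o in g]

    def __len__(self) -> int:
        return sum(len(g) for g in self.groups.values())


def _neighbor_context(ann, i: int, j: int) -> str:
    """Edge-class tag of the sequence-neighbour observation i -> j."""
    from .pairing import step_class

    cls = step_class(ann, min(i, j))
    if cls == "nwc-nb":
        return "nwc-nb-53" if j == i + 1 else "nwc-nb-35"
    return f"{cls}-{'53' if j == i + 1 else '35'}"


def _pair_context(ann, i: int, j: int) -> str | None:
    lo, hi = min(i, j), max(i, j)
    if (lo, hi) in [tuple(sorted(p)) for p in ann.wc_pairs]:
        return "wc-pair"
    if (lo, hi) in [tuple(sorted(p)) for p in ann.nwc_pairs]:
        return "nwc-pair"
    return None


def collect_pair_observations(
    corpus: list[RnaStructure],
    annotations: list | None = None,
) -> PairLibrary:
    """Record every ordered residue pair with origin distance <= 15 A.

    ``annotations`` may supply a PairingAnnotation per structure (flat
    residue order); when present, observations of sequence neighbours
    and annotated pairs are tagged with their edge class so that
    move sets can be built per edge type.
    """
    if not corpus:
        raise ValueError("empty corpus")
    lib = PairLibrary()
    for istruct, struct in enumerate(corpus):
        ann = annotations[istruct] if annotations else None
        frames: list[BaseFrame | None] = []
        for res in struct:
            try:
                frames.append(res.frame())
            except Exception as exc:  # noqa: BLE001 - log-and-skip contract
                log.warning("skipping residue %s%s: %s",
                            res.chain_id, res.index, exc)
                frames.append(None)
        n = len(struct.residues)
        for i in range(n):
            if frames[i] is None:
                continue
            for j in range(n):
                if j == i or frames[j] is None:
                    continue
                rel = None
                d = np.linalg.norm(frames[j].origin - frames[i].origin)
                if d > PAIR_RANGE or d < 1e-6:
                    continue
                rel = relative_orientation(frames[i], frames[j])
                sep = struct.same_chain_separation(i, j)
                ri, rj = struct.residues[i], struct.residues[j]
                context = None
                if ann is not None:
                    if ri.chain_id == rj.chain_id and abs(i - j) == 1:
                        context = _neighbor_context(ann, i, j)
                    else:
                        context = _pair_context(ann, i, j)
                cfg = pair_configuration(ri.base_type, frames[i],
                                         rj.base_type, frames[j], sep)
                lib.add(PairObservation(
                    base_i=ri.base_type, base_j=rj.base_type, rel=rel,
                    dmat=cfg.dmat, sep=sep, source=struct.name,
                    context=context,
                    transform=frames[i].as_transform().inverse().compose(
                        frames[j].as_transform()),
                ))
    return lib


# ---------------------------------------------------------------------------
# polar (base-oxygen / oxygen-oxygen) observations

@dataclass
class BaseOxygenObservation:
    base_type: str
    oxy_type: str
    distances: np.ndarray      # oxygen to the four base pseudo-atoms
    theta: float               # gating angle at the oxygen (degrees)
    polar_distance: float      # oxygen to nearest base N/O atom
    d_min: float               # oxygen to nearest base heavy atom


@dataclass
class OxygenOxygenObservation:
    pair_class: str
    distances: np.ndarray      # six pairwise distances of the four atoms
    d_oo: float


@dataclass
class PolarLibrary:
    base_oxygen: dict[tuple[str, str], list[BaseOxygenObservation]] = field(
        default_factory=dict
    )
    oxygen_oxygen: dict[str, list[OxygenOxygenObservation]] = field(
        default_factory=dict
    )

    def add_bo(self, obs: BaseOxygenObservation) -> None:
        self.base_oxygen.setdefault(
            (obs.base_type, obs.oxy_type), []
        ).append(obs)

    def add_oo(self, obs: OxygenOxygenObservation) -> None:
        self.oxygen_oxygen.setdefault(obs.pair_class, []).append(obs)


def oo_configuration(
    parent_a: np.ndarray, oxy_a: np.ndarray,
    oxy_b: np.ndarray, parent_b: np.ndarray,
) -> np.ndarray:
    """Six pairwise distances of the four defining atoms, in the fixed
    order (Ca-Oa, Ca-Ob, Ca-Cb, Oa-Ob, Oa-Cb, Ob-Cb)."""
    pts = [parent_a, oxy_a, oxy_b, parent_b]
    out = []
    for a in range(4):
        for b in range(a + 1, 4):
            out.append(float(np.linalg.norm(pts[a] - pts[b])))
    return np.array(out)


def oo_pair_class(type_a: str, type_b: str) -> str | None:
    key = "-".join(sorted((type_a, type_b)))
    mapping = {"O2'-O2'": "O2'-O2'", "O2'-OP": "O2'-OP", "OP-OP": "OP-OP"}
    return mapping.get(key)


def base_oxygen_geometry(
    base_type: str, frame: BaseFrame, base_atoms: dict[str, np.ndarray],
    oxy: np.ndarray, parent: np.ndarray,
) -> tuple[np.ndarray, float, float, float]:
    """(pseudo-atom distances, theta, polar distance, min base distance)
    for one oxygen near one base.  theta is measured at the oxygen,
    between the nearest base N/O atom and the oxygen's covalent parent."""
    pseudo = frame.pseudo_atoms()
    dists = np.linalg.norm(pseudo - oxy[None, :], axis=1)
    heavy = np.array([base_atoms[n] for n in chem.BASE_HEAVY_ATOMS[base_type]])
    d_min = float(np.min(np.linalg.norm(heavy - oxy[None, :], axis=1)))
    polar = np.array([base_atoms[n] for n in chem.BASE_POLAR_ATOMS[base_type]])
    pd = np.linalg.norm(polar - oxy[None, :], axis=1)
    k = int(np.argmin(pd))
    v1 = polar[k] - oxy
    v2 = parent - oxy
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return dists, theta, float(pd[k]), d_min


def collect_polar_observations(corpus: list[RnaStructure]) -> PolarLibrary:
    if not corpus:
        raise ValueError("empty corpus")
    lib = PolarLibrary()
    for struct in corpus:
        res_list = struct.residues
        frames = []
        for res in res_list:
            try:
                frames.append(res.frame())
            except Exception:  # noqa: BLE001
                frames.append(None)
        # oxygen inventory: (res index, atom name, type, coord, parent coord)
        oxygens = []
        for idx, res in enumerate(res_list):
            for name, parent in OXYGEN_PARENT.items():
                if name in res.atoms and parent in res.atoms:
                    oxygens.append((idx, name, oxygen_type(name),
                                    res.atoms[name], res.atoms[parent]))
        # base-oxygen
        for ib, res in enumerate(res_list):
            if frames[ib] is None:
                continue
            for (io, name, otype, oxy, parent) in oxygens:
                if io == ib:
                    continue
                geom = base_oxygen_geometry(
                    res.base_type, frames[ib], res.atoms, oxy, parent
                )
                if geom[3] > BASE_OXYGEN_RANGE:
                    continue
                lib.add_bo(BaseOxygenObservation(
                    res.base_type, otype, geom[0], geom[1], geom[2], geom[3]
                ))
        # oxygen-oxygen
        for a in range(len(oxygens)):
            ia, na, ta, oa, pa = oxygens[a]
            for b in range(a + 1, len(oxygens)):
                ib_, nb, tb, ob, pb = oxygens[b]
                if ia == ib_:
                    continue
                cls = oo_pair_class(ta, tb)
                if cls is None:
                    continue
                d = float(np.linalg.norm(oa - ob))
                if d > OXYGEN_OXYGEN_RANGE:
                    continue
                # fixed atom order: O2' side first in mixed class
                if ta <= tb:
                    cfg = oo_configuration(pa, oa, ob, pb)
                else:
                    cfg = oo_configuration(pb, ob, oa, pa)
                lib.add_oo(OxygenOxygenObservation(cls, cfg, d))
    return lib


# ---------------------------------------------------------------------------
# ribose rotamers and torsion statistics

@dataclass
class RiboseRotamer:
    base_type: str
    atoms_local: np.ndarray    # (8,3) ribose atoms in the base frame
    chi: float
    nu: float
    weight: float = 1.0


@dataclass
class RotamerLibrary:
    rotamers: dict[str, list[RiboseRotamer]] = field(default_factory=dict)

    def get(self, base_type: str) -> list[RiboseRotamer]:
        return self.rotamers.get(base_type, [])

    def add(self, rot: RiboseRotamer) -> None:
        self.rotamers.setdefault(rot.base_type, []).append(rot)


def ribose_improper(atoms: dict[str, np.ndarray]) -> float:
    """Improper angle nu between the C2'-C4'-O4' and C2'-C4'-C3' planes."""
    return dihedral(atoms["O4'"], atoms["C2'"], atoms["C4'"], atoms["C3'"])


def glycosidic_chi(base_type: str, atoms: dict[str, np.ndarray]) -> float:
    n = chem.glycosidic_nitrogen(base_type)
    c = "C4" if base_type in ("A", "G") else "C2"
    return dihedral(atoms["O4'"], atoms["C1'"], atoms[n], atoms[c])


def collect_rotamers(corpus: list[RnaStructure]) -> RotamerLibrary:
    if not corpus:
        raise ValueError("empty corpus")
    lib = RotamerLibrary()
    for struct in corpus:
        for res in struct:
            if not all(a in res.atoms for a in chem.RIBOSE_ATOMS):
                continue
            try:
                frame = res.frame()
            except Exception:  # noqa: BLE001
                continue
            local = np.array(
                [frame.to_local(res.atoms[a]) for a in chem.RIBOSE_ATOMS]
            )
            lib.add(RiboseRotamer(
                res.base_type, local,
                glycosidic_chi(res.base_type, res.atoms),
                ribose_improper(res.atoms),
            ))
    for group in lib.rotamers.values():
        w = 1.0 / len(group)
        for rot in group:
            rot.weight = w
    return lib


TORSION_BIN_DEG = 10.0
N_TORSION_BINS = 36
#: improper-angle boundary separating the two sugar-pucker regions;
#: C3'-endo sugars sit at strongly negative nu, C2'-endo near zero/positive
NU_SPLIT_DEG = -25.0


def torsion_bin(angle: float) -> int:
    return int(((angle + 180.0) % 360.0) // TORSION_BIN_DEG) % N_TORSION_BINS


def nu_region(nu: float) -> int:
    return 0 if nu < NU_SPLIT_DEG else 1


@dataclass
class TorsionTables:
    """Smoothed conditional distributions over binned backbone angles:
    P(eps, zeta | nu-region), P(alpha | zeta, beta), P(beta, gamma | nu)."""

    p_ez_nu: np.ndarray    # (2, 36, 36)
    p_a_zb: np.ndarray     # (36, 36, 36) -> last axis alpha
    p_bg_nu: np.ndarray    # (2, 36, 36)

    def energy(self, nu_i: float, eps: float, zeta: float,
               alpha: float, beta: float, gamma: float,
               nu_ip1: float) -> float:
        e1 = -np.log(self.p_ez_nu[nu_region(nu_i),
                                  torsion_bin(eps), torsion_bin(zeta)])
        e2 = -np.log(self.p_a_zb[torsion_bin(zeta), torsion_bin(beta),
                                 torsion_bin(alpha)])
        e3 = -np.log(self.p_bg_nu[nu_region(nu_ip1),
                                  torsion_bin(beta), torsion_bin(gamma)])
        return float(e1 + e2 + e3)


@dataclass
class TorsionSamples:
    """Raw backbone-step angles; also feeds the phosphate search grid."""

    rows: list[tuple[float, float, float, float, float, float, float]] = field(
        default_factory=list
    )  # (nu_i, eps, zeta, alpha, beta, gamma, nu_ip1)


def backbone_step_angles(res_i, res_ip1) -> tuple | None:
    """The seven angles of one dinucleotide step, or None on missing atoms."""
    a, b = res_i.atoms, res_ip1.atoms
    needed_a = ["C2'", "C3'", "O3'", "C4'", "O4'", "C1'"]
    needed_b = ["P", "O5'", "C5'", "C4'", "O4'", "C2'", "C3'", "C1'"]
    if any(x not in a for x in needed_a) or any(x not in b for x in needed_b):
        return None
    nu_i = ribose_improper(a)
    nu_ip1 = ribose_improper(b)
    eps = dihedral(a["C2'"], a["C3'"], a["O3'"], b["P"])
    zeta = dihedral(a["C3'"], a["O3'"], b["P"], b["O5'"])
    alpha = dihedral(a["O3'"], b["P"], b["O5'"], b["C5'"])
    beta = dihedral(b["P"], b["O5'"], b["C5'"], b["C4'"])
    gamma = dihedral(b["O5'"], b["C5'"], b["C4'"], b["O4'"])
    return (nu_i, eps, zeta, alpha, beta, gamma, nu_ip1)


def collect_torsion_samples(corpus: list[RnaStructure]) -> TorsionSamples:
    if not corpus:
        raise ValueError("empty corpus")
    samples = TorsionSamples()
    for struct in corpus:
        for i in range(len(struct.residues) - 1):
            if not struct.is_connected(i):
                continue
            row = backbone_step_angles(struct.residues[i],
                                       struct.residues[i + 1])
            if row is not None:
                samples.rows.append(row)
    return samples


#: width (in bins) of the circular Gaussian applied to the torsion
#: histograms; keeps the binned statistics kernel-smoothed like every
#: other density in the model instead of hard histogram steps
TORSION_BLUR_BINS = 1.0


def _circular_blur(counts: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d

    out = counts
    for ax in axes:
        out = gaussian_filter1d(out, TORSION_BLUR_BINS, axis=ax,
                                mode="wrap")
    return out


def build_torsion_tables(samples: TorsionSamples) -> TorsionTables:
    """Histogram the coupled angles, blur circularly, and add-one
    smooth so every conditional slice is strictly positive."""
    c_ez = np.zeros((2, N_TORSION_BINS, N_TORSION_BINS))
    c_a = np.zeros((N_TORSION_BINS, N_TORSION_BINS, N_TORSION_BINS))
    c_bg = np.zeros((2, N_TORSION_BINS, N_TORSION_BINS))
    for (nu_i, eps, zeta, alpha, beta, gamma, nu_ip1) in samples.rows:
        c_ez[nu_region(nu_i), torsion_bin(eps), torsion_bin(zeta)] += 1
        c_a[torsion_bin(zeta), torsion_bin(beta), torsion_bin(alpha)] += 1
        c_bg[nu_region(nu_ip1), torsion_bin(beta), torsion_bin(gamma)] += 1
    c_ez = _circular_blur(c_ez, (1, 2)) + 1.0
    c_a = _circular_blur(c_a, (0, 1, 2)) + 1.0
    c_bg = _circular_blur(c_bg, (1, 2)) + 1.0
    p_ez = c_ez / c_ez.sum(axis=(1, 2), keepdims=True)
    p_a = c_a / c_a.sum(axis=2, keepdims=True)
    p_bg = c_bg / c_bg.sum(axis=(1, 2), keepdims=True)
    return TorsionTables(p_ez, p_a, p_bg)


# ---------------------------------------------------------------------------
# epsilon-zeta search grid for phosphate rebuilding

@dataclass
class PhosphateGrid:
    """Two-level quantisation of the observed (eps, zeta) torus used by
    the hierarchical phosphate-closure search."""

    reps: np.ndarray        # (n_rep, 2) degrees
    subreps: np.ndarray     # (n_rep, n_sub, 2) degrees


def _circ_kmeans(samples_deg: np.ndarray, k: int, seed: int,
                 iters: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """k-means on the 2-torus via the 4D cos/sin embedding.  Returns
    (centers_deg (k,2), labels).  Deterministic for fixed seed."""
    rng = np.random.default_rng(seed)
    emb = np.column_stack([
        np.cos(np.radians(samples_deg[:, 0])),
        np.sin(np.radians(samples_deg[:, 0])),
        np.cos(np.radians(samples_deg[:, 1])),
        np.sin(np.radians(samples_deg[:, 1])),
    ])
    n = len(emb)
    idx = rng.choice(n, size=k, replace=n < k)
    centers = emb[idx].copy()
    labels = np.zeros(n, int)
    for _ in range(iters):
        d2 = np.sum((emb[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        labels = np.argmin(d2, axis=1)
        for c in range(k):
            members = emb[labels == c]
            if len(members):
                centers[c] = members.mean(axis=0)
    deg = np.column_stack([
        np.degrees(np.arctan2(centers[:, 1], centers[:, 0])),
        np.degrees(np.arctan2(centers[:, 3], centers[:, 2])),
    ])
    return deg, labels


def build_phosphate_grid(samples: TorsionSamples, n_rep: int = 50,
                         n_sub: int = 50, seed: int = 0) -> PhosphateGrid:
    ez = np.array([(r[1], r[2]) for r in samples.rows])
    if len(ez) == 0:
        raise ValueError("no backbone steps to build the phosphate grid from")
    reps, labels = _circ_kmeans(ez, n_rep, seed)
    subreps = np.zeros((n_rep, n_sub, 2))
    # half of the sub-representatives quantise the cluster members, the
    # other half form deterministic rings around the representative so
    # the final 1-degree stage can close onto minima a few degrees away
    # from an over-tight member cloud
    ring = []
    for radius, count in ((1.5, 6), (3.0, 6), (5.0, 7), (8.0, 6)):
        for k in range(count):
            ang = 2 * np.pi * k / count + 0.2 * radius
            ring.append((radius * np.cos(ang), radius * np.sin(ang)))
    ring = np.array(ring)
    for c in range(n_rep):
        members = ez[labels == c]
        if len(members) == 0:
            members = reps[c][None, :]
        k = min(n_sub - len(ring), len(members))
        sub, _ = _circ_kmeans(members, k, seed + 2 + c)
        block = [sub, reps[c][None, :] + ring]
        out = np.vstack(block)
        while len(out) < n_sub:
            out = np.vstack([out, sub[: n_sub - len(out)]])
        subreps[c] = out[:n_sub]
    return PhosphateGrid(reps, subreps)


# ---------------------------------------------------------------------------
# clash radii

FALLBACK_R0 = 2.8
MIN_CLASH_OBS = 20
MIN_CELL_OBS = 10
CLASH_DISTANCE_CAP = 5.0
BOND_SEPARATION_EXEMPT = 3

#: physical hard-core ceilings per element pair (Angstrom).  A percentile
#: estimate from a small corpus can exceed the true minimum approach when a
#: type pair is simply never close in the corpus; radii are clamped to these
#: ceilings (which also serve as fallbacks for unobserved pairs) so the
#: clash term penalises genuine overlap only.
ELEMENT_R0_CAP = {
    ("C", "C"): 3.0, ("C", "N"): 2.9, ("C", "O"): 2.8, ("C", "P"): 3.1,
    ("N", "N"): 2.7, ("N", "O"): 2.6, ("N", "P"): 3.1,
    ("O", "O"): 2.5, ("O", "P"): 2.8, ("P", "P"): 3.5,
}


def _element_of(atom_type: str) -> str:
    name = atom_type.split(".")[-1]
    return name[0]


def element_r0_cap(type_a: str, type_b: str) -> float:
    key = tuple(sorted((_element_of(type_a), _element_of(type_b))))
    return ELEMENT_R0_CAP.get(key, FALLBACK_R0)


def percentile_r0(distances) -> float:
    """Minimum-approach radius from a distance sample: the 5th
    percentile ('lower' interpolation, so 20 values give the smallest)."""
    return float(np.percentile(np.asarray(distances, float), 5,
                               method="lower"))


@dataclass
class ClashTable:
    """Minimum-approach radii per atom-type pair.

    ``isotropic`` maps a sorted type pair to r0; ``oriented`` maps
    (base-atom type, partner type) to a sparse {1 A grid cell: r0}
    resolved in the base-local frame of the base atom's residue."""

    isotropic: dict[tuple[str, str], float] = field(default_factory=dict)
    oriented: dict[tuple[str, str], dict[tuple[int, int, int], float]] = field(
        default_factory=dict
    )
    fallback: float = FALLBACK_R0

    def r0(self, type_a: str, type_b: str,
           cell: tuple[int, int, int] | None = None) -> float:
        if cell is not None:
            grid = self.oriented.get((type_a, type_b))
            if grid and cell in grid:
                return grid[cell]
        key = tuple(sorted((type_a, type_b)))
        cap = element_r0_cap(type_a, type_b)
        return min(self.isotropic.get(key, cap), cap)


def _structure_atom_list(struct: RnaStructure):
    out = []
    for idx, res in enumerate(struct.residues):
        for name, coord in res.atoms.items():
            out.append((idx, res.base_type, name, coord))
    return out


def _bond_separations(struct: RnaStructure, max_sep: int):
    """Map (residue idx, atom) pairs within ``max_sep`` covalent bonds."""
    adj: dict[tuple[int, str], set[tuple[int, str]]] = {}
    for idx, res in enumerate(struct.residues):
        graph = chem.residue_bond_graph(res.base_type)
        for a, nbrs in graph.items():
            if a not in res.atoms:
                continue
            for b in nbrs:
                if b in res.atoms:
                    adj.setdefault((idx, a), set()).add((idx, b))
        if idx + 1 < len(struct.residues) and struct.is_connected(idx):
            adj.setdefault((idx, "O3'"), set()).add((idx + 1, "P"))
            adj.setdefault((idx + 1, "P"), set()).add((idx, "O3'"))
    near: dict[tuple[int, str], dict[tuple[int, str], int]] = {}
    for start in adj:
        dist = {start: 0}
        frontier = [start]
        for depth in range(1, max_sep + 1):
            nxt = []
            for node in frontier:
                for nb in adj.get(node, ()):
                    if nb not in dist:
                        dist[nb] = depth
                        nxt.append(nb)
            frontier = nxt
        near[start] = dist
    return near


def estimate_r0(corpus: list[RnaStructure],
                fallback: float = FALLBACK_R0) -> ClashTable:
    """r0 per type pair = 5th percentile of observed close-approach
    distances (< 5 A), covalent neighbours within 3 bonds excluded;
    orientation-resolved radii on a 1 A base-frame grid where dense."""
    if not corpus:
        raise ValueError("empty corpus")
    samples: dict[tuple[str, str], list[float]] = {}
    cell_samples: dict[tuple[str, str], dict[tuple, list[float]]] = {}
    for struct in corpus:
        atoms = _structure_atom_list(struct)
        near = _bond_separations(struct, BOND_SEPARATION_EXEMPT)
        frames = []
        for res in struct.residues:
            try:
                frames.append(res.frame())
            except Exception:  # noqa: BLE001
                frames.append(None)
        for x in range(len(atoms)):
            ir, bt_i, an_i, c_i = atoms[x]
            for y in range(x + 1, len(atoms)):
                jr, bt_j, an_j, c_j = atoms[y]
                d = float(np.linalg.norm(c_i - c_j))
                if d > CLASH_DISTANCE_CAP:
                    continue
                if (jr, an_j) in near.get((ir, an_i), {}):
                    continue
                ti = chem.atom_type(bt_i, an_i)
                tj = chem.atom_type(bt_j, an_j)
                samples.setdefault(tuple(sorted((ti, tj))), []).append(d)
                for (bres, btype, bname, bcoord, other_t, other_c) in (
                    (ir, bt_i, an_i, c_i, tj, c_j),
                    (jr, bt_j, an_j, c_j, ti, c_i),
                ):
                    if not chem.is_base_atom(btype, bname):
                        continue
                    fr = frames[bres]
                    if fr is None:
                        continue
                    local = fr.to_local(other_c)
                    cell = tuple(np.floor(local).astype(int))
                    key = (chem.atom_type(btype, bname), other_t)
                    cell_samples.setdefault(key, {}).setdefault(
                        cell, []
                    ).append(d)
    table = ClashTable(fallback=fallback)
    for key, vals in samples.items():
        if len(vals) >= MIN_CLASH_OBS:
            table.isotropic[key] = percentile_r0(vals)
    for key, cells in cell_samples.items():
        cap = element_r0_cap(*key)
        grid = {}
        for cell, vals in cells.items():
            if len(vals) >= MIN_CELL_OBS:
                grid[cell] = min(percentile_r0(vals), cap)
        if grid:
            table.oriented[key] = grid
    return table


# ---------------------------------------------------------------------------
# orientation clustering (k-medoids under DDM)

@dataclass
class OrientationClusterSet:
    """Per pair type: representative configurations (medoids) in the
    canonical base order, plus member assignments."""

    pair_type: str
    sep: str
    center_dmats: np.ndarray        # (k, 4, 4)
    assignments: np.ndarray         # (n,) member -> center index
    objective: float                # RMS DDM to nearest center

    @property
    def k(self) -> int:
        return len(self.center_dmats)

    def nearest_center(self, dmat: np.ndarray) -> int:
        return int(np.argmin(ddm_many(dmat, self.center_dmats)))


def cluster_orientations(library: PairLibrary, pair_type: str, sep: str,
                         k: int = 80, seed: int = 0,
                         max_iter: int = 50) -> OrientationClusterSet:
    """k-medoids under the DDM metric, minimising the RMS distance of
    all observations to their nearest medoid.  Observations enter in
    canonical base order so both recording directions share clusters."""
    obs = library.get(pair_type, sep)
    if len(obs) < k:
        raise ValueError(
            f"only {len(obs)} observations for {pair_type}/{sep}; "
            f"use k <= {len(obs)}"
        )
    dmats = np.array([o.canonical_dmat() for o in obs])
    n = len(dmats)
    # full pairwise DDM matrix (fixture-scale corpora keep this small)
    diff = dmats[:, None, :, :] - dmats[None, :, :, :]
    dist = np.sqrt(np.mean(diff * diff, axis=(2, 3)))
    rng = np.random.default_rng(seed)
    medoids = list(rng.choice(n, size=k, replace=False))
    labels = np.argmin(dist[:, medoids], axis=1)
    prev_obj = np.inf
    for _ in range(max_iter):
        for c in range(k):
            members = np.where(labels == c)[0]
            if len(members) == 0:
                continue
            sub = dist[np.ix_(members, members)] ** 2
            medoids[c] = int(members[np.argmin(sub.sum(axis=1))])
        labels = np.argmin(dist[:, medoids], axis=1)
        obj = float(np.sqrt(np.mean(
            dist[np.arange(n), np.array(medoids)[labels]] ** 2
        )))
        if obj >= prev_obj - 1e-12:
            break
        prev_obj = obj
    obj = float(np.sqrt(np.mean(
        dist[np.arange(n), np.array(medoids)[labels]] ** 2
    )))
    return OrientationClusterSet(
        pair_type, sep, dmats[medoids].copy(), labels, obj
    )


# ---------------------------------------------------------------------------
# edge move sets

EDGE_TYPES = ("loop-nb-53", "loop-nb-35", "wc-nb-53", "wc-nb-35",
              "nwc-nb", "wc-pair", "nwc-pair")
#: observation context tags feeding each edge type's move set
EDGE_CONTEXTS = {
    "loop-nb-53": ("loop-nb-53",),
    "loop-nb-35": ("loop-nb-35",),
    "wc-nb-53": ("wc-nb-53",),
    "wc-nb-35": ("wc-nb-35",),
    "nwc-nb": ("nwc-nb-53", "nwc-nb-35"),
    "wc-pair": ("wc-pair",),
    "nwc-pair": ("nwc-pair",),
}
MOVE_SET_REPS = 60
MOVE_SET_SUBREPS = 60

_MOVE_METRIC_POINTS = np.vstack([np.zeros(3), np.eye(3) * 3.0])


def _transform_points(t: RigidTransform) -> np.ndarray:
    return t.apply(_MOVE_METRIC_POINTS)


def _transform_distance_matrix(transforms: list[RigidTransform]) -> np.ndarray:
    pts = np.array([_transform_points(t) for t in transforms])
    diff = pts[:, None] - pts[None, :]
    return np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=-1))


def _medoid_indices(dist: np.ndarray, k: int, seed: int,
                    max_iter: int = 30) -> np.ndarray:
    n = len(dist)
    rng = np.random.default_rng(seed)
    medoids = np.array(rng.choice(n, size=k, replace=False))
    labels = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        changed = False
        for c in range(k):
            members = np.where(labels == c)[0]
            if len(members) == 0:
                continue
            sub = dist[np.ix_(members, members)] ** 2
            best = int(members[np.argmin(sub.sum(axis=1))])
            if best != medoids[c]:
                medoids[c] = best
                changed = True
        labels = np.argmin(dist[:, medoids], axis=1)
        if not changed:
            break
    return medoids


@dataclass
class MoveSet:
    """Hierarchical move set for one edge type: 60 representative edge
    transforms, each refined into 60 sub-representatives (3600 leaves)."""

    edge_type: str
    transforms: list[list[RigidTransform]]   # [rep][subrep]
    representatives: list[RigidTransform] | None = None  # top medoids

    @property
    def n_reps(self) -> int:
        return len(self.transforms)

    @property
    def size(self) -> int:
        return sum(len(sub) for sub in self.transforms)

    def pick(self, rng: np.random.Generator) -> RigidTransform:
        i = int(rng.integers(self.n_reps))
        sub = self.transforms[i]
        return sub[int(rng.integers(len(sub)))]

    def leaves(self):
        return [t for sub in self.transforms for t in sub]


def build_move_set(library: PairLibrary, edge_type: str, seed: int = 0,
                   relax: bool = False) -> MoveSet:
    """Two-level clustering of the edge type's observed transforms.

    The metric is the RMS displacement of a small rigid probe (origin +
    three 3 A axis points), a base-type-independent analogue of the
    pseudo-atom DDM.  With ``relax`` small observation pools are padded
    by resampling with replacement so fixture corpora still yield the
    full 60 x 60 hierarchy.
    """
    contexts = EDGE_CONTEXTS[edge_type]
    pool = [o.transform for o in library.all_observations()
            if o.context in contexts and o.transform is not None]
    need = MOVE_SET_REPS * MOVE_SET_SUBREPS
    if len(pool) == 0:
        raise ValueError(f"no observations for edge type {edge_type!r}")
    if len(pool) < need and not relax:
        raise ValueError(
            f"{len(pool)} observations for edge type {edge_type!r}; "
            f"need {need} (or pass relax=True)"
        )
    rng = np.random.default_rng(seed)
    dist = _transform_distance_matrix(pool)
    k1 = min(MOVE_SET_REPS, len(pool))
    medoids = _medoid_indices(dist, k1, seed)
    labels = np.argmin(dist[:, medoids], axis=1)
    reps: list[list[RigidTransform]] = []
    for c in range(k1):
        members = np.where(labels == c)[0]
        if len(members) == 0:
            members = np.array([medoids[c]])
        k2 = min(MOVE_SET_SUBREPS, len(members))
        sub_d = dist[np.ix_(members, members)]
        sub_medoids = members[_medoid_indices(sub_d, k2, seed + 1 + c)]
        subs = [pool[int(m)] for m in sub_medoids]
        while len(subs) < MOVE_SET_SUBREPS:
            subs.append(pool[int(members[rng.integers(len(members))])])
        reps.append(subs)
    while len(reps) < MOVE_SET_REPS:
        reps.append(list(reps[int(rng.integers(len(reps)))]))
    return MoveSet(edge_type, reps, [pool[int(m)] for m in medoids])


# ---------------------------------------------------------------------------
# QM energy table

QM_SCALE_KCAL = 4.32


@dataclass
class QMTable:
    """Tabulated base-base interaction energies (kcal/mol) for the
    orientation cluster centers, consumed as an external input."""

    energies: dict[str, np.ndarray] = field(default_factory=dict)
    scale: float = QM_SCALE_KCAL

    def get(self, pair_type: str) -> np.ndarray | None:
        return self.energies.get(pair_type)
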