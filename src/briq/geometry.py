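"""Nucleobase reference frames, rigid transforms and orientation metrics.

Every nucleobase is treated as a rigid body carrying a local right-handed
coordinate system: the origin sits on C1', the x-axis points along the
glycosidic bond (C1'->N9 for purines, C1'->N1 for pyrimidines) and the
z-axis along the cross product of the glycosidic bond with the first
in-ring bond (N9->C4, resp. N1->C2).  The relative placement of two bases
is then a point in a six-dimensional rigid-body orientation space:
the origin-origin distance r, the inter-origin direction expressed in
each of the two local systems (two unit vectors), and a twist angle
omega about the inter-origin axis.

For fast similarity comparisons each base is reduced to four fixed
pseudo-atoms (T1..T4) in its local frame; a pair of bases is summarised
by the 4x4 matrix of cross distances between the pseudo-atom sets.  The
DDM metric between two pair configurations is the root-mean-square of
the element-wise differences of their cross-distance matrices.  It is
rotation/translation invariant, zero for congruent configurations, and
correlates tightly with all-atom superposition RMSD while being two
orders of magnitude cheaper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "MissingAtomError",
    "DegenerateGeometryError",
    "BaseFrame",
    "RigidTransform",
    "RelativeOrientation",
    "PSEUDO_ATOM_TEMPLATE",
    "PairConfiguration",
    "build_base_frame",
    "relative_orientation",
    "reconstruct_frame",
    "pair_configuration",
    "ddm",
    "superpose_rmsd",
    "unit",
    "angle_between",
    "dihedral",
]

#: tolerance below which a vector norm is considered degenerate (Angstrom)
DEGENERATE_NORM = 1e-6

#: Four fixed pseudo-atom positions in the base-local frame (Angstrom),
#: shared by all four base types.  Optimised (elsewhere) so that the DDM
#: metric tracks all-atom superposition RMSD.
PSEUDO_ATOM_TEMPLATE = np.array(
    [
        [2.158, 3.826, 1.427],
        [-0.789, -0.329, -1.273],
        [4.520, -3.006, 1.586],
        [6.018, 1.903, -1.638],
    ]
)
PSEUDO_ATOM_TEMPLATE.setflags(write=False)


class GeometryError(ValueError):
    """Base class for geometric construction failures."""


class MissingAtomError(GeometryError):
    """A frame-defining atom is absent from a residue."""


class DegenerateGeometryError(GeometryError):
    """Atoms are collinear/coincident so no frame or axis is defined."""


def unit(v: np.ndarray) -> np.ndarray:
    """Normalise ``v``; raise :class:`DegenerateGeometryError` if ~zero."""
    n = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if n < DEGENERATE_NORM:
        raise DegenerateGeometryError(f"vector norm {n:g} below tolerance")
    return v / n


def angle_between(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    nu = math.sqrt(u @ u)
    nv = math.sqrt(v @ v)
    if nu < DEGENERATE_NORM or nv < DEGENERATE_NORM:
        raise DegenerateGeometryError("coincident atoms in angle")
    return math.degrees(math.acos(
        min(1.0, max(-1.0, float(u @ v) / (nu * nv)))
    ))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in [-180, 180)."""
    b0 = p0 - p1
    b1 = p2 - p1
    n1 = math.sqrt(b1 @ b1)
    if n1 < DEGENERATE_NORM:
        raise DegenerateGeometryError("coincident atoms in dihedral")
    b1 = b1 / n1
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    cx = np.cross(b1, v)
    ang = math.degrees(math.atan2(float(cx @ w), float(v @ w)))
    return (ang + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "translation", np.asarray(self.translation, float))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass(frozen=True)
class BaseFrame:
    """Local coordinate system of a nucleobase.

    ``axes`` holds the x, y, z axis vectors as matrix *columns*, so a
    point p expressed in the local system maps to ``origin + axes @ p``
    in global coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "axes", np.asarray(self.axes, float))
        r = self.axes
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise GeometryError("frame axes are not orthonormal")
        if np.linalg.det(r) < 0:
            raise GeometryError("frame is left-handed")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def to_global(self, local_points: np.ndarray) -> np.ndarray:
        return np.asarray(local_points, float) @ self.axes.T + self.origin

    def to_local(self, global_points: np.ndarray) -> np.ndarray:
        return (np.asarray(global_points, float) - self.origin) @ self.axes

    def as_transform(self) -> RigidTransform:
        return RigidTransform(self.axes, self.origin)

    def transformed(self, t: RigidTransform) -> "BaseFrame":
        return BaseFrame(t.apply(self.origin), t.rotation @ self.axes)

    def pseudo_atoms(self) -> np.ndarray:
        """Global positions of the four pseudo-atoms."""
        return self.to_global(PSEUDO_ATOM_TEMPLATE)


# frame-defining atoms per base type: (glycosidic N, first in-ring C)
FRAME_ATOMS = {
    "A": ("N9", "C4"),
    "G": ("N9", "C4"),
    "C": ("N1", "C2"),
    "U": ("N1", "C2"),
}


def frame_from_atoms(c1p: np.ndarray, n: np.ndarray, c: np.ndarray) -> BaseFrame:
    """Frame with origin C1', x along C1'->N, z along (C1'N x NC)."""
    x = unit(np.asarray(n, float) - np.asarray(c1p, float))
    zraw = np.cross(np.asarray(n, float) - np.asarray(c1p, float),
                    np.asarray(c, float) - np.asarray(n, float))
    if np.linalg.norm(zraw) < DEGENERATE_NORM:
        raise DegenerateGeometryError("frame atoms are collinear")
    z = zraw / np.linalg.norm(zraw)
    y = np.cross(z, x)
    return BaseFrame(np.asarray(c1p, float), np.column_stack([x, y, z]))


def build_base_frame(residue) -> BaseFrame:
    """Build the local frame of a :class:`~briq.structure.BaseResidue`."""
    if residue.base_type not in FRAME_ATOMS:
        raise GeometryError(f"unsupported base type {residue.base_type!r}")
    n_name, c_name = FRAME_ATOMS[residue.base_type]
    for name in ("C1'", n_name, c_name):
        if name not in residue.atoms:
            raise MissingAtomError(
                f"residue {residue.base_type}{residue.index}: missing atom {name}"
            )
    return frame_from_atoms(
        residue.atoms["C1'"], residue.atoms[n_name], residue.atoms[c_name]
    )


def _signed_angle_about(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle from a to b about ``axis`` (right-hand rule), degrees."""
    ap = a - np.dot(a, axis) * axis
    bp = b - np.dot(b, axis) * axis
    na, nb = np.linalg.norm(ap), np.linalg.norm(bp)
    if na < DEGENERATE_NORM or nb < DEGENERATE_NORM:
        raise DegenerateGeometryError("reference axis parallel to rotation axis")
    ap, bp = ap / na, bp / nb
    ang = np.degrees(np.arctan2(np.dot(np.cross(ap, bp), axis), np.dot(ap, bp)))
    return float((ang + 180.0) % 360.0 - 180.0)


def _omega_reference(frame: BaseFrame, axis: np.ndarray) -> np.ndarray:
    """Reference axis for the omega twist: the frame's x-axis, falling back
    to the y-axis when x is (numerically) parallel to the inter-origin axis."""
    x = frame.x
    if np.linalg.norm(x - np.dot(x, axis) * axis) >= 1e-4:
        return x
    return frame.y


@dataclass(frozen=True)
class RelativeOrientation:
    """Six-dimensional relative placement of base j with respect to base i.

    r        -- origin-origin distance (Angstrom)
    omega    -- signed twist about the inter-origin axis (degrees, [-180,180)):
                angle from the projection of frame i's reference axis to the
                projection of frame j's, measured right-handed about the
                i->j direction.
    dir_ij   -- unit inter-origin direction expressed in frame i
    dir_ji   -- unit reverse direction expressed in frame j
    """

    r: float
    omega: float
    dir_ij: np.ndarray
    dir_ji: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "dir_ij", np.asarray(self.dir_ij, float))
        object.__setattr__(self, "dir_ji", np.asarray(self.dir_ji, float))


def relative_orientation(frame_i: BaseFrame, frame_j: BaseFrame) -> RelativeOrientation:
    d = frame_j.origin - frame_i.origin
    r = float(np.linalg.norm(d))
    if r < DEGENERATE_NORM:
        raise DegenerateGeometryError("coincident frame origins")
    u = d / r
    omega = _signed_angle_about(
        _omega_reference(frame_i, u), _omega_reference(frame_j, u), u
    )
    return RelativeOrientation(
        r=r,
        omega=omega,
        dir_ij=frame_i.axes.T @ u,
        dir_ji=frame_j.axes.T @ (-u),
    )


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < DEGENERATE_NORM:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < DEGENERATE_NORM:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _axis_angle(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = unit(np.asarray(axis, float))
    th = np.radians(degrees)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def reconstruct_frame(frame_i: BaseFrame, rel: RelativeOrientation) -> BaseFrame:
    """Invert :func:`relative_orientation`: rebuild frame j from frame i."""
    u = frame_i.axes @ rel.dir_ij  # global i->j direction
    origin_j = frame_i.origin + rel.r * u
    # any rotation R0 with R0 @ dir_ji == -u; the residual freedom is a spin
    # about u, fixed by the omega convention
    r0 = _rotation_aligning(unit(rel.dir_ji), -u)
    cand = BaseFrame(origin_j, r0)
    omega0 = _signed_angle_about(
        _omega_reference(frame_i, u), _omega_reference(cand, u), u
    )
    spin = _axis_angle(u, rel.omega - omega0)
    return BaseFrame(origin_j, spin @ r0)


@dataclass(frozen=True)
class PairConfiguration:
    """Rotation-invariant summary of the relative placement of two bases.

    ``dmat`` is the 4x4 matrix of distances from the pseudo-atoms of base
    i to those of base j; ``sep`` the sequence-separation class
    ("1", "2" or "2+").
    """

    base_i: str
    base_j: str
    dmat: np.ndarray
    sep: str = "2+"

    def __post_init__(self):
        object.__setattr__(self, "dmat", np.asarray(self.dmat, float))


def cross_distance_matrix(points_i: np.ndarray, points_j: np.ndarray) -> np.ndarray:
    diff = points_i[:, None, :] - points_j[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def pair_configuration(
    base_i: str, frame_i: BaseFrame, base_j: str, frame_j: BaseFrame, sep: str = "2+"
) -> PairConfiguration:
    return PairConfiguration(
        base_i,
        base_j,
        cross_distance_matrix(frame_i.pseudo_atoms(), frame_j.pseudo_atoms()),
        sep,
    )


def ddm(config_a: PairConfiguration, config_b: PairConfiguration) -> float:
    """RMS deviation between the pseudo-atom cross-distance matrices (Angstrom).

    Defined only for configurations of the same (ordered) base-type pair.
    """
    if (config_a.base_i, config_a.base_j) != (config_b.base_i, config_b.base_j):
        raise GeometryError(
            f"base-type mismatch: ({config_a.base_i},{config_a.base_j}) vs "
            f"({config_b.base_i},{config_b.base_j})"
        )
    return ddm_matrices(config_a.dmat, config_b.dmat)


def ddm_matrices(dmat_a: np.ndarray, dmat_b: np.ndarray) -> float:
    diff = dmat_a - dmat_b
    return float(np.sqrt(np.mean(diff * diff)))


def ddm_many(dmat: np.ndarray, dmats: np.ndarray) -> np.ndarray:
    """DDM between one 4x4 matrix and a stack of (n,4,4) matrices."""
    if len(dmats) == 0:
        return np.empty(0)
    diff = dmats - dmat[None, :, :]
    return np.sqrt(np.mean(diff * diff, axis=(1, 2)))


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Least-squares RMSD after optimal rigid (Kabsch) superposition."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise GeometryError(f"point-set shape mismatch {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise GeometryError("need at least 3 points for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def kabsch_transform(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Rigid transform minimising |T(mobile) - target|^2."""
    a = np.asarray(mobile, float)
    b = np.asarray(target, float)
    if a.shape != b.shape:
        raise GeometryError("point-set shape mismatch")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, cb - rot @ ca)
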