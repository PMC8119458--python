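"""Internal-consistency measurements of the orientation metric.

The four-pseudo-atom distance-matrix metric (DDM) is used throughout as
a fast surrogate for all-atom superposition RMSD; this module measures
how faithful the surrogate is over random base-base placements.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from . import chem
from .geometry import (
    BaseFrame,
    PSEUDO_ATOM_TEMPLATE,
    cross_distance_matrix,
    ddm_matrices,
    superpose_rmsd,
)

#: minimum heavy-atom separation for a sampled placement to count as
#: clash-free
CLASH_FREE_DISTANCE = 2.5

_PAIRS = [("G", "C"), ("A", "U"), ("G", "U"), ("A", "A"), ("C", "C"),
          ("G", "G"), ("U", "U"), ("A", "C"), ("A", "G"), ("C", "U")]


def _random_placement(rng: np.random.Generator) -> BaseFrame:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    r = rng.uniform(3.0, 15.0)
    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31 - 1))).as_matrix()
    return BaseFrame(r * direction, rot)


def _heavy_local(base_type: str) -> np.ndarray:
    tmpl = chem.base_template(base_type)
    return np.array([tmpl[n] for n in chem.BASE_HEAVY_ATOMS[base_type]])


def _sample_configuration(base_j: str, rng: np.random.Generator,
                          heavy_i: np.ndarray, heavy_j_local: np.ndarray):
    """One clash-free placement of base j relative to base i at identity."""
    while True:
        frame_j = _random_placement(rng)
        heavy_j = heavy_j_local @ frame_j.axes.T + frame_j.origin
        dmin = np.min(np.linalg.norm(
            heavy_i[:, None] - heavy_j[None], axis=2
        ))
        if dmin >= CLASH_FREE_DISTANCE:
            return frame_j, heavy_j


def ddm_rmsd_correlation(n_pairs: int = 10000, seed: int = 0
                         ) -> tuple[float, int]:
    """Pearson correlation between DDM and Kabsch RMSD over ``n_pairs``
    random pairs of clash-free base-base configurations.

    Each sample draws two placements of the same base-type pair (origin
    distance 3-15 A, uniform random rotation); DDM compares their
    pseudo-atom cross-distance matrices, RMSD superposes the combined
    base heavy atoms of one two-base system onto the other.
    """
    rng = np.random.default_rng(seed)
    ddms = np.empty(n_pairs)
    rmsds = np.empty(n_pairs)
    pseudo_i = PSEUDO_ATOM_TEMPLATE
    for k in range(n_pairs):
        bi, bj = _PAIRS[k % len(_PAIRS)]
        heavy_i = _heavy_local(bi)
        heavy_j_local = _heavy_local(bj)
        frame_a, heavy_a = _sample_configuration(bj, rng, heavy_i,
                                                 heavy_j_local)
        frame_b, heavy_b = _sample_configuration(bj, rng, heavy_i,
                                                 heavy_j_local)
        dmat_a = cross_distance_matrix(pseudo_i, frame_a.pseudo_atoms())
        dmat_b = cross_distance_matrix(pseudo_i, frame_b.pseudo_atoms())
        ddms[k] = ddm_matrices(dmat_a, dmat_b)
        coords_a = np.vstack([heavy_i, heavy_a])
        coords_b = np.vstack([heavy_i, heavy_b])
        rmsds[k] = superpose_rmsd(coords_a, coords_b)
    r = float(np.corrcoef(ddms, rmsds)[0, 1])
    return r, n_pairs
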