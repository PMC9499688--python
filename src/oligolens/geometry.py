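"""Core metric computations.

Superposition RMSD (Kabsch), radius of gyration, end-to-end distance,
minimum-image distances under an orthorhombic box, and ring-plane geometry
for aromatic stacking. All lengths in nm, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Residue, Topology

__all__ = [
    "RingGeometry", "SuperpositionResult",
    "min_image_distance", "min_image_displacement", "kabsch_superpose",
    "pairwise_min_distance", "radius_of_gyration", "end_to_end_distance",
    "ring_geometry", "interplane_angle",
]


@dataclass(frozen=True)
class RingGeometry:
    centroid: np.ndarray       # (3,) nm
    normal: np.ndarray         # unit vector, sign-canonicalized
    planarity_rmsd: float      # nm


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray       # (3, 3) proper rotation
    translation: np.ndarray    # (3,) nm
    rmsd: float                # nm


def min_image_displacement(a, b, box=None) -> np.ndarray:
    """Displacement b−a under the orthorhombic minimum-image convention.

    ``a`` and ``b`` broadcast; without a box this is the plain difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite coordinates")
    d = b - a
    if box is not None:
        box = np.asarray(box, dtype=float)
        if not (box > 0).all():
            raise ValueError("box edges must be positive")
        d = d - box * np.round(d / box)
    return d


def min_image_distance(a, b, box=None) -> float | np.ndarray:
    """Minimum-image distance between points (nm). Equals the Euclidean
    distance when no box is given, and never exceeds it."""
    d = min_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def pairwise_min_distance(coords_a: np.ndarray, coords_b: np.ndarray,
                          box=None) -> float:
    """Minimum over all (i, j) of the minimum-image distance between two
    coordinate sets; inf if either set is empty."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.inf
    d = min_image_displacement(coords_a[:, None, :], coords_b[None, :, :], box)
    return float(np.sqrt((d * d).sum(axis=-1)).min())


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper rotation (reflections excluded by the
    determinant correction), translation and post-fit RMSD. Requires >=3
    non-collinear points.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (M, 3) arrays")
    m = ref.shape[0]
    if m < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    ref_c = ref - w @ ref
    mob_c = mob - w @ mob
    # degenerate (collinear) sets have rank-<2 covariance
    if (np.linalg.matrix_rank(ref_c, tol=1e-10) < 2
            or np.linalg.matrix_rank(mob_c, tol=1e-10) < 2):
        raise ValueError("degenerate (collinear) point set")
    h = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = (w @ ref) - rot @ (w @ mob)
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt((w * ((fitted - ref) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration about the center of mass (nm)."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    if not (masses > 0).all():
        raise ValueError("masses must be positive")
    com = masses @ coords / masses.sum()
    dev2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * dev2).sum() / masses.sum()))


def end_to_end_distance(chain_residues: list[Residue], topology: Topology,
                        frame: Frame) -> float:
    """Cα(first)–Cα(last) distance over the amino-acid residues of a chain
    (cap residues excluded), in nm."""
    amino = [r for r in chain_residues if r.name not in ("ACE", "NH2")]
    if len(amino) < 2:
        raise ValueError("need a peptide chain with >=2 amino-acid residues")
    ends = []
    for res in (amino[0], amino[-1]):
        ca = None
        for i in res.atoms:
            if topology.atoms[i].name == "CA":
                ca = i
                break
        if ca is None:
            raise ValueError(f"residue {res.name}{res.seq_number} lacks CA")
        ends.append(frame.coordinates[ca])
    return float(np.linalg.norm(ends[1] - ends[0]))


def ring_geometry(ring_coords: np.ndarray) -> RingGeometry:
    """Centroid, least-squares plane normal and planarity RMSD of a ring.

    The normal is the smallest principal direction of the centered
    coordinates, sign-canonicalized to non-negative z (ties: non-negative
    y, then x) so stored normals are reproducible.
    """
    coords = np.asarray(ring_coords, dtype=float)
    if coords.shape[0] < 5:
        raise ValueError("a ring needs at least 5 atoms")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10:
        raise ValueError("collinear ring atoms")
    normal = vt[2]
    for k in (2, 1, 0):
        if abs(normal[k]) > 1e-12:
            if normal[k] < 0:
                normal = -normal
            break
    out_of_plane = centered @ normal
    return RingGeometry(
        centroid=centroid,
        normal=normal / np.linalg.norm(normal),
        planarity_rmsd=float(np.sqrt((out_of_plane ** 2).mean())),
    )


def interplane_angle(a: RingGeometry, b: RingGeometry) -> float:
    """Acute angle between two ring planes, degrees in [0, 90]; antiparallel
    normals are equivalent (|cos| folding)."""
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(min(1.0, c))))
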