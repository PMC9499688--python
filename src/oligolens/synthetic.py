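"""Deterministic synthetic conformer ensembles.

This module builds test ensembles for the analysis pipeline without any MD
engine: a peptide builder from sequence and backbone dihedrals (internal-
coordinate chain extension), an in-register β-sheet oligomer builder tuned
to satisfy Kabsch–Sander inter-strand hydrogen bonds, a rigid idealized
melatonin, placement of ligands at prescribed stacking geometries, and a
conformer-mixture ensemble generator with target secondary-structure
composition. The generator stands in for replica-exchange sampling: it
emulates ensemble *composition*, not thermodynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .core import Frame, Topology, Trajectory, build_topology
from .geometry import RingGeometry, ring_geometry
from .structure_metrics import (
    assign_secondary_structure,
    kabsch_sander_energy_residues,
    reconstruct_amide_hydrogens,
)
from .templates import ONE_TO_THREE, load_default_templates

logger = logging.getLogger(__name__)

__all__ = ["BuildRecipe", "ScenarioSpec", "build_peptide",
           "build_sheet_oligomer", "build_ligand", "place_ligand_stacked",
           "generate_ensemble", "HIAPP_20_29", "sample_coil_peptide"]

#: Amyloidogenic core of human islet amyloid polypeptide, residues 20-29.
HIAPP_20_29 = "SNNFGAILSS"

# backbone geometry (Å / degrees): Engh-Huber-style ideal values
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

EXTENDED_PHI_PSI = (-119.0, 113.0)
HELIX_PHI_PSI = (-57.0, -47.0)

NM_PER_A = 0.1


@dataclass(frozen=True)
class BuildRecipe:
    """Recipe for a single capped peptide chain."""

    sequence: str = HIAPP_20_29
    phi_psi: tuple[tuple[float, float], ...] | None = None  # per residue, deg
    ace_cap: bool = True
    nh2_cap: bool = True
    seq_start: int = 20           # author numbering of the first residue

    def dihedrals(self) -> list[tuple[float, float]]:
        if self.phi_psi is None:
            return [EXTENDED_PHI_PSI] * len(self.sequence)
        if len(self.phi_psi) != len(self.sequence):
            raise ValueError("phi_psi length must match sequence")
        return [tuple(map(float, pp)) for pp in self.phi_psi]


@dataclass
class ScenarioSpec:
    """Study conditions for a generated ensemble.

    Defaults mirror the octamer system: eight hIAPP 20-29 peptides; when
    ligands are enabled the peptide:ligand molar ratio is 1:4. Composition
    is a dict over {"beta", "coil", "helix"} cell-fraction targets (the
    remainder is unconstrained); ligand_placement is either
    ``{"mode": "random"}`` (non-interacting, >=2 nm from peptides) or
    ``{"mode": "stacked", "angle": deg, "distance": nm, "fraction": f}``.
    """

    n_peptides: int = 8
    n_ligands: int | None = None            # None -> 4 x n_peptides
    composition: dict = field(default_factory=lambda: {"beta": 0.16, "coil": 0.52})
    ligand_placement: dict = field(default_factory=lambda: {"mode": "random"})
    n_frames: int = 400
    noise_sigma: float = 0.005              # nm
    seed: int = 0
    recipe: BuildRecipe = field(default_factory=BuildRecipe)

    def resolved_n_ligands(self) -> int:
        return 4 * self.n_peptides if self.n_ligands is None else self.n_ligands


# ---------------------------------------------------------------------------
# internal-coordinate machinery

def _nerf(c: np.ndarray, b: np.ndarray, a: np.ndarray, bond: float,
          angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d bonded to c with |d-c| = bond, angle(d,c,b) and
    dihedral(d,c,b,a) as given (natural extension reference frame)."""
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # collinear reference; pick any perpendicular
        n = np.cross(bc, [0.0, 0.0, 1.0])
        if np.linalg.norm(n) < 1e-9:
            n = np.cross(bc, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(chi),
                        bond * np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# peptide builder

def _build_chain_coords(recipe: BuildRecipe, templates) -> tuple[list, dict]:
    """Build one chain in Å. Returns (residue entries for build_topology,
    name->coord dict keyed (res_slot, atom_name))."""
    seq3 = []
    for ch in recipe.sequence:
        if ch not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {ch!r}")
        seq3.append(ONE_TO_THREE[ch])
    dihedrals = recipe.dihedrals()
    coords: dict[tuple[int, str], np.ndarray] = {}
    # slot -1 = ACE cap, 0..n-1 residues, slot n = NH2 cap
    if recipe.ace_cap:
        ch3 = np.zeros(3)
        c = np.array([1.52, 0.0, 0.0])
        o = _nerf(c, ch3, ch3 + np.array([0.0, 0.0, 1.0]), 1.231, 121.0, 90.0)
        coords[(-1, "CH3")] = ch3
        coords[(-1, "C")] = c
        coords[(-1, "O")] = o

    prev = None  # (CA_like, C, N_like) of previous peptide unit
    for i, resname in enumerate(seq3):
        phi, psi_prev = dihedrals[i][0], (dihedrals[i - 1][1] if i else None)
        if i == 0:
            if recipe.ace_cap:
                n = _nerf(coords[(-1, "C")], coords[(-1, "CH3")],
                          coords[(-1, "O")], BOND_C_N, ANGLE_CA_C_N, 180.0)
                ca = _nerf(n, coords[(-1, "C")], coords[(-1, "CH3")],
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA)
                c = _nerf(ca, n, coords[(-1, "C")], BOND_CA_C,
                          ANGLE_N_CA_C, phi)
            else:
                n = np.zeros(3)
                ca = np.array([BOND_N_CA, 0.0, 0.0])
                c = _nerf(ca, n, n + np.array([0.0, 0.0, 1.0]),
                          BOND_CA_C, ANGLE_N_CA_C, 90.0)
        else:
            ca_p, c_p, n_p = prev
            n = _nerf(c_p, ca_p, n_p, BOND_C_N, ANGLE_CA_C_N, psi_prev)
            ca = _nerf(n, c_p, ca_p, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c = _nerf(ca, n, c_p, BOND_CA_C, ANGLE_N_CA_C, phi)
        psi = dihedrals[i][1]
        o = _nerf(c, ca, n, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        coords[(i, "N")] = n
        coords[(i, "CA")] = ca
        coords[(i, "C")] = c
        coords[(i, "O")] = o
        # side chain from template internal coordinates
        tmpl = templates[resname]
        local = {"N": n, "CA": ca, "C": c, "O": o}
        for ic in tmpl.ics:
            local[ic.atom] = _nerf(local[ic.parent], local[ic.angref],
                                   local[ic.dihref], ic.bond, ic.angle,
                                   ic.dihedral)
        for an, _ in tmpl.sidechain:
            if an in local:
                coords[(i, an)] = local[an]
        # amide H slot (bisector rule applied afterwards); PRO has none
        if resname != "PRO":
            coords[(i, "H")] = n.copy()  # placeholder, reconstructed below
        prev = (ca, c, n)
    if recipe.nh2_cap:
        ca_p, c_p, n_p = prev
        n_cap = _nerf(c_p, ca_p, n_p, BOND_C_N, ANGLE_CA_C_N, dihedrals[-1][1])
        h1 = _nerf(n_cap, c_p, ca_p, 1.01, 119.0, 0.0)
        h2 = _nerf(n_cap, c_p, ca_p, 1.01, 119.0, 180.0)
        coords[(len(seq3), "N")] = n_cap
        coords[(len(seq3), "HN1")] = h1
        coords[(len(seq3), "HN2")] = h2

    entries = []
    if recipe.ace_cap:
        entries.append(("ACE", recipe.seq_start - 1, ["CH3", "C", "O"]))
    for i, resname in enumerate(seq3):
        tmpl = templates[resname]
        names = ["N"] + (["H"] if resname != "PRO" else []) + ["CA", "C", "O"]
        names += [an for an, _ in tmpl.sidechain if (i, an) in coords]
        entries.append((resname, recipe.seq_start + i, names))
    if recipe.nh2_cap:
        entries.append(("NH2", recipe.seq_start + len(seq3), ["N", "HN1", "HN2"]))
    return entries, coords


def build_peptide(recipe: BuildRecipe, chain_id: str = "A",
                  templates=None) -> tuple[Topology, Frame]:
    """Build a single capped peptide chain from a recipe.

    The backbone is grown by sequential internal-coordinate extension with
    ideal bond lengths/angles and trans peptide bonds; side chains attach
    from the packaged templates at fixed default rotamers; amide hydrogens
    are placed by the carbonyl-bisector rule. Deterministic: the same
    recipe always yields bit-identical coordinates.
    """
    tset = templates if templates is not None else load_default_templates()
    entries, coords = _build_chain_coords(recipe, tset)
    topology = build_topology([(chain_id, "peptide", entries)], templates=tset)
    xyz = np.zeros((topology.n_atoms, 3))
    slot_of_res = {}
    k = 0
    if recipe.ace_cap:
        slot_of_res[0] = -1
        k = 1
    for i in range(len(recipe.sequence)):
        slot_of_res[k + i] = i
    if recipe.nh2_cap:
        slot_of_res[k + len(recipe.sequence)] = len(recipe.sequence)
    for ri, res in enumerate(topology.residues):
        slot = slot_of_res[ri]
        for gi in res.atoms:
            xyz[gi] = coords[(slot, topology.atoms[gi].name)] * NM_PER_A
    frame = reconstruct_amide_hydrogens(Frame(coordinates=xyz), topology)
    return topology, frame


def sample_coil_peptide(recipe: BuildRecipe, rng: np.random.Generator,
                        templates=None, max_tries: int = 60
                        ) -> tuple[Topology, Frame]:
    """Build a random-coil conformer: per-residue (φ,ψ) drawn uniformly
    outside the α-helix and β-strand basins, with heavy-atom self-clash
    rejection (<0.25 nm between residues ≥2 apart)."""
    tset = templates if templates is not None else load_default_templates()
    n = len(recipe.sequence)
    best = None
    for _ in range(max_tries):
        pp = []
        for _ in range(n):
            while True:
                phi = rng.uniform(-180.0, 180.0)
                psi = rng.uniform(-180.0, 180.0)
                if (abs(phi - HELIX_PHI_PSI[0]) < 35 and
                        abs(psi - HELIX_PHI_PSI[1]) < 35):
                    continue
                if -155 <= phi <= -85 and 85 <= psi <= 155:
                    continue  # β-strand basin
                break
            pp.append((phi, psi))
        cand = BuildRecipe(sequence=recipe.sequence, phi_psi=tuple(pp),
                           ace_cap=recipe.ace_cap, nh2_cap=recipe.nh2_cap,
                           seq_start=recipe.seq_start)
        top, frame = build_peptide(cand, templates=tset)
        if not _self_clash(top, frame):
            return top, frame
        best = (top, frame)
    logger.warning("coil sampling: clash rejection exhausted; using last draw")
    return best


def _self_clash(top: Topology, frame: Frame, cutoff: float = 0.25) -> bool:
    heavy = top.heavy_indices()
    res_of = np.array([top.atoms[i].residue_index for i in heavy])
    xyz = frame.coordinates[heavy]
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    sep = np.abs(res_of[:, None] - res_of[None, :])
    mask = sep >= 2
    return bool((d[mask] < cutoff).any())


# ---------------------------------------------------------------------------
# sheet oligomer builder

def _strand_frame_axes(top: Topology, frame: Frame):
    """Orthonormal axes of a built strand: u along the strand (Cα first→
    last); v the mean carbonyl direction (sign-alternated over the
    2-residue strand repeat), i.e. the direction along which a neighbour
    strand hydrogen-bonds; w = u × v (side-chain/pleat normal)."""
    amino = [ri for ri, res in enumerate(top.residues)
             if res.name not in ("ACE", "NH2")]
    cas = [top.atom_index(ri, "CA") for ri in amino]
    pts = frame.coordinates[cas]
    u = pts[-1] - pts[0]
    u /= np.linalg.norm(u)
    co = []
    for k, ri in enumerate(amino):
        c = frame.coordinates[top.atom_index(ri, "C")]
        o = frame.coordinates[top.atom_index(ri, "O")]
        d = (o - c) / np.linalg.norm(o - c)
        co.append(d if k % 2 == 0 else -d)
    v = np.mean(co, axis=0)
    v -= (v @ u) * u
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return u, v, w


def _interstrand_ks_score(top2: Topology, frame2: Frame) -> float:
    """Sum of clipped Kabsch–Sander energies over near-register inter-strand
    donor/acceptor pairs of a 2-chain topology (lower = better sheet), plus
    a steep steric wall below 0.25 nm heavy-atom separation so the
    optimizer cannot collapse the strands onto each other."""
    chains = top2.peptide_chains()
    amino = []
    for c in chains:
        amino.append([ri for ri in c.residues
                      if top2.residues[ri].name not in ("ACE", "NH2")])
    heavy = top2.heavy_indices()
    n_half = top2.n_atoms // 2
    xyz_a = frame2.coordinates[[i for i in heavy if i < n_half]]
    xyz_b = frame2.coordinates[[i for i in heavy if i >= n_half]]
    d = np.linalg.norm(xyz_a[:, None] - xyz_b[None], axis=-1)
    clash = np.maximum(0.0, 0.24 - d)
    total = float(1e4 * (clash ** 2).sum())
    for a_res in amino[0]:
        for b_res in amino[1]:
            ia = amino[0].index(a_res)
            ib = amino[1].index(b_res)
            if abs(ia - ib) > 1:
                continue
            for don, acc in ((a_res, b_res), (b_res, a_res)):
                try:
                    e = kabsch_sander_energy_residues(don, acc, frame2, top2)
                except ValueError:
                    continue
                # clip at a realistic strong-bond energy so shrinking a
                # bond below ~-3 kcal/mol gains nothing
                total += float(np.clip(e, -3.0, 0.0))
    return total


@lru_cache(maxsize=8)
def _sheet_pair_cached(sequence: str, ace_cap: bool, nh2_cap: bool,
                       seq_start: int, registry: str, spacing: float):
    recipe = BuildRecipe(sequence=sequence, phi_psi=None, ace_cap=ace_cap,
                         nh2_cap=nh2_cap, seq_start=seq_start)
    tset = load_default_templates()
    top1, frame1 = build_peptide(recipe, templates=tset)
    u, v, w = _strand_frame_axes(top1, frame1)
    xyz1 = frame1.coordinates
    center = xyz1.mean(axis=0)

    def transform(params):
        """Strand-2 coordinates for placement parameters (stagger along u,
        spacing along v, lift along w, small rotation about u)."""
        s, dv, dw, rot_u = params
        xyz = xyz1 - center
        if registry == "antiparallel":
            xyz = Rotation.from_rotvec(np.pi * v).apply(xyz)
        if abs(rot_u) > 1e-12:
            xyz = Rotation.from_rotvec(rot_u * u).apply(xyz)
        return xyz + center + s * u + dv * v + dw * w

    entries1, _ = _build_chain_coords(recipe, tset)
    top2 = build_topology([("A", "peptide", entries1),
                           ("B", "peptide", entries1)], templates=tset)

    def score(params):
        xyz2 = transform(params)
        coords = np.vstack([xyz1, xyz2])
        fr = reconstruct_amide_hydrogens(Frame(coordinates=coords), top2)
        return _interstrand_ks_score(top2, fr)

    # coarse deterministic grid over (stagger, spacing, lift), both sides
    # of the strand, then bounded local refinement from the best cell
    best_x, best_f = None, np.inf
    for sv in (spacing, -spacing):
        for s0 in np.linspace(-0.3, 0.3, 7):
            for dv0 in np.array([0.88, 0.96, 1.04, 1.12]) * sv:
                for dw0 in (-0.1, 0.0, 0.1):
                    f = score([s0, dv0, dw0, 0.0])
                    if f < best_f:
                        best_x, best_f = [s0, dv0, dw0, 0.0], f

    lo = np.array(best_x) - [0.12, 0.10, 0.10, 0.25]
    hi = np.array(best_x) + [0.12, 0.10, 0.10, 0.25]

    def boxed_score(params):
        # quadratic penalty keeps the refinement inside the grid cell
        excess = np.maximum(0.0, np.asarray(params) - hi) + \
            np.maximum(0.0, lo - np.asarray(params))
        return score(params) + 1e4 * float((excess ** 2).sum())

    res = minimize(boxed_score, x0=best_x, method="Nelder-Mead",
                   options={"maxiter": 600, "xatol": 1e-4, "fatol": 1e-6})
    params = res.x if res.fun < best_f else np.asarray(best_x)
    xyz2 = transform(params)
    # the optimized inter-strand rigid step, reapplied for further strands
    return recipe, tset, xyz1, xyz2, (u, v, w, params, center)


def build_sheet_oligomer(n_strands: int, recipe: BuildRecipe | None = None,
                         registry: str = "parallel",
                         strand_spacing: float = 0.48,
                         chain_ids: list[str] | None = None
                         ) -> tuple[Topology, Frame]:
    """In-register β-sheet of ``n_strands`` extended strands.

    Strand 1 is the extended conformer of the recipe; each further strand
    is the previous one advanced by an inter-strand rigid step whose
    stagger/spacing/lift (initialised at ``strand_spacing`` nm along the
    H-bond direction) is tuned once per (sequence, registry, spacing) to
    minimise the summed Kabsch–Sander energy of near-register inter-strand
    pairs, so interior residues satisfy backbone H-bonds.
    """
    if n_strands < 2:
        raise ValueError("need at least 2 strands")
    if strand_spacing <= 0:
        raise ValueError("strand spacing must be positive")
    if registry not in ("parallel", "antiparallel"):
        raise ValueError("registry must be parallel or antiparallel")
    recipe = recipe or BuildRecipe()
    if recipe.phi_psi is not None:
        raise ValueError("sheet builder uses the extended conformer; "
                         "leave phi_psi unset")
    rec, tset, xyz1, xyz2, (u, v, w, params, center) = _sheet_pair_cached(
        recipe.sequence, recipe.ace_cap, recipe.nh2_cap, recipe.seq_start,
        registry, strand_spacing)
    s, dv, dw, rot_u = params
    strands = [xyz1, xyz2]
    while len(strands) < n_strands:
        prev = strands[-2 if registry == "antiparallel" else -1]
        if registry == "antiparallel":
            # repeat the two-strand motif with a pure translation
            shift = 2 * (dv * v)
            strands.append(prev + shift + 0 * u)
        else:
            strands.append(prev + s * u + dv * v + dw * w)
    ids = chain_ids or [chr(ord("A") + k) for k in range(n_strands)]
    entries, _ = _build_chain_coords(rec, tset)
    top = build_topology([(cid, "peptide", entries) for cid in ids],
                         templates=tset)
    coords = np.vstack(strands[:n_strands])
    frame = reconstruct_amide_hydrogens(Frame(coordinates=coords), top)
    return top, frame


# ---------------------------------------------------------------------------
# ligand

def build_ligand(templates=None, chain_id: str = "x") -> tuple[Topology, Frame]:
    """Rigid idealized melatonin from the packaged internal coordinates:
    planar indole (benzene + pyrrole rings annotated), 5-methoxy, and an
    N-acetyl amide bearing the donor N-H and acceptor C=O."""
    tset = templates if templates is not None else load_default_templates()
    tmpl = tset["MEL"]
    local: dict[str, np.ndarray] = {}
    order = [an for an, _ in tmpl.sidechain]
    first = order[0]
    local[first] = np.zeros(3)
    for ic in tmpl.ics:
        if ic.angref is None:
            local[ic.atom] = local[ic.parent] + np.array([ic.bond, 0.0, 0.0])
        elif ic.dihref is None:
            a_dummy = local[ic.angref] + np.array([0.0, 0.0, 1.0])
            local[ic.atom] = _nerf(local[ic.parent], local[ic.angref],
                                   a_dummy, ic.bond, ic.angle, 90.0)
        else:
            local[ic.atom] = _nerf(local[ic.parent], local[ic.angref],
                                   local[ic.dihref], ic.bond, ic.angle,
                                   ic.dihedral)
    entries = [("MEL", 1, order)]
    top = build_topology([(chain_id, "ligand", entries)], templates=tset)
    xyz = np.array([local[top.atoms[i].name] for i in range(top.n_atoms)])
    return top, Frame(coordinates=xyz * NM_PER_A)


def place_ligand_stacked(ligand_coords: np.ndarray, ring_indices: list[int],
                         target: RingGeometry, angle: float,
                         centroid_distance: float) -> np.ndarray:
    """Rigidly move a ligand so that its (benzene) ring centroid sits at
    ``centroid_distance`` along the target ring normal and the interplane
    angle equals ``angle`` degrees; the residual azimuthal freedom is fixed
    by the minimal rotation taking the ligand normal onto the prescribed
    direction."""
    if not (0.0 <= angle <= 90.0):
        raise ValueError("angle must be in [0, 90] degrees")
    if centroid_distance <= 0:
        raise ValueError("centroid distance must be positive")
    own = ring_geometry(ligand_coords[ring_indices])
    nt = target.normal
    # deterministic in-plane direction for tilting
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(nt @ seed_vec) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    e1 = seed_vec - (seed_vec @ nt) * nt
    e1 /= np.linalg.norm(e1)
    desired = np.cos(np.radians(angle)) * nt + np.sin(np.radians(angle)) * e1
    axis = np.cross(own.normal, desired)
    s = np.linalg.norm(axis)
    c = float(own.normal @ desired)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else Rotation.from_rotvec(np.pi * e1).as_matrix()
    else:
        rot = Rotation.from_rotvec(axis / s * np.arctan2(s, c)).as_matrix()
    destination = target.centroid + centroid_distance * nt
    return (ligand_coords - own.centroid) @ rot.T + destination


# ---------------------------------------------------------------------------
# ensemble generator

def _chain_yields(recipe: BuildRecipe, noise_sigma: float = 0.0,
                  coil_frames: list[Frame] | None = None,
                  coil_topology: Topology | None = None
                  ) -> dict[str, dict[str, float]]:
    """Per-conformer-state secondary-structure cell yields, measured on the
    builder's own prototypes under the ensemble's coordinate noise (fixed
    internal RNG for the noise replicates). When the caller supplies its
    coil pool, the coil yield is the pool's own measured yield."""
    from .structure_metrics import CATEGORIES

    noise_rng = np.random.default_rng(1889)

    def noisy(frames):
        if noise_sigma <= 0:
            return frames
        return [Frame(coordinates=f.coordinates
                      + noise_rng.normal(0, noise_sigma,
                                         f.coordinates.shape))
                for f in frames]

    def fractions(top, frames):
        traj = Trajectory(topology=top, frames=noisy(frames))
        cats = assign_secondary_structure(traj).categories
        return {c: float((cats == c).mean()) for c in CATEGORIES}

    top_s, fr_s = build_sheet_oligomer(2, BuildRecipe(
        sequence=recipe.sequence, ace_cap=recipe.ace_cap,
        nh2_cap=recipe.nh2_cap, seq_start=recipe.seq_start))
    y_sheet = fractions(top_s, [fr_s] * 8)
    top_h, fr_h = build_peptide(BuildRecipe(
        sequence=recipe.sequence,
        phi_psi=tuple([HELIX_PHI_PSI] * len(recipe.sequence)),
        ace_cap=recipe.ace_cap, nh2_cap=recipe.nh2_cap,
        seq_start=recipe.seq_start))
    y_helix = fractions(top_h, [fr_h] * 8)
    if coil_frames is not None:
        y_coil = fractions(coil_topology, coil_frames)
    else:
        rng = np.random.default_rng(977)
        frames = []
        top_c = None
        for _ in range(40):
            top_c, fr_c = sample_coil_peptide(recipe, rng)
            frames.append(fr_c)
        y_coil = fractions(top_c, frames)
    return {"sheet": y_sheet, "helix": y_helix, "coil": y_coil}


def _state_probabilities(composition: dict, yields: dict) -> dict[str, float]:
    """Solve chain-state probabilities so expected cell fractions match the
    composition targets (beta via the sheet state; coil via the mix)."""
    t_beta = float(composition.get("beta", 0.0))
    p_s = 0.0
    if t_beta > 0:
        y = yields["sheet"]["beta_sheet"]
        if y <= 0:
            raise RuntimeError("sheet prototype yields no beta-sheet cells")
        p_s = min(1.0, t_beta / y)
    rest = 1.0 - p_s
    t_coil = composition.get("coil")
    t_helix = composition.get("helix")
    y_sc = yields["sheet"]["coil"]
    y_hc = yields["helix"]["coil"]
    y_cc = yields["coil"]["coil"]
    if t_helix is not None and yields["helix"]["helix"] > 0:
        p_h = min(rest, float(t_helix) / yields["helix"]["helix"])
        p_c = rest - p_h
    elif t_coil is not None:
        denom = y_cc - y_hc
        if abs(denom) < 1e-9:
            p_c = rest
        else:
            p_c = (float(t_coil) - p_s * y_sc - rest * y_hc) / denom
        p_c = float(np.clip(p_c, 0.0, rest))
        p_h = rest - p_c
    else:
        p_c, p_h = rest, 0.0
    return {"sheet": p_s, "helix": p_h, "coil": p_c}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def generate_ensemble(spec: ScenarioSpec, templates=None) -> Trajectory:
    """Generate a deterministic conformer-mixture ensemble.

    Each frame draws per-chain conformer states (β-sheet pair member /
    helix / random coil) with probabilities calibrated so the expected
    secondary-structure cell fractions match the composition targets;
    units are packed at random orientations without heavy-atom overlap;
    ligands are placed per the scenario; isotropic Gaussian noise of
    ``noise_sigma`` nm is added; every frame carries the cubic box.
    """
    tset = templates if templates is not None else load_default_templates()
    rng = np.random.default_rng(spec.seed)
    recipe = spec.recipe
    n_pep = spec.n_peptides
    n_lig = spec.resolved_n_ligands()

    # coil conformer pool: built once from the ensemble seed, reused across
    # frames. Its secondary-structure yield is measured exactly (under the
    # ensemble noise), which removes calibration bias from the coil state.
    # pool scales with ensemble length: small ensembles need few distinct
    # coils, long ones enough diversity for stable statistics
    pool_size = int(min(192, max(16, spec.n_frames)))
    top_c, _ = build_peptide(recipe, templates=tset)
    coil_pool = [sample_coil_peptide(recipe, rng, templates=tset)[1].coordinates
                 for _ in range(pool_size)]
    yields = _chain_yields(recipe, noise_sigma=spec.noise_sigma,
                           coil_frames=[Frame(coordinates=c)
                                        for c in coil_pool],
                           coil_topology=top_c)
    probs = _state_probabilities(spec.composition, yields)
    logger.info("state probabilities: %s", probs)

    # prototypes (chain-local coordinates)
    top1, frame1 = build_peptide(recipe, templates=tset)
    n_chain_atoms = top1.n_atoms
    top_pair, fr_pair = build_sheet_oligomer(2, BuildRecipe(
        sequence=recipe.sequence, ace_cap=recipe.ace_cap,
        nh2_cap=recipe.nh2_cap, seq_start=recipe.seq_start))
    pair_coords = (fr_pair.coordinates[:n_chain_atoms],
                   fr_pair.coordinates[n_chain_atoms:])
    top_hel, fr_hel = build_peptide(BuildRecipe(
        sequence=recipe.sequence,
        phi_psi=tuple([HELIX_PHI_PSI] * len(recipe.sequence)),
        ace_cap=recipe.ace_cap, nh2_cap=recipe.nh2_cap,
        seq_start=recipe.seq_start), templates=tset)
    lig_top1, lig_frame1 = build_ligand(templates=tset)
    lig_coords0 = lig_frame1.coordinates
    lig_ring = lig_top1.residues[0].rings[0]  # benzene listed first

    # full topology: peptide chains A.., then ligand chains
    pep_ids = [chr(ord("A") + k) for k in range(n_pep)]
    entries, _ = _build_chain_coords(recipe, tset)
    lig_order = [an for an, _ in tset["MEL"].sidechain]
    chain_specs = [(cid, "peptide", entries) for cid in pep_ids]
    for k in range(n_lig):
        chain_specs.append((f"L{k + 1}", "ligand", [("MEL", 1, lig_order)]))
    topology = build_topology(chain_specs, templates=tset)

    # box: cubic, 3x the largest unit extent
    extent = max(
        np.ptp(fr_pair.coordinates, axis=0).max(),
        np.ptp(frame1.coordinates, axis=0).max(),
    )
    box_edge = 3.0 * extent
    box = np.full(3, box_edge)

    # F23-equivalent ring (first PHE residue of each chain) for stacking
    phe_ring_of_chain: dict[int, list[int]] = {}
    for ci, chain in enumerate(topology.chains[:n_pep]):
        for ri in chain.residues:
            res = topology.residues[ri]
            if res.rings:
                phe_ring_of_chain[ci] = res.rings[0]
                break

    n_atoms = topology.n_atoms
    lig_atoms_per = lig_top1.n_atoms
    frames = []
    min_sep = 0.30  # nm between units (> the 0.2 nm overlap bound)
    for fi in range(spec.n_frames):
        # ---- chain states
        states = ["coil"] * n_pep
        order = rng.permutation(n_pep)
        n_pairs = n_pep // 2
        pair_slots = [(order[2 * k], order[2 * k + 1]) for k in range(n_pairs)]
        leftovers = list(order[2 * n_pairs:])
        units: list[tuple[list[int], np.ndarray]] = []  # (chain idx, coords)
        for a, b in pair_slots:
            if rng.random() < probs["sheet"]:
                states[a] = states[b] = "sheet"
                units.append(([a, b], np.vstack(pair_coords)))
            else:
                leftovers.extend([a, b])
        p_rest = probs["helix"] + probs["coil"]
        for ci in leftovers:
            if p_rest > 0 and rng.random() < probs["helix"] / p_rest:
                states[ci] = "helix"
                units.append(([ci], fr_hel.coordinates.copy()))
            else:
                states[ci] = "coil"
                pick = int(rng.integers(len(coil_pool)))
                units.append(([ci], coil_pool[pick]))

        # ---- packing
        placed_heavy: list[np.ndarray] = []
        coords = np.zeros((n_atoms, 3))
        for chains_in_unit, unit_xyz in units:
            unit_xyz = unit_xyz - unit_xyz.mean(axis=0)
            ok = False
            for _ in range(200):
                rot = _random_rotation(rng)
                pos = rng.uniform(0.15 * box_edge, 0.85 * box_edge, size=3)
                cand = unit_xyz @ rot.T + pos
                if all(_min_dist(cand, other) >= min_sep
                       for other in placed_heavy):
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    "unit packing failed after 200 tries; the box is too "
                    "crowded — reduce n_peptides or enlarge the box")
            placed_heavy.append(cand)
            for slot, ci in enumerate(chains_in_unit):
                lo = slot * n_chain_atoms
                target_atoms = [gi for ri in topology.chains[ci].residues
                                for gi in topology.residues[ri].atoms]
                coords[target_atoms] = cand[lo:lo + n_chain_atoms]

        # ---- ligands
        placement = dict(spec.ligand_placement)
        mode = placement.get("mode", "random")
        stack_targets: list[int] = []
        if n_lig and mode == "stacked":
            frac = float(placement.get("fraction", 1.0))
            ring_chains = list(phe_ring_of_chain)
            # at most one stacked ligand per aromatic ring
            n_stacked = min(int(round(frac * n_lig)), len(ring_chains))
            stack_targets = ring_chains[:n_stacked]
        for k in range(n_lig):
            ci = n_pep + k
            target_atoms = [gi for ri in topology.chains[ci].residues
                            for gi in topology.residues[ri].atoms]
            if k < len(stack_targets):
                ring_idx = phe_ring_of_chain[stack_targets[k]]
                ring_geo = ring_geometry(coords[ring_idx])
                lig_xyz = _random_rotation(rng) @ lig_coords0.T
                lig_xyz = place_ligand_stacked(
                    lig_xyz.T, lig_ring, ring_geo,
                    float(placement.get("angle", 60.0)),
                    float(placement.get("distance", 0.48)))
            else:
                base = lig_coords0 - lig_coords0.mean(axis=0)
                for _ in range(200):
                    rot = _random_rotation(rng)
                    pos = rng.uniform(0.05 * box_edge, 0.95 * box_edge, size=3)
                    lig_xyz = base @ rot.T + pos
                    far_pep = all(_min_dist(lig_xyz, ph) >= 2.0
                                  for ph in placed_heavy[:len(units)])
                    far_lig = all(_min_dist(lig_xyz, placed_heavy[j]) >= min_sep
                                  for j in range(len(units), len(placed_heavy)))
                    if far_pep and far_lig:
                        break
                else:
                    raise RuntimeError("ligand packing failed; enlarge the box")
            placed_heavy.append(lig_xyz)
            coords[target_atoms] = lig_xyz[:lig_atoms_per]

        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        frames.append(Frame(coordinates=coords, box=box.copy(), time=float(fi)))
    return Trajectory(topology=topology, frames=frames)


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((d * d).sum(axis=-1)).min())
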