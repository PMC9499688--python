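"""Secondary-structure assignment and solvent-accessible surface area.

Secondary structure is assigned by a self-contained implementation of the
classic Kabsch–Sander rules ("DSSP-lite"): backbone hydrogen bonds from the
electrostatic energy criterion, n-turns, parallel/antiparallel bridges and
ladders, bends, and the 8-state code {H,G,I,E,B,T,S,C}, mapped onto the six
reporting categories helix / β-sheet / β-bridge / turn / bend / coil.
SASA uses the Shrake–Rupley rolling-probe algorithm with a deterministic
golden-spiral sphere lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, Topology, Trajectory

__all__ = [
    "SecondaryStructureAssignment", "SasaResult",
    "reconstruct_amide_hydrogens", "kabsch_sander_energy",
    "assign_secondary_structure", "ss_population",
    "shrake_rupley_sasa", "CATEGORY_OF_CODE", "CATEGORIES",
]

#: Kabsch–Sander electrostatic prefactor, kcal/mol·Å.
KS_PREFACTOR = 0.084 * 332.0
#: H-bond assignment threshold, kcal/mol.
KS_CUTOFF = -0.5

CATEGORIES = ("helix", "beta_sheet", "beta_bridge", "turn", "bend", "coil")
CATEGORY_OF_CODE = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "beta_sheet", "B": "beta_bridge",
    "T": "turn", "S": "bend", "C": "coil",
}


@dataclass
class SecondaryStructureAssignment:
    """Per-frame × per-residue 8-state codes for the amino-acid residues of
    all peptide chains (caps excluded), plus the residue labels."""

    codes: np.ndarray            # (n_frames, n_residues) of single characters
    residue_indices: list[int]   # topology residue indices, same order
    labels: list[str]            # e.g. "S20"

    @property
    def categories(self) -> np.ndarray:
        cat = np.empty(self.codes.shape, dtype=object)
        for code, name in CATEGORY_OF_CODE.items():
            cat[self.codes == code] = name
        return cat


# ---------------------------------------------------------------------------
# amide hydrogen reconstruction

def reconstruct_amide_hydrogens(frame: Frame, topology: Topology) -> Frame:
    """Return a frame in which every backbone amide N lacking an explicit H
    gets one placed 0.10 nm from N along the bisector of the N−C(prev) and
    N−O(prev) directions (the standard DSSP construction).

    Residues already carrying H are untouched (idempotent). Prolines and
    first residues without a preceding carbonyl (no N-cap) are skipped.
    Note: a frame's coordinate array length must match the topology, so
    reconstruction can only fill in hydrogens that exist as atoms; builders
    in this package always create the H slot.
    """
    coords = frame.coordinates.copy()
    for chain in topology.peptide_chains():
        prev_ri = None
        for ri in chain.residues:
            res = topology.residues[ri]
            if res.name == "PRO" or res.name in ("NH2",):
                prev_ri = ri
                continue
            h = topology.find_atom(ri, "H")
            n = topology.find_atom(ri, "N")
            if h is None or n is None:
                prev_ri = ri
                continue
            # H counts as placed when it sits at a chemically sensible N-H
            # bond length; anything else (coincident with N, or a zeroed
            # placeholder) is reconstructed. Idempotent on placed hydrogens.
            if 0.05 < np.linalg.norm(coords[h] - coords[n]) < 0.15:
                prev_ri = ri
                continue
            if prev_ri is None:
                prev_ri = ri
                continue
            c_prev = topology.find_atom(prev_ri, "C")
            o_prev = topology.find_atom(prev_ri, "O")
            if c_prev is None or o_prev is None:
                prev_ri = ri
                continue
            u1 = coords[n] - coords[c_prev]
            u2 = coords[n] - coords[o_prev]
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            direction = u1 + u2
            direction /= np.linalg.norm(direction)
            coords[h] = coords[n] + 0.10 * direction
            prev_ri = ri
    return Frame(coordinates=coords, box=frame.box, time=frame.time)


# ---------------------------------------------------------------------------
# Kabsch–Sander energy

def kabsch_sander_energy(r_on: float, r_ch: float, r_oh: float,
                         r_cn: float) -> float:
    """Kabsch–Sander electrostatic H-bond energy (kcal/mol) from the four
    heavy/hydrogen distances in Å:

        E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)

    A backbone H-bond is assigned when E < −0.5 kcal/mol."""
    return KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def kabsch_sander_energy_residues(donor_res: int, acceptor_res: int,
                                  frame: Frame, topology: Topology) -> float:
    """KS energy of the backbone H-bond donated by residue ``donor_res``
    (N-H) to the carbonyl of ``acceptor_res``; distances taken from the
    frame (nm → Å)."""
    if donor_res == acceptor_res:
        raise ValueError("donor and acceptor must be distinct residues")
    pos = {}
    for ri, names in ((donor_res, ("N", "H")), (acceptor_res, ("C", "O"))):
        for nm in names:
            idx = topology.find_atom(ri, nm)
            if idx is None:
                res = topology.residues[ri]
                raise ValueError(
                    f"residue {res.name}{res.seq_number} lacks atom {nm}")
            pos[nm + str(ri)] = frame.coordinates[idx]
    n, h = pos[f"N{donor_res}"], pos[f"H{donor_res}"]
    c, o = pos[f"C{acceptor_res}"], pos[f"O{acceptor_res}"]
    ang = 10.0  # nm -> Å
    return kabsch_sander_energy(
        np.linalg.norm(o - n) * ang, np.linalg.norm(c - h) * ang,
        np.linalg.norm(o - h) * ang, np.linalg.norm(c - n) * ang)


# ---------------------------------------------------------------------------
# DSSP-lite

def _backbone_arrays(frame: Frame, topology: Topology):
    """Collect backbone coordinates of all amino-acid residues of peptide
    chains, in chain order. Returns (residue_indices, chain_of, pos dict)."""
    res_idx: list[int] = []
    chain_of: list[int] = []
    for ci, chain in enumerate(topology.peptide_chains()):
        for ri in chain.residues:
            res = topology.residues[ri]
            if res.name in ("ACE", "NH2"):
                continue
            res_idx.append(ri)
            chain_of.append(ci)
    m = len(res_idx)
    pos = {nm: np.full((m, 3), np.nan) for nm in ("N", "H", "CA", "C", "O")}
    have = {nm: np.zeros(m, dtype=bool) for nm in pos}
    for k, ri in enumerate(res_idx):
        for nm in pos:
            gi = topology.find_atom(ri, nm)
            if gi is not None:
                pos[nm][k] = frame.coordinates[gi]
                have[nm][k] = True
    return res_idx, np.asarray(chain_of), pos, have


def _ks_hbond_matrix(pos, have, chain_of) -> np.ndarray:
    """HB[a, d] = True when donor residue d (N-H) bonds acceptor residue a
    (C=O) with KS energy < −0.5 kcal/mol."""
    ang = 10.0
    n, h, c, o = (pos["N"] * ang, pos["H"] * ang, pos["C"] * ang,
                  pos["O"] * ang)
    m = n.shape[0]

    def dist(x, y):
        d = x[:, None, :] - y[None, :, :]
        return np.sqrt((d * d).sum(axis=-1))

    # distances indexed [acceptor, donor]
    r_on = dist(o, n)
    r_ch = dist(c, h)
    r_oh = dist(o, h)
    r_cn = dist(c, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = KS_PREFACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    valid_d = have["N"] & have["H"]
    valid_a = have["C"] & have["O"]
    allowed = valid_a[:, None] & valid_d[None, :]
    idx = np.arange(m)
    allowed[idx, idx] = False
    # donor's own amide carbonyl: N(i) is covalently bonded to C(i-1),
    # and a minimal sequence separation of 2 within a chain (KS convention)
    same_chain = chain_of[:, None] == chain_of[None, :]
    allowed[(idx[:, None] == idx[None, :] - 1) & same_chain] = False
    allowed[(idx[:, None] == idx[None, :] + 1) & same_chain] = False
    e = np.where(allowed, e, np.inf)
    # DSSP keeps only each donor's two lowest-energy H-bonds
    hb = np.zeros((m, m), dtype=bool)
    order = np.argsort(e, axis=0)
    for rank in (0, 1):
        acc = order[rank]
        ok = e[acc, idx] < KS_CUTOFF
        hb[acc[ok], idx[ok]] = True
    return hb


def assign_secondary_structure(traj: Trajectory) -> SecondaryStructureAssignment:
    """Assign 8-state secondary structure per (frame, residue) with the
    Kabsch–Sander rules.

    Per frame: backbone H-bonds by the KS energy criterion (amide hydrogens
    reconstructed where absent); n-turns (i → i+n, n = 3,4,5) give G/H/I
    where two consecutive turns overlap, T otherwise; parallel and
    antiparallel bridge patterns give B, ladders of ≥2 consecutive bridges
    give E; bend S where the Cα(i−2)/Cα(i)/Cα(i+2) direction change exceeds
    70°. Priority: H > E > B > G > I > T > S > C. Chains shorter than 3
    residues are all C.
    """
    top = traj.topology
    res_idx0, chain_of, _, _ = _backbone_arrays(traj.frames[0], top)
    labels = []
    for ri in res_idx0:
        res = top.residues[ri]
        one = res.name[0] if res.name not in ("ACE", "NH2") else "X"
        labels.append(f"{one}{res.seq_number}")
    m = len(res_idx0)
    codes = np.full((traj.n_frames, m), "C", dtype="U1")

    for fi, frame in enumerate(traj.frames):
        frame = reconstruct_amide_hydrogens(frame, top)
        res_idx, chain_of, pos, have = _backbone_arrays(frame, top)
        hb = _ks_hbond_matrix(pos, have, chain_of)
        idx = np.arange(m)
        same_chain = chain_of[:, None] == chain_of[None, :]

        # ----- n-turns: turn_n[i] True when CO(i) accepts from NH(i+n)
        turn = {}
        for nlen in (3, 4, 5):
            t = np.zeros(m, dtype=bool)
            ok = idx + nlen < m
            cand = idx[ok]
            same = chain_of[cand] == chain_of[cand + nlen]
            t[cand[same]] = hb[cand[same], cand[same] + nlen]
            turn[nlen] = t

        code = np.full(m, "C", dtype="U1")

        # ----- bridges (vectorized over all residue pairs)
        # A residue's ±1 neighbours are only referenced by the patterns that
        # need them, so chain termini can still carry bridges (as in DSSP).
        has_prev = np.zeros(m, dtype=bool)
        has_next = np.zeros(m, dtype=bool)
        has_prev[1:] = chain_of[1:] == chain_of[:-1]
        has_next[:-1] = chain_of[:-1] == chain_of[1:]
        flank = has_prev & has_next
        # padded H-bond matrices: P[a+1, d+1] = hb[a, d], Q = padded hb.T
        P = np.zeros((m + 2, m + 2), dtype=bool)
        P[1:m + 1, 1:m + 1] = hb
        Q = np.zeros((m + 2, m + 2), dtype=bool)
        Q[1:m + 1, 1:m + 1] = hb.T
        # parallel: [Hbond(i-1,j) & Hbond(j,i+1)] (needs i∓1)
        #        or [Hbond(j-1,i) & Hbond(i,j+1)] (needs j∓1)
        par = (P[0:m, 1:m + 1] & Q[2:m + 2, 1:m + 1] & flank[:, None]) | \
              (Q[1:m + 1, 0:m] & P[1:m + 1, 2:m + 2] & flank[None, :])
        # antiparallel: [Hbond(i,j) & Hbond(j,i)]
        #            or [Hbond(i-1,j+1) & Hbond(j-1,i+1)] (needs both ∓1)
        anti = (P[1:m + 1, 1:m + 1] & Q[1:m + 1, 1:m + 1]) | \
               (P[0:m, 2:m + 2] & Q[2:m + 2, 0:m]
                & flank[:, None] & flank[None, :])
        near = same_chain & (np.abs(idx[:, None] - idx[None, :]) < 3)
        par &= ~near
        anti &= ~near
        bridge = par | anti
        has_bridge = bridge.any(axis=1)
        # ladders: two bridges (i,j),(i+1,j') with j' = j±1 of same type
        in_ladder = np.zeros(m, dtype=bool)
        for i in range(m - 1):
            for j in np.flatnonzero(bridge[i]):
                for jp in (j - 1, j + 1):
                    if 0 <= jp < m and (
                        (par[i, j] and par[i + 1, jp])
                        or (anti[i, j] and anti[i + 1, jp])
                    ):
                        if chain_of[i] == chain_of[i + 1] and chain_of[j] == chain_of[jp]:
                            in_ladder[i] = in_ladder[i + 1] = True
                            in_ladder[j] = in_ladder[jp] = True

        # ----- helices: two consecutive n-turns
        helix_min = {}
        for nlen, sym in ((4, "H"), (3, "G"), (5, "I")):
            starts = np.zeros(m, dtype=bool)
            for i in range(1, m):
                if turn[nlen][i] and turn[nlen][i - 1] and chain_of[i - 1] == chain_of[i]:
                    starts[i] = True
            helix_min[sym] = starts

        # ----- bends
        bend = np.zeros(m, dtype=bool)
        ca = pos["CA"]
        for i in range(2, m - 2):
            if not (chain_of[i - 2] == chain_of[i] == chain_of[i + 2]):
                continue
            u = ca[i] - ca[i - 2]
            v = ca[i + 2] - ca[i]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu < 1e-9 or nv < 1e-9:
                continue
            cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
            if np.degrees(np.arccos(cosang)) > 70.0:
                bend[i] = True

        # ----- turn T: residues bracketed by any n-turn
        in_turn = np.zeros(m, dtype=bool)
        for nlen in (3, 4, 5):
            for i in np.flatnonzero(turn[nlen]):
                for k in range(i + 1, min(i + nlen, m)):
                    if chain_of[k] == chain_of[i]:
                        in_turn[k] = True

        # ----- priority H > E > B > G > I > T > S > C
        assigned = np.zeros(m, dtype=bool)

        def put(mask, sym):
            sel = mask & ~assigned
            code[sel] = sym
            assigned[sel] = True

        h4 = np.zeros(m, dtype=bool)
        for i in np.flatnonzero(helix_min["H"]):
            h4[i:i + 4] = True
        put(h4, "H")
        put(in_ladder, "E")
        put(has_bridge, "B")
        g3 = np.zeros(m, dtype=bool)
        for i in np.flatnonzero(helix_min["G"]):
            g3[i:i + 3] = True
        put(g3, "G")
        i5 = np.zeros(m, dtype=bool)
        for i in np.flatnonzero(helix_min["I"]):
            i5[i:i + 5] = True
        put(i5, "I")
        put(in_turn, "T")
        put(bend, "S")
        codes[fi] = code

    return SecondaryStructureAssignment(codes=codes, residue_indices=res_idx0,
                                        labels=labels)


def ss_population(assignment: SecondaryStructureAssignment,
                  per_residue: bool = False, n_blocks: int = 5):
    """Category populations from an assignment.

    Overall mode: dict category → (fraction, standard error over
    ``n_blocks`` equal trajectory blocks). Per-residue mode: DataFrame-like
    dict category → per-position fraction arrays.
    """
    import pandas as pd

    cats = assignment.categories
    nf, m = cats.shape
    if per_residue:
        data = {"label": assignment.labels}
        for cat in CATEGORIES:
            data[cat] = (cats == cat).mean(axis=0)
        return pd.DataFrame(data)
    out = {}
    blocks = np.array_split(np.arange(nf), min(n_blocks, nf))
    for cat in CATEGORIES:
        frac = float((cats == cat).mean())
        block_means = np.array([(cats[b] == cat).mean() for b in blocks])
        se = float(block_means.std(ddof=1) / np.sqrt(len(blocks))) \
            if len(blocks) > 1 else 0.0
        out[cat] = (frac, se)
    return out


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA

@dataclass
class SasaResult:
    per_atom: np.ndarray       # nm², aligned with heavy_indices
    heavy_indices: np.ndarray  # global atom indices the areas refer to
    per_residue: np.ndarray    # nm², aligned with topology.residues
    total: float               # nm²
    n_sphere_points: int
    probe_radius: float        # nm


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (Fibonacci spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(frame: Frame, topology: Topology, probe: float = 0.14,
                       n_points: int = 960,
                       atom_indices: np.ndarray | None = None) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area (nm²).

    Heavy atoms only; each atom's sphere of radius r_vdw + probe is sampled
    at ``n_points`` golden-spiral points, and a point is accessible when it
    lies outside every neighbour's inflated sphere. ``atom_indices``
    restricts the computation (e.g. peptide atoms only); hydrogens in the
    selection are ignored.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    if atom_indices is None:
        heavy = topology.heavy_indices()
    else:
        heavy = np.array([i for i in atom_indices
                          if not topology.atoms[i].is_hydrogen], dtype=np.intp)
    coords = frame.coordinates[heavy]
    radii = np.array([topology.atoms[i].vdw_radius for i in heavy]) + probe
    if not (radii > probe).all():
        raise ValueError("atom without a positive vdW radius")
    sphere = _golden_spiral(n_points)
    n = len(heavy)
    areas = np.zeros(n)
    tree = cKDTree(coords)
    rmax = radii.max()
    neighbor_lists = tree.query_ball_tree(tree, 2.0 * rmax)
    for i in range(n):
        nbrs = [j for j in neighbor_lists[i] if j != i]
        pts = coords[i] + radii[i] * sphere
        if nbrs:
            nbr_xyz = coords[nbrs]
            nbr_r = radii[nbrs]
            d2 = ((pts[:, None, :] - nbr_xyz[None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (nbr_r ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    per_res = np.zeros(len(topology.residues))
    for k, gi in enumerate(heavy):
        per_res[topology.atoms[gi].residue_index] += areas[k]
    return SasaResult(per_atom=areas, heavy_indices=heavy,
                      per_residue=per_res, total=float(areas.sum()),
                      n_sphere_points=n_points, probe_radius=probe)
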