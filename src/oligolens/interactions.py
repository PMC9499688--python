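"""Geometric interaction detectors and their ensemble statistics.

Contacts (heavy-atom distance criterion, 0.54 nm), hydrogen bonds
(donor–acceptor < 0.35 nm and D–H–A angle > 150°), inter-peptide contact
probability maps, ligand binding probabilities and H-bond profiles, π–π
stacking geometry and CH–π minimum distances. All detectors honour the
minimum-image convention when a frame carries a box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Frame, Residue, Topology, Trajectory
from .geometry import (
    interplane_angle,
    min_image_displacement,
    ring_geometry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HBondEvent", "ContactMap", "StackingEvent",
    "residue_contact", "interpeptide_contact_map", "detect_hbonds",
    "hbond_count_pdf", "ligand_binding_probability", "ligand_hbond_profile",
    "stacking_events", "chpi_min_distance",
    "CONTACT_CUTOFF", "HBOND_DISTANCE_CUTOFF", "HBOND_ANGLE_CUTOFF",
]

#: Heavy-atom contact cutoff, nm.
CONTACT_CUTOFF = 0.54
#: H-bond donor–acceptor distance cutoff, nm.
HBOND_DISTANCE_CUTOFF = 0.35
#: H-bond D–H–A angle cutoff, degrees.
HBOND_ANGLE_CUTOFF = 150.0

#: Stacking classification thresholds, degrees.
PARALLEL_MAX_ANGLE = 30.0
HERRINGBONE_MIN_ANGLE = 50.0


@dataclass(frozen=True)
class HBondEvent:
    donor_heavy: int
    hydrogen: int
    acceptor: int
    distance_da: float          # nm
    angle_dha: float            # degrees
    hb_class: str               # "MC-MC" | "MC-SC" | "SC-SC" | "peptide-ligand"
    donor_residue: int
    acceptor_residue: int


@dataclass
class ContactMap:
    labels: list[str]
    probabilities: np.ndarray   # (L, L), symmetric, in [0, 1]
    contact_class: str          # "MC-MC" | "SC-SC"
    n_frames: int
    n_chain_pairs: int


@dataclass(frozen=True)
class StackingEvent:
    frame: int
    ring_a: tuple[int, int]     # (residue index, ring number)
    ring_b: tuple[int, int]
    centroid_distance: float    # nm
    angle: float                # degrees in [0, 90]
    classification: str         # "parallel" | "intermediate" | "herringbone"


def classify_stacking(angle: float,
                      parallel_max: float = PARALLEL_MAX_ANGLE,
                      herringbone_min: float = HERRINGBONE_MIN_ANGLE) -> str:
    if angle <= parallel_max:
        return "parallel"
    if angle >= herringbone_min:
        return "herringbone"
    return "intermediate"


# ---------------------------------------------------------------------------
# contacts

def _subset_atoms(res: Residue, topology: Topology, subset: str) -> list[int]:
    if subset == "heavy":
        pool = res.atoms
    elif subset == "MC":
        pool = res.backbone_atoms
    elif subset == "SC":
        pool = res.sidechain_atoms
    else:
        raise ValueError(f"unknown subset {subset!r}")
    return [i for i in pool if not topology.atoms[i].is_hydrogen]


def residue_contact(res_a: Residue, res_b: Residue, frame: Frame,
                    topology: Topology, cutoff: float = CONTACT_CUTOFF,
                    subset: str = "heavy") -> bool:
    """True when any pair of chosen heavy atoms of the two residues is
    within ``cutoff`` under the minimum-image convention. Hydrogens never
    participate; an empty subset on both sides (e.g. Gly side chains) is
    False."""
    ia = _subset_atoms(res_a, topology, subset)
    ib = _subset_atoms(res_b, topology, subset)
    if not ia or not ib:
        logger.debug("residue_contact: empty heavy-atom subset (%s/%s)",
                     res_a.name, res_b.name)
        return False
    d = min_image_displacement(frame.coordinates[ia][:, None, :],
                               frame.coordinates[ib][None, :, :], frame.box)
    return bool((np.einsum("ijk,ijk->ij", d, d).min() <= cutoff * cutoff))


def interpeptide_contact_map(traj: Trajectory, contact_class: str = "MC-MC",
                             cutoff: float = CONTACT_CUTOFF) -> ContactMap:
    """Inter-peptide residue–residue contact probability map.

    Entry (i, j) is the fraction, over frames and unordered peptide chain
    pairs, of events in which residue position i of one chain contacts
    residue position j of the other; contributions are symmetrized by
    averaging the (i, j) and (j, i) orientations of each chain pair.
    """
    subset = {"MC-MC": "MC", "SC-SC": "SC"}[contact_class]
    top = traj.topology
    chains = top.peptide_chains()
    if len(chains) < 2:
        raise ValueError("need at least two peptide chains")
    residues_per_chain = []
    for c in chains:
        rs = [top.residues[ri] for ri in c.residues
              if top.residues[ri].name not in ("ACE", "NH2")]
        residues_per_chain.append(rs)
    lengths = {len(rs) for rs in residues_per_chain}
    if len(lengths) != 1:
        raise ValueError("peptide chains have unequal residue counts")
    L = lengths.pop()
    labels = [f"{r.name[0]}{r.seq_number}" for r in residues_per_chain[0]]
    counts = np.zeros((L, L))
    n_pairs = 0
    pair_list = [(p, q) for p in range(len(chains))
                 for q in range(p + 1, len(chains))]
    for frame in traj.frames:
        for p, q in pair_list:
            for i in range(L):
                for j in range(L):
                    if residue_contact(residues_per_chain[p][i],
                                       residues_per_chain[q][j], frame, top,
                                       cutoff=cutoff, subset=subset):
                        counts[i, j] += 0.5
                        counts[j, i] += 0.5
    n_pairs = len(pair_list)
    probs = counts / (traj.n_frames * n_pairs)
    return ContactMap(labels=labels, probabilities=probs,
                      contact_class=contact_class, n_frames=traj.n_frames,
                      n_chain_pairs=n_pairs)


# ---------------------------------------------------------------------------
# hydrogen bonds

def _chain_kind_of_residue(top: Topology) -> dict[int, str]:
    kind = {}
    for c in top.chains:
        for ri in c.residues:
            kind[ri] = c.kind
    return kind


def detect_hbonds(frame: Frame, topology: Topology,
                  scope: str = "inter-peptide",
                  distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
                  angle_cutoff: float = HBOND_ANGLE_CUTOFF
                  ) -> list[HBondEvent]:
    """All donor–hydrogen–acceptor triples satisfying the geometric
    criterion (d(D,A) < 0.35 nm and ∠D–H–A > 150°).

    ``scope``: "intra-peptide-set" (all peptide–peptide bonds, including
    within a chain but never within one residue), "inter-peptide"
    (peptide–peptide bonds between different chains), or "peptide-ligand".
    Classes: MC-MC / MC-SC / SC-SC from the heavy-atom partition, or
    "peptide-ligand".
    """
    top = topology
    kind_of = _chain_kind_of_residue(top)
    donors: list[tuple[int, int, int]] = []   # (residue, heavy, H)
    acceptors: list[tuple[int, int]] = []     # (residue, heavy)
    for ri, res in enumerate(top.residues):
        for heavy, hyd in res.donors:
            donors.append((ri, heavy, hyd))
        for heavy in res.acceptors:
            acceptors.append((ri, heavy))
    if not donors or not acceptors:
        return []
    chain_of_res = {}
    for ci, c in enumerate(top.chains):
        for ri in c.residues:
            chain_of_res[ri] = ci
    coords = frame.coordinates
    events: list[HBondEvent] = []
    d_res = np.array([d[0] for d in donors])
    d_heavy = np.array([d[1] for d in donors])
    d_h = np.array([d[2] for d in donors])
    a_res = np.array([a[0] for a in acceptors])
    a_heavy = np.array([a[1] for a in acceptors])
    # distance prefilter
    disp = min_image_displacement(coords[d_heavy][:, None, :],
                                  coords[a_heavy][None, :, :], frame.box)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", disp, disp))
    cand = np.argwhere(dist < distance_cutoff)
    for di, ai in cand:
        ri_d, ri_a = int(d_res[di]), int(a_res[ai])
        if ri_d == ri_a:
            continue
        kd, ka = kind_of[ri_d], kind_of[ri_a]
        if scope == "peptide-ligand":
            if {kd, ka} != {"peptide", "ligand"}:
                continue
        else:
            if kd != "peptide" or ka != "peptide":
                continue
            if scope == "inter-peptide" and \
                    chain_of_res[ri_d] == chain_of_res[ri_a]:
                continue
        h = int(d_h[di])
        dh = min_image_displacement(coords[h], coords[int(d_heavy[di])],
                                    frame.box)
        ha = min_image_displacement(coords[h], coords[int(a_heavy[ai])],
                                    frame.box)
        ndh, nha = np.linalg.norm(dh), np.linalg.norm(ha)
        if ndh < 1e-9 or nha < 1e-9:
            continue
        cosang = np.clip(dh @ ha / (ndh * nha), -1.0, 1.0)
        angle = float(np.degrees(np.arccos(cosang)))
        if angle <= angle_cutoff:
            continue
        if {kd, ka} == {"peptide", "ligand"}:
            hb_class = "peptide-ligand"
        else:
            part_d = "MC" if int(d_heavy[di]) in \
                top.residues[ri_d].backbone_atoms else "SC"
            part_a = "MC" if int(a_heavy[ai]) in \
                top.residues[ri_a].backbone_atoms else "SC"
            hb_class = "-".join(sorted((part_d, part_a)))
            hb_class = {"MC-MC": "MC-MC", "MC-SC": "MC-SC",
                        "SC-SC": "SC-SC"}[hb_class]
        events.append(HBondEvent(
            donor_heavy=int(d_heavy[di]), hydrogen=h,
            acceptor=int(a_heavy[ai]),
            distance_da=float(dist[di, ai]), angle_dha=angle,
            hb_class=hb_class, donor_residue=ri_d, acceptor_residue=ri_a))
    return events


def hbond_count_pdf(traj: Trajectory, hb_class: str = "MC",
                    **kwargs) -> dict[int, float]:
    """Normalized distribution of the per-frame count of inter-peptide
    H-bonds whose both partners are main-chain ("MC") or both side-chain
    ("SC") atoms."""
    wanted = {"MC": "MC-MC", "SC": "SC-SC"}[hb_class]
    counts: list[int] = []
    for frame in traj.frames:
        events = detect_hbonds(frame, traj.topology, scope="inter-peptide",
                               **kwargs)
        counts.append(sum(1 for e in events if e.hb_class == wanted))
    values, freq = np.unique(counts, return_counts=True)
    return {int(v): float(f) / len(counts) for v, f in zip(values, freq)}


# ---------------------------------------------------------------------------
# ligand analyses

def _residue_positions(top: Topology):
    """Residue positions shared by all peptide chains: list of labels and a
    per-chain list of residue indices."""
    chains = top.peptide_chains()
    per_chain = []
    for c in chains:
        per_chain.append([ri for ri in c.residues
                          if top.residues[ri].name not in ("ACE", "NH2")])
    L = len(per_chain[0])
    if any(len(p) != L for p in per_chain):
        raise ValueError("peptide chains have unequal residue counts")
    labels = [f"{top.residues[ri].name[0]}{top.residues[ri].seq_number}"
              for ri in per_chain[0]]
    return labels, per_chain


def ligand_binding_probability(traj: Trajectory,
                               cutoff: float = CONTACT_CUTOFF,
                               per_copy: bool = False):
    """Per-residue-position probability that a ligand is bound.

    Default ("any copy"): for position k, the fraction of (frame, peptide
    chain) pairs in which at least one heavy atom of *any* ligand lies
    within ``cutoff`` of a heavy atom of that chain's residue k.
    ``per_copy=True`` instead averages over (frame, chain, ligand copy)
    triples."""
    top = traj.topology
    lig_chains = top.ligand_chains()
    if not lig_chains:
        raise ValueError("no ligand chains in topology")
    labels, per_chain = _residue_positions(top)
    lig_atoms = [np.array([i for c in lig_chains
                           for ri in c.residues
                           for i in top.residues[ri].atoms
                           if not top.atoms[i].is_hydrogen])] \
        if not per_copy else \
        [np.array([i for ri in c.residues for i in top.residues[ri].atoms
                   if not top.atoms[i].is_hydrogen]) for c in lig_chains]
    L = len(labels)
    hits = np.zeros(L)
    for frame in traj.frames:
        for chain_res in per_chain:
            for group in lig_atoms:
                lig_xyz = frame.coordinates[group]
                for k, ri in enumerate(chain_res):
                    res = top.residues[ri]
                    heavy = [i for i in res.atoms
                             if not top.atoms[i].is_hydrogen]
                    d = min_image_displacement(
                        frame.coordinates[heavy][:, None, :],
                        lig_xyz[None, :, :], frame.box)
                    if np.einsum("ijk,ijk->ij", d, d).min() <= cutoff ** 2:
                        hits[k] += 1
    n_units = traj.n_frames * len(per_chain) * len(lig_atoms)
    return labels, hits / n_units


def ligand_hbond_profile(traj: Trajectory, **kwargs):
    """Average per-frame count of peptide–ligand H-bonds whose peptide
    heavy atom is main-chain (resp. side-chain) of residue position k,
    summed over chains and ligand copies."""
    top = traj.topology
    labels, per_chain = _residue_positions(top)
    pos_of_res = {}
    for chain_res in per_chain:
        for k, ri in enumerate(chain_res):
            pos_of_res[ri] = k
    L = len(labels)
    mc = np.zeros(L)
    sc = np.zeros(L)
    kind = _chain_kind_of_residue(top)
    for frame in traj.frames:
        events = detect_hbonds(frame, top, scope="peptide-ligand", **kwargs)
        for e in events:
            if kind[e.donor_residue] == "peptide":
                ri, heavy = e.donor_residue, e.donor_heavy
            else:
                ri, heavy = e.acceptor_residue, e.acceptor
            if ri not in pos_of_res:
                continue
            k = pos_of_res[ri]
            if heavy in top.residues[ri].backbone_atoms:
                mc[k] += 1
            else:
                sc[k] += 1
    return labels, mc / traj.n_frames, sc / traj.n_frames


# ---------------------------------------------------------------------------
# aromatic stacking and CH-pi

def _collect_rings(top: Topology, selection) -> list[tuple[int, int, list[int]]]:
    """Resolve a ring selection to (residue index, ring number, atom
    indices). ``selection`` is a predicate over residues or a list of
    (residue index, ring number) pairs or residue indices."""
    out = []
    if callable(selection):
        for ri, res in enumerate(top.residues):
            if selection(res):
                for rn, ring in enumerate(res.rings):
                    out.append((ri, rn, ring))
    else:
        for item in selection:
            if isinstance(item, tuple):
                ri, rn = item
                out.append((ri, rn, top.residues[ri].rings[rn]))
            else:
                ri = int(item)
                for rn, ring in enumerate(top.residues[ri].rings):
                    out.append((ri, rn, ring))
    return out


def stacking_events(traj: Trajectory, rings_a, rings_b,
                    parallel_max: float = PARALLEL_MAX_ANGLE,
                    herringbone_min: float = HERRINGBONE_MIN_ANGLE
                    ) -> list[StackingEvent]:
    """Closest-ring stacking geometry per frame.

    For each ring in ``rings_a``, pair it with the ring in ``rings_b`` of
    minimum centroid distance (excluding itself), and record centroid
    distance, interplane angle and classification."""
    top = traj.topology
    ra = _collect_rings(top, rings_a)
    rb = _collect_rings(top, rings_b)
    if not ra or not rb:
        raise ValueError("empty ring selection")
    events: list[StackingEvent] = []
    for fi, frame in enumerate(traj.frames):
        geos_a = [ring_geometry(frame.coordinates[r[2]]) for r in ra]
        geos_b = [ring_geometry(frame.coordinates[r[2]]) for r in rb]
        for (ri_a, rn_a, _), ga in zip(ra, geos_a):
            best = None
            for (ri_b, rn_b, _), gb in zip(rb, geos_b):
                if (ri_a, rn_a) == (ri_b, rn_b):
                    continue
                dist = float(np.linalg.norm(
                    min_image_displacement(ga.centroid, gb.centroid,
                                           frame.box)))
                if best is None or dist < best[0]:
                    best = (dist, ri_b, rn_b, gb)
            if best is None:
                continue
            dist, ri_b, rn_b, gb = best
            ang = interplane_angle(ga, gb)
            events.append(StackingEvent(
                frame=fi, ring_a=(ri_a, rn_a), ring_b=(ri_b, rn_b),
                centroid_distance=dist, angle=ang,
                classification=classify_stacking(ang, parallel_max,
                                                 herringbone_min)))
    return events


def chpi_min_distance(traj: Trajectory, methyl_residues, rings
                      ) -> np.ndarray:
    """Per-frame minimum distance (nm) from any methyl carbon of the
    selected residues to any selected ring centroid."""
    top = traj.topology
    if callable(methyl_residues):
        res_list = [ri for ri, res in enumerate(top.residues)
                    if methyl_residues(res)]
    else:
        res_list = [int(r) for r in methyl_residues]
    methyl_atoms: list[int] = []
    for ri in res_list:
        res = top.residues[ri]
        if not res.methyls:
            raise ValueError(
                f"residue {res.name}{res.seq_number} has no methyl "
                "annotation")
        methyl_atoms.extend(res.methyls)
    ring_defs = _collect_rings(top, rings)
    if not ring_defs:
        raise ValueError("empty ring selection")
    out = np.empty(traj.n_frames)
    for fi, frame in enumerate(traj.frames):
        centroids = np.array([frame.coordinates[r[2]].mean(axis=0)
                              for r in ring_defs])
        d = min_image_displacement(
            frame.coordinates[methyl_atoms][:, None, :],
            centroids[None, :, :], frame.box)
        out[fi] = float(np.sqrt(np.einsum("ijk,ijk->ij", d, d).min()))
    return out
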