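"""Contact, hydrogen-bond, ligand and stacking detectors against
hand-constructed boundary geometries and brute-force enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from oligolens.core import Frame, Trajectory, build_topology
from oligolens.geometry import ring_geometry
from oligolens.interactions import (
    CONTACT_CUTOFF,
    chpi_min_distance,
    classify_stacking,
    detect_hbonds,
    hbond_count_pdf,
    interpeptide_contact_map,
    ligand_binding_probability,
    ligand_hbond_profile,
    residue_contact,
    stacking_events,
)


def _toy_topology(templates, n_chains=2, spacing=None):
    """Chains of GLY-ALA-SER (heavy atoms only besides donor H)."""
    entries = [("GLY", 1, ["N", "CA", "C", "O"]),
               ("ALA", 2, ["N", "CA", "C", "O", "CB"]),
               ("SER", 3, ["N", "CA", "C", "O", "CB", "OG", "HG"])]
    specs = [(chr(ord("A") + k), "peptide", entries) for k in range(n_chains)]
    return build_topology(specs, templates=templates)


def _spread_coords(top, origin_step=5.0):
    """Well-separated default coordinates, one cluster per chain."""
    coords = np.zeros((top.n_atoms, 3))
    for ci, chain in enumerate(top.chains):
        base = np.array([ci * origin_step, 0.0, 0.0])
        k = 0
        for ri in chain.residues:
            for gi in top.residues[ri].atoms:
                coords[gi] = base + np.array([0.1 * k, 0.05 * ri, 0.0])
                k += 1
    return coords


class TestResidueContact:
    def test_within_cutoff(self, templates):
        top = _toy_topology(templates)
        coords = _spread_coords(top)
        ca_a = top.atom_index(top.chains[0].residues[0], "CA")
        ca_b = top.atom_index(top.chains[1].residues[0], "CA")
        coords[ca_b] = coords[ca_a] + [0.53, 0, 0]
        frame = Frame(coordinates=coords)
        ra = top.residues[top.chains[0].residues[0]]
        rb = top.residues[top.chains[1].residues[0]]
        assert residue_contact(ra, rb, frame, top)

    def test_beyond_cutoff(self, templates):
        top = _toy_topology(templates)
        coords = _spread_coords(top)
        # bring nearest heavy pair to exactly 0.55 nm
        ra = top.residues[top.chains[0].residues[0]]
        rb = top.residues[top.chains[1].residues[0]]
        frame = Frame(coordinates=coords)
        heavy_a = [i for i in ra.atoms if not top.atoms[i].is_hydrogen]
        heavy_b = [i for i in rb.atoms if not top.atoms[i].is_hydrogen]
        d = np.linalg.norm(coords[heavy_a][:, None]
                           - coords[heavy_b][None], axis=-1)
        gap = d.min()
        shift = (gap - 0.55)  # move chain B closer so min gap is 0.55
        for gi in [i for c in [top.chains[1]] for ri in c.residues
                   for i in top.residues[ri].atoms]:
            coords[gi][0] -= shift
        assert not residue_contact(ra, rb, Frame(coordinates=coords), top)

    def test_hydrogens_never_participate(self, templates):
        top = _toy_topology(templates)
        coords = _spread_coords(top)
        # put Ser A hydroxyl H of chain A right next to chain B's Ser HG
        ha = top.atom_index(top.chains[0].residues[2], "HG")
        hb = top.atom_index(top.chains[1].residues[2], "HG")
        coords[hb] = coords[ha] + [0.05, 0, 0]
        ra = top.residues[top.chains[0].residues[2]]
        rb = top.residues[top.chains[1].residues[2]]
        assert not residue_contact(ra, rb, Frame(coordinates=coords), top)

    def test_gly_sidechain_empty_is_false(self, templates):
        top = _toy_topology(templates)
        coords = _spread_coords(top)
        ra = top.residues[top.chains[0].residues[0]]  # GLY
        rb = top.residues[top.chains[1].residues[0]]  # GLY
        coords[top.atom_index(top.chains[1].residues[0], "CA")] = \
            coords[top.atom_index(top.chains[0].residues[0], "CA")] + 0.1
        assert not residue_contact(ra, rb, Frame(coordinates=coords), top,
                                   subset="SC")

    def test_symmetry(self, templates):
        top = _toy_topology(templates)
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 2, (top.n_atoms, 3))
        frame = Frame(coordinates=coords)
        for subset in ("heavy", "MC", "SC"):
            for ri in top.chains[0].residues:
                for rj in top.chains[1].residues:
                    a, b = top.residues[ri], top.residues[rj]
                    assert residue_contact(a, b, frame, top, subset=subset) \
                        == residue_contact(b, a, frame, top, subset=subset)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_cutoff_monotonicity(self, seed):
        """Shrinking the cutoff never creates a contact."""
        from oligolens.templates import load_default_templates
        templates = load_default_templates()
        top = _toy_topology(templates)
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 1.5, (top.n_atoms, 3))
        frame = Frame(coordinates=coords)
        a = top.residues[top.chains[0].residues[1]]
        b = top.residues[top.chains[1].residues[1]]
        got = [residue_contact(a, b, frame, top, cutoff=c)
               for c in (0.2, 0.4, 0.54, 0.8)]
        assert got == sorted(got)  # False before True


class TestContactMap:
    def test_static_parallel_strands_diagonal(self, sheet_pair):
        top, frame = sheet_pair
        traj = Trajectory(topology=top, frames=[frame])
        cmap = interpeptide_contact_map(traj, "MC-MC")
        assert np.allclose(cmap.probabilities, cmap.probabilities.T,
                           atol=1e-12)
        assert np.all(np.diag(cmap.probabilities) == 1.0)

    def test_distant_chains_all_zero(self, templates):
        top = _toy_topology(templates)
        coords = _spread_coords(top, origin_step=5.0)
        traj = Trajectory(topology=top, frames=[Frame(coordinates=coords)])
        cmap = interpeptide_contact_map(traj, "MC-MC")
        assert cmap.probabilities.max() == 0.0

    def test_matches_brute_force_enumeration(self, templates):
        """3 chains x 2 frames toy equals exhaustive enumeration over the
        3 chain pairs and both frames."""
        top = _toy_topology(templates, n_chains=3)
        rng = np.random.default_rng(3)
        frames = [Frame(coordinates=rng.uniform(0, 1.6, (top.n_atoms, 3)))
                  for _ in range(2)]
        traj = Trajectory(topology=top, frames=frames)
        for cls, subset in (("MC-MC", "MC"), ("SC-SC", "SC")):
            cmap = interpeptide_contact_map(traj, cls)
            L = 3
            oracle = np.zeros((L, L))
            pairs = [(0, 1), (0, 2), (1, 2)]
            for frame in frames:
                for p, q in pairs:
                    for i in range(L):
                        for j in range(L):
                            a = top.residues[top.chains[p].residues[i]]
                            b = top.residues[top.chains[q].residues[j]]
                            if residue_contact(a, b, frame, top,
                                               subset=subset):
                                oracle[i, j] += 0.5
                                oracle[j, i] += 0.5
            oracle /= len(frames) * len(pairs)
            assert np.allclose(cmap.probabilities, oracle, atol=1e-12)

    def test_sc_map_gly_rows_zero(self, templates):
        top = _toy_topology(templates)
        rng = np.random.default_rng(1)
        traj = Trajectory(topology=top, frames=[
            Frame(coordinates=rng.uniform(0, 0.8, (top.n_atoms, 3)))])
        cmap = interpeptide_contact_map(traj, "SC-SC")
        assert cmap.probabilities[0].max() == 0.0  # GLY is position 0


def _dha_topology(templates):
    """Minimal donor/acceptor pair: two SER residues in separate chains
    (hydroxyl donor and acceptor)."""
    entries = [("SER", 1, ["N", "CA", "C", "O", "CB", "OG", "HG"])]
    return build_topology([("A", "peptide", entries),
                           ("B", "peptide", entries)], templates=templates)


class TestHbondDetection:
    def place(self, top, d_pos, h_pos, a_pos):
        coords = _spread_coords(top, origin_step=8.0)
        coords[top.atom_index(0, "OG")] = d_pos
        coords[top.atom_index(0, "HG")] = h_pos
        coords[top.atom_index(1, "OG")] = a_pos
        # keep chain B's other acceptors far away
        return Frame(coordinates=coords)

    def test_collinear_detected(self, templates):
        top = _dha_topology(templates)
        frame = self.place(top, np.array([0.0, 0, 0]),
                           np.array([0.1, 0, 0]), np.array([0.33, 0, 0]))
        events = detect_hbonds(frame, top, scope="inter-peptide")
        pairs = {(e.donor_heavy, e.acceptor) for e in events}
        assert (top.atom_index(0, "OG"), top.atom_index(1, "OG")) in pairs
        ev = next(e for e in events
                  if e.donor_heavy == top.atom_index(0, "OG")
                  and e.acceptor == top.atom_index(1, "OG"))
        assert ev.distance_da == pytest.approx(0.33)
        assert ev.angle_dha == pytest.approx(180.0)
        assert ev.hb_class == "SC-SC"

    def test_distance_criterion(self, templates):
        top = _dha_topology(templates)
        frame = self.place(top, np.array([0.0, 0, 0]),
                           np.array([0.1, 0, 0]), np.array([0.36, 0, 0]))
        events = detect_hbonds(frame, top, scope="inter-peptide")
        assert not any(e.donor_heavy == top.atom_index(0, "OG")
                       and e.acceptor == top.atom_index(1, "OG")
                       for e in events)

    def test_angle_criterion(self, templates):
        top = _dha_topology(templates)
        d = np.array([0.0, 0, 0])
        a = np.array([0.33, 0, 0])
        # rotate H off the axis so the D-H-A angle is 149 degrees
        angle_dh = np.radians(180 - 149)
        # place H such that angle at H between D and A is 149:
        # iterate: position H on a circle around the D-A axis
        best = None
        for t in np.linspace(0.01, 0.2, 2000):
            for z in np.linspace(0.0, 0.12, 240):
                h = np.array([t, z, 0.0])
                v1 = d - h
                v2 = a - h
                ang = np.degrees(np.arccos(np.clip(
                    v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2),
                    -1.0, 1.0)))
                if best is None or abs(ang - 149) < abs(best[0] - 149):
                    best = (ang, h)
        _, h = best
        top_frame = self.place(top, d, h, a)
        events = detect_hbonds(top_frame, top, scope="inter-peptide")
        assert not any(e.donor_heavy == top.atom_index(0, "OG")
                       and e.acceptor == top.atom_index(1, "OG")
                       for e in events)

    def test_rigid_motion_invariance(self, sheet_pair):
        top, frame = sheet_pair
        base = detect_hbonds(frame, top, scope="inter-peptide")
        rot = Rotation.from_euler("xyz", [10, 50, -30],
                                  degrees=True).as_matrix()
        moved = Frame(coordinates=frame.coordinates @ rot.T + [1.0, -2.0, 3.0])
        after = detect_hbonds(moved, top, scope="inter-peptide")
        key = lambda ev: (ev.donor_heavy, ev.hydrogen, ev.acceptor)
        assert sorted(map(key, base)) == sorted(map(key, after))

    def test_hbonds_are_subset_of_contacts_at_035(self, sheet_pair):
        top, frame = sheet_pair
        events = detect_hbonds(frame, top, scope="inter-peptide")
        for e in events:
            ra = top.atoms[e.donor_heavy].residue_index
            rb = top.atoms[e.acceptor].residue_index
            assert residue_contact(top.residues[ra], top.residues[rb],
                                   frame, top, cutoff=0.35)


class TestHbondCountPdf:
    def test_two_state_fixture(self, templates):
        top = _dha_topology(templates)
        bonded = self.make(top, True)
        unbonded = self.make(top, False)
        frames = [bonded] * 6 + [unbonded] * 4
        traj = Trajectory(topology=top, frames=frames)
        pdf = hbond_count_pdf(traj, "SC")
        assert pdf == {1: pytest.approx(0.6), 0: pytest.approx(0.4)}
        assert sum(pdf.values()) == pytest.approx(1.0)

    def make(self, top, bonded):
        coords = _spread_coords(top, origin_step=8.0)
        if bonded:
            coords[top.atom_index(0, "OG")] = [0.0, 0, 0]
            coords[top.atom_index(0, "HG")] = [0.1, 0, 0]
            coords[top.atom_index(1, "OG")] = [0.30, 0, 0]
        return Frame(coordinates=coords)

    def test_no_bonds_point_mass_at_zero(self, templates):
        top = _toy_topology(templates)
        traj = Trajectory(topology=top, frames=[
            Frame(coordinates=_spread_coords(top))] * 5)
        assert hbond_count_pdf(traj, "MC") == {0: 1.0}


class TestLigandAnalyses:
    @pytest.fixture()
    def complex_traj(self, templates, melatonin):
        """2 peptide chains, 2 ligands, 3 frames; ligand 1 glued to chain
        A's Ser 3, ligand 2 far away."""
        lig_top, lig_frame = melatonin
        entries = [("GLY", 1, ["N", "CA", "C", "O"]),
                   ("ALA", 2, ["N", "CA", "C", "O", "CB"]),
                   ("SER", 3, ["N", "CA", "C", "O", "CB", "OG", "HG"])]
        lig_names = [lig_top.atoms[i].name for i in range(lig_top.n_atoms)]
        top = build_topology(
            [("A", "peptide", entries), ("B", "peptide", entries),
             ("L1", "ligand", [("MEL", 1, lig_names)]),
             ("L2", "ligand", [("MEL", 1, lig_names)])],
            templates=templates)
        npc = 16  # atoms per peptide chain (4 + 5 + 7)
        frames = []
        for _ in range(3):
            coords = np.zeros((top.n_atoms, 3))
            coords[:npc] = _spread_coords_chain(top, 0)
            coords[npc:2 * npc] = _spread_coords_chain(top, 1) + [6.0, 0, 0]
            lig = lig_frame.coordinates - lig_frame.coordinates.mean(axis=0)
            ser_cb = coords[top.atom_index(2, "CB")]
            coords[2 * npc:2 * npc + 19] = lig + ser_cb + [0.3, 0, 0]
            coords[2 * npc + 19:] = lig + [30.0, 30.0, 30.0]
            frames.append(Frame(coordinates=coords))
        return Trajectory(topology=top, frames=frames)

    def test_binding_probability_matches_enumeration(self, complex_traj):
        traj = complex_traj
        top = traj.topology
        labels, probs = ligand_binding_probability(traj)
        # brute force: (frame, chain) units with any-ligand contact
        lig_heavy = [i for a in top.atoms
                     if (i := a.serial - 1) >= 0
                     and top.residues[a.residue_index].name == "MEL"
                     and not a.is_hydrogen]
        oracle = np.zeros(3)
        for frame in traj.frames:
            for chain in top.peptide_chains():
                for k, ri in enumerate(chain.residues):
                    res = top.residues[ri]
                    heavy = [i for i in res.atoms
                             if not top.atoms[i].is_hydrogen]
                    d = np.linalg.norm(
                        frame.coordinates[heavy][:, None]
                        - frame.coordinates[lig_heavy][None], axis=-1)
                    if d.min() <= CONTACT_CUTOFF:
                        oracle[k] += 1
        oracle /= 3 * 2  # frames x chains
        assert np.allclose(probs, oracle, atol=1e-12)
        # the glued ligand binds chain A only: probability about 1/2
        assert probs[2] == pytest.approx(0.5)

    def test_no_ligands_is_error(self, sheet_pair):
        top, frame = sheet_pair
        traj = Trajectory(topology=top, frames=[frame])
        with pytest.raises(ValueError):
            ligand_binding_probability(traj)

    def test_far_ligands_zero(self, templates, melatonin):
        lig_top, lig_frame = melatonin
        entries = [("ALA", 1, ["N", "CA", "C", "O", "CB"])]
        lig_names = [lig_top.atoms[i].name for i in range(lig_top.n_atoms)]
        top = build_topology(
            [("A", "peptide", entries), ("B", "peptide", entries),
             ("L1", "ligand", [("MEL", 1, lig_names)])],
            templates=templates)
        coords = np.zeros((top.n_atoms, 3))
        coords[5:10] = [[1.0 + 0.1 * k, 0, 0] for k in range(5)]
        coords[10:] = lig_frame.coordinates + [10.0, 10.0, 10.0]
        traj = Trajectory(topology=top, frames=[Frame(coordinates=coords)])
        _, probs = ligand_binding_probability(traj)
        assert probs.max() == 0.0

    def test_hbond_profile_half_frames(self, templates, melatonin):
        """A ligand donor bonded to Ala backbone O in half the frames gives
        a 0.5 main-chain profile."""
        lig_top, lig_frame = melatonin
        entries = [("ALA", 5, ["N", "CA", "C", "O", "CB"])]
        lig_names = [lig_top.atoms[i].name for i in range(lig_top.n_atoms)]
        top = build_topology(
            [("A", "peptide", entries), ("B", "peptide", entries),
             ("L1", "ligand", [("MEL", 1, lig_names)])],
            templates=templates)
        n12 = top.atom_index(2, "N12")
        h12 = top.atom_index(2, "H12")
        o_a = top.atom_index(0, "O")

        def make(bonded):
            coords = np.zeros((top.n_atoms, 3))
            coords[0:5] = [[0.1 * k, 0, 0] for k in range(5)]
            coords[5:10] = [[4.0 + 0.1 * k, 0, 0] for k in range(5)]
            lig = lig_frame.coordinates - lig_frame.coordinates[
                lig_top.atoms.index(lig_top.atoms[n12 - 10])]
            coords[10:] = lig + [20.0, 0, 0]
            if bonded:
                # move the whole ligand so N12-H12 points at A's O
                shift = (coords[o_a] + [0.30, 0, 0]) - coords[n12]
                coords[10:] += shift
                # orient: H between N and O
                coords[h12] = coords[n12] - [0.1, 0, 0]
            return Frame(coordinates=coords)

        traj = Trajectory(topology=top, frames=[make(True), make(False)])
        labels, mc, sc = ligand_hbond_profile(traj)
        assert mc[0] == pytest.approx(0.5)
        assert sc[0] == pytest.approx(0.0)


def _spread_coords_chain(top, ci):
    n = sum(len(top.residues[ri].atoms) for ri in top.chains[ci].residues)
    return np.array([[0.12 * k, 0.0, 0.0] for k in range(n)])


def _hexagon(radius=0.139):
    ang = np.arange(6) * np.pi / 3
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(6)])


class TestStacking:
    @pytest.fixture()
    def two_phe_topology(self, templates):
        entries = [("PHE", 23, ["N", "CA", "C", "O", "CB", "CG", "CD1",
                                "CD2", "CE1", "CE2", "CZ"])]
        return build_topology([("A", "peptide", entries),
                               ("B", "peptide", entries)],
                              templates=templates)

    def _ring_coords(self, top, ci, center, rot=np.eye(3)):
        ring = top.residues[ci].rings[0]
        coords = _hexagon() @ rot.T + center
        return ring, coords

    def test_parallel_and_herringbone(self, two_phe_topology):
        top = two_phe_topology
        for angle_set, dist, expected in ((0.0, 0.40, "parallel"),
                                          (60.0, 0.48, "herringbone")):
            coords = np.zeros((top.n_atoms, 3))
            coords[:11] = 5.0  # park non-ring atoms away
            coords[11:] = 10.0
            ring_a = top.residues[0].rings[0]
            ring_b = top.residues[1].rings[0]
            coords[ring_a] = _hexagon()
            rot = Rotation.from_euler("x", angle_set, degrees=True).as_matrix()
            coords[ring_b] = _hexagon() @ rot.T + [0, 0, dist]
            traj = Trajectory(topology=top, frames=[Frame(coordinates=coords)])
            events = stacking_events(traj, [(0, 0)], [(1, 0)])
            assert len(events) == 1
            ev = events[0]
            assert ev.angle == pytest.approx(angle_set, abs=1e-6)
            assert ev.classification == expected

    def test_closest_ring_pairing(self, templates):
        entries = [("PHE", 23, ["N", "CA", "C", "O", "CB", "CG", "CD1",
                                "CD2", "CE1", "CE2", "CZ"])]
        top = build_topology(
            [("A", "peptide", entries)] +
            [(c, "peptide", entries) for c in "BCD"], templates=templates)
        coords = np.full((top.n_atoms, 3), 50.0)
        ring_a = top.residues[0].rings[0]
        coords[ring_a] = _hexagon()
        for k, d in enumerate((0.5, 0.7, 0.9)):
            ring = top.residues[k + 1].rings[0]
            coords[ring] = _hexagon() + [0, 0, d]
        traj = Trajectory(topology=top, frames=[Frame(coordinates=coords)])
        events = stacking_events(traj, [(0, 0)], [(1, 0), (2, 0), (3, 0)])
        ev = next(e for e in events if e.ring_a == (0, 0))
        assert ev.ring_b == (1, 0)
        assert ev.centroid_distance == pytest.approx(0.5, abs=1e-9)

    def test_classification_thresholds(self):
        assert classify_stacking(30.0) == "parallel"
        assert classify_stacking(40.0) == "intermediate"
        assert classify_stacking(50.0) == "herringbone"


class TestChPi:
    def test_methyl_above_ring(self, templates, melatonin):
        lig_top, lig_frame = melatonin
        entries = [("ILE", 26, ["N", "CA", "C", "O", "CB", "CG1", "CG2",
                                "CD1"])]
        lig_names = [lig_top.atoms[i].name for i in range(lig_top.n_atoms)]
        top = build_topology(
            [("A", "peptide", entries),
             ("L1", "ligand", [("MEL", 1, lig_names)])],
            templates=templates)
        coords = np.full((top.n_atoms, 3), 30.0)
        benz = top.residues[1].rings[0]
        coords[8:] = lig_frame.coordinates + 10.0
        centroid = coords[benz].mean(axis=0)
        geo = ring_geometry(coords[benz])
        cd1 = top.atom_index(0, "CD1")
        cg2 = top.atom_index(0, "CG2")
        coords[cd1] = centroid + 0.36 * geo.normal
        coords[cg2] = centroid + 0.50 * geo.normal
        traj = Trajectory(topology=top, frames=[Frame(coordinates=coords)])
        d = chpi_min_distance(traj, [0], [(1, 0)])
        assert d[0] == pytest.approx(0.36, abs=1e-9)

    def test_matches_brute_force(self, templates, melatonin):
        lig_top, lig_frame = melatonin
        entries = [("LEU", 27, ["N", "CA", "C", "O", "CB", "CG", "CD1",
                                "CD2"])]
        lig_names = [lig_top.atoms[i].name for i in range(lig_top.n_atoms)]
        top = build_topology(
            [("A", "peptide", entries),
             ("L1", "ligand", [("MEL", 1, lig_names)])],
            templates=templates)
        rng = np.random.default_rng(8)
        frames = []
        for _ in range(4):
            coords = rng.uniform(0, 3, (top.n_atoms, 3))
            frames.append(Frame(coordinates=coords))
        traj = Trajectory(topology=top, frames=frames)
        d = chpi_min_distance(traj, [0], [(1, 0)])
        methyls = top.residues[0].methyls
        ring = top.residues[1].rings[0]
        for fi, frame in enumerate(frames):
            centroid = frame.coordinates[ring].mean(axis=0)
            oracle = min(np.linalg.norm(frame.coordinates[m] - centroid)
                         for m in methyls)
            assert d[fi] == pytest.approx(oracle, abs=1e-12)

    def test_missing_methyl_annotation(self, templates):
        entries = [("GLY", 1, ["N", "CA", "C", "O"]),
                   ("PHE", 23, ["N", "CA", "C", "O", "CB", "CG", "CD1",
                                "CD2", "CE1", "CE2", "CZ"])]
        top = build_topology([("A", "peptide", entries)],
                             templates=templates)
        coords = np.zeros((top.n_atoms, 3))
        traj = Trajectory(topology=top, frames=[Frame(coordinates=coords)])
        with pytest.raises(ValueError, match="GLY"):
            chpi_min_distance(traj, [0], [(1, 0)])
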