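"""Multi-model PDB reading and writing.

The multi-model PDB (MODEL/ENDMDL blocks, optional CRYST1) is the package's
trajectory interchange format. Parsing and formatting of the records is
delegated to biotite; this module converts between biotite's Å-based atom
arrays and the package's nm-based annotated :class:`~oligolens.core.Trajectory`.
A plain-text frames format is also provided for small fixtures.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as biotite_pdb

from .core import Frame, Topology, Trajectory, build_topology
from .templates import TemplateSet, load_default_templates

__all__ = ["TrajectoryFormatError", "read_multi_model_pdb",
           "write_multi_model_pdb", "read_frames_text", "write_frames_text"]

A_PER_NM = 10.0


class TrajectoryFormatError(ValueError):
    pass


def _check_model_atom_counts(path) -> None:
    """Pre-scan MODEL blocks; raise naming the first model whose atom count
    deviates from model 1."""
    counts: list[tuple[int, int]] = []
    model_no, n, in_model = 0, 0, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                model_no += 1
                n = 0
            elif rec == "ENDMDL":
                counts.append((model_no, n))
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if not in_model and model_no == 0:
                    model_no = 1
                    in_model = True
                n += 1
    if in_model:
        counts.append((model_no, n))
    if len(counts) > 1:
        ref = counts[0][1]
        for model, cnt in counts[1:]:
            if cnt != ref:
                raise TrajectoryFormatError(
                    f"atom-count mismatch: model {model} has {cnt} atoms, "
                    f"model 1 has {ref}")


def read_multi_model_pdb(path, templates: TemplateSet | None = None) -> Trajectory:
    """Read a multi-model PDB file into an annotated Trajectory.

    One Frame per MODEL block (a file without MODEL records is a single
    implicit model); coordinates are converted Å → nm; a CRYST1 record with
    an orthorhombic cell becomes the frame box. Residue names must resolve
    against the template set, which supplies donor/acceptor/ring/methyl
    annotations.
    """
    tset = templates if templates is not None else load_default_templates()
    _check_model_atom_counts(path)
    pdb_file = biotite_pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)  # AtomArrayStack, Å
    if stack.array_length() == 0:
        raise TrajectoryFormatError(f"{path}: no atoms")

    # group atoms into residues (file order) and residues into chains
    res_starts = struc.get_residue_starts(stack)
    chain_specs: list[tuple[str, str, list]] = []
    atom_order: list[int] = []
    current_chain = None  # (chain_id, kind, residues)
    ligand_serial = 0
    for k, start in enumerate(res_starts):
        stop = res_starts[k + 1] if k + 1 < len(res_starts) else stack.array_length()
        resname = str(stack.res_name[start])
        if resname not in tset:
            raise TrajectoryFormatError(
                f"{path}: unknown residue {resname!r} with no template")
        tmpl = tset[resname]
        chain_id = str(stack.chain_id[start])
        names = [str(n) for n in stack.atom_name[start:stop]]
        entry = (resname, int(stack.res_id[start]), names)
        if tmpl.is_ligand:
            # each ligand copy is its own chain descriptor
            ligand_serial += 1
            chain_specs.append((f"{chain_id}:{ligand_serial}", "ligand", [entry]))
            current_chain = None
        else:
            if current_chain is None or current_chain[0] != chain_id:
                current_chain = (chain_id, "peptide", [])
                chain_specs.append(current_chain)
            current_chain[2].append(entry)
        atom_order.extend(range(start, stop))

    topology = build_topology(chain_specs, templates=tset)
    order = np.asarray(atom_order, dtype=np.intp)
    coords = np.asarray(stack.coord)[:, order, :] / A_PER_NM

    boxes = stack.box  # (m, 3, 3) in Å or None
    frames = []
    for m in range(coords.shape[0]):
        box = None
        if boxes is not None:
            cell = np.asarray(boxes[m])
            if np.isfinite(cell).all() and np.abs(cell - np.diag(np.diag(cell))).max() > 1e-6:
                raise TrajectoryFormatError(
                    f"{path}: non-orthorhombic box is not supported")
            diag = np.diag(cell) / A_PER_NM
            if np.isfinite(diag).all() and (diag > 0).all():
                box = diag
        frames.append(Frame(coordinates=coords[m], box=box, time=float(m)))
    return Trajectory(topology=topology, frames=frames)


def write_multi_model_pdb(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB (coordinates nm → Å,
    box as CRYST1). Round-trips with :func:`read_multi_model_pdb` to the
    0.0001 nm fixed-width precision of the format."""
    top = traj.topology
    n = top.n_atoms
    array = struc.AtomArray(n)
    chain_ids = np.empty(n, dtype="U4")
    res_ids = np.empty(n, dtype=int)
    res_names = np.empty(n, dtype="U5")
    atom_names = np.empty(n, dtype="U6")
    elements = np.empty(n, dtype="U2")
    hetero = np.zeros(n, dtype=bool)
    ligand_counter = 0
    for chain in top.chains:
        for ri in chain.residues:
            res = top.residues[ri]
            if chain.kind == "ligand":
                # each ligand copy needs a unique residue id so readers
                # (including ours) keep the copies apart
                ligand_counter += 1
                seq = ligand_counter
                cid = "L"
            else:
                seq = res.seq_number
                cid = res.chain_id.split(":")[0][:1] or "A"
            for gi in res.atoms:
                a = top.atoms[gi]
                chain_ids[gi] = cid
                res_ids[gi] = seq
                res_names[gi] = res.name
                atom_names[gi] = a.name
                elements[gi] = a.element
                hetero[gi] = chain.kind == "ligand"
    array.chain_id = chain_ids
    array.res_id = res_ids
    array.res_name = res_names
    array.atom_name = atom_names
    array.element = elements
    array.hetero = hetero
    stack = struc.stack([array] * traj.n_frames)
    stack.coord = traj.coords() * A_PER_NM
    box = traj.frames[0].box
    if box is not None:
        stack.box = np.repeat(np.diag(box * A_PER_NM)[None], traj.n_frames, axis=0)
    pdb_file = biotite_pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# plain-text frames format (fixture convenience): per frame, a line "N",
# a line "box bx by bz" or "nobox", then N rows "x y z" in nm.

def write_frames_text(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{fr.coordinates.shape[0]}\n")
            if fr.box is None:
                fh.write("nobox\n")
            else:
                fh.write("box %.9f %.9f %.9f\n" % tuple(fr.box))
            for row in fr.coordinates:
                fh.write("%.9f %.9f %.9f\n" % tuple(row))


def read_frames_text(path, topology: Topology) -> Trajectory:
    frames = []
    with open(path) as fh:
        lines = iter(fh.read().split("\n"))
    try:
        while True:
            header = next(lines).strip()
            if not header:
                break
            n = int(header)
            box_line = next(lines).split()
            box = None if box_line[0] == "nobox" else np.array(
                [float(x) for x in box_line[1:4]])
            coords = np.array([[float(x) for x in next(lines).split()]
                               for _ in range(n)])
            frames.append(Frame(coordinates=coords, box=box, time=float(len(frames))))
    except StopIteration:
        pass
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames")
    return Trajectory(topology=topology, frames=frames)
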