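"""Topology and trajectory data model.

Internal units are nm (lengths) and kcal/mol (energies) throughout the
package; PDB I/O converts Å↔nm at the boundary. Hydrogens are carried in
the topology only where they matter chemically (amide and other donor
hydrogens); contacts, SASA and stacking analyses operate on heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .templates import (
    BACKBONE_NAMES,
    MASSES,
    VDW_RADII,
    ResidueTemplate,
    TemplateSet,
    load_default_templates,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom", "Residue", "Chain", "Topology", "Frame", "Trajectory",
    "build_topology", "select", "SelectionError",
]


@dataclass
class Atom:
    serial: int                 # 1-based, unique, ordered
    name: str                   # PDB atom name
    element: str
    residue_index: int          # 0-based index into Topology.residues
    is_hydrogen: bool
    mass: float                 # amu
    vdw_radius: float           # nm (0.120 for H; H excluded from SASA/contacts)


@dataclass
class Residue:
    name: str
    chain_id: str
    seq_number: int             # author numbering (e.g. 20..29)
    atoms: list[int] = field(default_factory=list)       # global atom indices
    backbone_atoms: list[int] = field(default_factory=list)
    sidechain_atoms: list[int] = field(default_factory=list)
    donors: list[tuple[int, int]] = field(default_factory=list)   # (heavy, H)
    acceptors: list[int] = field(default_factory=list)
    rings: list[list[int]] = field(default_factory=list)
    methyls: list[int] = field(default_factory=list)


@dataclass
class Chain:
    chain_id: str
    kind: str                   # "peptide" | "ligand"
    residues: list[int] = field(default_factory=list)    # indices into Topology.residues


@dataclass
class Topology:
    atoms: list[Atom]
    residues: list[Residue]
    chains: list[Chain]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def sequence(self, chain: Chain | int) -> list[str]:
        if isinstance(chain, int):
            chain = self.chains[chain]
        return [self.residues[i].name for i in chain.residues]

    def peptide_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.kind == "peptide"]

    def ligand_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.kind == "ligand"]

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen],
                        dtype=np.intp)

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Global index of a named atom in a residue (KeyError if absent)."""
        res = self.residues[residue_index]
        for i in res.atoms:
            if self.atoms[i].name == atom_name:
                return i
        raise KeyError(f"residue {res.name}{res.seq_number} has no atom {atom_name!r}")

    def find_atom(self, residue_index: int, atom_name: str) -> int | None:
        try:
            return self.atom_index(residue_index, atom_name)
        except KeyError:
            return None

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        seen: set[int] = set()
        for chain in self.chains:
            overlap = seen.intersection(chain.residues)
            if overlap:
                raise ValueError(f"residues {sorted(overlap)} appear in two chains")
            seen.update(chain.residues)
        if seen != set(range(len(self.residues))):
            raise ValueError("chains do not cover all residues")
        for ri, res in enumerate(self.residues):
            heavy = {i for i in res.atoms if not self.atoms[i].is_hydrogen}
            parts = set(res.backbone_atoms) | set(res.sidechain_atoms)
            if {i for i in parts if not self.atoms[i].is_hydrogen} != heavy:
                raise ValueError(
                    f"residue {ri} ({res.name}): backbone/sidechain do not "
                    f"partition heavy atoms")


@dataclass
class Frame:
    coordinates: np.ndarray          # (N, 3) nm
    box: np.ndarray | None = None    # (3,) orthorhombic edges nm
    time: float = 0.0                # ps or frame index

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not (self.box > 0).all():
                raise ValueError("box must be 3 positive edge lengths (nm)")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame]

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValueError("a Trajectory needs at least one frame")
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {k} has {fr.coordinates.shape[0]} atoms, "
                    f"topology has {n}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """All coordinates as one (n_frames, N, 3) array."""
        return np.stack([f.coordinates for f in self.frames])


# ---------------------------------------------------------------------------
# topology assembly

def build_topology(
    chain_specs: list[tuple[str, str, list[tuple[str, int, list[str]]]]],
    templates: TemplateSet | None = None,
) -> Topology:
    """Assemble an annotated Topology from raw per-chain residue content.

    Parameters
    ----------
    chain_specs
        List of ``(chain_id, kind, residues)`` where each residue is
        ``(resname, seq_number, atom_names)``. ``kind`` is "peptide" or
        "ligand".
    templates
        Template set used to resolve elements, donors/acceptors, rings and
        methyls; defaults to the packaged tables.

    Donor pairs whose hydrogen is missing from the input are dropped with a
    logged warning (the donor is disabled, not an error); amide hydrogens
    are handled separately by reconstruction.
    """
    tset = templates if templates is not None else load_default_templates()
    atoms: list[Atom] = []
    residues: list[Residue] = []
    chains: list[Chain] = []
    for chain_id, kind, res_list in chain_specs:
        chain = Chain(chain_id=chain_id, kind=kind)
        for resname, seq, atom_names in res_list:
            tmpl: ResidueTemplate = tset[resname]
            ri = len(residues)
            res = Residue(name=resname, chain_id=chain_id, seq_number=seq)
            local: dict[str, int] = {}
            for an in atom_names:
                elem = tmpl.element_of(an)
                is_h = elem == "H"
                gi = len(atoms)
                atoms.append(Atom(
                    serial=gi + 1, name=an, element=elem, residue_index=ri,
                    is_hydrogen=is_h, mass=MASSES[elem],
                    vdw_radius=VDW_RADII[elem],
                ))
                local[an] = gi
                res.atoms.append(gi)
            # main-chain / side-chain split: cap residues are entirely
            # main-chain (they extend the backbone amide chain); ligands are
            # entirely side-chain-like (MC/SC does not apply to them).
            for an, gi in local.items():
                if tmpl.is_amino:
                    bb = an in BACKBONE_NAMES
                elif tmpl.is_cap:
                    bb = True
                else:
                    bb = False
                (res.backbone_atoms if bb else res.sidechain_atoms).append(gi)
            # donors/acceptors: template side-chain chemistry plus implicit
            # backbone amide N-H and carbonyl O for amino acids.
            donor_pairs = list(tmpl.donors)
            if tmpl.is_amino:
                if resname != "PRO":
                    donor_pairs.append(("N", "H"))
                res.acceptors.extend(
                    local[a] for a in ("O", "OXT") if a in local)
            for heavy, hyd in donor_pairs:
                if heavy not in local:
                    continue
                if hyd not in local:
                    if not (tmpl.is_amino and hyd == "H"):
                        logger.warning(
                            "residue %s%s: donor %s lacks hydrogen %s; "
                            "donor disabled", resname, seq, heavy, hyd)
                    continue
                res.donors.append((local[heavy], local[hyd]))
            res.acceptors.extend(local[a] for a in tmpl.acceptors if a in local)
            res.rings.extend(
                [local[a] for a in ring] for ring in tmpl.rings
                if all(a in local for a in ring))
            res.methyls.extend(local[a] for a in tmpl.methyls if a in local)
            residues.append(res)
            chain.residues.append(ri)
        chains.append(chain)
    top = Topology(atoms=atoms, residues=residues, chains=chains)
    top.validate()
    return top


# ---------------------------------------------------------------------------
# selection language

class SelectionError(ValueError):
    """Malformed selection expression; message carries the token position."""


_KEYWORDS = {"and", "or", "not", "peptide", "ligand", "heavy", "hydrogen",
             "backbone", "sidechain", "chain", "resname", "name", "resseq",
             "all", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for tok in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(tok)
    return out


class _Parser:
    """Recursive-descent parser for the small selection grammar:

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := unary ("and" unary)*
    unary    := "not" unary | primary
    primary  := "(" expr ")" | flag | field value+
    flag     := peptide | ligand | heavy | hydrogen | backbone | sidechain | all
    field    := chain | resname | name | resseq    (values: bare words,
                resseq also accepts "a-b" ranges)
    """

    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology
        n = topology.n_atoms
        self._all = np.ones(n, dtype=bool)

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(
                f"unexpected token {self.peek()!r} at position {self.pos}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        if self.peek() == "not":
            self.take()
            return ~self.unary()
        return self.primary()

    def _mask_over_residues(self, pred) -> np.ndarray:
        mask = np.zeros(self.top.n_atoms, dtype=bool)
        for res in self.top.residues:
            if pred(res):
                mask[res.atoms] = True
        return mask

    def _values(self) -> list[str]:
        vals: list[str] = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError(
                f"expected a value at position {self.pos}")
        return vals

    def primary(self) -> np.ndarray:
        tok = self.take()
        top = self.top
        if tok == "(":
            mask = self.or_expr()
            if self.take() != ")":
                raise SelectionError(f"missing ')' at position {self.pos}")
            return mask
        if tok == "all":
            return self._all.copy()
        if tok in ("peptide", "ligand"):
            kinds = {res.chain_id: c.kind for c in top.chains
                     for res in (top.residues[i] for i in c.residues)}
            return self._mask_over_residues(lambda r: kinds[r.chain_id] == tok)
        if tok == "heavy":
            return np.array([not a.is_hydrogen for a in top.atoms])
        if tok == "hydrogen":
            return np.array([a.is_hydrogen for a in top.atoms])
        if tok in ("backbone", "sidechain"):
            mask = np.zeros(top.n_atoms, dtype=bool)
            for res in top.residues:
                idx = (res.backbone_atoms if tok == "backbone"
                       else res.sidechain_atoms)
                mask[idx] = True
            return mask
        if tok == "chain":
            vals = set(self._values())
            return self._mask_over_residues(lambda r: r.chain_id in vals)
        if tok == "resname":
            vals = set(self._values())
            return self._mask_over_residues(lambda r: r.name in vals)
        if tok == "name":
            vals = set(self._values())
            return np.array([a.name in vals for a in top.atoms])
        if tok == "resseq":
            wanted: set[int] = set()
            for v in self._values():
                if "-" in v[1:]:
                    lo, hi = v.split("-", 1) if not v.startswith("-") else (v, v)
                    wanted.update(range(int(lo), int(hi) + 1))
                else:
                    wanted.add(int(v))
            return self._mask_over_residues(lambda r: r.seq_number in wanted)
        raise SelectionError(
            f"unknown token {tok!r} at position {self.pos - 1}")


def select(topology: Topology, expression: str) -> np.ndarray:
    """Evaluate a selection expression to an ordered array of atom indices.

    The order is ascending atom serial; an empty result is allowed.
    Grammar: ``peptide | ligand | heavy | hydrogen | backbone | sidechain |
    all | chain ID... | resname NAME... | name NAME... | resseq N or A-B``,
    combined with ``and``/``or``/``not`` and parentheses.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, topology).parse()
    return np.flatnonzero(mask).astype(np.intp)
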