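"""Residue and ligand template tables.

Templates carry everything the analyses need to know about a residue type
beyond its coordinates: which atoms exist, their elements and bonds,
hydrogen-bond donors and acceptors, aromatic rings, methyl carbons, and the
internal coordinates from which the synthetic builder constructs side
chains. They are shipped as a plain-text table (``data/residues.txt``)
parsed once at import.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "InternalCoordinate",
    "ResidueTemplate",
    "TemplateSet",
    "load_default_templates",
    "STANDARD_AA",
    "ONE_TO_THREE",
    "MASSES",
    "VDW_RADII",
]

#: Standard one-letter -> three-letter amino-acid codes.
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
STANDARD_AA = frozenset(ONE_TO_THREE.values())
CAP_RESIDUES = frozenset({"ACE", "NH2"})

#: Atomic masses in amu.
MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

#: Bondi van der Waals radii in nm (heavy atoms; H carried for completeness).
VDW_RADII = {"C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180, "H": 0.120}

#: Backbone atom names of standard amino acids (plus OXT on C-termini).
BACKBONE_NAMES = frozenset({"N", "H", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class InternalCoordinate:
    """Placement rule: ``atom`` bonded to ``parent`` at ``bond`` Å, with
    angle(atom, parent, angref) = ``angle`` deg and
    dihedral(atom, parent, angref, dihref) = ``dihedral`` deg.

    ``angref``/``dihref`` of ``None`` mark the self-rooted seed atoms of
    ligand templates (first atom at origin, second along +x, third in the
    xy-plane)."""

    atom: str
    parent: str
    angref: str | None
    dihref: str | None
    bond: float
    angle: float | None
    dihedral: float | None


@dataclass
class ResidueTemplate:
    name: str
    sidechain: list[tuple[str, str]] = field(default_factory=list)  # (name, element)
    ics: list[InternalCoordinate] = field(default_factory=list)
    bonds: list[tuple[str, str]] = field(default_factory=list)
    donors: list[tuple[str, str]] = field(default_factory=list)  # (heavy, hydrogen)
    acceptors: list[str] = field(default_factory=list)
    rings: list[list[str]] = field(default_factory=list)
    methyls: list[str] = field(default_factory=list)

    @property
    def is_amino(self) -> bool:
        return self.name in STANDARD_AA

    @property
    def is_cap(self) -> bool:
        return self.name in CAP_RESIDUES

    @property
    def is_ligand(self) -> bool:
        return not (self.is_amino or self.is_cap)

    def atom_names(self) -> list[str]:
        """All template atom names in build order (backbone first for
        amino acids)."""
        names = []
        if self.is_amino:
            names.extend(["N", "CA", "C", "O"] if self.name == "PRO"
                         else ["N", "H", "CA", "C", "O"])
        names.extend(n for n, _ in self.sidechain)
        return names

    def element_of(self, atom_name: str) -> str:
        for n, e in self.sidechain:
            if n == atom_name:
                return e
        if atom_name in BACKBONE_NAMES:
            return "H" if atom_name == "H" else atom_name[0]
        raise KeyError(f"atom {atom_name!r} not in template {self.name}")


class TemplateSet:
    """Dictionary of residue templates keyed by residue name."""

    def __init__(self, templates: dict[str, ResidueTemplate]):
        self._templates = dict(templates)

    def __contains__(self, name: str) -> bool:
        return name in self._templates

    def __getitem__(self, name: str) -> ResidueTemplate:
        try:
            return self._templates[name]
        except KeyError:
            raise KeyError(
                f"unknown residue {name!r}: no template supplied"
            ) from None

    def add(self, template: ResidueTemplate) -> None:
        self._templates[template.name] = template

    def names(self) -> list[str]:
        return sorted(self._templates)


def _parse_templates(text: str) -> TemplateSet:
    templates: dict[str, ResidueTemplate] = {}
    current: ResidueTemplate | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[RES"):
            name = line.strip("[]").split()[1]
            current = ResidueTemplate(name)
            templates[name] = current
            continue
        if current is None:
            raise ValueError(f"residues.txt line {lineno}: record outside block")
        fields = line.split()
        kind, args = fields[0], fields[1:]
        if kind == "sidechain":
            current.sidechain.append((args[0], args[1]))
        elif kind == "ic":
            atom, parent, angref, dihref = args[:4]
            bond, angle, dihedral = args[4:7]
            current.ics.append(InternalCoordinate(
                atom=atom,
                parent=parent,
                angref=None if angref == "." else angref,
                dihref=None if dihref == "." else dihref,
                bond=float(bond),
                angle=None if angle == "." else float(angle),
                dihedral=None if dihedral == "." else float(dihedral),
            ))
        elif kind == "bond":
            current.bonds.append((args[0], args[1]))
        elif kind == "donor":
            current.donors.append((args[0], args[1]))
        elif kind == "acceptor":
            current.acceptors.append(args[0])
        elif kind == "ring":
            if len(args) < 5:
                raise ValueError(f"residues.txt line {lineno}: ring needs >=5 atoms")
            current.rings.append(list(args))
        elif kind == "methyl":
            current.methyls.append(args[0])
        else:
            raise ValueError(f"residues.txt line {lineno}: unknown record {kind!r}")
    return TemplateSet(templates)


def load_default_templates() -> TemplateSet:
    """Load the packaged residue/ligand template tables."""
    text = (resources.files("oligolens") / "data" / "residues.txt").read_text()
    return _parse_templates(text)
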