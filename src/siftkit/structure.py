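"""Lightweight containers and PDB I/O for protein–ligand pose ensembles.

The containers deliberately stay small: an :class:`Atom` is a named point with
an element and bookkeeping, a :class:`Residue` groups atoms under a residue
key, a :class:`Complex` is one receptor conformation plus exactly one ligand,
and a :class:`PoseEnsemble` is an ordered list of complexes (one per PDB
MODEL) with optional docking scores.  Reading goes through :mod:`gemmi`;
writing is a fixed-width PDB formatter so that synthetic fixtures round-trip
at PDB coordinate precision (3 decimals, i.e. 1e-3 Å).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import yaml

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)

#: atom names that constitute the peptide backbone
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: residue names treated as solvent and discarded on parse
WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP3"})

#: default residue-class table; residues may belong to several classes
#: (His is aromatic, polar and charged).  Users may override via a YAML
#: mapping class -> residue list.
DEFAULT_CLASS_TABLE: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "PRO", "GLY"}),
    "aromatic": frozenset({"PHE", "TYR", "TRP", "HIS"}),
    "polar": frozenset({"SER", "THR", "ASN", "GLN", "CYS", "TYR", "HIS", "TRP"}),
    "charged": frozenset({"ASP", "GLU", "LYS", "ARG", "HIS"}),
}

CANONICAL_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class LigandNotFoundError(ValueError):
    """No residue matched the ligand selector."""


class InconsistentEnsembleError(ValueError):
    """Ligand atom inventory differs across models of one ensemble."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    residue_key: ResidueKey
    record: str = "protein"  # protein | ligand | solvent
    partial_charge: Optional[float] = None
    formal_charge: Optional[int] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def label(self) -> str:
        """Compact one-letter label in the Q143 style (falls back to the
        3-letter code for non-canonical names)."""
        one = THREE_TO_ONE.get(self.name.upper(), self.name)
        return f"{one}{self.key[1]}{self.key[2].strip()}"

    def classes(self, class_table: Optional[Mapping[str, frozenset[str]]] = None,
                strict: bool = False) -> frozenset[str]:
        return classify_residue(self.name, class_table, strict=strict)

    @property
    def backbone_atoms(self) -> list[Atom]:
        return partition_backbone(self)[0]

    @property
    def sidechain_atoms(self) -> list[Atom]:
        return partition_backbone(self)[1]

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.label} has no atom {name!r}")


@dataclass
class Ligand:
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"ligand {self.name} has no atom {name!r}")

    def inventory(self) -> tuple[tuple[str, str], ...]:
        """(name, element) tuple per atom, in order — the identity of the
        ligand for ensemble-consistency checks."""
        return tuple((a.name, a.element) for a in self.atoms)


@dataclass
class Complex:
    model_id: int
    protein_residues: list[Residue]
    ligand: Ligand
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_residues = sorted(self.protein_residues, key=lambda r: r.key)

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.protein_residues:
            if r.key == key:
                return r
        raise KeyError(f"no protein residue with key {key}")

    def protein_atoms(self) -> list[Atom]:
        return [a for r in self.protein_residues for a in r.atoms]


@dataclass
class Pose:
    complex: Complex
    score: Optional[float] = None  # kcal/mol, lower is better


@dataclass
class PoseEnsemble:
    poses: list[Pose]
    source: str = ""

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def __getitem__(self, i: int) -> Pose:
        return self.poses[i]

    def complexes(self) -> list[Complex]:
        return [p.complex for p in self.poses]

    def with_scores(self, scores: Sequence[float]) -> "PoseEnsemble":
        if len(scores) != len(self.poses):
            raise ValueError("score list length must match pose count")
        return PoseEnsemble(
            [Pose(p.complex, float(s)) for p, s in zip(self.poses, scores)],
            source=self.source,
        )


@dataclass
class EnzymeAnnotation:
    """Functional annotation of a protease: catalytic triad, oxyanion hole,
    specificity subsites and the nucleophile atom (e.g. the catalytic
    cysteine's SG)."""

    catalytic_triad: frozenset[ResidueKey]
    oxyanion_hole: frozenset[ResidueKey]
    subsites: dict[str, frozenset[ResidueKey]]
    nucleophile_atom: tuple[ResidueKey, str]

    def __post_init__(self) -> None:
        labels = list(self.subsites)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if self.subsites[a] & self.subsites[b]:
                    raise ValueError(f"subsites {a} and {b} overlap")

    @staticmethod
    def from_yaml(text: str, chain: str = "A") -> "EnzymeAnnotation":
        doc = yaml.safe_load(text)

        def keys(nums: Iterable[int]) -> frozenset[ResidueKey]:
            return frozenset((chain, int(n), "") for n in nums)

        nuc = doc["nucleophile_atom"]
        return EnzymeAnnotation(
            catalytic_triad=keys(doc["catalytic_triad"]),
            oxyanion_hole=keys(doc["oxyanion_hole"]),
            subsites={k: keys(v) for k, v in doc["subsites"].items()},
            nucleophile_atom=((chain, int(nuc["residue"]), ""), str(nuc["atom"])),
        )


def load_class_table(text: str) -> dict[str, frozenset[str]]:
    """Parse a YAML residue-class table: mapping class -> list of 3-letter codes."""
    doc = yaml.safe_load(text)
    return {str(k): frozenset(str(r).upper() for r in v) for k, v in doc.items()}


def classify_residue(name: str,
                     class_table: Optional[Mapping[str, frozenset[str]]] = None,
                     strict: bool = False) -> frozenset[str]:
    """Class subset ({polar, hydrophobic, aromatic, charged}) for a residue name.

    The mapping is pure in the name.  Unknown names raise in strict mode and
    return the empty set (with a warning) otherwise.
    """
    table = DEFAULT_CLASS_TABLE if class_table is None else class_table
    name = name.upper()
    known = any(name in members for members in table.values())
    if not known and name not in CANONICAL_RESIDUES:
        if strict:
            raise KeyError(f"unknown residue name {name!r}")
        logger.warning("unknown residue name %r: assigning no classes", name)
        return frozenset()
    return frozenset(cls for cls, members in table.items() if name in members)


def partition_backbone(residue: Residue) -> tuple[list[Atom], list[Atom]]:
    """Split a protein residue's atoms into (backbone, side chain).

    Backbone = N, CA, C, O (+ OXT) and any hydrogens bonded by name
    convention (H, HA); everything else is side chain.  Glycine therefore has
    an empty side chain.  Missing backbone atoms only warn.
    """
    backbone, sidechain = [], []
    for atom in residue.atoms:
        if atom.name in BACKBONE_ATOM_NAMES or atom.name in ("H", "HA", "H1", "H2", "H3"):
            backbone.append(atom)
        else:
            sidechain.append(atom)
    present = {a.name for a in backbone}
    missing = {"N", "CA", "C", "O"} - present
    if missing and not residue.name.upper() in WATER_NAMES:
        logger.warning("residue %s missing backbone atoms %s", residue.label, sorted(missing))
    return backbone, sidechain


def _selector_predicate(selector) -> Callable[[str, str], bool]:
    """Build a predicate (resname, chain) -> bool from a selector spec.

    Accepted forms: a plain residue name ("AMC"), "resname:AMC", "chain:L",
    or a callable.
    """
    if callable(selector):
        return selector
    sel = str(selector)
    if sel.startswith("chain:"):
        chain = sel.split(":", 1)[1]
        return lambda resname, ch: ch == chain
    if sel.startswith("resname:"):
        sel = sel.split(":", 1)[1]
    name = sel.upper()
    return lambda resname, ch: resname.upper() == name


def parse_complexes(pdb_text: str, ligand_selector="AMC",
                    keep_waters: bool = False) -> PoseEnsemble:
    """Parse PDB text (single- or multi-MODEL) into a :class:`PoseEnsemble`.

    HETATM groups matching *ligand_selector* become the ligand (exactly one
    per model is required); waters are discarded unless *keep_waters*; of
    alternate locations only blank/'A' are kept.  Docking scores are read
    from per-model ``REMARK SCORE <value>`` lines when present.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    structure.setup_entities()
    pred = _selector_predicate(ligand_selector)
    scores = _parse_model_scores(pdb_text)

    poses: list[Pose] = []
    ligand_inventory = None
    for model in structure:
        protein: dict[ResidueKey, Residue] = {}
        ligand_atoms: list[Atom] = []
        ligand_name = None
        for chain in model:
            for res in chain:
                resname = res.name.strip()
                if resname.upper() in WATER_NAMES and not keep_waters:
                    continue
                key: ResidueKey = (chain.name, res.seqid.num, res.seqid.icode.strip())
                is_ligand = res.het_flag == "H" and pred(resname, chain.name)
                for atom in res:
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    a = Atom(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_key=key,
                        record="ligand" if is_ligand else "protein",
                        formal_charge=int(atom.charge) if atom.charge else None,
                    )
                    if is_ligand:
                        ligand_atoms.append(a)
                        ligand_name = resname
                    elif res.het_flag == "H" and resname.upper() in WATER_NAMES:
                        continue
                    else:
                        protein.setdefault(key, Residue(key, resname)).atoms.append(a)
        if not ligand_atoms:
            raise LigandNotFoundError(
                f"ligand not found: selector {ligand_selector!r} matched no HETATM group"
            )
        lig = Ligand(ligand_name or "LIG", ligand_atoms)
        if ligand_inventory is None:
            ligand_inventory = lig.inventory()
        elif lig.inventory() != ligand_inventory:
            raise InconsistentEnsembleError(
                "inconsistent ensemble: ligand atom inventory differs across models"
            )
        cx = Complex(model_id=model.num, protein_residues=list(protein.values()), ligand=lig)
        poses.append(Pose(cx, scores.get(model.num)))
    if not poses:
        raise ValueError("no models found in PDB text")
    return PoseEnsemble(poses)


def _parse_model_scores(pdb_text: str) -> dict[int, Optional[float]]:
    scores: dict[int, Optional[float]] = {}
    current = 1
    for line in pdb_text.splitlines():
        if line.startswith("MODEL"):
            current = int(line.split()[1])
        elif line.startswith("REMARK SCORE"):
            scores[current] = float(line.split()[2])
    return scores


def _format_atom_line(record: str, serial: int, atom: Atom, resname: str) -> str:
    chain, resnum, icode = atom.residue_key
    name = atom.name
    # PDB atom-name column convention: 1-letter elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    charge = ""
    if atom.formal_charge:
        charge = f"{abs(atom.formal_charge)}{'+' if atom.formal_charge > 0 else '-'}"
    x, y, z = atom.coords
    return (
        f"{record:<6}{serial:>5} {name:<4} {resname:>3} {chain[:1] or 'A'}"
        f"{resnum:>4}{icode[:1] or ' '}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}{charge:<2}"
    )


def write_pdb(obj, include_scores: bool = True) -> str:
    """Serialise a :class:`Complex` or :class:`PoseEnsemble` to PDB text.

    Ensembles are written as multi-MODEL files (MODEL order = pose order);
    per-pose docking scores are preserved as ``REMARK SCORE`` lines.
    """
    if isinstance(obj, Complex):
        return "\n".join(_complex_lines(obj)) + "\nEND\n"
    if isinstance(obj, PoseEnsemble):
        lines: list[str] = []
        for i, pose in enumerate(obj.poses, start=1):
            lines.append(f"MODEL     {i:>4}")
            if include_scores and pose.score is not None:
                lines.append(f"REMARK SCORE {pose.score:.4f}")
            lines.extend(_complex_lines(pose.complex))
            lines.append("ENDMDL")
        lines.append("END")
        return "\n".join(lines) + "\n"
    raise TypeError(f"cannot write object of type {type(obj).__name__}")


def _complex_lines(cx: Complex) -> list[str]:
    lines = []
    serial = 0
    for res in cx.protein_residues:
        for atom in res.atoms:
            serial += 1
            lines.append(_format_atom_line("ATOM", serial, atom, res.name))
    for atom in cx.ligand.atoms:
        serial += 1
        lines.append(_format_atom_line("HETATM", serial, atom, cx.ligand.name))
    return lines
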