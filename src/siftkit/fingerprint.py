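"""Structural interaction fingerprints (SIFt) for protein–ligand complexes.

Each protein residue in contact with the ligand is described by nine boolean
interaction bits — any, backbone, side chain, polar, hydrophobic, H-bond
acceptor, H-bond donor, aromatic, charged — determined from atom–atom
distances, atom/residue typing and (for hydrogen bonds, when hydrogens are
present) the donor–H…acceptor angle.  Averaging the bit matrices over an
ensemble of complexes (docking poses, trajectory snapshots, a ligand series)
yields per-residue interaction frequencies, from which consensus binding-site
residues are extracted at a frequency cutoff (50% by default, on the "any
contact" bit).

Direction convention: the "H-bond donor" bit means the *protein residue*
donates the hydrogen.  "any" is recomputed as the OR of plain heavy-atom
contact and the eight specific bits, so it always dominates them.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .structure import (
    Atom,
    Complex,
    PoseEnsemble,
    Residue,
    ResidueKey,
    partition_backbone,
)

#: the nine fingerprint bits, in canonical (report) order
BIT_NAMES: tuple[str, ...] = (
    "any", "backbone", "sidechain", "polar", "hydrophobic",
    "hbond_acceptor", "hbond_donor", "aromatic", "charged",
)
N_BITS = len(BIT_NAMES)
_BIT_INDEX = {b: i for i, b in enumerate(BIT_NAMES)}

POLAR_ELEMENTS = frozenset({"N", "O", "S"})

COVALENT_RADII = {  # Å, for bond inference by distance
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
}

# Protein hydrogen-bond donor / acceptor heavy atoms, by (residue, atom name).
# Backbone N donates (except proline), backbone O/OXT accepts, for every
# residue; the entries below add the side-chain capabilities.
_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}

# Formally charged side-chain groups used for salt-bridge detection.
_POSITIVE_GROUPS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
}
_NEGATIVE_GROUPS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}

# Aromatic ring atom names per residue (TRP contributes two rings).
_AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")],
}


@dataclass(frozen=True)
class GeometricCriteria:
    """Distance/angle cutoffs for the nine interaction bits (Å, degrees)."""

    contact_cutoff: float = 4.5
    polar_cutoff: float = 4.0
    hbond_heavy_cutoff: float = 3.5
    hbond_angle_min: float = 120.0
    aromatic_centroid_cutoff: float = 5.0
    salt_bridge_cutoff: float = 4.0

    def __post_init__(self) -> None:
        vals = (self.contact_cutoff, self.polar_cutoff, self.hbond_heavy_cutoff,
                self.hbond_angle_min, self.aromatic_centroid_cutoff,
                self.salt_bridge_cutoff)
        if any(v <= 0 for v in vals):
            raise ValueError("all geometric criteria must be positive")
        if self.hbond_heavy_cutoff > self.contact_cutoff:
            raise ValueError("hbond_heavy_cutoff must not exceed contact_cutoff")


@dataclass
class InteractionBitMatrix:
    """Sparse residues × 9-bits boolean matrix for one complex."""

    residues: list[ResidueKey]
    bits: np.ndarray  # (n_residues, 9) bool
    labels: dict[ResidueKey, str] = field(default_factory=dict)
    complex_ref: str = ""

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (len(self.residues), N_BITS):
            raise ValueError("bits must have shape (n_residues, 9)")

    def bit(self, key: ResidueKey, name: str) -> bool:
        return bool(self.bits[self.residues.index(key), _BIT_INDEX[name]])

    def as_frame(self) -> pd.DataFrame:
        idx = [self.labels.get(k, str(k)) for k in self.residues]
        return pd.DataFrame(self.bits, index=idx, columns=BIT_NAMES)


@dataclass
class FingerprintProfile:
    """Per-residue interaction frequencies averaged over ``n_complexes``."""

    residues: list
    frequencies: np.ndarray  # (n_residues, 9) in [0, 1]
    n_complexes: Optional[int] = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (len(self.residues), N_BITS):
            raise ValueError("frequencies must have shape (n_residues, 9)")
        if np.any(self.frequencies < 0) or np.any(self.frequencies > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.n_complexes is not None:
            counts = self.frequencies * self.n_complexes
            if not np.allclose(counts, np.round(counts), atol=1e-9):
                raise ValueError("frequency × n_complexes must be integral")

    def label(self, residue) -> str:
        return self.labels.get(residue, residue if isinstance(residue, str) else str(residue))

    def frequency(self, residue, bit: str) -> float:
        return float(self.frequencies[self.residues.index(residue), _BIT_INDEX[bit]])

    def as_frame(self) -> pd.DataFrame:
        idx = [self.label(r) for r in self.residues]
        return pd.DataFrame(self.frequencies, index=idx, columns=BIT_NAMES)

    @staticmethod
    def from_table(text: str, n_complexes: Optional[int] = None) -> "FingerprintProfile":
        """Read a delimited frequency table (residue label + nine bit columns).

        Duplicate residue labels are preserved as independent rows, as found
        in published averaged-fingerprint tables.
        """
        df = pd.read_csv(io.StringIO(text), sep="\t")
        cols = list(df.columns[1:])
        if [c.lower() for c in cols] != [b.lower() for b in BIT_NAMES]:
            raise ValueError(f"expected bit columns {BIT_NAMES}, got {tuple(cols)}")
        residues = [str(r) for r in df.iloc[:, 0]]
        return FingerprintProfile(residues, df.iloc[:, 1:].to_numpy(float),
                                  n_complexes=n_complexes)


def _bonded(atoms: Sequence[Atom], slack: float = 1.25) -> nx.Graph:
    """Bond graph inferred from covalent radii (no CONECT records needed)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    coords = np.array([a.coords for a in atoms])
    for i in range(len(atoms)):
        ri = COVALENT_RADII.get(atoms[i].element.upper(), 0.77)
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        rj = np.array([COVALENT_RADII.get(a.element.upper(), 0.77) for a in atoms[i + 1:]])
        for off in np.nonzero(d <= slack * (ri + rj))[0]:
            g.add_edge(i, int(i + 1 + off))
    return g


def _apolar_carbons(atoms: Sequence[Atom]) -> list[Atom]:
    """Carbons with no bonded N/O/S (distance-inferred bonds)."""
    heavy = [a for a in atoms if not a.is_hydrogen]
    out = []
    for a in heavy:
        if a.element.upper() != "C":
            continue
        polar_near = any(
            b.element.upper() in POLAR_ELEMENTS
            and np.linalg.norm(a.coords - b.coords) <= 1.8
            for b in heavy if b is not a
        )
        if not polar_near:
            out.append(a)
    return out


def _attached_hydrogens(donor: Atom, atoms: Sequence[Atom]) -> list[Atom]:
    return [h for h in atoms if h.is_hydrogen
            and np.linalg.norm(h.coords - donor.coords) <= 1.3]


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))


def _hbond_geometry_ok(donor: Atom, acceptor: Atom, donor_side_atoms: Sequence[Atom],
                       criteria: GeometricCriteria) -> bool:
    d = np.linalg.norm(donor.coords - acceptor.coords)
    if d > criteria.hbond_heavy_cutoff:
        return False
    hydrogens = _attached_hydrogens(donor, donor_side_atoms)
    if not hydrogens:
        return True  # distance-only criterion when the structure lacks hydrogens
    return any(
        _angle_deg(donor.coords, h.coords, acceptor.coords) >= criteria.hbond_angle_min
        for h in hydrogens
    )


def _residue_donors(res: Residue) -> list[Atom]:
    names = set(_SIDECHAIN_DONORS.get(res.name.upper(), ()))
    if res.name.upper() != "PRO":
        names.add("N")
    return [a for a in res.atoms if a.name in names]


def _residue_acceptors(res: Residue) -> list[Atom]:
    names = set(_SIDECHAIN_ACCEPTORS.get(res.name.upper(), ())) | {"O", "OXT"}
    return [a for a in res.atoms if a.name in names]


def _ligand_donors(atoms: Sequence[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element.upper() in ("N", "O")
            and (a.formal_charge or 0) >= 0]


def _ligand_acceptors(atoms: Sequence[Atom]) -> list[Atom]:
    return [a for a in atoms if a.element.upper() in ("N", "O")
            and (a.formal_charge or 0) <= 0]


def _ligand_charged_atoms(atoms: Sequence[Atom]) -> list[tuple[Atom, int]]:
    """Ligand N/O atoms carrying a formal charge, with equivalent group
    members (an O bonded to the same carbon as a charged O shares the charge,
    as in a carboxylate)."""
    heavy = [a for a in atoms if not a.is_hydrogen]
    charged = [(a, int(np.sign(a.formal_charge or 0))) for a in heavy
               if (a.formal_charge or 0) != 0]
    out = {id(a): (a, s) for a, s in charged}
    for a, s in charged:
        # spread over chemically equivalent neighbours-of-neighbours
        for b in heavy:
            if b.element.upper() != a.element.upper() or id(b) in out:
                continue
            shared = any(
                np.linalg.norm(a.coords - c.coords) <= 1.8
                and np.linalg.norm(b.coords - c.coords) <= 1.8
                for c in heavy if c is not a and c is not b
            )
            if shared:
                out[id(b)] = (b, s)
    return list(out.values())


def ligand_rings(atoms: Sequence[Atom], max_size: int = 6,
                 planarity_rms: float = 0.1) -> list[np.ndarray]:
    """Perceive aromatic-candidate rings in a ligand without connectivity
    records: minimum cycle basis of the covalent-radius bond graph, keeping
    all-C/N rings of ≤ *max_size* atoms that are planar within
    *planarity_rms* Å RMS of the best-fit plane.  Returns ring centroids.
    """
    heavy = [a for a in atoms if not a.is_hydrogen]
    g = _bonded(heavy)
    centroids = []
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) > max_size or len(cycle) < 3:
            continue
        members = [heavy[i] for i in cycle]
        if any(a.element.upper() not in ("C", "N") for a in members):
            continue
        coords = np.array([a.coords for a in members])
        center = coords.mean(axis=0)
        # plane fit via SVD; smallest singular direction = plane normal
        _, s, _ = np.linalg.svd(coords - center)
        rms_off_plane = s[-1] / math.sqrt(len(members))
        if rms_off_plane <= planarity_rms:
            centroids.append(center)
    return centroids


def _residue_ring_centroids(res: Residue) -> list[np.ndarray]:
    centroids = []
    for ring in _AROMATIC_RINGS.get(res.name.upper(), ()):
        coords = [a.coords for a in res.atoms if a.name in ring]
        if len(coords) == len(ring):
            centroids.append(np.mean(coords, axis=0))
    return centroids


def detect_interactions(cx: Complex,
                        criteria: GeometricCriteria = GeometricCriteria()
                        ) -> InteractionBitMatrix:
    """Compute the nine-bit interaction fingerprint of one complex.

    Only residues with at least one bit set appear in the (sparse) result.
    Raises ``ValueError`` for a ligand without heavy atoms.
    """
    lig_heavy = cx.ligand.heavy_atoms()
    if not lig_heavy:
        raise ValueError("ligand has no heavy atoms")
    lig_coords = np.array([a.coords for a in lig_heavy])
    lig_polar = [a for a in lig_heavy if a.element.upper() in POLAR_ELEMENTS]
    lig_apolar_c = _apolar_carbons(cx.ligand.atoms)
    lig_donors = _ligand_donors(lig_heavy)
    lig_acceptors = _ligand_acceptors(lig_heavy)
    lig_charged = _ligand_charged_atoms(cx.ligand.atoms)
    lig_ring_centroids = ligand_rings(cx.ligand.atoms)
    lig_all_atoms = cx.ligand.atoms

    rows: list[ResidueKey] = []
    bits_rows: list[np.ndarray] = []
    labels: dict[ResidueKey, str] = {}

    for res in cx.protein_residues:
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        coords = np.array([a.coords for a in heavy])
        dmat = np.linalg.norm(coords[:, None, :] - lig_coords[None, :, :], axis=2)
        if dmat.min() > max(criteria.contact_cutoff, criteria.aromatic_centroid_cutoff):
            continue

        bits = np.zeros(N_BITS, dtype=bool)
        backbone, _ = partition_backbone(res)
        backbone_ids = {id(a) for a in backbone}

        contact_idx = np.nonzero(dmat.min(axis=1) <= criteria.contact_cutoff)[0]
        in_contact = len(contact_idx) > 0
        for i in contact_idx:
            if id(heavy[i]) in backbone_ids:
                bits[_BIT_INDEX["backbone"]] = True
            else:
                bits[_BIT_INDEX["sidechain"]] = True

        # polar: residue N/O/S near ligand N/O/S
        for a in heavy:
            if a.element.upper() not in POLAR_ELEMENTS:
                continue
            if any(np.linalg.norm(a.coords - b.coords) <= criteria.polar_cutoff
                   for b in lig_polar):
                bits[_BIT_INDEX["polar"]] = True
                break

        # hydrophobic: apolar carbon pair within contact cutoff
        for a in _apolar_carbons(res.atoms):
            if any(np.linalg.norm(a.coords - b.coords) <= criteria.contact_cutoff
                   for b in lig_apolar_c):
                bits[_BIT_INDEX["hydrophobic"]] = True
                break

        # H-bonds; "donor" bit = protein donates
        for donor in _residue_donors(res):
            if any(_hbond_geometry_ok(donor, acc, res.atoms, criteria)
                   for acc in lig_acceptors):
                bits[_BIT_INDEX["hbond_donor"]] = True
                break
        for acceptor in _residue_acceptors(res):
            if any(_hbond_geometry_ok(don, acceptor, lig_all_atoms, criteria)
                   for don in lig_donors):
                bits[_BIT_INDEX["hbond_acceptor"]] = True
                break

        # aromatic: ring-centroid distance
        for rc in _residue_ring_centroids(res):
            if any(np.linalg.norm(rc - lc) <= criteria.aromatic_centroid_cutoff
                   for lc in lig_ring_centroids):
                bits[_BIT_INDEX["aromatic"]] = True
                break

        # charged: oppositely signed N/O pair within the salt-bridge cutoff
        res_groups = [("+", _POSITIVE_GROUPS), ("-", _NEGATIVE_GROUPS)]
        for sign_label, groups in res_groups:
            names = groups.get(res.name.upper(), ())
            sign = 1 if sign_label == "+" else -1
            for a in (x for x in heavy if x.name in names):
                if any(s == -sign
                       and np.linalg.norm(a.coords - b.coords) <= criteria.salt_bridge_cutoff
                       for b, s in lig_charged):
                    bits[_BIT_INDEX["charged"]] = True
                    break
            if bits[_BIT_INDEX["charged"]]:
                break

        # "any" dominates by construction: plain contact OR any specific bit
        bits[_BIT_INDEX["any"]] = in_contact or bits.any()
        if bits.any():
            rows.append(res.key)
            bits_rows.append(bits)
            labels[res.key] = res.label

    bits_arr = (np.array(bits_rows, dtype=bool) if bits_rows
                else np.zeros((0, N_BITS), dtype=bool))
    return InteractionBitMatrix(rows, bits_arr, labels,
                                complex_ref=f"model {cx.model_id}")


def average_fingerprint(matrices: Sequence[InteractionBitMatrix]) -> FingerprintProfile:
    """Average bit matrices over a population of complexes.

    frequency(residue, bit) = (#matrices with the bit set) / (#matrices);
    a residue absent from a matrix contributes zero to its counts.
    """
    if not matrices:
        raise ValueError("cannot average an empty list of matrices")
    keys: list[ResidueKey] = []
    labels: dict = {}
    for m in matrices:
        for k in m.residues:
            if k not in keys:
                keys.append(k)
            labels.setdefault(k, m.labels.get(k, str(k)))
    keys.sort()
    counts = np.zeros((len(keys), N_BITS), dtype=float)
    index = {k: i for i, k in enumerate(keys)}
    for m in matrices:
        for k, row in zip(m.residues, m.bits):
            counts[index[k]] += row
    return FingerprintProfile(keys, counts / len(matrices),
                              n_complexes=len(matrices), labels=labels)


def _residue_number(profile: FingerprintProfile, residue) -> int:
    if isinstance(residue, tuple):
        return int(residue[1])
    label = profile.label(residue)
    digits = "".join(ch for ch in str(label) if ch.isdigit())
    return int(digits) if digits else 0


def consensus_residues(profile: FingerprintProfile, cutoff: float = 0.5,
                       bit: str = "any") -> list:
    """Residues whose *bit* frequency ≥ *cutoff*, ordered by descending
    frequency and then residue number (a 50% cutoff on the "any contact"
    bit gives the consensus binding site)."""
    if len(profile.residues) == 0:
        raise ValueError("profile is empty")
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    if bit not in _BIT_INDEX:
        raise ValueError(f"unknown bit selector {bit!r}; choose from {BIT_NAMES}")
    j = _BIT_INDEX[bit]
    hits = [(r, profile.frequencies[i, j]) for i, r in enumerate(profile.residues)
            if profile.frequencies[i, j] >= cutoff]
    hits.sort(key=lambda rf: (-rf[1], _residue_number(profile, rf[0])))
    return [r for r, _ in hits]


def profile_report(profile: FingerprintProfile) -> str:
    """Delimited frequency table (residue + nine bit columns), frequencies
    rounded to 2 decimals, rows sorted by descending "any"."""
    df = profile.as_frame().round(2)
    df = df.sort_values("any", ascending=False, kind="stable")
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index_label="residue", float_format="%.2f")
    return buf.getvalue()


class FingerprintModel:
    """Ensemble interaction-fingerprint estimator.

    Treats each complex of a pose ensemble as one Bernoulli observation per
    (residue, bit); ``fit()`` estimates the occurrence frequencies and their
    binomial standard errors.

    Parameters
    ----------
    data : PoseEnsemble or sequence of InteractionBitMatrix
        Complexes to fingerprint, or precomputed bit matrices.
    criteria : GeometricCriteria, optional
        Distance/angle cutoffs used when *data* is an ensemble.
    """

    def __init__(self, data, criteria: GeometricCriteria = GeometricCriteria()):
        if isinstance(data, PoseEnsemble):
            self.matrices = [detect_interactions(c, criteria) for c in data.complexes()]
        else:
            self.matrices = list(data)
        if not self.matrices:
            raise ValueError("no complexes to fingerprint")
        self.criteria = criteria

    def fit(self) -> "FingerprintResults":
        profile = average_fingerprint(self.matrices)
        return FingerprintResults(self, profile)


class FingerprintResults:
    """Fitted fingerprint frequencies with binomial uncertainties."""

    def __init__(self, model: FingerprintModel, profile: FingerprintProfile):
        self.model = model
        self.profile = profile
        self.n_complexes = profile.n_complexes
        p = profile.frequencies
        self.standard_errors = np.sqrt(p * (1 - p) / max(self.n_complexes, 1))

    @property
    def frequencies(self) -> np.ndarray:
        return self.profile.frequencies

    def consensus(self, cutoff: float = 0.5, bit: str = "any") -> list:
        return consensus_residues(self.profile, cutoff, bit)

    def summary(self) -> str:
        lines = [
            "Ensemble interaction fingerprint",
            f"complexes: {self.n_complexes}    interacting residues: "
            f"{len(self.profile.residues)}",
            "",
            profile_report(self.profile),
        ]
        return "\n".join(lines)
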