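"""Synthetic pocket–ligand fixtures with planted, known-by-construction truth.

Every stage of the pipeline can be exercised without external structures:

* :func:`make_planted_complex` builds a toy binding pocket around a rigid
  AMC-like fluorogenic ligand, placing one residue per requested interaction
  at exactly the requested geometry (distance, and angle for hydrogen bonds)
  and recording the expected fingerprint bits independently of the detector;
* :func:`make_catalytic_site_complex` builds a "zmCP1-mini" active site —
  catalytic triad, oxyanion hole, S1/S2 subsites with the canonical residue
  names and numbers — with a controllable scissile-carbon-to-sulfur distance
  and oxyanion hydrogen bond, for binding-mode triage;
* :func:`make_pose_ensemble` turns a planted complex into a multi-MODEL pose
  ensemble with per-interaction occurrence probability *p* and additional
  rigidly displaced poses hitting requested ligand RMSD values exactly;
* :func:`make_energy_series` and :func:`make_score_table` emit delimited
  snapshot-energy and docking-score tables with known means / known winner.

All generators are pure functions of their spec plus a seed: identical calls
produce byte-identical text.  Planted geometries should keep a ≥0.3 Å guard
band away from the detection cutoffs so tests cannot flake on floating-point
detail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fingerprint import (
    BIT_NAMES,
    GeometricCriteria,
    InteractionBitMatrix,
    N_BITS,
    _BIT_INDEX,
)
from .structure import Atom, Complex, Ligand, Pose, PoseEnsemble, Residue, write_pdb

# ---------------------------------------------------------------------------
# rigid templates


def _hexagon(center: np.ndarray, radius: float = 1.40) -> list[np.ndarray]:
    return [center + radius * np.array([math.cos(a), math.sin(a), 0.0])
            for a in np.linspace(0, 2 * math.pi, 7)[:-1]]


_RING2_CENTER = np.array([2.096, 1.212, 0.0])  # fused-hexagon geometry


def _amc_ligand_atoms() -> list[tuple[str, str, np.ndarray, int]]:
    """Rigid planar bicyclic AMC-like ligand with an Arg-like P1 side chain.

    (name, element, xyz, formal_charge) tuples.  Two fused planar hexagons
    (naphthalene-like, sharing an edge) stand in for the coumarin, with the
    amide leaving-group linkage on C3: the amide nitrogen N1, the scissile
    carbonyl carbon named "C", its oxygen "O", and a P1 side chain ending in
    a guanidinium group whose NH1 carries the +1 formal charge.
    """
    atoms: list[tuple[str, str, np.ndarray, int]] = []
    ring1 = _hexagon(np.array([0.0, 0.0, 0.0]))
    ring2 = _hexagon(_RING2_CENTER)
    seen: list[np.ndarray] = []
    idx = 1
    for p in ring1 + ring2:
        if any(np.linalg.norm(p - q) < 0.2 for q in seen):
            continue
        seen.append(p)
        atoms.append((f"C{idx}", "C", p, 0))
        idx += 1
    # amide linkage on C3 (-0.70, 1.21, 0), growing radially outward
    atoms += [
        ("N1", "N", np.array([-1.415, 2.450, 0.0]), 0),
        ("C", "C", np.array([-2.10, 3.60, 0.30]), 0),
        ("O", "O", np.array([-3.30, 3.45, 0.45]), 0),
    ]
    # Arg-like P1 chain ending in a guanidinium group (+1 on NH1)
    atoms += [
        ("CB", "C", np.array([-1.50, 4.90, 0.45]), 0),
        ("CG", "C", np.array([-2.45, 6.05, 0.55]), 0),
        ("CD", "C", np.array([-1.85, 7.40, 0.65]), 0),
        ("NE", "N", np.array([-2.80, 8.50, 0.75]), 0),
        ("CZ", "C", np.array([-2.35, 9.75, 0.85]), 0),
        ("NH1", "N", np.array([-1.05, 9.95, 0.85]), 1),
        ("NH2", "N", np.array([-3.20, 10.75, 0.95]), 0),
    ]
    return atoms


def make_amc_ligand(name: str = "AMC") -> Ligand:
    lig_atoms = [
        Atom(serial=i + 1, name=nm, element=el, coords=xyz.copy(),
             residue_key=("L", 1, ""), record="ligand",
             formal_charge=fc or None)
        for i, (nm, el, xyz, fc) in enumerate(_amc_ligand_atoms())
    ]
    return Ligand(name, lig_atoms)


#: ligand ring-carbon names usable as hydrophobic / aromatic anchors
LIGAND_RING_ATOMS = tuple(f"C{i}" for i in range(1, 11))
#: heavy atoms of the ligand's P1 group (the Arg-like side chain)
P1_GROUP = ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2")


def _backbone(with_h: bool = True) -> list[tuple[str, str, np.ndarray]]:
    atoms = [
        ("N", "N", np.array([0.0, 0.0, 0.0])),
        ("CA", "C", np.array([1.46, 0.0, 0.0])),
        ("C", "C", np.array([2.03, 1.39, 0.0])),
        ("O", "O", np.array([1.33, 2.40, 0.0])),
    ]
    if with_h:
        atoms.append(("H", "H", np.array([-0.60, -0.81, 0.0])))
    return atoms


def _ring_coords(center: np.ndarray, n: int, radius: float,
                 z: float) -> list[np.ndarray]:
    return [center + np.array([radius * math.cos(a), radius * math.sin(a), 0.0])
            + np.array([0.0, 0.0, z])
            for a in np.linspace(0, 2 * math.pi, n + 1)[:-1]]


def _sidechain(resname: str) -> list[tuple[str, str, np.ndarray]]:
    cb = np.array([2.00, -0.80, 1.15])
    chains = {
        "GLY": [],
        "ALA": [("CB", "C", cb)],
        "SER": [("CB", "C", cb), ("OG", "O", np.array([1.45, -2.06, 1.25]))],
        "CYS": [("CB", "C", cb), ("SG", "S", np.array([2.80, -1.90, 2.30]))],
        "LEU": [("CB", "C", cb), ("CG", "C", np.array([1.50, -2.20, 1.40])),
                ("CD1", "C", np.array([2.30, -3.25, 0.65])),
                ("CD2", "C", np.array([1.60, -2.60, 2.90]))],
        "MET": [("CB", "C", cb), ("CG", "C", np.array([1.50, -2.20, 1.40])),
                ("SD", "S", np.array([2.40, -3.55, 2.10])),
                ("CE", "C", np.array([1.50, -4.95, 1.90]))],
        "ASP": [("CB", "C", cb), ("CG", "C", np.array([1.50, -2.20, 1.40])),
                ("OD1", "O", np.array([0.28, -2.48, 1.40])),
                ("OD2", "O", np.array([2.40, -3.15, 1.50]))],
        "ASN": [("CB", "C", cb), ("CG", "C", np.array([1.50, -2.20, 1.40])),
                ("OD1", "O", np.array([0.28, -2.48, 1.40])),
                ("ND2", "N", np.array([2.40, -3.15, 1.50]))],
        "GLN": [("CB", "C", cb), ("CG", "C", np.array([1.50, -2.20, 1.40])),
                ("CD", "C", np.array([2.30, -3.45, 1.85])),
                ("OE1", "O", np.array([3.52, -3.45, 1.95])),
                ("NE2", "N", np.array([1.62, -4.58, 2.10]))],
        "ARG": [("CB", "C", cb), ("CG", "C", np.array([1.50, -2.20, 1.40])),
                ("CD", "C", np.array([2.30, -3.45, 1.85])),
                ("NE", "N", np.array([1.65, -4.65, 2.20])),
                ("CZ", "C", np.array([2.30, -5.80, 2.45])),
                ("NH1", "N", np.array([3.62, -5.85, 2.40])),
                ("NH2", "N", np.array([1.62, -6.90, 2.70]))],
    }
    if resname in chains:
        return chains[resname]
    if resname == "PHE":
        ring = _ring_coords(np.array([2.20, -3.40, 0.0]), 6, 1.39, 1.15)
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        return [("CB", "C", cb)] + [(n, "C", p) for n, p in zip(names, ring)]
    if resname == "HIS":
        ring = _ring_coords(np.array([2.05, -3.10, 0.0]), 5, 1.20, 1.15)
        names = ["CG", "ND1", "CE1", "NE2", "CD2"]
        elems = ["C", "N", "C", "N", "C"]
        return [("CB", "C", cb)] + [(n, e, p) for n, e, p in zip(names, elems, ring)]
    raise KeyError(f"no synthetic template for residue {resname!r}")


def residue_template(resname: str, with_h: bool = True
                     ) -> list[tuple[str, str, np.ndarray]]:
    return _backbone(with_h) + _sidechain(resname.upper())


# ---------------------------------------------------------------------------
# planting


@dataclass(frozen=True)
class PlantedInteraction:
    """One interaction to realise: residue, fingerprint class, geometry."""

    residue_name: str
    kind: str                      # fingerprint bit name (specific bits) or "contact"
    distance: float                # probe-atom-to-target distance, Å
    angle: Optional[float] = None  # donor–H…acceptor angle, degrees (H-bonds)
    probe_atom: Optional[str] = None
    ligand_atom: Optional[str] = None


#: default probe/target geometry per interaction class
_PLANT_DEFAULTS = {
    # kind: (residue, probe atom, ligand atom, distance)
    "contact": ("ALA", "CB", "C7", 3.8),
    "backbone": ("GLY", "CA", "C10", 3.8),
    "hydrophobic": ("LEU", "CD1", "C5", 3.8),
    "polar": ("SER", "OG", "N1", 3.2),
    "hbond_donor": ("GLN", "NE2", "O", 2.9),
    "hbond_acceptor": ("SER", "OG", "N1", 2.9),
    "aromatic": ("PHE", "ring", "ring", 4.0),
    "charged": ("ASP", "OD1", "NH1", 3.5),
}


@dataclass
class PlantSpec:
    interactions: list[PlantedInteraction] = field(default_factory=list)
    pocket_radius: float = 9.0     # Å clearance for non-interacting residues
    include_fillers: int = 4       # non-interacting pocket residues
    seed: int = 0

    def __post_init__(self) -> None:
        for pi in self.interactions:
            if pi.distance <= 0.5:
                raise ValueError(
                    f"unsatisfiable geometry: distance {pi.distance} Å for "
                    f"{pi.kind} is below covalent contact"
                )


@dataclass
class PlantedComplex:
    pdb_text: str
    complex: Complex
    truth: InteractionBitMatrix
    directions: dict = field(default_factory=dict)  # residue key -> unit vector


def planted_interaction(kind: str, distance: Optional[float] = None,
                        angle: Optional[float] = None,
                        residue_name: Optional[str] = None,
                        probe_atom: Optional[str] = None,
                        ligand_atom: Optional[str] = None) -> PlantedInteraction:
    """Convenience constructor filling class-appropriate defaults."""
    if kind not in _PLANT_DEFAULTS:
        raise ValueError(f"unknown interaction class {kind!r}")
    res, probe, target, d = _PLANT_DEFAULTS[kind]
    if kind == "hbond_donor" and angle is None:
        angle = 165.0
    return PlantedInteraction(
        residue_name=residue_name or res, kind=kind,
        distance=distance if distance is not None else d, angle=angle,
        probe_atom=probe_atom or probe, ligand_atom=ligand_atom or target,
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0, 1))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate π about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _place_residue(resname: str, probe_atom: str, anchor: np.ndarray,
                   direction: np.ndarray, distance: float,
                   with_h: bool = False) -> dict[str, tuple[str, np.ndarray]]:
    """Place a residue template so *probe_atom* lies at
    ``anchor + distance·direction`` with the rest of the residue pointing
    away from the anchor.  Returns {atom name: (element, coords)}."""
    template = residue_template(resname, with_h=with_h)
    coords = {n: (e, p.copy()) for n, e, p in template}
    if probe_atom == "ring":
        ring_names = [n for n, _, _ in template if n in
                      ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "ND1", "NE2")]
        probe_pos = np.mean([coords[n][1] for n in ring_names], axis=0)
    else:
        probe_pos = coords[probe_atom][1]
    rest = np.mean([p for n, (e, p) in coords.items()], axis=0)
    away = rest - probe_pos
    if np.linalg.norm(away) < 1e-9:
        away = np.array([0.0, 0.0, 1.0])
    rot = _rotation_onto(away, direction)
    target = anchor + distance * direction
    placed = {}
    for n, (e, p) in coords.items():
        placed[n] = (e, rot @ (p - probe_pos) + target)
    return placed


def _solve_hbond_hydrogen(donor: np.ndarray, acceptor: np.ndarray,
                          angle_deg: float, bond: float = 1.0) -> np.ndarray:
    """Position of the donor hydrogen giving the requested donor–H…acceptor
    angle, with the H in the donor–acceptor plane at 1.0 Å from the donor."""
    d = acceptor - donor
    dist = np.linalg.norm(d)
    u = d / dist
    # perpendicular in-plane direction
    perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(u, np.array([0.0, 1.0, 0.0]))
    perp /= np.linalg.norm(perp)

    def angle_at_h(alpha: float) -> float:
        h = donor + bond * (math.cos(alpha) * u + math.sin(alpha) * perp)
        v1, v2 = donor - h, acceptor - h
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(float(np.clip(c, -1, 1))))

    lo, hi = 0.0, math.pi / 2  # alpha=0 -> 180°, angle decreases with alpha
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if angle_at_h(mid) > angle_deg:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    return donor + bond * (math.cos(alpha) * u + math.sin(alpha) * perp)


# ---------------------------------------------------------------------------
# independent interaction audit
#
# The generator derives the ground-truth bits of a placed residue from its
# realised geometry with its own compact rule set (shared chemistry tables,
# separate logic) — never by calling the detector module under test.

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H"}

_SYN_DONORS = {
    "GLN": {"NE2"}, "ASN": {"ND2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "CYS": {"SG"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"},
}
_SYN_ACCEPTORS = {
    "GLN": {"OE1"}, "ASN": {"OD1"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "CYS": {"SG"}, "HIS": {"ND1", "NE2"}, "MET": {"SD"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}
_SYN_NEGATIVE = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_SYN_POSITIVE = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"},
                 "HIS": {"ND1", "NE2"}}
_SYN_RINGS = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
}
#: ligand guanidinium nitrogens share the +1 formal charge
_LIGAND_POSITIVE = {"NE", "NH1", "NH2"}


def _ligand_ring_name_sets() -> list[frozenset[str]]:
    """Atom-name sets of the ligand's two fused six-membered rings,
    recovered geometrically from the rigid template."""
    atoms = _amc_ligand_atoms()
    ring_atoms = [(n, p) for n, e, p, _ in atoms if e == "C" and n.startswith("C")
                  and n not in ("CB", "CG", "CD", "CZ", "C")]
    centers = (np.array([0.0, 0.0, 0.0]), _RING2_CENTER)
    return [frozenset(n for n, p in ring_atoms
                      if abs(np.linalg.norm(p - c) - 1.40) < 0.05)
            for c in centers]


def _apolar_carbon_names(named: list[tuple[str, str, np.ndarray]]) -> set[str]:
    """Carbons with no N/O/S within bonding distance, by the simple 1.8 Å rule."""
    out = set()
    for n, e, p in named:
        if e != "C":
            continue
        near_polar = any(e2 in ("N", "O", "S")
                         and 1e-6 < np.linalg.norm(p - p2) <= 1.8
                         for _, e2, p2 in named)
        if not near_polar:
            out.add(n)
    return out


def _audit_bits(resname: str, placed: dict[str, tuple[str, np.ndarray]],
                lig_atoms, criteria: GeometricCriteria
                ) -> tuple[np.ndarray, float]:
    """(bits, guard margin) the realised geometry implies for one residue.

    Each bit's margin is how far its decision evidence (the closest
    qualifying atom pair, or ring-centroid pair) sits from that bit's own
    cutoff; the returned margin is the minimum over bits, i.e. how much any
    atom would have to move to flip the fingerprint.
    """
    resname = resname.upper()
    bits = np.zeros(N_BITS, dtype=bool)
    inf = float("inf")
    # closest qualifying distance per bit, compared to that bit's cutoff
    dmin = {b: inf for b in BIT_NAMES}
    res_named = [(n, e, p) for n, (e, p) in placed.items()]
    res_heavy = [(n, e, p) for n, e, p in res_named if e != "H"]
    lig_named = [(a.name, a.element.upper(), a.coords,
                  int(a.formal_charge or 0)) for a in lig_atoms]
    lig_heavy = [(n, e, p, q) for n, e, p, q in lig_named if e != "H"]
    res_apolar = _apolar_carbon_names([(n, e, p) for n, e, p in res_heavy])
    lig_apolar = _apolar_carbon_names([(n, e, p) for n, e, p, _ in lig_heavy])
    donors = _SYN_DONORS.get(resname, set()) | ({"N"} if resname != "PRO" else set())
    acceptors = _SYN_ACCEPTORS.get(resname, set()) | {"O", "OXT"}
    hydrogens = [(n, p) for n, e, p in res_named if e == "H"]

    for rn, re_, rp in res_heavy:
        for ln, le, lp, lq in lig_heavy:
            d = float(np.linalg.norm(rp - lp))
            dmin["any"] = min(dmin["any"], d)
            part = "backbone" if rn in _BACKBONE_NAMES else "sidechain"
            dmin[part] = min(dmin[part], d)
            if rn in res_apolar and ln in lig_apolar:
                dmin["hydrophobic"] = min(dmin["hydrophobic"], d)
            if re_ in ("N", "O", "S") and le in ("N", "O", "S"):
                dmin["polar"] = min(dmin["polar"], d)
                if rn in donors and lq <= 0:
                    attached = [hp for hn, hp in hydrogens
                                if np.linalg.norm(hp - rp) <= 1.3]
                    angle_ok = not attached or any(
                        _deg(rp - hp, lp - hp) >= criteria.hbond_angle_min
                        for hp in attached
                    )
                    if angle_ok:
                        dmin["hbond_donor"] = min(dmin["hbond_donor"], d)
                if rn in acceptors and le in ("N", "O") and lq >= 0:
                    dmin["hbond_acceptor"] = min(dmin["hbond_acceptor"], d)
            if rn in _SYN_NEGATIVE.get(resname, ()) and le in ("N", "O") \
                    and ln in _LIGAND_POSITIVE:
                dmin["charged"] = min(dmin["charged"], d)
            # the ligand template carries no negative group, so bridges to
            # positively charged residues cannot occur

    lig_ring_centroids = [
        np.mean([p for n, e, p, _ in lig_heavy if n in names], axis=0)
        for names in _ligand_ring_name_sets()
    ]
    for ring_names in _SYN_RINGS.get(resname, ()):
        if not all(n in placed for n in ring_names):
            continue
        rc = np.mean([placed[n][1] for n in ring_names], axis=0)
        for lc in lig_ring_centroids:
            d = float(np.linalg.norm(rc - lc))
            dmin["aromatic"] = min(dmin["aromatic"], d)

    cutoffs = {
        "any": criteria.contact_cutoff,
        "backbone": criteria.contact_cutoff,
        "sidechain": criteria.contact_cutoff,
        "polar": criteria.polar_cutoff,
        "hydrophobic": criteria.contact_cutoff,
        "hbond_donor": criteria.hbond_heavy_cutoff,
        "hbond_acceptor": criteria.hbond_heavy_cutoff,
        "aromatic": criteria.aromatic_centroid_cutoff,
        "charged": criteria.salt_bridge_cutoff,
    }
    margin = inf
    for b in BIT_NAMES:
        if dmin[b] is inf:
            continue
        bits[_BIT_INDEX[b]] = dmin[b] <= cutoffs[b]
        margin = min(margin, abs(dmin[b] - cutoffs[b]))
    bits[_BIT_INDEX["any"]] |= bits.any()
    return bits, margin


def _deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(float(np.clip(c, -1.0, 1.0))))


def _spin_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(theta) * k + (1 - math.cos(theta)) * (k @ k)


def make_planted_complex(spec: PlantSpec,
                         criteria: GeometricCriteria = GeometricCriteria(),
                         guard_band: float = 0.25) -> PlantedComplex:
    """Build a pocket–ligand complex realising exactly the requested
    interactions, plus its ground-truth bit matrix.

    For each plant the residue is spun about its placement axis to the
    orientation that keeps every incidental atom pair farthest from the
    detection cutoffs; the realised geometry is audited with the generator's
    independent rule set and rejected (``ValueError``) if the requested
    interaction class is not realised or the guard margin stays below
    *guard_band*.
    """
    ligand = make_amc_ligand()
    lig_by_name = {a.name: a for a in ligand.atoms}
    lig_coords = np.array([a.coords for a in ligand.atoms])
    lig_center = lig_coords.mean(axis=0)

    residues: list[Residue] = []
    truth_rows: list[tuple] = []
    labels: dict = {}
    directions: dict = {}
    serial = 100
    occupied: list[np.ndarray] = []  # placed residue atom coords, for collisions

    anchor_use: dict[str, int] = {}
    for i, pi in enumerate(spec.interactions):
        key = ("A", 10 + i, "")
        if pi.kind == "aromatic":
            # stack parallel to the (planar) ligand ring system
            count = anchor_use.get("ring", 0)
            anchor_use["ring"] = count + 1
            candidates = [np.array([0.0, 0.0, 1.0 if count % 2 == 0 else -1.0])]
            ring_names = _ligand_ring_name_sets()[0]
            anchor = np.mean([lig_by_name[n].coords for n in ring_names], axis=0)
            probe = "ring"
        else:
            anchor = lig_by_name[pi.ligand_atom].coords
            probe = pi.probe_atom
            radial = anchor - lig_center
            if np.linalg.norm(radial) < 1e-6:
                radial = np.array([1.0, 0.0, 0.0])
            radial = radial / np.linalg.norm(radial)
            # repeated anchors fan out above/below the ligand plane
            count = anchor_use.get(pi.ligand_atom, 0)
            anchor_use[pi.ligand_atom] = count + 1
            sign = 1.0 if count % 2 == 0 else -1.0
            twist = 0.25 * np.array([math.cos(2.4 * i), math.sin(2.4 * i), 0.0])
            candidates = []
            for tilt_z in (0.55 * sign, -0.55 * sign, 0.0, 1.2 * sign):
                d = radial + np.array([0.0, 0.0, tilt_z * (1.0 + 0.4 * (count // 2))]) + twist
                candidates.append(d / np.linalg.norm(d))

        best = None  # (margin, placed, bits)
        for direction in candidates:
            base_placed = _place_residue(pi.residue_name, probe, anchor,
                                         direction, pi.distance)
            axis_point = anchor + pi.distance * direction
            for theta in np.linspace(0.0, 2 * math.pi, 36, endpoint=False):
                rot = _spin_matrix(direction, float(theta))
                placed = {n: (e, rot @ (p - axis_point) + axis_point)
                          for n, (e, p) in base_placed.items()}
                if pi.angle is not None and pi.kind == "hbond_donor":
                    placed["H" + pi.probe_atom[-2:]] = (
                        "H", _solve_hbond_hydrogen(placed[pi.probe_atom][1],
                                                   anchor, pi.angle))
                bits, margin = _audit_bits(pi.residue_name, placed, ligand.atoms,
                                           criteria)
                want = "any" if pi.kind == "contact" else pi.kind
                if not bits[_BIT_INDEX[want]]:
                    continue
                if occupied:
                    clash = min(
                        float(np.linalg.norm(p - q))
                        for _, (e, p) in placed.items() for q in occupied
                    )
                    if clash < 2.5:
                        continue
                if best is None or margin > best[0]:
                    best = (margin, placed, bits, direction)
            if best is not None and best[0] >= guard_band:
                break
        if best is None or best[0] < guard_band:
            raise ValueError(
                f"unsatisfiable geometry for {pi.kind} plant on "
                f"{pi.residue_name}: no orientation clears the cutoffs"
            )
        margin, placed, bits, direction = best
        if probe != "ring":
            measured = np.linalg.norm(placed[pi.probe_atom][1] - anchor)
            if abs(measured - pi.distance) > 1e-6:
                raise ValueError("unsatisfiable geometry: placement failed")

        res = Residue(key, pi.residue_name.upper())
        for name, (el, xyz) in placed.items():
            serial += 1
            res.atoms.append(Atom(serial, name, el, xyz, key, "protein"))
        residues.append(res)
        occupied.extend(xyz for _, (e, xyz) in placed.items())
        directions[key] = direction
        truth_rows.append((key, bits))
        labels[key] = res.label

    filler_names = ["ALA", "GLY", "LEU", "SER", "MET", "ASN"]
    filler_dirs = _fibonacci_directions(max(spec.include_fillers, 1))
    for j in range(spec.include_fillers):
        direction = filler_dirs[j]
        key = ("A", 50 + j, "")
        resname = filler_names[j % len(filler_names)]
        placed = _place_residue(resname, "CA", lig_center, direction,
                                spec.pocket_radius)
        # push outward until clear of every ligand atom and every residue
        shift = 0.0
        while shift < 60.0:
            pts = [xyz + shift * direction for _, xyz in placed.values()]
            min_lig = min(np.linalg.norm(p - lig_coords, axis=1).min()
                          for p in pts)
            min_res = (min(np.linalg.norm(p - q) for p in pts for q in occupied)
                       if occupied else float("inf"))
            if min_lig >= spec.pocket_radius and min_res >= 3.0:
                break
            shift += 0.5
        res = Residue(key, resname)
        for name, (el, xyz) in placed.items():
            serial += 1
            res.atoms.append(Atom(serial, name, el, xyz + shift * direction,
                                  key, "protein"))
        residues.append(res)
        occupied.extend(a.coords for a in res.atoms)

    cx = Complex(model_id=1, protein_residues=residues, ligand=ligand)
    keys = [k for k, _ in truth_rows]
    bits = (np.array([b for _, b in truth_rows], dtype=bool)
            if truth_rows else np.zeros((0, N_BITS), dtype=bool))
    truth = InteractionBitMatrix(keys, bits, labels, complex_ref="planted")
    return PlantedComplex(write_pdb(cx), cx, truth, directions)


# ---------------------------------------------------------------------------
# zmCP1-mini catalytic site

_MINI_SITE = [
    # (number, residue) — canonical zmCP1 active-site names
    (143, "GLN"), (147, "GLY"), (148, "CYS"), (149, "CYS"),
    (189, "CYS"), (190, "ASP"), (191, "GLY"), (193, "LEU"), (194, "MET"),
    (259, "ALA"), (283, "LEU"), (285, "HIS"), (286, "ALA"), (306, "ASN"),
]


def make_catalytic_site_complex(catalytic_distance: float = 4.33,
                                oxyanion_distance: float = 2.9,
                                p1_in_s1: bool = True,
                                s1_contact_distance: float = 3.8,
                                pocket_radius: float = 9.0) -> Complex:
    """Toy zmCP1 active site around the AMC-like ligand.

    Cys149 SG is placed at *catalytic_distance* from the ligand's scissile
    carbonyl carbon; Gln143 NE2 at *oxyanion_distance* from the P1
    guanidinium NH1; Gly147 (an S1 residue) in contact with the P1 chain
    when *p1_in_s1*.  The remaining site residues sit at *pocket_radius*
    clearance.  Deterministic (no randomness).
    """
    ligand = make_amc_ligand()
    lig_by_name = {a.name: a for a in ligand.atoms}
    lig_coords = np.array([a.coords for a in ligand.atoms])
    dirs = _fibonacci_directions(len(_MINI_SITE))

    residues = []
    serial = 1000
    for i, (num, resname) in enumerate(_MINI_SITE):
        key = ("A", num, "")
        direction = dirs[i]
        if num == 149:
            # approach the scissile carbon from above the ligand plane so the
            # thiolate's only close contact is the catalytic one
            placed = _place_residue(resname, "SG", lig_by_name["C"].coords,
                                    np.array([0.0, 0.0, 1.0]),
                                    catalytic_distance)
        elif num == 143:
            placed = _place_residue(resname, "NE2", lig_by_name["NH1"].coords,
                                    direction, oxyanion_distance)
        elif num == 147 and p1_in_s1:
            placed = _place_residue(resname, "CA", lig_by_name["CD"].coords,
                                    direction, s1_contact_distance)
        else:
            placed = _place_residue(resname, "CA", np.zeros(3), direction,
                                    pocket_radius)
            shift = 0.0
            while True:
                min_d = min(
                    np.linalg.norm((xyz + shift * direction) - lig_coords,
                                   axis=1).min()
                    for _, xyz in placed.values()
                )
                if min_d >= pocket_radius - 3.0:
                    break
                shift += 0.5
            placed = {n: (e, xyz + shift * direction)
                      for n, (e, xyz) in placed.items()}
        res = Residue(key, resname)
        for name, (el, xyz) in placed.items():
            serial += 1
            res.atoms.append(Atom(serial, name, el, xyz, key, "protein"))
        residues.append(res)
    return Complex(model_id=1, protein_residues=residues, ligand=ligand)


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class EnsembleSpec:
    n_poses: int = 20
    occurrence_p: float = 1.0
    rmsd_targets: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")
        if not 0.0 <= self.occurrence_p <= 1.0:
            raise ValueError("occurrence probability must lie in [0, 1]")


@dataclass
class EnsembleResult:
    pdb_text: str
    ensemble: PoseEnsemble
    pose_truth: list[InteractionBitMatrix]  # per interaction pose
    rmsd_values: list[float]                # per displaced pose (appended last)


def make_pose_ensemble(planted: PlantedComplex, spec: EnsembleSpec,
                       displacement: float = 4.0) -> EnsembleResult:
    """Multi-MODEL ensemble from a planted complex.

    Each of the *n_poses* interaction poses keeps each planted interaction
    with probability *occurrence_p*; switched-off interactions have their
    residue displaced radially out of every cutoff.  One extra pose per
    ``rmsd_targets`` entry carries the ligand rigidly translated by exactly
    that distance (heavy-atom RMSD equals the target by construction).
    """
    rng = np.random.default_rng(spec.seed)
    base = planted.complex
    poses: list[Pose] = []
    pose_truth: list[InteractionBitMatrix] = []

    for _ in range(spec.n_poses):
        keep = {key: bool(rng.random() <= spec.occurrence_p)
                for key in planted.truth.residues}
        residues = []
        for res in base.protein_residues:
            if res.key in keep and not keep[res.key]:
                direction = planted.directions[res.key]
                moved = Residue(res.key, res.name, [
                    Atom(a.serial, a.name, a.element,
                         a.coords + displacement * direction, a.residue_key,
                         a.record, a.partial_charge, a.formal_charge)
                    for a in res.atoms
                ])
                residues.append(moved)
            else:
                residues.append(res)
        cx = Complex(model_id=len(poses) + 1, protein_residues=residues,
                     ligand=base.ligand)
        score = float(np.round(rng.uniform(-10.0, -5.0), 1))
        poses.append(Pose(cx, score))
        on_keys = [k for k in planted.truth.residues if keep[k]]
        on_bits = np.array(
            [planted.truth.bits[planted.truth.residues.index(k)] for k in on_keys]
            or np.zeros((0, N_BITS)), dtype=bool,
        ).reshape(len(on_keys), N_BITS)
        pose_truth.append(InteractionBitMatrix(on_keys, on_bits,
                                               planted.truth.labels,
                                               complex_ref=f"pose {len(poses)}"))

    rmsd_values = []
    for target in spec.rmsd_targets:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        moved_ligand = Ligand(base.ligand.name, [
            Atom(a.serial, a.name, a.element, a.coords + target * direction,
                 a.residue_key, a.record, a.partial_charge, a.formal_charge)
            for a in base.ligand.atoms
        ])
        cx = Complex(model_id=len(poses) + 1,
                     protein_residues=base.protein_residues, ligand=moved_ligand)
        poses.append(Pose(cx, None))
        rmsd_values.append(float(target))

    ensemble = PoseEnsemble(poses, source="synthetic")
    # construction check: translation by t gives heavy-atom RMSD exactly t
    from .triage import heavy_atom_rmsd

    for target, pose in zip(rmsd_values, poses[spec.n_poses:]):
        got = heavy_atom_rmsd(pose.complex, base).rmsd
        if abs(got - target) > 0.01:
            raise AssertionError("internal RMSD construction check failed")
    return EnsembleResult(write_pdb(ensemble), ensemble, pose_truth, rmsd_values)


# ---------------------------------------------------------------------------
# tables


def make_energy_series(means: dict[str, float], sigma: float, n: int,
                       seed: int = 0) -> str:
    """Delimited snapshot series: each of dE_ele/dE_vdW/dG_PB/dG_np drawn
    i.i.d. normal around its stated mean with standard deviation *sigma*."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    cols = ("dE_ele", "dE_vdW", "dG_PB", "dG_np")
    missing = set(cols) - set(means)
    if missing:
        raise ValueError(f"means missing components {sorted(missing)}")
    lines = ["\t".join(cols)]
    for _ in range(n):
        draws = [means[c] + (sigma * rng.standard_normal() if sigma else 0.0)
                 for c in cols]
        lines.append("\t".join(f"{v:.6f}" for v in draws))
    return "\n".join(lines) + "\n"


_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def make_score_table(best_label: str = "R-AMC", gap: float = 2.1,
                     n_entries: int = 20, seed: int = 0,
                     best_score: float = -10.4, suffix: str = "-AMC") -> str:
    """Delimited docking-score table with a planted winner.

    The best entry beats the second-best by exactly *gap* (both on the
    1-decimal grid of typical docking reports); every remaining score lies
    at or above the second-best.
    """
    if n_entries < 2:
        raise ValueError("n_entries must be >= 2")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    labels = [best_label]
    for letter in _AA_LETTERS:
        candidate = f"{letter}{suffix}"
        if candidate != best_label and len(labels) < n_entries:
            labels.append(candidate)
    extra = 1
    while len(labels) < n_entries:
        labels.append(f"X{extra}{suffix}")
        extra += 1
    second = round(best_score + gap, 1)
    scores = [best_score, second]
    for _ in range(n_entries - 2):
        scores.append(round(second + rng.integers(0, 31) / 10.0, 1))
    lines = ["ligand\tscore"]
    lines += [f"{l}\t{s:.1f}" for l, s in zip(labels, scores)]
    return "\n".join(lines) + "\n"
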