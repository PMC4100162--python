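"""Docking-pose validation and binding-mode selection.

Two concerns live here.  First, redocking validation: the heavy-atom RMSD of
a docked ligand against its reference placement (no superposition — docked
and reference poses share the receptor frame), optionally minimised over the
element-preserving automorphisms of the ligand bond graph so that chemically
equivalent atoms (e.g. the two carboxylate oxygens) cannot inflate the value.
A pose within 2.5 Å of the reference counts as a docking success; otherwise
the run is a scoring failure.

Second, binding-mode triage for protease substrates: from an ensemble of
poses, keep those whose P1 (and optionally P2) group occupies the S1 (S2)
subsite, whose scissile carbonyl carbon sits within nucleophilic-attack
distance of the catalytic sulfur, and whose P1 charged group hydrogen-bonds
an oxyanion-hole residue; the best-scoring pose passing all applicable rules
is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .fingerprint import GeometricCriteria, _bonded, _hbond_geometry_ok
from .structure import Atom, Complex, EnzymeAnnotation, PoseEnsemble

DOCKING_SUCCESS = "success"
SCORING_FAILURE = "scoring_failure"

#: subsite occupied by each substrate position label
POSITION_SUBSITE = {"P1": "S1", "P2": "S2", "P1'": "S1'", "P2'": "S2'"}


@dataclass
class RmsdResult:
    rmsd: float  # Å
    mapping: tuple[tuple[str, str], ...]  # (pose atom, reference atom) pairs
    n_atoms: int

    def __post_init__(self) -> None:
        if self.rmsd < 0 or self.n_atoms < 1:
            raise ValueError("invalid RMSD result")


@dataclass
class TriageRules:
    """Cutoffs for the three binding-mode rules (Å)."""

    occupancy_cutoff: float = 4.5       # P-group heavy atom near subsite residue
    catalytic_max: float = 4.5          # scissile C to nucleophile S ("about 4 Å")
    scissile_atom: str = "C"            # ligand atom name of the scissile carbonyl C
    criteria: GeometricCriteria = field(default_factory=GeometricCriteria)


@dataclass
class TriageVerdict:
    pose_index: int
    passed: bool
    rule_results: dict[str, tuple[bool, Optional[float]]]
    selected: bool = False

    def __post_init__(self) -> None:
        if self.selected and not self.passed:
            raise ValueError("a pose cannot be selected without passing")


def _rmsd_for_pairs(pose_coords: np.ndarray, ref_coords: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((pose_coords - ref_coords) ** 2, axis=1))))


def _automorphisms(atoms: Sequence[Atom], max_mappings: int = 10000):
    """Element-preserving automorphisms of the ligand bond graph."""
    g = _bonded(atoms)
    for i, a in enumerate(atoms):
        g.nodes[i]["element"] = a.element.upper()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda n1, n2: n1["element"] == n2["element"]
    )
    for n, mapping in enumerate(matcher.isomorphisms_iter()):
        if n >= max_mappings:
            break
        yield mapping


def heavy_atom_rmsd(pose: Complex, reference: Complex,
                    symmetry: bool = False) -> RmsdResult:
    """Heavy-atom RMSD of the pose ligand against the reference ligand.

    Atoms correspond by name; with ``symmetry=True`` the minimum over
    element-preserving bond-graph automorphisms is returned instead, which
    never exceeds the name-matched value.
    """
    pose_atoms = pose.ligand.heavy_atoms()
    ref_atoms = reference.ligand.heavy_atoms()
    pose_names = {a.name for a in pose_atoms}
    ref_names = {a.name for a in ref_atoms}
    if pose_names != ref_names or len(pose_atoms) != len(ref_atoms):
        raise ValueError(
            "ligand atom inventory mismatch: only in pose "
            f"{sorted(pose_names - ref_names)}, only in reference "
            f"{sorted(ref_names - pose_names)}"
        )
    ref_by_name = {a.name: a for a in ref_atoms}
    ordered_ref = [ref_by_name[a.name] for a in pose_atoms]
    pose_coords = np.array([a.coords for a in pose_atoms])
    ref_coords = np.array([a.coords for a in ordered_ref])

    best = _rmsd_for_pairs(pose_coords, ref_coords)
    best_mapping = tuple((a.name, a.name) for a in pose_atoms)
    if symmetry:
        name_order = {a.name: j for j, a in enumerate(ref_atoms)}
        for mapping in _automorphisms(ref_atoms):
            # mapping permutes reference atoms; align to pose order by name
            permuted = np.array([
                ref_atoms[mapping[name_order[a.name]]].coords for a in pose_atoms
            ])
            value = _rmsd_for_pairs(pose_coords, permuted)
            if value < best:
                best = value
                best_mapping = tuple(
                    (a.name, ref_atoms[mapping[name_order[a.name]]].name)
                    for a in pose_atoms
                )
    return RmsdResult(best, best_mapping, len(pose_atoms))


def classify_docking(rmsd: float, threshold: float = 2.5) -> str:
    """Docking-success rule: success iff rmsd ≤ threshold (inclusive)."""
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    return DOCKING_SUCCESS if rmsd <= threshold else SCORING_FAILURE


def _min_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    return float(np.min(np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)))


def _subsite_occupancy(cx: Complex, annotation: EnzymeAnnotation, subsite: str,
                       group_atoms: Sequence[Atom], cutoff: float) -> tuple[bool, float]:
    residue_atoms = []
    for key in annotation.subsites.get(subsite, ()):
        try:
            residue_atoms.extend(cx.residue(key).heavy_atoms())
        except KeyError:
            continue
    if not residue_atoms or not group_atoms:
        return False, float("inf")
    d = _min_distance(np.array([a.coords for a in group_atoms]),
                      np.array([a.coords for a in residue_atoms]))
    return d <= cutoff, d


def _catalytic_distance(cx: Complex, annotation: EnzymeAnnotation,
                        scissile_atom: str, maximum: float) -> tuple[bool, float]:
    key, atom_name = annotation.nucleophile_atom
    try:
        nucleophile = cx.residue(key).atom(atom_name)
        scissile = cx.ligand.atom(scissile_atom)
    except KeyError:
        return False, float("inf")
    d = float(np.linalg.norm(nucleophile.coords - scissile.coords))
    return d <= maximum, d


def _oxyanion_hbond(cx: Complex, annotation: EnzymeAnnotation,
                    p1_atoms: Sequence[Atom], criteria: GeometricCriteria
                    ) -> tuple[bool, float]:
    """≥1 hydrogen bond between the P1 charged group (N/O atoms, treated as
    donors and acceptors) and an oxyanion-hole residue."""
    from .fingerprint import _residue_acceptors, _residue_donors

    best = float("inf")
    ok = False
    polar_p1 = [a for a in p1_atoms if a.element.upper() in ("N", "O")]
    for key in annotation.oxyanion_hole:
        try:
            res = cx.residue(key)
        except KeyError:
            continue
        partners = _residue_donors(res) + _residue_acceptors(res)
        for res_atom in partners:
            for lig_atom in polar_p1:
                d = float(np.linalg.norm(res_atom.coords - lig_atom.coords))
                best = min(best, d)
                if _hbond_geometry_ok(lig_atom, res_atom, cx.ligand.atoms, criteria) or \
                   _hbond_geometry_ok(res_atom, lig_atom, res.atoms, criteria):
                    ok = True
    return ok, best


def select_binding_mode(ensemble: PoseEnsemble, annotation: EnzymeAnnotation,
                        p_groups: Mapping[str, Sequence[str]],
                        rules: TriageRules = TriageRules()
                        ) -> tuple[list[TriageVerdict], Optional[int]]:
    """Evaluate the binding-mode rules on every pose and select one.

    Rules per pose: (R1) every declared P-group has ≥1 heavy atom within the
    occupancy cutoff of its subsite; (R2) the scissile carbonyl carbon is
    within ``catalytic_max`` of the nucleophile sulfur; (R3) the P1 group
    hydrogen-bonds an oxyanion-hole residue.  The selected pose is the
    best-scoring (lowest score) pose passing all rules, ties broken by pose
    index; ``None`` when no pose passes.

    Returns (verdicts, selected pose index or None).
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    if "P1" not in p_groups:
        raise ValueError("p_groups must define at least P1")

    verdicts: list[TriageVerdict] = []
    for i, pose in enumerate(ensemble):
        cx = pose.complex
        lig_names = {a.name for a in cx.ligand.atoms}
        results: dict[str, tuple[bool, Optional[float]]] = {}
        for position, atom_names in p_groups.items():
            missing = set(atom_names) - lig_names
            if missing:
                raise ValueError(
                    f"{position} atoms absent from ligand: {sorted(missing)}"
                )
            subsite = POSITION_SUBSITE.get(position, position)
            group = [cx.ligand.atom(n) for n in atom_names
                     if not cx.ligand.atom(n).is_hydrogen]
            ok, d = _subsite_occupancy(cx, annotation, subsite, group,
                                       rules.occupancy_cutoff)
            results[f"{position}_in_{subsite}"] = (ok, d)
        ok, d = _catalytic_distance(cx, annotation, rules.scissile_atom,
                                    rules.catalytic_max)
        results["catalytic_distance"] = (ok, d)
        p1_atoms = [cx.ligand.atom(n) for n in p_groups["P1"]]
        ok, d = _oxyanion_hbond(cx, annotation, p1_atoms, rules.criteria)
        results["oxyanion_hbond"] = (ok, d)
        verdicts.append(TriageVerdict(i, all(r[0] for r in results.values()), results))

    passing = [v for v in verdicts if v.passed]
    if not passing:
        return verdicts, None
    scored = [(ensemble[v.pose_index].score, v.pose_index) for v in passing]
    if all(s is None for s, _ in scored):
        selected = min(i for _, i in scored)
    else:
        selected = min(((s if s is not None else float("inf")), i)
                       for s, i in scored)[1]
    verdicts[selected].selected = True
    return verdicts, selected


def verdict_table(verdicts: Sequence[TriageVerdict]) -> str:
    """Delimited triage report: one row per pose, one column per rule."""
    if not verdicts:
        return ""
    rule_names = list(verdicts[0].rule_results)
    header = ["pose", "passed", "selected"]
    for r in rule_names:
        header += [r, f"{r}_dist"]
    lines = ["\t".join(header)]
    for v in verdicts:
        row = [str(v.pose_index), str(v.passed).lower(), str(v.selected).lower()]
        for r in rule_names:
            ok, d = v.rule_results[r]
            row += [str(ok).lower(), "inf" if d is None or np.isinf(d) else f"{d:.2f}"]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
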