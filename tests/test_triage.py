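"""Heavy-atom RMSD validation and binding-mode selection rules."""

import itertools

import numpy as np
import pytest

import siftkit as sk
from siftkit import synthetic as syn
from siftkit.structure import Atom, Complex, Ligand, Pose, PoseEnsemble
from siftkit.triage import (
    DOCKING_SUCCESS,
    SCORING_FAILURE,
    TriageRules,
    classify_docking,
    heavy_atom_rmsd,
    select_binding_mode,
)


def _ligand_complex(coords, names=None, elements=None):
    n = len(coords)
    names = names or [f"A{i}" for i in range(n)]
    elements = elements or ["C"] * n
    lig = Ligand("LIG", [Atom(i + 1, nm, el, c, ("L", 1, ""), "ligand")
                         for i, (nm, el, c) in enumerate(zip(names, elements,
                                                             coords))])
    return Complex(1, [], lig)


SQUARE = [[0.0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0, 1.5, 0]]


def test_rmsd_identity_and_rigid_translation():
    a = _ligand_complex(SQUARE)
    assert heavy_atom_rmsd(a, a).rmsd == 0.0
    b = _ligand_complex([[x + 3, y, z] for x, y, z in SQUARE])
    r = heavy_atom_rmsd(a, b)
    assert r.rmsd == pytest.approx(3.0)
    assert r.n_atoms == 4


def test_rmsd_symmetry_of_arguments():
    rng = np.random.default_rng(0)
    a = _ligand_complex(rng.normal(size=(5, 3)) * 3)
    b = _ligand_complex(rng.normal(size=(5, 3)) * 3)
    assert heavy_atom_rmsd(a, b).rmsd == pytest.approx(heavy_atom_rmsd(b, a).rmsd)


def test_rmsd_inventory_mismatch_names_offenders():
    a = _ligand_complex(SQUARE, names=["A0", "A1", "A2", "A3"])
    b = _ligand_complex(SQUARE, names=["A0", "A1", "A2", "B9"])
    with pytest.raises(ValueError, match="B9"):
        heavy_atom_rmsd(a, b)


def test_symmetry_correction_equals_brute_force_on_small_ligands():
    """Automorphism-corrected RMSD equals the minimum over all
    element-preserving atom permutations that preserve the bond graph
    (brute-forced for ≤8 atoms)."""
    from siftkit.fingerprint import _bonded

    rng = np.random.default_rng(7)
    # benzene-like ring: 6-fold symmetric bond graph
    ring = [[1.4 * np.cos(t), 1.4 * np.sin(t), 0.0]
            for t in np.linspace(0, 2 * np.pi, 7)[:-1]]
    ref = _ligand_complex(ring, names=[f"C{i}" for i in range(6)])
    # pose: ring rotated one step (atom labels shifted) plus noise
    shift = ring[1:] + ring[:1]
    noisy = [np.array(c) + rng.normal(scale=0.05, size=3) for c in shift]
    pose = _ligand_complex(noisy, names=[f"C{i}" for i in range(6)])

    corrected = heavy_atom_rmsd(pose, ref, symmetry=True).rmsd
    plain = heavy_atom_rmsd(pose, ref, symmetry=False).rmsd

    ref_atoms = ref.ligand.heavy_atoms()
    pose_coords = np.array([a.coords for a in pose.ligand.heavy_atoms()])
    g = _bonded(ref_atoms)
    edges = {frozenset(e) for e in g.edges()}
    best = np.inf
    for perm in itertools.permutations(range(6)):
        if {frozenset((perm[i], perm[j])) for i, j in edges} != edges:
            continue
        permuted = np.array([ref_atoms[perm[i]].coords for i in range(6)])
        best = min(best, float(np.sqrt(np.mean(
            np.sum((pose_coords - permuted) ** 2, axis=1)))))
    assert corrected == pytest.approx(best, abs=1e-9)
    assert corrected <= plain + 1e-12
    assert corrected < 0.2 < plain  # relabelling alone looked like ~1.4 Å


def test_symmetry_corrected_never_exceeds_name_matched(planted_trio):
    rng = np.random.default_rng(3)
    base = planted_trio.complex
    jitter = Ligand(base.ligand.name, [
        Atom(a.serial, a.name, a.element,
             a.coords + rng.normal(scale=0.3, size=3), a.residue_key,
             a.record, a.partial_charge, a.formal_charge)
        for a in base.ligand.atoms
    ])
    pose = Complex(1, [], jitter)
    ref = Complex(1, [], base.ligand)
    on = heavy_atom_rmsd(pose, ref, symmetry=True).rmsd
    off = heavy_atom_rmsd(pose, ref, symmetry=False).rmsd
    assert on <= off + 1e-12


@pytest.mark.parametrize("rmsd,expected", [
    (2.41, DOCKING_SUCCESS),   # redocking validation verdict
    (2.5, DOCKING_SUCCESS),    # inclusive boundary
    (0.0, DOCKING_SUCCESS),
    (2.51, SCORING_FAILURE),
    (7.0, SCORING_FAILURE),
])
def test_docking_success_rule(rmsd, expected):
    assert classify_docking(rmsd) == expected


def test_docking_rule_rejects_negative_rmsd():
    with pytest.raises(ValueError):
        classify_docking(-0.1)


def _pose_with(catalytic_distance, oxyanion_distance=2.9, p1_in_s1=True):
    return syn.make_catalytic_site_complex(
        catalytic_distance=catalytic_distance,
        oxyanion_distance=oxyanion_distance, p1_in_s1=p1_in_s1)


def test_select_binding_mode_picks_the_only_passing_pose():
    """The passing pose wins regardless of score rank."""
    good = _pose_with(4.0)
    bad_far = _pose_with(8.0)          # fails the catalytic-distance rule
    bad_no_hb = _pose_with(4.0, oxyanion_distance=6.0)  # fails oxyanion H-bond
    ensemble = PoseEnsemble([Pose(bad_far, -12.0), Pose(good, -6.0),
                             Pose(bad_no_hb, -11.0)])
    ann = sk.load_default_annotation()
    verdicts, selected = select_binding_mode(ensemble, ann,
                                             {"P1": list(syn.P1_GROUP)})
    assert selected == 1
    assert [v.passed for v in verdicts] == [False, True, False]
    assert verdicts[1].selected
    assert not verdicts[0].rule_results["catalytic_distance"][0]
    assert not verdicts[2].rule_results["oxyanion_hbond"][0]


def test_no_pose_within_catalytic_distance_selects_none():
    ensemble = PoseEnsemble([Pose(_pose_with(8.0), -9.0),
                             Pose(_pose_with(7.0), -8.0)])
    ann = sk.load_default_annotation()
    verdicts, selected = select_binding_mode(ensemble, ann,
                                             {"P1": list(syn.P1_GROUP)})
    assert selected is None
    assert len(verdicts) == 2
    assert not any(v.selected for v in verdicts)


def test_reported_catalytic_geometry_passes():
    """A pose with the scissile carbon 4.33 Å from the catalytic sulfur and
    a 2.08 Å oxyanion contact passes the distance and H-bond rules."""
    cx = _pose_with(4.33, oxyanion_distance=2.9)
    ensemble = PoseEnsemble([Pose(cx, -10.4)])
    ann = sk.load_default_annotation()
    verdicts, selected = select_binding_mode(ensemble, ann,
                                             {"P1": list(syn.P1_GROUP)})
    ok, measured = verdicts[0].rule_results["catalytic_distance"]
    assert ok and measured == pytest.approx(4.33, abs=0.01)
    assert verdicts[0].rule_results["oxyanion_hbond"][0]
    assert selected == 0


def test_missing_p1_atoms_error(catalytic_complex):
    ensemble = PoseEnsemble([Pose(catalytic_complex, -9.0)])
    ann = sk.load_default_annotation()
    with pytest.raises(ValueError, match="absent from ligand"):
        select_binding_mode(ensemble, ann, {"P1": ["QQ1"]})


def test_score_tie_breaks_by_pose_index():
    good = _pose_with(4.0)
    ensemble = PoseEnsemble([Pose(good, -9.0), Pose(good, -9.0)])
    ann = sk.load_default_annotation()
    _, selected = select_binding_mode(ensemble, ann, {"P1": list(syn.P1_GROUP)})
    assert selected == 0
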