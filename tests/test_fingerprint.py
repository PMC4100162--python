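"""Interaction-bit detection, ensemble averaging and consensus extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import siftkit as sk
from siftkit import synthetic as syn
from siftkit.fingerprint import (
    BIT_NAMES,
    FingerprintModel,
    FingerprintProfile,
    GeometricCriteria,
    average_fingerprint,
    consensus_residues,
    detect_interactions,
    profile_report,
)
from siftkit.structure import Atom, Complex, Ligand, Residue
from tests.conftest import ALL_KINDS


def test_criteria_validation():
    with pytest.raises(ValueError):
        GeometricCriteria(contact_cutoff=-1)
    with pytest.raises(ValueError):
        GeometricCriteria(hbond_heavy_cutoff=5.0, contact_cutoff=4.5)


def test_distant_ligand_gives_empty_matrix(planted_trio):
    base = planted_trio.complex
    far_ligand = Ligand(base.ligand.name, [
        Atom(a.serial, a.name, a.element, a.coords + np.array([50.0, 0, 0]),
             a.residue_key, a.record, a.partial_charge, a.formal_charge)
        for a in base.ligand.atoms
    ])
    cx = Complex(1, base.protein_residues, far_ligand)
    m = detect_interactions(cx)
    assert len(m.residues) == 0


def test_empty_ligand_is_an_error(planted_trio):
    cx = Complex(1, planted_trio.complex.protein_residues, Ligand("AMC", []))
    with pytest.raises(ValueError, match="heavy atoms"):
        detect_interactions(cx)


def test_detector_recovers_exactly_the_planted_bits(planted_all):
    """Precision and recall 1.0 on off-boundary planted geometries, for
    every interaction class at once."""
    m = detect_interactions(planted_all.complex)
    truth = planted_all.truth
    assert set(m.residues) == set(truth.residues)
    for key in truth.residues:
        got = m.bits[m.residues.index(key)]
        want = truth.bits[truth.residues.index(key)]
        assert np.array_equal(got, want), (key, dict(zip(BIT_NAMES, got)),
                                           dict(zip(BIT_NAMES, want)))


def test_planted_hbond_geometry_sets_donor_polar_any():
    planted = syn.make_planted_complex(syn.PlantSpec(interactions=[
        syn.planted_interaction("hbond_donor", distance=2.9, angle=165.0)]))
    m = detect_interactions(planted.complex)
    key = planted.truth.residues[0]
    assert m.bit(key, "hbond_donor") and m.bit(key, "polar") and m.bit(key, "any")
    assert not m.bit(key, "backbone")


def test_planted_salt_bridge_sets_charged_polar_sidechain():
    planted = syn.make_planted_complex(syn.PlantSpec(interactions=[
        syn.planted_interaction("charged", distance=3.2)]))
    m = detect_interactions(planted.complex)
    key = planted.truth.residues[0]
    for bit in ("charged", "polar", "sidechain", "any"):
        assert m.bit(key, bit)


def test_glycine_contact_is_backbone_only():
    planted = syn.make_planted_complex(syn.PlantSpec(interactions=[
        syn.planted_interaction("backbone")]))
    m = detect_interactions(planted.complex)
    key = planted.truth.residues[0]
    assert m.bit(key, "backbone")
    assert not m.bit(key, "sidechain")


def test_hbond_angle_rejects_bent_geometry():
    """With an explicit hydrogen, a 90° donor–H…acceptor angle fails the
    120° criterion even at favourable heavy-atom distance."""
    with pytest.raises(ValueError, match="unsatisfiable"):
        # the generator itself refuses: no orientation yields the donor bit
        syn.make_planted_complex(syn.PlantSpec(interactions=[
            syn.planted_interaction("hbond_donor", distance=2.9, angle=80.0)]))


def test_average_fingerprint_counts(planted_trio):
    m = detect_interactions(planted_trio.complex)
    one = average_fingerprint([m])
    assert np.array_equal(one.frequencies, m.bits.astype(float))
    empty = sk.InteractionBitMatrix([], np.zeros((0, 9), dtype=bool))
    half = average_fingerprint([m, empty])
    assert np.allclose(half.frequencies[half.residues.index(m.residues[0])],
                       0.5 * m.bits[0])
    with pytest.raises(ValueError):
        average_fingerprint([])


def test_average_matches_22_of_31_granularity(planted_trio):
    m = detect_interactions(planted_trio.complex)
    empty = sk.InteractionBitMatrix([], np.zeros((0, 9), dtype=bool))
    mats = [m] * 22 + [empty] * 9
    prof = average_fingerprint(mats)
    i = prof.residues.index(m.residues[0])
    assert prof.frequencies[i, 0] == pytest.approx(22 / 31)
    assert round(prof.frequencies[i, 0], 2) == 0.71


def test_profile_invariants_reject_bad_frequencies():
    with pytest.raises(ValueError):
        FingerprintProfile(["Q143"], np.full((1, 9), 1.5))
    with pytest.raises(ValueError):
        FingerprintProfile(["Q143"], np.full((1, 9), 0.37), n_complexes=10)


def test_recovery_of_planted_occurrence_frequency(planted_trio):
    """Observed frequency within 4·sqrt(p(1-p)/n) of the planted p."""
    p, n = 0.5, 200
    result = syn.make_pose_ensemble(planted_trio,
                                    syn.EnsembleSpec(n_poses=n, occurrence_p=p,
                                                     seed=11))
    fit = FingerprintModel(result.ensemble).fit()
    tol = 4 * np.sqrt(p * (1 - p) / n)
    for key in planted_trio.truth.residues:
        freq = fit.profile.frequency(key, "any")
        assert abs(freq - p) <= tol


def test_pose_truth_matches_detector_per_pose(planted_trio):
    result = syn.make_pose_ensemble(planted_trio,
                                    syn.EnsembleSpec(n_poses=30, occurrence_p=0.6,
                                                     seed=4))
    for pose, truth in zip(result.ensemble, result.pose_truth):
        m = detect_interactions(pose.complex)
        assert set(m.residues) == set(truth.residues)
        for key in truth.residues:
            assert np.array_equal(m.bits[m.residues.index(key)],
                                  truth.bits[truth.residues.index(key)])


def test_any_bit_dominates_all_specific_bits(planted_all):
    result = syn.make_pose_ensemble(planted_all,
                                    syn.EnsembleSpec(n_poses=40, occurrence_p=0.5,
                                                     seed=9))
    fit = FingerprintModel(result.ensemble).fit()
    any_col = fit.frequencies[:, 0]
    assert np.all(any_col[:, None] >= fit.frequencies[:, 1:] - 1e-12)


def test_averaging_linearity(planted_trio):
    mats = [detect_interactions(c) for c in syn.make_pose_ensemble(
        planted_trio, syn.EnsembleSpec(n_poses=12, occurrence_p=0.5, seed=2)
    ).ensemble.complexes()]
    a, b = mats[:5], mats[5:]
    full = average_fingerprint(mats)
    pa, pb = average_fingerprint(a), average_fingerprint(b)
    for i, key in enumerate(full.residues):
        fa = (pa.frequencies[pa.residues.index(key)]
              if key in pa.residues else np.zeros(9))
        fb = (pb.frequencies[pb.residues.index(key)]
              if key in pb.residues else np.zeros(9))
        expected = (len(a) * fa + len(b) * fb) / len(mats)
        assert np.allclose(full.frequencies[i], expected)


def test_consensus_on_reference_table_at_half_cutoff():
    profile = sk.load_reference_fingerprint()
    labels = consensus_residues(profile, 0.5)
    assert labels == ["Q143", "W308", "H285", "M194", "L283", "G144", "R268",
                      "A286", "L193", "G147", "S311", "C189", "D190", "G191",
                      "A286", "C149"]
    for excluded in ("N284", "D142", "Y270", "W150", "G262", "D271"):
        assert excluded not in labels


def test_consensus_full_and_vacuous_cutoffs():
    profile = sk.load_reference_fingerprint()
    assert consensus_residues(profile, 1.0) == ["Q143", "W308"]
    low = FingerprintProfile(["A1", "B2"], np.full((2, 9), 0.6))
    assert consensus_residues(low, 0.9) == []


@given(st.floats(min_value=0.05, max_value=0.95))
@settings(deadline=None, max_examples=20)
def test_consensus_monotone_in_cutoff(cutoff):
    profile = sk.load_reference_fingerprint()
    lower = set(consensus_residues(profile, cutoff))
    higher = set(consensus_residues(profile, min(cutoff + 0.05, 1.0)))
    assert higher <= lower


def test_consensus_rejects_unknown_bit():
    profile = sk.load_reference_fingerprint()
    with pytest.raises(ValueError, match="unknown bit"):
        consensus_residues(profile, 0.5, bit="halogen")


def test_profile_report_round_trips_to_two_decimals(planted_trio):
    result = syn.make_pose_ensemble(planted_trio,
                                    syn.EnsembleSpec(n_poses=17, occurrence_p=0.7,
                                                     seed=6))
    fit = FingerprintModel(result.ensemble).fit()
    text = profile_report(fit.profile)
    header = text.splitlines()[0].split("\t")
    assert header == ["residue"] + list(BIT_NAMES)
    reread = FingerprintProfile.from_table(text)
    original = fit.profile.as_frame().round(2).sort_values("any", ascending=False,
                                                           kind="stable")
    assert np.allclose(reread.frequencies, original.to_numpy(), atol=5e-3)


def test_model_results_surface(planted_trio):
    fit = FingerprintModel(
        syn.make_pose_ensemble(planted_trio,
                               syn.EnsembleSpec(n_poses=10, occurrence_p=1.0,
                                                seed=0)).ensemble).fit()
    assert fit.n_complexes == 10
    assert fit.standard_errors.shape == fit.frequencies.shape
    assert np.all(fit.standard_errors == 0)  # p = 1 everywhere it matters
    summary = fit.summary()
    assert "complexes: 10" in summary
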