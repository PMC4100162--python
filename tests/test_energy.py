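"""MM-PBSA bookkeeping, decomposition arithmetic and component evaluators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from siftkit.energy import (
    COULOMB_CONSTANT,
    LJ_PARAMS,
    BindingEnergyModel,
    EnergyComponents,
    ForceFieldParams,
    SnapshotSeries,
    average_binding,
    binding_free_energy,
    born_polar_solvation,
    coulomb_energy,
    decompose,
    evaluate_components,
    lennard_jones_energy,
    shrake_rupley_sasa,
    species_free_energy,
)
from siftkit.structure import Atom, Complex, Ligand, Residue
from siftkit.synthetic import make_energy_series

R_COLUMN = dict(dE_ele=-172.62, dE_vdW=-33.5, dG_PB=170.65, dG_np=-5.44)
D_COLUMN = dict(dE_ele=-106.88, dE_vdW=-31.4, dG_PB=129.89, dG_np=-5.46)


def test_species_free_energy_arithmetic():
    assert species_free_energy(EnergyComponents()) == 0.0
    c = EnergyComponents(E_int=1, E_vdW=2, E_ele=3, G_PB=4, G_np=5, TS=0)
    assert species_free_energy(c) == 15.0
    c = EnergyComponents(E_int=1, E_vdW=2, E_ele=3, G_PB=4, G_np=5, TS=10)
    assert species_free_energy(c) == 5.0


def test_binding_free_energy_non_interacting_limit():
    assert binding_free_energy(10.0, 7.0, 3.0) == 0.0
    assert binding_free_energy(-50.0, -5.0, -4.0) == pytest.approx(-41.0)


@pytest.mark.parametrize("column,nonpolar,polar,dg", [
    (R_COLUMN, -38.94, -1.97, -40.91),
    (D_COLUMN, -36.86, 23.01, -13.85),
])
def test_decomposition_reproduces_reference_columns(column, nonpolar, polar, dg):
    d = decompose(**column)
    assert round(d.nonpolar, 2) == nonpolar
    assert round(d.polar, 2) == polar
    assert round(d.dG_bind, 2) == dg
    # exact additivity before rounding
    assert d.dG_bind == pytest.approx(d.nonpolar + d.polar, abs=1e-9)
    assert d.dG_bind == pytest.approx(
        column["dE_ele"] + column["dE_vdW"] + column["dG_PB"] + column["dG_np"],
        abs=1e-9)


@given(st.lists(st.floats(min_value=-200, max_value=200), min_size=4, max_size=4))
@settings(deadline=None, max_examples=50)
def test_decomposition_additivity_property(vals):
    d = decompose(*vals)
    assert d.dG_bind == pytest.approx(d.nonpolar + d.polar, abs=1e-9)
    assert d.nonpolar == pytest.approx(d.dE_vdW + d.dG_np, abs=1e-9)
    assert d.polar == pytest.approx(d.dE_ele + d.dG_PB, abs=1e-9)


def test_average_binding_constant_series():
    text = make_energy_series(R_COLUMN, sigma=0.0, n=5, seed=0)
    fit = average_binding(SnapshotSeries.from_table(text))
    assert fit.dG_bind == pytest.approx(-40.91, abs=1e-9)
    assert fit.dG_bind_se == 0.0


def test_average_binding_recovers_noisy_mean():
    """Seeded Gaussian series around the reference mean recovers it within
    4σ/√n."""
    sigma, n = 2.0, 1000
    text = make_energy_series(R_COLUMN, sigma=sigma, n=n, seed=21)
    fit = BindingEnergyModel(SnapshotSeries.from_table(text)).fit()
    # four components each with sd sigma -> dG sd = 2*sigma
    assert abs(fit.dG_bind - (-40.91)) <= 4 * 2 * sigma / math.sqrt(n)


def test_average_invariant_to_snapshot_order():
    text = make_energy_series(R_COLUMN, sigma=3.0, n=50, seed=5)
    series = SnapshotSeries.from_table(text)
    shuffled = SnapshotSeries(series.deltas.sample(frac=1.0, random_state=1))
    assert (BindingEnergyModel(series).fit().dG_bind
            == pytest.approx(BindingEnergyModel(shuffled).fit().dG_bind))


def test_empty_series_rejected():
    import pandas as pd

    with pytest.raises(ValueError):
        SnapshotSeries(pd.DataFrame(columns=["dE_ele", "dE_vdW", "dG_PB",
                                             "dG_np"]))


def test_entropy_term_shifts_binding_energy_exactly():
    base = EnergyComponents(E_vdW=-30, E_ele=-100, G_PB=90, G_np=-5)
    with_ts = EnergyComponents(E_vdW=-30, E_ele=-100, G_PB=90, G_np=-5, TS=12.0)
    # enabling TS on the complex shifts dG_bind by exactly -ΔTS
    g0 = binding_free_energy(species_free_energy(base), 0.0, 0.0)
    g1 = binding_free_energy(species_free_energy(with_ts), 0.0, 0.0)
    assert g1 - g0 == pytest.approx(-12.0)


def _atom(name, element, coords, q=None):
    return Atom(1, name, element, coords, ("L", 1, ""), "ligand",
                partial_charge=q)


def test_coulomb_constant_oracle():
    atoms = [_atom("Q1", "C", [0, 0, 0], 1.0), _atom("Q2", "C", [1, 0, 0], 1.0)]
    assert coulomb_energy(atoms) == pytest.approx(COULOMB_CONSTANT)
    # distance-dependent dielectric halves it at r=2 relative to 1/r^2 scaling
    p = ForceFieldParams(distance_dependent=True)
    atoms[1].coords = np.array([2.0, 0, 0])
    assert coulomb_energy(atoms, p) == pytest.approx(COULOMB_CONSTANT / 4)


def test_missing_charges_strict_error():
    atoms = [_atom("Q1", "C", [0, 0, 0], 1.0), _atom("Q2", "C", [1, 0, 0])]
    with pytest.raises(ValueError, match="Q2"):
        coulomb_energy(atoms)
    assert coulomb_energy(atoms, ForceFieldParams(strict=False)) == 0.0


def test_lennard_jones_closed_form():
    sigma, eps = LJ_PARAMS["C"]
    p = ForceFieldParams(strict=False)
    pair = [_atom("C1", "C", [0, 0, 0]), _atom("C2", "C", [sigma, 0, 0])]
    assert lennard_jones_energy(pair, p) == pytest.approx(0.0, abs=1e-12)
    pair[1].coords = np.array([2 ** (1 / 6) * sigma, 0, 0])
    assert lennard_jones_energy(pair, p) == pytest.approx(-eps)


def test_sasa_isolated_sphere_closed_form():
    atom = _atom("O1", "O", [0, 0, 0])
    area = shrake_rupley_sasa([atom])
    exact = 4 * math.pi * (1.52 + 1.4) ** 2
    assert area == pytest.approx(exact, rel=0.02)


def test_sasa_buried_atom_is_zero():
    # an atom fully enclosed by a shell of large atoms has no accessible area
    center = _atom("C0", "C", [0, 0, 0])
    shell = [_atom(f"S{i}", "S", 2.0 * v, None) for i, v in enumerate(
        np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
                  [0, 0, -1], [0.58, 0.58, 0.58], [-0.58, 0.58, 0.58],
                  [0.58, -0.58, 0.58], [0.58, 0.58, -0.58],
                  [-0.58, -0.58, 0.58], [-0.58, 0.58, -0.58],
                  [0.58, -0.58, -0.58], [-0.58, -0.58, -0.58]]))]
    total = shrake_rupley_sasa([center] + shell)
    alone = shrake_rupley_sasa([center])
    assert total < sum(shrake_rupley_sasa([s]) for s in shell)
    assert alone > 0


def test_born_self_energy_closed_form():
    """A single unit charge reduces the screening model to the Born ion
    formula with the element's effective radius."""
    atom = _atom("O1", "O", [0, 0, 0], -1.0)
    exact = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5) / 1.50
    assert born_polar_solvation([atom]) == pytest.approx(exact)


def _two_body_complex(separation):
    key = ("A", 1, "")
    res = Residue(key, "ALA", [
        Atom(1, "CB", "C", [0.0, 0.0, 0.0], key, "protein", partial_charge=0.3),
    ])
    lig = Ligand("LIG", [
        Atom(2, "C1", "C", [separation, 0.0, 0.0], ("L", 1, ""), "ligand",
             partial_charge=-0.3),
    ])
    return Complex(1, [res], lig)


def test_evaluate_components_non_interacting_limit():
    """With the ligand beyond the pairwise cutoff + 10 Å the gas-phase
    deltas vanish and dG_bind reduces to the solvation terms."""
    params = ForceFieldParams(cutoff=12.0)
    near = evaluate_components(_two_body_complex(3.5), params)
    far = evaluate_components(_two_body_complex(25.0), params)
    for triple, interacting in ((near, True), (far, False)):
        cx, prot, lig = triple
        d_ele = cx.E_ele - prot.E_ele - lig.E_ele
        d_vdw = cx.E_vdW - prot.E_vdW - lig.E_vdW
        if interacting:
            assert abs(d_ele) > 1.0
        else:
            assert d_ele == pytest.approx(0.0, abs=1e-3)
            assert d_vdw == pytest.approx(0.0, abs=1e-6)
        assert cx.E_int == prot.E_int == lig.E_int == 0.0


def test_evaluate_components_sasa_burial_is_negative_np_delta():
    cx, prot, lig = evaluate_components(_two_body_complex(3.5))
    d_np = cx.G_np - prot.G_np - lig.G_np
    assert d_np < 0  # burial removes surface, and removes one beta offset
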