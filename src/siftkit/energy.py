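"""MM-PBSA end-state binding free-energy bookkeeping.

The binding free energy of a protein–ligand complex is estimated from
trajectory snapshots as

    ΔG_bind = G_complex − (G_protein + G_ligand)
    G = E_gas + G_solvation − TS,   E_gas = E_int + E_vdW + E_ele
    G_solvation = G_PB (polar) + G_np (nonpolar)

averaged over the snapshot series.  Under the single-trajectory protocol all
three species come from the same complex trajectory, so the internal strain
term ΔE_int cancels identically, and the solute entropy TS is neglected by
default (the substrates compared are near-identical).  The decomposition
groups ΔE_vdW + ΔG_np as the nonpolar contribution and ΔE_ele + ΔG_PB as the
polar contribution; their sum is ΔG_bind exactly.

The component evaluators (Coulomb, Lennard-Jones, Shrake–Rupley SASA for the
nonpolar term, and a pairwise Born-style screening model for the polar term)
let the bookkeeping run on raw coordinates.  The polar-solvation evaluator is
an analytic surrogate: it reproduces the qualitative screening behaviour of a
continuum solvent but makes no claim of numeric agreement with a
finite-difference Poisson–Boltzmann solver.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure import Atom, Complex

COULOMB_CONSTANT = 332.0636  # kcal·mol⁻¹·Å·e⁻²
WATER_DIELECTRIC = 78.5

#: Lennard-Jones parameters by element: (sigma Å, epsilon kcal/mol)
LJ_PARAMS = {
    "H": (2.47, 0.016), "C": (3.40, 0.086), "N": (3.25, 0.170),
    "O": (2.96, 0.210), "S": (3.56, 0.250), "P": (3.74, 0.200),
}

#: van der Waals radii (Å) for SASA
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
}

#: effective Born radii (Å) for the polar-solvation surrogate
BORN_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.50, "S": 1.80, "P": 1.85,
}

DELTA_COLUMNS = ("dE_ele", "dE_vdW", "dG_PB", "dG_np")


@dataclass
class EnergyComponents:
    """Energy terms of one species (or one set of deltas), kcal·mol⁻¹."""

    E_int: float = 0.0   # bond + angle + torsion strain
    E_vdW: float = 0.0
    E_ele: float = 0.0
    G_PB: float = 0.0    # polar solvation
    G_np: float = 0.0    # nonpolar solvation
    TS: float = 0.0      # solute entropy term (neglected by default)

    def __post_init__(self) -> None:
        for name in ("E_int", "E_vdW", "E_ele", "G_PB", "G_np", "TS"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def E_gas(self) -> float:
        return self.E_int + self.E_vdW + self.E_ele

    @property
    def G_solvation(self) -> float:
        return self.G_PB + self.G_np


@dataclass
class BindingDecomposition:
    """Polar/nonpolar decomposition of a binding free energy."""

    dE_ele: float
    dE_vdW: float
    dG_PB: float
    dG_np: float

    @property
    def nonpolar(self) -> float:
        return self.dE_vdW + self.dG_np

    @property
    def polar(self) -> float:
        return self.dE_ele + self.dG_PB

    @property
    def dG_bind(self) -> float:
        return self.nonpolar + self.polar


@dataclass
class SnapshotSeries:
    """Per-snapshot binding-energy deltas (columns dE_ele, dE_vdW, dG_PB,
    dG_np), or species triples reduced to deltas."""

    deltas: pd.DataFrame
    spacing_ps: Optional[float] = None

    def __post_init__(self) -> None:
        missing = set(DELTA_COLUMNS) - set(self.deltas.columns)
        if missing:
            raise ValueError(f"snapshot table missing columns {sorted(missing)}")
        if len(self.deltas) < 1:
            raise ValueError("snapshot series must contain at least one snapshot")

    def __len__(self) -> int:
        return len(self.deltas)

    @staticmethod
    def from_species(triples: Sequence[tuple[EnergyComponents, EnergyComponents,
                                             EnergyComponents]],
                     spacing_ps: Optional[float] = None) -> "SnapshotSeries":
        rows = []
        for cx, prot, lig in triples:
            rows.append({
                "dE_ele": cx.E_ele - prot.E_ele - lig.E_ele,
                "dE_vdW": cx.E_vdW - prot.E_vdW - lig.E_vdW,
                "dG_PB": cx.G_PB - prot.G_PB - lig.G_PB,
                "dG_np": cx.G_np - prot.G_np - lig.G_np,
            })
        return SnapshotSeries(pd.DataFrame(rows), spacing_ps)

    @staticmethod
    def from_table(text: str, spacing_ps: Optional[float] = None) -> "SnapshotSeries":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        return SnapshotSeries(df[list(DELTA_COLUMNS)].astype(float), spacing_ps)

    def to_table(self) -> str:
        buf = io.StringIO()
        self.deltas[list(DELTA_COLUMNS)].to_csv(buf, sep="\t", index=False)
        return buf.getvalue()


def species_free_energy(c: EnergyComponents) -> float:
    """G = E_gas + G_solvation − TS for one species."""
    return c.E_gas + c.G_solvation - c.TS


def binding_free_energy(complex_G: float, protein_G: float, ligand_G: float) -> float:
    """ΔG_bind = G_complex − (G_protein + G_ligand)."""
    return complex_G - (protein_G + ligand_G)


def decompose(dE_ele: float, dE_vdW: float, dG_PB: float, dG_np: float
              ) -> BindingDecomposition:
    """Group the four binding-energy components into nonpolar
    (ΔE_vdW + ΔG_np) and polar (ΔE_ele + ΔG_PB) contributions; their sum is
    ΔG_bind.  ΔE_int is identically zero under the single-trajectory
    protocol and is not a parameter."""
    return BindingDecomposition(dE_ele, dE_vdW, dG_PB, dG_np)


def average_binding(series: SnapshotSeries) -> "BindingEnergyResults":
    """Snapshot-averaged binding free energy (convenience wrapper around
    :class:`BindingEnergyModel`)."""
    return BindingEnergyModel(series).fit()


class BindingEnergyModel:
    """Snapshot-series estimator of the mean binding free energy.

    Each snapshot contributes one ΔG_bind = (ΔE_vdW + ΔG_np) + (ΔE_ele +
    ΔG_PB); ``fit()`` returns the arithmetic means of all components with
    standard errors of the mean.
    """

    def __init__(self, series: SnapshotSeries):
        self.series = series

    def fit(self) -> "BindingEnergyResults":
        return BindingEnergyResults(self, self.series)


class BindingEnergyResults:
    """Fitted snapshot-averaged binding energetics."""

    def __init__(self, model: BindingEnergyModel, series: SnapshotSeries):
        self.model = model
        self.n_snapshots = len(series)
        df = series.deltas
        per_snapshot = df["dE_ele"] + df["dE_vdW"] + df["dG_PB"] + df["dG_np"]
        self.per_snapshot_dG = per_snapshot.to_numpy()
        self.component_means = {c: float(df[c].mean()) for c in DELTA_COLUMNS}
        n = self.n_snapshots
        self.component_se = {
            c: float(df[c].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            for c in DELTA_COLUMNS
        }
        self.decomposition = decompose(**self.component_means)
        self.dG_bind = float(per_snapshot.mean())
        self.dG_bind_se = (float(per_snapshot.std(ddof=1) / math.sqrt(n))
                           if n > 1 else 0.0)

    def summary(self, label: str = "complex") -> str:
        """Report in the canonical decomposition-table shape: the four
        component rows, then Non-polar, Polar and ΔG_bind, 2 decimals."""
        d = self.decomposition
        rows = [
            ("dE_ele", d.dE_ele), ("dE_vdW", d.dE_vdW),
            ("dG_PB", d.dG_PB), ("dG_np", d.dG_np),
            ("Non-polar", d.nonpolar), ("Polar", d.polar),
            ("dG_bind", d.dG_bind),
        ]
        lines = [f"component\t{label}"]
        lines += [f"{name}\t{value:.2f}" for name, value in rows]
        lines.append(f"# n_snapshots={self.n_snapshots} "
                     f"dG_bind_se={self.dG_bind_se:.3f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# component evaluators


@dataclass
class ForceFieldParams:
    """Force-field-lite parameters for the component evaluators."""

    dielectric: float = 1.0              # gas-phase interior dielectric
    distance_dependent: bool = False     # ε(r) = dielectric · r when True
    cutoff: Optional[float] = None       # Å pairwise cutoff (None = no cutoff)
    gamma: float = 0.00542               # kcal·mol⁻¹·Å⁻², SASA surface tension
    beta: float = 0.92                   # kcal·mol⁻¹, SASA offset
    probe_radius: float = 1.4            # Å, solvent probe
    sasa_points: int = 512               # Shrake–Rupley sphere points
    water_dielectric: float = WATER_DIELECTRIC
    strict: bool = True

    lj_params: dict = field(default_factory=lambda: dict(LJ_PARAMS))
    vdw_radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    born_radii: dict = field(default_factory=lambda: dict(BORN_RADII))


def _charges(atoms: Sequence[Atom], strict: bool) -> np.ndarray:
    missing = [a.name for a in atoms if a.partial_charge is None]
    if missing and strict:
        raise ValueError(f"missing partial charges for atoms: {missing}")
    return np.array([a.partial_charge or 0.0 for a in atoms])


def coulomb_energy(atoms: Sequence[Atom], params: ForceFieldParams = ForceFieldParams()
                   ) -> float:
    """Pairwise Coulomb energy, k·q_i·q_j/(ε(r)·r), over all atom pairs."""
    q = _charges(atoms, params.strict)
    coords = np.array([a.coords for a in atoms])
    e = 0.0
    for i in range(len(atoms)):
        r = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        eps = params.dielectric * (r if params.distance_dependent else 1.0)
        term = COULOMB_CONSTANT * q[i] * q[i + 1:] / (eps * r)
        if params.cutoff is not None:
            term = term[r <= params.cutoff]
        e += float(np.sum(term))
    return e


def lennard_jones_energy(atoms: Sequence[Atom],
                         params: ForceFieldParams = ForceFieldParams()) -> float:
    """Pairwise 12-6 Lennard-Jones energy with Lorentz–Berthelot combination
    (σ_ij arithmetic mean, ε_ij geometric mean)."""
    sigmas, epsilons = [], []
    for a in atoms:
        el = a.element.upper()
        if el not in params.lj_params:
            if params.strict:
                raise ValueError(f"no LJ parameters for element {el} (atom {a.name})")
            sigmas.append(3.4)
            epsilons.append(0.1)
        else:
            s, e = params.lj_params[el]
            sigmas.append(s)
            epsilons.append(e)
    sig = np.array(sigmas)
    eps = np.array(epsilons)
    coords = np.array([a.coords for a in atoms])
    total = 0.0
    for i in range(len(atoms)):
        r = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        sij = 0.5 * (sig[i] + sig[i + 1:])
        eij = np.sqrt(eps[i] * eps[i + 1:])
        sr6 = (sij / r) ** 6
        term = 4.0 * eij * (sr6 ** 2 - sr6)
        if params.cutoff is not None:
            term = term[r <= params.cutoff]
        total += float(np.sum(term))
    return total


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(atoms: Sequence[Atom],
                       params: ForceFieldParams = ForceFieldParams()) -> float:
    """Solvent-accessible surface area (Ų) by Shrake–Rupley sphere sampling.

    Each atom's solvent-expanded sphere (r_vdW + probe) is sampled with a
    deterministic golden-spiral point set; points buried inside any other
    expanded sphere are discarded.
    """
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        return 0.0
    radii = np.array([
        params.vdw_radii.get(a.element.upper(), 1.7) + params.probe_radius
        for a in heavy
    ])
    coords = np.array([a.coords for a in heavy])
    unit = _sphere_points(params.sasa_points)
    area = 0.0
    for i in range(len(heavy)):
        points = coords[i] + radii[i] * unit
        buried = np.zeros(len(points), dtype=bool)
        for j in range(len(heavy)):
            if j == i:
                continue
            if np.linalg.norm(coords[j] - coords[i]) > radii[i] + radii[j]:
                continue
            buried |= (np.linalg.norm(points - coords[j], axis=1) < radii[j])
        accessible = np.count_nonzero(~buried) / len(points)
        area += accessible * 4.0 * math.pi * radii[i] ** 2
    return float(area)


def nonpolar_solvation(atoms: Sequence[Atom],
                       params: ForceFieldParams = ForceFieldParams()) -> float:
    """G_np = γ·SASA + β."""
    return params.gamma * shrake_rupley_sasa(atoms, params) + params.beta


def born_polar_solvation(atoms: Sequence[Atom],
                         params: ForceFieldParams = ForceFieldParams()) -> float:
    """Polar solvation by a pairwise analytic Born-style screening model.

    ΔG_pol = −½·k·(1/ε_in − 1/ε_w)·Σ_ij q_i q_j / f_ij with
    f_ij = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))) and fixed per-element
    effective radii.  A declared surrogate for a finite-difference PB solver:
    correct limiting behaviour, no numeric-agreement claim.
    """
    q = _charges(atoms, params.strict)
    if not np.any(q):
        return 0.0
    R = np.array([params.born_radii.get(a.element.upper(), 1.7) for a in atoms])
    coords = np.array([a.coords for a in atoms])
    prefactor = -0.5 * COULOMB_CONSTANT * (1.0 / params.dielectric
                                           - 1.0 / params.water_dielectric)
    total = 0.0
    for i in range(len(atoms)):
        r2 = np.sum((coords[i:] - coords[i]) ** 2, axis=1)
        rr = R[i] * R[i:]
        f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
        contrib = q[i] * q[i:] / f
        contrib[0] *= 0.5  # self term appears once in the double sum
        total += float(np.sum(contrib))
    # loop accumulates j ≥ i with the self term halved; doubling restores the
    # full symmetric double sum Σ_i Σ_j
    return prefactor * 2.0 * total


def evaluate_components(cx: Complex,
                        params: ForceFieldParams = ForceFieldParams()
                        ) -> tuple[EnergyComponents, EnergyComponents, EnergyComponents]:
    """Evaluate (complex, protein, ligand) energy components from one
    snapshot's coordinates (single-trajectory mode: the protein and ligand
    species are extracted from the complex, so ΔE_int ≡ 0)."""
    protein_atoms = cx.protein_atoms()
    ligand_atoms = cx.ligand.atoms
    all_atoms = protein_atoms + ligand_atoms

    def components(atoms: Sequence[Atom]) -> EnergyComponents:
        return EnergyComponents(
            E_int=0.0,
            E_vdW=lennard_jones_energy(atoms, params),
            E_ele=coulomb_energy(atoms, params),
            G_PB=born_polar_solvation(atoms, params),
            G_np=nonpolar_solvation(atoms, params),
        )

    return components(all_atoms), components(protein_atoms), components(ligand_atoms)
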