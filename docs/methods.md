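# Methods

## Scope and model of the data

`siftkit` analyses the *outputs* of docking and molecular-dynamics engines
for a papain-family cysteine protease bound to fluorogenic AMC substrates;
it does not dock, simulate, or build homology models.  Its inputs are pose
ensembles in multi-MODEL PDB, docking score tables (label, kcal·mol⁻¹), and
per-snapshot binding-energy component tables.  The shipped enzyme
annotation encodes the zmCP1 active site in mature-protein numbering:
catalytic triad Cys149–His285–Asn306, oxyanion hole Gln143/Cys149, S1 =
{Gly147, Cys189, Asp190, Gly191}, S2 = {Leu193, Met194, Ala259, Leu283,
Ala286}, nucleophile atom Cys149 SG.  The S2 membership of Ala259 is
reported inconsistently in the source literature; the default includes it,
and the annotation is a YAML file precisely so users can remove it without
touching code.

## Interaction fingerprints

Nine bits per residue, computed from geometry and typing:

| bit | rule | default cutoff |
|---|---|---|
| any | ≥1 heavy-atom pair in contact, or any specific bit | 4.5 Å |
| backbone / side chain | the contacting residue atom's partition | 4.5 Å |
| polar | residue N/O/S near ligand N/O/S | 4.0 Å |
| hydrophobic | apolar-carbon pair (no N/O/S within bonding distance) | 4.5 Å |
| H-bond donor / acceptor | donor–acceptor heavy-atom distance, plus donor–H…acceptor angle ≥ 120° when the hydrogen exists | 3.5 Å |
| aromatic | ring-centroid distance between residue and ligand rings | 5.0 Å |
| charged | oppositely signed formal-charge groups with an N/O pair in range | 4.0 Å |

The upstream description of this fingerprint names the nine bits and the
decision ingredients (distance, atom/residue type, hydrogen-bond angle) but
its defining equations are available only as unrecoverable figure images
and it publishes no numeric cutoffs; the cutoffs above follow common
structural-biology practice and live in `GeometricCriteria`, all
configurable.  Two conventions are ours and documented as such: the
"H-bond donor" bit means the **protein** donates (the direction is not
fixed upstream), and "any" is recomputed as the OR of plain contact and the
eight specific bits, so the hierarchy `any ≥ every other bit` holds by
construction.  Published averaged-fingerprint tables do not always satisfy
that hierarchy (and may contain duplicate residue rows); the shipped
reference table is preserved verbatim, duplicates included, and is used
only for consensus extraction — reproducing its frequencies is explicitly
not a goal.

Donor/acceptor typing without hydrogens uses residue templates (backbone N
donates except proline, backbone O accepts, Ser OG both, …); ligand N/O
atoms count as both donor and acceptor unless a formal charge forbids one
role.  Ligand rings are perceived without connectivity records: bonds are
inferred from covalent radii (sum × 1.25), and cycles of ≤6 all-C/N atoms
planar within 0.1 Å RMS count as rings.

Ensemble averaging treats each complex as one Bernoulli observation per
(residue, bit): `FingerprintModel.fit()` returns the frequency matrix with
binomial standard errors √(p(1−p)/n).  Consensus residues are those with
selected-bit frequency ≥ cutoff (default 0.5 on "any"), ordered by
descending frequency then residue number.

## Pose triage

Redocking validation uses ligand heavy-atom RMSD in the shared receptor
frame (no superposition).  With symmetry correction on, the reported value
is the minimum over element-preserving automorphisms of the
covalent-radius bond graph (networkx VF2), which can only lower the value;
tests verify equality with brute-force permutation on small ligands.  A
pose within 2.5 Å (inclusive — the upstream rule says "about") of the
reference is a docking success, otherwise a scoring failure.

Binding-mode selection applies three rules per pose: (R1) at least one
P-group heavy atom within the occupancy cutoff (default 4.5 Å, the contact
cutoff — no value is published) of its subsite; (R2) scissile carbonyl
carbon to nucleophile sulfur distance ≤ 4.5 Å, our operationalisation of
"about 4 Å" chosen so that both published accepted geometries (4.33 Å and
3.29 Å) pass; (R3) ≥1 hydrogen bond between the P1 charged group and an
oxyanion-hole residue, using the fingerprint criteria.  One wording issue
is resolved explicitly rather than silently: the upstream text says "the
carbon of the hydroxyl group" of the substrate, but an AMC anilide has no
hydroxyl — we read it as the scissile amide carbonyl carbon, which is the
atom the nucleophile attacks.  The selected pose is the best-scoring pose
passing all applicable rules; equal scores break by pose index (engine
order).  P-group membership is declared by atom names, never inferred from
chemistry.

## MM-PBSA bookkeeping

Per snapshot, ΔG_bind = G_complex − (G_protein + G_ligand) with
G = (E_int + E_vdW + E_ele) + (G_PB + G_np) − TS.  The implementation
assumes the single-trajectory protocol — all three species extracted from
the complex trajectory — so ΔE_int cancels identically; the absence of an
internal-energy row in the published decomposition supports this.  TS
defaults to zero (the compared substrates are near-identical, so entropy
differences are neglected upstream); enabling it shifts ΔG_bind by exactly
−ΔTS.  The decomposition groups nonpolar = ΔE_vdW + ΔG_np and polar =
ΔE_ele + ΔG_PB; this grouping was verified by independent summation of the
published two-ligand table before being coded, and the sums reproduce that
table exactly at two decimals.  The published prose quotes a best–worst
binding-energy difference 1.00 kcal·mol⁻¹ smaller than its own table
implies; the package always reports the computed difference (27.06).

Snapshot count and spacing are data properties, not constants: the
reference protocol takes one snapshot per 2 ps over a 2000 ps tail
(n = 1000), and the synthetic generator uses that n for recovery checks.

Component evaluators, for running the bookkeeping from raw coordinates:

* **E_ele** — pairwise Coulomb, k = 332.0636 kcal·mol⁻¹·Å·e⁻², fixed ε = 1
  (gas phase) with a distance-dependent option; optional pairwise cutoff.
* **E_vdW** — 12-6 Lennard-Jones with per-element parameters and
  Lorentz–Berthelot combination.
* **G_np** = γ·SASA + β with γ = 0.00542 kcal·mol⁻¹·Å⁻², β = 0.92
  kcal·mol⁻¹ (standard MM-PBSA surface-tension values); SASA by
  Shrake–Rupley sampling on a deterministic golden-spiral point set
  (512 points/atom, probe 1.4 Å), exact to <2% on an isolated sphere.
* **G_PB** — a pairwise analytic Born-style screening model
  (−½·k·(1/ε_in − 1/ε_w)·Σ q_iq_j/f_ij with the standard smoothed f_ij and
  fixed per-element effective radii).  This is a declared surrogate for a
  finite-difference Poisson–Boltzmann solver: it has the correct
  self-energy and non-interacting limits, but no numeric agreement with
  grid PB is claimed, and only the bookkeeping identities are test
  surfaces.

## Specificity ranking

Score tables follow the docking convention lower = better (a flag flips
it).  Ranking is a total order: ascending score, ties alphabetical by
label, so permuting input rows can never change a call.  The preference
call reports best, worst, the top-2 gap, and the amino acid of the best
label's variable prefix (R-AMC → Arg; F-R-AMC at P2 → Phe).  Report
rounding follows the conventions of the source tables: scores 1 decimal,
energies 2 decimals, frequencies 2 decimals.

## Synthetic data: what it emulates and what it does not

The generator builds a toy pocket around a rigid, planar AMC-like ligand —
two fused all-carbon hexagons standing in for the coumarin, an amide
linkage whose carbonyl carbon is named `C` (so the catalytic-distance rule
is exercised by name), and an Arg-like P1 chain ending in a guanidinium
group carrying the +1 formal charge.  Each requested interaction places
one residue template so its probe atom sits at exactly the requested
distance (and donor-H angle, solved to the requested value); the residue
is then spun about its placement axis to the orientation that keeps every
*incidental* atom pair farthest from the detection cutoffs.  Ground truth
is derived from the realised geometry by the generator's own compact rule
set — an independent re-derivation, never a call into the detector module
under test — and a plant is rejected outright if no orientation realises
the requested class with a guard margin of at least 0.25 Å from every
cutoff.  Defaults keep ≥0.3 Å margins so recovery tests cannot flake on
floating-point detail.

Pose ensembles toggle each planted interaction per pose with probability
*p* (the residue is displaced 4 Å radially when off — receptor-side
variation, keeping the ligand inventory identical across models), and
rigid ligand translations produce poses at exact RMSD targets.  A
"zmCP1-mini" builder arranges the real active-site residue names and
numbers (Gln143 … Asn306) around the ligand with controllable catalytic
and oxyanion distances, so subsite and oxyanion logic run against the
annotation actually shipped.

What the toys do **not** emulate: real side-chain rotamer statistics,
water-mediated contacts, correlated interaction occurrence across poses,
force-field-quality internal geometry, or chemically realistic conformers.
Passing recovery tests therefore demonstrates that the detectors implement
their stated geometric rules exactly — not that those rules capture every
interaction a crystallographer would annotate in real structures.

## Numerical and degenerate-input choices

Threshold comparisons are inclusive throughout.  PDB coordinates
round-trip at the format's 3-decimal precision; only altloc A is kept;
hydrogens are accepted but never required.  Glycine has an empty side
chain, so its side-chain bits are structurally zero.  An empty matrix
list, empty snapshot series, sub-two-entry score table, ligand-free model
and zero-heavy-atom ligand all raise explicit errors.  Unknown residue
names classify as the empty set with a warning (or raise in strict mode).
All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical fixtures and reports (no timestamps in outputs).

## Known limitations

The polar-solvation surrogate is qualitative; real MM-PBSA work should
import per-snapshot component tables from a PB solver and use only the
bookkeeping here.  Partial charges are taken from input or user templates
— there is no charge-derivation machinery.  Ligand ring perception assumes
reasonable bond lengths; grossly distorted geometries may mis-perceive
rings.  mmCIF, protonation-state assignment and structure repair are out
of scope.
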