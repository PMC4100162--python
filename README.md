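# siftkit

Post-docking substrate-specificity analysis for papain-family (C1A)
cysteine proteases — built around the maize cysteine protease 1 (zmCP1)
active site, but usable for any protease pocket you can annotate.

Docking a fluorogenic substrate library (R-AMC, F-R-AMC, …) against an
enzyme model produces three kinds of raw material: pose ensembles
(multi-MODEL PDB), score tables, and — after molecular dynamics — snapshot
energy series.  `siftkit` turns these into specificity statements:

* **Structural interaction fingerprints (SIFt).**  Every protein residue in
  contact with the ligand gets nine boolean bits — any, backbone, side
  chain, polar, hydrophobic, H-bond acceptor, H-bond donor, aromatic,
  charged — from atom–atom distances, residue/atom typing and the
  donor–H…acceptor angle when hydrogens are present.  Averaging over an
  ensemble of complexes gives per-residue frequencies
  `f(r, b) = #{complexes with bit b set at residue r} / #complexes`,
  and the consensus binding site is the residue set with
  `f(r, any) ≥ 0.5` (cutoff configurable).
* **Pose triage.**  Redocking validation by ligand heavy-atom RMSD (no
  superposition; optionally minimised over bond-graph automorphisms so
  symmetric ligands are not penalised), with the 2.5 Å success /
  scoring-failure rule; and binding-mode selection for protease substrates:
  P1 group in the S1 pocket, scissile carbonyl carbon within ~4 Å of the
  catalytic Cys sulfur, P1 charged group hydrogen-bonded to the oxyanion
  hole (Gln143/Cys149 in zmCP1).
* **MM-PBSA bookkeeping.**  ΔG_bind = ΔE_ele + ΔE_vdW + ΔG_PB + ΔG_np per
  snapshot (single-trajectory protocol, ΔE_int ≡ 0, entropy neglected),
  averaged over the series, and reported as the nonpolar (ΔE_vdW + ΔG_np)
  and polar (ΔE_ele + ΔG_PB) decomposition.  Component evaluators
  (Coulomb, Lennard-Jones, Shrake–Rupley SASA, and an analytic Born-style
  polar-solvation surrogate) let the bookkeeping run on raw coordinates.
* **Specificity ranking.**  Docking score tables (lower = better) are
  ranked into preference calls per substrate position (P1, P2), with the
  best/worst substrate and the top-2 score gap.
* **Synthetic fixtures.**  Pocket–ligand complexes with interactions of any
  class planted at exact geometry, pose ensembles with known per-interaction
  occurrence probability and exact RMSD displacements, snapshot energy
  series with known means, and score tables with a planted winner — all
  seeded and byte-reproducible, with ground truth recorded independently of
  the detectors.

## Worked example

Rank the shipped P1 substrate library and decompose the binding energies of
the best and worst substrates:

```python
import siftkit as sk

call = sk.rank_substrates(sk.load_p1_scores())
print(call.best.label, call.best.score, call.best_residue)
print(call.worst.label, call.worst.score)
print(round(call.gap_top2, 1))
```

prints

```
R-AMC -10.4 ARG
D-AMC -5.5
2.1
```

— the protease prefers arginine at P1 (best score −10.4 kcal·mol⁻¹, a
2.1 kcal·mol⁻¹ margin over the runner-up) and aspartate binds worst.
Feeding the shipped per-ligand energy components through the decomposition:

```python
from siftkit import decompose
d = decompose(**sk.load_reference_components()["R-AMC"])
print(round(d.nonpolar, 2), round(d.polar, 2), round(d.dG_bind, 2))
```

```
-38.94 -1.97 -40.91
```

so R-AMC's affinity is almost entirely nonpolar: the favourable
electrostatics (−172.62) are nearly cancelled by the polar solvation
penalty (+170.65).  For D-AMC the same arithmetic gives a *positive* polar
term (+23.01) and ΔG_bind = −13.85 kcal·mol⁻¹ — the energetic reading of
why a negatively charged P1 side chain is the worst substrate.

A fingerprint over a synthetic 10-pose ensemble, from the shell:

```sh
siftkit simulate --kind ensemble --seed 2 --n 10 --out poses.pdb
siftkit fingerprint poses.pdb
```

```
residue any     backbone  sidechain  polar  hydrophobic  hbond_acceptor  hbond_donor  aromatic  charged
Q10     0.60    0.00      0.60       0.60   0.00         0.00            0.60         0.00      0.00
L11     0.40    0.00      0.40       0.00   0.40         0.00            0.00         0.00      0.00
D12     0.60    0.00      0.60       0.60   0.00         0.60            0.00         0.00      0.60
```

Each row is a pocket residue; each number is the fraction of poses in which
that interaction bit was set (the generator planted each interaction with
probability 0.5, so frequencies scatter around 0.5).

The orchestrated pipeline (`siftkit run config.yaml --outdir report/`)
chains triage → fingerprint → consensus → ranking → energy decomposition
and writes one delimited table per stage; reruns are byte-identical.

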