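"""Substrate-specificity ranking from docking score tables.

A score table maps fluorogenic substrate labels (R-AMC, F-R-AMC, …) to
docking scores in kcal·mol⁻¹, lower = better binding.  Ranking a table gives
a preference call for the substrate position it probes: for a P1 library the
variable residue precedes the AMC leaving group (X-AMC); for a P2 library it
precedes a fixed P1 arginine (X-R-AMC).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .structure import ONE_TO_THREE


@dataclass(frozen=True)
class ScoreEntry:
    label: str
    score: float  # kcal/mol, lower = better


@dataclass
class ScoreTable:
    entries: list[ScoreEntry]
    position_label: str = "other"  # P1 | P2 | other
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate ligand labels: {sorted(dupes)}")
        bad = [e.label for e in self.entries if not math.isfinite(e.score)]
        if bad:
            raise ValueError(f"non-finite scores for: {bad}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PreferenceCall:
    """Ranked substrate preference at one position."""

    position: str
    ranked: list[ScoreEntry]  # ascending score (best first)

    @property
    def best(self) -> ScoreEntry:
        return self.ranked[0]

    @property
    def worst(self) -> ScoreEntry:
        return self.ranked[-1]

    @property
    def gap_top2(self) -> float:
        return self.ranked[1].score - self.ranked[0].score

    @property
    def best_residue(self) -> str:
        """3-letter code of the preferred residue, from the label prefix
        (R-AMC → ARG; F-R-AMC at P2 → PHE)."""
        prefix = self.best.label.split("-")[0].strip()
        return ONE_TO_THREE.get(prefix.upper(), prefix)

    def as_table(self) -> str:
        lines = ["rank\tligand\tscore"]
        lines += [f"{i + 1}\t{e.label}\t{e.score:.1f}"
                  for i, e in enumerate(self.ranked)]
        return "\n".join(lines) + "\n"


def read_score_table(text: str, position_label: str = "other") -> ScoreTable:
    """Parse a delimited (tab or comma) two-column table: ligand label, score.

    A header row is tolerated (and skipped) when its second field is not
    numeric.  Duplicate labels and non-numeric scores raise ``ValueError``
    with the offending row identified.
    """
    entries: list[ScoreEntry] = []
    rows = [r for r in text.splitlines() if r.strip()]
    if not rows:
        raise ValueError("empty score table")
    for lineno, row in enumerate(rows, start=1):
        sep = "\t" if "\t" in row else ","
        fields = [f.strip() for f in row.split(sep) if f.strip()]
        if len(fields) < 2:
            raise ValueError(f"row {lineno}: expected two columns, got {row!r}")
        label = " ".join(fields[0].split()).replace("- ", "-")
        try:
            score = float(fields[1].replace("−", "-"))
        except ValueError:
            if lineno == 1:  # header
                continue
            raise ValueError(f"row {lineno}: non-numeric score {fields[1]!r}")
        entries.append(ScoreEntry(label, score))
    if not entries:
        raise ValueError("score table contains no data rows")
    return ScoreTable(entries, position_label)


def rank_substrates(table: ScoreTable) -> PreferenceCall:
    """Total ordering of a score table: ascending score (lower binds better),
    ties broken alphabetically by label."""
    if len(table) < 2:
        raise ValueError("ranking requires at least two entries")
    sign = 1.0 if table.lower_is_better else -1.0
    ranked = sorted(table.entries, key=lambda e: (sign * e.score, e.label))
    return PreferenceCall(table.position_label, ranked)


def _load_data(name: str) -> str:
    return resources.files("siftkit.data").joinpath(name).read_text()


def load_p1_scores() -> ScoreTable:
    """Shipped P1 substrate-library docking scores (20 X-AMC ligands)."""
    return read_score_table(_load_data("p1_docking_scores.tsv"), "P1")


def load_p2_scores() -> ScoreTable:
    """Shipped P2 dipeptide-library docking scores (20 X-R-AMC ligands)."""
    return read_score_table(_load_data("p2_docking_scores.tsv"), "P2")


def load_reference_fingerprint():
    """Shipped ensemble-averaged interaction fingerprint table for the zmCP1
    binding site (frequencies over successfully docked poses; the duplicate
    A286 row of the source table is preserved verbatim)."""
    from .fingerprint import FingerprintProfile

    return FingerprintProfile.from_table(_load_data("averaged_fingerprint.tsv"))


def load_reference_components() -> dict[str, dict[str, float]]:
    """Shipped per-ligand binding-energy components (ΔE_ele, ΔE_vdW, ΔG_PB,
    ΔG_np in kcal·mol⁻¹) for the best (R-AMC) and worst (D-AMC) substrates."""
    text = _load_data("mmpbsa_components.tsv")
    lines = [l.split("\t") for l in text.strip().splitlines()]
    header = lines[0][1:]
    out: dict[str, dict[str, float]] = {lig: {} for lig in header}
    for row in lines[1:]:
        for lig, val in zip(header, row[1:]):
            out[lig][row[0]] = float(val)
    return out


def load_default_annotation():
    """Shipped zmCP1 enzyme annotation (catalytic triad, oxyanion hole,
    S1/S2 subsites, nucleophile atom)."""
    from .structure import EnzymeAnnotation

    return EnzymeAnnotation.from_yaml(_load_data("zmcp1_annotation.yaml"))
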