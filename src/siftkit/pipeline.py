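"""Orchestrated analysis: triage → fingerprint → consensus → ranking → energies.

``run_analysis`` executes whichever stages the configuration names inputs
for, writing one delimited table per stage into a report directory plus a
plain-text log.  Stages are independent: a missing input skips the stage
with a warning (or raises in strict mode).  For a fixed configuration the
report is byte-identical across reruns — no timestamps enter the outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import yaml

from . import specificity
from .energy import BindingEnergyModel, SnapshotSeries, decompose
from .fingerprint import FingerprintModel, GeometricCriteria, profile_report
from .structure import EnzymeAnnotation, parse_complexes, write_pdb
from .triage import TriageRules, select_binding_mode, verdict_table

logger = logging.getLogger(__name__)


class StageInputError(ValueError):
    pass


def _read(path_or_text: str) -> str:
    p = Path(path_or_text)
    if p.exists():
        return p.read_text()
    return path_or_text


def _load_annotation(value: Optional[str]) -> EnzymeAnnotation:
    if value in (None, "shipped", "default"):
        return specificity.load_default_annotation()
    return EnzymeAnnotation.from_yaml(Path(value).read_text())


def run_analysis(config, outdir, strict: bool = False) -> dict[str, object]:
    """Run the configured stages and write a report directory.

    Parameters
    ----------
    config : dict or str/Path
        Stage configuration (a mapping, or a path to / text of a YAML file).
        Recognised stage keys: ``rank`` (score tables), ``fingerprint``
        (pose-ensemble PDB), ``consensus`` (cutoff on the fingerprint),
        ``triage`` (ensemble + annotation + P-group atoms), ``mmpbsa``
        (snapshot series or printed component deltas).
    outdir : path-like
        Report directory (created if needed).
    strict : bool
        Raise instead of skipping a stage whose inputs are missing.

    Returns the in-memory stage results keyed by stage name.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(_read(str(config)))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    log_lines: list[str] = []

    def skip(stage: str, why: str) -> None:
        msg = f"stage {stage} skipped: {why}"
        if strict:
            raise StageInputError(msg)
        logger.warning(msg)
        log_lines.append(msg)

    # ----- ranking -------------------------------------------------------
    rank_cfg = config.get("rank")
    if rank_cfg is not None:
        calls = {}
        for pos in ("P1", "P2"):
            key = f"{pos.lower()}_scores"
            if key not in rank_cfg:
                continue
            src = rank_cfg[key]
            if src == "shipped":
                table = (specificity.load_p1_scores() if pos == "P1"
                         else specificity.load_p2_scores())
            else:
                table = specificity.read_score_table(_read(src), pos)
            call = specificity.rank_substrates(table)
            calls[pos] = call
            (outdir / f"ranking_{pos}.tsv").write_text(call.as_table())
            log_lines.append(
                f"rank {pos}: best {call.best.label} ({call.best.score:.1f}), "
                f"worst {call.worst.label} ({call.worst.score:.1f}), "
                f"top-2 gap {call.gap_top2:.1f}"
            )
        if calls:
            results["rank"] = calls
        else:
            skip("rank", "no score tables configured")

    # ----- triage --------------------------------------------------------
    triage_cfg = config.get("triage")
    ensemble_for_fp = None
    if triage_cfg is not None:
        if "ensemble_pdb" not in triage_cfg:
            skip("triage", "ensemble_pdb missing")
        else:
            ensemble = parse_complexes(
                _read(triage_cfg["ensemble_pdb"]),
                triage_cfg.get("ligand", "AMC"),
            )
            annotation = _load_annotation(triage_cfg.get("annotation"))
            p_groups = {k: v for k, v in (("P1", triage_cfg.get("p1_atoms")),
                                          ("P2", triage_cfg.get("p2_atoms")))
                        if v}
            rules = TriageRules(
                occupancy_cutoff=float(triage_cfg.get("occupancy_cutoff", 4.5)),
                catalytic_max=float(triage_cfg.get("catalytic_max", 4.5)),
                scissile_atom=triage_cfg.get("scissile_atom", "C"),
            )
            verdicts, selected = select_binding_mode(ensemble, annotation,
                                                     p_groups, rules)
            (outdir / "triage.tsv").write_text(verdict_table(verdicts))
            if selected is not None:
                (outdir / "selected_pose.pdb").write_text(
                    write_pdb(ensemble[selected].complex))
                ensemble_for_fp = ensemble
            results["triage"] = (verdicts, selected)
            log_lines.append(
                f"triage: {sum(v.passed for v in verdicts)}/{len(verdicts)} "
                f"poses pass; selected {selected}"
            )

    # ----- fingerprint + consensus --------------------------------------
    fp_cfg = config.get("fingerprint")
    fp_results = None
    if fp_cfg is not None:
        if "ensemble_pdb" not in fp_cfg and ensemble_for_fp is None:
            skip("fingerprint", "ensemble_pdb missing")
        else:
            if "ensemble_pdb" in fp_cfg:
                ensemble = parse_complexes(_read(fp_cfg["ensemble_pdb"]),
                                           fp_cfg.get("ligand", "AMC"))
            else:
                ensemble = ensemble_for_fp
            criteria = GeometricCriteria(**fp_cfg.get("criteria", {}))
            fp_results = FingerprintModel(ensemble, criteria).fit()
            (outdir / "fingerprint.tsv").write_text(
                profile_report(fp_results.profile))
            results["fingerprint"] = fp_results
            log_lines.append(
                f"fingerprint: {len(fp_results.profile.residues)} interacting "
                f"residues over {fp_results.n_complexes} complexes"
            )

    cons_cfg = config.get("consensus")
    if cons_cfg is not None:
        if fp_results is None:
            skip("consensus", "no fingerprint profile available")
        else:
            cutoff = float(cons_cfg.get("cutoff", 0.5))
            bit = cons_cfg.get("bit", "any")
            residues = fp_results.consensus(cutoff, bit)
            labels = [fp_results.profile.label(r) for r in residues]
            (outdir / "consensus.txt").write_text("\n".join(labels) + "\n")
            results["consensus"] = labels
            log_lines.append(
                f"consensus ({bit} ≥ {cutoff:g}): {len(labels)} residues"
            )

    # ----- binding energies ----------------------------------------------
    mm_cfg = config.get("mmpbsa")
    if mm_cfg is not None:
        if "series_table" in mm_cfg:
            series = SnapshotSeries.from_table(_read(mm_cfg["series_table"]))
            fit = BindingEnergyModel(series).fit()
            label = mm_cfg.get("label", "complex")
            (outdir / f"mmpbsa_{label}.tsv").write_text(fit.summary(label))
            results["mmpbsa"] = fit
            log_lines.append(
                f"mmpbsa {label}: dG_bind {fit.dG_bind:.2f} "
                f"± {fit.dG_bind_se:.2f} over {fit.n_snapshots} snapshots"
            )
        elif "components" in mm_cfg:
            # printed per-ligand component deltas -> decomposition report
            decomps = {}
            lines = ["component"]
            comp = mm_cfg["components"]
            if comp == "shipped":
                comp = specificity.load_reference_components()
            for ligand_label, values in comp.items():
                decomps[ligand_label] = decompose(**values)
                lines[0] += f"\t{ligand_label}"
            for row, attr in [("dE_ele", "dE_ele"), ("dE_vdW", "dE_vdW"),
                              ("dG_PB", "dG_PB"), ("dG_np", "dG_np"),
                              ("Non-polar", "nonpolar"), ("Polar", "polar"),
                              ("dG_bind", "dG_bind")]:
                lines.append(row + "".join(
                    f"\t{getattr(d, attr):.2f}" for d in decomps.values()))
            (outdir / "mmpbsa_decomposition.tsv").write_text(
                "\n".join(lines) + "\n")
            results["mmpbsa"] = decomps
            log_lines.append(
                "mmpbsa decomposition: " + ", ".join(
                    f"{k} dG_bind {d.dG_bind:.2f}" for k, d in decomps.items())
            )
        else:
            skip("mmpbsa", "no series_table or components configured")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
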