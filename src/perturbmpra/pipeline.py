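"""End-to-end orchestration of the synthetic perturbation-MPRA workflow.

simulate -> design -> build library -> associate -> count -> quantify ->
call FRSs -> test pairs. Every stage writes its tables under the run
directory, so partial results survive a failing stage, and the whole
run is deterministic given the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, frs, interaction, seqlib, simulate
from .config import RunConfig
from .design import build_ilp, check_constraints, solve_design
from .pwm import PWMScanner
from .quantify import compute_size_factors

log = logging.getLogger("perturbmpra")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns the summary report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed}
    sim = config.sim
    stage = "simulate-graph"
    try:
        log.info("stage %s: n_regions=%d n_motifs=%d n_properties=%d",
                 stage, sim.n_regions, sim.n_motifs, sim.n_properties)
        graph = simulate.generate_graph(sim)
        graph.to_dir(out / "graph")

        if config.run_design:
            stage = "design"
            model = build_ilp(graph)
            selection = solve_design(model)
            selection.edges.to_csv(out / "selection.tsv", sep="\t", index=False)
            report = check_constraints(graph, selection)
            (out / "constraint_report.json").write_text(
                json.dumps(report.to_dict(), indent=1)
            )
            summary["design"] = {
                "objective": selection.objective_value,
                "n_regions": len(selection.selected_regions),
                "n_motifs": len(selection.selected_motifs),
                "n_instances": len(selection.edges),
                "all_constraints_satisfied": report.all_satisfied,
            }
            sel_edges = selection.edges
        else:
            sel_edges = graph.instance_edges[["motif", "region"]]

        stage = "sequences"
        seqs, hits, pwms = simulate.generate_sequences(graph, sim)
        hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        _write_fasta(seqs, out / "regions.fasta")

        stage = "library"
        scanner = PWMScanner(pwms)
        contexts = [
            (seqs[h.region_id], int(h.start), int(h.end))
            for h in hits.head(6).itertuples()
        ]
        background = [seqs[r] for r in graph.regions]
        nonmotif = seqlib.derive_nonmotif_sequences(
            background, scanner, contexts, n_candidates=100, seed=config.seed
        )
        pair_list = _choose_pairs(sel_edges, hits, config.n_pairs)
        library, lib_log = seqlib.build_library(
            sel_edges, seqs, hits, nonmotif, sim, seed=config.seed,
            pair_list=pair_list, rand_window=config.rand_window,
        )
        man = seqlib.manifest(library)
        man.to_csv(out / "library.tsv", sep="\t", index=False)
        seqlib.write_fasta(library, out / "library.fasta")
        summary["library"] = {
            "n_sequences": len(library),
            "n_pairs": len(pair_list),
            "discarded": lib_log,
        }

        stage = "truth"
        usable = set(man.loc[man["category"] == "PERT", "perturbed_instances"]
                     .str.split(";").explode())
        sel_usable = sel_edges[
            (sel_edges["motif"].radd(sel_edges["region"] + "|")).isin(usable)
        ]
        truth = simulate.plant_truth(hits, sim, selected=sel_usable)
        truth.pairs = simulate.plant_pair_truth(pair_list, sim)
        truth.instances.to_csv(out / "truth_instances.tsv", sep="\t", index=False)
        truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)

        stage = "association"
        if config.run_association:
            bc_map = simulate.make_barcodes(list(man["seq_id"]), sim)
            reads = simulate.simulate_association_reads(
                bc_map, sim,
                ambiguous_fraction=config.ambiguous_fraction,
                shallow_fraction=config.shallow_fraction,
            )
            reads.to_csv(out / "association_reads.tsv", sep="\t", index=False)
            assignments, assoc_summary = assoc.assign_barcodes(
                reads, min_umis=config.min_umis, min_frac=config.min_frac
            )
            assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
            (out / "association_summary.json").write_text(
                json.dumps(assoc_summary.to_dict(), indent=1)
            )
            summary["association"] = assoc_summary.to_dict()

            stage = "counts"
            raw = simulate.simulate_counts(truth, man, sim, barcode_map=bc_map)
            mpra_reads = raw.drop(columns="sequence_id")
            counts, class_stats = assoc.count_barcodes(mpra_reads, assignments)
            counts = assoc.filter_counts(counts)
            counts.to_csv(out / "counts.tsv", sep="\t", index=False)
            class_stats.to_csv(out / "barcode_classes.tsv", sep="\t", index=False)
        else:
            raw = simulate.simulate_counts(truth, man, sim)
            counts = assoc.filter_counts(raw)
            counts.to_csv(out / "counts.tsv", sep="\t", index=False)

        if config.run_quantify or config.run_frs:
            stage = "quantify"
            size_factors = compute_size_factors(counts)
            size_factors.to_csv(out / "size_factors.tsv", sep="\t", index=False)
            tests = frs.run_comparisons(counts, man, size_factors)
            tests["alpha"].to_csv(out / "alpha.tsv", sep="\t", index=False)
            for key in (
                "per_tp_pert_wt", "temporal_pert_wt", "temporal_pert_scram",
                "temporal_wt_scram",
            ):
                tests[key].to_csv(out / f"test_{key}.tsv", sep="\t", index=False)

        if config.run_frs:
            stage = "frs"
            filt = frs.apply_filters(
                tests, man, nof_timepoints=sim.n_timepoints, fdr=config.fdr_threshold
            )
            filt.to_csv(out / "filters.tsv", sep="\t", index=False)
            calls = frs.consensus_frs(filt, man)
            calls = frs.categorize(
                calls, tests, nof_timepoints=sim.n_timepoints,
                fdr=config.fdr_threshold,
            )
            calls.to_csv(out / "frs.tsv", sep="\t", index=False)
            summary["frs"] = {
                "n_instances_tested": int(filt["instance_id"].nunique()),
                "n_frs": len(calls),
                "by_direction": calls["direction"].value_counts().to_dict(),
                "by_sub_category": calls["sub_category"].value_counts().to_dict()
                if len(calls)
                else {},
            }

        if config.run_pairs and pair_list:
            stage = "pairs"
            pair_tests = interaction.test_pairs(counts, man, size_factors)
            pair_tests.to_csv(out / "pair_tests.tsv", sep="\t", index=False)
            pair_calls = interaction.classify_pairs(
                pair_tests, filt, gamma_min=config.gamma_min,
                fdr=config.fdr_threshold,
            )
            pair_calls.to_csv(out / "pairs.tsv", sep="\t", index=False)
            summary["pairs"] = pair_calls["label"].value_counts().to_dict()
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary


def _choose_pairs(sel_edges, hits, n_pairs: int) -> list[tuple[str, str]]:
    """Deterministic double-perturbation pairs: regions with >= 2
    selected instances whose hit windows do not overlap."""
    if n_pairs <= 0:
        return []
    win = hits.groupby(["region_id", "motif_id"]).agg(
        start=("start", "min"), end=("end", "max")
    )
    pairs = []
    for r, sub in sel_edges.groupby("region"):
        motifs = sorted(sub["motif"])
        for a, b in zip(motifs, motifs[1:]):
            if (r, a) not in win.index or (r, b) not in win.index:
                continue
            wa, wb = win.loc[(r, a)], win.loc[(r, b)]
            if wa["end"] <= wb["start"] or wb["end"] <= wa["start"]:
                pairs.append((f"{r}|{a}", f"{r}|{b}"))
                break
        if len(pairs) >= n_pairs:
            break
    return pairs


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema checks on pipeline input tables; returns itemized issues.

    Recognized keys: hits, counts, association, fasta, barcode_length.
    Coordinates are asserted 0-based half-open with end > start.
    """
    issues: list[str] = []
    if "fasta" in paths:
        seqs = {}
        name = None
        for line in Path(paths["fasta"]).read_text().splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name:
                seqs[name] += line.strip()
        bad = [n for n, s in seqs.items() if set(s) - set("ACGTN")]
        if bad:
            issues.append(f"fasta: non-DNA characters in {bad[:3]}")
        paths = dict(paths)
        paths["_seqs"] = seqs
    if "hits" in paths:
        hits = pd.read_csv(paths["hits"], sep="\t")
        need = {"region_id", "motif_id", "start", "end", "strand"}
        if not need <= set(hits.columns):
            issues.append(f"hits: missing columns {sorted(need - set(hits.columns))}")
        else:
            if (hits["end"] <= hits["start"]).any():
                issues.append("hits: rows with end <= start (must be half-open)")
            if not hits["strand"].isin(["+", "-"]).all():
                issues.append("hits: strand must be + or -")
            seqs = paths.get("_seqs")
            if seqs:
                over = [
                    h.region_id
                    for h in hits.itertuples()
                    if h.region_id in seqs and h.end > len(seqs[h.region_id])
                ]
                if over:
                    issues.append(f"hits: out of region bounds in {over[:3]}")
    if "counts" in paths:
        counts = pd.read_csv(paths["counts"], sep="\t")
        need = {"barcode", "sequence_id", "timepoint", "replicate", "dna", "rna"}
        if not need <= set(counts.columns):
            issues.append(
                f"counts: missing columns {sorted(need - set(counts.columns))}"
            )
        elif (counts[["dna", "rna"]] < 0).any().any():
            issues.append("counts: negative counts")
        bl = paths.get("barcode_length")
        if bl and "barcode" in counts.columns:
            wrong = (counts["barcode"].str.len() != int(bl)).sum()
            if wrong:
                issues.append(
                    f"counts: {wrong} barcodes with length != {bl} (warning)"
                )
    if "association" in paths:
        reads = pd.read_csv(paths["association"], sep="\t")
        need = {"barcode", "sequence_id", "umi_count"}
        if not need <= set(reads.columns):
            issues.append(
                f"association: missing columns {sorted(need - set(reads.columns))}"
            )
    return issues
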