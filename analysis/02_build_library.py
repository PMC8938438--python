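"""Construct the oligo library for the selected instances.

Re-derives region sequences with planted motif hits, screens
dinucleotide-matched candidates for the two non-motif replacement
sequences, and assembles WT / SCRAM / RAND / PERT constructs (three
perturbation methods, single and double perturbations).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, study_config

from perturbmpra import seqlib, simulate
from perturbmpra.graph import TripartiteGraph
from perturbmpra.pipeline import _choose_pairs, _write_fasta
from perturbmpra.pwm import PWMScanner


def main():
    cfg = study_config()
    graph = TripartiteGraph.from_dir(RESULTS / "graph")
    sel_edges = pd.read_csv(RESULTS / "selection.tsv", sep="\t")
    seqs, hits, pwms = simulate.generate_sequences(graph, cfg.sim)
    hits.to_csv(RESULTS / "hits.tsv", sep="\t", index=False)
    _write_fasta(seqs, RESULTS / "regions.fasta")
    print(f"{len(seqs)} regions of {cfg.sim.region_length} bp, {len(hits)} planted hits")

    scanner = PWMScanner(pwms)
    contexts = [
        (seqs[h.region_id], int(h.start), int(h.end))
        for h in hits.head(6).itertuples()
    ]
    nonmotif = seqlib.derive_nonmotif_sequences(
        [seqs[r] for r in graph.regions], scanner, contexts,
        n_candidates=100, seed=cfg.seed,
    )
    print(f"non-motif replacements: {nonmotif[0]} / {nonmotif[1]}")

    pair_list = _choose_pairs(sel_edges, hits, cfg.n_pairs)
    library, log = seqlib.build_library(
        sel_edges, seqs, hits, nonmotif, cfg.sim, seed=cfg.seed,
        pair_list=pair_list, rand_window=cfg.rand_window,
    )
    man = seqlib.manifest(library)
    man.to_csv(RESULTS / "library.tsv", sep="\t", index=False)
    seqlib.write_fasta(library, RESULTS / "library.fasta")
    by_cat = man["category"].value_counts().to_dict()
    print(f"library: {len(man)} constructs {by_cat}; "
          f"{len(pair_list)} double-perturbation pairs; discarded: {log or 'none'}")


if __name__ == "__main__":
    main()
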