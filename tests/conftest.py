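"""Shared fixtures: tiny graphs, configs and count simulators.

The count simulators here are written directly against the generative
model (gamma latent abundance, gamma DNA measurement, NB RNA) and do
not go through the package's synthetic module, so calibration tests
are not circular.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from perturbmpra.config import SimConfig
from perturbmpra.graph import TripartiteGraph


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(
        n_regions=16,
        n_motifs=14,
        n_properties=2,
        seed=5,
        barcodes_per_sequence=15,
        broad_deg_range=(5, 9),
        prop_motif_frac=0.9,
        prop_region_frac=0.9,
    )


def toy_graph(
    n_regions: int,
    n_motifs: int,
    edges: list[tuple[int, int]],
    lowconf: set[tuple[int, int]] = frozenset(),
    groups: dict[int, str] | None = None,
    hand_picked: set[str] = frozenset(),
    properties: int = 0,
    prop_edges=None,
) -> TripartiteGraph:
    """Hand-built tripartite graph from integer indices."""
    regions = [f"r{i}" for i in range(n_regions)]
    motifs = [f"t{i}" for i in range(n_motifs)]
    props = [f"p{i}" for i in range(properties)]
    inst = pd.DataFrame(
        [(motifs[t], regions[r], (t, r) in lowconf) for t, r in edges],
        columns=["motif", "region", "low_confidence"],
    )
    mp, rp = [], []
    if prop_edges:
        for p, layer, i in prop_edges:
            if layer == "motif":
                mp.append((motifs[i], props[p]))
            else:
                rp.append((regions[i], props[p]))
    tf_group = {t: groups.get(i, f"g{i}") if groups else f"g{i}"
                for i, t in enumerate(motifs)}
    return TripartiteGraph(
        regions=regions,
        motifs=motifs,
        properties=props,
        instance_edges=inst,
        motif_prop_edges=pd.DataFrame(mp, columns=["motif", "property"]),
        region_prop_edges=pd.DataFrame(rp, columns=["region", "property"]),
        tf_group=tf_group,
        hand_picked=set(hand_picked),
    )


def simulate_two_groups(
    seed: int,
    log_fc: float = 0.0,
    n_bc: int = 30,
    n_tp: int = 1,
    n_rep: int = 3,
    alpha: float = 2.0,
    disp: float = 0.1,
    profile: np.ndarray | None = None,
) -> pd.DataFrame:
    """Counts for two constructs A (test) and B (reference).

    A's rate is B's times exp(log_fc) (optionally per-timepoint via
    ``profile``); each barcode has a latent gamma abundance measured by
    gamma DNA reads; RNA is NB around alpha * latent.
    """
    rng = np.random.default_rng(seed)
    eff = np.full(n_tp, log_fc) if profile is None else np.asarray(profile)
    rows = []
    for sid, shift in (("A", eff), ("B", np.zeros(n_tp))):
        latent = rng.gamma(4, 25, size=n_bc)
        for b in range(n_bc):
            for t in range(n_tp):
                mu = alpha * np.exp(shift[t]) * latent[b]
                for rep in range(n_rep):
                    d = int(round(rng.gamma(100, latent[b] / 100)))
                    y = rng.negative_binomial(1 / disp, (1 / disp) / (1 / disp + mu))
                    rows.append((f"{sid}{b}", sid, t, rep, d, y))
    return pd.DataFrame(
        rows, columns=["barcode", "sequence_id", "timepoint", "replicate", "dna", "rna"]
    )


def mini_study(
    config: SimConfig,
    category_mix: dict[str, float] | None = None,
    n_pairs: int = 0,
    nonadditive_frac: float = 0.5,
):
    """Small end-to-end synthetic study via the package generator.

    Returns (manifest, filtered counts, truth, size factors).
    """
    from perturbmpra import assoc, seqlib, simulate
    from perturbmpra.design import build_ilp, solve_design
    from perturbmpra.pipeline import _choose_pairs
    from perturbmpra.quantify import compute_size_factors

    graph = simulate.generate_graph(config)
    selection = solve_design(build_ilp(graph))
    seqs, hits, pwms = simulate.generate_sequences(graph, config)
    nonmotif = ("ACGTACGTACGTACGTACGT", "TTGGCCAATTGGCCAATTGG")
    pair_list = _choose_pairs(selection.edges, hits, n_pairs)
    library, _ = seqlib.build_library(
        selection.edges, seqs, hits, nonmotif, config, seed=config.seed,
        pair_list=pair_list,
    )
    man = seqlib.manifest(library)
    usable = set(
        man.loc[man["category"] == "PERT", "perturbed_instances"]
        .str.split(";").explode()
    )
    sel_usable = selection.edges[
        (selection.edges["region"] + "|" + selection.edges["motif"]).isin(usable)
    ]
    truth = simulate.plant_truth(hits, config, category_mix, selected=sel_usable)
    if pair_list:
        truth.pairs = simulate.plant_pair_truth(
            pair_list, config, nonadditive_frac=nonadditive_frac
        )
    counts = assoc.filter_counts(simulate.simulate_counts(truth, man, config))
    return man, counts, truth, compute_size_factors(counts)


def simulate_quartet(
    seed: int,
    gamma: float = 0.0,
    e1: float = -0.7,
    e2: float = -0.4,
    n_bc: int = 15,
    n_tp: int = 7,
    disp: float = 0.1,
    ids=("WT", "P1", "P2", "P12"),
) -> pd.DataFrame:
    """Counts for a double-perturbation quartet with interaction gamma."""
    rng = np.random.default_rng(seed)
    base = 3.0 * np.exp(np.sin(np.linspace(0, 2, n_tp)))
    eff = dict(zip(ids, [0.0, e1, e2, e1 + e2 + gamma]))
    rows = []
    for sid, e in eff.items():
        latent = rng.gamma(4, 25, size=n_bc)
        for b in range(n_bc):
            for t in range(n_tp):
                mu = base[t] * np.exp(e) * latent[b]
                for rep in range(3):
                    d = int(round(rng.gamma(100, latent[b] / 100)))
                    y = rng.negative_binomial(1 / disp, (1 / disp) / (1 / disp + mu))
                    rows.append((f"{sid}{b}", sid, t, rep, d, y))
    return pd.DataFrame(
        rows, columns=["barcode", "sequence_id", "timepoint", "replicate", "dna", "rna"]
    )
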