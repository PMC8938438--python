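"""Shared study configuration for the numbered analysis drivers.

One demo-scale synthetic study threads through scripts 01-06: the same
master seed and SimConfig reproduce every stage deterministically, so
each script can re-derive upstream state or read it from results/run.
"""

from pathlib import Path

from perturbmpra.config import RunConfig, SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "run"

SEED = 20


def study_config() -> RunConfig:
    sim = SimConfig(
        n_regions=18,
        n_motifs=14,
        n_properties=2,
        seed=SEED,
        barcodes_per_sequence=25,
        dup_hit_frac=0.15,
        broad_deg_range=(5, 9),
        prop_motif_frac=0.9,
        prop_region_frac=0.9,
    )
    return RunConfig(sim=sim, out_dir=str(RESULTS), seed=SEED, n_pairs=5)
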