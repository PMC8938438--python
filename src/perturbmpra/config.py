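"""Configuration objects for simulation and pipeline runs.

`SimConfig` describes the synthetic assay: a tripartite design graph
(regions x motifs x biological properties), 171-bp candidate regulatory
regions carrying planted transcription-factor motif hits, 15-nt reporter
barcodes, and count data over a differentiation time course (7 timepoints
x 3 replicates by default). DNA barcode abundances are gamma distributed;
RNA counts are negative binomial around alpha * DNA.

All configs serialize losslessly to/from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

#: temporal shapes used for planted wild-type activity profiles
TEMPORAL_BASIS = ("flat", "early-peak", "late-peak", "transient")


@dataclass
class SimConfig:
    """Parameters of the synthetic perturbation-MPRA study.

    The defaults mirror the assayed geometry: 171-bp regions, 15-bp
    barcodes, seven timepoints of neural differentiation and three
    infection replicates.
    """

    n_regions: int = 30
    n_motifs: int = 15
    n_properties: int = 3
    region_length: int = 171
    barcode_length: int = 15
    n_timepoints: int = 7
    n_replicates: int = 3
    barcodes_per_sequence: int = 30
    # latent per-barcode construct abundance: Gamma(shape, scale);
    # observed DNA reads are a gamma measurement of it (rounded)
    dna_shape: float = 4.0
    dna_scale: float = 25.0
    dna_meas_shape: float = 100.0
    # RNA counts: NB with variance mu + dispersion * mu^2
    rna_dispersion: float = 0.1
    # per-category |log fold effect| ranges used when planting ground truth
    effect_grid: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "essential": (1.0, 2.5),
            "contributing": (0.7, 1.5),
            "inhibiting": (0.7, 1.5),
            "silencing": (1.0, 2.0),
        }
    )
    # graph density knobs (defaults tuned so that paper-scale node counts
    # reproduce paper-scale edge totals; see synthetic module docs)
    broad_motif_frac: float = 0.7
    broad_deg_range: tuple[int, int] = (5, 24)
    sparse_deg_range: tuple[int, int] = (1, 4)
    prop_motif_frac: float = 0.12
    prop_region_frac: float = 0.08
    lowconf_frac: float = 0.10
    paired_group_frac: float = 0.5
    hand_picked_frac: float = 0.1
    # fraction of instance edges realized as two same-motif hits, and of
    # those, the share planted as an exact +/- palindromic duplicate
    dup_hit_frac: float = 0.0
    palindrome_frac: float = 0.5
    min_motif_len: int = 7
    max_motif_len: int = 12
    scram_alpha: float = 0.5
    wt_alpha_range: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_regions",
            "n_motifs",
            "region_length",
            "barcode_length",
            "n_timepoints",
            "n_replicates",
            "barcodes_per_sequence",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_properties < 0:
            raise ValueError("n_properties must be >= 0")
        if self.region_length < self.max_motif_len + 6:
            raise ValueError(
                "region_length must be at least max_motif_len + 6 "
                f"({self.max_motif_len + 6}), got {self.region_length}"
            )
        if self.rna_dispersion <= 0:
            raise ValueError("rna_dispersion must be > 0")
        if self.dna_shape <= 0 or self.dna_scale <= 0:
            raise ValueError("gamma parameters must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        kwargs = dict(data)
        for key in ("broad_deg_range", "sparse_deg_range", "wt_alpha_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "effect_grid" in kwargs and kwargs["effect_grid"] is not None:
            kwargs["effect_grid"] = {
                k: tuple(v) for k, v in kwargs["effect_grid"].items()
            }
        return cls(**kwargs)


@dataclass
class RunConfig:
    """End-to-end pipeline run: stage toggles, module parameters, paths."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "run"
    seed: int = 0
    # stage toggles
    run_design: bool = True
    run_library: bool = True
    run_association: bool = True
    run_quantify: bool = True
    run_frs: bool = True
    run_pairs: bool = True
    # module parameters
    min_umis: int = 3
    min_frac: float = 0.8
    fdr_threshold: float = 0.05
    rand_window: int = 12
    gamma_min: float = 0.5
    n_pairs: int = 0
    ambiguous_fraction: float = 0.15
    shallow_fraction: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(_plain(data), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = SimConfig.from_dict(data.pop("sim"))
        return cls(sim=sim, **data)


def _plain(obj: Any) -> Any:
    """Recursively convert tuples to lists so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
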