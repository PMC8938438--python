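"""Synthetic perturbation-MPRA study with planted ground truth.

Generates every input the downstream stages consume: a feasible
tripartite design graph, region sequences with planted motif hits,
barcode-association read tables, and DNA/RNA count matrices over the
time course — all seeded, with known per-instance effect directions,
sub-categories and pairwise interaction coefficients, so that each
analysis stage can be validated end to end.

Count model: DNA barcode abundances are Gamma(shape, scale) rounded to
integer reads; RNA counts are negative binomial with mean
``alpha * DNA * size_factor`` where alpha is the latent transcription
rate of the construct. Perturbed constructs scale the wild-type alpha by
the planted per-timepoint effect; scrambled controls sit at a flat
baseline.

Each stage draws from its own RNG stream derived from the master seed,
so stages can be re-run independently without perturbing one another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig, TEMPORAL_BASIS
from .graph import TripartiteGraph
from .pwm import PWM, BASES, random_pwm, revcomp

_STAGE_IDS = {
    "graph": 1,
    "motifs": 2,
    "sequences": 3,
    "truth": 4,
    "barcodes": 5,
    "association": 6,
    "counts": 7,
    "library": 8,
    "pairs": 9,
}

MAIN_CATEGORIES = ("activating", "dampening", "null")
SUB_CATEGORIES = ("essential", "contributing", "silencing", "inhibiting", "none")

#: default planted category mix over motif instances
DEFAULT_CATEGORY_MIX = {
    "essential": 0.20,
    "contributing": 0.35,
    "inhibiting": 0.15,
    "silencing": 0.10,
    "null": 0.20,
}


class GraphInfeasibleError(ValueError):
    """Parameter combination cannot produce an ILP-feasible graph."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for a named pipeline stage."""
    return np.random.default_rng([_STAGE_IDS[stage], int(seed)])


# ---------------------------------------------------------------------------
# graph generation
# ---------------------------------------------------------------------------

def generate_graph(config: SimConfig) -> TripartiteGraph:
    """Generate a design graph that is feasible for the selection ILP.

    Feasibility is guaranteed by construction via an all-selected
    certificate: TF groups have at most two motifs, every property is
    connected to at least 12 motifs and min(17, degree) regions, at most
    a fifth of instance edges are low-confidence, and at least 60% of
    motifs are broad (connected to >= 5 regions).
    """
    rng = stage_rng(config.seed, "graph")
    nR, nT, nP = config.n_regions, config.n_motifs, config.n_properties
    if nP > 0 and nT < 12:
        raise GraphInfeasibleError(
            f"each property must reach >= 12 motifs but n_motifs={nT} < 12"
        )
    n_broad = int(np.ceil(config.broad_motif_frac * nT))
    if nT > 0 and n_broad / nT < 0.6:
        raise GraphInfeasibleError(
            "broad_motif_frac must place >= 60% of motifs in the broad set "
            f"(got {n_broad}/{nT})"
        )
    lo_b, hi_b = config.broad_deg_range
    if lo_b < 5:
        raise GraphInfeasibleError("broad motifs need degree >= 5")
    if nR < lo_b:
        raise GraphInfeasibleError(
            f"n_regions={nR} cannot support broad motif degree >= {lo_b}"
        )

    regions = [f"R{i:04d}" for i in range(nR)]
    motifs = [f"M{i:04d}" for i in range(nT)]
    properties = [f"P{i:02d}" for i in range(nP)]

    broad_set = set(rng.choice(nT, size=n_broad, replace=False).tolist())
    lo_s, hi_s = config.sparse_deg_range
    edges = []
    for i, t in enumerate(motifs):
        if i in broad_set:
            deg = int(rng.integers(lo_b, min(hi_b, nR) + 1))
        else:
            deg = int(rng.integers(lo_s, min(hi_s, nR) + 1))
        for r_i in rng.choice(nR, size=deg, replace=False):
            edges.append((t, regions[r_i]))
    inst = pd.DataFrame(edges, columns=["motif", "region"])
    flags = rng.random(len(inst)) < config.lowconf_frac
    # hard cap: low-confidence edges can be at most a fifth of the total,
    # so the all-selected certificate satisfies the edge-confidence family
    cap = len(inst) // 5
    if flags.sum() > cap:
        on = np.nonzero(flags)[0]
        drop = rng.choice(on, size=flags.sum() - cap, replace=False)
        flags[drop] = False
    inst["low_confidence"] = flags

    # TF groups of size <= 2 (pairs for a configurable fraction of motifs)
    order = rng.permutation(nT)
    n_pairs = int(config.paired_group_frac * nT / 2)
    tf_group: dict[str, str] = {}
    g = 0
    k = 0
    for _ in range(n_pairs):
        tf_group[motifs[order[k]]] = f"TF{g:04d}"
        tf_group[motifs[order[k + 1]]] = f"TF{g:04d}"
        g += 1
        k += 2
    while k < nT:
        tf_group[motifs[order[k]]] = f"TF{g:04d}"
        g += 1
        k += 1
    groups = sorted(set(tf_group.values()))
    n_hand = max(1, int(config.hand_picked_frac * len(groups))) if groups else 0
    hand_picked = set(
        rng.choice(groups, size=min(n_hand, len(groups)), replace=False).tolist()
    )

    mp_rows, rp_rows = [], []
    if nP:
        k_m = max(12, int(round(config.prop_motif_frac * nT)))
        k_r = max(min(17, nR), int(round(config.prop_region_frac * nR)))
        for p in properties:
            for t_i in rng.choice(nT, size=min(k_m, nT), replace=False):
                mp_rows.append((motifs[t_i], p))
            for r_i in rng.choice(nR, size=min(k_r, nR), replace=False):
                rp_rows.append((regions[r_i], p))

    return TripartiteGraph(
        regions=regions,
        motifs=motifs,
        properties=properties,
        instance_edges=inst,
        motif_prop_edges=pd.DataFrame(mp_rows, columns=["motif", "property"]),
        region_prop_edges=pd.DataFrame(rp_rows, columns=["region", "property"]),
        tf_group=tf_group,
        hand_picked=hand_picked,
    )


# ---------------------------------------------------------------------------
# sequences and motif hits
# ---------------------------------------------------------------------------

def generate_motifs(graph: TripartiteGraph, config: SimConfig) -> dict[str, PWM]:
    rng = stage_rng(config.seed, "motifs")
    out = {}
    for t in graph.motifs:
        length = int(rng.integers(config.min_motif_len, config.max_motif_len + 1))
        out[t] = random_pwm(t, length, rng)
    return out


def generate_sequences(
    graph: TripartiteGraph,
    config: SimConfig,
    pwms: dict[str, PWM] | None = None,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, PWM]]:
    """Region sequences with each instance edge realized as a planted hit.

    Returns (sequences, hit table, PWM set). Hits are 0-based half-open;
    minus-strand hits carry the reverse complement of the motif
    consensus on the forward strand. A configurable fraction of edges is
    planted twice (same motif, second site), and of those a fraction is
    reported as an exact +/- duplicate at one site, emulating
    palindromic double reporting.
    """
    pwms = pwms or generate_motifs(graph, config)
    for t, pwm in pwms.items():
        if len(pwm) > config.region_length:
            raise ValueError(
                f"motif {t} (len {len(pwm)}) longer than region "
                f"({config.region_length} bp)"
            )
    rng = stage_rng(config.seed, "sequences")
    L = config.region_length
    seqs: dict[str, str] = {}
    hit_rows = []
    by_region = graph.instance_edges.groupby("region")["motif"]
    region_motifs = {r: list(g) for r, g in by_region}
    for r in graph.regions:
        seq = list(rng.choice(list(BASES), size=L))
        occupied: list[tuple[int, int]] = []
        for t in region_motifs.get(r, []):
            n_sites = 1
            palindrome = False
            if rng.random() < config.dup_hit_frac:
                if rng.random() < config.palindrome_frac:
                    palindrome = True
                else:
                    n_sites = 2
            for _ in range(n_sites):
                pwm = pwms[t]
                start = _place(rng, L, len(pwm), occupied)
                if start is None:
                    raise ValueError(
                        f"region {r} too crowded to plant motif {t}; "
                        "reduce motif degree or lengthen regions"
                    )
                occupied.append((start, start + len(pwm)))
                strand = "+" if rng.random() < 0.5 else "-"
                word = pwm.consensus if strand == "+" else revcomp(pwm.consensus)
                seq[start : start + len(pwm)] = list(word)
                hit_rows.append(
                    (r, t, start, start + len(pwm), strand, pwm.min_pvalue)
                )
                if palindrome:
                    # exact +/- duplicate: same site reported on both strands
                    other = "-" if strand == "+" else "+"
                    hit_rows.append(
                        (r, t, start, start + len(pwm), other, pwm.min_pvalue)
                    )
        seqs[r] = "".join(seq)
    hits = pd.DataFrame(
        hit_rows,
        columns=["region_id", "motif_id", "start", "end", "strand", "pvalue"],
    )
    return seqs, hits, pwms


def _place(rng, L, mlen, occupied, tries=200):
    """Random non-overlapping start for a length-mlen site, else None."""
    for _ in range(tries):
        s = int(rng.integers(0, L - mlen + 1))
        if all(s + mlen <= a or s >= b for a, b in occupied):
            return s
    # deterministic sweep fallback
    for s in range(L - mlen + 1):
        if all(s + mlen <= a or s >= b for a, b in occupied):
            return s
    return None


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted truth: per-instance effects and per-pair interactions.

    ``instances`` columns: instance_id, region_id, motif_id, direction,
    sub_category, and eff_t{k} = log(PERT alpha / WT alpha) at timepoint
    k. ``region_alpha`` columns: region_id plus alpha_t{k} wild-type
    rates. ``pairs`` columns: pair_id, instance1, instance2, gamma
    (log-scale interaction; 0 = additive).
    """

    instances: pd.DataFrame
    region_alpha: pd.DataFrame
    scram_alpha: float
    n_timepoints: int
    pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["pair_id", "instance1", "instance2", "gamma"]
        )
    )

    def __post_init__(self):
        inst = self.instances
        act = inst["sub_category"].isin(["essential", "contributing"])
        if not (inst.loc[act, "direction"] == "activating").all():
            raise ValueError("essential/contributing must be activating")
        damp = inst["sub_category"].isin(["silencing", "inhibiting"])
        if not (inst.loc[damp, "direction"] == "dampening").all():
            raise ValueError("silencing/inhibiting must be dampening")
        eff_cols = [c for c in inst.columns if c.startswith("eff_t")]
        null = inst["direction"] == "null"
        if null.any() and not np.allclose(
            inst.loc[null, eff_cols].to_numpy(float), 0.0
        ):
            raise ValueError("null instances must have all-zero effects")

    @property
    def eff_cols(self) -> list[str]:
        return [f"eff_t{k}" for k in range(self.n_timepoints)]

    @property
    def alpha_cols(self) -> list[str]:
        return [f"alpha_t{k}" for k in range(self.n_timepoints)]


def _temporal_profile(kind: str, ntp: int) -> np.ndarray:
    """Unit-peak temporal shape on a log scale."""
    t = np.linspace(0, 1, ntp)
    if kind == "flat":
        return np.ones(ntp)
    if kind == "early-peak":
        return np.exp(-((t - 0.15) ** 2) / 0.08)
    if kind == "late-peak":
        return np.exp(-((t - 0.85) ** 2) / 0.08)
    if kind == "transient":
        return np.exp(-((t - 0.5) ** 2) / 0.04)
    raise ValueError(f"unknown temporal profile {kind!r}")


def plant_truth(
    hits: pd.DataFrame,
    config: SimConfig,
    category_mix: dict[str, float] | None = None,
    selected: pd.DataFrame | None = None,
) -> GroundTruth:
    """Assign planted categories and effect sizes to motif instances.

    One instance per (region, motif) pair in ``hits`` (or in
    ``selected`` if given). Silencing instances are placed in dedicated
    regions whose wild-type activity sits at the scrambled baseline;
    all other regions receive a temporal activity profile drawn from
    the basis (flat, early-peak, late-peak, transient).
    """
    mix = dict(DEFAULT_CATEGORY_MIX if category_mix is None else category_mix)
    total = sum(mix.values())
    mix = {k: v / total for k, v in mix.items()}
    rng = stage_rng(config.seed, "truth")
    ntp = config.n_timepoints
    src = selected if selected is not None else hits
    if "region_id" not in src.columns:
        src = src.rename(columns={"region": "region_id", "motif": "motif_id"})
    inst = src[["region_id", "motif_id"]].drop_duplicates().reset_index(drop=True)

    cats = list(mix)
    draws = rng.choice(len(cats), size=len(inst), p=[mix[c] for c in cats])
    inst = inst.assign(cat=[cats[i] for i in draws])

    # silencing instances need their whole region at baseline; keep a
    # region either "silent" or "active" by majority of planted intent
    silent_regions = set()
    for r, sub in inst.groupby("region_id"):
        if (sub["cat"] == "silencing").any():
            silent_regions.add(r)
    # in silent regions, re-label activating categories as silencing/null
    relabel = inst["region_id"].isin(silent_regions) & ~inst["cat"].isin(
        ["silencing", "null"]
    )
    inst.loc[relabel, "cat"] = "silencing"

    regions = sorted(set(inst["region_id"]))
    lo_a, hi_a = config.wt_alpha_range
    rows = []
    for r in regions:
        if r in silent_regions:
            # silenced wild type: the flat element of the profile basis,
            # pinned at the scrambled baseline
            alpha = np.full(ntp, config.scram_alpha)
        else:
            # active regions are, by the assay's inclusion criterion,
            # temporally active: draw from the dynamic profile shapes
            kind = TEMPORAL_BASIS[1 + int(rng.integers(0, len(TEMPORAL_BASIS) - 1))]
            peak = float(rng.uniform(lo_a, hi_a))
            shape = _temporal_profile(kind, ntp)
            # activity rises from ~baseline toward the peak along the shape
            alpha = config.scram_alpha * (peak / config.scram_alpha) ** shape
        rows.append([r] + list(alpha))
    region_alpha = pd.DataFrame(
        rows, columns=["region_id"] + [f"alpha_t{k}" for k in range(ntp)]
    )
    alpha_map = region_alpha.set_index("region_id")

    recs = []
    for i, row in inst.iterrows():
        cat = row["cat"]
        wt = alpha_map.loc[row["region_id"]].to_numpy(float)
        eff = np.zeros(ntp)
        if cat == "essential":
            eff = np.log(config.scram_alpha / wt)
            direction, sub = "activating", "essential"
        elif cat == "contributing":
            lo, hi = config.effect_grid["contributing"]
            e = rng.uniform(lo, hi)
            # partial loss: PERT shrinks toward (but stays above) the
            # scrambled baseline, so the effect scales with WT activity
            pert = config.scram_alpha + (wt - config.scram_alpha) * np.exp(-e)
            eff = np.log(pert / wt)
            direction, sub = "activating", "contributing"
        elif cat == "inhibiting":
            lo, hi = config.effect_grid["inhibiting"]
            eff = np.full(ntp, rng.uniform(lo, hi))
            direction, sub = "dampening", "inhibiting"
        elif cat == "silencing":
            # de-repression unmasks temporal activity: the perturbed
            # construct follows a (non-flat) activation profile above
            # the baseline the silenced wild type sits at
            lo, hi = config.effect_grid["silencing"]
            kind = TEMPORAL_BASIS[1 + int(rng.integers(0, len(TEMPORAL_BASIS) - 1))]
            shape = _temporal_profile(kind, ntp)
            eff = rng.uniform(lo, hi) * (0.35 + 0.65 * shape)
            direction, sub = "dampening", "silencing"
        else:
            direction, sub = "null", "none"
        recs.append(
            [f"{row['region_id']}|{row['motif_id']}", row["region_id"], row["motif_id"], direction, sub]
            + list(eff)
        )
    instances = pd.DataFrame(
        recs,
        columns=["instance_id", "region_id", "motif_id", "direction", "sub_category"]
        + [f"eff_t{k}" for k in range(ntp)],
    )
    return GroundTruth(
        instances=instances,
        region_alpha=region_alpha,
        scram_alpha=config.scram_alpha,
        n_timepoints=ntp,
    )


def plant_pair_truth(
    pair_list: list[tuple[str, str]],
    config: SimConfig,
    nonadditive_frac: float = 0.5,
    gamma_range: tuple[float, float] = (0.8, 1.5),
) -> pd.DataFrame:
    """Planted interaction coefficients for double-perturbation pairs.

    A ``nonadditive_frac`` share of pairs receives a nonzero log-scale
    interaction gamma (random sign, magnitude in ``gamma_range``); the
    rest are exactly log-additive (gamma = 0).
    """
    rng = stage_rng(config.seed, "pairs")
    rows = []
    for k, (i1, i2) in enumerate(pair_list):
        if rng.random() < nonadditive_frac:
            gamma = float(
                rng.uniform(*gamma_range) * (1 if rng.random() < 0.5 else -1)
            )
        else:
            gamma = 0.0
        rows.append((f"{i1}+{i2}", i1, i2, gamma))
    return pd.DataFrame(rows, columns=["pair_id", "instance1", "instance2", "gamma"])


# ---------------------------------------------------------------------------
# barcodes, association reads, counts
# ---------------------------------------------------------------------------

def make_barcodes(
    sequence_ids: list[str], config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Unique random barcodes, ``barcodes_per_sequence`` per construct."""
    rng = rng if rng is not None else stage_rng(config.seed, "barcodes")
    n = len(sequence_ids) * config.barcodes_per_sequence
    seen: set[str] = set()
    codes: list[str] = []
    while len(codes) < n:
        block = rng.integers(0, 4, size=(n - len(codes), config.barcode_length))
        for row in block:
            bc = "".join(BASES[i] for i in row)
            if bc not in seen:
                seen.add(bc)
                codes.append(bc)
    return pd.DataFrame(
        {
            "barcode": codes,
            "sequence_id": np.repeat(sequence_ids, config.barcodes_per_sequence),
        }
    )


def simulate_association_reads(
    barcode_map: pd.DataFrame,
    config: SimConfig,
    ambiguous_fraction: float = 0.0,
    shallow_fraction: float = 0.0,
    mean_umis: float = 8.0,
) -> pd.DataFrame:
    """Association read table: (barcode, sequence_id, umi_count) rows.

    A configurable fraction of barcodes is made ambiguous (majority
    share below 80%) or shallow (winner supported by < 3 UMIs); the rest
    are cleanly assignable to their true construct.
    """
    rng = stage_rng(config.seed, "association")
    seq_ids = barcode_map["sequence_id"].unique()
    rows = []
    u = rng.random(len(barcode_map))
    for (bc, sid), x in zip(
        zip(barcode_map["barcode"], barcode_map["sequence_id"]), u
    ):
        if x < ambiguous_fraction:
            # 50-75% majority share: never assignable at the 80% rule
            total = int(rng.integers(8, 16))
            win = int(np.floor(total * rng.uniform(0.5, 0.75)))
            other = seq_ids[int(rng.integers(0, len(seq_ids)))]
            while other == sid and len(seq_ids) > 1:
                other = seq_ids[int(rng.integers(0, len(seq_ids)))]
            rows.append((bc, sid, max(win, 1)))
            rows.append((bc, other, max(total - win, 1)))
        elif x < ambiguous_fraction + shallow_fraction:
            rows.append((bc, sid, int(rng.integers(1, 3))))
        else:
            rows.append((bc, sid, 3 + int(rng.poisson(mean_umis - 3))))
    return pd.DataFrame(rows, columns=["barcode", "sequence_id", "umi_count"])


def sequence_alphas(
    truth: GroundTruth,
    library: pd.DataFrame,
    rand_effect: float = 0.0,
) -> pd.DataFrame:
    """Latent transcription rate per library construct and timepoint.

    ``library`` is a manifest with columns seq_id, category, parent_region
    and perturbed_instances (';'-joined instance ids, empty for WT/SCRAM).
    PERT alphas multiply the wild-type rate by each perturbed instance's
    planted effect, plus any planted pair interaction when both members
    of a pair are hit. SCRAM sits at the flat baseline; RAND tracks WT.
    """
    ntp = truth.n_timepoints
    alpha_map = truth.region_alpha.set_index("region_id")
    eff_map = truth.instances.set_index("instance_id")
    pair_lookup = {
        frozenset((p.instance1, p.instance2)): p.gamma
        for p in truth.pairs.itertuples()
    }
    rows = []
    for rec in library.itertuples():
        if rec.category == "SCRAM":
            alpha = np.full(ntp, truth.scram_alpha)
        else:
            alpha = alpha_map.loc[rec.parent_region].to_numpy(float).copy()
            if rec.category == "PERT":
                ids = [s for s in str(rec.perturbed_instances).split(";") if s]
                log_alpha = np.log(alpha)
                for iid in ids:
                    log_alpha += eff_map.loc[iid, truth.eff_cols].to_numpy(float)
                for a, b in itertools.combinations(ids, 2):
                    log_alpha += pair_lookup.get(frozenset((a, b)), 0.0)
                alpha = np.exp(log_alpha)
            elif rec.category == "RAND" and rand_effect:
                alpha = alpha * np.exp(rand_effect)
        rows.append([rec.seq_id] + list(alpha))
    return pd.DataFrame(rows, columns=["sequence_id"] + truth.alpha_cols)


def simulate_counts(
    truth: GroundTruth,
    library: pd.DataFrame,
    config: SimConfig,
    barcode_map: pd.DataFrame | None = None,
    rna_size_factor_sd: float = 0.15,
) -> pd.DataFrame:
    """DNA/RNA count matrix over barcodes x timepoints x replicates.

    Each barcode carries a latent construct abundance drawn once from
    Gamma(shape, scale); observed DNA reads per library are a rounded
    gamma measurement of it (shape ``dna_meas_shape``), and RNA counts
    are NB(mean = alpha * latent * size factor) with the configured
    dispersion. Zero-DNA barcodes can occur and survive into the table
    (the pairing filter handles them downstream).
    """
    rng = stage_rng(config.seed, "counts")
    if barcode_map is None:
        barcode_map = make_barcodes(list(library["seq_id"]), config)
    alphas = sequence_alphas(truth, library).set_index("sequence_id")
    ntp, nrep = config.n_timepoints, config.n_replicates
    sf_rna = np.exp(rng.normal(0.0, rna_size_factor_sd, size=(ntp, nrep)))
    disp = config.rna_dispersion
    nb_n = 1.0 / disp

    n_bc = len(barcode_map)
    latent = rng.gamma(config.dna_shape, config.dna_scale, size=n_bc)
    seq_alpha = alphas.loc[
        barcode_map["sequence_id"], [f"alpha_t{k}" for k in range(ntp)]
    ].to_numpy(float)  # (n_bc, ntp)
    frames = []
    for t in range(ntp):
        for rep in range(nrep):
            dna = np.round(
                rng.gamma(
                    config.dna_meas_shape, latent / config.dna_meas_shape
                )
            ).astype(int)
            mu = seq_alpha[:, t] * latent * sf_rna[t, rep]
            rna = np.zeros(n_bc, dtype=int)
            pos = mu > 0
            p = nb_n / (nb_n + mu[pos])
            rna[pos] = rng.negative_binomial(nb_n, p)
            frames.append(
                pd.DataFrame(
                    {
                        "barcode": barcode_map["barcode"].to_numpy(),
                        "sequence_id": barcode_map["sequence_id"].to_numpy(),
                        "timepoint": t,
                        "replicate": rep,
                        "dna": dna,
                        "rna": rna,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
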