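"""Oligo library construction: WT, SCRAM, RAND and perturbed variants.

Three perturbation methods disrupt a predicted motif site:

* methods 1 and 2 substitute the site with a length-matched prefix of
  one of two fixed "non-motif" sequences (dinucleotide-matched random
  sequences screened to create minimal scanner hits in context);
* method 3 shuffles the site's own nucleotides (seeded, re-drawn if the
  shuffle reproduces the original).

Controls: SCRAM shuffles the whole region (mononucleotide), RAND
perturbs a random 12-bp window (the median motif size) by each method.
Instances whose motif occurs twice as an exact +/- duplicate are
perturbed once on the plus strand (hit2); two distinct occurrences are
perturbed separately and jointly (hit2diff); three or more occurrences
are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .pwm import BASES, revcomp


@dataclass
class LibrarySequence:
    seq_id: str
    category: str  # WT | SCRAM | RAND | PERT
    method: int | None
    parent_region: str
    sequence: str
    design_class: str = ""  # hit1 | hit2 | hit2diff | double | ''
    perturbed_instances: list[str] = field(default_factory=list)
    #: (start, end, strand) windows that differ from WT
    perturbed_windows: list[tuple[int, int, str]] = field(default_factory=list)
    overlap: bool = False

    def __post_init__(self):
        if self.category in ("PERT", "RAND") and self.method not in (1, 2, 3):
            raise ValueError(f"{self.category} requires a perturbation method")
        if self.category in ("WT", "SCRAM") and self.method is not None:
            raise ValueError(f"{self.category} must not carry a method")


def manifest(library: list[LibrarySequence]) -> pd.DataFrame:
    rows = [
        (
            s.seq_id,
            s.category,
            0 if s.method is None else s.method,
            s.parent_region,
            s.design_class,
            ";".join(s.perturbed_instances),
            ",".join(f"{a}-{b}:{st}" for a, b, st in s.perturbed_windows),
            s.overlap,
            s.sequence,
        )
        for s in library
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "category", "method", "parent_region", "design_class",
            "perturbed_instances", "perturbed_windows", "overlap", "sequence",
        ],
    )


def write_fasta(library: list[LibrarySequence], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(
            Seq(s.sequence),
            id=s.seq_id,
            description=f"category={s.category} method={s.method or 0} region={s.parent_region}",
        )
        for s in library
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# non-motif replacement sequences
# ---------------------------------------------------------------------------

def dinucleotide_sequence(
    background: list[str], length: int, rng: np.random.Generator
) -> str:
    """Random sequence matching the background's dinucleotide frequencies
    (first-order Markov chain)."""
    counts = np.full((4, 4), 1e-9)
    idx = {b: i for i, b in enumerate(BASES)}
    start = np.full(4, 1e-9)
    for seq in background:
        if not seq:
            continue
        start[idx[seq[0]]] += 1
        for a, b in zip(seq, seq[1:]):
            counts[idx[a], idx[b]] += 1
    trans = counts / counts.sum(axis=1, keepdims=True)
    p0 = start / start.sum()
    out = [int(rng.choice(4, p=p0))]
    for _ in range(length - 1):
        out.append(int(rng.choice(4, p=trans[out[-1]])))
    return "".join(BASES[i] for i in out)


def derive_nonmotif_sequences(
    background: list[str],
    scanner,
    contexts: list[tuple[str, int, int]],
    n_candidates: int = 1000,
    seed: int = 0,
    length: int | None = None,
) -> tuple[str, str]:
    """Pick the two candidate replacement sequences creating fewest hits.

    Candidates of maximal motif length are drawn from a dinucleotide
    model of ``background``. Each is screened through ``scanner`` under
    two embeddings over the supplied motif contexts (region sequence,
    site start, site end): (1) the length-matched prefix between 3-bp
    WT flanks, (2) substituted into the full region. Candidates are
    ranked by hit count within each strategy and the two with the
    lowest median rank across strategies are returned (lowest candidate
    index breaks ties).
    """
    if not background:
        raise ValueError("background sequence set is empty")
    if not contexts:
        raise ValueError("need at least one motif context for screening")
    rng = np.random.default_rng(seed)
    if length is None:
        length = max(len(p) for p in getattr(scanner, "pwms", {}).values()) or 12
    cands = [dinucleotide_sequence(background, length, rng) for _ in range(n_candidates)]

    hits1 = np.zeros(n_candidates)
    hits2 = np.zeros(n_candidates)
    for i, cand in enumerate(cands):
        for seq, start, end in contexts:
            prefix = cand[: end - start]
            flanked = seq[max(start - 3, 0) : start] + prefix + seq[end : end + 3]
            hits1[i] += len(scanner(flanked))
            hits2[i] += len(scanner(seq[:start] + prefix + seq[end:]))
    from scipy.stats import rankdata

    r1 = rankdata(hits1, method="min")
    r2 = rankdata(hits2, method="min")
    med = np.median(np.stack([r1, r2]), axis=0)
    if not np.isfinite(med).any():
        raise ValueError("no candidate received a finite score")
    order = np.lexsort((np.arange(n_candidates), med))  # stable: index breaks ties
    return cands[order[0]], cands[order[1]]


# ---------------------------------------------------------------------------
# single-site perturbation
# ---------------------------------------------------------------------------

def perturb_site(
    region_seq: str,
    start: int,
    end: int,
    strand: str,
    method: int,
    nonmotif_pair: tuple[str, str],
    rng: np.random.Generator,
) -> str:
    """Replace or shuffle one motif window; the rest is untouched.

    Methods 1/2 insert the length-matched prefix of non-motif sequence
    1/2 (reverse-complemented for minus-strand hits, so the disrupted
    unit is the motif-bearing strand); method 3 re-shuffles the window's
    own nucleotides, re-drawn up to 100 times if identical to WT, then
    keeping the draw with maximal Hamming distance.
    """
    if not (0 <= start < end <= len(region_seq)):
        raise ValueError(f"hit [{start},{end}) outside region of length {len(region_seq)}")
    window = region_seq[start:end]
    if method in (1, 2):
        prefix = nonmotif_pair[method - 1][: end - start]
        if len(prefix) < end - start:
            raise ValueError("non-motif sequence shorter than the site")
        repl = prefix if strand == "+" else revcomp(prefix)
    elif method == 3:
        letters = list(window)
        best, best_d = None, -1
        for _ in range(100):
            perm = list(rng.permutation(letters))
            d = sum(a != b for a, b in zip(perm, window))
            if d > best_d:
                best, best_d = perm, d
            if d > 0 and "".join(perm) != window:
                best = perm
                break
        repl = "".join(best)
    else:
        raise ValueError(f"unknown perturbation method {method!r}")
    return region_seq[:start] + repl + region_seq[end:]


def scramble(seq: str, rng: np.random.Generator) -> str:
    """Full-sequence mononucleotide shuffle (redrawn if identity)."""
    for _ in range(100):
        s = "".join(rng.permutation(list(seq)))
        if s != seq:
            return s
    return s


# ---------------------------------------------------------------------------
# full library assembly
# ---------------------------------------------------------------------------

def build_library(
    selection,
    sequences: dict[str, str],
    hits: pd.DataFrame,
    nonmotif_pair: tuple[str, str],
    config: SimConfig,
    seed: int = 0,
    pair_list: list[tuple[str, str]] | None = None,
    rand_window: int = 12,
) -> tuple[list[LibrarySequence], list[str]]:
    """Assemble the full oligo set for a design selection.

    ``selection`` provides chosen (motif, region) instances (a
    DesignSelection or a DataFrame with motif/region columns);
    ``pair_list`` holds instance-id pairs for double perturbations.
    Returns (library, log) where log records discarded instances.
    """
    rng = np.random.default_rng(seed)
    sel_edges = selection if isinstance(selection, pd.DataFrame) else selection.edges
    log: list[str] = []
    library: list[LibrarySequence] = []

    regions = sorted(set(sel_edges["region"]))
    missing = [r for r in regions if r not in sequences]
    if missing:
        raise ValueError(f"no sequence for selected regions {missing[:5]}")

    hit_key = hits.groupby(["region_id", "motif_id"])

    for r in regions:
        wt = sequences[r]
        library.append(LibrarySequence(f"{r}|WT", "WT", None, r, wt))
        library.append(LibrarySequence(f"{r}|SCRAM", "SCRAM", None, r, scramble(wt, rng)))
        w = min(rand_window, len(wt))
        rstart = int(rng.integers(0, len(wt) - w + 1))
        for m in (1, 2, 3):
            library.append(
                LibrarySequence(
                    f"{r}|RAND|m{m}", "RAND", m, r,
                    perturb_site(wt, rstart, rstart + w, "+", m, nonmotif_pair, rng),
                    perturbed_windows=[(rstart, rstart + w, "+")],
                )
            )

    for rec in sel_edges.itertuples():
        t, r = rec.motif, rec.region
        try:
            sites = hit_key.get_group((r, t)).sort_values(["start", "strand"])
        except KeyError:
            raise ValueError(f"selected instance ({t}, {r}) has no motif hit") from None
        wt = sequences[r]
        iid = f"{r}|{t}"
        windows = list(zip(sites["start"], sites["end"], sites["strand"]))
        distinct = sorted({(a, b) for a, b, _ in windows})
        if len(windows) == 1:
            design_class, to_perturb = "hit1", [windows]
        elif len(windows) == 2 and len(distinct) == 1:
            # exact +/- duplicate: perturb the plus strand once
            plus = [w for w in windows if w[2] == "+"] or windows[:1]
            design_class, to_perturb = "hit2", [plus[:1]]
        elif len(windows) == 2:
            both = sorted(windows)  # left-to-right, plus strand first on ties
            design_class = "hit2diff"
            to_perturb = [[both[0]], [both[1]], both]
        else:
            log.append(f"discarded {iid}: {len(windows)} same-motif hits")
            continue
        for k, group in enumerate(to_perturb):
            label = (
                iid
                if design_class in ("hit1", "hit2")
                else f"{iid}|site{k}" if len(group) == 1 else f"{iid}|both"
            )
            for m in (1, 2, 3):
                seq = wt
                for a, b, st in sorted(group):
                    seq = perturb_site(seq, a, b, st, m, nonmotif_pair, rng)
                library.append(
                    LibrarySequence(
                        f"{label}|m{m}", "PERT", m, r, seq,
                        design_class=design_class,
                        perturbed_instances=[iid],
                        perturbed_windows=sorted(group),
                    )
                )

    if pair_list:
        prim = {
            (ls.perturbed_instances[0], ls.method): ls
            for ls in library
            if ls.category == "PERT" and len(ls.perturbed_instances) == 1
            and (ls.design_class != "hit2diff" or ls.seq_id.split("|")[-2] == "both")
        }
        for i1, i2 in pair_list:
            r1, r2 = i1.rsplit("|", 1)[0], i2.rsplit("|", 1)[0]
            if r1 != r2:
                raise ValueError(f"pair ({i1}, {i2}) spans two regions")
            wt = sequences[r1]
            for m in (1, 2, 3):
                w1 = prim[(i1, m)].perturbed_windows
                w2 = prim[(i2, m)].perturbed_windows
                wins = sorted(w1 + w2)
                overlap = any(
                    b1 > a2 for (_, b1, _), (a2, _, _) in zip(wins, wins[1:])
                )
                seq = wt
                for a, b, st in wins:  # left-to-right on overlap
                    seq = perturb_site(seq, a, b, st, m, nonmotif_pair, rng)
                library.append(
                    LibrarySequence(
                        f"{r1}|{i1.split('|')[1]}+{i2.split('|')[1]}|m{m}",
                        "PERT", m, r1, seq,
                        design_class="double",
                        perturbed_instances=[i1, i2],
                        perturbed_windows=wins,
                        overlap=overlap,
                    )
                )
    return library, log
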