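"""Minimal position-weight-matrix scanner with exact score p-values.

Stands in for a full motif-scanning suite: log-odds scoring of both
strands against a 0-order background, with p-values computed from the
exact distribution of integer-discretized scores under the background
(the standard dynamic-programming construction). Any callable with the
same signature as :meth:`PWMScanner.__call__` can be plugged in wherever
a scanner is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: number of integer score bins used for the exact null distribution
SCORE_BINS = 4096


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; non-ACGT become A (scored flat)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.zeros(arr.size, dtype=np.int8)
    for b, i in _IDX.items():
        out[arr == ord(b)] = i
    return out


@dataclass(frozen=True)
class PWM:
    motif_id: str
    probs: np.ndarray  # (L, 4) position probabilities, columns A C G T
    background: np.ndarray = None  # (4,)

    def __post_init__(self):
        if self.background is None:
            object.__setattr__(self, "background", np.full(4, 0.25))
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @cached_property
    def _log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(np.maximum(self.probs, 1e-9) / self.background)

    @cached_property
    def _int_scores(self) -> tuple[np.ndarray, float, float]:
        """Per-position scores on an integer grid: (ints, scale, offset)."""
        lo = self._log_odds
        smin = lo.min(axis=1).sum()
        smax = lo.max(axis=1).sum()
        span = max(smax - smin, 1e-9)
        scale = (SCORE_BINS - 1) / span
        ints = np.round((lo - lo.min(axis=1, keepdims=True)) * scale).astype(int)
        return ints, scale, smin

    @cached_property
    def _null_sf(self) -> np.ndarray:
        """P(integer score >= s) under the background, exact by DP."""
        ints, _, _ = self._int_scores
        dist = np.array([1.0])
        for i in range(len(self)):
            width = ints[i].max() + 1
            new = np.zeros(dist.size + width - 1)
            for b in range(4):
                new[ints[i, b] : ints[i, b] + dist.size] += (
                    self.background[b] * dist
                )
            dist = new
        sf = np.cumsum(dist[::-1])[::-1]
        return np.minimum(sf, 1.0)

    def score_int(self, window: np.ndarray) -> int:
        """Integer-grid log-odds score of an encoded window (+ strand)."""
        ints, _, _ = self._int_scores
        return int(ints[np.arange(len(self)), window].sum())

    def pvalue_of_int(self, s: int) -> float:
        sf = self._null_sf
        return float(sf[min(s, sf.size - 1)])

    @property
    def min_pvalue(self) -> float:
        """p-value of a consensus (maximal-score) match."""
        ints, _, _ = self._int_scores
        return self.pvalue_of_int(int(ints.max(axis=1).sum()))


class PWMScanner:
    """Scan sequences for hits of a motif collection on both strands.

    Calling the scanner on a sequence returns a hit table with 0-based
    half-open coordinates: columns motif_id, start, end, strand, score,
    pvalue, rows with ``pvalue < threshold`` only.
    """

    def __init__(self, pwms: dict[str, PWM], pvalue_threshold: float = 1e-4):
        self.pwms = dict(pwms)
        self.pvalue_threshold = pvalue_threshold

    def __call__(self, seq: str) -> pd.DataFrame:
        enc = encode(seq)
        comp = np.int8(3) - enc  # complement under ACGT coding
        rows = []
        for mid, pwm in self.pwms.items():
            L = len(pwm)
            if L > enc.size:
                continue
            ints, _, _ = pwm._int_scores
            pos_idx = np.arange(L)
            # all windows, vectorized over start positions
            win = np.lib.stride_tricks.sliding_window_view(enc, L)
            fwd = ints[pos_idx, win].sum(axis=1)
            # minus strand: revcomp of window matches the motif
            win_rc = np.lib.stride_tricks.sliding_window_view(comp, L)[:, ::-1]
            rev = ints[pos_idx, win_rc].sum(axis=1)
            sf = pwm._null_sf
            for strand, scores in (("+", fwd), ("-", rev)):
                pvals = sf[np.minimum(scores, sf.size - 1)]
                hit_at = np.nonzero(pvals < self.pvalue_threshold)[0]
                for s in hit_at:
                    rows.append(
                        (mid, int(s), int(s) + L, strand, int(scores[s]), float(pvals[s]))
                    )
        return pd.DataFrame(
            rows, columns=["motif_id", "start", "end", "strand", "score", "pvalue"]
        )

    def count_hits(self, seq: str) -> int:
        return len(self(seq))


def random_pwm(
    motif_id: str,
    length: int,
    rng: np.random.Generator,
    match_p: float = 0.88,
) -> PWM:
    """A sharply-peaked PWM around a random consensus word."""
    consensus = rng.integers(0, 4, size=length)
    probs = np.full((length, 4), (1 - match_p) / 3)
    probs[np.arange(length), consensus] = match_p
    return PWM(motif_id=motif_id, probs=probs)
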