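"""Barcode-to-sequence association and count-matrix assembly.

A barcode is confidently assigned to a construct when at least 3 unique
UMIs support the assignment and at least 80% of the barcode's UMIs map
to that construct (both bounds inclusive); everything else is ambiguous
and discarded. MPRA counts are then tallied against the confidently
assigned barcodes by exact match, and a barcode is kept within a
(timepoint, replicate) pair only if it is present in both the DNA and
RNA library of that pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AssociationSummary:
    n_barcodes: int
    n_assigned: int
    n_ambiguous: int

    @property
    def assigned_fraction(self) -> float:
        return self.n_assigned / self.n_barcodes if self.n_barcodes else 0.0

    def to_dict(self) -> dict:
        return {
            "n_barcodes": self.n_barcodes,
            "n_assigned": self.n_assigned,
            "n_ambiguous": self.n_ambiguous,
            "assigned_fraction": self.assigned_fraction,
        }


def assign_barcodes(
    read_table: pd.DataFrame, min_umis: int = 3, min_frac: float = 0.8
) -> tuple[pd.DataFrame, AssociationSummary]:
    """Assign each barcode to its majority sequence, or call it ambiguous.

    ``read_table`` columns: barcode, sequence_id, umi_count. The winner
    is the sequence with the most UMIs; assignment requires winner UMIs
    >= min_umis and winner/total >= min_frac. Ties are never assigned.
    Malformed rows (missing fields, non-positive counts) are skipped
    with a warning.
    """
    df = read_table.copy()
    bad = (
        df[["barcode", "sequence_id", "umi_count"]].isna().any(axis=1)
        | (pd.to_numeric(df["umi_count"], errors="coerce").fillna(-1) <= 0)
    )
    if bad.any():
        warnings.warn(f"skipped {int(bad.sum())} malformed association rows")
        df = df[~bad]
    df["umi_count"] = df["umi_count"].astype(int)

    agg = (
        df.groupby(["barcode", "sequence_id"], as_index=False)["umi_count"].sum()
    )
    totals = agg.groupby("barcode")["umi_count"].sum()
    # winner = max-UMI sequence; detect ties
    agg = agg.sort_values(["barcode", "umi_count"], ascending=[True, False])
    maxes = agg.groupby("barcode")["umi_count"].transform("max")
    n_max = (
        agg.assign(at_max=agg["umi_count"].eq(maxes))
        .groupby("barcode")["at_max"]
        .sum()
    )
    top = agg.drop_duplicates("barcode", keep="first").set_index("barcode")
    tie = n_max.reindex(top.index) > 1

    frac = top["umi_count"] / totals
    assigned = (top["umi_count"] >= min_umis) & (frac >= min_frac) & ~tie
    out = pd.DataFrame(
        {
            "barcode": top.index,
            "sequence_id": top["sequence_id"].to_numpy(),
            "n_umis": top["umi_count"].to_numpy(),
            "majority_fraction": frac.to_numpy(float),
            "status": np.where(assigned.to_numpy(), "assigned", "ambiguous"),
        }
    ).reset_index(drop=True)
    summary = AssociationSummary(
        n_barcodes=len(out),
        n_assigned=int((out["status"] == "assigned").sum()),
        n_ambiguous=int((out["status"] == "ambiguous").sum()),
    )
    return out, summary


def count_barcodes(
    mpra_reads: pd.DataFrame, assignments: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally MPRA reads against confidently assigned barcodes.

    ``mpra_reads`` columns: barcode, timepoint, replicate, dna, rna
    (already aggregated per barcode and library pair). Barcodes match
    the association table exactly; per-library fractions of assigned /
    ambiguous / unobserved barcodes are reported alongside the counts.
    """
    status = assignments.set_index("barcode")["status"]
    seq_of = assignments.loc[
        assignments["status"] == "assigned"
    ].set_index("barcode")["sequence_id"]

    cls = mpra_reads["barcode"].map(status).fillna("unobserved")
    cls = cls.where(cls != "ambiguous", "ambiguous")
    stats = (
        mpra_reads.assign(cls=cls.to_numpy())
        .groupby(["timepoint", "replicate", "cls"])
        .size()
        .unstack(fill_value=0)
    )
    stats = stats.div(stats.sum(axis=1), axis=0).reset_index()

    kept = mpra_reads[cls.to_numpy() == "assigned"].copy()
    kept["sequence_id"] = kept["barcode"].map(seq_of)
    counts = kept[
        ["barcode", "sequence_id", "timepoint", "replicate", "dna", "rna"]
    ].reset_index(drop=True)
    return counts, stats


def filter_counts(counts: pd.DataFrame, mode: str = "pair") -> pd.DataFrame:
    """Keep barcodes present in both DNA and RNA of a library pair.

    Evaluated per (timepoint, replicate), not globally: a barcode with
    DNA but no RNA at one timepoint is dropped there and kept wherever
    both libraries observe it. ``mode='any2'`` instead requires
    presence in at least two libraries overall (alternative reading).
    """
    if mode == "pair":
        keep = (counts["dna"] > 0) & (counts["rna"] > 0)
        out = counts[keep].reset_index(drop=True)
        for (t, r), sub in counts.groupby(["timepoint", "replicate"]):
            if not ((sub["dna"] > 0) & (sub["rna"] > 0)).any():
                warnings.warn(f"no barcodes retained for library pair t={t}, rep={r}")
        return out
    if mode == "any2":
        present = (counts["dna"] > 0).astype(int) + (counts["rna"] > 0).astype(int)
        n_lib = counts.assign(p=present).groupby("barcode")["p"].transform("sum")
        return counts[n_lib >= 2].reset_index(drop=True)
    raise ValueError(f"unknown filter mode {mode!r}")
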