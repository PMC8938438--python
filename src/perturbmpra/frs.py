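"""Functional-regulatory-site calling: filters, consensus, categories.

A perturbed motif instance passes the screen when, within a
perturbation method, (1) its PERT construct differs from WT at some
timepoint, (2) its temporal course differs from WT, (3) activity is
distinguishable from the scrambled baseline (WT at every timepoint, or
PERT at some timepoint, by the MAD z-test), and (4) the temporal course
of PERT or WT deviates from the scrambled null. The consensus FRS set
keeps instances passing all four filters under the shuffle method
(method 3) and at least one fixed-replacement method (1 or 2), with a
consistent direction of effect.

Directions: activating sites lose activity when perturbed (essential if
the perturbed construct is indistinguishable from scrambled,
contributing otherwise); dampening sites gain activity (silencing if
the wild type itself sits at the scrambled baseline, inhibiting
otherwise). Instances with significant effects in both directions are
reported as mixed and excluded from sub-categorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import (
    TestResult,
    alpha_by_timepoint,
    bh_adjust,
    estimate_alpha,
    mad_ztest,
    per_timepoint_test,
    scram_temporal_coefficients,
    temporal_test,
    temporal_vs_scram_test,
)

REQUIRED_TABLES = (
    "per_tp_pert_wt",
    "temporal_pert_wt",
    "temporal_pert_scram",
    "temporal_wt_scram",
    "mad_pert_scram",
    "mad_wt_scram",
)


def primary_pert_map(man: pd.DataFrame) -> pd.DataFrame:
    """Representative PERT construct per (instance, method).

    hit1/hit2 instances have one construct per method; for hit2diff the
    construct perturbing both sites represents the instance.
    """
    pert = man[(man["category"] == "PERT") & (man["design_class"] != "double")].copy()
    is_both = pert["seq_id"].str.split("|").str[-2] == "both"
    keep = (pert["design_class"] != "hit2diff") | is_both
    out = pert[keep][["perturbed_instances", "method", "seq_id", "parent_region"]]
    return out.rename(columns={"perturbed_instances": "instance_id"}).reset_index(
        drop=True
    )


def run_comparisons(
    counts: pd.DataFrame,
    man: pd.DataFrame,
    size_factors: pd.DataFrame,
    instances: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """All comparisons the filters need, with the canonical BH batches.

    Returns tables keyed by analysis: per-timepoint PERT-vs-WT (BH
    jointly across timepoints within a method), temporal PERT-vs-WT,
    temporal PERT-vs-SCRAM and WT-vs-SCRAM (the scrambled joint-model
    coefficients as offsets), and MAD z-tests of PERT and WT against
    the scrambled alpha null (BH within timepoint).
    """
    prim = instances if instances is not None else primary_pert_map(man)
    present = set(counts["sequence_id"])
    scram_ids = [s for s in man.loc[man["category"] == "SCRAM", "seq_id"] if s in present]
    scram_coefs = scram_temporal_coefficients(counts, scram_ids, size_factors)
    timepoints = sorted(counts["timepoint"].unique())

    alpha = estimate_alpha(
        counts[counts["sequence_id"].isin(
            set(prim["seq_id"])
            | set(prim["parent_region"] + "|WT")
            | set(scram_ids)
        )],
        size_factors,
    )
    alpha_tp = alpha_by_timepoint(alpha)
    scram_alpha = alpha_tp[alpha_tp["sequence_id"].isin(scram_ids)]

    pt_rows, t_pw, t_ps = [], [], []
    for rec in prim.itertuples():
        wt_id = f"{rec.parent_region}|WT"
        for t in timepoints:
            res = per_timepoint_test(counts, rec.seq_id, wt_id, t, size_factors)
            pt_rows.append(
                (rec.instance_id, rec.method, t, res.pvalue, res.effect)
            )
        res = temporal_test(counts, rec.seq_id, wt_id, size_factors)
        t_pw.append((rec.instance_id, rec.method, res.pvalue, res.effect))
        res = temporal_vs_scram_test(counts, rec.seq_id, scram_coefs, size_factors)
        t_ps.append((rec.instance_id, rec.method, res.pvalue))

    per_tp = pd.DataFrame(
        pt_rows, columns=["instance_id", "method", "timepoint", "pvalue", "effect"]
    )
    # correction batch: per-timepoint p-values corrected jointly across
    # all timepoints (within each method's analysis)
    per_tp["fdr"] = np.nan
    for m, idx in per_tp.groupby("method").groups.items():
        per_tp.loc[idx, "fdr"] = bh_adjust(per_tp.loc[idx, "pvalue"])

    temporal_pw = pd.DataFrame(
        t_pw, columns=["instance_id", "method", "pvalue", "effect"]
    )
    temporal_ps = pd.DataFrame(t_ps, columns=["instance_id", "method", "pvalue"])
    for df in (temporal_pw, temporal_ps):
        df["fdr"] = np.nan
        for m, idx in df.groupby("method").groups.items():
            df.loc[idx, "fdr"] = bh_adjust(df.loc[idx, "pvalue"])

    regions = sorted(set(prim["parent_region"]))
    tw_rows = []
    for r in regions:
        res = temporal_vs_scram_test(counts, f"{r}|WT", scram_coefs, size_factors)
        tw_rows.append((r, res.pvalue))
    temporal_ws = pd.DataFrame(tw_rows, columns=["region_id", "pvalue"])
    temporal_ws["fdr"] = bh_adjust(temporal_ws["pvalue"])

    mad_p = mad_ztest(
        alpha_tp[alpha_tp["sequence_id"].isin(set(prim["seq_id"]))], scram_alpha
    )
    mad_w = mad_ztest(
        alpha_tp[
            alpha_tp["sequence_id"].isin({f"{r}|WT" for r in regions})
        ],
        scram_alpha,
    )
    id_map = prim.set_index("seq_id")[["instance_id", "method"]]
    mad_p = mad_p.join(id_map, on="sequence_id")
    mad_w = mad_w.assign(region_id=mad_w["sequence_id"].str.rsplit("|", n=1).str[0])

    return {
        "per_tp_pert_wt": per_tp,
        "temporal_pert_wt": temporal_pw,
        "temporal_pert_scram": temporal_ps,
        "temporal_wt_scram": temporal_ws,
        "mad_pert_scram": mad_p,
        "mad_wt_scram": mad_w,
        "alpha": alpha_tp,
    }


def apply_filters(
    tests: dict[str, pd.DataFrame],
    man: pd.DataFrame,
    nof_timepoints: int = 7,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Evaluate the four filters per (instance, method).

    Boolean clauses exactly as specified: f1 = FDR(PERT,WT) < thr in
    >= 1 timepoint; f2 = FDR(temporal(PERT,WT)) < thr; f3 = WT beats
    SCRAM at every timepoint OR PERT beats SCRAM at >= 1 timepoint
    (MAD z); f4 = temporal PERT-vs-SCRAM OR temporal WT-vs-SCRAM.
    """
    for key in REQUIRED_TABLES:
        if key not in tests:
            raise ValueError(f"missing comparison table {key!r}")
    per_tp = tests["per_tp_pert_wt"]
    region_of = dict(
        zip(
            per_tp["instance_id"],
            per_tp["instance_id"].str.split("|").str[0],
        )
    )

    f1 = (
        per_tp.assign(sig=per_tp["fdr"] < fdr)
        .groupby(["instance_id", "method"])["sig"]
        .any()
    )
    t_pw = tests["temporal_pert_wt"].set_index(["instance_id", "method"])
    f2 = t_pw["fdr"] < fdr
    mad_w = tests["mad_wt_scram"]
    wt_all = (
        mad_w.assign(sig=mad_w["fdr"] < fdr)
        .groupby("region_id")["sig"]
        .agg(lambda s: s.all() and len(s) == nof_timepoints)
    )
    mad_p = tests["mad_pert_scram"]
    pert_any = (
        mad_p.assign(sig=mad_p["fdr"] < fdr)
        .groupby(["instance_id", "method"])["sig"]
        .any()
    )
    t_ps = tests["temporal_pert_scram"].set_index(["instance_id", "method"])
    t_ws = tests["temporal_wt_scram"].set_index("region_id")["fdr"] < fdr

    rows = []
    for (iid, m) in t_pw.index:
        r = region_of.get(iid, iid.split("|")[0])
        fl1 = bool(f1.get((iid, m), False))
        fl2 = bool(f2.loc[(iid, m)])
        fl3 = bool(wt_all.get(r, False)) or bool(pert_any.get((iid, m), False))
        fl4 = bool(t_ps.loc[(iid, m), "fdr"] < fdr) or bool(t_ws.get(r, False))
        sub = per_tp[(per_tp["instance_id"] == iid) & (per_tp["method"] == m)]
        sig = sub[sub["fdr"] < fdr]
        n_up = int((sig["effect"] > 0).sum())
        n_down = int((sig["effect"] < 0).sum())
        rows.append(
            (
                iid, m, fl1, fl2, fl3, fl4, fl1 and fl2 and fl3 and fl4,
                float(t_pw.loc[(iid, m), "effect"]),
                float(t_pw.loc[(iid, m), "fdr"]),
                n_up, n_down,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "instance_id", "method", "f1", "f2", "f3", "f4", "pass_all",
            "temporal_logfc", "temporal_fdr", "n_tp_up", "n_tp_down",
        ],
    )


def consensus_frs(
    filter_results: pd.DataFrame,
    man: pd.DataFrame | None = None,
    direction_mode: str = "temporal",
) -> pd.DataFrame:
    """Aggregate methods into the consensus FRS set.

    An instance is an FRS iff method 3 passes all four filters, method
    1 or 2 passes, and the direction of effect agrees among the passing
    methods. Direction is the sign of the temporal log fold change
    (``direction_mode='per_tp'`` uses the per-timepoint majority
    instead). Duplicates — identical perturbed coordinates under
    different PWMs — are resolved by the lowest temporal FDR.
    """
    out = []
    for iid, sub in filter_results.groupby("instance_id"):
        passing = sub[sub["pass_all"]]
        methods = set(passing["method"])
        if 3 not in methods or not (methods & {1, 2}):
            continue
        if direction_mode == "temporal":
            signs = {np.sign(e) for e in passing["temporal_logfc"]}
        else:
            signs = {
                np.sign(r.n_tp_down - r.n_tp_up) for r in passing.itertuples()
            }
        if len(signs) != 1:
            continue
        up = passing["n_tp_up"].sum()
        down = passing["n_tp_down"].sum()
        if up > 0 and down > 0:
            direction = "mixed"
        else:
            direction = "activating" if signs.pop() < 0 else "dampening"
        out.append(
            (
                iid,
                iid.split("|")[0],
                iid.split("|")[1],
                direction,
                ",".join(str(m) for m in sorted(methods)),
                float(passing["temporal_fdr"].min()),
            )
        )
    frs = pd.DataFrame(
        out,
        columns=[
            "instance_id", "region_id", "motif_id", "direction",
            "supporting_methods", "min_temporal_fdr",
        ],
    )
    if man is not None and len(frs):
        # duplicate removal: same perturbed coordinates, different PWM
        prim = primary_pert_map(man)
        coords = (
            man[man["seq_id"].isin(prim["seq_id"])]
            .drop_duplicates("perturbed_instances")
            .set_index("perturbed_instances")["perturbed_windows"]
        )
        frs = frs.assign(
            _key=frs["region_id"] + "@" + frs["instance_id"].map(coords).fillna("")
        )
        frs = (
            frs.sort_values(["_key", "min_temporal_fdr"], kind="stable")
            .drop_duplicates("_key", keep="first")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
    return frs


def categorize(
    frs: pd.DataFrame,
    tests: dict[str, pd.DataFrame],
    nof_timepoints: int = 7,
    fdr: float = 0.05,
    clause_mode: str = "or",
) -> pd.DataFrame:
    """Assign sub-categories to consensus FRSs.

    Activating: essential when the perturbed construct is at the
    scrambled baseline — temporal PERT-vs-SCRAM FDR > threshold OR the
    MAD test of PERT-vs-SCRAM is non-significant at every timepoint;
    otherwise contributing. Dampening: silencing when the wild type is
    at the baseline (same clauses on WT), otherwise inhibiting. The
    stated condition joins the two clauses with OR;
    ``clause_mode='and'`` switches to the conjunctive reading. Mixed
    instances are reported with sub_category 'mixed'.

    Baseline-similarity clauses are evaluated on the supporting-method
    evidence: all passing methods must agree the construct sits at the
    baseline.
    """
    t_ps = tests["temporal_pert_scram"]
    mad_p = tests["mad_pert_scram"]
    t_ws = tests["temporal_wt_scram"].set_index("region_id")
    mad_w = tests["mad_wt_scram"]

    sub_cats = []
    for rec in frs.itertuples():
        methods = [int(x) for x in rec.supporting_methods.split(",")]
        if rec.direction == "mixed":
            sub_cats.append("mixed")
            continue
        if rec.direction == "activating":
            clause_t, clause_m = [], []
            for m in methods:
                row = t_ps[
                    (t_ps["instance_id"] == rec.instance_id) & (t_ps["method"] == m)
                ]
                clause_t.append(bool((row["fdr"] > fdr).all()) and len(row) > 0)
                mm = mad_p[
                    (mad_p["instance_id"] == rec.instance_id) & (mad_p["method"] == m)
                ]
                clause_m.append(
                    len(mm) == nof_timepoints and bool((mm["fdr"] > fdr).all())
                )
            at_baseline = (
                (all(clause_t) or all(clause_m))
                if clause_mode == "or"
                else (all(clause_t) and all(clause_m))
            )
            sub_cats.append("essential" if at_baseline else "contributing")
        else:
            r = rec.region_id
            ct = bool(t_ws.loc[r, "fdr"] > fdr) if r in t_ws.index else False
            mm = mad_w[mad_w["region_id"] == r]
            cm = len(mm) == nof_timepoints and bool((mm["fdr"] > fdr).all())
            at_baseline = (ct or cm) if clause_mode == "or" else (ct and cm)
            sub_cats.append("silencing" if at_baseline else "inhibiting")
    return frs.assign(sub_category=sub_cats)


# ---------------------------------------------------------------------------
# activation dynamics
# ---------------------------------------------------------------------------

def fit_dynamics(
    wt_alpha: np.ndarray, pert_alpha: np.ndarray
) -> tuple[float, float, float]:
    """OLS of the absolute perturbation effect on wild-type activity.

    Fits delta = a + b * WT with delta = WT - PERT across timepoints,
    for activators active at every timepoint. Returns (a, b, R^2). The
    derived fold-change curve is FC = (1 - b) - a / WT in terms of the
    fitted intercept a and slope b.
    """
    wt = np.asarray(wt_alpha, float)
    pert = np.asarray(pert_alpha, float)
    if wt.size != pert.size or wt.size < 3:
        raise ValueError("need >= 3 matched timepoints for the dynamics fit")
    delta = wt - pert
    res = stats.linregress(wt, delta)
    return float(res.intercept), float(res.slope), float(res.rvalue**2)
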