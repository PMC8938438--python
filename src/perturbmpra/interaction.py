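"""Pairwise motif-interaction tests against the log-additive null.

Under the billboard model, perturbing two sites multiplies their
individual effects; the RNA GLM therefore includes binary covariates
Pert1 and Pert2 over the {WT, P1, P2, P12} constructs of a region, and
the full model adds their product: y ~ time + Pert1 * Pert2 versus
y ~ time + Pert1 + Pert2, compared by a likelihood-ratio test (df=1).
The interaction coefficient gamma is on the model's native natural-log
scale. A pair is called interacting when |gamma| exceeds the threshold
(0.5) and the BH-corrected p-value is below 0.05, consistently in
method 3 and in method 1 or 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glm import dummies
from .quantify import TestResult, bh_adjust, lrt_compare, _rna_offset


def test_interaction(
    counts: pd.DataFrame,
    wt_id: str,
    p1_id: str,
    p2_id: str,
    p12_id: str,
    size_factors: pd.DataFrame,
) -> tuple[float, TestResult]:
    """Gamma and LRT p-value for one double-perturbation quartet."""
    ids = [wt_id, p1_id, p2_id, p12_id]
    sub = counts[counts["sequence_id"].isin(ids)].reset_index(drop=True)
    missing = [s for s in ids if s not in set(sub["sequence_id"])]
    if missing:
        raise ValueError(f"missing constructs for interaction test: {missing}")
    offset = _rna_offset(sub, size_factors)
    pert1 = sub["sequence_id"].isin([p1_id, p12_id]).to_numpy(float)
    pert2 = sub["sequence_id"].isin([p2_id, p12_id]).to_numpy(float)
    Xt = dummies(sub["timepoint"], drop_first=True)
    base = [np.ones(len(sub)), Xt, pert1[:, None], pert2[:, None]]
    X_red = np.column_stack(base)
    X_full = np.column_stack(base + [(pert1 * pert2)[:, None]])
    res = lrt_compare(
        sub["rna"].to_numpy(float), X_full, X_red, offset,
        effect_index=X_full.shape[1] - 1,
    )
    return res.effect, res


def test_pairs(
    counts: pd.DataFrame,
    man: pd.DataFrame,
    size_factors: pd.DataFrame,
) -> pd.DataFrame:
    """Run the interaction test for every double construct, per method.

    Returns one row per (pair, method) with gamma, p and BH-corrected p
    (correction across all pairs within a method).
    """
    doubles = man[man["design_class"] == "double"]
    prim = man[
        (man["category"] == "PERT") & (man["design_class"] != "double")
    ].copy()
    is_both = prim["seq_id"].str.split("|").str[-2] == "both"
    prim = prim[(prim["design_class"] != "hit2diff") | is_both]
    single_id = prim.set_index(["perturbed_instances", "method"])["seq_id"]

    rows = []
    for rec in doubles.itertuples():
        i1, i2 = rec.perturbed_instances.split(";")
        pair_id = f"{i1}+{i2}"
        try:
            p1 = single_id.loc[(i1, rec.method)]
            p2 = single_id.loc[(i2, rec.method)]
            gamma, res = test_interaction(
                counts, f"{rec.parent_region}|WT", p1, p2, rec.seq_id, size_factors
            )
            rows.append(
                (pair_id, i1, i2, rec.parent_region, rec.method, gamma,
                 res.pvalue, bool(rec.overlap))
            )
        except (KeyError, ValueError):
            rows.append(
                (pair_id, i1, i2, rec.parent_region, rec.method,
                 np.nan, np.nan, bool(rec.overlap))
            )
    out = pd.DataFrame(
        rows,
        columns=["pair_id", "instance1", "instance2", "region_id", "method",
                 "gamma", "pvalue", "overlap"],
    )
    out["fdr"] = np.nan
    for m, idx in out.groupby("method").groups.items():
        good = out.loc[idx].dropna(subset=["pvalue"])
        out.loc[good.index, "fdr"] = bh_adjust(good["pvalue"])
    return out


def classify_pairs(
    pair_tests: pd.DataFrame,
    filter_results: pd.DataFrame,
    gamma_min: float = 0.5,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Label each pair additive / interacting / excluded.

    Exclusions, in order: overlapping assayed sites; non-functional
    pairs (neither single perturbation passes all four filters);
    inconsistent pairs (significance label differs between method 3 and
    both of methods 1 and 2). Significance = |gamma| > gamma_min and
    BH p < fdr within the method.
    """
    passed = set(
        map(tuple, filter_results.loc[filter_results["pass_all"],
                                      ["instance_id", "method"]].itertuples(index=False))
    )
    pass_any = {
        iid for iid, m in passed
    }
    rows = []
    for pair_id, sub in pair_tests.groupby("pair_id"):
        first = sub.iloc[0]
        label, reason = "", ""
        sig = {
            int(r.method): (
                abs(r.gamma) > gamma_min and r.fdr < fdr
                if np.isfinite(r.gamma) and np.isfinite(r.fdr)
                else None
            )
            for r in sub.itertuples()
        }
        if bool(first["overlap"]):
            label, reason = "excluded", "overlap"
        elif first["instance1"] not in pass_any and first["instance2"] not in pass_any:
            label, reason = "excluded", "non-functional"
        elif sig.get(3) is None or (sig.get(1) is None and sig.get(2) is None):
            label, reason = "excluded", "inconsistent"
        else:
            consistent = sig[3] in {
                s for m, s in sig.items() if m in (1, 2) and s is not None
            }
            if not consistent:
                label, reason = "excluded", "inconsistent"
            else:
                label = "interacting" if sig[3] else "additive"
        g3 = sub.loc[sub["method"] == 3, "gamma"]
        rows.append(
            (
                pair_id, first["instance1"], first["instance2"],
                first["region_id"], label, reason,
                float(g3.iloc[0]) if len(g3) else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "instance1", "instance2", "region_id",
                 "label", "exclusion_reason", "gamma_method3"],
    )
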