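"""Transcription-rate estimation and shared statistical machinery.

Per-construct transcription rates ("alpha") come from the nested GLM:
the DNA stage (gamma, log link, design ~ timepoint + replicate +
barcode) estimates latent construct abundance; the RNA stage (negative
binomial, log link, design ~ timepoint + replicate) estimates alpha per
timepoint and replicate, with the DNA fits and library-size factors as
fixed exposure offsets. Size factors are upper-quartile normalized and
computed once on the full dataset.

Also here: closed-form RNA/DNA ratios (pseudocount 1, per-sample median
normalization, cross-replicate averaging), the MAD-based z-test of
activity against scrambled negative controls, likelihood-ratio tests
for the three comparative designs (per-timepoint, temporal with an
interaction term, temporal against the scrambled baseline), and
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import dummies, estimate_dispersion, fit_nb_glm, gamma_factor_fit

MAD_SCALE = 1.4826  # normal-consistency factor


@dataclass
class TestResult:
    statistic: float
    df: int
    pvalue: float
    effect: float = np.nan  # log fold change where applicable
    fdr: float = np.nan
    converged: bool = True


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def compute_size_factors(counts: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile size factors per (timepoint, replicate) library.

    Computed once on the entire dataset and reused across all analyses.
    Factors are scaled to geometric mean 1 within each modality.
    """
    rows = []
    for (t, r), sub in counts.groupby(["timepoint", "replicate"]):
        uq_d = _upper_quartile(sub["dna"])
        uq_r = _upper_quartile(sub["rna"])
        rows.append((t, r, uq_d, uq_r))
    sf = pd.DataFrame(rows, columns=["timepoint", "replicate", "sf_dna", "sf_rna"])
    for col in ("sf_dna", "sf_rna"):
        vals = sf[col].to_numpy(float)
        if (vals <= 0).any():
            raise ValueError(f"degenerate library: zero {col.split('_')[1].upper()} counts")
        sf[col] = vals / np.exp(np.mean(np.log(vals)))
    return sf


def _upper_quartile(x: pd.Series) -> float:
    nz = x[x > 0]
    return float(np.percentile(nz, 75)) if len(nz) else 0.0


def _sf_lookup(size_factors: pd.DataFrame, sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    m = sub.merge(size_factors, on=["timepoint", "replicate"], how="left")
    return m["sf_dna"].to_numpy(float), m["sf_rna"].to_numpy(float)


def dna_offsets(
    sub: pd.DataFrame, size_factors: pd.DataFrame, pseudocount: float = 1.0
) -> np.ndarray:
    """Log latent DNA abundance per row, from per-sequence gamma fits.

    The barcode covariate is sequence-specific, so the DNA model is
    fitted independently per sequence (design ~ timepoint + replicate +
    barcode), on size-factor-normalized counts.
    """
    sub = sub.reset_index(drop=True)
    sf_dna, _ = _sf_lookup(size_factors, sub)
    out = np.empty(len(sub))
    norm = sub.assign(dna_norm=sub["dna"].to_numpy(float) / sf_dna)
    for _, idx in norm.groupby("sequence_id").groups.items():
        block = norm.loc[idx]
        mu = gamma_factor_fit(
            block, value="dna_norm", factors=("barcode", "timepoint", "replicate"),
            pseudocount=pseudocount,
        )
        out[norm.index.get_indexer(idx)] = mu
    return np.log(out)


# ---------------------------------------------------------------------------
# alpha estimation
# ---------------------------------------------------------------------------

def estimate_alpha(
    counts: pd.DataFrame, size_factors: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-(sequence, timepoint, replicate) transcription-rate estimates.

    Non-converged fits fall back to the ratio estimator
    sum(RNA/sf)/sum(DNA-hat) within the cell and are flagged.
    """
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    rows = []
    for sid, sub in counts.groupby("sequence_id"):
        sub = sub.reset_index(drop=True)
        log_dhat = dna_offsets(sub, size_factors)
        _, sf_rna = _sf_lookup(size_factors, sub)
        offset = log_dhat + np.log(sf_rna)
        Xt = dummies(sub["timepoint"], drop_first=True)
        Xr = dummies(sub["replicate"], drop_first=True)
        X = np.column_stack([np.ones(len(sub)), Xt, Xr])
        fit = fit_nb_glm(sub["rna"].to_numpy(float), X, offset)
        tp_levels = pd.unique(sub["timepoint"])
        rep_levels = pd.unique(sub["replicate"])
        for i, t in enumerate(tp_levels):
            for j, r in enumerate(rep_levels):
                if fit.converged:
                    eta = fit.params[0]
                    if i > 0:
                        eta += fit.params[i]
                    if j > 0:
                        eta += fit.params[len(tp_levels) - 1 + j]
                    alpha = float(np.exp(eta))
                else:
                    cell = (sub["timepoint"] == t) & (sub["replicate"] == r)
                    num = (sub.loc[cell, "rna"] / sf_rna[cell.to_numpy()]).sum()
                    den = np.exp(log_dhat[cell.to_numpy()]).sum()
                    alpha = float(num / den) if den > 0 else np.nan
                rows.append((sid, t, r, alpha, fit.llf, fit.converged))
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "timepoint", "replicate", "alpha", "loglik", "converged"],
    )


def alpha_by_timepoint(alpha_df: pd.DataFrame) -> pd.DataFrame:
    """Geometric mean of alpha across replicates, per sequence x timepoint."""
    g = (
        alpha_df.assign(log_alpha=np.log(alpha_df["alpha"]))
        .groupby(["sequence_id", "timepoint"])["log_alpha"]
        .mean()
        .reset_index()
    )
    g["alpha"] = np.exp(g.pop("log_alpha"))
    return g


# ---------------------------------------------------------------------------
# closed-form RNA/DNA ratios
# ---------------------------------------------------------------------------

def rna_dna_ratio(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sequence abundance and RNA/DNA ratios.

    Abundance (per modality, sequence and library): CPM-style
    ``1e6 * sum(counts) / (n_barcodes * library_total)``. Ratio (per
    sequence and library): mean over barcodes of the library-normalized
    (RNA+1)/(DNA+1) ratio, then divided by the per-sample median ratio
    and averaged across replicates. Sequences with zero barcodes in a
    library are emitted as missing.
    """
    ab_rows, ratio_rows = [], []
    for (t, r), lib in counts.groupby(["timepoint", "replicate"]):
        tot_d = float(lib["dna"].sum())
        tot_r = float(lib["rna"].sum())
        for sid, sub in lib.groupby("sequence_id"):
            nbc = len(sub)
            if nbc == 0:
                continue
            ab_rows.append(
                (
                    sid, t, r,
                    1e6 * sub["dna"].sum() / (nbc * tot_d) if tot_d else np.nan,
                    1e6 * sub["rna"].sum() / (nbc * tot_r) if tot_r else np.nan,
                )
            )
            num = (sub["rna"].to_numpy(float) + 1.0) / (tot_r + 1.0)
            den = (sub["dna"].to_numpy(float) + 1.0) / (tot_d + 1.0)
            ratio_rows.append((sid, t, r, float(np.mean(num / den))))
    abundance = pd.DataFrame(
        ab_rows, columns=["sequence_id", "timepoint", "replicate", "dna_per_seq", "rna_per_seq"]
    )
    ratios = pd.DataFrame(
        ratio_rows, columns=["sequence_id", "timepoint", "replicate", "ratio"]
    )
    med = ratios.groupby(["timepoint", "replicate"])["ratio"].transform("median")
    ratios["ratio_norm"] = ratios["ratio"] / med
    combined = (
        ratios.groupby(["sequence_id", "timepoint"])["ratio_norm"]
        .mean()
        .reset_index()
        .rename(columns={"ratio_norm": "ratio"})
    )
    return abundance, ratios.merge(
        combined, on=["sequence_id", "timepoint"], suffixes=("", "_combined")
    )


# ---------------------------------------------------------------------------
# MAD-based z-test against the scrambled null
# ---------------------------------------------------------------------------

def mad_ztest(
    alphas: pd.DataFrame,
    scram_alphas: pd.DataFrame,
    alternative: str = "greater",
    min_null: int = 10,
) -> pd.DataFrame:
    """Test each alpha against the scrambled-control null, per timepoint.

    z = (alpha - median(null)) / (1.4826 * MAD(null)); one-sided
    upper-tail normal p by default ("more active than SCRAM"). BH
    adjustment within each timepoint.
    """
    out = []
    null_by_tp = dict(tuple(scram_alphas.groupby("timepoint")))
    for t, sub in alphas.groupby("timepoint"):
        if t not in null_by_tp or len(null_by_tp[t]) < min_null:
            raise ValueError(f"need >= {min_null} scrambled alphas at timepoint {t}")
        null = null_by_tp[t]["alpha"].to_numpy(float)
        med = np.median(null)
        mad = np.median(np.abs(null - med)) * MAD_SCALE
        if mad == 0:
            raise ValueError(
                f"MAD of scrambled null is zero at timepoint {t}; "
                "jitter the null or enlarge the control set"
            )
        z = (sub["alpha"].to_numpy(float) - med) / mad
        if alternative == "greater":
            p = stats.norm.sf(z)
        elif alternative == "two-sided":
            p = 2 * stats.norm.sf(np.abs(z))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        block = sub[["sequence_id", "timepoint"]].copy()
        block["z"] = z
        block["pvalue"] = p
        block["fdr"] = bh_adjust(p)
        out.append(block)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

def lrt_compare(
    y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    offset: np.ndarray | None = None,
    dispersion: float | None = None,
    effect_index: int | None = None,
    return_full: bool = False,
):
    """LRT between nested NB GLMs; dispersion shared from the full fit.

    2*(ll_full - ll_reduced) ~ chi-square with df = rank difference.
    Raises if the reduced design is not nested in the full one.
    """
    rank_f = np.linalg.matrix_rank(X_full)
    if np.linalg.matrix_rank(np.column_stack([X_full, X_reduced])) > rank_f:
        raise ValueError("reduced design is not nested in the full design")
    df = rank_f - np.linalg.matrix_rank(X_reduced)
    full = fit_nb_glm(y, X_full, offset, dispersion)
    red = fit_nb_glm(y, X_reduced, offset, full.dispersion)
    stat = max(2.0 * (full.llf - red.llf), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    effect = float(full.params[effect_index]) if effect_index is not None else np.nan
    res = TestResult(
        statistic=float(stat), df=int(df), pvalue=p, effect=effect,
        converged=full.converged and red.converged,
    )
    return (res, full) if return_full else res


def _rna_offset(sub, size_factors):
    log_dhat = dna_offsets(sub, size_factors)
    _, sf_rna = _sf_lookup(size_factors, sub)
    return log_dhat + np.log(sf_rna)


def per_timepoint_test(
    counts: pd.DataFrame,
    test_seq: str,
    ref_seq: str,
    timepoint: int,
    size_factors: pd.DataFrame,
) -> TestResult:
    """Per-timepoint comparison (full RNA design ~sequence, reduced ~1).

    Effect is the log fold change of the test sequence over the
    reference at that timepoint.
    """
    sub = counts[
        counts["sequence_id"].isin([test_seq, ref_seq])
        & (counts["timepoint"] == timepoint)
    ].reset_index(drop=True)
    if sub["sequence_id"].nunique() < 2:
        raise ValueError(f"missing sequence in comparison at t={timepoint}")
    offset = _rna_offset(sub, size_factors)
    is_test = (sub["sequence_id"] == test_seq).to_numpy(float)
    X_full = np.column_stack([np.ones(len(sub)), is_test])
    X_red = np.ones((len(sub), 1))
    return lrt_compare(
        sub["rna"].to_numpy(float), X_full, X_red, offset, effect_index=1
    )


def temporal_test(
    counts: pd.DataFrame,
    test_seq: str,
    ref_seq: str,
    size_factors: pd.DataFrame,
) -> TestResult:
    """Temporal comparison: full RNA design ~time*sequence, reduced ~time.

    Effect is the sequence main coefficient (time-averaged log fold
    change of test over reference under treatment coding).
    """
    sub = counts[counts["sequence_id"].isin([test_seq, ref_seq])].reset_index(drop=True)
    if sub["sequence_id"].nunique() < 2:
        raise ValueError("missing sequence in temporal comparison")
    offset = _rna_offset(sub, size_factors)
    Xt = dummies(sub["timepoint"], drop_first=True)
    is_test = (sub["sequence_id"] == test_seq).to_numpy(float)
    X_full = np.column_stack(
        [np.ones(len(sub)), Xt, is_test, Xt * is_test[:, None]]
    )
    X_red = np.column_stack([np.ones(len(sub)), Xt])
    res, full = lrt_compare(
        sub["rna"].to_numpy(float), X_full, X_red, offset, return_full=True
    )
    # summary effect: log fold change averaged over timepoints (sequence
    # main coefficient plus the mean of its interaction terms)
    k = 1 + Xt.shape[1]
    inter = full.params[k + 1 :]
    res.effect = float(full.params[k] + np.concatenate([[0.0], inter]).mean())
    return res


def scram_temporal_coefficients(
    counts: pd.DataFrame, scram_ids: list[str], size_factors: pd.DataFrame
) -> pd.Series:
    """Joint NB model over all scrambled controls: log alpha per timepoint.

    Used as normalization offsets for the temporal-vs-null comparisons.
    """
    sub = counts[counts["sequence_id"].isin(scram_ids)].reset_index(drop=True)
    offset = _rna_offset(sub, size_factors)
    tp_levels = sorted(sub["timepoint"].unique())
    Xt = dummies(pd.Categorical(sub["timepoint"], categories=tp_levels), drop_first=True)
    X = np.column_stack([np.ones(len(sub)), Xt])
    fit = fit_nb_glm(sub["rna"].to_numpy(float), X, offset)
    coefs = {tp_levels[0]: fit.params[0]}
    for i, t in enumerate(tp_levels[1:]):
        coefs[t] = fit.params[0] + fit.params[1 + i]
    return pd.Series(coefs, name="log_alpha_scram")


def temporal_vs_scram_test(
    counts: pd.DataFrame,
    seq: str,
    scram_coefs: pd.Series,
    size_factors: pd.DataFrame,
) -> TestResult:
    """Does a sequence's temporal activity deviate from the SCRAM null?

    The scrambled joint-model coefficients enter the RNA model as
    per-timepoint offsets; full design ~timepoint, reduced ~1.
    """
    sub = counts[counts["sequence_id"] == seq].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no counts for sequence {seq}")
    offset = _rna_offset(sub, size_factors)
    offset = offset + sub["timepoint"].map(scram_coefs).to_numpy(float)
    Xt = dummies(sub["timepoint"], drop_first=True)
    X_full = np.column_stack([np.ones(len(sub)), Xt])
    X_red = np.ones((len(sub), 1))
    return lrt_compare(sub["rna"].to_numpy(float), X_full, X_red, offset)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one batch)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
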