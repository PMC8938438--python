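"""Filter logic, consensus rules, categorization and dynamics fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from perturbmpra.config import SimConfig
from perturbmpra.frs import apply_filters, categorize, consensus_frs, fit_dynamics, run_comparisons

from conftest import mini_study


# ---------------------------------------------------------------------------
# hand-built comparison tables for rule-logic tests
# ---------------------------------------------------------------------------

def make_tables(
    iid="R0|M0",
    region="R0",
    methods=(1, 2, 3),
    per_tp_fdr=0.01,
    per_tp_effect=-1.0,
    temporal_pw_fdr=0.01,
    temporal_pw_lfc=-1.0,
    temporal_ps_fdr=0.01,
    temporal_ws_fdr=0.01,
    mad_p_fdr=0.01,
    mad_w_fdr=0.01,
    ntp=7,
):
    """One instance with uniform stats across timepoints/methods."""
    rows_pt, rows_tpw, rows_tps, rows_mp = [], [], [], []
    for m in methods:
        for t in range(ntp):
            rows_pt.append((iid, m, t, per_tp_fdr, per_tp_effect, per_tp_fdr))
            rows_mp.append((iid, m, t, mad_p_fdr))
        rows_tpw.append((iid, m, 0.001, temporal_pw_lfc, temporal_pw_fdr))
        rows_tps.append((iid, m, 0.001, temporal_ps_fdr))
    return {
        "per_tp_pert_wt": pd.DataFrame(
            rows_pt,
            columns=["instance_id", "method", "timepoint", "pvalue", "effect", "fdr"],
        ),
        "temporal_pert_wt": pd.DataFrame(
            rows_tpw, columns=["instance_id", "method", "pvalue", "effect", "fdr"]
        ),
        "temporal_pert_scram": pd.DataFrame(
            rows_tps, columns=["instance_id", "method", "pvalue", "fdr"]
        ),
        "temporal_wt_scram": pd.DataFrame(
            [(region, 0.001, temporal_ws_fdr)], columns=["region_id", "pvalue", "fdr"]
        ),
        "mad_pert_scram": pd.DataFrame(
            rows_mp, columns=["instance_id", "method", "timepoint", "fdr"]
        ),
        "mad_wt_scram": pd.DataFrame(
            [(region, t, mad_w_fdr) for t in range(ntp)],
            columns=["region_id", "timepoint", "fdr"],
        ),
    }


class TestApplyFilters:
    def test_all_significant_passes_all_filters(self):
        filt = apply_filters(make_tables(), man=None)
        assert filt["pass_all"].all()
        assert filt[["f1", "f2", "f3", "f4"]].all().all()

    def test_f3_via_wt_clause_requires_every_timepoint(self):
        # WT beats SCRAM at all 7 timepoints while PERT never does
        tables = make_tables(mad_p_fdr=0.9, mad_w_fdr=0.01)
        assert apply_filters(tables, man=None)["f3"].all()
        # one WT timepoint failing breaks the clause
        tables["mad_wt_scram"].loc[3, "fdr"] = 0.9
        assert not apply_filters(tables, man=None)["f3"].any()

    def test_f3_via_pert_clause_single_timepoint_suffices(self):
        tables = make_tables(mad_p_fdr=0.9, mad_w_fdr=0.9)
        tables["mad_pert_scram"].loc[2, "fdr"] = 0.01  # one (method, tp) cell
        filt = apply_filters(tables, man=None).set_index("method")
        m = tables["mad_pert_scram"].loc[2, "method"]
        assert filt.loc[m, "f3"]

    def test_f4_requires_either_temporal_null_deviation(self):
        tables = make_tables(temporal_ps_fdr=0.9, temporal_ws_fdr=0.9)
        assert not apply_filters(tables, man=None)["f4"].any()
        tables2 = make_tables(temporal_ps_fdr=0.9, temporal_ws_fdr=0.01)
        assert apply_filters(tables2, man=None)["f4"].all()

    def test_missing_comparison_errors(self):
        tables = make_tables()
        del tables["temporal_pert_scram"]
        with pytest.raises(ValueError, match="temporal_pert_scram"):
            apply_filters(tables, man=None)

    def test_threshold_monotonicity(self):
        tables = make_tables(per_tp_fdr=0.03, temporal_pw_fdr=0.04,
                             temporal_ps_fdr=0.04, mad_p_fdr=0.03)
        loose = apply_filters(tables, man=None, fdr=0.05)["pass_all"].sum()
        tight = apply_filters(tables, man=None, fdr=0.01)["pass_all"].sum()
        assert tight <= loose


class TestConsensus:
    def test_requires_method3_and_one_fixed_method(self):
        tables = make_tables()
        filt = apply_filters(tables, man=None)
        # all three pass -> FRS
        assert len(consensus_frs(filt)) == 1
        # only methods 1+2 pass -> no FRS
        filt12 = filt.copy()
        filt12.loc[filt12["method"] == 3, "pass_all"] = False
        assert consensus_frs(filt12).empty
        # methods 3+1, consistent downward direction -> activating FRS
        filt31 = filt.copy()
        filt31.loc[filt31["method"] == 2, "pass_all"] = False
        out = consensus_frs(filt31)
        assert len(out) == 1 and out.loc[0, "direction"] == "activating"

    def test_direction_disagreement_drops_instance(self):
        filt = apply_filters(make_tables(), man=None)
        filt.loc[filt["method"] == 1, "temporal_logfc"] = +1.0
        filt.loc[filt["method"] == 2, "pass_all"] = False
        assert consensus_frs(filt).empty

    def test_order_invariance(self):
        filt = apply_filters(make_tables(), man=None)
        perm = filt.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            consensus_frs(filt), consensus_frs(perm)
        )

    def test_duplicate_coordinates_keep_lowest_temporal_fdr(self):
        t1 = make_tables(iid="R0|M0")
        t2 = make_tables(iid="R0|M1")
        tables = {k: pd.concat([t1[k], t2[k]]).drop_duplicates() for k in t1}
        filt = apply_filters(tables, man=None)
        filt.loc[filt["instance_id"] == "R0|M0", "temporal_fdr"] = 0.01
        filt.loc[filt["instance_id"] == "R0|M1", "temporal_fdr"] = 0.001
        man = pd.DataFrame(
            {
                "seq_id": ["R0|M0|m1", "R0|M0|m2", "R0|M0|m3",
                           "R0|M1|m1", "R0|M1|m2", "R0|M1|m3"],
                "category": "PERT",
                "method": [1, 2, 3, 1, 2, 3],
                "parent_region": "R0",
                "design_class": "hit1",
                "perturbed_instances": ["R0|M0"] * 3 + ["R0|M1"] * 3,
                # same perturbed window under two different PWMs
                "perturbed_windows": ["10-18:+"] * 6,
                "overlap": False,
                "sequence": "",
            }
        )
        out = consensus_frs(filt, man)
        assert len(out) == 1 and out.loc[0, "instance_id"] == "R0|M1"


class TestCategorize:
    def _frs(self, direction="activating"):
        return pd.DataFrame(
            {
                "instance_id": ["R0|M0"],
                "region_id": ["R0"],
                "motif_id": ["M0"],
                "direction": [direction],
                "supporting_methods": ["1,3"],
                "min_temporal_fdr": [0.001],
            }
        )

    def test_essential_when_pert_matches_scram(self):
        # PERT indistinguishable from SCRAM temporally -> essential
        tables = make_tables(temporal_ps_fdr=0.5, mad_p_fdr=0.01)
        out = categorize(self._frs(), tables)
        assert out.loc[0, "sub_category"] == "essential"

    def test_contributing_when_pert_above_scram(self):
        tables = make_tables(temporal_ps_fdr=0.01, mad_p_fdr=0.01)
        out = categorize(self._frs(), tables)
        assert out.loc[0, "sub_category"] == "contributing"

    def test_silencing_when_wt_at_baseline(self):
        tables = make_tables(temporal_ws_fdr=0.5)
        out = categorize(self._frs("dampening"), tables)
        assert out.loc[0, "sub_category"] == "silencing"

    def test_inhibiting_otherwise(self):
        tables = make_tables(temporal_ws_fdr=0.01, mad_w_fdr=0.01)
        out = categorize(self._frs("dampening"), tables)
        assert out.loc[0, "sub_category"] == "inhibiting"

    def test_and_clause_mode_is_stricter(self):
        tables = make_tables(temporal_ps_fdr=0.5, mad_p_fdr=0.01)
        assert categorize(self._frs(), tables).loc[0, "sub_category"] == "essential"
        assert (
            categorize(self._frs(), tables, clause_mode="and").loc[0, "sub_category"]
            == "contributing"
        )


class TestDynamics:
    def test_exact_linear_input(self):
        wt = np.array([1.0, 2, 3, 4, 5, 6, 7])
        delta = 0.2 + 0.5 * wt
        a, b, r2 = fit_dynamics(wt, wt - delta)
        assert (a, b) == pytest.approx((0.2, 0.5))
        assert r2 == pytest.approx(1.0)

    def test_noisy_slope_within_two_se(self):
        # |t| <= 2 covers ~89.8% at 5 residual df, so demand a rate
        # consistent with that nominal coverage
        rng = np.random.default_rng(0)
        recovered = []
        for i in range(100):
            wt = np.linspace(1, 6, 7)
            delta = 0.3 + 0.6 * wt + rng.normal(0, 0.05, 7)
            a, b, _ = fit_dynamics(wt, wt - delta)
            from scipy.stats import linregress

            se = linregress(wt, delta).stderr
            recovered.append(abs(b - 0.6) <= 2 * se)
        assert np.mean(recovered) >= 0.8

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_dynamics([1.0, 2.0], [0.5, 0.6])


class TestNullFalsePositives:
    def test_frs_rate_under_null_is_controlled(self):
        """With no planted effects the consensus FRS set stays <= 5%
        of tested instances (aggregated over 10 seeds)."""
        from perturbmpra.frs import primary_pert_map

        called = tested = 0
        for seed in range(10):
            cfg = SimConfig(
                n_regions=14, n_motifs=12, n_properties=0, seed=800 + seed,
                barcodes_per_sequence=12, broad_deg_range=(5, 6),
                sparse_deg_range=(1, 2), paired_group_frac=0.0,
                hand_picked_frac=0.2,
            )
            man, counts, truth, sf = mini_study(cfg, category_mix={"null": 1.0})
            prim = primary_pert_map(man)
            keep = prim["instance_id"].drop_duplicates().head(6)
            prim = prim[prim["instance_id"].isin(keep)]
            tests = run_comparisons(counts, man, sf, instances=prim)
            filt = apply_filters(tests, man)
            frs = consensus_frs(filt, man)
            tested += filt["instance_id"].nunique()
            called += len(frs)
        assert tested >= 50
        assert called / tested <= 0.05
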