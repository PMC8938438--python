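"""Selection-ILP tests: generator guarantees, solver vs enumeration,
and the solver-independent constraint checker."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from perturbmpra.config import SimConfig
from perturbmpra.design import (
    ConstraintParams,
    InfeasibleDesignError,
    build_ilp,
    check_constraints,
    solve_design,
)
from perturbmpra.graph import TripartiteGraph
from perturbmpra.simulate import GraphInfeasibleError, generate_graph

from conftest import toy_graph


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of toy designs
# ---------------------------------------------------------------------------

def brute_force_optimum(graph: TripartiteGraph, params=None) -> float | None:
    """Minimal objective over all 0/1 assignments, or None if infeasible.

    Edges are the selected-pair indicators (both endpoints chosen);
    every constraint family is evaluated directly from the
    definitions.
    """
    p = params or ConstraintParams()
    R, T = graph.regions, graph.motifs
    adj = list(zip(graph.instance_edges["motif"], graph.instance_edges["region"]))
    low = set(
        zip(
            graph.instance_edges.loc[graph.instance_edges["low_confidence"], "motif"],
            graph.instance_edges.loc[graph.instance_edges["low_confidence"], "region"],
        )
    )
    mp = {q: set(g) for q, g in graph.motif_prop_edges.groupby("property")["motif"]}
    rp = {q: set(g) for q, g in graph.region_prop_edges.groupby("property")["region"]}
    deg_t = {t: sum(1 for tt, _ in adj if tt == t) for t in T}
    deg_r = {r: sum(1 for _, rr in adj if rr == r) for r in R}
    broad = {t for t in T if deg_t[t] >= 5}
    groups: dict[str, list[str]] = {}
    for t in T:
        groups.setdefault(graph.tf_group[t], []).append(t)

    best = None
    for rbits in itertools.product([0, 1], repeat=len(R)):
        sel_r = {r for r, b in zip(R, rbits) if b}
        if len(sel_r) < p.region_fraction * len(R):
            continue
        for tbits in itertools.product([0, 1], repeat=len(T)):
            sel_t = {t for t, b in zip(T, tbits) if b}
            e = [(t, r) for t, r in adj if t in sel_t and r in sel_r]
            ok = True
            for q in graph.properties:
                if len(mp.get(q, set()) & sel_t) < p.min_motifs_per_property:
                    ok = False
                if len(rp.get(q, set()) & sel_r) < min(
                    p.min_regions_per_property, len(rp.get(q, set()))
                ):
                    ok = False
            for r in sel_r:
                n = sum(1 for t, rr in adj if rr == r and t in sel_t)
                if n < min(p.min_motifs_per_region, deg_r[r]):
                    ok = False
            for t in sel_t:
                n = sum(1 for tt, r in adj if tt == t and r in sel_r)
                if n < min(p.min_regions_per_motif, deg_t[t]):
                    ok = False
            for g, ts in groups.items():
                if len(sel_t & set(ts)) > p.max_motifs_per_group:
                    ok = False
            for g in graph.hand_picked:
                if not sel_t & set(groups[g]):
                    ok = False
            n_low = sum(1 for x in e if x in low)
            if len(e) < p.lowconf_multiplier * n_low:
                ok = False
            if broad:
                n_b = len(sel_t & broad)
                if n_b < p.broad_multiplier * (len(sel_t) - n_b):
                    ok = False
            if not ok:
                continue
            obj = len(sel_r) + p.edge_weight * len(e)
            if best is None or obj < best:
                best = obj
    return best


def random_toy(rng: np.random.Generator) -> TripartiteGraph:
    nR = int(rng.integers(2, 5))
    nT = int(rng.integers(1, 4))
    edges = [
        (t, r)
        for t in range(nT)
        for r in range(nR)
        if rng.random() < 0.7
    ]
    if not edges:
        edges = [(0, 0)]
    low = {e for e in edges if rng.random() < 0.2}
    groups = {i: f"g{i // 2}" for i in range(nT)}
    hand = {"g0"} if rng.random() < 0.3 else set()
    return toy_graph(nR, nT, edges, lowconf=low, groups=groups, hand_picked=hand)


# ---------------------------------------------------------------------------
# graph generation
# ---------------------------------------------------------------------------

class TestGenerateGraph:
    def test_feasibility_guarantees_by_construction(self):
        cfg = SimConfig(n_regions=100, n_motifs=40, n_properties=6, seed=1)
        g = generate_graph(cfg)
        assert (g.deg_T_prop() >= 12).all()
        # low-confidence edges capped at a fifth of instance edges
        assert g.instance_edges["low_confidence"].sum() <= len(g.instance_edges) / 5
        # at least 60% of motifs are broad, groups of at most 2 motifs
        assert len(g.broad_motifs()) >= 0.6 * len(g.motifs)
        sizes = pd.Series(list(g.tf_group.values())).value_counts()
        assert sizes.max() <= 2
        assert g.hand_picked

    def test_empty_property_layer_is_valid(self):
        cfg = SimConfig(n_regions=40, n_motifs=15, n_properties=0, seed=2)
        g = generate_graph(cfg)
        assert g.properties == []
        model = build_ilp(g)
        assert {1, 2} <= set(model.omitted_families)
        sel = solve_design(model)
        assert check_constraints(g, sel).all_satisfied

    def test_infeasible_parameters_raise_named_error(self):
        with pytest.raises(GraphInfeasibleError, match="12 motifs"):
            generate_graph(SimConfig(n_regions=40, n_motifs=11, n_properties=2, seed=0))
        with pytest.raises(GraphInfeasibleError, match="60%"):
            generate_graph(
                SimConfig(n_regions=40, n_motifs=20, n_properties=0, seed=0,
                          broad_motif_frac=0.4)
            )

    def test_paper_scale_edge_total(self):
        cfg = SimConfig(n_regions=1547, n_motifs=4393, n_properties=68, seed=1)
        g = generate_graph(cfg)
        assert abs(g.n_edges - 99165) <= 0.2 * 99165

    def test_determinism(self):
        cfg = SimConfig(n_regions=50, n_motifs=20, n_properties=2, seed=9)
        g1, g2 = generate_graph(cfg), generate_graph(cfg)
        pd.testing.assert_frame_equal(g1.instance_edges, g2.instance_edges)
        assert g1.tf_group == g2.tf_group


# ---------------------------------------------------------------------------
# ILP vs enumeration
# ---------------------------------------------------------------------------

class TestSolveDesign:
    def test_three_region_toy_matches_enumeration(self):
        g = toy_graph(3, 2, [(t, r) for t in range(2) for r in range(3)])
        sel = solve_design(build_ilp(g))
        assert sel.objective_value == pytest.approx(brute_force_optimum(g))
        assert check_constraints(g, sel).all_satisfied

    def test_random_toys_match_enumeration(self):
        rng = np.random.default_rng(0)
        n_feasible = 0
        for _ in range(60):
            g = random_toy(rng)
            oracle = brute_force_optimum(g)
            model = build_ilp(g)
            if oracle is None:
                with pytest.raises(InfeasibleDesignError):
                    solve_design(model, probe_on_infeasible=False)
            else:
                sel = solve_design(model)
                assert sel.objective_value == pytest.approx(oracle)
                assert check_constraints(g, sel).all_satisfied
                n_feasible += 1
        assert n_feasible >= 10  # the sweep must exercise real solves

    def test_property_with_too_few_motifs_is_infeasible(self):
        # one property connected to 11 motifs: the >= 12 bound cannot hold
        prop_edges = [(0, "motif", i) for i in range(11)]
        g = toy_graph(
            3, 11, [(t, r) for t in range(11) for r in range(3)],
            properties=1, prop_edges=prop_edges,
        )
        with pytest.raises(InfeasibleDesignError, match="12 motifs"):
            solve_design(build_ilp(g))

    def test_all_lowconf_edges_infeasible(self):
        edges = [(t, r) for t in range(2) for r in range(3)]
        g = toy_graph(3, 2, edges, lowconf=set(edges), hand_picked={"g0"},
                      groups={0: "g0", 1: "g1"})
        with pytest.raises(InfeasibleDesignError):
            solve_design(build_ilp(g), probe_on_infeasible=False)

    def test_handpicked_never_decreases_optimum(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = random_toy(rng)
            g.hand_picked = set()
            base = brute_force_optimum(g)
            if base is None:
                continue
            sel0 = solve_design(build_ilp(g))
            g2 = toy_graph(
                len(g.regions), len(g.motifs),
                [(int(t[1:]), int(r[1:]))
                 for t, r in zip(g.instance_edges["motif"], g.instance_edges["region"])],
                groups={i: g.tf_group[t] for i, t in enumerate(g.motifs)},
                hand_picked={g.tf_group[g.motifs[0]]},
            )
            g2.instance_edges["low_confidence"] = g.instance_edges[
                "low_confidence"
            ].to_numpy()
            try:
                sel1 = solve_design(build_ilp(g2), probe_on_infeasible=False)
            except InfeasibleDesignError:
                continue
            assert sel1.objective_value >= sel0.objective_value - 1e-9


# ---------------------------------------------------------------------------
# constraint checker
# ---------------------------------------------------------------------------

class TestCheckConstraints:
    def test_valid_solution_passes(self, small_config):
        g = generate_graph(small_config)
        sel = solve_design(build_ilp(g))
        report = check_constraints(g, sel)
        assert report.all_satisfied
        assert all(f.margin >= 0 for f in report.families.values())

    def test_motif_short_of_region_coverage_has_margin_minus_one(self):
        # motif t0 has graph degree 20 (so the cap is 20) but the
        # hand-built selection covers only 19 of its regions
        from perturbmpra.design import DesignSelection

        edges = [(0, r) for r in range(20)] + [(1, r) for r in range(20)]
        g = toy_graph(20, 2, edges)
        sel_r = g.regions[:19]
        chosen = [("t0", r) for r in sel_r] + [("t1", r) for r in sel_r]
        sel = DesignSelection(
            theta_r={r: int(r in sel_r) for r in g.regions},
            theta_t={t: 1 for t in g.motifs},
            edges=pd.DataFrame(chosen, columns=["motif", "region"]),
            objective_value=0.0,
        )
        report = check_constraints(g, sel)
        assert not report.families[4].satisfied
        assert report.families[4].margin == -1

    def test_empty_selection_violates_handpicked(self):
        g = toy_graph(2, 2, [(0, 0), (1, 1)], hand_picked={"g0"},
                      groups={0: "g0", 1: "g1"})
        from perturbmpra.design import DesignSelection

        sel = DesignSelection(
            theta_r={r: 0 for r in g.regions},
            theta_t={t: 0 for t in g.motifs},
            edges=pd.DataFrame(columns=["motif", "region"]),
            objective_value=0.0,
        )
        report = check_constraints(g, sel)
        assert not report.families[7].satisfied
        assert not report.families[8].satisfied
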