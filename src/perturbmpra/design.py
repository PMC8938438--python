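"""ILP selection of motif instances for a perturbation-MPRA library.

Given the tripartite design graph, select regions (theta_r), motifs
(theta_t) and instance edges (e_{t,r}) minimizing the number of
oligos to synthesize,

    minimize  sum_r theta_r + 3 * sum_{(t,r) in E} e_{t,r}

(one wild-type oligo per selected region plus three perturbation designs
per selected instance), subject to coverage constraints: every property
touched by enough selected motifs and regions, every selected motif seen
in enough regions, every selected region perturbed at enough motifs,
TF-group caps, hand-picked TFs forced in, a floor on the region count,
a cap on low-confidence edges, and a bias toward broadly-occurring motifs.

The model is solved with the HiGHS MILP backend (``scipy.optimize.milp``);
`check_constraints` re-verifies any selection directly from the edge
lists, independent of solver state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .graph import TripartiteGraph

FAMILY_NAMES = {
    1: "property-motif coverage (>= 12 motifs per property)",
    2: "property-region coverage (>= min(17, deg) regions per property)",
    3: "region-motif coverage (>= min(3, deg) motifs per selected region)",
    4: "motif-region coverage (>= min(20, deg) regions per selected motif)",
    5: "edge-node consistency (e = theta_t AND theta_r)",
    6: "TF-group cap (<= 2 motifs per TF)",
    7: "hand-picked TF coverage (>= 1 motif per hand-picked TF)",
    8: "region floor (>= 40% of regions selected)",
    9: "low-confidence edge cap (sum e >= 5 * sum lowconf e)",
    10: "broad-motif bias (broad >= 1.5 * sparse selected motifs)",
}


class InfeasibleDesignError(RuntimeError):
    """Raised when the design ILP is infeasible; carries a cause hint."""


@dataclass
class ConstraintParams:
    """Bounds of the selection program (canonical defaults)."""

    min_motifs_per_property: int = 12
    min_regions_per_property: int = 17
    min_motifs_per_region: int = 3
    min_regions_per_motif: int = 20
    max_motifs_per_group: int = 2
    region_fraction: float = 0.4
    lowconf_multiplier: float = 5.0
    broad_multiplier: float = 1.5
    edge_weight: float = 3.0


@dataclass
class ILPModel:
    graph: TripartiteGraph
    params: ConstraintParams
    c: np.ndarray
    A: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    row_family: np.ndarray  # family id per constraint row
    region_index: dict[str, int]
    motif_index: dict[str, int]
    edge_index: dict[tuple[str, str], int]
    omitted_families: list[int] = field(default_factory=list)

    @property
    def n_vars(self) -> int:
        return len(self.region_index) + len(self.motif_index) + len(self.edge_index)


@dataclass
class DesignSelection:
    theta_r: dict[str, int]
    theta_t: dict[str, int]
    edges: pd.DataFrame  # columns: motif, region
    objective_value: float
    optimal: bool = True
    gap: float = 0.0

    @property
    def selected_regions(self) -> set[str]:
        return {r for r, v in self.theta_r.items() if v}

    @property
    def selected_motifs(self) -> set[str]:
        return {t for t, v in self.theta_t.items() if v}


@dataclass
class FamilyReport:
    family: int
    name: str
    satisfied: bool
    margin: float
    detail: str = ""


@dataclass
class ConstraintReport:
    families: dict[int, FamilyReport]

    @property
    def all_satisfied(self) -> bool:
        return all(f.satisfied for f in self.families.values())

    def to_dict(self) -> dict:
        return {
            str(k): {
                "name": f.name,
                "satisfied": bool(f.satisfied),
                "margin": float(f.margin),
                "detail": f.detail,
            }
            for k, f in self.families.items()
        }


def build_ilp(
    graph: TripartiteGraph, params: ConstraintParams | None = None
) -> ILPModel:
    """Encode the selection program over ``graph``.

    Variable order: regions, then motifs, then instance edges. Families
    whose layer is empty (e.g. no properties) are omitted and logged on
    the model.
    """
    params = params or ConstraintParams()
    nR, nT = len(graph.regions), len(graph.motifs)
    edges = graph.instance_edges
    region_index = {r: i for i, r in enumerate(graph.regions)}
    motif_index = {t: nR + i for i, t in enumerate(graph.motifs)}
    edge_index = {
        (t, r): nR + nT + i
        for i, (t, r) in enumerate(zip(edges["motif"], edges["region"]))
    }
    n = nR + nT + len(edge_index)

    c = np.zeros(n)
    c[:nR] = 1.0
    c[nR + nT :] = params.edge_weight

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lbs: list[float] = []
    ubs: list[float] = []
    fams: list[int] = []
    omitted: list[int] = []
    r_i = 0

    def add_row(terms: list[tuple[int, float]], lo: float, hi: float, fam: int):
        nonlocal r_i
        for j, v in terms:
            rows.append(r_i)
            cols.append(j)
            vals.append(v)
        lbs.append(lo)
        ubs.append(hi)
        fams.append(fam)
        r_i += 1

    inf = np.inf
    mp_by_prop = graph.motif_prop_edges.groupby("property")["motif"]
    rp_by_prop = graph.region_prop_edges.groupby("property")["region"]
    mp_groups = {p: list(g) for p, g in mp_by_prop}
    rp_groups = {p: list(g) for p, g in rp_by_prop}

    # (1) each property covered by >= 12 motifs; (2) >= min(17, deg) regions
    if graph.properties:
        for p in graph.properties:
            ts = mp_groups.get(p, [])
            add_row(
                [(motif_index[t], 1.0) for t in ts],
                params.min_motifs_per_property,
                inf,
                1,
            )
            rs = rp_groups.get(p, [])
            add_row(
                [(region_index[r], 1.0) for r in rs],
                min(params.min_regions_per_property, len(rs)),
                inf,
                2,
            )
    else:
        omitted += [1, 2]

    # (3) selected region connected to >= min(3, deg) selected motifs
    by_region = {r: list(g) for r, g in edges.groupby("region")["motif"]}
    for r in graph.regions:
        ts = by_region.get(r, [])
        cap = min(params.min_motifs_per_region, len(ts))
        if cap == 0:
            continue
        add_row(
            [(motif_index[t], 1.0) for t in ts] + [(region_index[r], -float(cap))],
            0.0,
            inf,
            3,
        )

    # (4) selected motif connected to >= min(20, deg) selected regions
    by_motif = {t: list(g) for t, g in edges.groupby("motif")["region"]}
    for t in graph.motifs:
        rs = by_motif.get(t, [])
        cap = min(params.min_regions_per_motif, len(rs))
        if cap == 0:
            continue
        add_row(
            [(region_index[r], 1.0) for r in rs] + [(motif_index[t], -float(cap))],
            0.0,
            inf,
            4,
        )

    # (5) e >= theta_t + theta_r - 1, e <= theta_t, e <= theta_r.
    # The canonical program states only the lower bound (objective
    # pressure keeps e minimal); the upper bounds make e exactly the
    # selected-pair indicator so feasibility is solver-independent.
    for (t, r), j in edge_index.items():
        ti, ri = motif_index[t], region_index[r]
        add_row([(j, 1.0), (ti, -1.0), (ri, -1.0)], -1.0, inf, 5)
        add_row([(j, 1.0), (ti, -1.0)], -inf, 0.0, 5)
        add_row([(j, 1.0), (ri, -1.0)], -inf, 0.0, 5)

    # (6) <= 2 motifs per TF group; (7) hand-picked TFs represented
    if graph.tf_group:
        groups: dict[str, list[str]] = {}
        for t, g in graph.tf_group.items():
            groups.setdefault(g, []).append(t)
        for g, ts in groups.items():
            if len(ts) > params.max_motifs_per_group:
                add_row(
                    [(motif_index[t], 1.0) for t in ts],
                    -inf,
                    params.max_motifs_per_group,
                    6,
                )
        for g in sorted(graph.hand_picked):
            add_row([(motif_index[t], 1.0) for t in groups[g]], 1.0, inf, 7)
        if not graph.hand_picked:
            omitted.append(7)
    else:
        omitted += [6, 7]

    # (8) at least 40% of all regions selected
    add_row(
        [(region_index[r], 1.0) for r in graph.regions],
        params.region_fraction * nR,
        inf,
        8,
    )

    # (9) sum_E e >= 5 * sum_{E_p} e  (low-confidence edge cap)
    if edges["low_confidence"].any():
        low = dict(
            zip(zip(edges["motif"], edges["region"]), edges["low_confidence"])
        )
        terms = [
            (j, 1.0 - params.lowconf_multiplier if low[key] else 1.0)
            for key, j in edge_index.items()
        ]
        add_row(terms, 0.0, inf, 9)
    else:
        omitted.append(9)

    # (10) broad motifs >= 1.5 * sparse motifs among selected; vacuous
    # (and omitted) when the broad subset is empty
    broad = graph.broad_motifs()
    if broad:
        add_row(
            [
                (motif_index[t], 1.0 if t in broad else -params.broad_multiplier)
                for t in graph.motifs
            ],
            0.0,
            inf,
            10,
        )
    else:
        omitted.append(10)

    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(r_i, n) if r_i else (0, n)
    )
    return ILPModel(
        graph=graph,
        params=params,
        c=c,
        A=A,
        lb=np.array(lbs),
        ub=np.array(ubs),
        row_family=np.array(fams, dtype=int),
        region_index=region_index,
        motif_index=motif_index,
        edge_index=edge_index,
        omitted_families=sorted(set(omitted)),
    )


def solve_design(
    model: ILPModel,
    time_limit: float | None = None,
    mip_rel_gap: float = 0.0,
    probe_on_infeasible: bool = True,
) -> DesignSelection:
    """Solve the selection MILP; on infeasibility, probe for the cause.

    Probing relaxes constraint families one at a time (in canonical
    order) and reports the first family whose removal restores
    feasibility.
    """
    res = _run_milp(model, None, time_limit, mip_rel_gap)
    if res.status == 2:  # infeasible
        hint = ""
        if probe_on_infeasible:
            fam = _probe_infeasibility(model, time_limit)
            if fam is not None:
                hint = f"; relaxation probing implicates family ({fam}): {FAMILY_NAMES[fam]}"
        raise InfeasibleDesignError(f"design ILP infeasible{hint}")
    if res.x is None:
        raise InfeasibleDesignError(f"solver failed: {res.message}")
    x = np.round(res.x).astype(int)
    graph = model.graph
    theta_r = {r: int(x[j]) for r, j in model.region_index.items()}
    theta_t = {t: int(x[j]) for t, j in model.motif_index.items()}
    chosen = [
        (t, r) for (t, r), j in model.edge_index.items() if x[j] == 1
    ]
    edges = pd.DataFrame(chosen, columns=["motif", "region"])
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    return DesignSelection(
        theta_r=theta_r,
        theta_t=theta_t,
        edges=edges,
        objective_value=float(res.fun),
        optimal=(res.status == 0 and gap <= max(mip_rel_gap, 1e-9)),
        gap=gap,
    )


def _run_milp(model: ILPModel, drop_families, time_limit, mip_rel_gap):
    A, lb, ub = model.A, model.lb, model.ub
    if drop_families:
        keep = ~np.isin(model.row_family, list(drop_families))
        A, lb, ub = A[keep], lb[keep], ub[keep]
    constraints = LinearConstraint(A, lb, ub) if A.shape[0] else ()
    opts = {"mip_rel_gap": mip_rel_gap}
    if time_limit is not None:
        opts["time_limit"] = time_limit
    from scipy.optimize import Bounds

    return milp(
        model.c,
        constraints=constraints,
        integrality=np.ones(model.n_vars),
        bounds=Bounds(0, 1),
        options=opts,
    )


def _probe_infeasibility(model: ILPModel, time_limit) -> int | None:
    dropped: list[int] = []
    for fam in range(1, 11):
        if fam not in model.row_family:
            continue
        dropped.append(fam)
        res = _run_milp(model, dropped, time_limit, 0.05)
        if res.status != 2:
            return fam
    return None


def check_constraints(
    graph: TripartiteGraph,
    selection: DesignSelection,
    params: ConstraintParams | None = None,
) -> ConstraintReport:
    """Verify a selection against every constraint family.

    Recomputed entirely from the graph's edge lists and the selection;
    no solver state is consulted. Margins are worst-case slack (negative
    means violated).
    """
    params = params or ConstraintParams()
    sel_r = selection.selected_regions
    sel_t = selection.selected_motifs
    chosen = set(zip(selection.edges["motif"], selection.edges["region"]))
    fams: dict[int, FamilyReport] = {}

    def rep(fam, margin, detail=""):
        fams[fam] = FamilyReport(
            fam, FAMILY_NAMES[fam], margin >= 0, float(margin), detail
        )

    inst = graph.instance_edges
    # (1) & (2)
    if graph.properties:
        m1, m2 = np.inf, np.inf
        mp = {p: set(g) for p, g in graph.motif_prop_edges.groupby("property")["motif"]}
        rp = {p: set(g) for p, g in graph.region_prop_edges.groupby("property")["region"]}
        for p in graph.properties:
            ts = mp.get(p, set())
            m1 = min(m1, len(ts & sel_t) - params.min_motifs_per_property)
            rs = rp.get(p, set())
            m2 = min(
                m2,
                len(rs & sel_r) - min(params.min_regions_per_property, len(rs)),
            )
        rep(1, m1)
        rep(2, m2)

    # (3) selected regions
    by_region = {r: set(g) for r, g in inst.groupby("region")["motif"]}
    m3 = np.inf
    for r in sel_r:
        ts = by_region.get(r, set())
        m3 = min(
            m3,
            len(ts & sel_t) - min(params.min_motifs_per_region, len(ts)),
        )
    rep(3, m3 if sel_r else np.inf)

    # (4) selected motifs
    by_motif = {t: set(g) for t, g in inst.groupby("motif")["region"]}
    m4 = np.inf
    for t in sel_t:
        rs = by_motif.get(t, set())
        m4 = min(
            m4,
            len(rs & sel_r) - min(params.min_regions_per_motif, len(rs)),
        )
    rep(4, m4 if sel_t else np.inf)

    # (5) e exactly the selected-pair indicator over E
    expected = {
        (t, r)
        for t, r in zip(inst["motif"], inst["region"])
        if t in sel_t and r in sel_r
    }
    n_bad = len(chosen ^ expected)
    rep(5, -n_bad if n_bad else 0, f"{n_bad} inconsistent edges" if n_bad else "")

    # (6) & (7)
    if graph.tf_group:
        counts: dict[str, int] = {}
        for t in sel_t:
            g = graph.tf_group[t]
            counts[g] = counts.get(g, 0) + 1
        worst = max(counts.values(), default=0)
        rep(6, params.max_motifs_per_group - worst)
        if graph.hand_picked:
            m7 = min(
                (counts.get(g, 0) for g in graph.hand_picked), default=np.inf
            )
            rep(7, m7 - 1)

    # (8)
    rep(8, len(sel_r) - params.region_fraction * len(graph.regions))

    # (9)
    if inst["low_confidence"].any():
        lowset = set(
            zip(
                inst.loc[inst["low_confidence"], "motif"],
                inst.loc[inst["low_confidence"], "region"],
            )
        )
        n_low = sum(1 for e in chosen if e in lowset)
        rep(9, len(chosen) - params.lowconf_multiplier * n_low)

    # (10) — vacuous when the graph has no broad motifs
    broad = graph.broad_motifs()
    if broad:
        n_broad = len(sel_t & broad)
        n_sparse = len(sel_t) - n_broad
        rep(10, n_broad - params.broad_multiplier * n_sparse)

    return ConstraintReport(families=fams)
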