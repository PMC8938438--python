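"""Tripartite design graph: regions, motifs and biological properties.

The design universe for the selection ILP. Region and motif nodes are
joined by *instance* edges (a motif occurrence in a region, optionally
flagged low-confidence); both layers are annotated with property nodes
describing shared temporal/epigenomic behavior. Motifs are partitioned
into TF groups (several PWMs may represent one factor), a subset of which
may be hand-picked for mandatory inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: motifs connected to at least this many regions form the "broad" subset
BROAD_DEGREE = 5


@dataclass
class TripartiteGraph:
    regions: list[str]
    motifs: list[str]
    properties: list[str]
    #: columns: motif, region, low_confidence (bool)
    instance_edges: pd.DataFrame
    #: columns: motif, property
    motif_prop_edges: pd.DataFrame
    #: columns: region, property
    region_prop_edges: pd.DataFrame
    #: motif -> TF group id (groups partition the motif layer)
    tf_group: dict[str, str] = field(default_factory=dict)
    #: TF group ids whose factors must be represented in any selection
    hand_picked: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rset, tset, pset = set(self.regions), set(self.motifs), set(self.properties)
        if not set(self.instance_edges["motif"]) <= tset:
            raise ValueError("instance edge references unknown motif")
        if not set(self.instance_edges["region"]) <= rset:
            raise ValueError("instance edge references unknown region")
        if not set(self.motif_prop_edges["motif"]) <= tset:
            raise ValueError("motif-property edge references unknown motif")
        if not set(self.motif_prop_edges["property"]) <= pset:
            raise ValueError("motif-property edge references unknown property")
        if not set(self.region_prop_edges["region"]) <= rset:
            raise ValueError("region-property edge references unknown region")
        if not set(self.region_prop_edges["property"]) <= pset:
            raise ValueError("region-property edge references unknown property")
        missing = tset - set(self.tf_group)
        if self.tf_group and missing:
            raise ValueError(f"motifs without TF group: {sorted(missing)[:5]}")
        if not self.hand_picked <= set(self.tf_group.values()):
            raise ValueError("hand_picked contains unknown TF group")
        dup = self.instance_edges.duplicated(["motif", "region"])
        if dup.any():
            raise ValueError("duplicate instance edges")

    # -- degree helpers (all computed from raw edge lists) -------------
    def deg_R_motif(self) -> pd.Series:
        """Number of regions connected to each motif."""
        d = self.instance_edges.groupby("motif").size()
        return d.reindex(self.motifs, fill_value=0)

    def deg_T_region(self) -> pd.Series:
        """Number of motifs connected to each region."""
        d = self.instance_edges.groupby("region").size()
        return d.reindex(self.regions, fill_value=0)

    def deg_T_prop(self) -> pd.Series:
        d = self.motif_prop_edges.groupby("property").size()
        return d.reindex(self.properties, fill_value=0)

    def deg_R_prop(self) -> pd.Series:
        d = self.region_prop_edges.groupby("property").size()
        return d.reindex(self.properties, fill_value=0)

    def broad_motifs(self) -> set[str]:
        """Motifs connected to >= 5 regions (on the input graph)."""
        deg = self.deg_R_motif()
        return set(deg.index[deg >= BROAD_DEGREE])

    @property
    def n_edges(self) -> int:
        """Total edge count across all three edge types."""
        return (
            len(self.instance_edges)
            + len(self.motif_prop_edges)
            + len(self.region_prop_edges)
        )

    # -- I/O ------------------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame(
            [("region", r, "", False) for r in self.regions]
            + [
                (
                    "motif",
                    t,
                    self.tf_group.get(t, ""),
                    self.tf_group.get(t, "") in self.hand_picked,
                )
                for t in self.motifs
            ]
            + [("property", p, "", False) for p in self.properties],
            columns=["layer", "node_id", "tf_group", "hand_picked"],
        )
        nodes.to_csv(path / "nodes.tsv", sep="\t", index=False)
        self.instance_edges.to_csv(path / "instance_edges.tsv", sep="\t", index=False)
        self.motif_prop_edges.to_csv(
            path / "motif_prop_edges.tsv", sep="\t", index=False
        )
        self.region_prop_edges.to_csv(
            path / "region_prop_edges.tsv", sep="\t", index=False
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "TripartiteGraph":
        path = Path(path)
        nodes = pd.read_csv(path / "nodes.tsv", sep="\t", keep_default_na=False)
        motif_rows = nodes[nodes["layer"] == "motif"]
        tf_group = dict(zip(motif_rows["node_id"], motif_rows["tf_group"]))
        hand = set(
            motif_rows.loc[
                motif_rows["hand_picked"].astype(str).str.lower() == "true",
                "tf_group",
            ]
        )
        inst = pd.read_csv(path / "instance_edges.tsv", sep="\t")
        inst["low_confidence"] = inst["low_confidence"].astype(bool)
        return cls(
            regions=list(nodes.loc[nodes["layer"] == "region", "node_id"]),
            motifs=list(motif_rows["node_id"]),
            properties=list(nodes.loc[nodes["layer"] == "property", "node_id"]),
            instance_edges=inst,
            motif_prop_edges=pd.read_csv(path / "motif_prop_edges.tsv", sep="\t"),
            region_prop_edges=pd.read_csv(path / "region_prop_edges.tsv", sep="\t"),
            tf_group=tf_group,
            hand_picked=hand,
        )
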