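"""Metabolic pathway model, reaction coverage, and cross-talk networks.

A pathway database maps pathways to reactions and reactions to genes.
Two complementary summaries of differential expression are computed on
it: the reaction-coverage ratio (fraction of a pathway's reactions that
contain at least one DE gene), and a pathway cross-talk network in which
collapsed pathways are nodes, an edge joins two pathways whenever they
share at least one DE gene (weight = number shared, classed as <=5, 6-9
or >=10), and each node carries the score (#up - #down) of its DE genes.
Hormone-related pathways can be projected to the subgraph spanned by all
unweighted shortest paths between hormone pathway pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from droughtseq.errors import DesignError, FormatError
from droughtseq.enrich import is_scaffold_gene

EDGE_CLASSES = ("<=5", "6-9", ">=10")


def edge_weight_class(weight: int) -> str:
    if weight >= 10:
        return ">=10"
    if weight >= 6:
        return "6-9"
    return "<=5"


def node_score_class(score: int) -> str:
    """Shading class for a node: up-dominated, down-dominated or neutral."""
    if score > 0:
        return "up"
    if score < 0:
        return "down"
    return "neutral"


@dataclass
class PathwayDB:
    """pathway -> reactions -> genes, with hormone flags and a collapse map."""

    reactions: dict[str, set[str]]            # pathway id -> reaction ids
    reaction_genes: dict[str, set[str]]       # reaction id -> gene ids
    hormone: set[str] = field(default_factory=set)
    collapse_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pwy, rxns in self.reactions.items():
            for r in rxns:
                if r not in self.reaction_genes:
                    self.reaction_genes[r] = set()

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, collapse_map: dict[str, str] | None = None,
        drop_scaffolds: bool = True,
    ) -> "PathwayDB":
        """Build from rows (pathway_id, reaction_id, gene_id, is_hormone)."""
        required = {"pathway_id", "reaction_id", "gene_id"}
        if not required <= set(table.columns):
            raise FormatError(f"pathway table needs columns {sorted(required)}")
        df = table.copy()
        if drop_scaffolds:
            df = df[~df["gene_id"].astype(str).map(is_scaffold_gene)]
        reactions: dict[str, set[str]] = {}
        reaction_genes: dict[str, set[str]] = {}
        hormone: set[str] = set()
        for row in df.itertuples(index=False):
            reactions.setdefault(row.pathway_id, set()).add(row.reaction_id)
            reaction_genes.setdefault(row.reaction_id, set()).add(row.gene_id)
            if getattr(row, "is_hormone", False):
                hormone.add(row.pathway_id)
        return cls(
            reactions=reactions,
            reaction_genes=reaction_genes,
            hormone=hormone,
            collapse_map=dict(collapse_map or {}),
        )

    @classmethod
    def read_tsv(cls, path, collapse_map_path=None) -> "PathwayDB":
        table = pd.read_csv(path, sep="\t")
        cmap = None
        if collapse_map_path is not None:
            cdf = pd.read_csv(collapse_map_path, sep="\t")
            cmap = dict(zip(cdf.iloc[:, 0], cdf.iloc[:, 1]))
        return cls.from_table(table, collapse_map=cmap)

    def pathways(self) -> list[str]:
        return sorted(self.reactions)

    def pathway_genes(self, pathway: str) -> set[str]:
        return set().union(
            *(self.reaction_genes[r] for r in self.reactions[pathway])
        ) if self.reactions[pathway] else set()

    def gene_universe(self) -> set[str]:
        return set().union(*self.reaction_genes.values()) \
            if self.reaction_genes else set()

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "pathway_id": p,
                "reaction_id": r,
                "gene_id": g,
                "is_hormone": p in self.hormone,
            }
            for p in sorted(self.reactions)
            for r in sorted(self.reactions[p])
            for g in sorted(self.reaction_genes[r])
        ]
        return pd.DataFrame(
            rows, columns=["pathway_id", "reaction_id", "gene_id", "is_hormone"]
        )


def reaction_coverage(
    db: PathwayDB, de_set: set, min_reactions: int = 3
) -> pd.DataFrame:
    """Per-pathway ratio of reactions containing >= 1 DE gene.

    Pathways with fewer than ``min_reactions`` reactions are excluded from
    the report (small pathways make the ratio uninformative); zero-reaction
    pathways are dropped with a warning.
    """
    rows = []
    for pwy in db.pathways():
        rxns = db.reactions[pwy]
        if not rxns:
            warnings.warn(f"pathway {pwy} has no reactions; excluded",
                          stacklevel=2)
            continue
        if len(rxns) < min_reactions:
            continue
        hit = sum(1 for r in rxns if db.reaction_genes[r] & de_set)
        rows.append(
            {
                "pathway_id": pwy,
                "n_reactions": len(rxns),
                "n_reactions_with_de": hit,
                "ratio": hit / len(rxns),
            }
        )
    return pd.DataFrame(
        rows, columns=["pathway_id", "n_reactions", "n_reactions_with_de", "ratio"]
    ).set_index("pathway_id")


def _resolve_map(mapping: dict[str, str]) -> dict[str, str]:
    """Follow chains raw -> ... -> final target; reject cycles."""
    resolved = {}
    for start in mapping:
        seen = [start]
        cur = start
        while cur in mapping and mapping[cur] != cur:
            cur = mapping[cur]
            if cur in seen:
                raise DesignError(f"cyclic collapse map at {cur!r}")
            seen.append(cur)
        resolved[start] = cur
    return resolved


def collapse(db: PathwayDB, mapping: dict[str, str] | None = None) -> PathwayDB:
    """Merge related pathway variants per the collapse map.

    Member reaction/gene sets become unions; unmapped pathways pass
    through unchanged; a collapsed pathway is hormone-flagged if any
    source pathway was.
    """
    mapping = _resolve_map(mapping if mapping is not None else db.collapse_map)
    reactions: dict[str, set[str]] = {}
    hormone: set[str] = set()
    for pwy, rxns in db.reactions.items():
        target = mapping.get(pwy, pwy)
        reactions.setdefault(target, set()).update(rxns)
        if pwy in db.hormone:
            hormone.add(target)
    return PathwayDB(
        reactions=reactions,
        reaction_genes={r: set(g) for r, g in db.reaction_genes.items()},
        hormone=hormone,
        collapse_map={},
    )


def build_network(db: PathwayDB, de_table: pd.DataFrame) -> nx.Graph:
    """Pathway cross-talk graph from a (collapsed) DB and a DE table.

    ``de_table`` is indexed by gene with a ``direction`` column; only
    genes with direction ``up`` or ``down`` contribute.  Nodes are the
    pathways containing >= 1 DE gene; an edge joins two pathways iff they
    share >= 1 DE gene (a shared gene counts once per pair no matter how
    many reactions carry it).
    """
    directions = de_table.loc[
        de_table["direction"].isin(["up", "down"]), "direction"
    ]
    de_set = set(directions.index)
    graph = nx.Graph()
    de_by_pathway = {}
    for pwy in db.pathways():
        genes = db.pathway_genes(pwy) & de_set
        if not genes:
            continue
        de_by_pathway[pwy] = genes
        n_up = sum(1 for g in genes if directions[g] == "up")
        n_down = len(genes) - n_up
        score = n_up - n_down
        graph.add_node(
            pwy,
            n_up=n_up,
            n_down=n_down,
            score=score,
            score_class=node_score_class(score),
            is_hormone=pwy in db.hormone,
        )
    for a, b in itertools.combinations(sorted(de_by_pathway), 2):
        shared = de_by_pathway[a] & de_by_pathway[b]
        if shared:
            graph.add_edge(
                a, b,
                weight=len(shared),
                weight_class=edge_weight_class(len(shared)),
                shared_genes=",".join(sorted(shared)),
            )
    return graph


def hormone_subnetwork(
    graph: nx.Graph, hormone_pathways: set[str] | None = None,
    mode: str = "shortest_path",
) -> nx.Graph:
    """Project the cross-talk graph onto the hormone neighborhood.

    ``shortest_path`` mode keeps every node lying on at least one
    unweighted (hop-count) shortest path between any pair of hormone
    pathways, with all tied paths included; ``neighbors`` mode instead
    keeps hormone pathways plus their direct neighbors.  Hormone nodes
    are always retained, even as isolates.
    """
    if hormone_pathways is None:
        hormone_pathways = {
            n for n, d in graph.nodes(data=True) if d.get("is_hormone")
        }
    hormones = sorted(set(hormone_pathways) & set(graph.nodes))
    if len(hormones) < 2:
        raise DesignError("hormone subnetwork needs >= 2 hormone pathways")
    keep: set[str] = set(hormones)
    if mode == "shortest_path":
        for a, b in itertools.combinations(hormones, 2):
            if nx.has_path(graph, a, b):
                for path in nx.all_shortest_paths(graph, a, b):
                    keep.update(path)
    elif mode == "neighbors":
        for h in hormones:
            keep.update(graph.neighbors(h))
    else:
        raise DesignError(f"unknown hormone subnetwork mode {mode!r}")
    return graph.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_sif(graph: nx.Graph, sif_path, node_attr_path=None,
              edge_attr_path=None) -> None:
    """SIF edge list plus node/edge attribute tables for Cytoscape."""
    with open(sif_path, "w") as fh:
        isolated = [n for n in graph.nodes if graph.degree(n) == 0]
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\tshares_de_genes\t{b}\n")
        for n in sorted(isolated):
            fh.write(f"{n}\n")
    if node_attr_path is not None:
        pd.DataFrame(
            [{"node": n, **d} for n, d in sorted(graph.nodes(data=True))]
        ).to_csv(node_attr_path, sep="\t", index=False)
    if edge_attr_path is not None:
        pd.DataFrame(
            [
                {"source": a, "target": b, **d}
                for (a, b), d in sorted(
                    ((tuple(sorted(e)), d) for *e, d in graph.edges(data=True))
                )
            ]
        ).to_csv(edge_attr_path, sep="\t", index=False)
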