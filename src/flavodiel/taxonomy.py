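"""Taxonomy handling: LCA assignment and rank roll-ups.

A taxonomy is a rooted forest-free DAG of (taxid, parent, rank, name)
rows, supplied as a TSV so tests need no external database. The lowest
common ancestor of a hit set gives a contig's taxon; rolling contigs up
to order rank yields the order-level read totals used as normalization
denominators for the flavodoxin fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("root", "domain", "kingdom", "phylum", "class", "order",
         "family", "genus", "species")


@dataclass
class Taxonomy:
    parent: dict   # taxid -> parent taxid (root maps to itself or None)
    rank: dict     # taxid -> rank string
    name: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [t for t, p in self.parent.items()
                 if p is None or p == t]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for t in self.parent:
            if not self._reaches_root(t):
                raise ValueError(f"node {t} does not reach the root (cycle or orphan)")

    def _reaches_root(self, node) -> bool:
        seen = set()
        while node != self.root:
            if node in seen or node not in self.parent:
                return False
            seen.add(node)
            node = self.parent[node]
        return True

    def path_to_root(self, node) -> list:
        """Node and all its ancestors, ending at the root."""
        if node not in self.parent:
            raise KeyError(f"unknown taxid {node!r}")
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Taxonomy":
        parent, rank, name = {}, {}, {}
        for row in df.itertuples(index=False):
            taxid = str(row.taxid)
            parent[taxid] = None if pd.isna(row.parent) or str(row.parent) in ("", taxid) else str(row.parent)
            rank[taxid] = str(row.rank)
            name[taxid] = str(getattr(row, "name", taxid))
        return cls(parent=parent, rank=rank, name=name)

    @classmethod
    def read_tsv(cls, path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[""])
        return cls.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, "" if self.parent[t] is None else self.parent[t],
                 self.rank[t], self.name.get(t, t))
                for t in self.parent]
        return pd.DataFrame(rows, columns=["taxid", "parent", "rank", "name"])


def _depth(node, taxonomy: Taxonomy) -> int:
    return len(taxonomy.path_to_root(node)) - 1


def _lca_pair(a, b, taxonomy: Taxonomy):
    """Pairwise LCA by walking the deeper node up until the paths merge."""
    da, db = _depth(a, taxonomy), _depth(b, taxonomy)
    while da > db:
        a, da = taxonomy.parent[a], da - 1
    while db > da:
        b, db = taxonomy.parent[b], db - 1
    while a != b:
        a, b = taxonomy.parent[a], taxonomy.parent[b]
    return a


def lca(node_ids, taxonomy: Taxonomy):
    """Lowest common ancestor of a non-empty set of taxids.

    The deepest node that is an ancestor of (or equal to) every input;
    computed by folding the depth-aligned pairwise walk over the set.
    """
    ids = list(node_ids)
    if not ids:
        raise ValueError("lca of empty set")
    for node in ids:
        if node not in taxonomy.parent:
            raise KeyError(f"unknown taxid {node!r}")
    result = ids[0]
    for node in ids[1:]:
        result = _lca_pair(result, node, taxonomy)
    return result


def ancestor_at_rank(node, rank: str, taxonomy: Taxonomy):
    """The unique ancestor (or self) at the given rank, or None."""
    for anc in taxonomy.path_to_root(node):
        if taxonomy.rank[anc] == rank:
            return anc
    return None


def order_totals(
    assignments: dict,
    rpl: pd.DataFrame,
    taxonomy: Taxonomy,
    rank: str = "order",
) -> pd.DataFrame:
    """Sum reads/L per (order, sample) over contigs resolvable to that rank.

    ``assignments`` maps contig id -> taxid (its LCA); ``rpl`` is a
    contig x sample table. Contigs without an assignment, or whose taxon
    does not resolve to the requested rank, are excluded (and logged) so
    they never inflate a denominator.
    """
    groups = {}
    for contig in rpl.index:
        taxid = assignments.get(contig)
        if taxid is None:
            logger.warning("contig %r has no taxon assignment; excluded", contig)
            continue
        anc = ancestor_at_rank(taxid, rank, taxonomy)
        if anc is None:
            logger.info("contig %r resolves above %s rank; excluded", contig, rank)
            continue
        groups.setdefault(anc, []).append(contig)
    if not groups:
        return pd.DataFrame(columns=rpl.columns)
    rows = {order: rpl.loc[contigs].sum(axis=0) for order, contigs in groups.items()}
    out = pd.DataFrame(rows).T
    out.index.name = rank
    return out.sort_index()
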