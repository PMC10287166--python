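"""Evolutionary placement of query sequences on a fixed reference tree.

Each query is attached, one edge at a time, by a new node at the edge
midpoint with a free pendant branch; the pendant length is optimised by
golden-section search on the log-likelihood. Per-edge likelihoods are
converted to likelihood weight ratios (LWRs) by a numerically stable
softmax over all tree edges, and placements are filtered by the best
edge's LWR and the taxonomic resolution of its distal leaf set.

The engine precomputes, once per (tree, reference alignment), the
conditional likelihoods below every node and above every edge, so that a
single pendant-length evaluation costs only one 20x20 matrix product per
gamma category.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .likelihood import _scaled, compute_down_partials, leaf_partial
from .phylo import ReferencePhylogeny, edge_numbering, read_newick, write_newick
from .substitution import N_STATES, SubstitutionModel, encode_sequence

VALID_CLADES = ("cladeI", "cladeII", "bacterial_green", "cyano_dino_green", "outgroup")
PLACEMENT_CLADES = ("cladeI", "cladeII")
MIN_MAPPED_COLUMNS = 10


@dataclass
class AlignedQuery:
    """A query expressed in reference-alignment coordinates.

    ``column_map`` maps 0-based reference column -> residue code;
    unmapped reference columns are missing data, and query insertions
    relative to the reference are dropped.
    """
    query_id: str
    column_map: dict

    def n_mapped(self) -> int:
        return len(self.column_map)

    def codes(self, n_columns: int) -> np.ndarray:
        out = np.full(n_columns, -1, dtype=np.int64)
        for col, code in self.column_map.items():
            out[col] = code
        return out

    @classmethod
    def from_aligned_string(cls, query_id: str, aligned: str) -> "AlignedQuery":
        codes = encode_sequence(aligned)
        return cls(query_id, {i: int(c) for i, c in enumerate(codes) if c >= 0})


@dataclass
class EdgePlacement:
    edge_id: int
    log_likelihood: float
    pendant_length: float
    like_weight_ratio: float


@dataclass
class PlacementResult:
    query_id: str
    placements: list = field(default_factory=list)  # EdgePlacement, best first
    best_edge: int | None = None
    assigned_clade: str | None = None
    assigned_genus: str | None = None
    kept: bool = False
    reason: str | None = None

    @property
    def best(self) -> EdgePlacement | None:
        return self.placements[0] if self.placements else None


def golden_section_max(f, lo: float, hi: float, tol: float = 1e-6) -> tuple:
    """Maximise a unimodal function on [lo, hi]; returns (x, f(x))."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


class PlacementEngine:
    """Caches reference partials for fast per-edge query attachment."""

    def __init__(
        self,
        tree: ReferencePhylogeny,
        model: SubstitutionModel,
        ref_alignment: dict,
        pendant_bounds: tuple = (1e-8, 2.0),
        pendant_tol: float = 1e-6,
    ) -> None:
        self.tree = tree
        self.model = model
        self.pendant_bounds = pendant_bounds
        self.pendant_tol = pendant_tol
        codes = {
            k: (v if isinstance(v, np.ndarray) else encode_sequence(v))
            for k, v in ref_alignment.items()
        }
        self.n_sites = next(iter(codes.values())).size
        k = model.n_categories
        down, down_ls = compute_down_partials(tree, model, codes)

        # message from each child into its parent: M_c = P(t_c) @ D_c
        msg = {}
        for c in tree.edges:
            pm = model.transition_matrices(float(tree.lengths[c]))
            msg[c] = np.einsum("kxy,kys->kxs", pm, down[c])

        # up vectors W_e: partial at the parent-side endpoint of edge e,
        # seen from e (root prior included), with per-site log scalers
        up_w = [None] * tree.n_nodes
        up_ls = [None] * tree.n_nodes
        pi = model.frequencies
        for v in tree.preorder():
            for c in tree.children[v]:
                if v == tree.root:
                    w = np.broadcast_to(pi[None, :, None], (k, N_STATES, self.n_sites)).copy()
                    ls = np.zeros(self.n_sites)
                else:
                    pm = model.transition_matrices(float(tree.lengths[v]))
                    w = np.einsum("kyx,kys->kxs", pm, up_w[v])
                    ls = up_ls[v].copy()
                for sib in tree.children[v]:
                    if sib != c:
                        w = w * msg[sib]
                        ls = ls + down_ls[sib]
                w, extra = _scaled(w)
                up_w[c] = w
                up_ls[c] = ls + extra

        # midpoint attachment: C_e = (P(t/2)^T W_e) * (P(t/2) D_c)
        self._edge_core = {}
        self._edge_ls = {}
        for c in tree.edges:
            pm_half = model.transition_matrices(float(tree.lengths[c]) / 2.0)
            above = np.einsum("kyx,kys->kxs", pm_half, up_w[c])
            below = np.einsum("kxy,kys->kxs", pm_half, down[c])
            core, extra = _scaled(above * below)
            self._edge_core[c] = core
            self._edge_ls[c] = up_ls[c] + down_ls[c] + extra
        self._weights = model.category_weights

    def reference_loglik(self) -> float:
        """Likelihood of the reference alignment alone (no query attached)."""
        e = self.tree.edges[0]
        site = np.einsum("k,kxs->s", self._weights, self._edge_core[e])
        return float(np.sum(np.log(site) + self._edge_ls[e]))

    def edge_loglik(self, edge: int, query_part: np.ndarray, pendant: float,
                    site_mask: np.ndarray | None = None) -> float:
        """Log-likelihood with the query attached mid-edge at given pendant."""
        pm = self.model.transition_matrices(pendant)
        qp = np.einsum("kxy,ys->kxs", pm, query_part)
        site = np.einsum("k,kxs,kxs->s", self._weights, self._edge_core[edge], qp)
        logs = np.log(site) + self._edge_ls[edge]
        if site_mask is not None:
            logs = logs[site_mask]
        return float(logs.sum())

    def place(self, query: AlignedQuery) -> PlacementResult:
        """Attach the query to every edge; return per-edge LWRs, best first."""
        if query.n_mapped() < MIN_MAPPED_COLUMNS:
            return PlacementResult(query_id=query.query_id, kept=False,
                                   reason="insufficient overlap")
        codes = query.codes(self.n_sites)
        qpart = leaf_partial(codes)
        lo, hi = self.pendant_bounds
        records = []
        for e in self.tree.edges:
            pend, ll = golden_section_max(
                lambda t: self.edge_loglik(e, qpart, t), lo, hi, self.pendant_tol
            )
            records.append((e, ll, pend))
        lls = np.array([r[1] for r in records])
        lwr = np.exp(lls - lls.max())
        lwr /= lwr.sum()
        # best edge: max LWR, ties broken by smallest edge id
        order = sorted(range(len(records)),
                       key=lambda i: (-lls[i], records[i][0]))
        placements = [
            EdgePlacement(records[i][0], float(lls[i]), float(records[i][2]), float(lwr[i]))
            for i in order
        ]
        return PlacementResult(
            query_id=query.query_id,
            placements=placements,
            best_edge=placements[0].edge_id,
        )


def epa_place(
    tree: ReferencePhylogeny,
    ref_alignment: dict,
    model: SubstitutionModel,
    query: AlignedQuery,
    engine: PlacementEngine | None = None,
) -> PlacementResult:
    """Place a single aligned query on the reference tree (convenience API).

    For many queries on one tree construct a PlacementEngine once and call
    ``engine.place`` repeatedly.
    """
    if engine is None:
        engine = PlacementEngine(tree, model, ref_alignment)
    return engine.place(query)


@dataclass
class CladeAnnotation:
    """Per-leaf clade / genus / species / taxonomic-order annotations."""
    clade: dict
    genus: dict
    species: dict
    order_taxid: dict

    def validate(self, tree: ReferencePhylogeny) -> None:
        for lab in tree.leaf_labels:
            if lab not in self.clade:
                raise KeyError(f"leaf {lab!r} missing from annotation")
            if self.clade[lab] not in VALID_CLADES:
                raise ValueError(f"unknown clade label {self.clade[lab]!r} for {lab!r}")


def filter_and_assign(
    result: PlacementResult,
    tree: ReferencePhylogeny,
    annot: CladeAnnotation,
    lwr_min: float = 0.8,
) -> PlacementResult:
    """Keep placements that are confident and taxonomically resolved.

    A query is kept iff the best edge's LWR exceeds ``lwr_min``, the leaves
    distal to the best edge belong to exactly one genus, and that genus's
    clade is one of the two stramenopile flavodoxin clades. Unkept results
    carry a reason code ('lwr', 'rank', or 'clade').
    """
    if result.best is None:
        result.kept = False
        result.reason = result.reason or "no placement"
        return result
    best = result.best
    if not (best.like_weight_ratio > lwr_min):
        result.kept, result.reason = False, "lwr"
        return result
    leaves = [tree.labels[v] for v in tree.leaves_below(best.edge_id)]
    genera = {annot.genus[l] for l in leaves}
    clades = {annot.clade[l] for l in leaves}
    if len(genera) != 1:
        result.kept, result.reason = False, "rank"
        return result
    clade = clades.pop() if len(clades) == 1 else None
    if clade not in PLACEMENT_CLADES:
        result.kept, result.reason = False, "clade"
        return result
    result.kept = True
    result.reason = None
    result.assigned_clade = clade
    result.assigned_genus = genera.pop()
    return result


# ---------------------------------------------------------------------------
# jplace interchange
# ---------------------------------------------------------------------------

JPLACE_FIELDS = ["edge_num", "likelihood", "like_weight_ratio", "pendant_length"]


def write_jplace(results: list, tree: ReferencePhylogeny) -> str:
    """Serialise placements as a jplace (version 3) document."""
    numbers = edge_numbering(tree)
    placements = []
    for r in results:
        for p in r.placements:
            if p.edge_id not in numbers:
                raise KeyError(f"placement on unknown edge {p.edge_id}")
        placements.append({
            "p": [
                [numbers[p.edge_id], p.log_likelihood, p.like_weight_ratio, p.pendant_length]
                for p in r.placements
            ],
            "n": [r.query_id],
        })
    doc = {
        "version": 3,
        "tree": write_newick(tree, edge_numbers=numbers),
        "placements": placements,
        "fields": JPLACE_FIELDS,
        "metadata": {"software": "flavodiel"},
    }
    return json.dumps(doc, indent=1)


def read_jplace(text: str) -> tuple:
    """Parse a jplace document -> (tree, list of PlacementResult).

    The edge-numbered Newick is read back and edge numbers are mapped onto
    the reconstructed tree's edge ids.
    """
    doc = json.loads(text)
    if doc.get("fields") != JPLACE_FIELDS:
        raise ValueError(f"unsupported jplace fields: {doc.get('fields')}")
    import re
    newick = doc["tree"]
    stripped = re.sub(r"\{\d+\}", "", newick)
    tree = read_newick(stripped)
    numbers = edge_numbering(tree)
    by_number = {n: e for e, n in numbers.items()}
    results = []
    for entry in doc["placements"]:
        names = entry.get("n") or entry.get("nm")
        placements = [
            EdgePlacement(by_number[int(row[0])], float(row[1]), float(row[3]), float(row[2]))
            for row in entry["p"]
        ]
        results.append(PlacementResult(
            query_id=names[0],
            placements=placements,
            best_edge=placements[0].edge_id if placements else None,
        ))
    return tree, results
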