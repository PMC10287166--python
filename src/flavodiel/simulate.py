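"""Synthetic data generation for every pipeline input.

Generates a clade-annotated reference phylogeny (Yule topology,
exponential branch lengths), amino-acid sequences evolved along it under
the substitution model, environmental query contigs of known origin
(source leaf plus extra pendant divergence, optional truncation), a small
NCBI-style taxonomy, and a metatranscriptome count table with the cruise
sampling design: duplicate samples every 4 h for 4 d, two filter size
fractions, 14 spiked internal mRNA standards, and a multiplicative
cosinor diel signal on designated contigs with negative-binomial
overdispersion.

Every generator is deterministic under a fixed seed, and every output
parses with the pipeline's own readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import ReferencePhylogeny
from .placement import CladeAnnotation
from .substitution import N_STATES, SubstitutionModel, decode_sequence
from .taxonomy import Taxonomy

# genus -> taxonomic order used for the synthetic stramenopile reference
CLADE1_GENERA = {
    "Fragilariopsis": "Bacillariales",
    "Pseudonitzschia": "Bacillariales",
    "Corethron": "Corethrales",
}
CLADE2_GENERA = {
    "Chaetoceros": "Chaetocerotales",
    "Thalassiosira": "Thalassiosirales",
    "Cylindrotheca": "Bacillariales",
    "Amphora": "Thalassiophysales",
}
OUTGROUP_GENERA = {
    "Ectocarpus": "Ectocarpales",
    "Aureococcus": "Pelagomonadales",
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic datasets.

    The sampling design mirrors the diel cruise: duplicate samples every
    4 h for 4 d, sequential 3 um / 0.2 um filtration, 14 internal
    standards. Diel signal is a multiplicative cosinor,
    E[abundance](t) = baseline * exp(A * cos(2*pi*(t - phase)/24)).
    """
    seed: int = 1
    # reference tree
    n_clade1: int = 9
    n_clade2: int = 12
    n_outgroup: int = 6
    genera_clade1: int = 3
    genera_clade2: int = 4
    branch_length_mean: float = 0.1
    # sequences
    seq_length: int = 160
    alpha: float = 1.0
    # queries
    n_queries: int = 25
    pendant_divergence: float = 0.1
    query_clades: tuple = ("cladeI", "cladeII")
    truncate: bool = True
    min_span_fraction: float = 0.6
    # sampling design
    n_days: int = 4
    interval_h: float = 4.0
    start_hour: float = 2.0     # clock time of the first cast; 6 AM is sampled
    n_replicates: int = 2
    size_fractions: tuple = ("0.2um", "3um")
    liters: float = 8.0
    cruise: str = "SYN1"
    # spike-ins
    n_standards: int = 14
    standard_copies: tuple = ()
    mean_efficiency: float = 2e-3   # reads recovered per added copy
    efficiency_sd_log: float = 0.3
    # abundances
    baseline_rpl: float = 2000.0    # flavodoxin contig baseline, reads/L
    diel_amplitude: float = 1.0     # log-amplitude A of rhythmic contigs
    diel_phase: float = 6.0         # peak hour of rhythmic contigs
    rhythmic_fraction: float = 0.65
    nb_dispersion: float = 0.3
    background_contigs_per_order: int = 25
    background_rpl_mean: float = 5e4

    def __post_init__(self) -> None:
        if self.n_clade1 + self.n_clade2 < 2 or self.n_outgroup < 1:
            raise ValueError("clade sizes too small")
        if self.genera_clade1 > self.n_clade1 or self.genera_clade2 > self.n_clade2:
            raise ValueError("more genera than leaves in a clade")
        if self.interval_h * self.n_timepoints < 2 * 24:
            raise ValueError("design must cover at least two diel periods")
        if not self.standard_copies:
            self.standard_copies = tuple(
                np.unique(np.round(np.geomspace(1e5, 1e8, self.n_standards)).astype(int))
            )
        if len(self.standard_copies) != self.n_standards:
            raise ValueError("standard_copies must match n_standards")

    @property
    def n_timepoints(self) -> int:
        return int(round(self.n_days * 24 / self.interval_h))

    @property
    def sampling_hours(self) -> np.ndarray:
        return self.start_hour + np.arange(self.n_timepoints) * self.interval_h


@dataclass
class GroundTruth:
    """What the generators actually simulated, for recovery testing."""
    queries: pd.DataFrame          # query_id, source_leaf, clade, genus, span
    contig_diel: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_factors: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _yule_topology(n_leaves: int, rng: np.random.Generator):
    """Pure-birth topology as (parent, children) over local node ids; root 0."""
    if n_leaves == 1:
        return [ -1 ], [[]]
    parent = [-1]
    children = [[]]
    leaves = [0]
    while len(leaves) < n_leaves:
        split = leaves.pop(rng.integers(len(leaves)))
        for _ in range(2):
            parent.append(split)
            children.append([])
            children[split].append(len(parent) - 1)
            leaves.append(len(parent) - 1)
    return parent, children


def _partition_genera(children, root: int, n_genera: int, rng: np.random.Generator):
    """Split a subtree into ``n_genera`` monophyletic groups of nodes.

    Repeatedly splits the largest current group at its root until enough
    groups exist; returns the group root nodes.
    """
    groups = [root]

    def subtree_size(v):
        stack, n = [v], 0
        while stack:
            u = stack.pop()
            n += 1 if not children[u] else 0
            stack.extend(children[u])
        return n

    while len(groups) < n_genera:
        sizes = [subtree_size(g) if children[g] else 1 for g in groups]
        order = np.argsort(sizes)[::-1]
        splittable = [i for i in order if children[groups[i]]]
        if not splittable:
            raise ValueError("cannot split subtree into that many genera")
        i = splittable[0]
        g = groups.pop(i)
        groups.extend(children[g])
    return groups


def sim_tree(config: SimulationConfig):
    """Simulate the annotated reference phylogeny.

    Returns (tree, CladeAnnotation, annotation DataFrame). Clade I and
    clade II are monophyletic sister subtrees; genera are monophyletic
    subclades within each clade; remaining leaves are outgroup.
    """
    rng = np.random.default_rng(config.seed)
    blocks = {
        "cladeI": (config.n_clade1, config.genera_clade1, list(CLADE1_GENERA)),
        "cladeII": (config.n_clade2, config.genera_clade2, list(CLADE2_GENERA)),
        "outgroup": (config.n_outgroup, min(config.n_outgroup, len(OUTGROUP_GENERA)),
                     list(OUTGROUP_GENERA)),
    }
    # global arrays: root(0) -> [outgroup subtree, inner(1) -> [cladeI, cladeII]]
    parent = [-1, 0]
    children = [[1], []]
    labels = [None, None]
    annot_rows = []
    subtree_parent = {"outgroup": 0, "cladeI": 1, "cladeII": 1}
    genus_order_map = {**CLADE1_GENERA, **CLADE2_GENERA, **OUTGROUP_GENERA}
    for clade in ("cladeI", "cladeII", "outgroup"):
        n_leaves, n_genera, genus_names = blocks[clade]
        lp, lc = _yule_topology(n_leaves, rng)
        offset = len(parent)
        for i, p in enumerate(lp):
            parent.append(subtree_parent[clade] if p < 0 else p + offset)
            children.append([c + offset for c in lc[i]])
            labels.append(None)
        children[subtree_parent[clade]].append(offset)
        group_roots = _partition_genera(lc, 0, n_genera, rng)
        names = genus_names[:n_genera]
        leaf_counter = {}
        for g_root, genus in zip(group_roots, names):
            stack = [g_root]
            while stack:
                v = stack.pop()
                if lc[v]:
                    stack.extend(lc[v])
                else:
                    k = leaf_counter.setdefault(genus, 0) + 1
                    leaf_counter[genus] = k
                    species = f"{genus}_sp{k}"
                    labels[v + offset] = species
                    annot_rows.append((species, clade, genus, species,
                                       genus_order_map[genus]))
    n = len(parent)
    lengths = rng.exponential(config.branch_length_mean, size=n)
    lengths[0] = 0.0
    tree = ReferencePhylogeny(parent=np.array(parent), lengths=lengths,
                              labels=labels, children=children)
    annot_df = pd.DataFrame(annot_rows, columns=["leaf_label", "clade", "genus",
                                                 "species", "order_taxid"])
    annot = CladeAnnotation(
        clade=dict(zip(annot_df.leaf_label, annot_df.clade)),
        genus=dict(zip(annot_df.leaf_label, annot_df.genus)),
        species=dict(zip(annot_df.leaf_label, annot_df.species)),
        order_taxid=dict(zip(annot_df.leaf_label, annot_df.order_taxid)),
    )
    annot.validate(tree)
    return tree, annot, annot_df


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _evolve_branch(codes: np.ndarray, site_cats: np.ndarray,
                   model: SubstitutionModel, t: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Evolve one sequence along a branch of length t, per-site rates fixed."""
    if t == 0:
        return codes.copy()
    out = np.empty_like(codes)
    u = rng.random(codes.size)
    for k in range(model.n_categories):
        sel = site_cats == k
        if not sel.any():
            continue
        pmat = model.transition_matrix(t, model.category_rates[k])
        cum = pmat.cumsum(axis=1)
        out[sel] = (u[sel, None] < cum[codes[sel]]).argmax(axis=1)
    return out


def evolve_sequences(tree: ReferencePhylogeny, model: SubstitutionModel,
                     length: int, seed: int):
    """Evolve an alignment down the tree from a stationary root.

    Each site draws one gamma category (held fixed across the whole tree);
    the root sequence is drawn from the equilibrium frequencies. Returns
    (alignment dict label -> residues, site category array, node codes).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    site_cats = rng.integers(model.n_categories, size=length)
    codes = {tree.root: rng.choice(N_STATES, size=length, p=model.frequencies)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        codes[v] = _evolve_branch(codes[tree.parent[v]], site_cats, model,
                                  float(tree.lengths[v]), rng)
    alignment = {tree.labels[v]: decode_sequence(codes[v]) for v in tree.leaves}
    return alignment, site_cats, codes


def sim_queries(tree: ReferencePhylogeny, annot: CladeAnnotation,
                leaf_codes: dict, site_cats: np.ndarray,
                model: SubstitutionModel, config: SimulationConfig):
    """Evolve environmental query contigs from reference leaves.

    Each query takes a random source leaf in the configured clades,
    evolves it by the pendant divergence, and (optionally) truncates to a
    random contiguous span of at least ``min_span_fraction`` columns.
    Returns (queries: list of (id, residues in reference coordinates with
    gaps outside the span), GroundTruth).
    """
    rng = np.random.default_rng(config.seed + 1)
    source_labels = [tree.labels[v] for v in tree.leaves
                     if annot.clade[tree.labels[v]] in config.query_clades]
    if not source_labels:
        raise ValueError("no source leaves in the requested clades")
    label_to_node = {tree.labels[v]: v for v in tree.leaves}
    length = site_cats.size
    queries, truth_rows = [], []
    for i in range(config.n_queries):
        src = source_labels[rng.integers(len(source_labels))]
        evolved = _evolve_branch(leaf_codes[label_to_node[src]], site_cats,
                                 model, config.pendant_divergence, rng)
        if config.truncate:
            span_len = int(rng.integers(int(np.ceil(config.min_span_fraction * length)),
                                        length + 1))
            start = int(rng.integers(0, length - span_len + 1))
        else:
            start, span_len = 0, length
        residues = np.full(length, -1, dtype=np.int64)
        residues[start:start + span_len] = evolved[start:start + span_len]
        qid = f"contig_{i + 1:04d}"
        queries.append((qid, decode_sequence(residues)))
        truth_rows.append((qid, src, annot.clade[src], annot.genus[src],
                           start + 1, start + span_len))
    truth = pd.DataFrame(truth_rows, columns=["query_id", "source_leaf", "clade",
                                              "genus", "span_start", "span_end"])
    return queries, GroundTruth(queries=truth)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def sim_taxonomy(annot_df: pd.DataFrame) -> Taxonomy:
    """NCBI-style taxonomy covering the reference species plus their lineages."""
    parent, rank, name = {}, {}, {}

    def add(taxid, par, rk):
        parent[taxid], rank[taxid], name[taxid] = par, rk, taxid

    add("root", None, "root")
    add("Eukaryota", "root", "domain")
    add("Stramenopiles", "Eukaryota", "phylum")
    classes = {"Bacillariophyceae": ["Bacillariales", "Chaetocerotales",
                                     "Thalassiosirales", "Thalassiophysales",
                                     "Corethrales"],
               "Phaeophyceae": ["Ectocarpales"],
               "Pelagophyceae": ["Pelagomonadales"]}
    for cls, orders in classes.items():
        add(cls, "Stramenopiles", "class")
        for o in orders:
            add(o, cls, "order")
    for row in annot_df.itertuples(index=False):
        if row.genus not in parent:
            add(row.genus, row.order_taxid, "genus")
        if row.species not in parent:
            add(row.species, row.genus, "species")
    return Taxonomy(parent=parent, rank=rank, name=name)


# ---------------------------------------------------------------------------
# Metatranscriptome counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def cosinor_mean(baseline: float, amplitude: float, phase: float,
                 hours: np.ndarray, period: float = 24.0) -> np.ndarray:
    """Multiplicative cosinor: baseline * exp(A * cos(2 pi (t - phase)/T))."""
    return baseline * np.exp(amplitude * np.cos(2 * np.pi * (np.asarray(hours) - phase) / period))


def sim_metatranscriptome(config: SimulationConfig, truth: GroundTruth,
                          annot_df: pd.DataFrame, taxonomy: Taxonomy):
    """Simulate counts, sample metadata, taxon assignments and true factors.

    Flavodoxin contigs (the simulated queries) get a cosinor diel mean;
    clade I contigs are rhythmic with the configured amplitude/phase while
    clade II contigs stay flat, echoing the field pattern the design
    emulates. Per-order background contigs provide the denominator mass
    for order-level normalization. Counts are negative binomial around
    expected reads = reads_per_liter * liters * sample efficiency;
    spike-in recoveries are Poisson around added * efficiency.

    Returns (counts, meta frame, assignments dict, updated GroundTruth).
    """
    rng = np.random.default_rng(config.seed + 2)
    hours = config.sampling_hours
    genus_order = dict(zip(annot_df.genus, annot_df.order_taxid))

    # per-contig diel parameters
    diel_rows = []
    qdf = truth.queries
    n_rhythmic = int(round(config.rhythmic_fraction * (qdf.clade == "cladeI").sum()))
    rhythmic_ids = list(qdf.query_id[qdf.clade == "cladeI"][:n_rhythmic])
    for row in qdf.itertuples(index=False):
        rhythmic = row.query_id in rhythmic_ids
        base = config.baseline_rpl * float(rng.lognormal(0.0, 0.25))
        diel_rows.append((row.query_id, base,
                          config.diel_amplitude if rhythmic else 0.0,
                          config.diel_phase if rhythmic else np.nan))
    contig_diel = pd.DataFrame(diel_rows, columns=["contig", "baseline_rpl",
                                                   "amplitude", "phase"])

    # background contigs per order (flat in time)
    background = []
    for order in sorted(set(annot_df.order_taxid)):
        species = list(annot_df.species[annot_df.order_taxid == order])
        for j in range(config.background_contigs_per_order):
            bid = f"bg_{order}_{j + 1:03d}"
            base = config.background_rpl_mean * float(rng.lognormal(0.0, 0.5))
            background.append((bid, order, species[j % len(species)], base))

    # assignments: flavodoxin contigs -> source species; background -> species
    source_species = dict(zip(qdf.query_id, qdf.source_leaf))
    assignments = {qid: source_species[qid] for qid in qdf.query_id}
    for bid, _order, sp, _b in background:
        assignments[bid] = sp

    # samples
    meta_rows, factor_rows = [], []
    sample_ids = []
    added = np.asarray(config.standard_copies, float)
    eff = {}
    for t in hours:
        for rep in range(1, config.n_replicates + 1):
            for sf in config.size_fractions:
                sid = f"{config.cruise}_t{int(round(t)):03d}_r{rep}_{sf}"
                sample_ids.append(sid)
                e = config.mean_efficiency * float(
                    rng.lognormal(0.0, config.efficiency_sd_log))
                eff[sid] = e
                reads = rng.poisson(added * e)
                meta_rows.append({
                    "sample_id": sid, "cruise": config.cruise, "hours": float(t),
                    "time_of_day": float(t % 24.0), "replicate": rep,
                    "size_fraction": sf, "liters": config.liters,
                    **{f"spike_added_{k + 1:02d}": int(added[k])
                       for k in range(config.n_standards)},
                    **{f"spike_reads_{k + 1:02d}": int(reads[k])
                       for k in range(config.n_standards)},
                })
                factor_rows.append((sid, 1.0 / e))
    meta = pd.DataFrame(meta_rows)
    factors = pd.DataFrame(factor_rows, columns=["sample_id", "true_copies_per_read"])

    # counts: size-fraction shares split each contig's abundance
    if len(config.size_fractions) == 1:
        frac_share = {config.size_fractions[0]: 1.0}
    else:
        shares = np.linspace(0.4, 0.6, len(config.size_fractions))
        frac_share = dict(zip(config.size_fractions, shares / shares.sum()))
    contigs = list(contig_diel.contig) + [b[0] for b in background]
    count_rows = np.zeros((len(contigs), len(sample_ids)))
    meta_idx = meta.set_index("sample_id")
    for i, contig in enumerate(contigs):
        if i < len(contig_diel):
            row = contig_diel.iloc[i]
            mean_rpl = cosinor_mean(row.baseline_rpl, row.amplitude,
                                    0.0 if np.isnan(row.phase) else row.phase,
                                    meta_idx["hours"].to_numpy())
        else:
            base = background[i - len(contig_diel)][3]
            mean_rpl = np.full(len(sample_ids), base)
        share = np.array([frac_share[sf] for sf in meta_idx["size_fraction"]])
        eff_vec = np.array([eff[s] for s in meta_idx.index])
        mu = mean_rpl * share * config.liters * eff_vec
        count_rows[i] = _nb_draw(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(count_rows.astype(int), index=contigs, columns=sample_ids)
    counts.index.name = "contig"

    truth.contig_diel = contig_diel
    truth.sample_factors = factors
    return counts, meta, assignments, truth
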