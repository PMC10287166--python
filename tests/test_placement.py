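"""Evolutionary placement: engine consistency, filtering, jplace format."""

import numpy as np
import pytest

from conftest import graft_query, grid_best_edge, random_alignment

from flavodiel.likelihood import encode_alignment, felsenstein_loglik, leaf_partial
from flavodiel.phylo import read_newick
from flavodiel.placement import (AlignedQuery, CladeAnnotation, EdgePlacement,
                                 PlacementEngine, PlacementResult, epa_place,
                                 filter_and_assign, read_jplace, write_jplace)
from flavodiel.substitution import SubstitutionModel, encode_sequence


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(3)
    tree = read_newick("((A:0.1,B:0.2):0.15,(C:0.3,(D:0.05,E:0.4):0.2):0.1);")
    model = SubstitutionModel(alpha=1.0)
    aln = random_alignment(tree, rng, 60)
    engine = PlacementEngine(tree, model, encode_alignment(aln))
    return tree, model, aln, engine


def test_edge_attachment_likelihood_matches_regrafted_pruning(setup):
    """The cached up/down engine equals pruning on an explicitly grafted tree."""
    tree, model, aln, engine = setup
    rng = np.random.default_rng(11)
    qseq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
    qpart = leaf_partial(encode_sequence(qseq))
    for edge in tree.edges:
        for pendant in (0.01, 0.37, 1.5):
            fast = engine.edge_loglik(edge, qpart, pendant)
            grafted = graft_query(tree, edge, 0.5, pendant)
            slow = felsenstein_loglik(grafted, model, {**aln, "QUERY": qseq})
            assert abs(fast - slow) < 1e-8


def test_self_placement_recovers_terminal_edge(setup):
    tree, model, aln, engine = setup
    for label in ("A", "D"):
        q = AlignedQuery.from_aligned_string("q", aln[label])
        res = engine.place(q)
        assert tree.labels[res.best_edge] == label
        assert res.best.pendant_length < 1e-4


def test_like_weight_ratios_sum_to_one(setup):
    tree, model, aln, engine = setup
    rng = np.random.default_rng(5)
    for _ in range(5):
        qseq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        res = engine.place(AlignedQuery.from_aligned_string("q", qseq))
        total = sum(p.like_weight_ratio for p in res.placements)
        assert abs(total - 1.0) < 1e-9
        assert all(p.pendant_length >= 0 for p in res.placements)


def test_insufficient_overlap_rejected(setup):
    tree, model, aln, engine = setup
    res = engine.place(AlignedQuery.from_aligned_string("q", "ACDEF" + "-" * 55))
    assert not res.kept
    assert res.reason == "insufficient overlap"
    assert res.placements == []


def test_best_edge_agrees_with_grid_regraft_oracle():
    """Midpoint attachment + pendant optimisation vs dense regraft grid."""
    from flavodiel.simulate import SimulationConfig, evolve_sequences, sim_tree
    rng = np.random.default_rng(17)
    agree = total = 0
    for rep in range(6):
        cfg = SimulationConfig(seed=100 + rep, n_clade1=2, n_clade2=3,
                               n_outgroup=2, genera_clade1=1, genera_clade2=1,
                               seq_length=50)
        tree, annot, _ = sim_tree(cfg)
        model = SubstitutionModel(alpha=1.0)
        aln, cats, codes = evolve_sequences(tree, model, 50, seed=200 + rep)
        engine = PlacementEngine(tree, model, encode_alignment(aln))
        from flavodiel.simulate import _evolve_branch
        leaves = tree.leaves
        for q in range(3):
            src = leaves[rng.integers(len(leaves))]
            from flavodiel.substitution import decode_sequence
            qcodes = _evolve_branch(codes[src], cats, model, 0.3, rng)
            qseq = decode_sequence(qcodes)
            res = engine.place(AlignedQuery.from_aligned_string("q", qseq))
            oracle = grid_best_edge(tree, model, aln, qseq)
            total += 1
            agree += res.best_edge == oracle
    assert agree / total >= 0.9


def _annotation_for(tree):
    clade = {}
    genus = {}
    for lab in tree.leaf_labels:
        clade[lab] = {"A": "cladeII", "B": "cladeII", "C": "cladeI",
                      "D": "cladeI", "E": "outgroup"}[lab]
        genus[lab] = {"A": "Chaetoceros", "B": "Chaetoceros",
                      "C": "Fragilariopsis", "D": "Corethron", "E": "Ecto"}[lab]
    return CladeAnnotation(clade=clade, genus=genus,
                           species={l: l for l in tree.leaf_labels},
                           order_taxid={l: "O" for l in tree.leaf_labels})


def _single_edge_result(edge, lwr):
    return PlacementResult(query_id="q", best_edge=edge,
                           placements=[EdgePlacement(edge, -10.0, 0.1, lwr)])


def test_filter_low_lwr_not_kept(setup):
    tree, *_ = setup
    annot = _annotation_for(tree)
    leaf_a = tree.leaves[tree.leaf_labels.index("A")]
    res = filter_and_assign(_single_edge_result(leaf_a, 0.79), tree, annot)
    assert not res.kept and res.reason == "lwr"


def test_filter_multi_genus_edge_not_kept(setup):
    tree, *_ = setup
    annot = _annotation_for(tree)
    # edge above the (C,(D,E)) subtree subtends three genera
    internal = [v for v in tree.edges if not tree.is_leaf(v)
                and len(tree.leaves_below(v)) == 3][0]
    res = filter_and_assign(_single_edge_result(internal, 0.95), tree, annot)
    assert not res.kept and res.reason == "rank"


def test_filter_outgroup_not_kept_and_clade2_kept(setup):
    tree, *_ = setup
    annot = _annotation_for(tree)
    leaf_e = tree.leaves[tree.leaf_labels.index("E")]
    res = filter_and_assign(_single_edge_result(leaf_e, 0.95), tree, annot)
    assert not res.kept and res.reason == "clade"
    leaf_a = tree.leaves[tree.leaf_labels.index("A")]
    res = filter_and_assign(_single_edge_result(leaf_a, 0.95), tree, annot)
    assert res.kept and res.assigned_clade == "cladeII"
    assert res.assigned_genus == "Chaetoceros"


def test_jplace_round_trip_and_edge_bijection(setup):
    tree, model, aln, engine = setup
    rng = np.random.default_rng(23)
    results = []
    for i in range(3):
        qseq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        results.append(engine.place(AlignedQuery.from_aligned_string(f"q{i}", qseq)))
    doc = write_jplace(results, tree)
    tree2, results2 = read_jplace(doc)
    assert sorted(tree2.leaf_labels) == sorted(tree.leaf_labels)
    for r1, r2 in zip(results, results2):
        assert r1.query_id == r2.query_id
        for p1, p2 in zip(r1.placements, r2.placements):
            assert abs(p1.log_likelihood - p2.log_likelihood) < 1e-9
            assert abs(p1.like_weight_ratio - p2.like_weight_ratio) < 1e-9
            assert abs(p1.pendant_length - p2.pendant_length) < 1e-9


def test_jplace_empty_results_valid(setup):
    tree, *_ = setup
    import json
    doc = json.loads(write_jplace([], tree))
    assert doc["version"] == 3
    assert doc["placements"] == []
    assert doc["fields"][0] == "edge_num"


def test_epa_place_convenience_wrapper(setup):
    tree, model, aln, _ = setup
    res = epa_place(tree, aln, model, AlignedQuery.from_aligned_string("q", aln["C"]))
    assert tree.labels[res.best_edge] == "C"


def test_distant_outgroup_does_not_flip_ingroup_preference():
    """Adding a far-away leaf preserves the likelihood order of in-group edges."""
    rng = np.random.default_rng(31)
    model = SubstitutionModel(alpha=1.0)
    flips = trials = 0
    for rep in range(10):
        tree = read_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.2):0.1);")
        aln = random_alignment(tree, rng, 40)
        qseq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
        qpart = leaf_partial(encode_sequence(qseq))
        engine = PlacementEngine(tree, model, encode_alignment(aln))
        leaf_a = tree.leaves[tree.leaf_labels.index("A")]
        leaf_c = tree.leaves[tree.leaf_labels.index("C")]
        before = engine.edge_loglik(leaf_a, qpart, 0.1) - engine.edge_loglik(leaf_c, qpart, 0.1)
        big = read_newick("(((A:0.1,B:0.2):0.15,(C:0.3,D:0.2):0.1):0.05,FAR:3.0);")
        aln2 = {**aln, "FAR": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))}
        engine2 = PlacementEngine(big, model, encode_alignment(aln2))
        leaf_a2 = big.leaves[big.leaf_labels.index("A")]
        leaf_c2 = big.leaves[big.leaf_labels.index("C")]
        after = engine2.edge_loglik(leaf_a2, qpart, 0.1) - engine2.edge_loglik(leaf_c2, qpart, 0.1)
        trials += 1
        flips += (before > 0) != (after > 0)
    assert flips == 0
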