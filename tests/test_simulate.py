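"""Synthetic-data generators: determinism, ground truth, moment checks."""

import numpy as np
import pandas as pd
import pytest

from flavodiel.phylo import write_newick
from flavodiel.quantify import SampleMeta, reads_per_liter
from flavodiel.simulate import (SimulationConfig, _evolve_branch, _nb_draw,
                                cosinor_mean, evolve_sequences,
                                sim_metatranscriptome, sim_queries,
                                sim_taxonomy, sim_tree)
from flavodiel.substitution import SubstitutionModel, encode_sequence
from flavodiel.taxonomy import ancestor_at_rank


@pytest.fixture(scope="module")
def default_sim():
    cfg = SimulationConfig(seed=11)
    tree, annot, annot_df = sim_tree(cfg)
    return cfg, tree, annot, annot_df


def test_tree_deterministic_under_seed(default_sim):
    cfg, tree, _, _ = default_sim
    tree2, _, _ = sim_tree(SimulationConfig(seed=11))
    assert write_newick(tree) == write_newick(tree2)
    tree3, _, _ = sim_tree(SimulationConfig(seed=12))
    assert write_newick(tree) != write_newick(tree3)


def test_clades_are_monophyletic(default_sim):
    cfg, tree, annot, _ = default_sim
    label_node = {tree.labels[v]: v for v in tree.leaves}
    for clade in ("cladeI", "cladeII"):
        members = {l for l, c in annot.clade.items() if c == clade}
        # walk up from one member until the subtree covers all members
        node = label_node[next(iter(members))]
        while {tree.labels[v] for v in tree.leaves_below(node)} < members:
            node = int(tree.parent[node])
        below = {tree.labels[v] for v in tree.leaves_below(node)}
        assert below == members


def test_genera_sizes_and_annotation_complete(default_sim):
    cfg, tree, annot, annot_df = default_sim
    assert len(annot_df) == cfg.n_clade1 + cfg.n_clade2 + cfg.n_outgroup
    assert annot_df.clade.value_counts()["cladeI"] == cfg.n_clade1
    assert annot_df[annot_df.clade == "cladeII"].genus.nunique() == cfg.genera_clade2
    annot.validate(tree)  # raises if incomplete


def test_evolution_zero_branch_is_identity(default_sim):
    cfg, tree, _, _ = default_sim
    model = SubstitutionModel()
    rng = np.random.default_rng(0)
    codes = rng.integers(20, size=100)
    cats = rng.integers(4, size=100)
    out = _evolve_branch(codes, cats, model, 0.0, rng)
    assert np.array_equal(out, codes)


def test_branch_substitution_frequencies_match_transition_matrix():
    """Empirical child-state frequencies vs P(t) rows over 50,000 sites."""
    model = SubstitutionModel(n_categories=1)
    rng = np.random.default_rng(5)
    t = 0.5
    parent = rng.choice(20, size=50_000, p=model.frequencies)
    child = _evolve_branch(parent, np.zeros(50_000, dtype=int), model, t, rng)
    p = model.transition_matrix(t)
    bad = checked = 0
    for x in range(20):
        sel = parent == x
        n = sel.sum()
        if n < 500:
            continue
        freq = np.bincount(child[sel], minlength=20) / n
        se = np.sqrt(p[x] * (1 - p[x]) / n)
        with np.errstate(invalid="ignore"):
            z = np.abs(freq - p[x]) / np.where(se > 0, se, np.inf)
        checked += 20
        bad += (z > 3).sum()
    assert checked > 100
    assert bad / checked < 0.02  # ~0.3% expected beyond 3 SE


def test_leaf_composition_approaches_stationarity():
    model = SubstitutionModel(n_categories=1)
    rng = np.random.default_rng(6)
    start = np.zeros(50_000, dtype=int)  # far from equilibrium
    end = _evolve_branch(start, np.zeros(50_000, dtype=int), model, 50.0, rng)
    freq = np.bincount(end, minlength=20) / 50_000
    assert 0.5 * np.abs(freq - model.frequencies).sum() < 0.02


def test_queries_carry_ground_truth_and_zero_pendant_is_copy(default_sim):
    cfg, tree, annot, annot_df = default_sim
    model = SubstitutionModel(alpha=cfg.alpha)
    aln, cats, codes = evolve_sequences(tree, model, cfg.seq_length, cfg.seed)
    leaf_codes = {v: codes[v] for v in tree.leaves}
    cfg0 = SimulationConfig(seed=11, pendant_divergence=0.0, truncate=False,
                            n_queries=5)
    queries, truth = sim_queries(tree, annot, leaf_codes, cats, model, cfg0)
    assert len(truth.queries) == len(queries) == 5
    for (qid, seq), row in zip(queries, truth.queries.itertuples(index=False)):
        assert seq == aln[row.source_leaf]
        assert annot.genus[row.source_leaf] == row.genus


def test_truncation_respects_minimum_span(default_sim):
    cfg, tree, annot, annot_df = default_sim
    model = SubstitutionModel(alpha=cfg.alpha)
    aln, cats, codes = evolve_sequences(tree, model, cfg.seq_length, cfg.seed)
    leaf_codes = {v: codes[v] for v in tree.leaves}
    queries, truth = sim_queries(tree, annot, leaf_codes, cats, model, cfg)
    for (qid, seq), row in zip(queries, truth.queries.itertuples(index=False)):
        mapped = sum(c != "-" for c in seq)
        assert mapped >= cfg.min_span_fraction * cfg.seq_length
        assert mapped == row.span_end - row.span_start + 1


def test_nb_dispersion_limits_to_poisson():
    rng = np.random.default_rng(7)
    draws = _nb_draw(rng, np.full(10_000, 100.0), 1e-9)
    ratio = draws.var() / draws.mean()
    assert 0.9 < ratio < 1.1
    rng2 = np.random.default_rng(7)
    over = _nb_draw(rng2, np.full(10_000, 100.0), 0.3)
    assert over.var() / over.mean() > 5  # strongly overdispersed


def test_cosinor_mean_peaks_at_phase():
    hours = np.arange(0, 24, 0.5)
    mu = cosinor_mean(100.0, 1.0, 6.0, hours)
    assert hours[np.argmax(mu)] == 6.0
    flat = cosinor_mean(100.0, 0.0, 6.0, hours)
    assert np.allclose(flat, 100.0)


def test_metatranscriptome_spikein_factor_recovery(default_sim):
    """reads_per_liter recovers each sample's true copies-per-read within 5%."""
    cfg, tree, annot, annot_df = default_sim
    model = SubstitutionModel(alpha=cfg.alpha)
    aln, cats, codes = evolve_sequences(tree, model, cfg.seq_length, cfg.seed)
    leaf_codes = {v: codes[v] for v in tree.leaves}
    queries, truth = sim_queries(tree, annot, leaf_codes, cats, model, cfg)
    tax = sim_taxonomy(annot_df)
    counts, meta_df, assignments, truth = sim_metatranscriptome(cfg, truth,
                                                                annot_df, tax)
    meta = SampleMeta(meta_df)
    true_factor = truth.sample_factors.set_index("sample_id")["true_copies_per_read"]
    errs = [abs(meta.spike_factor(s) / true_factor[s] - 1.0)
            for s in meta.sample_ids]
    assert max(errs) < 0.05
    # all assignments resolve within the taxonomy, flavodoxin contigs to species
    for contig, taxid in assignments.items():
        assert ancestor_at_rank(taxid, "order", tax) is not None
    # design: duplicates every 4 h for 4 d, two size fractions
    assert meta_df.hours.nunique() == 24
    assert set(meta_df.size_fraction) == {"0.2um", "3um"}
    assert counts.shape[1] == 24 * 2 * 2


def test_null_amplitude_rejection_rate_near_alpha():
    """With A=0 everywhere the rhythm test rejects at about alpha."""
    from flavodiel.rhythm import TimeSeries, rain_like_test
    cfg = SimulationConfig(seed=21, rhythmic_fraction=0.0, n_queries=10,
                           background_contigs_per_order=0)
    tree, annot, annot_df = sim_tree(cfg)
    model = SubstitutionModel(alpha=cfg.alpha)
    aln, cats, codes = evolve_sequences(tree, model, cfg.seq_length, cfg.seed)
    leaf_codes = {v: codes[v] for v in tree.leaves}
    queries, truth = sim_queries(tree, annot, leaf_codes, cats, model, cfg)
    tax = sim_taxonomy(annot_df)
    counts, meta_df, _, truth = sim_metatranscriptome(cfg, truth, annot_df, tax)
    meta = SampleMeta(meta_df)
    rpl = reads_per_liter(counts, meta)
    frame = meta.frame
    rejections = total = 0
    for contig in truth.contig_diel.contig:
        grouped = {}
        for sid in rpl.columns:
            key = (float(frame.loc[sid, "hours"]), int(frame.loc[sid, "replicate"]))
            grouped[key] = grouped.get(key, 0.0) + float(rpl.loc[contig, sid])
        keys = sorted(grouped)
        series = TimeSeries(contig, np.array([k[0] for k in keys]),
                            np.array([grouped[k] for k in keys]),
                            np.array([k[1] for k in keys]))
        res = rain_like_test(series, n_perm=999, seed=total)
        total += 1
        rejections += res.p_value <= 0.05
    assert rejections <= 2  # 10 null contigs at alpha 0.05


def test_generated_files_parse_with_pipeline_readers(tmp_path):
    from flavodiel import io as fio
    from flavodiel.phylo import read_newick
    from flavodiel.pipeline import write_simulation
    from flavodiel.taxonomy import Taxonomy
    cfg = SimulationConfig(seed=31, n_queries=4, background_contigs_per_order=2)
    paths = write_simulation(cfg, tmp_path)
    tree = read_newick((tmp_path / "ref.nwk").read_text())
    aln = dict(fio.read_fasta(paths["ref_alignment"]))
    assert sorted(aln) == sorted(tree.leaf_labels)
    assert {len(s) for s in aln.values()} == {cfg.seq_length}
    annot = fio.read_annotation(paths["annotation"])
    annot.validate(tree)
    tax = Taxonomy.read_tsv(paths["taxonomy"])
    counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    meta = SampleMeta(pd.read_csv(paths["meta"], sep="\t"))
    assert set(counts.columns) <= set(meta.sample_ids)
    queries = fio.read_fasta(paths["queries"])
    assert len(queries) == cfg.n_queries
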