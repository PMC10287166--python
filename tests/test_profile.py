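"""Profile building, E-value calibration, search and dereplication."""

import numpy as np
import pytest
from scipy.stats import gumbel_r, kstest

from conftest import random_peptide

from flavodiel.profile import (ProfileModel, SeedAlignment, align_to_profile,
                               batch_scores, build_profile, calibrate_profile,
                               dereplicate, pairwise_identity, search_profile)
from flavodiel.substitution import AMINO_ACIDS


@pytest.fixture(scope="module")
def family():
    """A small synthetic family: seed alignment + member and decoy peptides."""
    rng = np.random.default_rng(0)
    base = random_peptide(rng, 90)
    rows = []
    for i in range(10):
        s = list(base)
        for j in rng.choice(90, 14, replace=False):
            s[j] = AMINO_ACIDS[rng.integers(20)]
        rows.append((f"seed{i}", "".join(s)))
    seed = SeedAlignment(sequences=rows)
    profile = build_profile(seed)
    calibrate_profile(profile, n_sims=2000, length=90, seed=1)
    return base, seed, profile


def test_match_column_scores_follow_stated_formula():
    """Two sequences, column {A, A}, uniform background, pseudocount 1."""
    seed = SeedAlignment(sequences=[("a", "AC"), ("b", "AD")])
    bg = np.full(20, 0.05)
    profile = build_profile(seed, background=bg, pseudocount=1.0)
    expected = np.log2(((2 + 0.05) / (2 + 1)) / 0.05)
    assert abs(profile.scores[0, AMINO_ACIDS.index("A")] - expected) < 1e-12


def test_single_sequence_profile_prefers_observed_residues():
    profile = build_profile(SeedAlignment(sequences=[("a", "ACD")]),
                            background=np.full(20, 0.05))
    assert profile.consensus() == "ACD"


def test_gap_majority_columns_excluded():
    seed = SeedAlignment(sequences=[("a", "A-C-"), ("b", "A--D"), ("c", "A--D")])
    profile = build_profile(seed)
    assert profile.match_columns == [1, 4]
    with pytest.raises(ValueError, match="no match columns"):
        build_profile(SeedAlignment(sequences=[("a", "--"), ("b", "--")]))


def test_profile_invariant_to_seed_order(family):
    base, seed, _ = family
    p1 = build_profile(SeedAlignment(sequences=seed.sequences))
    p2 = build_profile(SeedAlignment(sequences=seed.sequences[::-1]))
    assert p1.match_columns == p2.match_columns
    assert np.allclose(p1.scores, p2.scores)


def test_calibration_deterministic_and_evalue_monotone(family):
    _, _, profile = family
    p2 = build_profile(SeedAlignment(sequences=[(i, s) for i, s in
                                                zip("abcdefghij", [s for _, s in
                                                family[1].sequences])]))
    calibrate_profile(p2, n_sims=2000, length=90, seed=1)
    assert p2.gumbel_lambda == pytest.approx(profile.gumbel_lambda, abs=0)
    assert p2.gumbel_mu == pytest.approx(profile.gumbel_mu, abs=0)
    scores = np.linspace(0, 200, 50)
    ev = profile.e_value(scores)
    assert np.all(np.diff(ev) <= 0)


def test_calibrated_gumbel_fits_simulated_null(family):
    """KS distance between the fit and a fresh null sample is small."""
    _, _, profile = family
    rng = np.random.default_rng(99)
    seqs = rng.choice(20, size=(10_000, 90), p=profile.background)
    scores = batch_scores(profile, list(seqs))
    dist = kstest(scores, gumbel_r(loc=profile.gumbel_mu,
                                   scale=1.0 / profile.gumbel_lambda).cdf)
    assert dist.statistic < 0.05


def test_search_recruits_member_not_shuffles(family):
    base, _, profile = family
    rng = np.random.default_rng(5)
    shuffles = []
    for i in range(100):
        s = list(base)
        rng.shuffle(s)
        shuffles.append((f"shuf{i}", "".join(s)))
    hits = search_profile(profile, [("member", base)] + shuffles, e_max=0.001)
    ids = {h.query_id for h in hits}
    assert "member" in ids
    assert len(ids - {"member"}) < 5


def test_search_with_infinite_threshold_hits_every_nonempty(family):
    base, _, profile = family
    rng = np.random.default_rng(6)
    seqs = [(f"r{i}", random_peptide(rng, 50)) for i in range(10)] + [("empty", "")]
    hits = search_profile(profile, seqs, e_max=np.inf)
    assert {h.query_id for h in hits} == {f"r{i}" for i in range(10)}
    evs = [h.e_value for h in hits]
    assert evs == sorted(evs)


def test_empty_input_gives_empty_hits(family):
    assert search_profile(family[2], [], e_max=0.001) == []


def test_consensus_achieves_maximal_score_and_tiny_evalue(family):
    _, _, profile = family
    cons = profile.consensus()
    score = batch_scores(profile, [cons])[0]
    assert score == pytest.approx(profile.scores.max(axis=1).sum())
    assert profile.e_value(score) < 1e-10


def test_recruitment_type_one_error_controlled(family):
    """Background sequences pass e<0.001 at a rate well below 1%."""
    _, _, profile = family
    rng = np.random.default_rng(123)
    seqs = rng.choice(20, size=(10_000, 90), p=profile.background)
    scores = batch_scores(profile, list(seqs))
    profile.db_size = 10_000
    false = (profile.e_value(scores) < 0.001).sum()
    assert false / 10_000 <= 0.01


def test_align_to_profile_maps_reference_columns(family):
    base, _, profile = family
    fragment = base[20:75]
    amap = align_to_profile(profile, "q", fragment)
    # mapped columns fall inside the fragment's window (0-based, half-open)
    assert min(amap.column_map) >= 20 - 5
    assert max(amap.column_map) <= 75 + 5
    assert len(amap.column_map) >= 0.8 * len(fragment)


def test_identity_examples():
    a = "A" * 100
    b = "A" * 49 + "C" + "A" * 49 + "C"
    assert pairwise_identity(a, a) == 1.0
    assert pairwise_identity(a, b) == pytest.approx(0.98)


def test_dereplicate_identical_sequences_cluster():
    seq = "ACDEFGHIKLMNPQRSTVWY" * 5
    clusters = dereplicate([("x", seq), ("y", seq)], identity=0.99)
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == ["x", "y"]


def test_dereplicate_two_percent_divergence_splits():
    a = "ACDEFGHIKLMNPQRSTVWY" * 5
    b = a[:30] + "W" + a[31:60] + "W" + a[61:]
    clusters = dereplicate([("x", a), ("y", b)], identity=0.99)
    assert len(clusters) == 2


def test_dereplicate_partition_and_centroid_identity_oracle():
    """Every member matches its centroid at >= threshold per an independent
    Needleman-Wunsch oracle (Biopython), and clusters partition the input."""
    from Bio import Align
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-0.5)

    def bio_identity(a, b):
        alignment = aligner.align(a, b)[0]
        cols = alignment.length
        matches = sum(x == y for x, y in zip(alignment[0], alignment[1])
                      if x != "-" and y != "-")
        return matches / cols

    rng = np.random.default_rng(8)
    base = random_peptide(rng, 120)
    records = []
    for i in range(15):
        s = list(base)
        n_mut = int(rng.integers(0, 4)) if i % 3 else int(rng.integers(10, 30))
        for j in rng.choice(120, n_mut, replace=False):
            s[j] = AMINO_ACIDS[rng.integers(20)]
        records.append((f"v{i}", "".join(s)))
    clusters = dereplicate(records, identity=0.99)
    seqs = dict(records)
    seen = []
    for cl in clusters:
        seen.extend(cl.member_ids)
        for m in cl.member_ids:
            assert bio_identity(seqs[m], seqs[cl.centroid_id]) >= 0.99 - 1e-9
    assert sorted(seen) == sorted(seqs)


def test_uncalibrated_profile_refuses_evalues():
    profile = build_profile(SeedAlignment(sequences=[("a", "ACDE")]))
    with pytest.raises(RuntimeError, match="calibrat"):
        profile.e_value(10.0)
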