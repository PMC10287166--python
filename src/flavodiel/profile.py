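"""Profile-based recruitment of gene-family members.

A position-specific scoring model (log-odds in bits over the 20 amino
acids, with affine gap penalties) is built from a seed alignment,
calibrated against simulated background sequences so that raw local
alignment bit scores map to Gumbel-tail E-values, and then used to recruit
query peptides below an E-value threshold. Recruited sequences are
dereplicated by greedy centroid clustering at high identity.

The scoring model is deliberately a calibrated PSSM rather than a full
profile HMM: it is used purely as a recruitment filter, and the E-value
calibration (not the absolute bit scale) is what controls the retained
set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.stats import gumbel_r

from .substitution import AA_INDEX, AMINO_ACIDS, N_STATES, encode_sequence, wag_frequencies

logger = logging.getLogger(__name__)

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0
NEG = -1e9  # sentinel for impossible DP states / padded residues


@dataclass
class SeedAlignment:
    """A multiple alignment of seed family members."""
    sequences: list  # list of (id, aligned residue string)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("seed alignment is empty")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("seed alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])

    def column_codes(self) -> np.ndarray:
        """(n_sequences, n_columns) integer codes, -1 for gaps."""
        return np.stack([encode_sequence(s) for _, s in self.sequences])


@dataclass
class ProfileModel:
    """Calibrated position-specific scoring model.

    ``scores`` holds log2-odds bits, shape (n_match_columns, 20);
    ``match_columns`` are 1-based indices into the seed alignment.
    Gumbel parameters are set by :func:`calibrate_profile`;
    ``gumbel_lambda`` is the inverse scale of the fitted maximum-score
    distribution.
    """
    match_columns: list
    scores: np.ndarray
    background: np.ndarray
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    gumbel_lambda: float | None = None
    gumbel_mu: float | None = None
    db_size: int = 1

    def __post_init__(self) -> None:
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if list(self.match_columns) != sorted(set(self.match_columns)):
            raise ValueError("match_columns must be strictly increasing")
        if self.gumbel_lambda is not None and self.gumbel_lambda <= 0:
            raise ValueError("gumbel_lambda must be > 0")

    @property
    def n_match(self) -> int:
        return len(self.match_columns)

    def consensus(self) -> str:
        """Per-column argmax residues of the score matrix."""
        return "".join(AMINO_ACIDS[i] for i in self.scores.argmax(axis=1))

    def e_value(self, bit_score: float | np.ndarray):
        """Gumbel-tail E-value: db_size * P(S > s) under the null."""
        if self.gumbel_lambda is None:
            raise RuntimeError("profile is not calibrated")
        sf = gumbel_r.sf(bit_score, loc=self.gumbel_mu, scale=1.0 / self.gumbel_lambda)
        return self.db_size * sf


@dataclass
class SearchHit:
    query_id: str
    bit_score: float
    e_value: float
    aligned_span: tuple  # (start, end), 1-based inclusive on the query


@dataclass
class SequenceCluster:
    centroid_id: str
    member_ids: list
    identity_threshold: float = 0.99


def build_profile(
    seed: SeedAlignment,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    match_fraction: float = 0.5,
) -> ProfileModel:
    """Build a log-odds PSSM from a seed alignment.

    Columns with at least ``match_fraction`` non-gap residues become match
    columns. Per match column the score of amino acid a is

        log2( ((count_a + pseudocount * bg_a) / (n_eff + pseudocount)) / bg_a )

    with n_eff the number of observed residues in the column.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = wag_frequencies() if background is None else np.asarray(background, float)
    codes = seed.column_codes()
    n_seq = codes.shape[0]
    match_cols, rows = [], []
    for col in range(seed.n_columns):
        col_codes = codes[:, col]
        obs = col_codes[col_codes >= 0]
        if obs.size < match_fraction * n_seq or obs.size == 0:
            continue
        counts = np.bincount(obs, minlength=N_STATES).astype(float)
        probs = (counts + pseudocount * bg) / (obs.size + pseudocount)
        rows.append(np.log2(probs / bg))
        match_cols.append(col + 1)
    if not match_cols:
        raise ValueError("no match columns")
    return ProfileModel(
        match_columns=match_cols,
        scores=np.vstack(rows),
        background=bg,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


# ---------------------------------------------------------------------------
# Local alignment scoring (Smith-Waterman with affine gaps, vectorised
# across sequences; the per-row insertion/deletion chains collapse to
# running maxima, so the only Python loop is over query positions)
# ---------------------------------------------------------------------------

def _emission_matrix(profile: ProfileModel, codes: np.ndarray) -> np.ndarray:
    """(len(codes), n_match) emission bits; padded/unknown residues -> NEG."""
    emit = np.full((codes.size, profile.n_match), NEG)
    ok = codes >= 0
    emit[ok] = profile.scores[:, codes[ok]].T
    return emit


def batch_scores(profile: ProfileModel, sequences: list) -> np.ndarray:
    """Best local-alignment bit score of each sequence against the profile."""
    if not sequences:
        return np.zeros(0)
    codes = [s if isinstance(s, np.ndarray) else encode_sequence(s) for s in sequences]
    max_len = max(c.size for c in codes)
    n, m = len(codes), profile.n_match
    padded = np.full((n, max_len), -1, dtype=np.int64)
    for i, c in enumerate(codes):
        padded[i, : c.size] = c
    emit = np.full((n, max_len, m), NEG)
    for i, c in enumerate(codes):
        emit[i, : c.size] = _emission_matrix(profile, c)

    go, ge = profile.gap_open, profile.gap_extend
    jj = np.arange(m)
    prev_best = np.full((n, m), NEG)
    prev_m = np.full((n, m), NEG)
    prev_ix = np.full((n, m), NEG)
    best = np.full(n, 0.0)
    for i in range(max_len):
        diag = np.concatenate([np.zeros((n, 1)), np.maximum(prev_best[:, :-1], 0.0)], axis=1)
        diag[:, 0] = 0.0
        m_row = emit[:, i, :] + diag
        ix_row = np.maximum(prev_m - go, prev_ix - ge)
        # deletion chain: Iy[j] = max_{k<j} M[k] - go - (j-1-k)*ge
        t = m_row + ge * jj
        run = np.maximum.accumulate(t, axis=1)
        iy_row = np.full((n, m), NEG)
        iy_row[:, 1:] = run[:, :-1] - go - ge * (jj[1:] - 1)
        prev_best = np.maximum(np.maximum(m_row, ix_row), iy_row)
        best = np.maximum(best, m_row.max(axis=1))
        prev_m, prev_ix = m_row, ix_row
    return best


def _traceback_alignment(profile: ProfileModel, codes: np.ndarray) -> tuple:
    """Full DP with backpointers for one sequence.

    Returns (bit_score, span, column_map) where span is 1-based inclusive
    on the query and column_map maps match-column index (0-based) ->
    residue code.
    """
    m = profile.n_match
    L = codes.size
    go, ge = profile.gap_open, profile.gap_extend
    emit = _emission_matrix(profile, codes)
    M = np.full((L + 1, m + 1), NEG)
    Ix = np.full((L + 1, m + 1), NEG)
    Iy = np.full((L + 1, m + 1), NEG)
    ptr = np.zeros((L + 1, m + 1), dtype=np.int8)  # 0 start,1 M,2 Ix,3 Iy
    for i in range(1, L + 1):
        for j in range(1, m + 1):
            cands = (0.0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = int(np.argmax(cands))
            M[i, j] = emit[i - 1, j - 1] + cands[k]
            ptr[i, j] = k
            Ix[i, j] = max(M[i - 1, j] - go, Ix[i - 1, j] - ge)
            Iy[i, j] = max(M[i, j - 1] - go, Iy[i, j - 1] - ge)
    i, j = np.unravel_index(int(M.argmax()), M.shape)
    score = float(M[i, j])
    end = i
    column_map = {}
    state = 1
    while state != 0 and i > 0 and j > 0:
        if state == 1:
            column_map[j - 1] = int(codes[i - 1])
            nxt = ptr[i, j]
            i, j = i - 1, j - 1
            state = nxt if nxt != 0 else 0
        elif state == 2:  # gap in profile: unaligned query residue
            state = 1 if M[i - 1, j] - go >= Ix[i - 1, j] - ge else 2
            i -= 1
        else:  # skipped profile column
            state = 1 if M[i, j - 1] - go >= Iy[i, j - 1] - ge else 3
            j -= 1
    start = i + 1
    column_map = {k: v for k, v in column_map.items() if v >= 0}
    return score, (start, end), column_map


def calibrate_profile(
    profile: ProfileModel,
    n_sims: int = 2000,
    length: int = 200,
    seed: int = 0,
    db_size: int | None = None,
) -> ProfileModel:
    """Fit the Gumbel null of local-alignment scores by simulation.

    Scores ``n_sims`` i.i.d. background sequences of the given length and
    fits a Gumbel distribution to the score sample by maximum likelihood;
    E(s) = db_size * P(S > s) under the fit.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    rng = np.random.default_rng(seed)
    seqs = rng.choice(N_STATES, size=(n_sims, length), p=profile.background)
    scores = batch_scores(profile, list(seqs))
    if np.ptp(scores) == 0:
        raise ValueError("degenerate score distribution: all simulated scores equal")
    mu, scale = gumbel_r.fit(scores)
    profile.gumbel_mu = float(mu)
    profile.gumbel_lambda = 1.0 / float(scale)
    if db_size is not None:
        profile.db_size = int(db_size)
    return profile


def search_profile(
    profile: ProfileModel,
    sequences: list,
    e_max: float = 0.001,
    db_size: int | None = None,
) -> list:
    """Recruit sequences with E-value below ``e_max``, sorted ascending.

    ``sequences`` is a list of (id, residues). The E-value database size
    defaults to the number of sequences searched. Empty sequences are
    skipped with a warning.
    """
    records = [(i, sid, s) for i, (sid, s) in enumerate(sequences) if len(s) > 0]
    for sid, s in sequences:
        if len(s) == 0:
            logger.warning("skipping empty sequence %r", sid)
    if not records:
        return []
    profile.db_size = int(db_size) if db_size is not None else len(records)
    codes = [encode_sequence(s) for _, _, s in records]
    scores = batch_scores(profile, codes)
    evalues = profile.e_value(scores)
    hits = []
    for k, (_, sid, _seq) in enumerate(records):
        if evalues[k] < e_max:
            _, span, _ = _traceback_alignment(profile, codes[k])
            hits.append(SearchHit(query_id=sid, bit_score=float(scores[k]),
                                  e_value=float(evalues[k]), aligned_span=span))
    hits.sort(key=lambda h: (h.e_value, h.query_id))
    return hits


def align_to_profile(profile: ProfileModel, query_id: str, residues: str) -> AlignedQueryMap:
    """Align a peptide to the profile; map match columns to query residues.

    Query insertions relative to the profile are dropped, so the result
    lives entirely in profile (reference-alignment) coordinates.
    """
    codes = encode_sequence(residues)
    score, span, column_map = _traceback_alignment(profile, codes)
    ref_map = {profile.match_columns[j] - 1: code for j, code in column_map.items()}
    return AlignedQueryMap(query_id=query_id, bit_score=score, span=span, column_map=ref_map)


@dataclass
class AlignedQueryMap:
    query_id: str
    bit_score: float
    span: tuple
    column_map: dict  # 0-based seed-alignment column -> residue code


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            k = int(num)
            num = ""
            columns += k
            if ch == "=":
                matches += k
    return matches / columns


def dereplicate(sequences: list, identity: float = 0.99) -> list:
    """Greedy centroid clustering at the given identity threshold.

    ``sequences`` is a list of (id, residues). Input is processed in
    (length descending, id ascending) order for determinism; each sequence
    joins the first centroid it matches at >= identity, else founds a new
    cluster. Clusters partition the input.
    """
    if not (0 < identity <= 1):
        raise ValueError("identity must be in (0, 1]")
    order = sorted(sequences, key=lambda r: (-len(r[1]), r[0]))
    clusters: list[SequenceCluster] = []
    centroid_seq: list[str] = []
    for sid, seq in order:
        placed = False
        for cl, cseq in zip(clusters, centroid_seq):
            if pairwise_identity(seq, cseq) >= identity:
                cl.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(centroid_id=sid, member_ids=[sid],
                                            identity_threshold=identity))
            centroid_seq.append(seq)
    return clusters
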