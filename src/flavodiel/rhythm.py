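"""Non-parametric detection of diel (24 h) rhythmicity.

Per contig, abundances are grouped by local time-of-day and tested for a
rise-then-fall ("umbrella") pattern around each candidate peak phase with
a rank statistic: the sum, over consecutive group pairs in the umbrella
order, of Mann-Whitney concordant cross-group pair counts (ties count
half). The observed maximum over candidate phases is calibrated by
permuting whole timepoint blocks (replicate structure preserved), giving
an exact add-one permutation p-value; contigs are then corrected across
the family with Benjamini-Hochberg.

This is a permutation-calibrated umbrella test in the spirit of
rank-based rhythmicity detection; it is specified fully here and is not a
clone of any published implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TimeSeries:
    """One contig's longitudinal observations.

    hours are since series start; time-of-day = hours mod period.
    """
    contig_id: str
    hours: np.ndarray
    values: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, float)
        self.values = np.asarray(self.values, float)
        self.replicate = np.asarray(self.replicate)
        if not (self.hours.size == self.values.size == self.replicate.size):
            raise ValueError("hours, values, replicate must have equal length")
        if (self.values < 0).any():
            raise ValueError("abundance values must be >= 0")


@dataclass
class RhythmResult:
    contig_id: str
    period: float
    phases: np.ndarray          # candidate peak phases (times-of-day)
    statistics: np.ndarray      # umbrella statistic per phase
    best_phase: float
    p_value: float
    q_value: float | None = None
    significant: bool | None = None


def _pair_concordance(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Mann-Whitney count of pairs with lower < upper (+0.5 per tie).

    Inputs have shape (..., n1) and (..., n2); broadcast over leading axes.
    """
    a = lower[..., :, None]
    b = upper[..., None, :]
    return ((a < b) + 0.5 * (a == b)).sum(axis=(-2, -1))


def _umbrella_directions(n_groups: int, peak_index: int) -> tuple:
    """Linear umbrella order for a peak at ``peak_index``.

    Groups are arranged cyclically starting at the antipodal trough, rising
    to the peak and then falling. Returns (chain, ascending): ``chain`` is
    the ordered group indices; ``ascending[i]`` says whether the step from
    chain[i] to chain[i+1] is expected to rise.
    """
    k = n_groups
    trough = (peak_index + (k + 1) // 2) % k
    chain = [(trough + i) % k for i in range(k)]
    rise_steps = (peak_index - trough) % k
    ascending = [i < rise_steps for i in range(k - 1)]
    return chain, ascending


def umbrella_statistic(series: TimeSeries, peak_phase: float, period: float = 24.0) -> float:
    """Umbrella rank statistic of the series for one candidate peak phase.

    Observations are grouped by time-of-day; for each consecutive pair of
    groups in the umbrella order around ``peak_phase`` the Mann-Whitney
    concordant pair count (ties half) is accumulated. The maximum
    achievable value is the sum of group-size products along the chain.
    """
    tod = np.mod(series.hours, period)
    phases = np.unique(tod)
    if phases.size < 3:
        raise ValueError("need >= 3 distinct time-of-day groups")
    peaks = np.where(np.isclose(phases, peak_phase % period))[0]
    if peaks.size != 1:
        raise ValueError(f"peak phase {peak_phase} is not a sampled time-of-day")
    groups = [series.values[tod == ph] for ph in phases]
    chain, ascending = _umbrella_directions(phases.size, int(peaks[0]))
    stat = 0.0
    for i, asc in enumerate(ascending):
        a, b = groups[chain[i]], groups[chain[i + 1]]
        c_asc = float(_pair_concordance(a, b))
        stat += c_asc if asc else a.size * b.size - c_asc
    return stat


def _phase_statistics(values_by_group: list) -> np.ndarray:
    """Statistic for every candidate peak phase from per-group value arrays.

    values_by_group[g] has shape (..., n_g); leading axes broadcast (used
    to evaluate many permutations at once). Consecutive-pair concordances
    are shared between phases, so each cyclic adjacency is counted once.
    """
    k = len(values_by_group)
    c_asc = []
    sizes = [g.shape[-1] for g in values_by_group]
    for g in range(k):
        a, b = values_by_group[g], values_by_group[(g + 1) % k]
        c_asc.append(_pair_concordance(a, b))
    lead_shape = np.broadcast(*(np.empty(g.shape[:-1]) for g in values_by_group)).shape \
        if values_by_group[0].ndim > 1 else ()
    stats = np.zeros((k,) + lead_shape)
    for j in range(k):
        chain, ascending = _umbrella_directions(k, j)
        s = 0.0
        for i, asc in enumerate(ascending):
            g = chain[i]
            total = sizes[g] * sizes[(g + 1) % k]
            s = s + (c_asc[g] if asc else total - c_asc[g])
        stats[j] = s
    return stats


def rain_like_test(
    series: TimeSeries,
    period: float = 24.0,
    n_perm: int = 999,
    seed: int = 0,
) -> RhythmResult:
    """Permutation-calibrated max-over-phases umbrella test.

    The observed statistic is maximised over the sampled peak phases; the
    null distribution is built by permuting timepoint blocks (all
    replicates of a timepoint move together, preserving pairing) and
    re-maximising. p = (1 + #{null >= observed}) / (n_perm + 1); the best
    phase is the argmax (earliest time-of-day on ties).
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    span = series.hours.max() - series.hours.min()
    if span < 2 * period - 1e-9:
        raise ValueError("need >= 2 full periods of data")
    tod = np.mod(series.hours, period)
    phases = np.unique(tod)
    if phases.size < 3:
        raise ValueError("need >= 3 distinct time-of-day groups")

    # rectangular block structure: timepoints x replicates
    timepoints = np.unique(series.hours)
    block_index = {h: i for i, h in enumerate(timepoints)}
    blocks = [series.values[series.hours == h] for h in timepoints]
    sizes = {b.size for b in blocks}
    if len(sizes) != 1:
        raise ValueError("design must be rectangular: equal replicates per timepoint")
    n_rep = sizes.pop()
    block_values = np.stack(blocks)                     # (n_tp, n_rep)
    block_tod = np.mod(timepoints, period)

    rng = np.random.default_rng(seed)
    n_tp = timepoints.size
    perms = np.stack([np.arange(n_tp)] +
                     [rng.permutation(n_tp) for _ in range(n_perm)])
    permuted = block_values[perms]                      # (P+1, n_tp, n_rep)
    groups = []
    for ph in phases:
        sel = block_tod == ph
        g = permuted[:, sel, :].reshape(n_perm + 1, -1)
        groups.append(g)
    stats = _phase_statistics(groups)                   # (K, P+1)
    observed_by_phase = stats[:, 0]
    observed = observed_by_phase.max()
    null_max = stats[:, 1:].max(axis=0)
    p = (1.0 + float((null_max >= observed).sum())) / (n_perm + 1.0)
    best = int(np.argmax(observed_by_phase))            # argmax, earliest on tie
    return RhythmResult(
        contig_id=series.contig_id,
        period=period,
        phases=phases,
        statistics=observed_by_phase,
        best_phase=float(phases[best]),
        p_value=p,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def analyze_rhythmicity(
    series_list: list,
    period: float = 24.0,
    n_perm: int = 999,
    seed: int = 0,
    q_max: float = 0.05,
) -> list:
    """Run the umbrella permutation test per contig and BH-correct."""
    results = []
    for i, s in enumerate(series_list):
        results.append(rain_like_test(s, period=period, n_perm=n_perm,
                                      seed=seed + i))
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
        r.significant = bool(q < q_max)
    return results


def summarize_phases(results: list, q_max: float = 0.05) -> pd.DataFrame:
    """Histogram of significant contigs by best peak phase.

    Returns a frame with one row per candidate phase observed across
    results (column ``n_significant``) plus attrs ``n_tested``.
    """
    phases = sorted({float(ph) for r in results for ph in r.phases})
    counts = {ph: 0 for ph in phases}
    for r in results:
        sig = r.significant if r.significant is not None else (
            r.q_value is not None and r.q_value < q_max)
        if sig:
            counts[float(r.best_phase)] += 1
    out = pd.DataFrame({"phase": phases,
                        "n_significant": [counts[ph] for ph in phases]})
    out.attrs["n_tested"] = len(results)
    return out


def results_frame(results: list) -> pd.DataFrame:
    rows = [(r.contig_id, r.statistics.max(), r.best_phase, r.p_value,
             r.q_value, r.significant) for r in results]
    return pd.DataFrame(rows, columns=["contig", "statistic", "best_phase",
                                       "p", "q", "significant"])
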