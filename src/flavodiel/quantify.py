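"""Count normalization: spike-ins, taxon fractions, and sample combination.

Raw contig read counts are converted to absolute transcripts per liter
using the per-sample recovery of 14 spiked internal mRNA standards, summed
to clade x genus, expressed as a fraction of the order-level reads of each
genus, averaged over replicates, and summed over the two filter size
fractions. Additional helpers row-normalize incubation treatment tables
and compute TPM for culture transcriptomes.

All stages are pandas DataFrames; missing values are explicit NA, never
silent zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_STANDARDS = 14
SIZE_FRACTIONS = ("0.2um", "3um")


@dataclass
class SampleMeta:
    """Per-sample metadata table with spike-in standards.

    The frame must carry columns: sample_id, cruise, hours, replicate,
    size_fraction, liters, plus spike_added_NN / spike_reads_NN for the
    14 standards (when spike-in mode is on).
    """
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "cruise", "hours", "replicate", "size_fraction", "liters"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        if (self.frame["liters"] <= 0).any():
            raise ValueError("liters filtered must be > 0")
        self.frame = self.frame.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list:
        return list(self.frame["sample_id"])

    def spike_columns(self) -> tuple:
        added = sorted(c for c in self.frame.columns if c.startswith("spike_added_"))
        reads = sorted(c for c in self.frame.columns if c.startswith("spike_reads_"))
        if len(added) != N_STANDARDS or len(reads) != N_STANDARDS:
            raise ValueError(
                f"expected {N_STANDARDS} spike-in standards, found "
                f"{len(added)} added / {len(reads)} recovered columns"
            )
        return added, reads

    def spike_factor(self, sample_id: str, robust: bool = False) -> float:
        """Copies-per-read conversion: mean over standards of added/recovered.

        Standards with zero recovered reads are excluded (logged); if all
        standards failed the sample is unusable.
        """
        added_cols, reads_cols = self.spike_columns()
        row = self.frame.loc[sample_id]
        added = row[added_cols].to_numpy(float)
        reads = row[reads_cols].to_numpy(float)
        ok = reads > 0
        if not ok.any():
            raise ValueError(f"spike-in failure: all standards recovered 0 reads in {sample_id!r}")
        if not ok.all():
            logger.warning("sample %s: %d spike-in standards with 0 reads excluded",
                           sample_id, int((~ok).sum()))
        ratios = added[ok] / reads[ok]
        return float(np.median(ratios) if robust else ratios.mean())


def reads_per_liter(counts: pd.DataFrame, meta: SampleMeta, robust: bool = False) -> pd.DataFrame:
    """Scale a contig x sample count table to transcripts per liter.

    rpl(contig, s) = count * (mean over standards of added/recovered) / liters.
    """
    if not set(counts.columns) <= set(meta.sample_ids):
        unknown = sorted(set(counts.columns) - set(meta.sample_ids))
        raise ValueError(f"count columns without metadata: {unknown}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    out = counts.astype(float).copy()
    for s in counts.columns:
        factor = meta.spike_factor(s, robust=robust)
        out[s] = counts[s] * factor / float(meta.frame.loc[s, "liters"])
    return out


def aggregate_clade_genus(placements: list, rpl: pd.DataFrame) -> pd.DataFrame:
    """Sum reads/L over contigs sharing (clade, genus), per sample.

    Only placements with ``kept=True`` contribute; kept contigs without a
    count row are logged and skipped.
    """
    rows = {}
    for res in placements:
        if not res.kept:
            continue
        if res.query_id not in rpl.index:
            logger.warning("kept placement %r has no counts; skipped", res.query_id)
            continue
        key = (res.assigned_clade, res.assigned_genus)
        vec = rpl.loc[res.query_id]
        rows[key] = rows[key] + vec if key in rows else vec.copy()
    if not rows:
        return pd.DataFrame(columns=rpl.columns,
                            index=pd.MultiIndex.from_arrays([[], []], names=["clade", "genus"]))
    out = pd.DataFrame(rows).T
    out.index.names = ["clade", "genus"]
    return out.sort_index()


def order_normalize(
    clade_genus_rpl: pd.DataFrame,
    order_totals: pd.DataFrame,
    genus_to_order: dict,
) -> pd.DataFrame:
    """Divide clade x genus reads/L by the genus's order total per sample.

    A zero order total gives NA (never 0 or inf). Unknown genera are an
    error: silently dropping them would bias the fractions.
    """
    out = clade_genus_rpl.astype(float).copy()
    for clade, genus in out.index:
        order = genus_to_order.get(genus)
        if order is None:
            raise KeyError(f"genus {genus!r} has no order mapping")
        if order not in order_totals.index:
            out.loc[(clade, genus), :] = np.nan
            continue
        denom = order_totals.loc[order].reindex(out.columns).to_numpy(float)
        num = out.loc[(clade, genus)].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, num / denom, np.nan)
        out.loc[(clade, genus), :] = frac
    return out


def combine_samples(order_fraction: pd.DataFrame, meta: SampleMeta) -> pd.DataFrame:
    """Average replicates within (group, size fraction), then sum fractions.

    Groups are the hours column (station/timepoint). The replicate mean is
    NA-ignoring; the cross-fraction sum treats NA as identity but keeps NA
    when a cell is NA in both fractions.
    """
    frame = meta.frame
    cols = order_fraction.columns
    hours = frame.loc[cols, "hours"]
    fraction = frame.loc[cols, "size_fraction"]
    groups = sorted(hours.unique())
    combined = {}
    for g in groups:
        per_fraction = []
        for sf in sorted(fraction.unique()):
            sel = [c for c in cols if hours[c] == g and fraction[c] == sf]
            if sel:
                per_fraction.append(order_fraction[sel].mean(axis=1, skipna=True))
        if not per_fraction:
            continue
        stack = pd.concat(per_fraction, axis=1)
        all_na = stack.isna().all(axis=1)
        summed = stack.sum(axis=1, skipna=True)
        summed[all_na] = np.nan
        combined[g] = summed
    out = pd.DataFrame(combined)
    out.index = order_fraction.index
    return out


def row_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Divide each row by its row sum; all-zero rows become all-NA."""
    arr = values.to_numpy(float)
    if (arr < 0).any():
        raise ValueError("row_normalize requires non-negative values")
    sums = np.nansum(arr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = arr / sums[:, None]
    out[sums == 0, :] = np.nan
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized within-sample rates.

    rate = count / length; tpm = rate / sum(rates) * 1e6. All-zero samples
    become all-NA (logged) rather than dividing by zero.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = sorted(counts.index[lengths.isna()])
        raise ValueError(f"genes without length: {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be > 0")
    rates = counts.divide(lengths, axis=0).astype(float)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("samples with zero total rate set to NA: %s",
                       ", ".join(map(str, counts.columns[zero])))
    totals = totals.replace(0, np.nan)
    return rates.divide(totals, axis=1) * 1e6
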