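"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython; tables are TSV with NA as empty fields;
the profile model serialises to a self-describing TSV with a ``#``
header block.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .placement import CladeAnnotation
from .profile import ProfileModel, SearchHit
from .substitution import AMINO_ACIDS

FASTA_WRAP = 60


def read_fasta(path) -> list:
    """Read peptide FASTA as a list of (id, residues)."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list, path) -> None:
    """Write (id, residues) records wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seqs)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """TSV with exact-round-trip floats and empty-string NA."""
    df.to_csv(path, sep="\t", index=index, na_rep="", float_format="%.12g")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_annotation(path) -> CladeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"leaf_label", "clade", "genus", "species", "order_taxid"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    return CladeAnnotation(
        clade=dict(zip(df.leaf_label, df.clade)),
        genus=dict(zip(df.leaf_label, df.genus)),
        species=dict(zip(df.leaf_label, df.species)),
        order_taxid=dict(zip(df.leaf_label, df.order_taxid)),
    )


def write_hits(hits: list, path, db_size: int | None = None) -> None:
    with open(path, "w") as fh:
        if db_size is not None:
            fh.write(f"# e-values scaled to database size {db_size}\n")
        fh.write("query_id\tbit_score\te_value\tstart\tend\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.bit_score:.6g}\t{h.e_value:.6g}\t"
                     f"{h.aligned_span[0]}\t{h.aligned_span[1]}\n")


def read_hits(path) -> list:
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("query_id"):
                continue
            qid, score, ev, start, end = line.rstrip("\n").split("\t")
            hits.append(SearchHit(qid, float(score), float(ev),
                                  (int(start), int(end))))
    return hits


def write_profile(profile: ProfileModel, path) -> None:
    """Self-describing TSV: header block of scalars, then the score matrix."""
    with open(path, "w") as fh:
        fh.write("# flavodiel profile model\n")
        fh.write(f"# gap_open\t{profile.gap_open!r}\n")
        fh.write(f"# gap_extend\t{profile.gap_extend!r}\n")
        fh.write(f"# gumbel_lambda\t{profile.gumbel_lambda!r}\n")
        fh.write(f"# gumbel_mu\t{profile.gumbel_mu!r}\n")
        fh.write(f"# db_size\t{profile.db_size}\n")
        fh.write("# background\t" + "\t".join(repr(x) for x in profile.background) + "\n")
        fh.write("match_column\t" + "\t".join(AMINO_ACIDS) + "\n")
        for col, row in zip(profile.match_columns, profile.scores):
            fh.write(str(col) + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_profile(path) -> ProfileModel:
    scalars = {}
    background = None
    cols, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# ") and "\t" in line:
                key, *vals = line[2:].split("\t")
                if key == "background":
                    background = np.array([float(v) for v in vals])
                else:
                    scalars[key] = vals[0]
            elif line.startswith("#") or line.startswith("match_column"):
                continue
            elif line:
                parts = line.split("\t")
                cols.append(int(parts[0]))
                rows.append([float(x) for x in parts[1:]])
    lam = scalars.get("gumbel_lambda", "None")
    mu = scalars.get("gumbel_mu", "None")
    return ProfileModel(
        match_columns=cols,
        scores=np.array(rows),
        background=background,
        gap_open=float(scalars["gap_open"]),
        gap_extend=float(scalars["gap_extend"]),
        gumbel_lambda=None if lam == "None" else float(lam),
        gumbel_mu=None if mu == "None" else float(mu),
        db_size=int(scalars["db_size"]),
    )


def sha256_file(path) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
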