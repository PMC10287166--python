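"""End-to-end orchestration: recruit -> place -> quantify -> rhythm.

Each stage reads and writes plain TSV/FASTA/Newick/jplace files so stages
can also be run independently; ``run_pipeline`` chains them and records a
manifest with input checksums, seeds and per-stage record counts. All
randomness flows from the seeds in the run configuration, so a re-run
with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .likelihood import encode_alignment
from .phylo import read_newick, write_newick
from .placement import (AlignedQuery, PlacementEngine, filter_and_assign,
                        write_jplace)
from .profile import (SeedAlignment, align_to_profile, build_profile,
                      calibrate_profile, dereplicate, search_profile)
from .quantify import SampleMeta, aggregate_clade_genus, combine_samples, \
    order_normalize, reads_per_liter
from .rhythm import TimeSeries, analyze_rhythmicity, results_frame, summarize_phases
from .simulate import GroundTruth, SimulationConfig, evolve_sequences, \
    sim_metatranscriptome, sim_queries, sim_taxonomy, sim_tree
from .substitution import SubstitutionModel
from .taxonomy import Taxonomy, lca, order_totals

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (missing inputs, bad thresholds)."""


class DataError(ValueError):
    """Well-configured run aborted by malformed data."""


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for a full pipeline run."""
    tree: str
    ref_alignment: str
    annotation: str
    queries: str
    taxonomy: str
    counts: str
    meta: str
    assignments: str
    out_dir: str
    e_max: float = 0.001
    identity: float = 0.99
    lwr_min: float = 0.8
    q_max: float = 0.05
    alpha: float = 1.0
    n_perm: int = 999
    calibration_sims: int = 2000
    seed: int = 1
    spike_in: bool = True

    def validate(self) -> None:
        if not (0 < self.e_max):
            raise ConfigError("e_max must be > 0")
        if not (0 < self.identity <= 1):
            raise ConfigError("identity must be in (0, 1]")
        if not (0 <= self.lwr_min < 1):
            raise ConfigError("lwr_min must be in [0, 1)")
        if not (0 < self.q_max < 1):
            raise ConfigError("q_max must be in (0, 1)")
        for name in ("tree", "ref_alignment", "annotation", "queries",
                     "taxonomy", "counts", "meta", "assignments"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"input {name} not found: {p}")
        if self.spike_in:
            header = pd.read_csv(self.meta, sep="\t", nrows=0)
            if not any(c.startswith("spike_added_") for c in header.columns):
                raise ConfigError("spike-in mode on but metadata has no spike columns")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad run configuration: {exc}") from exc


def write_simulation(config: SimulationConfig, out_dir) -> dict:
    """Generate and write the full synthetic dataset; returns file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = SubstitutionModel(alpha=config.alpha)
    tree, annot, annot_df = sim_tree(config)
    alignment, site_cats, codes = evolve_sequences(tree, model,
                                                   config.seq_length, config.seed)
    leaf_codes = {v: codes[v] for v in tree.leaves}
    queries, truth = sim_queries(tree, annot, leaf_codes, site_cats, model, config)
    taxonomy = sim_taxonomy(annot_df)
    counts, meta, assignments, truth = sim_metatranscriptome(
        config, truth, annot_df, taxonomy)

    paths = {k: str(out / v) for k, v in dict(
        tree="ref.nwk", ref_alignment="ref.fasta", annotation="annot.tsv",
        queries="queries.fasta", taxonomy="tax.tsv", counts="counts.tsv",
        meta="meta.tsv", assignments="assign.tsv", truth="truth.tsv",
        truth_diel="truth_diel.tsv", truth_factors="truth_factors.tsv",
    ).items()}
    (out / "ref.nwk").write_text(write_newick(tree) + "\n")
    fio.write_fasta([(lab, alignment[lab]) for lab in sorted(alignment)],
                    paths["ref_alignment"])
    fio.write_table(annot_df, paths["annotation"], index=False)
    # queries in plain (unaligned) peptide form, as a recruiter would see them
    fio.write_fasta([(qid, seq.replace("-", "")) for qid, seq in queries],
                    paths["queries"])
    fio.write_table(taxonomy.to_frame(), paths["taxonomy"], index=False)
    fio.write_table(counts, paths["counts"])
    fio.write_table(meta, paths["meta"], index=False)
    assign_df = pd.DataFrame(sorted(assignments.items()),
                             columns=["contig_id", "taxid"])
    fio.write_table(assign_df, paths["assignments"], index=False)
    fio.write_table(truth.queries, paths["truth"], index=False)
    fio.write_table(truth.contig_diel, paths["truth_diel"], index=False)
    fio.write_table(truth.sample_factors, paths["truth_factors"], index=False)
    return paths


def _read_assignments(path, taxonomy: Taxonomy) -> dict:
    """Contig -> taxid; contigs with several hit taxids collapse to their LCA."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for contig, grp in df.groupby("contig_id"):
        taxids = set(grp["taxid"])
        out[contig] = next(iter(taxids)) if len(taxids) == 1 else lca(taxids, taxonomy)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {name: getattr(config, name)
              for name in ("tree", "ref_alignment", "annotation", "queries",
                           "taxonomy", "counts", "meta", "assignments")}
    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "input_sha256": {k: fio.sha256_file(v) for k, v in sorted(inputs.items())},
        "counts": {},
    }

    # ---- stage 1: recruit -------------------------------------------------
    try:
        ref_records = fio.read_fasta(config.ref_alignment)
        seed_aln = SeedAlignment(sequences=ref_records)
        query_records = fio.read_fasta(config.queries)
        profile = build_profile(seed_aln)
        typical_len = int(np.median([len(s) for _, s in query_records])) if query_records else 100
        calibrate_profile(profile, n_sims=config.calibration_sims,
                          length=max(typical_len, 50), seed=config.seed)
        hits = search_profile(profile, query_records, e_max=config.e_max)
        hit_ids = {h.query_id for h in hits}
        recruited = [(qid, seq) for qid, seq in query_records if qid in hit_ids]
        clusters = dereplicate(recruited, identity=config.identity)
        centroid_ids = {c.centroid_id for c in clusters}
        centroids = [(qid, seq) for qid, seq in recruited if qid in centroid_ids]
        fio.write_profile(profile, out / "profile.tsv")
        fio.write_hits(hits, out / "hits.tsv", db_size=profile.db_size)
        fio.write_table(pd.DataFrame(
            [(c.centroid_id, m) for c in clusters for m in c.member_ids],
            columns=["centroid_id", "member_id"]), out / "clusters.tsv", index=False)
        fio.write_fasta(centroids, out / "recruited.fasta")
    except Exception as exc:
        raise DataError(f"stage recruit failed: {exc}") from exc
    manifest["counts"]["queries"] = len(query_records)
    manifest["counts"]["recruited"] = len(recruited)
    manifest["counts"]["centroids"] = len(centroids)

    # ---- stage 2: place ---------------------------------------------------
    try:
        tree = read_newick(Path(config.tree).read_text())
        annot = fio.read_annotation(config.annotation)
        annot.validate(tree)
        ref_alignment = dict(ref_records)
        model = SubstitutionModel(alpha=config.alpha)
        engine = PlacementEngine(tree, model, encode_alignment(ref_alignment))
        results = []
        for qid, seq in centroids:
            amap = align_to_profile(profile, qid, seq)
            query = AlignedQuery(query_id=qid, column_map=amap.column_map)
            res = engine.place(query)
            res = filter_and_assign(res, tree, annot, lwr_min=config.lwr_min)
            results.append(res)
        placed = [r for r in results if r.placements]
        kept = [r for r in results if r.kept]
        (out / "placements.jplace").write_text(write_jplace(placed, tree))
        rows = []
        for r in results:
            b = r.best
            rows.append((r.query_id,
                         b.edge_id if b else "", f"{b.like_weight_ratio:.6g}" if b else "",
                         r.assigned_clade or "", r.assigned_genus or "",
                         r.kept, r.reason or ""))
        fio.write_table(pd.DataFrame(rows, columns=[
            "query_id", "best_edge", "lwr", "clade", "genus", "kept", "reason"]),
            out / "placement_summary.tsv", index=False)
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"stage place failed: {exc}") from exc
    manifest["counts"]["placed"] = len(placed)
    manifest["counts"]["kept"] = len(kept)

    # ---- stage 3: quantify ------------------------------------------------
    try:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        meta = SampleMeta(pd.read_csv(config.meta, sep="\t"))
        taxonomy = Taxonomy.read_tsv(config.taxonomy)
        assignments = _read_assignments(config.assignments, taxonomy)
        rpl = reads_per_liter(counts, meta) if config.spike_in else counts.astype(float)
        totals = order_totals(assignments, rpl, taxonomy)
        cg = aggregate_clade_genus(kept, rpl)
        annot_df = pd.read_csv(config.annotation, sep="\t", dtype=str)
        genus_to_order = dict(zip(annot_df.genus, annot_df.order_taxid))
        frac = order_normalize(cg, totals, genus_to_order)
        combined = combine_samples(frac, meta)
        fio.write_table(rpl.loc[sorted({r.query_id for r in kept} & set(rpl.index))],
                        out / "flavodoxin_rpl.tsv")
        fio.write_table(totals, out / "order_totals.tsv")
        fio.write_table(cg, out / "clade_genus_rpl.tsv")
        fio.write_table(frac, out / "order_fraction.tsv")
        fio.write_table(combined, out / "combined.tsv")
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"stage quantify failed: {exc}") from exc
    manifest["counts"]["normalized"] = int(cg.shape[0])

    # ---- stage 4: rhythm --------------------------------------------------
    try:
        frame = meta.frame
        series_list = []
        for r in sorted(kept, key=lambda r: r.query_id):
            if r.query_id not in rpl.index:
                continue
            vec = rpl.loc[r.query_id]
            grouped = {}
            for sid, val in vec.items():
                key = (float(frame.loc[sid, "hours"]), frame.loc[sid, "replicate"])
                grouped[key] = grouped.get(key, 0.0) + float(val)  # sum fractions
            hours = np.array([k[0] for k in sorted(grouped)])
            reps = np.array([k[1] for k in sorted(grouped)])
            values = np.array([grouped[k] for k in sorted(grouped)])
            series_list.append(TimeSeries(r.query_id, hours, values, reps))
        results_r = analyze_rhythmicity(series_list, n_perm=config.n_perm,
                                        seed=config.seed, q_max=config.q_max)
        rframe = results_frame(results_r)
        phases = summarize_phases(results_r, q_max=config.q_max)
        fio.write_table(rframe, out / "rhythm.tsv", index=False)
        fio.write_table(phases, out / "rhythm_phases.tsv", index=False)
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"stage rhythm failed: {exc}") from exc
    manifest["counts"]["tested_rhythm"] = len(series_list)
    manifest["counts"]["significant"] = int(rframe["significant"].sum())

    if not (manifest["counts"]["kept"] <= manifest["counts"]["placed"]
            <= manifest["counts"]["recruited"] <= manifest["counts"]["queries"]):
        raise DataError("stage counts are not monotone")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
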