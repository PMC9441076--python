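"""Staged orchestration: simulate -> classify -> cds -> rates -> seltest -> scan.

Every stage reads and writes plain TSV/FASTA so each can also be run
standalone; `run_pipeline` wires them together, enforces record
conservation (genes in = genes kept + genes dropped with reasons), and
writes a consolidated report: per-gene rates table, selection-test table,
scaffold table, summary JSON, BED track of per-gene divergence, and a
manifest carrying the seed, the config hash and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import classify as _classify
from . import scan as _scan
from .cds import build_codon_alignment, filter_and_annotate, longest_orf_6frame
from .rates import apply_omega_rules, compute_rates, ts_tv_counts
from .seltest import bh_adjust, bootstrap_D, call_positive_selection
from .simdata import SimConfig, emit_inputs, make_truth_set

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_tracks"]


@dataclass
class RunConfig:
    """All stage thresholds plus either a SimConfig or explicit input paths."""

    sim: Optional[SimConfig] = None
    inputs: Optional[dict] = None          # paths: transcripts_A/B, hits_A/B, scaffolds, annotations
    outdir: str = "divscan_out"
    seed: int = 0
    method: str = "yn00"                   # yn00 | ng86
    evalue_max: float = 1e-15
    overlap_frac: float = 0.9
    gap_tolerance_bp: int = 30
    min_len_nt: int = 300
    annotation_evalue_max: float = 1e-10
    require_annotation: bool = False
    run_seltest: bool = True
    n_reps: int = 1000
    alpha: float = 0.05
    t_div: float = 0.1
    min_scaffold_bp: int = 300_000
    class_edges: tuple = (0.05, 0.75)
    make_plots: bool = False

    def __post_init__(self):
        if self.method not in ("yn00", "ng86"):
            raise ValueError("method must be 'yn00' or 'ng86'")
        if self.sim is None and self.inputs is None:
            raise ValueError("either a SimConfig or input paths are required")
        for name, val, lo, hi in [("overlap_frac", self.overlap_frac, 0, 1),
                                  ("alpha", self.alpha, 0, 1)]:
            if not lo <= val <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        d["class_edges"] = list(self.class_edges)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where results land does not change what they are
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # stage 0: inputs
    if config.sim is not None:
        truth, lengths = make_truth_set(config.sim)
        paths = emit_inputs(truth, config.sim, out / "inputs", lengths)
        counts["simulated_genes"] = int(len(truth))
    else:
        paths = {k: Path(v) for k, v in config.inputs.items()}

    # stage 1: classification + pairing
    hits_A = _classify.read_hit_table(paths["hits_A"], config.evalue_max)
    hits_B = _classify.read_hit_table(paths["hits_B"], config.evalue_max)
    cls_A = _classify.classify_transcripts(hits_A, config.overlap_frac,
                                           config.gap_tolerance_bp)
    cls_B = _classify.classify_transcripts(hits_B, config.overlap_frac,
                                           config.gap_tolerance_bp)
    _classify.write_classification(cls_A, out / "classified_A.tsv")
    _classify.write_classification(cls_B, out / "classified_B.tsv")
    pairs = _classify.pair_orthologs(cls_A, cls_B, config.overlap_frac)
    _classify.write_pairs(pairs, out / "pairs.tsv")
    counts["hits_A"] = len(hits_A)
    counts["hits_B"] = len(hits_B)
    counts["transcripts_A"] = len(cls_A)
    counts["transcripts_B"] = len(cls_B)
    counts["anchored_pairs"] = len(pairs)

    # stage 2: CDS extraction, filtering, codon alignments
    seqs_A = _read_fasta(paths["transcripts_A"])
    seqs_B = _read_fasta(paths["transcripts_B"])
    annotations = pd.read_csv(paths["annotations"], sep="\t") \
        if paths.get("annotations") and Path(paths["annotations"]).exists() else None
    alignments = []
    drops = []
    for pair in pairs:
        sides = {}
        reason = None
        for label, tid, seqs in (("A", pair.transcript_id_A, seqs_A),
                                 ("B", pair.transcript_id_B, seqs_B)):
            if tid not in seqs:
                reason = f"missing_transcript_{label}"
                break
            cand = longest_orf_6frame(seqs[tid], tid)
            keep, why = filter_and_annotate(
                cand, annotations, min_len_nt=config.min_len_nt,
                evalue_max=config.annotation_evalue_max,
                require_annotation=config.require_annotation)
            if not keep:
                reason = f"{why}_{label}"
                break
            sides[label] = cand
        if reason is None:
            aln, why = build_codon_alignment(pair, sides["A"], sides["B"],
                                             min_codons=config.min_len_nt // 3)
            if aln is None:
                reason = why
            else:
                alignments.append(aln)
                continue
        drops.append((pair.gene_id, reason))
    pd.DataFrame(drops, columns=["gene_id", "reason"]).to_csv(
        out / "dropped.tsv", sep="\t", index=False)
    counts["codon_alignments"] = len(alignments)
    counts["dropped_pairs"] = len(drops)
    if len(alignments) + len(drops) != len(pairs):
        raise RuntimeError("record conservation violated in the cds stage")

    # stage 3: rates
    rates = []
    gene_rows = []
    for aln in alignments:
        r = apply_omega_rules(compute_rates(aln, method=config.method))
        ts, tv, _ = ts_tv_counts(aln)
        rates.append(r)
        gene_rows.append(dict(
            gene_id=r.gene_id, scaffold=aln.scaffold, start=aln.start,
            end=aln.end, strand=aln.strand, n_codons=r.n_codons,
            S=r.S, N=r.N, dS=r.dS, dN=r.dN, omega=r.omega, t=r.t,
            kappa=r.kappa, ts=ts, tv=tv, has_introns=aln.has_introns,
            flags=";".join(sorted(r.flags))))
    genes_df = pd.DataFrame(gene_rows)
    genes_df.to_csv(out / "genes.tsv", sep="\t", index=False, float_format="%.6g")
    counts["rated_genes"] = len(genes_df)

    # stage 4: selection test
    tests_df = pd.DataFrame()
    if config.run_seltest and alignments:
        ss = np.random.SeedSequence([config.seed, 2])
        tests = []
        for aln, child in zip(alignments, ss.spawn(len(alignments))):
            tests.append(bootstrap_D(aln, n_reps=config.n_reps,
                                     seed=np.random.default_rng(child),
                                     method=config.method, keep_reps=False))
        tests_df = call_positive_selection(rates, tests, alpha=config.alpha)
        tests_df.to_csv(out / "tests.tsv", sep="\t", index=False, float_format="%.6g")
        counts["significant_genes"] = int(tests_df["significant"].sum())

    # stage 5: scaffold scan
    scaffold_lengths = pd.read_csv(paths["scaffolds"], sep="\t")
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "method": config.method, "counts": counts}
    if len(genes_df):
        scans = _scan.order_genes_on_scaffolds(
            genes_df.rename(columns={"t": "t", "omega": "omega"}),
            scaffold_lengths, config.min_scaffold_bp)
        r_values = []
        scaffold_rows = []
        for s in scans:
            _scan.classify_pattern(s, t_div=config.t_div)
            div_mid = [m for _, m, t, _ in s.genes
                       if (not np.isfinite(t)) or t > config.t_div]
            s.dispersion_index = _scan.dispersion_index(div_mid)
            r = _scan.correlate_t_omega(s)
            if r is not None:
                r_values.append(r)
            scaffold_rows.append(dict(
                scaffold_id=s.scaffold_id, length_bp=s.length_bp,
                n_genes=s.n_genes, n_divergent=s.n_divergent, pattern=s.pattern,
                dispersion_index=s.dispersion_index, pearson_r=s.pearson_r,
                r_skipped=s.r_skipped_reason))
        scaffolds_df = pd.DataFrame(scaffold_rows)
        scaffolds_df.to_csv(out / "scaffolds.tsv", sep="\t", index=False,
                            float_format="%.6g")
        pd.DataFrame({"pearson_r": r_values}).to_csv(
            out / "r_distribution.tsv", sep="\t", index=False, float_format="%.6g")
        patterns = scaffolds_df["pattern"].value_counts(normalize=True).to_dict() \
            if len(scaffolds_df) else {}
        try:
            slope, intercept, rr = _scan.dn_ds_regression(rates)
            regression = {"slope": slope, "intercept": intercept, "r": rr}
        except ValueError as exc:
            regression = {"error": str(exc)}
        summary.update(
            divergence=_scan.divergence_summary(rates, config.class_edges),
            regression=regression,
            pattern_proportions={k: float(v) for k, v in sorted(patterns.items())},
            n_scaffolds_examined=int(len(scaffolds_df)),
            r_distribution={"n": len(r_values),
                            "mean": float(np.mean(r_values)) if r_values else None,
                            "frac_positive": float(np.mean([r > 0 for r in r_values]))
                            if r_values else None},
        )
        write_tracks(genes_df, scaffolds_df, out, make_plots=config.make_plots)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"seed": config.seed, "config": config.to_dict(),
                   "config_hash": config.config_hash(), "counts": counts},
                  fh, indent=2, sort_keys=True)
    return summary


def write_tracks(genes_df: pd.DataFrame, scaffolds_df: Optional[pd.DataFrame],
                 outdir, make_plots: bool = False) -> dict:
    """BED track of per-gene divergence plus optional static plots.

    BED is 0-based half-open, sorted by (chrom, start); score = t x 1000
    capped at 1000 (saturated genes at the cap).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bed = out / "tracks.bed"
    with open(bed, "w") as fh:
        fh.write("# divscan per-gene divergence track (score = min(t*1000, 1000))\n")
        if len(genes_df):
            rows = genes_df.sort_values(["scaffold", "start"])
            for r in rows.itertuples(index=False):
                t = r.t if np.isfinite(r.t) else np.inf
                score = int(min(t * 1000, 1000))
                fh.write(f"{r.scaffold}\t{r.start - 1}\t{r.end}\t{r.gene_id}"
                         f"\t{score}\t{r.strand}\n")
    paths = {"bed": bed}
    if make_plots and len(genes_df):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        t = genes_df["t"].to_numpy()
        axes[0].hist(t[np.isfinite(t)], bins=40)
        axes[0].set_xlabel("t (subs/codon)")
        axes[0].set_ylabel("genes")
        fin = genes_df[np.isfinite(genes_df["dS"]) & np.isfinite(genes_df["dN"])]
        axes[1].scatter(fin["dS"], fin["dN"], s=4, alpha=0.5)
        axes[1].set_xlabel("dS")
        axes[1].set_ylabel("dN")
        if scaffolds_df is not None and scaffolds_df["pearson_r"].notna().any():
            axes[2].hist(scaffolds_df["pearson_r"].dropna(), bins=20)
        axes[2].set_xlabel("per-scaffold Pearson r")
        fig.tight_layout()
        p = out / "plots.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths["plots"] = p
    return paths
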