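"""Classification tests: hit parsing, the five categories, ortholog pairing."""

import numpy as np
import pandas as pd
import pytest

from divscan.classify import (HitRecord, HitTableFormatError,
                              classify_transcripts, pair_orthologs,
                              read_hit_table)
from divscan.simdata import SimConfig, emit_inputs, make_truth_set


def _hit(q, s, qs, qe, ss, se, ev=1e-50, bits=500.0):
    strand = "+" if ss <= se else "-"
    return HitRecord(q, s, 99.0, qe - qs + 1, qs, qe, min(ss, se), max(ss, se),
                     ev, bits, strand)


def _row(q="t1", s="s1", qs=1, qe=900, ss=1000, se=1899, ev=1e-50):
    return f"{q}\t{s}\t99.0\t900\t0\t0\t{qs}\t{qe}\t{ss}\t{se}\t{ev}\t1700"


def test_read_hit_table_evalue_filter_and_strand(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("\n".join([
        _row("keep", ev=1e-20),
        _row("drop", ev=1e-10),        # above the 1e-15 cutoff
        _row("minus", ss=500, se=100),
    ]) + "\n")
    recs = read_hit_table(p)
    ids = {r.query_id for r in recs}
    assert ids == {"keep", "minus"}
    minus = next(r for r in recs if r.query_id == "minus")
    assert (minus.sstart, minus.send, minus.strand) == (100, 500, "-")


def test_read_hit_table_missing_columns_named(tmp_path):
    p = tmp_path / "short.tsv"
    p.write_text("q\ts\t99\t100\t0\t0\t1\t100\t1\t100\n")  # 10 columns
    with pytest.raises(HitTableFormatError, match="evalue"):
        read_hit_table(p)


def test_read_hit_table_skips_malformed_rows(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(_row("ok") + "\n" + "t2\ts1\tx\ty\t0\t0\t1\tz\t1\t9\t1e-50\tq\n")
    recs = read_hit_table(p)
    assert [r.query_id for r in recs] == ["ok"]


def test_extended_columns_tolerated(tmp_path):
    p = tmp_path / "wide.tsv"
    p.write_text(_row("w") + "\t900\t500000\textra\n")
    assert len(read_hit_table(p)) == 1


def test_five_categories():
    hits = [
        _hit("paralog", "s1", 1, 900, 1000, 1899),
        _hit("paralog", "s2", 1, 900, 5000, 5899),
        _hit("tandem", "s1", 1, 900, 10_000, 10_899),
        _hit("tandem", "s1", 1, 900, 20_000, 20_899),
        _hit("allele1", "s1", 1, 1501, 30_000, 31_500),
        _hit("allele2", "s1", 1, 1501, 30_000, 31_500),
        _hit("split", "s1", 1, 300, 40_000, 40_299),
        _hit("split", "s1", 301, 700, 40_900, 41_299),
        _hit("single", "s1", 1, 900, 50_000, 50_899),
    ]
    cats = {c.transcript_id: c for c in classify_transcripts(hits)}
    assert cats["paralog"].category == "scaffold_paralog"
    assert cats["tandem"].category == "tandem_paralog"
    assert cats["allele1"].category == "allelic"
    assert cats["allele2"].category == "allelic"
    assert cats["split"].category == "exon"
    assert cats["split"].n_segments == 2
    assert cats["single"].category == "uniq"
    assert cats["single"].anchor == ("s1", 50_000, 50_899, "+")
    # partition: every transcript got exactly one category
    assert len(cats) == 6


def test_small_gaps_merge_to_uniq():
    hits = [
        _hit("t", "s1", 1, 300, 1000, 1299),
        _hit("t", "s1", 301, 600, 1320, 1619),   # 20-bp gap <= tolerance 30
    ]
    c = classify_transcripts(hits)[0]
    assert c.category == "uniq" and c.n_segments == 1


def test_classification_order_invariant(rng):
    hits = [
        _hit("a", "s1", 1, 900, 1000, 1899),
        _hit("a", "s2", 1, 900, 1000, 1899),
        _hit("b", "s1", 1, 300, 5000, 5299),
        _hit("b", "s1", 301, 900, 6000, 6599),
        _hit("c", "s1", 1, 900, 9000, 9899),
    ]
    ref = {c.transcript_id: (c.category, c.n_segments)
           for c in classify_transcripts(hits)}
    for _ in range(5):
        perm = [hits[i] for i in rng.permutation(len(hits))]
        got = {c.transcript_id: (c.category, c.n_segments)
               for c in classify_transcripts(perm)}
        assert got == ref


def test_empty_hit_list():
    assert classify_transcripts([]) == []


def test_pair_orthologs_basic_and_exclusions():
    A = classify_transcripts([
        _hit("a_uniq", "s1", 1, 1201, 100, 1300),
        _hit("a_par", "s1", 1, 900, 5000, 5899),
        _hit("a_par", "s2", 1, 900, 100, 999),
    ])
    B = classify_transcripts([
        _hit("b_uniq", "s1", 1, 1201, 100, 1300),
        _hit("b_at_par_locus", "s1", 1, 900, 5000, 5899),
    ])
    pairs = pair_orthologs(A, B)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.transcript_id_A, p.transcript_id_B) == ("a_uniq", "b_uniq")
    assert (p.scaffold, p.start, p.end, p.strand) == ("s1", 100, 1300, "+")
    assert not p.has_introns


def test_ambiguous_locus_dropped():
    A = classify_transcripts([
        _hit("a1", "s1", 1, 900, 100, 999),
    ])
    # two B transcripts at (nearly) the same locus but below the allelic
    # overlap threshold with each other -> both candidates for a1
    B = [
        HitRecord("b1", "s1", 99.0, 900, 1, 900, 100, 999, 1e-50, 500, "+"),
        HitRecord("b2", "s1", 99.0, 820, 1, 820, 100, 919, 1e-50, 480, "+"),
    ]
    Bc = classify_transcripts(B, overlap_frac=0.95)
    assert {c.category for c in Bc} == {"uniq"}
    assert pair_orthologs(A, Bc, overlap_frac=0.8) == []


def test_truth_recovery_on_synthetic_bundle(tmp_path):
    """Classifier recovers generated categories and ortholog pairs exactly."""
    cfg = SimConfig(n_scaffolds=6, genes_per_scaffold=6, regime="custom",
                    frac_zero_divergence=0.4,
                    t_distribution={"kind": "constant", "value": 0.05},
                    complication_rates={"scaffold_paralog": 0.15,
                                        "tandem_paralog": 0.15,
                                        "allelic": 0.15, "intron_split": 0.15},
                    seed=21)
    truth, lengths = make_truth_set(cfg)
    paths = emit_inputs(truth, cfg, tmp_path, lengths)
    cls_A = {c.transcript_id: c for c in
             classify_transcripts(read_hit_table(paths["hits_A"]))}
    for row in truth.itertuples(index=False):
        got = cls_A[f"{row.gene_id}_A"]
        assert got.category == row.category_label, row.gene_id
        if row.category_label == "exon":
            assert got.n_segments == row.n_segments
    cls_B = classify_transcripts(read_hit_table(paths["hits_B"]))
    pairs = pair_orthologs(list(cls_A.values()), cls_B)
    paired_genes = {p.transcript_id_A.rsplit("_", 1)[0] for p in pairs}
    expect = set(truth.loc[truth["category_label"].isin(["uniq", "exon"]),
                           "gene_id"])
    assert paired_genes == expect
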