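"""CDS extraction, filtering and codon-alignment construction tests."""

import numpy as np
import pandas as pd
import pytest
from _oracles import longest_orf_all_frames
from Bio.Seq import Seq

from divscan.classify import AnchoredPair
from divscan.cds import (CdsCandidate, CodonAlignment, build_codon_alignment,
                         filter_and_annotate, longest_orf_6frame)


def test_simple_orf():
    # frame +1 holds the unique 5-codon maximum, bounded by TAA and TGA
    seq = "TAAGGACTAGCTAACTATTGA"
    c = longest_orf_6frame(seq)
    n, frame, nt = longest_orf_all_frames(seq)
    assert (nt, frame, n) == ("GGACTAGCTAACTAT", 1, 5)  # oracle agrees
    assert (c.nt_seq, c.frame) == (nt, frame)
    assert (c.start, c.end) == (4, 18)
    assert c.aa_seq == "GLANY"


def test_degenerate_sequence_rejected_downstream():
    c = CdsCandidate("t", 1, 0, 0, "", "")   # no stop-free run anywhere
    keep, reason = filter_and_annotate(c)
    assert not keep and reason == "no_orf"
    # a stop-dense sequence still yields only short runs, dropped by length
    c2 = longest_orf_6frame("TAATAATAA")
    keep, reason = filter_and_annotate(c2, min_len_nt=300)
    assert not keep and reason in ("no_orf", "too_short")


def test_too_short_input_raises():
    with pytest.raises(ValueError):
        longest_orf_6frame("AT")


def test_reverse_complement_symmetry():
    """Same maximal CDS length either way; same nt when the max is unique."""
    from _oracles import STOPS
    rng = np.random.default_rng(3)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), 120))
        rc = str(Seq(seq).reverse_complement())
        fwd = longest_orf_6frame(seq)
        rev = longest_orf_6frame(rc)
        assert fwd.length_nt == rev.length_nt
        # count maximal runs over all 6 frames to detect ties
        runs = []
        for s in (seq, rc):
            for off in range(3):
                run = 0
                for i in range(off, len(s) - 2, 3):
                    if s[i:i + 3] in STOPS:
                        runs.append(run)
                        run = 0
                    else:
                        run += 1
                runs.append(run)
        if runs.count(max(runs)) == 1:
            assert fwd.nt_seq == rev.nt_seq
            assert np.sign(fwd.frame) == -np.sign(rev.frame)


def test_longest_orf_matches_bruteforce_on_random_sequences():
    rng = np.random.default_rng(41)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        n, frame, nt = longest_orf_all_frames(seq)
        c = longest_orf_6frame(seq)
        assert c.length_nt == 3 * n
        if n:
            assert c.nt_seq == nt and c.frame == frame


def test_filter_reasons():
    def cand(nt, **kw):
        return CdsCandidate("t", 1, 1, len(nt), nt, "X" * (len(nt) // 3), **kw)

    keep, why = filter_and_annotate(cand(("ATG" * 100)[:299]))
    assert not keep and why == "too_short"        # 299 nt < 300

    assert filter_and_annotate(cand("ATG" * 100)) == (True, None)  # 300 nt kept

    keep, why = filter_and_annotate(cand("ATG" * 150, has_N=True))
    assert not keep and why == "ambiguous_base"
    keep, why = filter_and_annotate(cand("ATG" * 150, has_gap=True))
    assert not keep and why == "has_gap"

    ann = pd.DataFrame({"query_id": ["t"], "evalue": [1e-12]})
    assert filter_and_annotate(cand("ATG" * 200), ann, require_annotation=True)[0]
    weak = pd.DataFrame({"query_id": ["t"], "evalue": [1e-3]})
    keep, why = filter_and_annotate(cand("ATG" * 200), weak, require_annotation=True)
    assert not keep and why == "not_annotated"


def test_filter_idempotent():
    c = CdsCandidate("t", 1, 1, 450, "ATG" * 150, "M" * 150)
    assert filter_and_annotate(c) == filter_and_annotate(c) == (True, None)


def _pair(strand="+", startA=1001, endA=1900, startB=1001, endB=1900):
    return AnchoredPair(
        gene_id="s1:1001-1900", transcript_id_A="a", transcript_id_B="b",
        scaffold="s1", start=max(startA, startB), end=min(endA, endB),
        strand=strand, has_introns=False,
        anchor_A=("s1", startA, endA, strand), anchor_B=("s1", startB, endB, strand),
        q_interval_A=(1, endA - startA + 1), q_interval_B=(1, endB - startB + 1),
    )


def _cand(nt, start=1):
    return CdsCandidate("t", 1, start, start + len(nt) - 1, nt,
                        str(Seq(nt).translate()), source_len=len(nt) + start - 1)


def test_identical_cds_full_alignment():
    cds = "ATGGCTAAA" * 100  # 300 codons
    aln, reason = build_codon_alignment(_pair(startA=1001, endA=1900,
                                              startB=1001, endB=1900),
                                        _cand(cds), _cand(cds))
    assert reason is None
    assert aln.n_codons == 300
    assert aln.seq_A == aln.seq_B == cds


def test_partial_overlap_trimmed_in_frame():
    # B's anchor (and CDS) is 9 nt shorter: common overlap = 297 codons
    cds_a = "ATGGCTAAA" * 100
    cds_b = cds_a[9:]
    pair = _pair(startA=1001, endA=1900, startB=1010, endB=1900)
    aln, reason = build_codon_alignment(pair, _cand(cds_a), _cand(cds_b))
    assert reason is None
    assert aln.n_codons == 297
    assert aln.seq_A == cds_a[9:] and aln.seq_B == cds_b


def test_frame_incompatible_pair_dropped():
    cds_a = "ATGGCTAAA" * 100
    cds_b = cds_a[1:-2]  # off-frame by one
    pair = _pair(startA=1001, endA=1900, startB=1002, endB=1900)
    aln, reason = build_codon_alignment(pair, _cand(cds_a), _cand(cds_b))
    assert aln is None and reason == "frame_mismatch"


def test_minus_strand_pair():
    cds = "ATGGCTAAA" * 100
    pair = _pair(strand="-")
    aln, reason = build_codon_alignment(pair, _cand(cds), _cand(cds))
    assert reason is None and aln.n_codons == 300


def test_opposite_strand_anchors_raise():
    cds = "ATGGCTAAA" * 100
    pair = _pair()
    pair.anchor_B = ("s1", 1001, 1900, "-")
    with pytest.raises(ValueError, match="opposite strands"):
        build_codon_alignment(pair, _cand(cds), _cand(cds))


def test_codon_alignment_validation():
    with pytest.raises(ValueError, match="unequal"):
        CodonAlignment("g", "ATGATG", "ATG")
    with pytest.raises(ValueError, match="multiple of 3"):
        CodonAlignment("g", "ATGA", "ATGA")
    with pytest.raises(ValueError, match="stop"):
        CodonAlignment("g", "ATGTAAATG", "ATGTAAATG")
    with pytest.raises(ValueError, match="gap or ambiguous"):
        CodonAlignment("g", "ATGN-A", "ATGACA")
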