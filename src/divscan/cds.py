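"""CDS extraction, quality filtering and codon-alignment construction.

The coding stretch of a transcript is taken as the longest run of codons
bounded by stop codons (or the sequence ends) over the six reading
frames — no start codon is required.  Kept CDSs are filtered on length,
ambiguity characters and (optionally) protein-annotation evidence, then
paired CDSs of an anchored ortholog pair are trimmed to their common
in-frame overlap using the anchor coordinates; near-identical pairs make
re-alignment unnecessary, and pairs that cannot be brought into a common
frame are dropped with a reason rather than realigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio.Seq import Seq

from ._codon import STOP_CODONS
from .classify import AnchoredPair

__all__ = [
    "CdsCandidate",
    "CodonAlignment",
    "longest_orf_6frame",
    "filter_and_annotate",
    "build_codon_alignment",
]

_FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class CdsCandidate:
    """Longest stop-bounded codon run of one transcript."""

    transcript_id: str
    frame: int                 # +1,+2,+3 forward; -1,-2,-3 reverse complement
    start: int                 # 1-based inclusive coords on the *forward* transcript
    end: int
    nt_seq: str
    aa_seq: str
    has_N: bool = False
    has_gap: bool = False
    source_len: int = 0

    @property
    def length_nt(self) -> int:
        return len(self.nt_seq)


@dataclass
class CodonAlignment:
    """Gap-free, in-frame, stop-free paired CDS of one gene."""

    gene_id: str
    seq_A: str
    seq_B: str
    n_codons: int = 0
    scaffold: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    has_introns: bool = False

    def __post_init__(self):
        if len(self.seq_A) != len(self.seq_B):
            raise ValueError(f"{self.gene_id}: unequal sequence lengths")
        if len(self.seq_A) % 3:
            raise ValueError(f"{self.gene_id}: length not a multiple of 3")
        for seq in (self.seq_A, self.seq_B):
            if set(seq) - set("ACGT"):
                raise ValueError(f"{self.gene_id}: gap or ambiguous character")
            for i in range(0, len(seq), 3):
                if seq[i:i + 3] in STOP_CODONS:
                    raise ValueError(f"{self.gene_id}: internal stop codon")
        self.n_codons = len(self.seq_A) // 3


def _codon_runs(s: str, offset: int):
    """Yield (start_codon_index, [codons]) runs bounded by stops in one frame."""
    codons = [s[i:i + 3] for i in range(offset, len(s) - 2, 3)]
    run_start, run = 0, []
    for k, c in enumerate(codons):
        if c in STOP_CODONS:
            if run:
                yield run_start, run
            run_start, run = k + 1, []
        else:
            run.append(c)
    if run:
        yield run_start, run


def longest_orf_6frame(nt_seq: str, transcript_id: str = "") -> CdsCandidate:
    """Longest codon run between stops over the six frames.

    Ties break by frame order (+1,+2,+3,-1,-2,-3) then leftmost.  Codons
    containing N or '-' cannot be stops and are carried through with the
    corresponding flags set on the candidate.
    """
    seq = nt_seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 nt")
    if set(seq) - set("ACGTN-"):
        raise ValueError("sequence contains characters outside {A,C,G,T,N,-}")
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    best: Optional[tuple] = None  # (length, frame_rank, start) max-length min-rank
    for rank, frame in enumerate(_FRAMES):
        s = seq if frame > 0 else rc
        off = abs(frame) - 1
        for run_start, run in _codon_runs(s, off):
            if best is None or len(run) > best[0]:
                best = (len(run), rank, run_start, run)
    if best is None or best[0] == 0:
        return CdsCandidate(transcript_id, 1, 0, 0, "", "", source_len=L)
    n, rank, run_start, run = best
    frame = _FRAMES[rank]
    off = abs(frame) - 1
    nt = "".join(run)
    # coordinates on the strand that was scanned
    s_start = off + 3 * run_start + 1
    s_end = s_start + 3 * n - 1
    if frame > 0:
        start, end = s_start, s_end
    else:  # map back from the reverse complement
        start, end = L - s_end + 1, L - s_start + 1
    aa = str(Seq(nt.replace("-", "N")).translate())
    return CdsCandidate(transcript_id, frame, start, end, nt, aa,
                        has_N="N" in nt, has_gap="-" in nt, source_len=L)


def filter_and_annotate(cds: CdsCandidate, annotations=None, *,
                        min_len_nt: int = 300, evalue_max: float = 1e-10,
                        require_annotation: bool = False) -> tuple[bool, Optional[str]]:
    """Quality filter; returns (keep, drop_reason).

    ``annotations`` is a table (or mapping) of best-hit e-values per
    transcript; with ``require_annotation`` every kept CDS needs a hit at
    or below ``evalue_max``.  The filter is pure and idempotent.
    """
    if cds.length_nt == 0:
        return False, "no_orf"
    if cds.has_N:
        return False, "ambiguous_base"
    if cds.has_gap:
        return False, "has_gap"
    if cds.length_nt < min_len_nt:
        return False, "too_short"
    if require_annotation:
        ev = _best_evalue(annotations, cds.transcript_id)
        if ev is None or ev > evalue_max:
            return False, "not_annotated"
    return True, None


def _best_evalue(annotations, transcript_id) -> Optional[float]:
    if annotations is None:
        return None
    if isinstance(annotations, pd.DataFrame):
        sub = annotations[annotations["query_id"] == transcript_id]
        return float(sub["evalue"].min()) if len(sub) else None
    return annotations.get(transcript_id)


# ---------------------------------------------------------------------------

def _sense_geometry(cds: CdsCandidate, q_interval: tuple, anchor: tuple):
    """Genomic interval of a CDS plus its reading direction on the genome.

    Negative-frame candidates are treated as CDSs of the reverse-
    complemented transcript (antisense assembly), which flips the
    effective anchor strand.  For intron-split anchors the linear mapping
    is approximate but differences cancel when both pair members share
    the exon structure; mis-registered pairs are caught by the internal-
    stop validation downstream.
    """
    sc, a_start, a_end, strand = anchor
    qs, qe = q_interval
    cs, ce = cds.start, cds.end
    if cds.frame < 0:
        L = cds.source_len
        cs, ce = L - ce + 1, L - cs + 1
        qs, qe = L - qe + 1, L - qs + 1
        strand = "-" if strand == "+" else "+"
        # after flipping, coordinates live on the revcomp transcript
    if strand == "+":
        gs = a_start + (cs - qs)
        ge = a_start + (ce - qs)
    else:
        gs = a_end - (ce - qs)
        ge = a_end - (cs - qs)
    return gs, ge, strand


def build_codon_alignment(pair: AnchoredPair, cds_A: CdsCandidate,
                          cds_B: CdsCandidate, *,
                          min_codons: int = 100) -> tuple[Optional[CodonAlignment], Optional[str]]:
    """Trim two kept CDSs to their common in-frame overlap.

    Returns (alignment, None) or (None, drop_reason) with reasons
    ``frame_mismatch``, ``length_mismatch``, ``no_overlap``, ``too_short``
    or ``internal_stop``.  Anchors on opposite strands indicate an
    upstream bug and raise.
    """
    if pair.anchor_A[3] != pair.anchor_B[3]:
        raise ValueError(f"{pair.gene_id}: anchors on opposite strands")
    gsA, geA, sA = _sense_geometry(cds_A, pair.q_interval_A, pair.anchor_A)
    gsB, geB, sB = _sense_geometry(cds_B, pair.q_interval_B, pair.anchor_B)
    if sA != sB:
        return None, "frame_mismatch"
    g0, g1 = max(gsA, gsB), min(geA, geB)
    if g1 - g0 + 1 < 3:
        return None, "no_overlap"
    if sA == "+":
        if (gsA - gsB) % 3 != 0:
            return None, "frame_mismatch"
        off_A, off_B = g0 - gsA, g0 - gsB
    else:
        if (geA - geB) % 3 != 0:
            return None, "frame_mismatch"
        off_A, off_B = geA - g1, geB - g1
    shift = (-off_A) % 3
    off_A += shift
    off_B += shift
    n_nt = ((g1 - g0 + 1 - shift) // 3) * 3
    if n_nt <= 0:
        return None, "no_overlap"
    sub_A = cds_A.nt_seq[off_A:off_A + n_nt]
    sub_B = cds_B.nt_seq[off_B:off_B + n_nt]
    if len(sub_A) != len(sub_B) or len(sub_A) != n_nt:
        return None, "length_mismatch"
    if n_nt < 3 * min_codons:
        return None, "too_short"
    try:
        aln = CodonAlignment(
            gene_id=pair.gene_id, seq_A=sub_A, seq_B=sub_B,
            scaffold=pair.scaffold, start=pair.start, end=pair.end,
            strand=pair.strand, has_introns=pair.has_introns,
        )
    except ValueError as exc:
        reason = "internal_stop" if "stop" in str(exc) else "length_mismatch"
        return None, reason
    return aln, None
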