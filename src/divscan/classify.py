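"""Positional ortholog/paralog classification from genome-anchored hits.

Transcripts are discriminated by where and how often they land on the
reference genome: on several scaffolds (scaffold paralog), at several
non-overlapping loci of one scaffold (tandem paralog), at the same locus
as other transcripts of the same collection (allelic forms), or at a
single locus — split into co-linear segments (``exon``, i.e. an
intron-containing gene) or a single block (``uniq``).  Only single-locus,
non-allelic transcripts are retained and paired across the two
collections by reciprocal anchor overlap.

Coordinates are 1-based inclusive at the file boundary (BLAST tabular
convention, minus strand encoded as sstart > send) and held internally as
normalized (start <= end, explicit strand) intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HitRecord",
    "ClassifiedTranscript",
    "AnchoredPair",
    "HitTableFormatError",
    "read_hit_table",
    "classify_transcripts",
    "pair_orthologs",
    "write_classification",
    "write_pairs",
]

_COLUMNS = ["query_id", "subject_id", "pct_identity", "aln_length", "mismatch",
            "gapopen", "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


class HitTableFormatError(ValueError):
    pass


@dataclass
class HitRecord:
    """One genome-anchored alignment segment (strand-normalized)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    qstart: int
    qend: int
    sstart: int          # always <= send after normalization
    send: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self):
        if min(self.qstart, self.qend, self.sstart, self.send) < 1:
            raise ValueError(f"{self.query_id}: coordinates must be >= 1")
        if self.qstart > self.qend:
            raise ValueError(f"{self.query_id}: qstart > qend")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")


@dataclass
class ClassifiedTranscript:
    transcript_id: str
    category: str        # scaffold_paralog | tandem_paralog | allelic | exon | uniq
    anchor: Optional[tuple] = None        # (scaffold, start, end, strand)
    n_segments: int = 1
    q_interval: Optional[tuple] = None    # (qstart, qend) on the transcript
    segments: list = field(default_factory=list)


@dataclass
class AnchoredPair:
    gene_id: str
    transcript_id_A: str
    transcript_id_B: str
    scaffold: str
    start: int
    end: int
    strand: str
    has_introns: bool
    anchor_A: tuple = None
    anchor_B: tuple = None
    q_interval_A: tuple = None
    q_interval_B: tuple = None


def read_hit_table(path, evalue_max: float = 1e-15) -> list[HitRecord]:
    """Parse a BLAST outfmt-6-style TSV (extra columns tolerated).

    Rows above the e-value cutoff are dropped; malformed rows are
    reported (with line numbers) and skipped; minus-strand rows
    (sstart > send) are stored normalized with a strand flag.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        missing = _COLUMNS[df.shape[1]]
        raise HitTableFormatError(
            f"{path}: expected >= 12 tab-separated columns, got {df.shape[1]} "
            f"(first missing column: '{missing}')")
    records: list[HitRecord] = []
    bad: list[int] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ss, se = int(row[8]), int(row[9])
            strand = "+" if ss <= se else "-"
            rec = HitRecord(
                query_id=str(row[0]), subject_id=str(row[1]),
                pct_identity=float(row[2]), aln_length=int(row[3]),
                qstart=int(row[6]), qend=int(row[7]),
                sstart=min(ss, se), send=max(ss, se),
                evalue=float(row[10]), bitscore=float(row[11]),
                strand=strand,
            )
        except (ValueError, TypeError) as exc:
            bad.append(lineno)
            logger.warning("%s line %d: malformed row skipped (%s)", path, lineno, exc)
            continue
        if rec.evalue <= evalue_max:
            records.append(rec)
    if bad:
        logger.warning("%s: %d malformed rows skipped (lines %s)", path, len(bad), bad[:20])
    return records


# ---------------------------------------------------------------------------

def _dedup_best(hits: list[HitRecord]) -> list[HitRecord]:
    """Keep the best-bitscore hit among near-duplicate segments.

    Input tables may carry several rows per (query, locus); segments whose
    scaffold AND transcript intervals both overlap are alternative
    alignments of the same piece, so only the strongest is retained.
    """
    kept: list[HitRecord] = []
    for h in sorted(hits, key=lambda x: -x.bitscore):
        dup = False
        for k in kept:
            if (k.subject_id == h.subject_id
                    and h.sstart <= k.send and k.sstart <= h.send
                    and h.qstart <= k.qend and k.qstart <= h.qend):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def _chain_loci(hits: list[HitRecord], q_contig_bp: int) -> list[list[HitRecord]]:
    """Group one transcript's segments into loci.

    Segments on the same scaffold+strand that are contiguous on the
    transcript (within +-q_contig_bp) and co-linear on the scaffold form
    one locus (an intron-split anchor); anything else starts a new locus.
    """
    loci: list[list[HitRecord]] = []
    groups: dict = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.strand), []).append(h)
    for (_, strand), seg in groups.items():
        seg.sort(key=lambda h: h.qstart)
        chain = [seg[0]]
        for h in seg[1:]:
            prev = chain[-1]
            contiguous = abs(h.qstart - prev.qend - 1) <= q_contig_bp
            colinear = (h.sstart > prev.send) if strand == "+" else (h.send < prev.sstart)
            if contiguous and colinear:
                chain.append(h)
            else:
                loci.append(chain)
                chain = [h]
        loci.append(chain)
    return loci


def _reciprocal_overlap(a: tuple, b: tuple) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


def classify_transcripts(hits: Iterable[HitRecord], overlap_frac: float = 0.9,
                         gap_tolerance_bp: int = 30,
                         q_contig_bp: int = 10) -> list[ClassifiedTranscript]:
    """Assign each transcript exactly one of the five positional categories.

    Order-invariant in the input rows.  ``overlap_frac`` is the reciprocal
    anchor overlap above which co-located transcripts are called allelic;
    scaffold gaps larger than ``gap_tolerance_bp`` between transcript-
    contiguous segments indicate introns (exon category).
    """
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    if not by_query:
        logger.warning("classify_transcripts: empty hit list")
        return []

    out: list[ClassifiedTranscript] = []
    for qid in sorted(by_query):
        seg = _dedup_best(by_query[qid])
        loci = _chain_loci(seg, q_contig_bp)
        scaffolds = {l[0].subject_id for l in loci}
        if len(scaffolds) > 1:
            out.append(ClassifiedTranscript(qid, "scaffold_paralog"))
            continue
        if len(loci) > 1:
            out.append(ClassifiedTranscript(qid, "tandem_paralog"))
            continue
        chain = sorted(loci[0], key=lambda h: h.sstart)
        # merge segments separated by small scaffold gaps
        n_seg = 1
        for prev, nxt in zip(chain, chain[1:]):
            if nxt.sstart - prev.send - 1 > gap_tolerance_bp:
                n_seg += 1
        anchor = (chain[0].subject_id, chain[0].sstart, chain[-1].send,
                  chain[0].strand)
        q_iv = (min(h.qstart for h in chain), max(h.qend for h in chain))
        cat = "exon" if n_seg >= 2 else "uniq"
        out.append(ClassifiedTranscript(qid, cat, anchor=anchor, n_segments=n_seg,
                                        q_interval=q_iv,
                                        segments=[(h.sstart, h.send) for h in chain]))

    # allelic detection among anchored transcripts (union-find by overlap)
    anchored = [c for c in out if c.anchor is not None]
    parent = {c.transcript_id: c.transcript_id for c in anchored}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_scaffold: dict = {}
    for c in anchored:
        by_scaffold.setdefault((c.anchor[0], c.anchor[3]), []).append(c)
    for group in by_scaffold.values():
        group.sort(key=lambda c: c.anchor[1])
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if b.anchor[1] > a.anchor[2]:
                    break
                ov = _reciprocal_overlap(a.anchor[1:3], b.anchor[1:3])
                if ov >= overlap_frac:
                    parent[find(a.transcript_id)] = find(b.transcript_id)
    clusters: dict = {}
    for c in anchored:
        clusters.setdefault(find(c.transcript_id), []).append(c)
    for members in clusters.values():
        if len(members) > 1:
            for c in members:
                c.category = "allelic"
    return out


def pair_orthologs(classified_A: Iterable[ClassifiedTranscript],
                   classified_B: Iterable[ClassifiedTranscript],
                   overlap_frac: float = 0.9) -> list[AnchoredPair]:
    """Pair single-locus orthologs across the two collections.

    Only ``uniq``/``exon`` transcripts participate; anchors must share
    scaffold and strand and overlap reciprocally by >= overlap_frac.
    A locus with more than one candidate partner on either side is
    ambiguous and dropped (logged).
    """
    keep = lambda cs: [c for c in cs if c.category in ("uniq", "exon")]
    A, B = keep(classified_A), keep(classified_B)
    by_key: dict = {}
    for side, cs in (("A", A), ("B", B)):
        for c in cs:
            by_key.setdefault((c.anchor[0], c.anchor[3]), {"A": [], "B": []})[side].append(c)

    pairs: list[AnchoredPair] = []
    for (scaffold, strand), sides in sorted(by_key.items()):
        nodes = {("A", c.transcript_id): c for c in sides["A"]}
        nodes.update({("B", c.transcript_id): c for c in sides["B"]})
        parent = {k: k for k in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        linked = set()
        for a in sides["A"]:
            for b in sides["B"]:
                if _reciprocal_overlap(a.anchor[1:3], b.anchor[1:3]) >= overlap_frac:
                    ka, kb = ("A", a.transcript_id), ("B", b.transcript_id)
                    parent[find(ka)] = find(kb)
                    linked |= {ka, kb}
        comps: dict = {}
        for k in linked:
            comps.setdefault(find(k), []).append(k)
        for keys in sorted(comps.values()):
            c = {"A": [nodes[k] for k in keys if k[0] == "A"],
                 "B": [nodes[k] for k in keys if k[0] == "B"]}
            if len(c["A"]) == 1 and len(c["B"]) == 1:
                a, b = c["A"][0], c["B"][0]
                start = max(a.anchor[1], b.anchor[1])
                end = min(a.anchor[2], b.anchor[2])
                pairs.append(AnchoredPair(
                    gene_id=f"{scaffold}:{start}-{end}",
                    transcript_id_A=a.transcript_id,
                    transcript_id_B=b.transcript_id,
                    scaffold=scaffold, start=start, end=end, strand=strand,
                    has_introns=(a.category == "exon" or b.category == "exon"),
                    anchor_A=a.anchor, anchor_B=b.anchor,
                    q_interval_A=a.q_interval, q_interval_B=b.q_interval,
                ))
            else:
                logger.info("ambiguous locus %s:%s dropped (A=%s, B=%s)", scaffold,
                            strand, [x.transcript_id for x in c["A"]],
                            [x.transcript_id for x in c["B"]])
    pairs.sort(key=lambda p: (p.scaffold, p.start))
    return pairs


def write_classification(classified: list[ClassifiedTranscript], path) -> Path:
    rows = []
    for c in classified:
        sc, st, en, strand = c.anchor if c.anchor else ("", "", "", "")
        rows.append((c.transcript_id, c.category, sc, st, en, strand, c.n_segments))
    df = pd.DataFrame(rows, columns=["transcript_id", "category", "scaffold",
                                     "start", "end", "strand", "n_segments"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_pairs(pairs: list[AnchoredPair], path) -> Path:
    df = pd.DataFrame([(p.gene_id, p.transcript_id_A, p.transcript_id_B, p.scaffold,
                        p.start, p.end, p.strand, p.has_introns) for p in pairs],
                      columns=["gene_id", "transcript_id_A", "transcript_id_B",
                               "scaffold", "start", "end", "strand", "has_introns"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
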