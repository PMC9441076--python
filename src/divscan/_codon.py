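"""Universal-genetic-code tables shared by the simulator and the rate engines.

Everything here is precomputed once, at first use, from the standard DNA
codon table: codon indexing, translation, single-nucleotide neighbor
structure, equal-weight pathway difference counts for every ordered codon
pair, degeneracy classes, and the incidence matrices used by the
mutation-rate-weighted (YN00-style) site counting.

Codon pairs are addressed as ``u * 64 + v`` so that a codon alignment
reduces to a length-4096 count vector; every per-alignment statistic in
:mod:`divscan.rates` is then a dot product with one of these tables, which
is also what makes the codon bootstrap cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_IDX = {n: i for i, n in enumerate(NUCS)}
CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
CODON_IDX = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]  # the universal code
STOP_CODONS = frozenset(_table.stop_codons)
AA = [
    "*" if c in STOP_CODONS else _table.forward_table[c] for c in CODONS
]
IS_STOP = np.array([c in STOP_CODONS for c in CODONS])
SENSE = np.flatnonzero(~IS_STOP)  # 61 sense codons

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T; everything else (a != b) is a transversion."""
    return a != b and (a in _PURINES) == (b in _PURINES)


def translate(codon: str) -> str:
    return AA[CODON_IDX[codon]]


@dataclass(frozen=True)
class CodonTables:
    """Bundle of precomputed arrays; see module docstring."""

    # per codon (64,)
    ng86_s_sites: np.ndarray      # NG86 synonymous sites (stops -> nan);
                                  # mutations to stop codons are excluded and
                                  # the codon renormalized to 3 sites (the
                                  # PAML convention, so S + N = 3L)
    ng86_s_sites_raw: np.ndarray  # same but without renormalization: a stop
                                  # neighbor counts toward N (the biopython
                                  # convention); used only for cross-checks
    deg: np.ndarray               # (64, 3) #synonymous changes per position

    # per ordered pair (4096,) pathway-averaged difference counts
    sd: np.ndarray
    nd: np.ndarray
    sd_ts: np.ndarray
    sd_tv: np.ndarray
    nd_ts: np.ndarray
    nd_tv: np.ndarray
    ts_nt: np.ndarray             # plain per-position transition mismatches
    tv_nt: np.ndarray
    hamming: np.ndarray

    # kappa-estimation site classes, half-weighted over the two codons
    n4: np.ndarray
    ts4: np.ndarray
    tv4: np.ndarray
    n0: np.ndarray
    ts0: np.ndarray
    tv0: np.ndarray

    # (4096, 64): codon occurrence of both pair members
    pair2codon: np.ndarray
    # (4096, 3, 4): nucleotide occurrence by codon position (both members)
    pos_nt: np.ndarray

    # (64, 64) incidence of single-nucleotide neighbor classes
    syn_ts: np.ndarray
    syn_tv: np.ndarray
    non_ts: np.ndarray
    non_tv: np.ndarray

    # simulator neighbor lists
    neighbors: list = field(repr=False)  # per codon: (target, is_ts, is_nonsyn)


def _neighbors(u: int):
    """Sense single-nucleotide neighbors of codon u with change classes."""
    cu = CODONS[u]
    out = []
    for pos in range(3):
        for nt in NUCS:
            if nt == cu[pos]:
                continue
            cv = cu[:pos] + nt + cu[pos + 1:]
            v = CODON_IDX[cv]
            if IS_STOP[v]:
                continue
            out.append((v, is_transition(cu[pos], nt), AA[u] != AA[v]))
    return out


def _pathway_counts(u: int, v: int):
    """Average syn/nonsyn (split ts/tv) step counts over minimal pathways.

    Pathways passing through a stop codon are excluded; if every ordering
    is blocked, all orderings are used (standard NG86 fallback).
    """
    cu, cv = CODONS[u], CODONS[v]
    diff = [i for i in range(3) if cu[i] != cv[i]]
    if not diff:
        return 0.0, 0.0, 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = cu
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cv[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != cv:
                blocked = True
            syn = translate(cur) == translate(nxt)
            steps.append((syn, is_transition(cur[pos], cv[pos])))
            cur = nxt
        paths.append((blocked, steps))
    usable = [s for b, s in paths if not b] or [s for _, s in paths]
    acc = np.zeros(4)  # sd_ts, sd_tv, nd_ts, nd_tv
    for steps in usable:
        for syn, ts in steps:
            k = (0 if syn else 2) + (0 if ts else 1)
            acc[k] += 1.0
    acc /= len(usable)
    return tuple(acc)


@lru_cache(maxsize=1)
def tables() -> CodonTables:
    n = 64
    deg = np.zeros((n, 3))
    ng86_s = np.full(n, np.nan)
    ng86_s_raw = np.full(n, np.nan)
    syn_ts = np.zeros((n, n))
    syn_tv = np.zeros((n, n))
    non_ts = np.zeros((n, n))
    non_tv = np.zeros((n, n))
    neighbors: list = [None] * n

    for u in range(n):
        if IS_STOP[u]:
            neighbors[u] = []
            continue
        cu = CODONS[u]
        n_syn = 0
        n_non = 0
        for pos in range(3):
            for nt in NUCS:
                if nt == cu[pos]:
                    continue
                cv = cu[:pos] + nt + cu[pos + 1:]
                v = CODON_IDX[cv]
                if IS_STOP[v]:
                    continue  # mutations to stops are not opportunities
                if AA[u] == AA[v]:
                    deg[u, pos] += 1
                    n_syn += 1
                    (syn_ts if is_transition(cu[pos], nt) else syn_tv)[u, v] = 1
                else:
                    n_non += 1
                    (non_ts if is_transition(cu[pos], nt) else non_tv)[u, v] = 1
        ng86_s[u] = 3.0 * n_syn / (n_syn + n_non)
        ng86_s_raw[u] = n_syn / 3.0
        neighbors[u] = _neighbors(u)

    m = n * n
    sd_ts = np.zeros(m)
    sd_tv = np.zeros(m)
    nd_ts = np.zeros(m)
    nd_tv = np.zeros(m)
    ts_nt = np.zeros(m)
    tv_nt = np.zeros(m)
    hamming = np.zeros(m, dtype=np.int64)
    n4 = np.zeros(m)
    ts4 = np.zeros(m)
    tv4 = np.zeros(m)
    n0 = np.zeros(m)
    ts0 = np.zeros(m)
    tv0 = np.zeros(m)
    pair2codon = np.zeros((m, n))
    pos_nt = np.zeros((m, 3, 4))

    four = deg == 3
    zero = deg == 0

    for u in range(n):
        cu = CODONS[u]
        for v in range(n):
            p = u * n + v
            cv = CODONS[v]
            pair2codon[p, u] += 1
            pair2codon[p, v] += 1
            for pos in range(3):
                pos_nt[p, pos, NUC_IDX[cu[pos]]] += 1
                pos_nt[p, pos, NUC_IDX[cv[pos]]] += 1
                differs = cu[pos] != cv[pos]
                if differs:
                    hamming[p] += 1
                    ts = is_transition(cu[pos], cv[pos])
                    (ts_nt if ts else tv_nt)[p] += 1
                if IS_STOP[u] or IS_STOP[v]:
                    continue
                w4 = (four[u, pos] + four[v, pos]) / 2.0
                w0 = (zero[u, pos] + zero[v, pos]) / 2.0
                n4[p] += w4
                n0[p] += w0
                if differs:
                    ts = is_transition(cu[pos], cv[pos])
                    (ts4 if ts else tv4)[p] += w4
                    (ts0 if ts else tv0)[p] += w0
            if IS_STOP[u] or IS_STOP[v]:
                continue
            a, b, c, d = _pathway_counts(u, v)
            sd_ts[p], sd_tv[p], nd_ts[p], nd_tv[p] = a, b, c, d

    return CodonTables(
        ng86_s_sites=ng86_s,
        ng86_s_sites_raw=ng86_s_raw,
        deg=deg,
        sd=sd_ts + sd_tv,
        nd=nd_ts + nd_tv,
        sd_ts=sd_ts,
        sd_tv=sd_tv,
        nd_ts=nd_ts,
        nd_tv=nd_tv,
        ts_nt=ts_nt,
        tv_nt=tv_nt,
        hamming=hamming,
        n4=n4,
        ts4=ts4,
        tv4=tv4,
        n0=n0,
        ts0=ts0,
        tv0=tv0,
        pair2codon=pair2codon,
        pos_nt=pos_nt,
        syn_ts=syn_ts,
        syn_tv=syn_tv,
        non_ts=non_ts,
        non_tv=non_tv,
        neighbors=neighbors,
    )


def encode_codons(seq: str) -> np.ndarray:
    """Codon indices of an in-frame, gap/N-free nucleotide string."""
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    s = seq.upper()
    try:
        nt = np.array([NUC_IDX[c] for c in s], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-ACGT character in codon sequence: {e}") from None
    nt = nt.reshape(-1, 3)
    return nt[:, 0] * 16 + nt[:, 1] * 4 + nt[:, 2]


def pair_indices(seq_a: str, seq_b: str) -> np.ndarray:
    """Length-L vector of codon-pair indices u*64+v."""
    a = encode_codons(seq_a)
    b = encode_codons(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    return a * 64 + b


def pair_counts(seq_a: str, seq_b: str) -> np.ndarray:
    """Length-4096 codon-pair count vector of an alignment."""
    return np.bincount(pair_indices(seq_a, seq_b), minlength=4096).astype(float)
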