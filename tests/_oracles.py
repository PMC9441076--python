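"""Independent brute-force oracles used by the test suite.

Deliberately naive and written directly from the definitions (standard
genetic code, enumeration of frames / pathways / step-up rule) so they
share no code with the package internals they check.
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

_tab = CodonTable.unambiguous_dna_by_id[1]
STOPS = set(_tab.stop_codons)


def aa(codon: str) -> str:
    return "*" if codon in STOPS else _tab.forward_table[codon]


def is_ts(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def ng86_sites(codon: str) -> float:
    """NG86 synonymous sites of one codon.

    Mutations creating stop codons are not substitution opportunities and
    the codon is renormalized to 3 sites (S + N = 3 per codon), the
    convention of the PAML programs.
    """
    syn = non = 0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOPS:
                continue
            if aa(alt) == aa(codon):
                syn += 1
            else:
                non += 1
    return 3.0 * syn / (syn + non)


def ng86_sites_raw(codon: str) -> float:
    """Synonymous sites without renormalization (a stop neighbor counts
    toward N) — the biopython convention, used only for cross-checks."""
    syn = 0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOPS:
                continue
            if aa(alt) == aa(codon):
                syn += 1
    return syn / 3.0


def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Equal-weight pathway-averaged (Sd, Nd) between two codons.

    Pathways through stop codons are dropped; if all are blocked, all
    orderings are used.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS and nxt != c2:
                blocked = True
            if aa(cur) == aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((blocked, sd, nd))
    usable = [(s, n) for b, s, n in results if not b] or [(s, n) for _, s, n in results]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def ng86_counts(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) for an in-frame pair, straight from the definitions."""
    S = Sd = Nd = 0.0
    L = len(seq_a) // 3
    for i in range(L):
        ca = seq_a[3 * i:3 * i + 3]
        cb = seq_b[3 * i:3 * i + 3]
        S += (ng86_sites(ca) + ng86_sites(cb)) / 2
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    return S, 3 * L - S, Sd, Nd


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, literal step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, min(1.0, pvals[i] * m / rank))
        q[i] = val
        prev = val
    return q


def longest_orf_all_frames(seq: str):
    """(length_codons, frame_label, nt) of the longest stop-bounded run.

    Ties: frame order +1,+2,+3,-1,-2,-3 then leftmost.  Returns the best
    run even if length 0.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}
    rc = "".join(comp[c] for c in reversed(seq))
    best = (0, None, "")
    for label, s in [(1, seq), (2, seq), (3, seq), (-1, rc), (-2, rc), (-3, rc)]:
        off = abs(label) - 1
        codons = [s[i:i + 3] for i in range(off, len(s) - 2, 3)]
        run = []
        runs = []
        for c in codons:
            if len(c) < 3:
                break
            if c in STOPS:
                runs.append(run)
                run = []
            else:
                run.append(c)
        runs.append(run)
        for r in runs:
            if len(r) > best[0]:
                best = (len(r), label, "".join(r))
    return best
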