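"""Synthetic two-lineage transcriptome bundles with known truth.

Generates everything the downstream pipeline consumes — a scaffold layout,
two transcript collections diverged under a codon substitution process
with per-gene (t, omega), BLAST-tabular hit tables anchoring the
transcripts on the scaffolds, and a protein-annotation table — together
with a per-gene truth table, so every stage can be tested without any
external data.

Two named regimes mirror the two ends of a speciation continuum:

* ``early`` — allopatric populations: a majority of genes strictly
  identical (default 58%), the rest carrying a thin exponential tail of
  low divergence, scattered at random over scaffolds.
* ``late`` — long-separated sister species: near-universal high
  divergence (a truncated Gaussian around 1.8 substitutions/codon, so
  ~96% of genes exceed t = 0.75), which makes every scaffold an island
  of divergent genes.

A small fraction of genes receive one of four complications (scaffold
paralog, tandem paralog, allelic extra transcript, intron-split anchor);
complications are mutually exclusive per gene so truth labels stay
unambiguous.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codon import CODONS, SENSE, tables

__all__ = [
    "SimConfig",
    "early_config",
    "late_config",
    "make_truth_set",
    "evolve_codon_pair",
    "emit_inputs",
]

CATEGORIES = ("uniq", "exon", "scaffold_paralog", "tandem_paralog", "allelic")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Declarative description of one synthetic study.

    Distribution specs are small dicts, e.g.
    ``{"kind": "shifted_exponential", "shift": 0.015, "mean": 0.025}`` or
    ``{"kind": "truncated_normal", "mean": 1.8, "sd": 0.5, "min": 0.05}``
    for per-gene divergence, and ``{"kind": "mixture_uniform", "components":
    [[w, lo, hi], ...]}`` for per-gene omega.
    """

    n_scaffolds: int = 24
    scaffold_length_bp: tuple = (400_000, 600_000)
    genes_per_scaffold: int = 8
    gene_length_codons: int = 300
    regime: str = "custom"
    frac_zero_divergence: float = 0.0
    t_distribution: dict = field(default_factory=lambda: {"kind": "constant", "value": 0.1})
    omega_distribution: dict = field(default_factory=lambda: {"kind": "constant", "value": 0.2})
    kappa: float = 2.0
    island_spec: list = field(default_factory=list)
    complication_rates: dict = field(default_factory=lambda: {
        "scaffold_paralog": 0.0, "tandem_paralog": 0.0,
        "allelic": 0.0, "intron_split": 0.0,
    })
    annotated_fraction: float = 0.9
    utr_len: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.gene_length_codons < 2:
            raise ConfigurationError("gene_length_codons must be >= 2")
        if not 0 <= self.frac_zero_divergence <= 1:
            raise ConfigurationError("frac_zero_divergence must lie in [0, 1]")
        if not 0 <= self.annotated_fraction <= 1:
            raise ConfigurationError("annotated_fraction must lie in [0, 1]")
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        rates = self.complication_rates
        if any(not 0 <= v <= 1 for v in rates.values()) or sum(rates.values()) > 1:
            raise ConfigurationError("complication rates must be proportions summing to <= 1")
        for sc, g0, run, _level in self.island_spec:
            if sc >= self.n_scaffolds or g0 + run > self.genes_per_scaffold:
                raise ConfigurationError(
                    f"island_spec entry (scaffold {sc}, start {g0}, run {run}) "
                    f"exceeds the layout")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scaffold_length_bp"] = list(np.atleast_1d(self.scaffold_length_bp).tolist())
        d["island_spec"] = [list(i) for i in self.island_spec]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def early_config(**overrides) -> SimConfig:
    """Early-speciation regime matching the within-species marginals:
    58% strictly identical genes, low exponential-tailed divergence
    elsewhere (overall mean t ~ 0.017, mode of divergent genes ~ 0.025
    substitutions/codon), purifying-dominated omega."""
    cfg = dict(
        regime="early",
        frac_zero_divergence=0.58,
        t_distribution={"kind": "shifted_exponential", "shift": 0.015, "mean": 0.025},
        omega_distribution={"kind": "mixture_uniform", "components": [
            [0.44, 0.0, 0.25], [0.36, 0.25, 0.5], [0.14, 0.5, 1.0], [0.06, 1.0, 1.5]]},
        complication_rates={"scaffold_paralog": 0.03, "tandem_paralog": 0.03,
                            "allelic": 0.03, "intron_split": 0.03},
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def late_config(**overrides) -> SimConfig:
    """Late-speciation regime: nearly all genes highly divergent (~96%
    beyond t = 0.75 substitutions/codon), a handful identical, omega
    dominated by purifying selection with ~2% of genes above 1."""
    cfg = dict(
        regime="late",
        frac_zero_divergence=0.004,
        t_distribution={"kind": "truncated_normal", "mean": 1.8, "sd": 0.5, "min": 0.05},
        omega_distribution={"kind": "mixture_uniform", "components": [
            [0.30, 0.0, 0.0], [0.50, 0.02, 0.25], [0.18, 0.25, 1.0], [0.02, 1.0, 2.0]]},
        complication_rates={"scaffold_paralog": 0.03, "tandem_paralog": 0.03,
                            "allelic": 0.03, "intron_split": 0.03},
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def _draw(spec: dict, rng: np.random.Generator) -> float:
    kind = spec["kind"]
    if kind == "constant":
        return float(spec["value"])
    if kind == "shifted_exponential":
        return float(spec["shift"] + rng.exponential(spec["mean"]))
    if kind == "truncated_normal":
        lo = spec.get("min", 0.0)
        while True:
            x = rng.normal(spec["mean"], spec["sd"])
            if x >= lo:
                return float(x)
    if kind == "mixture_uniform":
        comps = spec["components"]
        w = np.array([c[0] for c in comps], dtype=float)
        i = rng.choice(len(comps), p=w / w.sum())
        lo, hi = comps[i][1], comps[i][2]
        return float(lo if hi <= lo else rng.uniform(lo, hi))
    raise ConfigurationError(f"unknown distribution kind: {kind!r}")


def _span_range(val) -> tuple[int, int]:
    a = np.atleast_1d(val)
    return (int(a[0]), int(a[0])) if a.size == 1 else (int(a[0]), int(a[1]))


# ---------------------------------------------------------------------------
# truth layout

def make_truth_set(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the gene layout and per-gene truth.

    Returns (truth table, scaffold length table).  Deterministic for a
    fixed config+seed; island_spec entries override the drawn divergence
    of the designated gene runs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lo, hi = _span_range(config.scaffold_length_bp)
    cds_nt = 3 * config.gene_length_codons
    cat_names = ["uniq", "scaffold_paralog", "tandem_paralog", "allelic", "exon"]
    p_comp = config.complication_rates
    probs = np.array([
        1.0 - sum(p_comp.values()),
        p_comp.get("scaffold_paralog", 0.0),
        p_comp.get("tandem_paralog", 0.0),
        p_comp.get("allelic", 0.0),
        p_comp.get("intron_split", 0.0),
    ])
    islands = {(sc, g0 + j): level
               for sc, g0, run, level in config.island_spec for j in range(run)}

    rows = []
    scaff = []
    for s in range(config.n_scaffolds):
        sid = f"scf{s:04d}"
        length = int(rng.integers(lo, hi + 1))
        scaff.append((sid, length))
        g = config.genes_per_scaffold
        slot = length // g
        if slot < cds_nt + 12_000:
            raise ConfigurationError("scaffolds too short for the gene layout")
        for i in range(g):
            cat = cat_names[rng.choice(5, p=probs)]
            n_seg = int(rng.integers(2, 4)) if cat == "exon" else 1
            introns = [int(rng.integers(200, 2001)) for _ in range(n_seg - 1)]
            span = cds_nt + sum(introns)
            start = i * slot + int(rng.integers(5_000, slot - span - 5_000))
            strand = "+" if rng.random() < 0.5 else "-"
            if (s, i) in islands:
                t = float(islands[(s, i)])
            elif rng.random() < config.frac_zero_divergence:
                t = 0.0
            else:
                t = _draw(config.t_distribution, rng)
            omega = 0.0 if t == 0 else _draw(config.omega_distribution, rng)
            rows.append(dict(
                gene_id=f"{sid}g{i:03d}", scaffold_id=sid,
                start_bp=start + 1, end_bp=start + span,  # 1-based inclusive
                strand=strand, true_t=t, true_omega=omega,
                category_label=cat, n_segments=n_seg,
                intron_lengths=",".join(map(str, introns)),
            ))
    truth = pd.DataFrame(rows).sort_values(["scaffold_id", "start_bp"]).reset_index(drop=True)
    lengths = pd.DataFrame(scaff, columns=["scaffold_id", "length_bp"])
    return truth, lengths


# ---------------------------------------------------------------------------
# codon-pair evolution

def _process_arrays(omega: float, kappa: float):
    """Per-codon total rates and neighbor samplers for one (omega, kappa)."""
    T = tables()
    rates = np.zeros(64)
    targets, cumw = [], []
    for u in range(64):
        nbrs = T.neighbors[u]
        if not nbrs:
            targets.append(np.empty(0, dtype=np.int64))
            cumw.append(np.empty(0))
            continue
        w = np.array([(kappa if ts else 1.0) * (omega if nonsyn else 1.0)
                      for _, ts, nonsyn in nbrs])
        targets.append(np.array([v for v, _, _ in nbrs], dtype=np.int64))
        cumw.append(np.cumsum(w))
        rates[u] = w.sum()
    rbar = rates[SENSE].mean()
    return rates, targets, cumw, rbar


def _evolve_branch(codons: np.ndarray, tau: float, rates, targets, cumw,
                   rng: np.random.Generator) -> np.ndarray:
    out = codons.copy()
    for i, u in enumerate(codons):
        cur = int(u)
        time = 0.0
        while True:
            r = rates[cur]
            if r <= 0:
                break
            time += rng.exponential(1.0 / r)
            if time >= tau:
                break
            j = int(np.searchsorted(cumw[cur], rng.random() * r, side="right"))
            cur = int(targets[cur][j])
        out[i] = cur
    return out


def evolve_codon_pair(ancestor_cds: str, t: float, omega: float, kappa: float,
                      seed=None) -> tuple[str, str]:
    """Evolve two descendants t/2 expected substitutions/codon apart each.

    Continuous-time single-nucleotide-step codon process: transitions
    weighted by kappa, nonsynonymous changes by omega, changes creating
    stop codons forbidden.  The clock is rescaled so that the expected
    number of substitutions per codon, averaged over a uniform
    sense-codon composition, equals the branch length.
    """
    if len(ancestor_cds) % 3:
        raise ValueError("ancestor length is not a multiple of 3")
    if t < 0 or omega < 0 or kappa < 0:
        raise ValueError("t, omega and kappa must be non-negative")
    from ._codon import encode_codons, IS_STOP
    anc = encode_codons(ancestor_cds)
    if IS_STOP[anc].any():
        raise ValueError("ancestor contains an internal stop codon")
    if t == 0:
        return ancestor_cds, ancestor_cds
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates, targets, cumw, rbar = _process_arrays(omega, kappa)
    tau = (t / 2.0) / rbar
    a = _evolve_branch(anc, tau, rates, targets, cumw, rng)
    b = _evolve_branch(anc, tau, rates, targets, cumw, rng)
    join = lambda ix: "".join(CODONS[int(u)] for u in ix)
    return join(a), join(b)


def random_ancestor(n_codons: int, rng: np.random.Generator) -> str:
    """Uniform sense-codon ancestor sequence."""
    return "".join(CODONS[int(u)] for u in rng.choice(SENSE, n_codons))


# ---------------------------------------------------------------------------
# file bundle

_STOPS = ("TAA", "TAG", "TGA")


def _utr(rng: np.random.Generator, n: int, terminal_stop: bool) -> str:
    s = "".join(rng.choice(list("ACGT"), max(n - 3, 0)))
    stop = _STOPS[int(rng.integers(3))]
    return s + stop if terminal_stop else stop + s


def _hit_row(qid, sid, qs, qe, ss, se, strand, pident=99.0):
    if strand == "-":
        ss, se = se, ss
    length = qe - qs + 1
    return [qid, sid, round(pident, 2), length, 0, 0, qs, qe, ss, se,
            1e-180, round(2.0 * length, 1)]


def _segment_rows(qid, sid, q0, cds_nt, start_bp, strand, seg_lens, introns):
    """Hit rows for a (possibly intron-split) anchor; q0 = 1-based qstart."""
    rows = []
    g_cursor = start_bp
    blocks = []
    for k, sl in enumerate(seg_lens):
        blocks.append((g_cursor, g_cursor + sl - 1))
        g_cursor += sl + (introns[k] if k < len(introns) else 0)
    if strand == "-":
        blocks = blocks[::-1]
    q_cursor = q0
    for k, sl in enumerate(seg_lens):
        b0, b1 = blocks[k]
        rows.append(_hit_row(qid, sid, q_cursor, q_cursor + sl - 1, b0, b1, strand))
        q_cursor += sl
    return rows


def emit_inputs(truth: pd.DataFrame, config: SimConfig, outdir,
                scaffold_lengths: pd.DataFrame | None = None) -> dict:
    """Write the full input bundle for a truth table; returns file paths.

    Transcripts are UTR + CDS + stop + UTR; hit rows realize the five
    positional categories; the annotation table marks a configurable
    fraction of genes with a strong best hit.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if scaffold_lengths is None:
        _, scaffold_lengths = make_truth_set(config)
    ss = np.random.SeedSequence([config.seed, 1])
    gene_rngs = [np.random.default_rng(c) for c in ss.spawn(len(truth))]
    cds_nt = 3 * config.gene_length_codons

    fa, fb, hits_a, hits_b, annot = [], [], [], [], []
    scaffold_ids = sorted(truth["scaffold_id"].unique())

    for gi, row in enumerate(truth.itertuples(index=False)):
        rng = gene_rngs[gi]
        anc = random_ancestor(config.gene_length_codons, rng)
        seq_a, seq_b = evolve_codon_pair(anc, row.true_t, row.true_omega,
                                         config.kappa, rng)
        tid_a, tid_b = f"{row.gene_id}_A", f"{row.gene_id}_B"
        recs = [(tid_a, seq_a, fa, hits_a), (tid_b, seq_b, fb, hits_b)]
        if row.category_label == "allelic":
            allele, _ = evolve_codon_pair(seq_a, 0.01, 0.5, config.kappa, rng)
            recs.append((f"{row.gene_id}_A2", allele, fa, hits_a))

        introns = [int(x) for x in row.intron_lengths.split(",") if x]
        n_seg = int(row.n_segments)
        seg_lens = [cds_nt // n_seg] * n_seg
        seg_lens[-1] += cds_nt - sum(seg_lens)

        for tid, cds, fasta, hits in recs:
            utr5 = _utr(rng, config.utr_len, terminal_stop=True)
            utr3 = _utr(rng, config.utr_len, terminal_stop=False)
            stop = _STOPS[int(rng.integers(3))]
            fasta.append((tid, utr5 + cds + stop + utr3))
            q0 = len(utr5) + 1
            hits.extend(_segment_rows(tid, row.scaffold_id, q0, cds_nt,
                                      row.start_bp, row.strand, seg_lens, introns))
            if row.category_label == "scaffold_paralog" and tid.endswith("_A"):
                other = scaffold_ids[(scaffold_ids.index(row.scaffold_id) + 1)
                                     % len(scaffold_ids)]
                p0 = int(rng.integers(200, 2000))
                hits.append(_hit_row(tid, other, q0, q0 + cds_nt - 1,
                                     p0, p0 + cds_nt - 1, "+", pident=95.0))
            if row.category_label == "tandem_paralog" and tid.endswith("_A"):
                p0 = row.end_bp + 4_000
                hits.append(_hit_row(tid, row.scaffold_id, q0, q0 + cds_nt - 1,
                                     p0, p0 + cds_nt - 1, row.strand, pident=95.0))
            if rng.random() < config.annotated_fraction:
                annot.append((tid, f"UP{gi:05d}", 1e-30, 250.0))
            else:
                # weak hit above the cutoff, exercises the e-value filter
                annot.append((tid, f"UPW{gi:05d}", 1e-3, 28.0))

    paths = {
        "transcripts_A": out / "transcripts_A.fasta",
        "transcripts_B": out / "transcripts_B.fasta",
        "hits_A": out / "hits_A.tsv",
        "hits_B": out / "hits_B.tsv",
        "annotations": out / "annotations.tsv",
        "scaffolds": out / "scaffolds.tsv",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.json",
    }
    for key, recs in (("transcripts_A", fa), ("transcripts_B", fb)):
        with open(paths[key], "w") as fh:
            for tid, seq in recs:
                fh.write(f">{tid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
    for key, rows in (("hits_A", hits_a), ("hits_B", hits_b)):
        pd.DataFrame(rows).to_csv(paths[key], sep="\t", header=False, index=False)
    pd.DataFrame(annot, columns=["query_id", "subject_id", "evalue", "bitscore"]) \
        .to_csv(paths["annotations"], sep="\t", index=False)
    scaffold_lengths.to_csv(paths["scaffolds"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump({"seed": config.seed, "config_hash": config.config_hash(),
                   "config": config.to_dict(), "n_genes": int(len(truth))},
                  fh, indent=2, sort_keys=True)
    return paths


def write_scaffold_table(lengths: pd.DataFrame, outdir) -> Path:
    p = Path(outdir) / "scaffolds.tsv"
    lengths.to_csv(p, sep="\t", index=False)
    return p
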