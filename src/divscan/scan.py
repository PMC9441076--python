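"""Divergence-landscape statistics along scaffolds.

Genes are ordered by anchor midpoint along scaffolds long enough to be
informative, each scaffold's divergence pattern is classified (no
divergent gene / isolated divergent genes / island of divergence), the
clustering of divergent genes is quantified by Fisher's dispersion index
on consecutive inter-gene distances, and the coupling of divergence t
with dN/dS is summarized per scaffold (Pearson r) and genome-wide (OLS
regression of dN on dS).

A gene whose synonymous distance saturates has divergence beyond any
threshold used here, so saturated genes count as divergent for pattern
classification and land in the open top bin of the divergence summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaffoldScan",
    "order_genes_on_scaffolds",
    "classify_pattern",
    "dispersion_index",
    "correlate_t_omega",
    "dn_ds_regression",
    "divergence_summary",
    "fixed_substitution_load",
]


@dataclass
class ScaffoldScan:
    scaffold_id: str
    length_bp: int
    genes: list = field(default_factory=list)  # (gene_id, midpoint, t, omega)
    n_divergent: int = 0
    pattern: Optional[str] = None              # A_none | B_isolated | C_island
    dispersion_index: Optional[float] = None
    pearson_r: Optional[float] = None
    r_skipped_reason: Optional[str] = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _is_divergent(t: float, t_div: float) -> bool:
    # saturated estimates (nan) are divergent beyond any finite threshold
    return (not math.isfinite(t)) or t > t_div


def order_genes_on_scaffolds(genes: pd.DataFrame, scaffold_lengths: pd.DataFrame,
                             min_scaffold_bp: int = 300_000) -> list[ScaffoldScan]:
    """Per-scaffold ordered gene landscapes.

    ``genes`` needs columns gene_id, scaffold, start, end, t, omega.
    Scaffolds shorter than ``min_scaffold_bp`` are excluded; genes
    anchored to a scaffold absent from the length table raise.
    """
    lengths = dict(zip(scaffold_lengths.iloc[:, 0], scaffold_lengths.iloc[:, 1]))
    unknown = sorted(set(genes["scaffold"]) - set(lengths))
    if unknown:
        raise ValueError(f"genes anchored to unknown scaffolds: {unknown[:10]}")
    scans = []
    for sid, sub in genes.groupby("scaffold"):
        length = int(lengths[sid])
        if length < min_scaffold_bp:
            continue
        mid = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
        order = np.argsort(mid, kind="stable")
        gl = [(sub["gene_id"].iloc[i], float(mid[i]), float(sub["t"].iloc[i]),
               float(sub["omega"].iloc[i])) for i in order]
        scans.append(ScaffoldScan(scaffold_id=sid, length_bp=length, genes=gl))
    scans.sort(key=lambda s: s.scaffold_id)
    return scans


def classify_pattern(scan: ScaffoldScan, t_div: float = 0.1,
                     max_isolated: int = 2, min_run: int = 3) -> str:
    """A_none / B_isolated / C_island divergence pattern of one scaffold.

    C_island when a run of >= min_run consecutive divergent genes exists
    or more than ``max_isolated`` divergent genes are present; this is the
    automated surrogate for the by-eye clustering criterion.
    """
    flags = [_is_divergent(t, t_div) for _, _, t, _ in scan.genes]
    n_div = sum(flags)
    scan.n_divergent = n_div
    if n_div == 0:
        scan.pattern = "A_none"
        return scan.pattern
    run, best = 0, 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    if best >= min_run or n_div > max_isolated:
        scan.pattern = "C_island"
    else:
        scan.pattern = "B_isolated"
    return scan.pattern


def dispersion_index(midpoints: Sequence[float]) -> Optional[float]:
    """Fisher's dispersion index s^2(d)/mean(d) of inter-gene distances.

    ``midpoints`` are positions of the divergent genes on one scaffold;
    d are consecutive differences; sample (n-1) variance.  Undefined
    (None) with fewer than two distances.
    """
    pos = np.sort(np.asarray(list(midpoints), dtype=float))
    if pos.size < 3:
        return None
    d = np.diff(pos)
    mean = d.mean()
    if mean == 0:
        return 0.0
    return float(d.var(ddof=1) / mean)


def correlate_t_omega(scan: ScaffoldScan, min_genes: int = 5) -> Optional[float]:
    """Pearson r between divergence t and omega along one scaffold.

    Needs more than ``min_genes`` genes with finite t and omega; skipped
    (None, with a reason recorded) on too few genes or zero variance.
    """
    vals = [(t, w) for _, _, t, w in scan.genes
            if math.isfinite(t) and math.isfinite(w)]
    if len(vals) <= min_genes:
        scan.r_skipped_reason = "too_few_genes"
        return None
    t = np.array([v[0] for v in vals])
    w = np.array([v[1] for v in vals])
    if np.ptp(t) == 0 or np.ptp(w) == 0:
        scan.r_skipped_reason = "zero_variance"
        return None
    r = float(stats.pearsonr(t, w).statistic)
    scan.pearson_r = r
    return r


def dn_ds_regression(rates: Iterable) -> tuple[float, float, float]:
    """OLS of dN on dS over all genes with finite rates: (slope, intercept, r)."""
    pts = [(r.dS, r.dN) for r in rates
           if math.isfinite(r.dS) and math.isfinite(r.dN)]
    if len(pts) < 3:
        raise ValueError("need at least 3 genes with finite dN and dS")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in dS")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def divergence_summary(rates: Iterable, class_edges: Sequence[float] = (0.05, 0.75),
                       omega_edges: Sequence[float] = (0.25, 0.5, 1.0)) -> dict:
    """Marginal distribution of divergence and omega over all genes.

    Returns the fraction of strictly identical genes (t = 0), fractions
    per half-open (edge_i, edge_{i+1}] divergence bin plus an open top
    bin (where saturated genes are counted), the means of the finite
    estimates, and omega-bin fractions.
    """
    edges = list(class_edges)
    if not edges or edges[0] != 0:
        edges = [0.0] + edges
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("class_edges must be strictly increasing")
    rl = list(rates)
    n = len(rl)
    if n == 0:
        return {"n_genes": 0}
    t = np.array([r.t for r in rl], dtype=float)
    w = np.array([r.omega for r in rl], dtype=float)
    sat = ~np.isfinite(t)
    identical = float(np.mean(t == 0))
    bins = {}
    for lo, hi in zip(edges, edges[1:]):
        frac = float(np.mean((t > lo) & (t <= hi)))
        bins[f"({lo},{hi}]"] = frac
    bins[f">{edges[-1]}"] = float(np.mean((t > edges[-1]) | sat))
    wbins = {}
    w_edges = [0.0] + list(omega_edges)
    wfin = w[np.isfinite(w)]
    for lo, hi in zip(w_edges, w_edges[1:]):
        wbins[f"({lo},{hi}]"] = float(np.mean((wfin > lo) & (wfin <= hi))) if len(wfin) else float("nan")
    wbins[f">{w_edges[-1]}"] = float(np.mean(wfin > w_edges[-1])) if len(wfin) else float("nan")
    return {
        "n_genes": n,
        "identical_fraction": identical,
        "t_bins": bins,
        "saturated_fraction": float(np.mean(sat)),
        "mean_t": float(np.nanmean(np.where(np.isfinite(t), t, np.nan))),
        "mean_omega": float(np.nanmean(np.where(np.isfinite(w), w, np.nan))),
        "omega_bins": wbins,
    }


def fixed_substitution_load(n_orthologs: int, divergent_fraction: float,
                            codons_per_gene: int, subs_per_codon: float) -> int:
    """Fixed coding substitutions implied by a divergence scan.

    Number of divergent genes (rounded) times gene length times per-codon
    divergence, rounded to the nearest ten — the back-of-envelope load of
    newly fixed differences between two separating lineages.
    """
    n_div = round(n_orthologs * divergent_fraction)
    total = n_div * codons_per_gene * subs_per_codon
    return int(round(total / 10.0)) * 10
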