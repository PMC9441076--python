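"""Pairwise substitution-rate engine (NG86 and YN00 counting methods).

Both estimators work on gap-free in-frame codon alignments and reduce the
alignment to a codon-pair count vector (see :mod:`divscan._codon`), so the
same vectorized core serves single alignments and bootstrap replicate
batches.

NG86 (Nei & Gojobori 1986): synonymous sites from codon degeneracy
fractions, differences averaged with equal weight over all minimal
mutational pathways that avoid stop codons, Jukes-Cantor multiple-hit
correction on pS and pN.

YN00 (Yang & Nielsen 2000 counting scheme): codon usage estimated from the
pair by position-specific nucleotide frequencies (F3x4), kappa estimated
from fourfold-degenerate and nondegenerate sites with a Kimura-2-parameter
correction, synonymous/nonsynonymous site counts weighted by kappa and
codon usage, equal-pathway difference counting, and a per-site-class K80
distance correction.  This is a non-iterative transcription of the
counting method; it reports kappa alongside the rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from ._codon import pair_counts, tables

__all__ = [
    "PairwiseRates",
    "ng86_rates",
    "yn00_rates",
    "compute_rates",
    "apply_omega_rules",
    "divergence_t",
    "ts_tv_counts",
]

_EPS = 1e-12


@dataclass
class PairwiseRates:
    """Per-gene pairwise rate estimates plus bookkeeping flags.

    ``omega`` is only populated by :func:`apply_omega_rules`; the raw
    engines leave it as the plain ratio (nan where undefined).
    """

    gene_id: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    dS: float
    dN: float
    omega: float
    t: float
    kappa: float = float("nan")
    se_dS: float = float("nan")
    se_dN: float = float("nan")
    ts_count: int = 0
    tv_count: int = 0
    method: str = "ng86"
    flags: set = field(default_factory=set)

    def replace(self, **kw) -> "PairwiseRates":
        new = dataclasses.replace(self, flags=set(self.flags))
        for k, v in kw.items():
            setattr(new, k, v)
        return new


# ---------------------------------------------------------------------------
# vectorized cores: C has shape (..., 4096)

def _jc(p):
    arg = 1.0 - 4.0 / 3.0 * p
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, _EPS)), np.nan)
    return np.where(arg > 0, d, np.nan)


def _k80(P, Q):
    """Kimura-2-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    ok = (w1 > 0) & (w2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -0.5 * np.log(np.where(ok, w1, 1.0)) - 0.25 * np.log(np.where(ok, w2, 1.0))
    return np.where(ok, d, np.nan)


def _ng86_core(C: np.ndarray) -> dict:
    T = tables()
    L = C.sum(axis=-1) / 1.0
    codon_counts = C @ T.pair2codon              # (..., 64), sums to 2L
    s_sites = np.nan_to_num(T.ng86_s_sites)
    S = (codon_counts @ s_sites) / 2.0
    N = 3.0 * L - S
    Sd = C @ T.sd
    Nd = C @ T.nd
    with np.errstate(invalid="ignore", divide="ignore"):
        pS = np.where(S > 0, Sd / np.maximum(S, _EPS), 0.0)
        pN = np.where(N > 0, Nd / np.maximum(N, _EPS), 0.0)
    dS = _jc(pS)
    dN = _jc(pN)
    se_dS = _jc_se(pS, S)
    se_dN = _jc_se(pN, N)
    return dict(L=L, S=S, N=N, Sd=Sd, Nd=Nd, dS=dS, dN=dN,
                se_dS=se_dS, se_dN=se_dN, kappa=np.full_like(S, np.nan))


def _jc_se(p, n):
    with np.errstate(invalid="ignore", divide="ignore"):
        var_p = p * (1.0 - p) / np.maximum(n, _EPS)
        deriv = 1.0 / np.maximum(1.0 - 4.0 / 3.0 * p, _EPS)
        return np.sqrt(var_p) * deriv


def _estimate_kappa(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled fourfold/nondegenerate-site kappa; returns (kappa, fallback mask)."""
    T = tables()
    n4 = C @ T.n4
    n0 = C @ T.n0
    kappas = []
    weights = []
    for n, ts, tv in ((n4, C @ T.ts4, C @ T.tv4), (n0, C @ T.ts0, C @ T.tv0)):
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(n > 0, ts / np.maximum(n, _EPS), 0.0)
            Q = np.where(n > 0, tv / np.maximum(n, _EPS), 0.0)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        with np.errstate(invalid="ignore", divide="ignore"):
            A = -0.5 * np.log(np.maximum(w1, _EPS)) + 0.25 * np.log(np.maximum(w2, _EPS))
            B = -0.5 * np.log(np.maximum(w2, _EPS))
            k = 2.0 * A / np.where(B > 0, B, np.nan)
        ok = (n > 0) & (w1 > 0) & (w2 > 0) & (B > 0) & (A > 0)
        kappas.append(np.where(ok, k, np.nan))
        weights.append(np.where(ok, n, 0.0))
    k4, k0 = kappas
    w4, w0 = weights
    wsum = w4 + w0
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = (np.nan_to_num(k4) * w4 + np.nan_to_num(k0) * w0) / np.where(wsum > 0, wsum, np.nan)
    fallback = ~(wsum > 0) | ~np.isfinite(kappa) | (kappa <= 0)
    kappa = np.where(fallback, 1.0, kappa)
    return kappa, fallback


def _f3x4(C: np.ndarray) -> np.ndarray:
    """Sense-codon frequencies from position-specific nucleotide frequencies."""
    T = tables()
    f = C @ T.pos_nt.reshape(4096, 12)           # (..., 12)
    f = f.reshape(C.shape[:-1] + (3, 4))
    f = f / np.maximum(f.sum(axis=-1, keepdims=True), _EPS)
    from ._codon import CODONS, IS_STOP, NUC_IDX
    idx = np.array([[NUC_IDX[c[j]] for j in range(3)] for c in CODONS])
    pi = (f[..., 0, idx[:, 0]] * f[..., 1, idx[:, 1]] * f[..., 2, idx[:, 2]])
    pi = np.where(IS_STOP, 0.0, pi)
    pi = pi / np.maximum(pi.sum(axis=-1, keepdims=True), _EPS)
    return pi                                     # (..., 64)


def _yn00_core(C: np.ndarray) -> dict:
    T = tables()
    L = C.sum(axis=-1)
    codon_counts = C @ T.pair2codon
    kappa, kfall = _estimate_kappa(C)
    pi = _f3x4(C)
    # per-codon neighbor-class frequency masses
    a_st = pi @ T.syn_ts.T
    a_sv = pi @ T.syn_tv.T
    a_nt = pi @ T.non_ts.T
    a_nv = pi @ T.non_tv.T
    k = kappa[..., None]
    syn_flux = k * a_st + a_sv
    tot_flux = syn_flux + k * a_nt + a_nv
    deg_frac = np.nan_to_num(T.ng86_s_sites) / 3.0   # fallback where flux ~ 0
    rho_s = np.where(tot_flux > _EPS, syn_flux / np.maximum(tot_flux, _EPS), deg_frac)
    S = (codon_counts * 3.0 * rho_s).sum(axis=-1) / 2.0
    N = 3.0 * L - S
    Sd_ts = C @ T.sd_ts
    Sd_tv = C @ T.sd_tv
    Nd_ts = C @ T.nd_ts
    Nd_tv = C @ T.nd_tv
    Sd = Sd_ts + Sd_tv
    Nd = Nd_ts + Nd_tv
    with np.errstate(invalid="ignore", divide="ignore"):
        PS = Sd_ts / np.maximum(S, _EPS)
        QS = Sd_tv / np.maximum(S, _EPS)
        PN = Nd_ts / np.maximum(N, _EPS)
        QN = Nd_tv / np.maximum(N, _EPS)
    dS = _k80(PS, QS)
    dN = _k80(PN, QN)
    # informational delta-method SEs on the total class proportions
    se_dS = _jc_se(PS + QS, S)
    se_dN = _jc_se(PN + QN, N)
    return dict(L=L, S=S, N=N, Sd=Sd, Nd=Nd, dS=dS, dN=dN,
                se_dS=se_dS, se_dN=se_dN, kappa=kappa, kappa_fallback=kfall)


def rates_from_counts(C: np.ndarray, method: str = "yn00") -> dict:
    """Vectorized rate estimates from codon-pair count vectors.

    ``C`` may carry leading batch dimensions; the last axis must be 4096.
    Used directly by the codon bootstrap.
    """
    if method == "ng86":
        return _ng86_core(np.asarray(C, dtype=float))
    if method == "yn00":
        return _yn00_core(np.asarray(C, dtype=float))
    raise ValueError(f"unknown method: {method!r}")


# ---------------------------------------------------------------------------
# public per-alignment API

def _finish(aln, core: dict, method: str) -> PairwiseRates:
    T = tables()
    C = pair_counts(aln.seq_A, aln.seq_B)
    flags = set()
    S = float(core["S"])
    N = float(core["N"])
    Sd = float(core["Sd"])
    Nd = float(core["Nd"])
    dS = float(core["dS"])
    dN = float(core["dN"])
    if Sd == 0 and Nd == 0:
        flags.add("identical")
    if not np.isfinite(dS) or not np.isfinite(dN):
        flags.add("saturated")
    if core.get("kappa_fallback") is not None and bool(core["kappa_fallback"]):
        flags.add("kappa_fallback")
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = dN / dS if (np.isfinite(dS) and dS > 0 and np.isfinite(dN)) else float("nan")
    t = _t_value(S, N, dS, dN)
    r = PairwiseRates(
        gene_id=getattr(aln, "gene_id", ""),
        n_codons=int(core["L"]),
        S=S, N=N, Sd=Sd, Nd=Nd, dS=dS, dN=dN,
        omega=float(omega), t=t,
        kappa=float(core["kappa"]),
        se_dS=float(core["se_dS"]), se_dN=float(core["se_dN"]),
        ts_count=int(round(float(C @ T.ts_nt))),
        tv_count=int(round(float(C @ T.tv_nt))),
        method=method,
        flags=flags,
    )
    return r


def ng86_rates(aln) -> PairwiseRates:
    """Nei-Gojobori (1986) equal-pathway rates with JC correction."""
    C = pair_counts(aln.seq_A, aln.seq_B)
    return _finish(aln, {k: v for k, v in _ng86_core(C).items()}, "ng86")


def yn00_rates(aln) -> PairwiseRates:
    """Yang-Nielsen (2000) counting-method rates (kappa + codon usage)."""
    C = pair_counts(aln.seq_A, aln.seq_B)
    return _finish(aln, {k: v for k, v in _yn00_core(C).items()}, "yn00")


def compute_rates(aln, method: str = "yn00") -> PairwiseRates:
    return yn00_rates(aln) if method == "yn00" else ng86_rates(aln)


def _t_value(S, N, dS, dN) -> float:
    if not (np.isfinite(dS) and np.isfinite(dN)):
        return float("nan")
    return float(3.0 * (S * dS + N * dN) / (S + N))


def divergence_t(rates: PairwiseRates) -> float:
    """Per-codon divergence t = 3(S*dS + N*dN)/(S+N); nan when saturated."""
    return _t_value(rates.S, rates.N, rates.dS, rates.dN)


def apply_omega_rules(raw: PairwiseRates) -> PairwiseRates:
    """Edge rules for the dN/dS ratio.

    dN=dS=0 -> omega 0 (identical gene); dN>0 with dS=0 -> S*dS is reset
    to 1 (i.e. dS := 1/S, one synonymous change assumed missed) and
    flagged; non-finite estimates are filtered (omega nan) and flagged
    rather than written as a numeric sentinel.
    """
    r = raw.replace()
    if not (np.isfinite(r.dS) and np.isfinite(r.dN)):
        r.omega = float("nan")
        r.flags |= {"saturated", "infinite_filtered"}
        return r
    if r.dN == 0 and r.dS == 0:
        r.omega = 0.0
        r.flags.add("identical")
        return r
    if r.dS == 0 and r.dN > 0:
        r.dS = 1.0 / r.S
        r.omega = r.dN * r.S
        r.flags.add("dS_zero_reset")
        return r
    if r.dS == 0:
        r.omega = 0.0
        return r
    r.omega = r.dN / r.dS
    return r


def ts_tv_counts(aln) -> tuple[int, int, dict]:
    """Site-by-site transition/transversion mismatch tallies.

    Returns (ts, tv, {"ts_rate", "tv_rate"}) with rates per nucleotide
    site of the alignment.
    """
    T = tables()
    C = pair_counts(aln.seq_A, aln.seq_B)
    ts = int(round(float(C @ T.ts_nt)))
    tv = int(round(float(C @ T.tv_nt)))
    n_nt = 3 * int(C.sum())
    return ts, tv, {"ts_rate": ts / n_nt, "tv_rate": tv / n_nt}
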