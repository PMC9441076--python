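"""Rate-engine tests: oracle equivalence, edge rules, symmetry, recovery."""

import numpy as np
import pytest
from _oracles import ng86_counts, pathway_differences
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_alignment
from divscan._codon import CODONS, SENSE, pair_counts
from divscan.cds import CodonAlignment
from divscan.rates import (PairwiseRates, apply_omega_rules, divergence_t,
                           ng86_rates, rates_from_counts, ts_tv_counts,
                           yn00_rates)


def _aln(seq_a, seq_b, gid="g"):
    return CodonAlignment(gene_id=gid, seq_A=seq_a, seq_B=seq_b)


def _random_pair(rng, n_codons=30, p_mut=0.4, max_changes=3):
    a = rng.choice(SENSE, n_codons)
    b = a.copy()
    for i in range(n_codons):
        if rng.random() < p_mut:
            c = list(CODONS[b[i]])
            for _ in range(int(rng.integers(1, max_changes + 1))):
                c[rng.integers(3)] = "ACGT"[rng.integers(4)]
            cc = "".join(c)
            if cc not in ("TAA", "TAG", "TGA"):
                from divscan._codon import CODON_IDX
                b[i] = CODON_IDX[cc]
    return ("".join(CODONS[i] for i in a), "".join(CODONS[i] for i in b))


@pytest.mark.parametrize("method", [ng86_rates, yn00_rates])
def test_identical_sequences(method):
    seq = "ATGAAACCCGGGTTTCTG" * 10
    r = method(_aln(seq, seq))
    assert r.Sd == 0 and r.Nd == 0
    assert r.dS == 0 and r.dN == 0
    assert "identical" in r.flags
    assert r.S > 0 and r.N > 0
    assert r.S + r.N == pytest.approx(3 * r.n_codons)


def test_single_synonymous_difference():
    # one TTT<->TTC third-position change in 20 codons: Sd=1, Nd=0, dN=0
    a = "TTT" + "GGC" * 19
    b = "TTC" + "GGC" * 19
    r = ng86_rates(_aln(a, b))
    assert r.Sd == pytest.approx(1.0)
    assert r.Nd == pytest.approx(0.0)
    assert r.dN == 0.0
    assert r.dS > 0


def test_double_substituted_codon_matches_pathway_enumeration():
    # TTT<->CTC: both orderings enumerated by the independent oracle
    sd, nd = pathway_differences("TTT", "CTC")
    a = "TTT" + "GGC" * 19
    b = "CTC" + "GGC" * 19
    r = ng86_rates(_aln(a, b))
    assert r.Sd == pytest.approx(sd, abs=1e-12)
    assert r.Nd == pytest.approx(nd, abs=1e-12)


def test_ng86_counts_match_bruteforce_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        sa, sb = _random_pair(rng)
        S, N, Sd, Nd = ng86_counts(sa, sb)
        r = ng86_rates(_aln(sa, sb))
        assert r.S == pytest.approx(S, abs=1e-9)
        assert r.N == pytest.approx(N, abs=1e-9)
        assert r.Sd == pytest.approx(Sd, abs=1e-9)
        assert r.Nd == pytest.approx(Nd, abs=1e-9)


def test_ng86_matches_biopython():
    """Cross-check pathway counts + JC against biopython's NG86.

    Biopython counts a mutation-to-stop toward N instead of excluding it
    and renormalizing, so its site counts are converted explicitly; the
    difference counts and the correction are then directly comparable.
    """
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    from _oracles import ng86_sites_raw
    rng = np.random.default_rng(5)
    checked = 0
    for _ in range(15):
        sa, sb = _random_pair(rng, n_codons=100, p_mut=0.15, max_changes=1)
        dN_bp, dS_bp = cal_dn_ds(CodonSeq(sa), CodonSeq(sb), method="NG86")
        if dS_bp < 0 or dN_bp < 0:  # biopython saturation sentinel
            continue
        r = ng86_rates(_aln(sa, sb))
        L = len(sa) // 3
        S_raw = sum((ng86_sites_raw(sa[3 * i:3 * i + 3])
                     + ng86_sites_raw(sb[3 * i:3 * i + 3])) / 2 for i in range(L))
        pS, pN = r.Sd / S_raw, r.Nd / (3 * L - S_raw)
        assert -0.75 * np.log(1 - 4 / 3 * pS) == pytest.approx(dS_bp, abs=5e-4)
        assert -0.75 * np.log(1 - 4 / 3 * pN) == pytest.approx(dN_bp, abs=5e-4)
        checked += 1
    assert checked >= 10


@pytest.mark.parametrize("method", [ng86_rates, yn00_rates])
def test_swap_symmetry(method):
    rng = np.random.default_rng(17)
    for _ in range(20):
        sa, sb = _random_pair(rng, 40)
        r1 = method(_aln(sa, sb))
        r2 = method(_aln(sb, sa))
        for attr in ("S", "N", "Sd", "Nd", "dS", "dN", "kappa"):
            v1, v2 = getattr(r1, attr), getattr(r2, attr)
            if np.isnan(v1) and np.isnan(v2):
                continue
            assert v1 == pytest.approx(v2, abs=1e-12), attr


def test_site_counts_sum_to_three_per_codon():
    rng = np.random.default_rng(23)
    for method in (ng86_rates, yn00_rates):
        for _ in range(10):
            sa, sb = _random_pair(rng, 50)
            r = method(_aln(sa, sb))
            assert r.S + r.N == pytest.approx(3 * r.n_codons, rel=1e-9)


def test_saturated_alignment_flagged():
    # every codon differs synonymously at a 2-fold site: pS >> 3/4
    a = "TTT" * 30
    b = "TTC" * 30
    r = ng86_rates(_aln(a, b))
    assert "saturated" in r.flags
    assert not np.isfinite(r.dS)
    assert not np.isfinite(divergence_t(r))


def test_kappa_estimation_orders_processes():
    """Estimated kappa should separate kappa=1 and kappa=4 simulations."""
    rng = np.random.default_rng(29)
    k1 = [yn00_rates(make_alignment("a", 300, 0.4, 1.0, 1.0, rng)).kappa
          for _ in range(20)]
    k4 = [yn00_rates(make_alignment("b", 300, 0.4, 1.0, 4.0, rng)).kappa
          for _ in range(20)]
    assert np.median(k1) < np.median(k4)
    assert np.median(k1) == pytest.approx(1.0, abs=0.4)
    assert np.median(k4) == pytest.approx(4.0, rel=0.4)


def test_divergence_t_formula():
    r = PairwiseRates("g", 100, S=100, N=200, Sd=0, Nd=0, dS=0.3, dN=0.03,
                      omega=0.1, t=0.0)
    assert divergence_t(r) == pytest.approx(3 * (100 * 0.3 + 200 * 0.03) / 300)
    r2 = r.replace(dS=0.0, dN=0.0)
    assert divergence_t(r2) == 0.0
    r3 = r.replace(S=150.0, N=150.0, dN=0.0, dS=0.2)
    assert divergence_t(r3) == pytest.approx(1.5 * 0.2)


def test_omega_edge_rules():
    base = dict(gene_id="g", n_codons=100, Sd=0, Nd=0, omega=float("nan"), t=0.0)
    both_zero = PairwiseRates(S=50, N=250, dS=0.0, dN=0.0, **base)
    r = apply_omega_rules(both_zero)
    assert r.omega == 0.0 and "identical" in r.flags

    dn_only = PairwiseRates(S=50, N=250, dS=0.0, dN=0.1, **base)
    r = apply_omega_rules(dn_only)
    assert r.dS == pytest.approx(1.0 / 50)       # S*dS reset to 1
    assert r.omega == pytest.approx(5.0)
    assert "dS_zero_reset" in r.flags

    plain = PairwiseRates(S=50, N=250, dS=0.2, dN=0.02, **base)
    assert apply_omega_rules(plain).omega == pytest.approx(0.1)

    sat = PairwiseRates(S=50, N=250, dS=float("nan"), dN=0.1, **base)
    r = apply_omega_rules(sat)
    assert not np.isfinite(r.omega)
    assert "infinite_filtered" in r.flags


def test_ts_tv_examples_and_conservation():
    ts, tv, rates = ts_tv_counts(_aln("AAA", "GAA"))
    assert (ts, tv) == (1, 0)                    # A<->G is a transition
    ts, tv, _ = ts_tv_counts(_aln("AAA" + "CCC" * 3, "ATA" + "CCC" * 3))
    assert (ts, tv) == (0, 1)                    # A<->T is a transversion
    assert ts_tv_counts(_aln("ATG", "ATG"))[:2] == (0, 0)
    rng = np.random.default_rng(31)
    for _ in range(20):
        sa, sb = _random_pair(rng, 40)
        ts, tv, _ = ts_tv_counts(_aln(sa, sb))
        mismatches = sum(x != y for x, y in zip(sa, sb))
        assert ts + tv == mismatches


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_pathway_table_matches_oracle_everywhere(seed):
    """Random codon pairs: table-driven Sd/Nd equals fresh enumeration."""
    rng = np.random.default_rng(seed)
    u = CODONS[int(rng.choice(SENSE))]
    v = CODONS[int(rng.choice(SENSE))]
    sd, nd = pathway_differences(u, v)
    core = rates_from_counts(pair_counts(u, v), "ng86")
    assert float(core["Sd"]) == pytest.approx(sd, abs=1e-12)
    assert float(core["Nd"]) == pytest.approx(nd, abs=1e-12)


def test_parameter_recovery_small():
    """Median YN00 omega within 25% of truth on a small batch (t=0.3, w=0.2)."""
    rng = np.random.default_rng(37)
    omegas = []
    for _ in range(60):
        r = yn00_rates(make_alignment("g", 300, 0.3, 0.2, 2.0, rng))
        if np.isfinite(r.dS) and r.dS > 0:
            omegas.append(r.dN / r.dS)
    assert abs(np.median(omegas) - 0.2) / 0.2 < 0.25
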