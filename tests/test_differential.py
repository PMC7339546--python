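"""DMC/DMR calling: exact Fisher oracles, calibration, filter semantics."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from bovmeth.differential import (call_dmcs, call_dmrs, dmc_test,
                                  element_methylation, fisher_exact_two_sided,
                                  tissue_specific_dmrs)
from bovmeth.simulate import simulate_null_pair
from bovmeth.types import GenomicInterval, SampleInfo, SampleSheet
from conftest import methylome_from_arrays


def fisher_oracle(m_a, u_a, m_b, u_b) -> float:
    """Exact two-sided hypergeometric enumeration with rational arithmetic."""
    n_a, n_b = m_a + u_a, m_b + u_b
    M, K = n_a + n_b, m_a + m_b
    denom = comb(M, K)
    probs = {k: Fraction(comb(n_a, k) * comb(n_b, K - k), denom)
             for k in range(max(0, K - n_b), min(K, n_a) + 1)}
    p_obs = probs[m_a]
    return float(sum(v for v in probs.values() if v <= p_obs))


@pytest.mark.parametrize("table", [
    (8, 2, 1, 9), (10, 0, 0, 10), (5, 5, 5, 5), (12, 4, 3, 13),
    (0, 16, 0, 16), (7, 9, 9, 7), (1, 15, 14, 2)])
def test_fisher_matches_enumeration_and_scipy(table):
    p = fisher_exact_two_sided(*table)
    assert abs(p - fisher_oracle(*table)) < 1e-12
    m_a, u_a, m_b, u_b = table
    assert p == pytest.approx(
        scipy_fisher([[m_a, u_a], [m_b, u_b]])[1], abs=1e-9)


def test_dmc_test_examples():
    diff, p = dmc_test(8, 2, 1, 9)
    assert diff == pytest.approx(0.7)
    assert p == pytest.approx(0.0055, abs=5e-4)
    diff, p = dmc_test(8, 2, 8, 2)
    assert diff == 0
    assert p == pytest.approx(1.0, abs=1e-9)
    diff, p = dmc_test(10, 0, 0, 10)
    assert diff == 1.0
    assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)


def _pair(diffs, depth=20):
    """Two methylomes over len(diffs) CpGs with designed level pairs."""
    pos = np.arange(len(diffs)) * 50
    la = np.array([d[0] for d in diffs])
    lb = np.array([d[1] for d in diffs])
    ma = np.round(la * depth).astype(int)
    mb = np.round(lb * depth).astype(int)
    a = methylome_from_arrays("a", "chr1", pos, ma, depth - ma)
    b = methylome_from_arrays("b", "chr1", pos, mb, depth - mb)
    return a, b


def test_call_dmcs_thresholds_and_depth():
    a, b = _pair([(0.9, 0.1)] * 5 + [(0.8, 0.8)] * 20)
    recs = call_dmcs(a, b)
    assert len(recs) == 5
    assert all(r.diff == pytest.approx(0.8) for r in recs)
    # depth below 10 in one sample -> site not tested
    a2 = methylome_from_arrays("a", "chr1", [0], [7], [1])   # depth 8
    b2 = methylome_from_arrays("b", "chr1", [0], [1], [11])
    assert call_dmcs(a2, b2) == []


def test_call_dmcs_antisymmetric():
    a, b = _pair([(0.9, 0.1), (0.2, 0.85), (0.8, 0.8), (0.1, 0.95)])
    ab = call_dmcs(a, b, q_max=1.0, diff_min=0.0, return_all=True)
    ba = call_dmcs(b, a, q_max=1.0, diff_min=0.0, return_all=True)
    assert [r.pos for r in ab] == [r.pos for r in ba]
    for x, y in zip(ab, ba):
        assert x.diff == pytest.approx(-y.diff)
        assert x.p_value == pytest.approx(y.p_value)
        assert x.q_value >= x.p_value  # BH never lowers a p-value


def test_null_calibration_quick():
    """Independent sampling from one truth: q<0.05 fraction within bounds."""
    a, b = simulate_null_pair(20_000, seed=12)
    recs = call_dmcs(a, b, return_all=True)
    frac = np.mean([r.q_value < 0.05 for r in recs])
    se = np.sqrt(0.05 * 0.95 / len(recs))
    assert frac <= 0.05 + 2 * se


def exact_fisher_power(n_a=16, n_b=16, p_a=0.7, p_b=0.3, alpha=0.05,
                       diff_min=0.3):
    """Exact power of the two-sided Fisher test at the given margins.

    Enumerates the joint Binomial table distribution; the effective BH
    threshold under an all-signal mixture is the fixed point
    t = alpha * G(t) of the p-value CDF G.
    """
    from scipy.stats import binom

    wa = binom.pmf(np.arange(n_a + 1), n_a, p_a)
    wb = binom.pmf(np.arange(n_b + 1), n_b, p_b)
    entries = []   # (p_value, prob, passes_diff)
    for ma in range(n_a + 1):
        for mb in range(n_b + 1):
            pr = wa[ma] * wb[mb]
            p = fisher_exact_two_sided(ma, n_a - ma, mb, n_b - mb)
            passes = abs(ma / n_a - mb / n_b) > diff_min
            entries.append((p, pr, passes))
    entries.sort()
    ps = np.array([e[0] for e in entries])
    prs = np.array([e[1] for e in entries])
    ok = np.array([e[2] for e in entries])
    cdf = np.cumsum(prs)

    def G(t):
        i = np.searchsorted(ps, t, side="right")
        return cdf[i - 1] if i else 0.0

    t = alpha
    for _ in range(100):
        t_new = alpha * G(t)
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return float(np.sum(prs[(ps <= t) & ok])), t


def test_power_matches_exact_oracle():
    power, t_eff = exact_fisher_power()
    rng = np.random.default_rng(21)
    n = 8000
    pos = np.arange(n) * 50
    ma = rng.binomial(16, 0.7, size=n)
    mb = rng.binomial(16, 0.3, size=n)
    a = methylome_from_arrays("a", "chr1", pos, ma, 16 - ma)
    b = methylome_from_arrays("b", "chr1", pos, mb, 16 - mb)
    recs = call_dmcs(a, b)
    recall = len(recs) / n
    assert abs(recall - power) <= 0.03


# -------------------------------------------------------- DMR 30-window fix

def build_dmr_fixture():
    """30 windows x 10 CpGs with designed per-window behaviour."""
    kinds = (["strong_hypo"] * 6 + ["weak_support"] * 5 + ["small_diff"] * 5
             + ["null"] * 8 + ["mixed"] * 6)
    pos, ma_, ua_, mb_, ub_ = [], [], [], [], []
    for w, kind in enumerate(kinds):
        for j in range(10):
            pos.append(w * 500 + j * 45)
            ma_.append(16)
            ua_.append(4)   # sample A: level 0.8 at every CpG, depth 20
            if kind == "strong_hypo":
                mb, ub = 2, 18
            elif kind == "weak_support":
                mb, ub = (0, 20) if j < 4 else (16, 4)
            elif kind == "small_diff":
                mb, ub = 12, 8
            elif kind == "null":
                mb, ub = 16, 4
            else:  # mixed: 6 strongly hypo CpGs + 4 mildly hyper CpGs
                mb, ub = (1, 19) if j < 6 else (20, 0)
            mb_.append(mb)
            ub_.append(ub)
    a = methylome_from_arrays("a", "chr1", pos, ma_, ua_)
    b = methylome_from_arrays("b", "chr1", pos, mb_, ub_)
    return a, b, kinds


def brute_force_dmrs(a, b, kinds):
    """Independent re-implementation: scipy Fisher + manual BH."""
    ca, cb = a.chroms["chr1"], b.chroms["chr1"]
    # per-site DMCs (diff > 0.3, BH q < 0.05 across all sites)
    site_p = [scipy_fisher([[m, u], [m2, u2]])[1]
              for m, u, m2, u2 in zip(ca.meth, ca.unmeth, cb.meth, cb.unmeth)]
    site_diff = (ca.meth / ca.coverage - cb.meth / cb.coverage)

    def bh(ps):
        n = len(ps)
        order = np.argsort(ps, kind="stable")
        q = np.empty(n)
        prev = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            prev = min(prev, ps[i] * n / rank)
            q[i] = prev
        return q

    site_q = bh(np.array(site_p))
    dmc_sign = {}
    for i in range(len(site_p)):
        if abs(site_diff[i]) > 0.3 and site_q[i] < 0.05:
            w = ca.pos[i] // 500
            dmc_sign.setdefault(w, []).append(np.sign(site_diff[i]))
    # windows on pooled counts
    win_p, win_diff = [], []
    for w in range(len(kinds)):
        sel = (ca.pos // 500) == w
        Ma, Na = ca.meth[sel].sum(), ca.coverage[sel].sum()
        Mb, Nb = cb.meth[sel].sum(), cb.coverage[sel].sum()
        win_p.append(scipy_fisher([[Ma, Na - Ma], [Mb, Nb - Mb]])[1])
        win_diff.append(Ma / Na - Mb / Nb)
    win_q = bh(np.array(win_p))
    survivors = set()
    for w in range(len(kinds)):
        if abs(win_diff[w]) <= 0.3 or win_q[w] >= 0.05:
            continue
        sign = np.sign(win_diff[w])
        if sum(1 for s in dmc_sign.get(w, []) if s == sign) >= 5:
            survivors.add(w)
    return survivors


def test_dmr_filter_semantics_exact():
    """Exactly the windows passing diff, q and DMC-support rules survive."""
    a, b, kinds = build_dmr_fixture()
    dmcs = call_dmcs(a, b, min_depth=10)
    dmrs = call_dmrs(a, b, dmcs)
    got = {d.start // 500 for d in dmrs}
    expected = brute_force_dmrs(a, b, kinds)
    assert got == expected
    # the fixture exercises every rule
    assert {kinds[w] for w in expected} == {"strong_hypo", "mixed"}
    for d in dmrs:
        assert d.direction == "hyper"  # A higher than B throughout
        assert d.n_dmc_same_direction >= 5


# ------------------------------------------------------- element filtering

def test_element_detection_rules():
    rng = np.random.default_rng(3)
    # 60 CpGs, 5 covered -> excluded (8.3% < 10%)
    pos = np.arange(60) * 10
    cov = np.zeros(60, int)
    cov[:5] = 10
    m = methylome_from_arrays("s", "chr1", pos, cov // 2, cov - cov // 2)
    tab = element_methylation([GenomicInterval("chr1", 0, 600, "e1")], m)
    assert not tab["passes"].iloc[0]
    # 30 CpGs, 5 detected -> included
    pos = np.arange(30) * 10
    cov = np.zeros(30, int)
    cov[:5] = 10
    m = methylome_from_arrays("s", "chr1", pos, cov, cov * 0)
    tab = element_methylation([GenomicInterval("chr1", 0, 300, "e2")], m)
    assert tab["passes"].iloc[0]
    assert tab["level"].iloc[0] == 1.0
    # 30 CpGs, 4 detected -> excluded
    cov[:5] = 0
    cov[:4] = 10
    m = methylome_from_arrays("s", "chr1", pos, cov, cov * 0)
    tab = element_methylation([GenomicInterval("chr1", 0, 300, "e3")], m)
    assert not tab["passes"].iloc[0]


# ------------------------------------------------------ tissue-specific DMR

def test_tissue_specific_dmr_ranking_and_merge():
    from bovmeth.differential import DMRRecord

    sheet = SampleSheet([
        SampleInfo("sperm", "sperm", "sperm"),
        SampleInfo("liver", "liver", "somatic"),
        SampleInfo("kidney", "kidney", "somatic"),
    ])

    def rec(start, direction="hypo", diff=-0.5):
        return DMRRecord("chr1", start, start + 500, diff, 1e-6, 1e-5, 6,
                         direction)

    # window 1000 is a hypo-DMR vs both other tissues; window 5000 only one
    dmr_sets = {
        ("sperm", "liver"): [rec(1000), rec(1500), rec(5000)],
        ("sperm", "kidney"): [rec(1000), rec(1500)],
    }
    calls = tissue_specific_dmrs(dmr_sets, sheet, "sperm", top_fraction=0.003)
    # with 3 ranked windows the top 0.3% keeps only the most frequent one
    assert len(calls) == 1
    assert (calls[0].start, calls[0].frequency) == (1000, 2)
    # a generous fraction (with warning) selects both frequent windows,
    # which merge; window 5000 fails the all-other-tissues requirement
    calls = tissue_specific_dmrs(dmr_sets, sheet, "sperm", top_fraction=0.67)
    assert len(calls) == 1
    c = calls[0]
    assert (c.start, c.end) == (1000, 2000)
    assert c.tissue == "sperm"
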