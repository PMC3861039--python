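"""Fisher/Benjamini–Yekutieli machinery against independent exact oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaexchange.comparison_stats import (
    CellClass,
    bhy_adjust,
    classify_cells,
    correlate,
    distribution_shift_test,
    fisher_cell_test,
)
from aaexchange.exchange_matrix import build_counts
from aaexchange.variant_ingest import Dataset


def fisher_oracle(a, a_tot, b, b_tot):
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    n = a_tot + b_tot
    k_col = a + b
    def weight(x):  # unnormalized P(top-left = x) with fixed margins
        if x < 0 or x > a_tot or k_col - x < 0 or k_col - x > b_tot:
            return 0
        return math.comb(a_tot, x) * math.comb(b_tot, k_col - x)
    total = sum(weight(x) for x in range(0, min(a_tot, k_col) + 1))
    w_obs = weight(a)
    # two-sided: all tables at most as probable as the observed one
    acc = sum(w for x in range(0, min(a_tot, k_col) + 1)
              if (w := weight(x)) <= w_obs * (1 + 1e-9))
    return acc / total


def test_fisher_identical_proportions():
    assert fisher_cell_test(5, 10, 5, 10) == pytest.approx(1.0)
    assert fisher_cell_test(0, 10, 0, 10) == pytest.approx(1.0)


def test_fisher_input_errors():
    with pytest.raises(ValueError):
        fisher_cell_test(-1, 10, 0, 10)
    with pytest.raises(ValueError):
        fisher_cell_test(11, 10, 0, 10)
    with pytest.raises(ValueError):
        fisher_cell_test(0, 0, 0, 10)


def test_fisher_symmetric_in_datasets():
    for args in [(3, 9, 1, 12), (0, 5, 4, 7), (2, 2, 0, 8)]:
        a, at, b, bt = args
        assert fisher_cell_test(a, at, b, bt) == pytest.approx(
            fisher_cell_test(b, bt, a, at)
        )


def test_fisher_matches_enumeration_on_small_margins():
    """Spot-check against the exact enumeration oracle (margins ≤ 8 here;
    the full ≤ 12 sweep runs in the acceptance suite)."""
    for at in range(1, 9):
        for bt in range(1, 9):
            for a in range(at + 1):
                for b in range(bt + 1):
                    assert fisher_cell_test(a, at, b, bt) == pytest.approx(
                        fisher_oracle(a, at, b, bt), rel=1e-7, abs=1e-12
                    )


def by_oracle(pvals):
    """Hand-executed Benjamini–Yekutieli step-up."""
    m = len(pvals)
    c = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, c * m / rank * pvals[i], 1.0)
        adj[i] = val
        prev = val
    return adj


def test_bhy_single_p_unchanged():
    assert bhy_adjust([0.037])[0] == pytest.approx(0.037)


def test_bhy_two_values_hand_formula():
    # m=2, c(2)=1.5: adj = (min(1.5*2*0.01, 0.06), 1.5*0.04*2/2) = (0.03, 0.06)
    adj = bhy_adjust([0.01, 0.04])
    assert adj == pytest.approx([0.03, 0.06])


def test_bhy_rejects_out_of_range():
    with pytest.raises(ValueError):
        bhy_adjust([0.5, 1.2])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bhy_matches_oracle_and_dominates_raw(pvals):
    adj = bhy_adjust(pvals)
    assert np.allclose(adj, by_oracle(pvals), rtol=1e-12, atol=1e-12)
    assert (adj >= np.asarray(pvals) - 1e-15).all()
    assert ((0 <= adj) & (adj <= 1)).all()
    # order-preserving in the raw ranks
    order = np.argsort(pvals)
    assert (np.diff(adj[order]) >= -1e-15).all()


def _counts(records):
    return build_counts(Dataset(records))


def test_classify_equal_matrices_not_significant(natural_counts):
    sig = classify_cells(natural_counts, natural_counts)
    for x in sig.classes.index:
        for y in sig.classes.columns:
            cls = sig.classes.at[x, y]
            if cls is not None and natural_counts.counts.at[x, y] > 0:
                assert cls is CellClass.NOT_SIGNIFICANT


def test_classify_absent_in_a():
    from aaexchange.variant_ingest import VariantRecord
    from aaexchange.genetic_code import translate

    def rec(rc, ac, pos):
        return VariantRecord("P", pos, rc, ac, translate(rc), translate(ac),
                             frozenset({"EUR"}))

    a = _counts([rec("CGA", "CAA", 1)])
    b = _counts([rec("CGA", "CAA", 1)] + [rec("GGC", "AGC", i) for i in (2, 3, 4)])
    sig = classify_cells(a, b)
    assert sig.classes.at["G", "S"] is CellClass.ABSENT_IN_A


def test_classify_detects_strong_excess():
    from aaexchange.variant_ingest import VariantRecord
    from aaexchange.genetic_code import translate

    def recs(rc, ac, n, start=0):
        return [
            VariantRecord("P", start + i, rc, ac, translate(rc), translate(ac),
                          frozenset({"EUR"}))
            for i in range(1, n + 1)
        ]

    # a: 200 R->Q and 200 K->I; b: 10 R->Q and 390 K->I
    a = _counts(recs("CGA", "CAA", 200) + recs("AAA", "ATA", 200, 1000))
    b = _counts(recs("CGA", "CAA", 10) + recs("AAA", "ATA", 390, 1000))
    sig = classify_cells(a, b, alpha=0.01)
    assert sig.classes.at["R", "Q"] is CellClass.MORE_IN_A
    assert sig.classes.at["K", "I"] is CellClass.MORE_IN_B
    assert (sig.p_adjusted.stack() >= sig.p.stack() - 1e-15).all()


def test_correlate_strength_labels():
    x = pd.Series(np.arange(10.0))
    assert correlate(x, 2 * x + 1).strength == "strong"
    assert correlate(x, 2 * x + 1).r == pytest.approx(1.0)
    rng = np.random.default_rng(5)
    # construct data with prescribed correlation by mixing
    z = pd.Series(rng.normal(size=5000))
    e = pd.Series(rng.normal(size=5000))
    for target, label in [(0.5, "moderate"), (0.1, "weak")]:
        y = target * z + np.sqrt(1 - target**2) * e
        rep = correlate(z, y)
        assert abs(rep.r - target) < 0.05
        assert rep.strength == label


def test_correlate_exclusions_and_errors():
    x = pd.Series([1.0, 2, 3, 4, 100], index=list("abcde"))
    y = pd.Series([1.0, 2, 3, 4, -50], index=list("abcde"))
    full = correlate(x, y)
    excl = correlate(x, y, exclusions=("e",))
    assert excl.n == 4 and excl.r > full.r
    with pytest.raises(ValueError):
        correlate(pd.Series([1.0, 1, 1]), pd.Series([1.0, 2, 3]))
    with pytest.raises(ValueError):
        correlate(pd.Series([1.0, 2]), pd.Series([1.0, 2]))


def test_distribution_shift_detects_beta_shift():
    rng = np.random.default_rng(7)
    a = rng.beta(5, 5, 10_000)
    b = rng.beta(4, 6, 10_000)
    p, ma, mb = distribution_shift_test(a, b)
    assert p < 1e-10
    assert ma > mb
    p_swap, _, _ = distribution_shift_test(b, a)
    assert p_swap == pytest.approx(p, rel=1e-9)


def test_distribution_shift_identical_samples():
    a = np.linspace(0, 1, 101)
    p, ma, mb = distribution_shift_test(a, a.copy())
    assert p > 0.9 and ma == mb
    with pytest.raises(ValueError):
        distribution_shift_test([], [1.0])
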