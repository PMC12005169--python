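"""Retention classes, fractionation profiles/bias test, GO enrichment."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from wgdkit.retention import (FractionationWindow, PangeneRow,
                              RetentionClass, classify_pangene,
                              classify_retention, fractionation_bias_test,
                              fractionation_profile, go_enrichment)
from wgdkit.simulate import pangene_table


# ---------------------------------------------------------------------------
# retention classification

@pytest.mark.parametrize("counts,expected", [
    ((1, 1, 2, 2), RetentionClass.RETAINED_BOTH),
    ((1, 1, 1, 1), RetentionClass.SINGLE_BOTH),
    ((1, 1, 2, 1), RetentionClass.RETAINED_A_ONLY),
    ((1, 1, 1, 2), RetentionClass.RETAINED_B_ONLY),
    ((2, 1, 2, 2), RetentionClass.FILTERED_OUT),
    ((1, 1, 0, 2), RetentionClass.FILTERED_OUT),
    ((1, 1, 3, 2), RetentionClass.FILTERED_OUT),
])
def test_single_row_classification(counts, expected):
    assert classify_pangene(PangeneRow("p", *counts)) is expected


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        PangeneRow("p", 1, -1, 2, 2)


def _oracle_class(o1, o2, a, b):
    """Independent restatement of the filter + partition rule."""
    if (o1, o2) != (1, 1) or a not in (1, 2) or b not in (1, 2):
        return "filtered_out"
    return {(2, 2): "retained_both", (1, 1): "single_both",
            (2, 1): "retained_A_only", (1, 2): "retained_B_only"}[(a, b)]


def test_exhaustive_enumeration_matches_oracle():
    """All 256 copy-count combinations in 0..3 agree with a brute-force
    restatement of the rule, and the totals are a partition."""
    rows = [PangeneRow(f"p{i}", *counts)
            for i, counts in enumerate(itertools.product(range(4), repeat=4))]
    classes, totals = classify_retention(rows)
    for row, cls in zip(rows, classes):
        assert cls.value == _oracle_class(row.out1, row.out2,
                                          row.ingroup_a, row.ingroup_b)
    assert sum(totals.values()) == len(rows)
    assert totals["retained_both"] == 1 and totals["single_both"] == 1


def test_simulated_unbiased_losses_balance_classes(sim_default):
    from scipy import stats

    pg = pangene_table(sim_default)
    rows = [PangeneRow(r.pangene, int(r.out1), int(r.out2),
                       int(r.ingA), int(r.ingB)) for r in pg.itertuples()]
    _, totals = classify_retention(rows)
    a, b = totals["retained_A_only"], totals["retained_B_only"]
    assert stats.binomtest(a, a + b, 0.5).pvalue > 0.01


# ---------------------------------------------------------------------------
# fractionation

def _ref(n, scaf="ref"):
    return [(f"g{i}", scaf) for i in range(n)]


def test_no_losses_gives_full_retention_everywhere():
    omap = {f"g{i}": ["hA", "hB"] for i in range(200)}
    windows = fractionation_profile(_ref(200), omap, window=100)
    assert len(windows) == 2
    assert all(w.retention_1 == 100.0 and w.retention_2 == 100.0
               for w in windows)


def test_constructed_deletion_recomputes_exactly():
    """30 genes deleted from homoeolog B in one window -> (100%, 70%)."""
    omap = {f"g{i}": ["hA", "hB"] for i in range(200)}
    for i in range(100, 130):
        omap[f"g{i}"] = ["hA"]
    windows = fractionation_profile(_ref(200), omap, window=100)
    # hA maps 200 genes, hB 170 -> hA is homoeolog 1
    assert windows[0].homoeolog_1 == "hA"
    assert (windows[0].retention_1, windows[0].retention_2) == (100.0, 100.0)
    assert (windows[1].retention_1, windows[1].retention_2) == (100.0, 70.0)


def test_short_scaffold_yields_truncated_window():
    omap = {f"g{i}": ["hA", "hB"] for i in range(50)}
    windows = fractionation_profile(_ref(50), omap, window=100)
    assert len(windows) == 1
    assert windows[0].truncated and windows[0].n_genes == 50


def test_gene_relabelling_invariance():
    rng = np.random.default_rng(0)
    omap = {f"g{i}": (["hA", "hB"] if rng.random() < 0.7 else ["hA"])
            for i in range(300)}
    w1 = fractionation_profile(_ref(300), omap, window=50)
    relabel = {f"g{i}": f"x{i}" for i in range(300)}
    w2 = fractionation_profile([(relabel[g], s) for g, s in _ref(300)],
                               {relabel[g]: v for g, v in omap.items()},
                               window=50)
    assert [(w.retention_1, w.retention_2) for w in w1] == \
        [(w.retention_1, w.retention_2) for w in w2]


def _windows_from_losses(p_loss_1, p_loss_2, n_windows, seed, per=50):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_windows):
        r1 = 100.0 * (per - rng.binomial(per, p_loss_1)) / per
        r2 = 100.0 * (per - rng.binomial(per, p_loss_2)) / per
        out.append(FractionationWindow("ref", i, per, "hA", "hB", r1, r2))
    return out


def _binomial_two_sided(pos, n):
    """Independent exact binomial oracle: two-sided tail sum at p=1/2."""
    pmf = [math.comb(n, k) / 2 ** n for k in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[pos] + 1e-12)


def test_symmetric_loss_not_flagged_and_matches_binomial_oracle():
    w = _windows_from_losses(0.2, 0.2, 50, seed=20)
    p, m1, m2 = fractionation_bias_test(w)
    assert p > 0.05
    d = [x.retention_1 - x.retention_2 for x in w]
    pos, neg = sum(x > 0 for x in d), sum(x < 0 for x in d)
    assert p == pytest.approx(_binomial_two_sided(pos, pos + neg), abs=1e-9)


def test_biased_loss_rejected():
    w = _windows_from_losses(0.05, 0.35, 50, seed=22)
    p, m1, m2 = fractionation_bias_test(w)
    assert p < 0.01
    assert m1 > m2


def test_identical_retention_gives_p_one():
    w = [FractionationWindow("ref", i, 50, "hA", "hB", 80.0, 80.0)
         for i in range(10)]
    assert fractionation_bias_test(w)[0] == 1.0


def test_too_few_windows_rejected():
    with pytest.raises(ValueError):
        fractionation_bias_test(_windows_from_losses(0.2, 0.2, 3, seed=1))


def test_simulated_biased_fractionation_detected(sim_biased):
    """loss_bias=0.9 separates the homoeolog retention curves."""
    res = sim_biased
    anc = res.truth.ancestor_of
    omap: dict[str, list[str]] = {}
    scaf_of = {g.gene_id: g.scaffold for g in res.genes["ingA"]}
    by_anc: dict[str, set] = {}
    for g in res.genes["ingA"]:
        by_anc.setdefault(anc[g.gene_id], set()).add(scaf_of[g.gene_id])
    for g in res.genes["out1"]:
        omap[g.gene_id] = sorted(by_anc.get(anc[g.gene_id], ()))
    ref = [(g.gene_id, g.scaffold) for g in res.genes["out1"]]
    windows = fractionation_profile(ref, omap, window=20)
    p, m1, m2 = fractionation_bias_test(windows)
    assert p < 0.01
    assert abs(m1 - m2) > 10


# ---------------------------------------------------------------------------
# GO enrichment

def _hypergeom_tail(count, M, total, n_draw):
    """Brute-force P(X >= count) by summation of the hypergeometric pmf."""
    tail = 0.0
    for k in range(count, min(total, n_draw) + 1):
        tail += (math.comb(total, k) * math.comb(M - total, n_draw - k)
                 / math.comb(M, n_draw))
    return tail


def test_proportional_term_not_enriched():
    universe = {f"g{i}" for i in range(1000)}
    group = {f"g{i}" for i in range(100)}
    g2g = {f"g{i}": {"GO:1"} for i in range(0, 1000, 10)}  # 10% everywhere
    df = go_enrichment(group, universe, g2g)
    assert df.iloc[0].p_value >= 0.5


def test_group_equal_universe_gives_p_one():
    universe = {f"g{i}" for i in range(50)}
    g2g = {f"g{i}": {"GO:1"} for i in range(20)}
    df = go_enrichment(set(universe), universe, g2g)
    assert (df.p_value == 1.0).all()
    assert df.iloc[0].expected == df.iloc[0].total


def test_p_value_matches_brute_force_tail_sum():
    """Constructed 2x2 table: 8 term genes in a group of 50, 12 in the
    remaining 950."""
    universe = {f"g{i}" for i in range(1000)}
    group = {f"g{i}" for i in range(50)}
    term = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(900, 912)}
    df = go_enrichment(group, universe, {g: {"GO:X"} for g in term})
    expected_p = _hypergeom_tail(8, 1000, 20, 50)
    assert df.iloc[0].p_value == pytest.approx(expected_p, rel=1e-9)
    assert df.iloc[0].expected == pytest.approx(20 * 50 / 1000)


def test_empty_group_and_foreign_genes_rejected():
    with pytest.raises(ValueError):
        go_enrichment(set(), {"a"}, {"a": {"GO:1"}})
    with pytest.raises(ValueError):
        go_enrichment({"z"}, {"a"}, {"a": {"GO:1"}})
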