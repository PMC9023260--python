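"""KS comparisons, GAAA binning, and hypergeometric overlap statistics."""

import logging
import math

import numpy as np
import pytest
from scipy import stats

from aremotif import (
    bin_gaaa,
    compare_categories,
    ks_statistic,
    ks_two_sample,
    overlap_test,
)


def brute_force_ks_d(x, y):
    """Max ECDF gap evaluated at every pooled value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return max(
        abs(np.mean(x <= v) - np.mean(y <= v)) for v in np.concatenate([x, y])
    )


def hypergeom_tail_by_enumeration(k, N, n, m):
    """P(overlap >= k) by direct summation of the hypergeometric pmf."""
    denom = math.comb(N, m)
    lo, hi = max(0, n + m - N), min(n, m)
    return sum(
        math.comb(n, j) * math.comb(N - n, m - j) for j in range(max(k, lo), hi + 1)
    ) / denom


# ------------------------------------------------------------------------- KS


def test_identical_samples_give_zero_statistic_unit_p():
    for method in ("asymptotic", "permutation"):
        res = ks_two_sample([1, 2, 3], [1, 2, 3], method=method, seed=0)
        assert res.D == 0.0
        assert res.p_value == 1.0


def test_fully_separated_pairs_exact_permutation_p():
    res = ks_two_sample([0, 1], [2, 3], method="permutation", seed=0)
    assert res.D == 1.0
    assert res.p_value == pytest.approx(2 / 6)  # 2 of the C(4,2)=6 splits reach D=1


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


def test_ks_statistic_matches_brute_force_on_small_samples():
    rng = np.random.default_rng(7)
    for _ in range(400):
        n1, n2 = rng.integers(1, 9, size=2)
        if rng.random() < 0.5:  # heavy ties
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
        else:
            x, y = rng.normal(size=n1), rng.normal(size=n2)
        assert ks_statistic(x, y) == pytest.approx(brute_force_ks_d(x, y))


def test_ks_statistic_agrees_with_scipy():
    rng = np.random.default_rng(11)
    for _ in range(100):
        x = rng.poisson(2.0, rng.integers(5, 60))
        y = rng.poisson(2.5, rng.integers(5, 60))
        assert ks_statistic(x, y) == pytest.approx(
            stats.ks_2samp(x, y, method="asymp").statistic
        )


def test_asymptotic_p_calibration_on_continuous_null():
    """Same-distribution pairs reject at about the nominal 5% rate."""
    rng = np.random.default_rng(123)
    n_rep, n = 2000, 500
    rejections = sum(
        ks_two_sample(rng.normal(size=n), rng.normal(size=n)).p_value < 0.05
        for _ in range(n_rep)
    )
    rate = rejections / n_rep
    se = math.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < 3 * se


# ------------------------------------------------------------------ category


def _as_mapping(values_by_cat):
    censuses, categories = {}, {}
    i = 0
    for cat, values in values_by_cat.items():
        for v in values:
            gene = f"g{i}"
            censuses[gene] = {"n": float(v)}
            categories[gene] = cat
            i += 1
    return censuses, categories


def test_compare_categories_symmetric_under_label_swap():
    rng = np.random.default_rng(5)
    a, b = rng.poisson(1.0, 50), rng.poisson(1.0, 50)
    cen1, cat1 = _as_mapping({"up": a, "unchanged": b})
    cen2, cat2 = _as_mapping({"up": b, "unchanged": a})
    d1 = compare_categories(cen1, cat1, "n").tests[("up", "unchanged")].D
    d2 = compare_categories(cen2, cat2, "n").tests[("up", "unchanged")].D
    assert d1 == pytest.approx(d2)


def test_compare_categories_reports_missing_pairs_without_raising():
    censuses, categories = _as_mapping({"up": [1, 2], "unchanged": [1, 1, 2]})
    report = compare_categories(censuses, categories, "n")
    assert report.tests[("up", "unchanged")] is not None
    assert report.tests[("down", "unchanged")] is None
    assert ("down", "unchanged") in report.missing
    assert report.summaries["up"].n == 2


def test_compare_categories_drops_excluded_genes():
    censuses, categories = _as_mapping({"up": [1], "unchanged": [2, 3]})
    censuses["low"] = {"n": 99.0}
    categories["low"] = "excluded"
    report = compare_categories(censuses, categories, "n")
    assert report.summaries["unchanged"].n == 2


def test_shifted_category_detected_in_nearly_all_replicates():
    """A +2 motif shift at 300 genes/side is essentially always significant."""
    rng = np.random.default_rng(99)
    hits = 0
    for _ in range(100):
        up = rng.poisson(1.0, 300) + 2
        unchanged = rng.poisson(1.0, 300)
        cen, cat = _as_mapping({"up": up, "unchanged": unchanged})
        p = compare_categories(cen, cat, "n").tests[("up", "unchanged")].p_value
        hits += p < 0.05
    assert hits >= 99


# ------------------------------------------------------------------- binning


def test_bin_gaaa_edges_are_left_open_right_closed():
    cen, cat = _as_mapping({"up": [5, 10, 11, 31]})
    summary = bin_gaaa(cen, cat, field="n")["up"]
    assert summary.counts == (0, 2, 1, 0, 1)  # 10 falls in (0,10]
    assert summary.fraction_gt_10 == pytest.approx(0.5)
    assert summary.fraction_with_motif == 1.0
    assert sum(summary.counts) == summary.n == 4


def test_bin_gaaa_all_zero_counts():
    cen, cat = _as_mapping({"down": [0, 0, 0]})
    summary = bin_gaaa(cen, cat, field="n")["down"]
    assert summary.counts == (3, 0, 0, 0, 0)
    assert summary.fraction_with_motif == 0.0


def test_bin_gaaa_empty_category_flagged_missing():
    cen, cat = _as_mapping({"up": [1, 2]})
    bins = bin_gaaa(cen, cat, field="n")
    assert bins["down"].missing
    assert bins["down"].counts == (0, 0, 0, 0, 0)
    assert not bins["up"].missing


# ------------------------------------------------------------------- overlap


def test_full_overlap_has_unit_fold():
    universe = [f"g{i}" for i in range(20)]
    res = overlap_test(universe, universe, universe)
    assert (res.k, res.fold) == (20, 1.0)
    assert res.p_exact == 1.0


def test_overlap_small_worked_example():
    universe = list("abcdefghij")
    res = overlap_test(list("abcde"), list("abcde"), universe)
    assert res.expected == pytest.approx(2.5)
    assert res.fold == pytest.approx(2.0)
    assert res.p_exact == pytest.approx(1 / 252)


def test_overlap_exact_tail_matches_enumeration_grid():
    rng = np.random.default_rng(3)
    for N in (6, 11, 23, 37, 48, 60):
        universe = [f"g{i}" for i in range(N)]
        for _ in range(5):
            n, m = rng.integers(1, N + 1, size=2)
            a = list(rng.choice(universe, n, replace=False))
            b = list(rng.choice(universe, m, replace=False))
            res = overlap_test(a, b, universe)
            assert res.p_exact == pytest.approx(
                hypergeom_tail_by_enumeration(res.k, N, n, m)
            )


def test_hypergeometric_pmf_sums_to_one_up_to_N60():
    """The enumeration oracle's pmf is a proper distribution for all N <= 60."""
    for N in range(1, 61):
        for n in {0, 1, N // 3, N // 2, N}:
            for m in {0, 1, N // 2, N}:
                assert hypergeom_tail_by_enumeration(0, N, n, m) == pytest.approx(1.0)


def test_normal_approximation_close_to_exact_for_large_universe():
    """Within its regime (expected overlap of tens or more) the continuity-
    corrected normal tail tracks the exact hypergeometric tail, and the
    agreement tightens as the universe grows at fixed list proportions."""
    N = 10_000
    for n, m in ((500, 1000), (1000, 1000), (2000, 3000)):
        expected = n * m / N
        sd = math.sqrt(n * m * (N - n) * (N - m) / (N**2 * (N - 1)))
        for k in {int(expected), int(expected + sd), int(expected + 3 * sd)}:
            universe = [f"g{i}" for i in range(N)]
            a = universe[:n]
            b = universe[: k] + universe[n: n + m - k]  # overlap exactly k
            res = overlap_test(a, b, universe)
            assert res.k == k
            assert abs(res.p_normal - res.p_exact) < 0.01

    def worst_gap(N):
        n = m = N // 10
        universe = [f"g{i}" for i in range(N)]
        gaps = []
        for k in (n * m // N, n * m // N + 2):
            b = universe[: k] + universe[n: n + m - k]
            res = overlap_test(universe[:n], b, universe)
            gaps.append(abs(res.p_normal - res.p_exact))
        return max(gaps)

    assert worst_gap(20_000) < worst_gap(2_000) < worst_gap(200)


def test_overlap_drops_foreign_ids_with_warning(caplog):
    universe = ["a", "b", "c"]
    with caplog.at_level(logging.WARNING, logger="aremotif"):
        res = overlap_test(["a", "zzz"], ["a", "b"], universe)
    assert res.n == 1 and res.k == 1
    assert any("dropping" in rec.message for rec in caplog.records)


def test_overlap_empty_universe_rejected():
    with pytest.raises(ValueError):
        overlap_test(["a"], ["a"], [])
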