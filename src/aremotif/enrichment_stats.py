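"""Distribution comparisons, GAAA binning, and gene-list overlap tests.

These are the statistics behind the category-wise motif analyses: two-sample
Kolmogorov-Smirnov comparisons of per-gene motif counts (or scores) between
the up/down/unchanged DE categories, five-bin GAAA summaries, and a
hypergeometric test of overlap between two gene lists drawn from a shared
universe.

Motif counts are discrete, so the KS samples carry heavy ties; the classic
asymptotic p (Kolmogorov distribution with effective size n1*n2/(n1+n2)) is
kept as the default to mirror standard practice, while a seeded permutation
mode is provided as the statistically safer choice for tied data. The two
are worth reporting together whenever they disagree by more than a factor of
two. No multiple-testing correction is applied across the three pairwise
comparisons; the raw p-values are reported as such.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special, stats

logger = logging.getLogger("aremotif")

#: The three pairwise category comparisons, in reporting order.
CATEGORY_PAIRS = (("up", "unchanged"), ("down", "unchanged"), ("up", "down"))

#: GAAA bin upper edges; bins are {0}, (0,10], (10,20], (20,30], (30, inf).
GAAA_BIN_EDGES = (0, 10, 20, 30)
GAAA_BIN_LABELS = ("0", "(0,10]", "(10,20]", "(20,30]", ">30")


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    n1: int
    n2: int
    method: str


@dataclass(frozen=True)
class CategorySummary:
    n: int
    mean: float
    median: float


@dataclass(frozen=True)
class ComparisonReport:
    """Pairwise KS tests of one census field across DE categories."""

    field: str
    summaries: dict[str, CategorySummary]
    tests: dict[tuple[str, str], KSResult | None]
    missing: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class BinSummary:
    """Five-bin occupancy of a count field within one DE category."""

    category: str
    bin_edges: tuple[int, ...]
    bin_labels: tuple[str, ...]
    counts: tuple[int, ...]
    fraction_gt_10: float
    fraction_with_motif: float
    n: int
    missing: bool


@dataclass(frozen=True)
class OverlapResult:
    k: int
    n: int
    m: int
    N: int
    expected: float
    fold: float
    p_normal: float
    p_exact: float


# ---------------------------------------------------------------------------
# Two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def _d_from_label_matrix(
    labels: np.ndarray, n1: int, n2: int, eval_mask: np.ndarray
) -> np.ndarray:
    """KS D for each row of an x-membership matrix over sorted pooled values.

    ``labels[r, i]`` says whether the i-th smallest pooled value belongs to x
    in permutation r; ``eval_mask`` marks the last index of each tie group,
    the only positions where the ECDF gap is well defined.
    """
    cum_x = np.cumsum(labels, axis=1)
    positions = np.arange(1, labels.shape[1] + 1)
    gaps = np.abs(cum_x / n1 - (positions - cum_x) / n2)
    return gaps[:, eval_mask].max(axis=1)


def ks_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """sup over all values of |ECDF_x - ECDF_y| (ties handled exactly)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pool = np.concatenate([x, y])
    order = np.argsort(pool, kind="stable")
    v = pool[order]
    eval_mask = np.r_[v[1:] != v[:-1], True]
    labels = (order < len(x))[None, :]
    return float(_d_from_label_matrix(labels, len(x), len(y), eval_mask)[0])


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "asymptotic",
    n_perm: int = 10000,
    seed: int | None = None,
) -> KSResult:
    """Two-sample KS test.

    ``asymptotic`` evaluates the Kolmogorov distribution at
    ``sqrt(n1*n2/(n1+n2)) * D``. ``permutation`` enumerates every label
    split exactly when there are at most ``n_perm`` of them (the p-value is
    then exact, e.g. 2/6 for fully separated samples of size two); otherwise
    it draws ``n_perm`` seeded random splits and reports the add-one
    estimate ``(1 + #{D* >= D}) / (1 + n_perm)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("asymptotic", "permutation"):
        raise ValueError(f"unknown method {method!r}")

    pool = np.concatenate([x, y])
    n = n1 + n2
    order = np.argsort(pool, kind="stable")
    v = pool[order]
    eval_mask = np.r_[v[1:] != v[:-1], True]
    obs_labels = (order < n1)[None, :]
    d = float(_d_from_label_matrix(obs_labels, n1, n2, eval_mask)[0])

    if method == "asymptotic":
        n_eff = n1 * n2 / (n1 + n2)
        p = float(special.kolmogorov(math.sqrt(n_eff) * d))
        p = min(1.0, max(0.0, p))
        return KSResult(d, p, n1, n2, "asymptotic")

    tol = 1e-12
    total_splits = math.comb(n, n1)
    if total_splits <= n_perm:
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
            dtype=np.intp,
        ).reshape(total_splits, n1)
        labels = np.zeros((total_splits, n), dtype=bool)
        np.put_along_axis(labels, combos, True, axis=1)
        d_perm = _d_from_label_matrix(labels, n1, n2, eval_mask)
        p = float(np.count_nonzero(d_perm >= d - tol) / total_splits)
    else:
        rng = np.random.default_rng(seed)
        base = np.zeros(n, dtype=bool)
        base[:n1] = True
        exceed = 0
        block = max(1, int(2e7) // n)
        done = 0
        while done < n_perm:
            m = min(block, n_perm - done)
            labels = np.tile(base, (m, 1))
            labels = rng.permuted(labels, axis=1)
            d_perm = _d_from_label_matrix(labels, n1, n2, eval_mask)
            exceed += int(np.count_nonzero(d_perm >= d - tol))
            done += m
        p = (1 + exceed) / (1 + n_perm)
    return KSResult(d, p, n1, n2, "permutation")


# ---------------------------------------------------------------------------
# Category-wise comparisons
# ---------------------------------------------------------------------------

def _field_value(obj, field: str) -> float:
    if hasattr(obj, field):
        return float(getattr(obj, field))
    try:
        return float(obj[field])
    except (TypeError, KeyError, IndexError):
        if isinstance(obj, (int, float)):
            return float(obj)
        raise ValueError(f"cannot extract field {field!r} from {obj!r}") from None


def compare_categories(
    censuses: Mapping[str, object],
    categories: Mapping[str, str],
    field: str,
    method: str = "asymptotic",
    n_perm: int = 10000,
    seed: int | None = None,
) -> ComparisonReport:
    """Pairwise KS comparison of one field across up/down/unchanged genes.

    ``censuses`` maps gene id to an object carrying ``field`` (a census, a
    score result, a mapping, or a bare number); ``categories`` maps gene id
    to its DE category. Genes categorised ``excluded`` or missing from
    either mapping are dropped. An empty category yields a missing
    comparison, not an exception.
    """
    values: dict[str, list[float]] = {"up": [], "down": [], "unchanged": []}
    for gene, cat in categories.items():
        if cat not in values or gene not in censuses:
            continue
        values[cat].append(_field_value(censuses[gene], field))

    summaries = {
        cat: CategorySummary(
            n=len(vals),
            mean=float(np.mean(vals)) if vals else float("nan"),
            median=float(np.median(vals)) if vals else float("nan"),
        )
        for cat, vals in values.items()
    }
    tests: dict[tuple[str, str], KSResult | None] = {}
    missing = []
    for pair in CATEGORY_PAIRS:
        a, b = pair
        if not values[a] or not values[b]:
            tests[pair] = None
            missing.append(pair)
            continue
        tests[pair] = ks_two_sample(
            values[a], values[b], method=method, n_perm=n_perm, seed=seed
        )
    return ComparisonReport(field, summaries, tests, tuple(missing))


def bin_counts(value: float) -> int:
    """Index of the five-bin GAAA category for one count value."""
    if value <= 0:
        return 0
    for i, edge in enumerate(GAAA_BIN_EDGES[1:], start=1):
        if value <= edge:
            return i
    return len(GAAA_BIN_EDGES)


def bin_gaaa(
    censuses: Mapping[str, object],
    categories: Mapping[str, str],
    field: str = "n_GAAA",
) -> dict[str, BinSummary]:
    """Five-bin summaries of a count field per DE category.

    Bins are {0}, (0,10], (10,20], (20,30], (30, inf): left-open,
    right-closed, so a count of exactly 10 falls in (0,10].
    ``fraction_gt_10`` is the share of genes with count > 10 and
    ``fraction_with_motif`` the share with at least one occurrence.
    """
    out = {}
    for cat in ("up", "down", "unchanged"):
        vals = [
            _field_value(censuses[g], field)
            for g, c in categories.items()
            if c == cat and g in censuses
        ]
        counts = [0] * (len(GAAA_BIN_EDGES) + 1)
        for v in vals:
            counts[bin_counts(v)] += 1
        n = len(vals)
        out[cat] = BinSummary(
            category=cat,
            bin_edges=GAAA_BIN_EDGES,
            bin_labels=GAAA_BIN_LABELS,
            counts=tuple(counts),
            fraction_gt_10=(sum(v > 10 for v in vals) / n) if n else 0.0,
            fraction_with_motif=(sum(v >= 1 for v in vals) / n) if n else 0.0,
            n=n,
            missing=(n == 0),
        )
    return out


# ---------------------------------------------------------------------------
# Gene-list overlap
# ---------------------------------------------------------------------------

def overlap_test(
    list_a: Iterable[str], list_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Hypergeometric test of overlap between two gene lists.

    Ids outside the universe are dropped with a logged warning. Reports the
    observed overlap ``k``, its expectation ``n*m/N``, the fold enrichment
    ``k/expected``, the exact hypergeometric upper tail P(K >= k), and the
    normal approximation with continuity correction (the approximation
    converges to the exact tail as the universe grows).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a, b = set(list_a), set(list_b)
    for name, s in (("list_a", a), ("list_b", b)):
        outside = s - universe
        if outside:
            logger.warning(
                "overlap_test: dropping %d id(s) from %s not in universe",
                len(outside),
                name,
            )
    a &= universe
    b &= universe
    k, n, m, N = len(a & b), len(a), len(b), len(universe)

    expected = n * m / N
    fold = k / expected if expected > 0 else float("nan")
    # scipy's hypergeom(M, n, N) draws N from a population of M with n marked
    p_exact = float(stats.hypergeom.sf(k - 1, N, n, m))
    if N > 1:
        var = n * m * (N - n) * (N - m) / (N * N * (N - 1))
    else:
        var = 0.0
    if var > 0:
        z = (k - 0.5 - expected) / math.sqrt(var)
        p_normal = float(stats.norm.sf(z))
    else:
        p_normal = 1.0  # degenerate draw: overlap is deterministic
    return OverlapResult(k, n, m, N, expected, fold, p_normal, p_exact)
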