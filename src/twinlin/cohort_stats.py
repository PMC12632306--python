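"""Cohort-level contingency and rank statistics, implemented from first principles.

Three procedures cover the category-vs-membrane association analyses:

* exact two-sided Fisher test for 2x2 tables by full hypergeometric
  enumeration over the table range with fixed margins;
* Monte Carlo Fisher test for r x c tables, sampling tables from the
  fixed-margin null by random relabelling and comparing table probabilities;
* Kruskal-Wallis rank test with tie correction and Bonferroni-adjusted
  pairwise follow-ups.

The equivalent scipy routines are used only as independent cross-checks in
the test suite; everything here is self-contained numpy/scipy-special code.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

# relative slack when comparing table probabilities, so that tables whose
# probability ties the observed one (up to float rounding) are included
_REL_EPS = 1e-7


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    B: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    if t.sum() <= 0:
        raise ValueError("table total must be positive")
    return t


def _log_table_prob(tables: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray) -> np.ndarray:
    """Log probability of fixed-margin tables: prod r_i! prod c_j! / (N! prod x_ij!).

    ``tables`` has shape (..., r, c).
    """
    n = row_sums.sum()
    const = gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)
    return const - gammaln(tables + 1).sum(axis=(-2, -1))


def fisher_exact_2x2(table, convention: str = "mass") -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table.

    ``convention`` selects the two-sided rule: ``"mass"`` sums the
    hypergeometric probabilities of all tables (margins fixed) no more
    probable than the observed one; ``"doubled"`` doubles the smaller
    one-sided tail (capped at 1).
    """
    t = _check_table(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    lo = max(0, r[0] - c[1])
    hi = min(r[0], c[0])
    ks = np.arange(lo, hi + 1)
    cand = np.zeros((len(ks), 2, 2), dtype=np.int64)
    cand[:, 0, 0] = ks
    cand[:, 0, 1] = r[0] - ks
    cand[:, 1, 0] = c[0] - ks
    cand[:, 1, 1] = r[1] - (c[0] - ks)
    logp = _log_table_prob(cand, r, c)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = int(t[0, 0]) - lo
    p_obs = probs[obs]
    if convention == "mass":
        p = probs[probs <= p_obs * (1 + _REL_EPS)].sum()
    elif convention == "doubled":
        lower = probs[: obs + 1].sum()
        upper = probs[obs:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown two-sided convention: {convention}")
    odds = np.inf if t[0, 1] * t[1, 0] == 0 else (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return TestResult(float(odds), float(min(1.0, p)), f"fisher_exact_2x2[{convention}]")


def sample_fixed_margin_tables(
    row_sums, col_sums, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``B`` r x c tables from the uniform fixed-margin (hypergeometric) null.

    Uses the relabelling construction: a vector of N column labels (c_j
    copies of label j) is permuted independently per replicate and
    cross-tabulated against the fixed row labels, which yields exactly the
    multivariate hypergeometric distribution of tables with both margins
    fixed.
    """
    row_sums = np.asarray(row_sums, dtype=np.int64)
    col_sums = np.asarray(col_sums, dtype=np.int64)
    n = int(row_sums.sum())
    if n != int(col_sums.sum()):
        raise ValueError("margins disagree on the total")
    r, c = len(row_sums), len(col_sums)
    row_labels = np.repeat(np.arange(r), row_sums)
    col_labels = np.repeat(np.arange(c), col_sums)
    perms = rng.permuted(np.tile(col_labels, (B, 1)), axis=1)
    flat = row_labels[None, :] * c + perms
    counts = np.zeros((B, r * c), dtype=np.int64)
    for cell in range(r * c):
        counts[:, cell] = (flat == cell).sum(axis=1)
    return counts.reshape(B, r, c)


def fisher_montecarlo(table, B: int = 100_000, seed: int = 0) -> TestResult:
    """Monte Carlo Fisher test for an r x c table with both margins fixed.

    The p-value uses the add-one estimator ``(1 + #{P(T*) <= P(T_obs)}) /
    (B + 1)``, which is never exactly zero and remains a valid p-value.
    Zero rows/columns are dropped (with margins recomputed) before testing.
    """
    t = _check_table(table)
    if min(t.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if B < 1000:
        raise ValueError("B must be at least 1000")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if min(t.shape) < 2:
        raise ValueError("table degenerate after dropping empty margins")
    r_sums = t.sum(axis=1)
    c_sums = t.sum(axis=0)
    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(t[None, :, :], r_sums, c_sums)[0]
    hits = 0
    # draw in chunks to bound memory at large B
    chunk = 20_000
    done = 0
    while done < B:
        b = min(chunk, B - done)
        tabs = sample_fixed_margin_tables(r_sums, c_sums, b, rng)
        logp = _log_table_prob(tabs, r_sums, c_sums)
        hits += int((logp <= obs_logp + abs(obs_logp) * _REL_EPS + 1e-12).sum())
        done += b
    p = (1 + hits) / (B + 1)
    return TestResult(float(np.exp(obs_logp)), float(p), "fisher_montecarlo", B=B, seed=seed)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    H = 12/(N(N+1)) * sum_j R_j^2/n_j - 3(N+1), divided by the tie factor
    1 - sum(t^3 - t)/(N^3 - N); p from the chi-square approximation with
    k - 1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1, dtype=float)
    # midranks for ties
    sorted_vals = pooled[order]
    i = 0
    tie_term = 0.0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            tsize = j - i + 1
            ranks[order[i : j + 1]] = (i + 1 + j + 1) / 2.0
            tie_term += tsize**3 - tsize
        i = j + 1
    sizes = np.array([len(g) for g in groups])
    idx = np.cumsum(sizes)[:-1]
    rank_sums = np.array([r.sum() for r in np.split(ranks, idx)])
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / sizes) - 3.0 * (n + 1)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:
        # every observation identical: no evidence of group differences
        return TestResult(0.0, 1.0, "kruskal_wallis[all-ties]")
    h /= denom
    p = float(chi2.sf(h, df=len(groups) - 1))
    return TestResult(float(h), p, "kruskal_wallis")


def kruskal_wallis_bonferroni(groups, pairs=None) -> tuple[TestResult, list[dict]]:
    """Omnibus Kruskal-Wallis plus Bonferroni-adjusted pairwise tests.

    ``pairs`` is a list of index pairs into ``groups``; all pairs by
    default.  Each pairwise comparison is a two-group Kruskal-Wallis
    (equivalent to a two-sided rank-sum test) with adjusted
    p = min(1, m * p).
    """
    omnibus = kruskal_wallis(groups)
    if pairs is None:
        pairs = list(combinations(range(len(groups)), 2))
    m = len(pairs)
    results = []
    for i, j in pairs:
        res = kruskal_wallis([groups[i], groups[j]])
        results.append(
            {
                "pair": (i, j),
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "pvalue_bonferroni": min(1.0, m * res.pvalue),
            }
        )
    return omnibus, results


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment min(1, m * p)."""
    if not 0 <= p <= 1 or m < 1:
        raise ValueError("invalid p or m")
    return min(1.0, m * p)
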