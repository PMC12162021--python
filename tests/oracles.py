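"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive enumeration, textbook
formulas, direct likelihood maximisation. Nothing imports the code paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, stats


def classify_oracle(records, criteria) -> str:
    """Exhaustive check of the four switching criteria over every
    (index SSRI, other prescription) pair.

    ``records`` is any iterable of (day:int, drug:str, drug_class:str);
    order-independent, duplicates on (day, drug) collapse.
    """
    recs = sorted({(int(day), str(drug), str(cls)) for day, drug, cls in records})
    ssris = sorted({d for _, d, c in recs if c == "SSRI"})
    for s in ssris:
        s_days = sorted(day for day, d, _ in recs if d == s)
        d0 = s_days[0]
        for day, d, c in recs:
            if d == s or c == "NON_AD":
                continue
            gap = day - d0
            if not (criteria.min_gap_days <= gap <= criteria.max_gap_days):
                continue
            total = len(s_days)
            before = sum(x < day for x in s_days)
            after = sum(x > day for x in s_days)
            if (
                total <= criteria.max_index_rx_total
                and before <= criteria.max_index_rx_before
                and after <= criteria.max_index_rx_after
            ):
                return "SWITCHER"
    for s in ssris:
        if sum(1 for _, d, _ in recs if d == s) >= criteria.min_nonswitcher_rx:
            return "NONSWITCHER"
    return "UNCLASSIFIED"


def chi2_oracle(table) -> tuple[float, float]:
    """Pearson chi-square from first principles (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row @ col / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, dof))


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sv = values[order]
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks

def ranksum_oracle(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum z statistic via the normal approximation (no tie or
    continuity correction), two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    allv = np.concatenate([x, y])
    ranks = _midranks(allv)
    r1 = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (r1 - mu) / sd
    return float(z), float(2 * stats.norm.sf(abs(z)))


def kruskal_oracle(*groups) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction, from the rank-sum formula."""
    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    n = len(allv)
    ranks = _midranks(allv)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + len(g)].sum()
        h += r * r / len(g)
        i += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(allv, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    h /= tie
    return float(h), float(stats.chi2.sf(h, len(groups) - 1))


def logit_loglik_oracle(y, X) -> float:
    """Maximised Bernoulli log-likelihood by direct numerical optimisation."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)

    def nll(beta):
        eta = X @ beta
        return -(y * eta - np.logaddexp(0.0, eta)).sum()

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        return -X.T @ (y - p)

    res = optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    return -float(res.fun)


def max_retention_oracle(ids, related_pairs) -> int:
    """Largest pair-free retained set by exhaustive subset search (<=~15 nodes)."""
    ids = sorted(set(ids))
    edges = {frozenset(p) for p in related_pairs}
    nodes = sorted({v for e in edges for v in e})
    free = [v for v in ids if v not in nodes]
    best = 0
    for r in range(len(nodes), -1, -1):
        for subset in itertools.combinations(nodes, r):
            ss = set(subset)
            if all(not e <= ss for e in edges):
                best = r
                break
        if best:
            break
    return len(free) + best
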