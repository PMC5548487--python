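"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written along a different path from the
implementation under test: scipy's contingency routine instead of the
explicit cell formula, statsmodels' multiple-testing code instead of the
hand-rolled step-down, a full-matrix edit-distance DP, exhaustive k-medoids
search, quadratic all-pairs duplicate detection, and numerical integration
of the gamma-mixture posterior.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
from scipy import integrate, special, stats
from statsmodels.stats.multitest import multipletests


def yates_p_oracle(n11: int, row: int, col: int, total: int) -> float:
    """Yates-corrected chi-square p via scipy.stats.chi2_contingency."""
    obs = np.array(
        [[n11, row - n11], [col - n11, total - row - col + n11]], dtype=float
    )
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (exp == 0).any():
        return 1.0
    return float(stats.chi2_contingency(obs, correction=True).pvalue)


def holm_oracle(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values via statsmodels."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def edit_distance_oracle(a: str, b: str) -> int:
    """Full-matrix Wagner-Fischer DP."""
    m, n = len(a), len(b)
    d = np.zeros((m + 1, n + 1), dtype=int)
    d[:, 0] = np.arange(m + 1)
    d[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i, j] = min(
                d[i - 1, j] + 1,
                d[i, j - 1] + 1,
                d[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(d[m, n])


_TOKEN_ORACLE_RE = re.compile(r"[a-z0-9]+")


def tokenize_oracle(raw: str, stopwords) -> frozenset[str]:
    """Regex-based tokenization oracle.

    The implementation deletes punctuation in place (so ``flu-oxetine``
    stays one token); this oracle reproduces that by stripping non-alnum,
    non-space characters before the token scan.
    """
    cleaned = re.sub(r"[^a-z0-9\s]", "", raw.casefold())
    return frozenset(
        t for t in _TOKEN_ORACLE_RE.findall(cleaned) if t not in set(stopwords)
    )


def all_pairs_duplicates(corpus, fingerprint) -> list[frozenset[str]]:
    """O(n^2) duplicate grouping by pairwise fingerprint comparison."""
    reports = corpus.reports
    n = len(reports)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    fps = [fingerprint(r) for r in reports]
    for i in range(n):
        for j in range(i + 1, n):
            if fps[i] == fps[j]:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(reports[i].report_id)
    return sorted(
        (frozenset(g) for g in groups.values() if len(g) >= 2), key=sorted
    )


def kmedoids_exhaustive_objective(dist: np.ndarray, k: int) -> float:
    """Optimal k-medoids objective by exhaustive medoid enumeration."""
    n = dist.shape[0]
    best = np.inf
    for meds in itertools.combinations(range(n), k):
        best = min(best, float(dist[:, list(meds)].min(axis=1).sum()))
    return best


def posterior_ebgm_quadrature(N: int, E: float, prior) -> float:
    """EBGM by numerical integration of the two-gamma posterior.

    Posterior density ∝ w_k' Gamma(lambda; alpha_k + N, rate beta_k + E);
    EBGM = exp(∫ ln(lambda) posterior(lambda) dlambda).
    """

    def nb_logpmf(n, alpha, beta, e):
        return (
            special.gammaln(alpha + n)
            - special.gammaln(alpha)
            - special.gammaln(n + 1.0)
            + alpha * (np.log(beta) - np.log(beta + e))
            + n * (np.log(e) - np.log(beta + e))
        )

    lw = np.array(
        [
            np.log(prior.w) + nb_logpmf(N, prior.alpha1, prior.beta1, E),
            np.log(1 - prior.w) + nb_logpmf(N, prior.alpha2, prior.beta2, E),
        ]
    )
    w = np.exp(lw - special.logsumexp(lw))
    a = np.array([prior.alpha1 + N, prior.alpha2 + N])
    b = np.array([prior.beta1 + E, prior.beta2 + E])

    def integrand(lam):
        dens = sum(w[k] * stats.gamma.pdf(lam, a=a[k], scale=1 / b[k]) for k in range(2))
        return np.log(lam) * dens

    hi = float(max(stats.gamma.ppf(1 - 1e-12, a=a, scale=1 / b)))
    val, _ = integrate.quad(integrand, 0, hi, limit=200)
    return float(np.exp(val))
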