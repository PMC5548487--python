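"""Ingredient–ADR disproportionality statistics.

For each (ingredient, ADR) pair a 2x2 table is formed by report-level
counting: N observed co-reports, E = R*C/T expected under independence, the
relative reporting ratio RRR = N/E, a Yates-corrected chi-square p-value, and
Holm step-down adjusted q-values over the full family of tested pairs.  The
signal filter keeps pairs with N >= 5, q < 0.05 and RRR > 1.  Empirical-Bayes
shrinkage fits a two-component gamma mixture prior to the whole array of
(N, E) pairs and reports EBGM with a 90% posterior interval (EB05, EB95).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .model import Corpus

MIN_N_DEFAULT = 5
Q_MAX_DEFAULT = 0.05
RRR_MIN_DEFAULT = 1.0

#: age bands (upper-edge exclusive) for the default stratification
DEFAULT_AGE_BANDS = ((0.0, 18.0), (18.0, 45.0), (45.0, 65.0), (65.0, float("inf")))


@dataclass(frozen=True)
class ContingencyTable:
    """Margins of one ingredient–ADR 2x2 table (report-level counts)."""

    n11: int
    row_total: int
    col_total: int
    grand_total: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.n11 <= min(self.row_total, self.col_total)
            and max(self.row_total, self.col_total) <= self.grand_total
        )
        if not ok:
            raise ValueError(f"inconsistent margins: {self}")

    @property
    def expected(self) -> float:
        if self.grand_total == 0:
            return 0.0
        return self.row_total * self.col_total / self.grand_total

    def cells(self) -> np.ndarray:
        n11, r, c, t = self.n11, self.row_total, self.col_total, self.grand_total
        return np.array([[n11, r - n11], [c - n11, t - r - c + n11]], dtype=float)


@dataclass
class SignalResult:
    ingredient_key: str
    adr_pt: str
    N: int
    E: float
    RRR: float
    p: float
    q: float
    passes_filter: bool
    EBGM: Optional[float] = None
    EB05: Optional[float] = None
    EB95: Optional[float] = None


@dataclass(frozen=True)
class EBPrior:
    """Two-component gamma mixture prior on the true reporting ratio."""

    w: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError("w must lie in [0, 1]")
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be positive")


# ---------------------------------------------------------------------------
# corpus -> report-level incidence frames
# ---------------------------------------------------------------------------


def _require_mapped(corpus: Corpus) -> None:
    for r in corpus.reports:
        for d in r.drugs:
            if d.mapping_score is None and not d.ingredient_keys:
                raise ValueError(
                    "corpus has unmapped drug entries; run ingredient mapping "
                    "(map_corpus) before computing signals"
                )
            break
        break


def incidence_frames(corpus: Corpus, role_filter: str = "PS"):
    """Report-level (report, ingredient) and (report, PT) incidence.

    ``role_filter`` is ``"PS"`` (default), ``"PS+SS"`` or ``"ALL"``.  A report
    counts once per ingredient it mentions under an allowed role, and once
    per distinct PT, regardless of within-report multiplicity.
    """
    allowed = {"PS": {"PS"}, "PS+SS": {"PS", "SS"}, "ALL": {"PS", "SS", "C", "I"}}[role_filter]
    drug_rows = [
        (r.report_id, k)
        for r in corpus.reports
        for d in r.drugs
        if d.role in allowed
        for k in d.ingredient_keys
    ]
    adr_rows = [(r.report_id, pt) for r in corpus.reports for pt in r.reactions]
    drugs = pd.DataFrame(drug_rows, columns=["report_id", "ingredient"]).drop_duplicates()
    adrs = pd.DataFrame(adr_rows, columns=["report_id", "adr"]).drop_duplicates()
    return drugs, adrs, len(corpus.reports)


def pair_count_frame(corpus: Corpus, role_filter: str = "PS") -> pd.DataFrame:
    """All (ingredient, adr) pairs with N >= 1, with margins R, C, T.

    This is the counting backbone shared by the global and the monthly
    analyses.
    """
    _require_mapped(corpus)
    drugs, adrs, total = incidence_frames(corpus, role_filter)
    if drugs.empty or adrs.empty:
        return pd.DataFrame(columns=["ingredient", "adr", "N", "R", "C", "T"])
    r_margin = drugs.groupby("ingredient").size().rename("R")
    c_margin = adrs.groupby("adr").size().rename("C")
    joint = (
        drugs.merge(adrs, on="report_id")
        .groupby(["ingredient", "adr"])
        .size()
        .rename("N")
        .reset_index()
    )
    joint = joint.merge(r_margin, on="ingredient").merge(c_margin, on="adr")
    joint["T"] = total
    return joint


def build_contingency(
    corpus: Corpus, ingredient: str, adr: str, role_filter: str = "PS"
) -> ContingencyTable:
    """The 2x2 margins for one pair (report-level counting)."""
    _require_mapped(corpus)
    drugs, adrs, total = incidence_frames(corpus, role_filter)
    with_i = set(drugs.loc[drugs["ingredient"] == ingredient, "report_id"]) if not drugs.empty else set()
    with_a = set(adrs.loc[adrs["adr"] == adr, "report_id"]) if not adrs.empty else set()
    return ContingencyTable(
        n11=len(with_i & with_a),
        row_total=len(with_i),
        col_total=len(with_a),
        grand_total=total,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def rrr(table: ContingencyTable) -> float:
    """Relative reporting ratio N/E; 0 when N = 0."""
    if table.n11 == 0:
        return 0.0
    e = table.expected
    if e == 0:
        raise ValueError("N > 0 with E = 0 violates the margins invariant")
    return table.n11 / e


def _yates_p_vec(n11, row, col, total):
    """Vectorized Yates-corrected chi-square p (1 df) from 2x2 margins.

    chi2 = sum over cells of (max(|O - E| - 0.5, 0))^2 / E.  Any zero
    expected cell yields p = 1 (degenerate table).
    """
    n11 = np.asarray(n11, dtype=float)
    row = np.asarray(row, dtype=float)
    col = np.asarray(col, dtype=float)
    total = np.asarray(total, dtype=float)
    obs = np.stack([n11, row - n11, col - n11, total - row - col + n11])
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = (
            np.stack([row * col, row * (total - col), (total - row) * col,
                      (total - row) * (total - col)])
            / total
        )
        corrected = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
        chi2 = np.where(exp > 0, corrected**2 / np.where(exp > 0, exp, 1.0), np.nan).sum(axis=0)
    degenerate = (exp <= 0).any(axis=0) | ~np.isfinite(chi2)
    p = np.where(degenerate, 1.0, stats.chi2.sf(np.where(degenerate, 0.0, chi2), df=1))
    return p


def yates_chi2_p(table: ContingencyTable) -> float:
    """Yates-corrected chi-square p-value for one 2x2 table."""
    return float(_yates_p_vec([table.n11], [table.row_total], [table.col_total], [table.grand_total])[0])


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted values, in the input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out


def detect_signals(
    corpus: Corpus,
    min_n: int = MIN_N_DEFAULT,
    q_max: float = Q_MAX_DEFAULT,
    rrr_min: float = RRR_MIN_DEFAULT,
    role_filter: str = "PS",
    with_eb: bool = False,
    eb_seed: int = 0,
) -> list[SignalResult]:
    """Score every observed (ingredient, PT) pair and apply the signal filter.

    The Holm family is all pairs with N >= 1 in scope.  With ``with_eb`` a
    gamma-mixture prior is fitted to the whole (N, E) array and EBGM/EB05/EB95
    attached to each result.
    """
    if not corpus.reports:
        return []
    frame = pair_count_frame(corpus, role_filter)
    if frame.empty:
        return []
    frame = frame.sort_values(["ingredient", "adr"], kind="stable").reset_index(drop=True)
    e = frame["R"] * frame["C"] / frame["T"]
    ratio = np.where(frame["N"] > 0, frame["N"] / e, 0.0)
    p = _yates_p_vec(frame["N"], frame["R"], frame["C"], frame["T"])
    q = holm_adjust(p)
    passes = (frame["N"] >= min_n) & (q < q_max) & (ratio > rrr_min)

    prior = None
    if with_eb:
        pairs = list(zip(frame["N"].tolist(), e.tolist()))
        prior = fit_eb_prior(pairs, seed=eb_seed)

    results = []
    rows = zip(
        frame["ingredient"].tolist(), frame["adr"].tolist(), frame["N"].tolist(),
        e.tolist(), ratio.tolist(), p.tolist(), q.tolist(), passes.tolist(),
    )
    for ing, adr, n_obs, e_i, rrr_i, p_i, q_i, ok in rows:
        ebgm = eb05 = eb95 = None
        if prior is not None and e_i > 0:
            ebgm, eb05, eb95 = eb_scores(int(n_obs), float(e_i), prior)
        results.append(
            SignalResult(
                ingredient_key=ing, adr_pt=adr, N=int(n_obs), E=float(e_i),
                RRR=float(rrr_i), p=float(p_i), q=float(q_i), passes_filter=bool(ok),
                EBGM=ebgm, EB05=eb05, EB95=eb95,
            )
        )
    return results


def signals_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ingredient": s.ingredient_key,
                "adr": s.adr_pt,
                "N": s.N,
                "E": s.E,
                "RRR": s.RRR,
                "p": s.p,
                "q": s.q,
                "EBGM": s.EBGM,
                "EB05": s.EB05,
                "EB95": s.EB95,
                "passes_filter": s.passes_filter,
            }
            for s in results
        ]
    )


# ---------------------------------------------------------------------------
# stratified expected counts
# ---------------------------------------------------------------------------


def _stratum_label(report, age_bands) -> tuple[str, str]:
    age = report.patient_age
    if age is None:
        band = "missing"
    else:
        band = "missing"
        for lo, hi in age_bands:
            if lo <= age < hi:
                band = f"[{lo},{hi})"
                break
    return band, report.patient_sex


def stratified_expected(
    corpus: Corpus,
    ingredient: str,
    adr: str,
    role_filter: str = "PS",
    age_bands=DEFAULT_AGE_BANDS,
) -> float:
    """Expected count summed over age-band x sex strata: sum_s R_s C_s / T_s.

    Conditions the independence null on demographics; strata with no reports
    contribute 0.
    """
    _require_mapped(corpus)
    allowed = {"PS": {"PS"}, "PS+SS": {"PS", "SS"}, "ALL": {"PS", "SS", "C", "I"}}[role_filter]
    tallies: dict[tuple[str, str], list[int]] = {}
    for r in corpus.reports:
        s = _stratum_label(r, age_bands)
        t = tallies.setdefault(s, [0, 0, 0])
        t[2] += 1
        if any(ingredient in d.ingredient_keys for d in r.drugs if d.role in allowed):
            t[0] += 1
        if adr in r.reactions:
            t[1] += 1
    return sum(rs * cs / ts for rs, cs, ts in tallies.values() if ts > 0)


# ---------------------------------------------------------------------------
# empirical-Bayes gamma-Poisson shrinkage
# ---------------------------------------------------------------------------


def _nb_logpmf(n, alpha, beta, e):
    """log P(N=n) when lambda ~ Gamma(alpha, rate beta) and N ~ Poisson(lambda*E)."""
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    return (
        special.gammaln(alpha + n)
        - special.gammaln(alpha)
        - special.gammaln(n + 1.0)
        + alpha * (np.log(beta) - np.log(beta + e))
        + n * (np.log(e) - np.log(beta + e))
    )


def _mixture_nll(theta, n, e):
    # theta = (logit w, log a1, log b1, log a2, log b2)
    w = special.expit(theta[0])
    a1, b1, a2, b2 = np.exp(theta[1:])
    l1 = _nb_logpmf(n, a1, b1, e) + np.log(max(w, 1e-300))
    l2 = _nb_logpmf(n, a2, b2, e) + np.log(max(1.0 - w, 1e-300))
    return -np.logaddexp(l1, l2).sum()


_PARAM_BOUND = (1e-4, 1e4)


def fit_eb_prior(
    pairs: Sequence[tuple[float, float]], seed: int = 0, n_starts: int = 6
) -> EBPrior:
    """Fit the two-gamma mixture prior by maximizing the marginal likelihood.

    Pairs with E <= 0 are excluded.  Multi-start L-BFGS-B on transformed
    parameters (logit weight, log gamma parameters), parameters bounded to
    [1e-4, 1e4]; the best of ``n_starts`` seeded starts wins.
    """
    arr = np.asarray([(n, e) for n, e in pairs if e > 0], dtype=float)
    if len(arr) < 50:
        raise ValueError(f"need >= 50 pairs with E > 0, got {len(arr)}")
    n, e = arr[:, 0], arr[:, 1]

    rng = np.random.default_rng(seed)
    lo, hi = np.log(_PARAM_BOUND[0]), np.log(_PARAM_BOUND[1])
    bounds = [(-12, 12)] + [(lo, hi)] * 4
    # one informed start near the classic default prior, the rest randomized
    starts = [np.array([1.0, np.log(0.2), np.log(0.1), np.log(2.0), np.log(4.0)])]
    for _ in range(n_starts - 1):
        starts.append(
            np.concatenate(
                [rng.normal(0, 2, size=1), rng.uniform(np.log(0.05), np.log(20.0), size=4)]
            )
        )

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _mixture_nll, x0, args=(n, e), method="L-BFGS-B", bounds=bounds
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("EB prior fit failed to converge from any start")
    w = float(special.expit(best.x[0]))
    a1, b1, a2, b2 = (float(v) for v in np.exp(best.x[1:]))
    return EBPrior(w=w, alpha1=a1, beta1=b1, alpha2=a2, beta2=b2)


def eb_prior_marginal_loglik(prior: EBPrior, pairs: Sequence[tuple[float, float]]) -> float:
    """Marginal log-likelihood of (N, E) pairs under a given prior."""
    arr = np.asarray([(n, e) for n, e in pairs if e > 0], dtype=float)
    theta = np.array(
        [special.logit(min(max(prior.w, 1e-12), 1 - 1e-12))]
        + [np.log(v) for v in (prior.alpha1, prior.beta1, prior.alpha2, prior.beta2)]
    )
    return -_mixture_nll(theta, arr[:, 0], arr[:, 1])


def eb_scores(N: int, E: float, prior: EBPrior) -> tuple[float, float, float]:
    """Posterior EBGM and (EB05, EB95) for one pair under the mixture prior.

    The posterior is again a two-gamma mixture with components
    Gamma(alpha_k + N, rate beta_k + E) and weights proportional to the
    prior-component marginal likelihoods of N.  EBGM = exp(E[ln lambda]);
    the percentiles come from root-finding on the mixture CDF.
    """
    if E <= 0:
        raise ValueError("eb_scores undefined for E <= 0")
    lw1 = np.log(max(prior.w, 1e-300)) + _nb_logpmf(N, prior.alpha1, prior.beta1, E)
    lw2 = np.log(max(1.0 - prior.w, 1e-300)) + _nb_logpmf(N, prior.alpha2, prior.beta2, E)
    norm = np.logaddexp(lw1, lw2)
    w1 = float(np.exp(lw1 - norm))
    w2 = 1.0 - w1
    a = np.array([prior.alpha1 + N, prior.alpha2 + N])
    b = np.array([prior.beta1 + E, prior.beta2 + E])
    weights = np.array([w1, w2])

    ebgm = float(np.exp(np.sum(weights * (special.digamma(a) - np.log(b)))))

    def mixture_cdf(x):
        return float(np.sum(weights * stats.gamma.cdf(x, a=a, scale=1.0 / b)))

    def percentile(prob):
        ppfs = stats.gamma.ppf(prob, a=a, scale=1.0 / b)
        lo, hi = float(min(ppfs)), float(max(ppfs))
        if hi - lo < 1e-12:
            return lo
        # the component ppfs bracket the mixture quantile analytically, but
        # float underflow in the weights can leave f with equal signs at the
        # endpoints; widen until a sign change (or a numerically-zero f) shows
        f_lo, f_hi = mixture_cdf(lo) - prob, mixture_cdf(hi) - prob
        for _ in range(60):
            if abs(f_lo) < 1e-13:
                return lo
            if abs(f_hi) < 1e-13:
                return hi
            if f_lo < 0 < f_hi:
                break
            if f_lo > 0:
                lo *= 0.5
                f_lo = mixture_cdf(lo) - prob
            if f_hi < 0:
                hi *= 2.0
                f_hi = mixture_cdf(hi) - prob
        return float(
            optimize.brentq(lambda x: mixture_cdf(x) - prob, lo, hi, xtol=1e-8, rtol=1e-12)
        )

    return ebgm, percentile(0.05), percentile(0.95)
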