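"""Reporting-bias quantification.

Covers indication/ADR conflation, reporter-occupation composition over
calendar periods, the distribution of the seven report outcomes, a logistic
regression of an ADR on suspect-drug / reporter / era covariates (IRLS fit),
and exposure-margin classification of target-level ADR liability.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import OCCUPATIONS, OUTCOMES, Corpus


@dataclass(frozen=True)
class ConflationRecord:
    """A report whose PS drug lists the same PT as indication and reaction."""

    report_id: str
    ingredient_key: str
    term: str


def _canon(s: str) -> str:
    return " ".join(s.casefold().split())


def find_conflations(corpus: Corpus) -> tuple[list[ConflationRecord], pd.Series]:
    """Reports where a primary-suspect drug's indication reappears verbatim
    (case-insensitively, on standardized PTs) among the report's reactions.

    The comparison is per PS drug against that drug's own indication.  The
    returned series gives, per calendar year, conflated reports divided by
    reports carrying any indication that year.
    """
    records: list[ConflationRecord] = []
    year_conflated: dict[int, int] = {}
    year_with_indication: dict[int, int] = {}
    for r in corpus.reports:
        reactions = {_canon(t) for t in r.reactions}
        has_indication = any(d.indication for d in r.drugs)
        flagged = False
        for d in r.drugs:
            if d.role != "PS" or not d.indication:
                continue
            if _canon(d.indication) in reactions:
                key = next(iter(sorted(d.ingredient_keys)), d.verbatim_name)
                records.append(ConflationRecord(r.report_id, key, d.indication))
                flagged = True
        date = r.analysis_date()
        if date is not None and has_indication:
            year_with_indication[date.year] = year_with_indication.get(date.year, 0) + 1
            if flagged:
                year_conflated[date.year] = year_conflated.get(date.year, 0) + 1
    years = sorted(year_with_indication)
    series = pd.Series(
        [year_conflated.get(y, 0) / year_with_indication[y] for y in years],
        index=pd.Index(years, name="year"),
        name="conflated_fraction",
    )
    return records, series


def reporter_composition(
    corpus: Corpus, period_breaks: Sequence[dt.date]
) -> pd.DataFrame:
    """Occupation fractions per calendar period.

    ``period_breaks`` are the period start dates (sorted); reports dated
    before the first break fall into a leading ``<first`` period.  Rows sum
    to 1; periods with no dated reports are omitted.
    """
    breaks = sorted(period_breaks)
    labels = [f"<{breaks[0].isoformat()}"] + [b.isoformat() for b in breaks]

    counts = {lab: dict.fromkeys(OCCUPATIONS, 0) for lab in labels}
    for r in corpus.reports:
        date = r.analysis_date()
        if date is None:
            continue
        lab = labels[0]
        for b, nxt in zip(breaks, labels[1:]):
            if date >= b:
                lab = nxt
        counts[lab][r.reporter_occupation] += 1
    rows = {
        lab: {occ: c / total for occ, c in occs.items()}
        for lab, occs in counts.items()
        if (total := sum(occs.values())) > 0
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(OCCUPATIONS))
    frame.index.name = "period"
    return frame


def outcome_distribution(corpus: Corpus, mode: str = "mentions") -> pd.Series:
    """Fractions over the seven outcome categories.

    ``mentions`` (default): each listed outcome counts once and the
    denominator is total outcome mentions.  ``worst``: one outcome per
    report, the most serious listed (by the OUTCOMES ordering), denominator
    reports with any outcome.
    """
    counts = dict.fromkeys(OUTCOMES, 0)
    severity = {o: i for i, o in enumerate(OUTCOMES)}
    for r in corpus.reports:
        if not r.outcomes:
            continue
        if mode == "mentions":
            for o in r.outcomes:
                counts[o] += 1
        elif mode == "worst":
            counts[min(r.outcomes, key=severity.__getitem__)] += 1
        else:
            raise ValueError(f"unknown mode: {mode!r}")
    total = sum(counts.values())
    return pd.Series(
        {o: (c / total if total else 0.0) for o, c in counts.items()}, name="fraction"
    )


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------


@dataclass
class GlmFit:
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    converged: bool
    n_obs: int
    n_iter: int
    names: list[str]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "z": self.zvalues}, index=self.names
        )


def irls_logit(
    X: np.ndarray,
    y: np.ndarray,
    names: Optional[list[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Binomial logistic regression (logit link) fit by IRLS.

    Convergence when the maximum absolute score drops below ``tol``.
    Perfect separation shows up as non-convergence (diverging coefficients)
    and is reported through the ``converged`` flag rather than an exception.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    beta = np.zeros(d)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # damped update guards against overshoot on nearly-separated data
        if np.max(np.abs(step)) > 10.0:
            step *= 10.0 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(beta)) > 1e6:
            break
    # under (quasi-)separation the score can vanish while the coefficients
    # run off to +-inf; treat implausibly large logits as non-convergence
    if np.max(np.abs(beta)) > 20.0:
        converged = False
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        bse = np.full(d, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / bse
    return GlmFit(
        params=beta,
        bse=bse,
        zvalues=z,
        converged=converged,
        n_obs=n,
        n_iter=it,
        names=names or [f"x{j}" for j in range(d)],
    )


def logistic_model(
    corpus: Corpus,
    response_adr: str,
    suspect_ingredient: str,
    covariates: Sequence[str] = ("suspect", "occupation", "pre_cutoff"),
    cutoff_date: Optional[dt.date] = None,
) -> GlmFit:
    """Model the probability of a report listing ``response_adr``.

    Covariates (all optional): ``suspect`` — indicator that the given
    ingredient appears as primary suspect; ``occupation`` — one-hot
    indicators versus the ``unknown`` baseline; ``pre_cutoff`` — indicator
    that the report's date precedes ``cutoff_date``.
    """
    cols: list[list[float]] = []
    y: list[float] = []
    names = ["intercept"]
    use_occ = "occupation" in covariates
    occ_levels = [o for o in OCCUPATIONS if o != "unknown"] if use_occ else []
    if "suspect" in covariates:
        names.append("suspect")
    names.extend(f"occ_{o}" for o in occ_levels)
    if "pre_cutoff" in covariates:
        if cutoff_date is None:
            raise ValueError("pre_cutoff covariate requires cutoff_date")
        names.append("pre_cutoff")

    for r in corpus.reports:
        row = [1.0]
        if "suspect" in covariates:
            row.append(
                float(
                    any(
                        suspect_ingredient in d.ingredient_keys
                        for d in r.drugs
                        if d.role == "PS"
                    )
                )
            )
        for o in occ_levels:
            row.append(float(r.reporter_occupation == o))
        if "pre_cutoff" in covariates:
            date = r.analysis_date()
            row.append(float(date is not None and date < cutoff_date))
        cols.append(row)
        y.append(float(response_adr in r.reactions))
    return irls_logit(np.asarray(cols), np.asarray(y), names=names)


# ---------------------------------------------------------------------------
# exposure margin
# ---------------------------------------------------------------------------

EM_THRESHOLD_DEFAULT = 10.0


def exposure_margin(
    ic50: float, cmax: float, threshold: float = EM_THRESHOLD_DEFAULT
) -> tuple[float, bool]:
    """EM = IC50 / free Cmax; flag = EM < threshold (predicted ADR liability).

    Both concentrations must be positive and in the same units — the ratio
    is meaningless otherwise, and unit metadata is not modeled here.
    """
    if ic50 <= 0 or cmax <= 0:
        raise ValueError("ic50 and cmax must be positive")
    em = ic50 / cmax
    return em, em < threshold
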