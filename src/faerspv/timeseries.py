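"""Month-resolved disproportionality and trajectory clustering.

Each month's 2x2 tables use that month's reports only, with Holm adjustment
applied within the month across all pairs tested there.  Trajectories of
per-month RRR values are clustered by k-medoids under the distance
``1 - Pearson r``, seeded with the maximum-dissimilarity heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Corpus
from .signals import _require_mapped, _yates_p_vec, holm_adjust, incidence_frames


@dataclass
class MonthlySeries:
    pair: tuple[str, str]
    months: list[str]  # "YYYY-MM" labels over the analyzed range
    N_t: np.ndarray  # NaN where the month has no reports at all
    E_t: np.ndarray
    RRR_t: np.ndarray
    q_t: np.ndarray

    @property
    def n_sig_months(self) -> int:
        return int(np.nansum(self.q_t < 0.05))

    @property
    def n_nonsig_months(self) -> int:
        return int(np.nansum(self.q_t >= 0.05))


def _month_of(report, date_field: str) -> Optional[pd.Period]:
    if date_field == "receipt_date":
        date = report.receipt_date
    else:
        date = report.analysis_date()
    if date is None:
        return None
    return pd.Period(f"{date.year}-{date.month:02d}", "M")


def monthly_signal_frame(
    corpus: Corpus,
    month_range: Optional[tuple[str, str]] = None,
    role_filter: str = "PS",
    date_field: str = "event_date",
) -> pd.DataFrame:
    """Per-month signal table for every pair with N >= 1 in that month.

    Columns: month, ingredient, adr, N, E, RRR, p, q.  The Holm family is,
    separately for each month, the pairs observed in that month.
    """
    _require_mapped(corpus)
    months_of: dict[str, Optional[pd.Period]] = {
        r.report_id: _month_of(r, date_field) for r in corpus.reports
    }
    drugs, adrs, _ = incidence_frames(corpus, role_filter)
    if drugs.empty or adrs.empty:
        return pd.DataFrame(columns=["month", "ingredient", "adr", "N", "E", "RRR", "p", "q"])

    month_col = pd.Series({rid: m for rid, m in months_of.items() if m is not None}, name="month")
    totals = month_col.value_counts()
    drugs = drugs.assign(month=drugs["report_id"].map(month_col)).dropna(subset=["month"])
    adrs = adrs.assign(month=adrs["report_id"].map(month_col)).dropna(subset=["month"])

    if month_range is not None:
        lo, hi = pd.Period(month_range[0], "M"), pd.Period(month_range[1], "M")
        if lo > hi:
            raise ValueError("empty month range")
        drugs = drugs[(drugs["month"] >= lo) & (drugs["month"] <= hi)]
        adrs = adrs[(adrs["month"] >= lo) & (adrs["month"] <= hi)]

    r_margin = drugs.groupby(["month", "ingredient"], observed=True).size().rename("R")
    c_margin = adrs.groupby(["month", "adr"], observed=True).size().rename("C")
    joint = (
        drugs.merge(adrs, on=["report_id", "month"])
        .groupby(["month", "ingredient", "adr"], observed=True)
        .size()
        .rename("N")
        .reset_index()
    )
    joint = joint.merge(r_margin, on=["month", "ingredient"]).merge(c_margin, on=["month", "adr"])
    joint["T"] = joint["month"].map(totals).astype(int)
    joint["E"] = joint["R"] * joint["C"] / joint["T"]
    joint["RRR"] = joint["N"] / joint["E"]
    joint["p"] = _yates_p_vec(joint["N"], joint["R"], joint["C"], joint["T"])
    joint["q"] = np.nan
    for _, idx in joint.groupby("month", observed=True).groups.items():
        joint.loc[idx, "q"] = holm_adjust(joint.loc[idx, "p"].to_numpy())
    joint["month"] = joint["month"].astype(str)
    return joint[["month", "ingredient", "adr", "N", "E", "RRR", "p", "q"]].sort_values(
        ["month", "ingredient", "adr"], kind="stable"
    ).reset_index(drop=True)


def monthly_signals(
    corpus: Corpus,
    pair: tuple[str, str],
    month_range: tuple[str, str],
    role_filter: str = "PS",
    date_field: str = "event_date",
    frame: Optional[pd.DataFrame] = None,
) -> MonthlySeries:
    """Month-indexed N/E/RRR/q vectors for one pair.

    Months inside the range with reports but no co-occurrence get N=0 (and
    q=NaN — the pair was not in that month's family); months with no reports
    at all are NaN throughout.  Pass a precomputed ``frame`` from
    :func:`monthly_signal_frame` to amortize the family-wide computation.
    """
    lo, hi = pd.Period(month_range[0], "M"), pd.Period(month_range[1], "M")
    if lo > hi:
        raise ValueError("empty month range")
    if frame is None:
        frame = monthly_signal_frame(corpus, month_range, role_filter, date_field)
    months = [str(m) for m in pd.period_range(lo, hi, freq="M")]

    months_with_data = set(frame["month"])
    ing, adr = pair
    sub = frame[(frame["ingredient"] == ing) & (frame["adr"] == adr)].set_index("month")

    n_t = np.full(len(months), np.nan)
    e_t = np.full(len(months), np.nan)
    rrr_t = np.full(len(months), np.nan)
    q_t = np.full(len(months), np.nan)
    for k, m in enumerate(months):
        if m in sub.index:
            row = sub.loc[m]
            n_t[k], e_t[k], rrr_t[k], q_t[k] = row["N"], row["E"], row["RRR"], row["q"]
        elif m in months_with_data:
            n_t[k], rrr_t[k] = 0.0, 0.0
    return MonthlySeries(pair=pair, months=months, N_t=n_t, E_t=e_t, RRR_t=rrr_t, q_t=q_t)


def monthly_fraction_profile(
    corpus: Corpus, ingredient: str, role_filter: str = "PS"
) -> pd.DataFrame:
    """Per-month composition of an ingredient's ADR mentions.

    Rows are months, columns PTs; each row of the returned frame sums to 1.
    Mentions are counted over reports where the ingredient appears under an
    allowed role.
    """
    _require_mapped(corpus)
    allowed = {"PS": {"PS"}, "PS+SS": {"PS", "SS"}, "ALL": {"PS", "SS", "C", "I"}}[role_filter]
    rows = []
    for r in corpus.reports:
        if not any(ingredient in d.ingredient_keys for d in r.drugs if d.role in allowed):
            continue
        month = _month_of(r, "event_date")
        if month is None:
            continue
        for pt in set(r.reactions):
            rows.append((str(month), pt))
    if not rows:
        return pd.DataFrame()
    counts = pd.DataFrame(rows, columns=["month", "adr"]).value_counts().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0).sort_index()


# ---------------------------------------------------------------------------
# trajectory clustering
# ---------------------------------------------------------------------------


def correlation_distance_matrix(series_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise ``1 - Pearson r`` distances between trajectory rows.

    Rows with zero variance cannot carry a correlation; they are assigned
    r = 0 (distance 1) against every other row and flagged in the returned
    boolean mask.
    """
    x = np.asarray(series_matrix, dtype=float)
    x = np.nan_to_num(x, nan=0.0)  # missing months imputed as 0
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return 1.0 - corr, constant


def _max_dissimilarity_medoids(dist: np.ndarray, k: int) -> list[int]:
    first = int(np.argmax(dist.sum(axis=1)))
    medoids = [first]
    while len(medoids) < k:
        min_d = dist[:, medoids].min(axis=1)
        min_d[medoids] = -np.inf
        medoids.append(int(np.argmax(min_d)))
    return medoids


@dataclass
class TrajectoryClustering:
    labels: np.ndarray
    medoids: list[int]
    objective: float
    constant_rows: np.ndarray  # zero-variance rows assigned by convention


def cluster_trajectories(series_matrix, k: int) -> TrajectoryClustering:
    """Deterministic k-medoids on 1 - Pearson r between RRR trajectories.

    Initial medoids come from the maximum-dissimilarity heuristic (first:
    largest total distance; next: largest minimum distance to those chosen);
    then greedy medoid swaps run to convergence.  Ties always break toward
    the lowest index, so the result is order-stable.
    """
    x = np.asarray(series_matrix, dtype=float)
    n = x.shape[0]
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= {n}, got k={k}")
    dist, constant = correlation_distance_matrix(x)

    medoids = _max_dissimilarity_medoids(dist, k)

    def objective(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    current = objective(medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = cand
                val = objective(trial)
                if val < current - 1e-12:
                    medoids, current = trial, val
                    improved = True
    medoids = sorted(medoids)
    labels = np.argmin(dist[:, medoids], axis=1)
    return TrajectoryClustering(
        labels=labels, medoids=medoids, objective=objective(medoids), constant_rows=constant
    )
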