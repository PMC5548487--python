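"""Seeded generator of FAERS-like corpora with planted ground truth.

The generator draws drug/ADR pairs independently under the null and plants
configurable departures from it: rate-multiplied associations (optionally
restricted to a month window), month-localized reporting spikes, synonym
fragmentation of ingredients across several name strings, exact-duplicate
injection, indication/ADR conflation, occupation mixtures that shift over
calendar time, and follow-up reports sharing a case id.  All randomness
flows through one ``numpy`` Generator so a (config, seed) pair is fully
reproducible.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import OCCUPATIONS, OUTCOMES, Corpus, DrugEntry, Report

_FILLER_TOKENS = ("20mg", "tablet", "oral", "solution", "hcl", "capsule", "injection")
_PUNCT = ("-", ".", "/", "(", ")")


@dataclass(frozen=True)
class PlantedAssociation:
    """One planted drug–ADR departure from independence.

    ``rate_multiplier`` scales the joint sampling weight of the pair within
    ``active_window`` (inclusive month range, e.g. ``("2004-03", "2004-08")``);
    ``None`` means the whole date range.
    """

    ingredient: int
    adr: int
    rate_multiplier: float
    active_window: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0:
            raise ValueError("rate_multiplier must be > 0")


@dataclass
class SyntheticConfig:
    n_reports: int = 10_000
    n_ingredients: int = 50
    n_adrs: int = 50
    background_drug_weights: Optional[Sequence[float]] = None  # default uniform
    background_adr_weights: Optional[Sequence[float]] = None
    planted_associations: list[PlantedAssociation] = field(default_factory=list)
    synonyms_per_ingredient: int = 1
    synonym_noise: float = 0.0
    duplicate_fraction: float = 0.0
    conflation_fraction: float = 0.0
    followup_fraction: float = 0.0
    #: number of ADR terms per report drawn from this categorical
    adr_count_weights: dict[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.15})
    #: number of drugs per report; extra drugs beyond the first are background
    drug_count_weights: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    #: map "YYYY-MM" period-start -> probability vector over OCCUPATIONS;
    #: the mixture in force for a month is the latest break at or before it
    occupation_mixture: Optional[dict[str, Sequence[float]]] = None
    outcome_weights: Optional[Sequence[float]] = None
    #: (ingredient, adr, (start, end), intensity): date-density multiplier for
    #: reports of that pair within the window
    spike_windows: list[tuple[int, int, tuple[str, str], float]] = field(default_factory=list)
    date_range: tuple[str, str] = ("2004-01", "2005-12")
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.duplicate_fraction, self.conflation_fraction, self.followup_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if not (0.0 <= self.synonym_noise <= 1.0):
            raise ValueError("synonym_noise must lie in [0, 1]")
        for name, w, n in (
            ("background_drug_weights", self.background_drug_weights, self.n_ingredients),
            ("background_adr_weights", self.background_adr_weights, self.n_adrs),
        ):
            if w is not None:
                w = np.asarray(w, dtype=float)
                if len(w) != n or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
                    raise ValueError(f"{name} must be a length-{n} probability vector")
        if self.occupation_mixture:
            for period, vec in self.occupation_mixture.items():
                vec = np.asarray(vec, dtype=float)
                if len(vec) != len(OCCUPATIONS) or abs(vec.sum() - 1.0) > 1e-9:
                    raise ValueError(f"occupation mixture for {period} is not a probability vector")


@dataclass
class GroundTruth:
    planted_associations: list[PlantedAssociation]
    duplicate_groups: list[frozenset[str]]
    conflated_report_ids: frozenset[str]
    synonym_map: dict[str, str]  # emitted name string -> ingredient key
    n_cases: int
    ingredient_keys: list[str]
    adr_terms: list[str]


def ingredient_key(i: int) -> str:
    return f"ING-{i:04d}"


def adr_term(j: int) -> str:
    # long enough (>20 chars) that a single typo keeps similarity >= 0.95
    return f"synthetic reaction condition {j:04d}"


def _base_name(i: int) -> str:
    return f"drugbrand{i:04d} molecule{i:04d}"


def perturb_name(name: str, noise: float, rng: np.random.Generator) -> str:
    """Perturb a drug name: token reordering, casing flips, punctuation
    insertion and appended filler tokens, at a rate set by ``noise``.

    ``noise=0`` returns the input unchanged.  Punctuation is inserted inside
    tokens (never whitespace), so tokenization recovers the original tokens.
    """
    if noise == 0.0:
        return name
    tokens = name.split()
    if rng.random() < noise and len(tokens) > 1:
        rng.shuffle(tokens)
    out = []
    for tok in tokens:
        if rng.random() < noise:
            tok = tok.upper() if rng.random() < 0.5 else tok.capitalize()
        if rng.random() < noise:
            pos = int(rng.integers(1, len(tok))) if len(tok) > 1 else 0
            tok = tok[:pos] + str(rng.choice(_PUNCT)) + tok[pos:]
        out.append(tok)
    n_fillers = int(rng.integers(0, 3)) if rng.random() < noise else 0
    for _ in range(n_fillers):
        out.append(str(rng.choice(_FILLER_TOKENS)))
    return " ".join(out)


def _month_list(date_range: tuple[str, str]) -> list[pd.Period]:
    start, end = date_range
    return list(pd.period_range(start=start, end=end, freq="M"))


def _window_mask(months: list[pd.Period], window: Optional[tuple[str, str]]) -> np.ndarray:
    if window is None:
        return np.ones(len(months), dtype=bool)
    lo, hi = pd.Period(window[0], "M"), pd.Period(window[1], "M")
    return np.array([lo <= m <= hi for m in months])


def _build_drug_entries(r, count, drug_idx, synonym_choice, synonyms, extra_drugs, indication, rng):
    """First drug comes from the joint draw and carries the indication; any
    further drugs are independent background draws deduplicated by
    ingredient (colliding pre-draws are skipped, so a report can end up with
    slightly fewer drugs than requested)."""
    entries = [
        DrugEntry(
            verbatim_name=synonyms[drug_idx[r]][synonym_choice[r]],
            role="PS",
            indication=indication,
        )
    ]
    if extra_drugs is not None:
        used = {int(drug_idx[r])}
        for extra in extra_drugs[r]:
            if len(entries) >= count:
                break
            extra = int(extra)
            if extra in used:
                continue
            used.add(extra)
            variants = synonyms[extra]
            name = variants[0] if len(variants) == 1 else variants[int(rng.integers(0, len(variants)))]
            entries.append(DrugEntry(verbatim_name=name, role="PS"))
    return entries


def generate(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth from a seeded configuration."""
    rng = np.random.default_rng(config.seed)
    months = _month_list(config.date_range)
    n_m, n_i, n_a = len(months), config.n_ingredients, config.n_adrs

    p = (
        np.asarray(config.background_drug_weights, dtype=float)
        if config.background_drug_weights is not None
        else np.full(n_i, 1.0 / n_i)
    )
    q = (
        np.asarray(config.background_adr_weights, dtype=float)
        if config.background_adr_weights is not None
        else np.full(n_a, 1.0 / n_a)
    )

    # joint weight over (month, ingredient, adr); months uniform a priori
    joint = np.einsum("i,j->ij", p, q)[None, :, :].repeat(n_m, axis=0)
    for assoc in config.planted_associations:
        mask = _window_mask(months, assoc.active_window)
        joint[mask, assoc.ingredient, assoc.adr] *= assoc.rate_multiplier
    for (i, a, window, intensity) in config.spike_windows:
        if intensity <= 0:
            raise ValueError("spike intensity must be > 0")
        mask = _window_mask(months, window)
        joint[mask, i, a] *= intensity
    total = joint.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("infeasible config: joint sampling weight is degenerate")
    flat = (joint / total).ravel()

    n = config.n_reports
    cells = rng.choice(flat.size, size=n, p=flat)
    month_idx, rest = np.divmod(cells, n_i * n_a)
    drug_idx, adr_idx = np.divmod(rest, n_a)

    # additional background ADR terms per report
    counts_k = np.array(sorted(config.adr_count_weights))
    counts_w = np.array([config.adr_count_weights[k] for k in counts_k], dtype=float)
    counts_w = counts_w / counts_w.sum()
    n_terms = rng.choice(counts_k, size=n, p=counts_w)

    dcounts_k = np.array(sorted(config.drug_count_weights))
    dcounts_w = np.array([config.drug_count_weights[k] for k in dcounts_k], dtype=float)
    dcounts_w = dcounts_w / dcounts_w.sum()
    n_drugs = rng.choice(dcounts_k, size=n, p=dcounts_w)

    # bulk pre-draws for the extra (background) ADR terms and drugs; the
    # per-report loop slices what it needs from these
    max_extra_adrs = int(counts_k.max()) - 1
    extra_adrs = (
        rng.choice(n_a, size=(n, max_extra_adrs), p=q) if max_extra_adrs > 0 else None
    )
    max_extra_drugs = min(int(dcounts_k.max()), n_i) - 1
    extra_drugs = (
        rng.choice(n_i, size=(n, max_extra_drugs), p=p) if max_extra_drugs > 0 else None
    )
    indication_draws = rng.choice(n_a, size=(n, 8), p=q)

    # dates: uniform day within the sampled month
    days_in_month = np.array([calendar.monthrange(m.year, m.month)[1] for m in months])
    day_of_month = (rng.random(n) * days_in_month[month_idx]).astype(int) + 1

    ages = rng.integers(18, 86, size=n).astype(float)
    sexes = np.where(rng.random(n) < 0.5, "F", "M")
    missing_event_date = rng.random(n) < 0.02

    occ_breaks: list[tuple[pd.Period, np.ndarray]] = []
    if config.occupation_mixture:
        for period in sorted(config.occupation_mixture):
            occ_breaks.append(
                (pd.Period(period, "M"), np.asarray(config.occupation_mixture[period], dtype=float))
            )

    out_w = (
        np.asarray(config.outcome_weights, dtype=float)
        if config.outcome_weights is not None
        else np.array([0.08, 0.04, 0.03, 0.01, 0.04, 0.30, 0.50])
    )
    out_w = out_w / out_w.sum()
    outcome_idx = rng.choice(len(OUTCOMES), size=n, p=out_w)

    conflate = rng.random(n) < config.conflation_fraction

    # synonym strings per ingredient; index 0 is the unperturbed base name
    synonym_map: dict[str, str] = {}
    synonyms: list[list[str]] = []
    for i in range(n_i):
        base = _base_name(i)
        variants = [base]
        attempts = 0
        while len(variants) < config.synonyms_per_ingredient and attempts < 20 * config.synonyms_per_ingredient:
            cand = perturb_name(base, max(config.synonym_noise, 1e-9), rng)
            attempts += 1
            if cand not in variants and cand not in synonym_map:
                variants.append(cand)
        synonyms.append(variants)
        for v in variants:
            synonym_map[v] = ingredient_key(i)
    synonym_choice = rng.integers(0, [len(synonyms[i]) for i in drug_idx])

    keys = [ingredient_key(i) for i in range(n_i)]
    terms = [adr_term(j) for j in range(n_a)]

    reports: list[Report] = []
    for r in range(n):
        m = months[month_idx[r]]
        event_date = None if missing_event_date[r] else dt.date(m.year, m.month, int(day_of_month[r]))
        receipt_date = (event_date or dt.date(m.year, m.month, 15)) + dt.timedelta(
            days=int(rng.integers(5, 60))
        )
        reacts = [terms[adr_idx[r]]]
        for k in range(int(n_terms[r]) - 1):
            extra = terms[int(extra_adrs[r, k])]
            if extra not in reacts:
                reacts.append(extra)
        if conflate[r]:
            indication = reacts[int(rng.integers(0, len(reacts)))]
        else:
            # a background condition distinct from every reported reaction
            indication = next(
                (terms[int(j)] for j in indication_draws[r] if terms[int(j)] not in reacts),
                next((t for t in terms if t not in reacts), reacts[0]),
            )
        if occ_breaks:
            vec = occ_breaks[0][1]
            for brk, v in occ_breaks:
                if brk <= m:
                    vec = v
            occupation = OCCUPATIONS[int(rng.choice(len(OCCUPATIONS), p=vec))]
        else:
            occupation = OCCUPATIONS[int(rng.integers(0, len(OCCUPATIONS)))]
        reports.append(
            Report(
                report_id=f"R{r:07d}",
                case_id=f"C{r:07d}",
                drugs=_build_drug_entries(
                    r, int(n_drugs[r]), drug_idx, synonym_choice, synonyms,
                    extra_drugs, indication, rng,
                ),
                reactions=reacts,
                event_date=event_date,
                receipt_date=receipt_date,
                reporter_occupation=occupation,
                patient_age=float(ages[r]),
                patient_sex=str(sexes[r]),
                outcomes=frozenset({OUTCOMES[outcome_idx[r]]}),
            )
        )

    n_cases = len(reports)

    # follow-up reports: same case, later receipt date, fresh report id
    n_follow = int(round(config.followup_fraction * n))
    if n_follow:
        for k, src in enumerate(rng.choice(n, size=n_follow, replace=False)):
            orig = reports[int(src)]
            reports.append(
                Report(
                    report_id=f"F{k:07d}",
                    case_id=orig.case_id,
                    drugs=list(orig.drugs),
                    reactions=list(orig.reactions),
                    event_date=orig.event_date,
                    receipt_date=(orig.receipt_date or dt.date(2000, 1, 1))
                    + dt.timedelta(days=int(rng.integers(30, 180))),
                    reporter_occupation=orig.reporter_occupation,
                    patient_age=orig.patient_age,
                    patient_sex=orig.patient_sex,
                    outcomes=orig.outcomes,
                )
            )

    # exact duplicates: verbatim copies under a new report id (and case id)
    duplicate_groups: list[frozenset[str]] = []
    n_dup = int(round(config.duplicate_fraction * n))
    if n_dup:
        for k, src in enumerate(rng.choice(n, size=n_dup, replace=False)):
            orig = reports[int(src)]
            dup_id = f"D{k:07d}"
            reports.append(
                Report(
                    report_id=dup_id,
                    case_id=f"CD{k:07d}",
                    drugs=list(orig.drugs),
                    reactions=list(orig.reactions),
                    event_date=orig.event_date,
                    receipt_date=orig.receipt_date,
                    reporter_occupation=orig.reporter_occupation,
                    patient_age=orig.patient_age,
                    patient_sex=orig.patient_sex,
                    outcomes=orig.outcomes,
                )
            )
            duplicate_groups.append(frozenset({orig.report_id, dup_id}))

    corpus = Corpus(
        reports=reports,
        provenance={
            "generator": "synthetic",
            "seed": config.seed,
            "n_reports_requested": n,
            "n_duplicates": n_dup,
            "n_followups": n_follow,
        },
    )
    truth = GroundTruth(
        planted_associations=list(config.planted_associations),
        duplicate_groups=duplicate_groups,
        conflated_report_ids=frozenset(
            f"R{r:07d}" for r in range(n) if conflate[r]
        ),
        synonym_map=synonym_map,
        n_cases=n_cases,
        ingredient_keys=keys,
        adr_terms=terms,
    )
    return corpus, truth
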