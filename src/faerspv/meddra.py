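"""Standardize verbatim ADR / indication strings to preferred terms (PTs).

Similarity is normalized Levenshtein: ``1 - d(a', b') / max(|a'|, |b'|)`` on
case-folded, whitespace-collapsed strings.  A candidate scoring at least
``s_perfect`` (default 0.95) is accepted immediately; otherwise the best
candidate wins if it reaches ``s_min`` (default 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .model import Corpus, DrugEntry, Report

S_PERFECT_DEFAULT = 0.95
S_MIN_DEFAULT = 0.90

UNMATCHED = None


def _canon(s: str) -> str:
    return " ".join(s.casefold().split())


def _edit_distance(a: str, b: str) -> int:
    # two-row DP; iterative over the shorter string for cache friendliness
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_similarity(a: str, b: str) -> float:
    """Normalized edit similarity in [0, 1]; 1 iff the canonical forms are
    equal.  Both strings empty -> 1 by convention."""
    a2, b2 = _canon(a), _canon(b)
    if not a2 and not b2:
        return 1.0
    longest = max(len(a2), len(b2))
    return 1.0 - _edit_distance(a2, b2) / longest


@dataclass
class MeddraVocabulary:
    """A flat preferred-term list plus manual verbatim->PT overrides."""

    preferred_terms: tuple[str, ...]
    manual_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pt in self.preferred_terms:
            if not pt:
                raise ValueError("preferred terms must be non-empty")
            if _canon(pt) in seen:
                raise ValueError(f"duplicate PT (case-insensitive): {pt!r}")
            seen[_canon(pt)] = pt
        # deterministic scan order: sorted; exact-canonical lookup table
        object.__setattr__(self, "_sorted", tuple(sorted(self.preferred_terms)))
        object.__setattr__(self, "_by_canon", seen)

    @classmethod
    def from_terms(cls, terms: Iterable[str], overrides: Optional[dict[str, str]] = None):
        return cls(preferred_terms=tuple(terms), manual_overrides=dict(overrides or {}))

    @classmethod
    def read(cls, path, overrides_path=None) -> "MeddraVocabulary":
        """Vocabulary file: one PT per line; overrides: ``verbatim<TAB>PT``."""
        terms = [ln for ln in Path(path).read_text().splitlines() if ln and not ln.startswith("#")]
        overrides = {}
        if overrides_path is not None:
            for ln in Path(overrides_path).read_text().splitlines():
                if not ln or ln.startswith("#"):
                    continue
                verbatim, pt = ln.split("\t")
                overrides[verbatim] = pt
        return cls(preferred_terms=tuple(terms), manual_overrides=overrides)


def normalize_adr(
    verbatim: str,
    vocab: MeddraVocabulary,
    s_perfect: float = S_PERFECT_DEFAULT,
    s_min: float = S_MIN_DEFAULT,
) -> tuple[Optional[str], float]:
    """Match one verbatim term; returns ``(PT, score)`` or ``(None, best_score)``.

    Overrides first; an exact canonical-form hit scores 1 immediately; then a
    sorted-order scan short-circuits at the first PT with s >= ``s_perfect``,
    else the argmax wins if it reaches ``s_min`` (ties -> lexicographically
    smallest PT, which the sorted scan yields for free).
    """
    if not vocab.preferred_terms:
        raise ValueError("empty vocabulary")
    if verbatim in vocab.manual_overrides:
        return vocab.manual_overrides[verbatim], 1.0
    hit = vocab._by_canon.get(_canon(verbatim))
    if hit is not None:
        return hit, 1.0
    best_pt, best_s = None, 0.0
    v = _canon(verbatim)
    for pt in vocab._sorted:
        p = _canon(pt)
        # length gap bounds the achievable similarity; skip hopeless candidates
        longest = max(len(v), len(p))
        if longest and 1.0 - abs(len(v) - len(p)) / longest < s_min:
            continue
        s = levenshtein_similarity(verbatim, pt)
        if s >= s_perfect:
            return pt, s
        if s > best_s:
            best_pt, best_s = pt, s
    if best_s >= s_min:
        return best_pt, best_s
    return UNMATCHED, best_s


@dataclass
class MatchRateReport:
    n_reactions: int
    n_reactions_matched: int
    n_indications: int
    n_indications_matched: int

    @property
    def reaction_match_rate(self) -> float:
        return self.n_reactions_matched / self.n_reactions if self.n_reactions else 1.0

    @property
    def indication_match_rate(self) -> float:
        return self.n_indications_matched / self.n_indications if self.n_indications else 1.0


def normalize_corpus(
    corpus: Corpus,
    vocab: MeddraVocabulary,
    s_perfect: float = S_PERFECT_DEFAULT,
    s_min: float = S_MIN_DEFAULT,
) -> tuple[Corpus, MatchRateReport]:
    """Standardize every reaction and indication string in the corpus.

    Unmatched strings are kept verbatim (flagged only through the match-rate
    report); dropping them would silently change report margins downstream.
    """
    cache: dict[str, Optional[str]] = {}

    def lookup(term: str) -> Optional[str]:
        if term not in cache:
            cache[term] = normalize_adr(term, vocab, s_perfect=s_perfect, s_min=s_min)[0]
        return cache[term]

    n_reac = n_reac_ok = n_indi = n_indi_ok = 0
    new_reports = []
    for r in corpus.reports:
        new_reactions = []
        for term in r.reactions:
            pt = lookup(term)
            n_reac += 1
            if pt is not None:
                n_reac_ok += 1
                new_reactions.append(pt)
            else:
                new_reactions.append(term)
        new_drugs = []
        for d in r.drugs:
            indication = d.indication
            if indication:
                pt = lookup(indication)
                n_indi += 1
                if pt is not None:
                    n_indi_ok += 1
                    indication = pt
            new_drugs.append(
                DrugEntry(
                    verbatim_name=d.verbatim_name,
                    role=d.role,
                    indication=indication,
                    ingredient_keys=d.ingredient_keys,
                    mapping_score=d.mapping_score,
                )
            )
        new_reports.append(
            Report(
                report_id=r.report_id,
                case_id=r.case_id,
                drugs=new_drugs,
                reactions=new_reactions,
                event_date=r.event_date,
                receipt_date=r.receipt_date,
                reporter_occupation=r.reporter_occupation,
                patient_age=r.patient_age,
                patient_sex=r.patient_sex,
                outcomes=r.outcomes,
                event_date_imputed=r.event_date_imputed,
            )
        )
    prov = dict(corpus.provenance)
    prov["adr_normalization"] = {
        "reactions_matched": n_reac_ok,
        "reactions_total": n_reac,
        "indications_matched": n_indi_ok,
        "indications_total": n_indi,
    }
    return Corpus(reports=new_reports, provenance=prov), MatchRateReport(
        n_reac, n_reac_ok, n_indi, n_indi_ok
    )
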