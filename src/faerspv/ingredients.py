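"""Map verbatim drug names to molecular-ingredient keys.

Names are tokenized (lowercase, punctuation stripped, low-information tokens
removed) and compared to a synonym table with the token-set Tanimoto
coefficient.  A candidate scoring at least ``t_exact`` (default 0.99) is an
exact match and short-circuits the scan; otherwise the best candidate wins if
it reaches ``t_min`` (default 0.2).  Manual overrides are consulted before
any scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .model import Corpus, Report

#: default low-information tokens ("articles, or often occurring words like 'acid'")
DEFAULT_STOPWORDS = frozenset({"a", "an", "the", "and", "of", "with", "for", "acid"})

T_MIN_DEFAULT = 0.2
T_EXACT_DEFAULT = 0.99

_NON_ALNUM = re.compile(r"[^0-9a-z\s]+")


def normalize_tokens(raw_name: str, stopwords: Iterable[str] = DEFAULT_STOPWORDS) -> frozenset[str]:
    """Tokenize a drug name: casefold, strip non-alphanumeric characters
    (digits are kept), split on whitespace, drop stopwords, collapse
    duplicates to set semantics.  May be empty.
    """
    cleaned = _NON_ALNUM.sub("", raw_name.casefold())
    return frozenset(tok for tok in cleaned.split() if tok and tok not in stopwords)


def token_tanimoto(tokens_a: frozenset[str], tokens_b: frozenset[str]) -> float:
    """|A∩B| / |A∪B|; 0 when the union is empty."""
    if not tokens_a and not tokens_b:
        return 0.0
    inter = len(tokens_a & tokens_b)
    if inter == 0:
        return 0.0
    return inter / (len(tokens_a) + len(tokens_b) - inter)


@dataclass
class SynonymTable:
    """Synonym strings mapped to ingredient-key sets, plus manual overrides."""

    entries: list[tuple[str, frozenset[str]]]
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    manual_overrides: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for syn, keys in self.entries:
            if not syn:
                raise ValueError("synonym strings must be non-empty")
            if not keys:
                raise ValueError(f"synonym {syn!r} maps to no ingredient key")
        # tokenized once up front; scan order is table order
        self._tokenized = [
            (syn, normalize_tokens(syn, self.stopwords), frozenset(keys))
            for syn, keys in self.entries
        ]

    @classmethod
    def from_mapping(cls, mapping: dict[str, str], **kwargs) -> "SynonymTable":
        """Build from a flat ``synonym -> single key`` dict (e.g. generator
        ground truth), in sorted-synonym order."""
        return cls(
            entries=[(syn, frozenset({key})) for syn, key in sorted(mapping.items())],
            **kwargs,
        )

    @classmethod
    def read_tsv(cls, path, overrides_path=None, stopwords=DEFAULT_STOPWORDS) -> "SynonymTable":
        """Read ``synonym<TAB>key[;key...]`` lines; '#' comments allowed."""
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            syn, keys = line.split("\t")
            entries.append((syn, frozenset(k for k in keys.split(";") if k)))
        overrides = {}
        if overrides_path is not None:
            for line in Path(overrides_path).read_text().splitlines():
                if not line or line.startswith("#"):
                    continue
                name, keys = line.split("\t")
                overrides[name] = frozenset(k for k in keys.split(";") if k)
        return cls(entries=entries, stopwords=frozenset(stopwords), manual_overrides=overrides)


@dataclass(frozen=True)
class MatchResult:
    ingredient_keys: frozenset[str]
    tc: float
    matched_synonym: str
    method: str  # exact | fuzzy | override | unmatched

    def __post_init__(self) -> None:
        if (self.method == "unmatched") != (not self.ingredient_keys):
            raise ValueError("unmatched iff no ingredient keys")


_UNMATCHED = MatchResult(frozenset(), 0.0, "", "unmatched")


def map_drug_name(
    raw_name: str,
    table: SynonymTable,
    t_min: float = T_MIN_DEFAULT,
    t_exact: float = T_EXACT_DEFAULT,
) -> MatchResult:
    """Match one verbatim drug name against the synonym table.

    Overrides first; then a scan of the table in order, short-circuiting at
    the first synonym with Tanimoto >= ``t_exact``; else the argmax if it
    reaches ``t_min`` (ties broken by longer synonym string, then
    lexicographically smaller).  Unmatched is a value, not an error.
    """
    override = table.manual_overrides.get(raw_name)
    if override:
        return MatchResult(frozenset(override), 1.0, raw_name, "override")

    tokens = normalize_tokens(raw_name, table.stopwords)
    best: Optional[tuple[float, int, str, str, frozenset[str]]] = None
    for syn, syn_tokens, keys in table._tokenized:
        tc = token_tanimoto(tokens, syn_tokens)
        if tc >= t_exact:
            return MatchResult(keys, tc, syn, "exact")
        if tc >= t_min:
            cand = (tc, len(syn), _NegStr(syn), syn, keys)
            if best is None or cand[:3] > best[:3]:
                best = cand
    if best is None:
        return _UNMATCHED
    return MatchResult(best[4], best[0], best[3], "fuzzy")


class _NegStr(str):
    """String with reversed ordering, so lexicographically-smaller wins a max."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


@dataclass
class CoverageReport:
    n_drug_rows: int
    n_matched: int
    n_unmatched: int
    top_unmatched: list[tuple[str, int]]  # (verbatim name, count), most frequent first

    @property
    def coverage(self) -> float:
        return self.n_matched / self.n_drug_rows if self.n_drug_rows else 1.0


def map_corpus(
    corpus: Corpus,
    table: SynonymTable,
    t_min: float = T_MIN_DEFAULT,
    t_exact: float = T_EXACT_DEFAULT,
) -> tuple[Corpus, CoverageReport]:
    """Annotate every drug entry with its mapped ingredient keys.

    Match results are cached per distinct verbatim name, which makes mapping
    a large corpus with few distinct names cheap.  The coverage report lists
    the most frequent unmatched names for manual-override curation.
    """
    if not table.entries and not table.manual_overrides:
        raise ValueError("synonym table is empty")

    cache: dict[str, MatchResult] = {}
    unmatched_counts: dict[str, int] = {}
    n_rows = 0
    n_matched = 0

    new_reports = []
    for r in corpus.reports:
        new_drugs = []
        for d in r.drugs:
            n_rows += 1
            res = cache.get(d.verbatim_name)
            if res is None:
                res = map_drug_name(d.verbatim_name, table, t_min=t_min, t_exact=t_exact)
                cache[d.verbatim_name] = res
            if res.method == "unmatched":
                unmatched_counts[d.verbatim_name] = unmatched_counts.get(d.verbatim_name, 0) + 1
                new_drugs.append(d.with_mapping((), None))
            else:
                n_matched += 1
                new_drugs.append(d.with_mapping(res.ingredient_keys, res.tc))
        new_reports.append(
            Report(
                report_id=r.report_id,
                case_id=r.case_id,
                drugs=new_drugs,
                reactions=list(r.reactions),
                event_date=r.event_date,
                receipt_date=r.receipt_date,
                reporter_occupation=r.reporter_occupation,
                patient_age=r.patient_age,
                patient_sex=r.patient_sex,
                outcomes=r.outcomes,
                event_date_imputed=r.event_date_imputed,
            )
        )
    top = sorted(unmatched_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:20]
    prov = dict(corpus.provenance)
    prov["ingredient_mapping"] = {"matched": n_matched, "unmatched": n_rows - n_matched}
    return (
        Corpus(reports=new_reports, provenance=prov),
        CoverageReport(n_rows, n_matched, n_rows - n_matched, top),
    )


def map_identity(corpus: Corpus) -> Corpus:
    """Annotate each drug with its own verbatim name as the ingredient key.

    This is the no-aggregation baseline: every name string is treated as a
    distinct ingredient, as when analysing FAERS without synonym
    normalization.
    """
    new_reports = []
    for r in corpus.reports:
        new_drugs = [d.with_mapping({d.verbatim_name}, 1.0) for d in r.drugs]
        new_reports.append(
            Report(
                report_id=r.report_id,
                case_id=r.case_id,
                drugs=new_drugs,
                reactions=list(r.reactions),
                event_date=r.event_date,
                receipt_date=r.receipt_date,
                reporter_occupation=r.reporter_occupation,
                patient_age=r.patient_age,
                patient_sex=r.patient_sex,
                outcomes=r.outcomes,
                event_date_imputed=r.event_date_imputed,
            )
        )
    return Corpus(reports=new_reports, provenance=dict(corpus.provenance))
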