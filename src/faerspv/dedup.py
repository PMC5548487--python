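"""Detection and collapsing of multiplied (exact-duplicate) reports.

Two reports are duplicates when they agree exactly on the five identifying
fields: drugs (as mapped ingredient sets), reactions, event date, patient
age and sex.  Matching is equality on a canonical fingerprint, not fuzzy
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Corpus, Report

#: sentinel for a missing field — two missing values compare equal only to
#: each other, never to a present value
_MISSING = "∅"


@dataclass(frozen=True)
class DuplicateGroup:
    fingerprint: str
    report_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.report_ids) < 2:
            raise ValueError("duplicate groups have size >= 2")


def report_fingerprint(report: Report) -> str:
    """Canonical key over (ingredients, PTs, event date, age, sex).

    Drug order is irrelevant (sorted sets).  If any drug is unmapped the
    fingerprint falls back to verbatim names and is tagged ``V|`` instead of
    ``I|`` so verbatim- and ingredient-keyed reports never collide.
    """
    all_mapped = all(d.ingredient_keys for d in report.drugs)
    if all_mapped:
        drug_part = ";".join(sorted({k for d in report.drugs for k in d.ingredient_keys}))
        tag = "I"
    else:
        drug_part = ";".join(sorted({d.verbatim_name for d in report.drugs}))
        tag = "V"
    return "|".join(
        [
            tag,
            drug_part,
            ";".join(sorted(set(report.reactions))),
            report.event_date.isoformat() if report.event_date else _MISSING,
            repr(report.patient_age) if report.patient_age is not None else _MISSING,
            report.patient_sex,
        ]
    )


def find_duplicate_groups(corpus: Corpus) -> list[DuplicateGroup]:
    """Fingerprint equivalence classes of size >= 2, sorted by fingerprint."""
    by_fp: dict[str, set[str]] = {}
    for r in corpus.reports:
        by_fp.setdefault(report_fingerprint(r), set()).add(r.report_id)
    return [
        DuplicateGroup(fp, frozenset(ids))
        for fp, ids in sorted(by_fp.items())
        if len(ids) >= 2
    ]


def deduplicate(corpus: Corpus, policy: str = "keep_first") -> Corpus:
    """Collapse each duplicate group to one representative.

    ``keep_first`` keeps the lexicographically smallest report_id.  The
    operation is idempotent and removes sum(group size - 1) reports.
    """
    if policy != "keep_first":
        raise ValueError(f"unknown deduplication policy: {policy!r}")
    drop: set[str] = set()
    for group in find_duplicate_groups(corpus):
        keep = min(group.report_ids)
        drop.update(group.report_ids - {keep})
    kept = [r for r in corpus.reports if r.report_id not in drop]
    prov = dict(corpus.provenance)
    prov["deduplicated"] = {"policy": policy, "reports_removed": len(drop)}
    return Corpus(reports=kept, provenance=prov)
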