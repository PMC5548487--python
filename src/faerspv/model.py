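"""Data model for spontaneous safety reports and FAERS quarterly ASCII ingest.

A :class:`Corpus` is the unit every pipeline stage consumes and produces.
Reports are plain dataclasses; readers map the `$`-delimited quarterly
extracts (legacy LAERS and post-2012Q4 layouts) onto them, and
:func:`write_normalized` / :func:`read_normalized` round-trip a corpus
through three documented tab-separated tables.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

NORMALIZED_FORMAT_VERSION = "1"

OCCUPATIONS = (
    "physician",
    "pharmacist",
    "other_health_professional",
    "consumer",
    "lawyer",
    "unknown",
)

SEXES = ("M", "F", "unknown")

DRUG_ROLES = ("PS", "SS", "C", "I")

OUTCOMES = (
    "Death",
    "Life-Threatening",
    "Disability",
    "Congenital Anomaly",
    "Required Intervention",
    "Hospitalization",
    "Other",
)

#: FAERS occupation codes -> enum values; unrecognized codes map to ``unknown``.
OCCUPATION_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "HP": "other_health_professional",
    "OT": "other_health_professional",
    "CN": "consumer",
    "LW": "lawyer",
}

#: FAERS outcome codes -> the seven outcome descriptors; unrecognized -> Other.
OUTCOME_CODES = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention",
    "HO": "Hospitalization",
    "OT": "Other",
}

ROLE_CODES = {"PS": "PS", "SS": "SS", "C": "C", "I": "I"}

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


@dataclass(frozen=True)
class IngredientKey:
    """Identifier of a molecular ingredient.

    ``key`` is an InChIKey for small molecules or a non-proprietary name for
    macromolecules (for which no InChIKey is typically available).
    """

    key: str
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.key:
            raise ValueError("ingredient key must be non-empty")
        if _looks_like_inchikey(self.key) and not _INCHIKEY_RE.match(self.key):
            raise ValueError(f"malformed InChIKey: {self.key!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


def _looks_like_inchikey(key: str) -> bool:
    # any hyphenated triple of uppercase letter blocks is presumed to be an
    # (attempted) InChIKey and validated against the strict 14-10-1 shape;
    # everything else is a free-text non-proprietary name
    parts = key.split("-")
    return (
        len(parts) == 3
        and all(p.isalpha() and p.isupper() for p in parts)
    )


@dataclass
class DrugEntry:
    """One drug row within a report."""

    verbatim_name: str
    role: str = "PS"
    indication: Optional[str] = None
    ingredient_keys: frozenset[str] = frozenset()
    mapping_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.verbatim_name:
            raise ValueError("verbatim_name must be non-empty")
        if self.role not in DRUG_ROLES:
            raise ValueError(f"unknown drug role: {self.role!r}")
        self.ingredient_keys = frozenset(self.ingredient_keys)

    def with_mapping(self, keys: Iterable[str], score: Optional[float]) -> "DrugEntry":
        """Return a copy annotated with mapped ingredient keys.

        Mapping annotations are applied by replacement, never mutation, so a
        scored entry's keys are immutable.
        """
        return DrugEntry(
            verbatim_name=self.verbatim_name,
            role=self.role,
            indication=self.indication,
            ingredient_keys=frozenset(keys),
            mapping_score=score,
        )


@dataclass
class Report:
    """One safety report (ISR)."""

    report_id: str
    case_id: str
    drugs: list[DrugEntry]
    reactions: list[str]
    event_date: Optional[dt.date] = None
    receipt_date: Optional[dt.date] = None
    reporter_occupation: str = "unknown"
    patient_age: Optional[float] = None
    patient_sex: str = "unknown"
    outcomes: frozenset[str] = frozenset()
    event_date_imputed: bool = False

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError(f"report {self.report_id}: needs >=1 drug")
        if not self.reactions:
            raise ValueError(f"report {self.report_id}: needs >=1 reaction")
        if self.reporter_occupation not in OCCUPATIONS:
            raise ValueError(f"unknown occupation: {self.reporter_occupation!r}")
        if self.patient_sex not in SEXES:
            raise ValueError(f"unknown sex: {self.patient_sex!r}")
        if self.patient_age is not None and not (0 <= self.patient_age <= 120):
            raise ValueError(f"age out of range: {self.patient_age}")
        if self.event_date and self.receipt_date and self.event_date > self.receipt_date:
            raise ValueError(
                f"report {self.report_id}: event_date {self.event_date} after "
                f"receipt_date {self.receipt_date}"
            )
        bad = set(self.outcomes) - set(OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcomes: {sorted(bad)}")
        self.outcomes = frozenset(self.outcomes)

    def analysis_date(self) -> Optional[dt.date]:
        """Event date, falling back to receipt date for time-binned analyses."""
        return self.event_date if self.event_date is not None else self.receipt_date


@dataclass
class Corpus:
    """A collection of reports plus ingest provenance."""

    reports: list[Report]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.reports:
            if r.report_id in seen:
                raise ValueError(f"duplicate report_id: {r.report_id}")
            seen.add(r.report_id)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def by_case(self) -> dict[str, list[Report]]:
        groups: dict[str, list[Report]] = {}
        for r in self.reports:
            groups.setdefault(r.case_id, []).append(r)
        return groups


# ---------------------------------------------------------------------------
# FAERS quarterly ASCII ingest
# ---------------------------------------------------------------------------

#: Per-dialect column names. LAERS (pre-2012Q4) keys rows by ISR; the modern
#: layout uses primaryid/caseid; the canonical fixture dialect uses the
#: normalized names directly.
DIALECTS: dict[str, dict[str, str]] = {
    "legacy_LAERS": {
        "report_id": "ISR",
        "case_id": "CASE",
        "event_date": "EVENT_DT",
        "receipt_date": "FDA_DT",
        "occupation": "OCCP_COD",
        "age": "AGE",
        "age_unit": "AGE_COD",
        "sex": "GNDR_COD",
        "role": "ROLE_COD",
        "drug_name": "DRUGNAME",
        "reaction": "PT",
        "indication": "INDI_PT",
        "outcome": "OUTC_COD",
        "drug_seq": "DRUG_SEQ",
    },
    "FAERS_2012Q4+": {
        "report_id": "primaryid",
        "case_id": "caseid",
        "event_date": "event_dt",
        "receipt_date": "fda_dt",
        "occupation": "occp_cod",
        "age": "age",
        "age_unit": "age_cod",
        "sex": "sex",
        "role": "role_cod",
        "drug_name": "drugname",
        "reaction": "pt",
        "indication": "indi_pt",
        "outcome": "outc_cod",
        "drug_seq": "drug_seq",
    },
    "canonical_fixture": {
        "report_id": "report_id",
        "case_id": "case_id",
        "event_date": "event_date",
        "receipt_date": "receipt_date",
        "occupation": "occupation",
        "age": "age",
        "age_unit": "age_unit",
        "sex": "sex",
        "role": "role",
        "drug_name": "drug_name",
        "reaction": "reaction",
        "indication": "indication",
        "outcome": "outcome",
        "drug_seq": "drug_seq",
    },
}

#: Conversion factors from FAERS AGE_COD units to years.
_AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / (365.25 * 24.0),
    "": 1.0,
}


def _read_dollar_table(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return df


def _parse_date(raw: str) -> Optional[dt.date]:
    raw = raw.strip()
    if not raw:
        return None
    # FAERS dates come as YYYYMMDD (sometimes truncated); fixtures use ISO.
    try:
        if "-" in raw:
            return dt.date.fromisoformat(raw)
        if len(raw) == 8:
            return dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
        if len(raw) == 6:
            return dt.date(int(raw[:4]), int(raw[4:6]), 1)
        if len(raw) == 4:
            return dt.date(int(raw), 1, 1)
    except ValueError:
        return None
    return None


def _parse_age(raw_age: str, raw_unit: str) -> Optional[float]:
    raw_age = raw_age.strip()
    if not raw_age:
        return None
    try:
        value = float(raw_age)
    except ValueError:
        return None
    factor = _AGE_UNIT_TO_YEARS.get(raw_unit.strip().upper())
    if factor is None:
        return None
    years = value * factor
    if not (0 <= years <= 120):
        return None
    return years


def parse_quarter(
    demo_file,
    drug_file,
    reac_file,
    indi_file=None,
    outc_file=None,
    dialect: str = "canonical_fixture",
) -> Corpus:
    """Parse one quarterly extract (`$`-delimited ASCII tables) into a Corpus.

    Rows are joined on the per-dialect report key.  DRUG/REAC/INDI/OUTC rows
    whose key appears in no DEMO row are dropped and counted in provenance.
    Unrecognized occupation codes map to ``unknown`` and unrecognized outcome
    codes to ``Other``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    cols = DIALECTS[dialect]
    key = cols["report_id"]

    demo = _read_dollar_table(
        demo_file, [key, cols["case_id"], cols["event_date"], cols["receipt_date"]]
    )
    drug = _read_dollar_table(drug_file, [key, cols["role"], cols["drug_name"]])
    reac = _read_dollar_table(reac_file, [key, cols["reaction"]])
    indi = _read_dollar_table(indi_file, [key, cols["indication"]]) if indi_file else None
    outc = _read_dollar_table(outc_file, [key, cols["outcome"]]) if outc_file else None

    dropped = 0
    known = set(demo[key])

    def _rows_by_key(df: Optional[pd.DataFrame]):
        nonlocal dropped
        rows: dict[str, list] = {}
        if df is None:
            return rows
        for row in df.itertuples(index=False):
            rid = getattr(row, key).strip()
            if rid not in known:
                dropped += 1
                continue
            rows.setdefault(rid, []).append(row)
        return rows

    drug_rows = _rows_by_key(drug)
    reac_rows = _rows_by_key(reac)
    indi_rows = _rows_by_key(indi)
    outc_rows = _rows_by_key(outc)

    # indications attach to a (report, drug_seq) pair when sequence numbers
    # exist in both tables, else to the first drug of the report
    reports: list[Report] = []
    skipped_incomplete = 0
    for row in demo.itertuples(index=False):
        rid = getattr(row, key).strip()
        if not rid:
            dropped += 1
            continue
        if rid not in drug_rows or rid not in reac_rows:
            skipped_incomplete += 1
            continue

        indi_by_seq: dict[str, str] = {}
        indi_default: Optional[str] = None
        for irow in indi_rows.get(rid, []):
            term = getattr(irow, cols["indication"]).strip()
            if not term:
                continue
            seq = getattr(irow, cols["drug_seq"], "") if hasattr(irow, cols["drug_seq"]) else ""
            if seq:
                indi_by_seq[str(seq).strip()] = term
            elif indi_default is None:
                indi_default = term

        drugs = []
        for j, drow in enumerate(drug_rows[rid]):
            name = getattr(drow, cols["drug_name"]).strip()
            if not name:
                continue
            seq = str(getattr(drow, cols["drug_seq"], j + 1)).strip()
            indication = indi_by_seq.get(seq)
            if indication is None and j == 0:
                indication = indi_default
            drugs.append(
                DrugEntry(
                    verbatim_name=name,
                    role=ROLE_CODES.get(getattr(drow, cols["role"]).strip().upper(), "C"),
                    indication=indication,
                )
            )
        reactions = [
            getattr(rrow, cols["reaction"]).strip()
            for rrow in reac_rows[rid]
            if getattr(rrow, cols["reaction"]).strip()
        ]
        outcomes = {
            OUTCOME_CODES.get(getattr(orow, cols["outcome"]).strip().upper(), "Other")
            for orow in outc_rows.get(rid, [])
            if getattr(orow, cols["outcome"]).strip()
        }
        if not drugs or not reactions:
            skipped_incomplete += 1
            continue

        event_date = _parse_date(getattr(row, cols["event_date"], "") or "")
        receipt_date = _parse_date(getattr(row, cols["receipt_date"], "") or "")
        if event_date and receipt_date and event_date > receipt_date:
            event_date = None  # inconsistent dates: keep the authoritative receipt date
        reports.append(
            Report(
                report_id=rid,
                case_id=(getattr(row, cols["case_id"]).strip() or rid),
                drugs=drugs,
                reactions=reactions,
                event_date=event_date,
                receipt_date=receipt_date,
                reporter_occupation=OCCUPATION_CODES.get(
                    getattr(row, cols["occupation"], "").strip().upper(), "unknown"
                ),
                patient_age=_parse_age(
                    getattr(row, cols["age"], "") or "", getattr(row, cols["age_unit"], "") or ""
                ),
                patient_sex=(
                    getattr(row, cols["sex"], "").strip().upper()
                    if getattr(row, cols["sex"], "").strip().upper() in ("M", "F")
                    else "unknown"
                ),
                outcomes=frozenset(outcomes),
            )
        )

    return Corpus(
        reports=reports,
        provenance={
            "dialect": dialect,
            "rows_dropped_orphan": dropped,
            "reports_skipped_incomplete": skipped_incomplete,
            "reports_ingested": len(reports),
        },
    )


def latest_report_per_case(corpus: Corpus) -> Corpus:
    """Keep exactly one report per case: greatest receipt date, then greatest
    report_id lexicographically. Idempotent."""
    chosen: dict[str, Report] = {}
    for r in corpus.reports:
        cur = chosen.get(r.case_id)
        if cur is None:
            chosen[r.case_id] = r
            continue
        key_new = (r.receipt_date or dt.date.min, r.report_id)
        key_cur = (cur.receipt_date or dt.date.min, cur.report_id)
        if key_new > key_cur:
            chosen[r.case_id] = r
    kept = [r for r in corpus.reports if chosen[r.case_id] is r]
    prov = dict(corpus.provenance)
    prov["case_deduplicated"] = True
    prov["followup_reports_dropped"] = len(corpus.reports) - len(kept)
    return Corpus(reports=kept, provenance=prov)


# ---------------------------------------------------------------------------
# Normalized on-disk representation
# ---------------------------------------------------------------------------

_LIST_SEP = ";"


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_normalized(corpus: Corpus, path) -> None:
    """Write a corpus as three TSV tables plus a JSON manifest.

    ``reports.tsv`` has one row per report; ``report_drugs.tsv`` one row per
    (report, drug); ``report_reactions.tsv`` one row per (report, reaction).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rep_rows = []
    drug_rows = []
    reac_rows = []
    for r in corpus.reports:
        rep_rows.append(
            {
                "report_id": r.report_id,
                "case_id": r.case_id,
                "event_date": _fmt(r.event_date),
                "receipt_date": _fmt(r.receipt_date),
                "occupation": r.reporter_occupation,
                "age": _fmt(r.patient_age),
                "sex": r.patient_sex,
                "outcomes": _LIST_SEP.join(sorted(r.outcomes)),
                "event_date_imputed": int(r.event_date_imputed),
            }
        )
        for seq, d in enumerate(r.drugs, start=1):
            drug_rows.append(
                {
                    "report_id": r.report_id,
                    "drug_seq": seq,
                    "verbatim_name": d.verbatim_name,
                    "role": d.role,
                    "indication": _fmt(d.indication),
                    "ingredient_keys": _LIST_SEP.join(sorted(d.ingredient_keys)),
                    "mapping_score": _fmt(d.mapping_score),
                }
            )
        for term in r.reactions:
            reac_rows.append({"report_id": r.report_id, "reaction": term})

    pd.DataFrame(rep_rows, columns=[
        "report_id", "case_id", "event_date", "receipt_date", "occupation",
        "age", "sex", "outcomes", "event_date_imputed",
    ]).to_csv(path / "reports.tsv", sep="\t", index=False)
    pd.DataFrame(drug_rows, columns=[
        "report_id", "drug_seq", "verbatim_name", "role", "indication",
        "ingredient_keys", "mapping_score",
    ]).to_csv(path / "report_drugs.tsv", sep="\t", index=False)
    pd.DataFrame(reac_rows, columns=["report_id", "reaction"]).to_csv(
        path / "report_reactions.tsv", sep="\t", index=False
    )
    (path / "corpus.json").write_text(
        json.dumps(
            {"format_version": NORMALIZED_FORMAT_VERSION, "provenance": corpus.provenance},
            indent=2,
            default=str,
        )
    )


def read_normalized(path) -> Corpus:
    """Inverse of :func:`write_normalized` (round-trip identity)."""
    path = Path(path)
    meta = json.loads((path / "corpus.json").read_text())
    if meta.get("format_version") != NORMALIZED_FORMAT_VERSION:
        raise FormatError(
            f"normalized-corpus format version mismatch: "
            f"found {meta.get('format_version')!r}, expected {NORMALIZED_FORMAT_VERSION!r}"
        )
    reps = pd.read_csv(path / "reports.tsv", sep="\t", dtype=str, keep_default_na=False)
    drugs = pd.read_csv(path / "report_drugs.tsv", sep="\t", dtype=str, keep_default_na=False)
    reacs = pd.read_csv(path / "report_reactions.tsv", sep="\t", dtype=str, keep_default_na=False)

    drugs_by_report: dict[str, list[DrugEntry]] = {}
    for row in drugs.itertuples(index=False):
        drugs_by_report.setdefault(row.report_id, []).append(
            DrugEntry(
                verbatim_name=row.verbatim_name,
                role=row.role,
                indication=row.indication or None,
                ingredient_keys=frozenset(
                    k for k in row.ingredient_keys.split(_LIST_SEP) if k
                ),
                mapping_score=float(row.mapping_score) if row.mapping_score else None,
            )
        )
    reacs_by_report: dict[str, list[str]] = {}
    for row in reacs.itertuples(index=False):
        reacs_by_report.setdefault(row.report_id, []).append(row.reaction)

    reports = []
    for row in reps.itertuples(index=False):
        reports.append(
            Report(
                report_id=row.report_id,
                case_id=row.case_id,
                drugs=drugs_by_report.get(row.report_id, []),
                reactions=reacs_by_report.get(row.report_id, []),
                event_date=dt.date.fromisoformat(row.event_date) if row.event_date else None,
                receipt_date=dt.date.fromisoformat(row.receipt_date) if row.receipt_date else None,
                reporter_occupation=row.occupation,
                patient_age=float(row.age) if row.age else None,
                patient_sex=row.sex,
                outcomes=frozenset(o for o in row.outcomes.split(_LIST_SEP) if o),
                event_date_imputed=bool(int(row.event_date_imputed)),
            )
        )
    return Corpus(reports=reports, provenance=meta.get("provenance", {}))
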