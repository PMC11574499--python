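"""Claims data model and delimited-table IO.

Four CSV contracts, all with required header rows:

=========  =====================================================
table      columns
=========  =====================================================
pharmacy   patient_id, claim_id, fill_date, days_supply, gpi
dx         patient_id, date, icd9
px         patient_id, date, cpt
gold       patient_id[, era_start], label   (label: PREP/NOT_PREP)
=========  =====================================================

Dates are ISO-8601 text in files and ``datetime.date`` objects in memory;
all downstream arithmetic is day-granular. Rows that violate a row-level
invariant (unparseable date, ``days_supply`` < 1, empty code) are rejected
and reported with their row number rather than aborting the load:
administrative claims are dirty, and surveillance use favors robustness
with an audit trail. Structural problems — a missing column, a duplicate
claim id, a gold label for a patient absent from the pharmacy table — are
errors.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codebook import CodeSystem

__all__ = [
    "PharmacyClaim",
    "ClinicalEvent",
    "GoldLabel",
    "CohortDataset",
    "RowRejection",
    "ResultRow",
    "ClaimsModelError",
    "read_cohort",
    "write_cohort",
    "write_results",
    "read_results",
    "REASON_DELIMITER",
]

#: Delimiter joining the ordered exclusion reasons in the results CSV.
REASON_DELIMITER = "|"


class ClaimsModelError(ValueError):
    """Structural problem in an input table."""


@dataclass(frozen=True, order=True)
class PharmacyClaim:
    """One dispensing event."""

    patient_id: str
    fill_date: dt.date
    days_supply: int
    gpi: str
    claim_id: str


@dataclass(frozen=True, order=True)
class ClinicalEvent:
    """One dated diagnosis (ICD-9) or procedure (CPT) record."""

    patient_id: str
    date: dt.date
    system: CodeSystem
    code: str


@dataclass(frozen=True)
class GoldLabel:
    """Reference PrEP / not-PrEP label, per patient or per era."""

    patient_id: str
    label: str  # PREP | NOT_PREP
    era_start: dt.date | None = None  # None => patient-level label


@dataclass(frozen=True)
class RowRejection:
    table: str
    row: int  # 1-based data-row number (header excluded)
    reason: str


@dataclass
class CohortDataset:
    """In-memory cohort: pharmacy claims, clinical events, optional gold labels."""

    claims: list[PharmacyClaim] = field(default_factory=list)
    events: list[ClinicalEvent] = field(default_factory=list)
    gold: list[GoldLabel] | None = None
    rejections: list[RowRejection] = field(default_factory=list)

    def sorted(self) -> "CohortDataset":
        """Canonical ordering, making the loader order-insensitive."""
        return CohortDataset(
            claims=sorted(self.claims, key=lambda c: (c.patient_id, c.fill_date, c.claim_id)),
            events=sorted(self.events, key=lambda e: (e.patient_id, e.date, e.system.value, e.code)),
            gold=None
            if self.gold is None
            else sorted(self.gold, key=lambda g: (g.patient_id, g.era_start or dt.date.min)),
            rejections=list(self.rejections),
        )

    @property
    def patient_ids(self) -> set[str]:
        return {c.patient_id for c in self.claims}


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(str(text).strip())


def _require_columns(df: pd.DataFrame, cols: list[str], table: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ClaimsModelError(f"{table} table {path}: missing column(s) {missing}")


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_cohort(
    pharmacy_path: str | Path,
    dx_path: str | Path,
    px_path: str | Path,
    gold_path: str | Path | None = None,
) -> CohortDataset:
    """Load a cohort from CSV tables; see the module docstring for contracts.

    Codes are kept raw — normalization happens at matching time. The returned
    dataset is canonically sorted; ``rejections`` lists every dropped row.
    """
    rejections: list[RowRejection] = []

    pharm = _read_csv(pharmacy_path)
    _require_columns(pharm, ["patient_id", "claim_id", "fill_date", "days_supply", "gpi"],
                     "pharmacy", pharmacy_path)
    claims: list[PharmacyClaim] = []
    seen_claim_ids: set[str] = set()
    for i, row in enumerate(pharm.itertuples(index=False), start=1):
        try:
            fill = _parse_date(row.fill_date)
            supply = int(row.days_supply)
        except (ValueError, TypeError):
            rejections.append(RowRejection("pharmacy", i, "unparseable fill_date or days_supply"))
            continue
        if supply < 1:
            rejections.append(RowRejection("pharmacy", i, f"days_supply {supply} < 1"))
            continue
        if not str(row.gpi).strip():
            rejections.append(RowRejection("pharmacy", i, "empty gpi"))
            continue
        if row.claim_id in seen_claim_ids:
            raise ClaimsModelError(f"pharmacy table: duplicate claim_id {row.claim_id!r}")
        seen_claim_ids.add(row.claim_id)
        claims.append(PharmacyClaim(str(row.patient_id), fill, supply, str(row.gpi), str(row.claim_id)))

    events: list[ClinicalEvent] = []
    for path, col, system, table in (
        (dx_path, "icd9", CodeSystem.ICD9_DX, "dx"),
        (px_path, "cpt", CodeSystem.CPT, "px"),
    ):
        df = _read_csv(path)
        _require_columns(df, ["patient_id", "date", col], table, path)
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                date = _parse_date(row.date)
            except ValueError:
                rejections.append(RowRejection(table, i, "unparseable date"))
                continue
            code = str(getattr(row, col)).strip()
            if not code:
                rejections.append(RowRejection(table, i, f"empty {col}"))
                continue
            events.append(ClinicalEvent(str(row.patient_id), date, system, code))

    gold: list[GoldLabel] | None = None
    if gold_path is not None:
        gdf = _read_csv(gold_path)
        _require_columns(gdf, ["patient_id", "label"], "gold", gold_path)
        era_level = "era_start" in gdf.columns
        known = {c.patient_id for c in claims}
        gold = []
        seen_keys: set[tuple] = set()
        for i, row in enumerate(gdf.itertuples(index=False), start=1):
            label = str(row.label).strip().upper()
            if label not in ("PREP", "NOT_PREP"):
                rejections.append(RowRejection("gold", i, f"invalid label {row.label!r}"))
                continue
            pid = str(row.patient_id)
            if pid not in known:
                raise ClaimsModelError(f"gold table: label for unknown patient {pid!r}")
            era_start = _parse_date(row.era_start) if era_level else None
            key = (pid, era_start)
            if key in seen_keys:
                raise ClaimsModelError(f"gold table: duplicate key {key}")
            seen_keys.add(key)
            gold.append(GoldLabel(pid, label, era_start))

    return CohortDataset(claims=claims, events=events, gold=gold, rejections=rejections).sorted()


def write_cohort(dataset: CohortDataset, out_dir: str | Path,
                 prefix: str = "") -> dict[str, Path]:
    """Write a dataset back out as the four CSV tables (gold only if present).

    Column order and row sort are deterministic so repeated runs are
    byte-identical. Returns the mapping of table name to file path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = dataset.sorted()
    paths: dict[str, Path] = {}

    pharm = pd.DataFrame(
        [(c.patient_id, c.claim_id, c.fill_date.isoformat(), c.days_supply, c.gpi) for c in ds.claims],
        columns=["patient_id", "claim_id", "fill_date", "days_supply", "gpi"],
    )
    paths["pharmacy"] = out / f"{prefix}pharmacy.csv"
    pharm.to_csv(paths["pharmacy"], index=False)

    for name, system, col in (("dx", CodeSystem.ICD9_DX, "icd9"), ("px", CodeSystem.CPT, "cpt")):
        rows = [(e.patient_id, e.date.isoformat(), e.code) for e in ds.events if e.system is system]
        df = pd.DataFrame(rows, columns=["patient_id", "date", col])
        paths[name] = out / f"{prefix}{name}.csv"
        df.to_csv(paths[name], index=False)

    if ds.gold is not None:
        era_level = any(g.era_start is not None for g in ds.gold)
        if era_level:
            rows = [(g.patient_id, "" if g.era_start is None else g.era_start.isoformat(), g.label)
                    for g in ds.gold]
            gdf = pd.DataFrame(rows, columns=["patient_id", "era_start", "label"])
        else:
            gdf = pd.DataFrame([(g.patient_id, g.label) for g in ds.gold],
                               columns=["patient_id", "label"])
        paths["gold"] = out / f"{prefix}gold.csv"
        gdf.to_csv(paths["gold"], index=False)
    return paths


@dataclass(frozen=True)
class ResultRow:
    """One classified exposure era, as serialized in the results CSV."""

    patient_id: str
    drug_class: str
    index_date: dt.date
    era_start: dt.date
    era_end: dt.date
    duration_days: int
    label: str
    reasons: tuple[str, ...]


_RESULT_COLUMNS = ["patient_id", "drug_class", "index_date", "era_start",
                   "era_end", "duration_days", "label", "reasons"]


def write_results(results: list, path: str | Path) -> Path:
    """Write classification results (IndicationResult or ResultRow) to CSV.

    Reasons are joined with :data:`REASON_DELIMITER`; an empty list writes an
    empty field. ``read_results(write_results(x)) == x`` at the row level.
    """
    rows = []
    for r in results:
        row = r.to_row() if hasattr(r, "to_row") else r
        rows.append((
            row.patient_id, row.drug_class, row.index_date.isoformat(),
            row.era_start.isoformat(), row.era_end.isoformat(),
            row.duration_days, row.label, REASON_DELIMITER.join(row.reasons),
        ))
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_results(path: str | Path) -> list[ResultRow]:
    df = _read_csv(path)
    _require_columns(df, _RESULT_COLUMNS, "results", path)
    out = []
    for row in df.itertuples(index=False):
        reasons = tuple(s for s in str(row.reasons).split(REASON_DELIMITER) if s)
        out.append(ResultRow(
            patient_id=str(row.patient_id),
            drug_class=str(row.drug_class),
            index_date=_parse_date(row.index_date),
            era_start=_parse_date(row.era_start),
            era_end=_parse_date(row.era_end),
            duration_days=int(row.duration_days),
            label=str(row.label),
            reasons=reasons,
        ))
    return out
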