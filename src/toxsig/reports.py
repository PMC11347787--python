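"""Spontaneous adverse-event report tables: reading, writing, screening, PT→SOC mapping.

A spontaneous report (FAERS-style) carries one or more drug entries with a
causality role, a non-empty list of MedDRA Preferred Terms (PTs) describing
the events, and categorical demographics.  Two text dialects are supported:

``simple_tsv``
    Tab-separated, one report per row, PTs joined by ``;``.
``openvigil_csv``
    Comma-separated with quoted multi-value cells, list items joined by ``,``
    (the shape of an OpenVigil frequency export).

Screening replaces manual reviewer adjudication with auditable, configurable
pattern blocklists: a report whose every PT matches a report-level pattern is
dropped outright (e.g. product-quality complaints), while PT-level patterns
remove individual terms (e.g. the drug's own indication, to avoid indication
bias) and drop the report only if nothing is left.  Every removal is logged
with a reason.
"""

from __future__ import annotations

import datetime as _dt
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

UNKNOWN = "unknown"

#: Recognised drug causality roles.
ROLES = ("primary suspect", "secondary suspect", "concomitant", "interacting", "unknown")

#: Roles retained by default during screening: the four named causality roles.
DEFAULT_ROLES = frozenset(ROLES[:4])


class ReportFormatError(ValueError):
    """A report table does not conform to the declared dialect."""


def normalize_term(term: str) -> str:
    """Collapse whitespace and lowercase — the canonical form for PT/drug matching."""
    return re.sub(r"\s+", " ", term.strip()).lower()


# ---------------------------------------------------------------------------
# list-cell escaping: within a multi-value cell, items are joined by the
# dialect's list separator; a literal separator inside an item is escaped
# with a backslash so round-trips are lossless.

def _join_list(items: Iterable[str], sep: str) -> str:
    return sep.join(i.replace("\\", "\\\\").replace(sep, "\\" + sep) for i in items)


def _split_list(cell: str, sep: str) -> list[str]:
    if cell == "":
        return []
    out: list[str] = []
    buf: list[str] = []
    i = 0
    while i < len(cell):
        ch = cell[i]
        if ch == "\\" and i + 1 < len(cell):
            buf.append(cell[i + 1])
            i += 2
        elif ch == sep:
            out.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(ch)
            i += 1
    out.append("".join(buf))
    return out


@dataclass(frozen=True)
class DrugEntry:
    """One drug named on a report, with its causality role."""

    name: str
    role: str = "primary suspect"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown drug role {self.role!r}; expected one of {ROLES}")
        if not self.name.strip():
            raise ValueError("drug name must be non-empty")


@dataclass
class ReportRecord:
    """A single spontaneous adverse-event report."""

    report_id: str
    drug_entries: tuple[DrugEntry, ...]
    pts: tuple[str, ...]
    sex: str = UNKNOWN
    age_years: float | None = None
    country: str = UNKNOWN
    received_date: _dt.date | None = None
    outcome: str = UNKNOWN

    def __post_init__(self) -> None:
        self.drug_entries = tuple(self.drug_entries)
        self.pts = tuple(self.pts)
        if not self.pts:
            raise ValueError(f"report {self.report_id!r}: PT list must be non-empty")
        if not self.drug_entries:
            raise ValueError(f"report {self.report_id!r}: at least one drug entry required")

    def pt_set(self) -> frozenset[str]:
        """Normalized, deduplicated PTs (a report counts once per PT)."""
        return frozenset(normalize_term(p) for p in self.pts)

    def drug_names(self) -> frozenset[str]:
        return frozenset(normalize_term(e.name) for e in self.drug_entries)


@dataclass
class ReportSet:
    """A collection of reports with free-text provenance (query, date window, ...)."""

    records: list[ReportRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
            raise ReportFormatError(f"duplicate report ids: {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class MedDRADict:
    """PT → SOC dictionary (one SOC per PT); lookups are case/whitespace-insensitive."""

    pt_to_soc: dict[str, str]

    def __post_init__(self) -> None:
        index: dict[str, str] = {}
        for pt, soc in self.pt_to_soc.items():
            key = normalize_term(pt)
            if key in index and index[key] != soc:
                raise ValueError(f"PT {pt!r} maps to both {index[key]!r} and {soc!r}")
            index[key] = soc
        self._index = index

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self._index

    def soc_of(self, pt: str) -> str | None:
        return self._index.get(normalize_term(pt))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MedDRADict":
        """Read a two-column ``pt<TAB>soc`` file; a ``pt``/``soc`` header row is skipped."""
        pairs: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ReportFormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
                pt, soc = parts[0].strip(), parts[1].strip()
                if lineno == 1 and normalize_term(pt) == "pt" and normalize_term(soc) == "soc":
                    continue
                pairs[pt] = soc
        return cls(pairs)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pt\tsoc\n")
            for pt in sorted(self.pt_to_soc):
                fh.write(f"{pt}\t{self.pt_to_soc[pt]}\n")


# ---------------------------------------------------------------------------
# table IO

_DIALECTS = {
    "simple_tsv": {"sep": "\t", "list_sep": ";"},
    "openvigil_csv": {"sep": ",", "list_sep": ","},
}

_COLUMNS = (
    "report_id", "drug", "role", "pts", "sex", "age_years",
    "country", "received_date", "outcome",
)


def _parse_age(cell: str) -> float | None:
    try:
        v = float(cell)
    except ValueError:
        return None
    return v if v >= 0 else None


def _parse_date(cell: str) -> _dt.date | None:
    try:
        return _dt.date.fromisoformat(cell)
    except ValueError:
        return None


def read_reports(path: str | Path, dialect: str = "simple_tsv") -> ReportSet:
    """Read a report table, preserving row order.

    Unknown or unparsable demographic fields become the unknown sentinel
    (``"unknown"`` for categoricals, ``None`` for age and date).  Missing
    mandatory columns and duplicate report ids raise :class:`ReportFormatError`.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep, list_sep = _DIALECTS[dialect]["sep"], _DIALECTS[dialect]["list_sep"]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ReportFormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    records: list[ReportRecord] = []
    for row in df.itertuples(index=False):
        names = _split_list(getattr(row, "drug"), list_sep)
        roles = _split_list(getattr(row, "role"), list_sep)
        roles += ["unknown"] * (len(names) - len(roles))
        entries = [DrugEntry(n, r) for n, r in zip(names, roles)]
        for con in _split_list(getattr(row, "concomitant_drugs", ""), list_sep):
            entries.append(DrugEntry(con, "concomitant"))
        pts = [p for p in _split_list(getattr(row, "pts"), list_sep) if p.strip()]
        if not pts:
            raise ReportFormatError(f"{path}: report {row.report_id!r} has no PTs")
        sex = normalize_term(getattr(row, "sex"))
        records.append(ReportRecord(
            report_id=row.report_id,
            drug_entries=tuple(entries),
            pts=tuple(pts),
            sex=sex if sex in ("male", "female") else UNKNOWN,
            age_years=_parse_age(getattr(row, "age_years")),
            country=getattr(row, "country").strip() or UNKNOWN,
            received_date=_parse_date(getattr(row, "received_date")),
            outcome=getattr(row, "outcome").strip() or UNKNOWN,
        ))
    return ReportSet(records, provenance=str(path))


def write_reports(rs: ReportSet, path: str | Path, dialect: str = "simple_tsv") -> None:
    """Write a report table; inverse of :func:`read_reports` on the same dialect."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep, list_sep = _DIALECTS[dialect]["sep"], _DIALECTS[dialect]["list_sep"]
    rows = []
    for r in rs:
        suspects = [e for e in r.drug_entries if e.role != "concomitant"]
        concomitant = [e for e in r.drug_entries if e.role == "concomitant"]
        rows.append({
            "report_id": r.report_id,
            "drug": _join_list([e.name for e in suspects], list_sep),
            "role": _join_list([e.role for e in suspects], list_sep),
            "pts": _join_list(r.pts, list_sep),
            "sex": r.sex,
            "age_years": "" if r.age_years is None else repr(float(r.age_years)),
            "country": "" if r.country == UNKNOWN else r.country,
            "received_date": "" if r.received_date is None else r.received_date.isoformat(),
            "outcome": "" if r.outcome == UNKNOWN else r.outcome,
            "concomitant_drugs": _join_list([e.name for e in concomitant], list_sep),
        })
    df = pd.DataFrame(rows, columns=list(_COLUMNS) + ["concomitant_drugs"])
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# screening

@dataclass(frozen=True)
class ScreenSpec:
    """Screening rules standing in for manual report adjudication.

    ``report_blocklist_patterns`` drop a report when *every* PT matches one of
    them; ``pt_blocklist_patterns`` remove matching PTs from each report and
    drop the report if no PT survives.  Patterns are case-insensitive regular
    expressions matched against whitespace-normalized PTs.  The date window is
    inclusive on both ends; reports with an unknown date are retained.
    """

    report_blocklist_patterns: tuple[str, ...] = ()
    pt_blocklist_patterns: tuple[str, ...] = ()
    date_window: tuple[_dt.date, _dt.date] | None = None
    roles_included: frozenset[str] = DEFAULT_ROLES

    def __post_init__(self) -> None:
        for p in self.report_blocklist_patterns + self.pt_blocklist_patterns:
            re.compile(p)  # raises re.error for a malformed pattern
        if self.date_window is not None and self.date_window[0] > self.date_window[1]:
            raise ValueError("date_window start must be <= end")
        bad = set(self.roles_included) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")


@dataclass
class ScreenResult:
    retained: ReportSet
    removed: ReportSet
    log: list[tuple[str, tuple[str, ...]]]  # (report_id, reasons) for removed reports


def screen_reports(rs: ReportSet, spec: ScreenSpec) -> ScreenResult:
    """Partition a report set into retained and removed reports, with reasons.

    Every input report lands in exactly one of the two outputs; each removed
    report carries at least one logged reason.  Screening is idempotent on the
    retained set.
    """
    rep_pats = [re.compile(p, re.IGNORECASE) for p in spec.report_blocklist_patterns]
    pt_pats = [re.compile(p, re.IGNORECASE) for p in spec.pt_blocklist_patterns]
    retained: list[ReportRecord] = []
    removed: list[ReportRecord] = []
    log: list[tuple[str, tuple[str, ...]]] = []
    for r in rs:
        reasons: list[str] = []
        if not ({e.role for e in r.drug_entries} & spec.roles_included):
            reasons.append("no drug entry with an included role")
        if spec.date_window is not None and r.received_date is not None:
            start, end = spec.date_window
            if not (start <= r.received_date <= end):
                reasons.append(f"received_date {r.received_date.isoformat()} outside window")
        # PT-level trim first, then the report-level check on the surviving
        # PTs: this order makes screening idempotent on the retained set.
        kept = [p for p in r.pts
                if not any(pat.search(normalize_term(p)) for pat in pt_pats)]
        if not kept:
            reasons.append("all PTs removed by the PT blocklist")
        elif rep_pats and all(any(p.search(normalize_term(k)) for p in rep_pats)
                              for k in kept):
            reasons.append("every PT matches the report blocklist")
        if reasons:
            removed.append(r)
            log.append((r.report_id, tuple(reasons)))
        else:
            retained.append(r if len(kept) == len(r.pts) else replace(r, pts=tuple(kept)))
    prov = (rs.provenance + " | screened").strip(" |")
    return ScreenResult(ReportSet(retained, prov), ReportSet(removed, prov), log)


def map_pt_to_soc(pts: Sequence[str], meddra: MedDRADict,
                  on_missing: str = "error") -> dict[str, str]:
    """Resolve each PT to its SOC.

    ``on_missing`` decides the fate of PTs absent from the dictionary:
    ``"error"`` raises, ``"skip"`` omits them, ``"unmapped"`` buckets them
    under the literal SOC name ``"unmapped"``.
    """
    if len(meddra) == 0:
        raise ValueError("empty MedDRA dictionary")
    if on_missing not in ("error", "skip", "unmapped"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    out: dict[str, str] = {}
    for pt in pts:
        soc = meddra.soc_of(pt)
        if soc is None:
            if on_missing == "error":
                raise KeyError(f"PT not in dictionary: {pt!r}")
            if on_missing == "skip":
                continue
            soc = "unmapped"
        out[pt] = soc
    return out
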