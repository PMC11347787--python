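"""Disproportionality analysis of spontaneous-report data.

The signal-detection engine: for one drug of interest against the background
of all other drugs in the report set, each adverse-event Preferred Term (PT)
yields a 2x2 contingency table

    =============  ===========  ==========
    .              target PT    other PTs
    =============  ===========  ==========
    target drug    a            b
    other drugs    c            d
    =============  ===========  ==========

from which three frequentist statistics are computed:

* reporting odds ratio  ROR = ad / bc, with a 95% Wald CI on the log scale,
  exp(ln ROR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d));
* proportional reporting ratio  PRR = [a/(a+b)] / [c/(c+d)];
* Pearson chi-square of the table, plain or with Yates continuity correction.

A PT is a *positive signal* when it passes the combined ROR + MHRA gate:
a >= 3 reports, ROR CI lower bound > 1, PRR >= 2 and chi-square >= 4.  The
module also aggregates positive PTs to System Organ Classes (SOCs), selects
"key SOCs" by the > 3 PTs and > 10 reports rule, and produces descriptive
count/percentage tables of the demographic fields.

Zero cells make the odds ratio and its CI undefined; the default policy keeps
them undefined (the affected gates then fail), with an optional
Haldane-Anscombe +0.5 continuity correction that is flagged in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reports import MedDRADict, ReportSet, map_pt_to_soc, normalize_term

__all__ = [
    "ContingencyTable", "SignalStatistics", "SignalCriteria", "SignalResult",
    "SOCSummary", "DescriptiveTable", "build_contingency", "ror_with_ci",
    "prr", "chi_square", "compute_statistics", "evaluate_signal",
    "detect_all_signals", "aggregate_by_soc", "select_key_socs",
    "descriptive_distribution", "percentage", "signals_to_dataframe",
    "DEFAULT_EXCLUDED_SOCS",
]

#: Non-organ SOCs excluded by default from key-SOC selection.
DEFAULT_EXCLUDED_SOCS = (
    "investigations",
    "infections and infestations",
    "general disorders and administration site conditions",
)


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the drug-event 2x2 table (non-negative integers, n >= 1)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("contingency table must contain at least one report")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalStatistics:
    """ROR/PRR/chi-square for one table; ``None`` marks an undefined statistic."""

    ror: float | None
    ror_ci95: tuple[float, float] | None
    prr: float | None
    chi2: float | None
    chi2_variant: str = "yates"
    continuity_corrected: bool = False  # True when Haldane-Anscombe +0.5 was applied


@dataclass(frozen=True)
class SignalCriteria:
    """The combined ROR + MHRA positivity gate.

    The CI gate is strict (lower bound must *exceed* the threshold); the PRR
    and chi-square gates are non-strict (>=).
    """

    min_reports: int = 3
    ror_ci_lower_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0

    def __post_init__(self) -> None:
        if self.min_reports < 1:
            raise ValueError("min_reports must be >= 1")


@dataclass(frozen=True)
class SignalResult:
    pt: str
    table: ContingencyTable
    stats: SignalStatistics
    positive: bool
    criteria_trace: Mapping[str, bool]


@dataclass(frozen=True)
class SOCSummary:
    soc: str
    pt_count: int
    report_count: int
    pts: tuple[str, ...]


@dataclass(frozen=True)
class DescriptiveTable:
    """Counts and 2-dp half-up percentages of one demographic field."""

    field: str
    bins: tuple[str, ...]
    counts: tuple[int, ...]
    percentages: tuple[float, ...]
    denominator: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": self.bins, "count": self.counts, "percentage": self.percentages,
        })


def percentage(count: int, denominator: int) -> float:
    """100*count/denominator rounded half-up to two decimals (display convention)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return float((Decimal(count * 100) / Decimal(denominator))
                 .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# tables and statistics

def build_contingency(rs: ReportSet, drug: str, pt: str) -> ContingencyTable:
    """Classify every report into exactly one cell of the drug x PT table.

    A report counts once per cell regardless of how many times the PT is
    listed on it (PT lists are deduplicated within a report).  A drug absent
    from the set legally yields a = b = 0.
    """
    if len(rs) == 0:
        raise ValueError("empty report set")
    if not pt.strip():
        raise ValueError("empty PT string")
    drug_n = normalize_term(drug)
    pt_n = normalize_term(pt)
    a = b = c = d = 0
    for r in rs:
        has_drug = drug_n in r.drug_names()
        has_pt = pt_n in r.pt_set()
        if has_drug and has_pt:
            a += 1
        elif has_drug:
            b += 1
        elif has_pt:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _effective_cells(t: ContingencyTable, zero_cell: str) -> tuple[float, float, float, float, bool]:
    if zero_cell not in ("undefined", "haldane"):
        raise ValueError(f"unknown zero-cell policy {zero_cell!r}")
    a, b, c, d = (float(x) for x in t.cells())
    if zero_cell == "haldane" and min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return a, b, c, d, False


def ror_with_ci(t: ContingencyTable, zero_cell: str = "undefined",
                ) -> tuple[float, float, float] | None:
    """ROR = ad/bc with the 95% Wald CI; ``None`` when a zero cell leaves it undefined."""
    a, b, c, d, _ = _effective_cells(t, zero_cell)
    if min(a, b, c, d) == 0:
        return None
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = 1.96 * se
    return ror, math.exp(math.log(ror) - half), math.exp(math.log(ror) + half)


def prr(t: ContingencyTable, zero_cell: str = "undefined") -> float | None:
    """PRR = [a/(a+b)] / [c/(c+d)]; ``None`` when the comparator rate is undefined."""
    a, b, c, d, _ = _effective_cells(t, zero_cell)
    if a + b == 0 or c == 0:
        return None
    return (a / (a + b)) / (c / (c + d))


def chi_square(t: ContingencyTable, variant: str = "yates") -> float | None:
    """Pearson chi-square of the 2x2 table.

    ``plain``  n(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)]
    ``yates``  n(|ad-bc| - n/2)^2 / [same denominator], floored at 0 when
               |ad-bc| <= n/2.

    Returns ``None`` when any margin is zero (statistic undefined).
    """
    if variant not in ("plain", "yates"):
        raise ValueError(f"unknown chi-square variant {variant!r}")
    a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return None
    diff = a * d - b * c
    if variant == "plain":
        return n * diff * diff / denom
    adj = abs(diff) - n / 2
    if adj <= 0:
        return 0.0
    return n * adj * adj / denom


def compute_statistics(t: ContingencyTable, variant: str = "yates",
                       zero_cell: str = "undefined") -> SignalStatistics:
    res = ror_with_ci(t, zero_cell)
    _, _, _, _, corrected = _effective_cells(t, zero_cell)
    return SignalStatistics(
        ror=res[0] if res else None,
        ror_ci95=(res[1], res[2]) if res else None,
        prr=prr(t, zero_cell),
        chi2=chi_square(t, variant),
        chi2_variant=variant,
        continuity_corrected=corrected,
    )


def evaluate_signal(pt: str, t: ContingencyTable, crit: SignalCriteria = SignalCriteria(),
                    variant: str = "yates", zero_cell: str = "undefined") -> SignalResult:
    """Apply the combined positivity criteria to one table.

    An undefined statistic fails its gate; ``positive`` is the conjunction of
    all gates, each recorded in ``criteria_trace``.
    """
    stats = compute_statistics(t, variant, zero_cell)
    trace = {
        "min_reports": t.a >= crit.min_reports,
        "ror_ci_lower": stats.ror_ci95 is not None and stats.ror_ci95[0] > crit.ror_ci_lower_gt,
        "prr": stats.prr is not None and stats.prr >= crit.prr_min,
        "chi2": stats.chi2 is not None and stats.chi2 >= crit.chi2_min,
    }
    return SignalResult(pt=pt, table=t, stats=stats, positive=all(trace.values()),
                        criteria_trace=trace)


def detect_all_signals(rs: ReportSet, drug: str, crit: SignalCriteria = SignalCriteria(),
                       variant: str = "yates", zero_cell: str = "undefined",
                       ) -> list[SignalResult]:
    """Evaluate every PT co-reported with the drug.

    Returns one :class:`SignalResult` per distinct PT appearing on at least
    one report of the drug (negatives included, with their full gate trace),
    sorted by descending report count a, ties broken lexicographically by PT.
    """
    drug_n = normalize_term(drug)
    total = len(rs)
    if total == 0:
        return []
    n_drug = 0
    a_counts: dict[str, int] = {}
    pt_totals: dict[str, int] = {}
    display: dict[str, str] = {}
    for r in rs:
        has_drug = drug_n in r.drug_names()
        if has_drug:
            n_drug += 1
        for raw in r.pts:
            key = normalize_term(raw)
            display.setdefault(key, raw)
        for key in r.pt_set():
            pt_totals[key] = pt_totals.get(key, 0) + 1
            if has_drug:
                a_counts[key] = a_counts.get(key, 0) + 1
    results = []
    for key, a in a_counts.items():
        b = n_drug - a
        c = pt_totals[key] - a
        d = total - n_drug - c
        t = ContingencyTable(a, b, c, d)
        results.append(evaluate_signal(display[key], t, crit, variant, zero_cell))
    results.sort(key=lambda r: (-r.table.a, normalize_term(r.pt)))
    return results


def aggregate_by_soc(signals: Iterable[SignalResult], meddra: MedDRADict,
                     on_missing: str = "error") -> list[SOCSummary]:
    """Group positive signals by SOC.

    ``report_count`` sums the per-PT a-cells without deduplicating reports
    that span several positive PTs (the convention of per-PT count summing).
    Sorted by PT count desc, report count desc, then SOC name.
    """
    positives = [s for s in signals if s.positive]
    soc_map = map_pt_to_soc([s.pt for s in positives], meddra, on_missing)
    grouped: dict[str, list[SignalResult]] = {}
    for s in positives:
        if s.pt not in soc_map:  # on_missing="skip"
            continue
        grouped.setdefault(soc_map[s.pt], []).append(s)
    out = []
    for soc, members in grouped.items():
        members.sort(key=lambda s: (-s.table.a, normalize_term(s.pt)))
        out.append(SOCSummary(
            soc=soc,
            pt_count=len(members),
            report_count=sum(s.table.a for s in members),
            pts=tuple(s.pt for s in members),
        ))
    out.sort(key=lambda s: (-s.pt_count, -s.report_count, s.soc))
    return out


def select_key_socs(summaries: Iterable[SOCSummary], min_pt: int = 3,
                    min_reports: int = 10,
                    exclude_socs: Sequence[str] = DEFAULT_EXCLUDED_SOCS,
                    ) -> list[SOCSummary]:
    """Keep SOCs with PT count > min_pt AND report count > min_reports (strict).

    Non-organ SOCs in ``exclude_socs`` (matched case-insensitively) are dropped
    regardless of size: they do not describe a specific organ system and are
    not meaningful units for mechanism analysis.
    """
    excluded = {normalize_term(s) for s in exclude_socs}
    return [s for s in summaries
            if s.pt_count > min_pt and s.report_count > min_reports
            and normalize_term(s.soc) not in excluded]


# ---------------------------------------------------------------------------
# descriptive tables

_CATEGORICAL_GETTERS = {
    "sex": lambda r: r.sex,
    "outcome": lambda r: r.outcome,
    "country": lambda r: r.country,
    "year": lambda r: None if r.received_date is None else str(r.received_date.year),
}


def descriptive_distribution(rs: ReportSet, field: str,
                             bins: Sequence | None = None,
                             denominator: str = "all_reports") -> DescriptiveTable:
    """Count/percentage table of one demographic field.

    ``field`` is one of ``sex``, ``age_bins``, ``outcome``, ``year``,
    ``country``.  For ``age_bins``, ``bins`` must be inclusive integer-year
    ranges ``(lo, hi)`` and must not overlap; ages are binned by completed
    years (floor).  For categorical fields, ``bins`` lists the categories to
    tabulate; when omitted, the observed known categories are used, ordered by
    count desc then name (unknowns are a bin only if listed explicitly).

    ``denominator`` is ``"all_reports"`` (every report in the set) or
    ``"known_only"`` (reports where the field is known).  Percentages are
    rounded half-up to two decimals.
    """
    if denominator not in ("all_reports", "known_only"):
        raise ValueError(f"unknown denominator policy {denominator!r}")
    if len(rs) == 0:
        raise ValueError("empty report set")

    if field == "age_bins":
        if not bins:
            raise ValueError("age_bins requires explicit bins")
        ranges = [(int(lo), int(hi)) for lo, hi in bins]
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"malformed age bin ({lo}, {hi})")
        for (lo1, hi1) in ranges:
            for (lo2, hi2) in ranges:
                if (lo1, hi1) != (lo2, hi2) and lo1 <= hi2 and lo2 <= hi1:
                    raise ValueError(f"overlapping age bins ({lo1},{hi1}) and ({lo2},{hi2})")
        ages = [int(r.age_years) for r in rs if r.age_years is not None]
        labels = tuple(f"{lo}-{hi}" for lo, hi in ranges)
        counts = tuple(sum(lo <= a <= hi for a in ages) for lo, hi in ranges)
        known = len(ages)
    elif field in _CATEGORICAL_GETTERS:
        get = _CATEGORICAL_GETTERS[field]
        values = [get(r) for r in rs]
        known_values = [v for v in values if v is not None and v != "unknown"]
        if bins is None:
            tally: dict[str, int] = {}
            for v in known_values:
                tally[v] = tally.get(v, 0) + 1
            labels = tuple(sorted(tally, key=lambda k: (-tally[k], k)))
        else:
            labels = tuple(str(b) for b in bins)
            if len(set(labels)) != len(labels):
                raise ValueError("duplicate bins")
        counts = tuple(sum(v == lab for v in values) for lab in labels)
        known = len(known_values)
    else:
        raise ValueError(f"unknown field {field!r}")

    den = len(rs) if denominator == "all_reports" else known
    if den == 0:
        raise ValueError(f"no reports with known {field!r} for known_only denominator")
    pcts = tuple(percentage(c, den) for c in counts)
    return DescriptiveTable(field=field, bins=labels, counts=counts,
                            percentages=pcts, denominator=den)


def signals_to_dataframe(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Flatten signal results into the output table (one row per PT)."""
    rows = []
    for r in results:
        ci = r.stats.ror_ci95
        rows.append({
            "pt": r.pt,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "ror": r.stats.ror,
            "ci_lower": ci[0] if ci else None,
            "ci_upper": ci[1] if ci else None,
            "prr": r.stats.prr,
            "chi2": r.stats.chi2,
            "chi2_variant": r.stats.chi2_variant,
            "positive": r.positive,
            "gates": ";".join(f"{k}={v}" for k, v in r.criteria_trace.items()),
        })
    return pd.DataFrame(rows, columns=["pt", "a", "b", "c", "d", "ror", "ci_lower",
                                       "ci_upper", "prr", "chi2", "chi2_variant",
                                       "positive", "gates"])
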