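"""Synthetic spontaneous-report generator with implanted signals of known strength.

Real spontaneous-report extracts cannot be redistributed, so every downstream
stage of the pipeline is exercised against data from this generator, whose
ground truth is known exactly.  Each synthetic report carries one suspect
drug drawn from a categorical distribution, ``m >= 1`` distinct PTs with
``m = 1 + Poisson(lambda - 1)`` (capped at the vocabulary size), and
demographics drawn independently from configurable categorical distributions.

Within a report for drug ``d``, PTs are drawn *without replacement* with
selection weight ``w_k * rho(d, k)``, where ``w_k`` is the baseline weight of
PT ``k`` and ``rho`` is the implanted reporting-rate multiplier (1 when not
implanted).  Sampling uses the Gumbel top-k construction, which is exactly
equivalent to successive (Plackett-Luce) weighted sampling without
replacement and vectorizes over reports.

Because the PT vocabulary is finite and weights renormalize after each draw,
the odds ratio induced in the drug x PT contingency table is *not* equal to
``rho``.  :func:`true_odds_ratio` computes the exact induced value by
enumerating per-report inclusion probabilities with a dynamic program over
drawn-PT subsets; simulation calibration (CI coverage, sensitivity) is judged
against that exact value.

The module also fabricates toy PT->SOC dictionaries and network-stage
fixtures (target sets, a scored interaction edge list, and a GMT annotation
collection) with planted structure whose ground truth is known by
construction.
"""

from __future__ import annotations

import copy
import datetime as _dt
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats as _st

from .enrich import AnnotationCollection
from .nettox import InteractionNetwork, TargetSet
from .reports import DrugEntry, MedDRADict, ReportRecord, ReportSet, UNKNOWN

__all__ = [
    "SyntheticConfig", "generate_reports", "generate_meddra_dict",
    "generate_network_fixtures", "true_odds_ratio", "pt_inclusion_probability",
    "events_per_report_pmf", "DEFAULT_DEMOGRAPHICS",
]

#: Default demographic category frequencies.  They mirror the marginal shape
#: of a paediatric-drug spontaneous-report extract: mostly under-18 patients,
#: a large fraction of unknown ages, US-dominated reporting, year counts
#: rising after approval, and mostly non-serious outcomes.
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.52, "female": 0.41, "unknown": 0.07},
    "age": {"0-12": 0.30, "13-17": 0.12, "18-64": 0.10, "65-100": 0.02, "unknown": 0.46},
    "country": {"US": 0.60, "RU": 0.09, "PT": 0.07, "FR": 0.05, "JP": 0.05, "other": 0.14},
    "year": {"2020": 0.08, "2021": 0.17, "2022": 0.24, "2023": 0.34, "2024": 0.17},
    "outcome": {"hospitalization": 0.165, "life-threatening": 0.082, "death": 0.040,
                "disability": 0.020, "non-serious": 0.693},
}

_DEMO_FIELDS = ("sex", "age", "country", "year", "outcome")


@dataclass
class SyntheticConfig:
    """Parameters of the report generator.

    ``implanted_signals`` is a list of ``(drug, pt, rho)`` triples; ``rho`` is
    the multiplicative boost applied to that PT's selection weight on reports
    of that drug (``rho = 0`` forbids the pair, ``rho = 1`` is the null).
    ``events_per_report_mean`` is the mean ``lambda >= 1`` of the 1-shifted
    Poisson count of distinct PTs per report.
    """

    n_reports: int
    drug_weights: dict[str, float]
    pt_baseline_weights: dict[str, float]
    implanted_signals: list[tuple[str, str, float]] = field(default_factory=list)
    events_per_report_mean: float = 2.0
    demographic_distributions: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_DEMOGRAPHICS))
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be a positive integer")
        if not self.drug_weights or not self.pt_baseline_weights:
            raise ValueError("drug and PT vocabularies must be non-empty")
        for label, weights in (("drug", self.drug_weights), ("PT", self.pt_baseline_weights)):
            for k, w in weights.items():
                if w <= 0:
                    raise ValueError(f"{label} weight for {k!r} must be strictly positive")
        if self.events_per_report_mean < 1:
            raise ValueError("events_per_report_mean must be >= 1")
        for drug, pt, rho in self.implanted_signals:
            if drug not in self.drug_weights:
                raise ValueError(f"implanted signal names unknown drug {drug!r}")
            if pt not in self.pt_baseline_weights:
                raise ValueError(f"implanted signal names unknown PT {pt!r}")
            if rho < 0:
                raise ValueError(f"implanted multiplier for ({drug!r}, {pt!r}) must be >= 0")
        for fld, dist in self.demographic_distributions.items():
            if fld not in _DEMO_FIELDS:
                raise ValueError(f"unknown demographic field {fld!r}")
            if not dist:
                raise ValueError(f"empty distribution for {fld!r}")
            total = 0.0
            for cat, p in dist.items():
                if p <= 0:
                    raise ValueError(f"probability for {fld!r}={cat!r} must be > 0")
                total += p
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"distribution for {fld!r} sums to {total}, not 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["implanted_signals"] = [tuple(t) for t in raw.get("implanted_signals", [])]
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_reports": self.n_reports,
            "drug_weights": dict(self.drug_weights),
            "pt_baseline_weights": dict(self.pt_baseline_weights),
            "implanted_signals": [list(t) for t in self.implanted_signals],
            "events_per_report_mean": self.events_per_report_mean,
            "demographic_distributions": {k: dict(v) for k, v in
                                          self.demographic_distributions.items()},
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _weight_matrix(config: SyntheticConfig) -> tuple[list[str], list[str], np.ndarray]:
    """Per-drug PT selection weights (D x K), implanted multipliers applied."""
    drugs = list(config.drug_weights)
    pts = list(config.pt_baseline_weights)
    base = np.array([config.pt_baseline_weights[p] for p in pts], dtype=float)
    W = np.tile(base, (len(drugs), 1))
    for drug, pt, rho in config.implanted_signals:
        W[drugs.index(drug), pts.index(pt)] *= rho
    return drugs, pts, W


def _parse_age_category(label: str, rng: np.random.Generator) -> float | None:
    if label == UNKNOWN:
        return None
    m = re.fullmatch(r"(\d+)-(\d+)", label)
    if not m:
        raise ValueError(f"unparsable age category {label!r} (expected 'lo-hi' or 'unknown')")
    lo, hi = int(m.group(1)), int(m.group(2))
    return float(rng.integers(lo, hi + 1))


def generate_reports(config: SyntheticConfig) -> ReportSet:
    """Draw a full synthetic report table; identical seeds give identical output.

    One root seed feeds a :class:`numpy.random.SeedSequence`, which is split
    into fixed per-component child streams (drug draws, event counts, PT
    selection, each demographic field, report dates) so the output is
    reproducible byte-for-byte through :func:`toxsig.reports.write_reports`.
    """
    config.validate()
    n = config.n_reports
    drugs, pts, W = _weight_matrix(config)
    K = len(pts)

    children = np.random.SeedSequence(config.seed).spawn(4 + len(_DEMO_FIELDS))
    rng_drug, rng_m, rng_gumbel, rng_day = (np.random.default_rng(s) for s in children[:4])
    rng_demo = {f: np.random.default_rng(s) for f, s in zip(_DEMO_FIELDS, children[4:])}

    dw = np.array([config.drug_weights[d] for d in drugs], dtype=float)
    drug_idx = rng_drug.choice(len(drugs), size=n, p=dw / dw.sum())

    m = 1 + rng_m.poisson(config.events_per_report_mean - 1.0, size=n)
    n_available = (W > 0).sum(axis=1)  # rho=0 removes a PT from that drug's menu
    m = np.minimum(m, n_available[drug_idx])

    # Gumbel top-k == successive weighted sampling without replacement.
    with np.errstate(divide="ignore"):
        logw = np.where(W > 0, np.log(W), -np.inf)
    keys = logw[drug_idx] + rng_gumbel.gumbel(size=(n, K))
    order = np.argsort(-keys, axis=1, kind="stable")

    demo_draws: dict[str, list[str]] = {}
    for fld in _DEMO_FIELDS:
        dist = config.demographic_distributions.get(fld, {UNKNOWN: 1.0})
        cats = list(dist)
        p = np.array([dist[c] for c in cats], dtype=float)
        idx = rng_demo[fld].choice(len(cats), size=n, p=p / p.sum())
        demo_draws[fld] = [cats[i] for i in idx]
    day_offsets = rng_day.integers(0, 365, size=n)

    records = []
    for i in range(n):
        year_cat = demo_draws["year"][i]
        if year_cat == UNKNOWN:
            date = None
        else:
            date = _dt.date(int(year_cat), 1, 1) + _dt.timedelta(days=int(day_offsets[i]))
        records.append(ReportRecord(
            report_id=f"R{i + 1:06d}",
            drug_entries=(DrugEntry(drugs[drug_idx[i]], "primary suspect"),),
            pts=tuple(pts[j] for j in order[i, : m[i]]),
            sex=demo_draws["sex"][i],
            age_years=_parse_age_category(demo_draws["age"][i], rng_demo["age"]),
            country=demo_draws["country"][i],
            received_date=date,
            outcome=demo_draws["outcome"][i],
        ))
    return ReportSet(records, provenance=f"synthetic(seed={config.seed}, n={n})")


# ---------------------------------------------------------------------------
# exact ground truth of the generator

def events_per_report_pmf(lam: float, k_max: int) -> np.ndarray:
    """pmf of m = min(1 + Poisson(lam-1), k_max), indexed 1..k_max (entry 0 unused)."""
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    pmf = np.zeros(k_max + 1)
    for m_ in range(1, k_max):
        pmf[m_] = _st.poisson.pmf(m_ - 1, lam - 1.0)
    pmf[k_max] = 1.0 - pmf.sum()
    return pmf


def pt_inclusion_probability(weights: Sequence[float], target: int, m: int) -> float:
    """Exact P(target PT among the first m weighted draws without replacement).

    Dynamic program over subsets of already-drawn PTs (Plackett-Luce
    successive sampling); feasible for vocabularies of up to ~16 PTs, which is
    what the calibration studies use.
    """
    w = np.asarray(weights, dtype=float)
    K = len(w)
    if K > 16:
        raise ValueError("exact enumeration supported for at most 16 PTs")
    if not (0 <= target < K):
        raise ValueError("target index out of range")
    if w[target] <= 0:
        return 0.0
    total = w.sum()
    candidates = [i for i in range(K) if w[i] > 0 and i != target]
    m = min(m, len(candidates) + 1)

    memo: dict[int, float] = {}

    def p_not_drawn(mask: int, draws_left: int, remaining: float) -> float:
        """P(target never drawn in draws_left successive draws), mask = drawn set."""
        if draws_left == 0:
            return 1.0
        key = mask * (K + 1) + draws_left
        if key in memo:
            return memo[key]
        acc = 0.0
        for i in candidates:
            bit = 1 << i
            if mask & bit:
                continue
            acc += w[i] / remaining * p_not_drawn(mask | bit, draws_left - 1, remaining - w[i])
        memo[key] = acc
        return acc

    return 1.0 - p_not_drawn(0, m, total)


def true_odds_ratio(config: SyntheticConfig, drug: str, pt: str) -> float:
    """Exact odds ratio induced in the drug x PT contingency table.

    Enumerates, for every drug, the probability that a report of that drug
    includes the target PT (mixing the inclusion DP over the truncated event
    count distribution), then forms the odds ratio of the expected cell
    probabilities.  This is the quantity the ROR estimates, and it differs
    from the implanted ``rho`` because of finite-vocabulary renormalization.
    """
    config.validate()
    drugs, pts, W = _weight_matrix(config)
    if drug not in drugs:
        raise ValueError(f"unknown drug {drug!r}")
    if pt not in pts:
        raise ValueError(f"unknown PT {pt!r}")
    di, ti = drugs.index(drug), pts.index(pt)
    dw = np.array([config.drug_weights[d] for d in drugs], dtype=float)
    p_drug = dw / dw.sum()
    lam = config.events_per_report_mean

    q = np.zeros(len(drugs))
    for j in range(len(drugs)):
        k_max = int((W[j] > 0).sum())
        pmf = events_per_report_pmf(lam, k_max)
        q[j] = sum(pmf[m_] * pt_inclusion_probability(W[j], ti, m_)
                   for m_ in range(1, k_max + 1))

    p_a = p_drug[di] * q[di]
    p_b = p_drug[di] * (1.0 - q[di])
    others = [j for j in range(len(drugs)) if j != di]
    p_c = sum(p_drug[j] * q[j] for j in others)
    p_d = sum(p_drug[j] * (1.0 - q[j]) for j in others)
    if min(p_a, p_b, p_c, p_d) <= 0:
        raise ValueError("induced odds ratio undefined (a structurally empty cell)")
    return (p_a * p_d) / (p_b * p_c)


# ---------------------------------------------------------------------------
# toy vocabularies and network fixtures

def generate_meddra_dict(n_pt: int, n_soc: int, seed: int) -> MedDRADict:
    """Toy PT->SOC dictionary: every PT maps to one SOC, every SOC non-empty."""
    if not (n_pt >= n_soc >= 1):
        raise ValueError("need n_pt >= n_soc >= 1")
    rng = np.random.default_rng(seed)
    pts = [f"PT_{i:04d}" for i in range(1, n_pt + 1)]
    socs = [f"SOC_{j:02d}" for j in range(1, n_soc + 1)]
    assignment = list(range(n_soc)) + list(rng.integers(0, n_soc, size=n_pt - n_soc))
    return MedDRADict({pt: socs[s] for pt, s in zip(pts, assignment)})


def generate_network_fixtures(n_genes: int, n_pathways: int, seed: int,
                              n_sources: int = 6, core_size: int = 11,
                              edge_prob: float = 0.05,
                              ) -> tuple[list[TargetSet], InteractionNetwork,
                                         AnnotationCollection]:
    """Target sets, a scored edge list, and a GMT collection with planted structure.

    The first ``min(core_size, n_genes)`` genes form a *core* included in
    every target set and every pathway — so with four pathways the core genes
    are exactly the targets of pathway-degree 4, and with six sources the core
    is part of the all-sources overlap signature.  Remaining memberships and
    edges are random but reproducible under the seed.  Scores are integers on
    the STRING-like 0-1000 scale (drawn in 150-1000).
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    core = genes[: min(core_size, n_genes)]
    rest = genes[len(core):]

    target_sets = []
    for s in range(n_sources):
        extra = [g for g in rest if rng.random() < 0.4]
        target_sets.append(TargetSet(f"SOURCE_{s + 1}", set(core) | set(extra)))

    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_prob:
                edges.append((genes[i], genes[j], float(rng.integers(150, 1001))))
    network = InteractionNetwork.from_edges(genes, edges)

    # Membership of non-core genes is random but never spans *all* pathways,
    # so the core is exactly the set of genes with full pathway degree.
    members: list[set[str]] = [set(core) for _ in range(n_pathways)]
    for g in rest:
        chosen = [t for t in range(n_pathways) if rng.random() < 0.3]
        if n_pathways > 1 and len(chosen) == n_pathways:
            chosen.remove(int(rng.choice(chosen)))
        for t in chosen:
            members[t].add(g)
    terms = {f"PWY_{t + 1:04d}": (f"synthetic pathway {t + 1}", frozenset(members[t]))
             for t in range(n_pathways)}
    annotations = AnnotationCollection(terms=terms, background=frozenset(genes))
    return target_sets, network, annotations
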