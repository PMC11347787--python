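# Methods

## Disproportionality model

A spontaneous-report database is treated as a collection of independent
reports, each naming one or more drugs and one or more MedDRA PTs.  For a
target drug and a target PT, every report falls in exactly one cell of the
2×2 table — *a* (drug & PT), *b* (drug, other PTs), *c* (other drugs, PT),
*d* (neither) — with PT lists deduplicated within a report so a report
contributes at most 1 to any cell.

Statistics on the table:

- **ROR** = *ad/bc*; 95% CI = exp(ln ROR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d)
  (Wald interval on the log scale).
- **PRR** = [*a*/(*a*+*b*)] / [*c*/(*c*+*d*)].
- **χ²**: plain *n*(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)] or Yates
  *n*(|ad−bc|−n/2)²/[same], floored at 0 when |ad−bc| ≤ n/2.

**Positivity** is the conjunction *a* ≥ 3 ∧ CI lower > 1 ∧ PRR ≥ 2 ∧ χ² ≥ 4.
The CI gate is strict ("exceeds 1"); PRR and χ² gates are non-strict.  The
χ² default is the Yates-corrected variant — conventional for MHRA-style
criteria and conservative; the plain variant is one keyword away for
sensitivity analyses.

**Zero cells.**  A zero cell leaves ROR (and, for *c* = 0, PRR) undefined;
the default policy records the statistic as undefined and fails the affected
gate rather than imputing — with the *a* ≥ 3 gate in force, an undefined
statistic can only arise from degenerate margins that should never silently
pass.  An optional Haldane–Anscombe correction (+0.5 on all four cells) is
available and flagged in the output.

**SOC aggregation** counts positive PTs per SOC and sums their *a*-cells
without deduplicating reports that carry several positive PTs: the summary is
a sum of per-PT report counts, not a count of distinct reports.  Key SOCs
require > 3 positive PTs and > 10 reports (strict), minus a configurable
exclusion list of non-organ classes (investigations; infections and
infestations; general disorders and administration site conditions).

**Descriptive tables** round percentages half-up to 2 decimals (computed
exactly with decimal arithmetic, so 0.125% → 0.13%).  Demographic tables
default to all reports in the set as denominator; a known-only denominator is
available per call.  Year bins use the calendar year of the received date;
age bins are inclusive completed-year ranges and must not overlap.

## Screening

Manual two-reviewer adjudication is replaced by auditable pattern
blocklists.  Per report, in order: (1) a report is removed if no drug entry
has an included role (default: the four named causality roles); (2) removed
if its known received date falls outside the inclusive date window (unknown
dates are retained — extraction windows normally guarantee membership);
(3) PT-level blocklist patterns (case-insensitive regex on
whitespace-normalized PTs) remove individual terms, e.g. the drug's own
indication, and the report is removed if no PT survives; (4) a report whose
*every surviving* PT matches a report-level pattern (product-quality issues,
medical procedures) is removed.  Applying the PT trim before the report-level
check makes screening idempotent on the retained set.  Every removal carries
at least one logged reason.

## Synthetic report generator

Each of *n* reports draws: one suspect drug from a categorical distribution;
an event count *m* = min(1 + Poisson(λ−1), available PTs) so every report has
at least one PT; *m* distinct PTs without replacement with weight
*w_k*·ρ(d, k), where ρ is the implanted multiplier (1 if not implanted, 0
forbids the pair); and independent categorical demographics.  Defaults for
the demographic tables mirror a paediatric-drug extract (male-majority,
mostly under-18 with ~46% unknown age, US-dominated reporting, counts rising
to a peak year, mostly non-serious outcomes).  Default λ = 2 events per
report.

Sampling without replacement uses the Gumbel top-*k* construction
(argsort of log-weights plus i.i.d. Gumbel noise), exactly equivalent to
successive Plackett–Luce sampling and vectorizable over reports.  One root
seed feeds a `SeedSequence` split into fixed per-component streams, so equal
seeds give byte-identical output tables.

Because weights renormalize after each within-report draw over a finite
vocabulary, the odds ratio induced in the contingency table is *not* ρ.
`true_odds_ratio` computes it exactly: a subset dynamic program enumerates
P(PT included | drug, m) for each drug (feasible up to ~16 PTs), mixes over
the truncated event-count distribution, and forms the odds ratio of the
expected cell probabilities.  Calibration studies compare estimates against
this exact value, and the DP itself is cross-checked against Monte-Carlo
sampling in the tests.

Calibration study designs (chosen once as realistic desk-scale conditions;
also the sizes `scripts/acceptance.py` runs): *null flag rate* — 5 drugs ×
30 equal-weight PTs, 600 reports, no implants, 200 replicates, fraction of
evaluated pairs with a ≥ 3 called positive; *sensitivity* — same design plus
one ρ = 10 implant (expected co-report count ≈ 45 ≥ 10), 200 replicates;
*CI coverage* — 3 drugs × 8 PTs, 800 reports, one ρ = 4 implant, 500
replicates, empirical coverage of the exact induced odds ratio by the 95%
Wald interval.  What the generator does **not** model — duplicate and
multi-drug reports, reporting-culture and secular trends, PT correlation
structure — means passing calibration shows the statistics and gates behave
correctly under independent sampling, not that real-extract biases are
handled.

## Network stage

Gene symbols are uppercased; no alias resolution.  Interaction scores live on
the STRING 0–1000 scale with a default edge filter of 400 (medium
confidence; no threshold is canonical, so it is exposed).  Centralities are
computed on the unweighted filtered graph: exact degree, unnormalized
shortest-path betweenness, and harmonic closeness divided by n−1 — harmonic
rather than classic closeness because disconnected subnetworks are the norm
and the harmonic form needs no connectivity assumption.  Ranking is degree
desc, betweenness desc, then symbol; key-node selection cutoffs are left to
the user.  Upset overlap counting assigns each gene of the union to exactly
one signature (the full set of sources containing it), so signature counts
sum to the union size.  The tripartite builder rejects any node appearing in
two layers.

## Enrichment

Raw p-value: one-tailed hypergeometric upper tail P(X ≥ k) for an overlap of
k between a background-restricted query of size n and a term of size K in a
background of N (scipy's stable implementation, clipped to [1e-300, 1]).
EASE score: the same tail on the table with one gene deducted from the
overlap cell — (k−1, n−k, K−k, N−K−n+k), i.e. margins N−1, K−1, n−1 — which
equals 1 for k ≤ 1 and is always ≥ the raw p.  Benjamini–Hochberg runs
across the tested terms of a collection.  The default background is the
union of all genes annotated in the GMT, overridable per call; the default
reporting filter keeps terms with k ≥ 2.  Null calibration is measured with
the overlap filter disabled (min_overlap = 0): conditioning reported terms
on k ≥ 2 selects large overlaps and their small p-values, so the filtered
list is not the object the super-uniformity claim is about.

## Numerical and convention choices

- Percentages: decimal arithmetic, half-up, 2 dp; full precision internally.
- Ranked outputs break ties deterministically (count desc, then
  lexicographic) so identical inputs give identical files.
- PT and drug matching is case-insensitive after whitespace collapsing;
  list-valued cells in report tables escape embedded separators with a
  backslash, so round trips are lossless.
- The 1.96 normal quantile is used verbatim in the CI (the field's printed
  convention) rather than a higher-precision quantile.

## Known limitations

Single-drug synthetic reports (no confounding by co-medication); no
Bayesian disproportionality (BCPNN/EBGM) or stratified RORs; no duplicate
-case detection; MedDRA itself is licensed and never bundled — PT→SOC
mappings arrive as user-supplied TSVs; enrichment ignores GO DAG structure
(no true-path propagation); no graph layout or visualization.
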