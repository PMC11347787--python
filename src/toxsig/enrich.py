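"""Over-representation analysis against GMT annotations (hypergeometric + EASE).

For a query gene set of effective size ``n`` (after restriction to the
background of ``N`` genes) and an annotation term covering ``K`` background
genes, the raw p-value is the one-tailed hypergeometric upper tail
``P(X >= k)`` of the observed overlap ``k``.  The *EASE score* is the same
tail recomputed after removing one gene from the overlap cell — the table
``(k-1, n-k, K-k, N-K-n+k)`` — a deliberately conservative penalization that
equals 1 whenever ``k <= 1``.  Benjamini-Hochberg step-up adjustment is
applied across all tested terms of a collection.

Annotations travel as GMT files (``term_id<TAB>description<TAB>gene...``);
the default background is the union of all genes annotated in the file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

if TYPE_CHECKING:  # pragma: no cover
    from .nettox import TargetSet

__all__ = [
    "AnnotationCollection", "EnrichmentResult", "hypergeometric_p", "ease_p",
    "benjamini_hochberg", "enrich_set", "top_terms", "split_terms_by_prefix",
]

_P_FLOOR = 1e-300


@dataclass
class AnnotationCollection:
    """GMT-style term annotations over a gene background.

    ``terms`` maps a term id to ``(description, genes)``; ``background`` is
    the population the hypergeometric draw is taken from (by default the
    union of all annotated genes).
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.terms = {t: (desc, frozenset(g.strip().upper() for g in genes))
                      for t, (desc, genes) in self.terms.items()}
        self.background = frozenset(g.strip().upper() for g in self.background)

    def term_genes(self, term: str) -> frozenset[str]:
        return self.terms[term][1]

    @classmethod
    def read_gmt(cls, path: str | Path, background: Iterable[str] | None = None,
                 strict: bool = False) -> "AnnotationCollection":
        """Read a GMT file; lines are ``term<TAB>description<TAB>gene1<TAB>...``.

        With ``strict=True`` and an explicit background, a term annotating a
        gene outside the background is an error; otherwise such genes are
        simply never counted (they cannot overlap a background-restricted
        query).
        """
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 columns")
                term, desc = parts[0].strip(), parts[1].strip()
                genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
                if term in terms:
                    raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
                terms[term] = (desc, genes)
        if background is None:
            bg = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
        else:
            bg = frozenset(g.strip().upper() for g in background)
            if strict:
                for term, (_, genes) in terms.items():
                    stray = genes - bg
                    if stray:
                        raise ValueError(
                            f"term {term!r} annotates genes outside the background: "
                            f"{sorted(stray)[:5]}")
        return cls(terms=terms, background=bg)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term in sorted(self.terms):
                desc, genes = self.terms[term]
                fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    description: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_ease: float
    p_adjusted: float
    overlap_genes: frozenset[str]


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= k <= min(K, n) and K <= N and n <= N and N >= 1):
        raise ValueError(f"inconsistent hypergeometric counts N={N}, K={K}, n={n}, k={k}")


def hypergeometric_p(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N, K, n); clipped to [1e-300, 1]."""
    _check_counts(N, K, n, k)
    if k == 0:
        return 1.0
    p = float(_st.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(_P_FLOOR, p))


def ease_p(N: int, K: int, n: int, k: int) -> float:
    """EASE score: the hypergeometric tail with one gene removed from the overlap.

    The penalized 2x2 table is ``(k-1, n-k, K-k, N-K-n+k)``, i.e. margins
    ``N-1``, ``K-1``, ``n-1``; the score equals 1 when ``k <= 1``.  Always
    at least as large as the raw p-value — a conservative guard against
    single-gene artifacts.
    """
    _check_counts(N, K, n, k)
    if k <= 1:
        return 1.0
    return hypergeometric_p(N - 1, K - 1, n - 1, k - 1)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values, in the input order, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich_set(query: "TargetSet", annotations: AnnotationCollection,
               min_overlap: int = 2) -> list[EnrichmentResult]:
    """Test the query against every term of the collection.

    The query is restricted to the background first (``n`` counts only
    background genes).  Terms with overlap ``k >= min_overlap`` are reported;
    BH adjustment runs across exactly those tested terms.  Results are sorted
    by raw p ascending, overlap descending, term id.  A query disjoint from
    the background yields an empty list with a warning.
    """
    if not annotations.background:
        raise ValueError("empty annotation background")
    if not annotations.terms:
        return []
    bg = annotations.background
    q = query.genes & bg
    if not q:
        warnings.warn(f"query {query.name!r} shares no genes with the background")
        return []
    N, n = len(bg), len(q)

    tested = []
    for term, (desc, genes) in annotations.terms.items():
        genes_bg = genes & bg
        overlap = q & genes_bg
        k, K = len(overlap), len(genes_bg)
        if k < min_overlap:
            continue
        tested.append((term, desc, K, k, overlap,
                       hypergeometric_p(N, K, n, k), ease_p(N, K, n, k)))
    adjusted = benjamini_hochberg([t[5] for t in tested])
    results = [EnrichmentResult(term=term, description=desc, N=N, K=K, n=n, k=k,
                                p_raw=p_raw, p_ease=p_e, p_adjusted=min(1.0, p_adj),
                                overlap_genes=frozenset(overlap))
               for (term, desc, K, k, overlap, p_raw, p_e), p_adj in zip(tested, adjusted)]
    results.sort(key=lambda r: (r.p_raw, -r.k, r.term))
    return results


def top_terms(results: Sequence[EnrichmentResult], top_n: int = 20,
              alpha: float = 0.05, on: str = "p_raw") -> list[EnrichmentResult]:
    """Significant terms (p < alpha on the chosen column), truncated to top_n."""
    if on not in ("p_raw", "p_adjusted"):
        raise ValueError(f"unknown p-value column {on!r}")
    kept = [r for r in results if getattr(r, on) < alpha]
    kept.sort(key=lambda r: (r.p_raw, -r.k, r.term))
    return kept[:top_n]


def split_terms_by_prefix(results: Sequence[EnrichmentResult],
                          prefix_map: dict[str, str]) -> dict[str, list[EnrichmentResult]]:
    """Partition results by term-id prefix (e.g. GO namespaces BP/CC/MF).

    ``prefix_map`` maps a term-id prefix to a namespace label; unmatched terms
    land under ``"other"``.  Longer prefixes win when several match.
    """
    out: dict[str, list[EnrichmentResult]] = {}
    prefixes = sorted(prefix_map, key=len, reverse=True)
    for r in results:
        label = next((prefix_map[p] for p in prefixes if r.term.startswith(p)), "other")
        out.setdefault(label, []).append(r)
    return out
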