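"""Substitution-enrichment statistics.

Per-protein binomial tests against the genome-wide substitution rate,
Benjamini–Hochberg FDR control at Q < 0.1, binomial GO-term enrichment over
the flagged proteins, a product-of-p-values score for terms shared between
two species, and a hypergeometric test for the overlap of two term sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from lepcompgen.snpdist import SubstitutionProfile

__all__ = [
    "EnrichmentResult",
    "binomial_upper_tail",
    "bh_fdr",
    "test_proteins",
    "go_enrichment",
    "combine_species_significance",
    "overlap_significance",
]


@dataclass
class EnrichmentResult:
    unit_id: str
    p_value: float
    q_value: float
    enriched: bool


def binomial_upper_tail(m: int, N: int, p: float) -> float:
    """P[X >= m] for X ~ Binomial(N, p).

    Computed through the regularized incomplete beta function (scipy's
    binomial survival function) for numerical stability; returns exactly 1.0
    when m == 0.
    """
    if not 0 <= m <= N:
        raise ValueError("m must be in [0, N]")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if m == 0:
        return 1.0
    return float(stats.binom.sf(m - 1, N, p))


def bh_fdr(
    p_values: dict[str, float], q_threshold: float = 0.1
) -> list[EnrichmentResult]:
    """Benjamini–Hochberg step-up adjustment.

    q_(i) = min_{j >= i} (n p_(j) / j) over the sorted p-values, capped at 1.
    A unit is flagged when its q-value is strictly below ``q_threshold``.
    Results are returned sorted by p-value.
    """
    ids = list(p_values)
    p = np.array([p_values[u] for u in ids], dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    return [
        EnrichmentResult(ids[order[i]], float(p[order[i]]), float(q_sorted[i]),
                         bool(q_sorted[i] < q_threshold))
        for i in range(n)
    ]


def test_proteins(
    profiles: list[SubstitutionProfile],
    mode: str = "ordered_only",
    q_threshold: float = 0.1,
) -> list[EnrichmentResult]:
    """Flag proteins significantly enriched in substitutions.

    The background rate p̄ is the total substitution count divided by the
    total protein length, computed in the same mode as the per-protein tests:
    ``all`` uses full lengths and all substitutions, ``ordered_only``
    restricts both to structurally ordered positions.  Each protein is then
    tested with :func:`binomial_upper_tail` and the family is controlled by
    BH at ``q_threshold``.
    """
    if mode not in ("all", "ordered_only"):
        raise ValueError("mode must be 'all' or 'ordered_only'")
    if mode == "all":
        counts = {pr.protein_id: pr.substitution_count for pr in profiles}
        lengths = {pr.protein_id: pr.length for pr in profiles}
    else:
        counts = {pr.protein_id: pr.ordered_count for pr in profiles}
        lengths = {pr.protein_id: pr.ordered_length for pr in profiles}
    total_len = sum(lengths.values())
    total_sub = sum(counts.values())
    if total_len == 0:
        raise ValueError("no testable positions")
    p_bar = total_sub / total_len
    if p_bar <= 0 or p_bar >= 1:
        raise ValueError("degenerate background substitution rate")
    pvals = {
        pid: binomial_upper_tail(counts[pid], lengths[pid], p_bar)
        for pid in counts
        if lengths[pid] > 0
    }
    return bh_fdr(pvals, q_threshold=q_threshold)


def go_enrichment(
    enriched_ids: set[str],
    go_annotations: dict[str, set[str]],
    universe_ids: set[str],
    q_threshold: float = 0.1,
) -> list[EnrichmentResult]:
    """Binomial GO-term enrichment over substitution-enriched proteins.

    For each term: P = fraction of universe proteins annotated with the term,
    m = number of enriched proteins carrying it, N = number of enriched
    proteins; p-value = P[X >= m], X ~ Binomial(N, P); BH across terms.
    """
    if not enriched_ids:
        raise ValueError("empty enriched set")
    if not enriched_ids <= universe_ids:
        raise ValueError("enriched set must be a subset of the universe")
    n_universe = len(universe_ids)
    N = len(enriched_ids)
    term_universe: dict[str, int] = {}
    term_enriched: dict[str, int] = {}
    for pid in universe_ids:
        for term in go_annotations.get(pid, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if pid in enriched_ids:
                term_enriched[term] = term_enriched.get(term, 0) + 1
    pvals = {}
    for term, k_u in term_universe.items():
        P = k_u / n_universe
        m = term_enriched.get(term, 0)
        pvals[term] = 1.0 if P >= 1.0 else binomial_upper_tail(m, N, P)
    return bh_fdr(pvals, q_threshold=q_threshold)


def combine_species_significance(p_a: float, p_b: float) -> float:
    """Combined cross-species significance score: the product of p-values."""
    return p_a * p_b


def overlap_significance(
    terms_a: set[str], terms_b: set[str], term_universe: set[str]
) -> float:
    """Hypergeometric upper-tail p-value for the overlap of two term sets.

    Probability of drawing at least ``|A ∩ B|`` marked terms when ``|B|``
    terms are drawn without replacement from a universe containing ``|A|``
    marked ones.
    """
    if not (terms_a <= term_universe and terms_b <= term_universe):
        raise ValueError("term sets must be subsets of the universe")
    M = len(term_universe)
    K = len(terms_a)
    n = len(terms_b)
    k = len(terms_a & terms_b)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))
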