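"""Category counting and enrichment of DE gene lists.

Two registries drive this stage: a hematopoietic cell-type registry
(I-Scope style — count DE transcripts per immune cell category to infer
composition shifts) and a functional registry (BIG-C / GO-BP style —
one-category-per-gene functional vocabulary).  Enrichment of a gene list
against the DE universe is tested per category with a Pearson chi-square
(no continuity correction) and with the upper-tail hypergeometric exact
test; the exact test doubles as the defensible oracle for the chi-square.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CategoryRegistry, ValidationError, harmonize_symbol, harmonize_symbols

logger = logging.getLogger("immunosig")


def _dedupe(genes: Iterable[str]) -> list[str]:
    """Harmonize and deduplicate, preserving first-seen order."""
    return list(dict.fromkeys(harmonize_symbols(genes)))


def count_by_category(
    increased: Sequence[str],
    decreased: Sequence[str],
    registry: CategoryRegistry,
) -> pd.DataFrame:
    """Tally genes per category per direction (I-Scope style counting).

    Returns a frame indexed by category (vocabulary order, plus a final
    ``<unmatched>`` row) with columns ``n_increased`` and ``n_decreased``;
    unmatched genes are counted, never silently dropped.  Per direction,
    column sums equal the deduplicated list length.
    """
    counts = pd.DataFrame(
        0,
        index=list(registry.vocabulary) + ["<unmatched>"],
        columns=["n_increased", "n_decreased"],
        dtype=int,
    )
    counts.index.name = "category"
    for col, genes in (("n_increased", increased), ("n_decreased", decreased)):
        for g in _dedupe(genes):
            cat = registry.mapping.get(g)
            counts.loc[cat if cat is not None else "<unmatched>", col] += 1
    return counts


def _two_by_two(k: int, n: int, K: int, N: int) -> np.ndarray:
    return np.array([[k, n - k], [K - k, N - n - K + k]], dtype=float)


def chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table.

    Degenerate tables (a zero margin) carry no association signal and
    return (0, 1).
    """
    table = np.asarray(table, dtype=float)
    if table.min() < 0:
        raise ValidationError("contingency cells must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def odds_ratio(table: np.ndarray) -> float:
    """Sample odds ratio with Haldane +0.5 correction when any cell is zero."""
    a, b, c, d = np.asarray(table, dtype=float).ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _category_rows(
    gene_list: Sequence[str],
    universe: Sequence[str],
    registry: CategoryRegistry,
) -> list[dict]:
    uni = set(_dedupe(universe))
    lst = _dedupe(gene_list)
    outside = [g for g in lst if g not in uni]
    if outside:
        raise ValidationError(
            f"gene list must be a subset of the universe; offenders: {outside[:5]}"
        )
    lst_set = set(lst)
    N, n = len(uni), len(lst_set)
    rows = []
    for cat in registry.vocabulary:
        members = {g for g in registry.genes_in(cat) if g in uni}
        K = len(members)
        if K == 0:
            logger.warning("category %r absent from the universe; skipped", cat)
            continue
        k = len(lst_set & members)
        rows.append(
            {"category": cat, "n": n, "N": N, "K": K, "k": k,
             "expected": n * K / N}
        )
    return rows


def chisq_enrich(
    gene_list: Sequence[str],
    universe: Sequence[str],
    registry: CategoryRegistry,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Chi-square category enrichment of a gene list against the universe.

    One row per category: overlap counts, expected overlap, chi-square
    statistic and p, odds ratio, -log10(p), and an ``enriched`` flag at
    ``p <= p_threshold`` with over-representation (k > expected).
    """
    rows = _category_rows(gene_list, universe, registry)
    for r in rows:
        table = _two_by_two(r["k"], r["n"], r["K"], r["N"])
        chi2, p = chi_square(table)
        r.update(
            chi2=chi2, p=p, odds_ratio=odds_ratio(table),
            neg_log10_p=float(-np.log10(p)) if p > 0 else np.inf,
            enriched=bool(p <= p_threshold and r["k"] > r["expected"]),
        )
    return pd.DataFrame(rows)


def exact_overlap_enrich(
    gene_list: Sequence[str],
    universe: Sequence[str],
    registry: CategoryRegistry,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Exact (hypergeometric upper-tail) category enrichment; flag at p < threshold."""
    rows = _category_rows(gene_list, universe, registry)
    for r in rows:
        p = hypergeom_tail(r["k"], r["N"], r["K"], r["n"])
        table = _two_by_two(r["k"], r["n"], r["K"], r["N"])
        r.update(
            p=p, odds_ratio=odds_ratio(table),
            neg_log10_p=float(-np.log10(p)) if p > 0 else np.inf,
            enriched=bool(p < p_threshold),
        )
    return pd.DataFrame(rows)


def run_enrichment(
    increased: Sequence[str],
    decreased: Sequence[str],
    universe: Sequence[str],
    registries: dict[str, CategoryRegistry],
    chi_p: float = 0.05,
    exact_p: float = 0.01,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Both enrichment tests, per direction, per registry.

    Returns one long frame with columns ``registry``, ``direction``,
    ``method`` plus the per-category statistics, sorted by -log10(p)
    descending within each (registry, direction, method) block.  BH
    correction across categories is available but off by default (raw-p
    thresholds are the convention this stage follows).
    """
    blocks = []
    for reg_name, registry in registries.items():
        for direction, genes in (("increased", increased), ("decreased", decreased)):
            for method, frame in (
                ("chisq", chisq_enrich(genes, universe, registry, chi_p)),
                ("exact", exact_overlap_enrich(genes, universe, registry, exact_p)),
            ):
                if frame.empty:
                    continue
                frame = frame.copy()
                if bh_correct:
                    from .diffexpr import bh_fdr

                    frame["q"] = bh_fdr(frame["p"].to_numpy())
                frame.insert(0, "method", method)
                frame.insert(0, "direction", direction)
                frame.insert(0, "registry", reg_name)
                blocks.append(
                    frame.sort_values("neg_log10_p", ascending=False, kind="stable")
                )
    if not blocks:
        return pd.DataFrame()
    return pd.concat(blocks, ignore_index=True)
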