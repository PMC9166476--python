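"""Functional enrichment of per-class perturbation gene lists.

For each *module* — one class and perturbation direction — the query list
is the union of that class's per-sample significant genes.  Each annotated
term is tested for over-representation in the query against the genomic
background (all genes in the expression matrix) with a one-sided
hypergeometric (Fisher exact) test, then filtered by a raw p-value cutoff
and a Bonferroni-corrected cutoff, the multiplier being the number of
terms tested within the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .stats import SignificanceCall

__all__ = [
    "EnrichmentRecord",
    "build_query_lists",
    "restrict_mapping",
    "fisher_enrichment",
    "filter_enriched",
    "records_table",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's over-representation test within one module."""

    module_name: str
    term: str
    vocabulary: str
    k: int  # query ∩ term
    n: int  # query size
    K: int  # background ∩ term
    N: int  # background size
    p: float
    p_bonferroni: float


def build_query_lists(calls_by_class: dict[str, list[SignificanceCall]]
                      ) -> dict[tuple[str, str], list[str]]:
    """Union of per-sample significant genes, per (class, direction).

    Lists are deduplicated and sorted; a class with no significant genes
    yields an empty list.
    """
    queries: dict[tuple[str, str], list[str]] = {}
    for label, calls in calls_by_class.items():
        for direction in ("up", "down"):
            genes: set[str] = set()
            for c in calls:
                genes |= c.genes(direction)
            queries[(label, direction)] = sorted(genes)
    return queries


def restrict_mapping(mapping: pd.DataFrame, background: list[str],
                     terms: list[str] | None = None) -> pd.DataFrame:
    """Keep only annotations of background genes (and listed terms)."""
    keep = mapping["gene"].isin(set(background))
    if terms is not None:
        keep &= mapping["term"].isin(set(terms))
    return mapping.loc[keep].drop_duplicates(subset=["gene", "term"])


def fisher_enrichment(query: list[str], background: list[str],
                      mapping: pd.DataFrame,
                      module_name: str = "query") -> list[EnrichmentRecord]:
    """One-sided over-representation test for every annotated term.

    ``mapping`` must carry ``gene`` and ``term`` columns (``vocabulary``
    optional).  For each term with at least one background gene, the
    p-value is ``P(X >= k)`` with ``X ~ Hypergeometric(N, K, n)``.
    Records are returned sorted by ascending p (term as tie-break); the
    Bonferroni multiplier is the number of terms tested here.
    """
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    q = list(dict.fromkeys(query))
    outside = [g for g in q if g not in bg_set]
    if outside:
        raise ValueError(f"query gene(s) not in background: {outside[:5]}")
    mapping = restrict_mapping(mapping, bg)
    has_vocab = "vocabulary" in mapping.columns
    n_bg = len(bg)
    n_q = len(q)
    q_set = set(q)

    term_groups = mapping.groupby("term", sort=True)
    n_tests = term_groups.ngroups
    records = []
    for term, grp in term_groups:
        term_genes = set(grp["gene"])
        big_k = len(term_genes)
        k = len(term_genes & q_set)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_q))
        p = min(p, 1.0)
        records.append(EnrichmentRecord(
            module_name=module_name, term=str(term),
            vocabulary=str(grp["vocabulary"].iloc[0]) if has_vocab else "custom",
            k=k, n=n_q, K=big_k, N=n_bg,
            p=p, p_bonferroni=min(1.0, p * n_tests)))
    records.sort(key=lambda r: (r.p, r.term))
    return records


def filter_enriched(records: list[EnrichmentRecord],
                    p_cutoff: float = 0.01,
                    bonferroni_cutoff: float = 1e-5
                    ) -> list[EnrichmentRecord]:
    """Two-tier filter: raw p < cutoff AND Bonferroni p < cutoff."""
    return [r for r in records
            if r.p < p_cutoff and r.p_bonferroni < bonferroni_cutoff]


def records_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
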