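"""Functional-term enrichment of trajectory sets.

Each trajectory set is tested against the gene background one functional
term at a time with the one-sided (enrichment direction) Fisher exact
test on the 2x2 table

                 annotated   not annotated
    in set           a             b
    not in set       c             d

followed by Benjamini-Hochberg step-up correction of the raw p-values,
applied within each annotation vocabulary (GO, KEGG, InterPro, ...)
separately by default. Terms with adjusted p below ``alpha`` (default
0.001) are flagged enriched. Singleton sets are not tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "fisher_right_tail",
    "bh_adjust",
    "enrich_sets",
]


class AnnotationTable:
    """gene_id -> set of (vocabulary, term_id, term_name) annotations."""

    def __init__(self, mapping: dict[str, set[tuple[str, str, str]]]):
        names: dict[tuple[str, str], str] = {}
        for terms in mapping.values():
            for vocab, term_id, term_name in terms:
                key = (vocab, term_id)
                if names.setdefault(key, term_name) != term_name:
                    raise ValueError(
                        f"term {term_id!r} in vocabulary {vocab!r} has "
                        "conflicting names")
        self.mapping = {g: set(t) for g, t in mapping.items()}

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        """Read TSV with columns gene_id, vocabulary, term_id, term_name."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_id", "vocabulary", "term_id", "term_name"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation TSV must have columns {sorted(required)}")
        mapping: dict[str, set] = {}
        for r in df.itertuples():
            mapping.setdefault(r.gene_id, set()).add(
                (r.vocabulary, r.term_id, r.term_name))
        return cls(mapping)

    def genes_with_term(self, vocab: str, term_id: str) -> set[str]:
        return {g for g, terms in self.mapping.items()
                if any(v == vocab and t == term_id for v, t, _ in terms)}

    def terms(self) -> list[tuple[str, str, str]]:
        out = set()
        for ts in self.mapping.values():
            out |= ts
        return sorted(out)


def fisher_right_tail(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail hypergeometric probability P(X >= a) for fixed margins."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("contingency counts must be non-negative integers")
    total = a + b + c + d
    annotated = a + c
    in_set = a + b
    return float(hypergeom.sf(a - 1, total, annotated, in_set))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """One (trajectory set, term) contingency test."""

    set_id: str
    vocabulary: str
    term_id: str
    term_name: str
    a: int
    b: int
    c: int
    d: int
    p_raw: float
    p_adj: float = float("nan")
    enriched: bool = False

    def to_row(self) -> dict:
        return {
            "set_id": self.set_id, "vocabulary": self.vocabulary,
            "term_id": self.term_id, "term_name": self.term_name,
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "p_raw": self.p_raw, "p_adj": self.p_adj,
            "enriched": self.enriched,
        }


def enrich_sets(sets, annotations: AnnotationTable, background: Iterable[str],
                alpha: float = 0.001, per_vocabulary: bool = True,
                min_set_size: int = 2) -> list[EnrichmentResult]:
    """Fisher/BH enrichment of every trajectory set against the background.

    Only (set, term) pairs where the term annotates at least one set member
    are tested; BH runs across all tested pairs, within each vocabulary
    when ``per_vocabulary`` (the default). Results come back sorted by
    adjusted then raw p.
    """
    background = set(background)
    results: list[EnrichmentResult] = []
    # term -> annotated genes restricted to the background
    term_genes: dict[tuple[str, str, str], set[str]] = {}
    for g, terms in annotations.mapping.items():
        if g not in background:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(g)
    N = len(background)
    for ts in sets:
        members = set(ts.member_genes)
        outside = members - background
        if outside:
            raise ValueError(
                f"set {ts.set_id} members outside background: {sorted(outside)}")
        if len(members) < min_set_size:
            continue
        for (vocab, term_id, term_name), annotated in sorted(
                term_genes.items()):
            a = len(members & annotated)
            if a == 0:
                continue
            b = len(members) - a
            c = len(annotated) - a
            d = N - a - b - c
            p = fisher_right_tail(a, b, c, d)
            results.append(EnrichmentResult(ts.set_id, vocab, term_id,
                                            term_name, a, b, c, d, p))
    if not results:
        return results
    if per_vocabulary:
        vocabs = {r.vocabulary for r in results}
        for vocab in vocabs:
            idx = [i for i, r in enumerate(results) if r.vocabulary == vocab]
            adj = bh_adjust([results[i].p_raw for i in idx])
            for i, pa in zip(idx, adj):
                results[i].p_adj = float(pa)
    else:
        adj = bh_adjust([r.p_raw for r in results])
        for r, pa in zip(results, adj):
            r.p_adj = float(pa)
    for r in results:
        r.enriched = bool(r.p_adj < alpha)
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.set_id, r.term_id))
    return results
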