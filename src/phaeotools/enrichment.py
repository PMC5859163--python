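"""Observed/expected functional-term enrichment with a chi-squared test.

The occurrence of a term within a gene set is compared with its occurrence
in the complete annotated catalog: the observed/expected ratio is the term's
in-set proportion over its catalog proportion, and significance comes from a
Pearson chi-squared test (df=1, no continuity correction) on the 2x2 table
of in-set/rest-of-catalog vs with/without term, thresholded at p < 0.05.
Cells with expected counts below 5 are flagged rather than silently switched
to another test.  No term-graph propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["TermMap", "load_term_map", "enrich"]


@dataclass(frozen=True)
class TermMap:
    """gene -> set of term ids; the key set is the catalog universe."""

    gene_terms: dict

    @property
    def catalog_size(self) -> int:
        return len(self.gene_terms)

    def catalog_hits(self, term: str) -> int:
        return sum(1 for ts in self.gene_terms.values() if term in ts)


def load_term_map(path) -> TermMap:
    """Read a 2-column (gene, term) TSV; one row per association."""
    gene_terms: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}, line {lineno}: expected 2 columns")
            gene_terms.setdefault(cols[0], set()).add(cols[1])
    return TermMap(gene_terms)


def _chi2_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-squared without continuity correction on [[a, b], [c, d]].

    Returns (chi2, p, min_expected).  A degenerate margin yields chi2=0, p=1.
    """
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 0.0, 1.0, 0.0
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    min_expected = min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / n
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return float(chi2), p, float(min_expected)


def enrich(gene_set, terms: TermMap, alpha: float = 0.05) -> pd.DataFrame:
    """Term enrichment of ``gene_set`` against the whole catalog background.

    One row per term occurring in the set, with observed/expected ratio,
    chi-squared statistic, p-value, a significance flag at ``alpha`` and a
    low-expected-count warning flag.  Sorted ascending by p.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    universe = terms.gene_terms
    outside = gene_set - universe.keys()
    if outside:
        raise KeyError(f"gene(s) not in catalog universe: {sorted(outside)[:5]}")
    set_size = len(gene_set)
    catalog_size = terms.catalog_size
    set_terms: dict = {}
    for g in gene_set:
        for t in universe[g]:
            set_terms[t] = set_terms.get(t, 0) + 1
    rows = []
    for term, set_hits in set_terms.items():
        catalog_hits = terms.catalog_hits(term)
        if catalog_hits == 0:
            raise ValueError(f"term {term!r} has zero catalog hits")
        a = set_hits
        b = set_size - set_hits
        c = catalog_hits - set_hits  # rest of catalog with term
        d = (catalog_size - set_size) - c
        chi2, p, min_exp = _chi2_2x2(a, b, c, d)
        oe = (set_hits / set_size) / (catalog_hits / catalog_size)
        rows.append(
            {
                "term": term,
                "set_hits": set_hits,
                "set_size": set_size,
                "catalog_hits": catalog_hits,
                "catalog_size": catalog_size,
                "oe_ratio": oe,
                "chi2": chi2,
                "p": p,
                "significant": p < alpha,
                "low_expected_count": min_exp < 5,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term", "set_hits", "set_size", "catalog_hits", "catalog_size",
            "oe_ratio", "chi2", "p", "significant", "low_expected_count",
        ],
    )
    return df.sort_values(["p", "term"]).reset_index(drop=True)
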