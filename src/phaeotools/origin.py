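"""Top-hit origin calling and acquisition dating over the deletion series.

For each gene the best hit from every reference sub-category is collated and
ranked; a gene receives an unambiguous evolutionary origin only when the top
two (by default) ranked sub-categories belong to the same group, i.e. top
hits are obtained in two or more sub-categories of one lineage before the
best hit from any other lineage.  Repeating the call over the
clade-deletion series (full library, then progressively removing pennate
diatoms, diatoms, ochrophytes, stramenopiles, SAR, SAR+CCTH) exposes older
signal: the shallowest library at which a foreign group is called dates the
acquisition to the corresponding ancestral branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .homology import HitTable, hit_sort_key, top_hit_per_subcategory
from .taxonomy import SERIES_BRANCHES, LibraryVariant, TaxonomyScheme

__all__ = [
    "AMBIGUOUS",
    "NO_HIT",
    "SELF_GROUPS",
    "RankedHits",
    "OriginCall",
    "AcquisitionPoint",
    "rank_subcategory_hits",
    "call_origin",
    "date_acquisition",
    "summarize_category_counts",
    "run_series",
]

AMBIGUOUS = "AMBIGUOUS"
NO_HIT = "NO_HIT"

#: The query's own lineage groups: calls landing here are vertical for dating.
SELF_GROUPS = frozenset({"diatoms", "non_diatom_stramenopiles"})

#: variant id -> acquisition branch label, in series order.
VARIANT_BRANCH = {vid: branch for vid, _flags, branch in SERIES_BRANCHES}
SERIES_ORDER = [vid for vid, _flags, _branch in SERIES_BRANCHES]


@dataclass(frozen=True)
class RankedHits:
    """A gene's best per-sub-category hits in strict hit order."""

    gene_id: str
    variant_id: str
    entries: tuple  # of (subcategory_id, group, evalue, bitscore)


@dataclass(frozen=True)
class OriginCall:
    gene_id: str
    variant_id: str
    call: str  # group token, AMBIGUOUS or NO_HIT
    supporting: frozenset = frozenset()


@dataclass(frozen=True)
class AcquisitionPoint:
    gene_id: str
    category: str | None  # foreign group token, or None for vertical genes
    branch: str  # terminal .. pre_sar, or "none"
    consistent: bool = True  # deeper variants all repeat the dated category


def rank_subcategory_hits(top_hits: dict, scheme: TaxonomyScheme, gene_id: str,
                          variant_id: str = "full") -> RankedHits:
    """Order a gene's per-sub-category best hits by the strict hit order.

    ``top_hits`` is the per-gene mapping produced by
    :func:`phaeotools.homology.top_hit_per_subcategory` (sub-category id ->
    best :class:`HitRecord`).
    """
    ranked = sorted(top_hits.values(), key=hit_sort_key)
    entries = tuple(
        (h.subject_subcategory, scheme.group_of(h.subject_subcategory),
         h.evalue, h.bitscore)
        for h in ranked
    )
    return RankedHits(gene_id=gene_id, variant_id=variant_id, entries=entries)


def call_origin(ranked: RankedHits, min_subcategories: int = 2,
                strictness: str = "strict") -> OriginCall:
    """Assign an origin group from ranked per-sub-category top hits.

    ``strict`` (default): the first ``min_subcategories`` entries must all
    share one group.  ``prefix``: at least ``min_subcategories`` entries of
    the top entry's group must precede the best hit from any other group —
    under the strict total hit order the two readings coincide, but the
    flag keeps the alternative reading explicit and selectable.
    """
    if strictness not in ("strict", "prefix"):
        raise ValueError("strictness must be 'strict' or 'prefix'")
    entries = ranked.entries
    if not entries:
        return OriginCall(ranked.gene_id, ranked.variant_id, NO_HIT)
    if len(entries) < min_subcategories:
        return OriginCall(ranked.gene_id, ranked.variant_id, AMBIGUOUS)
    top_group = entries[0][1]
    if strictness == "strict":
        head = entries[:min_subcategories]
        if all(e[1] == top_group for e in head):
            return OriginCall(
                ranked.gene_id, ranked.variant_id, top_group,
                frozenset(e[0] for e in head),
            )
        return OriginCall(ranked.gene_id, ranked.variant_id, AMBIGUOUS)
    # prefix reading: count same-group entries before the first foreign entry
    supporting = []
    for e in entries:
        if e[1] != top_group:
            break
        supporting.append(e[0])
    if len(supporting) >= min_subcategories:
        return OriginCall(
            ranked.gene_id, ranked.variant_id, top_group,
            frozenset(supporting[:min_subcategories]),
        )
    return OriginCall(ranked.gene_id, ranked.variant_id, AMBIGUOUS)


def date_acquisition(calls, self_groups=SELF_GROUPS) -> AcquisitionPoint:
    """Date a gene's acquisition from its calls across the deletion series.

    ``calls`` maps variant id -> :class:`OriginCall` and must cover the full
    seven-variant series.  Calls in ``self_groups`` (or AMBIGUOUS / NO_HIT)
    are vertical/uninformative.  The gene's foreign category is the call of
    the deepest library with a foreign call — deeper libraries have had more
    of the vertical lineage removed, so they expose the donor — and the
    acquisition branch maps from the shallowest library calling that same
    category (full -> terminal, minus-pennates -> pennate ancestor, ...).
    Genes whose foreign call is interrupted or replaced at intermediate
    depths keep the date of the shallowest appearance and are flagged as a
    non-monotone series (``consistent=False``).
    """
    missing = [v for v in SERIES_ORDER if v not in calls]
    if missing:
        raise KeyError(f"missing deletion-series variant(s): {missing}")
    series = [calls[v] for v in SERIES_ORDER]
    gene_id = series[0].gene_id

    def is_foreign(call):
        return call not in (AMBIGUOUS, NO_HIT) and call not in self_groups

    category = None
    for oc in series:  # deepest foreign call wins; iterate shallow -> deep
        if is_foreign(oc.call):
            category = oc.call
    if category is None:
        return AcquisitionPoint(gene_id, None, "none", True)
    idx = min(i for i, oc in enumerate(series) if oc.call == category)
    branch = VARIANT_BRANCH[SERIES_ORDER[idx]]
    consistent = all(oc.call == category for oc in series[idx:])
    return AcquisitionPoint(gene_id, category, branch, consistent)


def summarize_category_counts(calls) -> pd.DataFrame:
    """Contingency of gene counts per variant and call category.

    ``calls`` is an iterable of :class:`OriginCall`.  Rows are variants,
    columns categories (groups plus AMBIGUOUS and NO_HIT); every gene of a
    variant lands in exactly one cell, so each row sums to that variant's
    gene count.
    """
    rows: dict = {}
    for oc in calls:
        rows.setdefault(oc.variant_id, {}).setdefault(oc.call, 0)
        rows[oc.variant_id][oc.call] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    order = [v for v in SERIES_ORDER if v in df.index]
    extra = [v for v in df.index if v not in SERIES_ORDER]
    return df.reindex(order + extra)


def run_series(
    hit_tables: dict,
    scheme: TaxonomyScheme,
    variants,
    min_subcategories: int = 2,
    strictness: str = "strict",
    restrict_to: LibraryVariant | None = None,
) -> pd.DataFrame:
    """Call origins over a deletion series and date acquisitions.

    ``hit_tables`` maps variant id -> :class:`HitTable` (or a single table
    under the key ``"full"``, filtered per variant by sub-category).
    ``restrict_to`` applies an orthogonal filter (e.g. the complex-algae-free
    variant) before every deletion level.  Returns a per-gene frame with the
    per-variant calls, final category, branch and consistency flag.
    """
    per_gene_calls: dict = {}
    for variant in variants:
        table = hit_tables.get(variant.id, hit_tables.get("full"))
        if table is None:
            raise KeyError(f"no hit table for variant {variant.id!r}")
        if restrict_to is not None:
            variant = LibraryVariant(
                id=variant.id,
                excluded_flags=variant.excluded_flags | restrict_to.excluded_flags,
                included=variant.included & restrict_to.included,
            )
        tops = top_hit_per_subcategory(table, variant)
        for gene_id, per_subcat in tops.items():
            ranked = rank_subcategory_hits(per_subcat, scheme, gene_id, variant.id)
            oc = call_origin(ranked, min_subcategories, strictness)
            per_gene_calls.setdefault(gene_id, {})[variant.id] = oc
    # genes with no hits at some level still need a NO_HIT call there
    all_genes = sorted(per_gene_calls)
    rows = []
    for gene_id in all_genes:
        calls = per_gene_calls[gene_id]
        for vid in SERIES_ORDER:
            if vid not in calls:
                calls[vid] = OriginCall(gene_id, vid, NO_HIT)
        ap = date_acquisition(calls)
        row = {"gene_id": gene_id}
        for vid in SERIES_ORDER:
            row[f"call_{vid}"] = calls[vid].call
        row["category"] = ap.category if ap.category else "vertical"
        row["branch"] = ap.branch
        row["consistent"] = ap.consistent
        rows.append(row)
    return pd.DataFrame(rows)
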