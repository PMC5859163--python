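"""Reciprocal-best-hit conservation profiling over the nine groups.

A query gene is *shared* with a group when it has a reciprocal best hit
(RbH) in at least two separate sub-categories of that group — the
two-sub-category rule guards against contamination and sub-group-specific
transfers.  Per-gene presence vectors over the nine groups are tallied into
conservation patterns and binned into restriction classes (species-specific,
diatom-restricted, stramenopile-restricted, shared wider).
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import HitTable, hit_sort_key
from .taxonomy import TaxonomyScheme

__all__ = [
    "ConservationProfile",
    "reciprocal_best_hits",
    "group_presence",
    "tally_patterns",
    "restriction_class",
    "profiles_to_rows",
]

MIN_SUBCATEGORIES = 2


@dataclass(frozen=True)
class ConservationProfile:
    """Presence of a gene across the scheme's groups, with supporting bins."""

    gene_id: str
    presence: dict  # group token -> bool
    support: dict  # group token -> frozenset of sub-category ids

    @property
    def pattern(self) -> str:
        """Presence vector as a bit string in group order."""
        return "".join("1" if self.presence[g] else "0" for g in self.presence)


def _best_per_query(table: HitTable) -> dict:
    """query -> best hit under the strict hit order (self-hits ignored)."""
    best: dict = {}
    for hit in table:
        if hit.subject_id == hit.query_id:
            continue
        cur = best.get(hit.query_id)
        if cur is None or hit_sort_key(hit) < hit_sort_key(cur):
            best[hit.query_id] = hit
    return best


def reciprocal_best_hits(forward: HitTable, reverse: dict) -> dict:
    """Per-gene set of sub-categories with a reciprocal best hit.

    ``forward`` holds hits of the query proteome against all reference
    sub-categories (each hit annotated with its sub-category); ``reverse``
    maps sub-category id to the hit table of that sub-category's proteins
    searched back against the query proteome.  Sub-category ``S`` enters gene
    ``g``'s RbH set iff ``g``'s best hit within ``S`` is protein ``p`` and
    ``p``'s best hit among query genes is ``g``.  Both directions are assumed
    thresholded identically.
    """
    # best forward hit per (gene, subcategory)
    fwd_best: dict = {}
    for hit in forward:
        if hit.subject_id == hit.query_id:
            continue
        key = (hit.query_id, hit.subject_subcategory)
        cur = fwd_best.get(key)
        if cur is None or hit_sort_key(hit) < hit_sort_key(cur):
            fwd_best[key] = hit
    rev_best = {sc: _best_per_query(tbl) for sc, tbl in reverse.items()}
    out: dict = {}
    for (gene, subcat), hit in fwd_best.items():
        back = rev_best.get(subcat, {}).get(hit.subject_id)
        if back is not None and back.subject_id == gene:
            out.setdefault(gene, set()).add(subcat)
    return out


def group_presence(
    gene_id: str,
    rbh_set,
    scheme: TaxonomyScheme,
    min_subcategories: int = MIN_SUBCATEGORIES,
) -> ConservationProfile:
    """Fold a gene's RbH sub-category set into a per-group presence vector."""
    support = {g: set() for g in scheme.groups}
    for sc_id in rbh_set:
        support[scheme.group_of(sc_id)].add(sc_id)  # KeyError if unknown
    presence = {
        g: len(support[g]) >= min_subcategories for g in scheme.groups
    }
    return ConservationProfile(
        gene_id=gene_id,
        presence=presence,
        support={g: frozenset(s) for g, s in support.items()},
    )


def tally_patterns(profiles) -> list:
    """Counts per distinct presence pattern, sorted descending by count.

    Ties are broken by pattern key so the output is deterministic.
    """
    counts: dict = {}
    for p in profiles:
        counts[p.pattern] = counts.get(p.pattern, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def restriction_class(profile: ConservationProfile) -> str:
    """Bin a presence vector into the four evolutionary restriction classes.

    ``species_specific``: shared with no group at all.
    ``diatom_restricted``: shared with diatoms only.
    ``stramenopile_restricted``: shared within stramenopiles (non-diatom
    stramenopiles present, nothing outside the stramenopile groups).
    ``shared_wider``: anything else.
    """
    present = {g for g, v in profile.presence.items() if v}
    if not present:
        return "species_specific"
    if present == {"diatoms"}:
        return "diatom_restricted"
    if (
        present <= {"diatoms", "non_diatom_stramenopiles"}
        and "non_diatom_stramenopiles" in present
    ):
        return "stramenopile_restricted"
    return "shared_wider"


def profiles_to_rows(profiles, scheme: TaxonomyScheme) -> list:
    """Per-gene output rows: gene, presence per group, pattern, class."""
    rows = []
    for p in profiles:
        row = {"gene_id": p.gene_id}
        for g in scheme.groups:
            row[g] = int(p.presence[g])
        row["pattern"] = p.pattern
        row["restriction_class"] = restriction_class(p)
        rows.append(row)
    return rows
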