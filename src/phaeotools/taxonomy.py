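"""Two-level taxonomy scheme and clade-deletion reference libraries.

The reference proteome set is organised in two levels: fine *sub-categories*
(e.g. "cyanobacteria", "raphid pennate diatoms") nested in nine coarse
*groups* (diatoms, non-diatom stramenopiles, non-stramenopile SAR, CCTH,
green eukaryotes, red algae, amorphea, prokaryotes, viruses).  Every
evolutionary rule downstream (reciprocal-best-hit sharing, top-hit origin
calling, acquisition dating) is phrased over this scheme.

Nested clade membership is encoded as flags rather than a full tree:
``pennate_diatom ⊂ diatom ⊂ ochrophyte ⊂ stramenopile ⊂ sar``.  Flags are
sufficient to express every deletion rule used by the clade-deletion series
(progressively removing the query's closest relatives to expose older
homology signal) and the complex-algae-free filter.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import yaml

__all__ = [
    "CLADE_FLAGS",
    "FLAG_NESTING",
    "GROUPS",
    "SERIES_BRANCHES",
    "SubCategory",
    "TaxonomyScheme",
    "LibraryVariant",
    "load_scheme",
    "dump_scheme",
    "default_scheme",
    "build_variant",
    "deletion_series",
    "complex_algae_free",
]

#: Recognised nested-clade labels.
CLADE_FLAGS = frozenset(
    {
        "pennate_diatom",
        "diatom",
        "ochrophyte",
        "stramenopile",
        "sar",
        "ccth",
        "secondary_endosymbiotic_alga",
        "prokaryote",
        "virus",
    }
)

#: flag -> flag it implies (pennate_diatom => diatom => ... => sar).
FLAG_NESTING = {
    "pennate_diatom": "diatom",
    "diatom": "ochrophyte",
    "ochrophyte": "stramenopile",
    "stramenopile": "sar",
}

#: The nine groups, in canonical order.
GROUPS = (
    "diatoms",
    "non_diatom_stramenopiles",
    "non_stramenopile_sar",
    "ccth",
    "green",
    "red_algae",
    "amorphea",
    "prokaryotes",
    "viruses",
)

#: Deletion series: (variant id, cumulative excluded clade flags, branch label).
#: The branch label is the point of acquisition a foreign call first exposed
#: at that depth is dated to.
SERIES_BRANCHES = (
    ("full", frozenset(), "terminal"),
    ("minus_pennates", frozenset({"pennate_diatom"}), "pennate_ancestor"),
    ("minus_diatoms", frozenset({"diatom"}), "diatom_ancestor"),
    ("minus_ochrophytes", frozenset({"ochrophyte"}), "ochrophyte_ancestor"),
    ("minus_stramenopiles", frozenset({"stramenopile"}), "stramenopile_ancestor"),
    ("minus_sar", frozenset({"sar"}), "sar_ancestor"),
    ("minus_sar_ccth", frozenset({"sar", "ccth"}), "pre_sar"),
)


class SchemeError(ValueError):
    """A taxonomy scheme violates one of its invariants."""


@dataclass(frozen=True)
class SubCategory:
    """One fine taxonomic bin of the reference library."""

    id: str
    name: str
    group_id: str
    clade_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "clade_flags", frozenset(self.clade_flags))
        unknown = self.clade_flags - CLADE_FLAGS
        if unknown:
            raise SchemeError(
                f"sub-category {self.id!r}: unknown clade flag(s) {sorted(unknown)}"
            )
        for flag, implied in FLAG_NESTING.items():
            if flag in self.clade_flags and implied not in self.clade_flags:
                raise SchemeError(
                    f"sub-category {self.id!r}: flag {flag!r} requires {implied!r} "
                    "(clade nesting violated)"
                )


@dataclass(frozen=True)
class TaxonomyScheme:
    """Ordered groups plus the sub-categories binned into them."""

    groups: tuple = GROUPS
    sub_categories: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "sub_categories", tuple(self.sub_categories))
        if not self.sub_categories:
            raise SchemeError("scheme has no sub-categories")
        seen = set()
        for sc in self.sub_categories:
            if sc.id in seen:
                raise SchemeError(f"duplicate sub-category id {sc.id!r}")
            seen.add(sc.id)
            if sc.group_id not in self.groups:
                raise SchemeError(
                    f"sub-category {sc.id!r}: unknown group token {sc.group_id!r}"
                )

    def __iter__(self):
        return iter(self.sub_categories)

    @property
    def subcategory_ids(self):
        return [sc.id for sc in self.sub_categories]

    def subcategory(self, sc_id: str) -> SubCategory:
        for sc in self.sub_categories:
            if sc.id == sc_id:
                return sc
        raise KeyError(f"unknown sub-category id {sc_id!r}")

    def group_of(self, sc_id: str) -> str:
        return self.subcategory(sc_id).group_id

    def counts(self) -> dict:
        """Counts of prokaryotic (incl. viral) vs eukaryotic sub-categories."""
        prok = sum(1 for sc in self if "prokaryote" in sc.clade_flags)
        vir = sum(1 for sc in self if "virus" in sc.clade_flags)
        return {
            "prokaryotic": prok,
            "viral": vir,
            "eukaryotic": len(self.sub_categories) - prok - vir,
            "total": len(self.sub_categories),
        }


@dataclass(frozen=True)
class LibraryVariant:
    """A reference-library variant: the scheme minus some excluded clades."""

    id: str
    excluded_flags: frozenset
    included: frozenset  # sub-category ids

    def __contains__(self, sc_id: str) -> bool:
        return sc_id in self.included


# ---------------------------------------------------------------------------
# Scheme I/O


def load_scheme(source) -> TaxonomyScheme:
    """Load and validate a scheme from a YAML document (path, file or str).

    Expected layout::

        groups: [diatoms, ...]          # optional; defaults to the nine groups
        sub_categories:
          - id: raphid_pennates
            name: Raphid pennate diatoms
            group: diatoms
            flags: [pennate_diatom, diatom, ochrophyte, stramenopile, sar]
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    elif isinstance(source, str) and "\n" in source:
        doc = yaml.safe_load(io.StringIO(source))
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "sub_categories" not in doc:
        raise SchemeError("scheme document must contain a 'sub_categories' list")
    groups = tuple(doc.get("groups", GROUPS))
    subcats = []
    for entry in doc["sub_categories"] or []:
        subcats.append(
            SubCategory(
                id=str(entry["id"]),
                name=str(entry.get("name", entry["id"])),
                group_id=str(entry["group"]),
                clade_flags=frozenset(entry.get("flags", [])),
            )
        )
    return TaxonomyScheme(groups=groups, sub_categories=tuple(subcats))


def dump_scheme(scheme: TaxonomyScheme) -> str:
    """Serialize a scheme to the YAML layout read by :func:`load_scheme`."""
    doc = {
        "groups": list(scheme.groups),
        "sub_categories": [
            {
                "id": sc.id,
                "name": sc.name,
                "group": sc.group_id,
                "flags": sorted(sc.clade_flags),
            }
            for sc in scheme
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def _sc(id, name, group, *flags):
    return SubCategory(id, name, group, frozenset(flags))


_PENNATE = ("pennate_diatom", "diatom", "ochrophyte", "stramenopile", "sar")
_DIATOM = ("diatom", "ochrophyte", "stramenopile", "sar")
_OCHRO = ("ochrophyte", "stramenopile", "sar")
_STRAM = ("stramenopile", "sar")


def default_scheme() -> TaxonomyScheme:
    """Packaged default scheme: representative sub-categories per group.

    The full published sub-category list lives in supplementary material of
    the source datasets; the packaged default ships a representative,
    user-editable selection (at least two sub-categories per group, so the
    two-sub-category sharing and origin rules are exercisable) validated by
    the same invariants as any user config.
    """
    subcats = (
        # diatoms: two pennate, two centric lineages
        _sc("raphid_pennates", "Raphid pennate diatoms", "diatoms", *_PENNATE),
        _sc("araphid_pennates", "Araphid pennate diatoms", "diatoms", *_PENNATE),
        _sc("polar_centrics", "Polar centric diatoms", "diatoms", *_DIATOM),
        _sc("radial_centrics", "Radial centric diatoms", "diatoms", *_DIATOM),
        # non-diatom stramenopiles: other ochrophytes + plastid-lacking lines
        _sc("pelagophytes", "Pelagophytes and dictyochophytes",
            "non_diatom_stramenopiles", *_OCHRO),
        _sc("eustigmatophytes", "Eustigmatophytes", "non_diatom_stramenopiles",
            *_OCHRO),
        _sc("oomycetes", "Oomycetes", "non_diatom_stramenopiles", *_STRAM),
        _sc("labyrinthulomycetes", "Labyrinthulomycetes",
            "non_diatom_stramenopiles", *_STRAM),
        # non-stramenopile SAR
        _sc("dinoflagellates", "Dinoflagellates", "non_stramenopile_sar",
            "sar", "secondary_endosymbiotic_alga"),
        _sc("apicomplexans", "Apicomplexans and chromerids",
            "non_stramenopile_sar", "sar", "secondary_endosymbiotic_alga"),
        _sc("ciliates", "Ciliates", "non_stramenopile_sar", "sar"),
        _sc("chlorarachniophytes", "Chlorarachniophytes and other rhizarians",
            "non_stramenopile_sar", "sar", "secondary_endosymbiotic_alga"),
        # CCTH
        _sc("cryptomonads", "Cryptomonads", "ccth", "ccth",
            "secondary_endosymbiotic_alga"),
        _sc("haptophytes", "Haptophytes", "ccth", "ccth",
            "secondary_endosymbiotic_alga"),
        _sc("centrohelids", "Centrohelids and telonemids", "ccth", "ccth"),
        # green eukaryotes (incl. glaucophytes)
        _sc("chlorophytes", "Chlorophyte green algae", "green"),
        _sc("streptophytes", "Streptophytes and land plants", "green"),
        _sc("glaucophytes", "Glaucophytes", "green"),
        # red algae
        _sc("florideophytes", "Florideophyte red algae", "red_algae"),
        _sc("bangiophytes", "Bangiophyte red algae", "red_algae"),
        _sc("extremophile_reds", "Extremophilic red algae", "red_algae"),
        # amorphea (opisthokonts + amoebozoa + excavates)
        _sc("metazoa", "Metazoa", "amorphea"),
        _sc("fungi", "Fungi", "amorphea"),
        _sc("amoebozoa", "Amoebozoa", "amorphea"),
        _sc("excavates", "Excavates", "amorphea"),
        _sc("euglenids", "Euglenids", "amorphea", "secondary_endosymbiotic_alga"),
        # prokaryotes
        _sc("cyanobacteria", "Cyanobacteria", "prokaryotes", "prokaryote"),
        _sc("proteobacteria", "Proteobacteria", "prokaryotes", "prokaryote"),
        _sc("firmicutes", "Firmicutes", "prokaryotes", "prokaryote"),
        _sc("actinobacteria", "Actinobacteria", "prokaryotes", "prokaryote"),
        _sc("deinococcus_thermus", "Deinococcus-Thermus", "prokaryotes",
            "prokaryote"),
        _sc("archaea", "Archaea", "prokaryotes", "prokaryote"),
        # viruses
        _sc("dsdna_viruses", "Large dsDNA viruses", "viruses", "virus"),
        _sc("other_viruses", "Other viruses", "viruses", "virus"),
    )
    return TaxonomyScheme(groups=GROUPS, sub_categories=subcats)


# ---------------------------------------------------------------------------
# Library variants


def build_variant(scheme: TaxonomyScheme, excluded_flags, variant_id=None) -> LibraryVariant:
    """Reference-library variant keeping sub-categories disjoint from the flags."""
    excluded = frozenset(excluded_flags)
    unknown = excluded - CLADE_FLAGS
    if unknown:
        raise SchemeError(f"unknown clade label(s): {sorted(unknown)}")
    included = frozenset(
        sc.id for sc in scheme if not (sc.clade_flags & excluded)
    )
    if variant_id is None:
        variant_id = "minus_" + "_".join(sorted(excluded)) if excluded else "full"
    return LibraryVariant(id=variant_id, excluded_flags=excluded, included=included)


def deletion_series(scheme: TaxonomyScheme) -> list:
    """The seven-library deletion series, shallow to deep.

    Order: full library, then minus pennate diatoms, minus diatoms, minus
    ochrophytes, minus stramenopiles, minus SAR, minus SAR+CCTH.  Excluded
    sub-category sets grow monotonically along the series.
    """
    return [
        build_variant(scheme, flags, variant_id=vid)
        for vid, flags, _branch in SERIES_BRANCHES
    ]


def complex_algae_free(scheme: TaxonomyScheme, variant_id="complex_algae_free") -> LibraryVariant:
    """Variant removing secondary-endosymbiotic algae, exempting ochrophytes.

    Algae whose plastid derives from secondary (or higher) endosymbiosis can
    share genes with the query through their plastid history rather than
    vertical descent; removing them sharpens donor assignment.  Ochrophytes
    (the query's own lineage) are kept regardless of the flag.
    """
    excluded = frozenset(
        sc.id
        for sc in scheme
        if "secondary_endosymbiotic_alga" in sc.clade_flags
        and "ochrophyte" not in sc.clade_flags
    )
    included = frozenset(sc.id for sc in scheme) - excluded
    return LibraryVariant(
        id=variant_id,
        excluded_flags=frozenset({"secondary_endosymbiotic_alga"}),
        included=included,
    )
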