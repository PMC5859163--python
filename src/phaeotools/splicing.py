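"""Coverage-based intron-retention (IR) and exon-skipping (ES) calling.

Only genes annotated with two or more exons are analysed, and only introns
of at least 50 bp are IR-analysable.  Within each RNA-Seq sample a feature
(gene exonic union, intron, internal exon) *passes* coverage when more than
80% of its bases are covered at depth above 4x — one joint
horizontal/vertical rule.  A gene is expressed in a sample when its exonic
union passes; expressed samples are the informative denominator for
consensus: an intron is a retention event when retained in more than 20% of
informative samples, an internal exon is a skipping event when its inclusion
fraction lies strictly between 20% and 80%.

Splice sites are classified canonical when the transcript-orientation
dinucleotides are GT (donor) and AG (acceptor); on the minus strand this
reads CT..AC on the reference.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) and
bedGraph (already 0-based half-open) are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils
import numpy as np

from .epigenome import welch_t_test

__all__ = [
    "GeneModel",
    "CoverageTrack",
    "ASConfig",
    "ASEvent",
    "read_gff3",
    "read_bedgraph",
    "eligible_genes",
    "splice_site_class",
    "feature_passes",
    "per_sample_calls",
    "consensus_calls",
    "call_events",
    "expression_contrast",
]


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one gene (0-based half-open exons)."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # of (start, end), ascending, non-overlapping

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def introns(self) -> tuple:
        """Gaps between consecutive exons, genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def internal_exons(self) -> tuple:
        return self.exons[1:-1]

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])


class CoverageTrack:
    """Per-base read depth of one sample; absent positions have depth 0."""

    def __init__(self, sample_id: str, depths: dict):
        self.sample_id = sample_id
        self.depths = {c: np.asarray(d) for c, d in depths.items()}
        for c, d in self.depths.items():
            if (d < 0).any():
                raise ValueError(f"negative depth on {c}")

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth vector over [start, end); zeros outside the stored arrays."""
        out = np.zeros(end - start, dtype=float)
        arr = self.depths.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


@dataclass
class ASConfig:
    """Eligibility, coverage and consensus thresholds of the AS caller."""

    min_exons: int = 2
    min_intron_len: int = 50
    horizontal_frac: float = 0.80
    vertical_depth: float = 4.0
    consensus_low: float = 0.20
    consensus_high: float = 0.80

    def __post_init__(self):
        if not (0 < self.consensus_low < self.consensus_high < 1):
            raise ValueError("need 0 < consensus_low < consensus_high < 1")
        if self.vertical_depth <= 0:
            raise ValueError("vertical_depth must be > 0")


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    kind: str  # "IR" or "ES"
    feature: tuple  # (chrom, start, end)
    sample_fraction: float  # retention fraction (IR) / inclusion fraction (ES)


# ---------------------------------------------------------------------------
# Readers


def read_gff3(path) -> list:
    """Gene models from GFF3: one model per gene, exons of its first mRNA.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(parent, featuretype="exon", order_by="start")
        )
        if not exons:
            continue
        models.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                exons=tuple(exons),
            )
        )
    return models


def read_bedgraph(path, sample_id: str, chrom_sizes: dict) -> CoverageTrack:
    """Load a bedGraph (0-based half-open intervals) into dense depth arrays."""
    depths = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"{path}, line {lineno}: expected 4 columns")
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if chrom not in depths:
                raise KeyError(f"{path}, line {lineno}: unknown chrom {chrom!r}")
            depths[chrom][start:end] = value
    return CoverageTrack(sample_id, depths)


# ---------------------------------------------------------------------------
# Calling


def eligible_genes(models, cfg: ASConfig | None = None) -> list:
    """Genes with >= min_exons exons, paired with their IR-analysable introns.

    Introns shorter than ``min_intron_len`` are excluded from IR analysis;
    the gene itself stays eligible (for ES, and for IR on any qualifying
    intron).  Returns ``[(model, qualifying_introns), ...]``.
    """
    if cfg is None:
        cfg = ASConfig()
    out = []
    for m in models:
        if len(m.exons) < cfg.min_exons:
            continue
        qualifying = tuple(
            iv for iv in m.introns if iv[1] - iv[0] >= cfg.min_intron_len
        )
        out.append((m, qualifying))
    return out


def splice_site_class(intron: tuple, strand: str, genome: dict, chrom: str) -> str:
    """Classify an intron's splice sites as canonical or non-canonical.

    ``genome`` maps chrom -> sequence string.  Canonical means GT at the
    donor and AG at the acceptor in transcript orientation, i.e. reference
    GT..AG on '+' and CT..AC on '-'.
    """
    start, end = intron
    seq = genome[chrom]
    if start < 0 or end > len(seq) or end - start < 4:
        raise ValueError(f"intron ({start}, {end}) out of bounds on {chrom}")
    first2 = seq[start : start + 2].upper()
    last2 = seq[end - 2 : end].upper()
    if strand == "+":
        canonical = first2 == "GT" and last2 == "AG"
    else:
        canonical = first2 == "CT" and last2 == "AC"
    return "canonical" if canonical else "non_canonical"


def feature_passes(feature: tuple, track: CoverageTrack, cfg: ASConfig,
                   chrom: str) -> bool:
    """Joint horizontal/vertical coverage rule for one feature interval.

    True iff the fraction of bases with depth strictly above
    ``vertical_depth`` strictly exceeds ``horizontal_frac``.
    """
    start, end = feature
    if end <= start:
        raise ValueError(f"zero-length feature ({start}, {end})")
    d = track.depth(chrom, start, end)
    frac = float(np.mean(d > cfg.vertical_depth))
    return frac > cfg.horizontal_frac


def _union_passes(intervals, track: CoverageTrack, cfg: ASConfig, chrom: str) -> bool:
    depths = np.concatenate([track.depth(chrom, s, e) for s, e in intervals])
    return float(np.mean(depths > cfg.vertical_depth)) > cfg.horizontal_frac


def per_sample_calls(gene: GeneModel, qualifying_introns, track: CoverageTrack,
                     cfg: ASConfig | None = None):
    """Per-sample expression plus intron-retained / exon-included flags.

    A gene is expressed when its exonic union passes the coverage rule;
    feature flags are only reported for expressed genes (``None`` flags
    otherwise).  Returns ``(expressed, intron_retained, exon_included)``
    where the flag tuples align with ``qualifying_introns`` and
    ``gene.internal_exons``.
    """
    if cfg is None:
        cfg = ASConfig()
    expressed = _union_passes(gene.exons, track, cfg, gene.chrom)
    if not expressed:
        return False, None, None
    retained = tuple(
        feature_passes(iv, track, cfg, gene.chrom) for iv in qualifying_introns
    )
    included = tuple(
        feature_passes(ex, track, cfg, gene.chrom) for ex in gene.internal_exons
    )
    return True, retained, included


def consensus_calls(gene: GeneModel, qualifying_introns, per_sample,
                    cfg: ASConfig | None = None) -> list:
    """Fold per-sample flags into consensus IR/ES events for one gene.

    ``per_sample`` is a list of ``per_sample_calls`` results across samples.
    Only samples where the gene is expressed are informative; zero
    informative samples skips the gene with a warning.
    """
    if cfg is None:
        cfg = ASConfig()
    informative = [(r, i) for (exp, r, i) in per_sample if exp]
    if not informative:
        warnings.warn(f"{gene.gene_id}: expressed in no sample; skipped")
        return []
    n = len(informative)
    events = []
    for k, iv in enumerate(qualifying_introns):
        frac = sum(1 for r, _ in informative if r[k]) / n
        if frac > cfg.consensus_low:
            events.append(ASEvent(gene.gene_id, "IR", (gene.chrom, *iv), frac))
    for k, ex in enumerate(gene.internal_exons):
        frac = sum(1 for _, i in informative if i[k]) / n
        if cfg.consensus_low < frac < cfg.consensus_high:
            events.append(ASEvent(gene.gene_id, "ES", (gene.chrom, *ex), frac))
    return events


def call_events(models, tracks, cfg: ASConfig | None = None) -> list:
    """Full caller: eligibility, per-sample flags, consensus. All genes."""
    if cfg is None:
        cfg = ASConfig()
    events = []
    for model, qualifying in eligible_genes(models, cfg):
        per_sample = [
            per_sample_calls(model, qualifying, t, cfg) for t in tracks
        ]
        if not any(exp for exp, _r, _i in per_sample):
            continue  # uninformative gene; consensus would only warn
        events.extend(consensus_calls(model, qualifying, per_sample, cfg))
    return events


def expression_contrast(gene_sets: dict, expr, reference: str) -> list:
    """Welch contrasts of event-gene expression per condition vs a reference.

    ``gene_sets`` maps a label (e.g. ``("IR", "T15")``) to (gene ids,
    condition column); ``expr`` is a genes x conditions DataFrame of
    normalised counts.  Each set's expression under its condition is
    compared with the same genes' expression under ``reference`` by the
    Welch unequal-variance t-test.  Sets of fewer than two genes yield NA
    statistics.
    """
    rows = []
    for label, (genes, condition) in gene_sets.items():
        genes = [g for g in genes if g in expr.index]
        x = expr.loc[genes, condition].to_numpy(dtype=float)
        y = expr.loc[genes, reference].to_numpy(dtype=float)
        res = welch_t_test(x, y)
        rows.append(
            {
                "set": label,
                "condition": condition,
                "n": len(genes),
                "mean": float(np.mean(x)) if len(genes) else float("nan"),
                "mean_reference": float(np.mean(y)) if len(genes) else float("nan"),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return rows
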