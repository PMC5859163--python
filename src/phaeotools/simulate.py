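"""Seeded generators for every input the pipeline consumes, with truth.

Three families of generators emulate the study's three data layers:

* **Proteomes / hit tables** — gene families evolved over the clade
  hierarchy with planted vertical or horizontally-transferred histories.
  Sequence-level simulation (random ancestral peptides, i.i.d. per-site
  substitution per branch) feeds the internal aligner at desk scale;
  score-level simulation (hit scores decaying with planted clade distance)
  feeds the origin pipeline at larger n without quadratic alignment cost.
* **Coverage** — multi-exon gene models with canonical splice sites and
  per-sample per-base depth, with intron-retention and exon-skipping events
  planted by construction to satisfy (or, for negative controls, violate)
  the consensus rules.
* **Marks / expression** — feature intervals carrying epigenetic-mark
  combinations with configured frequencies, and count matrices where
  repressive marks multiply expression by a configured effect.

All generators are pure functions of their configuration: the same seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import homology
from .epigenome import ACTIVE_MARKS, MARKS, REPRESSIVE_MARKS
from .homology import AMINO_ACIDS, HitRecord, HitTable, SearchConfig
from .splicing import CoverageTrack, GeneModel
from .taxonomy import SERIES_BRANCHES, TaxonomyScheme, default_scheme

__all__ = [
    "SimConfig",
    "clade_level",
    "simulate_proteomes",
    "simulate_hit_tables",
    "write_hit_tables",
    "simulate_coverage",
    "write_coverage",
    "simulate_marks_expression",
    "simulate_term_map",
    "ORIGIN_CLASSES",
]

ORIGIN_CLASSES = ("vertical", "prokaryote", "red", "green", "species_specific")

#: origin class -> donor group token (None for non-HGT classes)
DONOR_GROUP = {"prokaryote": "prokaryotes", "red": "red_algae", "green": "green"}

BRANCHES = tuple(branch for _vid, _flags, branch in SERIES_BRANCHES)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    ``origin_mix`` gives the proportion of gene families per evolutionary
    history; HGT families additionally receive an acquisition branch
    (uniform over the seven datable branches unless fixed).  ``subst_prob``
    is the per-site substitution probability per clade branch.  Coverage
    depth is Poisson around ``depth_mean`` in noisy mode and exactly
    ``depth_mean`` noise-free.  ``score_noise_sd`` is the standard deviation
    of Gaussian noise added to simulated hit scores (score units; the
    planted score gap between adjacent clade levels is 30).
    """

    seed: int = 0
    n_families: int = 350
    origin_mix: dict = field(
        default_factory=lambda: {
            "vertical": 100 / 350,
            "prokaryote": 100 / 350,
            "red": 50 / 350,
            "green": 50 / 350,
            "species_specific": 50 / 350,
        }
    )
    seq_len: int = 300
    subst_prob: float = 0.05
    score_noise_sd: float = 8.0
    # coverage layer
    n_genes: int = 50
    n_samples: int = 12
    depth_mean: float = 20.0
    ir_rate: float = 0.24
    es_rate: float = 0.20
    expressed_prob: float = 0.9
    noncanonical_frac: float = 0.002
    # marks / expression layer
    n_features: int = 400
    n_expr_samples: int = 4
    mark_effect: float = 0.25

    def __post_init__(self):
        total = sum(self.origin_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"origin_mix proportions sum to {total}, not 1")
        for key, p in self.origin_mix.items():
            if key not in ORIGIN_CLASSES:
                raise ValueError(f"unknown origin class {key!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"origin_mix[{key!r}] outside [0, 1]")
        for name in ("subst_prob", "ir_rate", "es_rate", "expressed_prob",
                     "noncanonical_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]")


def desk_scale_scheme() -> TaxonomyScheme:
    """Ten-sub-category scheme (two per group over five groups).

    Keeps aligner-based all-vs-all analyses fast while still exercising the
    two-sub-category rules in every represented group.
    """
    full = default_scheme()
    keep = {
        "raphid_pennates", "polar_centrics",
        "pelagophytes", "oomycetes",
        "dinoflagellates", "ciliates",
        "chlorophytes", "streptophytes",
        "cyanobacteria", "proteobacteria",
    }
    return TaxonomyScheme(
        groups=full.groups,
        sub_categories=tuple(sc for sc in full if sc.id in keep),
    )


def clade_level(subcat) -> int:
    """Distance of a sub-category from the query, in clade-branch steps.

    1 = other pennate diatoms, 2 = centric diatoms, 3 = other ochrophytes,
    4 = plastid-lacking stramenopiles, 5 = other SAR, 6 = CCTH,
    7 = other eukaryotes, 8 = prokaryotes, 9 = viruses.
    """
    f = subcat.clade_flags
    if "pennate_diatom" in f:
        return 1
    if "diatom" in f:
        return 2
    if "ochrophyte" in f:
        return 3
    if "stramenopile" in f:
        return 4
    if "sar" in f:
        return 5
    if "ccth" in f:
        return 6
    if "prokaryote" in f:
        return 8
    if "virus" in f:
        return 9
    return 7


def _assign_origins(cfg: SimConfig, rng) -> pd.DataFrame:
    """Planted truth: per family an origin class, donor group and branch."""
    classes = list(cfg.origin_mix)
    counts = [int(round(cfg.origin_mix[c] * cfg.n_families)) for c in classes]
    # fix rounding drift on the largest class
    drift = cfg.n_families - sum(counts)
    counts[int(np.argmax(counts))] += drift
    rows = []
    i = 0
    for cls, k in zip(classes, counts):
        for _ in range(k):
            gene_id = f"gene{i:04d}"
            if cls in DONOR_GROUP:
                branch = BRANCHES[int(rng.integers(len(BRANCHES)))]
                donor = DONOR_GROUP[cls]
            else:
                branch, donor = "none", ""
            rows.append(
                {"gene_id": gene_id, "origin": cls, "donor_group": donor,
                 "branch": branch}
            )
            i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequence-level simulation


def _random_peptide(rng, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))

def _mutate(rng, seq: str, p: float) -> str:
    if p <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < p)[0]
    for i in hits:
        out[i] = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
    return "".join(out)


def simulate_proteomes(cfg: SimConfig, scheme: TaxonomyScheme | None = None):
    """Sequence-level families: per-sub-category FASTA dicts plus truth.

    Returns ``(subcat_proteomes, query_proteome, truth)`` where
    ``subcat_proteomes`` maps sub-category id -> {protein_id: sequence}.
    Vertical families are conserved within the stramenopile lineage (clade
    levels 1-4), with divergence growing with clade distance;
    horizontally-acquired families derive the query copy (and the recipient
    clade below the acquisition branch) from the donor group's sequence;
    species-specific families have no homologs.  Every group holds at least
    two sub-categories, so the two-sub-category sharing rules are
    exercisable.
    """
    if scheme is None:
        scheme = default_scheme()
    rng = np.random.default_rng(cfg.seed)
    truth = _assign_origins(cfg, rng)
    levels = {sc.id: clade_level(sc) for sc in scheme}
    branch_index = {branch: i for i, (_v, _f, branch) in enumerate(SERIES_BRANCHES)}
    subcat_proteomes: dict = {sc.id: {} for sc in scheme}
    query: dict = {}
    for row in truth.itertuples():
        gene, origin = row.gene_id, row.origin
        anc = _random_peptide(rng, cfg.seq_len)
        if origin == "species_specific":
            query[gene] = anc
            continue
        if origin == "vertical":
            query[gene] = _mutate(rng, anc, cfg.subst_prob * 0.5)
            for sc in scheme:
                lvl = levels[sc.id]
                if lvl <= 4:
                    subcat_proteomes[sc.id][f"{sc.id}|{gene}"] = _mutate(
                        rng, anc, cfg.subst_prob * lvl
                    )
            continue
        # horizontal acquisition: query copy descends from the donor lineage
        k = branch_index[row.branch]
        query[gene] = _mutate(rng, anc, cfg.subst_prob * 0.5)
        for sc in scheme:
            lvl = levels[sc.id]
            if sc.group_id == row.donor_group:
                subcat_proteomes[sc.id][f"{sc.id}|{gene}"] = _mutate(
                    rng, anc, cfg.subst_prob * 7
                )
            elif lvl <= k:
                subcat_proteomes[sc.id][f"{sc.id}|{gene}"] = _mutate(
                    rng, anc, cfg.subst_prob * lvl
                )
    return subcat_proteomes, query, truth


# ---------------------------------------------------------------------------
# Score-level simulation

_BASE_SCORE = 400.0
_LEVEL_GAP = 30.0
_DONOR_LEVEL = 7  # donor hits rank just below the deepest recipient copies


def simulate_hit_tables(
    cfg: SimConfig,
    scheme: TaxonomyScheme | None = None,
    noise: bool = False,
    truth: pd.DataFrame | None = None,
):
    """Score-level hit tables for the full reference library.

    Returns ``(table, subject_map, truth)``: one :class:`HitTable` of the
    full library (per-variant views are obtained by excluding sub-categories
    downstream) plus the subject -> sub-category map.  Hit scores decay
    linearly with planted clade distance (gap 30 per level from base 400),
    with a small deterministic per-sub-category offset breaking ties and,
    when ``noise`` is set, Gaussian perturbation of ``score_noise_sd``.
    """
    if scheme is None:
        scheme = default_scheme()
    rng = np.random.default_rng(cfg.seed + 1)
    if truth is None:
        truth = _assign_origins(cfg, rng)
    levels = {sc.id: clade_level(sc) for sc in scheme}
    branch_index = {branch: i for i, (_v, _f, branch) in enumerate(SERIES_BRANCHES)}
    offsets = {sc.id: 0.2 * i for i, sc in enumerate(scheme)}
    search_cfg = SearchConfig()
    table = HitTable()
    subject_map: dict = {}

    def add_hit(gene: str, sc_id: str, level: float):
        score = _BASE_SCORE - _LEVEL_GAP * level + offsets[sc_id]
        if noise:
            score += rng.normal(0.0, cfg.score_noise_sd)
        subject = f"{sc_id}|{gene}"
        subject_map[subject] = sc_id
        ev = homology.score_to_evalue(score, cfg.seq_len, cfg.seq_len, search_cfg)
        if ev > search_cfg.evalue_threshold:
            return
        table.append(
            HitRecord(
                query_id=gene,
                subject_id=subject,
                subject_subcategory=sc_id,
                percent_identity=min(99.0, 25.0 + score / 5.0),
                aln_length=cfg.seq_len,
                evalue=ev,
                bitscore=homology.bitscore(score, search_cfg),
            )
        )

    for row in truth.itertuples():
        if row.origin == "species_specific":
            continue
        if row.origin == "vertical":
            for sc in scheme:
                lvl = levels[sc.id]
                if lvl <= 4:
                    add_hit(row.gene_id, sc.id, lvl)
            continue
        k = branch_index[row.branch]
        for sc in scheme:
            lvl = levels[sc.id]
            if sc.group_id == row.donor_group:
                add_hit(row.gene_id, sc.id, _DONOR_LEVEL)
            elif lvl <= k:
                add_hit(row.gene_id, sc.id, lvl)
    return table, subject_map, truth


def write_hit_tables(table: HitTable, subject_map: dict, out_dir, scheme=None,
                     variants=None):
    """Write 12-column tabular files per library variant plus the subject map."""
    import os

    from .taxonomy import deletion_series

    if scheme is None:
        scheme = default_scheme()
    if variants is None:
        variants = deletion_series(scheme)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for variant in variants:
        path = os.path.join(out_dir, f"hits_{variant.id}.tsv")
        with open(path, "w") as fh:
            for h in table:
                if h.subject_subcategory not in variant:
                    continue
                fh.write(
                    "\t".join(
                        [
                            h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                            str(h.aln_length), "0", "0", "1", str(h.aln_length),
                            "1", str(h.aln_length), f"{h.evalue:.3e}",
                            f"{h.bitscore:.1f}",
                        ]
                    )
                    + "\n"
                )
        paths[variant.id] = path
    map_path = os.path.join(out_dir, "subject_map.tsv")
    with open(map_path, "w") as fh:
        for subject, sc in sorted(subject_map.items()):
            fh.write(f"{subject}\t{sc}\n")
    return paths, map_path


# ---------------------------------------------------------------------------
# Coverage simulation

_DNA = np.array(list("ACGT"))


def simulate_coverage(cfg: SimConfig, noise: bool = False):
    """Gene models, genome, per-sample coverage and planted IR/ES truth.

    Genes carry 5-7 exons (>= 50 bp introns, canonical splice sites except a
    ``noncanonical_frac`` of introns).  Where a gene is expressed in a
    sample its exons are covered at ``depth_mean`` (Poisson in noisy mode);
    introns and intergenic bases stay at background.  Planted IR introns
    receive exon-like depth in a subset of the gene's *expressed* samples
    sized to satisfy the >20% consensus rule; planted ES exons receive
    background depth in a subset sized to keep the inclusion fraction
    strictly inside (20%, 80%).  The skipped exon is always the smallest
    internal exon so the gene's exonic union still passes the expression
    filter in skipped samples.

    Returns ``(models, genome, tracks, truth)``; ``genome`` maps chrom ->
    sequence, ``tracks`` is one :class:`CoverageTrack` per sample.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    chrom = "chr1"
    models = []
    pos = 100
    layout = []  # (model, es_exon_index or None placeholder)
    for g in range(cfg.n_genes):
        n_exons = int(rng.integers(5, 8))
        es_exon = int(rng.integers(1, n_exons - 1))  # internal, kept small
        exons = []
        introns = []
        for e in range(n_exons):
            length = 80 if e == es_exon else int(rng.integers(100, 151))
            exons.append((pos, pos + length))
            pos += length
            if e < n_exons - 1:
                ilen = int(rng.integers(50, 121))
                introns.append((pos, pos + ilen))
                pos += ilen
        strand = "+" if rng.random() < 0.5 else "-"
        model = GeneModel(f"g{g:03d}", chrom, strand, tuple(exons))
        models.append(model)
        layout.append((model, es_exon))
        pos += 200
    genome_len = pos + 100
    seq = rng.choice(_DNA, size=genome_len)
    # plant splice sites in transcript orientation
    for model, _es in layout:
        for (istart, iend) in model.introns:
            canonical = rng.random() >= cfg.noncanonical_frac
            if model.strand == "+":
                donor, acceptor = ("GT", "AG") if canonical else ("GC", "AG")
                seq[istart], seq[istart + 1] = donor[0], donor[1]
                seq[iend - 2], seq[iend - 1] = acceptor[0], acceptor[1]
            else:
                first, last = ("CT", "AC") if canonical else ("CT", "GC")
                seq[istart], seq[istart + 1] = first[0], first[1]
                seq[iend - 2], seq[iend - 1] = last[0], last[1]
    genome = {chrom: "".join(seq)}

    expressed = rng.random((cfg.n_genes, cfg.n_samples)) < cfg.expressed_prob
    truth_rows = []
    plan = []  # per gene: (model, expressed_row, ir plans, es plans)
    for gi, (model, es_exon) in enumerate(layout):
        exp_samples = np.nonzero(expressed[gi])[0]
        ir_features = []
        es_features = []
        qualifying = [iv for iv in model.introns if iv[1] - iv[0] >= 50]
        if len(exp_samples) >= 2 and qualifying and rng.random() < cfg.ir_rate:
            iv = qualifying[int(rng.integers(len(qualifying)))]
            frac = rng.uniform(0.3, 0.7)
            k = max(1, int(np.ceil(frac * len(exp_samples))))
            chosen = rng.choice(exp_samples, size=k, replace=False)
            ir_features.append((iv, set(int(s) for s in chosen)))
            truth_rows.append(
                {"gene_id": model.gene_id, "kind": "IR", "chrom": model.chrom,
                 "start": iv[0], "end": iv[1],
                 "fraction": k / len(exp_samples)}
            )
        if len(exp_samples) >= 4 and rng.random() < cfg.es_rate:
            ex = model.exons[es_exon]
            frac = rng.uniform(0.3, 0.7)  # inclusion target
            k_skip = int(np.clip(round((1 - frac) * len(exp_samples)),
                                 1, len(exp_samples) - 1))
            incl = (len(exp_samples) - k_skip) / len(exp_samples)
            if 0.2 < incl < 0.8:
                chosen = rng.choice(exp_samples, size=k_skip, replace=False)
                es_features.append((ex, set(int(s) for s in chosen)))
                truth_rows.append(
                    {"gene_id": model.gene_id, "kind": "ES",
                     "chrom": model.chrom, "start": ex[0], "end": ex[1],
                     "fraction": incl}
                )
        plan.append((model, expressed[gi], ir_features, es_features))

    def draw(mean, size):
        if noise:
            return rng.poisson(mean, size=size).astype(float)
        return np.full(size, float(mean))

    tracks = []
    for s in range(cfg.n_samples):
        depth = np.zeros(genome_len)
        if noise:
            depth += rng.poisson(0.2, size=genome_len)
        for model, exp_row, ir_features, es_features in plan:
            if not exp_row[s]:
                continue
            skipped = {ex for ex, samples in es_features if s in samples}
            for ex in model.exons:
                if ex in skipped:
                    continue
                depth[ex[0]:ex[1]] = draw(cfg.depth_mean, ex[1] - ex[0])
            for iv, samples in ir_features:
                if s in samples:
                    depth[iv[0]:iv[1]] = draw(cfg.depth_mean, iv[1] - iv[0])
        tracks.append(CoverageTrack(f"sample{s:02d}", {chrom: depth}))
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "kind", "chrom", "start", "end", "fraction"]
    )
    return models, genome, tracks, truth


def write_coverage(models, genome, tracks, out_dir):
    """Write GFF3 gene models, genome FASTA and per-sample bedGraph files."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    gff_path = os.path.join(out_dir, "models.gff3")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            fh.write(
                f"{m.chrom}\tsim\tgene\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tsim\tmRNA\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons):
                fh.write(
                    f"{m.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.e{i};Parent={m.gene_id}.t1\n"
                )
    fasta_path = os.path.join(out_dir, "genome.fa")
    with open(fasta_path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    bg_paths = []
    for track in tracks:
        path = os.path.join(out_dir, f"{track.sample_id}.bedgraph")
        with open(path, "w") as fh:
            for chrom, depth in track.depths.items():
                # run-length encode constant-depth intervals
                change = np.nonzero(np.diff(depth))[0] + 1
                bounds = np.concatenate(([0], change, [len(depth)]))
                for a, b in zip(bounds[:-1], bounds[1:]):
                    v = depth[a]
                    if v != 0:
                        fh.write(f"{chrom}\t{a}\t{b}\t{v:g}\n")
        bg_paths.append(path)
    return gff_path, fasta_path, bg_paths


# ---------------------------------------------------------------------------
# Marks / expression simulation

_STATE_FREQ = {"unmarked": 0.25, "active_only": 0.20,
               "repressive_only": 0.35, "both": 0.20}
_CLASS_FREQ = {"gene": 0.70, "TE_classI": 0.15, "TE_classII": 0.15}


def simulate_marks_expression(cfg: SimConfig):
    """Feature intervals, per-mark BED intervals, counts and planted truth.

    Chromatin states are drawn with fixed frequencies (25% unmarked, 20%
    active-only, 35% repressive-only, 20% both); within a polarity a random
    non-empty mark subset is chosen (CG weighted highest among repressive
    marks).  Baseline expression is lognormal (median 100, sigma 1); any
    repressive mark multiplies the expectation by ``mark_effect``; counts
    are Poisson per sample around the expectation times that sample's
    planted size factor.

    Returns ``(features, mark_beds, counts, truth)`` where ``features`` is
    the ``annotate_marks`` input and ``mark_beds`` maps mark -> BED
    intervals.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    chrom = "chr1"
    flen, gap = 1000, 200
    states = list(_STATE_FREQ)
    state_p = np.array([_STATE_FREQ[s] for s in states])
    classes = list(_CLASS_FREQ)
    class_p = np.array([_CLASS_FREQ[c] for c in classes])
    rep_w = np.array([0.40, 0.12, 0.12, 0.12, 0.12, 0.12])  # CG-heavy
    planted_sf = np.resize([1.0, 1.3, 0.7, 1.1], cfg.n_expr_samples)

    features = []
    mark_beds: dict = {m: [] for m in MARKS}
    truth_rows = []
    expectations = []
    for i in range(cfg.n_features):
        start = 100 + i * (flen + gap)
        end = start + flen
        fid = f"feat{i:04d}"
        fclass = classes[int(rng.choice(len(classes), p=class_p))]
        state = states[int(rng.choice(len(states), p=state_p))]
        chosen = []
        if state in ("repressive_only", "both"):
            k = int(rng.integers(1, len(REPRESSIVE_MARKS) + 1))
            idx = rng.choice(len(REPRESSIVE_MARKS), size=k, replace=False,
                             p=rep_w / rep_w.sum())
            chosen += [REPRESSIVE_MARKS[j] for j in sorted(idx)]
        if state in ("active_only", "both"):
            k = int(rng.integers(1, len(ACTIVE_MARKS) + 1))
            idx = rng.choice(len(ACTIVE_MARKS), size=k, replace=False)
            chosen += [ACTIVE_MARKS[j] for j in sorted(idx)]
        for mark in chosen:
            a = start + int(rng.integers(0, flen // 2))
            b = a + int(rng.integers(100, flen - (a - start)))
            mark_beds[mark].append((chrom, a, min(b, end)))
        base = float(rng.lognormal(mean=math.log(100.0), sigma=1.0))
        repressed = any(m in REPRESSIVE_MARKS for m in chosen)
        expected = base * (cfg.mark_effect if repressed else 1.0)
        features.append((fid, chrom, start, end, fclass))
        expectations.append(expected)
        truth_rows.append(
            {"feature_id": fid, "feature_class": fclass, "state": state,
             "marks": "+".join(chosen) if chosen else "unmarked",
             "repressed": repressed, "expected_expression": expected}
        )
    counts = pd.DataFrame(
        rng.poisson(np.outer(expectations, planted_sf)),
        index=[f[0] for f in features],
        columns=[f"s{j}" for j in range(cfg.n_expr_samples)],
    )
    truth = pd.DataFrame(truth_rows).set_index("feature_id")
    truth["planted_size_factors"] = [list(planted_sf)] * len(truth)
    return features, mark_beds, counts, truth


def simulate_timecourse_expression(
    cfg: SimConfig,
    gene_ids,
    ir_genes=(),
    es_genes=(),
    conditions=("WT", "T15", "T45", "T90", "Tend"),
    ir_shift: float = 2.0,
    es_shift: float = 0.5,
) -> pd.DataFrame:
    """Normalised expression per gene and condition with planted AS effects.

    Baseline expression is lognormal (median 100, sigma 1) per gene and
    condition; genes undergoing intron retention are shifted x``ir_shift``
    and exon-skipping genes x``es_shift`` in every non-reference condition
    (the first condition is the reference).
    """
    rng = np.random.default_rng(cfg.seed + 5)
    ir_genes, es_genes = set(ir_genes), set(es_genes)
    data = {}
    for ci, cond in enumerate(conditions):
        values = rng.lognormal(mean=math.log(100.0), sigma=1.0, size=len(gene_ids))
        if ci > 0:
            for gi, g in enumerate(gene_ids):
                if g in ir_genes:
                    values[gi] *= ir_shift
                if g in es_genes:
                    values[gi] *= es_shift
        data[cond] = values
    return pd.DataFrame(data, index=list(gene_ids))


def simulate_term_map(cfg: SimConfig, gene_ids, enriched_genes=(),
                      enriched_term: str = "GO:ENRICHED",
                      n_terms: int = 20):
    """Random gene -> term assignments with one term enriched in a set."""
    rng = np.random.default_rng(cfg.seed + 4)
    enriched = set(enriched_genes)
    gene_terms: dict = {}
    for g in gene_ids:
        terms = {f"GO:{int(t):04d}" for t in rng.choice(n_terms, size=2)}
        if g in enriched:
            if rng.random() < 0.5:
                terms.add(enriched_term)
        elif rng.random() < 0.05:
            terms.add(enriched_term)
        gene_terms[g] = terms
    return gene_terms
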