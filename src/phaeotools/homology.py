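"""Similarity hits: tabular parsing and an exact local-alignment backend.

Production-scale similarity searches are supplied to the pipeline as
pre-computed 12-column tabular files (the de facto standard pairwise output:
query, subject, %identity, alignment length, mismatches, gap opens, qstart,
qend, sstart, send, e-value, bitscore).  For synthetic desk-scale tests the
module also provides an exact Smith–Waterman local aligner with affine gaps
(Gotoh recurrences) and a Karlin–Altschul e-value transform, so no external
search tool is needed.

Hit ordering is a strict total order throughout: ascending e-value, ties
broken by descending bitscore, then lexicographic subject id.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .taxonomy import LibraryVariant, TaxonomyScheme

__all__ = [
    "AMINO_ACIDS",
    "SearchConfig",
    "HitRecord",
    "HitTable",
    "hit_sort_key",
    "parse_hit_table",
    "smith_waterman",
    "sw_score",
    "score_to_evalue",
    "bitscore",
    "top_hit_per_subcategory",
    "all_vs_all_scores",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Gapped BLOSUM62 Karlin-Altschul parameters (gap open 11, extend 1).
_DEFAULT_K = 0.041
_DEFAULT_LAMBDA = 0.267


def _default_matrix():
    return substitution_matrices.load("BLOSUM62")


@dataclass
class SearchConfig:
    """Scoring and filtering parameters for similarity searches.

    ``gap_open`` is the cost of the first gapped position, ``gap_extend`` of
    each further one; both are applied as negative score contributions.
    ``karlin_K``/``karlin_lambda`` convert raw scores to e-values and bit
    scores.
    """

    evalue_threshold: float = 1e-10
    matrix: object = field(default_factory=_default_matrix)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_K: float = _DEFAULT_K
    karlin_lambda: float = _DEFAULT_LAMBDA

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are given as non-negative costs")


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit, annotated with its sub-category."""

    query_id: str
    subject_id: str
    subject_subcategory: str
    percent_identity: float
    aln_length: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"negative e-value on hit {self.query_id}->{self.subject_id}")
        if not math.isfinite(self.bitscore):
            raise ValueError(f"non-finite bitscore on hit {self.query_id}->{self.subject_id}")


def hit_sort_key(hit: HitRecord):
    """Strict total order: e-value asc, bitscore desc, subject id asc."""
    return (hit.evalue, -hit.bitscore, hit.subject_id)


class HitTable:
    """A list of :class:`HitRecord` with per-query grouping helpers."""

    def __init__(self, hits=()):
        self.hits = list(hits)

    def __len__(self):
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def append(self, hit: HitRecord):
        self.hits.append(hit)

    def by_query(self) -> dict:
        out: dict = {}
        for h in self.hits:
            out.setdefault(h.query_id, []).append(h)
        return out


_N_COLUMNS = 12


def parse_hit_table(
    path,
    scheme: TaxonomyScheme,
    subject_map: dict,
    cfg: SearchConfig | None = None,
    on_unmapped: str = "error",
) -> HitTable:
    """Parse a 12-column tabular hit file and map subjects to sub-categories.

    Rows with e-value above ``cfg.evalue_threshold`` are dropped (the
    threshold is inclusive: ``evalue <= threshold`` passes).  ``subject_map``
    maps subject ids to sub-category ids; subjects without a mapping raise by
    default, or are skipped with a warning when ``on_unmapped="skip"``.
    """
    if cfg is None:
        cfg = SearchConfig()
    if on_unmapped not in ("error", "skip"):
        raise ValueError("on_unmapped must be 'error' or 'skip'")
    known = set(scheme.subcategory_ids)
    table = HitTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _N_COLUMNS:
                raise ValueError(
                    f"{path}, line {lineno}: expected {_N_COLUMNS} tab-separated "
                    f"columns, found {len(cols)}"
                )
            try:
                pident = float(cols[2])
                alen = int(cols[3])
                evalue = float(cols[10])
                bits = float(cols[11])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-numeric field ({exc})")
            if evalue > cfg.evalue_threshold:
                continue
            subject = cols[1]
            subcat = subject_map.get(subject)
            if subcat is None:
                if on_unmapped == "skip":
                    warnings.warn(
                        f"{path}, line {lineno}: subject {subject!r} has no "
                        "sub-category mapping; skipped"
                    )
                    continue
                raise KeyError(
                    f"{path}, line {lineno}: subject {subject!r} has no "
                    "sub-category mapping"
                )
            if subcat not in known:
                raise KeyError(
                    f"{path}, line {lineno}: sub-category {subcat!r} not in scheme"
                )
            table.append(
                HitRecord(
                    query_id=cols[0],
                    subject_id=subject,
                    subject_subcategory=subcat,
                    percent_identity=pident,
                    aln_length=alen,
                    evalue=evalue,
                    bitscore=bits,
                )
            )
    return table


# ---------------------------------------------------------------------------
# Local alignment (Gotoh affine-gap Smith-Waterman)


def _encode(seq: str, alphabet_index: dict, label: str) -> np.ndarray:
    try:
        return np.array([alphabet_index[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown residue symbol {exc} in {label} sequence")


def _matrix_lookup(cfg: SearchConfig):
    alpha = str(cfg.matrix.alphabet)
    idx = {c: i for i, c in enumerate(alpha)}
    mat = np.asarray(cfg.matrix, dtype=float)
    return idx, mat


def sw_score(a: str, b: str, cfg: SearchConfig | None = None) -> float:
    """Optimal local-alignment score under affine gaps (score only).

    Row-vectorised Gotoh: within a row, the horizontal gap state satisfies a
    linear max-plus recurrence solved by a cumulative maximum, so the inner
    loop is pure numpy.
    """
    if cfg is None:
        cfg = SearchConfig()
    if not a or not b:
        return 0.0
    idx, mat = _matrix_lookup(cfg)
    ea = _encode(a, idx, "first")
    eb = _encode(b, idx, "second")
    open_cost = -(cfg.gap_open + cfg.gap_extend)  # first gapped position
    ext_cost = -cfg.gap_extend
    n = len(eb)
    neg = -1e30
    H_prev = np.zeros(n + 1)
    Iy_prev = np.full(n + 1, neg)  # gap in b (vertical)
    best = 0.0
    j_idx = np.arange(n)
    for i in range(len(ea)):
        sub = mat[ea[i], eb]
        M = H_prev[:-1] + sub  # diagonal from H[i-1][j-1]
        Iy = np.maximum(H_prev[1:] + open_cost, Iy_prev[1:] + ext_cost)
        A = np.maximum(np.maximum(M, Iy), 0.0)
        # Ix[p] = max_{q<p} A[q] + open + (p-1-q)*ext, via cumulative max
        B = A - ext_cost * j_idx
        cm = np.maximum.accumulate(B)
        Ix = np.full(n, neg)
        if n > 1:
            Ix[1:] = cm[:-1] + open_cost + ext_cost * (j_idx[1:] - 1)
        H = np.maximum(A, Ix)
        best = max(best, float(H.max()))
        H_prev = np.concatenate(([0.0], H))
        Iy_prev = np.concatenate(([neg], Iy))
    return best


def smith_waterman(a: str, b: str, cfg: SearchConfig | None = None):
    """Optimal local alignment with affine gaps; returns (score, spans).

    ``spans`` is ``((a_start, a_end), (b_start, b_end))`` in 0-based
    half-open coordinates of the best-scoring local alignment (``None`` for a
    score of 0).  Full three-state dynamic programming with traceback;
    symmetric in its arguments for symmetric substitution matrices.
    """
    if cfg is None:
        cfg = SearchConfig()
    if not a or not b:
        return 0.0, None
    idx, mat = _matrix_lookup(cfg)
    ea = _encode(a, idx, "first")
    eb = _encode(b, idx, "second")
    m, n = len(ea), len(eb)
    open_cost = -(cfg.gap_open + cfg.gap_extend)
    ext_cost = -cfg.gap_extend
    neg = -1e30
    H = np.zeros((m + 1, n + 1))
    Ix = np.full((m + 1, n + 1), neg)
    Iy = np.full((m + 1, n + 1), neg)
    for i in range(1, m + 1):
        srow = mat[ea[i - 1], eb]
        for j in range(1, n + 1):
            Ix[i, j] = max(H[i, j - 1] + open_cost, Ix[i, j - 1] + ext_cost)
            Iy[i, j] = max(H[i - 1, j] + open_cost, Iy[i - 1, j] + ext_cost)
            H[i, j] = max(0.0, H[i - 1, j - 1] + srow[j - 1], Ix[i, j], Iy[i, j])
    best = float(H.max())
    if best <= 0:
        return 0.0, None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    end_i, end_j = int(i), int(j)
    # traceback to the 0 cell that starts the local path
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + mat[ea[i - 1], eb[j - 1]]:
                i, j = i - 1, j - 1
            elif H[i, j] == Ix[i, j]:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            if Ix[i, j] == H[i, j - 1] + open_cost:
                state = "H"
                j -= 1
            else:
                j -= 1
        else:
            if Iy[i, j] == H[i - 1, j] + open_cost:
                state = "H"
                i -= 1
            else:
                i -= 1
    return best, ((int(i), end_i), (int(j), end_j))


def score_to_evalue(score: float, m: int, n: int, cfg: SearchConfig | None = None) -> float:
    """Karlin-Altschul expect value ``E = K * m * n * exp(-lambda * S)``."""
    if cfg is None:
        cfg = SearchConfig()
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return cfg.karlin_K * m * n * math.exp(-cfg.karlin_lambda * score)


def bitscore(score: float, cfg: SearchConfig | None = None) -> float:
    """Normalised bit score ``(lambda*S - ln K) / ln 2``."""
    if cfg is None:
        cfg = SearchConfig()
    return (cfg.karlin_lambda * score - math.log(cfg.karlin_K)) / math.log(2.0)


# ---------------------------------------------------------------------------
# Top hits


def top_hit_per_subcategory(hits: HitTable, variant: LibraryVariant) -> dict:
    """Per query, the single best hit in each admissible sub-category.

    Returns ``{query_id: {subcategory_id: HitRecord}}``.  Sub-categories
    excluded by ``variant`` are absent; self-hits (subject id equal to query
    id) are ignored.
    """
    out: dict = {}
    for hit in hits:
        if hit.subject_id == hit.query_id:
            continue
        if hit.subject_subcategory not in variant:
            continue
        per_query = out.setdefault(hit.query_id, {})
        cur = per_query.get(hit.subject_subcategory)
        if cur is None or hit_sort_key(hit) < hit_sort_key(cur):
            per_query[hit.subject_subcategory] = hit
    return out


def all_vs_all_scores(
    queries: dict,
    subjects: dict,
    subject_subcategory: str,
    cfg: SearchConfig | None = None,
    symmetric_cache: dict | None = None,
) -> HitTable:
    """Score every query against every subject with the internal aligner.

    Returns a thresholded :class:`HitTable` (both directions share scores by
    the symmetry of Smith-Waterman, so a cache may be passed to reuse them).
    Intended for synthetic desk-scale data only.
    """
    if cfg is None:
        cfg = SearchConfig()
    table = HitTable()
    for qid, qseq in queries.items():
        for sid, sseq in subjects.items():
            if qid == sid:
                continue
            key = (qid, sid) if qid <= sid else (sid, qid)
            if symmetric_cache is not None and key in symmetric_cache:
                s = symmetric_cache[key]
            else:
                s = sw_score(qseq, sseq, cfg)
                if symmetric_cache is not None:
                    symmetric_cache[key] = s
            ev = score_to_evalue(s, len(qseq), len(sseq), cfg)
            if ev > cfg.evalue_threshold:
                continue
            table.append(
                HitRecord(
                    query_id=qid,
                    subject_id=sid,
                    subject_subcategory=subject_subcategory,
                    percent_identity=float("nan"),
                    aln_length=0,
                    evalue=ev,
                    bitscore=bitscore(s, cfg),
                )
            )
    return table
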