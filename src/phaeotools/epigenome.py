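"""Chromatin-mark annotation, chromatin states, expression integration.

Eight epigenetic marks are considered with fixed polarity: DNA methylation
contexts CG, CHG, CHH and histone marks H3K27me3, H3K9me2, H3K9me3 are
repressive; H3K4me2 and H3K9_14Ac are active.  Features (genes or
transposable elements) are annotated for binary mark presence by interval
overlap, classified into chromatin states (unmarked / active-only /
repressive-only / both), and joined to expression: median-of-ratios size
factors normalise raw counts, genes are profiled by expression quartile, and
marked feature sets are compared with unmarked ones by the Welch
unequal-variance t-test (the statistical kernel shared across the package).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "MARKS",
    "MARK_POLARITY",
    "REPRESSIVE_MARKS",
    "ACTIVE_MARKS",
    "WelchResult",
    "welch_t_test",
    "read_bed",
    "annotate_marks",
    "chromatin_state",
    "methylation_context_class",
    "state_summary",
    "size_factors",
    "expression_quartiles",
    "compare_marked_vs_unmarked",
    "te_context_summary",
]

REPRESSIVE_MARKS = ("CG", "CHG", "CHH", "H3K27me3", "H3K9me2", "H3K9me3")
ACTIVE_MARKS = ("H3K4me2", "H3K9_14Ac")
MARKS = REPRESSIVE_MARKS + ACTIVE_MARKS
MARK_POLARITY = {m: "repressive" for m in REPRESSIVE_MARKS}
MARK_POLARITY.update({m: "active" for m in ACTIVE_MARKS})

FEATURE_CLASSES = ("gene", "TE_classI", "TE_classII", "TE_other")


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t_test(x, y) -> WelchResult:
    """Two-sample t-test with unequal variances (Welch).

    Statistic ``t = (mx - my) / sqrt(sx^2/nx + sy^2/ny)`` with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.  Samples
    of fewer than two finite values return NA (NaN) statistics; two samples
    with equal means and zero variance return ``t=0, p=1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        return WelchResult(float("nan"), float("nan"), float("nan"))
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0:
        if diff == 0:
            return WelchResult(0.0, float(nx + ny - 2), 1.0)
        return WelchResult(float("inf") if diff > 0 else float("-inf"),
                           float(nx + ny - 2), 0.0)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


# ---------------------------------------------------------------------------
# Mark annotation


def read_bed(path) -> list:
    """Minimal BED reader: (chrom, start, end) 0-based half-open intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}, line {lineno}: fewer than 3 columns")
            out.append((cols[0], int(cols[1]), int(cols[2])))
    return out


def annotate_marks(features, marks: dict, min_overlap: int = 1) -> pd.DataFrame:
    """Binary feature x mark presence matrix by interval overlap.

    ``features`` is an iterable of ``(feature_id, chrom, start, end,
    feature_class)``; ``marks`` maps mark name -> list of ``(chrom, start,
    end)`` intervals.  ``presence[m]`` is True when some interval of mark
    ``m`` overlaps the feature by at least ``min_overlap`` bases.
    """
    trees: dict = {}
    for mark, intervals in marks.items():
        per_chrom: dict = {}
        for chrom, s, e in intervals:
            if s >= e:
                raise ValueError(f"mark {mark}: malformed interval ({s}, {e})")
            per_chrom.setdefault(chrom, []).append((s, e))
        trees[mark] = {
            c: IntervalTree.from_tuples(ivs) for c, ivs in per_chrom.items()
        }
    rows = []
    for fid, chrom, start, end, fclass in features:
        if start >= end:
            raise ValueError(f"feature {fid}: malformed interval ({start}, {end})")
        row = {"feature_id": fid, "feature_class": fclass}
        for mark in marks:
            tree = trees[mark].get(chrom)
            present = False
            if tree is not None:
                for iv in tree.overlap(start, end):
                    if min(end, iv.end) - max(start, iv.begin) >= min_overlap:
                        present = True
                        break
            row[mark] = present
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("feature_id") if rows else df


def chromatin_state(row) -> str:
    """Partition a mark-presence row into one of four chromatin states."""
    active = any(bool(row[m]) for m in ACTIVE_MARKS if m in row)
    repressive = any(bool(row[m]) for m in REPRESSIVE_MARKS if m in row)
    if active and repressive:
        return "BOTH"
    if active:
        return "ACTIVE_ONLY"
    if repressive:
        return "REPRESSIVE_ONLY"
    return "UNMARKED"


def methylation_context_class(row) -> str:
    """Partition the (CG, CHG, CHH) presence triple into context classes.

    CG-only, CHH-only and CG+CHH are distinguished; any combination
    involving CHG is pooled as ``CHG_involved`` (``other_combination`` is
    reserved for presence triples outside the recognised table and is not
    reachable for well-formed rows).
    """
    cg, chg, chh = bool(row["CG"]), bool(row["CHG"]), bool(row["CHH"])
    if not (cg or chg or chh):
        return "unmethylated"
    if chg:
        return "CHG_involved"
    if cg and chh:
        return "CG_plus_CHH"
    if cg:
        return "CG_only"
    if chh:
        return "CHH_only"
    return "other_combination"


def state_summary(matrix: pd.DataFrame) -> pd.Series:
    """Venn-style chromatin-state counts over a feature-mark matrix."""
    states = matrix.apply(chromatin_state, axis=1)
    counts = states.value_counts()
    return counts.reindex(
        ["ACTIVE_ONLY", "REPRESSIVE_ONLY", "BOTH", "UNMARKED"], fill_value=0
    )


def te_context_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """TE class x methylation-context contingency (pure group-by)."""
    te = matrix[matrix["feature_class"].isin(["TE_classI", "TE_classII", "TE_other"])]
    ctx = te.apply(methylation_context_class, axis=1)
    return pd.crosstab(te["feature_class"], ctx)


# ---------------------------------------------------------------------------
# Expression


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples count matrix).

    For each sample the factor is the median, over genes whose geometric
    mean across samples is positive, of the gene count divided by that
    geometric mean.  Normalised counts are ``counts / factors``.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0 or (mat == 0).all():
        raise ValueError("all-zero count matrix")
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has a positive geometric mean across samples")
    ratios = mat[usable] / np.exp(log_geo[usable])[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def expression_quartiles(norm_expr: pd.Series) -> pd.Series:
    """Quartile label per gene (Q1 no/low expression .. Q4 very high).

    Boundaries are the 25/50/75 linear-interpolation percentiles; values
    tying a boundary are assigned to the lower quartile.
    """
    values = norm_expr.to_numpy(dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 genes for quartile profiling")
    q25, q50, q75 = np.quantile(values, [0.25, 0.50, 0.75])
    labels = np.where(
        values <= q25, "Q1",
        np.where(values <= q50, "Q2", np.where(values <= q75, "Q3", "Q4")),
    )
    return pd.Series(labels, index=norm_expr.index, name="quartile")


def compare_marked_vs_unmarked(matrix: pd.DataFrame, expr: pd.Series) -> pd.DataFrame:
    """Mean expression and Welch test per mark combination vs unmarked.

    One row per observed mark combination (``+``-joined mark names in
    canonical order), with n, mean normalised expression, Welch t and
    two-sided p against the unmarked feature set.
    """
    marks = [m for m in MARKS if m in matrix.columns]
    combos = matrix[marks].apply(
        lambda r: "+".join(m for m in marks if r[m]) or "unmarked", axis=1
    )
    unmarked_ids = combos.index[combos == "unmarked"]
    if len(unmarked_ids) == 0:
        raise ValueError("unmarked feature set is empty")
    baseline = expr.loc[unmarked_ids].to_numpy(dtype=float)
    rows = []
    for combo, ids in combos.groupby(combos).groups.items():
        if combo == "unmarked":
            continue
        values = expr.loc[ids].to_numpy(dtype=float)
        res = welch_t_test(values, baseline)
        rows.append(
            {
                "combination": combo,
                "n": len(ids),
                "mean_expression": float(values.mean()),
                "t": res.t,
                "p": res.p,
            }
        )
    df = pd.DataFrame(rows, columns=["combination", "n", "mean_expression", "t", "p"])
    return df.sort_values("combination").reset_index(drop=True)
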