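"""Condition-specific ("difference") histone peaks and their gene evidence.

A tumor peak is tumor-specific iff it overlaps no normal peak of the same
mark by at least ``min_overlap`` bp (0-based half-open intervals; touching
endpoints do not overlap), and symmetrically for normal-specific peaks.
Only specific peaks whose own calling p-value is below ``p_cut`` (default
0.05) are retained as difference peaks.  Difference peaks are then
intersected with promoter/enhancer regions to yield per-gene evidence
tuples (gene, element, mark, direction).
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "neglog10p", "neglog10q", "summit",
]


def read_narrowpeak(path, mark: str, condition: str, no_p_filter: bool = False) -> pd.DataFrame:
    """Read a narrowPeak (10-col) or BED6 peak file into a peak frame.

    narrowPeak column 8 holds -log10(p); plain BED6 carries no p-value and is
    accepted only with ``no_p_filter=True`` (peaks get the p=0 sentinel so the
    p<0.05 filter, if later applied, keeps them all).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 10:
        df = df.iloc[:, :10]
        df.columns = NARROWPEAK_COLS
        df["p_value"] = 10.0 ** (-df["neglog10p"])
    elif df.shape[1] >= 3:
        if not no_p_filter:
            raise ValueError(
                f"{path}: BED without a p-value column requires no_p_filter=True"
            )
        df = df.iloc[:, :3]
        df.columns = ["chrom", "start", "end"]
        df["p_value"] = 0.0
    else:
        raise ValueError(f"{path}: expected >=3 columns")
    df["mark"] = mark
    df["condition"] = condition
    return df[["chrom", "start", "end", "mark", "condition", "p_value"]]


def _trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        t = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            t.addi(int(s), int(e))
        trees[chrom] = t
    return trees


def _specific(query: pd.DataFrame, other_trees, direction, min_overlap, p_cut):
    rows = []
    for row in query.itertuples(index=False):
        tree = other_trees.get(row.chrom)
        if tree is not None:
            hits = tree.overlap(row.start, row.end)
            if any(min(h.end, row.end) - max(h.begin, row.start) >= min_overlap for h in hits):
                continue
        if row.p_value < p_cut:
            rows.append((row.chrom, row.start, row.end, row.mark, row.condition,
                         row.p_value, direction))
    return rows


def find_condition_specific(
    tumor_peaks: pd.DataFrame,
    normal_peaks: pd.DataFrame,
    mark: str,
    min_overlap: int = 1,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Peaks present in exactly one condition, filtered at p < ``p_cut``."""
    for df, cond in ((tumor_peaks, "tumor"), (normal_peaks, "normal")):
        if len(df) and (df["mark"] != mark).any():
            raise ValueError(f"mixed marks in {cond} peak set (expected {mark})")
    rows = _specific(tumor_peaks, _trees(normal_peaks), "tumor_specific", min_overlap, p_cut)
    rows += _specific(normal_peaks, _trees(tumor_peaks), "normal_specific", min_overlap, p_cut)
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "mark", "condition", "p_value", "direction"],
    )
    return out.sort_values(["chrom", "start", "end", "direction"]).reset_index(drop=True)


def overlap_regions(diff_peaks: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Unique (gene, element, mark) evidence tuples from peak/region overlaps.

    ``regions`` columns: gene_id, element, chrom, start, end.  Each difference
    peak overlapping a region by >=1 bp contributes one event; events are
    deduplicated to unique (gene_id, element, source) with direction retained
    (first occurrence wins on conflicting directions).
    """
    region_trees: dict[str, IntervalTree] = {}
    for chrom, sub in regions.groupby("chrom"):
        t = IntervalTree()
        for idx, row in sub.iterrows():
            t.addi(int(row["start"]), int(row["end"]), (row["gene_id"], row["element"]))
        region_trees[chrom] = t

    events = {}
    for row in diff_peaks.itertuples(index=False):
        tree = region_trees.get(row.chrom)
        if tree is None:
            continue
        for h in tree.overlap(row.start, row.end):
            gid, element = h.data
            key = (gid, element, row.mark)
            events.setdefault(key, row.direction)
    out = pd.DataFrame(
        [(g, el, m, d) for (g, el, m), d in events.items()],
        columns=["gene_id", "element", "source", "direction"],
    )
    return out.sort_values(["gene_id", "element", "source"]).reset_index(drop=True)
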