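"""Bump-hunting differential methylation regions with permutation p-values.

The per-probe statistic is the tumor-minus-normal mean beta difference.
Probes are chained into clusters when consecutive gaps are at most
``max_gap`` bp; within each cluster the statistic is smoothed by a centered
running mean over ``w`` probes.  Candidate regions are maximal same-sign
runs of probes whose smoothed statistic clears ``delta_cut`` in absolute
value (single-probe runs are discarded), scored by their area
(sum of |smoothed statistic| over member probes).  Significance comes from
``B`` full label permutations: null candidate areas are pooled over all
permutations and a region's p-value is
(1 + #{null areas >= observed area}) / (1 + B).  Regions with p < 0.01 are
significant.

Missing beta values are imputed beforehand with k-nearest-probe averaging
(:func:`knn_impute`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)


def knn_impute(beta: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing beta values from the k nearest probes (nan-Euclidean).

    Each missing cell (probe, sample) is replaced by the unweighted mean of
    that sample's values at the k probes nearest in Euclidean distance over
    the samples both probes observe.  Probes with no observed value raise.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mat = beta.to_numpy(dtype=float)
    all_missing = np.isnan(mat).all(axis=1)
    if all_missing.any():
        bad = list(beta.index[all_missing])
        raise ValueError(f"probe(s) with all values missing: {bad[:5]}")
    if not np.isnan(mat).any():
        return beta.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(mat)
    filled = np.clip(filled, 0.0, 1.0)
    return pd.DataFrame(filled, index=beta.index, columns=beta.columns)


def _clusters(pos: np.ndarray, max_gap: int) -> list[slice]:
    """Maximal runs of sorted positions with consecutive gaps <= max_gap."""
    if len(pos) == 0:
        return []
    breaks = np.where(np.diff(pos) > max_gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(pos)]])
    return [slice(int(s), int(e)) for s, e in zip(starts, ends)]


def _running_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered running mean with edge truncation (window shrinks at ends)."""
    n = len(x)
    half = w // 2
    cs = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _candidate_regions(d: np.ndarray, cluster_slices, delta_cut: float, w: int):
    """(start_idx, end_idx_exclusive, area) for each candidate run of probes."""
    out = []
    for sl in cluster_slices:
        sm = _running_mean(d[sl.start:sl.stop], w)
        above = np.abs(sm) >= delta_cut
        sign = np.sign(sm)
        # run boundaries: change in (above, sign) state
        state = np.where(above, sign, 0.0)
        idx = 0
        n = len(state)
        while idx < n:
            if state[idx] == 0:
                idx += 1
                continue
            j = idx
            while j < n and state[j] == state[idx]:
                j += 1
            if j - idx >= 2:
                area = float(np.abs(sm[idx:j]).sum())
                out.append((sl.start + idx, sl.start + j, area))
            idx = j
    return out


def find_bumps(
    probes: pd.DataFrame,
    beta: pd.DataFrame,
    condition: pd.Series,
    max_gap: int = 500,
    delta_cut: float = 0.1,
    w: int = 5,
    B: int = 100,
    seed: int = 0,
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Bump-hunting DMRs between tumor and normal beta profiles.

    ``probes`` columns: probe_id, chrom, pos (1-based); rows must align with
    ``beta`` (probes x samples, complete — run :func:`knn_impute` first).
    Returns a frame with chrom, start, end (0-based half-open spanning the
    member probes), n_probes, mean_delta, area, p_value, significant.
    """
    if beta.isna().any().any():
        raise ValueError("beta matrix contains missing values; impute first")
    if B < 20:
        logger.warning("find_bumps: B=%d permutations give coarse p-value resolution", B)
    condition = condition.loc[beta.columns]
    t_mask = (condition == "tumor").to_numpy()
    n_mask = (condition == "normal").to_numpy()
    if t_mask.sum() < 2 or n_mask.sum() < 2:
        raise ValueError("need >=2 samples per group")

    order = np.lexsort((probes["pos"].to_numpy(), probes["chrom"].to_numpy()))
    probes_s = probes.iloc[order].reset_index(drop=True)
    mat = beta.to_numpy(dtype=float)[order]
    pos = probes_s["pos"].to_numpy()
    chroms = probes_s["chrom"].to_numpy()

    cluster_slices: list[slice] = []
    start = 0
    for i in range(1, len(pos) + 1):
        if i == len(pos) or chroms[i] != chroms[start]:
            rel = _clusters(pos[start:i], max_gap)
            cluster_slices += [slice(start + s.start, start + s.stop) for s in rel]
            start = i

    contrast = t_mask.astype(float) / t_mask.sum() - n_mask.astype(float) / n_mask.sum()
    d_obs = mat @ contrast
    observed = _candidate_regions(d_obs, cluster_slices, delta_cut, w)

    rng = np.random.default_rng(seed)
    labels = np.arange(mat.shape[1])
    null_areas = []
    for _ in range(B):
        perm = rng.permutation(labels)
        d_perm = mat @ contrast[perm]
        null_areas += [a for _, _, a in _candidate_regions(d_perm, cluster_slices, delta_cut, w)]
    null_areas = np.sort(np.asarray(null_areas))

    rows = []
    for s, e, area in observed:
        n_ge = len(null_areas) - np.searchsorted(null_areas, area, side="left")
        p = (1.0 + n_ge) / (1.0 + B)
        member = slice(s, e)
        delta = d_obs[member]
        rows.append({
            "chrom": chroms[s],
            "start": int(pos[s] - 1),
            "end": int(pos[e - 1]),
            "n_probes": e - s,
            "mean_delta": float(delta.mean()),
            "area": area,
            "p_value": float(p),
            "significant": bool(p < p_cut),
        })
    cols = ["chrom", "start", "end", "n_probes", "mean_delta", "area", "p_value", "significant"]
    return pd.DataFrame(rows, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True)


def overlap_dmrs(dmrs: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Evidence tuple per significant DMR overlapping a region by >=1 bp."""
    region_trees: dict[str, IntervalTree] = {}
    for chrom, sub in regions.groupby("chrom"):
        t = IntervalTree()
        for _, row in sub.iterrows():
            t.addi(int(row["start"]), int(row["end"]), (row["gene_id"], row["element"]))
        region_trees[chrom] = t

    events = {}
    for row in dmrs.itertuples(index=False):
        if not row.significant:
            continue
        tree = region_trees.get(row.chrom)
        if tree is None:
            continue
        for h in tree.overlap(row.start, row.end):
            gid, element = h.data
            direction = "hyper" if row.mean_delta > 0 else "hypo"
            events.setdefault((gid, element, "DMR"), direction)
    out = pd.DataFrame(
        [(g, el, src, d) for (g, el, src), d in events.items()],
        columns=["gene_id", "element", "source", "direction"],
    )
    return out.sort_values(["gene_id", "element", "source"]).reset_index(drop=True)
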