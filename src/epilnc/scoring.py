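"""Single-sample GSEA scoring of epi-gene sets and score correlations.

Per sample, genes are ranked by expression (highest expression = rank N,
average ranks on ties).  Walking the list from the top, the enrichment score
is the running-sum integral of the difference between the rank-weighted
in-set ECDF (weights rank^alpha, alpha defaulting to 0.25) and the uniform
out-of-set ECDF.  Scores depend on ranks only, so any strictly monotone
per-sample transform of expression leaves them unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .epi_classify import SOURCES, ELEMENTS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name} is empty")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], tuple(parts[2:])))
    return sets


def build_epi_sets(annotations: pd.DataFrame, biotype: str = "lncRNA",
                   include_dmr: bool = True, min_size: int = 2) -> list[GeneSet]:
    """Mark x element membership sets over epi genes (the six histone sets,
    plus the two DMR sets flagged by name as auxiliary)."""
    epi = annotations[annotations["is_epi"] & (annotations["biotype"] == biotype)]
    sets = []
    for src in SOURCES:
        if src == "DMR" and not include_dmr:
            continue
        for el in ELEMENTS:
            members = tuple(epi.index[epi[f"{src}|{el}"]])
            if len(members) >= min_size:
                name = f"{src}_{el}" + ("_aux" if src == "DMR" else "")
                sets.append(GeneSet(name, members))
    return sets


def _sample_score(ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    n = len(ranks)
    n_in = int(in_set.sum())
    n_out = n - n_in
    if n_out == 0:
        return 0.0  # degenerate set covering every gene: ECDFs coincide
    w = ranks ** alpha
    in_ord = in_set[order]
    w_ord = np.where(in_ord, w[order], 0.0)
    denom = w_ord.sum()
    p_in = np.cumsum(w_ord) / denom
    p_out = np.cumsum(~in_ord) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    expr: pd.DataFrame,
    sets: list[GeneSet],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA enrichment scores (sets x samples) for an expression matrix.

    Set members absent from ``expr`` are dropped with a log message; a set
    with no matched member raises.  ``normalize`` applies a per-set min-max
    rescale across samples.
    """
    if len(expr) < 2:
        raise ValueError("expression matrix needs >=2 genes")
    gene_index = expr.index
    masks = {}
    for gs in sets:
        present = gene_index.isin(gs.genes)
        n_drop = len(gs.genes) - int(present.sum())
        if present.sum() == 0:
            raise ValueError(f"gene set {gs.name}: no members in expression matrix")
        if n_drop:
            logger.info("ssgsea: set %s lost %d members absent from matrix", gs.name, n_drop)
        masks[gs.name] = present

    mat = expr.to_numpy(dtype=float)
    out = np.zeros((len(sets), expr.shape[1]))
    for j in range(expr.shape[1]):
        x = mat[:, j]
        ranks = stats.rankdata(x, method="average")  # highest expression = N
        order = np.argsort(-ranks, kind="stable")    # descending, tie-stable
        for i, gs in enumerate(sets):
            out[i, j] = _sample_score(ranks, order, masks[gs.name], alpha)
    scores = pd.DataFrame(out, index=[gs.name for gs in sets], columns=expr.columns)
    if normalize:
        rng_ = scores.max(axis=1) - scores.min(axis=1)
        rng_ = rng_.replace(0.0, 1.0)
        scores = scores.sub(scores.min(axis=1), axis=0).div(rng_, axis=0)
    return scores


def compare_groups(scores: pd.DataFrame, condition: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney tumor-vs-normal per set, BH-adjusted across sets."""
    condition = condition.loc[scores.columns]
    t_cols = condition[condition == "tumor"].index
    n_cols = condition[condition == "normal"].index
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ValueError("need >=2 samples per group")
    rows = []
    for name, row in scores.iterrows():
        a, b = row[t_cols], row[n_cols]
        if a.nunique() == 1 and b.nunique() == 1 and a.iat[0] == b.iat[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({
            "set": name,
            "median_tumor": float(a.median()),
            "median_normal": float(b.median()),
            "direction": "up" if a.median() >= b.median() else "down",
            "p_value": p,
        })
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out


def correlate_scores(scores: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of every score row against every row of ``other``.

    ``other`` may be a second score matrix (pathway sets) or an expression
    submatrix (e.g. RNA-modification genes); columns must share the sample
    set.  Returns long-form rho/p/fdr over all pairs.
    """
    shared = scores.columns.intersection(other.columns)
    if len(shared) < 3:
        raise ValueError("need >=3 shared samples for correlation")
    rows = []
    for a_name, a in scores[shared].iterrows():
        for b_name, b in other[shared].iterrows():
            rho, p = stats.spearmanr(a, b)
            rows.append({"score_set": a_name, "other": b_name,
                         "rho": float(rho), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"].fillna(1.0).to_numpy())
    return out
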