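"""Epi-gene classification and the genomic evidence landscape.

A gene is epigenetically dysregulated ("epi") when it is differentially
expressed AND its promoter or enhancer carries at least ``min_evidence``
regulatory events (a differential histone peak or a significant DMR).  The
evidence categories are (source in {H3K27ac, H3K4me1, H3K4me3, DMR}) x
(element in {promoter, enhancer}) — eight in total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("H3K27ac", "H3K4me1", "H3K4me3", "DMR")
ELEMENTS = ("promoter", "enhancer")
CATEGORIES = [f"{src}|{el}" for src in SOURCES for el in ELEMENTS]


def classify(
    de: pd.DataFrame,
    events: pd.DataFrame,
    biotypes: pd.Series,
    min_evidence: int = 1,
) -> pd.DataFrame:
    """Per-gene epi annotation from DE calls and merged evidence tuples.

    Parameters
    ----------
    de : DE table indexed by gene_id with a boolean ``significant`` column.
    events : frame with gene_id, element, source, direction rows (may repeat
        across evidence channels; deduplicated to unique tuples).
    biotypes : gene_id -> "lncRNA" | "PCG" for every annotated gene.
    min_evidence : events required for condition (ii); default 1.

    Returns a frame indexed by gene_id with biotype, is_de, n_evidence,
    is_epi, and one boolean column per evidence category.
    """
    unknown = set(events["gene_id"]) - set(biotypes.index)
    if unknown:
        raise ValueError(f"events reference unknown gene ids: {sorted(unknown)[:5]}")

    uniq = events.drop_duplicates(subset=["gene_id", "element", "source"])
    bad_src = set(uniq["source"]) - set(SOURCES)
    if bad_src:
        raise ValueError(f"unknown evidence sources: {sorted(bad_src)}")

    out = pd.DataFrame(index=biotypes.index)
    out["biotype"] = biotypes
    sig = de["significant"].reindex(biotypes.index)
    out["is_de"] = sig.notna() & sig.eq(True)
    for cat in CATEGORIES:
        out[cat] = False
    for row in uniq.itertuples(index=False):
        out.loc[row.gene_id, f"{row.source}|{row.element}"] = True
    out["n_evidence"] = out[CATEGORIES].sum(axis=1).astype(int)
    out["is_epi"] = out["is_de"] & (out["n_evidence"] >= min_evidence)
    cols = ["biotype", "is_de", "n_evidence", "is_epi"] + CATEGORIES
    return out[cols]


def epi_counts(annotations: pd.DataFrame) -> dict[str, int]:
    """The four-way partition: epi/non-epi x lncRNA/PCG."""
    lnc = annotations["biotype"] == "lncRNA"
    epi = annotations["is_epi"]
    return {
        "epi_lncRNA": int((lnc & epi).sum()),
        "non_epi_lncRNA": int((lnc & ~epi).sum()),
        "epi_PCG": int((~lnc & epi).sum()),
        "non_epi_PCG": int((~lnc & ~epi).sum()),
    }


def landscape(annotations: pd.DataFrame) -> tuple[pd.DataFrame, dict, pd.Series]:
    """Category matrix over epi genes, promoter/enhancer split, co-occurrence.

    Returns (epi-gene x category boolean matrix, element_distribution with
    promoter/enhancer evidence fractions, per-gene count of distinct sources).
    """
    epi = annotations[annotations["is_epi"]]
    if epi.empty:
        raise ValueError("landscape requires at least one epi gene")
    matrix = epi[CATEGORIES].copy()
    totals = matrix.sum()
    prom = sum(totals[c] for c in CATEGORIES if c.endswith("promoter"))
    enh = sum(totals[c] for c in CATEGORIES if c.endswith("enhancer"))
    total = prom + enh
    element_distribution = {
        "promoter": float(prom / total) if total else np.nan,
        "enhancer": float(enh / total) if total else np.nan,
    }
    n_sources = pd.Series(0, index=matrix.index)
    for src in SOURCES:
        has = matrix[[f"{src}|{el}" for el in ELEMENTS]].any(axis=1)
        n_sources = n_sources + has.astype(int)
    return matrix, element_distribution, n_sources


def intersect_catalog(annotations: pd.DataFrame, catalog: list[str]) -> pd.DataFrame:
    """Epi-lncRNAs found in a curated cancer-lncRNA identifier list.

    Returns the evidence profile (category booleans) of each epi-lncRNA whose
    gene_id appears in ``catalog``.  An empty catalog yields an empty result
    with a warning.
    """
    if not catalog:
        logger.warning("intersect_catalog: empty catalog")
        return annotations.iloc[0:0]
    epi_lnc = annotations[annotations["is_epi"] & (annotations["biotype"] == "lncRNA")]
    return epi_lnc.loc[epi_lnc.index.intersection(pd.Index(catalog))]
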