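"""Gene models, regulatory regions and genomic characterization.

Coordinate conventions
----------------------
GTF files are 1-based with inclusive ends; BED-style intervals (promoters,
enhancers, peaks, DMRs) are 0-based half-open.  GTF coordinates are converted
on read; all interval arithmetic in this package is 0-based half-open.

A gene's canonical TSS is the 5' end of its gene span (gene_start on the +
strand, gene_end on the - strand).  The promoter is the strand-aware window
from ``upstream`` bp before the TSS to ``downstream`` bp after it (defaults
2000 / 500).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BIOTYPE_MAP = {"lncRNA": "lncRNA", "protein_coding": "PCG"}


@dataclass
class GeneModel:
    """One gene with its transcript/exon structure (1-based inclusive coords)."""

    gene_id: str
    biotype: str  # "lncRNA" | "PCG"
    chrom: str
    strand: str  # "+" | "-"
    start: int
    end: int
    # list of (transcript_id, [(exon_start, exon_end), ...]) 1-based inclusive
    transcripts: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")

    @property
    def tss(self) -> int:
        """Canonical TSS, 1-based."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegulatoryRegion:
    """Promoter or enhancer interval linked to a gene (0-based half-open)."""

    gene_id: str
    element: str  # "promoter" | "enhancer"
    chrom: str
    start: int
    end: int
    source: str  # "tss_window" | "enhancer_catalog"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}/{self.element}: end must exceed start")


def make_promoter(g: GeneModel, upstream: int = 2000, downstream: int = 500) -> RegulatoryRegion:
    """Strand-aware promoter window around the canonical TSS.

    On the + strand the window is [TSS-upstream, TSS+downstream) in 0-based
    half-open coordinates; on the - strand it is mirrored so "upstream" follows
    the direction of transcription.  Clipped at the chromosome start.
    """
    tss0 = g.tss - 1  # 0-based position of the TSS base
    if g.strand == "+":
        start, end = tss0 - upstream, tss0 + downstream
    else:
        start, end = tss0 - downstream + 1, tss0 + upstream + 1
    return RegulatoryRegion(g.gene_id, "promoter", g.chrom, max(start, 0), end, "tss_window")


def promoters_frame(genes: list[GeneModel], upstream: int = 2000, downstream: int = 500) -> pd.DataFrame:
    regions = [make_promoter(g, upstream, downstream) for g in genes]
    return regions_frame(regions)


def regions_frame(regions: list[RegulatoryRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.element, r.chrom, r.start, r.end, r.source) for r in regions],
        columns=["gene_id", "element", "chrom", "start", "end", "source"],
    )


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path) -> list[GeneModel]:
    """Read gene/transcript/exon features from a GENCODE-dialect GTF.

    Genes whose ``gene_type`` is neither lncRNA nor protein_coding are dropped
    (the number dropped is logged).  Raises on malformed lines (naming the
    line number) and on files containing zero usable genes.
    """
    genes: dict[str, GeneModel] = {}
    tx_exons: dict[str, dict[str, list[tuple[int, int]]]] = {}
    tx_order: dict[str, list[str]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno} ({len(fields)} fields)")
            chrom, _, feature, start, end, _, strand, _, attr = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed coordinates on line {lineno}") from exc
            attrs = _parse_attributes(attr)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}: line {lineno} lacks gene_id")
            if feature == "gene":
                gtype = attrs.get("gene_type", "")
                if gtype not in BIOTYPE_MAP:
                    dropped += 1
                    continue
                genes[gid] = GeneModel(gid, BIOTYPE_MAP[gtype], chrom, strand, start_i, end_i)
            elif feature == "transcript":
                tid = attrs.get("transcript_id")
                tx_exons.setdefault(gid, {}).setdefault(tid, [])
                tx_order.setdefault(gid, []).append(tid)
            elif feature == "exon":
                tid = attrs.get("transcript_id")
                tx_exons.setdefault(gid, {}).setdefault(tid, []).append((start_i, end_i))
    if dropped:
        logger.info("read_gtf: dropped %d genes with unsupported biotypes", dropped)
    for gid, g in genes.items():
        order = tx_order.get(gid) or sorted(tx_exons.get(gid, {}))
        for tid in order:
            exons = sorted(tx_exons.get(gid, {}).get(tid, []))
            g.transcripts.append((tid, exons))
    if not genes:
        raise ValueError(f"{path}: no lncRNA/protein_coding genes found")
    return list(genes.values())


def write_gtf(genes: list[GeneModel], path) -> None:
    """Write gene models as a GENCODE-dialect GTF (inverse of :func:`read_gtf`)."""
    inv = {"lncRNA": "lncRNA", "PCG": "protein_coding"}
    with open(path, "w") as fh:
        for g in genes:
            base = f'gene_id "{g.gene_id}"; gene_type "{inv[g.biotype]}";'
            fh.write(
                f"{g.chrom}\tepilnc\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{base}\n"
            )
            for tid, exons in g.transcripts:
                tstart = min(s for s, _ in exons)
                tend = max(e for _, e in exons)
                tattr = f'{base} transcript_id "{tid}";'
                fh.write(
                    f"{g.chrom}\tepilnc\ttranscript\t{tstart}\t{tend}\t.\t{g.strand}\t.\t{tattr}\n"
                )
                for es, ee in exons:
                    fh.write(
                        f"{g.chrom}\tepilnc\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t{tattr}\n"
                    )


# ---------------------------------------------------------------------------
# Enhancer catalogue
# ---------------------------------------------------------------------------

def read_enhancer_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "enhancer_id", "score", "strand"],
        usecols=range(6),
    )
    return df


def assign_enhancers(
    enhancers: pd.DataFrame, associations: pd.DataFrame, genes: list[GeneModel]
) -> list[RegulatoryRegion]:
    """Expand an enhancer catalogue + enhancer->gene table into regions.

    One region per (enhancer, gene) pair whose gene exists in the annotation;
    associations pointing at genes absent from the annotation are dropped with
    a warning.  Associations naming an unknown enhancer_id raise.
    """
    known_genes = {g.gene_id for g in genes}
    enh = enhancers.set_index("enhancer_id")
    missing = set(associations["enhancer_id"]) - set(enh.index)
    if missing:
        raise ValueError(f"associations reference unknown enhancer ids: {sorted(missing)[:5]}")
    regions: list[RegulatoryRegion] = []
    orphans = 0
    for eid, gid in associations[["enhancer_id", "gene_id"]].itertuples(index=False):
        if gid not in known_genes:
            orphans += 1
            continue
        row = enh.loc[eid]
        regions.append(
            RegulatoryRegion(gid, "enhancer", row["chrom"], int(row["start"]), int(row["end"]), "enhancer_catalog")
        )
    if orphans:
        logger.warning("assign_enhancers: dropped %d associations to absent genes", orphans)
    return regions


# ---------------------------------------------------------------------------
# Genomic characterization
# ---------------------------------------------------------------------------

def characterize_gene(g: GeneModel) -> dict:
    """Structural metrics of a single gene (transcript length = mature length)."""
    tx_lengths = [sum(e - s + 1 for s, e in exons) for _, exons in g.transcripts] or [g.length]
    n_exons = max((len(exons) for _, exons in g.transcripts), default=1)
    all_exons = [e - s + 1 for _, exons in g.transcripts for s, e in exons] or [g.length]
    return {
        "gene_id": g.gene_id,
        "biotype": g.biotype,
        "n_transcripts": max(len(g.transcripts), 1),
        "n_exons": max(n_exons, 1),
        "gene_length": g.length,
        "mean_transcript_length": float(np.mean(tx_lengths)),
        "mean_exon_length": float(np.mean(all_exons)),
    }


METRICS = ["n_transcripts", "n_exons", "gene_length", "mean_transcript_length", "mean_exon_length"]


def characterize(genes: list[GeneModel], epi_labels: dict[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-wise structural summary and epi vs non-epi Mann-Whitney tests.

    ``epi_labels`` maps gene_id -> "epi" | "non_epi"; unlabeled genes are
    ignored.  Returns (per-group medians, test table with one row per
    biotype x metric contrast).  Contrasts with a group of <2 members are
    skipped with a warning.
    """
    rows = [characterize_gene(g) for g in genes if g.gene_id in epi_labels]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("characterize: no labeled genes")
    df["epi"] = df["gene_id"].map(epi_labels)
    df["group"] = df.apply(lambda r: f"{r.epi}-{r.biotype}", axis=1)
    summary = df.groupby("group")[METRICS].median()
    summary["n"] = df.groupby("group").size()

    tests = []
    for biotype in sorted(df["biotype"].unique()):
        sub = df[df["biotype"] == biotype]
        a = sub[sub["epi"] == "epi"]
        b = sub[sub["epi"] == "non_epi"]
        if len(a) < 2 or len(b) < 2:
            logger.warning("characterize: %s contrast skipped (group too small)", biotype)
            continue
        for metric in METRICS:
            if a[metric].nunique() == 1 and b[metric].nunique() == 1 and a[metric].iat[0] == b[metric].iat[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a[metric], b[metric], alternative="two-sided").pvalue)
            tests.append({
                "biotype": biotype,
                "metric": metric,
                "median_epi": float(a[metric].median()),
                "median_non_epi": float(b[metric].median()),
                "p_value": p,
            })
    return summary, pd.DataFrame(tests)
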