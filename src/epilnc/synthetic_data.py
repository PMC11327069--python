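"""Synthetic multi-omics cohort with planted ground truth.

Generates a coherent toy tumor/normal cohort on a single linear chromosome
("chrS"): a GTF-style gene annotation (lncRNA + protein-coding), an enhancer
catalogue with explicit enhancer->gene associations, per-condition histone
peak sets (H3K27ac / H3K4me1 / H3K4me3), a 450K-style CpG beta matrix tiled
over promoters and enhancers, NB-distributed count and TPM expression
matrices, and a clinical survival table — together with the planted truth
(which genes are epigenetically dysregulated, where the differential peaks
and DMRs sit, which genes carry survival effects) so that every downstream
stage can be scored against a known answer.

Layout: each gene owns a fixed-width slot on chrS; the gene body sits near
the slot start (leaving room for the 2 kb promoter window on either strand),
an optional enhancer sits mid-slot, and a "neutral zone" at the slot end
hosts background peaks that never touch a regulatory region.

All randomness flows from one ``numpy.random.default_rng(seed)``; a given
config is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import GeneModel, make_promoter, regions_frame, write_gtf, RegulatoryRegion

SLOT = 20_000  # bp of chrS per gene
CHROM = "chrS"


@dataclass
class SimConfig:
    seed: int = 1
    n_genes: int = 300
    frac_lncRNA: float = 0.5
    n_tumor: int = 20
    n_normal: int = 20
    n_enhancers: int | None = None  # default: n_genes // 3
    probes_per_promoter: int = 12
    probes_per_enhancer: int = 10
    de_effect: float = 2.0          # |log2FC| planted in DE genes
    nb_dispersion: float = 0.1      # NB dispersion alpha (var = mu + alpha mu^2)
    dmr_delta: float = 0.3          # planted beta-value shift inside true DMRs
    peak_marks: tuple[str, ...] = ("H3K27ac", "H3K4me1", "H3K4me3")
    frac_epi: float = 0.1           # fraction of genes planted epi-dysregulated
    frac_de_only: float = 0.1       # extra DE genes without regulatory events
    surv_beta: tuple[float, ...] = (0.8, 0.8, -0.8, 0.8, 0.8, -0.8, 0.8, 0.8)
    censor_rate: float = 0.2
    missing_beta_frac: float = 0.02
    logit_noise_sd: float = 0.25    # ~0.05 beta-scale SD at beta ~ 0.3

    def __post_init__(self) -> None:
        for name in ("frac_lncRNA", "frac_epi", "frac_de_only", "censor_rate", "missing_beta_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 samples per condition")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_enhancers is None:
            self.n_enhancers = self.n_genes // 3
        if self.n_enhancers > self.n_genes:
            raise ValueError("n_enhancers cannot exceed n_genes (one enhancer slot per gene)")
        if self.probes_per_promoter < 2 or self.probes_per_enhancer < 2:
            raise ValueError("need >=2 probes per regulatory region to form DMRs")
        # promoter window is 2500 bp; probes must fit with distinct positions
        if self.probes_per_promoter > 2500 or self.probes_per_enhancer > 400:
            raise ValueError("planted probe tiling does not fit the toy regulatory regions")


@dataclass
class GroundTruth:
    """Planted signal: what a perfect pipeline should recover."""

    true_epi_genes: dict[str, list[tuple[str, str]]]   # gene -> [(source, element)]
    true_de_genes: dict[str, float]                    # gene -> signed log2FC
    true_dmrs: list[dict]                              # chrom/start/end/gene_id/sign
    true_diff_peaks: dict[str, list[dict]]             # mark -> [{chrom,start,end,condition}]
    true_surv_genes: dict[str, float]                  # gene -> Cox log-hazard coefficient

    def to_json(self) -> str:
        payload = {
            "true_epi_genes": {g: [list(ev) for ev in evs] for g, evs in self.true_epi_genes.items()},
            "true_de_genes": self.true_de_genes,
            "true_dmrs": self.true_dmrs,
            "true_diff_peaks": self.true_diff_peaks,
            "true_surv_genes": self.true_surv_genes,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class AnnotationBundle:
    genes: list[GeneModel]
    enhancers: pd.DataFrame        # chrom start end enhancer_id score strand
    associations: pd.DataFrame     # enhancer_id gene_id


@dataclass
class ExpressionBundle:
    counts: pd.DataFrame           # genes x samples, integers
    tpm: pd.DataFrame              # genes x samples
    condition: pd.Series           # sample -> "tumor" | "normal"


@dataclass
class PeakBundle:
    # (mark, condition) -> narrowPeak-style frame
    peaks: dict[tuple[str, str], pd.DataFrame]


@dataclass
class MethylationBundle:
    probes: pd.DataFrame           # probe_id chrom pos (1-based)
    beta: pd.DataFrame             # probes x samples, NaN where masked


@dataclass
class Cohort:
    cfg: SimConfig
    annotation: AnnotationBundle
    expression: ExpressionBundle
    peaks: PeakBundle
    methylation: MethylationBundle
    clinical: pd.DataFrame         # sample_id time_days event
    truth: GroundTruth


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _make_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    n_lnc = int(round(cfg.frac_lncRNA * cfg.n_genes))
    biotypes = np.array(["lncRNA"] * n_lnc + ["PCG"] * (cfg.n_genes - n_lnc))
    rng.shuffle(biotypes)
    for i in range(cfg.n_genes):
        slot = i * SLOT
        gstart0 = slot + 3000 + int(rng.integers(0, 500))
        glen = int(rng.integers(2000, 8001))
        start, end = gstart0 + 1, gstart0 + glen  # 1-based inclusive
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{i:04d}"
        g = GeneModel(gid, str(biotypes[i]), CHROM, strand, start, end)
        n_tx = int(rng.integers(1, 6))
        for t in range(n_tx):
            n_ex = int(rng.integers(1, 7))
            # choose 2*n_ex sorted breakpoints inside the gene span
            cuts = np.sort(rng.choice(np.arange(start, end + 1), size=2 * n_ex, replace=False))
            exons = [(int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(n_ex)]
            g.transcripts.append((f"{gid}.T{t}", exons))
        genes.append(g)
    return genes


def _make_enhancers(cfg: SimConfig, rng: np.random.Generator):
    host = rng.choice(cfg.n_genes, size=cfg.n_enhancers, replace=False)
    host.sort()
    rows, assoc = [], []
    for j, gi in enumerate(host):
        slot = int(gi) * SLOT
        estart = slot + 15_000 + int(rng.integers(0, 400))
        elen = int(rng.integers(400, 1201))
        eid = f"E{j:04d}"
        rows.append((CHROM, estart, estart + elen, eid, 0, "."))
        assoc.append((eid, f"G{int(gi):04d}"))
        if rng.random() < 0.3 and gi + 1 < cfg.n_genes:
            assoc.append((eid, f"G{int(gi) + 1:04d}"))
    enh = pd.DataFrame(rows, columns=["chrom", "start", "end", "enhancer_id", "score", "strand"])
    associations = pd.DataFrame(assoc, columns=["enhancer_id", "gene_id"])
    return enh, associations


def _plant_signal(cfg: SimConfig, rng: np.random.Generator, genes, enh, assoc):
    """Choose epi genes, their (source, element) events, and DE-only genes."""
    gene_enh: dict[str, list[int]] = {}
    enh_idx = enh.set_index("enhancer_id")
    for eid, gid in assoc.itertuples(index=False):
        gene_enh.setdefault(gid, []).append(enh_idx.index.get_loc(eid))
    # enhancer events are planted only on exclusively-owned enhancers, so a
    # planted signal never spills evidence onto a co-associated gene and the
    # ground-truth epi label set stays exact
    assoc_counts = assoc["enhancer_id"].value_counts()
    excl = {enh_idx.index.get_loc(eid) for eid, n in assoc_counts.items() if n == 1}
    plant_enh: dict[str, int] = {}
    for gid, eis in gene_enh.items():
        for ei in eis:
            if ei in excl:
                plant_enh[gid] = ei
                break

    n_epi = int(round(cfg.frac_epi * cfg.n_genes))
    n_de_only = int(round(cfg.frac_de_only * cfg.n_genes))
    picks = rng.choice(cfg.n_genes, size=n_epi + n_de_only, replace=False)
    epi_ids = [f"G{i:04d}" for i in picks[:n_epi]]
    de_only_ids = [f"G{i:04d}" for i in picks[n_epi:]]

    sources = list(cfg.peak_marks) + ["DMR"]
    true_epi: dict[str, list[tuple[str, str]]] = {}
    true_de: dict[str, float] = {}
    for gid in epi_ids:
        sign = 1.0 if rng.random() < 0.6 else -1.0
        true_de[gid] = sign * cfg.de_effect
        events = set()
        for _ in range(int(rng.integers(1, 3))):
            element = "promoter"
            if gid in plant_enh and rng.random() >= 0.7:
                element = "enhancer"
            source = sources[int(rng.integers(0, len(sources)))]
            events.add((source, element))
        true_epi[gid] = sorted(events)
    for gid in de_only_ids:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        true_de[gid] = sign * cfg.de_effect
    return true_epi, true_de, gene_enh, plant_enh


def _event_region(gid, element, genes_by_id, enh, plant_enh) -> tuple[int, int]:
    if element == "promoter":
        r = make_promoter(genes_by_id[gid])
        return r.start, r.end
    row = enh.iloc[plant_enh[gid]]
    return int(row["start"]), int(row["end"])


def _make_peaks(cfg, rng, genes, enh, plant_enh, true_epi):
    """Per-mark, per-condition narrowPeak frames with planted unique peaks."""
    genes_by_id = {g.gene_id: g for g in genes}
    peaks: dict[tuple[str, str], list] = {(m, c): [] for m in cfg.peak_marks for c in ("tumor", "normal")}
    true_diff: dict[str, list[dict]] = {m: [] for m in cfg.peak_marks}

    def add(mark, cond, start, end, p):
        peaks[(mark, cond)].append((CHROM, int(start), int(end), f"{mark}_{cond}_{len(peaks[(mark, cond)])}",
                                    0, ".", 5.0, -np.log10(p), -1.0, (end - start) // 2))

    # planted condition-specific peaks inside the event region
    for gid, events in true_epi.items():
        for source, element in events:
            if source == "DMR":
                continue
            rs, re = _event_region(gid, element, genes_by_id, enh, plant_enh)
            width = min(500, re - rs)
            off = int(rng.integers(0, re - rs - width + 1))
            cond = "tumor" if rng.random() < 0.7 else "normal"
            p = float(10 ** rng.uniform(-8, -4))
            add(source, cond, rs + off, rs + off + width, p)
            true_diff[source].append({"chrom": CHROM, "start": int(rs + off), "end": int(rs + off + width),
                                      "condition": cond, "gene_id": gid, "element": element})

    # shared background peaks (identical interval in both conditions -> never unique)
    for mark in cfg.peak_marks:
        for _ in range(max(cfg.n_genes // 2, 5)):
            slot = int(rng.integers(0, cfg.n_genes)) * SLOT
            s = slot + 17_500 + int(rng.integers(0, 1500))
            w = int(rng.integers(200, 600))
            p = float(10 ** rng.uniform(-8, -3))
            add(mark, "tumor", s, s + w, p)
            add(mark, "normal", s, s + w, p)
        # decoy unique peaks failing the p<0.05 filter, sitting in the neutral zone
        for _ in range(max(cfg.n_genes // 10, 2)):
            slot = int(rng.integers(0, cfg.n_genes)) * SLOT
            s = slot + 17_500 + int(rng.integers(0, 1500))
            w = int(rng.integers(200, 600))
            cond = "tumor" if rng.random() < 0.5 else "normal"
            add(mark, cond, s, s + w, float(rng.uniform(0.06, 0.5)))
        # significant unique peaks outside any regulatory region (no gene evidence)
        for _ in range(5):
            slot = int(rng.integers(0, cfg.n_genes)) * SLOT
            s = slot + 17_500 + int(rng.integers(0, 1500))
            w = int(rng.integers(200, 600))
            cond = "tumor" if rng.random() < 0.5 else "normal"
            add(mark, cond, s, s + w, float(10 ** rng.uniform(-6, -2)))

    cols = ["chrom", "start", "end", "name", "score", "strand", "signal", "neglog10p", "neglog10q", "summit"]
    frames = {}
    for key, rows in peaks.items():
        df = pd.DataFrame(rows, columns=cols).sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        frames[key] = df
    return PeakBundle(frames), true_diff


def _make_methylation(cfg, rng, genes, enh, gene_enh, plant_enh, true_epi):
    genes_by_id = {g.gene_id: g for g in genes}
    n_samples = cfg.n_tumor + cfg.n_normal
    tumor_cols = [f"T{i + 1:02d}" for i in range(cfg.n_tumor)]
    normal_cols = [f"N{i + 1:02d}" for i in range(cfg.n_normal)]

    # which (gene, element) regions carry a planted DMR, and its sign
    dmr_regions: dict[tuple[str, str], float] = {}
    for gid, events in true_epi.items():
        for source, element in events:
            if source == "DMR":
                dmr_regions[(gid, element)] = 1.0 if rng.random() < 0.5 else -1.0

    probe_rows, base_means, shifts = [], [], []
    true_dmrs = []
    pid = 0

    def tile(gid, element, rs, re, k, sign):
        nonlocal pid
        positions = np.unique(np.linspace(rs + 1, re, k).astype(int))  # 1-based
        if sign is not None:
            lo, hi = (0.15, 0.45) if sign > 0 else (0.55, 0.85)
            true_dmrs.append({"chrom": CHROM, "start": int(positions[0] - 1), "end": int(positions[-1]),
                              "gene_id": gid, "element": element, "sign": float(sign)})
        else:
            lo, hi = 0.2, 0.8
        for pos in positions:
            probe_rows.append((f"cg{pid:06d}", CHROM, int(pos)))
            base_means.append(float(rng.uniform(lo, hi)))
            shifts.append(0.0 if sign is None else float(sign * cfg.dmr_delta))
            pid += 1

    for g in genes:
        r = make_promoter(g)
        sign = dmr_regions.get((g.gene_id, "promoter"))
        tile(g.gene_id, "promoter", r.start, r.end, cfg.probes_per_promoter, sign)

    # tile each enhancer once; a planted enhancer-DMR of ANY associated gene
    # (the first positionally used one wins) sets the shift for its probes
    enh_genes: dict[int, list[str]] = {}
    for gid, eis in gene_enh.items():
        for ei in eis:
            enh_genes.setdefault(ei, []).append(gid)
    for pos_idx, eid_row in enumerate(enh.itertuples(index=False)):
        gid, sign = "NA", None
        for cand in enh_genes.get(pos_idx, []):
            s = dmr_regions.get((cand, "enhancer"))
            # only the gene that planted on this (exclusive) enhancer carries it
            if s is not None and plant_enh.get(cand) == pos_idx:
                gid, sign = cand, s
                break
        if gid == "NA" and enh_genes.get(pos_idx):
            gid = enh_genes[pos_idx][0]
        tile(gid, "enhancer", int(eid_row.start), int(eid_row.end), cfg.probes_per_enhancer, sign)

    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"])
    m = np.asarray(base_means)
    d = np.asarray(shifts)
    n_probes = len(m)

    normal_mu = np.clip(m, 0.02, 0.98)
    tumor_mu = np.clip(m + d, 0.02, 0.98)
    noise = rng.normal(0.0, cfg.logit_noise_sd, size=(n_probes, n_samples))
    mu_mat = np.column_stack([np.tile(tumor_mu[:, None], (1, cfg.n_tumor)),
                              np.tile(normal_mu[:, None], (1, cfg.n_normal))])
    beta = expit(logit(mu_mat) + noise)

    if cfg.missing_beta_frac > 0:
        mask = rng.random(beta.shape) < cfg.missing_beta_frac
        # every probe keeps at least one observed value
        all_gone = mask.all(axis=1)
        mask[all_gone, 0] = False
        beta = np.where(mask, np.nan, beta)

    beta_df = pd.DataFrame(beta, index=probes["probe_id"], columns=tumor_cols + normal_cols)
    return MethylationBundle(probes, beta_df), true_dmrs


def _gene_union_exon_length(g: GeneModel) -> int:
    ivals = sorted((s, e) for _, exons in g.transcripts for s, e in exons)
    if not ivals:
        return g.length
    total, cs, ce = 0, *ivals[0]
    for s, e in ivals[1:]:
        if s > ce + 1:
            total += ce - cs + 1
            cs, ce = s, e
        else:
            ce = max(ce, e)
    return total + ce - cs + 1


def _make_expression(cfg, rng, genes, true_de):
    n_t, n_n = cfg.n_tumor, cfg.n_normal
    tumor_cols = [f"T{i + 1:02d}" for i in range(n_t)]
    normal_cols = [f"N{i + 1:02d}" for i in range(n_n)]
    gids = [g.gene_id for g in genes]

    base = rng.lognormal(mean=np.log(300.0), sigma=0.8, size=len(gids))
    lfc = np.array([true_de.get(gid, 0.0) for gid in gids])
    lib = rng.lognormal(mean=0.0, sigma=0.15, size=n_t + n_n)

    mu_t = base * 2.0 ** lfc
    mu = np.column_stack([np.tile(mu_t[:, None], (1, n_t)), np.tile(base[:, None], (1, n_n))]) * lib[None, :]
    alpha = cfg.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    counts = rng.poisson(lam).astype(np.int64)

    lengths = np.array([_gene_union_exon_length(g) for g in genes], dtype=float)
    rate = counts / lengths[:, None]
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6

    cols = tumor_cols + normal_cols
    counts_df = pd.DataFrame(counts, index=gids, columns=cols)
    tpm_df = pd.DataFrame(tpm, index=gids, columns=cols)
    condition = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=cols, name="condition")
    return ExpressionBundle(counts_df, tpm_df, condition)


def _pick_surv_genes(cfg, genes, true_epi):
    """Prognostic genes: epi lncRNAs first, then epi PCGs, then fill randomly."""
    k = len(cfg.surv_beta)
    by_id = {g.gene_id: g for g in genes}
    epi_lnc = [gid for gid in sorted(true_epi) if by_id[gid].biotype == "lncRNA"]
    epi_pcg = [gid for gid in sorted(true_epi) if by_id[gid].biotype == "PCG"]
    pool = epi_lnc + epi_pcg + [g.gene_id for g in genes if g.gene_id not in true_epi]
    chosen = pool[:k]
    return dict(zip(chosen, cfg.surv_beta))


def _make_clinical(cfg, rng, expr: ExpressionBundle, surv_genes: dict[str, float]):
    tumor_cols = [c for c in expr.tpm.columns if expr.condition[c] == "tumor"]
    lp = np.zeros(len(tumor_cols))
    for gid, beta in surv_genes.items():
        x = np.log2(expr.tpm.loc[gid, tumor_cols].to_numpy() + 1.0)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        lp += beta * z
    base_rate = 1.0 / 1000.0  # median ~700 days at lp = 0
    times = rng.exponential(1.0 / (base_rate * np.exp(lp)))

    event = np.ones(len(times), dtype=int)
    obs = times.copy()
    if cfg.censor_rate > 0:
        # independent C ~ U(0, cmax) with cmax solving E[P(C < T)] = censor_rate
        def frac_cens(c):
            return float(np.mean(np.minimum(times / c, 1.0)))
        lo, hi = times.min() / 100, times.max() * 100
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if frac_cens(mid) > cfg.censor_rate:
                lo = mid
            else:
                hi = mid
        cmax = np.sqrt(lo * hi)
        cens = rng.uniform(0.0, cmax, size=len(times))
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    clinical = pd.DataFrame({
        "sample_id": tumor_cols,
        "time_days": np.round(np.maximum(obs, 1.0), 2),
        "event": event,
    })
    return clinical


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate the full synthetic cohort with planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    genes = _make_genes(cfg, rng)
    enh, assoc = _make_enhancers(cfg, rng)
    true_epi, true_de, gene_enh, plant_enh = _plant_signal(cfg, rng, genes, enh, assoc)
    peak_bundle, true_diff = _make_peaks(cfg, rng, genes, enh, plant_enh, true_epi)
    meth_bundle, true_dmrs = _make_methylation(cfg, rng, genes, enh, gene_enh, plant_enh, true_epi)
    expr_bundle = _make_expression(cfg, rng, genes, true_de)
    surv_genes = _pick_surv_genes(cfg, genes, true_epi)
    clinical = _make_clinical(cfg, rng, expr_bundle, surv_genes)
    truth = GroundTruth(true_epi, true_de, true_dmrs, true_diff, surv_genes)
    ann = AnnotationBundle(genes, enh, assoc)
    return Cohort(cfg, ann, expr_bundle, peak_bundle, meth_bundle, clinical, truth)


# ---------------------------------------------------------------------------
# toy gene sets (pathways + RNA-modification gene lists)
# ---------------------------------------------------------------------------

def toy_genesets(cohort: Cohort, n_random_sets: int = 4, set_size: int = 15):
    """Toy pathway gene sets and m6A/m5C/m1A gene lists for the scoring layer.

    One "EPI_DRIVEN" pathway shares members with the planted epi genes (a
    positive-correlation control); the remainder are random draws.
    """
    rng = np.random.default_rng(cohort.cfg.seed + 104729)
    gids = [g.gene_id for g in cohort.annotation.genes]
    epi = sorted(cohort.truth.true_epi_genes)
    sets = {}
    driven = list(epi[: set_size // 2])
    fill = [g for g in gids if g not in driven]
    driven += [fill[i] for i in rng.choice(len(fill), size=set_size - len(driven), replace=False)]
    sets["EPI_DRIVEN"] = driven
    for i in range(n_random_sets):
        idx = rng.choice(len(gids), size=set_size, replace=False)
        sets[f"RANDOM_{i + 1}"] = [gids[j] for j in idx]
    pcgs = [g.gene_id for g in cohort.annotation.genes if g.biotype == "PCG"]
    fams = ["m6A", "m5C", "m1A"]
    rows = [(pcgs[int(j)], fams[k % 3]) for k, j in
            enumerate(rng.choice(len(pcgs), size=min(15, len(pcgs)), replace=False))]
    rna_mod = pd.DataFrame(rows, columns=["gene_id", "family"])
    return sets, rna_mod


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundles(cohort: Cohort, out_dir) -> dict:
    """Write every bundle as flat text files; return a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    gtf = out / "annotation.gtf"
    write_gtf(cohort.annotation.genes, gtf)
    files.append(gtf)

    enh_bed = out / "enhancers.bed"
    cohort.annotation.enhancers.to_csv(enh_bed, sep="\t", header=False, index=False)
    files.append(enh_bed)
    assoc_tsv = out / "enhancer_gene.tsv"
    cohort.annotation.associations.to_csv(assoc_tsv, sep="\t", index=False)
    files.append(assoc_tsv)

    for (mark, cond), df in cohort.peaks.peaks.items():
        p = out / f"peaks_{mark}_{cond}.narrowPeak"
        df.to_csv(p, sep="\t", header=False, index=False, float_format="%.5f")
        files.append(p)

    probes = cohort.methylation.probes.set_index("probe_id")
    beta = cohort.methylation.beta
    probe_tsv = out / "methylation_beta.tsv"
    pd.concat([probes, beta], axis=1).to_csv(probe_tsv, sep="\t", float_format="%.4f", na_rep="NA")
    files.append(probe_tsv)

    counts_tsv = out / "counts.tsv"
    cohort.expression.counts.to_csv(counts_tsv, sep="\t", index_label="gene_id")
    files.append(counts_tsv)
    tpm_tsv = out / "tpm.tsv"
    cohort.expression.tpm.to_csv(tpm_tsv, sep="\t", index_label="gene_id", float_format="%.4f")
    files.append(tpm_tsv)
    cond_tsv = out / "conditions.tsv"
    cohort.expression.condition.to_frame().to_csv(cond_tsv, sep="\t", index_label="sample_id")
    files.append(cond_tsv)

    clin_tsv = out / "clinical.tsv"
    cohort.clinical.to_csv(clin_tsv, sep="\t", index=False, float_format="%.2f")
    files.append(clin_tsv)

    gt_json = out / "ground_truth.json"
    gt_json.write_text(cohort.truth.to_json())
    files.append(gt_json)

    sets, rna_mod = toy_genesets(cohort)
    gmt = out / "toy_pathways.gmt"
    with open(gmt, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    files.append(gmt)
    mod_tsv = out / "rna_mod_genes.tsv"
    rna_mod.to_csv(mod_tsv, sep="\t", index=False)
    files.append(mod_tsv)

    manifest = {
        "seed": cohort.cfg.seed,
        "n_peak_files": sum(1 for f in files if f.suffix == ".narrowPeak"),
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
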