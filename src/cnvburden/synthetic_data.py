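"""Synthetic case-control CNV cohorts with planted effects.

The generator emits every input the pipeline reads — sample metadata,
dual-caller CNV call tables, gene models, gene sets, a reference SV panel,
blacklist and genomic-disorder regions, and per-CNV pathogenicity scores —
with a known ground truth, so each QC stage and statistical family can be
tested end to end without external data.

Model
-----
* Per-sample truth CNV counts are Poisson, with status-specific rates: the
  case/control rate ratio per type is the planted effect.  For Poisson
  counts the log odds of case status is linear in the count with slope
  ``log(rate ratio)``, so the planted ratio is directly the logistic
  regression's estimand.
* Truth events are placed uniformly on the genome (log-uniform sizes,
  30 kb – 2 Mb, copy number 1 for deletions and 3 for duplications),
  excluding reserved blacklist segments; configurable fractions are then
  relocated onto blacklist, common-reference-SV, or genomic-disorder
  segments to exercise those filters.
* The primary (PennCNV-dialect) caller reports every truth event, with a
  configurable fraction given a failing quality score or confidence flag.
  The secondary (QuantiSNP-dialect) caller independently drops events with
  probability ``caller_discordance`` and jitters endpoints, preserving
  >= 50% reciprocal overlap for non-dropped events.
* Pathogenicity scores are Gaussian per metric and type with an optional
  case shift; gene-set enrichment plants extra set-targeted case events at a
  rate calibrated to the configured multiplier.

Defaults emulate a post-QC SNP-array cohort of 1,204 cases and 9,549
controls with ~0.14 deletions and ~0.15 duplications per control and a
planted case duplication rate ratio of 1.7 (no deletion effect), on a
desk-scale genome of six 30-Mb chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    DELETION,
    DUPLICATION,
    CnvCall,
    GeneModel,
    ReferenceSv,
    RegionSet,
    SampleRecord,
    ScoreAnnotation,
    SCORE_METRICS,
    write_cnv_calls,
    write_region_bed,
    internal_to_bed,
)

_FLOAT = "%.17g"


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; all randomness flows from ``seed``."""

    seed: int = 0
    n_cases: int = 1204
    n_controls: int = 9549
    genome: tuple[tuple[str, int], ...] = tuple(
        (str(i), 30_000_000) for i in range(1, 7)
    )
    n_genes: int = 600
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: int = 3_000
    gene_span: int = 100_000
    noncoding_every: int = 10  # every k-th gene is non-protein-coding
    # per-type control rates and planted case/control rate ratios
    rate_del: float = 0.14
    rate_dup: float = 0.15
    ratio_del: float = 1.0
    ratio_dup: float = 1.7
    size_min: int = 30_000
    size_max: int = 2_000_000  # log-uniform in [size_min, size_max]
    marker_spacing: int = 2_500  # bp per SNP marker
    caller_discordance: float = 0.05
    jitter_sd: float = 2_000.0
    frac_common: float = 0.05  # events relocated onto a common reference SV
    frac_blacklist: float = 0.02
    frac_gd: float = 0.05  # events relocated onto a genomic-disorder region
    frac_lowq: float = 0.05  # primary calls given |QS| <= 0.5
    frac_lowconf: float = 0.03  # primary calls given a failing confidence flag
    # sample array-quality metrics: (mean, sd) and the outlier fraction/value
    lrr_sd_dist: tuple[float, float] = (0.12, 0.02)
    baf_drift_dist: tuple[float, float] = (0.002, 0.0005)
    wf_dist: tuple[float, float] = (0.0, 0.02)
    metric_outlier_frac: float = 0.005
    # pathogenicity scores: per-metric mean for (deletion, duplication)
    score_mu: dict = field(
        default_factory=lambda: {
            "lr": (0.55, 0.45),
            "vest3": (0.50, 0.40),
            "fathmm": (0.45, 0.40),
            "pli": (0.30, 0.30),
            "cadd": (18.0, 14.0),
            "mvp": (0.50, 0.45),
        }
    )
    score_sd: float = 0.12
    cadd_sd: float = 5.0
    score_status_shift: float = 0.0  # added to case means (CADD: x10)
    score_missing_frac: float = 0.02
    # gene sets: name -> number of member genes; enrichment: name -> case
    # rate multiplier for duplications hitting the set
    gene_set_sizes: dict = field(
        default_factory=lambda: {"set_small": 12, "set_mid": 60, "set_large": 200}
    )
    set_enrichment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.genome:
            if length < 10 * self.size_max:
                raise ValueError(
                    f"chromosome {name} length {length} < 10 x max CNV size {self.size_max}"
                )
        for p in (
            self.caller_discordance,
            self.frac_common,
            self.frac_blacklist,
            self.frac_gd,
            self.frac_lowq,
            self.frac_lowconf,
            self.metric_outlier_frac,
            self.score_missing_frac,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if min(self.rate_del, self.rate_dup, self.ratio_del, self.ratio_dup) < 0:
            raise ValueError("rates and ratios must be non-negative")


@dataclass
class CohortBundle:
    """Everything the pipeline reads, as in-memory objects plus a writer."""

    config: SimConfig
    samples: list[SampleRecord]
    calls_penncnv: list[CnvCall]
    calls_quantisnp: list[CnvCall]
    genes: list[GeneModel]
    gene_sets: dict[str, list[str]]
    ref_svs: list[ReferenceSv]
    blacklist: RegionSet
    gd_regions: RegionSet
    scores: list[ScoreAnnotation]

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write the bundle in the pipeline's on-disk dialects; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        p = outdir / "samples.tsv"
        with open(p, "w") as fh:
            cols = ["sample_id", "status", "sex"] + [f"pc{i}" for i in range(1, 11)] + [
                "lrr_sd", "baf_drift", "wf"]
            fh.write("\t".join(cols) + "\n")
            for s in self.samples:
                vals = [s.sample_id, s.status, s.sex]
                vals += [_FLOAT % v for v in s.pcs]
                vals += [_FLOAT % s.lrr_sd, _FLOAT % s.baf_drift, _FLOAT % s.wf]
                fh.write("\t".join(vals) + "\n")
        paths["samples"] = str(p)

        p = outdir / "calls_penncnv.tsv"
        write_cnv_calls(self.calls_penncnv, p)
        paths["calls_penncnv"] = str(p)
        p = outdir / "calls_quantisnp.tsv"
        write_cnv_calls(self.calls_quantisnp, p)
        paths["calls_quantisnp"] = str(p)

        p = outdir / "genes.tsv"
        with open(p, "w") as fh:
            fh.write("gene_id\tsymbol\tchrom\tbiotype\texon_start\texon_end\n")
            for g in self.genes:
                for es, ee in g.exons:
                    fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.biotype}\t{es}\t{ee}\n")
        paths["gene_models"] = str(p)

        p = outdir / "gene_sets.tsv"
        with open(p, "w") as fh:
            fh.write("set_name\tsymbol\n")
            for name in sorted(self.gene_sets):
                for sym in self.gene_sets[name]:
                    fh.write(f"{name}\t{sym}\n")
        paths["gene_sets"] = str(p)

        p = outdir / "reference_svs.tsv"
        with open(p, "w") as fh:
            fh.write("chrom\tstart\tend\tsv_type\taf\n")
            for sv in self.ref_svs:
                b0, b1 = internal_to_bed(sv.start, sv.end)
                fh.write(f"{sv.chrom}\t{b0}\t{b1}\t{sv.sv_type}\t{_FLOAT % sv.af}\n")
        paths["reference_svs"] = str(p)

        p = outdir / "blacklist.bed"
        write_region_bed(self.blacklist, p)
        paths["blacklist"] = str(p)
        p = outdir / "gd_regions.bed"
        write_region_bed(self.gd_regions, p)
        paths["gd_regions"] = str(p)

        p = outdir / "scores.tsv"
        with open(p, "w") as fh:
            fh.write("sample_id\tchrom\tstart\tend\ttype\t" + "\t".join(SCORE_METRICS) + "\n")
            for s in self.scores:
                sid, chrom, start, end, typ = s.call_key
                vals = ["" if s.value(m) is None else _FLOAT % s.value(m) for m in SCORE_METRICS]
                fh.write(f"{sid}\t{chrom}\t{start}\t{end}\t{typ}\t" + "\t".join(vals) + "\n")
        paths["scores"] = str(p)
        return paths


# ---------------------------------------------------------------------------
# genome annotation layout
# ---------------------------------------------------------------------------

def _layout_regions(cfg: SimConfig) -> tuple[RegionSet, RegionSet, list[ReferenceSv]]:
    """Reserve deterministic blacklist / GD / common-SV segments per chromosome."""
    bl, gd, svs = [], [], []
    for chrom, length in cfg.genome:
        bl.append((chrom, int(0.40 * length), int(0.41 * length)))
        gd.append((chrom, int(0.70 * length), int(0.70 * length) + 500_000))
        gd.append((chrom, int(0.80 * length), int(0.80 * length) + 800_000))
        # common SVs (AF >= 1%) on reserved spots, one per type
        for t, frac, af in (
            (DELETION, 0.55, 0.05),
            (DUPLICATION, 0.60, 0.08),
        ):
            s = int(frac * length)
            svs.append(ReferenceSv(chrom, s, s + 200_000, t, af))
        # rare reference SVs (AF < 1%): matching them must NOT remove a call
        for t, frac in ((DELETION, 0.20), (DUPLICATION, 0.25)):
            s = int(frac * length)
            svs.append(ReferenceSv(chrom, s, s + 150_000, t, 0.002))
    return (
        RegionSet("blacklist", tuple(bl), "blacklist"),
        RegionSet("genomic_disorder", tuple(gd), "genomic_disorder"),
        svs,
    )


def _layout_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    total = sum(l for _, l in cfg.genome)
    genes: list[GeneModel] = []
    gid = 0
    lo, hi = cfg.exons_per_gene
    for chrom, length in cfg.genome:
        n_g = max(1, round(cfg.n_genes * length / total))
        spacing = length / (n_g + 1)
        for i in range(n_g):
            start = int((i + 1) * spacing - cfg.gene_span / 2)
            start = max(1, start)
            n_e = int(rng.integers(lo, hi + 1))
            # exons spread evenly across the gene span
            exons = []
            for j in range(n_e):
                es = start + int(j * (cfg.gene_span - cfg.exon_length) / max(1, n_e - 1))
                exons.append((es, es + cfg.exon_length - 1))
            gid += 1
            biotype = "lincRNA" if gid % cfg.noncoding_every == 0 else "protein_coding"
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    symbol=f"GENE{gid:05d}",
                    chrom=chrom,
                    biotype=biotype,
                    exons=tuple(exons),
                )
            )
    return genes


def _sample_table(cfg: SimConfig, rng: np.random.Generator) -> list[SampleRecord]:
    n = cfg.n_cases + cfg.n_controls
    sexes = rng.random(n) < 0.5
    pcs = rng.standard_normal((n, 10))
    lrr = np.abs(rng.normal(*cfg.lrr_sd_dist, size=n))
    baf = np.abs(rng.normal(*cfg.baf_drift_dist, size=n))
    wf = rng.normal(*cfg.wf_dist, size=n)
    out_mask = rng.random(n) < cfg.metric_outlier_frac
    lrr[out_mask] = cfg.lrr_sd_dist[0] + 12 * cfg.lrr_sd_dist[1]
    samples = []
    for i in range(n):
        status = "case" if i < cfg.n_cases else "control"
        prefix = "CASE" if status == "case" else "CTRL"
        idx = i if status == "case" else i - cfg.n_cases
        samples.append(
            SampleRecord(
                sample_id=f"{prefix}{idx:05d}",
                status=status,
                sex="male" if sexes[i] else "female",
                pcs=tuple(float(v) for v in pcs[i]),
                lrr_sd=float(lrr[i]),
                baf_drift=float(baf[i]),
                wf=float(wf[i]),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# event generation
# ---------------------------------------------------------------------------

def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return min(a[1], b[1]) - max(a[0], b[0]) >= 0


def _place_uniform(
    cfg: SimConfig,
    rng: np.random.Generator,
    blacklist_by_chrom: dict[str, tuple[int, int]],
) -> tuple[str, int, int]:
    total = sum(l for _, l in cfg.genome)
    weights = np.array([l for _, l in cfg.genome], dtype=float) / total
    log_lo, log_hi = math.log(cfg.size_min), math.log(cfg.size_max)
    for _ in range(100):
        ci = int(rng.choice(len(cfg.genome), p=weights))
        chrom, length = cfg.genome[ci]
        size = int(math.exp(rng.uniform(log_lo, log_hi)))
        start = int(rng.integers(1, length - size + 1))
        end = start + size - 1
        bl = blacklist_by_chrom.get(chrom)
        if bl is None or not _overlaps((start, end), bl):
            return chrom, start, end
    raise RuntimeError("could not place event off-blacklist (genome too small)")


def _markers(length: int, spacing: int) -> int:
    return max(1, round(length / spacing))


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate a complete synthetic cohort bundle; deterministic given seed.

    Sub-streams are derived from one seed sequence per component so that
    adding a component does not perturb the others.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (ss_samples, ss_genes, ss_events, ss_caller2, ss_scores, ss_sets) = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    blacklist, gd_regions, ref_svs = _layout_regions(cfg)
    genes = _layout_genes(cfg, ss_genes)
    samples = _sample_table(cfg, ss_samples)

    bl_by_chrom = {r[0]: (r[1], r[2]) for r in blacklist.regions}
    gd_list = list(gd_regions.regions)
    common_by_type = {
        t: [sv for sv in ref_svs if sv.sv_type == t and sv.af >= 0.01] for t in (DELETION, DUPLICATION)
    }

    rates = {
        DELETION: {"control": cfg.rate_del, "case": cfg.rate_del * cfg.ratio_del},
        DUPLICATION: {"control": cfg.rate_dup, "case": cfg.rate_dup * cfg.ratio_dup},
    }

    rng = ss_events
    truth: list[tuple[str, str, int, int, str]] = []  # sample, chrom, start, end, type
    for s in samples:
        for t in (DELETION, DUPLICATION):
            k = rng.poisson(rates[t][s.status])
            for _ in range(k):
                chrom, start, end = _place_uniform(cfg, rng, bl_by_chrom)
                u = rng.random()
                if u < cfg.frac_blacklist:
                    bs, be = bl_by_chrom[chrom]
                    size = end - start + 1
                    start = max(1, bs - size // 2)
                    end = start + size - 1
                elif u < cfg.frac_blacklist + cfg.frac_common:
                    sv = common_by_type[t][int(rng.integers(len(common_by_type[t])))]
                    chrom, start, end = sv.chrom, sv.start, sv.end
                elif u < cfg.frac_blacklist + cfg.frac_common + cfg.frac_gd:
                    chrom, start, end = gd_list[int(rng.integers(len(gd_list)))]
                truth.append((s.sample_id, chrom, start, end, t))

    # planted gene-set enrichment: extra case events targeted at set genes,
    # calibrated so the case rate of set-hitting events is ~multiplier x the
    # control rate (see methods note)
    coding = [g for g in genes if g.is_protein_coding]
    set_rng = ss_sets
    gene_sets: dict[str, list[str]] = {}
    order = set_rng.permutation(len(coding))
    cursor = 0
    for name, size in cfg.gene_set_sizes.items():
        size = min(size, len(coding) - cursor)
        members = [coding[i] for i in order[cursor : cursor + size]]
        cursor += size
        gene_sets[name] = sorted(g.symbol for g in members)

    if cfg.set_enrichment:
        sym_to_gene = {g.symbol: g for g in coding}
        n_ctrl = sum(1 for s in samples if s.status == "control")
        # empirical control rate of set-hitting duplications
        ctrl_ids = {s.sample_id for s in samples if s.status == "control"}
        for name, mult in cfg.set_enrichment.items():
            members = [sym_to_gene[s] for s in gene_sets[name] if s in sym_to_gene]
            if not members or mult <= 1.0:
                continue
            member_spans = [(g.chrom, *g.span) for g in members]
            hits = 0
            for sid, chrom, start, end, t in truth:
                if t == DUPLICATION and sid in ctrl_ids:
                    if any(c == chrom and _overlaps((start, end), (s0, e0)) for c, s0, e0 in member_spans):
                        hits += 1
            base_rate = hits / max(1, n_ctrl)
            extra_rate = (mult - 1.0) * base_rate
            for s in samples:
                if s.status != "case":
                    continue
                for _ in range(set_rng.poisson(extra_rate)):
                    g = members[int(set_rng.integers(len(members)))]
                    gs, ge = g.span
                    pad = int(set_rng.integers(5_000, 30_000))
                    truth.append((s.sample_id, g.chrom, max(1, gs - pad), ge + pad, DUPLICATION))

    # primary caller: every truth event, with quality columns
    calls_p: list[CnvCall] = []
    for sid, chrom, start, end, t in truth:
        lowq = rng.random() < cfg.frac_lowq
        qs_abs = rng.uniform(0.0, 0.5) if lowq else rng.uniform(0.55, 1.0)
        qs = -qs_abs if t == DELETION else qs_abs
        conf = rng.random() >= cfg.frac_lowconf
        calls_p.append(
            CnvCall(
                sample_id=sid,
                chrom=chrom,
                start=start,
                end=end,
                copy_number=1 if t == DELETION else 3,
                n_markers=_markers(end - start + 1, cfg.marker_spacing),
                caller="penncnv",
                qs=float(qs),
                confidence_pass=bool(conf),
            )
        )

    # secondary caller: independent drops and jittered endpoints
    rng2 = ss_caller2
    calls_q: list[CnvCall] = []
    for sid, chrom, start, end, t in truth:
        if rng2.random() < cfg.caller_discordance:
            continue
        if cfg.jitter_sd > 0:
            js = start + int(round(rng2.normal(0, cfg.jitter_sd)))
            je = end + int(round(rng2.normal(0, cfg.jitter_sd)))
            js, je = max(1, js), max(js, je)
            # a concordant secondary call must stay callable (>= size_min)
            # and preserve >= 50% reciprocal overlap with the truth
            # interval; otherwise fall back to the unjittered endpoints
            bp = min(end, je) - max(start, js) + 1
            if je - js + 1 < cfg.size_min or bp < 0.55 * max(end - start + 1, je - js + 1):
                js, je = start, end
        else:
            js, je = start, end
        calls_q.append(
            CnvCall(
                sample_id=sid,
                chrom=chrom,
                start=js,
                end=je,
                copy_number=1 if t == DELETION else 3,
                n_markers=_markers(je - js + 1, cfg.marker_spacing),
                caller="quantisnp",
                qs=None,
                confidence_pass=None,
            )
        )

    # pathogenicity scores for every primary call
    rng3 = ss_scores
    case_ids = {s.sample_id for s in samples if s.status == "case"}
    scores: list[ScoreAnnotation] = []
    for c in calls_p:
        ti = 0 if c.type == DELETION else 1
        is_case = c.sample_id in case_ids
        vals = {}
        for m in SCORE_METRICS:
            if rng3.random() < cfg.score_missing_frac:
                vals[m] = None
                continue
            mu = cfg.score_mu[m][ti]
            if m == "cadd":
                v = rng3.normal(mu + 10 * cfg.score_status_shift * is_case, cfg.cadd_sd)
                vals[m] = float(np.clip(v, 0.0, 60.0))
            else:
                v = rng3.normal(mu + cfg.score_status_shift * is_case, cfg.score_sd)
                vals[m] = float(np.clip(v, 0.0, 1.0))
        scores.append(ScoreAnnotation(call_key=c.key, **vals))

    return CohortBundle(
        config=cfg,
        samples=samples,
        calls_penncnv=calls_p,
        calls_quantisnp=calls_q,
        genes=genes,
        gene_sets=gene_sets,
        ref_svs=ref_svs,
        blacklist=blacklist,
        gd_regions=gd_regions,
        scores=scores,
    )


# ---------------------------------------------------------------------------
# deterministic worked-example fixture
# ---------------------------------------------------------------------------

def worked_example_fixture() -> CohortBundle:
    """A deterministic cohort reproducing the published gene-wise example.

    1,204 cases and 9,549 controls; exactly 95 controls and no case carry a
    duplication overlapping the designated gene (ZNF813-like zinc-finger
    locus on chromosome 19), and every call passes every QC stage.  The
    corrected carrier table (0, 1204, 95, 9454) gives OR = 0.0411 with 95% CI
    [0.0026, 0.66].  Deterministic background duplications and deletions on
    other genes (every 15th and 20th sample respectively, both cohorts
    equally) keep the global regressions well-posed.
    """
    cfg = SimConfig(seed=0, n_cases=1204, n_controls=9549)
    rng = np.random.default_rng(20_190_813)  # fixture-internal stream
    # array-quality metrics are drawn uniform (bounded at mean + sqrt(3)*SD),
    # so the 3xSD outlier filter provably removes no sample
    n = cfg.n_cases + cfg.n_controls
    sexes = rng.random(n) < 0.5
    pcs = rng.standard_normal((n, 10))
    lrr = rng.uniform(0.10, 0.14, size=n)
    baf = rng.uniform(0.001, 0.003, size=n)
    wf = rng.uniform(-0.04, 0.04, size=n)
    samples = []
    for i in range(n):
        status = "case" if i < cfg.n_cases else "control"
        prefix = "CASE" if status == "case" else "CTRL"
        idx = i if status == "case" else i - cfg.n_cases
        samples.append(
            SampleRecord(
                sample_id=f"{prefix}{idx:05d}",
                status=status,
                sex="male" if sexes[i] else "female",
                pcs=tuple(float(v) for v in pcs[i]),
                lrr_sd=float(lrr[i]),
                baf_drift=float(baf[i]),
                wf=float(wf[i]),
            )
        )

    chrom = "19"
    genes: list[GeneModel] = []
    target_start = 2_000_000
    exons = tuple(
        (target_start + j * 15_000, target_start + j * 15_000 + 2_999) for j in range(4)
    )
    genes.append(GeneModel("G_ZNF", "ZNF813", chrom, "protein_coding", exons))
    for i in range(10):
        gs = 4_000_000 + i * 400_000
        genes.append(
            GeneModel(
                f"G_BG{i:02d}",
                f"BG{i:02d}",
                chrom,
                "protein_coding",
                tuple((gs + j * 20_000, gs + j * 20_000 + 2_999) for j in range(3)),
            )
        )

    def mk(sample_id: str, start: int, end: int, cn: int, caller: str) -> CnvCall:
        return CnvCall(
            sample_id=sample_id,
            chrom=chrom,
            start=start,
            end=end,
            copy_number=cn,
            n_markers=max(10, (end - start + 1) // 2_500),
            caller=caller,
            qs=(0.9 if cn > 2 else -0.9) if caller == "penncnv" else None,
            confidence_pass=True if caller == "penncnv" else None,
        )

    calls_p: list[CnvCall] = []
    calls_q: list[CnvCall] = []
    controls = [s for s in samples if s.status == "control"]
    for s in controls[:95]:
        start, end = target_start - 5_000, target_start + 55_000  # covers all 4 exons
        calls_p.append(mk(s.sample_id, start, end, 3, "penncnv"))
        calls_q.append(mk(s.sample_id, start, end, 3, "quantisnp"))
    # background calls, both cohorts equally, never touching the target gene
    for i, s in enumerate(samples):
        if i % 15 == 0:
            g = genes[1 + (i // 15) % 10]
            start, end = g.exons[0][0] - 2_000, g.exons[-1][1] + 2_000
            calls_p.append(mk(s.sample_id, start, end, 3, "penncnv"))
            calls_q.append(mk(s.sample_id, start, end, 3, "quantisnp"))
        if i % 20 == 0:
            g = genes[1 + (i // 20) % 10]
            start, end = g.exons[0][0] - 4_000, g.exons[-1][1] + 4_000
            calls_p.append(mk(s.sample_id, start, end, 1, "penncnv"))
            calls_q.append(mk(s.sample_id, start, end, 1, "quantisnp"))

    blacklist = RegionSet("blacklist", ((chrom, 15_000_000, 15_100_000),), "blacklist")
    gd = RegionSet("genomic_disorder", ((chrom, 18_000_000, 18_800_000),), "genomic_disorder")
    ref_svs = [ReferenceSv(chrom, 10_000_000, 10_200_000, DELETION, 0.002)]
    scores = [
        ScoreAnnotation(call_key=c.key, lr=0.5, vest3=0.5, fathmm=0.5, pli=0.3, cadd=15.0, mvp=0.5)
        for c in calls_p
    ]
    gene_sets = {"background_set": [f"BG{i:02d}" for i in range(10)], "target_set": ["ZNF813"]}

    cfg = SimConfig(seed=0, n_cases=1204, n_controls=9549)
    return CohortBundle(
        config=cfg,
        samples=samples,
        calls_penncnv=calls_p,
        calls_quantisnp=calls_q,
        genes=genes,
        gene_sets=gene_sets,
        ref_svs=ref_svs,
        blacklist=blacklist,
        gd_regions=gd,
        scores=scores,
    )
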