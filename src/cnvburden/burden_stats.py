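"""Case-control burden statistics for rare CNVs.

Five test families, each with its own Bonferroni scheme and always run
separately for deletions and duplications:

* **global burden** — logistic regression of case status on a per-sample
  burden metric (CNV count, summed CNV length in 100-kb units, or number of
  distinct genes hit), adjusting for sex, the first 10 ancestry principal
  components, and LRR_SD (``status ~ metric + sex + PC1-10 + LRR_SD``);
  Bonferroni 0.05/6 and, for the four size-bin subsets, 0.05/8.
* **gene-wise burden** — per gene, a two-sided Fisher exact test on the
  2x2 carrier table (a carrier is a sample with >= 1 CNV of the given type
  hitting the gene); odds ratios for tables with a zero cell use the
  Haldane/Altman +0.5 correction.
* **gene-set enrichment** — logistic regression with the per-sample count
  of CNVs hitting any member gene of the set as metric; Bonferroni 0.05/30.
* **genomic-disorder-region burden** — one 2x2 Fisher test per CNV type on
  event counts (not carriers) inside vs outside the regions.
* **pathogenicity-score burden** — logistic regression on per-sample mean
  pathogenicity scores, among carriers only; Bonferroni 0.05/12.

Inference for regressions is Wald (normal quantile 1.96 for 95% CIs);
Fisher p-values are exact two-sided hypergeometric sums, never a chi-square
approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .io_formats import (
    DELETION,
    DUPLICATION,
    CnvCall,
    GeneModel,
    SampleRecord,
    ScoreAnnotation,
    SCORE_METRICS,
)
from .interval_ops import GeneHit

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal quantile for 95% Wald intervals
CNV_TYPES = (DELETION, DUPLICATION)
DEFAULT_SIZE_BINS = (30_000, 100_000, 500_000, 1_000_000)

# relative tolerance when comparing table probabilities in the two-sided
# Fisher sum (floating-point tie guard)
_FISHER_TIE_RTOL = 1e-7

# |coefficient| beyond this on a count/score metric indicates separation
_SEPARATION_COEF = 15.0


class UntestableError(ValueError):
    """Raised when a test's preconditions are not met (e.g. constant metric)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssociationResult:
    identifier: str
    effect: float  # odds ratio
    ci_low: float
    ci_high: float
    p: float
    test: str  # "logistic_wald" | "fisher_exact"
    n_tests: int
    alpha_adj: float
    passed: bool
    n_case: int
    n_control: int
    note: str = ""


@dataclass
class BurdenRow:
    """Per-sample burden metrics over the analysis-ready call set."""

    sample_id: str
    n_del: int = 0
    n_dup: int = 0
    len_del: float = 0.0  # summed length in 100-kb units
    len_dup: float = 0.0
    genes_del: int = 0  # distinct genes hit
    genes_dup: int = 0
    bin_counts: dict = field(default_factory=dict)  # (type, bin) -> count
    bin_gene_counts: dict = field(default_factory=dict)
    set_counts: dict = field(default_factory=dict)  # (set, type) -> CNV count
    set_gene_counts: dict = field(default_factory=dict)  # (set, type) -> genes hit
    mean_scores: dict = field(default_factory=dict)  # (metric, type) -> float|None

    def count(self, cnv_type: str) -> int:
        return self.n_del if cnv_type == DELETION else self.n_dup

    def length(self, cnv_type: str) -> float:
        return self.len_del if cnv_type == DELETION else self.len_dup

    def genes(self, cnv_type: str) -> int:
        return self.genes_del if cnv_type == DELETION else self.genes_dup


# ---------------------------------------------------------------------------
# burden metric construction
# ---------------------------------------------------------------------------

def assign_size_bin(length: int, bins: Sequence[int] = DEFAULT_SIZE_BINS) -> int:
    """Return the 1-based size-bin index for a call length in bp.

    Bins are left-closed, right-open on the lower edges in ``bins``; the last
    bin is unbounded above.  Lengths below the first edge violate the QC
    precondition and raise.
    """
    if length < bins[0]:
        raise ValueError(f"call length {length} below QC minimum {bins[0]}")
    for i in range(len(bins) - 1, 0, -1):
        if length >= bins[i]:
            return i + 1
    return 1


def compute_burden_rows(
    calls: Sequence[CnvCall],
    gene_hits: Sequence[GeneHit],
    samples: Sequence[SampleRecord],
    *,
    genes: Sequence[GeneModel] = (),
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    scores: Sequence[ScoreAnnotation] = (),
    bins: Sequence[int] = DEFAULT_SIZE_BINS,
) -> list[BurdenRow]:
    """Aggregate the post-QC call set into one burden row per sample.

    Every sample in ``samples`` gets a row (all-zero for non-carriers).
    Lengths are reported in 100-kb units.  Per-metric mean pathogenicity
    scores average over the sample's calls of each type, skipping missing
    values; a sample with no scored calls of a type has a missing mean.
    """
    gene_sets = gene_sets or {}
    symbol_of = {g.gene_id: g.symbol for g in genes}
    hits_by_call: dict[tuple, set[str]] = {}
    for h in gene_hits:
        hits_by_call.setdefault(h.call_key, set()).add(h.gene_id)

    known_keys = {c.key for c in calls}
    scores_by_call: dict[tuple, ScoreAnnotation] = {}
    for s in scores:
        if s.call_key not in known_keys:
            raise ValueError(f"score annotation references unknown call: {s.call_key}")
        scores_by_call[s.call_key] = s

    set_members = {name: set(members) for name, members in gene_sets.items()}

    calls_by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        calls_by_sample.setdefault(c.sample_id, []).append(c)

    rows = []
    for sample in samples:
        row = BurdenRow(sample_id=sample.sample_id)
        gene_acc = {t: set() for t in CNV_TYPES}
        bin_gene_acc: dict[tuple, set] = {}
        score_acc: dict[tuple, list[float]] = {}
        for c in calls_by_sample.get(sample.sample_id, ()):  # deterministic input order
            t = c.type
            hit_genes = hits_by_call.get(c.key, set())
            if t == DELETION:
                row.n_del += 1
                row.len_del += c.length / 100_000.0
            else:
                row.n_dup += 1
                row.len_dup += c.length / 100_000.0
            gene_acc[t] |= hit_genes
            b = assign_size_bin(c.length, bins)
            row.bin_counts[(t, b)] = row.bin_counts.get((t, b), 0) + 1
            bin_gene_acc.setdefault((t, b), set()).update(hit_genes)
            hit_symbols = {symbol_of.get(g, g) for g in hit_genes}
            for name, members in set_members.items():
                in_set = hit_symbols & members
                if in_set:
                    row.set_counts[(name, t)] = row.set_counts.get((name, t), 0) + 1
                    row.set_gene_counts.setdefault((name, t), set()).update(in_set)
            ann = scores_by_call.get(c.key)
            if ann is not None:
                for m in SCORE_METRICS:
                    v = ann.value(m)
                    if v is not None:
                        score_acc.setdefault((m, t), []).append(v)
        row.genes_del = len(gene_acc[DELETION])
        row.genes_dup = len(gene_acc[DUPLICATION])
        row.bin_gene_counts = {k: len(v) for k, v in bin_gene_acc.items()}
        row.set_gene_counts = {k: len(v) for k, v in row.set_gene_counts.items()}
        row.mean_scores = {k: float(np.mean(v)) for k, v in score_acc.items()}
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# primitive tests
# ---------------------------------------------------------------------------

def bonferroni(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise threshold alpha / n_tests; significance is strict <."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def odds_ratio_2x2(
    table: ContingencyTable2x2, zero_correction: str = "auto"
) -> tuple[float, float, float]:
    """Sample odds ratio with 95% Wald CI on the log scale.

    ``zero_correction``: ``none`` (fail on a zero cell), ``haldane_0.5``
    (always add 0.5 to every cell), or ``auto`` (add 0.5 only when some cell
    is zero — the Haldane/Altman convention for Fisher tables with empty
    cells).  CI = exp(ln OR +/- 1.96 * sqrt(sum of reciprocal cells)).
    """
    a, b, c, d = table.cells
    if a + b + c + d == 0:
        raise ValueError("all cells zero")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("zero margin: odds ratio undefined")
    has_zero = min(a, b, c, d) == 0
    if zero_correction == "none":
        if has_zero:
            raise ValueError("zero cell with correction disabled")
        corr = 0.0
    elif zero_correction == "haldane_0.5":
        corr = 0.5
    elif zero_correction == "auto":
        corr = 0.5 if has_zero else 0.0
    else:
        raise ValueError(f"unknown zero_correction: {zero_correction!r}")
    a2, b2, c2, d2 = a + corr, b + corr, c + corr, d + corr
    or_ = (a2 * d2) / (b2 * c2)
    se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    log_or = math.log(or_)
    return or_, math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities of tables no more probable than the observed one (relative
    tie tolerance 1e-7).  Computed in log space, so large margins are exact
    rather than approximated.
    """
    a, b, c, d = table.cells
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if min(row1, c + d, col1, b + d) == 0:
        raise ValueError("zero margin: Fisher test undefined")
    k_min = max(0, row1 + col1 - n_total)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    logpmf = hypergeom.logpmf(ks, n_total, col1, row1)
    log_obs = logpmf[a - k_min]
    keep = logpmf <= log_obs + math.log1p(_FISHER_TIE_RTOL)
    return float(min(1.0, math.exp(logsumexp(logpmf[keep]))))


# ---------------------------------------------------------------------------
# logistic regression machinery
# ---------------------------------------------------------------------------

def _design_matrix(samples: Sequence[SampleRecord], values: Sequence[float], adjust: bool):
    y = np.array([1.0 if s.is_case else 0.0 for s in samples])
    cols = [np.ones(len(samples)), np.asarray(values, dtype=float)]
    names = ["const", "metric"]
    if adjust:
        cols.append(np.array([1.0 if s.sex == "male" else 0.0 for s in samples]))
        names.append("sex")
        pcs = np.array([s.pcs for s in samples])
        for i in range(10):
            cols.append(pcs[:, i])
            names.append(f"pc{i + 1}")
        cols.append(np.array([s.lrr_sd for s in samples]))
        names.append("lrr_sd")
    return y, np.column_stack(cols), names


def logistic_burden_test(
    samples: Sequence[SampleRecord],
    values: Sequence[float],
    identifier: str,
    *,
    n_tests: int = 1,
    alpha: float = 0.05,
    adjust: bool = True,
) -> AssociationResult:
    """Covariate-adjusted logistic burden regression.

    Fits ``status ~ metric (+ sex + PC1-10 + LRR_SD)`` by maximum
    likelihood; effect is the odds ratio exp(beta_metric), CI the 95% Wald
    interval, p the two-sided Wald test of beta_metric.  Separation or
    non-convergence yields a flagged result with non-finite effect rather
    than an exception; a constant metric raises :class:`UntestableError`.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    values = np.asarray(values, dtype=float)
    if len(values) != len(samples):
        raise ValueError("metric values not aligned with samples")
    n_case = sum(1 for s in samples if s.is_case)
    n_control = len(samples) - n_case
    if n_case == 0 or n_control == 0:
        raise UntestableError("need at least one case and one control")
    if np.ptp(values) == 0:
        raise UntestableError("constant predictor")

    y, X, _names = _design_matrix(samples, values, adjust)
    alpha_adj = bonferroni(alpha, n_tests)
    note = ""
    try:
        fit = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        converged = bool(fit.mle_retvals.get("converged", False))
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not converged or not math.isfinite(beta) or not math.isfinite(se) or abs(beta) > _SEPARATION_COEF:
            raise PerfectSeparationError("separation or non-convergence")
        p = float(fit.pvalues[1])
        return AssociationResult(
            identifier=identifier,
            effect=math.exp(beta),
            ci_low=math.exp(beta - Z95 * se),
            ci_high=math.exp(beta + Z95 * se),
            p=p,
            test="logistic_wald",
            n_tests=n_tests,
            alpha_adj=alpha_adj,
            passed=p < alpha_adj,
            n_case=n_case,
            n_control=n_control,
        )
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
        note = f"flagged: {exc}"
        logger.warning("logistic fit for %s flagged: %s", identifier, exc)
    return AssociationResult(
        identifier=identifier,
        effect=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        p=float("nan"),
        test="logistic_wald",
        n_tests=n_tests,
        alpha_adj=alpha_adj,
        passed=False,
        n_case=n_case,
        n_control=n_control,
        note=note,
    )


# ---------------------------------------------------------------------------
# test families
# ---------------------------------------------------------------------------

def global_burden_tests(
    samples: Sequence[SampleRecord],
    rows: Sequence[BurdenRow],
    *,
    alpha: float = 0.05,
    n_tests: int = 6,
) -> list[AssociationResult]:
    """The six global regressions: {count, length, genes} x {del, dup}."""
    metrics = {
        "count": BurdenRow.count,
        "length_100kb": BurdenRow.length,
        "genes": BurdenRow.genes,
    }
    out = []
    for t in CNV_TYPES:
        for name, getter in metrics.items():
            values = [getter(r, t) for r in rows]
            ident = f"global_{name}_{t}"
            try:
                out.append(
                    logistic_burden_test(samples, values, ident, n_tests=n_tests, alpha=alpha)
                )
            except UntestableError as exc:
                logger.warning("%s untested: %s", ident, exc)
    return out


def size_bin_burden_tests(
    samples: Sequence[SampleRecord],
    rows: Sequence[BurdenRow],
    *,
    bins: Sequence[int] = DEFAULT_SIZE_BINS,
    alpha: float = 0.05,
    n_tests: int = 8,
) -> list[AssociationResult]:
    """Per size-bin regressions of CNV count and gene count, per type."""
    out = []
    for t in CNV_TYPES:
        for b in range(1, len(bins) + 1):
            for name, source in (("count", "bin_counts"), ("genes", "bin_gene_counts")):
                values = [getattr(r, source).get((t, b), 0) for r in rows]
                ident = f"bin{b}_{name}_{t}"
                try:
                    out.append(
                        logistic_burden_test(samples, values, ident, n_tests=n_tests, alpha=alpha)
                    )
                except UntestableError as exc:
                    logger.info("%s untested: %s", ident, exc)
    return out


def gene_wise_burden(
    calls: Sequence[CnvCall],
    gene_hits: Sequence[GeneHit],
    samples: Sequence[SampleRecord],
    cnv_type: str,
    *,
    alpha: float = 0.05,
    n_tests: int | None = None,
    symbol_of: Mapping[str, str] | None = None,
) -> list[AssociationResult]:
    """Per-gene Fisher exact tests on carrier counts.

    A carrier is a sample with >= 1 CNV of ``cnv_type`` hitting the gene.
    Genes with zero carriers are skipped (not tested).  The Bonferroni family
    size defaults to the number of genes actually tested.
    """
    type_keys = {c.key for c in calls if c.type == cnv_type}
    carriers: dict[str, set[str]] = {}
    for h in gene_hits:
        if h.call_key in type_keys:
            carriers.setdefault(h.gene_id, set()).add(h.call_key[0])
    carriers = {g: s for g, s in carriers.items() if s}

    case_ids = {s.sample_id for s in samples if s.is_case}
    n_case, n_control = len(case_ids), len(samples) - len(case_ids)
    n = n_tests if n_tests is not None else max(1, len(carriers))
    alpha_adj = bonferroni(alpha, n)

    out = []
    for gene_id in sorted(carriers):
        carrier_ids = carriers[gene_id]
        a = len(carrier_ids & case_ids)
        c = len(carrier_ids) - a
        tab = ContingencyTable2x2(a, n_case - a, c, n_control - c)
        p = fisher_exact_2x2(tab)
        or_, lo, hi = odds_ratio_2x2(tab, zero_correction="auto")
        ident = symbol_of.get(gene_id, gene_id) if symbol_of else gene_id
        out.append(
            AssociationResult(
                identifier=ident,
                effect=or_,
                ci_low=lo,
                ci_high=hi,
                p=p,
                test="fisher_exact",
                n_tests=n,
                alpha_adj=alpha_adj,
                passed=p < alpha_adj,
                n_case=a,
                n_control=c,
            )
        )
    return out


def gene_set_enrichment(
    samples: Sequence[SampleRecord],
    rows: Sequence[BurdenRow],
    set_name: str,
    cnv_type: str,
    *,
    alpha: float = 0.05,
    n_tests: int = 30,
    metric: str = "events",
) -> AssociationResult | None:
    """Logistic enrichment test for one gene set and CNV type.

    The default metric is the per-sample count of CNVs of the type hitting
    >= 1 member gene (``events``); ``genes`` counts distinct member genes hit
    instead.  Sets with zero CNVs in both cohorts are untested (None).
    """
    source = "set_counts" if metric == "events" else "set_gene_counts"
    values = [getattr(r, source).get((set_name, cnv_type), 0) for r in rows]
    if sum(values) == 0:
        logger.warning("gene set %s (%s): no CNVs in either cohort, untested", set_name, cnv_type)
        return None
    ident = f"{set_name}_{cnv_type}"
    try:
        return logistic_burden_test(samples, values, ident, n_tests=n_tests, alpha=alpha)
    except UntestableError as exc:
        logger.warning("gene set %s (%s) untested: %s", set_name, cnv_type, exc)
        return None


def gd_region_burden(
    calls: Sequence[CnvCall],
    gd_flags: Mapping[tuple, bool],
    samples: Sequence[SampleRecord],
    cnv_type: str,
    *,
    alpha: float = 0.05,
    n_tests: int = 2,
) -> AssociationResult | None:
    """Fisher test of CNV events inside vs outside genomic-disorder regions.

    The counting unit is CNV events, not carriers: the 2x2 table is
    (case events in / case events out / control events in / control events
    out).  Untested (None) when no events of the type exist.
    """
    case_ids = {s.sample_id for s in samples if s.is_case}
    a = b = c = d = 0
    for call in calls:
        if call.type != cnv_type:
            continue
        inside = gd_flags.get(call.key, False)
        if call.sample_id in case_ids:
            a, b = (a + 1, b) if inside else (a, b + 1)
        else:
            c, d = (c + 1, d) if inside else (c, d + 1)
    if a + b == 0 or c + d == 0:
        logger.warning("GD-region burden (%s): missing events in one cohort, untested", cnv_type)
        return None
    alpha_adj = bonferroni(alpha, n_tests)
    if a + c == 0 or b + d == 0:
        # no variation in exposure: every event on the same side of the
        # regions in both cohorts carries no association information
        return AssociationResult(
            identifier=f"gd_region_{cnv_type}",
            effect=1.0,
            ci_low=float("nan"),
            ci_high=float("nan"),
            p=1.0,
            test="fisher_exact",
            n_tests=n_tests,
            alpha_adj=alpha_adj,
            passed=False,
            n_case=a + b,
            n_control=c + d,
            note="degenerate: no exposure variation",
        )
    tab = ContingencyTable2x2(a, b, c, d)
    p = fisher_exact_2x2(tab)
    or_, lo, hi = odds_ratio_2x2(tab, zero_correction="auto")
    return AssociationResult(
        identifier=f"gd_region_{cnv_type}",
        effect=or_,
        ci_low=lo,
        ci_high=hi,
        p=p,
        test="fisher_exact",
        n_tests=n_tests,
        alpha_adj=alpha_adj,
        passed=p < alpha_adj,
        n_case=a + b,
        n_control=c + d,
    )


def pathogenicity_burden(
    samples: Sequence[SampleRecord],
    rows: Sequence[BurdenRow],
    metric: str,
    cnv_type: str,
    *,
    alpha: float = 0.05,
    n_tests: int = 12,
) -> AssociationResult | None:
    """Regression of case status on the per-sample mean pathogenicity score.

    Only samples carrying >= 1 scored CNV of the type enter; fewer than two
    carriers in either cohort, or a constant score, yields None (untested).
    """
    if metric not in SCORE_METRICS:
        raise ValueError(f"unknown pathogenicity metric: {metric!r}")
    rows_by_id = {r.sample_id: r for r in rows}
    sub_samples, values = [], []
    for s in samples:
        r = rows_by_id.get(s.sample_id)
        if r is None:
            continue
        v = r.mean_scores.get((metric, cnv_type))
        if v is not None:
            sub_samples.append(s)
            values.append(v)
    n_case = sum(1 for s in sub_samples if s.is_case)
    n_control = len(sub_samples) - n_case
    ident = f"{metric}_{cnv_type}"
    if n_case < 2 or n_control < 2:
        logger.warning("pathogenicity %s: <2 carriers per cohort, untested", ident)
        return None
    try:
        return logistic_burden_test(sub_samples, values, ident, n_tests=n_tests, alpha=alpha)
    except UntestableError as exc:
        logger.warning("pathogenicity %s untested: %s", ident, exc)
        return None
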