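"""Sample-level and CNV-level quality-control cascade.

The cascade runs in a fixed, logged order and records one
:class:`FilterReport` per stage (counting primary-caller calls), so a run is
auditable stage by stage:

1. sample metric outliers (mean + k*SD on LRR_SD, BAF drift, |WF|)
2. sample call-count cap (>150 pre-QC calls per sample)
3. call size / marker minimum (30 kb, 10 SNP markers)
4. consensus quality score (|QS| > 0.5)
5. dual-caller consensus (>= 50% reciprocal overlap with the secondary caller)
6. rarity against the reference SV panel (AF < 1%)
7. blacklist exclusion (any overlapping base)
8. high-confidence classifier flag
9. protein-coding exon intersection

Sample-level stages drop the removed samples' calls from both caller
streams; the size/marker filter is also applied to the secondary caller's
calls before consensus so both sides of the reciprocal-overlap match are
comparably filtered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import interval_ops
from .config import IntervalConfig, QcConfig
from .io_formats import CnvCall, GeneModel, RegionSet, ReferenceSv, SampleRecord
from .interval_ops import GeneHit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterReport:
    stage: str
    n_in: int
    n_out: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class QcResult:
    calls: list[CnvCall]
    samples: list[SampleRecord]
    reports: list[FilterReport]
    gene_hits: list[GeneHit]


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    if n < 2:
        raise ValueError("fewer than 2 samples: SD undefined")
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def filter_samples_by_metric_outliers(
    samples: Sequence[SampleRecord], k: float = 3.0
) -> tuple[list[SampleRecord], list[FilterReport]]:
    """Remove samples whose array-quality metrics are cohort outliers.

    A sample is removed iff any metric among LRR_SD, BAF drift and |WF|
    strictly exceeds ``cohort mean + k * cohort SD`` of that metric, with the
    cohort statistics computed once over cases and controls jointly (sample
    SD, ddof = 1).  One report per metric, applied in a fixed order, so the
    per-metric removal counts are additive.
    """
    metrics = {
        "lrr_sd": lambda s: s.lrr_sd,
        "baf_drift": lambda s: s.baf_drift,
        "abs_wf": lambda s: abs(s.wf),
    }
    cutoffs = {}
    for name, getter in metrics.items():
        mean, sd = _mean_sd([getter(s) for s in samples])
        cutoffs[name] = mean + k * sd
    kept = list(samples)
    reports = []
    for name, getter in metrics.items():
        n_in = len(kept)
        kept = [s for s in kept if getter(s) <= cutoffs[name]]
        reports.append(FilterReport(f"sample_metric_{name}", n_in, len(kept)))
    return kept, reports


def filter_samples_by_call_count(
    samples: Sequence[SampleRecord],
    calls: Sequence[CnvCall],
    max_calls: int = 150,
) -> list[SampleRecord]:
    """Remove samples with more than ``max_calls`` pre-QC calls (strict >).

    ``calls`` should be the primary caller's pre-QC calls, counted per
    sample; exactly ``max_calls`` calls is kept.
    """
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    return [s for s in samples if counts.get(s.sample_id, 0) <= max_calls]


def filter_calls_size_markers(
    calls: Sequence[CnvCall], min_len: int = 30_000, min_markers: int = 10
) -> list[CnvCall]:
    """Keep calls with length >= ``min_len`` bp and >= ``min_markers`` SNP
    markers (both thresholds inclusive on the keep side)."""
    return [c for c in calls if c.length >= min_len and c.n_markers >= min_markers]


def filter_calls_quality(
    calls: Sequence[CnvCall],
    qs_min: float = 0.5,
    require_confidence: bool = True,
) -> list[CnvCall]:
    """Keep calls with |QS| strictly above ``qs_min`` and, when
    ``require_confidence``, a true high-confidence flag.

    Calls with missing QS are removed while QS filtering is active; missing
    confidence flags fail the confidence requirement.
    """
    kept = []
    for c in calls:
        if c.qs is None or abs(c.qs) <= qs_min:
            continue
        if require_confidence and not c.confidence_pass:
            continue
        kept.append(c)
    return kept


def _restrict_to_samples(calls: Sequence[CnvCall], samples: Sequence[SampleRecord]) -> list[CnvCall]:
    ids = {s.sample_id for s in samples}
    return [c for c in calls if c.sample_id in ids]


def run_qc_cascade(
    calls_penncnv: Sequence[CnvCall],
    calls_quantisnp: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    *,
    genes: Sequence[GeneModel],
    ref_svs: Sequence[ReferenceSv],
    blacklist: RegionSet,
    qc: QcConfig | None = None,
    intervals: IntervalConfig | None = None,
) -> QcResult:
    """Run the full QC cascade and return the analysis-ready call set.

    Reports count primary-caller (PennCNV-stream) calls per stage; sample
    stages emit call-level reports reflecting the calls lost with their
    samples.  Disabled stages (``qc.stages_enabled``) are identity.
    """
    qc = qc or QcConfig()
    intervals = intervals or IntervalConfig()
    enabled = qc.stages_enabled

    reports: list[FilterReport] = []
    cur = list(calls_penncnv)
    secondary = list(calls_quantisnp)
    kept_samples = list(samples)

    def report(stage: str, n_in: int, n_out: int) -> None:
        reports.append(FilterReport(stage, n_in, n_out))
        logger.info("QC stage %-18s: %6d -> %6d (removed %d)", stage, n_in, n_out, n_in - n_out)

    # 1. sample metric outliers
    n_in = len(cur)
    if enabled.get("sample_metrics", True):
        kept_samples, _metric_reports = filter_samples_by_metric_outliers(
            kept_samples, k=qc.metric_sd_k
        )
        cur = _restrict_to_samples(cur, kept_samples)
        secondary = _restrict_to_samples(secondary, kept_samples)
    report("sample_metrics", n_in, len(cur))

    # 2. sample call-count cap (counted on pre-QC primary calls)
    n_in = len(cur)
    if enabled.get("sample_call_count", True):
        kept_samples = filter_samples_by_call_count(
            kept_samples, cur, max_calls=qc.max_calls_per_sample
        )
        cur = _restrict_to_samples(cur, kept_samples)
        secondary = _restrict_to_samples(secondary, kept_samples)
    report("sample_call_count", n_in, len(cur))

    # 3. size / marker minimum (both caller streams)
    n_in = len(cur)
    if enabled.get("size_markers", True):
        cur = filter_calls_size_markers(cur, qc.min_length_bp, qc.min_markers)
        secondary = filter_calls_size_markers(secondary, qc.min_length_bp, qc.min_markers)
    report("size_markers", n_in, len(cur))

    # 4. consensus quality score
    n_in = len(cur)
    if enabled.get("qs", True):
        cur = filter_calls_quality(cur, qs_min=qc.qs_min, require_confidence=False)
    report("qs", n_in, len(cur))

    # 5. dual-caller consensus
    n_in = len(cur)
    if enabled.get("consensus", True):
        cur = interval_ops.consensus_filter(cur, secondary, t=intervals.consensus_ro)
    report("consensus", n_in, len(cur))

    # 6. rarity
    n_in = len(cur)
    if enabled.get("rarity", True):
        cur = interval_ops.rarity_filter(
            cur, ref_svs, af_max=intervals.rarity_af_max, t=intervals.rarity_ro
        )
    report("rarity", n_in, len(cur))

    # 7. blacklist
    n_in = len(cur)
    if enabled.get("blacklist", True):
        cur = interval_ops.blacklist_filter(cur, blacklist)
    report("blacklist", n_in, len(cur))

    # 8. high-confidence flag
    n_in = len(cur)
    if enabled.get("confidence", True) and qc.require_confidence:
        cur = [c for c in cur if c.confidence_pass]
    report("confidence", n_in, len(cur))

    # 9. protein-coding exon intersection
    n_in = len(cur)
    gene_hits: list[GeneHit] = []
    if enabled.get("exon", True):
        cur, gene_hits = interval_ops.exon_filter(
            cur,
            genes,
            min_bp=intervals.exon_min_bp,
            require_containment=intervals.exon_containment,
        )
    else:
        # gene hits are still needed downstream for gene-level metrics
        _, gene_hits = interval_ops.exon_filter(
            cur, genes, min_bp=intervals.exon_min_bp,
            require_containment=intervals.exon_containment,
        )
    report("exon", n_in, len(cur))

    return QcResult(calls=cur, samples=kept_samples, reports=reports, gene_hits=gene_hits)
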