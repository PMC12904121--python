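"""Interval arithmetic for CNV filtering and annotation.

Everything here is built on one primitive: the base-pair overlap of two
1-based inclusive intervals.  Reciprocal overlap at threshold ``t`` means the
shared span covers at least ``t`` of *each* interval's own length — the
standard criterion for calling two structural variants "the same" event.

Stages implemented on top of it:

* dual-caller consensus (a primary call must be reproduced by the secondary
  caller at >= 50% reciprocal overlap, same sample, same type),
* rarity against a reference SV panel (a call matching a common same-type
  reference variant is discarded),
* blacklist exclusion (any shared base removes the call),
* protein-coding exon intersection (gene assignment),
* genomic-disorder-region membership (>= 50% reciprocal overlap).

Problem sizes after per-sample grouping are small, so matching is done with
direct interval comparisons per (sample, chromosome, type) group.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import CnvCall, GeneModel, RegionSet, ReferenceSv

Interval = tuple[str, int, int]  # (chrom, start, end), 1-based inclusive


@dataclass(frozen=True)
class OverlapResult:
    bp_overlap: int
    frac_a: float  # bp_overlap / length(a)
    frac_b: float


@dataclass(frozen=True)
class GeneHit:
    """A (call, gene) intersection: the call touches >= 1 exon of the gene."""

    call_key: tuple[str, str, int, int, str]
    gene_id: str
    n_exons_hit: int


def _length(iv: Interval) -> int:
    return iv[2] - iv[1] + 1


def overlap(a: Interval, b: Interval) -> OverlapResult:
    """Base-pair overlap of two 1-based inclusive intervals.

    Zero when the chromosomes differ; otherwise
    ``max(0, min(end_a, end_b) - max(start_a, start_b) + 1)``.
    """
    if a[0] != b[0]:
        return OverlapResult(0, 0.0, 0.0)
    bp = min(a[2], b[2]) - max(a[1], b[1]) + 1
    if bp <= 0:
        return OverlapResult(0, 0.0, 0.0)
    return OverlapResult(bp, bp / _length(a), bp / _length(b))


def reciprocal_ge(a: Interval, b: Interval, t: float) -> bool:
    """True iff a and b reciprocally overlap by at least ``t`` (inclusive)."""
    if not 0.0 < t <= 1.0:
        raise ValueError(f"reciprocal-overlap threshold must be in (0, 1], got {t}")
    ov = overlap(a, b)
    return ov.frac_a >= t and ov.frac_b >= t


# ---------------------------------------------------------------------------
# call-level filters
# ---------------------------------------------------------------------------

def consensus_filter(
    primary_calls: Sequence[CnvCall],
    secondary_calls: Sequence[CnvCall],
    t: float = 0.5,
) -> list[CnvCall]:
    """Keep primary-caller calls confirmed by the secondary caller.

    A primary call is retained iff at least one secondary call from the same
    sample, of the same type (deletion/duplication, not exact copy number),
    reciprocally overlaps it at threshold ``t``.  One secondary call may
    confirm several primary calls.
    """
    by_group: dict[tuple[str, str, str], list[Interval]] = defaultdict(list)
    for c in secondary_calls:
        by_group[(c.sample_id, c.chrom, c.type)].append(c.interval)
    kept = []
    for c in primary_calls:
        partners = by_group.get((c.sample_id, c.chrom, c.type), ())
        if any(reciprocal_ge(c.interval, p, t) for p in partners):
            kept.append(c)
    return kept


def rarity_filter(
    calls: Sequence[CnvCall],
    ref_svs: Sequence[ReferenceSv],
    af_max: float = 0.01,
    t: float = 0.5,
) -> list[CnvCall]:
    """Keep only rare calls.

    A call is removed iff some same-type reference SV reciprocally overlaps
    it at threshold ``t`` and has allele frequency >= ``af_max``.  Calls
    matching no reference SV are treated as rare and retained.
    """
    common: dict[tuple[str, str], list[Interval]] = defaultdict(list)
    for sv in ref_svs:
        if sv.af >= af_max:
            common[(sv.chrom, sv.sv_type)].append(sv.interval)
    kept = []
    for c in calls:
        hits = common.get((c.chrom, c.type), ())
        if not any(reciprocal_ge(c.interval, iv, t) for iv in hits):
            kept.append(c)
    return kept


def blacklist_filter(calls: Sequence[CnvCall], blacklist: RegionSet) -> list[CnvCall]:
    """Remove any call sharing >= 1 bp with a blacklist region."""
    if blacklist.role != "blacklist":
        raise ValueError(f"expected a blacklist RegionSet, got role {blacklist.role!r}")
    by_chrom: dict[str, list[Interval]] = defaultdict(list)
    for r in blacklist.regions:
        by_chrom[r[0]].append(r)
    kept = []
    for c in calls:
        if not any(overlap(c.interval, r).bp_overlap >= 1 for r in by_chrom.get(c.chrom, ())):
            kept.append(c)
    return kept


def exon_filter(
    calls: Sequence[CnvCall],
    genes: Sequence[GeneModel],
    min_bp: int = 1,
    require_containment: bool = False,
) -> tuple[list[CnvCall], list[GeneHit]]:
    """Keep calls intersecting >= 1 exon of >= 1 protein-coding gene.

    Emits one :class:`GeneHit` per (call, gene) pair with the number of exons
    hit.  ``min_bp`` sets the minimum per-exon overlap; with
    ``require_containment`` an exon counts only when fully inside the call
    (the stricter "exon encompassed" reading).  Non-protein-coding genes
    never produce hits.
    """
    coding = [g for g in genes if g.is_protein_coding]
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in coding:
        by_chrom[g.chrom].append(g)
    kept: list[CnvCall] = []
    hits: list[GeneHit] = []
    for c in calls:
        call_hits = []
        for g in by_chrom.get(c.chrom, ()):
            n = 0
            for es, ee in g.exons:
                if require_containment:
                    ok = c.start <= es and ee <= c.end
                else:
                    ok = overlap(c.interval, (g.chrom, es, ee)).bp_overlap >= min_bp
                if ok:
                    n += 1
            if n:
                call_hits.append(GeneHit(call_key=c.key, gene_id=g.gene_id, n_exons_hit=n))
        if call_hits:
            kept.append(c)
            hits.extend(call_hits)
    return kept, hits


def gd_region_assign(
    calls: Sequence[CnvCall], gd: RegionSet, t: float = 0.5
) -> dict[tuple[str, str, int, int, str], bool]:
    """Flag each call as inside/outside the genomic-disorder regions.

    A call is "inside" iff it reciprocally overlaps >= 1 region at ``t``.
    """
    if gd.role != "genomic_disorder":
        raise ValueError(f"expected a genomic_disorder RegionSet, got role {gd.role!r}")
    by_chrom: dict[str, list[Interval]] = defaultdict(list)
    for r in gd.regions:
        by_chrom[r[0]].append(r)
    return {
        c.key: any(reciprocal_ge(c.interval, r, t) for r in by_chrom.get(c.chrom, ()))
        for c in calls
    }
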