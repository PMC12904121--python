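"""Readers and writers for every external table the pipeline touches.

All genomic coordinates are held internally as 1-based inclusive positions
(the PennCNV convention), so ``length = end - start + 1``.  BED-dialect
inputs, which are 0-based half-open on disk, are converted at the read
boundary and converted back on write.  Chromosome labels are normalized to
a canonical form without a ``chr`` prefix; autosomes and X/Y are accepted,
mitochondrial labels are rejected (array CNV calling covers nuclear
chromosomes only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DELETION = "deletion"
DUPLICATION = "duplication"

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}
_MITO_LABELS = {"M", "MT", "CHRM", "CHRMT"}

# floats are written with 17 significant digits so a write/read round trip
# is exact
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Raised when an input table violates its documented column contract."""


def normalize_chrom(label: str) -> str:
    """Return the canonical chromosome label (no ``chr`` prefix).

    Accepts ``1``..``22``, ``X``, ``Y`` with or without a ``chr`` prefix,
    case-insensitively.  Mitochondrial and unknown labels raise
    :class:`FormatError`.
    """
    raw = str(label).strip()
    name = raw.upper()
    if name.startswith("CHR"):
        name = name[3:]
    if name in {"M", "MT"}:
        raise FormatError(f"mitochondrial chromosome not supported: {raw!r}")
    if name not in _VALID_CHROMS:
        raise FormatError(f"unknown chromosome label: {raw!r}")
    return name


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvCall:
    """One caller's copy-number call for one sample.

    ``start``/``end`` are 1-based inclusive.  A call is a deletion iff
    ``copy_number < 2`` and a duplication iff ``copy_number > 2``;
    copy-neutral rows (``copy_number == 2``) are rejected at read time.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    n_markers: int
    caller: str  # "penncnv" | "quantisnp"
    qs: float | None = None
    confidence_pass: bool | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"malformed coordinates start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.copy_number == 2:
            raise FormatError("neutral copy number (cn=2) is not a CNV")
        if self.copy_number < 0:
            raise FormatError(f"negative copy number: {self.copy_number}")
        if self.n_markers < 1:
            raise FormatError(f"n_markers must be positive, got {self.n_markers}")
        if self.qs is not None and not -1.0 <= self.qs <= 1.0:
            raise FormatError(f"qs outside [-1, 1]: {self.qs}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def type(self) -> str:
        return DELETION if self.copy_number < 2 else DUPLICATION

    @property
    def key(self) -> tuple[str, str, int, int, str]:
        """Identity used to join score annotations and region flags."""
        return (self.sample_id, self.chrom, self.start, self.end, self.type)

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 11))


@dataclass(frozen=True)
class SampleRecord:
    """Phenotype status plus the covariates and array-quality metrics."""

    sample_id: str
    status: str  # "case" | "control"
    sex: str  # "female" | "male"
    pcs: tuple[float, ...]  # PC1..PC10 ancestry principal components
    lrr_sd: float
    baf_drift: float
    wf: float

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise FormatError(f"unrecognized status: {self.status!r}")
        if self.sex not in ("female", "male"):
            raise FormatError(f"unrecognized sex: {self.sex!r}")
        if len(self.pcs) != 10:
            raise FormatError("expected 10 principal components")
        if self.lrr_sd < 0 or self.baf_drift < 0:
            raise FormatError("lrr_sd and baf_drift must be non-negative")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    biotype: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, ordered

    def __post_init__(self) -> None:
        if not self.exons:
            raise FormatError(f"gene {self.gene_id} has zero exon rows")
        for s, e in self.exons:
            if s > e:
                raise FormatError(f"gene {self.gene_id} exon start > end: {s}-{e}")

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == "protein_coding"

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass(frozen=True)
class ReferenceSv:
    chrom: str
    start: int
    end: int
    sv_type: str  # "deletion" | "duplication"
    af: float  # population allele frequency

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise FormatError(f"allele frequency outside [0, 1]: {self.af}")
        if self.sv_type not in (DELETION, DUPLICATION):
            raise FormatError(f"unknown sv_type: {self.sv_type!r}")
        if self.start > self.end:
            raise FormatError("reference SV start > end")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class RegionSet:
    """A labelled set of genomic regions (blacklist or genomic-disorder)."""

    label: str
    regions: tuple[tuple[str, int, int], ...]
    role: str  # "blacklist" | "genomic_disorder"


SCORE_METRICS = ("lr", "vest3", "fathmm", "pli", "cadd", "mvp")


@dataclass(frozen=True)
class ScoreAnnotation:
    """Per-CNV pathogenicity scores; any metric may be missing (None)."""

    call_key: tuple[str, str, int, int, str]
    lr: float | None = None
    vest3: float | None = None
    fathmm: float | None = None
    pli: float | None = None
    cadd: float | None = None
    mvp: float | None = None

    def value(self, metric: str) -> float | None:
        return getattr(self, metric)


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to 1-based inclusive."""
    start, end = int(start0) + 1, int(end0)
    if start > end:
        raise FormatError(
            f"BED interval [{start0}, {end0}) converts to empty internal interval"
        )
    return start, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """Convert 1-based inclusive coordinates to 0-based half-open BED."""
    return int(start) - 1, int(end)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_DIALECT_COLUMNS = {
    "penncnv": ["sample_id", "chrom", "start", "end", "cn", "numsnp"],
    "quantisnp": ["sample_id", "chrom", "start", "end", "cn", "numsnp"],
}


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("empty file: %s", path)
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return df


def read_cnv_calls(path: str | Path, dialect: str) -> list[CnvCall]:
    """Read one caller's per-sample CNV call table.

    The two supported dialects share the mandatory columns ``sample_id``,
    ``chrom``, ``start``, ``end``, ``cn``, ``numsnp``; the ``penncnv``
    dialect may additionally carry ``qs`` (consensus quality score in
    [-1, 1]) and ``conf_pass`` (high-confidence classifier flag), the
    ``quantisnp`` dialect an unused ``logbf`` column.  Positions are 1-based
    inclusive on disk.  Copy-neutral rows are rejected.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = _read_tsv(path, _DIALECT_COLUMNS[dialect])
    if df.empty:
        logger.warning("no CNV calls in %s", path)
        return []
    has_qs = dialect == "penncnv" and "qs" in df.columns
    has_conf = dialect == "penncnv" and "conf_pass" in df.columns
    calls: list[CnvCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            qs = None
            if has_qs:
                raw = getattr(row, "qs")
                qs = None if pd.isna(raw) or raw == "" else float(raw)
            conf = None
            if has_conf:
                raw = getattr(row, "conf_pass")
                if pd.isna(raw) or raw == "":
                    conf = None
                elif str(raw).lower() in ("true", "1", "t", "yes"):
                    conf = True
                elif str(raw).lower() in ("false", "0", "f", "no"):
                    conf = False
                else:
                    raise FormatError(f"unparseable conf_pass value: {raw!r}")
            calls.append(
                CnvCall(
                    sample_id=str(row.sample_id),
                    chrom=normalize_chrom(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    copy_number=int(row.cn),
                    n_markers=int(row.numsnp),
                    caller=dialect,
                    qs=qs,
                    confidence_pass=conf,
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    return calls


_SAMPLE_COLUMNS = ["sample_id", "status", "sex", *PC_COLUMNS, "lrr_sd", "baf_drift", "wf"]


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata table (status, sex, PC1-10, array QC metrics)."""
    df = _read_tsv(path, _SAMPLE_COLUMNS)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.sample_id)
        if sid in seen:
            raise FormatError(f"{path}, line {i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            pcs = tuple(float(getattr(row, c)) for c in PC_COLUMNS)
            rec = SampleRecord(
                sample_id=sid,
                status=str(row.status),
                sex=str(row.sex),
                pcs=pcs,
                lrr_sd=float(row.lrr_sd),
                baf_drift=float(row.baf_drift),
                wf=float(row.wf),
            )
        except (FormatError, ValueError, TypeError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
        records.append(rec)
    return records


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the gene-model table (one row per exon, 1-based inclusive)."""
    df = _read_tsv(path, ["gene_id", "symbol", "chrom", "biotype", "exon_start", "exon_end"])
    genes: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gid = str(row.gene_id)
        try:
            chrom = normalize_chrom(row.chrom)
            exon = (int(row.exon_start), int(row.exon_end))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
        rec = genes.setdefault(
            gid, {"symbol": str(row.symbol), "chrom": chrom, "biotype": str(row.biotype), "exons": []}
        )
        if rec["chrom"] != chrom:
            raise FormatError(f"{path}, line {i}: gene {gid} spans multiple chromosomes")
        rec["exons"].append(exon)
    out = []
    for gid, rec in genes.items():
        out.append(
            GeneModel(
                gene_id=gid,
                symbol=rec["symbol"],
                chrom=rec["chrom"],
                biotype=rec["biotype"],
                exons=tuple(sorted(rec["exons"])),
            )
        )
    return out


def read_region_bed(path: str | Path, role: str, label: str | None = None) -> RegionSet:
    """Read a 3-column BED file into a :class:`RegionSet` (role: blacklist or
    genomic_disorder).  BED is 0-based half-open on disk; internal coordinates
    are 1-based inclusive."""
    if role not in ("blacklist", "genomic_disorder"):
        raise ValueError(f"unknown region role: {role!r}")
    path = Path(path)
    regions: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}, line {i}: expected >= 3 BED columns")
            try:
                chrom = normalize_chrom(parts[0])
                start, end = bed_to_internal(int(parts[1]), int(parts[2]))
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}, line {i}: {exc}") from exc
            regions.append((chrom, start, end))
    return RegionSet(label=label or path.stem, regions=tuple(regions), role=role)


def read_reference_svs(path: str | Path) -> list[ReferenceSv]:
    """Read the reference structural-variant table (BED coordinates plus
    ``sv_type`` and ``af`` columns)."""
    df = _read_tsv(path, ["chrom", "start", "end", "sv_type", "af"])
    svs: list[ReferenceSv] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = bed_to_internal(int(row.start), int(row.end))
            svs.append(
                ReferenceSv(
                    chrom=normalize_chrom(row.chrom),
                    start=start,
                    end=end,
                    sv_type=str(row.sv_type),
                    af=float(row.af),
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    return svs


def read_scores(path: str | Path) -> list[ScoreAnnotation]:
    """Read the per-CNV pathogenicity-score table (LR, VEST3, FATHMM, pLI,
    CADD, MVP); blank cells are missing values."""
    df = _read_tsv(path, ["sample_id", "chrom", "start", "end", "type", *SCORE_METRICS])
    out: list[ScoreAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            key = (
                str(row.sample_id),
                normalize_chrom(row.chrom),
                int(row.start),
                int(row.end),
                str(row.type),
            )
            vals = {}
            for m in SCORE_METRICS:
                raw = getattr(row, m)
                vals[m] = None if pd.isna(raw) or raw == "" else float(raw)
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
        out.append(ScoreAnnotation(call_key=key, **vals))
    return out


def read_gene_sets(path: str | Path, known_symbols: Iterable[str] | None = None) -> dict[str, list[str]]:
    """Read the two-column (set_name, symbol) gene-set table.

    Membership is by symbol; symbols absent from the gene models are retained
    with a warning when ``known_symbols`` is supplied.
    """
    df = _read_tsv(path, ["set_name", "symbol"])
    sets: dict[str, list[str]] = {}
    known = set(known_symbols) if known_symbols is not None else None
    for row in df.itertuples(index=False):
        name, sym = str(row.set_name), str(row.symbol)
        if known is not None and sym not in known:
            logger.warning("gene set %s names unknown gene symbol %s", name, sym)
        sets.setdefault(name, []).append(sym)
    return sets


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

ASSOCIATION_COLUMNS = [
    "identifier",
    "effect",
    "ci_low",
    "ci_high",
    "p",
    "test",
    "n_case",
    "n_control",
    "n_tests",
    "alpha_adj",
    "pass",
    "note",
]


def write_association_table(results: Sequence, path: str | Path) -> None:
    """Write association results as TSV, sorted by p then identifier.

    ``results`` are AssociationResult-like records (see burden_stats); they
    must be homogeneous in test family.  NaN p-values (flagged results) sort
    last.
    """
    families = {r.test for r in results}
    if len(families) > 1:
        raise ValueError(f"results mix test families: {sorted(families)}")
    rows = [
        {
            "identifier": r.identifier,
            "effect": r.effect,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p,
            "test": r.test,
            "n_case": r.n_case,
            "n_control": r.n_control,
            "n_tests": r.n_tests,
            "alpha_adj": r.alpha_adj,
            "pass": r.passed,
            "note": r.note,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    if not df.empty:
        df = df.sort_values(
            ["p", "identifier"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_cnv_calls(calls: Sequence[CnvCall], path: str | Path) -> None:
    """Write calls in the penncnv dialect plus a derived ``type`` column."""
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "cn": c.copy_number,
            "numsnp": c.n_markers,
            "qs": "" if c.qs is None else _FLOAT_FMT % c.qs,
            "conf_pass": "" if c.confidence_pass is None else str(c.confidence_pass).lower(),
            "type": c.type,
        }
        for c in calls
    ]
    cols = ["sample_id", "chrom", "start", "end", "cn", "numsnp", "qs", "conf_pass", "type"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_region_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.regions:
            b0, b1 = internal_to_bed(start, end)
            fh.write(f"{chrom}\t{b0}\t{b1}\n")
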