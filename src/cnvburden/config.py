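"""Configuration objects for the pipeline.

One YAML document with sections ``qc``, ``intervals``, ``stats``, ``sim``,
``inputs`` and top-level ``seed``/``output_dir`` drives every command.  Each
default below is the pipeline's documented operating point: 30 kb / 10-marker
minimum call size, |QS| > 0.5, >150-calls-per-sample cap, 3xSD array-metric
outlier cut, 50% reciprocal overlap for consensus/rarity/genomic-disorder
matching, and 1% allele-frequency rarity cutoff.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

QC_STAGES = (
    "sample_metrics",
    "sample_call_count",
    "size_markers",
    "qs",
    "consensus",
    "rarity",
    "blacklist",
    "confidence",
    "exon",
)


@dataclass
class QcConfig:
    min_length_bp: int = 30_000
    min_markers: int = 10
    max_calls_per_sample: int = 150
    qs_min: float = 0.5
    metric_sd_k: float = 3.0
    require_confidence: bool = True
    stages_enabled: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in QC_STAGES}
    )


@dataclass
class IntervalConfig:
    consensus_ro: float = 0.5
    rarity_ro: float = 0.5
    rarity_af_max: float = 0.01
    gd_ro: float = 0.5
    exon_min_bp: int = 1
    exon_containment: bool = False


@dataclass
class StatsConfig:
    alpha: float = 0.05
    # Bonferroni family sizes; None = derive from the number of tests run
    n_tests_global: int = 6
    n_tests_sizebin: int = 8
    n_tests_genewise: int | None = None
    n_tests_geneset: int = 30
    n_tests_gd: int = 2
    n_tests_pathogenicity: int = 12
    size_bins_bp: tuple[int, ...] = (30_000, 100_000, 500_000, 1_000_000)
    # gene-set metric: count CNV events hitting any set gene ("events") or
    # count distinct set genes hit ("genes")
    geneset_metric: str = "events"


@dataclass
class InputPaths:
    calls_penncnv: str | None = None
    calls_quantisnp: str | None = None
    samples: str | None = None
    gene_models: str | None = None
    gene_sets: str | None = None
    reference_svs: str | None = None
    blacklist: str | None = None
    gd_regions: str | None = None
    scores: str | None = None
    # optional pre-filtered inputs (outputs of cmd_qc) for stage isolation
    filtered_calls: str | None = None
    gene_hits: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "cnvburden_run"
    qc: QcConfig = field(default_factory=QcConfig)
    intervals: IntervalConfig = field(default_factory=IntervalConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    inputs: InputPaths = field(default_factory=InputPaths)
    sim: dict = field(default_factory=dict)  # forwarded to synthetic_data.SimConfig

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stats"]["size_bins_bp"] = list(self.stats.size_bins_bp)
        return d


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML; absent keys take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "cnvburden_run")),
        qc=_build(QcConfig, raw.get("qc", {}) or {}),
        intervals=_build(IntervalConfig, raw.get("intervals", {}) or {}),
        stats=_build(StatsConfig, raw.get("stats", {}) or {}),
        inputs=_build(InputPaths, raw.get("inputs", {}) or {}),
        sim=raw.get("sim", {}) or {},
    )
    if isinstance(cfg.stats.size_bins_bp, list):
        cfg.stats.size_bins_bp = tuple(cfg.stats.size_bins_bp)
    default_stages = {s: True for s in QC_STAGES}
    default_stages.update(cfg.qc.stages_enabled)
    cfg.qc.stages_enabled = default_stages
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
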