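"""Shared builders for small, hand-checkable fixtures."""

from __future__ import annotations

import pytest

from cnvburden.io_formats import CnvCall, GeneModel, SampleRecord


def make_call(
    sample_id="S1",
    chrom="1",
    start=1_000_000,
    end=1_049_999,
    cn=3,
    n_markers=20,
    caller="penncnv",
    qs=0.9,
    conf=True,
) -> CnvCall:
    if caller != "penncnv":
        qs, conf = None, None
    return CnvCall(
        sample_id=sample_id,
        chrom=chrom,
        start=start,
        end=end,
        copy_number=cn,
        n_markers=n_markers,
        caller=caller,
        qs=qs,
        confidence_pass=conf,
    )


def make_sample(
    sample_id="S1",
    status="control",
    sex="female",
    pcs=None,
    lrr_sd=0.1,
    baf_drift=0.002,
    wf=0.0,
) -> SampleRecord:
    return SampleRecord(
        sample_id=sample_id,
        status=status,
        sex=sex,
        pcs=tuple(pcs) if pcs is not None else (0.0,) * 10,
        lrr_sd=lrr_sd,
        baf_drift=baf_drift,
        wf=wf,
    )


def make_gene(gene_id="G1", symbol=None, chrom="1", biotype="protein_coding", exons=None):
    return GeneModel(
        gene_id=gene_id,
        symbol=symbol or gene_id,
        chrom=chrom,
        biotype=biotype,
        exons=tuple(exons) if exons else ((1_000_000, 1_002_999),),
    )


@pytest.fixture
def small_cohort():
    """Three controls and two cases with distinct covariates."""
    return [
        make_sample("A", "case", "male", pcs=[0.1] * 10, lrr_sd=0.11),
        make_sample("B", "case", "female", pcs=[-0.2] * 10, lrr_sd=0.12),
        make_sample("C", "control", "male", pcs=[0.0] * 10, lrr_sd=0.10),
        make_sample("D", "control", "female", pcs=[0.3] * 10, lrr_sd=0.13),
        make_sample("E", "control", "male", pcs=[-0.1] * 10, lrr_sd=0.09),
    ]
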