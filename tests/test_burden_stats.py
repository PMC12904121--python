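"""Burden statistics: exact tests, corrected odds ratios, regressions."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats

from cnvburden import burden_stats as bs
from cnvburden.burden_stats import AssociationResult, ContingencyTable2x2
from cnvburden.interval_ops import GeneHit
from cnvburden.io_formats import ScoreAnnotation
from cnvburden.synthetic_data import SimConfig, simulate_cohort
from cnvburden.quality_control import run_qc_cascade
from cnvburden.pipeline_cli import inputs_from_bundle

from conftest import make_call, make_gene, make_sample


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p with exact rational arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    probs = {}
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs[k] = Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
    p_obs = probs[a] * (1 + Fraction(1, 10**7))
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestOddsRatio:
    def test_altman_corrected_zero_cell_table(self):
        # 0/1204 case carriers vs 95/9454 control non-carrier split
        or_, lo, hi = bs.odds_ratio_2x2(ContingencyTable2x2(0, 1204, 95, 9454), "auto")
        assert or_ == pytest.approx(0.0411, abs=5e-5)
        assert lo == pytest.approx(0.0026, abs=5e-5)
        assert hi == pytest.approx(0.66, abs=5e-3)

    def test_balanced_table_without_correction(self):
        or_, lo, hi = bs.odds_ratio_2x2(ContingencyTable2x2(5, 5, 5, 5), "none")
        assert or_ == 1.0
        assert math.log(lo) == pytest.approx(-math.log(hi), abs=1e-12)

    def test_cross_product(self):
        or_, _, _ = bs.odds_ratio_2x2(ContingencyTable2x2(30, 70, 10, 90), "none")
        assert or_ == pytest.approx(27 / 7, rel=1e-12)

    def test_explicit_haldane_always_corrects(self):
        or_, _, _ = bs.odds_ratio_2x2(ContingencyTable2x2(30, 70, 10, 90), "haldane_0.5")
        assert or_ == pytest.approx((30.5 * 90.5) / (70.5 * 10.5), rel=1e-12)

    def test_zero_cell_without_correction_fails(self):
        with pytest.raises(ValueError):
            bs.odds_ratio_2x2(ContingencyTable2x2(0, 10, 5, 5), "none")

    def test_all_zero_fails(self):
        with pytest.raises(ValueError):
            bs.odds_ratio_2x2(ContingencyTable2x2(0, 0, 0, 0))


class TestFisherExact:
    def test_enumerated_example(self):
        assert bs.fisher_exact_2x2(ContingencyTable2x2(2, 8, 8, 2)) == pytest.approx(
            4252 / 184756, rel=1e-12
        )

    def test_modal_table_p_is_one(self):
        assert bs.fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            got = bs.fisher_exact_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert got == pytest.approx(fisher_oracle(int(a), int(b), int(c), int(d)), rel=1e-10)

    def test_matches_scipy_on_large_margins(self):
        # independent route: scipy's implementation, large counts
        tab = ContingencyTable2x2(60, 1144, 295, 9254)
        assert bs.fisher_exact_2x2(tab) == pytest.approx(
            scipy.stats.fisher_exact([[60, 1144], [295, 9254]])[1], rel=1e-9
        )


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 6, 0.05 / 6), (0.05, 1, 0.05), (0.05, 1891, 0.05 / 1891), (0.05, 30, 0.05 / 30)],
    )
    def test_threshold(self, alpha, n, expected):
        assert bs.bonferroni(alpha, n) == pytest.approx(expected, rel=1e-12)

    def test_zero_tests_fails(self):
        with pytest.raises(ValueError):
            bs.bonferroni(0.05, 0)


class TestSizeBins:
    @pytest.mark.parametrize(
        "length,bin_", [(30_000, 1), (99_999, 1), (100_000, 2), (499_999, 2), (500_000, 3), (2_000_000, 4)]
    )
    def test_left_closed_bins(self, length, bin_):
        assert bs.assign_size_bin(length) == bin_

    def test_below_qc_minimum_fails(self):
        with pytest.raises(ValueError):
            bs.assign_size_bin(29_999)


def _cohort(n_case, n_control, values_case, values_control, seed=0):
    """Samples with mildly varying covariates plus aligned metric values."""
    rng = np.random.default_rng(seed)
    samples, values = [], []
    for i in range(n_case):
        samples.append(
            make_sample(f"CA{i}", "case", "male" if rng.random() < 0.5 else "female",
                        pcs=rng.normal(0, 1, 10), lrr_sd=float(abs(rng.normal(0.1, 0.01))))
        )
        values.append(values_case[i])
    for i in range(n_control):
        samples.append(
            make_sample(f"CO{i}", "control", "male" if rng.random() < 0.5 else "female",
                        pcs=rng.normal(0, 1, 10), lrr_sd=float(abs(rng.normal(0.1, 0.01))))
        )
        values.append(values_control[i])
    return samples, values


class TestLogisticBurden:
    def test_saturated_binary_model_equals_log_cross_product_or(self):
        # 30/70 exposed cases, 10/90 exposed controls, no covariates
        samples, values = _cohort(100, 100, [1] * 30 + [0] * 70, [1] * 10 + [0] * 90)
        res = bs.logistic_burden_test(samples, values, "binary", adjust=False)
        assert math.log(res.effect) == pytest.approx(math.log(27 / 7), abs=1e-6)

    def test_constant_predictor_raises(self):
        samples, values = _cohort(5, 5, [1.0] * 5, [1.0] * 5)
        with pytest.raises(bs.UntestableError, match="constant"):
            bs.logistic_burden_test(samples, values, "const")

    def test_separation_is_flagged_not_raised(self):
        samples, values = _cohort(20, 20, [1.0] * 20, [0.0] * 20)
        res = bs.logistic_burden_test(samples, values, "sep", adjust=False)
        assert not math.isfinite(res.effect) or res.note.startswith("flagged")
        assert res.note != "" and res.passed is False

    def test_null_metric_ci_covers_one(self):
        # a single replicate can reject by chance; coverage is the property
        n_reps, covered = 30, 0
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            n = 600
            vc = rng.poisson(1.0, n).astype(float)
            vk = rng.poisson(1.0, n).astype(float)
            samples, values = _cohort(n, n, vc, vk, seed=seed)
            res = bs.logistic_burden_test(samples, values, "null")
            covered += res.ci_low < 1.0 < res.ci_high
        assert covered >= 24  # binomial(30, 0.95) lower tail is negligible here

    def test_length_regression_scales_inversely(self):
        rng = np.random.default_rng(3)
        n = 800
        vc = rng.gamma(2.0, 1.5, n)
        vk = rng.gamma(2.0, 1.0, n)
        samples, values = _cohort(n, n, vc, vk, seed=3)
        r1 = bs.logistic_burden_test(samples, values, "len")
        r2 = bs.logistic_burden_test(samples, [v * 10 for v in values], "len10")
        assert math.log(r1.effect) == pytest.approx(10 * math.log(r2.effect), rel=1e-6)
        assert r1.p == pytest.approx(r2.p, rel=1e-6)


class TestBurdenRows:
    def test_length_in_100kb_units(self):
        samples = [make_sample("S1")]
        calls = [
            make_call("S1", start=1, end=150_000, cn=3),
            make_call("S1", start=500_001, end=750_000, cn=3),
        ]
        (row,) = bs.compute_burden_rows(calls, [], samples)
        assert row.len_dup == pytest.approx(4.0)
        assert row.n_dup == 2 and row.n_del == 0

    def test_non_carrier_gets_zero_row(self):
        (row,) = bs.compute_burden_rows([], [], [make_sample("S1")])
        assert row.n_del == row.n_dup == 0 and row.mean_scores == {}

    def test_distinct_gene_counting(self):
        samples = [make_sample("S1")]
        calls = [
            make_call("S1", start=1, end=50_000, cn=3),
            make_call("S1", start=100_001, end=150_000, cn=3),
        ]
        hits = [GeneHit(calls[0].key, "G1", 1), GeneHit(calls[1].key, "G1", 1)]
        (row,) = bs.compute_burden_rows(calls, hits, samples)
        assert row.genes_dup == 1

    def test_bin_counts_sum_to_totals(self):
        rng = np.random.default_rng(0)
        samples = [make_sample(f"S{i}") for i in range(20)]
        calls = []
        for i, s in enumerate(samples):
            for j in range(int(rng.integers(0, 4))):
                length = int(rng.integers(30_000, 2_000_000))
                start = 1 + j * 3_000_000
                calls.append(make_call(s.sample_id, start=start, end=start + length - 1,
                                       cn=1 if rng.random() < 0.5 else 3))
        rows = bs.compute_burden_rows(calls, [], samples)
        for row in rows:
            for t, total in (("deletion", row.n_del), ("duplication", row.n_dup)):
                assert sum(v for (tt, _), v in row.bin_counts.items() if tt == t) == total

    def test_mean_scores_skip_missing(self):
        samples = [make_sample("S1")]
        calls = [
            make_call("S1", start=1, end=50_000, cn=3),
            make_call("S1", start=100_001, end=150_000, cn=3),
        ]
        scores = [
            ScoreAnnotation(call_key=calls[0].key, lr=0.2),
            ScoreAnnotation(call_key=calls[1].key, lr=0.8, pli=0.4),
        ]
        (row,) = bs.compute_burden_rows(calls, [], samples, scores=scores)
        assert row.mean_scores[("lr", "duplication")] == pytest.approx(0.5)
        assert row.mean_scores[("pli", "duplication")] == pytest.approx(0.4)
        assert ("cadd", "duplication") not in row.mean_scores

    def test_unknown_score_key_fails(self):
        samples = [make_sample("S1")]
        calls = [make_call("S1")]
        ghost = ScoreAnnotation(call_key=("S1", "1", 5, 10, "deletion"), lr=0.5)
        with pytest.raises(ValueError, match="unknown call"):
            bs.compute_burden_rows(calls, [], samples, scores=[ghost])


class TestGeneWise:
    def _fixture(self, case_carriers, control_carriers, n_case=1204, n_control=9549):
        samples = [make_sample(f"CA{i}", "case") for i in range(n_case)]
        samples += [make_sample(f"CO{i}", "control") for i in range(n_control)]
        calls, hits = [], []
        for i in range(case_carriers):
            c = make_call(f"CA{i}", cn=3)
            calls.append(c)
            hits.append(GeneHit(c.key, "G1", 1))
        for i in range(control_carriers):
            c = make_call(f"CO{i}", cn=3)
            calls.append(c)
            hits.append(GeneHit(c.key, "G1", 1))
        return calls, hits, samples

    def test_protective_duplication_worked_example(self):
        calls, hits, samples = self._fixture(0, 95)
        (res,) = bs.gene_wise_burden(calls, hits, samples, "duplication", n_tests=1891)
        assert res.effect == pytest.approx(0.0411, abs=5e-5)
        assert (res.ci_low, res.ci_high) == (
            pytest.approx(0.0026, abs=5e-5), pytest.approx(0.66, abs=5e-3))
        assert res.p == pytest.approx(2.22e-5, rel=0.01)
        assert res.passed and res.p < 0.05 / 1891

    def test_single_carrier_each_arm_is_null(self):
        calls, hits, samples = self._fixture(1, 1, n_case=100, n_control=100)
        (res,) = bs.gene_wise_burden(calls, hits, samples, "duplication")
        assert res.p > 0.9 and not res.passed

    def test_single_carrier_cannot_pass_large_family(self):
        calls, hits, samples = self._fixture(1, 0, n_case=100, n_control=100)
        (res,) = bs.gene_wise_burden(calls, hits, samples, "duplication", n_tests=100)
        assert res.p >= 0.05 / 100 and not res.passed

    def test_zero_carrier_genes_skipped(self):
        calls, hits, samples = self._fixture(2, 3, n_case=10, n_control=10)
        res = bs.gene_wise_burden(calls, hits, samples, "deletion")  # no deletions at all
        assert res == []


class TestGdRegionBurden:
    def _run(self, a, b, c, d):
        samples = [make_sample("CA", "case"), make_sample("CO", "control")]
        calls, flags = [], {}
        pos = 1
        for sid, inside, n in (("CA", True, a), ("CA", False, b), ("CO", True, c), ("CO", False, d)):
            for _ in range(n):
                call = make_call(sid, start=pos, end=pos + 49_999, cn=3)
                pos += 60_000
                calls.append(call)
                flags[call.key] = inside
        return bs.gd_region_burden(calls, flags, samples, "duplication")

    def test_cross_product_or_and_oracle_p(self):
        res = self._run(6, 174, 40, 1669)
        assert res.effect == pytest.approx((6 * 1669) / (174 * 40), rel=1e-12)
        assert res.p == pytest.approx(fisher_oracle(6, 174, 40, 1669), rel=1e-9)

    def test_doubling_cells_keeps_or_shrinks_p(self):
        r1 = self._run(6, 174, 40, 1669)
        r2 = self._run(12, 348, 80, 3338)
        assert r2.effect == pytest.approx(r1.effect, rel=1e-12)
        assert r2.p < r1.p

    def test_no_exposure_variation_degenerate(self):
        res = self._run(0, 50, 0, 100)
        assert res.effect == 1.0 and res.p == 1.0 and "degenerate" in res.note


class TestPathogenicityBurden:
    def _rows(self, samples, values):
        rows = []
        for s, v in zip(samples, values):
            r = bs.BurdenRow(sample_id=s.sample_id)
            if v is not None:
                r.mean_scores[("pli", "duplication")] = v
            rows.append(r)
        return rows

    def test_constant_scores_untested(self):
        samples, _ = _cohort(5, 5, [0] * 5, [0] * 5)
        rows = self._rows(samples, [0.5] * 10)
        assert bs.pathogenicity_burden(samples, rows, "pli", "duplication") is None

    def test_too_few_carriers_untested(self):
        samples, _ = _cohort(5, 5, [0] * 5, [0] * 5)
        rows = self._rows(samples, [0.1, None, None, None, None, 0.5, 0.7, 0.2, None, None])
        assert bs.pathogenicity_burden(samples, rows, "pli", "duplication") is None

    def test_only_carriers_enter(self):
        rng = np.random.default_rng(1)
        samples, _ = _cohort(50, 50, [0] * 50, [0] * 50, seed=1)
        values = [float(rng.uniform(0, 1)) if i % 2 == 0 else None for i in range(100)]
        res = bs.pathogenicity_burden(samples, rows=self._rows(samples, values),
                                      metric="pli", cnv_type="duplication")
        assert res is not None
        assert res.n_case + res.n_control == sum(v is not None for v in values)


class TestGeneSetReduction:
    def test_all_gene_set_equals_global_count_regression(self):
        bundle = simulate_cohort(
            SimConfig(seed=9, n_cases=250, n_controls=1000, genome=(("1", 25_000_000),), n_genes=120)
        )
        qc_res = run_qc_cascade(
            bundle.calls_penncnv, bundle.calls_quantisnp, bundle.samples,
            genes=bundle.genes, ref_svs=bundle.ref_svs, blacklist=bundle.blacklist,
        )
        all_set = {"everything": [g.symbol for g in bundle.genes if g.is_protein_coding]}
        rows = bs.compute_burden_rows(
            qc_res.calls, qc_res.gene_hits, qc_res.samples,
            genes=bundle.genes, gene_sets=all_set,
        )
        enr = bs.gene_set_enrichment(qc_res.samples, rows, "everything", "duplication", n_tests=1)
        glob = bs.logistic_burden_test(
            qc_res.samples, [r.n_dup for r in rows], "global", n_tests=1
        )
        # every post-QC call hits >= 1 coding gene, so the set metric is n_dup
        assert enr.effect == pytest.approx(glob.effect, rel=1e-10)
        assert enr.p == pytest.approx(glob.p, rel=1e-10)

    def test_disjoint_set_untested(self):
        samples = [make_sample("A", "case"), make_sample("B", "control")]
        rows = [bs.BurdenRow(sample_id="A"), bs.BurdenRow(sample_id="B")]
        assert bs.gene_set_enrichment(samples, rows, "ghost_set", "duplication") is None
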