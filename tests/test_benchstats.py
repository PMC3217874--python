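"""Error rates, composition tests, occurrence tables and masked-search
evaluation."""

import numpy as np
import pytest
from scipy import stats

from tmclass.benchstats import (
    CHI2_CRITICAL_20x2,
    ConfusionCounts,
    HitRecord,
    anchor_vs_functional_rates,
    composition_test_20x2,
    occurrence_table,
    origin_slope,
    rates,
    read_hit_table,
    residue_enrichment,
    scale_correlation,
    search_eval,
    write_hit_table,
)
from tmclass.datasets import OCCURRENCE_EXPECTED_SIMPLE
from tmclass.scales import STANDARD_RESIDUES, default_scale
from tmclass.synthetic_fixtures import gen_hit_table, gen_measure_cloud
from tmclass.zscore import DEFAULT_REFERENCE_STATS as REF

SCALE = default_scale()


class TestRates:
    def test_worked_examples(self):
        r = rates(ConfusionCounts(tp=3, fp=1, tn=0, fn=0))
        assert r.fdr == 0.25 and r.sensitivity == 1.0
        assert rates(ConfusionCounts(tp=9, fn=1)).fnr == pytest.approx(0.10)

    def test_empty_denominators_are_not_applicable(self):
        r = rates(ConfusionCounts())
        assert r.fpr is None and r.fnr is None and r.fdr is None
        assert r.sensitivity is None

    def test_matches_direct_formulas_on_random_counts(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 30, size=4))
            r = rates(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            if fp + tn:
                assert r.fpr == fp / (fp + tn)
                assert 0 <= r.fpr <= 1
            if tp + fn:
                assert r.fnr == fn / (tp + fn)
                assert r.sensitivity == 1 - r.fnr
            if fp + tp:
                assert r.fdr == fp / (fp + tp)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestAnchorVsFunctionalRates:
    def test_simulated_fnr_matches_ten_percent_at_f_1282(self):
        n = 2000
        functionals = gen_measure_cloud(
            REF.mu_c, REF.sigma_c, REF.mu_phi, REF.sigma_phi, REF.rho, n, seed=11
        )
        anchors = gen_measure_cloud(1.6, 0.35, 7.0, 2.0, -0.3, 500, seed=12)
        _, fnr = anchor_vs_functional_rates(anchors, functionals, REF, f=1.282)
        mc_se = np.sqrt(0.1 * 0.9 / n)
        assert abs(fnr - 0.10) <= 3 * mc_se

    @pytest.mark.parametrize(
        "f,theoretical", [(0.840, 0.20), (1.000, 0.16), (1.282, 0.10),
                          (1.645, 0.05), (1.980, 0.025)]
    )
    def test_fnr_within_five_points_of_theoretical_at_all_f(self, f, theoretical):
        # the reference distribution's exact tail rate differs from the
        # one-tailed quantile rate by up to a few points, as observed
        # empirically; all five stay within a 5-point band
        functionals = gen_measure_cloud(
            REF.mu_c, REF.sigma_c, REF.mu_phi, REF.sigma_phi, REF.rho, 4000, seed=13
        )
        anchors = functionals[:100]
        _, fnr = anchor_vs_functional_rates(anchors, functionals, REF, f=f)
        assert abs(fnr - theoretical) <= 0.05

    def test_anchors_identical_to_functionals_complement(self):
        cloud = gen_measure_cloud(
            REF.mu_c, REF.sigma_c, REF.mu_phi, REF.sigma_phi, REF.rho, 1000, seed=14
        )
        fpr, fnr = anchor_vs_functional_rates(cloud, cloud, REF, f=1.282)
        assert fpr == pytest.approx(1.0 - fnr)

    def test_empty_set_rejected(self):
        cloud = gen_measure_cloud(2.4, 0.3, 0.6, 2.8, -0.4, 10, seed=0)
        with pytest.raises(ValueError):
            anchor_vs_functional_rates([], cloud, REF, 1.282)


def _naive_chi2(table):
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / table.sum()
    terms = np.zeros_like(table)
    nz = expected > 0
    terms[nz] = (table[nz] - expected[nz]) ** 2 / expected[nz]
    return terms.sum()


class TestCompositionTest:
    def test_identical_compositions_not_significant(self, rng):
        counts = rng.integers(50, 200, size=20)
        out = composition_test_20x2(counts, counts)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert not out["significant_fixed_critical"]

    def test_matches_textbook_formula(self, rng):
        for _ in range(50):
            a = rng.integers(1, 300, size=20)
            b = rng.integers(1, 300, size=20)
            out = composition_test_20x2(a, b)
            assert out["chi2"] == pytest.approx(
                _naive_chi2(np.stack([a, b], axis=1)), rel=1e-9
            )
            assert out["df"] == 19

    def test_fixed_critical_value_matches_exact_quantile(self):
        assert round(float(stats.chi2.ppf(0.95, 19)), 2) == CHI2_CRITICAL_20x2

    def test_zero_row_dropped_and_flagged(self):
        a = np.full(20, 50)
        b = np.full(20, 50)
        a[0] = 0
        b[0] = 0
        out = composition_test_20x2(a, b)
        assert out["df"] == 18
        assert not out["reliable"]


class TestResidueEnrichment:
    def test_identical_compositions_yield_empty_sets(self, rng):
        counts = rng.integers(100, 400, size=20)
        enr_a, enr_b, _ = residue_enrichment(counts, counts)
        assert enr_a == set() and enr_b == set()

    def test_constructed_leucine_enrichment(self):
        # A: 90% Leu; B: uniform. n = 10,000 each.
        a = {aa: 9000 if aa == "L" else 1000 // 19 for aa in STANDARD_RESIDUES}
        a["L"] = 9000
        b = {aa: 500 for aa in STANDARD_RESIDUES}
        enr_a, enr_b, detail = residue_enrichment(a, b)
        assert "L" in enr_a
        assert "L" not in enr_b
        # the per-test level is the Bonferroni share of the familywise 0.05
        sig = detail[detail.significant]
        assert (sig.pvalue < 0.05 / 20).all()

    def test_per_test_alpha_is_familywise_over_twenty(self):
        # borderline residue: p just above 0.0025 must not be called
        a = {aa: 1000 for aa in STANDARD_RESIDUES}
        b = dict(a)
        grid = np.arange(1001, 1400)
        pvals = []
        for extra in grid:
            table = np.array([[extra, 20000 - extra], [1000, 19000]])
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            pvals.append(p)
        pvals = np.array(pvals)
        just_above = grid[np.argmax(pvals < 0.0025) - 1]
        a["A"] = int(just_above)
        enr_a, _, detail = residue_enrichment(a, b)
        row = detail[detail.residue == "A"].iloc[0]
        assert row.pvalue >= 0.0025
        assert "A" not in enr_a


class TestScaleCorrelation:
    def test_difference_proportional_to_scale_gives_unity(self):
        diff = {aa: 0.01 * SCALE[aa] for aa in STANDARD_RESIDUES}
        assert scale_correlation(diff, SCALE) == pytest.approx(1.0)

    def test_sign_flip_negates(self):
        diff = np.array([SCALE[aa] for aa in STANDARD_RESIDUES]) * 0.02 + 0.001
        r = scale_correlation(diff, SCALE)
        assert scale_correlation(-diff, SCALE) == pytest.approx(-r)

    def test_orthogonalized_difference_gives_zero(self):
        vals = np.array([SCALE[aa] for aa in STANDARD_RESIDUES])
        rng = np.random.default_rng(3)
        diff = rng.normal(size=20)
        centered = vals - vals.mean()
        diff = diff - diff.mean()
        diff = diff - centered * (diff @ centered) / (centered @ centered)
        assert scale_correlation(diff, SCALE) == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_not_applicable(self):
        assert scale_correlation({aa: 0.0 for aa in STANDARD_RESIDUES}, SCALE) is None


class TestOccurrenceTable:
    def test_published_expected_counts_regress_to_printed_slopes(self):
        n_tm = OCCURRENCE_EXPECTED_SIMPLE["n_tm"]
        slope_a, r2_a = origin_slope(n_tm, OCCURRENCE_EXPECTED_SIMPLE["f_1.282"])
        slope_b, r2_b = origin_slope(n_tm, OCCURRENCE_EXPECTED_SIMPLE["f_1.645"])
        assert round(slope_a, 3) == 0.218
        assert round(slope_b, 3) == 0.112
        assert r2_a > 0.9 and r2_b > 0.8

    def test_all_complex_bin_has_zero_expected(self):
        cloud = gen_measure_cloud(REF.mu_c, 0.05, REF.mu_phi, 0.05, -0.2, 50, seed=5)
        table, slope, _ = occurrence_table({3: cloud}, REF, f=1.282)
        assert table.loc[0, "ratio_simple"] == 0.0
        assert table.loc[0, "expected_simple"] == 0.0
        assert slope == 0.0

    def test_ratios_sum_to_one_and_expected_scales_with_ntm(self):
        groups = {
            n: gen_measure_cloud(2.0, 0.4, 3.0, 2.5, -0.4, 200, seed=n)
            for n in (1, 2, 5)
        }
        table, _, _ = occurrence_table(groups, REF, f=1.282)
        assert np.allclose(table.ratio_simple + table.ratio_complex, 1.0)
        assert np.allclose(
            table.expected_simple, table.ratio_simple * table.n_tm
        )

    def test_empty_bin_skipped_with_warning(self):
        cloud = gen_measure_cloud(2.4, 0.3, 0.6, 2.8, -0.4, 20, seed=1)
        with pytest.warns(UserWarning, match="empty bin"):
            table, _, _ = occurrence_table({1: cloud, 2: []}, REF, f=1.282)
        assert list(table.n_tm) == [1]


def _hit(subject, family, e, orig, masked, control):
    return HitRecord("q", subject, family, e, orig, masked, control)


class TestSearchEval:
    def test_hand_enumerated_toy_table(self):
        hits = [
            _hit("s1", "FAM", 1e-10, 100, 90, 80),
            _hit("s2", "FAM", 1e-8, 60, 50, 90),
            _hit("s3", "FAM", 1e-5, 40, 70, 20),
            _hit("x1", "OTHER", 1e-6, 55, 45, 60),
            _hit("x2", "OTHER", 1e-4, 30, 65, 10),
        ]
        out = search_eval(hits, "FAM")
        # cutoff = min masked score among FAM = 50
        assert out["cutoff"]["score"] == 50
        m = out["masked"]["counts"]
        assert (m.tp, m.fn, m.fp, m.tn) == (3, 0, 1, 1)
        o = out["original"]["counts"]
        assert (o.tp, o.fn, o.fp, o.tn) == (2, 1, 1, 1)
        c = out["control"]["counts"]
        assert (c.tp, c.fn, c.fp, c.tn) == (2, 1, 1, 1)
        assert out["masked"]["sensitivity"] == 1.0
        assert out["masked"]["fdr"] == pytest.approx(1 / 4)

    def test_evalue_and_label_filters(self):
        hits = [
            _hit("s1", "FAM", 0.5, 100, 90, 80),   # above E-value cutoff
            _hit("s2", None, 1e-9, 100, 90, 80),   # unlabeled
        ]
        assert search_eval(hits, "FAM") is None

    def test_masked_sensitivity_always_one(self, rng):
        for seed in range(20):
            hits, _ = gen_hit_table(
                n_same_family=int(rng.integers(1, 8)),
                n_other=int(rng.integers(0, 15)),
                seed=seed,
            )
            out = search_eval(hits, "FAM1")
            assert out["masked"]["sensitivity"] == 1.0

    def test_matches_generator_ground_truth(self):
        for seed in (0, 7, 42):
            hits, truth = gen_hit_table(n_same_family=6, n_other=12, seed=seed)
            out = search_eval(hits, "FAM1")
            for variant in ("original", "masked", "control"):
                assert out[variant]["counts"] == truth[variant]

    def test_tsv_round_trip(self, tmp_path):
        hits, _ = gen_hit_table(seed=3)
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        back = read_hit_table(path)
        assert len(back) == len(hits)
        for b, h in zip(back, hits):
            assert (b.query_id, b.subject_id, b.family) == (
                h.query_id, h.subject_id, h.family
            )
            assert b.e_value == pytest.approx(h.e_value)
            assert b.score_masked == pytest.approx(h.score_masked)
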