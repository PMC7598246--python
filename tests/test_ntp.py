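"""Nearest-template prediction, Fisher exact test, cohort summaries."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

import sigrev as sr
from sigrev.exceptions import DegenerateInputError, InvalidConfigError
from sigrev.reference import load_cohort_reference, summarize_cohort_reference


class TestTemplate:
    def test_construction_order_and_size(self, small_signature):
        tpl = sr.build_template(small_signature)
        assert tpl.genes == small_signature.up + small_signature.down
        assert len(tpl.genes) == len(small_signature.up) + len(small_signature.down)
        assert tpl.weights.tolist() == [1, 1, 1, -1, -1, -1]

    def test_weights_restricted_to_unit(self):
        with pytest.raises(InvalidConfigError):
            sr.Template(["a", "b"], np.array([0.5, -1.0]))


class TestNTPDistance:
    def test_perfect_match_orthogonal_antimatch(self, small_signature):
        tpl = sr.build_template(small_signature)
        d_pos, d_neg = sr.ntp_distance(tpl.weights, tpl)
        assert (d_pos, d_neg) == pytest.approx((0.0, 2.0))
        ortho = np.array([1, -1, 0, 1, -1, 0], dtype=float)
        assert sum(ortho * tpl.weights) == 0
        assert sr.ntp_distance(ortho, tpl) == pytest.approx((1.0, 1.0))
        assert sr.ntp_distance(-tpl.weights, tpl) == pytest.approx((2.0, 0.0))

    def test_complementarity_holds_exactly(self, small_signature):
        rng = np.random.default_rng(0)
        tpl = sr.build_template(small_signature)
        for _ in range(50):
            x = rng.normal(size=6)
            d_pos, d_neg = sr.ntp_distance(x, tpl)
            assert d_pos + d_neg == pytest.approx(2.0, abs=1e-12)
            assert 0 <= d_pos <= 2

    def test_zero_vector_undefined(self, small_signature):
        tpl = sr.build_template(small_signature)
        with pytest.raises(DegenerateInputError):
            sr.ntp_distance(np.zeros(6), tpl)

    def test_scale_invariance_of_calls(self, small_signature):
        """Cosine classification is invariant to positive per-sample scaling."""
        cohort, _ = sr.gen_signature_cohort(20, 0, small_signature, 0.5, 0.3,
                                            seed=3, n_genes=60)
        cls1 = sr.classify_cohort(cohort, small_signature, n_resample=200, seed=9)
        # scaling a sample's expression rescales its z-scores only through
        # the per-gene standardization; scale all samples jointly instead
        scaled = sr.ExpressionMatrix(cohort.values * 3.7, cohort.groups, "log2")
        cls2 = sr.classify_cohort(scaled, small_signature, n_resample=200, seed=9)
        assert [c.label for c in cls1.calls] == [c.label for c in cls2.calls]
        assert [c.d_pos for c in cls1.calls] == pytest.approx(
            [c.d_pos for c in cls2.calls])


class TestNTPSignificance:
    def test_perfect_match_hits_resolution_floor(self, small_signature):
        tpl = sr.build_template(small_signature)
        rng = np.random.default_rng(1)
        universe = rng.normal(size=500)
        universe[:6] = tpl.weights * 5
        p = sr.ntp_significance(tpl.weights * 5, tpl, universe,
                                n_resample=200, seed=2)
        assert p == pytest.approx(1 / 201)

    def test_null_p_uniform_mean_half(self, small_signature):
        cohort, _ = sr.gen_signature_cohort(200, 0, small_signature, 0.0, 1.0,
                                            seed=4, n_genes=400, log2_effect=0.0)
        cls = sr.classify_cohort(cohort, small_signature, n_resample=200, seed=5)
        pvals = np.array([c.p for c in cls.calls])
        assert abs(pvals.mean() - 0.5) < 0.06

    def test_fixed_seed_reproducible(self, small_signature):
        cohort, _ = sr.gen_signature_cohort(10, 0, small_signature, 0.5, 0.5, seed=6)
        a = sr.classify_cohort(cohort, small_signature, n_resample=100, seed=7)
        b = sr.classify_cohort(cohort, small_signature, n_resample=100, seed=7)
        assert [c.p for c in a.calls] == [c.p for c in b.calls]


class TestClassifyCohort:
    def test_noiseless_fully_positive_cohort(self, small_signature):
        # normals (inverse pattern) provide the contrast that survives
        # per-gene cohort standardization
        cohort, _ = sr.gen_signature_cohort(20, 10, small_signature, 1.0, 0.05,
                                            seed=8, log2_effect=2.0)
        cls = sr.classify_cohort(cohort, small_signature, n_resample=200, seed=9)
        tumor_calls = [c for c in cls.calls if c.sample_id.startswith("T")]
        assert all(c.label == sr.ntp.POS for c in tumor_calls)
        normal_calls = [c for c in cls.calls if c.sample_id.startswith("N")]
        assert all(c.label == sr.ntp.NEG for c in normal_calls)

    def test_alpha_zero_leaves_all_unclassified(self, small_signature):
        cohort, _ = sr.gen_signature_cohort(10, 0, small_signature, 1.0, 0.1, seed=10)
        cls = sr.classify_cohort(cohort, small_signature, alpha=0.0,
                                 n_resample=100, seed=11)
        assert all(c.label == sr.ntp.UNCLASSIFIED for c in cls.calls)

    def test_planted_fraction_recovered(self, small_signature):
        errs = []
        for seed in range(5):
            cohort, truth = sr.gen_signature_cohort(60, 0, small_signature, 0.5,
                                                    0.5, seed=seed)
            cls = sr.classify_cohort(cohort, small_signature, n_resample=500,
                                     seed=seed)
            errs.append(abs(cls.proportion_positive - 0.5))
        assert np.mean(errs) <= 0.10


class TestSensSpec:
    def _cls(self, labels):
        calls = [sr.NTPCall(s, 0.1, 1.9, 0.001, 0.001, lab)
                 for s, lab in labels.items()]
        return sr.CohortClassification(calls, alpha=0.05)

    def test_counting(self):
        labels = {f"t{i}": "POS" for i in range(9)}
        labels["t9"] = "NEG"
        labels.update({f"n{i}": ("POS" if i < 2 else "NEG") for i in range(10)})
        truth = {s: ("tumor" if s.startswith("t") else "normal") for s in labels}
        out = sr.sens_spec(self._cls(labels), truth)
        assert out["sensitivity"] == pytest.approx(0.9)
        assert out["specificity"] == pytest.approx(0.8)

    def test_degenerate_all_positive(self):
        labels = {"t0": "POS", "t1": "POS", "n0": "POS"}
        truth = {"t0": "tumor", "t1": "tumor", "n0": "normal"}
        out = sr.sens_spec(self._cls(labels), truth)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 0.0

    def test_missing_class_is_error(self):
        labels = {"t0": "POS"}
        with pytest.raises(DegenerateInputError):
            sr.sens_spec(self._cls(labels), {"t0": "tumor"})

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160):
            labels = {f"t{i}": ("POS" if i < n * 0.7 else "NEG") for i in range(n)}
            labels.update({f"n{i}": "NEG" for i in range(n)})
            truth = {s: ("tumor" if s.startswith("t") else "normal") for s in labels}
            out = sr.sens_spec(self._cls(labels), truth)
            lo, hi = out["sensitivity_ci"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum hypergeometric probabilities of all
    tables with the same margins whose probability <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_hand_enumerated_tables(self):
        assert sr.fisher_2x2([[3, 1], [1, 3]]) == pytest.approx(0.4857, abs=2e-4)
        assert sr.fisher_2x2([[5, 0], [0, 5]]) == pytest.approx(0.0079, abs=2e-4)

    def test_identical_row_proportions_give_p1(self):
        assert sr.fisher_2x2([[4, 8], [2, 4]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_for_small_totals(self):
        for total in range(2, 21, 3):
            for a in range(total + 1):
                for b in range(total + 1 - a):
                    for c in range(total + 1 - a - b):
                        d = total - a - b - c
                        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
                            continue
                        assert sr.fisher_2x2([[a, b], [c, d]]) == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-9), (a, b, c, d)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidConfigError):
            sr.fisher_2x2([[1, -2], [3, 4]])


class TestCohortSummaries:
    def test_reported_row_means(self):
        # across-dataset means of the reported signature-positive percentages
        assert sr.mean_across_datasets(
            [53.9, 55.8, 44.5, 50.6, 58.2, 53.3], decimals=1) == 52.7
        assert sr.mean_across_datasets(
            [25.2, 60.5, 50.1, 62.1, 40.7, 40.0], decimals=1) == 46.4
        assert sr.mean_across_datasets([7.0]) == 7.0

    def test_reference_table_summary(self):
        table = load_cohort_reference()
        assert set(table.signature) == {"Huh7-R-A7", "HepG2-R", "HCC-3sp-R", "Xeno-R"}
        summary = summarize_cohort_reference(table).set_index("signature")
        assert summary.loc["Huh7-R-A7", "mean_pct_positive"] == 52.7
        assert summary.loc["Xeno-R", "mean_sensitivity"] == 0.73
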