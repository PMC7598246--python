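"""Signature-extraction pipeline: filters, moderated t, multiplicity, TMM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sigrev as sr
from sigrev.exceptions import (
    DegenerateInputError,
    InvalidConfigError,
    WrongScaleError,
)


def _matrix(values, groups=None, scale="log2", samples=None):
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples)
    g = pd.Series(groups, index=samples) if groups is not None else None
    return sr.ExpressionMatrix(df, g, scale)


class TestNoiseFilter:
    def test_all_below_cutoff_removed_and_partial_kept(self):
        m = _matrix([[5.0] * 10, [7.0] * 8 + [5.0] * 2, [8.0] * 10])
        out = sr.noise_filter(m, cutoff=6, fraction=0.85)
        assert list(out.values.index) == ["g1", "g2"]

    def test_boundary_fraction_is_inclusive(self):
        # 9 of 10 samples below (90% >= 85%) -> removed
        m = _matrix([[5.0] * 9 + [7.0]])
        assert sr.noise_filter(m).values.empty

    def test_rejects_count_scale(self):
        m = _matrix([[5, 5, 5]], scale="count")
        with pytest.raises(WrongScaleError):
            sr.noise_filter(m)


class TestCollapseProbes:
    def test_mean_identity_and_unmapped_drop(self):
        m = _matrix([[2.0, 2.0], [4.0, 4.0], [1.0, 1.0], [9.0, 9.0]])
        out = sr.collapse_probes(m, {"g0": "A", "g1": "A", "g2": "B"})
        assert out.values.loc["A"].tolist() == [3.0, 3.0]
        assert out.values.loc["B"].tolist() == [1.0, 1.0]
        assert "g3" not in out.values.index and len(out.values) == 2

    def test_three_probe_mean(self):
        m = _matrix([[1.0], [2.0], [6.0]])
        out = sr.collapse_probes(m, {"g0": "A", "g1": "A", "g2": "A"})
        assert out.values.loc["A", "s0"] == pytest.approx(3.0)

    def test_empty_mapping_is_an_error(self):
        with pytest.raises(InvalidConfigError):
            sr.collapse_probes(_matrix([[1.0]]), {})


class TestModeratedT:
    def test_identical_group_means_give_t0_p1(self):
        x = np.tile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], (5, 1))
        m = _matrix(x, ["case"] * 3 + ["control"] * 3)
        de = sr.moderated_ttest(m)
        assert np.allclose(de.table["t"], 0.0)
        assert np.allclose(de.table["p"], 1.0)

    def test_zero_prior_df_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(11)
        x = rng.normal(8, 1, size=(40, 8))
        m = _matrix(x, ["case"] * 4 + ["control"] * 4)
        de = sr.moderated_ttest(m, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(x[:, :4], x[:, 4:], axis=1, equal_var=True)
        assert np.allclose(de.table["t"], t_ref)
        assert np.allclose(de.table["p"], p_ref)

    def test_matches_limma_on_frozen_fixture(self):
        # fixture regenerated bit-identically; oracle values frozen from
        # limma 3.58.1 lmFit/eBayes on the same matrix
        rng = np.random.default_rng(42)
        sd = np.exp(rng.normal(-1, 0.5, size=50))
        x = rng.normal(8, 1, size=(50, 1)) + rng.normal(0, 1, size=(50, 6)) * sd[:, None]
        x[:5, :3] += 2.0
        m = _matrix(x, ["case"] * 3 + ["control"] * 3)
        de = sr.moderated_ttest(m)
        assert de.df_prior == pytest.approx(4.189575, abs=1e-5)
        assert de.s2_prior == pytest.approx(0.1102965, abs=1e-6)
        # spot-check moderated t / p of the first genes from the limma run
        expected = {0: (7.27950443, 7.597955e-05),
                    1: (8.70112229, 2.051662e-05),
                    2: (6.33326256, 2.033614e-04)}
        for i, (t, p) in expected.items():
            assert de.table["t"].iloc[i] == pytest.approx(t, rel=1e-6)
            assert de.table["p"].iloc[i] == pytest.approx(p, rel=1e-5)

    def test_null_pvalues_uniform(self):
        cfg = sr.SimConfig(n_genes=2000, de_fraction=0.0, log2_effect=0.0,
                           noise_sd=0.5, seed=5)
        m, _ = sr.gen_two_group_matrix(cfg)
        de = sr.moderated_ttest(m)
        assert stats.kstest(de.table["p"], "uniform").pvalue > 0.01

    def test_single_sample_group_is_an_error(self):
        m = _matrix(np.ones((3, 3)), ["case", "control", "control"])
        with pytest.raises(DegenerateInputError):
            sr.moderated_ttest(m)


class TestMultiplicity:
    def test_mean_fp_cutoff_is_k_over_g(self):
        assert sr.control_mean_fp(np.linspace(0, 1, 10000), k=1) == pytest.approx(1e-4)
        assert sr.control_mean_fp([0.5] * 10) == pytest.approx(0.1)
        with pytest.raises(InvalidConfigError):
            sr.control_mean_fp([0.5], k=0)

    def test_bh_hand_computed_stepup(self):
        out = sr.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])
        assert sr.bh_fdr([0.03]).iloc[0] == pytest.approx(0.03)
        assert np.allclose(sr.bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_bh_order_invariant(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(sr.bh_fdr(p).to_numpy()[perm], sr.bh_fdr(p[perm]))

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(InvalidConfigError):
            sr.bh_fdr([0.5, 1.5])


class TestFoldChangeFilter:
    def test_rule_application(self, two_group_matrix):
        de = sr.moderated_ttest(two_group_matrix)
        tab = de.table.copy()
        tab.loc[:, "fold_change"] = [4.0, 0.2, 2.0, 1.0, 3.01, 0.25, 0.24, 5.0]
        tab.loc[:, "log2fc"] = np.log2(tab["fold_change"])
        de2 = sr.DEResult(tab, de.s2_prior, de.df_prior, de.df_residual)
        up, down = sr.fold_change_filter(de2)
        assert set(up) == {"G00000", "G00004", "G00007"}
        assert set(down) == {"G00001", "G00006"}  # 0.25 is not < 0.25

    def test_invalid_thresholds(self, two_group_matrix):
        de = sr.moderated_ttest(two_group_matrix)
        with pytest.raises(InvalidConfigError):
            sr.fold_change_filter(de, up_min=0.2, down_max=0.25)


class TestCountFilter:
    def test_low_count_rules(self):
        m = _matrix([[4, 4, 6, 9, 9, 9],    # two below in group a -> removed
                     [5, 5, 0, 9, 9, 9],    # only one below -> kept
                     [9, 9, 9, 9, 9, 9]],   # no-op
                    ["a"] * 3 + ["b"] * 3, scale="count")
        out = sr.count_filter(m)
        assert list(out.values.index) == ["g1", "g2"]

    def test_requires_counts(self, two_group_matrix):
        with pytest.raises(WrongScaleError):
            sr.count_filter(two_group_matrix)


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(100, size=30)
        m = _matrix(np.column_stack([col, col]), scale="count")
        assert np.allclose(sr.tmm_normalize(m), 1.0)

    def test_global_doubling_absorbed_by_library_size(self):
        # doubling every count doubles the library size, so composition is
        # unchanged and TMM factors stay {1, 1} (edgeR-verified)
        rng = np.random.default_rng(2)
        col = rng.poisson(200, size=40) + 1
        m = _matrix(np.column_stack([col, 2 * col]), scale="count")
        assert np.allclose(sr.tmm_normalize(m), 1.0)

    def test_matches_edger_on_frozen_fixture(self):
        # frozen from edgeR 4.0.16 calcNormFactors(method="TMM")
        rng = np.random.default_rng(42)
        rng.normal(-1, 0.5, size=50)          # advance stream as in generation
        rng.normal(8, 1, size=(50, 1))
        rng.normal(0, 1, size=(50, 6))
        mu = rng.gamma(2, 100, size=30)
        counts = rng.poisson(mu[:, None] * np.array([1.0, 1.3, 0.7, 2.0])[None, :]
                             * np.exp(rng.normal(0, 0.3, size=(30, 4))))
        m = _matrix(counts, scale="count")
        expected = [0.9940322952, 0.9791912131, 0.9871603779, 1.0407448784]
        assert np.allclose(sr.tmm_normalize(m), expected, atol=1e-8)

    def test_factors_positive_geometric_mean_one(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.poisson(50, size=(100, 5)), scale="count")
        f = sr.tmm_normalize(m).to_numpy()
        assert (f > 0).all()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_is_degenerate(self):
        m = _matrix([[0, 5], [0, 5]], scale="count")
        with pytest.raises(DegenerateInputError):
            sr.tmm_normalize(m)


class TestBuildSignature:
    def test_noiseless_recovery_of_planted_sets(self):
        cfg = sr.SimConfig(n_genes=200, de_fraction=0.1, log2_effect=2.5,
                           noise_sd=1e-6, baseline_mean=8.0, seed=4)
        m, truth = sr.gen_two_group_matrix(cfg)
        de = sr.moderated_ttest(m)
        sig = sr.build_signature(de, p_cutoff=sr.control_mean_fp(de.table["p"]),
                                 fc_up=3.0, fc_down=1 / 3)
        assert set(sig.up) == truth.de_up
        assert set(sig.down) == truth.de_down

    def test_thresholds_recorded(self, two_group_matrix):
        de = sr.moderated_ttest(two_group_matrix)
        sig = sr.build_signature(de, p_cutoff=0.5, fc_up=1.5, fc_down=0.5)
        assert sig.thresholds == {"p_cutoff": 0.5, "fc_up": 1.5, "fc_down": 0.5}
        assert "p<0.5" in sig.provenance

    def test_tie_break_is_lexicographic(self):
        tab = pd.DataFrame({
            "log2fc": [2.0, 2.0, -2.0, -2.0],
            "fold_change": [4.0, 4.0, 0.25, 0.25],
            "t": [5.0, 5.0, -5.0, -5.0],
            "p": [1e-6] * 4,
            "adj_p": [1e-6] * 4,
            "s2": [0.1] * 4,
        }, index=["gB", "gA", "gD", "gC"])
        de = sr.DEResult(tab, 0.1, 1.0, 4.0)
        sig = sr.build_signature(de, p_cutoff=0.01, fc_up=2.0, fc_down=0.5)
        assert sig.up == ["gA", "gB"]
        assert sig.down == ["gC", "gD"]


def test_pipeline_recovers_planted_signature_over_seeds():
    """noise_filter -> collapse -> moderated t -> mean-FP cutoff -> FC filter
    recovers planted DE genes (sensitivity >= 0.9, FDR <= 0.1, 20 seeds).

    FC cutoffs (2, 0.5) sit inside the planted |log2FC| = 2 so the filter
    tests direction, not a knife-edge against the planted effect itself.
    """
    hits = planted_total = false = called = 0
    for seed in range(20):
        cfg = sr.SimConfig(n_genes=1000, de_fraction=0.05, log2_effect=2.0,
                           noise_sd=0.5, n_samples_per_group=3, seed=seed)
        m, truth = sr.gen_two_group_matrix(cfg)
        probe_map = {g: g for g in m.values.index}
        m = sr.collapse_probes(sr.noise_filter(m), probe_map)
        de = sr.moderated_ttest(m)
        sig = sr.build_signature(de, p_cutoff=sr.control_mean_fp(de.table["p"]),
                                 fc_up=2.0, fc_down=0.5)
        detected = set(sig.up) | set(sig.down)
        planted = truth.de_up | truth.de_down
        hits += len(detected & planted)
        planted_total += len(planted)
        false += len(detected - planted)
        called += len(detected)
    assert hits / planted_total >= 0.9
    assert false / max(1, called) <= 0.1
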