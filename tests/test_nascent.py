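"""Quantification arithmetic, pausing indices, DE calls, metagenes, U tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hypoxpipe import nascent
from hypoxpipe.nascent import (
    classify_de, compare_distributions, de_test, filter_low_expression,
    fold_changes, gene_cpm, metagene_profile, normalize_cpm_per_bp,
    pausing_index,
)
from conftest import make_rcm


class TestNormalization:
    def test_hand_computed_cpm_per_bp(self):
        m = make_rcm([[100]], [550], library_sizes=[1_000_000])
        val = normalize_cpm_per_bp(m).iloc[0, 0]
        assert val == pytest.approx(100 / 550, abs=1e-12)

    def test_zero_counts_give_zero(self):
        m = make_rcm([[0, 7]], [100], library_sizes=[1e6, 1e6])
        assert normalize_cpm_per_bp(m).iloc[0, 0] == 0.0

    def test_doubling_library_halves_values(self):
        m1 = make_rcm([[40], [60]], [100, 200], library_sizes=[1e6])
        m2 = make_rcm([[40], [60]], [100, 200], library_sizes=[2e6])
        assert np.allclose(normalize_cpm_per_bp(m1), 2 * normalize_cpm_per_bp(m2))

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError, match="region_lengths"):
            make_rcm([[1]], [0])


class TestLowExpressionFilter:
    def test_gene_below_threshold_everywhere_excluded(self):
        # 0.4 cpm in both samples of a 1e6-read library
        m = make_rcm([[0, 0], [1000, 1000]], [100, 100],
                     library_sizes=[1e6, 1e6])
        m.counts.iloc[0] = [0, 0]
        kept = filter_low_expression(m, 0.5)
        assert list(kept) == ["g1"]

    def test_single_sample_above_threshold_retains(self):
        m = make_rcm([[0, 1]], [100], library_sizes=[1e6, 1e6])
        # 1 count in 1e6 reads = 1 cpm >= 0.5 in one sample
        assert list(filter_low_expression(m, 0.5)) == ["g0"]

    def test_zero_threshold_keeps_everything(self):
        m = make_rcm([[0, 0], [5, 5]], [100, 100], library_sizes=[1e6, 1e6])
        assert len(filter_low_expression(m, 0.0)) == 2


class TestPausingIndex:
    def test_equal_densities_give_unit_pi(self):
        tss = make_rcm([[55]], [550], "tss", library_sizes=[1e6])
        body = make_rcm([[1000]], [10_000], "body", library_sizes=[1e6])
        pt = pausing_index(tss, body)
        assert pt["pi"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_toy_pi_is_40(self):
        tss = make_rcm([[110]], [550], "tss", library_sizes=[1e6])
        body = make_rcm([[50]], [10_000], "body", library_sizes=[1e6])
        assert pausing_index(tss, body)["pi"].iloc[0] == pytest.approx(40.0, abs=1e-12)

    def test_zero_body_density_flagged_nan(self):
        tss = make_rcm([[10]], [550], "tss", library_sizes=[1e6])
        body = make_rcm([[0]], [10_000], "body", library_sizes=[1e6])
        assert np.isnan(pausing_index(tss, body)["pi"].iloc[0])

    def test_uniform_count_scaling_cancels(self, nascent_counts):
        tss, body = nascent_counts["tss"], nascent_counts["body"]
        pi1 = pausing_index(tss, body)["pi"]
        s = tss.counts.columns[0]
        tss2 = make_scaled(tss, s, 7)
        body2 = make_scaled(body, s, 7)
        pi2 = pausing_index(tss2, body2)["pi"]
        np.testing.assert_allclose(pi1.to_numpy(), pi2.to_numpy(), rtol=1e-12)

    def test_misaligned_gene_sets_rejected(self):
        tss = make_rcm([[1], [2]], [550, 550], "tss")
        body = make_rcm([[1]], [1000], "body")
        with pytest.raises(ValueError, match="gene sets"):
            pausing_index(tss, body)


def make_scaled(rcm, sample, factor):
    counts = rcm.counts.copy()
    counts[sample] = counts[sample] * factor
    lib = rcm.library_sizes.copy()
    lib[sample] = lib[sample] * factor
    from hypoxpipe.nascent import RegionCountMatrix
    return RegionCountMatrix(rcm.region_class, counts, rcm.region_lengths,
                             lib, rcm.samples)


class TestFoldChanges:
    def test_identical_groups_have_zero_fold_change(self):
        tss = make_rcm([[10, 10]], [550], "tss", library_sizes=[1e6, 1e6])
        body = make_rcm([[40, 40]], [2000], "body", library_sizes=[1e6, 1e6])
        fc = fold_changes(tss, body, ["s0"], ["s1"])
        assert np.allclose(fc.to_numpy(), 0.0)

    def test_body_doubling_flips_pi_fold_change(self):
        tss = make_rcm([[1000, 1000]], [550], "tss", library_sizes=[1e6, 1e6])
        body = make_rcm([[4000, 8000]], [2000], "body", library_sizes=[1e6, 1e6])
        fc = fold_changes(tss, body, ["s0"], ["s1"], pseudocount=0.0)
        assert fc["log2fc_body"].iloc[0] == pytest.approx(1.0)
        assert fc["log2fc_tss"].iloc[0] == pytest.approx(0.0)
        assert fc["log2fc_pi"].iloc[0] == pytest.approx(-1.0)

    def test_unknown_sample_raises(self):
        tss = make_rcm([[1, 1]], [550], "tss")
        body = make_rcm([[1, 1]], [550], "body")
        with pytest.raises(ValueError, match="absent"):
            fold_changes(tss, body, ["s0"], ["nope"])


class TestClassifyDe:
    @pytest.mark.parametrize(
        "q,fc,label",
        [(0.05, 2.0, "up"), (0.05, 0.5, "down"), (0.5, 3.0, "ns"),
         (0.05, 1.2, "ns")],
    )
    def test_threshold_rules(self, q, fc, label):
        out = classify_de(pd.Series({"g": np.log2(fc)}), pd.Series({"g": q}))
        assert out.loc["g", "label"] == label

    def test_missing_q_set_to_ns(self):
        out = classify_de(pd.Series({"g": 2.0, "h": 2.0}),
                          pd.Series({"g": 0.01}))
        assert out.loc["h", "label"] == "ns"
        assert out.loc["g", "label"] == "up"

    def test_builtin_test_requires_replicates(self):
        m = make_rcm([[5, 6]], [100])
        with pytest.raises(ValueError, match="replicates"):
            de_test(m, ["s0"], ["s1"])


class TestMetagene:
    def _flat_signal(self, value=2.0):
        return pd.DataFrame(dict(chrom=["chr1"], start=[0], end=[100_000],
                                 value=[value]))

    def _models(self, strands=("+", "+")):
        return pd.DataFrame([
            dict(gene_id=f"g{i}", chrom="chr1", strand=s, tss=20_000 + 7000 * i,
                 body_start=21_001 + 7000 * i, body_end=25_000 + 7000 * i)
            for i, s in enumerate(strands)])

    def test_constant_signal_gives_flat_profile(self):
        prof = metagene_profile(self._flat_signal(), self._flat_signal(),
                                self._models(), window=1000, n_bins=20)
        assert np.allclose(prof["mean"], 2.0)
        assert np.allclose(prof["hi"] - prof["lo"], 0.0, atol=1e-9)

    def test_single_gene_profile_equals_its_signal(self):
        sig = pd.DataFrame(dict(chrom=["chr1"], start=[20_000], end=[20_500],
                                value=[3.0]))
        prof = metagene_profile(sig, sig.iloc[0:0], self._models(("+",)),
                                window=1000, n_bins=20)
        inside = (prof["bin"] >= 50) & (prof["bin"] < 450)
        assert np.allclose(prof.loc[inside, "mean"], 3.0)
        assert np.allclose(prof.loc[prof["bin"] < -100, "mean"], 0.0)

    def test_strand_flip_equivariance(self):
        # signal upstream-heavy for + genes; mirrored setup for - genes
        plus_sig = pd.DataFrame(dict(chrom=["chr1"], start=[20_000], end=[20_600],
                                     value=[5.0]))
        m_plus = self._models(("+",))
        prof_plus = metagene_profile(plus_sig, plus_sig.iloc[0:0], m_plus,
                                     window=1000, n_bins=20)
        m_minus = m_plus.assign(strand="-")
        minus_sig = pd.DataFrame(dict(chrom=["chr1"], start=[19_400], end=[20_000],
                                      value=[5.0]))
        prof_minus = metagene_profile(minus_sig.iloc[0:0], minus_sig, m_minus,
                                      window=1000, n_bins=20)
        np.testing.assert_allclose(prof_plus["mean"], prof_minus["mean"])

    def test_empty_gene_set_raises(self):
        with pytest.raises(ValueError, match="empty gene set"):
            metagene_profile(self._flat_signal(), self._flat_signal(),
                             self._models().iloc[0:0])


class TestMannWhitney:
    def test_identical_samples_give_p_one_r_zero(self):
        out = compare_distributions([1, 2, 3], [1, 2, 3])
        assert out["p"] == pytest.approx(1.0)
        assert out["r"] == pytest.approx(0.0)

    def test_fully_separated_small_groups_exact_p(self):
        out = compare_distributions([1, 2, 3], [4, 5, 6])
        assert out["method"] == "exact"
        assert out["u"] == 0.0
        assert out["p"] == pytest.approx(0.1, abs=1e-12)  # 2 * 1/20
        assert out["r"] == pytest.approx(-1.0)

    def test_all_tied_degenerate(self):
        out = compare_distributions([5, 5, 5], [5, 5, 5])
        assert out["p"] == 1.0 and out["r"] == 0.0

    def test_exact_and_normal_approximation_agree(self):
        from scipy import stats
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(size=8)
            b = rng.normal(0.5, size=8)
            exact = stats.mannwhitneyu(a, b, method="exact").pvalue
            approx = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
            assert abs(exact - approx) <= 0.02

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_distributions([1, 2], [3, 4, 5])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(1, 10_000), st.floats(0.1, 100.0))
def test_pi_library_invariance_property(scale, density):
    """PI never depends on per-sample depth (library factor cancels)."""
    tss = make_rcm([[int(110 * density)]], [550], "tss", library_sizes=[1e6])
    body = make_rcm([[50]], [10_000], "body", library_sizes=[1e6])
    pi1 = pausing_index(tss, body)["pi"].iloc[0]
    tss2 = make_scaled(tss, "s0", scale)
    body2 = make_scaled(body, "s0", scale)
    pi2 = pausing_index(tss2, body2)["pi"].iloc[0]
    assert pi2 == pytest.approx(pi1, rel=1e-12)
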