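"""Association-factor arithmetic, peak classes, scaling, overlap statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hypoxpipe import peaklink
from hypoxpipe.peaklink import (
    acute_late_partition, association_factor, classify_peak_gene,
    common_peak_scaling, conservation_groups, nearest_tss, overlap_stats,
)


class TestAssociationFactor:
    def test_zero_distance_returns_pnrd(self):
        assert association_factor(1.0, 0) == pytest.approx(1.0, abs=1e-15)

    def test_one_decay_length(self):
        assert association_factor(0.5, 500, d0=500) == pytest.approx(
            0.5 * np.exp(-1.0), abs=1e-12)

    def test_half_distance_is_d0_ln2(self):
        d_half = 500 * np.log(2)
        assert association_factor(2.0, d_half) == pytest.approx(1.0, abs=1e-12)
        assert association_factor(2.0, 1000 + d_half) == pytest.approx(
            association_factor(2.0, 1000) / 2, abs=1e-12)

    def test_growing_form_available(self):
        assert association_factor(1.0, 500, d0=500, decay=False) == pytest.approx(
            np.e, abs=1e-12)

    def test_invalid_d0_rejected(self):
        with pytest.raises(ValueError, match="d0"):
            association_factor(1.0, 100, d0=0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0.01, 100), st.floats(0, 1e5), st.floats(1, 1e4))
    def test_decay_monotone_and_bounded(self, pnrd, dc, step):
        a1 = association_factor(pnrd, dc)
        a2 = association_factor(pnrd, dc + step)
        assert 0 <= a2 < a1 <= pnrd


class TestClassifyPeakGene:
    @pytest.mark.parametrize(
        "af,dc,expected",
        [
            (0.2, 100, "proximal"),
            (0.05, 6_000, "distal"),
            (0.05, 60_000, "intergenic"),
            (0.05, 2_000, "other"),
            (0.05, 5_000, "distal"),   # closed lower bound
            (0.05, 50_000, "distal"),  # closed upper bound
            (0.05, 50_001, "intergenic"),
        ],
    )
    def test_class_rules(self, af, dc, expected):
        links = pd.DataFrame(dict(af=[af], dc=[dc]))
        assert classify_peak_gene(links).iloc[0] == expected

    def test_classes_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(1)
        links = pd.DataFrame(dict(af=rng.uniform(0, 0.3, 500),
                                  dc=rng.uniform(0, 80_000, 500)))
        klass = classify_peak_gene(links)
        assert klass.isin(["proximal", "distal", "intergenic", "other"]).all()


def test_nearest_tss_picks_closest_gene():
    models = pd.DataFrame([
        dict(gene_id="a", chrom="chr1", strand="+", tss=10_000),
        dict(gene_id="b", chrom="chr1", strand="-", tss=50_000),
    ])
    peaks = pd.DataFrame([
        dict(peak_id="p1", chrom="chr1", center=12_000),
        dict(peak_id="p2", chrom="chr1", center=49_000),
        dict(peak_id="p3", chrom="chr9", center=100),
    ])
    out = nearest_tss(peaks, models).set_index("peak_id")
    assert out.loc["p1", "gene_id"] == "a" and out.loc["p1", "dc"] == 2000
    assert out.loc["p2", "gene_id"] == "b"
    # signed distance is in transcription direction: peak upstream of a '-' TSS
    assert out.loc["p2", "dc_signed"] == 1000
    assert np.isinf(out.loc["p3", "dc"])


class TestCommonPeakScaling:
    def _peaks(self, tags):
        return pd.DataFrame(dict(chrom="chr1", start=[100, 5000],
                                 end=[600, 5400], tags=tags))

    def test_identical_samples_give_unit_factors(self):
        sets = {"a": self._peaks([10, 20]), "b": self._peaks([10, 20])}
        out = common_peak_scaling(sets)
        assert np.allclose(out["factor"], 1.0)

    def test_two_to_one_tags_give_4_3_and_2_3(self):
        sets = {"a": self._peaks([20, 40]), "b": self._peaks([10, 20])}
        out = common_peak_scaling(sets)
        assert out.loc["a", "factor"] == pytest.approx(4 / 3)
        assert out.loc["b", "factor"] == pytest.approx(2 / 3)

    def test_factors_average_to_one(self):
        rng = np.random.default_rng(2)
        sets = {s: self._peaks(rng.integers(1, 100, 2)) for s in "abcd"}
        assert common_peak_scaling(sets)["factor"].mean() == pytest.approx(1.0)

    def test_threshold_adjustment_scales_base(self):
        sets = {"a": self._peaks([20, 40]), "b": self._peaks([10, 20])}
        out = common_peak_scaling(sets, base_threshold=6.0)
        assert out.loc["a", "adjusted_threshold"] == pytest.approx(8.0)

    def test_disjoint_peak_sets_raise_with_diagnostic(self):
        a = pd.DataFrame(dict(chrom="chr1", start=[0], end=[100], tags=[5]))
        b = pd.DataFrame(dict(chrom="chr1", start=[500], end=[600], tags=[5]))
        with pytest.raises(ValueError, match="pairwise overlaps"):
            common_peak_scaling({"a": a, "b": b})


class TestOverlapStats:
    def test_balanced_table_is_null(self):
        u = [f"g{i}" for i in range(40)]
        a = u[:20]
        b = u[10:30]
        out = overlap_stats(a, b, u)
        assert out["table"].tolist() == [[10, 10], [10, 10]]
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_perfect_overlap_capped_or_tiny_p(self):
        u = [f"g{i}" for i in range(100)]
        a = u[:20]
        out = overlap_stats(a, a, u)
        assert np.isinf(out["odds_ratio"]) and out["or_capped"]
        assert out["p"] < 1e-15

    def test_symmetric_in_set_order(self):
        u = [f"g{i}" for i in range(60)]
        a, b = u[:25], u[15:40]
        ab = overlap_stats(a, b, u)
        ba = overlap_stats(b, a, u)
        assert ab["p"] == pytest.approx(ba["p"], abs=1e-12)
        assert ab["odds_ratio"] == pytest.approx(ba["odds_ratio"])

    def test_matches_reference_exact_test(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n11, n10, n01, n00 = rng.integers(0, 15, 4)
            table = np.array([[n11, n10], [n01, n00]])
            if table.sum() == 0:
                continue
            mine = peaklink._fisher_exact_p(table)
            ref = stats.fisher_exact(table).pvalue
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_stats([], [], [])


class TestPartitions:
    def test_equal_sets_leave_only_acute(self):
        out = acute_late_partition({"a", "b"}, {"a", "b"})
        assert out["acute"] == {"a", "b"}
        assert not out["late"] and not out["nascent_only"]

    def test_disjoint_sets_have_empty_acute(self):
        out = acute_late_partition({"a"}, {"b"})
        assert not out["acute"]
        assert out["late"] == {"b"} and out["nascent_only"] == {"a"}

    def test_partition_is_disjoint_cover(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        nasc = set(rng.choice(genes, 20, replace=False))
        mrna = set(rng.choice(genes, 25, replace=False))
        out = acute_late_partition(nasc, mrna)
        assert out["acute"] | out["late"] | out["nascent_only"] == nasc | mrna
        assert not (out["acute"] & out["late"])
        assert not (out["acute"] & out["nascent_only"])


class TestConservationGroups:
    CALLS = {
        "HCT116": {"core1", "s3", "s2", "solo"},
        "RKO": {"core1", "s3", "s2"},
        "A549": {"core1", "s3"},
        "H460": {"core1"},
    }

    def test_group_assignment(self):
        out = conservation_groups(self.CALLS, "HCT116").set_index("gene_id")
        assert out.loc["core1", "group"] == "core"
        assert out.loc["s3", "group"] == "shared3"
        assert out.loc["s2", "group"] == "shared2"
        assert out.loc["solo", "group"] == "reference_only"

    def test_groups_partition_reference_up_genes(self):
        out = conservation_groups(self.CALLS, "HCT116")
        assert len(out) == len(self.CALLS["HCT116"])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            conservation_groups(self.CALLS, "HeLa")


def test_enhancer_productivity_follows_linked_gene_class(gene_sim, small_config):
    """Distal peaks are productive iff a linked gene is up; productive windows
    gain more signal under the induced condition."""
    from hypoxpipe import annotation, simulate
    peaks = simulate.simulate_peaks(gene_sim.truth, small_config)
    models = annotation.build_annotation(gene_sim.transcripts, gene_sim.tss_counts)
    links = peaklink.link_peaks(peaks.peaks, models)
    truth = gene_sim.truth.set_index("gene_id")
    de_labels = pd.Series(np.where(truth["induced"], "up", "ns"), index=truth.index)
    calls = peaklink.classify_enhancer_productivity(
        links, de_labels, peaks.signal, peaks.peaks)
    merged = calls.merge(peaks.truth, on="peak_id")
    assert ((merged["productivity"] == "productive")
            == merged["productive"].astype(bool)).all()
    fc = merged["window_signal_hypoxia"] / merged["window_signal_normoxia"]
    prod = merged["productivity"] == "productive"
    assert fc[prod].median() > fc[~prod].median()
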