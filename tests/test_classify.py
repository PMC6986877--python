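"""GBR classification rules, TSS distribution test, accessibility tests."""

import math

import numpy as np
import pandas as pd
import pytest

from glireg.classify import (
    LABELS,
    accessibility_compare,
    annotate_promoters,
    classify_gbrs,
    mean_tissues_per_class,
    summarize_classes,
    tss_distribution_test,
)
from glireg.intervals import GeneAnnotation, GenomicInterval, RegionSet
from glireg.diff import DIFF_COLUMNS


def diff_row(region_id, start, end, q=0.5, log2fc=0.0, presence_a=True,
             presence_b=True, chrom="chr1"):
    peak_type = {
        (True, True): "shared", (True, False): "a_only",
        (False, True): "b_only", (False, False): "neither",
    }[(presence_a, presence_b)]
    return (
        region_id, chrom, start, end, 5.0, 5.0 - log2fc, log2fc,
        0.0, 10.0, q, q, presence_a, presence_b, peak_type,
    )


def diff_table(rows):
    return pd.DataFrame(rows, columns=DIFF_COLUMNS)


def gbr_set(*spans, chrom="chr1"):
    return RegionSet(
        GenomicInterval(chrom, s, e, id=f"gbr{i}") for i, (s, e) in enumerate(spans)
    )


class TestClassifyRules:
    def test_no_overlapping_acetylation(self):
        gbrs = gbr_set((0, 1000))
        diff = diff_table([diff_row("m1", 50_000, 51_000)])
        out = classify_gbrs(gbrs, diff)
        assert out.loc[0, "label"] == "non_acetylated"

    def test_presence_a_false_is_not_acetylated(self):
        gbrs = gbr_set((0, 1000))
        diff = diff_table([diff_row("m1", 0, 1000, presence_a=False, presence_b=True)])
        assert classify_gbrs(gbrs, diff).loc[0, "label"] == "non_acetylated"

    def test_complete_absence_is_dependent(self):
        gbrs = gbr_set((0, 1000))
        diff = diff_table([diff_row("m1", 0, 1000, q=0.001, log2fc=2.0,
                                    presence_b=False)])
        assert classify_gbrs(gbrs, diff).loc[0, "label"] == "hh_dependent"

    def test_significant_reduction_is_sensitive(self):
        gbrs = gbr_set((0, 1000))
        diff = diff_table([diff_row("m1", 0, 1000, q=0.01, log2fc=1.2)])
        assert classify_gbrs(gbrs, diff).loc[0, "label"] == "hh_sensitive"

    def test_non_significant_is_stable(self):
        gbrs = gbr_set((0, 1000))
        diff = diff_table([diff_row("m1", 0, 1000, q=0.5, log2fc=1.2)])
        assert classify_gbrs(gbrs, diff).loc[0, "label"] == "stable"

    def test_negative_fold_change_is_stable(self):
        gbrs = gbr_set((0, 1000))
        diff = diff_table([diff_row("m1", 0, 1000, q=0.01, log2fc=-1.2)])
        assert classify_gbrs(gbrs, diff).loc[0, "label"] == "stable"

    def test_dependent_requires_all_regions_absent(self):
        # one vanished region + one retained region -> sensitive, not dependent
        gbrs = gbr_set((0, 2000))
        diff = diff_table([
            diff_row("m1", 0, 900, q=0.001, log2fc=2.0, presence_b=False),
            diff_row("m2", 1000, 2000, q=0.01, log2fc=1.0),
        ])
        assert classify_gbrs(gbrs, diff).loc[0, "label"] == "hh_sensitive"

    def test_labels_partition_gbrs(self):
        rng = np.random.default_rng(15)
        gbrs = gbr_set(*[(i * 3000, i * 3000 + 1000) for i in range(40)])
        rows = []
        for i in range(60):
            start = int(rng.integers(0, 120_000))
            rows.append(diff_row(
                f"m{i}", start, start + 800,
                q=float(rng.random()), log2fc=float(rng.normal()),
                presence_a=bool(rng.random() < 0.8),
                presence_b=bool(rng.random() < 0.8),
            ))
        out = classify_gbrs(gbrs, diff_table(rows))
        assert len(out) == len(gbrs)
        assert out["label"].isin(LABELS).all()

    def test_null_differential_forces_no_responsive_labels(self):
        gbrs = gbr_set(*[(i * 3000, i * 3000 + 1000) for i in range(10)])
        rows = [diff_row(f"m{i}", i * 3000, i * 3000 + 1000, q=1.0, log2fc=0.0)
                for i in range(10)]
        out = classify_gbrs(gbrs, diff_table(rows))
        assert set(out["label"]) == {"stable"}

    def test_empty_gbr_set_rejected(self):
        with pytest.raises(ValueError):
            classify_gbrs(RegionSet(), diff_table([diff_row("m1", 0, 1000)]))

    def test_fdr_threshold_respected(self):
        gbrs = gbr_set((0, 1000))
        diff = diff_table([diff_row("m1", 0, 1000, q=0.04, log2fc=1.0)])
        assert classify_gbrs(gbrs, diff, fdr=0.05).loc[0, "label"] == "hh_sensitive"
        assert classify_gbrs(gbrs, diff, fdr=0.01).loc[0, "label"] == "stable"


class TestTssDistribution:
    @staticmethod
    def _setup(n_stable=6, n_resp=4, proximal_stable=4, proximal_resp=1):
        """Plant GBRs so the 2x2 table is fixed by construction."""
        genes, gbr_ivs, labels = [], [], []
        pos = 10_000
        idx = 0

        def add(label, proximal):
            nonlocal pos, idx
            gene = GeneAnnotation(f"g{idx}", "chr1", "+", pos + 2000)
            genes.append(gene)
            if proximal:
                start = pos + 500  # inside [tss-2000, tss+1000)
            else:
                start = pos + 6000  # clear of the window
            gbr_ivs.append(GenomicInterval("chr1", start, start + 500, id=f"gbr{idx}"))
            labels.append(label)
            pos += 20_000
            idx += 1

        for i in range(n_stable):
            add("stable", i < proximal_stable)
        for i in range(n_resp):
            add("hh_sensitive" if i % 2 else "hh_dependent", i < proximal_resp)
        gbrs = RegionSet(gbr_ivs)
        classes = pd.DataFrame({
            "gbr_id": [iv.id for iv in gbr_ivs],
            "label": labels,
        })
        return classes, gbrs, genes

    def test_table_recovered_from_planted_geometry(self):
        classes, gbrs, genes = self._setup()
        table, p = tss_distribution_test(classes, gbrs, genes)
        assert (table.a, table.b, table.c, table.d) == (4, 2, 1, 3)
        assert 0 <= p <= 1

    def test_margins_equal_class_sizes(self):
        classes, gbrs, genes = self._setup(n_stable=8, n_resp=5,
                                           proximal_stable=3, proximal_resp=2)
        table, _ = tss_distribution_test(classes, gbrs, genes)
        assert table.a + table.b == 8
        assert table.c + table.d == 5

    def test_planted_proximity_bias_detected(self):
        classes, gbrs, genes = self._setup(n_stable=40, n_resp=30,
                                           proximal_stable=35, proximal_resp=5)
        _, p = tss_distribution_test(classes, gbrs, genes)
        assert p < 0.05

    def test_both_fully_proximal_gives_one(self):
        classes, gbrs, genes = self._setup(n_stable=5, n_resp=5,
                                           proximal_stable=5, proximal_resp=5)
        _, p = tss_distribution_test(classes, gbrs, genes)
        assert p == pytest.approx(1.0)

    def test_missing_class_rejected(self):
        classes, gbrs, genes = self._setup()
        only_stable = classes[classes["label"] == "stable"]
        with pytest.raises(ValueError, match="responsive"):
            tss_distribution_test(only_stable, gbrs, genes)


class TestAccessibility:
    @staticmethod
    def _frame(labels, a, b):
        classes = pd.DataFrame({"gbr_id": [f"g{i}" for i in range(len(labels))],
                                "label": labels})
        signal = pd.DataFrame(
            {"condition_a": a, "condition_b": b},
            index=[f"g{i}" for i in range(len(labels))],
        )
        return classes, signal

    def test_identical_distributions_symmetric(self):
        labels = ["stable"] * 10 + ["hh_dependent"] * 10
        vals = list(range(10)) + list(range(10))
        classes, signal = self._frame(labels, [float(v) for v in vals],
                                      [float(v) for v in vals])
        out = accessibility_compare(signal, classes).set_index("versus")
        assert out.loc["hh_dependent", "p_signal_a"] == pytest.approx(0.5, abs=0.02)

    def test_extreme_separation_exact_p(self):
        # completely separated untied samples hit the exact enumeration
        # path: one-sided p = 1 / C(12, 6)
        labels = ["stable"] * 6 + ["hh_dependent"] * 6
        a = [12.0, 11.0, 10.0, 9.0, 8.0, 7.0] + [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
        classes, signal = self._frame(labels, a, [0.0] * 12)
        out = accessibility_compare(signal, classes).set_index("versus")
        assert out.loc["hh_dependent", "p_signal_a"] == pytest.approx(
            1 / math.comb(12, 6)
        )

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(16)
        labels = ["stable"] * 200 + ["hh_sensitive"] * 50
        a = np.concatenate([rng.normal(8, 0.5, 200), rng.normal(6.5, 0.5, 50)])
        b = a - np.concatenate([np.zeros(200), np.full(50, 1.0)])
        classes, signal = self._frame(labels, a, b)
        out = accessibility_compare(signal, classes).set_index("versus")
        assert out.loc["hh_sensitive", "p_signal_a"] < 1e-6
        assert out.loc["hh_sensitive", "p_log2_ratio"] < 1e-6

    def test_missing_group_yields_nan(self):
        labels = ["stable"] * 5
        classes, signal = self._frame(labels, [1.0] * 5, [1.0] * 5)
        out = accessibility_compare(signal, classes).set_index("versus")
        assert np.isnan(out.loc["hh_dependent", "p_signal_a"])

    def test_missing_signal_dropped_with_warning(self, caplog):
        labels = ["stable"] * 4 + ["hh_dependent"] * 4
        classes, signal = self._frame(labels, [5.0] * 8, [4.0] * 8)
        signal = signal.drop(index="g0")
        with caplog.at_level("WARNING"):
            out = accessibility_compare(signal, classes)
        assert out.set_index("versus").loc["hh_dependent", "n_stable"] == 3


class TestSummaries:
    def test_summarize_counts(self):
        classes = pd.DataFrame({
            "gbr_id": list("abcdef"),
            "label": ["stable", "stable", "hh_sensitive", "hh_dependent",
                      "non_acetylated", "stable"],
        })
        s = summarize_classes(classes)
        assert s["counts"]["stable"] == 3
        assert s["n_responsive"] == 2
        assert s["n_acetylated"] == 5
        assert s["fraction_stable_of_acetylated"] == pytest.approx(3 / 5)

    def test_mean_tissues_per_class(self):
        # synthetic stand-in reporter table with hand-computed class means
        table = pd.DataFrame({
            "gbr_class": ["hh_responsive"] * 4 + ["stable"] * 5,
            "n_tissues": [1, 2, 2, 3, 2, 3, 3, 4, 2],
        })
        out = mean_tissues_per_class(table)
        assert out["hh_responsive"] == pytest.approx(2.0)
        assert out["stable"] == pytest.approx(2.8)

    def test_mean_tissues_empty(self):
        assert mean_tissues_per_class(pd.DataFrame(columns=["gbr_class", "n_tissues"])) == {}


def test_annotate_promoters_flags():
    gbrs = gbr_set((9_000, 9_500), (50_000, 50_500))
    genes = [GeneAnnotation("g1", "chr1", "+", 10_000)]
    cpg = RegionSet([GenomicInterval("chr1", 9_000, 9_200, id="cpg1")])
    classes = pd.DataFrame({"gbr_id": ["gbr0", "gbr1"], "label": ["stable", "stable"]})
    out = annotate_promoters(classes, gbrs, genes, cpg)
    assert out["promoter_proximal"].tolist() == [True, False]
    assert out["cpg_promoter"].tolist() == [True, False]
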