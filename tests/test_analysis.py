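import math

import numpy as np
import pandas as pd
import pytest

from nuiforge.analysis import (
    SaturationCurve,
    annotate_genic,
    fit_power_law,
    frame_classify,
    project_growth,
    rarefaction,
    tissue_specificity,
)
from nuiforge.clustering import RepresentativeNUI
from nuiforge.formats import BedRecord
from nuiforge.synthetic import SimulationConfig, simulate_expression


def nui(size, start=1000, nui_id=None, chrom="chr1"):
    return RepresentativeNUI(
        nui_id=nui_id or f"n{size}@{start}",
        chrom=chrom,
        ref_start=start,
        ref_end=start,
        sequence="A" * size,
        sample_id="S1",
        haplotype_id="1",
        support_samples=2,
        global_score=1.0,
        component_id="c",
        cluster_id="c#0",
    )


class TestRarefaction:
    def test_shared_identical_sets_constant_curve(self):
        sets = {f"S{i}": {"a", "b", "c"} for i in range(6)}
        curve = rarefaction(sets, n_perm=20, seed=0)
        assert curve.mean_counts == [3.0] * 6
        assert project_growth(curve, n_points=6) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_sets_linear_curve(self):
        c = 7
        sets = {f"S{i:02d}": {f"id{i}_{j}" for j in range(c)} for i in range(12)}
        curve = rarefaction(sets, n_perm=5, seed=1)
        assert curve.mean_counts == [float(c * (n + 1)) for n in range(12)]
        increment = project_growth(curve)
        assert abs(increment - c) / c < 0.05

    def test_deterministic_for_seed(self):
        sets = {f"S{i}": {f"x{i}", f"y{i % 3}"} for i in range(8)}
        c1 = rarefaction(sets, n_perm=10, seed=5)
        c2 = rarefaction(sets, n_perm=10, seed=5)
        assert c1.mean_counts == c2.mean_counts

    def test_relabeling_invariance(self):
        sets = {f"S{i}": {f"x{i}", "shared"} for i in range(6)}
        relabeled = {f"Z{i}": sets[f"S{i}"] for i in range(6)}
        c1 = rarefaction(sets, n_perm=50, seed=2)
        c2 = rarefaction(relabeled, n_perm=50, seed=2)
        assert c1.mean_counts == c2.mean_counts

    def test_curve_non_decreasing(self):
        rng = np.random.default_rng(3)
        sets = {
            f"S{i}": {f"id{j}" for j in rng.integers(0, 50, size=10)}
            for i in range(9)
        }
        curve = rarefaction(sets, n_perm=25, seed=4)
        assert all(
            a <= b for a, b in zip(curve.mean_counts, curve.mean_counts[1:])
        )

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            rarefaction({"S1": {"a"}}, n_perm=1, seed=0)


class TestProjectGrowth:
    def test_exact_power_law_recovered(self):
        a, b = 37.5, 0.62
        ns = list(range(5, 25))
        ys = [a * n**b for n in ns]
        fa, fb = fit_power_law(np.array(ns[-10:], float), np.array(ys[-10:]))
        assert fa == pytest.approx(a, abs=1e-6)
        assert fb == pytest.approx(b, abs=1e-6)
        curve = SaturationCurve(n_samples=ns, mean_counts=ys)
        increment = project_growth(curve)
        assert increment == pytest.approx(a * 25**b - a * 24**b, rel=1e-9)

    def test_linear_data_gives_b_one(self):
        ns = list(range(1, 15))
        curve = SaturationCurve(n_samples=ns, mean_counts=[12.0 * n for n in ns])
        project_growth(curve)
        assert curve.b == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            project_growth(SaturationCurve(n_samples=[1], mean_counts=[5.0]))


class TestFrameClassify:
    def test_multiple_of_three_in_frame(self):
        flags, _ = frame_classify([nui(30)])
        assert flags == {"n30@1000": True}

    def test_non_multiple_out_of_frame(self):
        flags, _ = frame_classify([nui(29)])
        assert flags == {"n29@1000": False}

    def test_fraction_over_small_class(self):
        nuis = [nui(27, 100), nui(30, 200), nui(31, 300)]
        _, frac = frame_classify(nuis)
        assert frac == pytest.approx(2 / 3)

    def test_large_nuis_excluded_from_fraction(self):
        nuis = [nui(27, 100), nui(3000, 200)]
        _, frac = frame_classify(nuis)
        assert frac == 1.0


class TestAnnotateGenic:
    def features(self):
        return [
            BedRecord("chr1", 900, 1100, "coding_exon"),
            BedRecord("chr1", 800, 1500, "intron"),
            BedRecord("chr1", 2000, 2100, "utr3"),
            BedRecord("chr1", 2050, 2200, "utr5"),
        ]

    def test_exon_beats_intron(self):
        labels = annotate_genic([nui(50, start=1000, nui_id="x")], self.features())
        assert labels["x"][0] == "coding_exon"

    def test_intron_only(self):
        labels = annotate_genic([nui(50, start=1300, nui_id="x")], self.features())
        assert labels["x"][0] == "intron"

    def test_utr3_beats_utr5(self):
        labels = annotate_genic([nui(50, start=2060, nui_id="x")], self.features())
        assert labels["x"][0] == "utr3"

    def test_intergenic(self):
        labels = annotate_genic([nui(50, start=5000, nui_id="x")], self.features())
        assert labels["x"][0] == "intergenic"

    def test_regulatory_flag_separate(self):
        reg = [BedRecord("chr1", 4990, 5100, "enhancer")]
        labels = annotate_genic(
            [nui(50, start=5000, nui_id="x")], self.features(), reg
        )
        assert labels["x"] == ("intergenic", True)

    def test_unknown_feature_class_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            annotate_genic([nui(50)], [BedRecord("chr1", 0, 10, "promoter")])


def welch_t_closed_form(a, b):
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    return (ma - mb) / math.sqrt(va / na + vb / nb)


class TestTissueSpecificity:
    def frame_from(self, values, tissues):
        samples = [f"s{i}" for i in range(values.shape[1])]
        labels = dict(zip(samples, tissues))
        return pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                            columns=samples), labels

    def test_identical_distributions_not_specific(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(50, 150, size=(20, 12))
        frame, labels = self.frame_from(counts, ["a"] * 6 + ["b"] * 6)
        calls = tissue_specificity(frame, labels)
        assert not any(c.specific for c in calls)

    def test_welch_t_matches_closed_form(self):
        # planted shift delta=4 at sd ~0.5, n=10 per group
        rng = np.random.default_rng(1)
        log_a = rng.normal(11.0, 0.5, size=10)
        log_b = rng.normal(7.0, 0.5, size=10)
        counts = np.round(2.0 ** np.concatenate([log_a, log_b])).astype(int)
        frame, labels = self.frame_from(
            counts.reshape(1, -1), ["t"] * 10 + ["rest"] * 10
        )
        calls = tissue_specificity(frame, labels)
        call = next(c for c in calls if c.tissue == "t")
        expected_t = welch_t_closed_form(
            np.log2(counts[:10] + 1.0), np.log2(counts[10:] + 1.0)
        )
        assert call.t_stat == pytest.approx(expected_t, abs=1e-9)
        assert call.specific

    def test_low_count_gene_excluded(self):
        counts = np.array([[1, 1, 1, 1, 1, 1, 1, 1], [50, 60, 50, 60, 50, 60, 50, 60]])
        frame, labels = self.frame_from(counts, ["a"] * 4 + ["b"] * 4)
        calls = tissue_specificity(frame, labels)
        assert {c.gene for c in calls} == {"g1"}

    def test_zero_variance_gene_skipped(self, caplog):
        counts = np.array([[100] * 8, [50, 60, 70, 80, 10, 20, 30, 40]])
        frame, labels = self.frame_from(counts, ["a"] * 4 + ["b"] * 4)
        with caplog.at_level("INFO"):
            calls = tissue_specificity(frame, labels)
        assert all(np.isfinite(c.t_stat) for c in calls)

    def test_planted_effects_recovered(self):
        config = SimulationConfig(
            seed=9,
            expr_genes=300,
            expr_effect_genes=8,
            expr_n_per_tissue=6,
        )
        counts, labels, effect = simulate_expression(config)
        calls = tissue_specificity(counts, labels)
        called = {
            (c.tissue, c.gene) for c in calls if c.specific
        }
        planted = {(t, g) for t, genes in effect.items() for g in genes}
        recall = len(called & planted) / len(planted)
        assert recall >= 0.95

    def test_null_raw_p_uniformity(self):
        config = SimulationConfig(
            seed=10,
            expr_genes=2000,
            expr_effect_genes=0,
            expr_tissues=("a", "b"),
            expr_n_per_tissue=10,
        )
        counts, labels, _ = simulate_expression(config)
        calls = tissue_specificity(counts, labels)
        pvals = [c.p_raw for c in calls if c.tissue == "a"]
        frac = sum(1 for p in pvals if p < 0.05) / len(pvals)
        assert abs(frac - 0.05) <= 0.01
        assert sum(1 for c in calls if c.specific) / len(calls) <= 0.05
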