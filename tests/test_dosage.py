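"""Dosage-compensation tests: filtering, M:F ratios, rank tests against
brute-force enumeration, sex-bias classes, expression tracks and the
compensation verdict."""

import itertools

import numpy as np
import pandas as pd
import pytest

from xyscan import dosage as dm
from xyscan._stats import rank_sum_test, signed_rank_test
from xyscan.simdata import SEX_CHROM, build_truth, picta_like, simulate_rna


def _sex_map(n=3):
    return pd.DataFrame({
        "sample": [f"M{i}" for i in range(n)] + [f"F{i}" for i in range(n)],
        "sex": ["M"] * n + ["F"] * n})


def _matrix(genes, male, female, n=3):
    data = {f"M{i}": male for i in range(n)}
    data.update({f"F{i}": female for i in range(n)})
    return pd.DataFrame(data, index=genes)


class TestFilterExpressed:
    def test_all_zero_gene_removed(self):
        m = _matrix(["g1", "g2"], [0.0, 5.0], [0.0, 5.0])
        out = dm.filter_expressed(m, _sex_map(), min_expr=1.0)
        assert list(out.index) == ["g2"]

    def test_single_sex_expression_removed(self):
        m = _matrix(["g1", "g2"], [5.0, 5.0], [0.0, 5.0])
        out = dm.filter_expressed(m, _sex_map(), min_expr=1.0)
        assert list(out.index) == ["g2"]

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(0)
        sm = _sex_map()
        m = pd.DataFrame(rng.exponential(2, size=(100, 6)),
                         index=[f"g{i}" for i in range(100)],
                         columns=sm["sample"])
        out = dm.filter_expressed(m, sm, min_expr=1.0)
        for g in m.index:
            male_ok = (m.loc[g, ["M0", "M1", "M2"]] >= 1).sum() >= 2
            female_ok = (m.loc[g, ["F0", "F1", "F2"]] >= 1).sum() >= 2
            assert (g in out.index) == (male_ok and female_ok)

    def test_empty_result_raises(self):
        m = _matrix(["g1"], [0.0], [0.0])
        with pytest.raises(ValueError):
            dm.filter_expressed(m, _sex_map(), min_expr=1.0)


class TestMfLog2:
    def test_equal_means_zero(self):
        m = _matrix(["g"], [4.0], [4.0])
        assert dm.mf_log2_per_gene(m, _sex_map()).iloc[0] == pytest.approx(0.0)

    def test_halved_male_is_minus_one(self):
        m = _matrix(["g"], [5.0], [10.0])
        assert dm.mf_log2_per_gene(m, _sex_map()).iloc[0] == pytest.approx(-1.0)

    def test_antisymmetric_under_sex_swap(self):
        rng = np.random.default_rng(1)
        sm = _sex_map()
        m = pd.DataFrame(rng.exponential(5, size=(30, 6)) + 0.1,
                         index=[f"g{i}" for i in range(30)],
                         columns=sm["sample"])
        fwd = dm.mf_log2_per_gene(m, sm)
        swapped = sm.assign(sex=sm.sex.map({"M": "F", "F": "M"}))
        rev = dm.mf_log2_per_gene(m, swapped)
        assert np.allclose(fwd, -rev)


from oracles import brute_force_rank_sum_p, brute_force_signed_rank_p


class TestRankTests:
    def test_signed_rank_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = int(rng.integers(6, 12))
            x = rng.normal(size=n)
            y = x + rng.normal(0.3, 1.0, size=n)
            _, p = signed_rank_test(y, x)
            assert p == pytest.approx(brute_force_signed_rank_p(y - x),
                                      rel=1e-9)

    def test_rank_sum_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=int(rng.integers(3, 7)))
            y = rng.normal(0.5, 1.0, size=int(rng.integers(3, 7)))
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(brute_force_rank_sum_p(x, y), rel=1e-9)

    def test_all_zero_differences_convention(self):
        x = np.ones(10)
        stat, p = signed_rank_test(x, x)
        assert p == 1.0


class TestPairedAndGroupTests:
    def test_identical_sexes_not_significant(self):
        rng = np.random.default_rng(4)
        vals = rng.exponential(5, 50) + 0.5
        m = _matrix([f"g{i}" for i in range(50)], vals, vals)
        _, p = dm.test_mf_x(m, _sex_map(), list(m.index))
        assert p == 1.0

    def test_halved_males_strongly_significant(self):
        rng = np.random.default_rng(5)
        f = rng.exponential(5, 100) + 0.5
        m = _matrix([f"g{i}" for i in range(100)], f * 0.5, f)
        _, p = dm.test_mf_x(m, _sex_map(), list(m.index))
        assert p < 1e-10

    def test_too_few_genes_rejected(self):
        m = _matrix(["g1", "g2"], [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            dm.test_mf_x(m, _sex_map(), ["g1", "g2"])

    def test_x_vs_autosomes_detects_deficit(self):
        rng = np.random.default_rng(6)
        auto = rng.lognormal(2, 0.3, 200)
        x_def = auto[:80] * 0.5
        genes = [f"a{i}" for i in range(200)] + [f"x{i}" for i in range(80)]
        m = _matrix(genes, np.concatenate([auto, x_def]),
                    np.concatenate([auto, auto[:80]]))
        _, p_same = dm.test_x_vs_autosomes(m, _sex_map(),
                                           [f"a{i}" for i in range(100)],
                                           [f"a{i}" for i in range(100, 200)])
        assert p_same > 0.05
        _, p_def = dm.test_x_vs_autosomes(m, _sex_map(),
                                          [f"x{i}" for i in range(80)],
                                          [f"a{i}" for i in range(200)])
        assert p_def < 1e-6


class TestSexBias:
    def test_no_differences_all_unbiased(self):
        rng = np.random.default_rng(7)
        vals = rng.exponential(5, 40) + 0.5
        m = _matrix([f"g{i}" for i in range(40)], vals, vals)
        out = dm.sex_bias_classes(m, _sex_map(),
                                  [f"g{i}" for i in range(10)],
                                  [f"g{i}" for i in range(10, 40)])
        assert out["chi2"] == 0.0
        assert (out["classes"] == "unbiased").all()

    def test_injected_male_biased_genes_detected(self):
        # rank-sum needs enough replicates to be able to reject at all
        # (the smallest exact p at 6 vs 6 is 2/924)
        rng = np.random.default_rng(8)
        n = 120
        base = rng.lognormal(2, 0.2, n)
        male = base.copy()
        male[:20] *= 4.0  # strongly male-biased autosomal genes
        noise = lambda: rng.lognormal(0, 0.05, n)
        sm = _sex_map(6)
        data = {s: male * noise() for s in sm.loc[sm.sex == "M", "sample"]}
        data.update({s: base * noise()
                     for s in sm.loc[sm.sex == "F", "sample"]})
        m = pd.DataFrame(data, index=[f"g{i}" for i in range(n)])
        out = dm.sex_bias_classes(m, sm,
                                  [f"g{i}" for i in range(100, 120)],
                                  [f"g{i}" for i in range(100)])
        detected = set(out["classes"][out["classes"] == "male_biased"].index)
        assert detected == {f"g{i}" for i in range(20)}

    def test_uncompensated_x_shows_female_biased_excess(self):
        cfg = picta_like(length=6_000_000, compensation=False, seed=9,
                         chrom_length=3_000_000, n_genes_per_chrom=150,
                         n_males=6, n_females=6)
        truth = build_truth(cfg)
        _, expr = simulate_rna(cfg, truth)
        genes = truth.genes
        x_genes = list(genes.loc[(genes.chrom == SEX_CHROM)
                                 & (genes.stratum == "old"), "gene"])
        a_genes = list(genes.loc[genes.chrom != SEX_CHROM, "gene"])
        out = dm.sex_bias_classes(expr, cfg.samples, x_genes, a_genes)
        x_counts = out["counts"].loc["X"]
        a_counts = out["counts"].loc["autosomes"]
        assert x_counts["female_biased"] > x_counts["male_biased"]
        assert x_counts["female_biased"] / x_counts.sum() > (
            a_counts["female_biased"] / max(a_counts.sum(), 1))


class TestExpressionTrack:
    WINDOWS = pd.DataFrame({"chrom": "chrX",
                            "start": [0, 1000, 2000],
                            "end": [1000, 2000, 3000]})

    def _gene_pos(self, genes, positions):
        return pd.DataFrame({"gene": genes, "chrom": "chrX",
                             "start": positions,
                             "end": [p + 100 for p in positions]})

    def test_uniform_expression_flat_at_zero(self):
        m = _matrix(["g1", "g2", "g3"], [4.0, 4.0, 4.0], [4.0, 4.0, 4.0])
        gp = self._gene_pos(["g1", "g2", "g3"], [100, 1100, 2100])
        out = dm.expression_track(m, _sex_map(), gp, self.WINDOWS, span=1)
        assert np.allclose(out.mf_log2, 0.0)

    def test_window_without_genes_missing_not_zero(self):
        m = _matrix(["g1"], [4.0], [4.0])
        gp = self._gene_pos(["g1"], [100])
        out = dm.expression_track(m, _sex_map(), gp, self.WINDOWS, span=1)
        assert np.isnan(out.mf_log2.iloc[1])
        assert np.isnan(out.mf_log2.iloc[2])

    def test_matches_brute_force_on_toy_input(self):
        m = _matrix(["g1", "g2", "g3"], [2.0, 8.0, 4.0], [4.0, 4.0, 4.0])
        gp = self._gene_pos(["g1", "g2", "g3"], [100, 200, 1100])
        out = dm.expression_track(m, _sex_map(), gp, self.WINDOWS, span=1)
        assert out.mf_log2.iloc[0] == pytest.approx((np.log2(0.5)
                                                     + np.log2(2.0)) / 2)
        assert out.mf_log2.iloc[1] == pytest.approx(0.0)


class TestVerdict:
    @staticmethod
    def _one(seed, comp):
        cfg = picta_like(length=6_000_000, compensation=comp, seed=seed,
                         chrom_length=3_000_000, n_genes_per_chrom=120)
        truth = build_truth(cfg)
        _, expr = simulate_rna(cfg, truth)
        g = truth.genes
        x = list(g.loc[(g.chrom == SEX_CHROM) & (g.stratum == "old"), "gene"])
        a = list(g.loc[g.chrom != SEX_CHROM, "gene"])
        m = dm.filter_expressed(dm.median_center(expr, ref_genes=a),
                                cfg.samples)
        return dm.dosage_verdict(m, cfg.samples, x, a,
                                 ase_x_genes=list(g.loc[g.ase, "gene"]))

    def test_compensated_truth_yields_complete(self):
        rep = self._one(2, True)
        assert rep.verdict == dm.COMPLETE
        assert abs(rep.median_x_mf_log2) <= 0.25

    def test_uncompensated_truth_yields_absent(self):
        rep = self._one(2, False)
        assert rep.verdict == dm.ABSENT
        assert rep.median_x_mf_log2 == pytest.approx(-1.0, abs=0.25)
        assert rep.p_mf_x < 0.01 and rep.p_x_vs_a_male < 0.01

    def test_no_degenerate_stratum_not_applicable(self):
        rng = np.random.default_rng(10)
        vals = rng.lognormal(2, 0.3, 60) + 0.5
        m = _matrix([f"g{i}" for i in range(60)], vals, vals)
        rep = dm.dosage_verdict(m, _sex_map(),
                                [f"g{i}" for i in range(20)],
                                [f"g{i}" for i in range(20, 60)],
                                has_degenerate_stratum=False)
        assert rep.verdict == dm.NOT_APPLICABLE

    def test_pipeline_report_written(self, sim_dir):
        import json
        report = json.loads((sim_dir / "dosage_report.json").read_text())
        assert report["verdict"] in {dm.COMPLETE, dm.PARTIAL, dm.ABSENT,
                                     dm.NOT_APPLICABLE}
        track = pd.read_csv(sim_dir / "expression_track.tsv", sep="\t")
        assert {"mf_log2", "smooth_mf_log2"} <= set(track.columns)
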