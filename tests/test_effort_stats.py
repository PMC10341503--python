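"""Transcription-effort statistics: per-gene efforts, ranking, cumulative
curves, logarithmic fits, concentration summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import txeffort as tx
from txeffort import datasets

from conftest import make_matrix, per_million_from_counts


class TestGeneEffort:
    @pytest.mark.parametrize(
        "sample,gene,expected",
        [
            ("WPG", "990338", 5.97),  # Hsp20-family chaperone, minimal medium
            ("PDB", "1067414", 2.10),
            ("MPY", "1067414", 1.37),
            ("MPY", "957843", 1.95),  # GAPDH NAD-binding domain
            ("PDB", "957843", 1.36),
        ],
    )
    def test_top10_table_reproduces_printed_efforts(self, sample, gene, expected):
        m = datasets.top10_matrix(sample)
        assert round(tx.gene_effort(m, gene, sample), 2) == expected

    def test_single_nonzero_gene_has_full_effort(self):
        pm = per_million_from_counts({"s": {"g1": 5.0, "g2": 0.0}})
        assert tx.gene_effort(pm, "g1", "s") == pytest.approx(100.0)

    def test_unknown_gene_and_sample_raise(self, small_pm):
        with pytest.raises(tx.UnknownGeneError):
            tx.gene_effort(small_pm, "nope", "s1")
        with pytest.raises(tx.UnknownSampleError):
            tx.gene_effort(small_pm, "gA", "nope")

    def test_requires_per_million_unit(self):
        m = make_matrix({"s": {"g1": 5, "g2": 5}})
        with pytest.raises(ValueError, match="per_million"):
            tx.gene_effort(m, "g1", "s")

    def test_conservation_over_full_sample(self, bundle_pm):
        for sample in bundle_pm.sample_ids:
            efforts = 100.0 * bundle_pm.sample(sample).to_numpy() / 1e6
            assert efforts.sum() == pytest.approx(100.0, abs=1e-6)

    def test_group_effort_sums_member_efforts(self, small_pm):
        # gA 50% + gC 15%; an absent gene contributes nothing
        assert tx.group_effort(small_pm, ["gA", "gC", "missing"], "s1") == pytest.approx(65.0)


class TestRankGenes:
    def test_top10_wpg_order_matches_printed_table(self):
        m = datasets.top10_matrix("WPG")
        assert tx.rank_genes(m, "WPG")[:3] == ["990338", "1125059", "985714"]

    def test_ties_broken_by_ascending_gene_id(self):
        pm = per_million_from_counts({"s": {"gB": 1.0, "gA": 1.0, "gC": 2.0}})
        assert tx.rank_genes(pm, "s") == ["gC", "gA", "gB"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.integers(0, 50, size=50)  # many ties
        genes = [f"g{i:02d}" for i in range(50)]
        pm = per_million_from_counts({"s": dict(zip(genes, values + 1.0))})
        oracle = [g for g, _ in sorted(zip(genes, values + 1.0), key=lambda t: (-t[1], t[0]))]
        assert tx.rank_genes(pm, "s") == oracle


class TestCumulativeCurve:
    def test_top10_wpg_rank3_cumulative(self):
        m = datasets.top10_matrix("WPG")
        curve = tx.cumulative_effort_curve(m, "WPG")
        # hand sum of the three largest printed values over the 1e6 total
        expected = 100 * (59710.6 + 37904.9 + 19175.7) / 1e6
        assert curve.cumulative_effort[2] == pytest.approx(expected)
        assert round(curve.cumulative_effort[2], 2) == 11.68

    def test_uniform_four_gene_sample(self):
        pm = per_million_from_counts({"s": {f"g{i}": 1.0 for i in range(4)}})
        assert np.allclose(tx.cumulative_effort_curve(pm, "s").cumulative_effort, [25, 50, 75, 100])

    def test_full_matrix_curve_ends_at_100(self, bundle_pm):
        for sample in bundle_pm.sample_ids:
            curve = tx.cumulative_effort_curve(bundle_pm, sample)
            assert curve.cumulative_effort[-1] == pytest.approx(100.0, abs=1e-6)
            assert (np.diff(curve.cumulative_effort) >= -1e-12).all()


class TestFitLogCurve:
    def test_recovers_exact_logarithmic_model(self):
        ranks = np.arange(1, 101)
        y = 3.0 * np.log(ranks) + 2.0
        curve = tx.CumulativeCurve(
            sample_id="s",
            ranks=ranks,
            gene_ids=tuple(f"g{i}" for i in ranks),
            effort=np.full(100, 1.0),
            cumulative_effort=y,
        )
        fit = tx.fit_log_curve(curve)
        assert fit.a == pytest.approx(3.0, abs=1e-8)
        assert fit.b == pytest.approx(2.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-8)

    def test_matches_normal_equations_oracle_on_noisy_data(self):
        rng = np.random.default_rng(5)
        ranks = np.arange(1, 201)
        y = 10 * np.log(ranks) + 5 + rng.normal(0, 1.0, size=200)
        y = np.maximum.accumulate(y)  # keep nondecreasing
        curve = tx.CumulativeCurve(
            sample_id="s",
            ranks=ranks,
            gene_ids=tuple(f"g{i}" for i in ranks),
            effort=np.full(200, 0.5),
            cumulative_effort=y,
        )
        fit = tx.fit_log_curve(curve)
        # independent closed-form least squares via the normal equations
        x = np.log(ranks.astype(float))
        n = len(x)
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        a = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        b = (sy - a * sx) / n
        ss_res = float(np.sum((y - (a * x + b)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1 - ss_res / ss_tot
        assert fit.a == pytest.approx(a, abs=1e-8)
        assert fit.b == pytest.approx(b, abs=1e-8)
        assert fit.r_squared == pytest.approx(r2, abs=1e-8)

    def test_constant_curve_flagged_degenerate(self):
        curve = tx.CumulativeCurve(
            sample_id="s",
            ranks=np.arange(1, 6),
            gene_ids=tuple("abcde"),
            effort=np.array([100.0, 0, 0, 0, 0]),
            cumulative_effort=np.full(5, 100.0),
        )
        fit = tx.fit_log_curve(curve, use_ranks=(1, 5))
        assert fit.degenerate and fit.a == 0.0 and fit.r_squared == 1.0

    def test_default_fit_uses_only_nonzero_ranks(self):
        pm = per_million_from_counts(
            {"s": {**{f"g{i:02d}": float(20 - i) for i in range(10)}, "z1": 0.0, "z2": 0.0}}
        )
        fit = tx.fit_log_curve(tx.cumulative_effort_curve(pm, "s"))
        assert fit.n_points == 10

    def test_too_few_points_rejected(self):
        pm = per_million_from_counts({"s": {"g1": 1.0, "g2": 1.0}})
        with pytest.raises(ValueError, match="3 points"):
            tx.fit_log_curve(tx.cumulative_effort_curve(pm, "s"))


class TestMinGenesForEffort:
    @pytest.mark.parametrize("sample,expected", [("WPG", 3), ("PDB", 7), ("MPY", 8)])
    def test_top10_tables_reach_ten_percent(self, sample, expected):
        m = datasets.top10_matrix(sample)
        assert tx.min_genes_for_effort(m, sample, 10.0) == expected

    def test_zero_threshold_needs_no_genes(self, small_pm):
        assert tx.min_genes_for_effort(small_pm, "s1", 0.0) == 0

    def test_exact_boundary_counts(self, small_pm):
        # s1 efforts: 50, 30, 15, 5 -> cumulative 50, 80, 95, 100
        assert tx.min_genes_for_effort(small_pm, "s1", 50.0) == 1
        assert tx.min_genes_for_effort(small_pm, "s1", 80.0) == 2
        assert tx.min_genes_for_effort(small_pm, "s1", 80.0001) == 3

    def test_unreachable_threshold_on_partial_matrix(self):
        m = datasets.top10_matrix("WPG")  # top-10 carry ~21% of the total
        with pytest.raises(tx.InsufficientDataError):
            tx.min_genes_for_effort(m, "WPG", 50.0)

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            values = rng.random(n) * rng.integers(1, 1000)
            pm = per_million_from_counts({"s": {f"g{i:02d}": v for i, v in enumerate(values)}})
            sorted_eff = 100 * np.sort(values)[::-1] / values.sum()
            for threshold in range(1, 100, 7):
                acc, k = 0.0, 0
                while acc < threshold - 1e-9:  # brute-force scan
                    acc += sorted_eff[k]
                    k += 1
                assert tx.min_genes_for_effort(pm, "s", float(threshold)) == k

    def test_monotone_in_threshold(self, bundle_pm):
        sample = bundle_pm.sample_ids[0]
        ks = [tx.min_genes_for_effort(bundle_pm, sample, t) for t in (10, 25, 50, 75, 80, 95)]
        assert ks == sorted(ks)


class TestExpressedStats:
    @pytest.mark.parametrize(
        "expressed,expected", [(10941, 88.6), (10442, 84.6), (10870, 88.0), (10599, 85.8)]
    )
    def test_catalog_fractions_round_to_printed_values(self, expressed, expected):
        assert round(tx.expressed_fraction(expressed, 12346), 1) == expected

    def test_counts_and_threshold(self):
        pm = per_million_from_counts({"s": {"g1": 10.0, "g2": 1.0, "g3": 0.0}})
        stats = tx.expressed_gene_stats(pm, catalog_size=10)
        assert stats["s"].expressed_genes == 2
        assert stats["s"].expressed_fraction == pytest.approx(20.0)
        high = tx.expressed_gene_stats(pm, detection_threshold=5e5, catalog_size=10)
        assert high["s"].expressed_genes == 1

    def test_all_zero_sample_counts_zero(self):
        m = make_matrix({"s": {"g1": 0.0, "g2": 0.0}})
        stats = tx.expressed_gene_stats(m, catalog_size=5)
        assert stats["s"].expressed_genes == 0
        assert stats["s"].expressed_fraction == 0.0

    def test_catalog_smaller_than_matrix_rejected(self, small_pm):
        with pytest.raises(ValueError, match="catalog"):
            tx.expressed_gene_stats(small_pm, catalog_size=2)


class TestParetoSummary:
    def test_uniform_matrix_needs_eighty_percent_of_genes(self):
        n = 40
        pm = per_million_from_counts({"s": {f"g{i:02d}": 1.0 for i in range(n)}})
        summary = tx.pareto_summary(pm, "s")
        assert summary.genes_for_threshold == int(np.ceil(0.8 * n))

    def test_single_gene_matrix(self):
        pm = per_million_from_counts({"s": {"g1": 7.0}})
        summary = tx.pareto_summary(pm, "s")
        assert summary.genes_for_threshold == 1
        assert summary.gene_fraction == pytest.approx(100.0)

    def test_synthetic_default_lands_in_pareto_band(self, bundle_pm):
        # more genes than the 10% of the catalog that carries 75%, but fewer
        # than the 2000-gene (16.2%) ceiling at 80%
        for sample in bundle_pm.sample_ids:
            summary = tx.pareto_summary(bundle_pm, sample, catalog_size=12346)
            assert 10.0 <= summary.gene_fraction < 100.0 * 2000 / 12346


class TestConcentrationSummary:
    def test_threshold_ladder_is_monotone(self, bundle_pm):
        s = tx.concentration_summary(bundle_pm, bundle_pm.sample_ids[0], catalog_size=12346)
        ks = list(s.threshold_to_k.values())
        assert ks == sorted(ks)
        assert s.log_fit is not None and 0 <= s.log_fit.r_squared <= 1

    def test_invalid_threshold_ladder_rejected(self, bundle_pm):
        with pytest.raises(ValueError, match="strictly increasing"):
            tx.concentration_summary(bundle_pm, bundle_pm.sample_ids[0], thresholds=(50, 10))


@given(
    st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=3, max_size=40).filter(
        lambda v: sum(v) > 0
    )
)
def test_effort_scale_invariance_property(values):
    """Efforts from counts are invariant to rescaling the library c>0."""
    genes = {f"g{i:02d}": v for i, v in enumerate(values)}
    pm1 = per_million_from_counts({"s": genes})
    pm2 = per_million_from_counts({"s": {g: v * 13.7 for g, v in genes.items()}})
    g0 = next(iter(genes))
    assert tx.gene_effort(pm1, g0, "s") == pytest.approx(
        tx.gene_effort(pm2, g0, "s"), rel=1e-9, abs=1e-12
    )
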