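import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdx.convdx import (
    DegenerateCorrelationError,
    PlacementSummary,
    assess_methylation,
    chance_overlap_envelope,
    estimate_conversion_rate,
    expected_chance_overlap,
    intersect_replicates,
    partition_by_placement,
    select_unconverted_sites,
    spearman_coverage_correlation,
)
from methdx.genome import ReferenceGenome
from methdx.simulate import SeqSimConfig, simulate_genome, simulate_methylome, simulate_pileup

from conftest import make_site_table


class TestConversionRate:
    def test_pooled_arithmetic(self):
        t = make_site_table(
            [("chr1", i, "+", "CHH", 0, 1000, 0) for i in range(9)]
            + [("chr1", 100, "+", "CHH", 41, 959, 0)]
        )
        cs = estimate_conversion_rate(t)
        assert cs.total_unconverted == 41
        assert cs.total_converted == 9959
        assert round(100 * cs.conversion_rate, 2) == 99.59

    def test_fully_converted(self):
        t = make_site_table([("chr1", 1, "+", "CpG", 0, 10, 0)])
        assert estimate_conversion_rate(t).conversion_rate == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            estimate_conversion_rate(make_site_table([]))

    def test_zero_informative_rejected(self):
        t = make_site_table([("chr1", 1, "+", "CpG", 0, 0, 4)])
        with pytest.raises(ValueError, match="informative"):
            estimate_conversion_rate(t)

    def test_scope_filters_before_pooling(self):
        t = make_site_table(
            [
                ("chr1", 1, "+", "CpG", 5, 5, 0),
                ("chr1", 4, "+", "CHH", 0, 10, 0),
            ]
        )
        assert estimate_conversion_rate(t, "non-CpG").conversion_rate == 1.0
        assert estimate_conversion_rate(t, "CpG").conversion_rate == 0.5
        assert estimate_conversion_rate(t, "all").conversion_rate == 0.75


class TestSelectUnconverted:
    def test_all_converted_gives_empty(self):
        t = make_site_table([("chr1", i, "+", "CpG", 0, 6, 0) for i in range(5)])
        assert len(select_unconverted_sites(t)) == 0

    def test_proportion_uses_informative_depth(self):
        t = make_site_table([("chr1", 3, "+", "CpG", 1, 5, 0)])
        out = select_unconverted_sites(t)
        assert len(out) == 1
        assert out.iloc[0].proportion == pytest.approx(1 / 6, abs=1e-9)

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(3)
        rows = [
            ("chr1", i, "+", "CpG", int(rng.integers(0, 4)), int(rng.integers(0, 10)), 0)
            for i in range(300)
        ]
        t = make_site_table(rows)
        out = select_unconverted_sites(t, min_unconverted=2)
        expected = {r[1] for r in rows if r[4] >= 2}
        assert set(out["pos"]) == expected


class TestIntersectReplicates:
    def test_disjoint_sites_empty(self):
        t1 = select_unconverted_sites(make_site_table([("chr1", 1, "+", "CpG", 1, 5, 0)]))
        t2 = select_unconverted_sites(make_site_table([("chr1", 9, "+", "CpG", 1, 5, 0)]))
        assert len(intersect_replicates(t1, t2)) == 0

    def test_pooled_proportion_arithmetic(self):
        t1 = select_unconverted_sites(make_site_table([("chr1", 1, "+", "CpG", 1, 4, 0)]))
        t2 = select_unconverted_sites(make_site_table([("chr1", 1, "+", "CpG", 1, 9, 0)]))
        row = intersect_replicates(t1, t2).iloc[0]
        assert row.combined_depth == 15
        assert row.pooled_proportion == pytest.approx(2 / 15)

    def test_mixed_merge_modes_rejected(self):
        t1 = select_unconverted_sites(make_site_table([("chr1", 1, "+", "CpG", 1, 4, 0)]))
        t2 = select_unconverted_sites(
            make_site_table([("chr1", 1, "+", "CpG", 1, 4, 0)], cpg_merged=True)
        )
        with pytest.raises(ValueError, match="merge"):
            intersect_replicates(t1, t2)

    def test_matches_nested_loop_join(self):
        rng = np.random.default_rng(11)

        def random_table(seed_offset):
            rows = [
                ("chr1", int(p), "+", "CpG", int(rng.integers(1, 4)),
                 int(rng.integers(0, 12)), 0)
                for p in rng.choice(200, 60, replace=False)
            ]
            return select_unconverted_sites(make_site_table(rows))

        t1, t2 = random_table(0), random_table(1)
        shared = intersect_replicates(t1, t2)
        oracle = {}
        for a in t1.itertuples(index=False):
            for b in t2.itertuples(index=False):
                if (a.chrom, a.pos, a.strand) == (b.chrom, b.pos, b.strand):
                    oracle[(a.chrom, a.pos, a.strand)] = (
                        a.depth, a.n_unconverted, b.depth, b.n_unconverted
                    )
        got = {
            (r.chrom, r.pos, r.strand): (r.depth_1, r.x_1, r.depth_2, r.x_2)
            for r in shared.itertuples(index=False)
        }
        assert got == oracle


class TestPlacementPartition:
    def test_worked_example_84_of_1038(self):
        genome = ReferenceGenome({"chr1": "ACGT" * 300, "scaffold1": "ACGT" * 300})
        rows = [("chr1", 4 * i + 1, "+", "CpG", 1, 5, 0) for i in range(84)]
        rows += [("scaffold1", 4 * i + 1, "+", "CpG", 1, 5, 0) for i in range(1038 - 84)]
        shared = intersect_replicates(
            select_unconverted_sites(make_site_table(rows)),
            select_unconverted_sites(make_site_table(rows)),
        )
        summary = partition_by_placement(shared, genome)
        assert summary.n_placed == 84
        assert summary.n_total == 1038
        assert summary.placed_percent == 8.1

    @pytest.mark.parametrize(
        "n_placed,n_unplaced,percent", [(3, 0, 100.0), (1, 2, 33.3)]
    )
    def test_percentage_rounding(self, n_placed, n_unplaced, percent):
        assert PlacementSummary(n_placed, n_unplaced).placed_percent == percent

    def test_empty_table_rejected(self, tiny_genome):
        empty = intersect_replicates(
            select_unconverted_sites(make_site_table([])),
            select_unconverted_sites(make_site_table([])),
        )
        with pytest.raises(ValueError, match="empty"):
            partition_by_placement(empty, tiny_genome)

    def test_unknown_chromosome_rejected(self, tiny_genome):
        t = select_unconverted_sites(make_site_table([("chrZ", 1, "+", "CpG", 1, 5, 0)]))
        shared = intersect_replicates(t, t)
        with pytest.raises(ValueError, match="absent"):
            partition_by_placement(shared, tiny_genome)


def _exact_spearman_oracle(x, y):
    """Brute-force rho and two-sided permutation p via scipy ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_of(perm):
        return np.corrcoef(rx, perm)[0, 1]

    rho = rho_of(ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(np.array(perm))) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


class TestSpearman:
    def test_perfect_inverse_monotone(self):
        depths = np.array([2, 3, 5, 8, 13])
        df = pd.DataFrame({"combined_depth": depths, "pooled_proportion": 1 / depths})
        res = spearman_coverage_correlation(df)
        assert res.rho == pytest.approx(-1.0)

    def test_midrank_example_with_ties(self):
        df = pd.DataFrame(
            {"combined_depth": [2, 4, 4, 10], "pooled_proportion": [0.5, 0.25, 0.3, 0.1]}
        )
        res = spearman_coverage_correlation(df)
        assert res.rho == pytest.approx(-0.9487, abs=2e-4)

    def test_constant_proportion_rejected(self):
        df = pd.DataFrame({"combined_depth": [1, 2, 3], "pooled_proportion": [0.1] * 3})
        with pytest.raises(DegenerateCorrelationError):
            spearman_coverage_correlation(df)

    def test_too_few_points_rejected(self):
        df = pd.DataFrame({"combined_depth": [1, 2], "pooled_proportion": [0.2, 0.1]})
        with pytest.raises(DegenerateCorrelationError):
            spearman_coverage_correlation(df)

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_exact_permutation_matches_enumeration_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(1, 30, n).astype(float)
        y = rng.random(n)
        df = pd.DataFrame({"combined_depth": x, "pooled_proportion": y})
        res = spearman_coverage_correlation(df)
        assert res.method == "exact permutation"
        rho_o, p_o = _exact_spearman_oracle(x, y)
        assert res.rho == pytest.approx(rho_o, abs=1e-12)
        assert res.p == pytest.approx(p_o, abs=1e-12)

    def test_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.integers(5, 500, 60).astype(float)
        y = 1.0 / x + rng.normal(0, 0.01, 60)
        df = pd.DataFrame({"combined_depth": x, "pooled_proportion": y})
        res = spearman_coverage_correlation(df)
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestChanceOverlap:
    def test_closed_form_single_site(self):
        assert expected_chance_overlap([1], [1], 0.5) == pytest.approx(0.25)

    def test_zero_rate_means_no_overlap(self):
        assert expected_chance_overlap([5, 9], [3, 2], 0.0) == 0.0

    def test_monte_carlo_agrees_with_formula(self):
        rng = np.random.default_rng(9)
        d1 = rng.integers(1, 40, 200)
        d2 = rng.integers(1, 40, 200)
        eps = 0.03
        expected = expected_chance_overlap(d1, d2, eps)
        n_sim = 400
        counts = np.empty(n_sim)
        for i in range(n_sim):
            x1 = rng.binomial(d1, eps)
            x2 = rng.binomial(d2, eps)
            counts[i] = ((x1 >= 1) & (x2 >= 1)).sum()
        se = counts.std(ddof=1) / np.sqrt(n_sim)
        assert abs(counts.mean() - expected) < 3 * se

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            expected_chance_overlap([1, 2], [1], 0.1)


def _replicate_tables(conv_rate, shared_prop):
    """Minimal two-replicate site tables with a prescribed global conversion
    rate and shared-site unconverted proportion; depths descend so the
    artifact correlation is strongly negative."""
    n_shared = 40
    rows = []
    # non-CpG backbone setting the global conversion rate
    n_backbone = 10_000
    u = int(round(n_backbone * (1 - conv_rate)))
    rows.append(("chr1", 0, "+", "CHH", u, n_backbone - u, 0))
    for i in range(n_shared):
        depth = 10 + 10 * i
        x = max(1, int(round(depth * shared_prop)))
        rows.append(("chr1", 10 + 2 * i, "+", "CpG", x, depth - x, 0))
    return make_site_table(rows)


class TestVerdict:
    def test_low_conversion_rate_is_inconclusive(self, tiny_genome):
        genome = ReferenceGenome({"chr1": "ACGT" * 5000})
        t = _replicate_tables(conv_rate=0.90, shared_prop=0.05)
        report = assess_methylation(t, t, genome)
        assert report.verdict == "inconclusive"

    def test_artifact_signature_is_absent(self):
        genome = ReferenceGenome({"chr1": "ACGT" * 5000})
        # shared proportions ~ 1/depth: rho -> -1, pooled fraction small
        rows = [("chr1", 0, "+", "CHH", 40, 9960, 0)]
        for i in range(40):
            depth = 200 + 40 * i
            rows.append(("chr1", 10 + 2 * i, "+", "CpG", 1, depth - 1, 0))
        t = make_site_table(rows)
        report = assess_methylation(t, t, genome)
        assert report.verdict == "absent"
        assert report.correlation.rho <= -0.8

    def test_methylation_signature_is_present(self):
        genome = ReferenceGenome({"chr1": "ACGT" * 5000})
        rng = np.random.default_rng(2)
        rows = [("chr1", 0, "+", "CHH", 40, 9960, 0)]
        for i in range(40):
            depth = int(rng.integers(10, 400))
            x = rng.binomial(depth, 0.8)
            rows.append(("chr1", 10 + 2 * i, "+", "CpG", int(x), depth - int(x), 0))
        t = make_site_table(rows)
        report = assess_methylation(t, t, genome)
        assert report.verdict == "present"

    def test_report_serializes_to_json(self, tmp_path):
        genome = ReferenceGenome({"chr1": "ACGT" * 5000})
        t = _replicate_tables(conv_rate=0.997, shared_prop=0.4)
        report = assess_methylation(t, t, genome)
        out = tmp_path / "report.json"
        report.to_json(out)
        import json

        loaded = json.loads(out.read_text())
        assert loaded["verdict"] == report.verdict
        assert loaded["schema_version"] == "1"
        assert "thresholds" in loaded


class TestMethylatedModelProperty:
    def test_uniform_methylome_breaks_depth_dependence(self):
        # at m = 0.8 the shared-site proportion tracks the methylation level,
        # not 1/depth, so the artifact correlation signature disappears
        genome = simulate_genome(1, 1, [60_000, 3_000], gc=0.4, seed=40)
        meth = simulate_methylome(genome, "uniform", m=0.8)
        cfg = dict(mean_depth=8.0, eps_conv=0.004, eps_seq=0.001,
                   unplaced_mean_depth=120.0,
                   unplaced_depth_model="negative_binomial",
                   unplaced_nb_dispersion=2.0)
        r1 = simulate_pileup(genome, meth, SeqSimConfig(seed=41, **cfg))
        r2 = simulate_pileup(genome, meth, SeqSimConfig(seed=42, **cfg))
        report = assess_methylation(r1, r2, genome)
        assert report.verdict == "present"
        assert report.pooled_shared_fraction == pytest.approx(0.8, abs=0.03)
        assert report.correlation.rho > -0.8
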