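import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import fisher_two_sided_oracle, revcomp, scan_count_oracle
from txaging.io import PWMRecord, Region
from txaging.motifs import (
    build_threshold_series,
    calibrate_min_p,
    count_window_matches,
    direction_bias_test,
    estimate_background,
    family_from_screen,
    scan_sequence,
    score_length_adjusted,
    screen_motifs,
    sweep_foreground_contrast,
    two_sided_fisher_lookup,
)
from txaging.simulate import make_pwm_collection, simulate_motif_regions


def random_pwm(rng, length=None):
    length = length or int(rng.integers(4, 10))
    counts = rng.integers(1, 40, size=(length, 4)).astype(float)
    return PWMRecord.from_counts(f"m{rng.integers(1e6)}", counts)


class TestScan:
    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pwm = random_pwm(rng)
            length = int(rng.integers(pwm.length, 200))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            assert scan_sequence(seq, pwm) == scan_count_oracle(seq, pwm.probs, pwm.background)

    def test_n_windows_skipped(self):
        rng = np.random.default_rng(43)
        pwm = random_pwm(rng, length=5)
        seq = "".join(rng.choice(list("ACGTN"), size=150, p=[0.23, 0.23, 0.23, 0.23, 0.08]))
        assert scan_sequence(seq, pwm) == scan_count_oracle(seq, pwm.probs, pwm.background)

    def test_overlapping_hits_collapse_greedily(self):
        # "AA" motif on "AAAA": hits at 0,1,2 collapse to two matches
        pwm = PWMRecord.from_counts("aa", np.array([[1.0, 0, 0, 0], [1.0, 0, 0, 0]]))
        assert scan_sequence("AAAA", pwm) == 2

    def test_sequence_shorter_than_motif(self):
        pwm = PWMRecord.from_counts("aa", np.array([[1.0, 0, 0, 0], [1.0, 0, 0, 0]]))
        assert scan_sequence("A", pwm) == 0

    def test_strand_symmetry(self):
        rng = np.random.default_rng(44)
        for _ in range(20):
            pwm = random_pwm(rng)
            seq = "".join(rng.choice(list("ACGT"), size=120))
            assert scan_sequence(seq, pwm) == scan_sequence(revcomp(seq), pwm)

    def test_single_strand_mode(self):
        pwm = PWMRecord.from_counts("m", np.eye(4)[[0, 0, 1]] * 1.0)  # AAC
        assert scan_sequence("GTTAAC", pwm, both_strands=False) == 1  # only forward AAC
        assert scan_sequence("GTTGGG", pwm, both_strands=False) == 0  # GTT = revcomp only

    def test_estimate_background(self):
        freqs = estimate_background(["AACC", "GGTT", "NN"])
        assert np.allclose(freqs, 0.25)


class TestWindowCounts:
    def test_planted_counts_recovered(self, small_config, rng):
        directions = pd.Series(["up"] * 20 + ["down"] * 20, index=[f"g{i}" for i in range(40)])
        regions, truth = simulate_motif_regions(small_config, directions, rng=rng)
        pwms = make_pwm_collection(small_config, rng=rng)
        table = count_window_matches(regions, pwms)
        assert (table["planted"] == truth.loc[table.index]).all()

    def test_duplicate_gene_window_rejected(self):
        pwm = PWMRecord.from_counts("m", np.full((2, 4), 1.0))
        regions = [Region("r1", "ACGT", linked_gene="g1"), Region("r2", "ACGT", linked_gene="g1")]
        with pytest.raises(ValueError, match="duplicate"):
            count_window_matches(regions, [pwm])


class TestThresholdSeries:
    def make_counts(self, histogram):
        counts, genes = [], []
        i = 0
        for value, n in histogram.items():
            for _ in range(n):
                genes.append(f"g{i}")
                counts.append(value)
                i += 1
        return pd.Series(counts, index=genes)

    def test_cumulative_set_sizes(self, rng):
        counts = self.make_counts({0: 500, 1: 300, 2: 150, 3: 50})
        directions = pd.Series(rng.choice(["up", "down"], size=1000), index=counts.index)
        series = build_threshold_series(counts, directions)
        assert list(series.table["size"]) == [500, 200, 50]

    def test_small_sets_excluded_from_rank_score(self, rng):
        counts = self.make_counts({0: 500, 1: 300, 2: 150, 3: 50})
        directions = pd.Series(rng.choice(["up", "down"], size=1000), index=counts.index)
        series = build_threshold_series(counts, directions, min_set_size=100)
        eligible = series.table[series.table["size"] >= 100]
        assert series.rank_score == pytest.approx(np.max(np.abs(eligible["prop"] - 0.5)))

    def test_no_matches_flagged_empty(self):
        counts = self.make_counts({0: 10})
        directions = pd.Series(["up"] * 10, index=counts.index)
        assert build_threshold_series(counts, directions).empty

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.integers(0, 6), min_size=5, max_size=60), st.randoms(use_true_random=False))
    def test_nesting_invariant(self, count_values, random):
        counts = pd.Series(count_values, index=[f"g{i}" for i in range(len(count_values))])
        directions = pd.Series(
            [random.choice(["up", "down", "ns"]) for _ in count_values], index=counts.index
        )
        series = build_threshold_series(counts, directions, min_set_size=3)
        if not series.empty:
            sizes = series.table["size"].to_numpy()
            assert (np.diff(sizes) <= 0).all()
            assert (series.table["u"] + series.table["d"] <= series.table["size"]).all()
            assert (np.diff(series.table["u"].to_numpy()) <= 0).all()


class TestDirectionBias:
    def test_matches_enumeration_oracle(self):
        p, prop = direction_bias_test(80, 20, 500, 500)
        assert p == pytest.approx(fisher_two_sided_oracle(80, 20, 420, 480), rel=1e-9)
        assert prop == pytest.approx(0.8)

    def test_balanced_table_p_one(self):
        p, prop = direction_bias_test(50, 50, 500, 500)
        assert p == 1.0 and prop == 0.5

    def test_background_consistency_enforced(self):
        with pytest.raises(ValueError):
            direction_bias_test(10, 5, 8, 100)


class TestMinPCalibration:
    def test_lookup_matches_scipy_fisher(self, rng):
        for _ in range(20):
            U = int(rng.integers(20, 200))
            D = int(rng.integers(20, 200))
            s = int(rng.integers(2, min(U + D, 60)))
            table = two_sided_fisher_lookup(s, U, D)
            lo, hi = max(0, s - D), min(s, U)
            for u in rng.integers(lo, hi + 1, size=5):
                expected = stats.fisher_exact([[u, s - u], [U - u, D - (s - u)]]).pvalue
                assert table[u] == pytest.approx(expected, rel=1e-6)

    def test_single_set_p_star_near_nominal(self):
        # one set, no multiplicity: P* sits near 0.05 (set large enough that
        # the discrete p-value support is dense around the nominal level)
        rng = np.random.default_rng(55)
        memberships = np.zeros((8000, 1), dtype=bool)
        memberships[:1600, 0] = True
        labels = np.zeros(8000, dtype=bool)
        labels[:4000] = True
        calib = calibrate_min_p(memberships, labels, n_trials=2000, rng=rng)
        assert calib.p_star == pytest.approx(0.05, abs=0.01)

    def test_p_star_decreases_with_family_size(self):
        rng = np.random.default_rng(56)
        n_genes = 600
        labels = rng.random(n_genes) < 0.5
        full = rng.random((n_genes, 30)) < 0.25
        p_stars = []
        for n_sets in (1, 5, 30):
            calib = calibrate_min_p(full[:, :n_sets], labels, n_trials=1000, rng=np.random.default_rng(7))
            p_stars.append(calib.p_star)
        assert p_stars[0] >= p_stars[1] >= p_stars[2]

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            calibrate_min_p(np.ones((10, 1), dtype=bool), np.zeros(10, dtype=bool), n_trials=50)

    def test_family_construction_matches_screen(self, small_config, rng):
        directions = pd.Series(
            rng.choice(["up", "down", "ns"], size=60, p=[0.4, 0.4, 0.2]), index=[f"g{i}" for i in range(60)]
        )
        regions, _ = simulate_motif_regions(small_config, directions, rng=rng)
        pwms = make_pwm_collection(small_config, rng=rng)
        table = count_window_matches(regions, pwms)
        memberships, up_labels, set_index = family_from_screen(table, directions)
        assert memberships.shape[0] == int(directions.isin(["up", "down"]).sum())
        assert memberships.shape[1] == len(set_index)
        sets = screen_motifs(table, directions, min_set_size=10)
        # every family set corresponds to a screened set with matching size
        merged = set_index.merge(sets, on=["motif", "t"])
        assert (merged["u"] + merged["d"] == memberships.sum(axis=0)).all()


class TestLengthAdjustment:
    def test_perfect_fit_gives_zero_residuals(self):
        lengths = np.linspace(500, 3000, 60)
        counts = 0.01 * lengths  # exactly count = exp(ln 0.01 + 1 * ln length)
        out = score_length_adjusted(lengths, counts)
        assert np.allclose(out["score"], 0.0, atol=1e-5)
        assert out.attrs["coef"]["ln_length"] == pytest.approx(1.0, abs=1e-5)

    def test_pearson_residual_formula(self):
        lengths = np.linspace(500, 3000, 60)
        counts = 0.01 * lengths
        counts[0] = 2 * counts[0]
        out = score_length_adjusted(lengths, counts)
        coef = out.attrs["coef"]
        mu = np.exp(coef["intercept"] + coef["ln_length"] * np.log(lengths[0]))
        assert out["score"].iloc[0] == pytest.approx((counts[0] - mu) / np.sqrt(mu), rel=1e-6)

    def test_adjustment_removes_length_effect(self):
        rng = np.random.default_rng(60)
        lengths = rng.uniform(500, 5000, 5000)
        counts = rng.poisson(lengths / 1000.0)
        out = score_length_adjusted(lengths, counts)
        assert abs(np.corrcoef(out["score"], np.log(lengths))[0, 1]) < 0.05

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            score_length_adjusted(np.full(10, 100.0), np.ones(10))


class TestForegroundSweep:
    def build(self, rng, enriched):
        n = 600
        genes = [f"g{i}" for i in range(n)]
        scores = pd.Series(rng.normal(0, 1, n), index=[f"r{i}" for i in range(n)])
        region_gene = pd.Series(genes, index=scores.index)
        ranked = genes[:]  # already ordered by aging p
        if enriched:
            scores.iloc[:100] += 1.5  # regions of the top-ranked genes
        return scores, region_gene, ranked

    def test_planted_enrichment_significant_at_small_k(self, rng):
        scores, region_gene, ranked = self.build(rng, enriched=True)
        sweep = sweep_foreground_contrast(scores, region_gene, ranked, k_grid=[100, 300, 600])
        assert sweep.loc[sweep["k"] == 100, "significant"].item()
        fg_means = sweep.sort_values("k")["fg_mean"].to_numpy()
        assert fg_means[0] > fg_means[-1]

    def test_degenerate_background_flagged(self, rng):
        scores, region_gene, ranked = self.build(rng, enriched=False)
        sweep = sweep_foreground_contrast(scores, region_gene, ranked, k_grid=[600])
        row = sweep.iloc[0]
        assert row["degenerate"] and not row["significant"]

    def test_null_rarely_significant(self):
        flags = []
        for seed in range(10):
            rng = np.random.default_rng(600 + seed)
            scores, region_gene, ranked = self.build(rng, enriched=False)
            rng.shuffle(ranked)
            sweep = sweep_foreground_contrast(scores, region_gene, ranked, k_grid=[100, 200, 300, 400, 500])
            flags.extend(sweep["significant"].tolist())
        assert np.mean(flags) <= 0.10
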