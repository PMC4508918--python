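"""Trinomial enrichment statistic, exact test, FDR, and scan reports."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admixscan.scan import (
    EnrichmentScan,
    ExpectedProportions,
    MultinomialTailTable,
    annotate_genes,
    bh_qvalues,
    combination_frequency_grid,
    exact_multinomial_tail,
    locus_counts,
    logfold_enrichment,
    merge_significant_segments,
    population_average_proportions,
    scan_genome,
    trinomial_logpmf,
    trinomial_pmf,
)
from conftest import diploid_all, segments_frame, windows_frame

P_COLOMBIA = ExpectedProportions(0.073, 0.181, 0.746)


def counts_frame(rows):
    df = pd.DataFrame(rows, columns=["x_AFR", "x_NAM", "x_EUR"])
    df.insert(0, "locus_id", [f"L{i}" for i in range(len(df))])
    df.insert(1, "chrom", "chr1")
    df.insert(2, "start", np.arange(len(df)) * 100)
    df.insert(3, "end", np.arange(len(df)) * 100 + 100)
    df["n"] = df[["x_AFR", "x_NAM", "x_EUR"]].sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# expected proportions and locus counts
# ---------------------------------------------------------------------------

class TestExpectedProportions:
    def test_all_eur_loci(self):
        p = population_average_proportions(counts_frame([(0, 0, 4), (0, 0, 4)]))
        assert tuple(p) == (0.0, 0.0, 1.0)

    def test_pooled_arithmetic(self):
        p = population_average_proportions(
            counts_frame([(1, 1, 2), (1, 1, 2)]))
        assert tuple(p) == (0.25, 0.25, 0.5)

    def test_sums_to_one(self, rng):
        rows = rng.integers(0, 20, size=(50, 3))
        p = population_average_proportions(counts_frame(rows))
        assert sum(p) == pytest.approx(1.0)


class TestLocusCounts:
    def test_single_diploid_fully_eur(self):
        seg = diploid_all({"chr1": 1000}, ["I1"], {"chr1": "EUR"})
        w = windows_frame([("chr1", 0, 1000, "L1")])
        out = locus_counts(seg, w)
        assert list(out[["x_AFR", "x_NAM", "x_EUR"]].iloc[0]) == [0, 0, 2]
        assert out["n"].iloc[0] == 2

    def test_midpoint_boundary_half_open_convention(self):
        # boundary exactly at midpoint 50: the segment starting there wins
        seg = segments_frame([("I1", 0, "chr1", 0, 50, "AFR"),
                              ("I1", 0, "chr1", 50, 100, "EUR")])
        w = windows_frame([("chr1", 0, 100, "L1")])
        out = locus_counts(seg, w)
        assert out["x_EUR"].iloc[0] == 1 and out["x_AFR"].iloc[0] == 0

    def test_uncovered_haplotype_reduces_n(self):
        seg = segments_frame([("I1", 0, "chr1", 0, 100, "AFR"),
                              ("I1", 1, "chr1", 0, 40, "EUR")])  # mid=50 uncovered
        w = windows_frame([("chr1", 0, 100, "L1")])
        out = locus_counts(seg, w)
        assert out["n"].iloc[0] == 1

    def test_full_cohort_every_locus_n_120(self, rng):
        inds = [f"I{i}" for i in range(60)]
        seg = diploid_all({"chr1": 10_000}, inds, {"chr1": "EUR"})
        w = windows_frame([("chr1", i * 1000, (i + 1) * 1000, f"L{i}")
                           for i in range(10)])
        out = locus_counts(seg, w)
        assert (out["n"] == 120).all()

    def test_window_on_absent_chromosome_flagged_n0(self):
        seg = diploid_all({"chr1": 1000}, ["I1"], {"chr1": "EUR"})
        w = windows_frame([("chr2", 0, 1000, "L1")])
        out = locus_counts(seg, w)
        assert out["n"].iloc[0] == 0

    def test_x_windows_count_males_once(self):
        seg = segments_frame(
            [("F1", h, "chrX", 0, 1000, "NAM") for h in (0, 1)]
            + [("M1", 0, "chrX", 0, 1000, "EUR")])
        w = windows_frame([("chrX", 0, 1000, "LX")])
        out = locus_counts(seg, w, chrom_class="X")
        assert out["n"].iloc[0] == 3


# ---------------------------------------------------------------------------
# trinomial pmf
# ---------------------------------------------------------------------------

class TestTrinomialPmf:
    def test_degenerate_certain_outcome(self):
        assert trinomial_pmf(5, 0, 0, ExpectedProportions(1, 0, 0)) == 1.0

    def test_worked_example_factorial_oracle(self):
        # 4!/(2!1!1!) * 0.5^2 * 0.25 * 0.25 = 12 * 0.015625
        p = ExpectedProportions(0.5, 0.25, 0.25)
        expect = (math.factorial(4) // (math.factorial(2) * 1 * 1)
                  ) * 0.5**2 * 0.25 * 0.25
        assert expect == pytest.approx(0.1875)
        assert trinomial_pmf(2, 1, 1, p) == pytest.approx(expect)

    def test_all_eur_at_colombian_proportions(self):
        # 120 EUR chromosomes out of 120: log10 pmf = 120 log10(0.746)
        val = trinomial_pmf(0, 0, 120, P_COLOMBIA)
        assert math.log10(val) == pytest.approx(120 * math.log10(0.746))
        assert math.log10(val) == pytest.approx(-15.27, abs=0.05)

    def test_zero_probability_category_with_observation(self):
        assert trinomial_pmf(1, 0, 4, ExpectedProportions(0, 0.2, 0.8)) == 0.0

    def test_normalisation_over_all_compositions(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 31))
            p = rng.dirichlet([1, 1, 1])
            y1, y2 = np.meshgrid(np.arange(n + 1), np.arange(n + 1),
                                 indexing="ij")
            keep = (y1 + y2) <= n
            y = np.column_stack([y1[keep], y2[keep], n - y1[keep] - y2[keep]])
            total = np.exp(trinomial_logpmf(y, p)).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_multinomial(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 200))
            p = rng.dirichlet([2, 2, 2])
            x = rng.multinomial(n, p)
            ours = trinomial_logpmf([x], p)[0]
            ref = stats.multinomial.logpmf(x, n, p)
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            trinomial_logpmf([[-1, 1, 1]], np.array([1 / 3] * 3))


# ---------------------------------------------------------------------------
# exact multinomial tail
# ---------------------------------------------------------------------------

class TestExactTail:
    def test_mode_has_tail_one(self):
        p = ExpectedProportions(0.073, 0.181, 0.746)
        n = 120
        y1, y2 = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = (y1 + y2) <= n
        y = np.column_stack([y1[keep], y2[keep], n - y1[keep] - y2[keep]])
        mode = y[np.argmax(trinomial_logpmf(y, np.array(p)))]
        assert exact_multinomial_tail(*mode, p) == pytest.approx(1.0, abs=1e-12)

    def test_hand_enumeration_n2(self):
        # p=(0.5,0.25,0.25), observed (0,2,0): pmf=0.0625; outcomes with
        # pmf <= 0.0625 are (0,2,0) and (0,0,2) -> P = 0.125
        p = ExpectedProportions(0.5, 0.25, 0.25)
        assert exact_multinomial_tail(0, 2, 0, p) == pytest.approx(0.125)

    def test_tail_at_least_pmf_and_at_most_one(self, rng):
        p = ExpectedProportions(*rng.dirichlet([1, 1, 1]))
        table = MultinomialTailTable(40, p)
        for _ in range(50):
            x = rng.multinomial(40, np.array(p))
            tail = table.tail(*x)
            assert trinomial_pmf(*x, p) <= tail <= 1.0 + 1e-12

    def test_monte_carlo_agreement_small(self, rng):
        p = np.array([0.2, 0.3, 0.5])
        x = (3, 9, 18)
        exact = exact_multinomial_tail(*x, ExpectedProportions(*p))
        draws = rng.multinomial(30, p, size=200_000)
        lp_obs = trinomial_logpmf([list(x)], p)[0]
        lp = trinomial_logpmf(draws, p)
        mc = (lp <= lp_obs + 1e-9).mean()
        se = np.sqrt(exact * (1 - exact) / len(draws))
        assert abs(mc - exact) < 4 * se

    def test_enumeration_size_guard(self):
        with pytest.raises(ValueError):
            MultinomialTailTable(10_001, ExpectedProportions(1 / 3, 1 / 3, 1 / 3))


# ---------------------------------------------------------------------------
# BH q-values
# ---------------------------------------------------------------------------

class TestBHQvalues:
    def test_hand_step_up_example(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, 0.04)

    def test_single_p_unchanged(self):
        assert bh_qvalues(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.random(100))
        q = bh_qvalues(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_matches_hand_rolled_step_up(self, rng):
        p = rng.random(57)
        order = np.argsort(p)
        m = len(p)
        stepped = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(bh_qvalues(p), oracle, atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues(np.array([0.1, np.nan]))


# ---------------------------------------------------------------------------
# log-fold enrichment
# ---------------------------------------------------------------------------

class TestLogfold:
    def test_counts_at_expectation_are_zero(self):
        p = ExpectedProportions(0.25, 0.25, 0.5)
        np.testing.assert_allclose(
            logfold_enrichment(np.array([30, 30, 60]), p), 0.0)

    def test_doubling_gives_plus_one(self):
        p = ExpectedProportions(0.1, 0.4, 0.5)
        lf = logfold_enrichment(np.array([2 * 12, 48, 60]), p, n=120)
        assert lf[0] == pytest.approx(1.0)

    def test_colombian_worked_example(self):
        lf = logfold_enrichment(np.array([30, 20, 70]), P_COLOMBIA, n=120)
        assert lf[0] == pytest.approx(math.log2(30 / (120 * 0.073)), rel=1e-12)
        assert lf[0] == pytest.approx(1.776, abs=2e-3)

    def test_zero_count_is_negative_infinity(self):
        lf = logfold_enrichment(np.array([0, 60, 60]),
                                ExpectedProportions(0.1, 0.45, 0.45))
        assert lf[0] == -np.inf


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

class TestScan:
    def test_injected_extreme_locus_flagged(self, rng):
        # background at the population average, one locus all-AFR
        rows = [tuple(rng.multinomial(120, np.array(P_COLOMBIA)))
                for _ in range(300)]
        rows.append((120, 0, 0))
        scanner = EnrichmentScan(alpha_p=1e-9).fit_counts(counts_frame(rows))
        res = scanner.results_
        assert bool(res["significant"].iloc[-1])
        assert res["enriched"].iloc[-1] == "AFR"
        assert res["depleted"].iloc[-1] in ("NAM", "EUR")
        # the classical point-probability score is itself far below threshold
        assert res["pmf"].iloc[-1] < 1e-9

    def test_deterministic_result_table(self, small_cohort):
        from admixscan.simulate import make_windows
        w = make_windows(small_cohort.config.chrom_lengths, 2_000_000)
        a = scan_genome(small_cohort.segments, w)
        b = scan_genome(small_cohort.segments, w)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_n_loci_excluded_from_bh_m(self, rng):
        rows = [tuple(rng.multinomial(10, np.array(P_COLOMBIA)))
                for _ in range(20)]
        counts = counts_frame(rows)
        empty = counts_frame([(0, 0, 0)])
        counts = pd.concat([counts, empty], ignore_index=True)
        scanner = EnrichmentScan().fit_counts(counts)
        assert scanner.n_excluded_ == 1
        assert len(scanner.results_) == 20

    def test_score_choice_pmf_vs_tail(self, rng):
        rows = [tuple(rng.multinomial(60, np.array(P_COLOMBIA)))
                for _ in range(50)]
        counts = counts_frame(rows)
        res_pmf = EnrichmentScan(score="pmf").fit_counts(counts).results_
        res_tail = EnrichmentScan(score="exact_tail").fit_counts(counts).results_
        # both report both columns; q differs by score choice
        assert (res_pmf["pmf"] == res_tail["pmf"]).all()
        assert not (res_pmf["q_value"] == res_tail["q_value"]).all()

    def test_detection_power_at_strong_excess(self, rng):
        # fourfold AFR excess at 5% of loci is reliably detected at q < 0.05
        p0 = np.array(P_COLOMBIA)
        p_alt = np.array([4 * 0.073, 0.181, 0.746])
        p_alt /= p_alt.sum()
        rows = [tuple(rng.multinomial(120, p0)) for _ in range(1900)]
        rows += [tuple(rng.multinomial(120, p_alt)) for _ in range(100)]
        scanner = EnrichmentScan().fit_counts(counts_frame(rows))
        q = scanner.results_["q_value"].to_numpy()
        assert (q[-100:] < 0.05).mean() > 0.8


# ---------------------------------------------------------------------------
# combination grid, merging, gene annotation
# ---------------------------------------------------------------------------

class TestCombinationGrid:
    def test_identical_loci_single_cell(self):
        grid = combination_frequency_grid(counts_frame([(1, 2, 3)] * 5))
        assert grid.to_numpy().sum() == pytest.approx(1.0)
        assert grid.loc[1, 2] == pytest.approx(1.0)

    def test_two_equal_combinations(self):
        grid = combination_frequency_grid(
            counts_frame([(1, 2, 3), (2, 2, 2), (1, 2, 3), (2, 2, 2)]))
        assert grid.loc[1, 2] == pytest.approx(0.5)
        assert grid.loc[2, 2] == pytest.approx(0.5)

    def test_heterogeneous_n_bins_proportions(self):
        grid = combination_frequency_grid(
            counts_frame([(1, 1, 2), (2, 2, 4), (0, 0, 4)]))
        assert grid.to_numpy().sum() == pytest.approx(1.0)
        # (1,1,2)/4 and (2,2,4)/8 share the proportion cell (0.25, 0.25)
        assert (grid.to_numpy() == 2 / 3).any()


class TestMergeAndAnnotate:
    def base_results(self):
        rows = [(120, 0, 0), (120, 0, 0), (0, 120, 0), (5, 20, 95),
                (120, 0, 0)]
        scanner = EnrichmentScan(alpha_p=1e-9,
                                 expected=P_COLOMBIA).fit_counts(
            counts_frame(rows))
        return scanner.results_

    def test_adjacent_same_ancestry_merge(self):
        res = self.base_results()
        merged = merge_significant_segments(res)
        afr = merged[merged["enriched"] == "AFR"]
        # first two adjacent AFR loci merge; the last AFR locus is isolated
        assert len(afr) == 2
        assert afr.iloc[0]["n_loci"] == 2
        assert afr.iloc[1]["n_loci"] == 1

    def test_different_ancestries_do_not_merge(self):
        res = self.base_results()
        merged = merge_significant_segments(res)
        assert set(merged["enriched"]) == {"AFR", "NAM"}
        nam = merged[merged["enriched"] == "NAM"]
        assert len(nam) == 1 and nam.iloc[0]["n_loci"] == 1

    def test_annotate_overlap_semantics(self):
        segs = pd.DataFrame({"chrom": ["chr1"], "start": [100],
                             "end": [200], "enriched": ["AFR"]})
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1", "chr1"],
            "start": [120, 200, 150, 90],
            "end": [180, 250, 260, 100],
            "name": ["inside", "abutting", "spanning", "left_outside"]})
        out = annotate_genes(segs, genes)
        assert out["genes"].iloc[0] == "inside,spanning"
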