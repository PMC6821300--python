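"""D-statistic estimators, jackknife, z-tests, windows, suites."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from retinet.introgression import (
    DResult,
    PatternCounts,
    QuartetAssignment,
    cluster_pattern_counts,
    count_patterns,
    d_from_counts,
    d_from_frequencies,
    d_test,
    jackknife_se,
    quartet_concordance,
    run_d_suite,
    significance_stars,
    windowed_d,
)
from retinet.simulate import (
    SimulationConfig,
    simulate_cluster_alignments,
    simulate_locus_patterns,
    simulate_window_frequencies,
)
from retinet.variation import BiallelicSite

QUARTET = QuartetAssignment("p1", "p2", "p3", "out")


def blocks_of(*ab_pairs):
    return [
        PatternCounts(f"b{i}", c_abba=a, c_baba=b, n_sites=a + b)
        for i, (a, b) in enumerate(ab_pairs)
    ]


class TestCountPatterns:
    def _site(self, bases):
        return BiallelicSite("c", 0, tuple(zip(("p1", "p2", "p3", "out"), bases)))

    def test_direct_tally(self):
        sites = [self._site("AGGA"), self._site("GAGA"), self._site("AGGA")]
        counts = count_patterns(sites, QUARTET)
        assert (counts.c_abba, counts.c_baba) == (2, 1)

    def test_empty_block(self):
        counts = count_patterns([], QUARTET, block_id="empty")
        assert (counts.c_abba, counts.c_baba, counts.c_bbaa, counts.n_sites) == (0, 0, 0, 0)

    def test_conservation_per_cluster(self, base_config):
        config = SimulationConfig(n_loci=30, sites_per_locus=300, seed=8)
        clusters = [(t.locus_id, a) for t, a in simulate_cluster_alignments(config)]
        q = QuartetAssignment(*config.quartet)
        for counts in cluster_pattern_counts(clusters, q):
            informative = counts.c_abba + counts.c_baba + counts.c_bbaa
            assert informative <= counts.n_sites  # rest are uninformative patterns


class TestDFromCounts:
    @pytest.mark.parametrize(
        "totals,expected", [((30, 10), 0.5), ((10, 10), 0.0)]
    )
    def test_totals(self, totals, expected):
        _, _, d = d_from_counts(blocks_of(totals))
        assert d == pytest.approx(expected)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        num, den, d = d_from_counts(blocks_of((2, 0), (0, 2), (2, 0)))
        assert (num, den) == (2, 6)
        assert d == pytest.approx(1 / 3, abs=1e-4)
        # asymmetric case where the two conventions disagree
        _, _, d2 = d_from_counts(blocks_of((3, 0), (0, 1)))
        per_block_mean = np.mean([1.0, -1.0])
        assert d2 == pytest.approx(0.5) and per_block_mean == 0.0

    def test_zero_denominator_flagged(self):
        with pytest.raises(ZeroDivisionError):
            d_from_counts(blocks_of((0, 0), (0, 0)))


class TestDFromFrequencies:
    def test_pure_abba_snp(self):
        _, _, d = d_from_frequencies([[0, 1, 1, 0]])
        assert d == 1.0

    def test_hand_evaluated_snp(self):
        num, den, d = d_from_frequencies([[0.2, 0.8, 1.0, 0.0]])
        assert num == pytest.approx(0.60) and den == pytest.approx(0.68)
        assert d == pytest.approx(0.88235, abs=1e-5)

    def test_indicator_frequencies_reduce_to_counts(self):
        rng = np.random.default_rng(0)
        freqs = rng.integers(0, 2, size=(200, 4)).astype(float)
        freqs[:, 3] = 0.0  # derived states are polarized against the outgroup
        abba = ((1 - freqs[:, 0]) * freqs[:, 1] * freqs[:, 2]).sum()
        baba = (freqs[:, 0] * (1 - freqs[:, 1]) * freqs[:, 2]).sum()
        num, den, d = d_from_frequencies(freqs)
        assert d == pytest.approx((abba - baba) / (abba + baba), abs=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            d_from_frequencies([[0.5, 1.2, 0.1, 0.0]])


class TestJackknife:
    def test_identical_blocks_zero_variance(self):
        blocks = blocks_of(*[(3, 1)] * 5)
        num = np.array([b.c_abba - b.c_baba for b in blocks])
        den = np.array([b.c_abba + b.c_baba for b in blocks])
        se, n = jackknife_se(num, den)
        assert se == 0.0 and n == 5

    def test_hand_computed_delete_one(self):
        # deletions give theta = {0, 1, 0}; se = sqrt((2/3) * 6/9) = 2/3
        blocks = blocks_of((2, 0), (0, 2), (2, 0))
        num = np.array([b.c_abba - b.c_baba for b in blocks])
        den = np.array([b.c_abba + b.c_baba for b in blocks])
        se, _ = jackknife_se(num, den)
        assert se == pytest.approx(2 / 3, abs=1e-4)

    def test_insufficient_blocks(self):
        with pytest.raises(ValueError, match="insufficient_blocks"):
            jackknife_se(np.array([1.0]), np.array([1.0]))

    def test_undefined_deletion_skipped_with_warning(self):
        # deleting the only informative block empties the denominator;
        # that deletion is skipped and n adjusted from 3 to 2
        num = np.array([3.0, 0.0, 0.0])
        den = np.array([3.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="skipped"):
            se, n = jackknife_se(num, den)
        assert n == 2 and se == 0.0


class TestDTest:
    def test_transcriptome_scan_effect_sizes(self):
        # headline effect sizes: D/SE pairs and their two-tailed outcome
        z1 = 0.0976 / 0.0110
        assert z1 == pytest.approx(8.873, abs=5e-3)
        assert 2 * norm.sf(z1) < 0.001
        z2 = 0.1391 / 0.0109
        assert z2 == pytest.approx(12.76, abs=5e-3)
        assert 2 * norm.sf(z2) < 0.001
        assert significance_stars(2 * norm.sf(z1)) == "***"

    def test_zero_d_gives_p_one(self):
        res = d_test(blocks_of((2, 2), (3, 3), (1, 1), (5, 1), (1, 5)), QUARTET)
        assert res.d == 0.0 and res.p_two_tailed == pytest.approx(1.0)

    def test_degenerate_se(self):
        res = d_test(blocks_of((3, 1), (3, 1), (3, 1)), QUARTET)
        assert res.se == 0.0 and "degenerate" in res.flags and res.p_two_tailed == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=20),
                st.integers(min_value=0, max_value=20),
            ),
            min_size=3,
            max_size=30,
        )
    )
    def test_d_bounded_and_antisymmetric(self, pairs):
        if sum(a + b for a, b in pairs) == 0:
            return
        blocks = blocks_of(*pairs)
        swapped = blocks_of(*[(b, a) for a, b in pairs])
        _, _, d = d_from_counts(blocks)
        _, _, d_swapped = d_from_counts(swapped)
        assert -1.0 <= d <= 1.0
        assert d_swapped == pytest.approx(-d, abs=1e-12)


class TestWindowedD:
    def test_single_window_se_flagged(self):
        table = pd.DataFrame(
            {
                "chrom": "c",
                "pos": np.repeat([10, 20, 30], 4),
                "pop": ["p1", "p2", "p3", "out"] * 3,
                "derived_freq": [0.1, 0.9, 0.8, 0.0] * 3,
                "n_chrom": 10,
            }
        )
        windows, chrom = windowed_d(table, QUARTET, 50_000)
        assert len(windows) == 1
        assert "se_undefined_single_window" in chrom.flags
        assert chrom.d == pytest.approx(windows.loc[0, "d"])

    def test_null_window_z_calibration(self):
        config = SimulationConfig(gamma=0.0, n_windows=200, snps_per_window=50, seed=13)
        table, _ = simulate_window_frequencies(config)
        windows, chrom = windowed_d(
            table, QuartetAssignment(*config.quartet), config.window_size
        )
        frac_extreme = (windows["z"].abs() > 1.96).mean()
        assert frac_extreme < 0.12  # ~5% nominal, wide binomial slack at n=200
        assert abs(chrom.z) < 3

    def test_planted_tracts_rank_top(self):
        config = SimulationConfig(
            gamma=0.8, n_windows=50, snps_per_window=60, tract_fraction=0.2, seed=17
        )
        table, tracts = simulate_window_frequencies(config)
        windows, _ = windowed_d(table, QuartetAssignment(*config.quartet), config.window_size)
        in_tract = (windows["start"] // config.window_size).isin(tracts)
        assert windows.loc[in_tract, "d"].mean() > windows.loc[~in_tract, "d"].mean()
        # tract windows dominate the top of the D ranking
        top = windows.nlargest(len(tracts), "d")
        assert (top["start"] // config.window_size).isin(tracts).mean() >= 0.8


@pytest.fixture(scope="module")
def clusters():
    config = SimulationConfig(n_loci=150, sites_per_locus=300, gamma=0.3, seed=19)
    return config, [(t.locus_id, a) for t, a in simulate_cluster_alignments(config)]


class TestSuite:
    def test_quartet_swap_negates_d(self, clusters):
        config, data = clusters
        p1, p2, p3, og = config.quartet
        suite = run_d_suite(
            data,
            [QuartetAssignment(p1, p2, p3, og), QuartetAssignment(p2, p1, p3, og)],
        )
        assert suite.loc[0, "d"] == pytest.approx(-suite.loc[1, "d"], abs=1e-12)
        assert suite.loc[0, "z"] == pytest.approx(-suite.loc[1, "z"], abs=1e-9)

    def test_sixteen_quartets_order_preserved(self, clusters):
        config, data = clusters
        taxa = list(config.taxa)
        quartets = [
            QuartetAssignment(taxa[i % 7], taxa[(i + 1) % 7], taxa[(i + 2) % 7], taxa[-1])
            for i in range(16)
        ]
        suite = run_d_suite(data, quartets)
        assert len(suite) == 16
        assert list(suite["quartet"]) == [str(q) for q in quartets]

    def test_unknown_label_names_quartet(self, clusters):
        _, data = clusters
        bad = QuartetAssignment("sara", "hortense", "nessus", "iulia")
        with pytest.raises(KeyError, match="nessus"):
            run_d_suite(data, [bad])


class TestConcordance:
    def test_majority_and_tie_rules(self):
        # cluster "a": 5 BBAA + 1 ABBA columns; cluster "b": 2 ABBA + 2 BABA (tie)
        bbaa, abba, baba = ("GGAA", "AGGA", "GAGA")

        def aln(*columns):
            rows = ["".join(col[i] for col in columns) for i in range(4)]
            return dict(zip(("p1", "p2", "p3", "out"), rows))

        clusters = [
            ("a", aln(*([bbaa] * 5 + [abba]))),
            ("b", aln(abba, abba, baba, baba)),
        ]
        table = quartet_concordance(clusters, QUARTET)
        assert list(table["majority"]) == ["BBAA", "unresolved"]
        assert table.loc[0, "c_bbaa"] == 5 and table.loc[1, "c_abba"] == 2

    def test_majority_tracks_truth_classes(self):
        config = SimulationConfig(n_loci=300, sites_per_locus=300, gamma=0.3, seed=23)
        sim = simulate_cluster_alignments(config)
        clusters = [(t.locus_id, a) for t, a in sim]
        table = quartet_concordance(clusters, QuartetAssignment(*config.quartet))
        merged = table.set_index("cluster_id")
        expected_majority = {
            "introgressed": "ABBA",
            "ils_abba": "ABBA",
            "ils_baba": "BABA",
            "ils_bbaa": "BBAA",
            "concordant": "BBAA",
        }
        informative = [
            (t, merged.loc[t.locus_id, "majority"])
            for t, _ in sim
            if t.n_informative_sites >= 3
        ]
        agree = sum(expected_majority[t.genealogy_class] == m for t, m in informative)
        assert informative and agree / len(informative) > 0.9
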