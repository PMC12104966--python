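"""Genetic-monitoring core: heterozygosity, inbreeding projection, windows, parentage."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lynxmon import popgen, synthdata
from lynxmon.popgen import (
    EmptyDataError,
    Scenario,
    effective_inbreeding,
    expected_heterozygosity,
    inbreeding_depression,
    observed_heterozygosity,
    parentage_exclusion,
    private_alleles,
    flag_f1,
    relative_fitness,
    scenario_series,
    traveling_window,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# Heterozygosity


class TestObservedHeterozygosity:
    def test_direct_count(self, four_individual_table):
        per_locus, mean = observed_heterozygosity(four_individual_table)
        assert mean == pytest.approx(0.5)
        assert per_locus.iloc[0] == pytest.approx(0.5)

    def test_all_homozygous(self):
        table = make_table([[(1, 1), (3, 3)], [(2, 2), (3, 3)]])
        per_locus, mean = observed_heterozygosity(table)
        assert (per_locus == 0).all() and mean == 0

    def test_fully_missing_locus_excluded_from_mean(self):
        with_missing = make_table([[(1, 2), (0, 0)], [(1, 1), (0, 0)]])
        without = make_table([[(1, 2)], [(1, 1)]])
        _, m1 = observed_heterozygosity(with_missing)
        _, m2 = observed_heterozygosity(without)
        assert m1 == pytest.approx(m2)

    def test_empty_table_raises(self):
        table = make_table([[(0, 0)], [(0, 0)]])
        with pytest.raises(EmptyDataError):
            observed_heterozygosity(table)


def brute_force_he(table):
    """Independent oracle: explicit allele counting per locus, plain Python."""
    values = []
    for j, locus in enumerate(table.locus_names):
        alleles = []
        for i in range(len(table)):
            a, b = table.genotypes[i, j]
            if a != 0:
                alleles += [int(a), int(b)]
        n = len(alleles) // 2
        if n < 2:
            values.append(np.nan)
            continue
        counts = {}
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
        sum_p2 = sum((c / len(alleles)) ** 2 for c in counts.values())
        values.append((2 * n) / (2 * n - 1) * (1 - sum_p2))
    return values, float(np.nanmean(values))


class TestExpectedHeterozygosity:
    def test_monomorphic_locus_zero(self):
        table = make_table([[(1, 1)], [(1, 1)], [(1, 1)]])
        per_locus, mean = expected_heterozygosity(table)
        assert mean == 0

    def test_two_genotype_unbiased_correction(self):
        # alleles at 0.5/0.5 with n = 2: (4/3) * 0.5
        table = make_table([[(1, 1)], [(2, 2)]])
        _, mean = expected_heterozygosity(table)
        assert mean == pytest.approx(4 / 3 * 0.5)

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n, n_loci = rng.integers(3, 15), rng.integers(1, 6)
            geno = rng.integers(1, 6, size=(n, n_loci, 2))
            missing = rng.random((n, n_loci)) < 0.15
            geno[missing] = 0
            table = make_table(geno.tolist())
            try:
                per_locus, mean = expected_heterozygosity(table)
            except EmptyDataError:
                continue
            oracle_locus, oracle_mean = brute_force_he(table)
            np.testing.assert_allclose(
                per_locus.to_numpy(), oracle_locus, atol=1e-12
            )
            assert mean == pytest.approx(oracle_mean, abs=1e-12)

    def test_strict_mode_rejects_thin_locus(self):
        table = make_table([[(1, 2), (1, 1)], [(1, 2), (0, 0)]])
        with pytest.raises(ValueError):
            expected_heterozygosity(table, strict=True)


# ---------------------------------------------------------------------------
# Inbreeding projection


class TestInbreedingChain:
    def test_effective_inbreeding_identity_and_extremes(self):
        assert effective_inbreeding(0.5, 0.5) == 0
        assert effective_inbreeding(0.0, 0.592) == 1
        assert effective_inbreeding(0.4026, 0.592) == pytest.approx(0.32, abs=5e-3)
        assert effective_inbreeding(0.7, 0.592) < 0  # reported as-is
        with pytest.raises(ValueError):
            effective_inbreeding(0.4, 0.0)

    @pytest.mark.parametrize(
        "fe,expected",
        [(0.32, 0.85), (0.19, 0.68), (0.0, 0.0)],
    )
    def test_lethal_equivalents_transform(self, fe, expected):
        assert round(inbreeding_depression(fe, 12.0), 2) == expected

    def test_delta_domain_errors(self):
        with pytest.raises(ValueError):
            inbreeding_depression(-0.1)
        with pytest.raises(ValueError):
            inbreeding_depression(0.1, 0.0)

    @given(
        fe=st.floats(0.0, 3.0),
        fe2=st.floats(0.0, 3.0),
        b2=st.floats(0.5, 30.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_delta_monotone_and_bounded(self, fe, fe2, b2):
        d1, d2 = inbreeding_depression(fe, b2), inbreeding_depression(fe2, b2)
        # delta < 1 mathematically; equality only through float saturation
        assert 0 <= d1 <= 1
        if fe <= fe2:
            assert d1 <= d2

    def test_delta_strictly_increasing_on_grid(self):
        grid = [inbreeding_depression(fe, 12.0) for fe in np.linspace(0, 1, 21)]
        assert all(a < b for a, b in zip(grid, grid[1:]))

    def test_fitness_algebraic_identity(self):
        # fitness * (1 + delta/(1-delta)) == 1 for any delta in [0, 1)
        for delta in np.linspace(0, 0.99, 25):
            fit = relative_fitness(delta)
            assert fit * (1 + delta / (1 - delta)) == pytest.approx(1.0)

    def test_fitness_more_than_doubles_between_scenarios(self):
        ratio = relative_fitness(inbreeding_depression(0.19)) / relative_fitness(
            inbreeding_depression(0.32)
        )
        assert ratio == pytest.approx(2.18, abs=0.05)
        assert ratio > 2

    def test_fitness_complement(self):
        assert relative_fitness(0.85) == pytest.approx(0.15)
        assert relative_fitness(0.0) == 1.0


# ---------------------------------------------------------------------------
# Traveling window


def _random_table(rng, n, n_loci=4):
    geno = rng.integers(1, 5, size=(n, n_loci, 2))
    dates = [f"20{10 + i // 10:02d}-01-{1 + i % 10:02d}" for i in range(n)]
    return make_table(geno.tolist(), dates=dates)


class TestTravelingWindow:
    def test_single_window_at_boundary(self):
        rng = np.random.default_rng(0)
        table = _random_table(rng, 10)
        series = traveling_window(table, 0.592, width=10)
        assert len(series) == 1
        assert series.frame["n"].iloc[0] == 10

    def test_series_length_formula(self):
        rng = np.random.default_rng(1)
        table = _random_table(rng, 23)
        for width, step in [(10, 1), (10, 3), (5, 5)]:
            series = traveling_window(table, 0.592, width=width, step=step)
            assert len(series) == (23 - width) // step + 1

    def test_constant_table_constant_fe(self):
        table = make_table([[(1, 2)]] * 12, dates=[f"2020-01-{d + 1:02d}" for d in range(12)])
        series = traveling_window(table, 0.592, width=5)
        assert series.frame["fe"].nunique() == 1

    def test_step_equal_width_partitions_input(self):
        rng = np.random.default_rng(2)
        table = _random_table(rng, 20)
        series = traveling_window(table, 0.592, width=5, step=5)
        flat = [iid for ids in series.member_ids for iid in ids]
        ordered = table.sort_chronologically().meta["individual_id"].tolist()
        assert flat == ordered

    def test_fitness_equals_one_minus_delta(self):
        rng = np.random.default_rng(3)
        series = traveling_window(_random_table(rng, 15), 0.592, width=6)
        np.testing.assert_allclose(
            series.frame["fitness"], 1 - series.frame["delta"], atol=0
        )

    def test_insufficient_data_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(EmptyDataError):
            traveling_window(_random_table(rng, 5), 0.592, width=6)

    def test_drift_without_immigration_fe_trend_increasing(self):
        # Fe accumulates under pure drift: positive Spearman trend over
        # windows in at least 95% of replicate simulations.
        from scipy.stats import spearmanr

        cfg = synthdata.DriftConfig(
            immigrant_generation=None, generations=25, samples_per_generation=4
        )
        hits = 0
        n_rep = 200
        for r in range(n_rep):
            rng = np.random.default_rng(50_000 + r)
            table, _ = synthdata.simulate_drift_population(cfg, rng)
            series = traveling_window(table, 0.592, width=40, step=2)
            rho, _ = spearmanr(
                series.frame["window_index"], series.frame["fe"]
            )
            hits += rho > 0
        assert hits >= 0.95 * n_rep


class TestScenarioSeries:
    def test_fully_connected_equals_remnant_without_translocations(self):
        rng = np.random.default_rng(5)
        table = _random_table(rng, 15)
        a = scenario_series(table, Scenario.REMNANT_ONLY, width=10)
        b = scenario_series(table, Scenario.FULLY_CONNECTED, width=10)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_exclusion_list_removes_exactly_flagged(self, drift_table_and_truth):
        table, _ = drift_table_and_truth
        excluded = table.meta.loc[
            table.meta["group"] == "translocated", "individual_id"
        ].head(3).tolist()
        series = scenario_series(table, "fully_connected", excluded_ids=excluded)
        members = {iid for ids in series.member_ids for iid in ids}
        assert not members & set(excluded)

    def test_unknown_scenario_rejected(self, drift_table_and_truth):
        table, _ = drift_table_and_truth
        with pytest.raises(ValueError):
            scenario_series(table, "everything")

    def test_scenarios_are_nested(self, drift_table_and_truth):
        table, _ = drift_table_and_truth
        sizes = []
        for sc in ["remnant_only", "dinaric_reinforcement", "fully_connected"]:
            series = scenario_series(table, sc)
            sizes.append(len({i for ids in series.member_ids for i in ids}))
        assert sizes[0] <= sizes[1] <= sizes[2]


# ---------------------------------------------------------------------------
# Private alleles and parentage


class TestPrivateAlleles:
    def test_no_private_when_candidates_within_reference(self):
        ref = make_table([[(1, 2)], [(2, 3)]])
        cand = make_table([[(1, 3)], [(2, 2)]])
        priv = private_alleles(ref, cand)
        assert all(len(v) == 0 for v in priv.values())

    def test_allele_seen_once_in_reference_is_not_private(self):
        ref = make_table([[(1, 1)], [(1, 4)]])  # allele 4 appears once
        cand = make_table([[(4, 4)]])
        assert private_alleles(ref, cand)["L01"] == set()

    def test_disjoint_immigrant_ranges_all_flagged(self, drift_table_and_truth):
        table, truth = drift_table_and_truth
        pre = table.subset((table.meta["group"] == "remnant").to_numpy())
        imm = table.subset((table.meta["group"] == "translocated").to_numpy())
        priv = private_alleles(pre, imm)
        assert sum(len(v) for v in priv.values()) > 0
        # every translocated animal carries only immigrant-range alleles
        for i in range(len(imm)):
            alleles = {
                table.locus_names[j]: tuple(imm.genotypes[i, j])
                for j in range(imm.n_loci)
            }
            assert flag_f1(alleles, priv)

    def test_empty_reference_rejected(self):
        ref = make_table([[(1, 1)]]).subset(np.array([False]))
        cand = make_table([[(1, 1)]])
        with pytest.raises(EmptyDataError):
            private_alleles(ref, cand)


def enumerate_pair_compatible(off, mum, dad):
    """Oracle: explicit enumeration of one-from-each-parent allele partitions."""
    ok_loci = []
    for j in range(off.shape[0]):
        if 0 in (off[j, 0], mum[j, 0], dad[j, 0]):
            ok_loci.append(True)  # untyped locus cannot exclude
            continue
        compatible = False
        for a_from_mum, a_from_dad in itertools.permutations(off[j], 2):
            if a_from_mum in mum[j] and a_from_dad in dad[j]:
                compatible = True
        ok_loci.append(compatible)
    return ok_loci


class TestParentage:
    def test_no_shared_allele_excluded_at_zero_tolerance(self):
        off = make_table([[(1, 2)]], prefix="O")
        cand = make_table([[(3, 4)], [(1, 3)]])
        res = parentage_exclusion(0, off, cand)
        assert res.mismatch_counts == {"I000": 1, "I001": 0}
        assert "I000" not in res.compatible_mothers

    def test_tolerance_one_retains_single_mismatch(self):
        off = make_table([[(1, 2), (5, 6)]], prefix="O")
        cand = make_table([[(3, 4), (5, 5)]])  # one mismatching locus
        strict = parentage_exclusion(0, off, cand, mismatch_tolerance=0)
        relaxed = parentage_exclusion(0, off, cand, mismatch_tolerance=1)
        assert not strict.compatible_mothers
        assert relaxed.compatible_mothers == ["I000"]

    def test_all_missing_offspring_rejected(self):
        off = make_table([[(0, 0)]], prefix="O")
        cand = make_table([[(1, 1)]])
        with pytest.raises(EmptyDataError):
            parentage_exclusion(0, off, cand)

    def test_pair_compatibility_matches_enumeration_on_two_locus_cases(self):
        # all ordered 2-locus genotype triples over alleles {1, 2, 3}
        rng = np.random.default_rng(9)
        for _ in range(300):
            off_g = rng.integers(1, 4, (1, 2, 2))
            mum_g = rng.integers(1, 4, (2, 2))
            dad_g = rng.integers(1, 4, (2, 2))
            off = make_table(off_g.tolist(), prefix="O")
            cand = make_table([mum_g.tolist(), dad_g.tolist()])
            res = parentage_exclusion(
                0, off, cand,
                candidate_sex={"I000": "female", "I001": "male"},
            )
            oracle = all(enumerate_pair_compatible(off_g[0], mum_g, dad_g))
            # the pair can only appear if both pass the single-parent screen
            singles_ok = (
                res.mismatch_counts["I000"] == 0
                and res.mismatch_counts["I001"] == 0
            )
            assert (("I000", "I001") in res.compatible_pairs) == (
                oracle and singles_ok
            )

    def test_true_parents_always_compatible_in_clean_trios(self):
        rng = np.random.default_rng(21)
        off, cand, truth = synthdata.simulate_pedigree_trios(rng, n_trios=30)
        sex = dict(zip(cand.meta["individual_id"], cand.meta["sex"]))
        for _, row in truth.iterrows():
            res = parentage_exclusion(row["offspring_id"], off, cand,
                                      candidate_sex=sex)
            assert row["mother"] in res.compatible_mothers
            assert row["father"] in res.compatible_fathers
            assert (row["mother"], row["father"]) in res.compatible_pairs
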