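from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from patgwas.replication import (
    clump,
    concordance_binomial,
    one_sided_replication_test,
    power_decile_table,
    replication_power,
)


def brute_force_clump(df, window_bp=1_000_000, largest=True):
    """Independent oracle: plain-python greedy with the same tie rule."""
    remaining = df.reset_index(drop=True).to_dict("records")
    for i, r in enumerate(remaining):
        r["_i"] = i
    leads = []
    half = window_bp // 2
    while remaining:
        best = None
        for r in remaining:
            if best is None:
                best = r
                continue
            better = r["m"] > best["m"] if largest else r["m"] < best["m"]
            if better or (
                r["m"] == best["m"]
                and (r["chrom"], r["pos"]) < (best["chrom"], best["pos"])
            ):
                best = r
        leads.append(best["_i"])
        remaining = [
            r
            for r in remaining
            if not (
                r["chrom"] == best["chrom"]
                and best["pos"] - half <= r["pos"] < best["pos"] + half
            )
        ]
    return leads


class TestClump:
    def test_within_window_suppression(self):
        df = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [1_000_000, 1_400_000], "m": [0.99, 0.95]}
        )
        out = clump(df)
        assert len(out) == 1 and out["m"].iloc[0] == 0.99

    def test_outside_window_both_retained(self):
        df = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [1_000_000, 2_500_000], "m": [0.99, 0.95]}
        )
        assert len(clump(df)) == 2

    def test_different_chromosomes_never_suppress(self):
        df = pd.DataFrame(
            {"chrom": ["1", "2"], "pos": [1_000_000, 1_000_100], "m": [0.99, 0.95]}
        )
        assert len(clump(df)) == 2

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2", "3"], size=100),
                "pos": rng.integers(1, 20_000_000, size=100),
                "m": np.round(rng.uniform(0.5, 1.0, size=100), 3),
            }
        )
        got = clump(df)["pos"].tolist()
        oracle = df.iloc[brute_force_clump(df)]["pos"].tolist()
        assert got == oracle

    def test_smallest_p_rule(self):
        df = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [1_000_000, 1_200_000], "p": [1e-9, 1e-12]}
        )
        out = clump(df, score="p")
        assert out["p"].iloc[0] == 1e-12

    def test_no_two_leads_share_a_window(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], size=200),
                "pos": rng.integers(1, 10_000_000, size=200),
                "m": rng.uniform(size=200),
            }
        )
        out = clump(df)
        for c, grp in out.groupby("chrom"):
            pos = np.sort(grp["pos"].to_numpy())
            assert np.all(np.diff(pos) >= 500_000)


class TestOneSidedReplication:
    def test_null_center_gives_half(self):
        p, rep = one_sided_replication_test(0.1, 0.0, 0.05, 1e-4)
        assert p == pytest.approx(0.5) and not rep

    def test_negative_direction_tail(self):
        # both effects negative, |z| = 3.9 -> p = 1 - Phi(3.9)
        p, rep = one_sided_replication_test(-0.2, -0.039, 0.01, 1.22e-4)
        assert p == pytest.approx(norm.sf(3.9), rel=1e-10)
        assert p == pytest.approx(4.81e-5, rel=1e-2)
        assert rep

    def test_bonferroni_threshold_matches_printed_level(self):
        assert 0.05 / 408 == pytest.approx(1.22e-4, rel=5e-3)
        assert 0.05 / 735 == pytest.approx(6.80e-5, rel=5e-3)

    def test_zero_discovery_effect_is_an_error(self):
        with pytest.raises(ValueError, match="direction"):
            one_sided_replication_test(0.0, 0.1, 0.05, 0.05)

    def test_replicated_implies_same_direction(self):
        rng = np.random.default_rng(2)
        bd = rng.normal(size=500)
        bd[bd == 0] = 0.1
        br = rng.normal(size=500) * 0.02
        p, rep = one_sided_replication_test(bd, br, 0.01, 0.05)
        same = np.sign(bd) == np.sign(br)
        assert np.all(same[rep])


class TestConcordanceBinomial:
    def test_single_coin(self):
        assert concordance_binomial(1, 1) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "n_same,n_total,expected",
        [(378, 408, 4.34e-78), (716, 735, 1.06e-184), (209, 218, 6.43e-51)],
    )
    def test_extreme_tails_to_printed_precision(self, n_same, n_total, expected):
        assert concordance_binomial(n_same, n_total) == pytest.approx(
            expected, rel=5e-3
        )

    def test_matches_exact_fraction_summation_small_n(self):
        for n_total in (1, 5, 17, 30):
            for n_same in (0, n_total // 2, n_total):
                exact = Fraction(
                    sum(comb(n_total, k) for k in range(n_same, n_total + 1)),
                    2**n_total,
                )
                assert concordance_binomial(n_same, n_total) == pytest.approx(
                    float(exact), rel=1e-12
                )

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            concordance_binomial(5, 3)


class TestReplicationPower:
    def test_zero_effect_power_equals_size(self):
        alpha = 1.22e-4
        assert replication_power(0.0, 0.3, 100_000, alpha) == pytest.approx(alpha)

    def test_monotone_in_n_and_effect(self):
        alpha = 1e-4
        p1 = replication_power(0.02, 0.3, 50_000, alpha)
        p2 = replication_power(0.02, 0.3, 200_000, alpha)
        p3 = replication_power(0.04, 0.3, 50_000, alpha)
        assert p2 > p1 and p3 > p1

    def test_noncentrality_at_threshold_gives_half(self):
        # lambda = Phi^-1(1 - alpha) puts the mean exactly on the cutoff
        alpha = 0.01
        lam = norm.isf(alpha)
        maf, n = 0.25, 10_000.0
        beta = lam / np.sqrt(2 * maf * (1 - maf) * n)
        assert replication_power(beta, maf, n, alpha) == pytest.approx(0.5)

    def test_invalid_maf(self):
        with pytest.raises(ValueError, match="maf"):
            replication_power(0.1, 0.7, 1000, 0.05)


class TestPowerDeciles:
    def test_expected_matches_observed_in_synthetic_cohort(self):
        # fully synthetic replication cohort with known true effects: within
        # each decile the observed replication count must sit within 3
        # binomial SDs of the summed power
        rng = np.random.default_rng(3)
        n = 4000
        alpha = 1e-3
        maf = rng.uniform(0.05, 0.5, size=n)
        n_rep = 100_000
        beta = rng.normal(0.0, 0.008, size=n)
        beta[beta == 0] = 0.001
        lam = np.abs(beta) * np.sqrt(2 * maf * (1 - maf) * n_rep)
        # replication z centred on the true (= discovery) effect
        z = rng.normal(loc=lam, scale=1.0)
        p = norm.sf(z)
        replicated = p < alpha
        power = replication_power(beta, maf, n_rep, alpha)
        table = power_decile_table(power, replicated, z > 0)
        for _, row in table.iterrows():
            if row["n_variants"] == 0:
                continue
            exp = row["expected_replications"]
            sd = max(np.sqrt(exp * (1 - exp / max(row["n_variants"], 1))), 1.0)
            assert abs(row["observed_replications"] - exp) <= 3 * sd

    def test_decile_binning_covers_unit_interval(self):
        power = np.array([0.0, 0.05, 0.15, 0.95, 1.0])
        t = power_decile_table(power, np.zeros(5, bool), np.ones(5, bool))
        assert t["n_variants"].sum() == 5
        assert t.loc[0, "n_variants"] == 2  # 0.0 and 0.05
        assert t.loc[9, "n_variants"] == 2  # 0.95 and 1.0
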