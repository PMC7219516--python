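"""Usage tables, Fisher/FDR comparisons, mutation binning and KW/Dunn tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from bcrep import (
    EmptyInputError,
    ParameterError,
    compare_mutation,
    compare_usage,
    cdr3_length_compare,
    dunn_posthoc,
    mutation_profile,
    usage_table,
)
from bcrep.stats import MUTATION_BIN_LABELS, _bin_fractions, _fisher_label


def _lin_df(genes, donor="d1", subset="naive", mut=None, cdr3_aa=None):
    n = len(genes)
    return pd.DataFrame(
        {
            "lineage_id": [f"L{i}" for i in range(n)],
            "donor_id": donor,
            "subset": subset,
            "locus": "IGH",
            "v_call": genes,
            "v_family": [g.split("-")[0] for g in genes],
            "j_call": "IGHJ4",
            "cdr3_aa": cdr3_aa if cdr3_aa is not None else ["ARGW"] * n,
            "v_identity_pct": 100.0 - np.asarray(mut if mut is not None else [0.0] * n),
        }
    )


class TestUsageTable:
    def test_counting_forces_frequencies(self):
        lin = _lin_df(["IGHV3-7", "IGHV3-7", "IGHV1-69", "IGHV6-1"])
        gene = usage_table(lin, level="gene", segment="V")
        assert gene.frequencies.loc["IGHV3-7", ("d1", "naive")] == 50.0
        assert gene.frequencies.loc["IGHV1-69", ("d1", "naive")] == 25.0
        fam = usage_table(lin, level="family", segment="V")
        assert fam.frequencies.loc["IGHV3", ("d1", "naive")] == 50.0
        assert fam.frequencies.loc["IGHV1", ("d1", "naive")] == 25.0
        assert fam.frequencies.loc["IGHV6", ("d1", "naive")] == 25.0

    def test_single_lineage_is_100_percent(self):
        t = usage_table(_lin_df(["IGHV3-7"]))
        assert t.frequencies.iloc[0, 0] == 100.0

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            usage_table(_lin_df([]).iloc[:0])

    def test_stratum_sums_and_pooling(self, lineages_small):
        t = usage_table(lineages_small, level="gene", segment="V")
        assert np.allclose(t.frequencies.sum(axis=0), 100.0, atol=1e-6)
        manual = t.counts.T.groupby(level="subset").sum().T
        assert t.pooled.equals(manual)

    def test_simulated_frequencies_near_configured(self, sim_small, lineages_small):
        _, truth = sim_small
        cfg = truth.config
        sub = lineages_small[lineages_small["subset"] == "naive"]
        n = len(sub)
        freq = sub["v_call"].value_counts() / n
        for gene, p in zip(cfg.v_genes, cfg.v_usage["naive"]):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq.get(gene, 0.0) - p) <= 4 * se  # 3 s.e. + slack for 20 tests


class TestCompareUsage:
    @staticmethod
    def fisher_two_sided_oracle(a, b, c, d):
        """Exhaustive hypergeometric enumeration of the two-sided p-value."""
        n1, n2 = a + b, c + d
        k = a + c
        rv = hypergeom(n1 + n2, n1, k)
        p_obs = rv.pmf(a)
        return sum(
            rv.pmf(x) for x in range(max(0, k - n2), min(k, n1) + 1)
            if rv.pmf(x) <= p_obs * (1 + 1e-9)
        )

    def test_symmetric_table_is_null(self):
        odds, p = _fisher_label(50, 1000, 50, 1000)
        assert odds == 1.0 and p == 1.0

    @pytest.mark.parametrize("table", [(10, 90, 30, 70), (3, 7, 9, 1), (0, 12, 5, 5)])
    def test_fisher_matches_enumeration(self, table):
        a, b, c, d = table
        _, p = _fisher_label(a, a + b, c, c + d)
        assert p == pytest.approx(self.fisher_two_sided_oracle(a, b, c, d), abs=1e-10)

    def test_fisher_matches_oracle_on_all_small_margins(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b == 0 or c + d == 0:
                continue
            _, p = _fisher_label(int(a), int(a + b), int(c), int(c + d))
            assert p == pytest.approx(
                self.fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), abs=1e-9
            )

    def test_bh_adjustment_and_consistency_flags(self, lineages_small):
        t = usage_table(lineages_small, level="gene", segment="V")
        res = compare_usage(t, "IgM_lo", "IgM_hi")
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert res["consistent"].dtype == bool
        # consistency requires every donor individually significant
        donors = [c for c in res.columns if c.startswith("p_donor")]
        for _, row in res[res["consistent"]].iterrows():
            assert all(row[c] < 0.05 for c in donors)

    def test_absent_subset_errors(self, lineages_small):
        t = usage_table(lineages_small)
        with pytest.raises(ParameterError):
            compare_usage(t, "naive", "plasma")


class TestMutationProfile:
    def test_bin_edges(self):
        fracs = _bin_fractions(np.array([0.0, 1.9, 2.0, 11.0]))
        assert np.allclose(fracs, [0.5, 0.25, 0, 0, 0, 0.25])

    def test_all_zero_goes_to_first_bin(self):
        assert _bin_fractions(np.zeros(7))[0] == 1.0

    def test_exactly_ten_is_fifth_bin(self):
        fracs = _bin_fractions(np.array([10.0]))
        assert fracs[4] == 1.0 and fracs[5] == 0.0

    def test_fractions_sum_to_one_per_stratum(self, lineages_small):
        prof = mutation_profile(lineages_small)
        assert np.allclose(prof.bins[list(MUTATION_BIN_LABELS)].sum(axis=1), 1.0,
                           atol=1e-9)
        assert np.allclose(prof.bins_pooled.sum(axis=1), 1.0, atol=1e-9)

    def test_simulated_mean_matches_binomial_expectation(self, sim_small, lineages_small):
        _, truth = sim_small
        for subset, (a, b) in truth.config.shm.items():
            sub = lineages_small[lineages_small["subset"] == subset]
            mut = 100.0 - sub["v_identity_pct"]
            expect = 100.0 * a / (a + b)
            se = mut.std(ddof=1) / math.sqrt(len(mut))
            assert abs(mut.mean() - expect) <= 3 * se


class TestKruskalDunn:
    def test_disjoint_supports_are_overwhelmingly_significant(self):
        rng = np.random.default_rng(5)
        lin = pd.concat(
            [
                _lin_df([f"IGHV3-{i}" for i in range(30)], subset="naive",
                        mut=rng.uniform(0, 1, 30)),
                _lin_df([f"IGHV3-{i}" for i in range(30)], subset="IgM_hi",
                        mut=rng.uniform(10, 11, 30)),
            ],
            ignore_index=True,
        )
        omnibus_p, pairwise = compare_mutation(lin)
        # closed form: mean ranks 45.5 (IgM_hi, sorted first) vs 15.5 (naive):
        # z = 30/sqrt((60*61/12)*(2/30))
        z_expect = 30.0 / math.sqrt((60 * 61 / 12) * (2 / 30))
        assert pairwise.iloc[0]["z"] == pytest.approx(z_expect)
        assert pairwise.iloc[0]["p_adj"] < 1e-6
        assert omnibus_p < 1e-6

    def test_identical_values_everywhere_yield_p_one(self):
        lin = pd.concat(
            [_lin_df(["IGHV3-7"] * 5, subset=s, mut=[2.0] * 5)
             for s in ("naive", "IgM_lo", "IgM_hi")],
            ignore_index=True,
        )
        omnibus_p, pairwise = compare_mutation(lin)
        assert omnibus_p == 1.0
        assert (pairwise["p_adj"] == 1.0).all()

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ParameterError):
            compare_mutation(_lin_df(["IGHV3-7"] * 5, mut=[1, 2, 3, 4, 5]))

    def test_dunn_correction_bounds(self):
        rng = np.random.default_rng(1)
        groups = {s: rng.normal(size=12) for s in "abcd"}
        res = dunn_posthoc(groups, correction="bonferroni")
        assert ((res["p_adj"] >= res["p"] - 1e-12) & (res["p_adj"] <= 1.0)).all()

    def test_cdr3_length_compare(self):
        same = pd.concat(
            [_lin_df(["IGHV3-7"] * 10, subset=s, cdr3_aa=["A" * 14] * 10)
             for s in ("naive", "IgM_hi")],
            ignore_index=True,
        )
        p_same, pw_same, summary = cdr3_length_compare(same)
        assert p_same == 1.0 and (pw_same["p_adj"] == 1.0).all()
        assert set(summary["median"]) == {14.0}

        diff = pd.concat(
            [_lin_df(["IGHV3-7"] * 10, subset="naive", cdr3_aa=["A" * 10] * 10),
             _lin_df(["IGHV3-7"] * 10, subset="IgM_hi", cdr3_aa=["A" * 20] * 10)],
            ignore_index=True,
        )
        p_diff, pw_diff, _ = cdr3_length_compare(diff)
        assert p_diff < 1e-4 and (pw_diff["p_adj"] < 1e-3).all()
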