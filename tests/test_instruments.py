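import itertools

import numpy as np
import pandas as pd
import pytest

from mrkit import instruments
from mrkit.exceptions import ConfigurationError, MissingLdError, NoInstrumentsError
from mrkit.instruments import InstrumentConfig, LdInfo
from mrkit.simulate import SimulationConfig, simulate_univariable

from conftest import make_summary


class TestSignificanceFilter:
    def test_strict_inequality(self):
        data = make_summary(
            ["rs1", "rs2", "rs3"], [0.1] * 3, [0.01] * 3, pval=[1e-9, 1e-7, 1e-8]
        )
        kept = instruments.filter_significance(data, 5e-8)
        assert list(kept.df["variant_id"]) == ["rs1", "rs3"]

    def test_all_nonsignificant_empty(self):
        data = make_summary(["rs1", "rs2"], [0.1] * 2, [0.1] * 2, pval=[0.5, 0.5])
        assert instruments.filter_significance(data, 5e-8).n_records == 0

    def test_planted_instruments_recovered(self):
        # 50 strong signals among 1000 variants at biobank sample size
        exposure, _, truth = simulate_univariable(
            SimulationConfig(seed=42, n_snps=1000, instrument_effect_sd=0.03)
        )
        strong = exposure.df["pval"] < 5e-8
        true_f = truth.gamma**2 * (2 * 0.275 * 0.725 * 400_000)
        planted = np.argsort(true_f)[-50:]
        kept = instruments.filter_significance(exposure, 5e-8)
        assert set(exposure.df.loc[planted, "variant_id"]) <= set(
            kept.df["variant_id"]
        )
        assert strong.sum() == kept.n_records


class TestFStatistics:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.1, 0.01, 100.0), (0.0, 0.05, 0.0), (0.03, 0.02, 2.25)],
    )
    def test_f_formula(self, beta, se, expected):
        data = make_summary(["rs1"], [beta], [se], pval=[0.5])
        f = instruments.compute_f_statistics(data)
        assert f.loc[0, "F"] == pytest.approx(expected)

    def test_sign_invariance(self, rng):
        beta = rng.normal(size=20)
        se = rng.uniform(0.01, 0.1, size=20)
        pos = make_summary([f"rs{i}" for i in range(20)], beta, se, pval=[0.5] * 20)
        neg = make_summary([f"rs{i}" for i in range(20)], -beta, se, pval=[0.5] * 20)
        np.testing.assert_allclose(
            instruments.compute_f_statistics(pos)["F"],
            instruments.compute_f_statistics(neg)["F"],
        )


def _brute_force_clump(df, r2_lookup, kb, r2_max):
    """Exhaustive greedy reference: same rule, independent implementation."""
    remaining = df.sort_values(["pval", "variant_id"]).to_dict("records")
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index["variant_id"])
        survivors = []
        for row in remaining:
            linked = False
            if row["chromosome"] == index["chromosome"] and abs(
                row["position"] - index["position"]
            ) <= kb * 1000:
                key = tuple(sorted([row["variant_id"], index["variant_id"]]))
                linked = r2_lookup.get(key, 1.0) > r2_max
            if not linked:
                survivors.append(row)
        remaining = survivors
    return kept


class TestClump:
    def test_linked_pair_keeps_smaller_p(self):
        data = make_summary(
            ["rsA", "rsB"], [0.1, 0.1], [0.01, 0.01], pval=[1e-20, 1e-9],
            pos=[1000, 6000],
        )
        ld = LdInfo.from_pairs([("rsA", "rsB", 0.9)])
        kept = instruments.clump(data, ld, clump_kb=10, clump_r2=0.001)
        assert list(kept.df["variant_id"]) == ["rsA"]

    def test_different_chromosomes_both_kept(self):
        data = make_summary(
            ["rsA", "rsB"], [0.1, 0.1], [0.01, 0.01], pval=[1e-20, 1e-9],
            chrom=["1", "2"], pos=[1000, 1000],
        )
        kept = instruments.clump(data, LdInfo(), clump_kb=10, clump_r2=0.001)
        assert set(kept.df["variant_id"]) == {"rsA", "rsB"}

    def test_missing_ld_same_window_treated_linked_or_error(self):
        data = make_summary(
            ["rsA", "rsB"], [0.1, 0.1], [0.01, 0.01], pval=[1e-20, 1e-9],
            pos=[1000, 6000],
        )
        kept = instruments.clump(data, LdInfo(), clump_kb=10, clump_r2=0.001)
        assert list(kept.df["variant_id"]) == ["rsA"]
        with pytest.raises(MissingLdError):
            instruments.clump(
                data, LdInfo(), clump_kb=10, clump_r2=0.001, missing_ld="error"
            )

    def test_ten_snp_window_matches_brute_force(self, rng):
        n = 10
        ids = [f"rs{i:02d}" for i in range(n)]
        pvals = rng.uniform(1e-30, 1e-8, size=n)
        data = make_summary(ids, [0.1] * n, [0.01] * n, pval=pvals,
                            pos=list(range(1000, 1000 + n)))
        lookup = {}
        ld = LdInfo()
        for a, b in itertools.combinations(ids, 2):
            r2 = float(rng.uniform(0, 1)) if rng.random() < 0.5 else 0.0
            lookup[tuple(sorted([a, b]))] = r2
            ld.set_r2(a, b, r2)
        kept = instruments.clump(data, ld, clump_kb=10_000, clump_r2=0.001)
        expected = _brute_force_clump(data.df, lookup, 10_000, 0.001)
        assert list(kept.df["variant_id"]) == expected

    def test_row_order_invariance(self, rng):
        n = 8
        ids = [f"rs{i:02d}" for i in range(n)]
        pvals = [1e-10] * n  # all tied: variant_id breaks ties
        data = make_summary(ids, [0.1] * n, [0.01] * n, pval=pvals,
                            pos=[1000 + 100 * i for i in range(n)])
        ld = LdInfo()
        for a, b in itertools.combinations(ids, 2):
            ld.set_r2(a, b, 0.5 if (a, b) == ("rs00", "rs01") else 0.0)
        shuffled = data.df.sample(frac=1, random_state=3)
        data2 = make_summary(
            list(shuffled["variant_id"]),
            list(shuffled["beta"]),
            list(shuffled["se"]),
            pval=list(shuffled["pval"]),
            pos=list(shuffled["position"]),
        )
        k1 = instruments.clump(data, ld, 10, 0.001)
        k2 = instruments.clump(data2, ld, 10, 0.001)
        assert list(k1.df["variant_id"]) == list(k2.df["variant_id"])

    def test_independent_mode_removes_only_duplicates(self):
        data = make_summary(
            ["rsA", "rsB", "rsC"], [0.1] * 3, [0.01] * 3,
            pval=[1e-20, 1e-9, 1e-10], pos=[1000, 1000, 2000],
        )
        kept = instruments.clump(data, LdInfo.make_independent(), 10_000, 0.001)
        assert set(kept.df["variant_id"]) == {"rsA", "rsC"}


class TestSelectInstruments:
    def test_identity_when_all_pass(self):
        data = make_summary(
            ["rs1", "rs2"], [0.5, 0.6], [0.01, 0.01], pval=[1e-20, 1e-30],
            chrom=["1", "2"],
        )
        result = instruments.select_instruments(
            data, LdInfo.make_independent(), InstrumentConfig()
        )
        assert set(result.data.df["variant_id"]) == {"rs1", "rs2"}
        assert result.stage_counts == {
            "input": 2, "significance": 2, "clump": 2, "f_filter": 2,
        }

    def test_planted_attrition_matches_handmade_oracle(self, rng):
        # 120 significant (3 weak), 80 non-significant, 8 LD pairs to prune
        ids = [f"rs{i:03d}" for i in range(200)]
        pval = np.concatenate([np.full(120, 1e-12), np.full(80, 1e-3)])
        beta = np.concatenate([np.full(117, 0.5), np.full(3, 0.01), np.full(80, 0.5)])
        se = np.full(200, 0.01)
        # place 8 pairs of significant SNPs 1 kb apart, everything else far
        pos = (np.arange(200) * 100_000).tolist()
        for k in range(8):
            pos[2 * k + 1] = pos[2 * k] + 1000
        data = make_summary(ids, beta, se, pval=pval, pos=pos)
        ld = LdInfo()
        for k in range(8):
            ld.set_r2(ids[2 * k], ids[2 * k + 1], 0.95)
        result = instruments.select_instruments(
            data, ld, InstrumentConfig(clump_kb=10, f_min=10)
        )
        assert result.stage_counts["significance"] == 120
        assert result.stage_counts["clump"] == 112  # 8 partners removed
        assert result.stage_counts["f_filter"] == 112 - 3  # F = 1 for weak trio
        counts = list(result.stage_counts.values())
        assert counts == sorted(counts, reverse=True)

    def test_error_names_emptying_stage(self):
        data = make_summary(["rs1"], [0.1], [0.1], pval=[0.5])
        with pytest.raises(NoInstrumentsError) as err:
            instruments.select_instruments(data, LdInfo.make_independent())
        assert err.value.stage == "significance"

        weak = make_summary(["rs1"], [0.01], [0.01], pval=[1e-20])
        with pytest.raises(NoInstrumentsError) as err:
            instruments.select_instruments(weak, LdInfo.make_independent())
        assert err.value.stage == "f_filter"


class TestLdInfo:
    def test_symmetric_lookup_and_validation(self):
        ld = LdInfo.from_pairs([("a", "b", 0.3)])
        assert ld.r2("b", "a") == 0.3
        assert ld.r2("a", "a") == 1.0
        assert ld.r2("a", "zz") is None
        with pytest.raises(ConfigurationError):
            ld.set_r2("a", "c", 1.5)

    def test_matrix_and_tsv_sources_agree(self, tmp_path):
        ids = ["rs1", "rs2", "rs3"]
        mat = pd.DataFrame(
            [[1.0, 0.2, 0.0], [0.2, 1.0, 0.7], [0.0, 0.7, 1.0]],
            index=ids, columns=ids,
        )
        from_matrix = LdInfo.from_matrix(mat)
        tsv = tmp_path / "ld.tsv"
        tsv.write_text(
            "variant_a\tvariant_b\tr2\nrs1\trs2\t0.2\nrs1\trs3\t0.0\nrs2\trs3\t0.7\n"
        )
        from_tsv = LdInfo.read_tsv(tsv)
        for a in ids:
            for b in ids:
                assert from_matrix.r2(a, b) == pytest.approx(from_tsv.r2(a, b))
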