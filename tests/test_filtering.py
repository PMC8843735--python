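import numpy as np
import pandas as pd
import pytest

from tumorevo import filtering as flt
from tumorevo.filtering import (
    CallerConflictError,
    UndefinedValueError,
    compute_maf,
    copy_number_at,
    count_impactful_variants,
    flag_expressed,
    high_quality_subset,
    high_quality_union,
    maf_purity_correlation,
    merge_caller_calls,
    nonprivate_filter,
    recurrent_impact_selection,
    reinterrogate,
)
from tumorevo.stats import DegenerateDataError, InsufficientDataError

from conftest import make_samples, make_table


@pytest.mark.parametrize(
    "alt,ref,expected", [(10, 90, 0.10), (0, 50, 0.0), (7, 13, 0.35)]
)
def test_compute_maf(alt, ref, expected):
    assert compute_maf(alt, ref) == pytest.approx(expected)


def test_compute_maf_zero_depth_undefined():
    with pytest.raises(UndefinedValueError):
        compute_maf(0, 0)


class TestMergeCallers:
    def _caller_df(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "variant_id", "alt_count", "ref_count", "pass"]
        )

    def test_union_and_pass_all_semantics(self):
        r = ("s1", "v1", 10, 90, True)
        per_caller = {
            "a": self._caller_df([r]),
            "b": self._caller_df([("s1", "v1", 10, 90, True), ("s1", "v2", 5, 95, True)]),
            "c": self._caller_df([r]),
        }
        table = merge_caller_calls(per_caller, make_samples(["s1"]))
        obs = table.observations.set_index("variant_id")
        # PASS in all three callers -> pass_all
        assert bool(obs.loc["v1", "pass_all"])
        # called by only one caller -> retained, pass_all False
        assert not bool(obs.loc["v2", "pass_all"])
        assert bool(obs.loc["v2", "pass_any"])

    def test_pass_in_one_of_three_retained(self):
        per_caller = {
            "a": self._caller_df([("s1", "v1", 8, 92, True)]),
            "b": self._caller_df([("s1", "v1", 8, 92, False)]),
            "c": self._caller_df([("s1", "v1", 8, 92, False)]),
        }
        table = merge_caller_calls(per_caller, make_samples(["s1"]))
        row = table.observations.iloc[0]
        assert row["pass_any"] and not row["pass_all"]

    def test_empty_inputs_give_empty_table(self):
        empty = self._caller_df([])
        table = merge_caller_calls(
            {"a": empty, "b": empty, "c": empty}, make_samples([])
        )
        assert table.observations.empty

    def test_conflicting_counts_raise(self):
        per_caller = {
            "a": self._caller_df([("s1", "v1", 10, 90, True)]),
            "b": self._caller_df([("s1", "v1", 11, 89, True)]),
        }
        with pytest.raises(CallerConflictError):
            merge_caller_calls(per_caller, make_samples(["s1"]))


class TestImpactCounting:
    def test_counts_high_impact_above_maf(self):
        rows = (
            [{"sample_id": "s1", "variant_id": f"h{i}", "alt_count": 20,
              "ref_count": 80, "impact": "HIGH"} for i in range(3)]
            + [{"sample_id": "s1", "variant_id": f"l{i}", "alt_count": 40,
                "ref_count": 60, "impact": "LOW"} for i in range(2)]
        )
        table = make_table(rows)
        assert count_impactful_variants(table)["s1"] == 3

    def test_maf_exactly_at_threshold_excluded(self):
        table = make_table(
            [{"sample_id": "s1", "variant_id": "v", "alt_count": 5,
              "ref_count": 95, "impact": "HIGH"}]
        )
        assert count_impactful_variants(table, min_maf=0.05)["s1"] == 0

    def test_sample_without_variants_counts_zero(self):
        table = make_table(
            [{"sample_id": "s1", "variant_id": "v", "alt_count": 20,
              "ref_count": 80, "impact": "HIGH"}],
            sample_ids=["s1", "s2"],
        )
        assert count_impactful_variants(table)["s2"] == 0


class TestHighQualityAndRescue:
    def test_high_quality_requires_pass_all_and_maf(self, toy_table):
        hq = high_quality_subset(toy_table)
        # v1 pass-all at maf .20/.30 in s1/s3; s2 row not called
        assert hq["s1"] == {"v1"}
        assert hq["s3"] == {"v1"}
        assert hq["s2"] == set()
        # v2 in s1 has maf .40 but one caller failed -> dropped

    def test_rescue_marks_low_maf_carrier(self, toy_table):
        rescued = reinterrogate(toy_table, high_quality_union(toy_table))
        obs = rescued.observations.set_index(["sample_id", "variant_id"])
        # v1 in s2: maf 0.03, no caller PASS, but HQ elsewhere + alt reads
        assert bool(obs.loc[("s2", "v1"), "rescued"])

    def test_never_hq_never_rescued(self, toy_table):
        rescued = reinterrogate(toy_table, high_quality_union(toy_table))
        obs = rescued.observations
        assert not obs.loc[obs["variant_id"] == "v3", "rescued"].any()

    def test_zero_alt_reads_not_rescued(self, toy_table):
        rescued = reinterrogate(toy_table, {"v2"})
        obs = rescued.observations.set_index(["sample_id", "variant_id"])
        assert not bool(obs.loc[("s2", "v2"), "rescued"])

    def test_rescue_never_removes_observations(self, toy_table):
        before = toy_table.observations
        after = reinterrogate(toy_table, high_quality_union(toy_table)).observations
        assert len(after) == len(before)
        assert (after["rescued"] | ~before["rescued"]).all()


class TestSharingFilters:
    def test_nonprivate_threshold(self, toy_table):
        rescued = reinterrogate(toy_table, high_quality_union(toy_table))
        shared = nonprivate_filter(rescued, min_samples=2)
        assert "v1" in shared  # 3 samples after rescue
        assert "v3" not in shared  # private to s3
        assert nonprivate_filter(rescued, min_samples=1) >= shared

    def test_flag_expressed_thresholds(self):
        rna = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s1"],
                "variant_id": ["v1", "v2", "v3"],
                "supporting_read_count": [5, 0, 2],
            }
        )
        assert flag_expressed({"v1", "v2", "v3"}, rna) == {"v1", "v3"}
        assert flag_expressed({"v1", "v2", "v3"}, rna, min_reads=3) == {"v1"}

    def test_recurrent_selection_matches_enumeration(self, rng):
        # brute-force oracle over a random 10-variant toy cohort
        samples = [f"s{i}" for i in range(4)]
        rows = []
        for v in range(10):
            for s in samples:
                alt = int(rng.integers(0, 30))
                rows.append(
                    {
                        "sample_id": s,
                        "variant_id": f"v{v}",
                        "alt_count": alt,
                        "ref_count": 100 - alt,
                        "pass_c1": alt > 0 and rng.random() > 0.3,
                        "pass_c2": alt > 0 and rng.random() > 0.3,
                        "pass_c3": alt > 0 and rng.random() > 0.3,
                    }
                )
        table = make_table(rows, sample_ids=samples)
        expressed = {f"v{v}" for v in range(0, 10, 2)}
        got = recurrent_impact_selection(table, expressed, 3, 0.05)
        obs = table.observations
        expect = set()
        for v in obs["variant_id"].unique():
            sub = obs[(obs["variant_id"] == v) & (obs["pass_any"] | obs["rescued"])]
            if (
                sub["sample_id"].nunique() >= 3
                and (sub["maf"] > 0.05).any()
                and v in expressed
            ):
                expect.add(v)
        assert got == expect

    def test_filters_shrink_as_thresholds_tighten(self, rng):
        samples = [f"s{i}" for i in range(5)]
        rows = []
        for v in range(15):
            for s in samples:
                alt = int(rng.integers(0, 40))
                rows.append({"sample_id": s, "variant_id": f"v{v}",
                             "alt_count": alt, "ref_count": 100 - alt})
        table = make_table(rows, sample_ids=samples)
        expressed = set(table.observations["variant_id"])
        prev = None
        for ms in (1, 2, 3, 4, 5):
            cur = recurrent_impact_selection(table, expressed, ms, 0.05)
            if prev is not None:
                assert cur <= prev
            prev = cur
        prev = None
        for mm in (0.0, 0.05, 0.1, 0.2, 0.4):
            cur = recurrent_impact_selection(table, expressed, 2, mm)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestRescueSuperset:
    def test_rescue_only_adds_recurrent_variants(self):
        # with heavy caller dropout, rescue recovers a superset
        from tumorevo import synthetic

        for seed in range(3):
            cfg = synthetic.SimulationConfig(
                n_samples_pre=2, n_samples_post=4, n_clones=4,
                mutations_per_clone=15, caller_dropout=0.3, seed=seed,
            )
            cohort = synthetic.simulate_cohort(cfg)
            table = cohort.variants
            expressed = set(table.observations["variant_id"])
            without = recurrent_impact_selection(table, expressed)
            rescued = reinterrogate(table, high_quality_union(table))
            with_rescue = recurrent_impact_selection(rescued, expressed)
            assert with_rescue >= without


class TestMafPurityCorrelation:
    def _table(self, mafs, purity):
        rows = [
            {"sample_id": f"s{i}", "variant_id": "v", "alt_count": int(m * 1000),
             "ref_count": 1000 - int(m * 1000)}
            for i, m in enumerate(mafs)
        ]
        ids = [f"s{i}" for i in range(len(mafs))]
        return make_table(rows, sample_ids=ids,
                          purity={s: p for s, p in zip(ids, purity)})

    def test_proportional_maf_gives_r_one(self):
        purity = [0.4, 0.5, 0.6, 0.8]
        table = self._table([p / 2 for p in purity], purity)
        assert maf_purity_correlation(table, "v").r == pytest.approx(1.0)

    def test_constant_maf_degenerate(self):
        with pytest.raises(DegenerateDataError):
            maf_purity_correlation(self._table([0.3, 0.3, 0.3], [0.4, 0.6, 0.8]), "v")

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            maf_purity_correlation(self._table([0.2, 0.4], [0.5, 0.9]), "v")

    def test_copy_neutral_restriction(self):
        purity = [0.4, 0.5, 0.6, 0.8, 0.9]
        table = self._table([p / 2 for p in purity], purity)
        cn = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(5)],
                "chrom": ["chr1"] * 5,
                "start": [1] * 5,
                "end": [10**6] * 5,
                "cn_total": [2, 2, 2, 2, 4],
            }
        )
        res = maf_purity_correlation(table, "v", cn=cn, copy_neutral_only=True)
        assert res.n == 4
        assert copy_number_at(cn, "s4", "chr1", 100) == 4
        assert copy_number_at(cn, "s4", "chr2", 100) is None
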