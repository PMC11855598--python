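import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonesort import variants as var
from clonesort.sim import driver_clonality_example
from conftest import make_shared_private_table, wide_table


class TestFilterCascade:
    def test_engineered_table_retains_three(self, cascade_table):
        df, pon = cascade_table
        retained, tally = var.apply_filters(df, pon_hits=pon)
        assert tally["retained"] == 3
        assert set(retained["gene"]) == {"primary_pass", "relaxed_pair", "relaxed_second"}
        assert tally == {"panel_of_normals": 1, "vaf_below_min": 1,
                         "insufficient_alt_reads": 1, "retained": 3}

    def test_vaf_floor_discards_high_depth_artifact(self):
        df = wide_table({"artifact": {"A": (10, 2000)}}, ["A"])
        retained, tally = var.apply_filters(df)
        assert len(retained) == 0 and tally["vaf_below_min"] == 1

    def test_relaxed_rule_rescues_sibling_population(self):
        df = wide_table({"shared": {"A": (2, 40), "B": (8, 80)}}, ["A", "B"])
        retained, _ = var.apply_filters(df)
        assert retained["pass_A"].iloc[0] and retained["pass_B"].iloc[0]

    def test_relaxed_rule_never_overrides_vaf_floor(self):
        # 2 alt reads at 0.5% VAF: sibling support must not rescue it
        df = wide_table({"lowvaf": {"A": (2, 400), "B": (80, 200)}}, ["A", "B"])
        retained, _ = var.apply_filters(df)
        assert not retained["pass_A"].iloc[0]
        assert retained["pass_B"].iloc[0]

    def test_panel_of_normals_removes_everywhere(self):
        df = wide_table({"germ": {"A": (50, 100), "B": (40, 100)}}, ["A", "B"])
        pon = pd.Series(2, index=df.index)
        retained, tally = var.apply_filters(df, pon_hits=pon)
        assert len(retained) == 0 and tally["panel_of_normals"] == 1

    def test_unknown_population_raises(self):
        df = wide_table({"v": {"A": (10, 100)}}, ["A"])
        with pytest.raises(ValueError):
            var.apply_filters(df, patient_populations=["B"])

    def test_total_depth_mode(self):
        cfg = var.FilterConfig(count_mode="total")
        df = wide_table({"v": {"A": (2, 2)}}, ["A"])  # VAF 100%, depth 2 < 3
        retained, _ = var.apply_filters(df, cfg)
        assert len(retained) == 0

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_idempotence_and_tally_conservation(self, data):
        n = data.draw(st.integers(1, 30))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        depth = rng.integers(1, 200, size=(n, 2))
        alt = (depth * rng.beta(0.3, 3, size=(n, 2))).astype(int)
        rows = {f"v{i}": {"A": (int(alt[i, 0]), int(depth[i, 0])),
                          "B": (int(alt[i, 1]), int(depth[i, 1]))} for i in range(n)}
        df = wide_table(rows, ["A", "B"])
        retained, tally = var.apply_filters(df)
        assert sum(tally.values()) == n
        again, tally2 = var.apply_filters(retained.drop(
            columns=[c for c in retained.columns if c.startswith("pass_")]))
        assert tally2["retained"] == len(retained)
        pd.testing.assert_frame_equal(again, retained)

    def test_filter_config_invariant(self):
        with pytest.raises(ValueError):
            var.FilterConfig(min_alt_reads=2, shared_min_alt_reads=3)


class TestVariantRecord:
    def test_context_only_for_snvs(self):
        with pytest.raises(ValueError):
            var.VariantRecord("chr1", 5, "AT", "A", context="T[C>T]A")

    def test_vaf(self):
        r = var.VariantRecord("chr1", 5, "A", "T", depths={"A": (10, 90)})
        assert r.vaf("A") == pytest.approx(0.1)

    def test_records_to_frame(self):
        recs = [var.VariantRecord("chr1", 5, "A", "T", gene="NRAS",
                                  effect="non-synonymous", depths={"A": (10, 90)})]
        df = var.records_to_frame(recs, ["A", "B"])
        assert df["alt_A"].iloc[0] == 10 and df["dp_B"].iloc[0] == 0


class TestDrivers:
    def test_non_synonymous_driver_flagged(self):
        df = wide_table({"NRAS": {"A": (30, 100)}}, ["A"])
        flagged, _, _ = var.annotate_drivers(df, ["NRAS"])
        assert flagged["is_driver"].iloc[0]

    def test_synonymous_driver_not_flagged(self):
        df = wide_table({"NRAS": {"A": (30, 100)}}, ["A"])
        df["effect"] = "synonymous"
        flagged, _, summary = var.annotate_drivers(df, ["NRAS"])
        assert not flagged["is_driver"].any() and summary["n_drivers"] == 0

    def test_cohort_example_ten_of_fourteen_clonal(self):
        variants_df, clonality = driver_clonality_example()
        genes = set(variants_df["gene"])
        _, matrix, summary = var.annotate_drivers(variants_df, genes, clonality)
        assert summary["n_drivers"] == 14
        assert summary["n_clonal"] == 10
        assert summary["pct_clonal"] == 71.4
        assert set(np.unique(matrix.to_numpy())) <= {"absent", "clonal", "subclonal"}


class TestTmb:
    def test_arithmetic(self):
        rows = {f"v{i}": {"A": (20, 100)} for i in range(390)}
        df = wide_table(rows, ["A"])
        assert var.tmb(df, "A", callable_mb=30.0) == 13.0

    def test_zero_mutations(self):
        df = wide_table({"v": {"A": (0, 100)}}, ["A"])
        assert var.tmb(df, "A") == 0.0

    def test_invalid_mb(self):
        df = wide_table({"v": {"A": (10, 100)}}, ["A"])
        with pytest.raises(ValueError):
            var.tmb(df, "A", callable_mb=0)

    def test_simulator_truth_division(self):
        rows = {f"v{i}": {"A": (20, 100)} for i in range(357)}
        df = wide_table(rows, ["A"])
        assert var.tmb(df, "A", callable_mb=35.7) == 10.0


class TestSharedPrivate:
    def test_mostly_shared_patient(self):
        df = make_shared_private_table(995, 40, 37)  # 1072 total
        s = var.shared_private_summary(df, ["A", "B"])
        assert s["total"] == 1072 and s["shared_all"] == 995
        assert s["shared_all_pct"] == 92.8

    def test_mostly_private_metastasis(self):
        df = make_shared_private_table(351, 0, 813)  # 1164 total
        s = var.shared_private_summary(df, ["A", "B"])
        assert s["private"] == 813 and s["private_pct"] == 69.8

    def test_fully_shared(self):
        df = make_shared_private_table(10, 0, 0)
        s = var.shared_private_summary(df, ["A", "B"])
        assert s["shared_all_pct"] == 100.0 and s["private_pct"] == 0.0

    def test_percentages_sum_to_hundred(self):
        df = make_shared_private_table(7, 5, 3)
        s = var.shared_private_summary(df, ["A", "B"])
        total_pct = s["shared_all_pct"] + s["shared_some_pct"] + s["private_pct"]
        assert abs(total_pct - 100.0) <= 0.1
        assert s["shared_all"] + s["shared_some"] + s["private"] == s["total"]

    def test_requires_two_populations(self):
        df = wide_table({"v": {"A": (10, 100)}}, ["A"])
        with pytest.raises(ValueError):
            var.shared_private_summary(df, ["A"])
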