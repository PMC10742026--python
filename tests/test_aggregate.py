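"""Compound-level aggregation, prioritization filters, ranks and correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sindex.aggregate import (
    delta_delta_s,
    ds_distribution_summary,
    endpoint_correlation,
    endpoint_means,
    prioritize,
    rank_table,
    summarize_compound,
    summarize_screen,
)
from sindex.config import RunConfig
from sindex.types import CompoundCellScore, PairwiseDelta

TEST_LINES = ["T1", "T2", "T3", "T4"]


def deltas_for(values, compound="CPD", reference="REF"):
    out = []
    for line, v in zip(TEST_LINES, values):
        out.append(PairwiseDelta(
            compound_id=compound, reference_cell_line=reference, test_cell_line=line,
            delta_s=v, call="indeterminate" if v is None else ("resistant" if v > 0 else "sensitive"),
        ))
    return out


def quality_for(compound="CPD", r2=0.95, lines=None, flags=(), reference="REF"):
    q = {}
    for line in (lines or [reference] + TEST_LINES):
        q[(compound, line)] = CompoundCellScore(
            compound_id=compound, cell_line_id=line, eff=100.0, ac50_um=1.0,
            s=2.0, r2=r2, flags=frozenset(flags if line == reference else ()),
        )
    return q


class TestSummarize:
    def test_hand_arithmetic(self):
        s = summarize_compound(deltas_for([-0.5, -0.7, -0.6, -0.8]))
        assert s.ds_mean == pytest.approx(-0.65)
        assert s.ds_variance == pytest.approx(0.0166667, abs=1e-6)
        assert s.ds_variance_of_mean == pytest.approx(0.0166667 / 4, abs=1e-6)
        assert s.n_lines == 4

    def test_single_value_has_no_variance(self):
        s = summarize_compound(deltas_for([1.2, None, None, None]))
        assert s.ds_mean == pytest.approx(1.2)
        assert s.ds_variance is None and s.ds_variance_of_mean is None
        assert s.n_lines == 1 and s.n_indeterminate == 3

    def test_all_indeterminate_excluded(self):
        s = summarize_compound(deltas_for([None, None, None, None]))
        assert s.verdict == "excluded:no_data"
        assert s.ds_mean is None

    def test_matches_two_pass_oracle_on_fuzzed_input(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 2, size=1000).tolist()
        deltas = [PairwiseDelta("C", "REF", f"L{i}", delta_s=v)
                  for i, v in enumerate(values)]
        s = summarize_compound(deltas)
        mean = sum(values) / len(values)                       # naive two-pass
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert s.ds_mean == pytest.approx(mean, abs=1e-12)
        assert s.ds_variance == pytest.approx(var, abs=1e-12)

    def test_mixed_compounds_rejected(self):
        bad = deltas_for([-0.5, -0.6, -0.7, -0.8]) + deltas_for([0.1], compound="OTHER")
        with pytest.raises(ValueError):
            summarize_compound(bad)


class TestPrioritize:
    def run(self, values, r2=0.95, cfg=None, quality=None):
        s = summarize_compound(deltas_for(values))
        (out,) = prioritize([s], quality or quality_for(r2=r2), "REF", TEST_LINES,
                            cfg or RunConfig())
        return out

    def test_strong_sensitive_hit_prioritized(self):
        out = self.run([-0.6, -0.7, -0.6, -0.7])
        assert out.verdict == "sensitive_prioritized"
        assert out.audit["r2_ok"] and out.audit["effect_ok"] and out.audit["noninferiority_ok"]

    def test_below_effect_threshold_never_prioritized(self):
        out = self.run([-0.45, -0.45, -0.45, -0.45])
        assert out.verdict == "not_prioritized"
        assert out.audit["effect_ok"] is False

    def test_non_inferiority_arithmetic(self):
        # ds_mean 0.6 with variance-of-mean 0.25: 0.6 - 0.5 = 0.1 < 0.3
        a = math.sqrt(1.5)  # sample variance of [-a, 0, 0, +a] offsets is 1.0
        s = summarize_compound(deltas_for([0.6 - a, 0.6, 0.6, 0.6 + a]))
        assert s.ds_mean == pytest.approx(0.6)
        assert s.ds_variance_of_mean == pytest.approx(0.25, abs=1e-12)
        (out,) = prioritize([s], quality_for(), "REF", TEST_LINES, RunConfig())
        assert out.audit["noninferiority_margin"] == pytest.approx(0.1, abs=1e-12)
        assert out.audit["noninferiority_ok"] is False
        assert out.verdict == "not_prioritized"

    def test_low_r2_anywhere_blocks(self):
        q = quality_for()
        q[("CPD", "T3")] = CompoundCellScore("CPD", "T3", 100.0, 1.0, 2.0, r2=0.5)
        out = self.run([-0.9, -0.9, -0.9, -0.9], quality=q)
        assert out.verdict == "not_prioritized"
        assert out.audit["r2_ok"] is False

    def test_missing_line_excluded(self):
        q = quality_for()
        del q[("CPD", "T4")]
        out = self.run([-0.9, -0.9, -0.9, -0.9], quality=q)
        assert out.verdict == "excluded:missing_fit"
        assert out.audit["missing_lines"] == ["T4"]

    def test_no_response_reference_exempt_from_r2(self):
        q = quality_for(flags=("no_response",))
        q[("CPD", "REF")] = CompoundCellScore(
            "CPD", "REF", 0.0, 1.0, None, r2=None, flags=frozenset({"no_response"}))
        out = self.run([-0.9, -0.9, -0.9, -0.9], quality=q)
        assert out.verdict == "sensitive_prioritized"
        assert "REF" in out.audit["r2_exempt"]

    def test_r2_mean_mode(self):
        q = quality_for()
        q[("CPD", "T3")] = CompoundCellScore("CPD", "T3", 100.0, 1.0, 2.0, r2=0.5)
        out = self.run([-0.9, -0.9, -0.9, -0.9], quality=q,
                       cfg=RunConfig(r2_mode="mean"))  # mean R2 = 0.8375 >= 0.8
        assert out.verdict == "sensitive_prioritized"

    @settings(derandomize=True, max_examples=100)
    @given(
        mean=st.floats(min_value=0.51, max_value=3.0),
        spread=st.floats(min_value=0.0, max_value=0.3),
        shrink=st.floats(min_value=0.1, max_value=1.0),
    )
    def test_monotone_in_variance_and_effect(self, mean, spread, shrink):
        """Shrinking the spread or growing |ds mean| never demotes a hit."""
        base = [mean - spread, mean, mean, mean + spread]
        s0 = summarize_compound(deltas_for(base))
        (v0,) = prioritize([s0], quality_for(), "REF", TEST_LINES, RunConfig())
        tighter = [mean - spread * shrink, mean, mean, mean + spread * shrink]
        s1 = summarize_compound(deltas_for(tighter))
        (v1,) = prioritize([s1], quality_for(), "REF", TEST_LINES, RunConfig())
        larger = [v * 1.5 for v in base]
        s2 = summarize_compound(deltas_for(larger))
        (v2,) = prioritize([s2], quality_for(), "REF", TEST_LINES, RunConfig())
        if v0.verdict == "resistant_prioritized":
            assert v1.verdict == "resistant_prioritized"
            assert v2.verdict == "resistant_prioritized"


class TestDeltaDeltaS:
    def test_simple_difference(self):
        assert delta_delta_s(-1.0, -0.2) == pytest.approx(-0.8)

    def test_null_case(self):
        assert delta_delta_s(-0.4, -0.4) == 0.0

    def test_antisymmetry(self):
        assert delta_delta_s(-1.0, -0.2) == -delta_delta_s(-0.2, -1.0)

    def test_mismatched_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            delta_delta_s(-1.0, -0.2, reference_tumor="A", reference_control="B")


class TestEndpointCorrelation:
    def frame(self, x, y):
        return pd.DataFrame({
            "test_cell_line": "T1", "delta_s": x, "delta_pac50": y,
            "delta_pauc": y,
        })

    def test_perfect_linear_relation(self):
        x = [0.0, 1.0, 2.0, 3.0]
        df = self.frame(x, [2 * v + 1 for v in x])
        out = endpoint_correlation(df)
        row = out[(out.endpoint_x == "delta_s") & (out.endpoint_y == "delta_pac50")]
        assert row.r2.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert row.n.iloc[0] == 4

    def test_orthogonal_vectors(self):
        df = self.frame([-1.0, 0.0, 1.0], [1.0, -2.0, 1.0])
        out = endpoint_correlation(df)
        row = out[(out.endpoint_x == "delta_s") & (out.endpoint_y == "delta_pac50")]
        assert row.r2.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=50), rng.normal(size=50)
        df = self.frame(x.tolist(), y.tolist())
        out = endpoint_correlation(df)
        row = out[(out.endpoint_x == "delta_s") & (out.endpoint_y == "delta_pac50")]
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r2 = cov ** 2 / (np.mean((x - x.mean()) ** 2) * np.mean((y - y.mean()) ** 2))
        assert row.r2.iloc[0] == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        df = self.frame([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        out = endpoint_correlation(df)
        row = out[(out.endpoint_x == "delta_s") & (out.endpoint_y == "delta_pac50")]
        assert math.isnan(row.r2.iloc[0]) and row.n.iloc[0] == 3

    def test_incomplete_pairs_dropped_listwise(self):
        df = self.frame([0.0, 1.0, 2.0, None], [0.0, 2.0, 4.0, 9.0])
        out = endpoint_correlation(df)
        row = out[(out.endpoint_x == "delta_s") & (out.endpoint_y == "delta_pac50")]
        assert row.n.iloc[0] == 3


class TestRankTable:
    def means(self, ds, dpac50=None, dpauc=None):
        n = len(ds)
        return pd.DataFrame({
            "compound": [f"C{i}" for i in range(n)],
            "ds_mean": ds,
            "dpac50_mean": dpac50 if dpac50 is not None else ds,
            "dpauc_mean": dpauc if dpauc is not None else ds,
        })

    def test_ascending_ranks_most_sensitive_first(self):
        rc = rank_table(self.means([-1.0, 0.0, 1.0]))
        assert rc.table["rank_ds_mean"].tolist() == [1.0, 2.0, 3.0]

    def test_ties_get_average_ranks(self):
        rc = rank_table(self.means([-1.0, -1.0, 0.5]))
        assert rc.table["rank_ds_mean"].tolist() == [1.5, 1.5, 3.0]

    def test_identical_orderings_have_unit_concordance(self):
        rc = rank_table(self.means([-1.0, -0.2, 0.4, 1.3]))
        assert rc.concordance[("ds_mean", "dpac50_mean")] == pytest.approx(1.0)

    def test_rank_sums_conserved(self):
        rng = np.random.default_rng(3)
        n = 25
        rc = rank_table(self.means(rng.normal(size=n).tolist()))
        for col in ("rank_ds_mean", "rank_dpac50_mean", "rank_dpauc_mean"):
            assert rc.table[col].sum() == pytest.approx(n * (n + 1) / 2)

    def test_undefined_cells_left_unranked(self):
        rc = rank_table(self.means([-1.0, 0.0, 1.0], dpac50=[0.5, None, -0.5]))
        ranks = rc.table["rank_dpac50_mean"]
        assert math.isnan(ranks.iloc[1])
        assert sorted(ranks.dropna()) == [1.0, 2.0]

    def test_needs_two_compounds(self):
        with pytest.raises(ValueError):
            rank_table(self.means([-1.0]))


class TestDistributionSummary:
    def test_counts(self):
        arr, counts = ds_distribution_summary([-1.0, -0.2, 0.7])
        assert counts == (1, 1, 1)
        assert arr.tolist() == [-1.0, -0.2, 0.7]

    def test_all_zero(self):
        _, counts = ds_distribution_summary([0.0] * 5)
        assert counts == (0, 5, 0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=-3, max_value=3, allow_nan=False), min_size=1))
    def test_counts_conserve_n(self, values):
        _, counts = ds_distribution_summary(values)
        assert sum(counts) == len(values)
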