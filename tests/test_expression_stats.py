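import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from relict.expression_stats import (
    DEFAULT_EXTINCTION_COEFFICIENTS,
    KineticAssay,
    activity_from_kinetics,
    average_by_species,
    compare_gene_panel,
    correlate_activity_expression,
    mann_whitney_test,
)


def exact_two_sided_p(a, b):
    """Independent oracle: full enumeration of group assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    def u_of(idx):
        r1 = sum(ranks[pooled[i]] for i in idx)
        return r1 - n1 * (n1 + 1) / 2
    u_obs = u_of(range(n1))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    total = len(us)
    cdf = sum(u <= u_obs for u in us) / total
    sf = sum(u >= u_obs for u in us) / total
    return min(1.0, 2 * min(cdf, sf))


class TestAverageBySpecies:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["individual", "species", "clade", "gene", "tpm"])

    def test_single_individuals_unchanged(self):
        t = self._table([("i1", "a", "x", "g", 10.0), ("i2", "b", "x", "g", 7.0)])
        assert average_by_species(t, "g") == {"a": 10.0, "b": 7.0}

    def test_arithmetic_mean(self):
        t = self._table([(f"i{k}", "a", "x", "g", v) for k, v in enumerate([10, 20, 30])])
        assert average_by_species(t, "g")["a"] == pytest.approx(20.0)

    def test_row_order_invariance(self):
        rows = [(f"i{k}", f"s{k % 3}", "x", "g", float(k)) for k in range(9)]
        t1 = self._table(rows)
        t2 = self._table(rows[::-1])
        assert average_by_species(t1, "g") == average_by_species(t2, "g")

    def test_unknown_gene_rejected(self):
        t = self._table([("i1", "a", "x", "g", 1.0)])
        with pytest.raises(ValueError):
            average_by_species(t, "nope")


class TestMannWhitney:
    def test_identical_groups_symmetric(self):
        res = mann_whitney_test([1, 2, 3], [1, 2, 3])
        assert res.U == pytest.approx(4.5)
        assert res.Z == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_separated_pair_exact_third(self):
        res = mann_whitney_test([1, 2], [3, 4], mode="exact")
        assert res.U == 0
        assert res.p == pytest.approx(1 / 3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1.0])

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n1 in range(1, 5):
            for n2 in range(1, 5):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                a, b = vals[:n1], vals[n1:]
                res = mann_whitney_test(a, b, mode="exact")
                assert res.p == pytest.approx(exact_two_sided_p(a, b), abs=1e-12)

    def test_exact_and_normal_agree_at_moderate_n(self):
        # Without a continuity correction the discrete exact p and the normal
        # approximation differ by up to ~0.04 at n=8-9 (half the point mass of
        # the observed U); the gap shrinks as n grows.
        rng = np.random.default_rng(42)
        max_diff_small, max_diff_larger = 0.0, 0.0
        for _ in range(100):
            a = rng.permutation(np.arange(100.0))[:8]
            b = rng.permutation(np.setdiff1d(np.arange(100.0), a))[:9]
            exact = mann_whitney_test(a, b, mode="exact")
            normal = mann_whitney_test(a, b, mode="normal")
            max_diff_small = max(max_diff_small, abs(exact.p - normal.p))
            a = rng.permutation(np.arange(100.0))[:14]
            b = rng.permutation(np.setdiff1d(np.arange(100.0), a))[:14]
            exact = mann_whitney_test(a, b, mode="exact")
            normal = mann_whitney_test(a, b, mode="normal")
            max_diff_larger = max(max_diff_larger, abs(exact.p - normal.p))
        assert max_diff_small < 0.05
        assert max_diff_larger < max_diff_small

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=8, unique=True),
        st.lists(st.integers(51, 99), min_size=2, max_size=8, unique=True),
    )
    def test_monotone_transform_invariance(self, a, b):
        res1 = mann_whitney_test(a, b)
        transform = lambda v: math.exp(0.1 * v) + 3
        res2 = mann_whitney_test([transform(v) for v in a], [transform(v) for v in b])
        assert res1.U == pytest.approx(res2.U)
        assert res1.p == pytest.approx(res2.p)

    def test_ties_fall_back_to_tie_corrected_normal(self):
        res = mann_whitney_test([1, 1, 2], [1, 2, 2], mode="auto")
        assert res.method == "normal"
        assert 0 <= res.p <= 1


class TestGenePanel:
    def _panel_table(self, seed=0, n_down=30, n_up=5, n_null=65, shift=3.0):
        rng = np.random.default_rng(seed)
        rows = []
        genes = (
            [f"down{i}" for i in range(n_down)]
            + [f"up{i}" for i in range(n_up)]
            + [f"null{i}" for i in range(n_null)]
        )
        for gene in genes:
            for k, clade in enumerate(["A"] * 6 + ["B"] * 6):
                mu = 5.0
                if clade == "A" and gene.startswith("down"):
                    mu -= shift
                if clade == "A" and gene.startswith("up"):
                    mu += shift
                rows.append(
                    dict(individual=f"{gene}_{k}", species=f"sp{k}", clade=clade,
                         gene=gene, tpm=float(np.exp(mu + 0.3 * rng.standard_normal())))
                )
        return pd.DataFrame(rows), genes

    def test_planted_directions_recovered(self):
        table, genes = self._panel_table()
        summary = compare_gene_panel(table, genes, ("A", "B"))
        assert summary.n_tested == len(genes)
        sig = summary.per_gene[summary.per_gene["p"] < 0.05]
        for _, row in sig.iterrows():
            if row["gene"].startswith("down"):
                assert row["direction"] == "down"
            if row["gene"].startswith("up"):
                assert row["direction"] == "up"
        assert summary.n_down >= 25  # nearly all planted downs detected
        assert summary.n_up >= 3

    def test_null_panel_type_one_error(self):
        table, genes = self._panel_table(seed=1, n_down=0, n_up=0, n_null=200, shift=0.0)
        summary = compare_gene_panel(table, genes, ("A", "B"))
        # per-gene level ~alpha: binomial(200, 0.05) stays below ~0.11
        assert summary.n_significant <= 22

    def test_bh_correction_reduces_calls(self):
        table, genes = self._panel_table()
        raw = compare_gene_panel(table, genes, ("A", "B"))
        bh = compare_gene_panel(table, genes, ("A", "B"), correction="fdr_bh")
        assert bh.n_significant <= raw.n_significant
        assert "p_adjusted" in bh.per_gene.columns

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            compare_gene_panel(pd.DataFrame(), [], ("A", "B"))


class TestKinetics:
    def test_zero_slope_zero_activity(self):
        assay = KineticAssay(0.0, epsilon=5.56)
        assert activity_from_kinetics(assay) == 0.0

    def test_dimensional_analysis_unit_case(self):
        assay = KineticAssay(1.31, epsilon=1.31, path_cm=1.0, dilution=1.0,
                             reaction_to_sample_volume=1.0)
        assert activity_from_kinetics(assay) == pytest.approx(1.0)

    def test_default_extinction_coefficients(self):
        assert DEFAULT_EXTINCTION_COEFFICIENTS == {
            "AREase": 1.31, "CPOase": 5.56, "DZOase": 3.0, "POase": 18.0
        }

    def test_dilution_and_volumes_scale_linearly(self):
        base = activity_from_kinetics(KineticAssay(0.5, epsilon=2.0))
        scaled = activity_from_kinetics(
            KineticAssay(0.5, epsilon=2.0, dilution=10.0, reaction_to_sample_volume=20.0)
        )
        assert scaled == pytest.approx(200.0 * base)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            KineticAssay(1.0, epsilon=0.0)


class TestCorrelation:
    def test_perfect_linear_r2_one(self):
        expr = {f"s{i}": float(np.exp(i)) for i in range(5)}
        act = {f"s{i}": 2.0 * np.log(np.exp(i) + 0.01) + 1.0 for i in range(5)}
        res = correlate_activity_expression(act, expr)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_four_point_closed_form(self):
        # hand-computable: log(tpm + 0.01) with tpm = e^k - 0.01
        xs = np.array([0.0, 1.0, 2.0, 3.0])
        ys = np.array([1.0, 2.0, 2.0, 4.0])
        expr = {f"s{i}": float(np.exp(x) - 0.01) for i, x in enumerate(xs)}
        act = {f"s{i}": float(y) for i, y in enumerate(ys)}
        sxx = ((xs - xs.mean()) ** 2).sum()
        sxy = ((xs - xs.mean()) * (ys - ys.mean())).sum()
        slope = sxy / sxx
        intercept = ys.mean() - slope * xs.mean()
        r2 = sxy**2 / (sxx * ((ys - ys.mean()) ** 2).sum())
        res = correlate_activity_expression(act, expr)
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.r_squared == pytest.approx(r2)
        assert res.n == 4

    def test_too_few_shared_species(self):
        with pytest.raises(ValueError, match="shared"):
            correlate_activity_expression({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
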