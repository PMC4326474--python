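import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import xgram


def series(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.Series(values, index=genes, dtype=float)


class TestBoxcarProfile:
    def test_r0_recovers_the_transcriptome(self):
        o = xgram.GeneOrdering([f"g{i}" for i in range(5)])
        tg = xgram.boxcar_profile(series([3, 1, 4, 1, 5]), o, 0)
        assert np.allclose(tg.values, [3, 1, 4, 1, 5])

    def test_constant_input_stays_constant_under_any_coverage(self):
        o = xgram.GeneOrdering([f"g{i}" for i in range(6)])
        expr = series([7.0, 7.0, 7.0], genes=["g0", "g2", "g5"])
        tg = xgram.boxcar_profile(expr, o, 2)
        covered = ~np.isnan(tg.values)
        assert np.allclose(tg.values[covered], 7.0)

    def test_truncated_end_windows(self):
        o = xgram.GeneOrdering([f"g{i}" for i in range(5)])
        tg = xgram.boxcar_profile(series([1, 2, 3, 4, 5]), o, 1)
        assert np.allclose(tg.values, [1.5, 2, 3, 4, 4.5])

    def test_theta_weighted_mean_skips_unmeasured_position(self):
        o = xgram.GeneOrdering(["g0", "g1", "g2"])
        expr = series([2.0, 4.0], genes=["g0", "g2"])
        tg = xgram.boxcar_profile(expr, o, 1)
        assert tg.values[1] == pytest.approx(3.0)
        assert not tg.theta[1]

    def test_all_uncovered_window_is_missing(self):
        o = xgram.GeneOrdering([f"g{i}" for i in range(9)])
        expr = series([1.0], genes=["g0"])
        tg = xgram.boxcar_profile(expr, o, 1)
        assert np.isnan(tg.values[5])

    def test_unmapped_genes_reported_not_silently_dropped(self):
        o = xgram.GeneOrdering(["g0", "g1"])
        tg = xgram.boxcar_profile(series([1, 2, 3], genes=["g0", "g1", "zz"]), o, 0)
        assert tg.unmapped == ["zz"]

    def test_empty_overlap_errors(self):
        o = xgram.GeneOrdering(["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            xgram.boxcar_profile(series([1.0], genes=["zz"]), o, 1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), r=st.integers(0, 6))
    def test_linearity(self, seed, r):
        rng = np.random.default_rng(seed)
        n = 15
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        theta = rng.random(n) < 0.8
        if not theta.any():
            theta[0] = True
        a, b = 2.0, -0.5
        lhs = xgram.boxcar_smooth(a * x + b * y, theta, r)
        rhs = a * xgram.boxcar_smooth(x, theta, r) + b * xgram.boxcar_smooth(y, theta, r)
        assert np.allclose(lhs, rhs, equal_nan=True)

    def test_interior_windows_preserve_global_mean_of_constant_blocks(self):
        # full coverage: each interior window is an exact mean, so smoothing
        # a linear ramp leaves interior values untouched
        n, r = 50, 3
        x = np.arange(n, dtype=float)
        sm = xgram.boxcar_smooth(x, np.ones(n, bool), r)
        assert np.allclose(sm[r : n - r], x[r : n - r])

    def test_window_sizes(self):
        w = xgram.window_sizes(10, 2)
        assert w[0] == 3 and w[5] == 5 and w[9] == 3


class TestClassProfiles:
    @staticmethod
    def _design(conds, n_b, n_a):
        rows = []
        for c in conds:
            for b in range(1, n_b + 1):
                for a in range(1, n_a + 1):
                    rows.append(
                        {
                            "sample": f"{c}_b{b}_t{a}",
                            "condition": c,
                            "bio_rep": b,
                            "tech_rep": a,
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_replicates_have_zero_sd(self):
        genes = [f"g{i}" for i in range(10)]
        o = xgram.GeneOrdering(genes)
        vals = np.tile(np.arange(10.0), (4, 1)).T
        expr = pd.DataFrame(vals, index=genes, columns=[f"A_b1_t{a}" for a in range(1, 5)])
        design = pd.DataFrame(
            {
                "sample": expr.columns,
                "condition": "A",
                "bio_rep": 1,
                "tech_rep": range(1, 5),
            }
        )
        cp = xgram.class_profiles(expr, design, o, 2)["A"]
        assert np.allclose(cp.sd, 0)

    def test_two_replicates_average(self):
        genes = [f"g{i}" for i in range(4)]
        o = xgram.GeneOrdering(genes)
        expr = pd.DataFrame(
            {"A_b1_t1": [1.0, 1, 1, 1], "A_b2_t1": [3.0, 3, 3, 3]}, index=genes
        )
        design = pd.DataFrame(
            {
                "sample": expr.columns,
                "condition": "A",
                "bio_rep": [1, 2],
                "tech_rep": 1,
            }
        )
        cp = xgram.class_profiles(expr, design, o, 0)["A"]
        assert np.allclose(cp.mean, 2.0)
        assert np.allclose(cp.se, cp.sd / np.sqrt(2))

    def test_technical_sd_shrinks_like_inverse_sqrt_window(self):
        """Per-position SD of smoothed technical replicates approaches
        sigma_xi / sqrt(w) at interior positions."""
        rng = np.random.default_rng(21)
        n, reps, sigma, r = 3000, 6, 0.5, 10
        genes = [f"g{i:04d}" for i in range(n)]
        o = xgram.GeneOrdering(genes)
        base = rng.normal(8, 1, n)
        expr = pd.DataFrame(
            {f"A_b1_t{a}": base + sigma * rng.standard_normal(n) for a in range(1, reps + 1)},
            index=genes,
        )
        design = pd.DataFrame(
            {
                "sample": expr.columns,
                "condition": "A",
                "bio_rep": 1,
                "tech_rep": range(1, reps + 1),
            }
        )
        cp = xgram.class_profiles(expr, design, o, r)["A"]
        w = 2 * r + 1
        interior = np.sqrt(np.mean(cp.sd[r : n - r] ** 2))
        assert interior == pytest.approx(sigma / np.sqrt(w), rel=0.15)

    def test_unknown_condition_errors(self):
        genes = ["g0", "g1"]
        o = xgram.GeneOrdering(genes)
        expr = pd.DataFrame({"s1": [1.0, 2.0]}, index=genes)
        design = pd.DataFrame(
            {"sample": ["s1"], "condition": ["A"], "bio_rep": [1], "tech_rep": [1]}
        )
        with pytest.raises(ValueError, match="not present"):
            xgram.class_profiles(expr, design, o, 0, conditions=["B"])


class TestRelativeProfile:
    def _setup(self, values_by_bio):
        genes = [f"g{i}" for i in range(4)]
        o = xgram.GeneOrdering(genes)
        cols, rows = {}, []
        for b, v in enumerate(values_by_bio, start=1):
            for a in (1, 2):
                name = f"F_b{b}_t{a}"
                cols[name] = np.full(4, float(v))
                rows.append(
                    {"sample": name, "condition": "F", "bio_rep": b, "tech_rep": a}
                )
        return pd.DataFrame(cols, index=genes), pd.DataFrame(rows), o

    def test_identical_samples_relative_to_self_is_one(self):
        expr, design, o = self._setup([5.0, 5.0])
        rel = xgram.relative_profile(expr, design, o, 1, reference="F")
        assert np.allclose(rel.to_numpy(), 1.0)

    def test_two_constant_bio_reps(self):
        a, b = 2.0, 6.0
        expr, design, o = self._setup([a, b])
        rel = xgram.relative_profile(expr, design, o, 0, reference="F")
        assert np.allclose(rel.loc[("F", 1)], 2 * a / (a + b))
        assert np.allclose(rel.loc[("F", 2)], 2 * b / (a + b))
        # reference class relative to itself averages to 1
        assert np.allclose(rel.mean(axis=0), 1.0)

    def test_zero_reference_flagged_missing(self):
        expr, design, o = self._setup([0.0, 0.0])
        rel = xgram.relative_profile(expr, design, o, 0, reference="F")
        assert rel.isna().all().all()


class TestProjectGeneSet:
    def test_full_set_projects_to_one(self):
        o = xgram.GeneOrdering([f"g{i}" for i in range(6)])
        gs = xgram.GeneSet("all", "", frozenset(o.order))
        tp = xgram.project_gene_set(gs, o, 2)
        assert np.allclose(tp.profile, 1.0)

    def test_disjoint_set_projects_to_zero(self):
        o = xgram.GeneOrdering([f"g{i}" for i in range(6)])
        gs = xgram.GeneSet("none", "", frozenset(["zz"]))
        tp = xgram.project_gene_set(gs, o, 2)
        assert np.allclose(tp.profile, 0.0)
        assert tp.n_mapped == 0

    def test_single_interior_member_spreads_to_third(self):
        o = xgram.GeneOrdering([f"g{i}" for i in range(7)])
        gs = xgram.GeneSet("one", "", frozenset(["g3"]))
        tp = xgram.project_gene_set(gs, o, 1)
        assert np.allclose(tp.profile[2:5], 1 / 3)
        assert np.allclose(tp.profile[[0, 1, 5, 6]], 0.0)
        # indicator integrates to the number of mapped members
        assert tp.indicator.sum() == 1


class TestDecomposeVariance:
    def test_identical_technical_replicates_give_zero_xi(self, clustered_expression):
        expression, design, truth, labels = clustered_expression
        # collapse technical noise: copy t1 into all technical replicates
        e = expression.copy()
        for _, grp in design.groupby(["condition", "bio_rep"]):
            cols = list(grp["sample"])
            for c in cols[1:]:
                e[c] = e[cols[0]]
        o = xgram.true_ordering(labels)
        vc = xgram.decompose_variance(e, design, o, 5)
        assert vc.sigma2_xi.abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_all_samples_identical_gives_all_zero(self):
        genes = [f"g{i}" for i in range(20)]
        o = xgram.GeneOrdering(genes)
        base = np.linspace(5, 8, 20)
        cols, rows = {}, []
        for b in (1, 2):
            for a in (1, 2):
                name = f"A_b{b}_t{a}"
                cols[name] = base
                rows.append(
                    {"sample": name, "condition": "A", "bio_rep": b, "tech_rep": a}
                )
        vc = xgram.decompose_variance(
            pd.DataFrame(cols, index=genes), pd.DataFrame(rows), o, 2
        )
        assert vc.sigma2_xi.abs().max() == 0
        assert vc.sigma2_b.abs().max() == 0
        assert np.nanmax(np.abs(vc.kappa_bar)) == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_replication_errors(self):
        genes = ["g0", "g1"]
        o = xgram.GeneOrdering(genes)
        expr = pd.DataFrame({"s1": [1.0, 2.0]}, index=genes)
        design = pd.DataFrame(
            {"sample": ["s1"], "condition": ["A"], "bio_rep": [1], "tech_rep": [1]}
        )
        with pytest.raises(ValueError, match="technical"):
            xgram.decompose_variance(expr, design, o, 1)

    def test_correlated_biology_shows_in_kappa(self):
        """rho_bio = 1 makes whole clusters move together: kappa_bar within a
        cluster approaches sigma_b^2; rho_bio = 0 leaves it near zero."""
        genes = [f"g{i:04d}" for i in range(1000)]
        labels = {g: i // 100 for i, g in enumerate(genes)}
        o = xgram.true_ordering(labels)
        signals = xgram.make_signal(labels, conditions=("A",), seed=1)
        out = {}
        for rho in (0.0, 1.0):
            spec = xgram.SyntheticExpressionSpec(rho_bio=rho, seed=4)
            e, d, _ = xgram.make_expression(labels, spec, signals)
            vc = xgram.decompose_variance(e, d, o, 10)
            out[rho] = float(np.nanmean(vc.kappa_bar))
        assert abs(out[0.0]) < 0.02
        assert out[1.0] == pytest.approx(0.09, rel=0.35)
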