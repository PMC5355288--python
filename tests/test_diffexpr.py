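"""Preprocessing, moderated-t differential expression, FDR adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from netpipe.diffexpr import (
    DETable,
    ExpressionMatrix,
    benjamini_hochberg,
    collapse_probes,
    fit_de,
    overlap_genes,
    quantile_normalize,
    restricted_test,
    split_by_direction,
)
from netpipe.interactome import GeneList
from netpipe.synthetic import SimConfig, choose_de_genes, simulate_expression


def make_matrix(values, genes=None, samples=None, groups=None, **design_cols):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    design = {"group": groups or ["case"] * (len(samples) // 2) + ["control"] * (len(samples) - len(samples) // 2)}
    design.update(design_cols)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        design=pd.DataFrame(design, index=pd.Index(samples, name="sample_id")),
    )


def bh_step_up_oracle(p):
    """Hand implementation of the step-up formula: adj_p(i) = min_{j>=rank(i)} n p_(j) / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, n * p[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestQuantileNormalize:
    def test_hand_computed_rank_means(self):
        m = make_matrix(np.array([[1, 2], [2, 4], [3, 6]]))
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 3.0, 4.5])

    def test_permuted_columns_unchanged(self, rng):
        col = rng.normal(size=30)
        vals = np.column_stack([col, rng.permutation(col), rng.permutation(col)])
        m = make_matrix(vals, groups=["case", "case", "control"])
        np.testing.assert_allclose(quantile_normalize(m).values.to_numpy(), vals)

    def test_idempotent_and_equal_column_means(self, rng):
        m = make_matrix(rng.normal(size=(40, 6)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy())
        means = once.values.mean(axis=0).to_numpy()
        np.testing.assert_allclose(means, means[0])

    def test_non_finite_input_names_cells(self):
        m = make_matrix([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match=r"\(g1, s0\)"):
            quantile_normalize(m)


class TestCollapseProbes:
    def test_mean_of_probe_rows(self):
        m = make_matrix([[1, 3], [3, 5]], genes=["p1", "p2"])
        out = collapse_probes(m, {"p1": "GENE1", "p2": "GENE1"})
        np.testing.assert_allclose(out.values.loc["GENE1"], [2.0, 4.0])

    def test_single_probe_unchanged_and_unmapped_dropped(self):
        m = make_matrix([[1, 2], [5, 6]], genes=["p1", "p_unmapped"])
        out = collapse_probes(m, {"p1": "GENE1"})
        assert out.gene_ids == ["GENE1"]
        np.testing.assert_allclose(out.values.loc["GENE1"], [1.0, 2.0])

    def test_matches_brute_force_group_mean(self, rng):
        vals = rng.normal(size=(50, 4))
        probes = [f"p{i}" for i in range(50)]
        mapping = {p: f"GENE{rng.integers(10)}" for p in probes}
        out = collapse_probes(make_matrix(vals, genes=probes), mapping)
        for gene in set(mapping.values()):
            rows = [i for i, p in enumerate(probes) if mapping[p] == gene]
            expected = np.mean([vals[i] for i in rows], axis=0)
            np.testing.assert_allclose(out.values.loc[gene].to_numpy(), expected)

    def test_empty_mapping_errors(self):
        with pytest.raises(ValueError, match="empty"):
            collapse_probes(make_matrix([[1, 2]]), {})


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_identities(self):
        np.testing.assert_allclose(benjamini_hochberg([0.37]), [0.37])
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            np.testing.assert_allclose(benjamini_hochberg(p), bh_step_up_oracle(p), atol=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_raw_p(self, p):
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestFitDE:
    def test_no_shrinkage_limit_equals_ordinary_t(self, rng):
        """With d0 = 0 the moderated t is the classical pooled two-sample t."""
        vals = rng.normal(size=(30, 12))
        m = make_matrix(vals, groups=["case"] * 6 + ["control"] * 6)
        table = fit_de(m, d0=0.0).table
        t_ref, p_ref = stats.ttest_ind(vals[:, :6], vals[:, 6:], axis=1, equal_var=True)
        np.testing.assert_allclose(table["t"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(table["p"], p_ref, rtol=1e-10)

    def test_infinite_shrinkage_limit_pools_all_variance(self, rng):
        """As d0 -> inf every gene's t becomes logFC / (s0 sqrt(v))."""
        vals = rng.normal(size=(20, 10))
        m = make_matrix(vals, groups=["case"] * 5 + ["control"] * 5)
        s0 = 0.7
        table = fit_de(m, d0=np.inf, s0_sq=s0).table
        v = 1 / 5 + 1 / 5
        np.testing.assert_allclose(
            table["t"], table["logFC"] / np.sqrt(s0 * v), rtol=1e-6
        )

    def test_confounded_design_errors(self, rng):
        m = make_matrix(
            rng.normal(size=(5, 8)),
            groups=["case"] * 4 + ["control"] * 4,
            batch=["x"] * 4 + ["y"] * 4,
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_de(m, covariates=("batch",))

    def test_tiny_group_errors(self, rng):
        m = make_matrix(rng.normal(size=(5, 4)), groups=["case", "control", "control", "control"])
        with pytest.raises(ValueError, match="need >= 2"):
            fit_de(m)

    def test_covariate_adjustment_removes_batch_shift(self, rng):
        """A strong batch shift inflates the null without adjustment and is
        absorbed by the batch covariate."""
        cfg = SimConfig(seed=5, n_genes=500, de_fraction=0.0, batch_sd=0.8)
        expr, _ = simulate_expression(cfg)
        unadj = fit_de(expr)
        adj = fit_de(expr, covariates=("batch",))
        assert adj.table["p"].median() > 0.2
        assert (adj.table["adj_p"] <= 0.05).mean() <= 0.01

    def test_recovers_planted_logfc_single_seed(self):
        """Mean |logFC error| over planted-DE genes matches its closed form.

        The estimate is unbiased with per-gene sd sigma_g*sqrt(1/n1+1/n2),
        so E|err| = sqrt(2/pi)*E[sigma]*sqrt(1/14+1/7); under the
        scaled-inv-chi2(4, 0.05) prior E[sigma] = sqrt(d0*s0^2)*
        Gamma(1.5)/(sqrt(2)*Gamma(2)) ~ 0.280, giving ~0.104."""
        cfg = SimConfig(seed=11, n_genes=2000)
        de_genes = choose_de_genes(cfg)
        expr, truth = simulate_expression(cfg, de_genes)
        table = fit_de(expr).table
        de_mask = truth["is_de"].to_numpy()
        err = np.abs(table["logFC"].to_numpy()[de_mask] - truth["delta"].to_numpy()[de_mask])
        assert err.mean() == pytest.approx(0.104, abs=0.02)

    def test_adj_p_at_least_raw_p(self, rng):
        m = make_matrix(rng.normal(size=(100, 10)), groups=["case"] * 5 + ["control"] * 5)
        table = fit_de(m).table
        assert (table["adj_p"] >= table["p"] - 1e-12).all()


class TestRestrictedAndSplit:
    def _random_table(self, rng, n=1000):
        p = rng.uniform(size=n)
        tab = pd.DataFrame(
            {
                "logFC": rng.normal(size=n),
                "t": rng.normal(size=n),
                "p": p,
                "adj_p": benjamini_hochberg(p),
                "direction": "up",
            },
            index=[f"G{i:04d}" for i in range(n)],
        )
        tab["direction"] = np.where(tab["logFC"] > 0, "up", "down")
        return DETable(table=tab, d0=4.0, s0_sq=0.05)

    def test_singleton_subset_is_bh_identity(self, rng):
        t = self._random_table(rng, n=50)
        gene = t.genes[7]
        out = restricted_test(t, GeneList([gene]))
        assert out.table.at[gene, "adj_p"] == pytest.approx(t.table.at[gene, "p"])

    def test_restricted_adjustment_vs_brute_force(self, rng):
        t = self._random_table(rng)
        subset = GeneList(list(rng.choice(t.genes, size=25, replace=False)))
        out = restricted_test(t, subset)
        expected = bh_step_up_oracle(t.table.loc[list(subset), "p"].to_numpy())
        np.testing.assert_allclose(out.table["adj_p"].to_numpy(), expected)
        np.testing.assert_allclose(out.table["p"], t.table.loc[list(subset), "p"])

    def test_unmeasured_subset_genes_reported(self, rng):
        t = self._random_table(rng, n=20)
        subset = GeneList(t.genes[:3] + ["ZZ1", "ZZ2", "ZZ3", "ZZ4", "ZZ5"])
        out = restricted_test(t, subset)
        assert len(out.table) == 3
        assert sorted(out.missing_genes) == ["ZZ1", "ZZ2", "ZZ3", "ZZ4", "ZZ5"]

    def test_disjoint_subset_errors(self, rng):
        with pytest.raises(ValueError, match="no subset gene"):
            restricted_test(self._random_table(rng, n=10), GeneList(["NOPE"]))

    def test_split_by_direction_example_and_oracle(self, rng):
        tab = pd.DataFrame(
            {
                "logFC": [1.0, -1.0, 0.5],
                "t": [5, -5, 1],
                "p": [0.001, 0.001, 0.1],
                "adj_p": [0.01, 0.01, 0.2],
                "direction": ["up", "down", "up"],
            },
            index=["A", "B", "C"],
        )
        up, down = split_by_direction(DETable(tab, 4.0, 0.05), fdr_q=0.05)
        assert up.symbols == ["A"] and down.symbols == ["B"]
        t = self._random_table(rng)
        up, down = split_by_direction(t, fdr_q=0.2)
        expect_up = {g for g in t.genes if t.table.at[g, "adj_p"] <= 0.2 and t.table.at[g, "logFC"] > 0}
        expect_down = {g for g in t.genes if t.table.at[g, "adj_p"] <= 0.2 and t.table.at[g, "logFC"] < 0}
        assert up.as_set == expect_up and down.as_set == expect_down
        assert not (up.as_set & down.as_set)

    def test_overlap_counts(self, rng):
        n, shared = overlap_genes(GeneList(["A", "B", "C"]), GeneList(["B", "C", "D"]))
        assert n == 2 and shared.as_set == {"B", "C"}
        assert overlap_genes(GeneList(["A"]), GeneList(["B"]))[0] == 0
        a = GeneList([f"G{i}" for i in rng.integers(0, 100, size=40)])
        b = GeneList([f"G{i}" for i in rng.integers(0, 100, size=40)])
        brute = sum(1 for x in a if any(x == y for y in b))
        assert overlap_genes(a, b)[0] == brute
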