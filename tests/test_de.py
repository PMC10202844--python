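"""Differential-expression stage: filtering, voom weights, weighted least
squares, empirical-Bayes moderation, FDR, deduplication and selection —
each checked against an independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mnrseq as m
from mnrseq.de import (
    LinearFits,
    compute_contrasts,
    fit_scaled_f_prior,
    voom_weights,
)


# ---------------------------------------------------------------------------
# oracles

def bh_oracle(p):
    """Step-up definition evaluated literally: q_i = min over j with
    p_(j) >= p_(i) of m*p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    mm = len(p)
    q = np.empty(mm)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    for i in range(mm):
        cands = [mm * ranked[j] / (j + 1) for j in range(mm) if ranked[j] >= ranked[i]]
        q[order[i]] = min(1.0, min(cands))
    return q


def wls_oracle(X, y, w):
    """Normal equations evaluated directly."""
    W = np.diag(w)
    A = X.T @ W @ X
    beta = np.linalg.solve(A, X.T @ W @ y)
    resid = y - X @ beta
    s2 = (w * resid**2).sum() / (len(y) - X.shape[1])
    return beta, s2, np.sqrt(np.diag(np.linalg.inv(A)))


# ---------------------------------------------------------------------------

class TestFilter:
    def test_max_below_threshold_removed_boundary_retained(self, small_design):
        counts = np.vstack([
            np.full(24, 14),                      # max 14 -> removed
            np.r_[15, np.zeros(23, dtype=int)],   # single 15 -> retained
        ])
        mat = m.TranscriptCountMatrix(["low", "edge"], ["G1", "G2"],
                                      list(small_design.sample_ids), counts)
        kept = m.filter_low_counts(mat, 15)
        assert kept.transcript_ids == ["edge"]

    def test_matches_brute_force_row_max_scan(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 40, size=(100, 10))
        mat = m.TranscriptCountMatrix(
            [f"T{i}" for i in range(100)], [f"G{i}" for i in range(100)],
            [f"s{j}" for j in range(10)], counts,
        )
        kept = m.filter_low_counts(mat, 15)
        expected = [f"T{i}" for i in range(100) if max(counts[i]) >= 15]
        assert kept.transcript_ids == expected


class TestVoom:
    def test_weights_positive_finite(self, null_sim):
        mat, design, _ = null_sim
        expr = voom_weights(m.filter_low_counts(mat, 15), design)
        assert np.all(np.isfinite(expr.weights))
        assert np.all(expr.weights > 0)
        assert np.all(np.isfinite(expr.logcpm))

    def test_constant_log_variance_gives_flat_weights(self, small_design):
        # counts log-normal with constant log-sd across a wide mean range:
        # the fitted trend is flat, so weights are nearly constant
        rng = np.random.default_rng(2)
        base = rng.uniform(4, 10, size=1500)
        y = np.round(2.0 ** (base[:, None] + rng.normal(0, 0.4, (1500, 24)))).astype(int)
        mat = m.TranscriptCountMatrix(
            [f"T{i}" for i in range(1500)], [f"G{i}" for i in range(1500)],
            list(small_design.sample_ids), y,
        )
        expr = voom_weights(m.filter_low_counts(mat, 15), small_design)
        cv = expr.weights.std() / expr.weights.mean()
        assert cv < 0.2

    def test_low_abundance_transcripts_downweighted_under_nb_noise(self, small_design):
        rng = np.random.default_rng(3)
        n_half = 1000
        mus = np.r_[np.full(n_half, 8.0), np.full(n_half, 600.0)]
        phi = 0.05
        nn = 1 / phi
        counts = rng.negative_binomial(nn, nn / (nn + mus[:, None]),
                                       size=(2 * n_half, 24))
        mat = m.TranscriptCountMatrix(
            [f"T{i}" for i in range(2 * n_half)],
            [f"G{i}" for i in range(2 * n_half)],
            list(small_design.sample_ids), counts,
        )
        expr = voom_weights(m.filter_low_counts(mat, 1), small_design)
        w_low = np.median(expr.weights[:n_half])
        w_high = np.median(expr.weights[n_half:])
        assert w_low < w_high


class TestWeightedLM:
    def test_unit_weights_equal_ols(self, small_design):
        rng = np.random.default_rng(4)
        X = small_design.model_matrix
        y = rng.normal(size=(5, 24))
        expr = m.de.WeightedExpression(logcpm=y, weights=np.ones_like(y),
                                       lib_sizes=np.ones(24))
        fits = m.fit_weighted_lm(expr, small_design)
        beta_ols = y @ np.linalg.pinv(X).T
        np.testing.assert_allclose(fits.beta, beta_ols, atol=1e-10)

    def test_matches_normal_equations_oracle(self, small_design):
        rng = np.random.default_rng(5)
        X = small_design.model_matrix
        y = rng.normal(size=(20, 24))
        w = rng.uniform(0.2, 3.0, size=(20, 24))
        expr = m.de.WeightedExpression(logcpm=y, weights=w, lib_sizes=np.ones(24))
        fits = m.fit_weighted_lm(expr, small_design)
        for t in range(20):
            beta, s2, su = wls_oracle(X, y[t], w[t])
            np.testing.assert_allclose(fits.beta[t], beta, atol=1e-8)
            assert fits.sigma2[t] == pytest.approx(s2, abs=1e-8)
            np.testing.assert_allclose(fits.stdev_unscaled[t], su, atol=1e-8)

    def test_duplicated_sample_half_weight_equals_single_full_weight(self):
        # two copies of a sample at weight 1/2 give the same fit as one copy
        # at weight 1 (classic weighting equivalence)
        rng = np.random.default_rng(6)
        X1 = np.column_stack([np.ones(6), [0, 1, 0, 1, 0, 1], [1, 2, 3, 4, 5, 6]])
        y1 = rng.normal(size=6)
        Xd = np.repeat(X1, 2, axis=0)
        yd = np.repeat(y1, 2)
        b1, _, _ = wls_oracle(X1, y1, np.ones(6))
        bd, _, _ = wls_oracle(Xd, yd, np.full(12, 0.5))
        np.testing.assert_allclose(b1, bd, atol=1e-10)


class TestModeration:
    def _fits(self, rng, n=200, d=10, beta=None):
        s2 = stats.chi2.rvs(d, size=n, random_state=rng) / d
        beta_arr = np.tile(beta if beta is not None else rng.normal(size=7), (n, 1))
        return LinearFits(
            beta=beta_arr, sigma2=s2, df_residual=float(d),
            stdev_unscaled=np.full((n, 7), 0.5), ok=np.ones(n, bool),
        )

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(7)
        fits = self._fits(rng)
        mod = m.ebayes_moderate(fits, df_prior_override=0.0)
        ordinary = fits.beta[:, 4] / (0.5 * np.sqrt(fits.sigma2))
        np.testing.assert_allclose(mod.t["MNR"], ordinary, rtol=1e-10)

    def test_moderated_t_monotone_decreasing_in_variance(self):
        n = 50
        s2 = np.linspace(0.1, 5.0, n)
        fits = LinearFits(
            beta=np.ones((n, 7)), sigma2=s2, df_residual=10.0,
            stdev_unscaled=np.full((n, 7), 0.5), ok=np.ones(n, bool),
        )
        mod = m.ebayes_moderate(fits)
        t = np.abs(mod.t["MNR"])
        assert np.all(np.diff(t) < 0)

    def test_prior_recovered_from_scaled_f_variances(self):
        # s^2 = s0^2 * (chi2_d/d) / (chi2_d0/d0) with d0=4, s0^2=2
        rng = np.random.default_rng(8)
        d, d0, s02 = 10, 4.0, 2.0
        s2 = s02 * (stats.chi2.rvs(d, size=5000, random_state=rng) / d) / (
            stats.chi2.rvs(d0, size=5000, random_state=rng) / d0)
        d0_hat, s02_hat = fit_scaled_f_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s02_hat == pytest.approx(s02, rel=0.15)

    def test_identical_variances_flag_infinite_prior(self):
        fits = LinearFits(
            beta=np.ones((20, 7)), sigma2=np.full(20, 2.0), df_residual=10.0,
            stdev_unscaled=np.full((20, 7), 0.5), ok=np.ones(20, bool),
        )
        mod = m.ebayes_moderate(fits)
        assert np.isinf(mod.df_prior)
        np.testing.assert_allclose(mod.s2_post, mod.s2_prior)

    def test_zero_variance_transcripts_floored_and_flagged(self):
        rng = np.random.default_rng(9)
        s2 = np.r_[0.0, stats.chi2.rvs(10, size=30, random_state=rng) / 10]
        fits = LinearFits(
            beta=np.ones((31, 7)), sigma2=s2, df_residual=10.0,
            stdev_unscaled=np.full((31, 7), 0.5), ok=np.ones(31, bool),
        )
        mod = m.ebayes_moderate(fits)
        assert mod.zero_variance_flag[0] and not mod.zero_variance_flag[1:].any()
        assert np.isfinite(mod.t["MNR"]).all()


class TestBH:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(m.bh_fdr([0.03]), [0.03])

    def test_uniform_ladder_collapses_to_common_value(self):
        np.testing.assert_allclose(m.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            m.bh_fdr([0.1, np.nan])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_step_up_oracle_and_dominates_p(self, p):
        q = m.bh_fdr(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDedupe:
    def _table(self, rng, n=60, n_genes=20):
        return pd.DataFrame(
            {
                "transcript_id": [f"T{i:03d}" for i in range(n)],
                "gene_symbol": [f"G{rng.integers(n_genes):02d}" for _ in range(n)],
                "t_mod": rng.normal(size=n),
                "p": rng.uniform(size=n).round(2),  # rounding forces ties
            }
        )

    def test_keeps_most_significant_transcript(self):
        tab = pd.DataFrame(
            {
                "transcript_id": ["a", "b"],
                "gene_symbol": ["G", "G"],
                "t_mod": [1.0, 5.0],
                "p": [0.5, 0.01],
            }
        )
        out = m.dedupe_gene_symbols(tab)
        assert list(out["transcript_id"]) == ["b"]

    def test_unique_symbols_unchanged(self):
        rng = np.random.default_rng(10)
        tab = self._table(rng, n=15, n_genes=1000)
        assert len(m.dedupe_gene_symbols(tab)) == len(tab)

    def test_matches_group_by_min_oracle_with_tie_breaks(self):
        rng = np.random.default_rng(11)
        tab = self._table(rng)
        out = m.dedupe_gene_symbols(tab).set_index("gene_symbol")
        for gene, grp in tab.groupby("gene_symbol"):
            best = sorted(
                grp.itertuples(),
                key=lambda r: (r.p, -abs(r.t_mod), r.transcript_id),
            )[0]
            assert out.loc[gene, "transcript_id"] == best.transcript_id


class TestSelection:
    def _tables(self, rows):
        tab = pd.DataFrame(rows)
        return {"MNR_x_time_sq": tab}

    def test_fdr_hit_joins_primary_set(self):
        tables = self._tables([
            {"transcript_id": "t", "gene_symbol": "A", "contrast": "MNR_x_time_sq",
             "coefficient": 1.0, "t_mod": 4.0, "p": 0.0001, "fdr": 0.09},
        ])
        primary, network = m.select_candidates(tables, m.PipelineConfig())
        assert list(primary["gene_symbol"]) == ["A"]
        assert list(network["gene_symbol"]) == ["A"]

    def test_sub_threshold_p_with_high_fdr_is_network_only(self):
        tables = self._tables([
            {"transcript_id": "t", "gene_symbol": "B", "contrast": "MNR_x_time_sq",
             "coefficient": 1.0, "t_mod": 3.0, "p": 0.0009, "fdr": 0.14},
        ])
        primary, network = m.select_candidates(tables, m.PipelineConfig())
        assert primary.empty
        assert list(network["gene_symbol"]) == ["B"]

    def test_empty_tables_give_empty_sets(self):
        tables = {"MNR": pd.DataFrame(columns=[
            "transcript_id", "gene_symbol", "contrast", "coefficient",
            "t_mod", "p", "fdr"])}
        primary, network = m.select_candidates(tables, m.PipelineConfig())
        assert primary.empty and network.empty


class TestPipelineInvariance:
    def test_results_invariant_to_sample_permutation(self, null_sim):
        mat, design, _ = null_sim
        res = m.DifferentialExpression(mat, design).fit()
        rng = np.random.default_rng(12)
        perm = rng.permutation(mat.n_samples)
        mat_p = m.TranscriptCountMatrix(
            list(mat.transcript_ids), list(mat.gene_symbols),
            [mat.sample_ids[i] for i in perm], mat.counts[:, perm],
        )
        design_p = m.StudyDesign(
            sample_ids=[design.sample_ids[i] for i in perm],
            group=design.group[perm], sex=design.sex[perm],
            gestational_day=design.gestational_day[perm],
        )
        res_p = m.DifferentialExpression(mat_p, design_p).fit()
        for name in res.tables:
            np.testing.assert_allclose(
                res.tables[name]["p"], res_p.tables[name]["p"], rtol=1e-8
            )

    def test_quadratic_signal_lands_in_quadratic_contrast(self):
        # strong, clean quadratic-only signal: the routing property under test
        # is which contrast picks it up, not the study's power
        spec = m.SimulationSpec(n_genes=400, frac_de=0.1, frac_splice=0.0,
                                de_effect=2.5, bio_log_sd=0.3, nb_dispersion=0.1,
                                seed=13)
        mat, design, truth = m.simulate_counts(spec)
        res = m.DifferentialExpression(mat, design).fit()
        tx = truth[truth.level == "transcript"].set_index("id")
        quad = res.tables["MNR_x_time_sq"]
        lin = res.tables["MNR_x_time"]
        is_de = tx["is_de"].reindex(quad["transcript_id"]).to_numpy(dtype=bool)
        # injected transcripts should rank low in quadratic-contrast p
        u = stats.mannwhitneyu(quad["p"][is_de], quad["p"][~is_de],
                               alternative="less")
        assert u.pvalue < 0.01
        # and the linear contrast stays quiet on them
        assert (lin["fdr"][is_de] < 0.1).mean() < 0.05
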