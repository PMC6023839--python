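"""Differential expression: collapse, CV filter, moderated t, stable filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from talnet import de
from talnet.simulate import SimulationConfig, StableFeature, generate_expression

from conftest import make_matrix


# ---------------------------------------------------------------------------
# probe collapse
# ---------------------------------------------------------------------------

class TestCollapseProbes:
    def test_keeps_probe_with_largest_row_sum(self, rng):
        vals = rng.normal(5, 1, (3, 12))
        vals[1] += 2.0  # p2 has the larger total
        m = make_matrix(vals, features=["p1", "p2", "p3"])
        out = de.collapse_probes(m, {"p1": "GENE", "p2": "GENE", "p3": "OTHER"})
        assert list(out.feature_ids) == ["GENE", "OTHER"]
        assert np.allclose(out.values.loc["GENE"], vals[1])

    def test_sum_method_adds_probe_rows(self, rng):
        vals = rng.normal(5, 1, (2, 12))
        m = make_matrix(vals, features=["p1", "p2"])
        out = de.collapse_probes(m, {"p1": "G", "p2": "G"}, method="sum")
        assert np.allclose(out.values.loc["G"], vals.sum(axis=0))

    def test_one_probe_per_gene_is_renaming(self, rng):
        vals = rng.normal(5, 1, (2, 12))
        m = make_matrix(vals, features=["p1", "p2"])
        out = de.collapse_probes(m, {"p1": "A", "p2": "B"})
        assert np.allclose(out.values.to_numpy(), vals)

    def test_unmapped_probe_dropped_and_empty_map_passthrough(self, rng):
        vals = rng.normal(5, 1, (2, 12))
        m = make_matrix(vals, features=["p1", "p2"])
        out = de.collapse_probes(m, {"p1": "A"})
        assert out.feature_ids == ["A"]
        with pytest.warns(UserWarning, match="pass-through"):
            out2 = de.collapse_probes(m, {})
        assert out2.values.equals(m.values)


# ---------------------------------------------------------------------------
# CV filter
# ---------------------------------------------------------------------------

class TestCvFilter:
    def test_constant_row_removed_and_high_cv_kept(self):
        vals = np.vstack([np.full(12, 7.0),                      # CV 0
                          10.0 + 2.0 * np.linspace(-1, 1, 12)])  # CV ~ 0.12
        m = make_matrix(vals)
        out = de.cv_filter(m, min_cv=0.10)
        assert out.feature_ids == ["g1"]

    def test_zero_threshold_is_identity(self, rng):
        m = make_matrix(rng.normal(5, 1, (10, 12)))
        assert de.cv_filter(m, min_cv=0.0).feature_ids == m.feature_ids

    def test_zero_mean_feature_kept(self, rng):
        vals = rng.normal(5, 1, (2, 12))
        vals[0] -= vals[0].mean()  # exact zero mean
        m = make_matrix(vals)
        assert "g0" in de.cv_filter(m, min_cv=0.10).feature_ids


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

class TestModeratedT:
    def test_unmoderated_equals_pooled_two_sample_t(self, rng):
        """With moderation off the statistic is the classical pooled t."""
        vals = rng.normal(5, 1, (50, 12))
        m = make_matrix(vals)
        res = de.moderated_t_test(m, moderate=False)
        ref = stats.ttest_ind(vals[:, :5], vals[:, 5:], axis=1)
        assert np.allclose(res["t"], ref.statistic, atol=1e-10)
        assert np.allclose(res["p_value"], ref.pvalue, atol=1e-10)

    def test_shrinkage_pulls_variances_towards_prior(self, rng):
        """Moderated |t| is larger than ordinary |t| for high-variance genes
        and smaller for low-variance genes (regression to the prior)."""
        n = 400
        sds = np.where(np.arange(n) < n // 2, 0.3, 3.0)
        vals = rng.normal(0, 1, (n, 12)) * sds[:, None] + 5.0
        vals[:, :5] += 1.0
        m = make_matrix(vals)
        mod = de.moderated_t_test(m)["t"].to_numpy()
        raw = de.moderated_t_test(m, moderate=False)["t"].to_numpy()
        assert np.mean(np.abs(mod[n // 2:]) > np.abs(raw[n // 2:])) > 0.8
        assert np.mean(np.abs(mod[:n // 2]) < np.abs(raw[:n // 2])) > 0.8

    def test_null_type_one_error_calibrated(self, rng):
        fracs = []
        for _ in range(20):
            m = make_matrix(rng.standard_normal((2000, 12)))
            res = de.moderated_t_test(m)
            fracs.append((res["p_value"] < 0.05).mean())
        assert 0.035 < np.mean(fracs) < 0.065

    def test_bh_adjustment_stepwise_example(self, rng):
        """p = (0.01, 0.02, 0.03, 0.04) all BH-adjust to 0.04."""
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_zero_residual_df_errors(self):
        vals = np.random.default_rng(0).normal(5, 1, (5, 3))
        m = make_matrix(vals, n_relapse=1, n_remission=2)
        with pytest.raises(ValueError, match="two samples"):
            de.moderated_t_test(m)


class TestCallDifferential:
    def _result(self, log2fc, adj_p):
        return pd.DataFrame({
            "log2FC": log2fc,
            "fold_change": np.where(np.asarray(log2fc) >= 0,
                                    2.0 ** np.asarray(log2fc),
                                    -(2.0 ** -np.asarray(log2fc))),
            "t": 0.0, "p_value": adj_p, "adj_p": adj_p, "call": "ns",
        }, index=[f"f{i}" for i in range(len(log2fc))])

    def test_strong_upregulated_feature_called_up(self):
        # linear FC 7.37 at adjusted p 0.003 passes both gates
        res = de.call_differential(self._result([np.log2(7.37)], [0.003]))
        assert res["call"].iloc[0] == "up"
        assert res["fold_change"].iloc[0] == pytest.approx(7.37)

    def test_boundary_fold_change_is_ns(self):
        res = de.call_differential(self._result([np.log2(1.5)], [0.001]))
        assert res["call"].iloc[0] == "ns"

    def test_calls_partition_features(self, rng):
        m = make_matrix(rng.normal(5, 1, (500, 12)))
        res = de.call_differential(de.moderated_t_test(m))
        counts = res["call"].value_counts()
        assert counts.sum() == 500

    def test_monotone_in_alpha_and_fc(self, rng):
        vals = rng.normal(5, 0.5, (300, 12))
        vals[:50, :5] += rng.uniform(0.5, 1.5, (50, 1))
        m = make_matrix(vals)
        base = de.moderated_t_test(m)
        loose = set(de.de_features(de.call_differential(base, 1.5, 0.05)))
        tight_alpha = set(de.de_features(de.call_differential(base, 1.5, 0.01)))
        tight_fc = set(de.de_features(de.call_differential(base, 2.5, 0.05)))
        assert tight_alpha <= loose
        assert tight_fc <= loose


# ---------------------------------------------------------------------------
# stable expression filter
# ---------------------------------------------------------------------------

def brute_force_stable(matrix, features):
    """Independent oracle: explicit min/max comparison per feature."""
    out = {}
    for f in features:
        rel = matrix.subset([f]).condition_values("relapse").to_numpy().ravel()
        rem = matrix.subset([f]).condition_values("remission").to_numpy().ravel()
        if min(rel) > max(rem):
            out[f] = "stable_up"
        elif max(rel) < min(rem):
            out[f] = "stable_down"
    return out


class TestStableFilter:
    def test_separated_feature_is_stable_up(self):
        vals = np.array([[5, 6, 7, 8, 9, 1, 2, 3, 4, 4.5, 4.8, 4.9]])
        m = make_matrix(vals)
        assert de.stable_expression_filter(m).to_dict() == {"g0": "stable_up"}

    def test_overlapping_ranges_excluded(self, rng):
        m = make_matrix(rng.normal(5, 1, (20, 12)))
        # overlap is near-certain for iid rows; verify against the oracle
        got = de.stable_expression_filter(m).to_dict()
        assert got == brute_force_stable(m, m.feature_ids)

    def test_tie_excluded(self):
        vals = np.array([[5, 6, 7, 8, 5, 1, 2, 3, 4, 4.5, 4.8, 5.0]])
        m = make_matrix(vals)  # min(relapse) == max(remission) == 5
        assert de.stable_expression_filter(m).empty

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(200):
            vals = rng.normal(0, 1, (10, 12)) + rng.choice(
                [0, 1.5], size=(10, 1))
            m = make_matrix(vals)
            got = de.stable_expression_filter(m).to_dict()
            assert got == brute_force_stable(m, m.feature_ids)

    def test_recovers_planted_stable_set_via_de_calls(self):
        """Pipeline semantics: the filter runs on the DE calls; with only
        stable features planted, the recovered set equals the planted set."""
        cfg = SimulationConfig(seed=4, n_genes=200, n_mirnas=5, n_tfs=2)
        genes = cfg.gene_universe()
        cfg.stable_spec = [StableFeature(g, "up") for g in genes[:6]]
        cfg.stable_spec += [StableFeature(g, "down") for g in genes[6:10]]
        g, _, truth = generate_expression(cfg)
        res = de.call_differential(de.moderated_t_test(g))
        stable = de.stable_expression_filter(g, de.de_features(res))
        assert stable.to_dict() == truth.stable_genes
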