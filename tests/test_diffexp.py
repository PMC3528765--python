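"""Moderated-t machinery: pooled-t identity, prior recovery, agreement with
the Bioconductor reference implementation, BH step-up, probeset collapse and
centroid clustering."""
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brcadel.containers import ExpressionMatrix
from brcadel.diffexp import (
    ModeratedTTest, bh_adjust, centroid_cluster, collapse_probesets,
    estimate_var_prior, moderated_t, select_signature, trigamma_inverse,
)


def _pooled_t(matrix):
    """Independent direct-formula pooled two-sample t (the d0=0 oracle)."""
    case = matrix.group_columns("BRCA2").to_numpy()
    ctrl = matrix.group_columns("BRCAX").to_numpy()
    n1, n2 = case.shape[1], ctrl.shape[1]
    s2 = (case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)) / (
        n1 + n2 - 2)
    return (case.mean(axis=1) - ctrl.mean(axis=1)) / np.sqrt(s2 * (1 / n1 + 1 / n2))


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self, two_group_matrix):
        stats = moderated_t(two_group_matrix, df_prior=0.0)
        np.testing.assert_allclose(stats.t.to_numpy(), _pooled_t(two_group_matrix),
                                   atol=1e-10)

    def test_d0_infinite_shrinks_fully_to_prior(self, two_group_matrix):
        stats = moderated_t(two_group_matrix, df_prior=np.inf)
        assert np.allclose(stats.table["s2_post"], stats.s2_prior)
        diff = stats.table["mean_case"] - stats.table["mean_control"]
        se = np.sqrt(stats.s2_prior * (1 / stats.n_case + 1 / stats.n_control))
        np.testing.assert_allclose(stats.t.to_numpy(), diff / se, atol=1e-12)

    def test_t_sign_matches_mean_difference(self, two_group_matrix):
        stats = moderated_t(two_group_matrix)
        diff = stats.table["mean_case"] - stats.table["mean_control"]
        assert (np.sign(stats.t) == np.sign(diff)).all()

    def test_moderated_variance_between_gene_and_prior(self, two_group_matrix):
        stats = moderated_t(two_group_matrix)
        assert 0 < stats.df_prior < np.inf
        lo = np.minimum(stats.table["s2"], stats.s2_prior)
        hi = np.maximum(stats.table["s2"], stats.s2_prior)
        inner = ~np.isclose(stats.table["s2"], stats.s2_prior)
        assert ((stats.table["s2_post"][inner] > lo[inner])
                & (stats.table["s2_post"][inner] < hi[inner])).all()

    def test_invariant_to_constant_gene_shift(self, two_group_matrix):
        base = moderated_t(two_group_matrix)
        shifted = ExpressionMatrix(
            two_group_matrix.values.add(
                pd.Series(np.arange(len(two_group_matrix.gene_ids)),
                          index=two_group_matrix.gene_ids), axis=0),
            two_group_matrix.labels)
        np.testing.assert_allclose(moderated_t(shifted).t, base.t, atol=1e-10)

    def test_equal_group_means_give_zero_t_unit_p(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0],
             [1.0, 5.0, 3.0, 2.0, 4.0, 2.0, 2.0, 3.0]],
            index=["flat", "noisy"],
            columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["BRCA2"] * 4 + ["BRCAX"] * 4, index=values.columns)
        stats = moderated_t(ExpressionMatrix(values, labels))
        assert stats.t["flat"] == pytest.approx(0.0, abs=1e-12)
        assert stats.table.loc["flat", "p_value"] == pytest.approx(1.0)

    def test_identical_variances_collapse_to_full_shrinkage(self):
        """Zero spread in log s2 is underdispersed relative to chi-squared
        sampling noise, so the prior df estimate is infinite and every gene
        receives the same moderated variance."""
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, size=8)
        values = pd.DataFrame([base + i for i in range(20)],
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["BRCA2"] * 4 + ["BRCAX"] * 4, index=values.columns)
        stats = moderated_t(ExpressionMatrix(values, labels))
        assert np.isinf(stats.df_prior)
        assert np.allclose(stats.table["s2_post"], stats.table["s2_post"].iloc[0])

    def test_group_smaller_than_two_rejected(self, two_group_matrix):
        y = np.array(["BRCA2"] + ["BRCAX"] * 10)
        with pytest.raises(ValueError):
            ModeratedTTest().fit(two_group_matrix.values.T.to_numpy(), y)

    def test_prior_recovery_from_scaled_f_variances(self):
        """Moment matching recovers (d0, s02) from s2 ~ s02 * F(d, d0)."""
        d, d0_true, s02_true = 6, 4.0, 0.8
        d0s, s02s = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sigma2 = d0_true * s02_true / rng.chisquare(d0_true, size=2000)
            s2 = sigma2 * rng.chisquare(d, size=2000) / d
            d0, s02 = estimate_var_prior(s2, d)
            d0s.append(d0)
            s02s.append(s02)
        assert 2.5 <= np.median(d0s) <= 6.0
        assert abs(np.median(s02s) - s02_true) / s02_true < 0.25

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for y in (0.01, 0.5, 2.0, 50.0):
            assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_bioconductor_limma(self, two_group_matrix, tmp_path):
        """Full agreement (t, p, prior df, prior variance) with limma eBayes."""
        xf = tmp_path / "X.tsv"
        two_group_matrix.values.to_csv(xf, sep="\t", index=False, header=False)
        stats = moderated_t(two_group_matrix)
        out = tmp_path / "py.tsv"
        stats.table[["t", "p_value"]].to_csv(out, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            X <- as.matrix(read.table("{xf}", sep="\\t"))
            grp <- factor(c(rep("case", {stats.n_case}), rep("ctrl", {stats.n_control})),
                          levels=c("ctrl", "case"))
            fit <- eBayes(lmFit(X, model.matrix(~grp)))
            py <- read.table("{out}", sep="\\t", header=TRUE)
            stopifnot(max(abs(fit$t[, 2] - py$t)) < 1e-8)
            stopifnot(max(abs(fit$p.value[, 2] - py$p_value)) < 1e-8)
            cat(fit$df.prior, fit$s2.prior, sep="\\n")
        """)
        res = subprocess.run(["Rscript", "-"], input=script, text=True,
                             capture_output=True, check=True)
        r_d0, r_s02 = map(float, res.stdout.strip().splitlines()[-2:])
        assert stats.df_prior == pytest.approx(r_d0, rel=1e-5)
        assert stats.s2_prior == pytest.approx(r_s02, rel=1e-5)


def _bh_brute_force(p):
    """Quadratic-time literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        candidates = [m * p[j] / (rank_j + 1)
                      for rank_j, j in enumerate(order) if rank_j + 1 >= rank_i]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_matches_brute_force_definition(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, _bh_brute_force(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()


class TestSelectSignature:
    def test_no_gene_passes_gives_empty_signature(self, two_group_matrix):
        sig = select_signature(moderated_t(two_group_matrix), fdr_threshold=1e-12)
        assert len(sig) == 0

    def test_threshold_one_selects_everything(self, two_group_matrix):
        stats = moderated_t(two_group_matrix)
        assert len(select_signature(stats, 1.0 + 1e-9)) == len(stats.table)

    def test_monotone_in_threshold(self, two_group_matrix):
        stats = moderated_t(two_group_matrix)
        prev = None
        for thr in (0.5, 0.2, 0.05, 0.01):
            genes = set(select_signature(stats, thr).genes)
            if prev is not None:
                assert genes <= prev
            prev = genes

    def test_weights_are_t_values(self, two_group_matrix):
        stats = moderated_t(two_group_matrix)
        sig = select_signature(stats, 1.0)
        np.testing.assert_allclose(sig.weights, stats.t.loc[sig.genes])


class TestCollapseProbesets:
    def test_single_probeset_retained_unchanged(self, two_group_matrix):
        mapping = {g: f"SYM_{g}" for g in two_group_matrix.gene_ids}
        out = collapse_probesets(two_group_matrix, mapping)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   two_group_matrix.values.to_numpy())

    def test_most_variable_probeset_wins(self):
        values = pd.DataFrame(
            {"s1": [0.0, 0.0], "s2": [1.0, 2.0], "s3": [2.0, 4.0]},
            index=["p_low", "p_high"])
        labels = pd.Series(["BRCA2", "BRCAX", "BRCAX"], index=values.columns)
        out = collapse_probesets(ExpressionMatrix(values, labels),
                                 {"p_low": "GENE", "p_high": "GENE"})
        np.testing.assert_allclose(out.values.loc["GENE"], [0.0, 2.0, 4.0])

    def test_matches_argmax_sd_oracle(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(size=(10, 6)),
                              index=[f"p{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(6)])
        labels = pd.Series(["BRCA2"] * 3 + ["BRCAX"] * 3, index=values.columns)
        mapping = {f"p{i}": f"G{i % 3}" for i in range(10)}
        out = collapse_probesets(ExpressionMatrix(values, labels), mapping)
        for gene in ("G0", "G1", "G2"):
            probes = [p for p, g in mapping.items() if g == gene]
            best = max(probes, key=lambda p: values.loc[p].std(ddof=1))
            np.testing.assert_allclose(out.values.loc[gene], values.loc[best])

    def test_no_mapped_probes_is_error(self, two_group_matrix):
        with pytest.raises(ValueError):
            collapse_probesets(two_group_matrix, {"not_a_probe": "X"})


class TestCentroidCluster:
    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=6)
        values = pd.DataFrame([base, rng.normal(size=6), base],
                              index=["a", "b", "a2"],
                              columns=[f"s{i}" for i in range(6)])
        labels = pd.Series(["BRCA2"] * 3 + ["BRCAX"] * 3, index=values.columns)
        order = centroid_cluster(ExpressionMatrix(values, labels))[0]
        pos = {g: i for i, g in enumerate(order)}
        assert abs(pos["a"] - pos["a2"]) == 1

    def test_correlated_pair_adjacent(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        values = pd.DataFrame(
            [x, x + rng.normal(0, 0.05, 8), -x],
            index=["r1", "r2", "anti"], columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["BRCA2"] * 4 + ["BRCAX"] * 4, index=values.columns)
        order = centroid_cluster(ExpressionMatrix(values, labels))[0]
        pos = {g: i for i, g in enumerate(order)}
        assert abs(pos["r1"] - pos["r2"]) == 1

    def test_single_row(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["only"],
                              columns=[f"s{i}" for i in range(4)])
        labels = pd.Series(["BRCA2", "BRCA2", "BRCAX", "BRCAX"],
                           index=values.columns)
        genes, samples = centroid_cluster(ExpressionMatrix(values, labels))
        assert genes == ["only"] and len(samples) == 4
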