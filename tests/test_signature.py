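"""Moderated DE, signature specificity, stratification, rank score, PCs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import twinupv as tw
from twinupv.cohort import Orientation
from twinupv.errors import ConfigurationError
from twinupv.signature import Signature, fit_variance_prior

from conftest import heavy_typeb_individuals, truth_groups


def toy_orientation(n_pairs: int) -> Orientation:
    idx = [f"P{i}" for i in range(n_pairs)]
    tab = pd.DataFrame(
        {"light": [f"{p}a" for p in idx], "heavy": [f"{p}b" for p in idx], "tie": False},
        index=pd.Index(idx, name="pair"),
    )
    return Orientation(tab)


def toy_expression(diffs: np.ndarray, seed: int = 0) -> tuple[pd.DataFrame, Orientation]:
    """genes x pairs difference matrix realized as heavy/light columns."""
    rng = np.random.default_rng(seed)
    n_genes, n_pairs = diffs.shape
    ori = toy_orientation(n_pairs)
    base = rng.normal(7, 1, size=(n_genes, n_pairs))
    cols = {}
    for j, p in enumerate(ori.pairs):
        cols[f"{p}a"] = base[:, j]
        cols[f"{p}b"] = base[:, j] + diffs[:, j]
    expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    return expr, ori


class TestModeratedDE:
    def test_prior_df_zero_equals_ordinary_paired_t(self):
        """With no shrinkage, the moderated test is the classical paired t."""
        rng = np.random.default_rng(0)
        diffs = rng.normal(0, 1, size=(500, 12)) * rng.uniform(0.2, 3, size=(500, 1))
        expr, ori = toy_expression(diffs)
        labels = pd.Series(0, index=ori.pairs)
        res = tw.paired_moderated_de(expr, ori, labels, prior_df=0.0)[0]
        ref = stats.ttest_1samp(diffs, 0.0, axis=1)
        np.testing.assert_allclose(res["t"].to_numpy(), ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p"].to_numpy(), ref.pvalue, atol=1e-10)

    def test_all_zero_differences(self):
        diffs = np.zeros((5, 8))
        expr, ori = toy_expression(diffs)
        labels = pd.Series(0, index=ori.pairs)
        res = tw.paired_moderated_de(expr, ori, labels)[0]
        assert (res["effect"] == 0).all()
        assert (res["t"] == 0).all()
        assert (res["p"] == 1).all()

    def test_single_gene_equals_ordinary_t(self):
        diffs = np.array([[0.4, 0.1, 0.9, -0.2, 0.5, 0.3]])
        expr, ori = toy_expression(diffs)
        labels = pd.Series(0, index=ori.pairs)
        res = tw.paired_moderated_de(expr, ori, labels)[0]
        ref = stats.ttest_1samp(diffs[0], 0.0)
        assert res["t"].iloc[0] == pytest.approx(ref.statistic, abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_null_type_one_rate(self):
        """Null simulation, 2,000 genes, 40 pairs: alpha=0.001 holds."""
        rng = np.random.default_rng(7)
        diffs = rng.normal(0, 0.35, size=(2000, 40))
        expr, ori = toy_expression(diffs)
        labels = pd.Series(0, index=ori.pairs)
        res = tw.paired_moderated_de(expr, ori, labels)[0]
        frac = (res["p"] < 0.001).mean()
        assert 0.0 <= frac <= 0.003

    def test_moderation_shrinks_toward_prior(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0, 1, size=(300, 6)) * rng.uniform(0.1, 4, size=(300, 1))
        expr, ori = toy_expression(diffs)
        labels = pd.Series(0, index=ori.pairs)
        res = tw.paired_moderated_de(expr, ori, labels)[0]
        assert 0 < res.attrs["prior_df"] < np.inf
        mod_t = res["t"].to_numpy()
        raw_t = stats.ttest_1samp(diffs, 0.0, axis=1).statistic
        # moderated statistics have less extreme tails than the raw t
        assert np.abs(mod_t).max() < np.abs(raw_t).max()

    def test_small_cluster_skipped(self):
        diffs = np.zeros((3, 6))
        expr, ori = toy_expression(diffs)
        labels = pd.Series([0, 0, 0, 0, 1, 1], index=ori.pairs)
        res = tw.paired_moderated_de(expr, ori, labels)
        assert 0 in res and 1 not in res

    def test_cross_check_against_limma_oracle(self, tmp_path):
        """Independent oracle: R/limma's empirical-Bayes moderated t.

        Same intercept-only design on the paired differences; the prior
        (df, variance) and per-gene moderated t must agree to float
        precision.
        """
        import subprocess

        rng = np.random.default_rng(0)
        diffs = rng.normal(0, 1, size=(200, 10)) * rng.uniform(0.3, 2.0, size=(200, 1))
        diffs[:20] += 0.8
        data = tmp_path / "diffs.txt"
        out = tmp_path / "limma.txt"
        np.savetxt(data, diffs)
        script = (
            f'y <- as.matrix(read.table("{data}")); '
            "suppressMessages(library(limma)); "
            "fit <- eBayes(lmFit(y, design=matrix(1, ncol(y), 1))); "
            f'write.table(cbind(fit$t, fit$p.value), "{out}", '
            "row.names=FALSE, col.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True,
                       timeout=120)
        ref = np.loadtxt(out)
        expr, ori = toy_expression(diffs)
        labels = pd.Series(0, index=ori.pairs)
        res = tw.paired_moderated_de(expr, ori, labels)[0]
        np.testing.assert_allclose(res["t"].to_numpy(), ref[:, 0], atol=1e-8)
        np.testing.assert_allclose(res["p"].to_numpy(), ref[:, 1], atol=1e-8)

    def test_variance_prior_moment_matching_recovers_truth(self):
        """Gene variances drawn from a scaled inv-chi2 prior are recovered."""
        rng = np.random.default_rng(3)
        d0_true, s0_true, df = 8.0, 0.5, 10
        v = d0_true * s0_true / rng.chisquare(d0_true, size=5000)
        s2 = v * rng.chisquare(df, size=5000) / df
        d0, s0 = fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0 == pytest.approx(s0_true, rel=0.1)


class TestSignatureDerivation:
    @staticmethod
    def _tables(rows: dict[str, dict[str, tuple[float, float]]]) -> dict:
        """rows: gene -> cluster -> (effect, p)."""
        clusters = sorted({c for v in rows.values() for c in v})
        out = {}
        for c in clusters:
            out[c] = pd.DataFrame(
                {
                    "effect": [rows[g][c][0] for g in rows],
                    "p": [rows[g][c][1] for g in rows],
                },
                index=pd.Index(list(rows), name="gene"),
            )
        return out

    def test_specificity_filter_excludes_shared_genes(self):
        tables = self._tables(
            {
                "gA": {"B": (2.0, 1e-6), "A": (0.0, 0.9)},      # typeB-specific
                "gB": {"B": (2.0, 1e-6), "A": (1.5, 1e-5)},      # shared: excluded
                "gC": {"B": (0.1, 0.5), "A": (0.0, 0.9)},        # not significant
                "gD": {"B": (-1.8, 1e-6), "A": (0.0, 0.8)},      # typeB-specific down
            }
        )
        sig = tw.derive_typeB_signature(tables, "B", gene_kmeans_k=1)
        assert set(sig.gene_names) == {"gA", "gD"}
        assert sig.direction_of("gA") == "up_in_heavy"
        assert sig.direction_of("gD") == "down_in_heavy"

    def test_alpha_one_boundary_does_not_crash(self):
        tables = self._tables(
            {"gA": {"B": (2.0, 1e-6), "A": (0.0, 0.9)}}
        )
        sig = tw.derive_typeB_signature(tables, "B", alpha=1.0)
        assert len(sig) == 0

    def test_empty_candidates_warn_not_error(self):
        tables = self._tables({"gA": {"B": (0.0, 0.9), "A": (0.0, 0.9)}})
        sig = tw.derive_typeB_signature(tables, "B")
        assert len(sig) == 0
        assert sig.provenance["n_candidates"] == 0

    def test_missing_typeb_table_is_error(self):
        tables = self._tables({"gA": {"A": (0.0, 0.9)}})
        with pytest.raises(ConfigurationError):
            tw.derive_typeB_signature(tables, "B")

    def test_recovery_on_planted_cohort(self, default_cohort, default_de):
        sig = tw.derive_typeB_signature(default_de, "typeB", seed=0)
        roles = default_cohort.truth["gene_role"]
        planted = {g for g, r in roles.items() if r.startswith("signature")}
        nulls = {g for g, r in roles.items() if r == "null"}
        selected = set(sig.gene_names)
        assert len(selected & planted) / len(planted) >= 0.8
        assert len(selected & nulls) / max(len(selected), 1) <= 0.05


class TestStratification:
    def test_four_planted_groups(self, default_cohort, default_de):
        sig = tw.derive_typeB_signature(default_de, "typeB", seed=0)
        strat = tw.stratify_individuals(
            default_cohort.expression, sig, n_boot=50, seed=0,
            phenotypes=default_cohort.phenotypes,
        )
        assert strat.chosen_k == 4
        assert (strat.stability >= 0.75).all()

    def test_unstructured_data_chooses_k1(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(30, 200)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"I{i}" for i in range(200)],
        )
        sig = Signature(
            pd.DataFrame({"direction": ["up_in_heavy"] * 30},
                         index=pd.Index([f"g{i}" for i in range(30)], name="gene")),
            0.001, "B",
        )
        strat = tw.stratify_individuals(expr, sig, n_boot=0, seed=0)
        assert strat.chosen_k == 1
        assert strat.stability is None

    def test_determinism(self, default_cohort, default_de):
        sig = tw.derive_typeB_signature(default_de, "typeB", seed=0)
        a = tw.stratify_individuals(default_cohort.expression, sig, n_boot=0, seed=4)
        b = tw.stratify_individuals(default_cohort.expression, sig, n_boot=0, seed=4)
        pd.testing.assert_series_equal(a.clusters, b.clusters)

    def test_missing_genes_error(self, small_cohort):
        sig = Signature(
            pd.DataFrame({"direction": ["up_in_heavy"]},
                         index=pd.Index(["not_a_gene"], name="gene")),
            0.001, "B",
        )
        with pytest.raises(ConfigurationError, match="not_a_gene"):
            tw.stratify_individuals(small_cohort.expression, sig)


class TestUpvbRank:
    @staticmethod
    def _sig(up, down=()):
        genes = list(up) + list(down)
        return Signature(
            pd.DataFrame(
                {"direction": ["up_in_heavy"] * len(up) + ["down_in_heavy"] * len(down)},
                index=pd.Index(genes, name="gene"),
            ),
            0.001, "B",
        )

    def test_extremal_individual_scores_n(self):
        n = 10
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(4, n)),
            index=["u1", "u2", "d1", "d2"],
            columns=[f"I{i}" for i in range(n)],
        )
        expr.loc[["u1", "u2"], "I0"] = 99.0
        expr.loc[["d1", "d2"], "I0"] = -99.0
        score = tw.upvb_rank(expr, self._sig(["u1", "u2"], ["d1", "d2"]))
        assert score["I0"] == n

    def test_identical_individuals_equal_scores(self):
        expr = pd.DataFrame(
            {"I0": [1.0, 2.0], "I1": [1.0, 2.0], "I2": [5.0, 0.0]},
            index=["a", "b"],
        )
        score = tw.upvb_rank(expr, self._sig(["a", "b"]))
        assert score["I0"] == score["I1"]

    def test_monotone_transform_invariance(self, default_cohort, default_de):
        sig = tw.derive_typeB_signature(default_de, "typeB", seed=0)
        expr = default_cohort.expression
        r1 = tw.upvb_rank(expr, sig)
        r2 = tw.upvb_rank(np.exp(expr / 3.0) + 5.0, sig)
        pd.testing.assert_series_equal(r1, r2)

    def test_planted_auc(self, default_cohort, default_de):
        sig = tw.derive_typeB_signature(default_de, "typeB", seed=0)
        score = tw.upvb_rank(default_cohort.expression, sig)
        heavy = heavy_typeb_individuals(default_cohort)
        y = [1 if i in heavy else 0 for i in score.index]
        assert roc_auc_score(y, score.to_numpy()) >= 0.95

    def test_missing_gene_warns_all_missing_errors(self, small_cohort, caplog):
        present = small_cohort.expression.index[0]
        sig = self._sig([present, "ghost"])
        score = tw.upvb_rank(small_cohort.expression, sig)
        assert len(score) == small_cohort.expression.shape[1]
        with pytest.raises(ConfigurationError):
            tw.upvb_rank(small_cohort.expression, self._sig(["ghost"]))


class TestPCContribution:
    def test_contract_sums(self, small_cohort):
        genes = list(small_cohort.expression.index[:10])
        pc = tw.pc_signature_contribution(small_cohort.expression, genes)
        np.testing.assert_allclose(pc.contributions.sum(axis=0), 1.0, atol=1e-8)
        assert pc.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_single_latent_dimension(self):
        """Set genes ride one latent factor; selection finds exactly 1 PC.

        Variance share is computed analytically from the construction:
        PC1 variance ~ n_set * a^2 * var(z) + noise; everything else is
        i.i.d. noise of smaller variance.
        """
        rng = np.random.default_rng(2)
        n_ind, n_set, n_noise = 80, 20, 180
        a, s_noise = 2.0, 0.3
        z = rng.normal(0, 1, n_ind)
        Xset = a * z[None, :] + rng.normal(0, s_noise, size=(n_set, n_ind))
        Xnoise = rng.normal(0, s_noise, size=(n_noise, n_ind))
        expr = pd.DataFrame(
            np.vstack([Xset, Xnoise]),
            index=[f"s{i}" for i in range(n_set)] + [f"n{i}" for i in range(n_noise)],
            columns=[f"I{i}" for i in range(n_ind)],
        )
        pc = tw.pc_signature_contribution(expr, [f"s{i}" for i in range(n_set)])
        assert not pc.uninformative
        assert len(pc.selected_pcs) == 1
        expected = (n_set * a**2) / (n_set * a**2 + (n_set + n_noise) * s_noise**2)
        assert pc.cumulative_variance_fraction == pytest.approx(expected, abs=0.05)

    def test_all_genes_uninformative(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(0, 1, size=(40, 30)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"I{i}" for i in range(30)],
        )
        pc = tw.pc_signature_contribution(expr, list(expr.index))
        assert pc.uninformative

    def test_too_few_individuals(self):
        expr = pd.DataFrame(np.zeros((5, 2)), index=list("abcde"), columns=["x", "y"])
        with pytest.raises(Exception):
            tw.pc_signature_contribution(expr, ["a"])
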