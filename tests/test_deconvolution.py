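"""Deconvolution, purification, DE, M/I scores, GSEA."""

import numpy as np
import pandas as pd
import pytest

from sclc_taxonomy import deconvolve as dcv
from sclc_taxonomy import synthetic as syn
from sclc_taxonomy.matrix import ExpressionMatrix, ValidationError
from sclc_taxonomy.preprocess import counts_to_log_tpm, tpm_from_log


@pytest.fixture(scope="module")
def signature():
    rng = np.random.default_rng(0)
    genes = [f"m{i}" for i in range(24)]
    sig = pd.DataFrame(0.1 * rng.random((24, 4)), index=genes, columns=dcv.CELL_TYPES)
    for k, ct in enumerate(dcv.CELL_TYPES):
        sig.iloc[6 * k : 6 * (k + 1), k] += 10.0
    return sig


class TestFractions:
    def test_pure_reference_member(self, signature):
        bulk = signature["epithelial"].rename("s")
        fr = dcv.estimate_fractions(bulk, signature)
        assert fr["epithelial"] == pytest.approx(1.0, abs=1e-9)
        assert fr.drop("epithelial").abs().max() < 1e-9

    def test_constructed_mixture(self, signature):
        bulk = (0.6 * signature["epithelial"] + 0.4 * signature["immune"]).rename("s")
        fr = dcv.estimate_fractions(bulk, signature)
        assert fr["epithelial"] == pytest.approx(0.6, abs=1e-6)
        assert fr["immune"] == pytest.approx(0.4, abs=1e-6)

    def test_simplex_constraint(self, signature):
        rng = np.random.default_rng(1)
        bulk = pd.Series(rng.random(24), index=signature.index)
        fr = dcv.estimate_fractions(bulk, signature)
        assert fr.min() >= 0
        assert fr.sum() == pytest.approx(1.0)

    def test_all_zero_bulk_errors(self, signature):
        bulk = pd.Series(0.0, index=signature.index)
        with pytest.raises(ValidationError):
            dcv.estimate_fractions(bulk, signature)

    def test_cohort_fraction_recovery(self, default_cohort):
        """NNLS fractions on noisy bulk TPM: MAE < 0.08 at default noise."""
        truth = default_cohort["truth"]
        tpm = tpm_from_log(default_cohort["logtpm"])
        fr = dcv.fractions_table(tpm, truth.celltype_signature)
        mae = np.abs(fr.to_numpy() - truth.fractions.to_numpy()).mean()
        assert mae < 0.08


class TestGroupwise:
    def test_single_cell_type_returns_mean_bulk(self):
        rng = np.random.default_rng(2)
        vals = rng.random((15, 10)) + 1.0
        X = ExpressionMatrix(
            vals, [f"g{i}" for i in range(15)], [f"s{j}" for j in range(10)], "TPM"
        )
        fr = pd.DataFrame(
            {"epithelial": np.linspace(0.95, 1.0, 10), "fibroblast": 0.0,
             "endothelial": 0.0, "immune": 0.0},
            index=X.sample_ids,
        )
        fr = fr.div(fr.sum(axis=1), axis=0)
        with pytest.warns(UserWarning, match="constant fraction"):
            prof = dcv.groupwise_expression(X, fr)
        # epithelial column close to the f-weighted bulk level; others zero
        assert np.all(prof[["fibroblast", "endothelial", "immune"]].to_numpy() == 0)
        assert np.allclose(prof["epithelial"], vals.mean(axis=1), rtol=0.05)

    def test_outputs_nonnegative(self, default_cohort):
        truth = default_cohort["truth"]
        tpm = tpm_from_log(default_cohort["logtpm"])
        sub = tpm.subset_samples(tpm.sample_ids[:20])
        prof = dcv.groupwise_expression(sub, truth.fractions.iloc[:20])
        assert prof.to_numpy().min() >= 0

    def test_recovers_planted_epithelial_profile(self, default_cohort):
        """Group-mode NNLS on the noise-free bulk expectation recovers the
        planted epithelial profile at r > 0.95."""
        truth = default_cohort["truth"]
        labels = np.array(truth.subtype_labels)
        members = [s for s, l in zip(truth.fractions.index, labels) if l == "SCLC-A"]
        from sclc_taxonomy.matrix import ExpressionMatrix

        clean = ExpressionMatrix(
            truth.expected_bulk_tpm[members].to_numpy(),
            list(truth.expected_bulk_tpm.index), members, "TPM",
        )
        prof = dcv.groupwise_expression(clean, truth.fractions.loc[members])
        planted = truth.epithelial_linear[members].mean(axis=1)
        r = np.corrcoef(np.log1p(prof["epithelial"]), np.log1p(planted))[0, 1]
        assert r > 0.95

    def test_too_few_samples_rejected(self, default_cohort):
        truth = default_cohort["truth"]
        tpm = tpm_from_log(default_cohort["logtpm"])
        with pytest.raises(ValidationError):
            dcv.groupwise_expression(
                tpm.subset_samples(tpm.sample_ids[:5]), truth.fractions.iloc[:5]
            )


class TestEpithelialPerSample:
    def _setup(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(12)]
        P = pd.DataFrame(
            rng.random((12, 4)) + 0.5, index=genes, columns=dcv.CELL_TYPES
        )
        return genes, P

    def test_zero_residual_returns_group_profile(self):
        genes, P = self._setup()
        f = pd.DataFrame(
            [[0.5, 0.2, 0.2, 0.1]], index=["s0"], columns=dcv.CELL_TYPES
        )
        bulk_vals = (P.to_numpy() @ f.iloc[0].to_numpy())[:, None]
        bulk = ExpressionMatrix(bulk_vals, genes, ["s0"], "TPM")
        est, flags = dcv.epithelial_per_sample(
            bulk, f, {"grp": P}, pd.Series({"s0": "grp"})
        )
        assert np.allclose(est["s0"], P["epithelial"])
        assert not flags["s0"]

    def test_pure_epithelial_sample_returns_bulk(self):
        genes, P = self._setup()
        f = pd.DataFrame([[1.0, 0.0, 0.0, 0.0]], index=["s0"], columns=dcv.CELL_TYPES)
        bulk_vals = (P["epithelial"].to_numpy() * 1.3)[:, None]  # off-profile bulk
        bulk = ExpressionMatrix(bulk_vals, genes, ["s0"], "TPM")
        est, _ = dcv.epithelial_per_sample(bulk, f, {"grp": P}, pd.Series({"s0": "grp"}))
        # w = 1 and residual attribution is fully epithelial → ê = bulk
        assert np.allclose(est["s0"], bulk_vals[:, 0])

    def test_low_epithelial_fraction_flagged(self):
        genes, P = self._setup()
        f = pd.DataFrame([[0.03, 0.5, 0.3, 0.17]], index=["s0"], columns=dcv.CELL_TYPES)
        bulk_vals = (P.to_numpy() @ f.iloc[0].to_numpy())[:, None]
        bulk = ExpressionMatrix(bulk_vals, genes, ["s0"], "TPM")
        _, flags = dcv.epithelial_per_sample(bulk, f, {"grp": P}, pd.Series({"s0": "grp"}))
        assert flags["s0"]

    def test_recovers_planted_ne_gradient(self, default_cohort):
        """Per-sample purified epithelial NE-axis contrast tracks the planted
        NE position (Spearman ≥ 0.7)."""
        from scipy.stats import spearmanr

        truth = default_cohort["truth"]
        tpm = tpm_from_log(default_cohort["logtpm"])
        fr = dcv.fractions_table(tpm, truth.celltype_signature)
        labels = pd.Series(truth.subtype_labels, index=tpm.sample_ids)
        profiles = {"__pooled__": dcv.groupwise_expression(tpm, fr)}
        groups = {}
        for st in labels.unique():
            members = [s for s in tpm.sample_ids if labels[s] == st]
            if len(members) >= 8:
                profiles[st] = dcv.groupwise_expression(
                    tpm.subset_samples(members), fr.loc[members]
                )
            for s in members:
                groups[s] = st if st in profiles else "__pooled__"
        est, _ = dcv.epithelial_per_sample(tpm, fr, profiles, pd.Series(groups))
        log_est = np.log2(est + 1.0)
        nonne = sorted(truth.programs["NONNE"] | truth.programs["EMT"])
        ne = sorted(truth.programs["NE"])
        contrast = log_est.loc[nonne].mean() - log_est.loc[ne].mean()
        rho = spearmanr(contrast.to_numpy(), truth.ne_position).statistic
        assert rho >= 0.7


class TestDE:
    def _groups(self, seed=4, delta=0.0, n=10):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(20)]
        A = pd.DataFrame(rng.normal(5, 1, size=(20, n)), index=genes)
        B = pd.DataFrame(rng.normal(5, 1, size=(20, n)), index=genes)
        A.iloc[0] += delta
        return A, B

    def test_identical_groups_no_signal(self):
        A, _ = self._groups()
        de = dcv.epithelial_de(A, A.copy(), n_classifier=10)
        assert np.allclose(de.table["t"], 0.0, atol=1e-12)

    def test_planted_gene_ranks_first(self):
        A, B = self._groups(delta=5.0)
        de = dcv.epithelial_de(A, B, n_classifier=10)
        assert de.table.iloc[0]["gene"] == "g0"
        assert de.up_in_a[0] == "g0"

    def test_bh_matches_bruteforce_stepup(self):
        A, B = self._groups(seed=5, delta=2.0)
        de = dcv.epithelial_de(A, B, n_classifier=10)
        p = de.table["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert np.allclose(de.table["q"].to_numpy(), adj, atol=1e-12)

    def test_too_few_samples_rejected(self):
        A, B = self._groups()
        with pytest.raises(ValidationError):
            dcv.epithelial_de(A.iloc[:, :2], B)


class TestIntrinsicScores:
    def _expr(self):
        vals = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        return ExpressionMatrix(vals, ["m1", "m2", "i1", "i2"], ["sM", "sI"], "log2TPM")

    def test_diff_is_m_minus_i(self):
        scores = dcv.mi_intrinsic_scores(self._expr(), ["m1", "m2"], ["i1", "i2"])
        assert scores.loc["sM", "diff"] == pytest.approx(1.0)
        assert scores.loc["sI", "diff"] == pytest.approx(-1.0)
        assert np.allclose(scores["diff"], scores["M_score"] - scores["I_score"])

    def test_swap_negates(self):
        a = dcv.mi_intrinsic_scores(self._expr(), ["m1", "m2"], ["i1", "i2"])
        b = dcv.mi_intrinsic_scores(self._expr(), ["i1", "i2"], ["m1", "m2"])
        assert np.allclose(a["diff"].to_numpy(), -b["diff"].to_numpy())

    def test_missing_both_lists_errors(self):
        with pytest.raises(ValidationError):
            dcv.mi_intrinsic_scores(self._expr(), ["zz"], ["qq"])

    def test_mesenchymal_like_panel_positive_diff_and_anticorrelation(self):
        """Cell-line-like panel with opposed M/I programs: diff > 0 in ≥ 90%
        of mesenchymal-like lines and M vs I scores anti-correlated."""
        rng = np.random.default_rng(6)
        m_genes = [f"M{i}" for i in range(20)]
        i_genes = [f"I{i}" for i in range(20)]
        n = 30
        axis = rng.uniform(-1, 1, size=n)  # latent M-vs-I identity
        vals = np.vstack(
            [5 + 2 * axis + rng.normal(scale=0.5, size=n) for _ in m_genes]
            + [5 - 2 * axis + rng.normal(scale=0.5, size=n) for _ in i_genes]
        )
        X = ExpressionMatrix(
            np.maximum(vals, 0), m_genes + i_genes,
            [f"cl{i}" for i in range(n)], "log2TPM",
        )
        scores = dcv.mi_intrinsic_scores(X, m_genes, i_genes)
        mes = axis > 0.3
        assert (scores["diff"].to_numpy()[mes] > 0).mean() >= 0.9
        assert np.corrcoef(scores["M_score"], scores["I_score"])[0, 1] < 0


class TestGeneDiffCorrelation:
    def test_perfect_and_anti_correlation(self):
        diff = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        vals = np.vstack([diff.to_numpy(), 5.0 - diff.to_numpy(), [1, 1, 2, 2]])
        X = ExpressionMatrix(vals, ["up", "down", "other"], list("abcd"), "log2TPM")
        out = dcv.gene_diff_correlation(X, diff)
        assert out.loc["up", "r"] == pytest.approx(1.0)
        assert out.loc["down", "r"] == pytest.approx(-1.0)

    def test_matches_hand_computed_pair(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        X = ExpressionMatrix(y[None, :], ["g"], [f"s{i}" for i in range(5)], "log2TPM")
        out = dcv.gene_diff_correlation(X, pd.Series(x, index=X.sample_ids))
        r_hand = np.sum((x - 3) * (y - y.mean())) / np.sqrt(
            np.sum((x - 3) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert out.loc["g", "r"] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_gene_skipped(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        X = ExpressionMatrix(vals, ["flat", "var"], list("abcd"), "log2TPM")
        out = dcv.gene_diff_correlation(X, pd.Series([1, 2, 3, 4.0], index=list("abcd")))
        assert "flat" not in out.index


class TestCelltypeGSEA:
    def test_top_set_positive_and_significant(self):
        rng = np.random.default_rng(7)
        stats = pd.Series(
            np.sort(rng.normal(size=200))[::-1], index=[f"g{i}" for i in range(200)]
        )
        es, p = dcv.celltype_gsea(stats, {f"g{i}" for i in range(10)}, n_perm=500, seed=1)
        assert es > 0
        assert p < 0.05

    def test_null_p_uniform_ish(self):
        rng = np.random.default_rng(8)
        stats = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        ps = []
        for rep in range(200):
            genes = rng.choice(stats.index, size=10, replace=False)
            _, p = dcv.celltype_gsea(stats, set(genes), n_perm=99, seed=rep)
            ps.append(p)
        assert 0.4 <= float(np.mean(ps)) <= 0.6

    def test_es_matches_direct_running_sum(self):
        rng = np.random.default_rng(9)
        stats = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        gene_set = set(rng.choice(stats.index, size=7, replace=False))
        es, _ = dcv.celltype_gsea(stats, gene_set, n_perm=10, seed=0)
        srt = stats.sort_values(ascending=False)
        w = np.abs(srt.to_numpy())
        in_set = srt.index.isin(gene_set)
        hits = np.where(in_set, w, 0.0)
        run = np.cumsum(hits / hits.sum() - (~in_set) / (~in_set).sum())
        assert es == pytest.approx(run[np.argmax(np.abs(run))], abs=1e-12)
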