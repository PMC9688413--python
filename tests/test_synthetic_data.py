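"""Generator contracts: planted structure, determinism, noise regimes."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls
from scipy.stats import spearmanr

from sclc_taxonomy import synthetic as syn
from sclc_taxonomy.matrix import ValidationError
from sclc_taxonomy.signatures import ssgsea_score


class TestCohortConfig:
    def test_non_simplex_proportions_rejected(self):
        with pytest.raises(ValidationError, match="simplex"):
            syn.CohortConfig(subtype_proportions=(0.5, 0.2, 0.1, 0.1, 0.05, 0.5))

    def test_nonpositive_dirichlet_rejected(self):
        bad = dict(syn._DEFAULT_FRACTION_DIRICHLET)
        bad["SCLC-M"] = (1.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValidationError, match="Dirichlet"):
            syn.CohortConfig(fraction_dirichlet=bad)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValidationError):
            syn.CohortConfig(n_samples=0)


class TestGenerateCohort:
    def test_seed_determinism(self):
        a = syn.generate_cohort(syn.CohortConfig(seed=7))
        b = syn.generate_cohort(syn.CohortConfig(seed=7))
        assert np.array_equal(a[0].values, b[0].values)
        assert a[2].subtype_labels == b[2].subtype_labels
        pd.testing.assert_frame_equal(a[3], b[3])

    def test_poisson_limit_variance_equals_mean(self):
        # with dispersion → ∞ counts are Poisson: var ≈ mean per gene
        cfg = syn.CohortConfig(
            n_samples=200, noise_dispersion=np.inf, seed=3,
            subtype_proportions=(0, 0, 1.0, 0, 0, 0),  # one subtype → shared mean
            ne_jitter=0.0, activity_sd=0.0, n_background_modules=0,
            gene_noise_sd=0.0, depth_cv=0.0,
            fraction_dirichlet={k: tuple(1e6 * x for x in v)
                                for k, v in syn._DEFAULT_FRACTION_DIRICHLET.items()},
        )
        counts, _, truth, _ = syn.generate_cohort(cfg)
        v = counts.values
        mean = v.mean(axis=1)
        var = v.var(axis=1)
        keep = mean > 50
        ratio = var[keep] / mean[keep]
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)

    def test_fractions_on_simplex(self, default_cohort):
        fr = default_cohort["truth"].fractions.to_numpy()
        assert np.all(fr >= 0)
        assert np.allclose(fr.sum(axis=1), 1.0)

    def test_counts_nonnegative_integers(self, default_cohort):
        v = default_cohort["counts"].values
        assert v.min() >= 0
        assert np.allclose(v, np.round(v))

    def test_nnls_on_expected_bulk_recovers_fractions(self, default_cohort):
        """Oracle: NNLS of the noise-free bulk expectation on the true
        per-sample cell-type profiles recovers the planted fractions."""
        truth = default_cohort["truth"]
        errs = []
        stroma = truth.stroma_linear
        for j, s in enumerate(truth.fractions.index):
            design = np.column_stack(
                [truth.epithelial_linear[s].to_numpy()]
                + [stroma[ct].to_numpy() for ct in syn.CELL_TYPES[1:]]
            )
            bulk = truth.expected_bulk_tpm[s].to_numpy()
            coef, _ = nnls(design, bulk)
            coef = coef / coef.sum()
            errs.append(np.abs(coef - truth.fractions.loc[s].to_numpy()).mean())
        assert float(np.mean(errs)) < 0.05

    def test_immune_genes_elevated_in_inflamed_bulk(self, balanced_cohort):
        truth = balanced_cohort["truth"]
        X = balanced_cohort["logtpm"].to_frame()
        imm = sorted(truth.programs["IMMUNE"])
        labels = np.array(truth.subtype_labels)
        infl = X.loc[imm, labels == "SCLC-I"].mean().mean()
        rest = X.loc[imm, labels != "SCLC-I"].mean().mean()
        assert infl > rest + 0.5

    def test_survival_hazard_ordering(self):
        # mesenchymal/hypoxic tumors run shorter survival in expectation
        cfg = syn.CohortConfig(n_samples=600, seed=9, censor_high=2000.0, censor_low=1000.0)
        _, _, truth, clinical = syn.generate_cohort(cfg)
        labels = np.array(truth.subtype_labels)
        t = clinical["os_time"].to_numpy()
        worse = t[np.isin(labels, ["SCLC-M", "SCLC-H"])].mean()
        better = t[np.isin(labels, ["SCLC-A", "SCLC-I", "SCLC-N"])].mean()
        assert worse < better

    def test_program_effect_monotone_in_ssgsea_gap(self):
        """Raising program_effect widens the EMT ssGSEA gap between the
        mesenchymal subtype and the rest, on noise-free expectations."""
        gaps = []
        for eff in (1.0, 3.0):
            cfg = syn.CohortConfig(
                n_samples=36, n_genes=500, program_effect=eff, seed=21,
                subtype_proportions=(1 / 6,) * 6,
            )
            _, _, truth, _ = syn.generate_cohort(cfg)
            X = np.log2(truth.expected_bulk_tpm + 1.0)
            labels = np.array(truth.subtype_labels)
            emt = truth.programs["EMT"]
            scores = np.array([ssgsea_score(X[s], emt) for s in X.columns])
            gaps.append(scores[labels == "SCLC-M"].mean() - scores[labels != "SCLC-M"].mean())
        assert gaps[1] > gaps[0]


class TestTimeCourse:
    def test_config_validation(self):
        with pytest.raises(ValidationError, match="increasing"):
            syn.TimeCourseConfig(timepoints=(4, 4, 11))
        with pytest.raises(ValidationError, match="sum"):
            syn.TimeCourseConfig(n_cells=10, cells_per_timepoint=(5, 4))

    def test_empty_shared_genes_errors(self, default_cohort):
        with pytest.raises(ValidationError, match="non-empty"):
            syn.generate_mouse_timecourse(
                syn.TimeCourseConfig(), [], default_cohort["truth"].programs
            )

    def test_latent_time_tracks_day_labels(self, mouse_timecourse):
        tc = mouse_timecourse["tc"]
        rho = spearmanr(tc.latent_time, tc.day).statistic
        assert rho > 0.8

    def test_ne_program_decreases_nonne_increases(self, mouse_timecourse):
        tc = mouse_timecourse["tc"]
        truth = mouse_timecourse["truth"]
        dense = tc.umi.toarray().astype(float)
        depth = np.maximum(dense.sum(axis=0), 1)
        norm = np.log1p(1e4 * dense / depth)
        idx = {g: i for i, g in enumerate(tc.gene_ids)}
        ne_rows = [idx[g] for g in truth.programs["NE"] if g in idx]
        nne_rows = [idx[g] for g in truth.programs["NONNE"] if g in idx]
        rho_ne = spearmanr(tc.latent_time, norm[ne_rows].mean(axis=0)).statistic
        rho_nne = spearmanr(tc.latent_time, norm[nne_rows].mean(axis=0)).statistic
        assert rho_ne < -0.5
        assert rho_nne > 0.5

    def test_flat_gradient_equalises_programs(self, default_cohort):
        truth = default_cohort["truth"]
        shared = sorted(truth.programs["NE"] | truth.programs["NONNE"])
        cfg = syn.TimeCourseConfig(n_cells=400, gradient_sharpness=0.0, seed=6)
        tc = syn.generate_mouse_timecourse(cfg, shared, truth.programs)
        dense = tc.umi.toarray().astype(float)
        idx = {g: i for i, g in enumerate(tc.gene_ids)}
        ne_rows = [idx[g] for g in truth.programs["NE"]]
        early = tc.latent_time < 0.5
        ne_early = dense[np.ix_(ne_rows, np.flatnonzero(early))].mean()
        ne_late = dense[np.ix_(ne_rows, np.flatnonzero(~early))].mean()
        assert ne_early == pytest.approx(ne_late, rel=0.1)

    def test_mean_function_deterministic_in_latent_time(self, default_cohort):
        truth = default_cohort["truth"]
        shared = sorted(truth.programs["NE"] | truth.programs["NONNE"])
        m1 = syn.timecourse_mean_log2(shared, truth.programs, [0.37], 2.0)
        m2 = syn.timecourse_mean_log2(shared, truth.programs, [0.37], 2.0)
        assert np.array_equal(m1, m2)

    def test_seed_determinism(self, default_cohort):
        truth = default_cohort["truth"]
        shared = sorted(truth.programs["NE"] | truth.programs["NONNE"])
        cfg = syn.TimeCourseConfig(n_cells=100, seed=8)
        a = syn.generate_mouse_timecourse(cfg, shared, truth.programs)
        b = syn.generate_mouse_timecourse(cfg, shared, truth.programs)
        assert (a.umi != b.umi).nnz == 0
        assert np.array_equal(a.latent_time, b.latent_time)


class TestCrossSpeciesAlignability:
    def test_matched_ne_extremes_correlate_best(self, default_cohort):
        """Per-unit standardised profiles: a human sample near an NE-axis
        extreme correlates better with the mouse expectation at the matched
        extreme than with the opposite extreme (noise-free expectations)."""
        truth = default_cohort["truth"]
        shared = sorted(truth.programs["NE"] | truth.programs["NONNE"] | truth.programs["EMT"])
        human = np.log2(truth.epithelial_linear.loc[shared] + 1.0)
        ne_pos = truth.ne_position
        mouse = syn.timecourse_mean_log2(shared, truth.programs, [0.1, 0.9], 1.5)

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return float(a @ b / np.sqrt((a**2).sum() * (b**2).sum()))

        j_lo = int(np.argmin(np.abs(ne_pos - 0.1)))
        j_hi = int(np.argmin(np.abs(ne_pos - 0.9)))
        h_lo = human.iloc[:, j_lo].to_numpy()
        h_hi = human.iloc[:, j_hi].to_numpy()
        assert corr(h_lo, mouse[:, 0]) > corr(h_lo, mouse[:, 1])
        assert corr(h_hi, mouse[:, 1]) > corr(h_hi, mouse[:, 0])


class TestIHCGenerator:
    def test_empty(self):
        assert len(syn.generate_ihc_cohort(0, [], seed=1)) == 0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValidationError):
            syn.generate_ihc_cohort(2, ["SCLC-M"], seed=1)

    def test_unknown_label_errors(self):
        with pytest.raises(ValidationError, match="unknown"):
            syn.generate_ihc_cohort(1, ["NOPE"], seed=1)

    def test_inflamed_cd8_exceeds_mesenchymal(self):
        infl = syn.generate_ihc_cohort(50, ["SCLC-I"] * 50, seed=2)
        mes = syn.generate_ihc_cohort(50, ["SCLC-M"] * 50, seed=3)
        cd8_cols = [f"cd8_f{i}" for i in range(1, 6)]
        assert infl[cd8_cols].to_numpy().mean() > mes[cd8_cols].to_numpy().mean()

    def test_mesenchymal_mostly_vimentin_positive_others_not(self):
        mes = syn.generate_ihc_cohort(60, ["SCLC-M"] * 60, seed=4)
        oth = syn.generate_ihc_cohort(60, ["SCLC-A"] * 60, seed=5)
        assert (mes["vimentin_proportion"] > 0).mean() > 0.8
        assert (oth["vimentin_proportion"] > 0).mean() < 0.3

    def test_seed_determinism(self):
        labels = ["SCLC-M", "SCLC-I", "SCLC-A"] * 5
        a = syn.generate_ihc_cohort(15, labels, seed=9)
        b = syn.generate_ihc_cohort(15, labels, seed=9)
        pd.testing.assert_frame_equal(a, b)
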