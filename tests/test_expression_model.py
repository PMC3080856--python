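"""Normalization and moderated differential expression.

Includes two independent oracles: the ordinary one-sample t-test (the
moderated statistic with zero prior df) and R/limma's eBayes fit on the
same oriented M matrix.
"""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rdnakit import expression_model as em
from rdnakit import synthetic_data as sd


def _spot_frame(gene_ids, hyb, m, a):
    log_r = a + m / 2.0
    log_g = a - m / 2.0
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "hybridization_id": hyb,
            "intensity_red": 2.0**log_r,
            "intensity_green": 2.0**log_g,
            "pass_qc": True,
        }
    )


class TestLoessNormalize:
    def test_zero_m_stays_zero(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(300)]
        spots = _spot_frame(genes, "h1", np.zeros(300), rng.uniform(6, 14, 300))
        out = em.loess_normalize(spots)
        assert np.allclose(out.m["h1"].to_numpy(), 0.0, atol=1e-8)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(300)]
        spots = _spot_frame(
            genes, "h1", np.full(300, 0.5), rng.uniform(6, 14, 300)
        )
        out = em.loess_normalize(spots)
        assert np.allclose(out.m["h1"].to_numpy(), 0.0, atol=1e-6)

    def test_linear_trend_residuals_uncorrelated_with_a(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(500)]
        a = rng.uniform(6, 14, 500)
        spots = _spot_frame(genes, "h1", 0.2 * a, a)
        out = em.loess_normalize(spots)
        merged = pd.DataFrame({"m": out.m["h1"], "a": out.a["h1"]}).dropna()
        r = np.corrcoef(merged["m"], merged["a"])[0, 1]
        assert abs(r) < 0.05

    def test_median_m_near_zero_on_symmetric_data(self, spots):
        out = em.loess_normalize(spots)
        medians = out.m.median(axis=0)
        assert (medians.abs() < 0.01).all()

    def test_too_few_spots_rejected(self):
        spots = _spot_frame([f"g{i}" for i in range(5)], "h1",
                            np.zeros(5), np.full(5, 10.0))
        with pytest.raises(em.InsufficientDataError):
            em.loess_normalize(spots)

    def test_nonpositive_intensity_rejected(self):
        spots = _spot_frame([f"g{i}" for i in range(30)], "h1",
                            np.zeros(30), np.full(30, 10.0))
        spots.loc[0, "intensity_red"] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            em.loess_normalize(spots)

    @pytest.mark.parametrize("span", [0.0, 1.5])
    def test_invalid_span(self, span):
        spots = _spot_frame([f"g{i}" for i in range(30)], "h1",
                            np.zeros(30), np.full(30, 10.0))
        with pytest.raises(ValueError):
            em.loess_normalize(spots, span=span)

    def test_failed_qc_spots_become_nan(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(100)]
        spots = _spot_frame(genes, "h1", np.zeros(100), rng.uniform(6, 14, 100))
        spots.loc[spots["gene_id"] == "g7", "pass_qc"] = False
        out = em.loess_normalize(spots)
        assert np.isnan(out.m.at["g7", "h1"])


def _fits_from_rows(rows):
    """Build a fit table directly from per-gene oriented M tuples."""
    recs = []
    for gene, values in rows.items():
        v = np.asarray(values, dtype=float)
        recs.append(
            {
                "gene_id": gene,
                "log_fc": v.mean(),
                "s2": v.var(ddof=1) if len(v) > 1 else np.nan,
                "df": len(v) - 1,
                "n_obs": len(v),
                "tested": len(v) >= 2,
            }
        )
    return pd.DataFrame(recs).set_index("gene_id")


@pytest.fixture(scope="module")
def toy_matrix():
    genes = ["g0", "g1"]
    m = pd.DataFrame(
        {
            "gross_vs_wildtype_r0": [1.0, 0.8],
            "gross_vs_wildtype_r1": [1.0, 1.2],
            "gross_vs_wildtype_r2": [1.0, np.nan],
            "gross_vs_wildtype_r3": [1.0, np.nan],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    # dye-swapped arrays carry negated M values
    design = sd.dye_balanced_design(["gross"], n_reps=4)
    swapped = design[design["red_genotype"] == "wildtype"]["hybridization_id"]
    m[list(swapped)] = -m[list(swapped)]
    return em.NormalizedMatrix(m=m, a=m * 0 + 10.0), design


class TestFitContrast:

    def test_hand_arithmetic(self, toy_matrix):
        matrix, design = toy_matrix
        fits = em.fit_contrast(matrix, design, ("gross", "wildtype"))
        assert fits.at["g0", "log_fc"] == pytest.approx(1.0)
        assert fits.at["g0", "s2"] == pytest.approx(0.0)
        assert fits.at["g0", "df"] == 3
        assert fits.at["g1", "log_fc"] == pytest.approx(1.0)
        assert fits.at["g1", "s2"] == pytest.approx(0.08)
        assert fits.at["g1", "df"] == 1

    def test_min_obs_filter(self, toy_matrix):
        matrix, design = toy_matrix
        fits = em.fit_contrast(matrix, design, ("gross", "wildtype"), min_obs=3)
        assert not fits.at["g1", "tested"]
        assert np.isnan(fits.at["g1", "log_fc"])

    def test_missing_contrast_rejected(self, toy_matrix):
        matrix, design = toy_matrix
        with pytest.raises(ValueError):
            em.fit_contrast(matrix, design, ("mild1", "wildtype"))


class TestModerateAndTest:
    def test_forced_infinite_prior_closed_form(self):
        fits = _fits_from_rows({"g0": [0.4, 0.4, 0.4, 0.4]})
        res = em.moderate_and_test(fits, d0=np.inf, s0_sq=0.04)
        # t = 0.4 / sqrt(0.04 / 4) = 4.0
        assert res.at["g0", "t_mod"] == pytest.approx(4.0)

    def test_identical_variances_give_constant_posterior(self):
        rng = np.random.default_rng(4)
        rows = {}
        for i in range(50):
            v = rng.normal(0, 0.3, 5)
            v = (v - v.mean()) / v.std(ddof=1) * 0.3 + rng.normal()  # s2 = 0.09
            rows[f"g{i}"] = v
        res = em.moderate_and_test(_fits_from_rows(rows))
        post = res["s2_post"].to_numpy()
        assert np.allclose(post, post[0])
        # forcing the prior to the common variance reproduces it exactly
        forced = em.moderate_and_test(_fits_from_rows(rows), d0=np.inf, s0_sq=0.09)
        assert np.allclose(forced["s2_post"], 0.09)

    def test_zero_prior_df_equals_ordinary_t(self, gross_results, matrix, design):
        fits = em.fit_contrast(matrix, design, ("gross", "wildtype"))
        res = em.moderate_and_test(fits, d0=0.0, s0_sq=1.0)
        oriented = em.oriented_m(matrix, design, ("gross", "wildtype"))
        sub = res[res["tested"] & (res["s2"] > 0)].head(200)
        for gene in sub.index:
            vals = oriented.loc[gene].dropna().to_numpy()
            t_ref, p_ref = stats.ttest_1samp(vals, 0.0)
            assert res.at[gene, "t_mod"] == pytest.approx(t_ref, abs=1e-10)
            assert res.at[gene, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_posterior_between_data_and_prior(self, gross_results):
        res = gross_results
        s0 = res.attrs["s0_sq"]
        ok = res["tested"]
        lo = np.minimum(res.loc[ok, "s2"], s0)
        hi = np.maximum(res.loc[ok, "s2"], s0)
        assert (res.loc[ok, "s2_post"] >= lo - 1e-12).all()
        assert (res.loc[ok, "s2_post"] <= hi + 1e-12).all()

    def test_all_zero_variances_fall_back_with_warning(self):
        fits = _fits_from_rows({f"g{i}": [0.5, 0.5, 0.5] for i in range(20)})
        with pytest.warns(RuntimeWarning, match="zero"):
            res = em.moderate_and_test(fits)
        assert np.isfinite(res["t_mod"]).all()

    def test_too_few_genes_rejected(self):
        fits = _fits_from_rows({"g0": [0.1, 0.2, 0.3]})
        with pytest.raises(em.InsufficientDataError):
            em.moderate_and_test(fits)

    def test_null_type_i_calibration(self):
        # pure-noise fits: raw p < 0.05 near 5%
        rng = np.random.default_rng(5)
        rows = {f"g{i}": rng.normal(0, 0.3, 6) for i in range(4000)}
        res = em.moderate_and_test(_fits_from_rows(rows))
        rate = float((res["p"] < 0.05).mean())
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 4000)

    def test_limma_cross_check(self, tmp_path):
        """Independent oracle: R/limma eBayes on the same oriented matrix."""
        rng = np.random.default_rng(6)
        n_genes, n_arrays = 200, 6
        data = rng.normal(0, 0.3, size=(n_genes, n_arrays))
        data[:20] += 0.8  # some true effects
        genes = [f"g{i}" for i in range(n_genes)]
        mat = pd.DataFrame(
            data, index=pd.Index(genes, name="gene_id"),
            columns=[f"a{j}" for j in range(n_arrays)],
        )
        rows = {g: mat.loc[g].to_numpy() for g in genes}
        res = em.moderate_and_test(_fits_from_rows(rows))

        m_path = tmp_path / "m.tsv"
        out_path = tmp_path / "limma.tsv"
        mat.to_csv(m_path, sep="\t")
        script = f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{m_path}", row.names=1))
        fit <- eBayes(lmFit(m))
        out <- data.frame(gene_id=rownames(m), t=fit$t[,1], p=fit$p.value[,1],
                          d0=fit$df.prior, s0=fit$s2.prior)
        write.table(out, "{out_path}", sep="\t", row.names=FALSE, quote=FALSE)
        """
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out_path, sep="\t").set_index("gene_id")
        assert res.attrs["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-3)
        assert res.attrs["s0_sq"] == pytest.approx(ref["s0"].iloc[0], rel=1e-3)
        np.testing.assert_allclose(
            res.loc[genes, "t_mod"], ref.loc[genes, "t"], rtol=1e-4
        )
        np.testing.assert_allclose(
            res.loc[genes, "p"], ref.loc[genes, "p"], rtol=1e-3
        )


class TestAdjustBH:
    def test_worked_example(self):
        adj = em.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        assert np.allclose(em.adjust_bh(np.full(7, 0.2)), 0.2)

    def test_single_value_identity(self):
        assert em.adjust_bh(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_brute_force_step_up_oracle(self):
        def bh_oracle(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(7)
        for _ in range(5):
            p = rng.random(40)
            assert np.allclose(em.adjust_bh(p), bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            em.adjust_bh(np.array([0.5, 1.2]))

    def test_adjusted_at_least_raw(self, gross_results):
        ok = gross_results["tested"]
        assert (
            gross_results.loc[ok, "p_adj"] >= gross_results.loc[ok, "p"] - 1e-12
        ).all()


class TestPermutationFDR:
    def test_deterministic_under_seed(self, matrix, design):
        a = em.permutation_fdr(matrix, design, ("gross", "wildtype"),
                               p_cut=0.01, n_perm=10, seed=3)
        b = em.permutation_fdr(matrix, design, ("gross", "wildtype"),
                               p_cut=0.01, n_perm=10, seed=3)
        assert np.array_equal(a.permuted_counts, b.permuted_counts)

    def test_strong_signal_low_fdr(self, matrix, design):
        fdr = em.permutation_fdr(matrix, design, ("gross", "wildtype"),
                                 p_cut=0.001, n_perm=20, seed=4)
        assert not fdr.undefined
        assert fdr.fdr <= 0.05

    def test_zero_observed_flagged_not_error(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(50)]
        design = sd.dye_balanced_design(["gross"], n_reps=4)
        m = pd.DataFrame(
            rng.normal(0, 0.2, (50, 4)),
            index=pd.Index(genes, name="gene_id"),
            columns=design["hybridization_id"],
        )
        matrix = em.NormalizedMatrix(m=m, a=m * 0 + 10)
        fdr = em.permutation_fdr(matrix, design, ("gross", "wildtype"),
                                 p_cut=1e-12, n_perm=10, seed=5)
        assert fdr.undefined
        assert np.isnan(fdr.fdr)


class TestCallDE:
    def test_all_p_one_empty(self):
        fits = _fits_from_rows({f"g{i}": [0.0, 0.0, 1e-6] for i in range(20)})
        res = em.moderate_and_test(fits)
        res["p"] = 1.0
        res["p_adj"] = 1.0
        assert len(em.call_de(res, "x", 0.001, 0.05)) == 0

    def test_threshold_semantics_and_monotonicity(self, gross_results):
        strict = em.call_de(gross_results, "gross", 0.001, 0.05)
        loose = em.call_de(gross_results, "gross", 0.05, 0.05)
        assert strict.members <= loose.members
        for g in strict.members:
            assert gross_results.at[g, "p"] < 0.001
            assert gross_results.at[g, "p_adj"] < 0.05

    def test_direction_matches_sign(self, gross_results):
        de = em.call_de(gross_results, "gross", 0.01, 0.05)
        for g in de.members:
            assert de.direction[g] == np.sign(gross_results.at[g, "log_fc"])

    def test_invalid_threshold(self, gross_results):
        with pytest.raises(ValueError):
            em.call_de(gross_results, "x", 0.0)
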