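"""Moderated enrichment testing: OLS oracle, moderation, BH, calling."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from ricproteo.datatypes import SampleInfo, Thresholds, ValidationError
from ricproteo.diffexp import (
    EnrichmentModel,
    benjamini_hochberg,
    build_design,
    call_enrichment_classes,
    estimate_moderation,
    fit_linear_models,
    moderated_test,
    peptide_filter,
    tissue_contrasts,
    trigamma_inverse,
)

from conftest import make_quant, make_samples


def _two_group_samples():
    return make_samples(n_plus=2, n_minus=1)


# ------------------------------------------------------------------- OLS
def test_equal_group_values_give_exact_contrast():
    samples = _two_group_samples()
    m = pd.DataFrame([[5.0, 5.0, 2.0]], columns=[s.sample_id for s in samples])
    fit = fit_linear_models(m, samples)
    np.testing.assert_allclose(fit.beta, [3.0], atol=1e-12)
    np.testing.assert_allclose(fit.s_sq[fit.df_resid >= 1], 0.0, atol=1e-12)


def test_constant_replicate_reduces_to_two_sample():
    samples = [
        SampleInfo("a", "t", "eric", "plusUV", 1, "b"),
        SampleInfo("b", "t", "eric", "plusUV", 1, "b"),
        SampleInfo("c", "t", "eric", "minusUV", 1, "b"),
        SampleInfo("d", "t", "eric", "minusUV", 1, "b"),
    ]
    design = build_design(samples)
    assert not any(c.startswith("rep_") for c in design.columns)
    m = pd.DataFrame([[4.0, 6.0, 1.0, 3.0]], columns=list("abcd"))
    fit = fit_linear_models(m, samples)
    np.testing.assert_allclose(fit.beta, [3.0])  # mean(4,6) - mean(1,3)
    assert fit.df_resid[0] == 2


@pytest.mark.parametrize("seed", range(5))
def test_coefficients_match_normal_equations_oracle(seed):
    """Random multi-tissue designs with missing cells: contrast estimates
    match a brute-force per-protein normal-equations solve to 1e-10."""
    rng = np.random.default_rng(seed)
    samples = []
    for t in ("brain", "kidney"):
        samples += make_samples(tissue=t)
    ids = [s.sample_id for s in samples]
    G = 60
    Y = rng.normal(10, 2, (G, len(ids)))
    Y[rng.random((G, len(ids))) < 0.15] = np.nan
    m = pd.DataFrame(Y, columns=ids)
    design = build_design(samples)
    contrasts = tissue_contrasts(design, samples)
    X = design.to_numpy()
    for tissue, c in contrasts.items():
        fit = fit_linear_models(m, samples, design, contrast=c)
        for g in range(G):
            obs = ~np.isnan(Y[g])
            Xs, ys = X[obs], Y[g][obs]
            # greedy rank-increasing column selection, as documented
            keep = []
            for j in range(X.shape[1]):
                if np.any(Xs[:, j] != 0) and np.linalg.matrix_rank(
                    Xs[:, keep + [j]]
                ) > len(keep):
                    keep.append(j)
            Xk = Xs[:, keep]
            if not set(np.where(c != 0)[0]) <= set(keep) or len(ys) < len(keep):
                assert not fit.testable[g]
                continue
            beta = np.linalg.solve(Xk.T @ Xk, Xk.T @ ys)
            expected = c[keep] @ beta
            assert fit.testable[g]
            np.testing.assert_allclose(fit.beta[g], expected, atol=1e-10)
            v = c[keep] @ np.linalg.inv(Xk.T @ Xk) @ c[keep]
            np.testing.assert_allclose(fit.v_contrast[g], v, atol=1e-10)


def test_protein_with_missing_condition_is_untestable():
    samples = _two_group_samples()
    m = pd.DataFrame(
        [[5.0, 5.5, np.nan], [np.nan, np.nan, 2.0]],
        columns=[s.sample_id for s in samples],
    )
    fit = fit_linear_models(m, samples)
    assert not fit.testable.any()


# -------------------------------------------------------------- moderation
def test_trigamma_inverse_roundtrip():
    ys = np.concatenate([np.logspace(-5, 6, 40), [polygamma(1, 2.0)]])
    for y in ys:
        x = trigamma_inverse(float(y))
        assert abs(float(polygamma(1, x)) - y) <= 1e-8 * y


def test_equal_variances_give_infinite_prior_df():
    mod = estimate_moderation(np.full(50, 0.7), np.full(50, 3))
    assert math.isinf(mod.d0)
    np.testing.assert_allclose(mod.s0_sq, 0.7, rtol=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_moderation_parameter_recovery(seed):
    """Variances drawn from the scaled inverse-chi-square model with d0=4,
    s0^2=1 are recovered inside the stated intervals."""
    rng = np.random.default_rng(1000 + seed)
    G, d0, s0, dg = 5000, 4.0, 1.0, 3
    true_var = s0 / (rng.chisquare(d0, G) / d0)
    s2 = true_var * rng.chisquare(dg, G) / dg
    mod = estimate_moderation(s2, np.full(G, dg))
    assert 3.0 <= mod.d0 <= 5.3
    assert 0.9 <= mod.s0_sq <= 1.1


def test_all_zero_variances_fallback():
    mod = estimate_moderation(np.zeros(20), np.full(20, 2))
    assert math.isinf(mod.d0)
    assert mod.warning is not None


# ----------------------------------------------------------- moderated t
def _random_fit(seed=0, G=200):
    rng = np.random.default_rng(seed)
    samples = _two_group_samples()
    Y = rng.normal(10, 1, (G, 3))
    m = pd.DataFrame(Y, columns=[s.sample_id for s in samples])
    return m, samples, fit_linear_models(m, samples)


def test_d0_zero_equals_ordinary_t():
    m, samples, fit = _random_fit(3)
    tab = moderated_test(fit, (0.0, 1.0))
    t_ord = fit.beta / np.sqrt(fit.s_sq * fit.v_contrast)
    p_ord = 2 * stats.t.sf(np.abs(t_ord), fit.df_resid)
    ok = np.isfinite(tab["t_mod"])
    np.testing.assert_allclose(tab["t_mod"][ok], t_ord[ok], atol=1e-12)
    np.testing.assert_allclose(tab["p_value"][ok], p_ord[ok], atol=1e-12)


def test_d0_infinite_uses_prior_variance_and_normal_reference():
    _, _, fit = _random_fit(4)
    s0 = 0.8
    tab = moderated_test(fit, (math.inf, s0))
    expected_t = fit.beta / np.sqrt(s0 * fit.v_contrast)
    np.testing.assert_allclose(tab["t_mod"], expected_t, atol=1e-12)
    np.testing.assert_allclose(
        tab["p_value"], 2 * stats.norm.sf(np.abs(expected_t)), atol=1e-12
    )


def test_null_type_i_calibration():
    """Null 2-vs-1 design, heteroscedastic variances: fraction of p < 0.05
    across replicates lies in [0.035, 0.065]."""
    samples = _two_group_samples()
    ids = [s.sample_id for s in samples]
    rng = np.random.default_rng(0)
    rates = []
    for _ in range(200):
        G = 2000
        sd = np.exp(rng.normal(0, 0.4, G))
        m = pd.DataFrame(rng.normal(0, sd[:, None], (G, 3)), columns=ids)
        fit = fit_linear_models(m, samples)
        mod = estimate_moderation(fit.s_sq, fit.df_resid)
        tab = moderated_test(fit, mod)
        rates.append(float((tab["p_value"] < 0.05).mean()))
    assert 0.035 <= np.mean(rates) <= 0.065


def test_moderation_shrinks_t_spread():
    """On heavy-tailed variances the moderated t has smaller spread than the
    ordinary t."""
    samples = _two_group_samples()
    rng = np.random.default_rng(6)
    G = 3000
    sd = np.exp(rng.normal(0, 1.0, G))
    m = pd.DataFrame(rng.normal(0, sd[:, None], (G, 3)),
                     columns=[s.sample_id for s in samples])
    fit = fit_linear_models(m, samples)
    mod = estimate_moderation(fit.s_sq, fit.df_resid)
    tab = moderated_test(fit, mod)
    t_ord = fit.beta / np.sqrt(fit.s_sq * fit.v_contrast)
    ok = np.isfinite(t_ord) & np.isfinite(tab["t_mod"])
    assert tab["t_mod"][ok].var() <= np.var(t_ord[ok])


def test_agrees_with_limma_oracle(tmp_path):
    """Full dual-route check: t, p, log2fc and the (d0, s0^2) prior match
    the reference empirical-Bayes implementation run through Rscript."""
    rng = np.random.default_rng(7)
    samples = _two_group_samples()
    G = 300
    Y = rng.normal(10, 1, (G, 3))
    Y[:50, :2] += 2.0
    m = pd.DataFrame(Y, index=[f"P{i}" for i in range(G)],
                     columns=[s.sample_id for s in samples])
    design = build_design(samples)
    c = tissue_contrasts(design, samples)["liver"]
    fit = fit_linear_models(m, samples, design, contrast=c)
    mod = estimate_moderation(fit.s_sq, fit.df_resid)
    tab = moderated_test(fit, mod)

    m.to_csv(tmp_path / "mat.tsv", sep="\t")
    script = tmp_path / "cmp.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        f'm <- as.matrix(read.delim("{tmp_path}/mat.tsv", row.names=1))\n'
        'design <- cbind(plusUV=c(1,1,0), minusUV=c(0,0,1))\n'
        'fit <- eBayes(contrasts.fit(lmFit(m, design), c(1,-1)))\n'
        'out <- data.frame(t=fit$t[,1], p=fit$p.value[,1], lfc=fit$coefficients[,1],\n'
        '                  d0=fit$df.prior, s02=fit$s2.prior)\n'
        f'write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)\n'
    )
    res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
    assert res.returncode == 0, res.stderr
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
    np.testing.assert_allclose(mod.d0, ref["d0"].iloc[0], rtol=1e-10)
    np.testing.assert_allclose(mod.s0_sq, ref["s02"].iloc[0], rtol=1e-10)
    np.testing.assert_allclose(tab["t_mod"], ref["t"], atol=1e-10)
    np.testing.assert_allclose(tab["p_value"], ref["p"], atol=1e-10)
    np.testing.assert_allclose(tab["log2fc"], ref["lfc"], atol=1e-10)


# ---------------------------------------------------------------------- BH
def test_bh_hand_computed_example():
    np.testing.assert_allclose(
        benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
    )


def test_bh_single_p_unchanged():
    np.testing.assert_allclose(benjamini_hochberg(np.array([0.37])), [0.37])


def test_bh_matches_reference_on_random_vectors():
    rng = np.random.default_rng(12)
    for _ in range(1000):
        n = rng.integers(1, 60)
        p = rng.random(n) ** rng.uniform(0.5, 3)
        mine = benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(mine, ref, atol=1e-12)


def test_bh_handles_missing():
    p = np.array([0.01, np.nan, 0.04])
    out = benjamini_hochberg(p)
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], multipletests([0.01, 0.04], method="fdr_bh")[1])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        benjamini_hochberg(np.array([0.5, 1.5]))


# ------------------------------------------------------------------ calling
@pytest.mark.parametrize(
    "fdr,log2fc,expected",
    [
        (0.01, 1.5, "hit"),              # clears both hit thresholds
        (0.10, 0.8, "candidate"),        # FDR < 0.2, FC > 1.5
        (0.01, -2.0, "no_hit"),          # depletion is not enrichment
        (0.01, 1.0, "hit"),              # boundary: log2fc >= 1 counts
        (0.06, 3.0, "candidate"),        # misses hit FDR, strong FC
        (0.5, 3.0, "no_hit"),
        (0.01, 0.3, "no_hit"),
    ],
)
def test_enrichment_class_rules(fdr, log2fc, expected):
    tab = pd.DataFrame({"log2fc": [log2fc], "fdr": [fdr], "p_value": [fdr / 2]})
    out = call_enrichment_classes(tab, Thresholds())
    assert out["enrich_class"].iloc[0] == expected


def test_undetected_proteins_marked_not_detected():
    tab = pd.DataFrame(
        {"log2fc": [2.0, np.nan], "fdr": [0.001, np.nan], "p_value": [0.0001, np.nan]},
        index=["A", "B"],
    )
    out = call_enrichment_classes(tab, detected=pd.Series({"A": True, "B": False}))
    assert list(out["enrich_class"]) == ["hit", "not_detected"]


def test_peptide_filter():
    samples = make_samples()
    q = make_quant(np.ones((3, 3)), samples, peptides=[1, 2, 3])
    kept = peptide_filter(q, 2)
    assert list(kept.proteins) == ["P001", "P002"]
    assert peptide_filter(q, 1).n_proteins == 3
    q2 = make_quant(np.ones((3, 3)), samples, peptides=[5, 2, 3])
    assert peptide_filter(q2, 2).n_proteins == 3


def test_model_excludes_low_peptide_proteins_from_testing(sim_experiment):
    _, q, _ = sim_experiment
    eric = q.subset_samples([s.sample_id for s in q.samples if s.assay == "eric"])
    res = EnrichmentModel.from_quant(eric).fit()
    low = q.unique_peptides < 2
    for tab in res.tables.values():
        assert tab.loc[low, "p_value"].isna().all()


def test_results_summary_mentions_counts(fitted_eric):
    _, _, res = fitted_eric
    text = res.summary()
    assert "prior df" in text and "hit" in text
    counts = res.class_counts()
    assert set(counts.columns) == {"brain", "kidney", "liver"}
    assert (counts.sum(axis=0) == len(next(iter(res.tables.values())))).all()
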