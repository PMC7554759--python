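import numpy as np
import pandas as pd
import pytest

from l1burden.association import (
    bonferroni,
    burden_trend,
    fit_logistic,
    make_design,
    per_locus_association,
    threshold_association,
    two_by_two_or,
)
from l1burden.burden import categorize, compute_burden, sweep_thresholds
from l1burden.synth import SimulationConfig, default_ha_set, generate_cohort, make_synthetic_study_catalog
from tests.conftest import make_phenotypes


def two_group_data(n0, k0, n1, k1):
    """n0 unexposed with k0 cases; n1 exposed with k1 cases."""
    y = [1] * k0 + [0] * (n0 - k0) + [1] * k1 + [0] * (n1 - k1)
    x = [0.0] * n0 + [1.0] * n1
    idx = pd.Index(range(len(y)))
    return pd.Series(y, index=idx, dtype=float), pd.DataFrame({"exposed": x}, index=idx)


def test_no_effect_symmetry():
    y, X = two_group_data(40, 10, 60, 15)  # identical 25% outcome proportions
    fit = fit_logistic(y, X)
    or_, lo, hi = fit.odds_ratio("exposed")
    assert or_ == pytest.approx(1.0, abs=1e-8)
    assert fit.params["exposed"] == pytest.approx(0.0, abs=1e-8)
    assert lo < 1.0 < hi


def test_logistic_matches_2x2_closed_form():
    """With intercept + one binary exposure the MLE is the cross-product OR."""
    n_hc_b, n_hc_a, n_pd_b, n_pd_a = 94, 77, 148, 198
    y, X = two_group_data(n_hc_b + n_pd_b, n_pd_b, n_hc_a + n_pd_a, n_pd_a)
    fit = fit_logistic(y, X)
    or_hat, se_closed = two_by_two_or(n_hc_b, n_hc_a, n_pd_b, n_pd_a)
    assert fit.odds_ratio("exposed")[0] == pytest.approx(or_hat, abs=1e-6)
    assert fit.bse["exposed"] == pytest.approx(se_closed, rel=1e-6)


def test_logistic_matches_grid_search_oracle():
    """MLE on an 8-point toy agrees with a brute-force likelihood maximizer."""
    y = np.array([0, 0, 1, 0, 1, 1, 0, 1], dtype=float)
    x = np.array([-1.2, -0.8, -0.5, 0.1, 0.4, 0.9, 1.3, 2.0])
    b0g, b1g = np.meshgrid(np.arange(-3, 3, 0.005), np.arange(-3, 3, 0.005), indexing="ij")
    eta = b0g[..., None] + b1g[..., None] * x
    loglik = np.sum(y * eta - np.log1p(np.exp(eta)), axis=-1)
    i, j = np.unravel_index(np.argmax(loglik), loglik.shape)
    fit = fit_logistic(pd.Series(y), pd.DataFrame({"x": x}))
    assert fit.params["const"] == pytest.approx(b0g[i, j], abs=1e-2)
    assert fit.params["x"] == pytest.approx(b1g[i, j], abs=1e-2)
    # the analytic optimum beats every grid point
    eta_hat = fit.params["const"] + fit.params["x"] * x
    assert np.sum(y * eta_hat - np.log1p(np.exp(eta_hat))) >= loglik[i, j] - 1e-10


def test_label_swap_inverts_odds_ratios():
    y, X = two_group_data(100, 30, 110, 55)
    fit = fit_logistic(y, X)
    flipped = fit_logistic(1.0 - y, X)
    assert flipped.odds_ratio("exposed")[0] == pytest.approx(1.0 / fit.odds_ratio("exposed")[0])
    assert flipped.pvalues["exposed"] == pytest.approx(fit.pvalues["exposed"], rel=1e-6)


def test_single_class_outcome_and_rank_deficiency_raise():
    y, X = two_group_data(20, 0, 20, 0)
    with pytest.raises(ValueError, match="single class"):
        fit_logistic(y, X)
    y2, X2 = two_group_data(20, 5, 20, 10)
    X2["exposed_copy"] = X2["exposed"]
    with pytest.raises(ValueError, match="rank deficient"):
        fit_logistic(y2, X2)


def test_separation_is_flagged():
    y = pd.Series([0.0] * 10 + [1.0] * 10)
    X = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
    fit = fit_logistic(y, X)
    assert fit.separation


def test_bonferroni_arithmetic():
    assert bonferroni([0.0005], m=72)[0] == pytest.approx(0.036)
    assert bonferroni([0.02], m=72)[0] == 1.0  # capped
    p = np.array([0.01, 0.2, 0.5])
    assert np.allclose(bonferroni(p, m=1), p)  # idempotent for m = 1


def test_make_design_codings():
    pheno = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c", "d"],
            "status": ["PD", "HC", "PD", "HC"],
            "sex": ["male", "female", "male", "female"],
            "age": [60.0, 55.0, 70.0, 65.0],
            "family_history": ["first_degree", "other", "none", "unknown"],
        }
    )
    d = make_design(pheno)
    assert list(d.columns) == ["sex_male", "age", "fh_first_degree", "fh_other"]
    assert list(d["sex_male"]) == [1.0, 0.0, 1.0, 0.0]
    assert d.loc["a", "fh_first_degree"] == 1.0 and d.loc["b", "fh_other"] == 1.0
    assert d.loc["d"].isna().any()  # unknown family history propagates as NaN
    b = make_design(pheno, famhist_coding="binary")
    assert list(b.columns) == ["sex_male", "age", "fh_any"]
    assert list(b["fh_any"].fillna(-1)) == [1.0, 1.0, 0.0, -1.0]


def test_per_locus_null_simulation_not_significant():
    """Genotypes independent of status leave no locus Bonferroni-significant."""
    cat, poly = make_synthetic_study_catalog()
    cfg = SimulationConfig(n_samples=2000, log_or=0.0)
    matrix, pheno = generate_cohort(cat, cfg, seed=202)
    table = per_locus_association(matrix, pheno, locus_ids=poly)
    assert len(table) == 72
    assert (table["p_bonferroni"].dropna() > 0.05).all()
    assert np.allclose(table["p_bonferroni"], np.minimum(1.0, 72 * table["p"]), equal_nan=True)


def test_burden_trend_linear_saturated_case():
    """With burden identical to the case indicator, OLS recovers the mean gap."""
    pheno = make_phenotypes(30, 30, seed=1)
    burden = pd.DataFrame(
        {
            "sample_id": pheno["sample_id"],
            "burden": (pheno["status"] == "PD").astype(float) * 3.0 + 2.0,
            "n_loci_used": 16,
            "complete": True,
        }
    )
    fit = burden_trend(burden, pheno, model="linear")
    assert fit.model == "linear"
    assert fit.beta == pytest.approx(3.0, abs=1e-8)


def test_burden_trend_logistic_recovers_per_allele_effect():
    """A per-allele log-OR of 0.2 is recovered at n = 5000."""
    rng = np.random.default_rng(77)
    n = 5000
    burden_vals = rng.binomial(16, 0.3, n).astype(float)
    logit = -1.0 + 0.2 * (burden_vals - burden_vals.mean())
    status = np.where(rng.random(n) < 1 / (1 + np.exp(-logit)), "PD", "HC")
    pheno = make_phenotypes(0, n, seed=2)
    pheno["status"] = status
    burden = pd.DataFrame({"sample_id": pheno["sample_id"], "burden": burden_vals,
                           "n_loci_used": 16, "complete": True})
    fit = burden_trend(burden, pheno, model="logistic")
    assert fit.beta == pytest.approx(0.2, abs=0.05)


def test_burden_trend_constant_burden_errors():
    pheno = make_phenotypes(10, 10)
    burden = pd.DataFrame({"sample_id": pheno["sample_id"], "burden": 4.0,
                           "n_loci_used": 16, "complete": True})
    with pytest.raises(ValueError, match="constant"):
        burden_trend(burden, pheno)


def test_threshold_association_single_grouping():
    pheno = make_phenotypes(60, 80, seed=3)
    rng = np.random.default_rng(5)
    burden = pd.DataFrame({"sample_id": pheno["sample_id"],
                           "burden": rng.binomial(16, 0.3, 140).astype(float),
                           "n_loci_used": 16, "complete": True})
    g = categorize(burden, pheno, 5)
    table = threshold_association([g], pheno)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["ci_low"] <= row["or"] <= row["ci_high"]
    assert 0.0 <= row["p"] <= 1.0
    assert row[["n_HC_below", "n_HC_at_or_above", "n_PD_below", "n_PD_at_or_above"]].sum() == 140


def test_threshold_association_has_no_sweepwise_correction():
    """The output schema carries raw per-threshold p values only."""
    pheno = make_phenotypes(100, 100, seed=9)
    rng = np.random.default_rng(9)
    burden = pd.DataFrame({"sample_id": pheno["sample_id"],
                           "burden": rng.binomial(16, 0.35, 200).astype(float),
                           "n_loci_used": 16, "complete": True})
    sweep = sweep_thresholds(burden, pheno)
    table = threshold_association(sweep, pheno)
    assert "p" in table.columns
    assert not any(c.startswith("p_") for c in table.columns)
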