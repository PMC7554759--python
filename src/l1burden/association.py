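"""Covariate-adjusted case-control association.

Three views of the same question — does carrying more (highly active)
RC-L1 elements increase Parkinson's disease risk? —

* per-locus additive logistic regression (presence-allele count 0/1/2 as
  exposure) with Bonferroni correction over the loci tested;
* a trend model entering the burden as a continuous term (logistic of
  status on burden, or linear of burden on status — the direction is
  configurable because both are in common use);
* per-threshold logistic fits of status on the at-or-above indicator for
  every admissible grouping of a sweep, yielding a forest-plot-ready table
  of odds ratios.  No multiplicity correction is applied across sweep
  thresholds.

All models adjust for sex, age (years, untransformed) and family history
of disease (two dummies, first-degree and other relative, against a
no-family-history reference; a binary any-vs-none coding is available).
Logistic fits are maximum likelihood via iteratively reweighted least
squares with Wald z inference; quasi-separation is flagged, not silently
accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .burden import ThresholdGrouping
from .genotypes import GenotypeMatrix

__all__ = [
    "LogisticFit",
    "TrendFit",
    "make_design",
    "fit_logistic",
    "per_locus_association",
    "burden_trend",
    "threshold_association",
    "bonferroni",
    "plot_forest",
]

logger = logging.getLogger(__name__)

#: |beta| beyond which a logistic coefficient is treated as quasi-separated.
SEPARATION_BETA = 15.0
Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class LogisticFit:
    """Wald summary of one logistic regression."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float
    converged: bool
    separation: bool
    n: int

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        """(OR, CI low, CI high) for one term, CI = exp(beta +/- 1.96 SE)."""
        b, se = self.params[term], self.bse[term]
        return float(np.exp(b)), float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se))


@dataclass
class TrendFit:
    """Burden-trend model summary; beta is per one presence allele."""

    model: str  # "logistic" (status ~ burden + cov) or "linear" (burden ~ status + cov)
    beta: float
    se: float
    p: float
    params: pd.Series
    n: int


def make_design(
    phenotypes: pd.DataFrame,
    famhist_coding: str = "dummy",
    covariates: Sequence[str] = ("sex", "age", "family_history"),
) -> pd.DataFrame:
    """Numeric covariate design (no intercept) from a phenotype table.

    sex: male=1/female=0; age in years untransformed; family history as two
    dummies (``fh_first_degree``, ``fh_other``; reference = none) or, with
    ``famhist_coding="binary"``, one any-vs-none dummy.  Samples with
    unknown family history get NaN and are dropped by the fitters.
    """
    pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes.columns else phenotypes
    cols: dict[str, pd.Series] = {}
    if "sex" in covariates:
        cols["sex_male"] = (pheno["sex"] == "male").astype(float)
    if "age" in covariates:
        cols["age"] = pheno["age"].astype(float)
    if "family_history" in covariates:
        fh = pheno["family_history"]
        known = fh != "unknown"
        if famhist_coding == "dummy":
            cols["fh_first_degree"] = (fh == "first_degree").astype(float).where(known)
            cols["fh_other"] = (fh == "other").astype(float).where(known)
        elif famhist_coding == "binary":
            cols["fh_any"] = fh.isin(["first_degree", "other"]).astype(float).where(known)
        else:
            raise ValueError(f"unknown famhist_coding {famhist_coding!r}")
    return pd.DataFrame(cols, index=pheno.index)


def fit_logistic(outcome: pd.Series | np.ndarray, design: pd.DataFrame) -> LogisticFit:
    """Logistic regression of a binary outcome on a covariate design.

    An intercept column is added automatically.  Rows with any NaN in the
    outcome or design are dropped.  Raises on a single-class outcome or a
    rank-deficient design; non-convergence and quasi-separation (any
    |beta| > 15) are flagged on the result.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), index=design.index, name="outcome")
    frame = pd.concat([y, design], axis=1).dropna()
    y = frame["outcome"]
    X = sm.add_constant(frame.drop(columns="outcome"), has_constant="add")
    if y.nunique() < 2:
        raise ValueError("outcome has a single class")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"design is rank deficient (rank {rank} < {X.shape[1]} columns)")
    model = sm.Logit(y, X)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=100, method="newton")
        converged = bool(res.mle_retvals.get("converged", True))
    except (np.linalg.LinAlgError, PerfectSeparationError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200, method="bfgs")
        converged = False
    separation = bool(np.any(np.abs(res.params.drop(labels=["const"], errors="ignore")) > SEPARATION_BETA))
    if separation:
        logger.warning("possible quasi-separation: max |beta| = %.2f", float(np.abs(res.params).max()))
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        zvalues=res.tvalues,
        pvalues=res.pvalues,
        llf=float(res.llf),
        converged=converged,
        separation=separation,
        n=int(len(y)),
    )


def bonferroni(pvalues: np.ndarray | pd.Series, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p), m defaulting to len(p)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def per_locus_association(
    matrix: GenotypeMatrix | pd.DataFrame,
    phenotypes: pd.DataFrame,
    locus_ids: Sequence[str] | None = None,
    famhist_coding: str = "dummy",
) -> pd.DataFrame:
    """Additive per-locus logistic association with Bonferroni correction.

    Each locus's presence-allele count (0/1/2) is the exposure in a
    logistic model of case status adjusted for sex, age and family
    history; available-case per locus.  Adjusted p values use m = number of
    loci tested.
    """
    data = matrix.data if isinstance(matrix, GenotypeMatrix) else matrix
    loci = list(locus_ids) if locus_ids is not None else list(data.columns)
    if not loci:
        raise ValueError("no loci to test")
    pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes.columns else phenotypes
    common = data.index.intersection(pheno.index)
    base = make_design(pheno.loc[common], famhist_coding=famhist_coding)
    y = (pheno.loc[common, "status"] == "PD").astype(float)
    rows = []
    for lid in loci:
        design = base.copy()
        design.insert(0, "presence", data.loc[common, lid].astype(float))
        try:
            fit = fit_logistic(y, design)
            beta, se, p = float(fit.params["presence"]), float(fit.bse["presence"]), float(fit.pvalues["presence"])
            rows.append({"locus_id": lid, "beta": beta, "se": se, "or": float(np.exp(beta)),
                         "p": p, "n": fit.n, "separation": fit.separation})
        except ValueError as exc:
            logger.warning("locus %s skipped: %s", lid, exc)
            rows.append({"locus_id": lid, "beta": np.nan, "se": np.nan, "or": np.nan,
                         "p": np.nan, "n": 0, "separation": False})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p"].to_numpy(), m=len(loci))
    return out


def burden_trend(
    burden: pd.DataFrame,
    phenotypes: pd.DataFrame,
    model: str = "logistic",
    famhist_coding: str = "dummy",
) -> TrendFit:
    """Burden-trend association over complete-case samples.

    ``model="logistic"`` regresses case status on burden + covariates;
    ``model="linear"`` regresses burden on a case indicator + covariates
    (OLS).  Either way ``beta`` is the coefficient tying burden to status.
    """
    cc = burden.loc[burden["complete"]].set_index("sample_id")
    if len(cc) < 10:
        raise ValueError("fewer than 10 complete-case samples")
    if float(cc["burden"].std()) == 0.0:
        raise ValueError("burden is constant")
    pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes.columns else phenotypes
    common = cc.index.intersection(pheno.index)
    design = make_design(pheno.loc[common], famhist_coding=famhist_coding)
    status = (pheno.loc[common, "status"] == "PD").astype(float)
    b = cc.loc[common, "burden"].astype(float)
    if model == "logistic":
        design.insert(0, "burden", b)
        fit = fit_logistic(status, design)
        return TrendFit(model="logistic", beta=float(fit.params["burden"]), se=float(fit.bse["burden"]),
                        p=float(fit.pvalues["burden"]), params=fit.params, n=fit.n)
    if model == "linear":
        design.insert(0, "status_pd", status)
        frame = pd.concat([b.rename("burden"), design], axis=1).dropna()
        X = sm.add_constant(frame.drop(columns="burden"), has_constant="add")
        res = sm.OLS(frame["burden"], X).fit()
        return TrendFit(model="linear", beta=float(res.params["status_pd"]), se=float(res.bse["status_pd"]),
                        p=float(res.pvalues["status_pd"]), params=res.params, n=int(res.nobs))
    raise ValueError(f"unknown model {model!r}")


def threshold_association(
    groupings: Sequence[ThresholdGrouping],
    phenotypes: pd.DataFrame,
    famhist_coding: str = "dummy",
    adjusted: bool = True,
) -> pd.DataFrame:
    """Per-threshold logistic odds ratios (forest-plot-ready table).

    For each grouping, case status is regressed on the at-or-above
    indicator (plus covariates when ``adjusted``).  Columns: t, or, ci_low,
    ci_high, p, beta, se, the 2x2 counts, n, separation.  Thresholds are
    deliberately not corrected for multiplicity across the sweep.
    """
    pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes.columns else phenotypes
    rows = []
    for g in groupings:
        idx = g.groups.index.intersection(pheno.index)
        indicator = (g.groups.loc[idx] == "at_or_above").astype(float)
        if adjusted:
            design = make_design(pheno.loc[idx], famhist_coding=famhist_coding)
        else:
            design = pd.DataFrame(index=idx)
        design.insert(0, "at_or_above", indicator)
        y = (pheno.loc[idx, "status"] == "PD").astype(float)
        fit = fit_logistic(y, design)
        or_, lo, hi = fit.odds_ratio("at_or_above")
        rows.append(
            {"t": g.t, "or": or_, "ci_low": lo, "ci_high": hi,
             "p": float(fit.pvalues["at_or_above"]),
             "beta": float(fit.params["at_or_above"]), "se": float(fit.bse["at_or_above"]),
             "n_HC_below": g.n_hc_below, "n_HC_at_or_above": g.n_hc_at_or_above,
             "n_PD_below": g.n_pd_below, "n_PD_at_or_above": g.n_pd_at_or_above,
             "n": fit.n, "separation": fit.separation}
        )
    return pd.DataFrame(rows)


def two_by_two_or(n_hc_below: int, n_hc_above: int, n_pd_below: int, n_pd_above: int) -> tuple[float, float]:
    """Closed-form 2x2 odds ratio and its Woolf log-OR standard error."""
    or_ = (n_pd_above * n_hc_below) / (n_pd_below * n_hc_above)
    se = float(np.sqrt(1 / n_hc_below + 1 / n_hc_above + 1 / n_pd_below + 1 / n_pd_above))
    return float(or_), se


def plot_forest(table: pd.DataFrame, path: str | None = None, title: str = "Odds of disease by burden threshold"):
    """Forest plot of a threshold_association table (OR with 95% CI per t)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 0.5 * len(table) + 1.5))
    ys = np.arange(len(table))[::-1]
    ax.errorbar(table["or"], ys,
                xerr=[table["or"] - table["ci_low"], table["ci_high"] - table["or"]],
                fmt="D", color="black", ecolor="black", capsize=3)
    ax.axvline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_yticks(ys)
    ax.set_yticklabels([f"≥{int(t)}" for t in table["t"]])
    ax.set_xlabel("odds ratio (95% CI)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
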