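"""Longitudinal contrasts of clinical features between burden groups.

Repeated clinical measures (e.g. MDS-UPDRS part I, levodopa-equivalent
daily dose, DaTscan striatal binding ratios) collected at discrete visits
(months 0/12/24/36) are modelled per feature with a linear mixed-effects
model

    value ~ group + visit + group:visit  +  (1 | patient)

fitted by restricted maximum likelihood.  Visits are categorical — the
interest is in group differences at specific visits, not slopes — and the
per-patient random intercept absorbs stable between-patient level
differences.  Estimated marginal means (EMMs) give the model-based mean of
each group x visit cell over the uniform reference grid, and per-visit
pairwise contrasts compare the two burden groups at each visit separately
(normal-approximation inference, no multiplicity adjustment across
visits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats

__all__ = [
    "MixedModelFit",
    "fit_lmm",
    "estimated_marginal_means",
    "pairwise_contrasts",
    "screen_features",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["patient_id", "visit_month", "value"]


@dataclass
class MixedModelFit:
    """A fitted random-intercept model for one clinical feature.

    Keeps the fixed-effect estimates with their covariance, the variance
    components, and the design information needed to evaluate the fixed
    part at arbitrary group x visit cells.
    """

    fe_params: pd.Series
    fe_cov: pd.DataFrame
    sigma2_patient: float
    sigma2_residual: float
    llf: float
    converged: bool
    group_levels: tuple[str, str]
    visit_levels: tuple[int, ...]
    design_info: object
    n_obs: int
    n_patients: int

    def cell_design(self, group: str, visit: int) -> np.ndarray:
        """Fixed-effect design row for one group x visit cell."""
        grid = pd.DataFrame({"group": [group], "visit_month": [visit]})
        (X,) = build_design_matrices([self.design_info], grid)
        return np.asarray(X)[0]


def _prepare(records: pd.DataFrame, groups: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    df = records[RECORD_COLUMNS].dropna(subset=["value"]).copy()
    if df.duplicated(subset=["patient_id", "visit_month"]).any():
        raise ValueError("multiple records for one (patient, visit)")
    gmap = pd.Series(groups)
    df["group"] = df["patient_id"].map(gmap)
    if df["group"].isna().any():
        orphan = df.loc[df["group"].isna(), "patient_id"].iloc[0]
        raise ValueError(f"no group assignment for patient {orphan!r}")
    return df


def fit_lmm(
    records: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_levels: Sequence[str] | None = None,
) -> MixedModelFit:
    """Fit value ~ group * visit with a per-patient random intercept (REML).

    ``records`` is long-format with columns patient_id, visit_month, value
    (one feature at a time); ``groups`` maps patient to burden group.
    Unbalanced data — patients with missing visits — are used as-is.
    ``group_levels`` fixes the (reference, comparison) order; default is
    sorted order.
    """
    df = _prepare(records, groups)
    levels = tuple(group_levels) if group_levels is not None else tuple(sorted(df["group"].unique()))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    if set(df["group"].unique()) != set(levels):
        raise ValueError("group_levels do not match the data")
    counts = df.groupby("group")["patient_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 patients per group")
    visits = tuple(sorted(df["visit_month"].unique()))
    if len(visits) < 2:
        raise ValueError("need >= 2 visits")
    df["group"] = pd.Categorical(df["group"], categories=levels)
    df["visit_month"] = pd.Categorical(df["visit_month"], categories=visits)
    model = smf.mixedlm("value ~ group * visit_month", data=df, groups=df["patient_id"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError:
            res = model.fit(reml=True, method="powell")
    k = len(res.fe_params)
    fe_cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=res.fe_params.index, columns=res.fe_params.index
    )
    sigma2_patient = float(np.asarray(res.cov_re).ravel()[0])
    return MixedModelFit(
        fe_params=res.fe_params,
        fe_cov=fe_cov,
        sigma2_patient=sigma2_patient,
        sigma2_residual=float(res.scale),
        llf=float(res.llf),
        converged=bool(res.converged),
        group_levels=levels,
        visit_levels=visits,
        design_info=model.data.design_info,
        n_obs=int(len(df)),
        n_patients=int(df["patient_id"].nunique()),
    )


def estimated_marginal_means(fit: MixedModelFit) -> pd.DataFrame:
    """EMM per group x visit cell with SE and normal 95% CI.

    The EMM of a cell is the fixed-effect linear predictor evaluated there;
    with only the two design factors this is the model-based cell mean.
    """
    if not fit.converged:
        logger.warning("EMMs from a non-converged fit")
    z = stats.norm.ppf(0.975)
    beta = fit.fe_params.to_numpy()
    cov = fit.fe_cov.to_numpy()
    rows = []
    for g in fit.group_levels:
        for v in fit.visit_levels:
            x = fit.cell_design(g, v)
            est = float(x @ beta)
            se = float(np.sqrt(x @ cov @ x))
            rows.append(
                {"group": g, "visit_month": v, "emmean": est, "se": se,
                 "ci_low": est - z * se, "ci_high": est + z * se}
            )
    return pd.DataFrame(rows)


def pairwise_contrasts(fit: MixedModelFit) -> pd.DataFrame:
    """Per-visit between-group contrast (comparison minus reference group).

    The contrast at visit v is EMM(group2, v) - EMM(group1, v); its SE
    comes from the contrast vector and the fixed-effect covariance, with a
    normal-approximation two-sided p value and no multiplicity adjustment.
    """
    g1, g2 = fit.group_levels
    beta = fit.fe_params.to_numpy()
    cov = fit.fe_cov.to_numpy()
    rows = []
    for v in fit.visit_levels:
        L = fit.cell_design(g2, v) - fit.cell_design(g1, v)
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else np.nan
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        rows.append({"visit_month": v, "estimate": est, "se": se, "z": z, "p": p})
    return pd.DataFrame(rows)


def screen_features(
    records: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_levels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit -> EMM -> contrast for every feature; flag significant visits.

    ``records`` is long-format with an extra ``feature_name`` column.  The
    output has one row per (feature, visit): group means with CIs, the
    contrast p value, and a significance flag at ``alpha``.  Features that
    fail to fit (e.g. constant values) are logged and skipped.
    """
    if "feature_name" not in records.columns:
        raise ValueError("records need a feature_name column")
    rows = []
    for feature, sub in records.groupby("feature_name", sort=True):
        if sub["value"].dropna().nunique() <= 1:
            logger.warning("feature %s skipped: constant or empty values", feature)
            continue
        try:
            fit = fit_lmm(sub, groups, group_levels=group_levels)
            emms = estimated_marginal_means(fit).set_index(["group", "visit_month"])
            contrasts = pairwise_contrasts(fit)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("feature %s skipped: %s", feature, exc)
            continue
        g1, g2 = fit.group_levels
        for _, c in contrasts.iterrows():
            v = c["visit_month"]
            e1, e2 = emms.loc[(g1, v)], emms.loc[(g2, v)]
            rows.append(
                {"feature": feature, "visit_month": v,
                 f"mean_{g1}": e1["emmean"], f"ci_low_{g1}": e1["ci_low"], f"ci_high_{g1}": e1["ci_high"],
                 f"mean_{g2}": e2["emmean"], f"ci_low_{g2}": e2["ci_low"], f"ci_high_{g2}": e2["ci_high"],
                 "p": c["p"], "significant": bool(c["p"] < alpha)}
            )
    return pd.DataFrame(rows)
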