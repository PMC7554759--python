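"""Per-individual presence-allele burden and threshold groupings.

The burden of an individual is the total number of presence alleles over a
chosen locus set (e.g. the autosomal highly active RC-L1s).  Individuals
are then dichotomized at an integer threshold t — below (burden <= t-1)
versus at-or-above (burden >= t) — and a constrained sweep enumerates every
threshold whose smaller category still holds at least a minimum fraction of
both cases and controls, so that downstream odds ratios are never driven by
tiny cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import RcL1Catalog
from .genotypes import GenotypeMatrix

__all__ = [
    "read_phenotypes",
    "validate_phenotypes",
    "polymorphic_loci",
    "compute_burden",
    "categorize",
    "sweep_thresholds",
    "ThresholdGrouping",
]

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["sample_id", "status", "sex", "age", "family_history"]
STATUSES = {"PD", "HC"}
SEXES = {"male", "female"}
FAMILY_HISTORY = {"first_degree", "other", "none", "unknown"}


def validate_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table and return it indexed by sample_id."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    df = phenotypes.copy()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in phenotype table")
    for col, allowed in (("status", STATUSES), ("sex", SEXES), ("family_history", FAMILY_HISTORY)):
        bad = set(df[col].unique()) - allowed
        if bad:
            raise ValueError(f"invalid {col} values {sorted(bad)}; allowed: {sorted(allowed)}")
    if (df["age"] <= 0).any():
        raise ValueError("ages must be positive")
    return df.set_index("sample_id", drop=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep="\t"))


def polymorphic_loci(matrix: GenotypeMatrix | pd.DataFrame) -> set[str]:
    """Loci where both a presence and an absence allele are observed.

    Equivalently, loci whose presence-allele frequency over non-missing
    genotypes is strictly between 0 and 1.  Loci with no called genotype at
    all are not polymorphic.
    """
    data = matrix.data if isinstance(matrix, GenotypeMatrix) else matrix
    if data.empty:
        raise ValueError("empty genotype matrix")
    n_obs = data.notna().sum(axis=0)
    presence = data.sum(axis=0, skipna=True)
    freq = presence / (2.0 * n_obs)
    poly = (n_obs > 0) & (freq > 0.0) & (freq < 1.0)
    return set(data.columns[poly])


def compute_burden(
    matrix: GenotypeMatrix | pd.DataFrame,
    locus_set: Iterable[str],
    catalog: RcL1Catalog | None = None,
    exclude_sex_chromosomes: bool = False,
    missing_policy: str = "complete_case",
) -> pd.DataFrame:
    """Per-sample burden: total presence alleles over a locus set.

    With ``exclude_sex_chromosomes`` (requires ``catalog`` for chromosome
    lookup) chrX/chrY loci are dropped first, so males and females can be
    analyzed together.  Under the default ``complete_case`` policy a sample
    with any missing genotype over the locus set gets ``complete=False``
    and its burden is summed over observed loci only; downstream
    association uses complete cases.  The alternative
    ``available_case_rescaled`` policy rescales each sample's observed sum
    to the full locus-set size (burden becomes fractional).

    Returns a DataFrame with columns sample_id, burden, n_loci_used,
    complete.
    """
    data = matrix.data if isinstance(matrix, GenotypeMatrix) else matrix
    loci = list(locus_set)
    unknown = set(loci) - set(data.columns)
    if unknown:
        raise ValueError(f"loci not in matrix: {sorted(unknown)}")
    if exclude_sex_chromosomes:
        if catalog is None:
            raise ValueError("exclude_sex_chromosomes requires a catalog")
        loci = [lid for lid in loci if not catalog[lid].on_sex_chromosome]
    if not loci:
        raise ValueError("locus set is empty after filtering")
    sub = data[loci]
    n_obs = sub.notna().sum(axis=1)
    total = sub.sum(axis=1, skipna=True)
    complete = n_obs == len(loci)
    if missing_policy == "complete_case":
        burden = total
    elif missing_policy == "available_case_rescaled":
        with np.errstate(invalid="ignore", divide="ignore"):
            burden = total * (len(loci) / n_obs.replace(0, np.nan))
        burden = burden.fillna(0.0)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return pd.DataFrame(
        {
            "sample_id": sub.index,
            "burden": burden.to_numpy(),
            "n_loci_used": n_obs.to_numpy() if missing_policy == "complete_case" else len(loci),
            "complete": complete.to_numpy(),
        }
    ).reset_index(drop=True)


@dataclass
class ThresholdGrouping:
    """Dichotomization of complete-case samples at burden threshold ``t``.

    ``groups`` maps sample_id to ``"below"`` (burden <= t-1) or
    ``"at_or_above"`` (burden >= t); counts is the status x group 2x2 table.
    """

    t: int
    groups: pd.Series
    n_hc_below: int
    n_hc_at_or_above: int
    n_pd_below: int
    n_pd_at_or_above: int
    admissible: bool | None = None

    @property
    def pct_hc_at_or_above(self) -> float:
        return 100.0 * self.n_hc_at_or_above / (self.n_hc_below + self.n_hc_at_or_above)

    @property
    def pct_pd_at_or_above(self) -> float:
        return 100.0 * self.n_pd_at_or_above / (self.n_pd_below + self.n_pd_at_or_above)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(hc_below, hc_at_or_above, pd_below, pd_at_or_above)."""
        return (self.n_hc_below, self.n_hc_at_or_above, self.n_pd_below, self.n_pd_at_or_above)


def categorize(burden: pd.DataFrame, phenotypes: pd.DataFrame, t: int) -> ThresholdGrouping:
    """Dichotomize complete-case samples at burden >= t and cross-tabulate."""
    if t < 1:
        raise ValueError("threshold t must be >= 1")
    cc = burden.loc[burden["complete"]].set_index("sample_id")
    pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes.columns else phenotypes
    missing = set(cc.index) - set(pheno.index)
    if missing:
        raise ValueError(f"phenotype missing for complete-case samples: {sorted(missing)[:5]}")
    status = pheno.loc[cc.index, "status"]
    at_or_above = cc["burden"] >= t
    groups = pd.Series(np.where(at_or_above, "at_or_above", "below"), index=cc.index, name="group")
    return ThresholdGrouping(
        t=t,
        groups=groups,
        n_hc_below=int(((status == "HC") & ~at_or_above).sum()),
        n_hc_at_or_above=int(((status == "HC") & at_or_above).sum()),
        n_pd_below=int(((status == "PD") & ~at_or_above).sum()),
        n_pd_at_or_above=int(((status == "PD") & at_or_above).sum()),
    )


def sweep_thresholds(
    burden: pd.DataFrame,
    phenotypes: pd.DataFrame,
    min_fraction: float = 0.05,
) -> list[ThresholdGrouping]:
    """All admissible threshold groupings, in ascending t.

    Candidate thresholds are every integer from the minimum observed
    complete-case burden to the maximum plus one.  A grouping is admissible
    iff each of its two categories contains at least ``min_fraction`` of
    the controls *and* of the cases.  An empty list (with a logged warning)
    means no threshold satisfies the constraint.
    """
    if not (0.0 < min_fraction < 0.5):
        raise ValueError("min_fraction must be in (0, 0.5)")
    cc = burden.loc[burden["complete"]]
    if cc.empty:
        raise ValueError("no complete-case samples")
    lo, hi = int(np.floor(cc["burden"].min())), int(np.ceil(cc["burden"].max()))
    out: list[ThresholdGrouping] = []
    for t in range(max(lo, 1), hi + 2):
        g = categorize(burden, phenotypes, t)
        n_hc = g.n_hc_below + g.n_hc_at_or_above
        n_pd = g.n_pd_below + g.n_pd_at_or_above
        ok = (
            g.n_hc_below >= min_fraction * n_hc
            and g.n_hc_at_or_above >= min_fraction * n_hc
            and g.n_pd_below >= min_fraction * n_pd
            and g.n_pd_at_or_above >= min_fraction * n_pd
        )
        g.admissible = ok
        if ok:
            out.append(g)
    if not out:
        logger.warning("no admissible thresholds at min_fraction=%s", min_fraction)
    return out


def groupings_frame(groupings: Sequence[ThresholdGrouping]) -> pd.DataFrame:
    """Tabular view of a threshold sweep (one row per grouping)."""
    return pd.DataFrame(
        {
            "t": [g.t for g in groupings],
            "n_HC_below": [g.n_hc_below for g in groupings],
            "n_HC_at_or_above": [g.n_hc_at_or_above for g in groupings],
            "n_PD_below": [g.n_pd_below for g in groupings],
            "n_PD_at_or_above": [g.n_pd_at_or_above for g in groupings],
            "admissible": [bool(g.admissible) for g in groupings],
        }
    )
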