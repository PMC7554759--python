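"""Catalog of retrotransposition-competent LINE-1 (RC-L1) loci.

An RC-L1 is a full-length LINE-1 element with evidence of mobilization
ability: activity in a cellular retrotransposition assay (expressed as a
percentage of the highly active L1RP/L1.3 benchmark elements), or having
been traced — via 3' transductions — as the source of new germline or
somatic insertions.  Each locus is either *reference* (present in the
reference genome assembly; its absence in an individual appears as a
deletion call) or *non-reference* (absent from the assembly; its presence
appears as a mobile-element insertion call).

This module loads and validates catalog tables, summarizes the three
activity parameters, derives upper-quartile activity thresholds over a
stated locus subset, and classifies loci as *highly active* (HA): strictly
exceeding the top-quartile cut-off on at least one observed parameter.

Coordinates are stored 0-based, half-open throughout; conversion to and
from 1-based VCF positions is done explicitly at the I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RcL1Locus",
    "RcL1Catalog",
    "ActivityThresholds",
    "CatalogSummary",
    "HaClassification",
    "CatalogError",
    "read_catalog",
    "write_catalog",
    "write_bed",
    "summarize_catalog",
    "compute_ha_thresholds",
    "classify_ha",
]

#: TSV column order for the catalog exchange format.
CATALOG_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "is_reference",
    "assay_activity_pct",
    "germline_td_count",
    "somatic_td_count",
    "allele_frequency",
]

PARAMETER_FIELDS = ("assay_activity_pct", "germline_td_count", "somatic_td_count")

SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})


class CatalogError(ValueError):
    """Raised on malformed catalog input or invariant violations."""


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome names to the ``chr``-prefixed dialect."""
    chrom = str(chrom).strip()
    if not chrom:
        raise CatalogError("empty chromosome name")
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


@dataclass(frozen=True)
class RcL1Locus:
    """One RC-L1 locus with its activity evidence.

    ``start``/``end`` are hg38-style 0-based half-open coordinates.
    Reference elements span the full ~6 kb body; non-reference elements are
    point insertions, so their interval is a narrow breakpoint window.
    Any of the three activity parameters, and the population allele
    frequency of the presence allele, may be absent (``None``).
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    is_reference: bool
    assay_activity_pct: float | None = None
    germline_td_count: int | None = None
    somatic_td_count: int | None = None
    allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise CatalogError(
                f"locus {self.locus_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.assay_activity_pct is not None and self.assay_activity_pct < 0:
            raise CatalogError(f"locus {self.locus_id!r}: negative assay activity")
        for name in ("germline_td_count", "somatic_td_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CatalogError(f"locus {self.locus_id!r}: negative {name}")
        af = self.allele_frequency
        if af is not None and not (0.0 <= af <= 1.0):
            raise CatalogError(f"locus {self.locus_id!r}: allele frequency {af} not in [0, 1]")

    @property
    def on_sex_chromosome(self) -> bool:
        return self.chrom in SEX_CHROMOSOMES


class RcL1Catalog:
    """Ordered, validated collection of :class:`RcL1Locus`."""

    def __init__(self, loci: Iterable[RcL1Locus]):
        self.loci: tuple[RcL1Locus, ...] = tuple(loci)
        self._by_id: dict[str, RcL1Locus] = {}
        seen_coords: set[tuple] = set()
        for locus in self.loci:
            if locus.locus_id in self._by_id:
                raise CatalogError(f"duplicate locus_id {locus.locus_id!r}")
            self._by_id[locus.locus_id] = locus
            coord = (locus.chrom, locus.start, locus.end, locus.is_reference)
            if coord in seen_coords:
                raise CatalogError(f"duplicate locus coordinates {coord}")
            seen_coords.add(coord)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[RcL1Locus]:
        return iter(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def __getitem__(self, locus_id: str) -> RcL1Locus:
        return self._by_id[locus_id]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def subset(self, locus_ids: Iterable[str]) -> "RcL1Catalog":
        ids = set(locus_ids)
        unknown = ids - set(self._by_id)
        if unknown:
            raise CatalogError(f"unknown locus ids: {sorted(unknown)}")
        return RcL1Catalog(l for l in self.loci if l.locus_id in ids)

    def reference(self) -> "RcL1Catalog":
        return RcL1Catalog(l for l in self.loci if l.is_reference)

    def nonreference(self) -> "RcL1Catalog":
        return RcL1Catalog(l for l in self.loci if not l.is_reference)

    def autosomal_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci if not l.on_sex_chromosome]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.loci:
            rows.append(
                {
                    "locus_id": l.locus_id,
                    "chrom": l.chrom,
                    "start": l.start,
                    "end": l.end,
                    "is_reference": l.is_reference,
                    "assay_activity_pct": l.assay_activity_pct,
                    "germline_td_count": l.germline_td_count,
                    "somatic_td_count": l.somatic_td_count,
                    "allele_frequency": l.allele_frequency,
                }
            )
        return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def _parse_optional_float(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CatalogError(f"row {row}: non-numeric {column} value {value!r}") from None


def _parse_optional_int(value, row: int, column: str) -> int | None:
    f = _parse_optional_float(value, row, column)
    if f is None:
        return None
    if f != int(f):
        raise CatalogError(f"row {row}: {column} value {value!r} is not an integer")
    return int(f)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def read_catalog(path: str | Path) -> RcL1Catalog:
    """Read an RC-L1 catalog from its TSV exchange format.

    Required header columns: ``locus_id, chrom, start, end, is_reference,
    assay_activity_pct, germline_td_count, somatic_td_count,
    allele_frequency``; empty cells mean *absent* for the last four.
    Rows violating locus invariants are reported with their row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog {path}: missing required columns {missing}")
    loci = []
    for i, rec in enumerate(df.to_dict("records"), start=2):  # header is line 1
        flag = str(rec["is_reference"]).strip().lower()
        if flag in _TRUE:
            is_ref = True
        elif flag in _FALSE:
            is_ref = False
        else:
            raise CatalogError(f"row {i}: is_reference value {rec['is_reference']!r} not boolean")
        try:
            locus = RcL1Locus(
                locus_id=str(rec["locus_id"]).strip(),
                chrom=normalize_chrom(rec["chrom"]),
                start=int(rec["start"]),
                end=int(rec["end"]),
                is_reference=is_ref,
                assay_activity_pct=_parse_optional_float(rec["assay_activity_pct"], i, "assay_activity_pct"),
                germline_td_count=_parse_optional_int(rec["germline_td_count"], i, "germline_td_count"),
                somatic_td_count=_parse_optional_int(rec["somatic_td_count"], i, "somatic_td_count"),
                allele_frequency=_parse_optional_float(rec["allele_frequency"], i, "allele_frequency"),
            )
        except ValueError as exc:
            if isinstance(exc, CatalogError):
                raise CatalogError(f"row {i}: {exc}") from None
            raise CatalogError(f"row {i}: {exc}") from None
        loci.append(locus)
    return RcL1Catalog(loci)


def write_catalog(catalog: RcL1Catalog, path: str | Path) -> None:
    """Write the catalog back to its TSV exchange format (round-trip safe)."""
    df = catalog.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="")


def write_bed(catalog: RcL1Catalog, path: str | Path) -> None:
    """Export a BED6 track (chrom, start, end, locus_id, 0, .) for browsers."""
    with open(path, "w") as fh:
        for l in catalog:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t0\t.\n")


@dataclass(frozen=True)
class ActivityThresholds:
    """Upper-quartile (75th percentile) cut-offs for the three parameters."""

    q3_activity_pct: float
    q3_germline: float
    q3_somatic: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.q3_activity_pct, self.q3_germline, self.q3_somatic)


@dataclass
class CatalogSummary:
    """Distributional summary of a catalog's activity evidence.

    Bin counts are over loci with the parameter observed; "source" loci are
    those with the respective transduction count >= 1.
    """

    n_loci: int
    n_reference: int
    n_nonreference: int
    activity_values: np.ndarray
    germline_values: np.ndarray
    somatic_values: np.ndarray
    n_germline_sources: int
    n_somatic_sources: int
    activity_bin_edges: np.ndarray
    activity_bin_counts: np.ndarray

    @property
    def n_activity_observed(self) -> int:
        return self.activity_values.size

    def activity_fraction_below(self, cutoff: float) -> float:
        """Fraction of assayed loci with activity strictly below ``cutoff``."""
        if self.activity_values.size == 0:
            return 0.0
        return float(np.mean(self.activity_values < cutoff))

    def activity_fraction_above(self, cutoff: float) -> float:
        """Fraction of assayed loci with activity strictly above ``cutoff``."""
        if self.activity_values.size == 0:
            return 0.0
        return float(np.mean(self.activity_values > cutoff))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": "assay_activity_pct", "n_observed": self.n_activity_observed},
            {"parameter": "germline_td_count", "n_observed": self.germline_values.size,
             "n_sources": self.n_germline_sources},
            {"parameter": "somatic_td_count", "n_observed": self.somatic_values.size,
             "n_sources": self.n_somatic_sources},
        ]
        return pd.DataFrame(rows)


def summarize_catalog(
    catalog: RcL1Catalog, activity_bin_width: float = 10.0, activity_bins: Sequence[float] | None = None
) -> CatalogSummary:
    """Summarize the three activity parameters over a catalog.

    ``activity_bins`` overrides the default equal-width binning of assay
    activity (width ``activity_bin_width`` percent, starting at 0).
    """
    if len(catalog) == 0:
        raise CatalogError("cannot summarize an empty catalog")
    act = np.array([l.assay_activity_pct for l in catalog if l.assay_activity_pct is not None], dtype=float)
    germ = np.array([l.germline_td_count for l in catalog if l.germline_td_count is not None], dtype=float)
    som = np.array([l.somatic_td_count for l in catalog if l.somatic_td_count is not None], dtype=float)
    if activity_bins is not None:
        edges = np.asarray(activity_bins, dtype=float)
    elif act.size:
        top = max(act.max(), activity_bin_width)
        edges = np.arange(0.0, top + activity_bin_width, activity_bin_width)
    else:
        edges = np.array([0.0, activity_bin_width])
    counts, edges = np.histogram(act, bins=edges)
    return CatalogSummary(
        n_loci=len(catalog),
        n_reference=len(catalog.reference()),
        n_nonreference=len(catalog.nonreference()),
        activity_values=act,
        germline_values=germ,
        somatic_values=som,
        n_germline_sources=int(np.sum(germ >= 1)),
        n_somatic_sources=int(np.sum(som >= 1)),
        activity_bin_edges=edges,
        activity_bin_counts=counts,
    )


def compute_ha_thresholds(
    catalog: RcL1Catalog,
    locus_subset: Iterable[str],
    quartile_method: str = "linear",
) -> ActivityThresholds:
    """Upper-quartile thresholds of the three parameters over a locus subset.

    The 75th percentile of each parameter is taken over the loci in
    ``locus_subset`` with that parameter observed, using the numpy
    percentile ``method`` given by ``quartile_method`` (default linear
    interpolation between order statistics).
    """
    subset = catalog.subset(locus_subset)
    if len(subset) == 0:
        raise CatalogError("empty locus subset")
    values = {}
    for name in PARAMETER_FIELDS:
        obs = np.array([getattr(l, name) for l in subset if getattr(l, name) is not None], dtype=float)
        if obs.size == 0:
            raise CatalogError(f"no observed values for {name} in the subset")
        values[name] = float(np.quantile(obs, 0.75, method=quartile_method))
    return ActivityThresholds(
        q3_activity_pct=values["assay_activity_pct"],
        q3_germline=values["germline_td_count"],
        q3_somatic=values["somatic_td_count"],
    )


@dataclass
class HaClassification:
    """Highly-active call per locus with the exceeded-parameter flags."""

    flags: pd.DataFrame  # locus_id, exceeds_activity, exceeds_germline, exceeds_somatic, is_ha
    thresholds: ActivityThresholds

    @property
    def ha_ids(self) -> set[str]:
        return set(self.flags.loc[self.flags["is_ha"], "locus_id"])

    @property
    def all_three_ids(self) -> set[str]:
        m = self.flags["exceeds_activity"] & self.flags["exceeds_germline"] & self.flags["exceeds_somatic"]
        return set(self.flags.loc[m, "locus_id"])


def classify_ha(catalog: RcL1Catalog, thresholds: ActivityThresholds) -> HaClassification:
    """Classify catalog loci as highly active (HA).

    A locus is HA iff at least one *observed* parameter is strictly greater
    than its upper-quartile threshold; absent parameters never qualify.
    """
    for v in thresholds.as_tuple():
        if not np.isfinite(v):
            raise CatalogError("thresholds must be finite")
    rows = []
    for l in catalog:
        ea = l.assay_activity_pct is not None and l.assay_activity_pct > thresholds.q3_activity_pct
        eg = l.germline_td_count is not None and l.germline_td_count > thresholds.q3_germline
        es = l.somatic_td_count is not None and l.somatic_td_count > thresholds.q3_somatic
        rows.append(
            {
                "locus_id": l.locus_id,
                "exceeds_activity": ea,
                "exceeds_germline": eg,
                "exceeds_somatic": es,
                "is_ha": ea or eg or es,
            }
        )
    return HaClassification(flags=pd.DataFrame(rows), thresholds=thresholds)
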