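"""Harmonize structural-variant calls into presence-allele genotypes.

Reference RC-L1s are part of the reference assembly, so an individual
*lacking* the element carries a deletion allele: Delly2-style ``SVTYPE=DEL``
records overlapping the catalog interval genotype these loci.  Non-reference
RC-L1s are absent from the assembly, so carriers show MELT-style
mobile-element insertion records (``MEINFO`` family LINE1) at the catalog
breakpoint.  Both call dialects are converted into one samples x loci
matrix of presence-allele counts — the number of chromosomes carrying the
L1 (0/1/2, or missing) regardless of reference status.

Reference loci with no overlapping deletion call are imputed as fixed
present (2 everywhere); non-reference loci with no insertion call are
absent from the cohort (0 everywhere).  Both imputations are flagged in the
per-locus report so downstream analyses can distinguish imputed from
called genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .catalog import RcL1Catalog, normalize_chrom

__all__ = [
    "DeletionCall",
    "InsertionCall",
    "GenotypeMatrix",
    "load_deletion_vcf",
    "load_mei_vcf",
    "match_reference_loci",
    "match_nonreference_loci",
    "build_genotype_matrix",
    "write_genotype_matrix",
    "read_genotype_matrix",
]

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for a missing per-sample allele count


@dataclass(frozen=True)
class DeletionCall:
    """A deletion SV record; the alternate allele is the deletion itself.

    ``allele_counts[i]`` is sample *i*'s count of deletion alleles
    (0 hom-ref, 1 het, 2 hom-del, -1 missing).  Coordinates are 0-based
    half-open, converted from the 1-based VCF POS/END.
    """

    chrom: str
    start: int
    end: int
    allele_counts: np.ndarray

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InsertionCall:
    """A mobile-element insertion record with its 0-based breakpoint."""

    chrom: str
    position: int
    family: str
    allele_counts: np.ndarray


def _allele_counts(variant, n_samples: int) -> np.ndarray:
    counts = np.empty(n_samples, dtype=np.int8)
    for i, gt in enumerate(variant.genotypes):
        alleles = gt[:-1]  # last entry is the phased flag
        if any(a < 0 for a in alleles):
            counts[i] = MISSING
        else:
            counts[i] = sum(1 for a in alleles if a > 0)
    return counts


def load_deletion_vcf(path: str | Path) -> tuple[list[DeletionCall], list[str]]:
    """Load ``SVTYPE=DEL`` records from a multi-sample VCF.

    Returns the deletion calls (0-based half-open intervals) and the VCF
    sample order.  Non-deletion records are skipped with a warning; a DEL
    record without an END is an error.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[DeletionCall] = []
    for variant in vcf:
        svtype = variant.INFO.get("SVTYPE")
        if svtype != "DEL":
            logger.warning("skipping non-DEL record %s:%s (SVTYPE=%s)", variant.CHROM, variant.POS, svtype)
            continue
        end = variant.INFO.get("END")
        if end is None:
            raise ValueError(f"DEL record at {variant.CHROM}:{variant.POS} lacks INFO/END")
        calls.append(
            DeletionCall(
                chrom=normalize_chrom(variant.CHROM),
                start=variant.POS - 1,
                end=int(end),
                allele_counts=_allele_counts(variant, len(samples)),
            )
        )
    return calls, samples


def load_mei_vcf(path: str | Path, family: str = "LINE1") -> tuple[list[InsertionCall], list[str]]:
    """Load mobile-element insertion records of one family from a VCF.

    The element family is read from the first ``MEINFO`` field; records of
    other families are skipped with a warning, records lacking a family
    annotation are an error.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[InsertionCall] = []
    for variant in vcf:
        meinfo = variant.INFO.get("MEINFO")
        if meinfo is None:
            raise ValueError(f"insertion record at {variant.CHROM}:{variant.POS} lacks INFO/MEINFO")
        fam = str(meinfo).split(",")[0]
        if family.upper() not in fam.upper().replace("/", ""):
            logger.warning("skipping non-%s insertion %s:%s (%s)", family, variant.CHROM, variant.POS, fam)
            continue
        calls.append(
            InsertionCall(
                chrom=normalize_chrom(variant.CHROM),
                position=variant.POS - 1,
                family=fam,
                allele_counts=_allele_counts(variant, len(samples)),
            )
        )
    return calls, samples


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Reciprocal overlap of two half-open intervals (0 if disjoint)."""
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return inter / max(a_end - a_start, b_end - b_start)


def match_reference_loci(
    deletions: Sequence[DeletionCall],
    catalog: RcL1Catalog,
    min_reciprocal_overlap: float = 0.5,
    slop: int = 500,
) -> dict[str, DeletionCall]:
    """Assign deletion calls to reference RC-L1 loci.

    A call is a candidate for a locus if their reciprocal overlap reaches
    ``min_reciprocal_overlap`` or both breakpoints lie within ``slop`` bp of
    the locus ends.  Candidate pairs are resolved greedily by descending
    reciprocal overlap (ties by smaller length difference) with every call
    and locus used at most once.  Unmatched loci are simply absent from the
    returned mapping.
    """
    ref = catalog.reference()
    candidates: list[tuple[float, int, int, str]] = []
    for locus in ref:
        for idx, call in enumerate(deletions):
            if call.chrom != locus.chrom:
                continue
            ro = reciprocal_overlap(call.start, call.end, locus.start, locus.end)
            near = abs(call.start - locus.start) <= slop and abs(call.end - locus.end) <= slop
            if ro >= min_reciprocal_overlap or near:
                length_diff = abs(call.length - (locus.end - locus.start))
                candidates.append((ro, length_diff, idx, locus.locus_id))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    matched: dict[str, DeletionCall] = {}
    used_calls: set[int] = set()
    for ro, _ld, idx, locus_id in candidates:
        if locus_id in matched or idx in used_calls:
            continue
        matched[locus_id] = deletions[idx]
        used_calls.add(idx)
    return matched


def match_nonreference_loci(
    insertions: Sequence[InsertionCall],
    catalog: RcL1Catalog,
    max_distance: int = 100,
) -> dict[str, InsertionCall]:
    """Assign insertion calls to non-reference RC-L1 loci.

    A call matches a locus when its breakpoint lies within ``max_distance``
    bp of the locus position on the same chromosome; the nearest call wins,
    ties broken by the lower breakpoint coordinate, each call used once.
    """
    nonref = catalog.nonreference()
    candidates: list[tuple[int, int, int, str]] = []
    for locus in nonref:
        for idx, call in enumerate(insertions):
            if call.chrom != locus.chrom:
                continue
            dist = abs(call.position - locus.start)
            if dist <= max_distance:
                candidates.append((dist, call.position, idx, locus.locus_id))
    candidates.sort(key=lambda c: (c[0], c[1]))
    matched: dict[str, InsertionCall] = {}
    used_calls: set[int] = set()
    for _dist, _pos, idx, locus_id in candidates:
        if locus_id in matched or idx in used_calls:
            continue
        matched[locus_id] = insertions[idx]
        used_calls.add(idx)
    return matched


@dataclass
class GenotypeMatrix:
    """Samples x loci presence-allele counts with a per-locus provenance report.

    ``data`` holds floats 0/1/2 with NaN for missing; ``report`` has one row
    per locus: whether a call matched, the imputation applied
    (``fixed_present`` / ``absent`` / empty), and the cohort presence-allele
    frequency over non-missing entries.
    """

    data: pd.DataFrame
    report: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.data.columns)

    def presence_frequency(self) -> pd.Series:
        """Per-locus presence-allele frequency over non-missing genotypes."""
        return self.data.mean(axis=0, skipna=True) / 2.0


def build_genotype_matrix(
    ref_matches: Mapping[str, DeletionCall],
    nonref_matches: Mapping[str, InsertionCall],
    catalog: RcL1Catalog,
    sample_ids: Sequence[str],
) -> GenotypeMatrix:
    """Combine matched calls into one presence-allele genotype matrix.

    Matched reference loci flip deletion-allele counts (presence = 2 - del);
    unmatched reference loci are imputed fixed present.  Matched
    non-reference loci use the insertion-allele count directly; unmatched
    ones are absent from the cohort.  Column order follows the catalog.
    """
    n = len(sample_ids)
    for locus_id, call in list(ref_matches.items()) + list(nonref_matches.items()):
        if len(call.allele_counts) != n:
            raise ValueError(
                f"call matched to {locus_id} has {len(call.allele_counts)} genotypes "
                f"but {n} sample ids were given"
            )
    columns: dict[str, np.ndarray] = {}
    report_rows = []
    for locus in catalog:
        lid = locus.locus_id
        imputed = ""
        if locus.is_reference:
            call = ref_matches.get(lid)
            if call is None:
                col = np.full(n, 2.0)
                imputed = "fixed_present"
            else:
                counts = call.allele_counts.astype(float)
                col = 2.0 - counts
                col[counts == MISSING] = np.nan
        else:
            call = nonref_matches.get(lid)
            if call is None:
                col = np.full(n, 0.0)
                imputed = "absent"
            else:
                col = call.allele_counts.astype(float)
                col[call.allele_counts == MISSING] = np.nan
        columns[lid] = col
        with np.errstate(invalid="ignore"):
            freq = float(np.nanmean(col) / 2.0) if np.any(~np.isnan(col)) else np.nan
        report_rows.append(
            {"locus_id": lid, "is_reference": locus.is_reference, "matched": call is not None,
             "imputed": imputed, "presence_freq": freq}
        )
    data = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    report = pd.DataFrame(report_rows)
    return GenotypeMatrix(data=data, report=report)


def write_genotype_matrix(matrix: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.genotypes.tsv`` (0/1/2/NA) and ``<prefix>.loci.tsv``."""
    geno_path = Path(f"{prefix}.genotypes.tsv")
    report_path = Path(f"{prefix}.loci.tsv")
    out = matrix.data.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(geno_path, sep="\t")
    matrix.report.to_csv(report_path, sep="\t", index=False)
    return geno_path, report_path


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genotype TSV (rows samples, columns loci, NA = missing)."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
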