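"""Genotype ingestion and per-variant QC.

The central container is :class:`GenotypeMatrix`, a samples x variants table
of risk-allele dosages (0, 1, 2, or missing). Genotypes can be read from a
biallelic VCF (matched to the catalogue by rsID or by chrom:pos:ref:alt) or
from a delimited dosage table. QC reports per-variant call rate, genotype
counts and the exact Hardy-Weinberg p-value; following the reference
analysis, QC flags are reported rather than enforced (exclusion is a
pipeline option, since a genuine rare-variant cluster can fail HWE and still
be a validated call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .catalog import Catalog, VariantDef
from .hwe import hwe_exact_test

__all__ = [
    "GenotypeMatrix",
    "VariantQc",
    "read_genotypes",
    "variant_qc",
    "UnsupportedRecordError",
]

#: QC thresholds used for flagging (not exclusion)
CALL_RATE_THRESHOLD = 0.97
HWE_P_THRESHOLD = 0.05


class UnsupportedRecordError(ValueError):
    """A VCF record overlapping a catalogue variant cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Risk-allele dosage matrix: rows = samples, columns = variants.

    Dosages are stored as floats with NaN for missing so pandas alignment
    semantics apply; valid non-missing values are {0, 1, 2}.
    """

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicate variant ids")
        values = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError(
                f"dosages must be 0, 1, 2 or missing; found {values[bad][:5]}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return len(self.dosages.index)

    def dosage(self, variant_id: str) -> pd.Series:
        if variant_id not in self.dosages.columns:
            raise KeyError(f"unknown variant_id {variant_id!r}")
        return self.dosages[variant_id]

    def call_rate(self, variant_id: str) -> float:
        """Fraction of samples with a called genotype at the variant."""
        col = self.dosage(variant_id)
        return float(col.notna().mean()) if len(col) else 0.0

    def genotype_counts(self, variant_id: str) -> tuple[int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt) in risk-allele dosage terms."""
        col = self.dosage(variant_id)
        return (
            int((col == 0).sum()),
            int((col == 1).sum()),
            int((col == 2).sum()),
        )

    def complete_cases(self, variant_ids: list[str]) -> tuple["GenotypeMatrix", list[str]]:
        """Drop samples missing any genotype among ``variant_ids``.

        Mirrors the panel-testing rule that only samples genotyped for all
        variants under test are included. Returns the retained matrix and
        the list of excluded sample ids.
        """
        missing_cols = [v for v in variant_ids if v not in self.dosages.columns]
        if missing_cols:
            raise KeyError(f"variants absent from matrix: {missing_cols}")
        sub = self.dosages[list(variant_ids)]
        keep = sub.notna().all(axis=1)
        excluded = list(sub.index[~keep])
        return GenotypeMatrix(self.dosages.loc[keep]), excluded

    # -- delimited-table round trip ---------------------------------------
    def to_table(self, path: str | Path, sep: str = "\t") -> None:
        out = self.dosages.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep=sep, na_rep="NA")

    @classmethod
    def from_table(cls, path: str | Path, sep: str = "\t") -> "GenotypeMatrix":
        df = pd.read_csv(path, sep=sep, index_col="sample_id", na_values=["NA"])
        df.index = df.index.astype(str)
        return cls(df.astype(float))


def _dosage_from_gt(gt: list, risk_index: int) -> float:
    """Count risk alleles in a cyvcf2 genotype [a0, a1, phased].

    Half-calls and fully missing genotypes (-1 alleles) are missing.
    """
    alleles = gt[:-1]
    if len(alleles) != 2 or any(a < 0 for a in alleles):
        return np.nan
    return float(sum(1 for a in alleles if a == risk_index))


def read_genotypes(path: str | Path, catalog: Catalog) -> GenotypeMatrix:
    """Read catalogue-variant dosages from a biallelic VCF.

    Records are matched to catalogue variants by the VCF ID column (rsID)
    first, then by chrom:pos:ref:alt. Catalogue variants without a matching
    record come back as all-missing columns with a warning. A multiallelic
    record overlapping a catalogue variant raises
    :class:`UnsupportedRecordError`; records for loci outside the catalogue
    are ignored.
    """
    by_id = {v.variant_id: v for v in catalog.variants}
    by_locus = {
        (v.chrom, v.pos, v.ref, v.alt): v
        for v in catalog.variants
        if v.chrom is not None and v.pos is not None
    }
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for record in vcf:
        variant: VariantDef | None = by_id.get(record.ID)
        if variant is None and len(record.ALT) == 1:
            variant = by_locus.get(
                (record.CHROM, record.POS, record.REF, record.ALT[0])
            )
        if variant is None:
            continue
        if len(record.ALT) != 1:
            raise UnsupportedRecordError(
                f"multiallelic record at {record.CHROM}:{record.POS} overlaps "
                f"catalogue variant {variant.variant_id!r}; split it first"
            )
        if variant.risk_allele == record.REF:
            risk_index = 0
        elif variant.risk_allele == record.ALT[0]:
            risk_index = 1
        else:
            raise UnsupportedRecordError(
                f"record for {variant.variant_id!r} carries alleles "
                f"{record.REF}/{record.ALT[0]}, neither is the catalogue "
                f"risk allele {variant.risk_allele!r}"
            )
        columns[variant.variant_id] = np.array(
            [_dosage_from_gt(gt, risk_index) for gt in record.genotypes]
        )
    unmatched = [vid for vid in by_id if vid not in columns]
    if unmatched:
        warnings.warn(
            f"no VCF record for catalogue variant(s) {unmatched}; "
            "recorded as all-missing",
            stacklevel=2,
        )
        for vid in unmatched:
            columns[vid] = np.full(len(samples), np.nan)
    df = pd.DataFrame(
        {vid: columns[vid] for vid in by_id}, index=pd.Index(samples, name="sample_id")
    )
    return GenotypeMatrix(df)


@dataclass(frozen=True)
class VariantQc:
    """Per-variant QC summary."""

    variant_id: str
    call_rate: float
    counts: tuple[int, int, int]
    hwe_p: float
    monomorphic: bool
    flags: tuple[str, ...]


def variant_qc(matrix: GenotypeMatrix, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Call rate, genotype counts and exact HWE p-value per variant.

    Flags (``low_call_rate``, ``hwe_departure``, ``monomorphic``) are
    advisory; nothing is excluded here.
    """
    rows = []
    for vid in variant_ids or matrix.variant_ids:
        call_rate = matrix.call_rate(vid)
        counts = matrix.genotype_counts(vid)
        n_called = sum(counts)
        if n_called == 0:
            hwe_p, monomorphic = float("nan"), True
        else:
            n_alt = 2 * counts[2] + counts[1]
            monomorphic = min(n_alt, 2 * n_called - n_alt) == 0
            hwe_p = hwe_exact_test(*counts)
        flags = []
        if call_rate < CALL_RATE_THRESHOLD:
            flags.append("low_call_rate")
        if monomorphic:
            flags.append("monomorphic")
        elif hwe_p < HWE_P_THRESHOLD:
            flags.append("hwe_departure")
        rows.append(
            {
                "variant_id": vid,
                "call_rate": call_rate,
                "n_hom_ref": counts[0],
                "n_het": counts[1],
                "n_hom_alt": counts[2],
                "hwe_p": hwe_p,
                "monomorphic": monomorphic,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
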