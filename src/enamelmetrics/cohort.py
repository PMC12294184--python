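"""Genotype tables and diagnostic-yield arithmetic.

The molecular side of the study is consumed as a per-patient variant table
(one row per patient × variant) mirroring the published tables of
disease-causing variants (DCVs) and of non-conclusive findings.  A row is
*conclusive* when the variant counts as a molecular diagnosis for that
patient — pathogenic or likely pathogenic in a zygosity consistent with the
gene's inheritance mode.  Likely-pathogenic single-allele findings in
autosomal-recessive genes are therefore carried with ``conclusive=False``:
conclusiveness is an explicit column, not re-derived from the ACMG class.

Patients enrolled without any reportable variant appear as rows with empty
variant fields so the table still spans the whole cohort (24 patients from
20 families in the packaged digitization).

All fractions are computed over distinct patients or families, so
compound-heterozygous patients with two rows, and variants shared within a
family, are never double-counted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "VariantRecord",
    "CohortSummary",
    "VariantTableError",
    "read_variant_table",
    "write_variant_table",
    "packaged_cohort",
    "diagnostic_yield",
    "gene_family_fraction",
    "count_novel_dcv",
    "cohort_summary",
]

ZYGOSITIES = ("het", "hom", "hemi")
ACMG_CLASSES = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")
INHERITANCES = ("AD", "AR", "XLD")

# gene-level syntactic check of an HGVS cDNA string, e.g. c.92T>C,
# c.588+1del, c.1259_1260insAG, c.103-3T>C, c.-132T>C
_HGVS_C = re.compile(
    r"^c\.[-*]?\d+[0-9_+\-*]*"
    r"(?:[ACGTacgt]+>[ACGTacgt]+|del(?:ins)?[ACGTacgt]*|ins[ACGTacgt]+|dup[ACGTacgt]*)?$"
)


class VariantTableError(ValueError):
    """Raised for malformed or inconsistent variant tables."""


@dataclass(frozen=True)
class VariantRecord:
    """One patient × variant row.

    ``gene is None`` marks an enrolment-only row: the patient is part of
    the cohort but carries no reportable variant.
    """

    patient_id: str
    family_id: str
    gene: str | None = None
    transcript: str | None = None
    cdna_change: str | None = None
    zygosity: str | None = None
    protein_outcome: str | None = None
    acmg_class: str | None = None
    novel: bool = False
    conclusive: bool = False
    inheritance: str | None = None

    def __post_init__(self) -> None:
        if self.gene is None:
            if self.conclusive:
                raise VariantTableError(
                    f"{self.patient_id}: enrolment-only row cannot be conclusive")
            return
        if self.zygosity not in ZYGOSITIES:
            raise VariantTableError(
                f"{self.patient_id}/{self.gene}: invalid zygosity {self.zygosity!r}")
        if self.acmg_class not in ACMG_CLASSES:
            raise VariantTableError(
                f"{self.patient_id}/{self.gene}: invalid ACMG class {self.acmg_class!r}")
        if self.cdna_change and not _HGVS_C.match(self.cdna_change):
            raise VariantTableError(
                f"{self.patient_id}/{self.gene}: unparseable HGVS string "
                f"{self.cdna_change!r}")
        if self.conclusive and self.acmg_class not in ("pathogenic", "likely_pathogenic"):
            raise VariantTableError(
                f"{self.patient_id}/{self.gene}: conclusive rows must be "
                f"pathogenic or likely pathogenic, got {self.acmg_class!r}")
        if self.inheritance is not None and self.inheritance not in INHERITANCES:
            raise VariantTableError(
                f"{self.patient_id}/{self.gene}: invalid inheritance "
                f"{self.inheritance!r}")


REQUIRED_COLUMNS = ["patient_id", "family_id", "gene", "transcript", "cdna_change",
                    "zygosity", "protein_outcome", "acmg_class", "novel",
                    "conclusive", "inheritance"]


def _parse_bool(v, row: int, col: str) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "", "nan"):
        return False
    raise VariantTableError(f"row {row}: cannot parse {col}={v!r} as boolean")


def read_variant_table(path) -> list[VariantRecord]:
    """Read and validate a variant CSV; malformed rows raise with a
    row-level message, duplicate (patient, variant) rows are rejected."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"missing required columns: {missing}")
    records: list[VariantRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        def opt(v):
            v = str(v).strip()
            return v or None

        try:
            rec = VariantRecord(
                patient_id=str(row.patient_id).strip(),
                family_id=str(row.family_id).strip(),
                gene=opt(row.gene),
                transcript=opt(row.transcript),
                cdna_change=opt(row.cdna_change),
                zygosity=opt(row.zygosity),
                protein_outcome=opt(row.protein_outcome),
                acmg_class=opt(row.acmg_class),
                novel=_parse_bool(row.novel, i, "novel"),
                conclusive=_parse_bool(row.conclusive, i, "conclusive"),
                inheritance=opt(row.inheritance),
            )
        except VariantTableError as e:
            raise VariantTableError(f"row {i}: {e}") from None
        key = (rec.patient_id, rec.gene, rec.cdna_change)
        if rec.gene is not None and key in seen:
            raise VariantTableError(
                f"row {i}: duplicate (patient, variant) entry {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_variant_table(records: list[VariantRecord], path) -> None:
    rows = []
    for r in records:
        d = asdict(r)
        d = {k: ("" if v is None else v) for k, v in d.items()}
        rows.append(d)
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)


def packaged_cohort() -> list[VariantRecord]:
    """The packaged digitization of the published variant tables
    (24 patients, 20 families)."""
    with resources.as_file(
        resources.files("enamelmetrics.data") / "ai_cohort_variants.csv"
    ) as p:
        return read_variant_table(p)


# ---------------------------------------------------------------------------
# yield arithmetic
# ---------------------------------------------------------------------------

def _conclusive_patients(records: list[VariantRecord]) -> set[str]:
    return {r.patient_id for r in records if r.conclusive}


def diagnostic_yield(records: list[VariantRecord], n_patients: int) -> float:
    """Fraction of patients with at least one conclusive variant."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    diagnosed = _conclusive_patients(records)
    if len(diagnosed) > n_patients:
        raise VariantTableError(
            f"{len(diagnosed)} conclusively diagnosed patients exceed the "
            f"declared cohort size {n_patients}")
    return len(diagnosed) / n_patients


def gene_family_fraction(records: list[VariantRecord], gene: str,
                         n_families: int) -> float:
    """Fraction of families carrying a conclusive variant in *gene*."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    known = {r.gene for r in records if r.gene}
    if gene not in known:
        warnings.warn(f"gene {gene!r} not present in the table", stacklevel=2)
        return 0.0
    fams = {r.family_id for r in records if r.conclusive and r.gene == gene}
    return len(fams) / n_families


def count_novel_dcv(records: list[VariantRecord]) -> int:
    """Number of distinct novel conclusive variants, deduplicated by
    (gene, cDNA change)."""
    return len({(r.gene, r.cdna_change) for r in records if r.conclusive and r.novel})


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_families: int
    dcv_patient_fraction: float
    non_conclusive_fraction: float
    gene_family_fractions: dict
    n_novel_dcv: int


def cohort_summary(records: list[VariantRecord],
                   n_patients: int | None = None,
                   n_families: int | None = None) -> CohortSummary:
    """Full yield summary; cohort sizes default to the distinct patient and
    family ids present in the table."""
    if n_patients is None:
        n_patients = len({r.patient_id for r in records})
    if n_families is None:
        n_families = len({r.family_id for r in records})
    genes = sorted({r.gene for r in records if r.conclusive and r.gene})
    dy = diagnostic_yield(records, n_patients)
    return CohortSummary(
        n_patients=n_patients,
        n_families=n_families,
        dcv_patient_fraction=dy,
        non_conclusive_fraction=1.0 - dy,
        gene_family_fractions={g: gene_family_fraction(records, g, n_families)
                               for g in genes},
        n_novel_dcv=count_novel_dcv(records),
    )
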