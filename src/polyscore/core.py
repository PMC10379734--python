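"""Core containers: variant records, dosage panels, cohort-table validation.

Dosages are stored as an ``n_individuals x n_variants`` float matrix with
``numpy.nan`` as the missing sentinel; every non-missing entry is the integer
count (0/1/2) of the variant's *effect allele* carried by the individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

SEX_LEVELS = ("man", "woman")
ETHNICITY_LEVELS = ("Russian", "Tatar", "Udmurt", "mixed")
INCOME_LEVELS = ("lower-than-average", "average-and-higher")
PBI_SCALES = ("maternal_care", "maternal_protection", "paternal_care", "paternal_protection")
PBI_CAT_LEVELS = ("high", "low")

#: Columns a cohort table must carry (pbi categorical columns are derived).
COHORT_REQUIRED_COLUMNS = (
    "sample_id",
    "depression",
    "sex",
    "age",
    "ethnicity",
    "income",
    "full_family",
    "maltreatment",
) + PBI_SCALES

BDI_RANGE = (0, 63)


class PanelError(ValueError):
    """Raised for malformed genotype panels or variant metadata."""


class CohortError(ValueError):
    """Raised for malformed cohort tables."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic panel SNP.

    ``locus_label`` is the gene symbol used to group variants for LD-proxy
    pruning; ``eaf`` is the (target or observed) effect-allele frequency and
    is annotation only — dosage matrices are authoritative for realized
    frequencies.
    """

    variant_id: str
    locus_label: str
    chrom: str
    pos: int
    effect_allele: str
    non_effect_allele: str
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.non_effect_allele not in VALID_BASES:
            raise PanelError(
                f"{self.variant_id}: alleles must be single bases, got "
                f"{self.effect_allele!r}/{self.non_effect_allele!r}"
            )
        if self.effect_allele == self.non_effect_allele:
            raise PanelError(f"{self.variant_id}: effect and non-effect allele are identical")
        if self.pos <= 0:
            raise PanelError(f"{self.variant_id}: position must be positive (1-based)")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise PanelError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")

    def flipped(self) -> "VariantRecord":
        """Return the record with effect/non-effect alleles exchanged."""
        return replace(
            self,
            effect_allele=self.non_effect_allele,
            non_effect_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class GenotypePanel:
    """Ordered variant list plus an effect-allele dosage matrix."""

    variants: list[VariantRecord]
    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise PanelError("dosage matrix must be 2-dimensional")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise PanelError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != n:
            raise PanelError("sample_ids are not unique")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != m:
            raise PanelError("variant_ids are not unique")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise PanelError("non-missing dosages must be 0, 1 or 2")

    # -- lookups -----------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def index_of(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise PanelError(f"variant {variant_id!r} not in panel") from None

    def variant(self, variant_id: str) -> VariantRecord:
        return self.variants[self.index_of(variant_id)]

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    # -- summaries ---------------------------------------------------------

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def observed_eaf(self) -> np.ndarray:
        """Per-variant realized effect-allele frequency among called genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def genotype_counts(self, variant_id: str) -> tuple[int, int, int]:
        """(hom effect, het, hom non-effect) counts for one variant."""
        x = self.dosage_of(variant_id)
        return (
            int(np.nansum(x == 2.0)),
            int(np.nansum(x == 1.0)),
            int(np.nansum(x == 0.0)),
        )

    # -- transforms --------------------------------------------------------

    def subset(self, variant_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.index_of(v) for v in variant_ids]
        return GenotypePanel(
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
            sample_ids=list(self.sample_ids),
        )

    def flip(self, variant_ids: Iterable[str]) -> "GenotypePanel":
        """Re-orient the listed variants to the opposite allele (x -> 2 - x)."""
        flip_set = set(variant_ids)
        variants = []
        dosages = self.dosages.copy()
        for j, v in enumerate(self.variants):
            if v.variant_id in flip_set:
                variants.append(v.flipped())
                dosages[:, j] = 2.0 - dosages[:, j]
                flip_set.discard(v.variant_id)
            else:
                variants.append(v)
        if flip_set:
            raise PanelError(f"cannot flip absent variants: {sorted(flip_set)}")
        return GenotypePanel(variants=variants, dosages=dosages, sample_ids=list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        """Samples x variants dosage DataFrame (NaN = missing)."""
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.variant_ids)


# ---------------------------------------------------------------------------
# Parental Bonding Instrument dichotomization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PBICutoffs:
    """Cut-off scores splitting each PBI scale into high/low.

    A score greater than or equal to the cut-off is assigned to "high";
    the boundary rule is fixed so categorization is deterministic.
    """

    maternal_care: float = 27.0
    maternal_protection: float = 13.5
    paternal_care: float = 24.0
    paternal_protection: float = 12.5

    def for_scale(self, scale: str) -> float:
        if scale not in PBI_SCALES:
            raise CohortError(f"unknown PBI scale {scale!r}")
        return getattr(self, scale)


def categorize_pbi(cohort: pd.DataFrame, cutoffs: PBICutoffs | None = None) -> pd.DataFrame:
    """Append ``<scale>_cat`` high/low columns derived from the raw PBI scores."""
    cutoffs = cutoffs or PBICutoffs()
    out = cohort.copy()
    for scale in PBI_SCALES:
        if scale not in out.columns:
            raise CohortError(f"cohort table lacks PBI column {scale!r}")
        raw = pd.to_numeric(out[scale], errors="raise")
        out[f"{scale}_cat"] = np.where(raw >= cutoffs.for_scale(scale), "high", "low")
    return out


def validate_cohort(
    cohort: pd.DataFrame,
    age_range: tuple[float, float] = (10.0, 90.0),
    allow_missing_depression: bool = True,
) -> pd.DataFrame:
    """Validate levels and ranges of a cohort table; returns the table.

    Rows with missing depression are retained but flagged in a boolean
    ``depression_missing`` column (analysis stages drop them listwise).
    """
    missing_cols = [c for c in COHORT_REQUIRED_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise CohortError(f"cohort table missing required columns: {missing_cols}")
    if len(cohort) == 0:
        raise CohortError("cohort table has no rows")
    if cohort["sample_id"].duplicated().any():
        dupes = cohort.loc[cohort["sample_id"].duplicated(), "sample_id"].tolist()
        raise CohortError(f"duplicate sample_ids: {dupes}")

    for col, levels in (("sex", SEX_LEVELS), ("ethnicity", ETHNICITY_LEVELS), ("income", INCOME_LEVELS)):
        bad = set(cohort[col].dropna()) - set(levels)
        if bad:
            raise CohortError(f"unknown {col} level(s): {sorted(bad)}")

    dep = pd.to_numeric(cohort["depression"], errors="coerce")
    dep_missing = dep.isna()
    if dep_missing.any() and not allow_missing_depression:
        raise CohortError("missing depression scores not allowed")
    observed = dep[~dep_missing]
    if ((observed < BDI_RANGE[0]) | (observed > BDI_RANGE[1])).any():
        bad_rows = cohort.loc[(dep < BDI_RANGE[0]) | (dep > BDI_RANGE[1]), "sample_id"].tolist()
        raise CohortError(f"depression outside BDI range {BDI_RANGE} for samples {bad_rows}")
    if (observed != observed.round()).any():
        raise CohortError("depression scores must be integers")

    age = pd.to_numeric(cohort["age"], errors="coerce")
    if ((age < age_range[0]) | (age > age_range[1])).any():
        raise CohortError(f"age outside plausible range {age_range}")

    out = cohort.copy()
    out["depression_missing"] = dep_missing.to_numpy()
    return out
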