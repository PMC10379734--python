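"""Readers and writers for the pipeline's external formats.

Supported genotype dialects:

* ``dosage_tsv`` — the native interchange format: one row per variant with
  metadata columns followed by one dosage column per sample ('.' = missing).
* ``vcf`` — minimal VCF 4.x with GT genotypes (read via cyvcf2); biallelic
  SNPs only.
* ``plink_text`` — PLINK-text .ped/.map pairs ('0' = missing allele).

Positions are 1-based throughout and no strand complementation happens at
read time — allele harmonization is the scoring module's job.
"""

from __future__ import annotations

import os
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    CohortError,
    COHORT_REQUIRED_COLUMNS,
    GenotypePanel,
    PanelError,
    PBICutoffs,
    VariantRecord,
    VALID_BASES,
    categorize_pbi,
    validate_cohort,
)

MISSING_TOKENS = {".", "", "NA", "nan"}

_DOSAGE_META_COLS = ["variant_id", "locus_label", "chrom", "pos", "effect_allele", "non_effect_allele", "eaf"]


class WeightFileRecord(NamedTuple):
    """One row of an external-weights TSV (beta signed, as published)."""

    variant_id: str
    effect_allele: str
    non_effect_allele: str
    beta: float


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# genotype panels
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | os.PathLike,
    format: str = "dosage_tsv",
    effect_allele_policy: str = "minor_allele",
    weights: Sequence[WeightFileRecord] | None = None,
) -> GenotypePanel:
    """Read a genotype panel and orient dosages to the designated effect allele.

    ``effect_allele_policy`` applies to VCF and PLINK-text input, whose records
    do not name an effect allele: ``minor_allele`` designates the minor allele
    (ties broken toward the ALT / first-seen allele), ``from_weights`` takes the
    orientation from a supplied weights list and rejects allele mismatches.
    The dosage TSV stores its orientation explicitly and is read verbatim.
    """
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    if format == "vcf":
        panel = _read_vcf(path)
    elif format == "plink_text":
        panel = _read_plink_text(path)
    else:
        raise FormatError(f"unknown genotype format {format!r}")
    return _apply_effect_allele_policy(panel, effect_allele_policy, weights)


def _apply_effect_allele_policy(
    panel: GenotypePanel, policy: str, weights: Sequence[WeightFileRecord] | None
) -> GenotypePanel:
    if policy == "minor_allele":
        eaf = panel.observed_eaf()
        to_flip = [v.variant_id for v, f in zip(panel.variants, eaf) if np.isfinite(f) and f > 0.5]
        return panel.flip(to_flip)
    if policy == "from_weights":
        if weights is None:
            raise FormatError("effect_allele_policy='from_weights' requires a weights list")
        by_id = {w.variant_id: w for w in weights}
        to_flip, mismatched = [], []
        for v in panel.variants:
            w = by_id.get(v.variant_id)
            if w is None:
                continue
            if (w.effect_allele, w.non_effect_allele) == (v.effect_allele, v.non_effect_allele):
                continue
            if (w.effect_allele, w.non_effect_allele) == (v.non_effect_allele, v.effect_allele):
                to_flip.append(v.variant_id)
            else:
                mismatched.append(v.variant_id)
        if mismatched:
            raise FormatError(f"allele mismatch with weights file for variants: {mismatched}")
        return panel.flip(to_flip)
    raise FormatError(f"unknown effect_allele_policy {policy!r}")


def _read_dosage_tsv(path: str | os.PathLike) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) <= len(_DOSAGE_META_COLS):
        raise FormatError(f"{path}: no variants in dosage TSV")
    missing = [c for c in _DOSAGE_META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: dosage TSV lacks columns {missing}")
    sample_ids = [c for c in df.columns if c not in _DOSAGE_META_COLS]
    if not sample_ids:
        raise FormatError(f"{path}: dosage TSV has no sample columns")
    variants = []
    for _, row in df.iterrows():
        eaf_tok = row["eaf"]
        variants.append(
            VariantRecord(
                variant_id=row["variant_id"],
                locus_label=row["locus_label"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                effect_allele=row["effect_allele"],
                non_effect_allele=row["non_effect_allele"],
                eaf=None if eaf_tok in MISSING_TOKENS else float(eaf_tok),
            )
        )
    raw = df[sample_ids].to_numpy(dtype=object).T  # samples x variants
    dosages = np.full(raw.shape, np.nan)
    for (i, j), tok in np.ndenumerate(raw):
        if tok not in MISSING_TOKENS:
            dosages[i, j] = float(tok)
    return GenotypePanel(variants=variants, dosages=dosages, sample_ids=sample_ids)


def write_genotypes(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Write the native dosage TSV (deterministic column order, '.' = missing)."""
    rows = []
    for j, v in enumerate(panel.variants):
        row = {
            "variant_id": v.variant_id,
            "locus_label": v.locus_label,
            "chrom": v.chrom,
            "pos": v.pos,
            "effect_allele": v.effect_allele,
            "non_effect_allele": v.non_effect_allele,
            "eaf": "." if v.eaf is None else repr(float(v.eaf)),
        }
        for i, sid in enumerate(panel.sample_ids):
            x = panel.dosages[i, j]
            row[sid] = "." if np.isnan(x) else str(int(x))
        rows.append(row)
    pd.DataFrame(rows, columns=_DOSAGE_META_COLS + list(panel.sample_ids)).to_csv(
        path, sep="\t", index=False
    )


def _read_vcf(path: str | os.PathLike) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    variants, columns = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(f"multi-allelic record {rec.ID or f'{rec.CHROM}:{rec.POS}'} not supported")
        ref, alt = rec.REF, rec.ALT[0]
        if ref not in VALID_BASES or alt not in VALID_BASES:
            raise FormatError(f"{rec.ID}: only single-base SNP alleles supported ({ref}/{alt})")
        try:
            locus = rec.INFO.get("GENE") or ""
        except Exception:
            locus = ""
        variants.append(
            VariantRecord(
                variant_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                locus_label=locus,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                effect_allele=alt,  # ALT-oriented on read; policy re-orients after
                non_effect_allele=ref,
            )
        )
        gts = np.asarray(rec.gt_types, dtype=float)  # 0/1/2 = ALT count, 3 = missing
        gts[gts == 3] = np.nan
        columns.append(gts)
    if not variants:
        raise FormatError(f"{path}: VCF contains no variant records")
    return GenotypePanel(variants=variants, dosages=np.column_stack(columns), sample_ids=sample_ids)


def _read_plink_text(path: str | os.PathLike) -> GenotypePanel:
    """Read a PLINK-text fileset given either the .ped or the .map path."""
    base, ext = os.path.splitext(str(path))
    if ext not in {".ped", ".map"}:
        base = str(path)
    ped_path, map_path = base + ".ped", base + ".map"
    for p in (ped_path, map_path):
        if not os.path.exists(p):
            raise FormatError(f"PLINK-text fileset incomplete: {p} not found")

    map_df = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if map_df.shape[1] not in (3, 4):
        raise FormatError(f"{map_path}: expected 3 or 4 columns, got {map_df.shape[1]}")
    has_cm = map_df.shape[1] == 4
    chroms = map_df[0].tolist()
    ids = map_df[1].tolist()
    positions = map_df[3 if has_cm else 2].astype(int).tolist()
    m = len(ids)

    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    if ped.shape[1] != 6 + 2 * m:
        raise FormatError(
            f"{ped_path}: expected {6 + 2 * m} columns for {m} map variants, got {ped.shape[1]}"
        )
    sample_ids = ped[1].tolist()
    allele_cols = ped.iloc[:, 6:].to_numpy(dtype=object)

    variants, dosage_cols = [], []
    for j in range(m):
        a1 = allele_cols[:, 2 * j]
        a2 = allele_cols[:, 2 * j + 1]
        called = (a1 != "0") & (a2 != "0")
        seen = sorted(set(a1[called]) | set(a2[called]))
        bad = [b for b in seen if b not in VALID_BASES]
        if bad:
            raise FormatError(f"{ids[j]}: non-SNP alleles {bad}")
        if len(seen) > 2:
            raise FormatError(f"multi-allelic record {ids[j]} not supported")
        if len(seen) == 0:
            raise FormatError(f"{ids[j]}: all genotypes missing, alleles unknown")
        if len(seen) == 1:  # monomorphic: invent the complement so the record is well-formed
            other = next(b for b in "ACGT" if b != seen[0])
            seen = [seen[0], other]
        counted, alt = seen[0], seen[1]
        x = np.where(called, (a1 == counted).astype(float) + (a2 == counted).astype(float), np.nan)
        variants.append(
            VariantRecord(
                variant_id=ids[j],
                locus_label="",
                chrom=chroms[j],
                pos=positions[j],
                effect_allele=counted,
                non_effect_allele=alt,
            )
        )
        dosage_cols.append(x)
    return GenotypePanel(variants=variants, dosages=np.column_stack(dosage_cols), sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


def read_cohort_table(
    path: str | os.PathLike,
    pbi_cutoffs: PBICutoffs | None = None,
    age_range: tuple[float, float] = (10.0, 90.0),
) -> pd.DataFrame:
    """Read, validate and PBI-categorize a cohort TSV.

    Rows with missing depression are retained and flagged; any other
    validation failure raises :class:`~polyscore.core.CohortError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", na_values=sorted(MISSING_TOKENS), keep_default_na=True)
    except pd.errors.EmptyDataError:
        raise CohortError(f"{path}: empty cohort file") from None
    if len(df) == 0:
        raise CohortError(f"{path}: cohort file has a header but no rows")
    df = validate_cohort(df, age_range=age_range)
    df["full_family"] = df["full_family"].astype(int)
    df["maltreatment"] = df["maltreatment"].astype(int)
    return categorize_pbi(df, pbi_cutoffs)


def write_cohort_table(cohort: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in COHORT_REQUIRED_COLUMNS if c in cohort.columns]
    extra = [c for c in cohort.columns if c not in cols and not c.endswith("_cat") and c != "depression_missing"]
    cohort[cols + extra].to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# weight files
# ---------------------------------------------------------------------------


def read_weights(path: str | os.PathLike) -> list[WeightFileRecord]:
    """Read a weights TSV (variant_id, effect_allele, non_effect_allele, beta)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: weights file is empty (header required)") from None
    required = ["variant_id", "effect_allele", "non_effect_allele", "beta"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: weights TSV lacks columns {missing}")
    records: list[WeightFileRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        vid = row["variant_id"]
        if vid in seen:
            raise FormatError(f"{path}: duplicate variant_id {vid!r}")
        seen.add(vid)
        for col in ("effect_allele", "non_effect_allele"):
            if row[col] not in VALID_BASES:
                raise FormatError(f"{path} row {i + 1} ({vid}): allele {row[col]!r} is not a single base")
        try:
            beta = float(row["beta"])
        except ValueError:
            raise FormatError(f"{path} row {i + 1} ({vid}): non-numeric beta {row['beta']!r}") from None
        if not np.isfinite(beta):
            raise FormatError(f"{path} row {i + 1} ({vid}): beta must be finite")
        records.append(WeightFileRecord(vid, row["effect_allele"], row["non_effect_allele"], beta))
    return records


def write_weights(records: Sequence[WeightFileRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(records, columns=["variant_id", "effect_allele", "non_effect_allele", "beta"]).to_csv(
        path, sep="\t", index=False
    )
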