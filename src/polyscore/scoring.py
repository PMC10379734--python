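"""Polygenic-score weight sets and individual scoring.

A score is the weighted sum of per-variant scoring-allele dosages,
``PGS = sum_i w_i * x_i``. Negative published effects are recoded to the
opposite allele: a term ``beta * x`` with ``beta < 0`` becomes
``|beta| * (2 - x)``, so every stored weight is non-negative and the score
always counts risk-increasing alleles. The recoding shifts each score by the
constant ``sum_{beta<0} 2|beta|`` relative to the naive signed sum and leaves
every downstream regression fit unchanged.

External summary-statistic weights are harmonized to the panel orientation
(allele swap -> negate beta; strand complement where needed; A/T and C/G
strand-ambiguous variants dropped by default) before the same recoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import GenotypePanel, PanelError
from .io import WeightFileRecord

__all__ = ["WeightEntry", "WeightSet", "build_weights", "harmonize_external_weights", "score_individuals"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ScoringError(ValueError):
    pass


class WeightEntry(NamedTuple):
    variant_id: str
    scoring_allele: str
    weight: float


@dataclass
class WeightSet:
    """Non-negative scoring weights with provenance."""

    entries: list[WeightEntry]
    mode: str  # "weighted" | "unweighted"
    provenance: str  # "in_sample" | "external"
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("weighted", "unweighted"):
            raise ScoringError(f"unknown mode {self.mode!r}")
        if self.provenance not in ("in_sample", "external"):
            raise ScoringError(f"unknown provenance {self.provenance!r}")
        ids = [e.variant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ScoringError("duplicate variant_ids in weight set")
        for e in self.entries:
            if not np.isfinite(e.weight) or e.weight < 0:
                raise ScoringError(f"{e.variant_id}: weight must be finite and >= 0, got {e.weight}")
            if self.mode == "unweighted" and e.weight not in (0.0, 1.0):
                raise ScoringError(f"{e.variant_id}: unweighted mode requires unit weights")

    @property
    def variant_ids(self) -> list[str]:
        return [e.variant_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["variant_id", "scoring_allele", "weight"])


def build_weights(assoc: pd.DataFrame, mode: str = "weighted", provenance: str = "in_sample",
                  source_label: str = "") -> WeightSet:
    """Turn an association table into a recoded, non-negative weight set.

    Positive beta scores the effect allele with weight |beta|; negative beta
    scores the non-effect allele with weight |beta|. Unweighted mode applies
    the same allele orientation with unit weights.
    """
    if len(assoc) == 0:
        raise ScoringError("association table is empty")
    undefined = assoc.loc[~np.isfinite(pd.to_numeric(assoc["beta"], errors="coerce")), "variant_id"]
    if len(undefined):
        raise ScoringError(f"undefined beta for variants: {undefined.tolist()}")
    entries = []
    for _, row in assoc.iterrows():
        beta = float(row["beta"])
        if beta == 0.0:
            warnings.warn(f"{row['variant_id']}: beta is exactly 0; scoring the effect allele "
                          "with zero weight", stacklevel=2)
            allele = row["effect_allele"]
        else:
            allele = row["effect_allele"] if beta > 0 else row["non_effect_allele"]
        weight = abs(beta) if mode == "weighted" else (1.0 if beta != 0.0 else 0.0)
        entries.append(WeightEntry(row["variant_id"], allele, weight))
    return WeightSet(entries=entries, mode=mode, provenance=provenance, source_label=source_label)


def harmonize_external_weights(
    raw: Sequence[WeightFileRecord],
    panel: GenotypePanel,
    mode: str = "weighted",
    drop_strand_ambiguous: bool = True,
    source_label: str = "external",
) -> tuple[WeightSet, pd.DataFrame]:
    """Align published weights to panel allele orientation, then recode.

    Per variant the action is one of: ``match`` (orientation identical),
    ``swap`` (alleles exchanged -> beta negated), ``flip`` (strand complement),
    ``flip_swap``, ``dropped_ambiguous`` (A/T, C/G pairs under the default
    policy), ``dropped_mismatch`` (alleles irreconcilable) or
    ``dropped_absent`` (variant not on the panel). The returned log records
    one row per input weight.
    """
    panel_by_id = {v.variant_id: v for v in panel.variants}
    log_rows = []
    harmonized = []
    for rec in raw:
        row = {"variant_id": rec.variant_id, "beta_in": rec.beta, "action": "", "beta_out": np.nan,
               "scoring_allele": ""}
        v = panel_by_id.get(rec.variant_id)
        if v is None:
            row["action"] = "dropped_absent"
            log_rows.append(row)
            continue
        if drop_strand_ambiguous and rec.effect_allele == _COMPLEMENT[rec.non_effect_allele]:
            row["action"] = "dropped_ambiguous"
            log_rows.append(row)
            continue
        pair = (rec.effect_allele, rec.non_effect_allele)
        flipped = (_COMPLEMENT[rec.effect_allele], _COMPLEMENT[rec.non_effect_allele])
        panel_pair = (v.effect_allele, v.non_effect_allele)
        if pair == panel_pair:
            action, beta = "match", rec.beta
        elif pair == panel_pair[::-1]:
            action, beta = "swap", -rec.beta
        elif flipped == panel_pair:
            action, beta = "flip", rec.beta
        elif flipped == panel_pair[::-1]:
            action, beta = "flip_swap", -rec.beta
        else:
            row["action"] = "dropped_mismatch"
            log_rows.append(row)
            continue
        row["action"] = action
        row["beta_out"] = beta
        # recoding toward a non-negative weight, in panel orientation
        if beta >= 0:
            allele = v.effect_allele
        else:
            allele = v.non_effect_allele
        row["scoring_allele"] = allele
        weight = abs(beta) if mode == "weighted" else (1.0 if beta != 0.0 else 0.0)
        harmonized.append(WeightEntry(rec.variant_id, allele, weight))
        log_rows.append(row)
    if not harmonized:
        raise ScoringError("no scorable variants after harmonization")
    ws = WeightSet(entries=harmonized, mode=mode, provenance="external", source_label=source_label)
    return ws, pd.DataFrame(log_rows)


def score_individuals(
    panel: GenotypePanel,
    weights: WeightSet,
    missing_policy: str = "mean_dosage",
) -> pd.DataFrame:
    """Score every individual: ``sample_id, pgs, n_variants_used``.

    The dosage entering each term counts the entry's scoring allele (``2 - x``
    when it is the panel's non-effect allele). Missing genotypes are replaced
    by the variant's cohort-mean scoring-allele dosage (``mean_dosage``) or
    the term is omitted (``skip``); ``n_variants_used`` counts the variants
    with an observed genotype either way.
    """
    if missing_policy not in ("mean_dosage", "skip"):
        raise ScoringError(f"unknown missing_policy {missing_policy!r}")
    cols = []
    used_entries = []
    for entry in weights.entries:
        try:
            j = panel.index_of(entry.variant_id)
        except PanelError:
            warnings.warn(f"weight variant {entry.variant_id} absent from panel; excluded",
                          stacklevel=2)
            continue
        v = panel.variants[j]
        x = panel.dosages[:, j]
        if entry.scoring_allele == v.effect_allele:
            pass
        elif entry.scoring_allele == v.non_effect_allele:
            x = 2.0 - x
        else:
            raise ScoringError(
                f"{entry.variant_id}: scoring allele {entry.scoring_allele!r} matches neither "
                f"panel allele ({v.effect_allele}/{v.non_effect_allele})"
            )
        cols.append(x)
        used_entries.append(entry)
    if not cols:
        raise ScoringError("no weight variants present in panel")

    dos = np.column_stack(cols)
    w = np.array([e.weight for e in used_entries])
    observed = ~np.isnan(dos)
    n_used = observed.sum(axis=1)
    if missing_policy == "mean_dosage":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
            col_means = np.nanmean(dos, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        filled = np.where(observed, dos, col_means[None, :])
        pgs = filled @ w
    else:
        pgs = np.where(observed, dos, 0.0) @ w
    return pd.DataFrame({"sample_id": panel.sample_ids, "pgs": pgs, "n_variants_used": n_used})
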