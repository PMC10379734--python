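"""Variant-level quality control: call rate, MAF, Hardy-Weinberg, LD pruning.

The HWE test is the exact conditional test (all heterozygote counts
compatible with the observed allele counts are enumerated and every genotype
configuration no more probable than the observed one contributes to the
two-sided p). LD between variants sharing a locus label is the
haplotype-frequency r-squared, with haplotype frequencies estimated from
unphased genotypes by expectation-maximization — the estimand PLINK-style
pruning uses; a genotype-correlation estimator is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import lgamma, log, exp
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import GenotypePanel, PanelError

__all__ = ["hwe_exact_test", "hwe_chisq_test", "ld_r2", "run_qc", "QcReport"]

_REL_EPS = 1.0 + 1e-12  # guards the "<= observed probability" comparison


class QcError(ValueError):
    pass


def _log_het_prob(n_het: int, n: int, n_eff: int) -> float:
    """Log conditional probability of ``n_het`` heterozygotes given allele counts.

    P(h | n, n_eff) = C * n! / (n_hom_eff! h! n_hom_oth!) * 2^h, the random
    union-of-gametes distribution conditioned on 2n alleles of which n_eff are
    the effect allele.
    """
    n_hom_eff = (n_eff - n_het) // 2
    n_hom_oth = n - n_hom_eff - n_het
    return (
        lgamma(n + 1)
        - lgamma(n_hom_eff + 1)
        - lgamma(n_het + 1)
        - lgamma(n_hom_oth + 1)
        + n_het * log(2.0)
        + lgamma(n_eff + 1)
        + lgamma(2 * n - n_eff + 1)
        - lgamma(2 * n + 1)
    )


def hwe_exact_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value from genotype counts."""
    for c in (n_hom_effect, n_het, n_hom_other):
        if c < 0 or c != int(c):
            raise QcError("genotype counts must be non-negative integers")
    n = n_hom_effect + n_het + n_hom_other
    if n < 1:
        raise QcError("at least one genotyped individual required")
    n_eff = 2 * n_hom_effect + n_het
    n_oth = 2 * n - n_eff
    if n_eff == 0 or n_oth == 0:
        return 1.0  # monomorphic: a single compatible configuration

    h_min = n_eff % 2
    h_max = min(n_eff, n_oth)
    hs = range(h_min, h_max + 1, 2)
    log_probs = {h: _log_het_prob(h, n, n_eff) for h in hs}
    obs = log_probs[n_het]
    p = sum(exp(lp) for lp in log_probs.values() if exp(lp) <= exp(obs) * _REL_EPS)
    return min(1.0, p)


def hwe_chisq_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """One-degree-of-freedom chi-square HWE test (no continuity correction)."""
    n = n_hom_effect + n_het + n_hom_other
    if n < 1:
        raise QcError("at least one genotyped individual required")
    p = (2 * n_hom_effect + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_effect, n_het, n_hom_other], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# LD r-squared
# ---------------------------------------------------------------------------


def _em_r2(x: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> float:
    """Haplotype-frequency r2 from two unphased dosage vectors (no missing)."""
    n = x.size
    p_a = x.mean() / 2.0
    p_b = y.mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        warnings.warn("monomorphic variant in LD computation; r2 defined as 0", stacklevel=3)
        return 0.0
    # 3x3 genotype table, indices = effect-allele dosage at each locus
    table = np.zeros((3, 3))
    for i, j in zip(x.astype(int), y.astype(int)):
        table[i, j] += 1

    # haplotypes: AB, Ab, aB, ab; only the double heterozygote is phase-ambiguous
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    n_dh = table[1, 1]
    # unambiguous haplotype counts contributed by the eight other cells
    base = np.zeros(4)
    base[0] = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    base[1] = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    base[2] = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    base[3] = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        frac = 0.5 if cis + trans == 0 else cis / (cis + trans)
        counts = base + n_dh * np.array([frac, 1 - frac, 1 - frac, frac])
        new_f = counts / (2.0 * n)
        if np.abs(new_f - f).max() < tol:
            f = new_f
            break
        f = new_f
    pa = f[0] + f[1]
    pb = f[0] + f[2]
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return 0.0
    d = f[0] - pa * pb
    return float(min(1.0, d * d / denom))


def ld_r2(panel: GenotypePanel, variant_a: str, variant_b: str, method: str = "em") -> float:
    """Pairwise LD r-squared between two panel variants.

    ``method='em'`` (default) is the haplotype-frequency r2 from EM over
    unphased genotypes; ``method='corr'`` is the squared Pearson correlation
    of dosages. Individuals missing either genotype are excluded.
    """
    x = panel.dosage_of(variant_a)
    y = panel.dosage_of(variant_b)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        raise QcError(f"fewer than 2 individuals genotyped at both {variant_a} and {variant_b}")
    x, y = x[ok], y[ok]
    if variant_a == variant_b:
        return 1.0
    if method == "em":
        return _em_r2(x, y)
    if method == "corr":
        if x.std() == 0 or y.std() == 0:
            warnings.warn("monomorphic variant in LD computation; r2 defined as 0", stacklevel=2)
            return 0.0
        return float(np.corrcoef(x, y)[0, 1] ** 2)
    raise QcError(f"unknown LD method {method!r}")


# ---------------------------------------------------------------------------
# the QC pipeline
# ---------------------------------------------------------------------------

STATUS_KEPT = "kept"
STATUS_CALLRATE = "dropped_callrate"
STATUS_MAF = "dropped_maf"
STATUS_HWE = "dropped_hwe"
STATUS_PROXY = "dropped_proxy"


@dataclass
class QcReport:
    """Per-variant QC ledger; one row per input variant, statuses exclusive."""

    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def kept_ids(self) -> list[str]:
        return self.table.loc[self.table["status"] == STATUS_KEPT, "variant_id"].tolist()

    def counts(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep=".")


def run_qc(
    panel: GenotypePanel,
    call_rate_min: float = 0.98,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.05,
    proxy_r2_threshold: float = 0.2,
    proxy_keep_list: Iterable[str] | None = None,
    assoc_p: Mapping[str, float] | None = None,
    hwe_method: str = "exact",
    ld_method: str = "em",
) -> tuple[GenotypePanel, QcReport]:
    """Apply the exclusion cascade call rate -> MAF -> HWE -> LD proxies.

    MAF and HWE are computed on called genotypes of variants surviving the
    call-rate filter. The proxy step examines every variant pair sharing a
    ``locus_label``; for a pair with r2 at or above the threshold one member
    is dropped — the one named by ``proxy_keep_list`` survives, otherwise the
    member with the smaller preliminary association p (``assoc_p``), otherwise
    the earlier variant in panel order. Flagged pairs are resolved in order of
    decreasing r2.
    """
    for name, val in (
        ("call_rate_min", call_rate_min),
        ("maf_min", maf_min),
        ("hwe_alpha", hwe_alpha),
        ("proxy_r2_threshold", proxy_r2_threshold),
    ):
        if not (0.0 <= val <= 1.0):
            raise QcError(f"{name} must lie in [0, 1], got {val}")
    keep_list = set(proxy_keep_list or ())
    unknown = keep_list - set(panel.variant_ids)
    if unknown:
        raise QcError(f"proxy_keep_list names unknown variants: {sorted(unknown)}")
    hwe_test = hwe_exact_test if hwe_method == "exact" else hwe_chisq_test

    rows = {}
    call_rates = panel.call_rate()
    eafs = panel.observed_eaf()
    for j, v in enumerate(panel.variants):
        rows[v.variant_id] = {
            "variant_id": v.variant_id,
            "locus_label": v.locus_label,
            "call_rate": call_rates[j],
            "eaf": eafs[j],
            "maf": min(eafs[j], 1 - eafs[j]) if np.isfinite(eafs[j]) else np.nan,
            "hwe_p": np.nan,
            "status": STATUS_KEPT,
            "proxy_partner": None,
            "proxy_r2": np.nan,
        }

    surviving = []
    for v in panel.variants:
        row = rows[v.variant_id]
        if row["call_rate"] < call_rate_min:
            row["status"] = STATUS_CALLRATE
            continue
        surviving.append(v)

    still = []
    for v in surviving:
        row = rows[v.variant_id]
        if not np.isfinite(row["maf"]) or row["maf"] <= maf_min:
            # "MAF higher than the threshold" is the inclusion rule
            if maf_min > 0.0 or not np.isfinite(row["maf"]):
                row["status"] = STATUS_MAF
                continue
        still.append(v)
    surviving = still

    still = []
    for v in surviving:
        row = rows[v.variant_id]
        row["hwe_p"] = hwe_test(*panel.genotype_counts(v.variant_id))
        if hwe_alpha > 0.0 and row["hwe_p"] < hwe_alpha:
            row["status"] = STATUS_HWE
            continue
        still.append(v)
    surviving = still

    # proxy pruning among surviving variants sharing a locus label
    by_locus: dict[str, list] = {}
    for v in surviving:
        if v.locus_label:
            by_locus.setdefault(v.locus_label, []).append(v)
    flagged = []
    for locus, members in by_locus.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                r2 = ld_r2(panel, a.variant_id, b.variant_id, method=ld_method)
                if r2 >= proxy_r2_threshold:
                    flagged.append((r2, a.variant_id, b.variant_id))
    order = {vid: k for k, vid in enumerate(panel.variant_ids)}
    dropped: set[str] = set()
    for r2, a_id, b_id in sorted(flagged, key=lambda t: (-t[0], order[t[1]], order[t[2]])):
        if a_id in dropped or b_id in dropped:
            continue
        if a_id in keep_list and b_id in keep_list:
            raise QcError(
                f"proxy_keep_list names both members of the flagged pair ({a_id}, {b_id})"
            )
        if a_id in keep_list:
            victim = b_id
        elif b_id in keep_list:
            victim = a_id
        elif assoc_p is not None and a_id in assoc_p and b_id in assoc_p:
            victim = a_id if assoc_p[a_id] > assoc_p[b_id] else b_id
        else:
            victim = a_id if order[a_id] > order[b_id] else b_id
        partner = b_id if victim == a_id else a_id
        dropped.add(victim)
        rows[victim]["status"] = STATUS_PROXY
        rows[victim]["proxy_partner"] = partner
        rows[victim]["proxy_r2"] = r2

    kept_ids = [v.variant_id for v in surviving if v.variant_id not in dropped]
    report = QcReport(
        table=pd.DataFrame([rows[v.variant_id] for v in panel.variants]),
        thresholds={
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "hwe_alpha": hwe_alpha,
            "hwe_method": hwe_method,
            "proxy_r2_threshold": proxy_r2_threshold,
            "ld_method": ld_method,
        },
    )
    return panel.subset(kept_ids), report
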