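"""Per-SNP covariate-adjusted regression and the social-factor screen.

Each variant is tested with ordinary least squares of the depression score on
its effect-allele dosage plus sex, age and ethnicity (one-hot against a
configurable reference), the additive single-SNP model whose per-allele
coefficients later serve as in-sample PGS weights. Binary social factors are
screened with the Mann-Whitney U test against a per-test alpha/m threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

from .core import ETHNICITY_LEVELS, GenotypePanel, PBI_SCALES

__all__ = [
    "fit_snp_regression",
    "mannwhitney_screen",
    "mannwhitney_test",
    "correction_threshold",
    "benjamini_hochberg",
    "build_covariate_design",
    "DEFAULT_SCREEN_FACTORS",
]


class AssociationError(ValueError):
    pass


DEFAULT_COVARIATES = ("sex", "age", "ethnicity")

#: factor name -> (column, value coded 1, value coded 0); the screen compares
#: depression between the two groups of each binary factor.
DEFAULT_SCREEN_FACTORS: dict[str, tuple[str, object, object]] = {
    "sex": ("sex", "woman", "man"),
    "income": ("income", "lower-than-average", "average-and-higher"),
    "full_family": ("full_family", 1, 0),
    "maltreatment": ("maltreatment", 1, 0),
    **{scale: (f"{scale}_cat", "high", "low") for scale in PBI_SCALES},
}


def build_covariate_design(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    ethnicity_ref: str = "mixed",
) -> pd.DataFrame:
    """Numeric design columns for the requested covariates (no intercept).

    Sex is coded man=0 / woman=1; ethnicity expands to one-hot indicator
    columns against the reference level.
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = (cohort["sex"].to_numpy() == "woman").astype(float)
        elif cov == "age":
            cols["age"] = pd.to_numeric(cohort["age"]).to_numpy(dtype=float)
        elif cov == "ethnicity":
            for lev in ETHNICITY_LEVELS:
                if lev == ethnicity_ref:
                    continue
                cols[f"ethnicity_{lev}"] = (cohort["ethnicity"].to_numpy() == lev).astype(float)
        else:
            cols[cov] = pd.to_numeric(cohort[cov]).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index)


def fit_snp_regression(
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    ethnicity_ref: str = "mixed",
    standardize_dosage: bool = False,
) -> pd.DataFrame:
    """Additive per-SNP association scan.

    Returns one row per variant: ``variant_id, effect_allele,
    non_effect_allele, beta, se, p, n_used, note``. ``beta`` is the raw
    per-allele coefficient on the depression-score scale (z-scaled dosage
    optional via ``standardize_dosage``). Individuals missing the variant's
    genotype, the outcome, or any covariate are excluded for that variant
    only; a zero-variance dosage after exclusions is flagged with undefined
    beta.
    """
    if list(panel.sample_ids) != list(cohort["sample_id"]):
        raise AssociationError("panel and cohort sample_ids are not aligned")
    y_all = pd.to_numeric(cohort["depression"], errors="coerce").to_numpy(dtype=float)
    design = build_covariate_design(cohort, covariates, ethnicity_ref)
    cov_mat = design.to_numpy(dtype=float)
    base_ok = ~np.isnan(y_all) & ~np.isnan(cov_mat).any(axis=1)

    rows = []
    for j, v in enumerate(panel.variants):
        x = panel.dosages[:, j]
        ok = base_ok & ~np.isnan(x)
        n_used = int(ok.sum())
        row = {
            "variant_id": v.variant_id,
            "effect_allele": v.effect_allele,
            "non_effect_allele": v.non_effect_allele,
            "eaf": float(np.nanmean(x) / 2.0) if n_used else np.nan,
            "beta": np.nan,
            "se": np.nan,
            "p": np.nan,
            "n_used": n_used,
            "note": "",
        }
        if n_used < cov_mat.shape[1] + 3:
            row["note"] = "too_few_observations"
            rows.append(row)
            continue
        xv = x[ok]
        if xv.std() == 0:
            row["note"] = "zero_dosage_variance"
            rows.append(row)
            continue
        if standardize_dosage:
            xv = (xv - xv.mean()) / xv.std(ddof=1)
        cov_ok = cov_mat[ok]
        # drop covariate columns constant within the analysis subset
        keep_cols = cov_ok.std(axis=0) > 0
        exog = np.column_stack([np.ones(n_used), xv, cov_ok[:, keep_cols]])
        res = sm.OLS(y_all[ok], exog).fit()
        row["beta"] = float(res.params[1])
        row["se"] = float(res.bse[1])
        row["p"] = float(res.pvalues[1])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mann-Whitney screen
# ---------------------------------------------------------------------------


def mannwhitney_test(group1, group0, exact_limit: int = 8) -> tuple[float, float]:
    """(U statistic of group1, two-sided p); exact when both groups are small
    and tie-free, else the tie/continuity-corrected normal approximation."""
    group1 = np.asarray(group1, dtype=float)
    group0 = np.asarray(group0, dtype=float)
    pooled = np.concatenate([group1, group0])
    tie_free = np.unique(pooled).size == pooled.size
    small = len(group1) <= exact_limit and len(group0) <= exact_limit
    method = "exact" if (small and tie_free) else "asymptotic"
    res = mannwhitneyu(group1, group0, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_screen(
    cohort: pd.DataFrame,
    factors: Mapping[str, tuple[str, object, object]] | None = None,
    outcome: str = "depression",
    alpha: float = 0.05,
    exact_limit: int = 8,
) -> pd.DataFrame:
    """Univariate screen of binary social factors against the outcome.

    ``significant_after_correction`` compares each p-value with the
    alpha/m per-test bound for the m screened factors.
    """
    factors = dict(factors) if factors is not None else dict(DEFAULT_SCREEN_FACTORS)
    if not factors:
        raise AssociationError("no factors to screen")
    threshold = correction_threshold(alpha, len(factors))
    y = pd.to_numeric(cohort[outcome], errors="coerce")

    rows = []
    for name, (col, level1, level0) in factors.items():
        in1 = (cohort[col] == level1) & y.notna()
        in0 = (cohort[col] == level0) & y.notna()
        g1 = y[in1].to_numpy(dtype=float)
        g0 = y[in0].to_numpy(dtype=float)
        if len(g1) == 0 or len(g0) == 0:
            raise AssociationError(f"factor {name!r} has an empty group")
        if np.array_equal(np.sort(g1), np.sort(g0)):
            u, p = len(g1) * len(g0) / 2.0, 1.0
        else:
            u, p = mannwhitney_test(g1, g0, exact_limit)
        rows.append(
            {
                "factor": name,
                "group1": str(level1),
                "group0": str(level0),
                "n1": len(g1),
                "n0": len(g0),
                "mean1": g1.mean(),
                "sd1": g1.std(ddof=1) if len(g1) > 1 else np.nan,
                "mean0": g0.mean(),
                "sd0": g0.std(ddof=1) if len(g0) > 1 else np.nan,
                "U": u,
                "p": p,
                "significant_after_correction": bool(p < threshold.value),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple-testing thresholds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrectionThreshold:
    """Per-test significance bound alpha/m with its 2-significant-figure display."""

    value: float
    display: str
    alpha: float
    m: int

    def __float__(self) -> float:
        return self.value


def correction_threshold(alpha: float = 0.05, m: int = 8) -> CorrectionThreshold:
    """Bonferroni-style per-test threshold alpha/m over m screened factors."""
    if not (0.0 < alpha < 1.0):
        raise AssociationError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise AssociationError(f"number of tests must be >= 1, got {m}")
    value = alpha / m
    exponent = int(np.floor(np.log10(abs(value))))
    quantum = Decimal(1).scaleb(exponent - 1)  # two significant figures
    display_dec = Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP)
    return CorrectionThreshold(value=value, display=format(display_dec, "f"), alpha=alpha, m=m)


def benjamini_hochberg(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Boolean rejections under the Benjamini-Hochberg step-up procedure."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    out = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.nonzero(passed))
        out[order[: k + 1]] = True
    return out
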