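"""Nested regression models of depression on PGS, demographics and social factors.

Model 1 regresses the depression score on the polygenic score alone; Model 2
on sex, ethnicity and age; Model 3 on PGS plus those demographics; Model 4
adds the social/rearing predictors surviving AIC backward elimination with
PGS, sex, age and ethnicity forced. Adjusted r-squared
``1 - (1 - R2)(n - 1)/(n - k - 1)`` decomposes the variance explained across
the nested specifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import ETHNICITY_LEVELS, GenotypePanel, PBI_SCALES
from .association import fit_snp_regression
from .scoring import WeightSet, build_weights, score_individuals

__all__ = [
    "ModelFit",
    "fit_linear_model",
    "backward_eliminate",
    "model_terms",
    "run_model_suite",
    "ModelSuiteResult",
    "split_half_model1_r2",
    "SOCIAL_CANDIDATE_TERMS",
]


class ModelError(ValueError):
    pass


#: Social/lifestyle terms eligible for backward elimination in Model 4.
SOCIAL_CANDIDATE_TERMS = (
    "income",
    "full_family",
    "maltreatment",
    "maternal_care",
    "maternal_protection",
    "paternal_care",
    "paternal_protection",
)

_DEMOGRAPHIC_TERMS = ("sex", "ethnicity", "age")


def model_terms(model_id: int, subgroup: str = "full") -> tuple[list[str], list[str]]:
    """(terms, forced_terms) for one of the four nested models.

    In the women-only subgroup sex is constant and is dropped from every
    specification.
    """
    if model_id == 1:
        terms: list[str] = ["pgs"]
    elif model_id == 2:
        terms = list(_DEMOGRAPHIC_TERMS)
    elif model_id == 3:
        terms = ["pgs", *_DEMOGRAPHIC_TERMS]
    elif model_id == 4:
        terms = ["pgs", *_DEMOGRAPHIC_TERMS, *SOCIAL_CANDIDATE_TERMS]
    else:
        raise ModelError(f"model_id must be 1-4, got {model_id}")
    forced = [t for t in terms if t not in SOCIAL_CANDIDATE_TERMS]
    if subgroup == "women":
        terms = [t for t in terms if t != "sex"]
        forced = [t for t in forced if t != "sex"]
    return terms, forced


def _term_columns(data: pd.DataFrame, term: str, ethnicity_ref: str) -> dict[str, np.ndarray]:
    if term == "pgs":
        return {"pgs": pd.to_numeric(data["pgs"]).to_numpy(dtype=float)}
    if term == "sex":
        return {"sex": (data["sex"].to_numpy() == "woman").astype(float)}
    if term == "age":
        return {"age": pd.to_numeric(data["age"]).to_numpy(dtype=float)}
    if term == "ethnicity":
        return {
            f"ethnicity_{lev}": (data["ethnicity"].to_numpy() == lev).astype(float)
            for lev in ETHNICITY_LEVELS
            if lev != ethnicity_ref
        }
    if term == "income":
        return {"income_average": (data["income"].to_numpy() == "average-and-higher").astype(float)}
    if term in ("full_family", "maltreatment"):
        return {term: pd.to_numeric(data[term]).to_numpy(dtype=float)}
    if term in PBI_SCALES:
        return {f"{term}_high": (data[f"{term}_cat"].to_numpy() == "high").astype(float)}
    raise ModelError(f"unknown model term {term!r}")


@dataclass
class ModelFit:
    """A fitted linear model with its fit statistics.

    ``aic`` follows the convention ``n log(RSS/n) + 2 (k + 2)`` (Gaussian
    likelihood with the variance counted as a parameter); only differences
    matter for elimination.
    """

    terms: list[str]
    coef_table: pd.DataFrame  # term, beta, se, p
    r2: float
    adjusted_r2: float
    f_statistic: float
    model_p: float
    aic: float
    n_used: int
    design_columns: list[str]
    outcome: str = "depression"

    def summary(self) -> str:
        lines = [
            f"OLS: {self.outcome} ~ {' + '.join(self.terms)}",
            f"n = {self.n_used}   R2 = {self.r2:.4f}   adj. R2 = {self.adjusted_r2:.4f}",
            f"F = {self.f_statistic:.3f}   model p = {self.model_p:.3g}   AIC = {self.aic:.2f}",
            "",
            self.coef_table.to_string(index=False, float_format=lambda v: f"{v: .4g}"),
        ]
        return "\n".join(lines)


def _aliased_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    kept: list[int] = []
    aliased: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


def fit_linear_model(
    data: pd.DataFrame,
    terms: Sequence[str],
    outcome: str = "depression",
    ethnicity_ref: str = "mixed",
) -> ModelFit:
    """OLS of ``outcome`` on the named terms with listwise deletion.

    Ethnicity expands to one-hot columns against the reference level; a
    rank-deficient design raises an error listing the aliased columns.
    """
    terms = list(terms)
    if not terms:
        raise ModelError("at least one predictor term required")
    y_all = pd.to_numeric(data[outcome], errors="coerce").to_numpy(dtype=float)
    col_map: dict[str, np.ndarray] = {}
    for t in terms:
        col_map.update(_term_columns(data, t, ethnicity_ref))
    names = list(col_map)
    X_all = np.column_stack([col_map[c] for c in names])
    ok = ~np.isnan(y_all) & ~np.isnan(X_all).any(axis=1)
    n_used = int(ok.sum())
    k = X_all.shape[1]
    if n_used <= k + 1:
        raise ModelError(f"{n_used} usable rows cannot identify {k} predictors plus intercept")
    X = np.column_stack([np.ones(n_used), X_all[ok]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_columns(X, ["const"] + names)
        raise ModelError(f"rank-deficient design; aliased columns: {aliased}")
    res = sm.OLS(y_all[ok], X).fit()
    rss = float(res.ssr)
    aic = n_used * np.log(rss / n_used) + 2 * (k + 2)
    coef = pd.DataFrame(
        {
            "term": ["const"] + names,
            "beta": res.params,
            "se": res.bse,
            "p": res.pvalues,
        }
    )
    return ModelFit(
        terms=terms,
        coef_table=coef,
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        f_statistic=float(res.fvalue),
        model_p=float(res.f_pvalue),
        aic=float(aic),
        n_used=n_used,
        design_columns=names,
        outcome=outcome,
    )


def backward_eliminate(
    data: pd.DataFrame,
    terms: Sequence[str],
    forced_terms: Sequence[str],
    outcome: str = "depression",
    ethnicity_ref: str = "mixed",
) -> tuple[ModelFit, pd.DataFrame]:
    """AIC backward elimination over the non-forced terms.

    At each step the single removable term whose removal most decreases AIC
    is dropped; elimination stops when no removal decreases AIC. Ties break
    toward the term earlier in the declared order. Returns the final fit and
    a step log (step, removed term, AIC before/after).
    """
    terms = list(terms)
    forced = list(forced_terms)
    unknown = [t for t in forced if t not in terms]
    if unknown:
        raise ModelError(f"forced terms not among model terms: {unknown}")
    current = list(terms)
    fit = fit_linear_model(data, current, outcome, ethnicity_ref)
    path_rows = [{"step": 0, "removed": "", "aic": fit.aic, "terms": "+".join(current)}]
    step = 0
    while True:
        removable = [t for t in current if t not in forced]
        if not removable:
            break
        candidates = []
        for t in removable:
            trial_terms = [u for u in current if u != t]
            trial = fit_linear_model(data, trial_terms, outcome, ethnicity_ref)
            candidates.append((trial.aic, current.index(t), t, trial))
        best_aic, _, best_term, best_fit = min(candidates)
        if best_aic >= fit.aic:
            break
        step += 1
        current = [u for u in current if u != best_term]
        fit = best_fit
        path_rows.append({"step": step, "removed": best_term, "aic": fit.aic, "terms": "+".join(current)})
    return fit, pd.DataFrame(path_rows)


# ---------------------------------------------------------------------------
# the model suite
# ---------------------------------------------------------------------------

DEFAULT_SUITE_CONDITIONS = (("weighted", "full"), ("unweighted", "full"), ("weighted", "women"))


@dataclass
class ModelSuiteResult:
    """Fits of Models 1-4 across weighting modes and subgroups."""

    fits: dict  # (mode, subgroup) -> {model_id or "4_full": ModelFit}
    elimination_paths: dict  # (mode, subgroup) -> DataFrame
    weights: dict  # mode -> WeightSet
    scores: dict  # mode -> DataFrame
    assoc: pd.DataFrame
    min_subgroup_n: int = 50

    def incremental_adjusted_r2(self) -> pd.DataFrame:
        """Adjusted r-squared matrix: rows = Models 1-4, columns = conditions."""
        cols = {}
        for (mode, subgroup), fits in self.fits.items():
            label = f"{mode}/{subgroup}"
            cols[label] = [fits[m].adjusted_r2 if m in fits else np.nan for m in (1, 2, 3, 4)]
        return pd.DataFrame(cols, index=pd.Index([1, 2, 3, 4], name="model"))

    def to_markdown(self) -> str:
        parts = ["## Adjusted r-squared by model and condition", "",
                 self.incremental_adjusted_r2().round(4).to_markdown(), ""]
        for (mode, subgroup), fits in self.fits.items():
            for mid in (1, 2, 3, 4):
                if mid not in fits:
                    continue
                parts += [f"### Model {mid} ({mode} PGS, {subgroup} sample)", "",
                          "```", fits[mid].summary(), "```", ""]
        return "\n".join(parts)


def _subset_rows(panel: GenotypePanel, cohort: pd.DataFrame, mask: np.ndarray):
    idx = np.flatnonzero(mask)
    sub_panel = GenotypePanel(
        variants=list(panel.variants),
        dosages=panel.dosages[idx],
        sample_ids=[panel.sample_ids[i] for i in idx],
    )
    return sub_panel, cohort.iloc[idx].reset_index(drop=True)


def run_model_suite(
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    conditions: Sequence[tuple[str, str]] = DEFAULT_SUITE_CONDITIONS,
    covariates: Sequence[str] = ("sex", "age", "ethnicity"),
    ethnicity_ref: str = "mixed",
    missing_policy: str = "mean_dosage",
    min_subgroup_n: int = 50,
) -> ModelSuiteResult:
    """Estimate in-sample weights, score, and fit Models 1-4 per condition.

    ``conditions`` pairs a weighting mode (weighted/unweighted) with a
    subgroup (full/women). Weights always come from the full-sample per-SNP
    scan; subgroup conditions refit the models inside the subgroup. A
    subgroup smaller than ``min_subgroup_n`` is skipped with a warning.
    """
    import warnings as _warnings

    assoc = fit_snp_regression(panel, cohort, covariates=covariates, ethnicity_ref=ethnicity_ref)
    modes = {mode for mode, _ in conditions}
    weight_sets: dict[str, WeightSet] = {m: build_weights(assoc, mode=m) for m in modes}
    score_tables = {m: score_individuals(panel, w, missing_policy=missing_policy)
                    for m, w in weight_sets.items()}

    fits: dict = {}
    paths: dict = {}
    for mode, subgroup in conditions:
        data = cohort.merge(score_tables[mode], on="sample_id", how="left", validate="1:1")
        if subgroup == "women":
            mask = (data["sex"] == "woman").to_numpy()
        elif subgroup == "full":
            mask = np.ones(len(data), dtype=bool)
        else:
            raise ModelError(f"unknown subgroup {subgroup!r}")
        sub = data.loc[mask].reset_index(drop=True)
        if mask.sum() < min_subgroup_n:
            _warnings.warn(f"subgroup {subgroup!r} has only {int(mask.sum())} rows; skipped",
                           stacklevel=2)
            continue
        condition_fits = {}
        for mid in (1, 2, 3):
            terms, _ = model_terms(mid, subgroup)
            condition_fits[mid] = fit_linear_model(sub, terms, ethnicity_ref=ethnicity_ref)
        terms4, forced4 = model_terms(4, subgroup)
        condition_fits["4_full"] = fit_linear_model(sub, terms4, ethnicity_ref=ethnicity_ref)
        condition_fits[4], paths[(mode, subgroup)] = backward_eliminate(
            sub, terms4, forced4, ethnicity_ref=ethnicity_ref
        )
        fits[(mode, subgroup)] = condition_fits
    return ModelSuiteResult(
        fits=fits,
        elimination_paths=paths,
        weights=weight_sets,
        scores=score_tables,
        assoc=assoc,
        min_subgroup_n=min_subgroup_n,
    )


def split_half_model1_r2(
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    rng: np.random.Generator,
    covariates: Sequence[str] = ("sex", "age", "ethnicity"),
) -> tuple[float, float]:
    """(in-sample adjusted r2, split-half out-of-sample r2) for Model 1.

    In-sample: weights estimated and the PGS-only model fitted on the full
    cohort — the circular design whose optimism this quantifies. Out-of-
    sample: weights estimated on a random half, individuals of the other half
    scored with them and the PGS-only model fitted there.
    """
    assoc_full = fit_snp_regression(panel, cohort, covariates=covariates)
    scores_full = score_individuals(panel, build_weights(assoc_full))
    data_full = cohort.merge(scores_full, on="sample_id", validate="1:1")
    in_sample = fit_linear_model(data_full, ["pgs"]).adjusted_r2

    n = len(cohort)
    perm = rng.permutation(n)
    half = perm[: n // 2]
    mask_train = np.zeros(n, dtype=bool)
    mask_train[half] = True
    train_panel, train_cohort = _subset_rows(panel, cohort, mask_train)
    test_panel, test_cohort = _subset_rows(panel, cohort, ~mask_train)
    assoc_train = fit_snp_regression(train_panel, train_cohort, covariates=covariates)
    usable = assoc_train[np.isfinite(assoc_train["beta"])]
    scores_test = score_individuals(test_panel, build_weights(usable))
    data_test = test_cohort.merge(scores_test, on="sample_id", validate="1:1")
    oos = fit_linear_model(data_test, ["pgs"]).r2
    return float(in_sample), float(oos)
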