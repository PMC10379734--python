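"""High-level modelling interface.

:class:`PolygenicScoreModel` bundles the full analysis — variant QC,
per-SNP association, weight construction with sign recoding, scoring, and
the four nested regression models with AIC backward elimination — behind a
statsmodels-style ``Model.fit() -> Results`` pair.

Example
-------
>>> from polyscore import make_study_cohort, PolygenicScoreModel
>>> bundle = make_study_cohort(seed=1)
>>> results = PolygenicScoreModel.from_bundle(bundle).fit()
>>> print(results.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenotypePanel
from .simulate import CohortBundle, STUDY_PROXY_KEEP_LIST
from .qc import QcReport, run_qc
from .association import correction_threshold, mannwhitney_screen
from .models import DEFAULT_SUITE_CONDITIONS, ModelSuiteResult, run_model_suite

__all__ = ["PolygenicScoreModel", "PolygenicScoreResults"]


class PolygenicScoreModel:
    """Depression-score PGS analysis on a genotype panel plus cohort table.

    Parameters
    ----------
    panel
        Genotype panel (pre- or post-QC; with ``apply_qc`` the exclusion
        cascade runs first).
    cohort
        Validated cohort table with depression, demographics, social factors
        and derived PBI categories.
    conditions
        (weighting mode, subgroup) pairs to fit; defaults to weighted/full,
        unweighted/full and weighted/women.
    proxy_keep_list
        Variants that must survive LD pruning (defaults to the study's kept
        proxies when they are on the panel).
    """

    def __init__(
        self,
        panel: GenotypePanel,
        cohort: pd.DataFrame,
        conditions: Sequence[tuple[str, str]] = DEFAULT_SUITE_CONDITIONS,
        apply_qc: bool = True,
        call_rate_min: float = 0.98,
        maf_min: float = 0.05,
        hwe_alpha: float = 0.05,
        proxy_r2_threshold: float = 0.2,
        proxy_keep_list: Sequence[str] | None = None,
        covariates: Sequence[str] = ("sex", "age", "ethnicity"),
        ethnicity_ref: str = "mixed",
        missing_policy: str = "mean_dosage",
    ) -> None:
        if list(panel.sample_ids) != list(cohort["sample_id"]):
            raise ValueError("panel and cohort sample_ids are not aligned")
        self.panel = panel
        self.cohort = cohort
        self.conditions = tuple(conditions)
        self.apply_qc = apply_qc
        self.qc_params = dict(
            call_rate_min=call_rate_min,
            maf_min=maf_min,
            hwe_alpha=hwe_alpha,
            proxy_r2_threshold=proxy_r2_threshold,
        )
        if proxy_keep_list is None:
            proxy_keep_list = sorted(STUDY_PROXY_KEEP_LIST & set(panel.variant_ids))
        self.proxy_keep_list = list(proxy_keep_list)
        self.covariates = tuple(covariates)
        self.ethnicity_ref = ethnicity_ref
        self.missing_policy = missing_policy

    @classmethod
    def from_bundle(cls, bundle: CohortBundle, **kwargs) -> "PolygenicScoreModel":
        return cls(bundle.panel, bundle.cohort, **kwargs)

    def fit(self) -> "PolygenicScoreResults":
        if self.apply_qc:
            scorable, qc_report = run_qc(
                self.panel, proxy_keep_list=self.proxy_keep_list, **self.qc_params
            )
        else:
            scorable, qc_report = self.panel, None
        suite = run_model_suite(
            scorable,
            self.cohort,
            conditions=self.conditions,
            covariates=self.covariates,
            ethnicity_ref=self.ethnicity_ref,
            missing_policy=self.missing_policy,
        )
        screen = mannwhitney_screen(self.cohort)
        return PolygenicScoreResults(
            model=self, scorable_panel=scorable, qc_report=qc_report, suite=suite, screen=screen
        )


@dataclass
class PolygenicScoreResults:
    """Fitted estimates, QC ledger, screen table and model suite."""

    model: PolygenicScoreModel
    scorable_panel: GenotypePanel
    qc_report: QcReport | None
    suite: ModelSuiteResult
    screen: pd.DataFrame

    @property
    def assoc(self) -> pd.DataFrame:
        return self.suite.assoc

    @property
    def model_fits(self) -> dict:
        return self.suite.fits

    def incremental_adjusted_r2(self) -> pd.DataFrame:
        return self.suite.incremental_adjusted_r2()

    def summary(self) -> str:
        screen_threshold = correction_threshold(m=len(self.screen))
        lines = [
            "Polygenic score analysis of depression level",
            "=" * 60,
            f"variants on panel: {self.model.panel.n_variants}; scorable after QC: "
            f"{self.scorable_panel.n_variants}",
            f"individuals: {self.model.panel.n_individuals}",
            "",
            f"social screen (Mann-Whitney, per-test threshold {screen_threshold.display}):",
            self.screen[["factor", "n1", "n0", "U", "p", "significant_after_correction"]]
            .to_string(index=False, float_format=lambda v: f"{v: .4g}"),
            "",
            "adjusted r-squared by model (rows) and condition (columns):",
            self.incremental_adjusted_r2().round(4).to_string(),
        ]
        for (mode, subgroup), fits in self.suite.fits.items():
            lines += ["", f"--- Model 4 ({mode} PGS, {subgroup} sample) after elimination ---",
                      fits[4].summary()]
        return "\n".join(lines)

    def plot_incremental_r2(self, ax=None):
        """Grouped bar chart of adjusted r-squared per model and condition."""
        import matplotlib.pyplot as plt

        table = self.incremental_adjusted_r2()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        x = np.arange(len(table.index))
        width = 0.8 / len(table.columns)
        for i, col in enumerate(table.columns):
            ax.bar(x + i * width, table[col], width, label=col)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels([f"Model {m}" for m in table.index])
        ax.set_ylabel("adjusted $r^2$")
        ax.legend(frameon=False, fontsize=8)
        return ax
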