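"""Synthetic genotype-phenotype cohorts with the statistical structure the
downstream analysis assumes.

The generator draws unlinked variants under Hardy-Weinberg proportions at a
target effect-allele frequency, induces linkage disequilibrium within
designated pairs through a two-locus haplotype distribution (genotypes formed
by random union of gametes, so the target r-squared is the haplotype-frequency
r-squared that LD pruning estimates), perturbs designated variants away from
HWE via an inbreeding coefficient F (P(het) = 2pq(1-F)), and builds a bounded
0-63 integer depression score from an additive SNP + covariate model with
Gaussian noise.

:func:`default_study_config` encodes the study conditions this package
emulates: a 32-variant panel (30 characterized variants plus two HWE
violators), three intra-locus LD pairs at r-squared 0.44 / 0.23 / 0.55,
published per-allele effects (notably +0.67 and -0.73 BDI points/allele at
the two associated loci), cohort covariate prevalences, and n = 1065.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    ETHNICITY_LEVELS,
    GenotypePanel,
    PBI_SCALES,
    PBICutoffs,
    VariantRecord,
    categorize_pbi,
)

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "default_study_config",
    "make_study_cohort",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotype",
    "variance_components",
    "marginal_snp_effects",
    "scale_snp_effects_to_share",
    "STUDY_LD_PAIRS",
    "STUDY_PROXY_KEEP_LIST",
    "STUDY_HWE_VIOLATIONS",
]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# The study panel: 30 characterized variants
# (variant_id, locus, chrom, pos, effect allele, non-effect allele,
#  effect-allele frequency, per-allele effect on depression score).
# ---------------------------------------------------------------------------

STUDY_PANEL = (
    ("rs3093077", "CRP", "1", 159709846, "G", "T", 0.079, -0.24),
    ("rs33911258", "AVPR1B", "1", 206118034, "G", "A", 0.167, 0.01),
    ("rs1800587", "IL1A", "2", 112785383, "A", "G", 0.278, 0.29),
    ("rs16944", "IL1B", "2", 112837290, "A", "G", 0.378, -0.26),
    ("rs7632287", "OXTR", "3", 8749760, "A", "G", 0.199, -0.16),
    ("rs2254298", "OXTR", "3", 8760542, "A", "G", 0.095, -0.13),
    ("rs53576", "OXTR", "3", 8762685, "A", "G", 0.473, -0.04),
    ("rs2228485", "OXTR", "3", 8768017, "G", "A", 0.208, -0.25),
    ("rs237911", "OXTR", "3", 8768322, "G", "A", 0.165, -0.04),
    ("rs9818870", "MRAS", "3", 138403280, "T", "C", 0.139, 0.36),
    ("rs1317082", "TERC", "3", 169779797, "G", "A", 0.341, -0.01),
    ("rs7726159", "TERT", "5", 1282204, "A", "C", 0.337, -0.31),
    ("rs41423247", "NR3C1", "5", 143399010, "C", "G", 0.352, -0.04),
    ("rs1800629", "TNF", "6", 31575254, "A", "G", 0.109, 0.04),
    ("rs1041981", "TNF", "6", 31573007, "A", "C", 0.248, -0.46),
    ("rs3800373", "FKBP5", "6", 35574699, "C", "A", 0.234, -0.01),
    ("rs1360780", "FKBP5", "6", 35639794, "T", "C", 0.280, -0.11),
    ("rs13212041", "HTR1B", "6", 77461407, "C", "T", 0.177, 0.12),
    ("rs10457441", "MIR2113", "6", 98124244, "C", "T", 0.419, 0.48),
    ("rs2148710", "FYN", "6", 111801023, "T", "C", 0.135, 0.32),
    ("rs2715157", "PCLO", "7", 82839058, "A", "G", 0.438, 0.67),
    ("rs531564", "MIR124", "8", 3445535, "C", "G", 0.151, -0.22),
    ("rs2487999", "OBFC1", "10", 103900068, "T", "C", 0.087, 0.65),
    ("rs1800955", "DRD4", "11", 636784, "C", "T", 0.402, -0.26),
    ("rs187238", "IL18", "11", 112164265, "G", "C", 0.283, -0.73),
    ("rs3803107", "AVPR1A", "12", 63147054, "T", "C", 0.176, 0.64),
    ("rs1042615", "AVPR1A", "12", 63150429, "A", "G", 0.403, -0.03),
    ("rs10459194", "MIR135", "12", 99039512, "C", "T", 0.302, 0.52),
    ("rs2230912", "P2RX7", "12", 121184393, "G", "A", 0.170, -0.01),
    ("rs1042173", "SLC6A4", "17", 30197993, "T", "G", 0.454, 0.32),
)

# Two out-of-equilibrium variants completing the 32-variant panel. Their
# coordinates/alleles/frequencies are synthetic stand-ins (the originals are
# not characterized in the source tables); the inbreeding coefficients are
# back-computed from the reported exclusion statistics at n = 1065.
STUDY_HWE_VIOLATOR_ROWS = (
    ("rs13316193", "OXTR", "3", 8755997, "T", "C", 0.30, 0.0),
    ("rs7322347", "HTR2A", "13", 46837850, "T", "A", 0.42, 0.0),
)
STUDY_HWE_VIOLATIONS = (("rs13316193", 0.205), ("rs7322347", 0.091))

#: Intra-locus LD pairs (variant dropped in the study, its kept proxy, r2).
STUDY_LD_PAIRS = (
    ("rs237911", "rs2228485", 0.44),
    ("rs1041981", "rs1800629", 0.23),
    ("rs1360780", "rs3800373", 0.55),
)
STUDY_PROXY_KEEP_LIST = frozenset({"rs2228485", "rs1800629", "rs3800373"})

#: Cohort margins: category prevalences observed in the study sample.
STUDY_PREVALENCES = {
    "woman": 844 / 1065,
    "ethnicity": {
        "Russian": 357 / 1065,
        "Tatar": 340 / 1065,
        "Udmurt": 234 / 1065,
        "mixed": 134 / 1065,
    },
    "income_lower": 113 / 1065,
    "full_family": 892 / 1065,
    "maltreatment": 104 / 1065,
    "pbi_high": {
        "maternal_care": 728 / 1065,
        "maternal_protection": 575 / 1065,  # count-based; the printed % is a typo
        "paternal_care": 564 / 1065,
        "paternal_protection": 500 / 1065,
    },
}

#: Conditional covariate effects on the latent depression score (full-model
#: scale); rearing factors that did not survive elimination get near-zero
#: conditional effects.
STUDY_COVARIATE_EFFECTS = {
    "woman": 1.50,
    "age": -0.27,  # per year, age centered at the midpoint of age_range
    "ethnicity": {"Russian": -1.68, "Tatar": -2.54, "Udmurt": -1.34, "mixed": 0.0},
    "income_average": -1.90,
    "full_family": 0.0,
    "maltreatment": 0.50,
    "pbi_high": {
        "maternal_care": -2.65,
        "maternal_protection": 1.52,
        "paternal_care": -1.07,
        "paternal_protection": 1.43,
    },
}

_PBI_SCALE_RANGES = {
    "maternal_care": (0, 36),
    "maternal_protection": (0, 39),
    "paternal_care": (0, 36),
    "paternal_protection": (0, 39),
}
_PBI_SCALE_SD = {
    "maternal_care": 8.0,
    "maternal_protection": 7.0,
    "paternal_care": 8.0,
    "paternal_protection": 7.0,
}

#: Target mean of the latent depression score (study sample mean).
STUDY_DEPRESSION_MEAN = 8.36
#: Noise scale chosen so the marginal depression SD is about 7 score points.
STUDY_NOISE_SD = 6.6


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic cohort."""

    variants: list[VariantRecord]
    n_individuals: int = 1065
    ld_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    hwe_violations: list[tuple[str, float]] = field(default_factory=list)
    missing_rate: float = 0.005
    true_snp_betas: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=lambda: _deepcopy_dict(STUDY_COVARIATE_EFFECTS))
    covariate_prevalences: dict = field(default_factory=lambda: _deepcopy_dict(STUDY_PREVALENCES))
    age_range: tuple[float, float] = (18.0, 25.0)
    intercept: float = 0.0
    noise_sd: float = STUDY_NOISE_SD
    discretize: bool = True
    exact_frequencies: bool = False
    pbi_cutoffs: PBICutoffs = field(default_factory=PBICutoffs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise SimulationError("n_individuals must be at least 2")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate variant ids in config")
        for v in self.variants:
            if v.eaf is None:
                raise SimulationError(f"{v.variant_id}: target effect-allele frequency required")
        paired: set[str] = set()
        for a, b, r2 in self.ld_pairs:
            if not (0.0 <= r2 < 1.0):
                raise SimulationError(f"target r2 {r2} outside [0, 1)")
            for vid in (a, b):
                if vid not in ids:
                    raise SimulationError(f"LD pair names unknown variant {vid!r}")
                if vid in paired:
                    raise SimulationError(f"variant {vid!r} appears in more than one LD pair")
                paired.add(vid)
        for vid, f in self.hwe_violations:
            if vid not in ids:
                raise SimulationError(f"HWE violation names unknown variant {vid!r}")
            p = self.variant(vid).eaf
            if not (-p / (1 - p) if p < 1 else -np.inf) - 1e-12 <= f <= 1.0:
                raise SimulationError(f"{vid}: inbreeding coefficient {f} infeasible at eaf {p}")
        probs = self.covariate_prevalences
        for key in ("woman", "income_lower", "full_family", "maltreatment"):
            if not (0.0 <= probs[key] <= 1.0):
                raise SimulationError(f"prevalence {key} outside [0, 1]")
        eth = probs["ethnicity"]
        if abs(sum(eth.values()) - 1.0) > 1e-6:
            raise SimulationError(f"ethnicity probabilities sum to {sum(eth.values()):.6f}, not 1")
        for scale, p in probs["pbi_high"].items():
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"PBI prevalence for {scale} outside [0, 1]")

    def variant(self, variant_id: str) -> VariantRecord:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise SimulationError(f"unknown variant {variant_id!r}")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "variants": [
                {
                    "variant_id": v.variant_id,
                    "locus_label": v.locus_label,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "effect_allele": v.effect_allele,
                    "non_effect_allele": v.non_effect_allele,
                    "eaf": float(v.eaf),
                }
                for v in self.variants
            ],
            "n_individuals": self.n_individuals,
            "ld_pairs": [list(p) for p in self.ld_pairs],
            "hwe_violations": [list(p) for p in self.hwe_violations],
            "missing_rate": self.missing_rate,
            "true_snp_betas": dict(self.true_snp_betas),
            "covariate_effects": _deepcopy_dict(self.covariate_effects),
            "covariate_prevalences": _deepcopy_dict(self.covariate_prevalences),
            "age_range": list(self.age_range),
            "intercept": self.intercept,
            "noise_sd": self.noise_sd,
            "discretize": self.discretize,
            "exact_frequencies": self.exact_frequencies,
            "pbi_cutoffs": {s: self.pbi_cutoffs.for_scale(s) for s in PBI_SCALES},
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["variants"] = [VariantRecord(**v) for v in d["variants"]]
        d["ld_pairs"] = [tuple(p) for p in d.get("ld_pairs", [])]
        d["hwe_violations"] = [tuple(p) for p in d.get("hwe_violations", [])]
        d["age_range"] = tuple(d.get("age_range", (18.0, 25.0)))
        if "pbi_cutoffs" in d:
            d["pbi_cutoffs"] = PBICutoffs(**d["pbi_cutoffs"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortBundle:
    """A simulated panel + cohort together with the generating truth."""

    panel: GenotypePanel
    cohort: pd.DataFrame
    truth: SimulationConfig


def _deepcopy_dict(d: dict) -> dict:
    return {k: (dict(v) if isinstance(v, dict) else v) for k, v in d.items()}


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _largest_remainder_counts(probs: np.ndarray, total: int) -> np.ndarray:
    """Integer class counts summing to ``total``, proportional to ``probs``."""
    probs = np.asarray(probs, dtype=float)
    raw = probs * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def max_attainable_r2(p_a: float, p_b: float) -> float:
    """Largest haplotype-frequency r-squared for positive D at the given EAFs."""
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    return 0.0 if denom == 0 else d_max**2 / denom


def _haplotype_probs(p_a: float, p_b: float, r2: float) -> np.ndarray:
    """Probabilities of haplotypes (AB, Ab, aB, ab) achieving the target r2."""
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    d = math.sqrt(r2 * denom)
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    if d > d_max + 1e-12:
        raise SimulationError(
            f"target r2 {r2:.3f} infeasible at frequencies ({p_a}, {p_b}); "
            f"maximum attainable r2 is {max_attainable_r2(p_a, p_b):.3f}"
        )
    f = np.array(
        [
            p_a * p_b + d,
            p_a * (1 - p_b) - d,
            (1 - p_a) * p_b - d,
            (1 - p_a) * (1 - p_b) + d,
        ]
    )
    return np.clip(f, 0.0, 1.0) / np.clip(f, 0.0, 1.0).sum()


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw a genotype panel under the configured frequencies, LD and HWE structure.

    With ``exact_frequencies`` the genotype (and haplotype) class counts are
    rounded to the target proportions and randomly assigned to individuals, so
    realized frequencies, r-squared and HWE statistics match their targets up
    to integer rounding; otherwise classes are sampled multinomially.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals
    f_by_id = dict(config.hwe_violations)
    paired = {a for a, _, _ in config.ld_pairs} | {b for _, b, _ in config.ld_pairs}

    columns: dict[str, np.ndarray] = {}
    for v in config.variants:
        if v.variant_id in paired:
            continue
        p = float(v.eaf)
        f_in = f_by_id.get(v.variant_id, 0.0)
        q = 1.0 - p
        probs = np.clip([p * p + f_in * p * q, 2 * p * q * (1 - f_in), q * q + f_in * p * q], 0.0, 1.0)
        probs = probs / probs.sum()
        if config.exact_frequencies:
            counts = _largest_remainder_counts(probs, n)
            x = np.repeat([2.0, 1.0, 0.0], counts)
            rng.shuffle(x)
        else:
            x = rng.choice([2.0, 1.0, 0.0], size=n, p=probs)
        columns[v.variant_id] = x

    for a, b, r2 in config.ld_pairs:
        p_a, p_b = float(config.variant(a).eaf), float(config.variant(b).eaf)
        hap_probs = _haplotype_probs(p_a, p_b, r2)
        if config.exact_frequencies:
            counts = _largest_remainder_counts(hap_probs, 2 * n)
            haps = np.repeat(np.arange(4), counts)
            rng.shuffle(haps)
        else:
            haps = rng.choice(4, size=2 * n, p=hap_probs)
        # haplotype index -> allele at (a, b): 0=AB, 1=Ab, 2=aB, 3=ab
        allele_a = np.isin(haps, (0, 1)).astype(float).reshape(n, 2).sum(axis=1)
        allele_b = np.isin(haps, (0, 2)).astype(float).reshape(n, 2).sum(axis=1)
        columns[a] = allele_a
        columns[b] = allele_b

    dosages = np.column_stack([columns[v.variant_id] for v in config.variants])
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    return GenotypePanel(variants=list(config.variants), dosages=dosages, sample_ids=_sample_ids(n))


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the demographic/social table (depression column left missing)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals
    prev = config.covariate_prevalences

    eth_levels = list(ETHNICITY_LEVELS)
    eth_probs = np.array([prev["ethnicity"][lev] for lev in eth_levels])
    table = pd.DataFrame(
        {
            "sample_id": _sample_ids(n),
            "depression": np.nan,
            "sex": np.where(rng.random(n) < prev["woman"], "woman", "man"),
            "age": rng.uniform(config.age_range[0], config.age_range[1], size=n),
            "ethnicity": rng.choice(eth_levels, size=n, p=eth_probs / eth_probs.sum()),
            "income": np.where(
                rng.random(n) < prev["income_lower"], "lower-than-average", "average-and-higher"
            ),
            "full_family": (rng.random(n) < prev["full_family"]).astype(int),
            "maltreatment": (rng.random(n) < prev["maltreatment"]).astype(int),
        }
    )
    for scale in PBI_SCALES:
        lo, hi = _PBI_SCALE_RANGES[scale]
        sd = _PBI_SCALE_SD[scale]
        cutoff = config.pbi_cutoffs.for_scale(scale)
        p_high = prev["pbi_high"][scale]
        # scores are rounded to integers: the smallest integer >= cutoff is the
        # effective category boundary, reached from half a point below it
        mu = (np.ceil(cutoff) - 0.5) - sd * norm.ppf(1.0 - p_high)
        raw = np.clip(np.round(rng.normal(mu, sd, size=n)), lo, hi)
        table[scale] = raw.astype(int)
    return categorize_pbi(table, config.pbi_cutoffs)


def _covariate_linear_term(cohort: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    eff = config.covariate_effects
    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])
    term = np.zeros(len(cohort))
    term += eff["woman"] * (cohort["sex"].to_numpy() == "woman")
    term += eff["age"] * (cohort["age"].to_numpy() - age_mid)
    term += np.array([eff["ethnicity"][e] for e in cohort["ethnicity"]])
    term += eff["income_average"] * (cohort["income"].to_numpy() == "average-and-higher")
    term += eff["full_family"] * cohort["full_family"].to_numpy()
    term += eff["maltreatment"] * cohort["maltreatment"].to_numpy()
    for scale in PBI_SCALES:
        term += eff["pbi_high"][scale] * (cohort[f"{scale}_cat"].to_numpy() == "high")
    return term


def simulate_phenotype(
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill the depression column from the additive SNP + covariate model.

    The latent score is ``intercept + sum(beta_i * x_i) + covariate terms +
    N(0, noise_sd)``; with ``discretize`` it is rounded and clipped to the
    0-63 scale. Missing dosages contribute their variant's observed mean.
    """
    if list(panel.sample_ids) != list(cohort["sample_id"]):
        raise SimulationError("panel and cohort sample_ids are not aligned")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    betas = np.array([config.true_snp_betas.get(v.variant_id, 0.0) for v in config.variants])
    dos = panel.dosages.copy()
    if np.isnan(dos).any():
        col_means = np.nanmean(dos, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos[nan_r, nan_c] = col_means[nan_c]

    latent = (
        config.intercept
        + dos @ betas
        + _covariate_linear_term(cohort, config)
        + rng.normal(0.0, config.noise_sd, size=len(cohort))
    )
    out = cohort.copy()
    if config.discretize:
        out["depression"] = np.clip(np.round(latent), 0, 63).astype(int)
    else:
        out["depression"] = latent
    return out


# ---------------------------------------------------------------------------
# analytic moments of the generative model
# ---------------------------------------------------------------------------


def _snp_moments(config: SimulationConfig) -> tuple[float, float]:
    """(mean, variance) of the latent SNP term under the configured law."""
    f_by_id = dict(config.hwe_violations)
    mean = 0.0
    var = 0.0
    for v in config.variants:
        beta = config.true_snp_betas.get(v.variant_id, 0.0)
        p = float(v.eaf)
        f_in = f_by_id.get(v.variant_id, 0.0)
        mean += beta * 2 * p
        var += beta**2 * 2 * p * (1 - p) * (1 + f_in)
    for a, b, r2 in config.ld_pairs:
        pa, pb = float(config.variant(a).eaf), float(config.variant(b).eaf)
        d = math.sqrt(r2 * pa * (1 - pa) * pb * (1 - pb))
        var += (
            2
            * config.true_snp_betas.get(a, 0.0)
            * config.true_snp_betas.get(b, 0.0)
            * 2
            * d
        )
    return mean, var


def _covariate_moments(config: SimulationConfig) -> tuple[float, float]:
    eff, prev = config.covariate_effects, config.covariate_prevalences
    mean = 0.0
    var = 0.0

    def bern(effect: float, p: float) -> None:
        nonlocal mean, var
        mean += effect * p
        var += effect**2 * p * (1 - p)

    bern(eff["woman"], prev["woman"])
    bern(eff["income_average"], 1.0 - prev["income_lower"])
    bern(eff["full_family"], prev["full_family"])
    bern(eff["maltreatment"], prev["maltreatment"])
    for scale in PBI_SCALES:
        bern(eff["pbi_high"][scale], prev["pbi_high"][scale])
    levels = list(prev["ethnicity"])
    e_vals = np.array([eff["ethnicity"][lev] for lev in levels])
    e_probs = np.array([prev["ethnicity"][lev] for lev in levels])
    e_mean = float(e_vals @ e_probs)
    mean += e_mean
    var += float((e_vals - e_mean) ** 2 @ e_probs)
    # age is centered at the range midpoint
    span = config.age_range[1] - config.age_range[0]
    var += eff["age"] ** 2 * span**2 / 12.0
    return mean, var


def variance_components(config: SimulationConfig) -> dict[str, float]:
    """Analytic variance decomposition of the latent depression score."""
    _, v_snp = _snp_moments(config)
    _, v_cov = _covariate_moments(config)
    v_noise = config.noise_sd**2
    total = v_snp + v_cov + v_noise
    return {
        "snp": v_snp,
        "covariate": v_cov,
        "noise": v_noise,
        "total": total,
        "snp_share": v_snp / total if total else 0.0,
        "covariate_share": v_cov / total if total else 0.0,
    }


def expected_latent_mean(config: SimulationConfig) -> float:
    m_snp, _ = _snp_moments(config)
    m_cov, _ = _covariate_moments(config)
    return config.intercept + m_snp + m_cov


def marginal_snp_effects(config: SimulationConfig) -> dict[str, float]:
    """Per-variant *marginal* regression slopes implied by the generative model.

    Single-SNP regression estimates the marginal projection; for a variant in
    an LD pair this is ``beta_a + beta_b * cov(x_a, x_b) / var(x_a)`` with
    ``cov = 2D`` and ``var = 2 p q`` under random union of gametes.
    """
    out = {v.variant_id: config.true_snp_betas.get(v.variant_id, 0.0) for v in config.variants}
    for a, b, r2 in config.ld_pairs:
        pa, pb = float(config.variant(a).eaf), float(config.variant(b).eaf)
        d = math.sqrt(r2 * pa * (1 - pa) * pb * (1 - pb))
        beta_a = config.true_snp_betas.get(a, 0.0)
        beta_b = config.true_snp_betas.get(b, 0.0)
        out[a] = beta_a + beta_b * d / (pa * (1 - pa))
        out[b] = beta_b + beta_a * d / (pb * (1 - pb))
    return out


def scale_snp_effects_to_share(config: SimulationConfig, share: float) -> SimulationConfig:
    """Rescale all SNP effects so the SNP term explains ``share`` of latent variance."""
    if not (0.0 <= share < 1.0):
        raise SimulationError("variance share must be in [0, 1)")
    _, v_snp = _snp_moments(config)
    if v_snp == 0:
        raise SimulationError("config has no non-zero SNP effects to rescale")
    _, v_cov = _covariate_moments(config)
    other = v_cov + config.noise_sd**2
    c = math.sqrt(share * other / ((1.0 - share) * v_snp))
    new_betas = {k: c * v for k, v in config.true_snp_betas.items()}
    cfg = replace(config, true_snp_betas=new_betas)
    return _recenter(cfg)


def _recenter(config: SimulationConfig, target_mean: float = STUDY_DEPRESSION_MEAN) -> SimulationConfig:
    cfg = replace(config, intercept=0.0)
    return replace(cfg, intercept=target_mean - expected_latent_mean(cfg))


# ---------------------------------------------------------------------------
# the study-like bundle
# ---------------------------------------------------------------------------


def default_study_config(
    n_individuals: int = 1065,
    seed: int = 0,
    exact_frequencies: bool = True,
    discretize: bool = True,
    missing_rate: float = 0.005,
) -> SimulationConfig:
    """The generator's default conditions: the 32-variant study panel."""
    variants = [
        VariantRecord(vid, locus, chrom, pos, ea, nea, eaf)
        for vid, locus, chrom, pos, ea, nea, eaf, _ in STUDY_PANEL + STUDY_HWE_VIOLATOR_ROWS
    ]
    betas = {row[0]: row[7] for row in STUDY_PANEL + STUDY_HWE_VIOLATOR_ROWS}
    cfg = SimulationConfig(
        variants=variants,
        n_individuals=n_individuals,
        ld_pairs=list(STUDY_LD_PAIRS),
        hwe_violations=list(STUDY_HWE_VIOLATIONS),
        missing_rate=missing_rate,
        true_snp_betas=betas,
        exact_frequencies=exact_frequencies,
        discretize=discretize,
        seed=seed,
    )
    return _recenter(cfg)


def make_study_cohort(seed: int = 0, n_individuals: int = 1065, **config_overrides) -> CohortBundle:
    """Generate the study-like bundle: panel, cohort and generating truth."""
    config = default_study_config(n_individuals=n_individuals, seed=seed, **config_overrides)
    rng = np.random.default_rng(seed)
    panel = simulate_genotypes(config, rng)
    cohort = simulate_covariates(config, rng)
    cohort = simulate_phenotype(panel, cohort, config, rng)
    return CohortBundle(panel=panel, cohort=cohort, truth=config)
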