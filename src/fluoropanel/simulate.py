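"""Synthetic cohort generation.

Real genotype-by-toxicity data of the kind this package analyses comes from
clinical trials and is access-restricted, so every analysis path here is
exercised on synthetic cohorts that emulate an 888-patient adjuvant
capecitabine trial:

* **Genotypes** are drawn independently per variant under Hardy-Weinberg
  proportions (1-q)^2, 2q(1-q), q^2. Default allele frequencies come from
  the bundled catalogue's European values: common toxicity-risk SNPs at
  MAF 0.07-0.43, rare DPD-deficiency alleles at frequencies giving expected
  carrier counts of 0-2 per 888 patients.
* **Toxicity grades** come from a logistic liability model per endpoint:
  P(grade >= 3) = expit(logit(baseline) + sum_v dosage_v * ln OR_v), with a
  configured fraction of grade >= 3 events escalated to grade 4, grades 0-2
  assigned to non-events in fixed proportions, and treatment-related death
  sampled only among patients with a grade 4 event. Default effect sizes
  follow the reported associations: OR 4.4 per no-function allele and 1.59
  per decreased-function allele on the DPD-driven endpoints, OR 3.8 for the
  strongest common SNP (rs12132152) and 2.0 for the ENOSF1 allele
  (rs2612091) on hand-foot syndrome. Endpoints are conditionally
  independent given genotype.
* **Planted-strata cohorts** construct genotypes that guarantee each
  sample's risk tier, so classification can be validated by round-trip;
  the default stratum sizes are (critical 2, high 52, standard 236,
  standard-with-high-HFS-risk 598).

Every cohort records its seed and is byte-reproducible from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .catalog import Catalog, FunctionClass, default_catalog
from .diagnostics import Endpoint
from .genotypes import GenotypeMatrix
from .scoring import RiskTier

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "default_config",
    "simulate_genotypes",
    "simulate_toxicity",
    "simulate_cohort",
    "planted_strata_cohort",
    "write_vcf",
    "DEFAULT_STRATA_COUNTS",
]

#: default planted stratum sizes for an 888-patient cohort
DEFAULT_STRATA_COUNTS = {
    RiskTier.CRITICAL.value: 2,
    RiskTier.HIGH.value: 52,
    RiskTier.STANDARD.value: 236,
    RiskTier.STANDARD_HIGH_HFS.value: 598,
}

#: graded endpoints the generator simulates directly
SIMULATED_ENDPOINTS = (
    Endpoint.DIARRHOEA.value,
    Endpoint.VOMITING.value,
    Endpoint.HFS.value,
    Endpoint.NEUTROPENIA.value,
    Endpoint.THROMBOCYTOPENIA.value,
    Endpoint.MUCOSITIS_STOMATITIS.value,
)

_DEFAULT_BASELINE_G34 = {
    Endpoint.DIARRHOEA.value: 0.07,
    Endpoint.VOMITING.value: 0.03,
    Endpoint.HFS.value: 0.23,
    Endpoint.NEUTROPENIA.value: 0.02,
    Endpoint.THROMBOCYTOPENIA.value: 0.008,
    Endpoint.MUCOSITIS_STOMATITIS.value: 0.018,
}

# P(grade 4 | grade >= 3); HFS and mucositis cap at grade 3
_DEFAULT_GRADE4_FRACTION = {
    Endpoint.DIARRHOEA.value: 0.14,
    Endpoint.VOMITING.value: 0.05,
    Endpoint.HFS.value: 0.0,
    Endpoint.NEUTROPENIA.value: 0.17,
    Endpoint.THROMBOCYTOPENIA.value: 0.10,
    Endpoint.MUCOSITIS_STOMATITIS.value: 0.0,
}

_DPD_DRIVEN_ENDPOINTS = (
    Endpoint.DIARRHOEA.value,
    Endpoint.VOMITING.value,
    Endpoint.NEUTROPENIA.value,
    Endpoint.THROMBOCYTOPENIA.value,
    Endpoint.MUCOSITIS_STOMATITIS.value,
)

_NO_FUNCTION_OR = 4.4       # per no-function allele, DPD-driven endpoints
_DECREASED_FUNCTION_OR = 1.59  # per decreased-function allele (HapB3 HR as OR)
_COMMON_SNP_ORS = {
    # (variant_id, endpoint) -> odds ratio per risk allele
    ("rs2612091", Endpoint.HFS.value): 2.0,
    ("rs12132152", Endpoint.HFS.value): 3.8,
    ("rs12022243", Endpoint.HFS.value): 1.5,
    ("rs12022243", Endpoint.DIARRHOEA.value): 1.5,
    ("rs895819", Endpoint.DIARRHOEA.value): 1.6,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 888
    allele_freq: Mapping[str, float] = field(default_factory=dict)
    baseline_grade34: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE_G34)
    )
    grade4_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GRADE4_FRACTION)
    )
    #: (variant_id, endpoint) -> odds ratio per risk allele
    effect_sizes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    #: baseline P(death | >=1 grade-4 event)
    death_given_grade4: float = 0.13
    #: grade distribution among non-events (grades 0, 1, 2)
    grade_probs_nonevent: tuple[float, float, float] = (0.60, 0.25, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        for vid, q in self.allele_freq.items():
            if not 0.0 <= q <= 0.5:
                raise ConfigError(
                    f"allele frequency for {vid!r} is {q}, outside [0, 0.5]"
                )
        for ep, p in self.baseline_grade34.items():
            if not 0.0 < p < 1.0:
                raise ConfigError(
                    f"baseline grade>=3 prevalence for {ep!r} is {p}, "
                    "must be in (0, 1)"
                )
        for ep, f in self.grade4_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"grade-4 fraction for {ep!r} outside [0, 1]")
        for key, odds_ratio in self.effect_sizes.items():
            if odds_ratio <= 0:
                raise ConfigError(f"odds ratio for {key} must be > 0")
        if not np.isclose(sum(self.grade_probs_nonevent), 1.0):
            raise ConfigError("grade_probs_nonevent must sum to 1")


def default_config(catalog: Catalog | None = None, seed: int = 0, n_samples: int = 888) -> SimulationConfig:
    """Study-condition defaults derived from the bundled catalogue.

    Allele frequencies are the catalogue's European MAFs; effect sizes are
    the reported per-allele odds ratios (4.4 no-function, 1.59 decreased
    function, common-SNP effects on HFS/diarrhoea).
    """
    catalog = catalog or default_catalog()
    freqs = {
        v.variant_id: float(v.maf_by_population.get("EUR", 0.0))
        for v in catalog.variants
    }
    effects: dict[tuple[str, str], float] = {}
    for v in catalog.variants:
        if v.function_class is FunctionClass.NO_FUNCTION:
            for ep in _DPD_DRIVEN_ENDPOINTS:
                effects[(v.variant_id, ep)] = _NO_FUNCTION_OR
            effects[(v.variant_id, Endpoint.DEATH.value)] = _NO_FUNCTION_OR
        elif v.function_class is FunctionClass.DECREASED_FUNCTION:
            for ep in _DPD_DRIVEN_ENDPOINTS:
                effects[(v.variant_id, ep)] = _DECREASED_FUNCTION_OR
    effects.update(_COMMON_SNP_ORS)
    return SimulationConfig(
        n_samples=n_samples, allele_freq=freqs, effect_sizes=effects, seed=seed
    )


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw dosages under HWE, independently across variants."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_samples
    data = {
        vid: rng.binomial(2, q, size=n).astype(float)
        for vid, q in config.allele_freq.items()
    }
    return GenotypeMatrix(pd.DataFrame(data, index=_sample_ids(n)))


def simulate_toxicity(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-endpoint CTCAE grades from a logistic liability model.

    Returns a long-form toxicity table (sample_id, endpoint, grade) covering
    the six component endpoints plus binary death. Effects referencing
    variants absent from the genotype matrix are ignored (dosage zero).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    dosages = genotypes.dosages.fillna(0.0)
    n = len(dosages)
    endpoints = list(config.baseline_grade34)
    for _, ep in config.effect_sizes:
        if ep not in endpoints and ep != Endpoint.DEATH.value:
            raise ConfigError(
                f"effect size references endpoint {ep!r} but no baseline "
                "prevalence is configured for it"
            )
    frames = []
    any_grade4 = np.zeros(n, dtype=bool)
    for endpoint in endpoints:
        eta = np.full(n, logit(config.baseline_grade34[endpoint]))
        for (vid, ep), odds_ratio in config.effect_sizes.items():
            if ep == endpoint and vid in dosages.columns:
                eta = eta + dosages[vid].to_numpy() * np.log(odds_ratio)
        event = rng.random(n) < expit(eta)
        grade4 = event & (
            rng.random(n) < config.grade4_fraction.get(endpoint, 0.0)
        )
        any_grade4 |= grade4
        grades = np.where(event, np.where(grade4, 4, 3), 0)
        nonevent = ~event
        grades[nonevent] = rng.choice(
            [0, 1, 2], size=int(nonevent.sum()), p=config.grade_probs_nonevent
        )
        frames.append(
            pd.DataFrame(
                {"sample_id": dosages.index, "endpoint": endpoint, "grade": grades}
            )
        )
    # treatment-related death: only among patients with a grade-4 event
    eta_death = np.full(n, logit(config.death_given_grade4))
    for (vid, ep), odds_ratio in config.effect_sizes.items():
        if ep == Endpoint.DEATH.value and vid in dosages.columns:
            eta_death = eta_death + dosages[vid].to_numpy() * np.log(odds_ratio)
    death = any_grade4 & (rng.random(n) < expit(eta_death))
    frames.append(
        pd.DataFrame(
            {
                "sample_id": dosages.index,
                "endpoint": Endpoint.DEATH.value,
                "grade": death.astype(int),
            }
        )
    )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth."""

    genotypes: GenotypeMatrix
    toxicity: pd.DataFrame
    truth: pd.DataFrame  # per-sample: planted_tier (may be NA)
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Genotypes + toxicity under the configured study conditions."""
    config = config or default_config()
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    toxicity = simulate_toxicity(genotypes, config, rng)
    truth = pd.DataFrame(
        {"planted_tier": pd.Series(pd.NA, index=genotypes.dosages.index)}
    )
    return SyntheticCohort(genotypes, toxicity, truth, config)


# genotype templates guaranteeing a tier; cycled deterministically within
# each stratum. Entries are {variant_id: dosage}.
_CRITICAL_TEMPLATES = (
    {"rs1801266": 2},                      # two no-function alleles, AS 0
    {"rs3918290": 1, "rs56038477": 1},     # no-function + decreased, AS 0.5
)
_HIGH_TEMPLATES = (
    {"rs3918290": 1},      # one no-function allele, AS 1
    {"rs67376798": 1},     # one decreased-function allele, AS 1.5
    {"rs56038477": 1},     # HapB3 heterozygote, AS 1.5
    {"rs56038477": 2},     # HapB3 homozygote, AS 1
    {"rs777425216": 1},    # rare no-function allele, AS 1
)
_HFS_TEMPLATES = (
    {"rs2612091": 1},
    {"rs2612091": 2},
    {"rs12132152": 1},
    {"rs2612091": 1, "rs12132152": 1},
)


def planted_strata_cohort(
    counts: Mapping[str, int] | None = None,
    config: SimulationConfig | None = None,
) -> SyntheticCohort:
    """Cohort whose genotypes guarantee the planted tier of every sample.

    ``counts`` maps tier name -> number of samples (default 2/52/236/598).
    Deficiency and HFS genotypes are set from per-tier templates; all other
    catalogue variants are dosage 0. Toxicity is then simulated from the
    planted genotypes under ``config``.
    """
    counts = dict(counts) if counts is not None else dict(DEFAULT_STRATA_COUNTS)
    unknown = set(counts) - {t.value for t in RiskTier}
    if unknown:
        raise ConfigError(f"unknown tier(s) in counts: {sorted(unknown)}")
    if any(c < 0 for c in counts.values()):
        raise ConfigError("stratum counts must be non-negative")
    n = sum(counts.values())
    if config is None:
        config = replace(default_config(), n_samples=n)
    elif config.n_samples != n:
        raise ConfigError(
            f"counts sum to {n} but config.n_samples = {config.n_samples}"
        )
    catalog = default_catalog()
    variant_ids = [v.variant_id for v in catalog.variants]
    dosages = pd.DataFrame(
        0.0, index=_sample_ids(n), columns=variant_ids
    )
    tiers: list[str] = []
    row = 0
    plan = (
        (RiskTier.CRITICAL.value, _CRITICAL_TEMPLATES),
        (RiskTier.HIGH.value, _HIGH_TEMPLATES),
        (RiskTier.STANDARD.value, ({},)),
        (RiskTier.STANDARD_HIGH_HFS.value, _HFS_TEMPLATES),
    )
    for tier, templates in plan:
        for i in range(counts.get(tier, 0)):
            for vid, dose in templates[i % len(templates)].items():
                dosages.iloc[row, dosages.columns.get_loc(vid)] = float(dose)
            tiers.append(tier)
            row += 1
    genotypes = GenotypeMatrix(dosages)
    rng = np.random.default_rng(config.seed)
    toxicity = simulate_toxicity(genotypes, config, rng)
    truth = pd.DataFrame(
        {"planted_tier": pd.Series(tiers, index=dosages.index)}
    )
    return SyntheticCohort(genotypes, toxicity, truth, config)


def write_vcf(
    matrix: GenotypeMatrix, catalog: Catalog, path: str | Path
) -> None:
    """Emit the dosage matrix as a VCF 4.2 file with GT calls.

    Only catalogue variants with genomic coordinates are written; dosage is
    expressed relative to the catalogue risk allele. Round-trips through
    :func:`fluoropanel.genotypes.read_genotypes`.
    """
    variants = [
        catalog.variant(vid)
        for vid in matrix.variant_ids
        if catalog.variant(vid).chrom is not None
    ]
    variants.sort(key=lambda v: (v.chrom, v.pos))
    contigs = sorted({v.chrom for v in variants})
    samples = matrix.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fluoropanel-simulator\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            col = matrix.dosage(v.variant_id)
            risk_is_alt = v.risk_allele == v.alt
            gts = []
            for d in col.to_numpy():
                if np.isnan(d):
                    gts.append("./.")
                    continue
                n_risk = int(d)
                n_alt = n_risk if risk_is_alt else 2 - n_risk
                gts.append(("0/0", "0/1", "1/1")[n_alt])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
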