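"""Variant catalogue and panel-model definitions.

A catalogue is the single source of truth for the analysis: every variant a
panel may genotype, its DPD function class and per-allele activity value, and
the named panel models (sets of variants plus a positivity cut-point) built
from those variants. A curated default catalogue covering 22 candidate
variants and panel models 1-15 ships with the package
(:func:`default_catalog`).

Function classes and per-allele activity values follow the CPIC convention
for DPD phenotype prediction: a normal allele contributes 1.0, a decreased
function allele 0.5 and a no-function allele 0.0 to the diploid activity
score. Common toxicity-risk SNPs (criterion-1 variants such as the ENOSF1
hand-foot-syndrome allele) do not alter DPD activity and carry 1.0.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "FunctionClass",
    "InclusionCriterion",
    "VariantDef",
    "PanelModel",
    "Catalog",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "default_catalog",
]


class CatalogError(ValueError):
    """Raised when a catalogue file is malformed or internally inconsistent."""


class FunctionClass(str, Enum):
    NO_FUNCTION = "no_function"
    DECREASED_FUNCTION = "decreased_function"
    COMMON_TOXICITY_RISK = "common_toxicity_risk"

    @property
    def allele_activity(self) -> float:
        """Per-allele DPD activity value implied by the function class."""
        return _ACTIVITY[self]


_ACTIVITY = {
    FunctionClass.NO_FUNCTION: 0.0,
    FunctionClass.DECREASED_FUNCTION: 0.5,
    FunctionClass.COMMON_TOXICITY_RISK: 1.0,
}


class InclusionCriterion(str, Enum):
    #: common variant with statistical evidence of association with global
    #: fluoropyrimidine toxicity (>=1 study, >=500 patients, OR/HR >= 1.5)
    CRITERION1_COMMON = "criterion1_common"
    #: DPYD variant identified in >=1 patient with DPD deficiency, with
    #: supporting functional evidence
    CRITERION2_DEFICIENCY = "criterion2_deficiency"


@dataclass(frozen=True)
class VariantDef:
    """One catalogued variant.

    ``variant_id`` is the primary key (an rsID where one is established,
    otherwise an HGVS-style short name); ``hgvs_name`` is descriptive
    metadata. ``risk_allele`` is the toxicity-associated allele expressed on
    the VCF reference strand; genotype dosages count copies of this allele.
    """

    variant_id: str
    hgvs_name: str
    gene: str
    function_class: FunctionClass
    risk_allele: str
    inclusion_criterion: InclusionCriterion
    maf_by_population: Mapping[str, float] = field(default_factory=dict)
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    detected: bool = False
    provenance: str = "curated"

    @property
    def allele_activity(self) -> float:
        return self.function_class.allele_activity

    @property
    def is_deficiency(self) -> bool:
        """True for alleles that reduce DPD activity (activity < 1.0)."""
        return self.function_class is not FunctionClass.COMMON_TOXICITY_RISK

    def __post_init__(self) -> None:
        for pop, freq in self.maf_by_population.items():
            if not 0.0 <= freq <= 1.0:
                raise CatalogError(
                    f"variant {self.variant_id!r}: MAF for population "
                    f"{pop!r} is {freq}, outside [0, 1]"
                )


@dataclass(frozen=True)
class PanelModel:
    """A named panel: an ordered set of variants and a positivity cut-point.

    The panel's binary test is positive when the summed risk-allele count
    across the panel variants is at or above ``cutpoint`` (default 1).
    """

    model_id: str
    variant_ids: tuple[str, ...]
    cutpoint: int = 1

    def __post_init__(self) -> None:
        if self.cutpoint < 1:
            raise CatalogError(
                f"model {self.model_id!r}: cutpoint must be >= 1, "
                f"got {self.cutpoint}"
            )
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise CatalogError(
                f"model {self.model_id!r}: duplicate variant ids"
            )


@dataclass(frozen=True)
class Catalog:
    """Validated collection of variants and panel models."""

    variants: tuple[VariantDef, ...]
    models: tuple[PanelModel, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for v in self.variants:
            if v.variant_id in seen:
                raise CatalogError(f"duplicate variant_id {v.variant_id!r}")
            seen.add(v.variant_id)
        model_ids: set[str] = set()
        for m in self.models:
            if m.model_id in model_ids:
                raise CatalogError(f"duplicate model_id {m.model_id!r}")
            model_ids.add(m.model_id)
            missing = [vid for vid in m.variant_ids if vid not in seen]
            if missing:
                raise CatalogError(
                    f"model {m.model_id!r} references unknown variant(s) "
                    f"{missing}"
                )

    # -- lookups -----------------------------------------------------------
    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(v.variant_id for v in self.variants)

    def variant(self, variant_id: str) -> VariantDef:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(f"unknown variant_id {variant_id!r}")

    def model(self, model_id: str) -> PanelModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(f"unknown model_id {model_id!r}")

    def model_variants(self, model_id: str) -> list[VariantDef]:
        """Resolve a model's variants, in the model's declared order."""
        return [self.variant(vid) for vid in self.model(model_id).variant_ids]

    def deficiency_variants(self) -> list[VariantDef]:
        """All DPYD alleles that reduce DPD activity."""
        return [v for v in self.variants if v.is_deficiency]

    def detected_variants(self) -> list[VariantDef]:
        return [v for v in self.variants if v.detected]

    def subset(self, variant_ids: Iterable[str]) -> "Catalog":
        keep = set(variant_ids)
        return Catalog(
            variants=tuple(v for v in self.variants if v.variant_id in keep),
            models=(),
        )


# -- file I/O --------------------------------------------------------------

_REQUIRED_VARIANT_FIELDS = (
    "variant_id",
    "hgvs_name",
    "gene",
    "function_class",
    "risk_allele",
    "inclusion_criterion",
)


def _parse_variant(rec: Mapping) -> VariantDef:
    missing = [k for k in _REQUIRED_VARIANT_FIELDS if k not in rec]
    if missing:
        raise CatalogError(
            f"variant record {rec.get('variant_id', '<no id>')!r}: "
            f"missing required field(s) {missing}"
        )
    try:
        fclass = FunctionClass(rec["function_class"])
    except ValueError:
        raise CatalogError(
            f"variant {rec['variant_id']!r}: unknown function_class "
            f"{rec['function_class']!r}"
        ) from None
    try:
        criterion = InclusionCriterion(rec["inclusion_criterion"])
    except ValueError:
        raise CatalogError(
            f"variant {rec['variant_id']!r}: unknown inclusion_criterion "
            f"{rec['inclusion_criterion']!r}"
        ) from None
    if "allele_activity" in rec and float(rec["allele_activity"]) != fclass.allele_activity:
        raise CatalogError(
            f"variant {rec['variant_id']!r}: allele_activity "
            f"{rec['allele_activity']} inconsistent with function_class "
            f"{fclass.value} (expected {fclass.allele_activity}); change the "
            f"function class instead of overriding the activity value"
        )
    return VariantDef(
        variant_id=str(rec["variant_id"]),
        hgvs_name=str(rec["hgvs_name"]),
        gene=str(rec["gene"]),
        function_class=fclass,
        risk_allele=str(rec["risk_allele"]),
        inclusion_criterion=criterion,
        maf_by_population=dict(rec.get("maf", {})),
        chrom=str(rec["chrom"]) if "chrom" in rec else None,
        pos=int(rec["pos"]) if "pos" in rec else None,
        ref=str(rec["ref"]) if "ref" in rec else None,
        alt=str(rec["alt"]) if "alt" in rec else None,
        detected=bool(rec.get("detected", False)),
        provenance=str(rec.get("provenance", "curated")),
    )


def load_catalog(path: str | Path) -> Catalog:
    """Load and validate a catalogue (variants + models) from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _catalog_from_doc(doc)


def _catalog_from_doc(doc: Mapping) -> Catalog:
    if not isinstance(doc, Mapping) or "variants" not in doc:
        raise CatalogError("catalogue file must contain a 'variants' list")
    variants = tuple(_parse_variant(rec) for rec in doc["variants"])
    models = []
    for rec in doc.get("models", []):
        if "model_id" not in rec or "variants" not in rec:
            raise CatalogError(
                f"model record {rec.get('model_id', '<no id>')!r}: "
                "requires 'model_id' and 'variants'"
            )
        models.append(
            PanelModel(
                model_id=str(rec["model_id"]),
                variant_ids=tuple(str(v) for v in rec["variants"]),
                cutpoint=int(rec.get("cutpoint", 1)),
            )
        )
    return Catalog(variants=variants, models=tuple(models))


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalogue back to YAML; round-trips through load_catalog."""
    doc = {
        "variants": [
            {
                "variant_id": v.variant_id,
                "hgvs_name": v.hgvs_name,
                "gene": v.gene,
                "function_class": v.function_class.value,
                "inclusion_criterion": v.inclusion_criterion.value,
                "risk_allele": v.risk_allele,
                **({"chrom": v.chrom} if v.chrom is not None else {}),
                **({"pos": v.pos} if v.pos is not None else {}),
                **({"ref": v.ref} if v.ref is not None else {}),
                **({"alt": v.alt} if v.alt is not None else {}),
                "detected": v.detected,
                "provenance": v.provenance,
                "maf": dict(v.maf_by_population),
            }
            for v in catalog.variants
        ],
        "models": [
            {
                "model_id": m.model_id,
                "cutpoint": m.cutpoint,
                "variants": list(m.variant_ids),
            }
            for m in catalog.models
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def default_catalog() -> Catalog:
    """The bundled 22-variant catalogue with panel models 1-15."""
    ref = importlib.resources.files("fluoropanel.data") / "default_catalog.yaml"
    doc = yaml.safe_load(ref.read_text())
    return _catalog_from_doc(doc)
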