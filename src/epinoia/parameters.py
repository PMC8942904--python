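"""Phenotypic variance, heritabilities, and genetic-variance partitions.

The plot-level phenotypic variance sums the model's components with the
spatial contribution entering as nine times the per-position variance (each
plot is covered by nine position effects):

    sigma_P^2 = sigma_l^2 [+ sigma_g^2 [+ sigma_h^2]] + sigma_f^2
                + 9 sigma_s^2 + sigma_e^2

Narrow-sense plot heritability h^2 = sigma_g^2 / sigma_P^2 is meaningful only
for the purely additive genomic model: when an epistatic term is present the
partition of genetic variance is not orthogonal and the additive estimate is
not interpretable on its own, so requesting h^2 there emits a warning.
Broad-sense H^2 divides the model's total genetic variance (line + genomic
terms) by sigma_P^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import InputError, UndefinedStatisticError
from .mixed_model import MODEL_TERMS, VarianceComponents

__all__ = [
    "HeritabilityReport",
    "phenotypic_variance",
    "narrow_sense_h2",
    "broad_sense_H2",
    "total_genetic_variance",
    "variance_partition",
    "heritability_report",
]

_GENETIC = {"I": ("line",), "I+GA": ("line", "additive"),
            "I+GA+GAA": ("line", "additive", "epistatic")}


def _components(vc: VarianceComponents, model: str) -> dict[str, float]:
    if model not in MODEL_TERMS:
        raise InputError(f"unknown model {model!r}; choose from {list(MODEL_TERMS)}")
    needed = list(MODEL_TERMS[model]) + ["error"]
    missing = [nm for nm in needed if nm not in vc.sigma2]
    if missing:
        raise InputError(f"variance components missing for model {model!r}: {missing}")
    bad = {nm: v for nm, v in vc.sigma2.items() if v < 0}
    if bad:
        raise InputError(f"negative variance components: {bad} (floor them upstream)")
    return {nm: vc.sigma2[nm] for nm in needed}


def phenotypic_variance(vc: VarianceComponents, model: str | None = None) -> float:
    """Plot phenotypic variance: component sum with spatial counted 9x."""
    model = model or vc.model
    comp = _components(vc, model)
    total = 0.0
    for nm, v in comp.items():
        total += 9.0 * v if nm == "spatial" else v
    return total


def total_genetic_variance(vc: VarianceComponents, model: str | None = None) -> float:
    """sigma_G^2: line (I), + additive (I+GA), + epistatic (I+GA+GAA)."""
    model = model or vc.model
    comp = _components(vc, model)
    return sum(comp[nm] for nm in _GENETIC[model])


def narrow_sense_h2(vc: VarianceComponents, model: str | None = None) -> float:
    """h^2 = sigma_g^2 / sigma_P^2 (additive genomic model)."""
    model = model or vc.model
    if model == "I":
        raise InputError("the I-model has no additive genomic component; h^2 undefined")
    if model == "I+GA+GAA":
        warnings.warn(
            "narrow-sense h^2 under I+GA+GAA is not interpretable: the additive "
            "and epistatic variances do not partition orthogonally",
            UserWarning, stacklevel=2)
    sp2 = phenotypic_variance(vc, model)
    if sp2 == 0.0:
        raise UndefinedStatisticError("phenotypic variance is zero; h^2 undefined")
    return vc.sigma2["additive"] / sp2


def broad_sense_H2(vc: VarianceComponents, model: str | None = None) -> float:
    """H^2 = sigma_G^2 / sigma_P^2 with the model-specific genetic sum."""
    model = model or vc.model
    sp2 = phenotypic_variance(vc, model)
    if sp2 == 0.0:
        raise UndefinedStatisticError("phenotypic variance is zero; H^2 undefined")
    return total_genetic_variance(vc, model) / sp2


def variance_partition(vc: VarianceComponents, model: str | None = None) -> dict[str, float]:
    """Share of each genetic component (line / additive / epistatic) in sigma_G^2."""
    model = model or vc.model
    sg2 = total_genetic_variance(vc, model)
    if sg2 == 0.0:
        raise UndefinedStatisticError("total genetic variance is zero; partition undefined")
    comp = _components(vc, model)
    return {nm: comp[nm] / sg2 for nm in _GENETIC[model]}


@dataclass
class HeritabilityReport:
    """Heritability summary for one model fit.

    Raw precision is retained; ``rounded()`` mirrors the 2-decimal
    (heritabilities) / 3-decimal (variances) reporting convention.
    """

    model: str
    phenotypic_variance: float
    total_genetic_variance: float
    h2: float | None
    H2: float
    partition: dict[str, float]

    def rounded(self) -> dict:
        return {
            "model": self.model,
            "phenotypic_variance": round(self.phenotypic_variance, 3),
            "total_genetic_variance": round(self.total_genetic_variance, 3),
            "h2": None if self.h2 is None else round(self.h2, 2),
            "H2": round(self.H2, 2),
            "partition_pct": {k: round(100.0 * v, 1) for k, v in self.partition.items()},
        }

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "phenotypic_variance": self.phenotypic_variance,
            "total_genetic_variance": self.total_genetic_variance,
            "h2": self.h2,
            "H2": self.H2,
            "partition": dict(self.partition),
        }


def heritability_report(vc: VarianceComponents, model: str | None = None) -> HeritabilityReport:
    model = model or vc.model
    h2 = narrow_sense_h2(vc, model) if model == "I+GA" else None
    return HeritabilityReport(
        model=model,
        phenotypic_variance=phenotypic_variance(vc, model),
        total_genetic_variance=total_genetic_variance(vc, model),
        h2=h2,
        H2=broad_sense_H2(vc, model),
        partition=variance_partition(vc, model),
    )
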