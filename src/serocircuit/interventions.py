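"""Experimental conditions: inflammation levels, drug treatments, variants.

Treatments are parameter edits on a copy of the base model:

* ``ssri`` lowers transporter affinity (Michaelis constant Km: 170 -> 200 nM);
* ``antiinflammatory`` attenuates the cytokine term inside the synthesis/
  reuptake factors (blocker B: 1 -> 0.55);
* ``combined`` applies both.

Two mechanistic variants complement the baseline circuit: an NMDA
excitotoxicity variant (SCC NMDA time constant scaled by 1.05, modelling
kynurenine-pathway agonism of NMDA receptors) and a postsynaptic
receptor-density reduction (SCC R scaled by 0.92, modelling the reduced SCC
5HT1A density reported in depression; the PFC's 5HT2A density is left
untouched, which keeps PFC observables at their baseline values).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .params import DEGREE_LEVELS, InflammationCondition, ModelParams

__all__ = [
    "TreatmentSpec", "VariantSpec", "ConditionSpec",
    "TREATMENTS", "VARIANTS",
    "degree_of_inflammation", "apply_treatment", "apply_variant",
    "build_condition_params", "build_condition_grid",
]


@dataclass(frozen=True)
class TreatmentSpec:
    """A drug treatment as a (Km, B) parameter assignment."""

    name: str
    Km_value: float   # nM
    B_value: float


TREATMENTS: dict[str, TreatmentSpec] = {
    "none": TreatmentSpec("none", 170.0, 1.0),
    "ssri": TreatmentSpec("ssri", 200.0, 1.0),
    "antiinflammatory": TreatmentSpec("antiinflammatory", 170.0, 0.55),
    "combined": TreatmentSpec("combined", 200.0, 0.55),
}


@dataclass(frozen=True)
class VariantSpec:
    """A mechanistic model variant as multiplicative parameter scalings."""

    name: str
    tau_NMDA_scale_SCC: float = 1.0
    R_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_NMDA_scale_SCC <= 0 or self.R_scale <= 0:
            raise ValueError("variant scale factors must be positive")


VARIANTS: dict[str, VariantSpec] = {
    "baseline": VariantSpec("baseline"),
    "nmda_excitotoxicity": VariantSpec("nmda_excitotoxicity", tau_NMDA_scale_SCC=1.05),
    "receptor_reduction": VariantSpec("receptor_reduction", R_scale=0.92),
}


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the condition grid: degree x treatment x variant."""

    degree_label: str
    treatment: TreatmentSpec
    variant: VariantSpec = field(default_factory=lambda: VARIANTS["baseline"])

    def __post_init__(self) -> None:
        if self.degree_label not in DEGREE_LEVELS:
            raise ValueError(f"unknown degree label {self.degree_label!r}")

    @property
    def degree(self) -> float:
        return DEGREE_LEVELS[self.degree_label]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.degree_label, self.treatment.name, self.variant.name)


def degree_of_inflammation(cyt: float, cyt_b: float) -> float:
    """Degree of inflammation: TNFα fold-elevation [Cyt]/[Cyt]b."""
    if cyt_b <= 0:
        raise ValueError("basal cytokine concentration must be > 0")
    if cyt < 0:
        raise ValueError("cytokine concentration must be >= 0")
    return cyt / cyt_b


def apply_treatment(base_params: ModelParams, spec: TreatmentSpec | str
                    ) -> ModelParams:
    """Return a copy of ``base_params`` with Km and B set per the treatment."""
    if isinstance(spec, str):
        try:
            spec = TREATMENTS[spec]
        except KeyError:
            raise ValueError(f"unknown treatment {spec!r}") from None
    return base_params.replace(
        kin_pfc=dataclasses.replace(base_params.kin_pfc, Km=spec.Km_value),
        kin_scc=dataclasses.replace(base_params.kin_scc, Km=spec.Km_value),
        inflammation=dataclasses.replace(base_params.inflammation, B=spec.B_value),
    )


def apply_variant(base_params: ModelParams, spec: VariantSpec | str
                  ) -> ModelParams:
    """Return a copy of ``base_params`` with the variant scalings applied.

    Both scalings target the SCC: the NMDA time constant by construction,
    and the receptor density because the variant models the reduced
    postsynaptic 5HT1A density of the SCC specifically — scaling the PFC's
    5HT2A density as well would depress PFC serotonin, which the variant is
    not meant to touch.
    """
    if isinstance(spec, str):
        try:
            spec = VARIANTS[spec]
        except KeyError:
            raise ValueError(f"unknown variant {spec!r}") from None
    return base_params.replace(
        scc=dataclasses.replace(
            base_params.scc,
            R=base_params.scc.R * spec.R_scale,
            tau_NMDA=base_params.scc.tau_NMDA * spec.tau_NMDA_scale_SCC),
    )


def build_condition_params(spec: ConditionSpec,
                           base_params: ModelParams | None = None) -> ModelParams:
    """Effective model parameters for one grid condition."""
    params = base_params if base_params is not None else ModelParams()
    params = params.replace(
        inflammation=InflammationCondition(degree=spec.degree,
                                           B=params.inflammation.B))
    params = apply_treatment(params, spec.treatment)
    params = apply_variant(params, spec.variant)
    return params


def build_condition_grid() -> list[ConditionSpec]:
    """Full deterministic grid: 3 variants x 4 degrees x 4 treatments = 48.

    Ordering: baseline variant first, degrees from control to severe,
    treatments none/ssri/antiinflammatory/combined innermost; the first
    element is (control, none, baseline).
    """
    return [
        ConditionSpec(degree_label=deg, treatment=TREATMENTS[trt],
                      variant=VARIANTS[var])
        for var in ("baseline", "nmda_excitotoxicity", "receptor_reduction")
        for deg in ("control", "mild", "moderate", "severe")
        for trt in ("none", "ssri", "antiinflammatory", "combined")
    ]
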