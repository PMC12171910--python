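"""Prediction-equation library: new predictors, published forms, transforms.

Houses the two newly developed predictor forms (%BF from log10 of the sum
of four skinfolds plus sex; TBW from the 50 kHz resistance index plus
weight and sex), the density-to-%BF transforms (Siri and the age/sex
adjusted Weststrate-Deurenberg modification recommended for children), and
a registry of published comparison equations.

Registry caveat: entries flagged ``coefficients_verified: false`` carry
synthetic placeholder coefficients standing in for published values that
could not be transcribed from the original sources here; they exercise the
dispatch and comparison machinery and must be replaced from the cited
publications before any real-data use.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .cole import ColeParameters
from .dilution import BodyComposition, HydrationTable, composition_from_ffm

__all__ = [
    "PredictionEquation",
    "load_equation_registry",
    "ssf_pbf",
    "bia_tbw",
    "siri_pbf",
    "weststrate_deurenberg_pbf",
    "evaluate_equation",
]

_FORMS = ("pbf_log10_ssf", "density_log10_ssf", "linear_bia")


@dataclass(frozen=True)
class PredictionEquation:
    """A published or newly fitted predictor with named coefficients."""

    eq_id: str
    citation: str
    output_kind: str            # pbf | density | tbw | ffm
    functional_form: str
    coefficients: Mapping[str, object]
    sex_specific: bool = False
    coefficients_verified: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.output_kind not in ("pbf", "density", "tbw", "ffm"):
            raise ValueError(f"unknown output_kind {self.output_kind!r}")
        if self.functional_form not in _FORMS:
            raise ValueError(
                f"unknown functional_form {self.functional_form!r}")
        if self.sex_specific:
            missing = {"male", "female"} - set(self.coefficients)
            if missing:
                raise ValueError(
                    f"{self.eq_id}: sex-specific equation missing {missing}")


def load_equation_registry() -> dict[str, PredictionEquation]:
    ref = importlib.resources.files("bodycomp.data").joinpath(
        "equation_registry.json")
    with ref.open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return {eq_id: PredictionEquation(eq_id=eq_id, **entry)
            for eq_id, entry in raw.items()}


def ssf_pbf(skinfolds_mm, sex: int, coeffs: tuple[float, float, float]
            ) -> float:
    """%BF = b0 + b1*log10(SSF) + b2*sex with SSF the sum of 4 sites."""
    ssf = float(sum(skinfolds_mm))
    if ssf <= 0 or any(s <= 0 for s in skinfolds_mm):
        raise ValueError("skinfolds must be positive")
    b0, b1, b2 = coeffs
    return b0 + b1 * math.log10(ssf) + b2 * sex


def bia_tbw(r50_ohm: float, height_cm: float, weight_kg: float, sex: int,
            coeffs: tuple[float, float, float, float]) -> float:
    """TBW = c0 + c1*RI + c2*weight + c3*sex, RI = height^2/R50 (cm^2/ohm)."""
    if min(r50_ohm, height_cm, weight_kg) <= 0:
        raise ValueError("inputs must be positive")
    c0, c1, c2, c3 = coeffs
    ri = height_cm ** 2 / r50_ohm
    return c0 + c1 * ri + c2 * weight_kg + c3 * sex


def siri_pbf(density_kg_per_l: float) -> float:
    """Classic two-compartment transform: %BF = (4.95/D - 4.50)*100."""
    if not (0.9 < density_kg_per_l < 1.2):
        raise ValueError("density out of supported range (0.9, 1.2)")
    return (4.95 / density_kg_per_l - 4.50) * 100.0


# Age-adjusted density transform, %BF = (a0 - a1*(age-ref))/D - (b0 - b1*(age-ref)),
# in the style recommended for children; reduces to Siri when a1 = b1 = 0,
# a0 = 495, b0 = 450.
_WD_COEFFS = {
    1: {"a0": 562.0, "a1": 4.2, "age_ref": 2.0, "b0": 525.0, "b1": 4.7},
    0: {"a0": 553.0, "a1": 7.3, "age_ref": 10.0, "b0": 514.0, "b1": 8.0},
}
_WD_AGE_RANGE = (2.0, 18.0)


def weststrate_deurenberg_pbf(density_kg_per_l: float, age_years: float,
                              sex: int,
                              coeffs: Optional[Mapping] = None) -> float:
    """Age- and sex-adjusted density-to-%BF transform for children.

    Accounts for the higher hydration (lower FFM density) of children, so
    it returns lower %BF than the Siri transform at equal density.
    """
    if not (0.9 < density_kg_per_l < 1.2):
        raise ValueError("density out of supported range (0.9, 1.2)")
    if not (_WD_AGE_RANGE[0] <= age_years <= _WD_AGE_RANGE[1]):
        raise ValueError(
            f"age {age_years} outside supported range {_WD_AGE_RANGE}")
    c = _WD_COEFFS[sex] if coeffs is None else coeffs
    da = age_years - c["age_ref"]
    return ((c["a0"] - c["a1"] * da) / density_kg_per_l
            - (c["b0"] - c["b1"] * da))


def _resolve_linear_inputs(c: Mapping[str, float], subject,
                           cole_params: Optional[ColeParameters]) -> float:
    out = float(c.get("intercept", 0.0))
    needs_impedance = any(c.get(k, 0.0) != 0.0 for k in ("ri", "xc50", "r50"))
    if needs_impedance and cole_params is None:
        raise ValueError("equation requires Cole parameters (missing input: "
                         "cole_params)")
    if c.get("ri", 0.0) != 0.0:
        out += c["ri"] * subject.height_cm ** 2 / cole_params.r50_ohm
    if c.get("r50", 0.0) != 0.0:
        out += c["r50"] * cole_params.r50_ohm
    if c.get("xc50", 0.0) != 0.0:
        out += c["xc50"] * cole_params.xc50_ohm
    out += c.get("weight", 0.0) * subject.weight_kg
    out += c.get("height", 0.0) * subject.height_cm
    out += c.get("age", 0.0) * subject.age_years
    out += c.get("sex", 0.0) * subject.sex
    return out


def evaluate_equation(eq: PredictionEquation, subject,
                      cole_params: Optional[ColeParameters] = None,
                      hydration: Optional[HydrationTable] = None,
                      density_transform: str = "weststrate_deurenberg",
                      ) -> BodyComposition:
    """Evaluate one registry equation into a full BodyComposition.

    Density outputs pass through the configured density->%BF transform;
    %BF / TBW / FFM outputs are completed into FM, FFM and TBW using body
    weight and the hydration table.
    """
    if hydration is None:
        hydration = HydrationTable.default()
    c = eq.coefficients
    if eq.sex_specific:
        c = c["male" if subject.sex == 1 else "female"]

    if eq.functional_form == "pbf_log10_ssf":
        value = ssf_pbf(subject.skinfolds_mm, subject.sex,
                        (c["b0"], c["b1"], c.get("b2", 0.0)))
        kind = "pbf"
    elif eq.functional_form == "density_log10_ssf":
        ssf = subject.ssf_mm
        density = c["c0"] - c["c1"] * math.log10(ssf)
        if density_transform == "siri":
            value = siri_pbf(density)
        elif density_transform == "weststrate_deurenberg":
            value = weststrate_deurenberg_pbf(density, subject.age_years,
                                              subject.sex)
        else:
            raise ValueError(
                f"unknown density transform {density_transform!r}")
        kind = "pbf"
    elif eq.functional_form == "linear_bia":
        value = _resolve_linear_inputs(c, subject, cole_params)
        kind = eq.output_kind
    else:  # pragma: no cover - guarded in PredictionEquation
        raise ValueError(f"unknown form {eq.functional_form!r}")

    hf = hydration.lookup(subject.sex, subject.age_years)
    w = subject.weight_kg
    if kind == "pbf":
        pbf = min(max(value, 0.0), 100.0 - 1e-9)
        ffm = w * (1.0 - pbf / 100.0)
        tbw = ffm * hf
    elif kind == "tbw":
        tbw = value
        ffm = tbw / hf
    elif kind == "ffm":
        ffm = value
        tbw = ffm * hf
    else:  # pragma: no cover
        raise ValueError(kind)
    return composition_from_ffm(w, ffm, tbw_l=tbw, method_tag=eq.eq_id)


def new_ssf_equation(coeffs: tuple[float, float, float],
                     eq_id: str = "new_ssf") -> PredictionEquation:
    """Wrap freshly fitted skinfold coefficients as a registry equation."""
    b0, b1, b2 = coeffs
    return PredictionEquation(
        eq_id=eq_id, citation="this study", output_kind="pbf",
        functional_form="pbf_log10_ssf",
        coefficients={"b0": b0, "b1": b1, "b2": b2})


def new_bia_equation(coeffs: tuple[float, float, float, float],
                     eq_id: str = "new_bia") -> PredictionEquation:
    """Wrap freshly fitted resistance-index coefficients as an equation."""
    c0, c1, c2, c3 = coeffs
    return PredictionEquation(
        eq_id=eq_id, citation="this study", output_kind="tbw",
        functional_form="linear_bia",
        coefficients={"intercept": c0, "ri": c1, "weight": c2, "sex": c3})
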