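"""Hanai mixture-theory prediction of fluid volumes from Cole parameters.

Extracellular water follows the Hanai dilute-suspension result

    V_ECW = k_ecw * (H^2 * sqrt(W) / R0)^(2/3)

with k_ecw = 1e-3 * (kb^2 * rho_ecw^2 / D_b)^(1/3) built from the apparent
extracellular resistivity rho_ecw (ohm*cm), the body proportion factor kb
(~4.3 in adults) and body density D_b. The BMI-adjusted variant replaces the
constant with k_ecw = a/BMI + b. Intracellular water solves the implicit
relation

    (1 + v)^(5/2) = ((R_E + R_I)/R_I) * (1 + k_rho * v),   v = V_ICW/V_ECW

with R_E = R0, R_I = R0*Rinf/(R0 - Rinf) and k_rho = rho_icw/rho_ecw.

Note on k_rho: the implicit relation has the physically expected behaviour
(V_ICW -> 0 as Rinf -> R0, monotone in Rinf) only when k_rho <= 5/2; above
that the root tends to a strictly positive limit as R_I -> infinity. The
shipped coefficient registry therefore keeps rho_icw/rho_ecw below 5/2.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional

from scipy.optimize import brentq

from .dilution import BodyComposition, HydrationTable, composition_from_ffm

__all__ = [
    "MixtureCoefficients",
    "load_registry",
    "get_coefficients",
    "kb_from_anthropometry",
    "ecw_volume",
    "icw_volume",
    "tbw_mixture",
    "ADULT_KB",
]

#: Published adult body proportion factor.
ADULT_KB = 4.3

_ICW_TOL = 1e-12
_ICW_BRACKET_MAX = 10.0  # upper bound on V_ICW/V_ECW


@dataclass(frozen=True)
class MixtureCoefficients:
    """Resistivity/geometry constants selecting a mixture-theory variant."""

    rho_ecw: float          # ohm*cm
    rho_icw: float          # ohm*cm
    body_density: float     # kg/L
    kb: float = ADULT_KB
    variant: str = "ward"
    moissl_ecw_a: float = 0.0
    moissl_ecw_b: float = 0.0
    moissl_icw_a: float = 0.0
    moissl_icw_b: float = 0.0

    def __post_init__(self) -> None:
        if self.rho_ecw <= 0 or self.rho_icw <= 0:
            raise ValueError("resistivities must be positive")
        if self.rho_icw <= self.rho_ecw:
            raise ValueError("rho_icw must exceed rho_ecw")
        if self.kb <= 0:
            raise ValueError("kb must be positive")
        if not (0.9 < self.body_density < 1.2):
            raise ValueError("body density must lie in (0.9, 1.2)")
        if self.variant not in ("ward", "moon", "moissl"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def k_rho(self) -> float:
        return self.rho_icw / self.rho_ecw

    def k_ecw(self, bmi: Optional[float] = None) -> float:
        """ECW volume coefficient; BMI-dependent for the moissl variant."""
        if self.variant == "moissl":
            if bmi is None or bmi <= 0:
                raise ValueError("moissl variant requires a positive BMI")
            return self.moissl_ecw_a / bmi + self.moissl_ecw_b
        return 1e-3 * (self.kb ** 2 * self.rho_ecw ** 2
                       / self.body_density) ** (1.0 / 3.0)

    def with_kb(self, kb: float) -> "MixtureCoefficients":
        return replace(self, kb=kb)


def load_registry() -> dict[str, dict]:
    """Coefficient registry shipped with the package, keyed by variant."""
    ref = importlib.resources.files("bodycomp.data").joinpath(
        "mixture_registry.json")
    with ref.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def get_coefficients(variant: str = "ward",
                     kb: Optional[float] = None) -> MixtureCoefficients:
    """Look up a registry coefficient set, optionally overriding kb."""
    reg = load_registry()
    if variant not in reg:
        raise KeyError(
            f"unknown mixture variant {variant!r}; have {sorted(reg)}")
    entry = {k: v for k, v in reg[variant].items() if k != "citation"}
    coeffs = MixtureCoefficients(variant=variant, **entry)
    if kb is not None:
        coeffs = coeffs.with_kb(kb)
    return coeffs


def kb_from_anthropometry(
    height_cm: float,
    segment_proportions: Optional[Mapping[str, tuple[float, float]]] = None,
) -> float:
    """Body proportion factor from a series-of-cylinders body model.

    Each entry of ``segment_proportions`` maps a segment name on the
    wrist-to-ankle current path (arm, trunk, leg) to
    (length/height, circumference/height). Modelling segments as cylinders
    in series gives

        K_B = sum(l_i/c_i^2) * sum(l_i*c_i^2)       (relative units)

    which is dimensionless and invariant under uniform scaling. With no
    proportions configured the published adult value 4.3 is returned.
    """
    if height_cm <= 0:
        raise ValueError("height must be positive")
    if segment_proportions is None:
        return ADULT_KB
    s1 = 0.0
    s2 = 0.0
    for name, (lam, gam) in segment_proportions.items():
        if lam <= 0 or gam <= 0:
            raise ValueError(f"segment {name!r}: proportions must be positive")
        s1 += lam / gam ** 2
        s2 += lam * gam ** 2
    return s1 * s2


def ecw_volume(r0_ohm: float, height_cm: float, weight_kg: float,
               coeffs: MixtureCoefficients) -> float:
    """Extracellular water volume (L) from R0 and body size."""
    if min(r0_ohm, height_cm, weight_kg) <= 0:
        raise ValueError("inputs must be positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    k = coeffs.k_ecw(bmi=bmi)
    return k * (height_cm ** 2 * math.sqrt(weight_kg) / r0_ohm) ** (2.0 / 3.0)


def icw_volume(v_ecw_l: float, r0_ohm: float, rinf_ohm: float,
               coeffs: MixtureCoefficients) -> float:
    """Intracellular water volume (L) solving the Hanai implicit relation.

    The root of f(v) = (1+v)^{5/2} - ((R_E+R_I)/R_I)(1 + k_rho v) in
    v = V_ICW/V_ECW is found by safeguarded bracketing (Brent) on
    [0, 10], then verified to |f| < 1e-9.
    """
    if not (r0_ohm > rinf_ohm > 0):
        raise ValueError("require r0 > rinf > 0")
    if v_ecw_l <= 0:
        raise ValueError("V_ECW must be positive")
    re_ = r0_ohm
    ri = r0_ohm * rinf_ohm / (r0_ohm - rinf_ohm)
    ratio = (re_ + ri) / ri
    krho = coeffs.k_rho

    def f(v: float) -> float:
        return (1.0 + v) ** 2.5 - ratio * (1.0 + krho * v)

    hi = _ICW_BRACKET_MAX
    if f(hi) <= 0:
        raise ValueError("no positive root bracket for the ICW relation")
    v = brentq(f, 0.0, hi, xtol=_ICW_TOL, rtol=8.9e-16)
    if abs(f(v)) > 1e-9:
        raise ValueError(f"ICW root residual {f(v):.3g} exceeds 1e-9")
    return v * v_ecw_l


def tbw_mixture(params, subject, coeffs: MixtureCoefficients,
                hydration: HydrationTable) -> BodyComposition:
    """Mixture-theory body composition for one subject.

    TBW = V_ECW + V_ICW from the fitted Cole parameters; FFM uses the same
    hydration table as the dilution reference; FM and %BF by difference.
    """
    v_ecw = ecw_volume(params.r0_ohm, subject.height_cm, subject.weight_kg,
                       coeffs)
    v_icw = icw_volume(v_ecw, params.r0_ohm, params.rinf_ohm, coeffs)
    tbw = v_ecw + v_icw
    hf = hydration.lookup(subject.sex, subject.age_years)
    ffm = tbw / hf
    return composition_from_ffm(subject.weight_kg, ffm, tbw_l=tbw,
                                method_tag=f"bis_{coeffs.variant}")
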