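"""Deuterium-dilution reference body composition.

The reference chain is: administered D2O dose and urine enrichments give the
deuterium dilution space (plateau method); the dilution space overestimates
total body water (TBW) because deuterium exchanges with non-aqueous hydrogen,
so a fixed 4 % correction is applied; TBW is converted to fat-free mass (FFM)
with an age- and sex-specific hydration fraction; fat mass (FM) is the
difference from body weight and %BF is FM as a percentage of weight.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "DilutionAssay",
    "HydrationTable",
    "BodyComposition",
    "dilution_space",
    "tbw_from_dilution",
    "ffm_from_tbw",
    "composition_from_ffm",
    "DILUTION_SPACE_CORRECTION",
    "DEFAULT_DOSE_PURITY",
    "DEFAULT_ENRICHMENT_UNIT_SCALE",
]

#: Ratio of deuterium dilution space to TBW (the "4 % correction").
DILUTION_SPACE_CORRECTION = 1.04

#: Fraction of the nominal dose that is D2O (isotopic + chemical purity).
DEFAULT_DOSE_PURITY = 0.999

#: Converts grams of D2O per kg of body water to the enrichment unit used in
#: assays (mg/kg, i.e. ppm by mass above baseline).
DEFAULT_ENRICHMENT_UNIT_SCALE = 1000.0


@dataclass(frozen=True)
class DilutionAssay:
    """One subject's deuterium dilution measurement (plateau protocol)."""

    subject_id: str
    dose_g: float
    baseline_enrichment: float  # ppm
    plateau_enrichment: float   # ppm
    weight_kg: float

    def __post_init__(self) -> None:
        if self.dose_g <= 0:
            raise ValueError(f"{self.subject_id}: dose must be positive")
        if self.plateau_enrichment <= self.baseline_enrichment:
            raise ValueError(
                f"{self.subject_id}: plateau enrichment must exceed baseline"
            )
        if self.weight_kg <= 0:
            raise ValueError(f"{self.subject_id}: weight must be positive")


@dataclass(frozen=True)
class BodyComposition:
    """Two-compartment body composition from one method for one subject.

    Invariants: ffm_kg + fm_kg equals body weight, pbf = 100*fm/weight, and
    all masses/volumes are non-negative.
    """

    tbw_l: float
    ffm_kg: float
    fm_kg: float
    pbf: float
    method_tag: str = ""

    @property
    def weight_kg(self) -> float:
        return self.ffm_kg + self.fm_kg

    def __post_init__(self) -> None:
        if min(self.tbw_l, self.ffm_kg, self.fm_kg) < 0:
            raise ValueError("body composition fields must be non-negative")

    @classmethod
    def from_ffm(cls, weight_kg: float, ffm_kg: float, tbw_l: float,
                 method_tag: str = "") -> "BodyComposition":
        """Complete FM and %BF from weight and FFM (FM by difference)."""
        return composition_from_ffm(weight_kg, ffm_kg, tbw_l=tbw_l,
                                    method_tag=method_tag)

    def retag(self, tag: str) -> "BodyComposition":
        return replace(self, method_tag=tag)


def _load_resource_csv(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("bodycomp.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class HydrationTable:
    """Hydration fraction (TBW/FFM) by sex and integer age band.

    Children are more hydrated than the 0.732 adult constant; the shipped
    default table carries age- and sex-specific values for ages 6-10 that
    decline with age, girls slightly above boys, consistent with
    reference-child values. An alternative table in the style of the older
    Lohman constants is available via :meth:`lohman`.
    """

    entries: pd.DataFrame = field(repr=False)
    name: str = "custom"

    def __post_init__(self) -> None:
        required = {"sex", "age_low", "age_high", "hf"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"hydration table needs columns {sorted(required)}")
        hf = self.entries["hf"]
        if not ((hf > 0.70) & (hf < 0.80)).all():
            raise ValueError("hydration fractions must lie in (0.70, 0.80)")

    @classmethod
    def default(cls) -> "HydrationTable":
        return cls(_load_resource_csv("hydration_wells.csv"), name="wells")

    @classmethod
    def lohman(cls) -> "HydrationTable":
        return cls(_load_resource_csv("hydration_lohman.csv"), name="lohman")

    @classmethod
    def constant(cls, hf: float = 0.732) -> "HydrationTable":
        """A flat table (e.g. the 0.732 adult constant) for both sexes."""
        rows = [
            {"sex": s, "age_low": 0, "age_high": 120, "hf": hf}
            for s in (0, 1)
        ]
        return cls(pd.DataFrame(rows), name=f"constant_{hf}")

    def lookup(self, sex: int, age_years: float) -> float:
        m = self.entries[
            (self.entries["sex"] == sex)
            & (self.entries["age_low"] <= age_years)
            & (age_years < self.entries["age_high"])
        ]
        if m.empty:
            raise KeyError(
                f"no hydration entry for sex={sex}, age={age_years:.2f} "
                f"in table '{self.name}'"
            )
        return float(m.iloc[0]["hf"])


def dilution_space(assay: DilutionAssay,
                   dose_purity: float = DEFAULT_DOSE_PURITY,
                   unit_scale: float = DEFAULT_ENRICHMENT_UNIT_SCALE) -> float:
    """Deuterium dilution space V_D (litres) by the plateau method.

    V_D = dose_g * dose_purity * unit_scale / (plateau - baseline); linear in
    dose and inversely proportional to the net enrichment.
    """
    net = assay.plateau_enrichment - assay.baseline_enrichment
    if net <= 0:
        raise ValueError("net enrichment must be positive")
    return assay.dose_g * dose_purity * unit_scale / net


def tbw_from_dilution(vd_l: float) -> float:
    """TBW (litres) from dilution space: divide by 1.04 (4 % exchange)."""
    if vd_l <= 0:
        raise ValueError("dilution space must be positive")
    return vd_l / DILUTION_SPACE_CORRECTION


def ffm_from_tbw(tbw_l: float, age_years: float, sex: int,
                 table: HydrationTable) -> float:
    """FFM (kg) = TBW / hydration fraction for the subject's age and sex.

    Water litres and kilograms are treated 1:1.
    """
    if tbw_l <= 0:
        raise ValueError("TBW must be positive")
    hf = table.lookup(sex, age_years)
    return tbw_l / hf


def composition_from_ffm(weight_kg: float, ffm_kg: float, *,
                         tbw_l: float = 0.0,
                         method_tag: str = "") -> BodyComposition:
    """FM = weight - FFM; %BF = 100*FM/weight. Negative FM is an error."""
    if ffm_kg <= 0 or weight_kg <= 0:
        raise ValueError("weight and FFM must be positive")
    if ffm_kg > weight_kg * (1 + 1e-12):
        raise ValueError(
            f"negative fat mass: FFM {ffm_kg:.3f} kg exceeds weight "
            f"{weight_kg:.3f} kg"
        )
    fm = max(weight_kg - ffm_kg, 0.0)
    return BodyComposition(
        tbw_l=tbw_l,
        ffm_kg=ffm_kg,
        fm_kg=fm,
        pbf=100.0 * fm / weight_kg,
        method_tag=method_tag,
    )


def reference_composition(assay: DilutionAssay, age_years: float, sex: int,
                          table: HydrationTable,
                          dose_purity: float = DEFAULT_DOSE_PURITY,
                          unit_scale: float = DEFAULT_ENRICHMENT_UNIT_SCALE,
                          ) -> BodyComposition:
    """Full reference chain: assay -> V_D -> TBW -> FFM -> FM -> %BF."""
    vd = dilution_space(assay, dose_purity=dose_purity, unit_scale=unit_scale)
    tbw = tbw_from_dilution(vd)
    ffm = ffm_from_tbw(tbw, age_years, sex, table)
    return composition_from_ffm(assay.weight_kg, ffm, tbw_l=tbw,
                                method_tag="dilution")
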