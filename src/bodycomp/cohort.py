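"""Synthetic cohort generator with known ground-truth body composition.

Emulates a cross-sectional sample of 7- to 9-year-old children (158
subjects, 75 boys) spanning a wide adiposity range (roughly 14-58 %BF,
girls ~38.7 %BF, boys ~35.1 %BF on average). For every subject the
generator produces mutually consistent ground truth (FFM + FM = weight,
TBW = FFM * hydration fraction), a Cole-model impedance spectrum that is an
exact forward image of the mixture-theory volume equations (so the analysis
chain can recover truth to numerical precision when noise is off), a
log-linear skinfold set, and a deuterium dilution assay.

All randomness flows from one seed through per-subject substreams, so
subsetting a cohort is stable and identical seeds give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .cole import ColeParameters, ImpedanceSpectrum, cole_impedance
from .dilution import (
    DEFAULT_DOSE_PURITY,
    DEFAULT_ENRICHMENT_UNIT_SCALE,
    DILUTION_SPACE_CORRECTION,
    BodyComposition,
    DilutionAssay,
    HydrationTable,
)
from .mixture import MixtureCoefficients, get_coefficients

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "Cohort",
    "generate_cohort",
    "forward_impedance",
    "forward_skinfolds",
    "implied_bia_coefficients",
    "cohort_table",
    "spectra_table",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort.

    Defaults encode the emulated study: 158 children (75 boys), ages
    6.5-9.6 y, sex-specific %BF means 38.7 (girls) / 35.1 (boys) clipped to
    the observed 14.2-57.5 range, and a log-linear skinfold model
    %BF = b0 + b1*log10(SSF) + b2*sex.
    """

    n_total: int = 158
    n_male: int = 75
    age_range_years: tuple[float, float] = (6.5, 9.6)
    pbf_mean_by_sex: dict = field(
        default_factory=lambda: {0: 38.7, 1: 35.1})
    pbf_sd: float = 8.5
    pbf_range_clip: tuple[float, float] = (14.2, 57.5)
    ssf_model_coeffs: tuple[float, float, float] = (-40.0, 50.0, -1.5)
    ssf_noise_sd: float = 3.5       # %BF
    impedance_noise_sd: float = 0.5  # ohm
    dilution_noise_cv: float = 0.02
    seed: int = 158

    # anthropometry model (age- and sex-linear means, Gaussian scatter)
    height_mean_at8_cm: float = 127.0
    height_slope_cm_per_yr: float = 5.8
    height_sex_offset_cm: float = 0.5
    height_sd_cm: float = 5.5
    ffmi_mean: float = 13.0          # fat-free mass index, kg/m^2
    ffmi_sd: float = 1.2

    # impedance forward model
    ecw_frac_mean: float = 0.45      # ECW/TBW, with per-subject scatter
    ecw_frac_sd: float = 0.013
    alpha_range: tuple[float, float] = (0.65, 0.78)
    fc_range_khz: tuple[float, float] = (25.0, 60.0)
    n_freq: int = 256
    freq_range_khz: tuple[float, float] = (3.0, 1000.0)
    bis_variant: str = "ward"

    # skinfold site partition (triceps, biceps, subscapular, suprailiac)
    skinfold_proportions: tuple[float, float, float, float] = (
        0.35, 0.15, 0.30, 0.20)

    # dilution assay
    dose_g_per_kg: float = 0.5
    baseline_ppm: float = 155.0

    def __post_init__(self) -> None:
        if not (0 <= self.n_male <= self.n_total):
            raise ValueError("require 0 <= n_male <= n_total")
        lo, hi = self.age_range_years
        if not (6.5 <= lo < hi <= 9.6):
            raise ValueError("age range must lie within (6.5, 9.6)")
        for name in ("pbf_sd", "ssf_noise_sd", "impedance_noise_sd",
                     "dilution_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        clo, chi = self.pbf_range_clip
        if not (0 < clo < chi < 100):
            raise ValueError("pbf_range_clip must lie within (0, 100)")
        if self.ssf_model_coeffs[1] <= 0:
            raise ValueError("ssf slope b1 must be positive")
        props = self.skinfold_proportions
        if any(p <= 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("skinfold proportions must be positive and "
                             "sum to 1")


@dataclass(frozen=True)
class SubjectRecord:
    """One child's anthropometry plus (synthetic-only) ground truth."""

    subject_id: str
    sex: int                     # female = 0, male = 1
    age_years: float
    height_cm: float
    weight_kg: float
    skinfolds_mm: tuple[float, float, float, float]
    waist_cm: float
    hip_cm: float
    truth: Optional[BodyComposition] = None

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (female) or 1 (male)")
        vals = (self.age_years, self.height_cm, self.weight_kg,
                self.waist_cm, self.hip_cm, *self.skinfolds_mm)
        if any(v <= 0 for v in vals):
            raise ValueError(
                f"{self.subject_id}: anthropometry must be strictly positive")

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def ssf_mm(self) -> float:
        return float(sum(self.skinfolds_mm))


class Cohort(NamedTuple):
    """Generated cohort: subjects, impedance spectra, dilution assays.

    ``cole_truth`` carries the noise-free forward Cole parameters that the
    spectra were generated from (useful for fast large-scale checks that do
    not need a spectral refit).
    """

    records: list
    spectra: list
    assays: list
    cole_truth: list


def _subject_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(i,))))


def _truncnorm(rng: np.random.Generator, mu: float, sd: float,
               lo: float, hi: float) -> float:
    if sd == 0:
        return min(max(mu, lo), hi)
    for _ in range(10000):
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def forward_skinfolds(pbf: float, sex: int, spec: CohortSpec,
                      noise_draw: float = 0.0
                      ) -> tuple[float, float, float, float]:
    """Invert the log-linear skinfold model for one subject.

    SSF = 10**((pbf - b0 - b2*sex - noise)/b1); the four site values
    partition SSF by the fixed positive proportions of the spec.
    """
    b0, b1, b2 = spec.ssf_model_coeffs
    exponent = (pbf - b0 - b2 * sex - noise_draw) / b1
    if not -30.0 < exponent < 30.0:
        raise ValueError(f"%BF {pbf} implies an unrepresentable SSF")
    ssf = 10.0 ** exponent
    if not math.isfinite(ssf) or ssf <= 0:
        raise ValueError(f"%BF {pbf} implies non-positive SSF")
    return tuple(p * ssf for p in spec.skinfold_proportions)


def forward_impedance(subject: SubjectRecord,
                      coeffs: MixtureCoefficients,
                      *,
                      ecw_frac: float = 0.45,
                      fc_khz: float = 50.0,
                      alpha: float = 0.72) -> ColeParameters:
    """Cole parameters that are the exact mixture-theory image of truth TBW.

    Inverts the extracellular Hanai power law for R0 and the intracellular
    implicit relation (in closed form) for Rinf, so that `tbw_mixture`
    applied to the result reproduces the subject's ground-truth TBW.
    Degenerate ICW = 0 gives Rinf = R0 (no intracellular conduction path);
    a tiny offset keeps the returned parameters inside the r0 > rinf
    invariant.
    """
    if subject.truth is None:
        raise ValueError(f"{subject.subject_id}: ground truth not set")
    tbw = subject.truth.tbw_l
    v_ecw = ecw_frac * tbw
    v_icw = tbw - v_ecw
    if v_ecw <= 0:
        raise ValueError("ECW fraction must be positive")
    bmi = subject.bmi
    k = coeffs.k_ecw(bmi=bmi)
    h2sw = subject.height_cm ** 2 * math.sqrt(subject.weight_kg)
    r0 = h2sw / (v_ecw / k) ** 1.5
    if v_icw <= 0:
        rinf = r0 * (1 - 1e-12)
    else:
        v = v_icw / v_ecw
        g = (1.0 + v) ** 2.5 / (1.0 + coeffs.k_rho * v)
        if g <= 1.0:
            raise ValueError(
                f"ICW/ECW ratio {v:.3f} not representable with "
                f"k_rho={coeffs.k_rho:.3f} (requires (1+v)^2.5 > 1+k_rho*v)")
        ri = r0 / (g - 1.0)
        rinf = ri * r0 / (ri + r0)
    tau = 1.0 / (2 * math.pi * fc_khz * 1000.0)
    return ColeParameters.from_model(r0, rinf, tau, alpha)


def generate_cohort(spec: CohortSpec,
                    hydration: Optional[HydrationTable] = None,
                    coeffs: Optional[MixtureCoefficients] = None) -> Cohort:
    """Generate a full synthetic cohort (pure function of the spec).

    Returns records with ground truth, per-subject impedance spectra
    (forward Cole model + Gaussian instrument noise), dilution assays
    (multiplicative lognormal enrichment noise) and the noise-free Cole
    parameters.
    """
    if hydration is None:
        hydration = HydrationTable.default()
    if coeffs is None:
        coeffs = get_coefficients(spec.bis_variant)

    records: list[SubjectRecord] = []
    spectra: list[ImpedanceSpectrum] = []
    assays: list[DilutionAssay] = []
    cole_truth: list[ColeParameters] = []

    freqs = np.logspace(math.log10(spec.freq_range_khz[0]),
                        math.log10(spec.freq_range_khz[1]), spec.n_freq)
    clip_lo, clip_hi = spec.pbf_range_clip

    for i in range(spec.n_total):
        rng = _subject_rng(spec.seed, i)
        sid = f"S{i + 1:04d}"
        sex = 1 if i < spec.n_male else 0

        age = rng.uniform(*spec.age_range_years)
        h_mu = (spec.height_mean_at8_cm
                + spec.height_slope_cm_per_yr * (age - 8.0)
                + spec.height_sex_offset_cm * sex)
        height = rng.normal(h_mu, spec.height_sd_cm)

        # latent adiposity (truncated Gaussian per sex) + regression error;
        # the same error enters forward_skinfolds so the planted log-linear
        # model holds with error independent of log10(SSF).
        latent = _truncnorm(rng, spec.pbf_mean_by_sex[sex], spec.pbf_sd,
                            clip_lo, clip_hi)
        ssf_err = rng.normal(0.0, spec.ssf_noise_sd)
        pbf = float(np.clip(latent + ssf_err, 5.0, 70.0))

        ffmi = max(rng.normal(spec.ffmi_mean, spec.ffmi_sd), 9.0)
        ffm = ffmi * (height / 100.0) ** 2
        weight = ffm / (1.0 - pbf / 100.0)
        fm = weight - ffm
        hf = hydration.lookup(sex, age)
        tbw = ffm * hf
        truth = BodyComposition(tbw_l=tbw, ffm_kg=ffm, fm_kg=fm, pbf=pbf,
                                method_tag="truth")

        skinfolds = forward_skinfolds(pbf, sex, spec, noise_draw=ssf_err)
        bmi = weight / (height / 100.0) ** 2
        waist = 2.2 * bmi + 0.25 * height + rng.normal(0.0, 2.0)
        hip = 1.08 * waist + rng.normal(0.0, 1.5)

        record = SubjectRecord(
            subject_id=sid, sex=sex, age_years=age, height_cm=height,
            weight_kg=weight, skinfolds_mm=skinfolds, waist_cm=waist,
            hip_cm=hip, truth=truth)

        ecw_frac = float(np.clip(
            rng.normal(spec.ecw_frac_mean, spec.ecw_frac_sd), 0.38, 0.52))
        alpha = rng.uniform(*spec.alpha_range)
        fc = rng.uniform(*spec.fc_range_khz)
        params = forward_impedance(record, coeffs, ecw_frac=ecw_frac,
                                   fc_khz=fc, alpha=alpha)
        z = cole_impedance(params, freqs)
        r_noise = rng.normal(0.0, spec.impedance_noise_sd, spec.n_freq)
        x_noise = rng.normal(0.0, spec.impedance_noise_sd, spec.n_freq)
        spectrum = ImpedanceSpectrum(
            subject_id=sid, freq_khz=freqs,
            r_ohm=z.real + r_noise,
            xc_ohm=np.maximum(-z.imag + x_noise, 0.0))

        dose = spec.dose_g_per_kg * weight
        vd = tbw * DILUTION_SPACE_CORRECTION
        net = dose * DEFAULT_DOSE_PURITY * DEFAULT_ENRICHMENT_UNIT_SCALE / vd
        if spec.dilution_noise_cv > 0:
            net *= math.exp(rng.normal(0.0, spec.dilution_noise_cv))
        assay = DilutionAssay(
            subject_id=sid, dose_g=dose,
            baseline_enrichment=spec.baseline_ppm,
            plateau_enrichment=spec.baseline_ppm + net,
            weight_kg=weight)

        records.append(record)
        spectra.append(spectrum)
        assays.append(assay)
        cole_truth.append(params)

    return Cohort(records, spectra, assays, cole_truth)


def implied_bia_coefficients(spec: CohortSpec, n: int = 20000,
                             seed: Optional[int] = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Population (c0, c1, c2, c3) of TBW = c0 + c1*RI + c2*W + c3*sex.

    The generator's impedance is mixture-theory consistent, so the linear
    single-frequency model has no planted coefficients; this computes the
    generator's implied coefficients as the large-n least-squares projection
    of reference (dilution) TBW on (RI, weight, sex), with the generator's
    own noise structure. Returns (coefficients, standard errors).
    """
    from dataclasses import replace as _replace

    from .dilution import reference_composition

    big = _replace(spec, n_total=n,
                   n_male=int(round(n * spec.n_male / spec.n_total)),
                   seed=spec.seed if seed is None else seed)
    cohort = generate_cohort(big)
    hydration = HydrationTable.default()
    ri = np.array([r.height_cm ** 2 / p.r50_ohm
                   for r, p in zip(cohort.records, cohort.cole_truth)])
    w = np.array([r.weight_kg for r in cohort.records])
    sex = np.array([float(r.sex) for r in cohort.records])
    tbw_ref = np.array([
        reference_composition(a, r.age_years, r.sex, hydration).tbw_l
        for r, a in zip(cohort.records, cohort.assays)])
    X = np.column_stack([np.ones(n), ri, w, sex])
    beta, *_ = np.linalg.lstsq(X, tbw_ref, rcond=None)
    resid = tbw_ref - X @ beta
    sigma2 = resid @ resid / (n - X.shape[1])
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


_SKINFOLD_COLS = ("sf_triceps_mm", "sf_biceps_mm", "sf_subscapular_mm",
                  "sf_suprailiac_mm")


def cohort_table(cohort: Cohort, include_truth: bool = True) -> pd.DataFrame:
    """Wide per-subject table (anthropometry, assay columns, truth)."""
    rows = []
    for rec, assay in zip(cohort.records, cohort.assays):
        row = {
            "subject_id": rec.subject_id,
            "sex": rec.sex,
            "age_years": rec.age_years,
            "height_cm": rec.height_cm,
            "weight_kg": rec.weight_kg,
            **dict(zip(_SKINFOLD_COLS, rec.skinfolds_mm)),
            "waist_cm": rec.waist_cm,
            "hip_cm": rec.hip_cm,
            "dose_g": assay.dose_g,
            "baseline_ppm": assay.baseline_enrichment,
            "plateau_ppm": assay.plateau_enrichment,
        }
        if include_truth and rec.truth is not None:
            row.update({
                "truth_tbw_l": rec.truth.tbw_l,
                "truth_ffm_kg": rec.truth.ffm_kg,
                "truth_fm_kg": rec.truth.fm_kg,
                "truth_pbf": rec.truth.pbf,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def spectra_table(cohort: Cohort) -> pd.DataFrame:
    """Long-format spectra table (subject_id, freq_khz, r_ohm, xc_ohm)."""
    frames = [
        pd.DataFrame({
            "subject_id": s.subject_id,
            "freq_khz": s.freq_khz,
            "r_ohm": s.r_ohm,
            "xc_ohm": s.xc_ohm,
        })
        for s in cohort.spectra
    ]
    return pd.concat(frames, ignore_index=True)


def records_from_table(df: pd.DataFrame) -> list[SubjectRecord]:
    """Rebuild SubjectRecords (with truth when present) from a cohort CSV."""
    records = []
    has_truth = "truth_tbw_l" in df.columns
    for _, row in df.iterrows():
        truth = None
        if has_truth:
            truth = BodyComposition(
                tbw_l=row["truth_tbw_l"], ffm_kg=row["truth_ffm_kg"],
                fm_kg=row["truth_fm_kg"], pbf=row["truth_pbf"],
                method_tag="truth")
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), sex=int(row["sex"]),
            age_years=float(row["age_years"]),
            height_cm=float(row["height_cm"]),
            weight_kg=float(row["weight_kg"]),
            skinfolds_mm=tuple(float(row[c]) for c in _SKINFOLD_COLS),
            waist_cm=float(row["waist_cm"]), hip_cm=float(row["hip_cm"]),
            truth=truth))
    return records


def assays_from_table(df: pd.DataFrame) -> list[DilutionAssay]:
    return [
        DilutionAssay(
            subject_id=str(row["subject_id"]), dose_g=float(row["dose_g"]),
            baseline_enrichment=float(row["baseline_ppm"]),
            plateau_enrichment=float(row["plateau_ppm"]),
            weight_kg=float(row["weight_kg"]))
        for _, row in df.iterrows()
    ]


def spectra_from_table(df: pd.DataFrame) -> list[ImpedanceSpectrum]:
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("freq_khz")
        out.append(ImpedanceSpectrum(
            subject_id=str(sid),
            freq_khz=grp["freq_khz"].to_numpy(),
            r_ohm=grp["r_ohm"].to_numpy(),
            xc_ohm=grp["xc_ohm"].to_numpy()))
    return out
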