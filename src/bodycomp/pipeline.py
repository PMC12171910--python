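"""End-to-end pipeline stages tying the modules into reproducible runs.

Stages: simulate a cohort, compute the dilution reference, fit Cole models
to every spectrum, develop the skinfold and impedance predictors with
double cross-validation, and compare every candidate equation against the
reference with the agreement battery and combined ranking.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementReport, compare_method, rank_equations
from .cohort import (
    Cohort,
    CohortSpec,
    cohort_table,
    generate_cohort,
    spectra_table,
)
from .cole import ColeParameters, fit_cole
from .dilution import BodyComposition, HydrationTable, reference_composition
from .equations import (
    PredictionEquation,
    evaluate_equation,
    load_equation_registry,
    new_bia_equation,
    new_ssf_equation,
)
from .regression import CrossValReport, double_cross_validate, stepwise_select

__all__ = [
    "simulate_to_dir",
    "fit_cole_all",
    "reference_all",
    "build_analysis_frame",
    "develop_equations",
    "compare_equations",
]

BIA_CANDIDATES = ("ri", "weight_kg", "age_years", "sex")
SSF_PREDICTORS = ("log10_ssf", "sex")


def simulate_to_dir(spec: CohortSpec, outdir: str | Path) -> dict:
    """Write cohort, spectra and truth tables plus a replay manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec)
    cohort_table(cohort, include_truth=False).to_csv(
        outdir / "cohort.csv", index=False)
    cohort_table(cohort, include_truth=True).to_csv(
        outdir / "cohort_with_truth.csv", index=False)
    spectra_table(cohort).to_csv(outdir / "spectra.csv", index=False)
    manifest = {
        "package_version": __version__,
        "seed": spec.seed,
        "n_total": spec.n_total,
        "n_male": spec.n_male,
        "bis_variant": spec.bis_variant,
        "created_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items()},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def fit_cole_all(spectra: Sequence,
                 fit_window_khz: tuple[float, float] = (3.0, 500.0)
                 ) -> list[ColeParameters]:
    return [fit_cole(s, fit_window_khz) for s in spectra]


def reference_all(records: Sequence, assays: Sequence,
                  hydration: Optional[HydrationTable] = None
                  ) -> list[BodyComposition]:
    if hydration is None:
        hydration = HydrationTable.default()
    return [reference_composition(a, r.age_years, r.sex, hydration)
            for r, a in zip(records, assays)]


def build_analysis_frame(records: Sequence,
                         cole_params: Sequence[ColeParameters],
                         reference: Sequence[BodyComposition]
                         ) -> pd.DataFrame:
    """Per-subject analysis table joining anthropometry, impedance, reference.

    Columns include the two derived predictors of the study: log10 of the
    skinfold sum and the 50 kHz resistance index height^2/R50 (cm^2/ohm).
    """
    rows = []
    for rec, cp, ref in zip(records, cole_params, reference):
        rows.append({
            "subject_id": rec.subject_id,
            "sex": rec.sex,
            "age_years": rec.age_years,
            "height_cm": rec.height_cm,
            "weight_kg": rec.weight_kg,
            "bmi": rec.bmi,
            "ssf_mm": rec.ssf_mm,
            "log10_ssf": np.log10(rec.ssf_mm),
            "r0_ohm": cp.r0_ohm,
            "rinf_ohm": cp.rinf_ohm,
            "r50_ohm": cp.r50_ohm,
            "xc50_ohm": cp.xc50_ohm,
            "ri": rec.height_cm ** 2 / cp.r50_ohm,
            "ref_tbw_l": ref.tbw_l,
            "ref_ffm_kg": ref.ffm_kg,
            "ref_fm_kg": ref.fm_kg,
            "ref_pbf": ref.pbf,
        })
    return pd.DataFrame(rows)


def develop_equations(df: pd.DataFrame, seed: int, alpha: float = 0.05
                      ) -> dict:
    """Develop and double-cross-validate both predictor families.

    The skinfold model regresses reference %BF on log10(SSF) and sex; the
    impedance model selects predictors of reference TBW among RI, weight,
    age and sex by stepwise regression, then cross-validates the selected
    set. Returns the stepwise trace, both CrossValReports, and the fitted
    new equations.
    """
    ssf_cv = double_cross_validate(df, "ref_pbf", SSF_PREDICTORS, seed,
                                   alpha=alpha)
    step_fit, trace = stepwise_select(
        df["ref_tbw_l"].to_numpy(), df[list(BIA_CANDIDATES)].to_numpy(),
        BIA_CANDIDATES, response="ref_tbw_l")
    selected = list(step_fit.predictors) or ["ri", "weight_kg"]
    bia_cv = double_cross_validate(df, "ref_tbw_l", selected, seed,
                                   alpha=alpha)

    ssf_coeffs = _coef_tuple(ssf_cv, SSF_PREDICTORS)
    bia_source = bia_cv.pooled_fit or bia_cv.group1_fit
    cmap = bia_source.coef_dict()
    name_map = {"ri": "ri", "weight_kg": "weight", "age_years": "age",
                "sex": "sex"}
    bia_coeffs = {"intercept": cmap.get("intercept", 0.0)}
    bia_coeffs.update({name_map[p]: cmap[p] for p in selected})
    new_bia = PredictionEquation(
        eq_id="new_bia", citation="this study", output_kind="tbw",
        functional_form="linear_bia", coefficients=bia_coeffs)
    return {
        "ssf_cv": ssf_cv,
        "bia_cv": bia_cv,
        "stepwise_fit": step_fit,
        "stepwise_trace": trace,
        "new_ssf_equation": new_ssf_equation(ssf_coeffs),
        "new_bia_equation": new_bia,
    }


def _coef_tuple(cv: CrossValReport, predictors) -> tuple:
    fit = cv.pooled_fit or cv.group1_fit
    cmap = fit.coef_dict()
    return tuple([cmap.get("intercept", 0.0)]
                 + [cmap.get(p, 0.0) for p in predictors])


def compare_equations(records: Sequence,
                      cole_params: Sequence[ColeParameters],
                      reference: Sequence[BodyComposition],
                      equations: Sequence[PredictionEquation],
                      quantity: str = "ffm_kg",
                      hydration: Optional[HydrationTable] = None,
                      ) -> tuple[dict[str, AgreementReport], pd.DataFrame]:
    """Evaluate equations over the cohort and rank them against reference.

    Equations that cannot be evaluated for some subject (missing inputs)
    are dropped with a warning entry rather than aborting the run.
    """
    if hydration is None:
        hydration = HydrationTable.default()
    reports: dict[str, AgreementReport] = {}
    for eq in equations:
        preds = []
        try:
            for rec, cp in zip(records, cole_params):
                preds.append(evaluate_equation(eq, rec, cole_params=cp,
                                               hydration=hydration))
        except (ValueError, KeyError) as exc:
            import warnings

            warnings.warn(f"skipping {eq.eq_id}: {exc}")
            continue
        reports[eq.eq_id] = compare_method(reference, preds,
                                           quantity=quantity,
                                           label=eq.eq_id)
    rank_df = rank_equations(list(reports.values()))
    return reports, rank_df


def bland_altman_frame(reference: Sequence[BodyComposition],
                       predicted: Sequence[BodyComposition],
                       quantity: str = "ffm_kg") -> pd.DataFrame:
    """Per-subject means/differences table for limits-of-agreement plots."""
    ref = np.array([getattr(c, quantity) for c in reference])
    pred = np.array([getattr(c, quantity) for c in predicted])
    return pd.DataFrame({
        "mean": (ref + pred) / 2.0,
        "difference": ref - pred,
    })


def default_registry_equations() -> list[PredictionEquation]:
    return list(load_equation_registry().values())
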