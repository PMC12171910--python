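"""Cole-model analysis of whole-body impedance spectra.

Tissue impedance over the beta-dispersion is described by the four-parameter
Cole model

    Z(omega) = Rinf + (R0 - Rinf) / (1 + (j*omega*tau)**alpha)

whose locus in the complex plane (resistance R against reactance magnitude
Xc) is a circular arc depressed below the real axis by (1-alpha)*pi/2.
R0 and Rinf (the zero- and infinite-frequency resistances) feed mixture
theory; the 50 kHz resistance R50 feeds single-frequency prediction
equations. Spectra store reactance as a positive magnitude; the model's
imaginary part is -Xc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ImpedanceSpectrum",
    "ColeParameters",
    "NonDispersiveSpectrumError",
    "ColeFitError",
    "cole_impedance",
    "fit_cole",
    "fit_cole_replicates",
]

_MIN_POINTS = 8
_XC_DISPERSION_THRESHOLD = 1e-2  # ohm


class NonDispersiveSpectrumError(ValueError):
    """Raised when a spectrum carries no usable reactance dispersion."""


class ColeFitError(RuntimeError):
    """Raised when the nonlinear fit fails to converge."""


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Multi-frequency (R, Xc) measurement for one subject."""

    subject_id: str
    freq_khz: np.ndarray
    r_ohm: np.ndarray
    xc_ohm: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_khz, dtype=float)
        r = np.asarray(self.r_ohm, dtype=float)
        x = np.asarray(self.xc_ohm, dtype=float)
        if not (len(f) == len(r) == len(x)):
            raise ValueError("freq, R and Xc must have equal length")
        if len(f) < _MIN_POINTS:
            raise ValueError(f"need at least {_MIN_POINTS} frequencies")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("resistances must be strictly positive")
        object.__setattr__(self, "freq_khz", f)
        object.__setattr__(self, "r_ohm", r)
        object.__setattr__(self, "xc_ohm", x)

    def __len__(self) -> int:
        return len(self.freq_khz)


@dataclass(frozen=True)
class ColeParameters:
    """Fitted Cole parameters plus the 50 kHz model values used downstream."""

    r0_ohm: float
    rinf_ohm: float
    tau_s: float
    alpha: float
    rmse_ohm: float = 0.0
    r50_ohm: float = float("nan")
    xc50_ohm: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.r0_ohm > self.rinf_ohm > 0):
            raise ValueError("require r0 > rinf > 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.tau_s <= 0:
            raise ValueError("tau must be positive")

    @classmethod
    def from_model(cls, r0: float, rinf: float, tau: float, alpha: float,
                   rmse: float = 0.0) -> "ColeParameters":
        """Build parameters, evaluating R50/Xc50 from the model itself."""
        z50 = _cole_z(r0, rinf, tau, alpha, np.array([50.0]))[0]
        return cls(r0_ohm=r0, rinf_ohm=rinf, tau_s=tau, alpha=alpha,
                   rmse_ohm=rmse, r50_ohm=z50.real, xc50_ohm=-z50.imag)

    @property
    def fc_khz(self) -> float:
        """Characteristic frequency (kHz) where omega*tau = 1."""
        return 1.0 / (2 * math.pi * self.tau_s) / 1000.0


def _cole_z(r0: float, rinf: float, tau: float, alpha: float,
            freq_khz: np.ndarray) -> np.ndarray:
    omega = 2 * math.pi * np.asarray(freq_khz, dtype=float) * 1000.0
    return rinf + (r0 - rinf) / (1.0 + (1j * omega * tau) ** alpha)


def cole_impedance(params: ColeParameters, freq_khz) -> np.ndarray:
    """Complex impedance Z = R - j*Xc of the Cole model at freq_khz (kHz)."""
    f = np.asarray(freq_khz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    return _cole_z(params.r0_ohm, params.rinf_ohm, params.tau_s,
                   params.alpha, f)


def _circle_init(freq_khz: np.ndarray, r: np.ndarray, xc: np.ndarray
                 ) -> tuple[float, float, float, float]:
    """Initial (r0, rinf, tau, alpha) from an algebraic circle fit.

    The (R, Xc) locus lies on a circle whose intersections with the real
    axis are R0 and Rinf and whose centre depth below the axis encodes alpha
    (standard Cole-plot geometry). tau is seeded from the frequency of the
    reactance peak.
    """
    # Kasa fit: x^2 + y^2 + D x + E y + F = 0
    A = np.column_stack([r, xc, np.ones_like(r)])
    b = -(r ** 2 + xc ** 2)
    (D, E, F), *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = -D / 2.0, -E / 2.0
    rad2 = cx ** 2 + cy ** 2 - F
    rad = math.sqrt(max(rad2, 1e-12))
    half_chord = math.sqrt(max(rad2 - cy ** 2, 1e-12))
    r0 = cx + half_chord
    rinf = max(cx - half_chord, 1e-3)
    if r0 <= rinf:
        r0, rinf = max(r.max(), rinf * 1.01 + 1e-3), min(r.min(), rinf)
    # depression angle theta: centre at depth -cy below axis (cy<0 when
    # alpha<1); alpha = 1 - 2*theta/pi
    sin_theta = min(max(-cy / rad, 0.0), 0.95)
    alpha = 1.0 - 2.0 * math.asin(sin_theta) / math.pi
    alpha = min(max(alpha, 0.3), 1.0)
    f_peak = float(freq_khz[np.argmax(xc)])
    tau = 1.0 / (2 * math.pi * max(f_peak, 1e-3) * 1000.0)
    return r0, rinf, tau, alpha


def _objective(r0, rinf, tau, alpha, f, r, xc) -> float:
    z = _cole_z(r0, rinf, tau, alpha, f)
    return float(np.sum((z.real - r) ** 2 + (-z.imag - xc) ** 2))


def fit_cole(spectrum: ImpedanceSpectrum,
             fit_window_khz: tuple[float, float] = (3.0, 500.0),
             xtol: float = 1e-12) -> ColeParameters:
    """Fit the Cole model by complex nonlinear least squares.

    Residuals are the stacked real and imaginary misfits over the fit
    window, unweighted. Initialization comes from a circle fit to the
    (R, Xc) locus, so the returned objective never exceeds the
    initializer's. Deterministic given data and window.
    """
    lo, hi = fit_window_khz
    mask = (spectrum.freq_khz >= lo) & (spectrum.freq_khz <= hi)
    f = spectrum.freq_khz[mask]
    r = spectrum.r_ohm[mask]
    xc = spectrum.xc_ohm[mask]
    if len(f) < _MIN_POINTS:
        raise ValueError(
            f"only {len(f)} frequencies inside window {fit_window_khz}; "
            f"need {_MIN_POINTS}"
        )
    if np.max(np.abs(xc)) < _XC_DISPERSION_THRESHOLD:
        raise NonDispersiveSpectrumError(
            f"{spectrum.subject_id}: non-dispersive spectrum "
            f"(max |Xc| < {_XC_DISPERSION_THRESHOLD} ohm)"
        )

    r0_i, rinf_i, tau_i, alpha_i = _circle_init(f, r, xc)
    x0 = np.array([max(r0_i - rinf_i, 1e-3), rinf_i,
                   math.log(tau_i), alpha_i])

    def resid(p):
        dr, rinf, log_tau, alpha = p
        z = _cole_z(rinf + dr, rinf, math.exp(log_tau), alpha, f)
        return np.concatenate([z.real - r, -z.imag - xc])

    lower = [1e-6, 1e-6, math.log(1e-9), 0.05]
    upper = [np.inf, np.inf, math.log(1e-2), 1.0]
    sol = least_squares(resid, x0, bounds=(lower, upper), method="trf",
                        xtol=xtol, ftol=1e-14, gtol=1e-14, max_nfev=2000)
    if not sol.success:
        raise ColeFitError(
            f"{spectrum.subject_id}: Cole fit did not converge "
            f"(last cost {sol.cost:.3g})"
        )
    dr, rinf, log_tau, alpha = sol.x
    rmse = math.sqrt(2.0 * sol.cost / len(f))  # per-point complex residual
    return ColeParameters.from_model(rinf + dr, rinf, math.exp(log_tau),
                                     alpha, rmse=rmse)


def fit_cole_replicates(spectra: list[ImpedanceSpectrum],
                        fit_window_khz: tuple[float, float] = (3.0, 500.0)
                        ) -> ColeParameters:
    """Fit each replicate spectrum and average the fitted parameters.

    Mirrors the convention of averaging duplicate instrument measurements;
    R50/Xc50 are re-evaluated from the averaged model.
    """
    if not spectra:
        raise ValueError("no spectra given")
    fits = [fit_cole(s, fit_window_khz) for s in spectra]
    return ColeParameters.from_model(
        float(np.mean([p.r0_ohm for p in fits])),
        float(np.mean([p.rinf_ohm for p in fits])),
        float(np.mean([p.tau_s for p in fits])),
        float(np.mean([p.alpha for p in fits])),
        rmse=float(np.mean([p.rmse_ohm for p in fits])),
    )
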