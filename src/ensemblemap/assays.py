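"""Biochemical models for allosteric-site validation.

Percent tethering and percent inhibition from raw measurements, saturation
EC50 for covalent-tethering dose series, the partial noncompetitive
inhibition model v(c) = v0 * (1 - Imax * c / (Ki + c)) (which plateaus at
(1 - Imax) * v0 for Imax < 1), Michaelis-Menten kinetics, and conversion of
absorbance rates to kcat via the pNPP extinction coefficient.

All fits are unweighted least squares on replicate means (Hill coefficient
fixed at 1); standard errors come from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, ValidationError
from .simulate import DoseResponseTable, KineticsTable

_BOUNDARY_TOL = 1e-6


@dataclass
class AssayConstants:
    """pNPP assay constants: extinction coefficient (M^-1 cm^-1), optical
    path length (cm), enzyme concentration (nM)."""

    extinction_coefficient: float = 18000.0
    path_length: float = 0.29
    enzyme_concentration: float = 200.0

    def __post_init__(self) -> None:
        if min(self.extinction_coefficient, self.path_length) <= 0:
            raise ValidationError("assay constants must be positive")


@dataclass
class InhibitionFit:
    ki: float | None = None  # uM
    max_inhibition: float | None = None  # fraction
    ec50: float | None = None  # uM
    standard_errors: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 0
    boundary_flag: bool = False


@dataclass
class KineticsFit:
    vmax: float  # rate units (mAU/min)
    km: float  # mM
    kcat: float | None = None  # per minute
    standard_errors: dict[str, float] = field(default_factory=dict)


def percent_inhibition(rate_fragment: float, rate_dmso: float, rate_no_enzyme: float) -> float:
    """100 * (1 - (Rate_frag - Rate_noE) / (Rate_DMSO - Rate_noE))."""
    denom = rate_dmso - rate_no_enzyme
    if denom == 0:
        raise ValidationError("DMSO and no-enzyme control rates coincide")
    return 100.0 * (1.0 - (rate_fragment - rate_no_enzyme) / denom)


def percent_tethering(peak_unmodified: float, peak_modified: float) -> float:
    """Conjugated fraction from relative mass-spectrum peak heights:
    100 * modified / (modified + unmodified)."""
    if peak_unmodified < 0 or peak_modified < 0:
        raise ValidationError("peak heights must be non-negative")
    total = peak_unmodified + peak_modified
    if total == 0:
        raise ValidationError("both peaks are zero")
    return 100.0 * peak_modified / total


def fit_ec50(table: DoseResponseTable) -> InhibitionFit:
    """One-site saturation fit response = c / (EC50 + c) on replicate means."""
    conc = table.concentrations
    if len(np.unique(conc)) < 4:
        raise ValidationError("EC50 fit needs at least 4 distinct doses")
    y = table.means()
    if float(np.std(y)) < 1e-12:
        raise FitFailureError("flat dose-response data: EC50 unidentifiable")

    def model(c, ec50):
        return c / (ec50 + c)

    try:
        popt, pcov = curve_fit(
            model, conc, y, p0=[float(np.median(conc))],
            bounds=([1e-12], [np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"EC50 fit did not converge: {exc}") from exc
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return InhibitionFit(ec50=float(popt[0]), standard_errors={"ec50": se},
                         n_replicates=table.n_replicates)


def fit_partial_noncompetitive(table: DoseResponseTable, v0: float) -> InhibitionFit:
    """Fit v(c) = v0 * (1 - Imax * c / (Ki + c)); returns Ki and Imax.

    Imax is bounded to [0, 1]; an estimate pinned at either bound sets the
    boundary flag (Imax = 1 reduces to full noncompetitive inhibition,
    Imax = 0 to no inhibition).
    """
    conc = table.concentrations
    if len(np.unique(conc)) < 5:
        raise ValidationError("partial noncompetitive fit needs at least 5 distinct doses")
    y = table.means()

    def model(c, ki, imax):
        return v0 * (1.0 - imax * c / (ki + c))

    pos = conc[conc > 0]
    try:
        popt, pcov = curve_fit(
            model, conc, y,
            p0=[float(np.median(pos)), 0.5],
            bounds=([1e-12, 0.0], [np.inf, 1.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"inhibition fit did not converge: {exc}") from exc
    ki, imax = float(popt[0]), float(popt[1])
    diag = np.diag(pcov)
    se = {
        "ki": float(np.sqrt(diag[0])) if np.isfinite(diag[0]) else float("nan"),
        "max_inhibition": float(np.sqrt(diag[1])) if np.isfinite(diag[1]) else float("nan"),
    }
    # flat data drives Imax toward 0 with Ki ridging to infinity (only the
    # ratio is identifiable), so judge the lower boundary by the predicted
    # effect over the measured dose range, not by Imax alone
    c_max = float(conc.max())
    predicted_effect = imax * c_max / (ki + c_max)
    boundary = (
        imax <= _BOUNDARY_TOL
        or imax >= 1.0 - _BOUNDARY_TOL
        or predicted_effect <= 0.02
    )
    return InhibitionFit(ki=ki, max_inhibition=imax, standard_errors=se,
                         n_replicates=table.n_replicates, boundary_flag=boundary)


def fit_michaelis_menten(
    table: KineticsTable, constants: AssayConstants | None = None
) -> KineticsFit:
    """Least-squares Michaelis-Menten fit v = Vmax * S / (Km + S) on
    replicate means; kcat is attached when assay constants are supplied."""
    sub = table.substrate_concentrations
    if len(np.unique(sub)) < 5:
        raise ValidationError("Michaelis-Menten fit needs at least 5 substrate concentrations")
    y = table.means()

    def model(s, vmax, km):
        return vmax * s / (km + s)

    try:
        popt, pcov = curve_fit(
            model, sub, y,
            p0=[float(y.max()), float(np.median(sub))],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    diag = np.diag(pcov)
    fit = KineticsFit(
        vmax=vmax, km=km,
        standard_errors={
            "vmax": float(np.sqrt(diag[0])) if np.isfinite(diag[0]) else float("nan"),
            "km": float(np.sqrt(diag[1])) if np.isfinite(diag[1]) else float("nan"),
        },
    )
    if constants is not None:
        fit.kcat = rate_to_kcat(vmax, constants)
    return fit


def rate_to_kcat(rate_mau_per_min: float, constants: AssayConstants) -> float:
    """Absorbance rate (mAU/min) -> turnover number (min^-1).

    kcat = (rate / 1000) / (epsilon * path) / [E]; the first factor converts
    mAU to AU, Beer-Lambert converts AU/min to M/min, and dividing by the
    molar enzyme concentration gives per-enzyme turnovers per minute.
    """
    if constants.enzyme_concentration <= 0:
        raise ValidationError("enzyme concentration must be positive")
    molar_rate = (rate_mau_per_min / 1000.0) / (
        constants.extinction_coefficient * constants.path_length
    )
    return molar_rate / (constants.enzyme_concentration * 1e-9)
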