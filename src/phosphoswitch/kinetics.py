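"""In vitro kinase-assay analysis: Michaelis–Menten, logistic IC50, Ki.

These are the formulas used to parameterize the cellular model from
solution kinase assays: initial-rate saturation curves on the ATF2
substrate (v = Vmax·S/(KM+S), with KM = 17.3 µM for pp-p38 on the WT
TAD), logistic dose–response fits of peptide competition series, and the
competitive-inhibition conversion Ki = IC50/(1 + S/KM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

#: substrate dilution series used in the saturation assays (µM)
DEFAULT_SUBSTRATE_SERIES_UM = (100.0, 50.0, 25.0, 10.0, 5.0, 2.5, 1.0, 0.5)

#: 3-fold peptide dilution series starting from 1 mM (µM), 12 doses
DEFAULT_DOSE_SERIES_UM = tuple(1000.0 / 3.0 ** i for i in range(12))

KM_REF_UM = 17.3           # pp-p38 → MBP-ATF2(19-100) WT
ASSAY_SUBSTRATE_UM = 2.0   # substrate concentration in the competition assay


class NoInhibitionError(ValueError):
    """The dose–response series shows no inhibition to fit."""


class DegenerateDataError(ValueError):
    """The rate series is degenerate (e.g. all zero)."""


@dataclass(frozen=True)
class MichaelisMentenFit:
    vmax: float
    km: float
    vmax_se: float
    km_se: float
    non_saturating: bool   # flagged when KM estimate > 10 × max substrate

    def rate(self, s):
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


@dataclass(frozen=True)
class Ic50Fit:
    ic50: float
    hill: float
    top: float
    bottom: float

    def activity(self, dose):
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (dose / self.ic50) ** self.hill
        )


def fit_michaelis_menten(substrate_um, rates) -> MichaelisMentenFit:
    """Nonlinear least squares of v = Vmax·S/(KM + S).

    Requires ≥ 4 distinct substrate concentrations; all-zero (or
    negative-only) rates raise :class:`DegenerateDataError`.  A KM
    estimate beyond 10× the largest substrate concentration sets the
    ``non_saturating`` flag instead of failing.
    """
    s = np.asarray(substrate_um, dtype=float)
    v = np.asarray(rates, dtype=float)
    if s.shape != v.shape:
        raise ValueError("substrate and rate arrays must align")
    if len(np.unique(s)) < 4:
        raise ValueError("need ≥ 4 distinct substrate concentrations")
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")
    if np.max(v) <= 0:
        raise DegenerateDataError("rates are all ≤ 0; nothing to fit")
    order = np.argsort(s)
    s, v = s[order], v[order]
    p0 = (float(np.max(v)), float(np.median(s)))
    popt, pcov = curve_fit(
        lambda x, vmax, km: vmax * x / (km + x),
        s, v, p0=p0, bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=10000,
    )
    se = np.sqrt(np.diag(pcov))
    flagged = bool(popt[1] > 10.0 * np.max(s))
    if flagged:
        warnings.warn(
            f"KM estimate {popt[1]:.3g} µM exceeds 10× the largest substrate "
            "concentration; data do not saturate"
        )
    return MichaelisMentenFit(float(popt[0]), float(popt[1]),
                              float(se[0]), float(se[1]), flagged)


def fit_ic50(dose_um, activity, top_max: float = 1.2,
             flat_threshold: float = 0.1) -> Ic50Fit:
    """4-parameter logistic dose–response fit with a free Hill slope.

    ``activity`` is normalized to the no-inhibitor reaction; floor and
    ceiling are constrained to [0, ``top_max``].  A response range below
    ``flat_threshold`` raises :class:`NoInhibitionError`; non-monotone
    trends beyond noise only warn.
    """
    d = np.asarray(dose_um, dtype=float)
    a = np.asarray(activity, dtype=float)
    if d.shape != a.shape:
        raise ValueError("dose and activity arrays must align")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if len(np.unique(d)) < 5:
        raise ValueError("need ≥ 5 doses spanning the transition")
    order = np.argsort(d)
    d, a = d[order], a[order]
    if np.ptp(a) < flat_threshold:
        raise NoInhibitionError(
            f"activity range {np.ptp(a):.3g} below {flat_threshold}; flat curve"
        )
    lo_mean = float(np.mean(a[: max(2, len(a) // 4)]))
    hi_mean = float(np.mean(a[-max(2, len(a) // 4):]))
    if hi_mean > lo_mean + 0.1:
        warnings.warn("activity increases with dose beyond noise; "
                      "check normalization")

    def fourpl(x, bottom, top, ic50, hill):
        return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)

    half = np.exp(np.interp(0.5 * (np.max(a) + np.min(a)),
                            a[::-1], np.log(d)[::-1]))
    p0 = (max(float(np.min(a)), 0.0), min(float(np.max(a)), top_max),
          float(half), 1.0)
    popt, _ = curve_fit(
        fourpl, d, a, p0=p0,
        bounds=([0.0, 0.0, 1e-9, 0.1], [top_max, top_max, 1e9, 10.0]),
        maxfev=20000,
    )
    return Ic50Fit(ic50=float(popt[2]), hill=float(popt[3]),
                   top=float(popt[1]), bottom=float(popt[0]))


def ki_from_ic50(ic50_um: float, substrate_um: float, km_um: float) -> float:
    """Competitive-inhibition constant: Ki = IC50 / (1 + S/KM)."""
    if km_um <= 0:
        raise ZeroDivisionError("KM must be positive")
    if ic50_um <= 0 or substrate_um < 0:
        raise ValueError("IC50 must be positive and S nonnegative")
    return ic50_um / (1.0 + substrate_um / km_um)


def ic50_from_ki(ki_um: float, substrate_um: float, km_um: float) -> float:
    """Inverse conversion, used when generating synthetic inhibition data."""
    if km_um <= 0:
        raise ZeroDivisionError("KM must be positive")
    return ki_um * (1.0 + substrate_um / km_um)
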