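"""Four-parameter-logistic dose-response fitting and IC50 categorisation.

Percent inhibition is modelled against log10 concentration with the
four-parameter logistic (4PL)

    y(x) = bottom + (top - bottom) / (1 + 10^(hill * (log10 IC50 - x)))

fitted by bounded least squares jointly over all replicates.  The reported
IC50 is NOT the inflection parameter but the concentration where the fitted
curve crosses 50 % inhibition; a fit falls into one of three categories:

* IN_RANGE     — the 50 % crossing lies within the assayed window;
* EXTRAPOLATED — the fitted curve crosses 50 % only above the top assay
                 concentration (IC50 reported by extrapolation);
* BASELINE     — the curve never reaches 50 %, its maximum fitted response
                 inside the window stays below a baseline threshold
                 (default 25 %), or the optimiser failed; no IC50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InsufficientDataError

IN_RANGE = "IN_RANGE"
EXTRAPOLATED = "EXTRAPOLATED"
BASELINE = "BASELINE"
CATEGORIES = (IN_RANGE, EXTRAPOLATED, BASELINE)

#: study assay window, molar
DEFAULT_ASSAY_RANGE = (5e-9, 1e-4)
DEFAULT_BASELINE_THRESHOLD = 25.0

# bounds keep fits non-degenerate while allowing assay noise beyond [0, 100]
BOTTOM_BOUNDS = (-20.0, 30.0)
TOP_BOUNDS = (30.0, 120.0)
HILL_BOUNDS = (0.2, 5.0)
#: percent inhibition is an assay-normalised scale, so the upper plateau is
#: pinned to 100 % by default; partial curves (no plateau in-window) leave a
#: free top unidentifiable and its extrapolation meaningless.  Set
#: ``fix_top=False`` to free it within TOP_BOUNDS.
FIXED_TOP = 100.0


def logistic4(log10_conc, bottom, top, hill, log10_ic50):
    """4PL response (percent inhibition) at log10 molar concentration."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_ic50 - log10_conc)))


def crossing_log10(bottom: float, top: float, hill: float, log10_ic50: float):
    """log10 concentration where the fitted curve equals 50 % inhibition,
    or None if the curve never reaches 50 % (requires bottom < 50 < top)."""
    if not (bottom < 50.0 < top):
        return None
    return log10_ic50 - np.log10((top - 50.0) / (50.0 - bottom)) / hill


@dataclass
class DoseResponseFit:
    compound_id: str
    enzyme_id: str
    bottom: float
    top: float
    hill: float
    log10_ic50: float  # log10 molar of the 50% crossing; NaN for BASELINE
    ic50: float  # molar; NaN for BASELINE
    category: str
    rmse: float
    n_points: int
    converged: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def categorize_fit(
    bottom: float,
    top: float,
    hill: float,
    log10_ic50_param: float,
    assay_range: tuple[float, float],
    baseline_threshold: float = DEFAULT_BASELINE_THRESHOLD,
    converged: bool = True,
) -> tuple[str, float]:
    """Category plus the 50 % crossing (log10 molar; NaN when BASELINE).

    Crossings below the assay minimum keep their fitted value and are
    labelled IN_RANGE — the assay cannot resolve potency beyond its lowest
    concentration.
    """
    lo, hi = np.log10(assay_range[0]), np.log10(assay_range[1])
    if not converged:
        return BASELINE, np.nan
    max_resp = max(
        logistic4(lo, bottom, top, hill, log10_ic50_param),
        logistic4(hi, bottom, top, hill, log10_ic50_param),
    )
    if max_resp < baseline_threshold - 1e-9:  # epsilon: boundary goes to the fit
        return BASELINE, np.nan
    x50 = crossing_log10(bottom, top, hill, log10_ic50_param)
    if x50 is None:
        return BASELINE, np.nan
    if x50 > hi:
        return EXTRAPOLATED, float(x50)
    return IN_RANGE, float(x50)


def fit_dose_response(
    series: pd.DataFrame,
    assay_range: tuple[float, float] = DEFAULT_ASSAY_RANGE,
    baseline_threshold: float = DEFAULT_BASELINE_THRESHOLD,
    n_restarts: int = 3,
    fix_top: bool = True,
) -> DoseResponseFit:
    """Fit one compound x enzyme dose-response series.

    ``series`` holds columns ``concentration_m`` and ``percent_inhibition``
    (plus optional ``compound_id``/``enzyme_id`` carried into the result);
    replicates enter the least-squares loss jointly, never averaged first.
    Requires >= 4 distinct concentrations.  Non-convergence after jittered
    restarts yields a BASELINE fit flagged ``converged=False``.  With
    ``fix_top`` (default) the upper plateau is pinned at 100 %.
    """
    conc = series["concentration_m"].to_numpy(dtype=float)
    y = series["percent_inhibition"].to_numpy(dtype=float)
    if np.unique(conc).size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {np.unique(conc).size}"
        )
    x = np.log10(conc)
    compound = str(series["compound_id"].iloc[0]) if "compound_id" in series else ""
    enzyme = str(series["enzyme_id"].iloc[0]) if "enzyme_id" in series else ""

    lo, hi = np.log10(assay_range[0]), np.log10(assay_range[1])
    if fix_top:
        model = lambda xx, bottom, hill, lic50: logistic4(xx, bottom, FIXED_TOP, hill, lic50)
        bounds = (
            [BOTTOM_BOUNDS[0], HILL_BOUNDS[0], lo - 4.0],
            [BOTTOM_BOUNDS[1], HILL_BOUNDS[1], hi + 4.0],
        )
        base_p0 = [0.0, 1.0, 0.0]
        jitter_sd = [5.0, 0.3, 0.5]
    else:
        model = logistic4
        bounds = (
            [BOTTOM_BOUNDS[0], TOP_BOUNDS[0], HILL_BOUNDS[0], lo - 4.0],
            [BOTTOM_BOUNDS[1], TOP_BOUNDS[1], HILL_BOUNDS[1], hi + 4.0],
        )
        base_p0 = [0.0, 100.0, 1.0, 0.0]
        jitter_sd = [5.0, 5.0, 0.3, 0.5]
    # start at the concentration whose mean response is nearest 50 %
    base_p0[-1] = float(x[np.argmin(np.abs(y - 50.0))])
    p0 = np.clip(
        base_p0, np.asarray(bounds[0]) + 1e-9, np.asarray(bounds[1]) - 1e-9
    )

    params, ok = None, False
    jitter_rng = np.random.default_rng(0)  # restart jitter only; fit is deterministic
    for attempt in range(1 + n_restarts):
        start = p0 if attempt == 0 else np.clip(
            p0 + jitter_rng.normal(0.0, jitter_sd),
            np.asarray(bounds[0]) + 1e-9,
            np.asarray(bounds[1]) - 1e-9,
        )
        try:
            params, _ = curve_fit(model, x, y, p0=start, bounds=bounds, maxfev=20_000)
            ok = True
            break
        except RuntimeError:
            continue
    if not ok:
        return DoseResponseFit(
            compound_id=compound,
            enzyme_id=enzyme,
            bottom=np.nan,
            top=np.nan,
            hill=np.nan,
            log10_ic50=np.nan,
            ic50=np.nan,
            category=BASELINE,
            rmse=float(np.sqrt(np.mean((y - y.mean()) ** 2))),
            n_points=y.size,
            converged=False,
        )

    if fix_top:
        bottom, hill, lic50 = (float(v) for v in params)
        top = FIXED_TOP
    else:
        bottom, top, hill, lic50 = (float(v) for v in params)
    resid = y - logistic4(x, bottom, top, hill, lic50)
    rmse = float(np.sqrt(np.mean(resid**2)))
    category, x50 = categorize_fit(
        bottom, top, hill, lic50, assay_range, baseline_threshold, converged=True
    )
    return DoseResponseFit(
        compound_id=compound,
        enzyme_id=enzyme,
        bottom=bottom,
        top=top,
        hill=hill,
        log10_ic50=x50,
        ic50=float(10.0**x50) if np.isfinite(x50) else np.nan,
        category=category,
        rmse=rmse,
        n_points=y.size,
        converged=True,
    )


def fit_panel(
    table: pd.DataFrame,
    assay_range: tuple[float, float] = DEFAULT_ASSAY_RANGE,
    baseline_threshold: float = DEFAULT_BASELINE_THRESHOLD,
    fix_top: bool = True,
) -> pd.DataFrame:
    """Fit every compound x enzyme series of a tidy inhibition table.

    Returns one row per pair with the :class:`DoseResponseFit` fields.
    """
    fits = []
    for (_, _), grp in table.groupby(["compound_id", "enzyme_id"], sort=True):
        fits.append(
            fit_dose_response(
                grp, assay_range, baseline_threshold, fix_top=fix_top
            ).to_dict()
        )
    return pd.DataFrame(fits)


def summarize_categories(fits: pd.DataFrame | Iterable[DoseResponseFit]) -> dict:
    """Percentage of fits per category (IN_RANGE / EXTRAPOLATED / BASELINE)."""
    if isinstance(fits, pd.DataFrame):
        cats = fits["category"]
    else:
        cats = pd.Series([f.category for f in fits])
    if len(cats) == 0:
        raise InsufficientDataError("no fits to summarize")
    frac = cats.value_counts(normalize=True) * 100.0
    return {c: float(frac.get(c, 0.0)) for c in CATEGORIES}
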