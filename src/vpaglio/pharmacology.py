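"""Dose-response fitting and derived pharmacology statistics.

Temozolomide chemosensitivity curves are fitted with the four-parameter
logistic (variable-slope) model on log10 concentration:

    response(x) = bottom + (top - bottom) / (1 + 10^((log_ic50 - x) * hill))

after normalizing fluorescence to the intra-plate no-drug control mean
(control = 100%).  Both the curve-midpoint IC50 (log_ic50) and the
absolute IC50 (concentration at 50% of control) are reported, since a
"50% growth reduction compared to control" is the absolute variant while
variable-slope fitting conventionally yields the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import DataValidationError

DOSE_COLUMNS = ("cell_line", "vpa_status", "concentration", "replicate", "fluorescence")


@dataclass
class FitResult:
    bottom: float
    top: float
    hill: float
    log_ic50: float  # log10 of curve midpoint concentration
    ic50: float  # midpoint, concentration units
    ic50_abs: float  # concentration at 50% of control; nan if the curve never crosses
    rss: float
    converged: bool
    n_points: int
    increasing: bool  # response rises with dose (flagged, fit still reported)
    extrapolated: bool  # ic50 outside the fitted concentration span


@dataclass
class RescueResult:
    sirna: str
    relative_proliferation: float
    interpretation: str  # sensitized (<1) / desensitized (>1) / neutral


def read_dose_response(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(DOSE_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: dose table missing columns {sorted(missing)}")
    if (df["fluorescence"] <= 0).any():
        raise DataValidationError(f"{path}: fluorescence values must be positive")
    if (df["concentration"] < 0).any():
        raise DataValidationError(f"{path}: negative concentration")
    return df


def _model(x, bottom, top, hill, log_ic50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x) * hill))


def fit_4pl(
    table: pd.DataFrame,
    bottom_bounds: tuple[float, float] = (0.0, 50.0),
    top_bounds: tuple[float, float] = (50.0, 150.0),
    hill_bounds: tuple[float, float] = (-10.0, -0.05),
    midpoint_margin: float = 1.0,
) -> FitResult:
    """Least-squares 4PL fit of one curve (one cell line x VPA status).

    ``table`` needs ``concentration`` and ``fluorescence`` columns with
    at least one zero-concentration control row (used for normalization)
    and >= 4 distinct positive concentrations.  All replicate points are
    fitted, not their means.  Because responses are normalized to the
    control (= 100%), the plateaus are constrained to meaningful ranges
    (viability cannot be negative, the top sits near the control level)
    and the slope to inhibition; the midpoint may extend
    ``midpoint_margin`` decades beyond the tested range.  A deterministic
    multi-start grid over hill slopes {-0.5, -1, -2} and midpoint guesses
    seeds the optimizer; the best residual sum of squares wins.  A fit
    whose midpoint lands on the search boundary is unidentifiable from
    the data and reported as non-converged (e.g. a flat curve).
    """
    ctrl = table.loc[table["concentration"] == 0, "fluorescence"]
    if ctrl.empty:
        raise DataValidationError("no zero-concentration control rows")
    dosed = table[table["concentration"] > 0]
    if dosed["concentration"].nunique() < 4:
        raise DataValidationError("need >= 4 distinct positive concentrations")
    resp = dosed["fluorescence"].to_numpy(float) / ctrl.mean() * 100.0
    x = np.log10(dosed["concentration"].to_numpy(float))
    increasing = bool(np.polyfit(x, resp, 1)[0] > 0)

    lo = [bottom_bounds[0], top_bounds[0], hill_bounds[0], x.min() - midpoint_margin]
    hi = [bottom_bounds[1], top_bounds[1], hill_bounds[1], x.max() + midpoint_margin]
    b0 = float(np.clip(resp.min(), *bottom_bounds))
    t0 = float(np.clip(resp.max(), *top_bounds))
    mid_guess = x[np.argmin(np.abs(resp - (b0 + t0) / 2))]
    best = None
    for h0 in (-0.5, -1.0, -2.0):
        for l0 in (mid_guess, np.median(x)):
            try:
                sol = least_squares(
                    lambda p: _model(x, *p) - resp,
                    x0=np.clip([b0, t0, h0, l0], lo, hi),
                    bounds=(lo, hi),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=5000,
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if sol.success and (best is None or rss < best[0]):
                best = (rss, sol.x)
    if best is None:
        return FitResult(*[np.nan] * 7, False, len(resp), increasing, False)
    rss, (bottom, top, hill, log_ic50) = best
    span = top - bottom
    at_boundary = log_ic50 <= lo[3] + 1e-3 or log_ic50 >= hi[3] - 1e-3
    converged = bool(
        np.isfinite([bottom, top, hill, log_ic50]).all() and span > 1.0 and not at_boundary
    )
    ic50 = 10.0**log_ic50
    # absolute IC50: concentration where the fitted curve crosses 50% of control
    ic50_abs = np.nan
    if converged and (top - 50.0) > 0 and (50.0 - bottom) > 0:
        ratio = (top - 50.0) / (50.0 - bottom)
        ic50_abs = 10.0 ** (log_ic50 - np.log10(ratio) / hill)
    extrapolated = bool(
        converged and not (10.0 ** x.min() <= ic50 <= 10.0 ** x.max())
    )
    return FitResult(
        bottom=float(bottom),
        top=float(top),
        hill=float(hill),
        log_ic50=float(log_ic50),
        ic50=float(ic50),
        ic50_abs=float(ic50_abs),
        rss=rss,
        converged=converged,
        n_points=len(resp),
        increasing=increasing,
        extrapolated=extrapolated,
    )


def fit_all_curves(table: pd.DataFrame) -> pd.DataFrame:
    """fit_4pl per (cell_line, vpa_status) group of a dose-response table."""
    rows = []
    for (line, status), grp in table.groupby(["cell_line", "vpa_status"], sort=True):
        fit = fit_4pl(grp)
        rows.append({"cell_line": line, "vpa_status": status, **fit.__dict__})
    return pd.DataFrame(rows)


def ic50_reduction(ic50_naive: float, ic50_vpa: float) -> float:
    """Relative IC50 reduction after VPA: 1 - IC50_vpa / IC50_naive.

    Positive values mean sensitization (response curve shifted left);
    negative values mean desensitization.
    """
    if ic50_naive <= 0 or ic50_vpa <= 0:
        raise DataValidationError("IC50 values must be positive")
    return 1.0 - ic50_vpa / ic50_naive


def sirna_rescue(readings: pd.DataFrame, control: str = "siCTRL") -> list[RescueResult]:
    """VPA-induced TMZ sensitization per siRNA, normalized so siCTRL = 1.

    ``readings`` has columns sirna, vpa (0/1), tmz (0/1), value.  The
    VPA-induced effect of an siRNA is

        effect = [mean(vpa+,tmz+)/mean(vpa+,tmz-)] / [mean(vpa-,tmz+)/mean(vpa-,tmz-)]

    and the reported value is effect(siRNA)/effect(siCTRL): > 1 means the
    knockdown weakened the VPA-induced sensitization (desensitization,
    the presumed rescue), < 1 means additional sensitization.
    """
    required = {"sirna", "vpa", "tmz", "value"}
    missing = required - set(readings.columns)
    if missing:
        raise DataValidationError(f"rescue table missing columns {sorted(missing)}")
    if (readings["value"] <= 0).any():
        raise DataValidationError("proliferation readings must be positive")

    def effect(sub: pd.DataFrame, name: str) -> float:
        means = sub.groupby(["vpa", "tmz"])["value"].mean()
        for key in [(1, 1), (1, 0), (0, 1), (0, 0)]:
            if key not in means.index:
                raise DataValidationError(f"siRNA {name!r}: missing condition vpa={key[0]}, tmz={key[1]}")
        return (means[(1, 1)] / means[(1, 0)]) / (means[(0, 1)] / means[(0, 0)])

    groups = {name: grp for name, grp in readings.groupby("sirna")}
    if control not in groups:
        raise DataValidationError(f"control siRNA {control!r} absent from table")
    e_ctrl = effect(groups[control], control)
    out = []
    for name, grp in groups.items():
        val = effect(grp, name) / e_ctrl
        if np.isclose(val, 1.0, atol=1e-9):
            interp = "neutral"
        else:
            interp = "desensitized" if val > 1 else "sensitized"
        out.append(RescueResult(sirna=name, relative_proliferation=float(val), interpretation=interp))
    return out


def ddct_fold(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the delta-delta-Ct method: 2^(-ddCt)."""
    vals = [ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator]
    if not np.isfinite(vals).all():
        raise DataValidationError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
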