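"""Enzyme-inhibition data reduction and model fitting.

Pipeline for fluorometric activity plates: replicate reduction (median over
technical replicates, mean over experimental replicates, ratio to the 0 µM
inhibitor control), IC50 estimation by a two-parameter log-logistic model
with AIC selection against a constant (no-inhibition) model, a
Michaelis–Menten fit of the uninhibited velocities, a mixed-inhibition fit
for K_i and α, and the confidence-interval rule assigning the mode of
inhibition (MOI).

The mixed-inhibition velocity model is

    v = V_max·[S] / { K_m·(1 + [I]/K_i) + [S]·(1 + [I]/(α·K_i)) }

with [S], [I] in µM. α ≫ 1 means the inhibitor blocks substrate binding
(competitive); α ≈ 1 leaves substrate affinity unchanged (noncompetitive);
intermediate behavior is mixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

PLATE_COLUMNS = ("inhibitor_conc", "substrate_conc", "tech_rep", "exp_rep", "fluorescence")


class DataError(ValueError):
    """Malformed plate data (e.g. missing 0 µM control block)."""


class FitError(RuntimeError):
    """A nonlinear fit failed to converge."""


@dataclass
class IC50Fit:
    """Result of the log-logistic vs constant model comparison.

    ``model`` is the AIC winner; a constant winner means no measurable
    inhibition and ``ic50`` is +inf. ``censored`` flags an estimate above
    the highest tested concentration, reported as "> max".
    """

    model: str  # {"log_logistic", "constant"}
    ic50: float  # µM, +inf for the constant model
    slope: float | None
    ci95: tuple[float, float] | None
    aic_ll: float | None
    aic_const: float
    censored: bool
    max_conc: float

    @property
    def display(self) -> str:
        if math.isinf(self.ic50):
            return "inf"
        if self.censored:
            return f"> {self.max_conc:g}"
        return f"{self.ic50:.3g}"


@dataclass
class MichaelisMentenFit:
    v_max: float
    k_m: float
    ci95_v_max: tuple[float, float]
    ci95_k_m: tuple[float, float]


@dataclass
class InhibitionFit:
    """Mixed-inhibition estimates and the derived mode of inhibition."""

    v_max: float
    k_m: float
    k_i: float  # µM
    alpha: float
    ci95_ki: tuple[float, float]
    ci95_alpha: tuple[float, float]
    moi: str  # {"competitive", "noncompetitive", "mixed"}


# ---------------------------------------------------------------------------
# data reduction


def _check_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise DataError(f"plate data missing columns {missing}")
    return plate


def reduce_replicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Average activity per (substrate_conc, inhibitor_conc).

    Median over technical replicates within each experimental replicate
    (robust to single-well outliers), then mean over experimental
    replicates. Returns columns substrate_conc, inhibitor_conc, activity.
    """
    _check_plate(plate)
    med = (
        plate.groupby(["substrate_conc", "inhibitor_conc", "exp_rep"], sort=True)["fluorescence"]
        .median()
        .reset_index()
    )
    avg = (
        med.groupby(["substrate_conc", "inhibitor_conc"], sort=True)["fluorescence"]
        .mean()
        .reset_index()
        .rename(columns={"fluorescence": "activity"})
    )
    return avg


def normalize_activity(plate: pd.DataFrame) -> pd.DataFrame:
    """Concentration–response ratios per substrate concentration.

    The averaged activity at each inhibitor concentration is divided by the
    matched 0 µM inhibitor control, so the ratio at 0 µM is 1 by
    construction. Returns columns substrate_conc, inhibitor_conc,
    activity_ratio.
    """
    avg = reduce_replicates(plate)
    out = []
    for s, block in avg.groupby("substrate_conc", sort=True):
        ctrl = block.loc[block["inhibitor_conc"] == 0.0, "activity"]
        if ctrl.empty:
            raise DataError(f"no 0 µM inhibitor control for substrate_conc={s}")
        c = float(ctrl.iloc[0])
        b = block.copy()
        b["activity_ratio"] = b["activity"] / c
        out.append(b[["substrate_conc", "inhibitor_conc", "activity_ratio"]])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# IC50


def log_logistic(conc: np.ndarray, slope: float, log_ic50: float) -> np.ndarray:
    """Two-parameter log-logistic response, limits 1 → 0:
    ratio = 1 / (1 + exp(b·(ln[I] − ln IC50)))."""
    return 1.0 / (1.0 + np.exp(slope * (np.log(conc) - log_ic50)))


def _aic_ls(rss: float, n: int, k_params: int) -> float:
    """AIC for a least-squares fit: n·ln(RSS/n) + 2k, k counting fitted
    parameters plus one for the residual variance."""
    return n * math.log(rss / n) + 2 * (k_params + 1)


def fit_ic50(cr: pd.DataFrame, max_conc: float | None = None) -> IC50Fit:
    """Fit log-logistic and constant models to one concentration–response
    series and keep the AIC winner.

    ``cr`` needs columns inhibitor_conc and activity_ratio with ≥ 4
    distinct concentrations including the 0 µM anchor. The 0 µM point
    anchors normalization only and is excluded from both fits (it has no
    logarithm); both models therefore see the same points and their AICs
    are comparable. The IC50 CI is a Wald interval on ln IC50,
    exponentiated. If the optimizer fails, the constant model is returned
    with a warning.
    """
    conc = np.asarray(cr["inhibitor_conc"], dtype=float)
    ratio = np.asarray(cr["activity_ratio"], dtype=float)
    if np.unique(conc).size < 4 or not (conc == 0).any():
        raise DataError("need ≥ 4 distinct concentrations including the 0 µM control")
    mask = conc > 0
    x, y = conc[mask], ratio[mask]
    n = x.size
    if max_conc is None:
        max_conc = float(x.max())

    rss_const = float(((y - 1.0) ** 2).sum())
    aic_const = _aic_ls(rss_const, n, 0)

    try:
        p0 = (1.0, float(np.log(np.median(x))))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(log_logistic, x, y, p0=p0, maxfev=10000)
        resid = y - log_logistic(x, *popt)
        rss_ll = float((resid**2).sum())
        if not np.all(np.isfinite(pcov)):
            raise RuntimeError("singular covariance")
    except RuntimeError as exc:
        warnings.warn(f"log-logistic fit failed ({exc}); falling back to the constant model")
        return IC50Fit(
            model="constant", ic50=math.inf, slope=None, ci95=None,
            aic_ll=None, aic_const=aic_const, censored=False, max_conc=max_conc,
        )

    aic_ll = _aic_ls(rss_ll, n, 2)
    if aic_const <= aic_ll:
        return IC50Fit(
            model="constant", ic50=math.inf, slope=None, ci95=None,
            aic_ll=aic_ll, aic_const=aic_const, censored=False, max_conc=max_conc,
        )
    slope, log_ic50 = popt
    se = math.sqrt(pcov[1, 1])
    tq = stats.t.ppf(0.975, df=max(n - 2, 1))
    with np.errstate(over="ignore"):
        ci = (float(np.exp(log_ic50 - tq * se)), float(np.exp(log_ic50 + tq * se)))
        ic50 = float(np.exp(log_ic50))
    return IC50Fit(
        model="log_logistic", ic50=ic50, slope=float(slope), ci95=ci,
        aic_ll=aic_ll, aic_const=aic_const, censored=ic50 > max_conc, max_conc=max_conc,
    )


# ---------------------------------------------------------------------------
# Michaelis–Menten and mixed inhibition


def michaelis_menten(s: np.ndarray, v_max: float, k_m: float) -> np.ndarray:
    return v_max * s / (k_m + s)


def mixed_inhibition(
    s: np.ndarray, i: np.ndarray, v_max: float, k_m: float, k_i: float, alpha: float
) -> np.ndarray:
    return v_max * s / (k_m * (1.0 + i / k_i) + s * (1.0 + i / (alpha * k_i)))


def _wald_ci(est: float, se: float, df: int) -> tuple[float, float]:
    tq = stats.t.ppf(0.975, df=max(df, 1))
    return (est - tq * se, est + tq * se)


def fit_michaelis_menten(
    v: np.ndarray, s: np.ndarray, relative_error: bool = False
) -> MichaelisMentenFit:
    """Nonlinear least-squares fit of v = V_max·[S]/(K_m + [S]) with
    asymptotic 95% CIs. Use only uninhibited ([I] = 0) measurements.

    ``relative_error=True`` weights residuals by 1/v (appropriate when the
    measurement error is a constant coefficient of variation, as with
    fluorescence intensities); the default is an unweighted fit.
    """
    v = np.asarray(v, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.unique(s).size < 3:
        raise DataError("need ≥ 3 distinct substrate concentrations")
    p0 = (float(v.max()), float(np.median(s)))
    sigma = np.abs(v) if relative_error else None
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten, s, v, p0=p0, sigma=sigma, maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    df = v.size - 2
    se = np.sqrt(np.diag(pcov))
    return MichaelisMentenFit(
        v_max=float(popt[0]),
        k_m=float(popt[1]),
        ci95_v_max=_wald_ci(float(popt[0]), float(se[0]), df),
        ci95_k_m=_wald_ci(float(popt[1]), float(se[1]), df),
    )


def fit_mixed_inhibition(
    v: np.ndarray,
    s: np.ndarray,
    i: np.ndarray,
    v_max: float,
    k_m: float,
    fix_mm: bool = True,
) -> InhibitionFit:
    """Estimate K_i and α from velocities over a substrate × inhibitor grid.

    V_max and K_m are fixed at their uninhibited-fit values by default
    (``fix_mm=False`` refits all four parameters jointly). K_i and α are
    fitted on the log scale to enforce positivity; their Wald CIs are
    exponentiated, giving asymmetric positive intervals. The MOI is then
    assigned from the α CI via :func:`assign_moi`.
    """
    v = np.asarray(v, dtype=float)
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    if np.unique(s).size < 3 or np.unique(i[i > 0]).size < 2:
        raise DataError("need ≥ 3 substrate and ≥ 2 nonzero inhibitor concentrations")

    if fix_mm:
        def model(si, log_ki, log_alpha):
            ss, ii = si
            return mixed_inhibition(ss, ii, v_max, k_m, np.exp(log_ki), np.exp(log_alpha))

        p0 = (math.log(np.median(i[i > 0])), 0.0)
        n_par = 2
    else:
        def model(si, log_ki, log_alpha, vm, km):
            ss, ii = si
            return mixed_inhibition(ss, ii, vm, km, np.exp(log_ki), np.exp(log_alpha))

        p0 = (math.log(np.median(i[i > 0])), 0.0, v_max, k_m)
        n_par = 4

    try:
        popt, pcov = optimize.curve_fit(model, (s, i), v, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"mixed-inhibition fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(np.diag(pcov))):
        raise FitError("mixed-inhibition fit has a singular covariance")

    df = v.size - n_par
    se = np.sqrt(np.diag(pcov))
    log_ki, log_alpha = float(popt[0]), float(popt[1])
    lo_ki, hi_ki = _wald_ci(log_ki, float(se[0]), df)
    lo_a, hi_a = _wald_ci(log_alpha, float(se[1]), df)
    ci_alpha = (math.exp(lo_a), math.exp(hi_a))
    if not fix_mm:
        v_max, k_m = float(popt[2]), float(popt[3])
    if abs(log_alpha) > 15:
        warnings.warn("α estimate pinned at an extreme value; fit may be unidentifiable")
    return InhibitionFit(
        v_max=v_max,
        k_m=k_m,
        k_i=math.exp(log_ki),
        alpha=math.exp(log_alpha),
        ci95_ki=(math.exp(lo_ki), math.exp(hi_ki)),
        ci95_alpha=ci_alpha,
        moi=assign_moi(ci_alpha),
    )


def assign_moi(ci95_alpha: tuple[float, float]) -> str:
    """Mode of inhibition from the 95% CI of α.

    competitive iff lower > 1 and upper > 10; noncompetitive iff lower < 1
    and 1 < upper < 10; anything else (including CI limits exactly at 1 or
    10) is mixed.
    """
    lower, upper = ci95_alpha
    if lower > upper:
        raise ValueError("CI lower limit exceeds upper limit")
    if lower > 1.0 and upper > 10.0:
        return "competitive"
    if lower < 1.0 and 1.0 < upper < 10.0:
        return "noncompetitive"
    return "mixed"
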