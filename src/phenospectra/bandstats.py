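"""Spectrum-level statistics: wavelength grouping, treatment tests, diurnal
slopes, trough depths and trait-reflectance correlation.

Adjacent wavelengths are strongly collinear, so inference is run on a reduced
set of representative bands found by greedy correlation grouping.  Treatment
contrasts (well-watered vs water-deficit) are tested per band within each
day-hour cell with fixed-effects models, and every report is multiplicity-
corrected with the Benjamini-Hochberg procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .indices import rmcorr

__all__ = [
    "WavelengthGroups",
    "EffectReport",
    "group_wavelengths",
    "treatment_tests",
    "diurnal_slope",
    "trough_depth",
    "correlate_traits_reflectance",
]


@dataclass
class WavelengthGroups:
    """Partition of the band axis into collinearity groups.

    Each group is represented by its seed band (the first band that opened
    the group while scanning left to right).
    """

    groups: list[list[float]]
    representatives: list[float]
    threshold: float
    flagged: list[float] = field(default_factory=list)  # constant bands

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def group_wavelengths(
    wavelengths: np.ndarray, spectra: np.ndarray, threshold: float = 0.80
) -> WavelengthGroups:
    """Greedy left-to-right collinearity grouping along the wavelength axis.

    A band joins the current group while its Pearson correlation with the
    group's seed band stays at or above the threshold; otherwise it opens a
    new group and becomes that group's seed (and representative).  Constant
    bands (undefined correlation) form their own flagged group.
    """
    wl = np.asarray(wavelengths, dtype=float)
    X = np.asarray(spectra, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if X.shape[1] != wl.size:
        raise ValueError("spectra columns must match wavelengths")
    sd = X.std(axis=0)
    groups: list[list[float]] = []
    reps: list[float] = []
    flagged: list[float] = []
    seed_col: np.ndarray | None = None
    for j, w in enumerate(wl):
        if sd[j] == 0:
            groups.append([w])
            reps.append(w)
            flagged.append(w)
            seed_col = None
            continue
        if seed_col is not None:
            r = float(np.corrcoef(seed_col, X[:, j])[0, 1])
            if r >= threshold:
                groups[-1].append(w)
                continue
        groups.append([w])
        reps.append(w)
        seed_col = X[:, j]
    return WavelengthGroups(groups, reps, threshold, flagged)


@dataclass
class EffectReport:
    """One tested contrast (treatment difference or diurnal slope)."""

    target: float | str
    contrast: str
    estimate: float
    raw_p: float
    adjusted_p: float = float("nan")
    significant: bool = False
    stderr: float = float("nan")
    n: int = 0


def _bh_adjust(reports: list[EffectReport], alpha: float) -> None:
    if not reports:
        return
    raw = np.array([r.raw_p for r in reports])
    _, adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    for r, p in zip(reports, adj):
        r.adjusted_p = float(p)
        r.significant = bool(p < alpha)


def treatment_tests(
    records: pd.DataFrame,
    bands: list[float],
    alpha: float = 0.05,
    treatment_column: str = "treatment",
) -> list[EffectReport]:
    """WW-vs-WD contrasts per band within each day-hour cell, BH-corrected.

    ``records`` is a long per-plant spectra table (columns plant_id,
    treatment, day, hour plus one float column per wavelength).  Each cell is
    tested with a two-sample t contrast (the per-cell slice of the factorial
    fixed-effects model); cells missing a treatment are skipped.
    """
    reports: list[EffectReport] = []
    band_cols = _nearest_band_columns(records, bands)
    for (day, hour), cell in records.groupby(["day", "hour"]):
        arms = cell.groupby(treatment_column)
        if arms.ngroups < 2:
            continue
        for requested, col in band_cols.items():
            vals = {t: g[col].to_numpy(float) for t, g in arms}
            ww, wd = vals.get("WW"), vals.get("WD")
            if ww is None or wd is None or ww.size < 2 or wd.size < 2:
                continue
            t, p = stats.ttest_ind(ww, wd)
            reports.append(
                EffectReport(
                    target=requested,
                    contrast=f"WW-WD day {day} hour {hour:g}",
                    estimate=float(ww.mean() - wd.mean()),
                    raw_p=float(p),
                    n=int(ww.size + wd.size),
                )
            )
    _bh_adjust(reports, alpha)
    return reports


def _nearest_band_columns(records: pd.DataFrame, bands: list[float]) -> dict:
    cols = np.array([c for c in records.columns if isinstance(c, float)])
    if cols.size == 0:
        raise ValueError("records carry no wavelength columns")
    out = {}
    for b in bands:
        out[float(b)] = float(cols[np.argmin(np.abs(cols - b))])
    return out


@dataclass
class DiurnalSlopeReport:
    """Per-treatment hourly trends (percent reflectance per hour)."""

    slopes: dict
    interaction_estimate: float
    interaction_p: float


def diurnal_slope(
    hours: np.ndarray,
    values: np.ndarray,
    treatments: np.ndarray,
    percent_scale: bool = True,
) -> DiurnalSlopeReport:
    """OLS hourly slope per treatment plus the slope-difference test.

    ``values`` are reflectance fractions; slopes are reported on the percent
    scale by default.  The treatment difference is the interaction term of
    value ~ hour * treatment.  Needs >= 3 distinct hours.
    """
    hours = np.asarray(hours, dtype=float)
    y = np.asarray(values, dtype=float) * (100.0 if percent_scale else 1.0)
    treat = np.asarray(treatments)
    if np.unique(hours).size < 3:
        raise ValueError("need at least 3 distinct hours")
    slopes = {}
    for t in np.unique(treat):
        sel = treat == t
        if np.ptp(y[sel]) == 0:  # constant series: flat trend by definition
            slopes[str(t)] = {"slope": 0.0, "stderr": 0.0, "p": 1.0,
                              "n": int(sel.sum())}
            continue
        Xd = sm.add_constant(hours[sel])
        fit = sm.OLS(y[sel], Xd).fit()
        slopes[str(t)] = {
            "slope": float(fit.params[1]),
            "stderr": float(fit.bse[1]),
            "p": float(fit.pvalues[1]),
            "n": int(sel.sum()),
        }
    inter_est, inter_p = np.nan, np.nan
    uniq = np.unique(treat)
    if np.ptp(y) == 0:
        inter_est, inter_p = 0.0, 1.0
    elif uniq.size == 2:
        # code the second level (sorted order) as 1: WD when levels are WD/WW
        # sorted gives [WD, WW]; use WW as reference so the interaction is
        # slope(WD) - slope(WW)
        ref = "WW" if "WW" in uniq.astype(str) else str(uniq[0])
        ind = (treat.astype(str) != ref).astype(float)
        Xd = np.column_stack([np.ones_like(hours), hours, ind, hours * ind])
        fit = sm.OLS(y, Xd).fit()
        inter_est = float(fit.params[3])
        inter_p = float(fit.pvalues[3])
    return DiurnalSlopeReport(slopes, inter_est, inter_p)


def trough_depth(
    wavelengths: np.ndarray,
    spectrum: np.ndarray,
    ridge_nm: float = 1825.0,
    valley_nm: float = 1955.0,
) -> float | np.ndarray:
    """Absorption trough depth: rho(ridge) - rho(valley), nearest bands.

    Default is the SWIR water trough with its shoulder at 1825 nm and valley
    at 1955 nm.  ``spectrum`` may be 1-D or a stack (..., bands).
    """
    wl = np.asarray(wavelengths, dtype=float)
    spec = np.asarray(spectrum, dtype=float)
    for nm in (ridge_nm, valley_nm):
        half_step = 0.5 * float(np.median(np.diff(wl))) if wl.size > 1 else 0.0
        if nm < wl[0] - half_step or nm > wl[-1] + half_step:
            raise ValueError(f"{nm} nm outside the wavelength grid")
    i = int(np.argmin(np.abs(wl - ridge_nm)))
    j = int(np.argmin(np.abs(wl - valley_nm)))
    out = spec[..., i] - spec[..., j]
    return float(out) if np.ndim(out) == 0 else out


def correlate_traits_reflectance(
    records: pd.DataFrame,
    trait_columns: list[str],
    bands: list[float],
    method: str = "pearson",
    alpha: float = 0.05,
    treatment_column: str = "treatment",
    subject_column: str = "plant_id",
) -> pd.DataFrame:
    """Per-treatment trait-band correlations with BH-adjusted p values.

    ``method`` is "pearson" or "rmcorr" (repeated-measures correlation using
    the subject column).  Pairs with fewer than 3 complete observations are
    an error for the whole call if no pair survives.
    """
    if method not in ("pearson", "rmcorr"):
        raise ValueError("method must be 'pearson' or 'rmcorr'")
    band_cols = _nearest_band_columns(records, bands)
    rows = []
    for treat, sub in records.groupby(treatment_column):
        for trait in trait_columns:
            for requested, col in band_cols.items():
                ok = sub[[trait, col]].notna().all(axis=1)
                if ok.sum() < 3:
                    continue
                x = sub.loc[ok, col].to_numpy(float)
                y = sub.loc[ok, trait].to_numpy(float)
                if method == "pearson":
                    if np.ptp(x) == 0 or np.ptp(y) == 0:
                        continue
                    r, p = stats.pearsonr(x, y)
                else:
                    ids = sub.loc[ok, subject_column].to_numpy()
                    try:
                        r = rmcorr(ids, x, y)
                    except ValueError:
                        continue
                    # p from the t distribution on the within-subject dof
                    k = np.unique(ids).size
                    dof = max(ok.sum() - k - 1, 1)
                    t = r * np.sqrt(dof / max(1e-300, 1 - r**2))
                    p = 2 * stats.t.sf(abs(t), dof)
                rows.append(
                    {
                        "treatment": treat,
                        "trait": trait,
                        "band": requested,
                        "r": float(r),
                        "raw_p": float(p),
                        "n": int(ok.sum()),
                    }
                )
    if not rows:
        raise ValueError("no trait-band pair had >= 3 complete observations")
    out = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(out["raw_p"], alpha=alpha, method="fdr_bh")
    out["adjusted_p"] = adj
    out["significant"] = out["adjusted_p"] < alpha
    return out
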