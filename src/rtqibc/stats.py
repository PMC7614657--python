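"""Cell gating, normalization, and population statistics.

This module implements the statistical layer of the pipeline: percentile
gates derived from reference populations of known cell-cycle phase, the
Hill dose-response model of EdU incorporation versus non-degradable CDT1
(ND-CDT1) expression, geminin-stratified IC50 analysis, robust
zero-intercept line fits, bootstrap percentile confidence intervals,
time-binned summaries, outlier trimming, subsampling, and t-tests.

The central model is the Hill equation

    EdU(x) = EdU_max - (EdU_max - EdU_min) / (1 + (IC50 / x)^n)

where ``x`` is single-cell ND-CDT1 expression (a.u.), ``EdU_max`` is the
EdU incorporation of cells not expressing ND-CDT1 (held fixed during
fitting, estimated from ND-CDT1-negative cells), ``EdU_min`` is the
incorporation floor at saturating ND-CDT1, ``IC50`` the half-inhibitory
expression level, and ``n`` the Hill coefficient.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "DoseResponseFit",
    "GateDirection",
    "GateThreshold",
    "hill_curve",
    "derive_gate",
    "fit_hill",
    "fold_inhibition",
    "stratified_dose_response",
    "robust_line_through_origin",
    "bootstrap_ci",
    "binned_summary",
    "normalize_values",
    "trim_outliers",
    "subsample_equal",
    "t_test",
]


def hill_curve(x, edu_max: float, edu_min: float, ic50: float, n: float):
    """Evaluate the inhibitory Hill dose-response at expression level(s) ``x``.

    ``x`` must be positive; the curve decreases from ``edu_max`` (x -> 0)
    to ``edu_min`` (x -> inf) with midpoint at ``x = ic50``.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio = (ic50 / x) ** n
    return edu_max - (edu_max - edu_min) / (1.0 + ratio)


@dataclass
class DoseResponseFit:
    """Hill dose-response parameters with fit metadata.

    ``edu_max`` is always fixed from ND-CDT1-negative cells; ``edu_min``
    may be fitted or fixed; ``ic50`` and ``n_hill`` are fitted.
    """

    edu_max: float
    edu_min: float
    ic50: float
    n_hill: float
    fitted_edu_min: bool = True
    fitted_ic50: bool = True
    fitted_n: bool = True
    covariance: np.ndarray | None = None
    n_cells: int = 0
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.n_hill <= 0:
            raise ValueError("n_hill must be positive")
        if self.edu_min > self.edu_max:
            raise ValueError("edu_min must not exceed edu_max")

    def predict(self, x):
        return hill_curve(x, self.edu_max, self.edu_min, self.ic50, self.n_hill)


class GateDirection(enum.Enum):
    ABOVE_IS_POSITIVE = "above_is_positive"
    BELOW_IS_POSITIVE = "below_is_positive"


@dataclass
class GateThreshold:
    """A marker positivity threshold derived from a reference population."""

    value: float
    percentile: float
    reference: str = ""
    direction: GateDirection = GateDirection.ABOVE_IS_POSITIVE

    def is_positive(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.direction is GateDirection.ABOVE_IS_POSITIVE:
            return values > self.value
        return values < self.value


def derive_gate(
    reference_values,
    percentile: float = 99.0,
    direction: GateDirection = GateDirection.ABOVE_IS_POSITIVE,
    reference: str = "",
    min_cells: int = 50,
) -> GateThreshold:
    """Percentile gate from cells of known phase (e.g. live-identified G1).

    The threshold is the stated percentile (99th by default, 95th for
    some markers) of the reference distribution.
    """
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < min_cells:
        raise ValueError(f"need >= {min_cells} reference cells, got {ref.size}")
    value = float(np.percentile(ref, percentile))
    return GateThreshold(value=value, percentile=percentile, reference=reference, direction=direction)


def _hill_residuals(params, x, y, edu_max, fix_edu_min):
    if fix_edu_min is None:
        emin, ic50, n = params
    else:
        emin = fix_edu_min
        ic50, n = params
    if ic50 <= 0 or n <= 0:
        # keep Levenberg-Marquardt inside the valid parameter region
        return np.full(x.size, 1e6)
    return hill_curve(x, edu_max, emin, ic50, n) - y


def fit_hill(
    ndcdt1,
    edu,
    edu_max: float,
    fix_edu_min: float | None = None,
    min_cells: int = 100,
) -> DoseResponseFit:
    """Least-squares Hill fit of single-cell EdU versus ND-CDT1 expression.

    EdU values are assumed background-subtracted (G1 background removed
    for a true zero). ``edu_max`` is fixed by the caller. Fitting uses
    Levenberg-Marquardt with the initialization: EdU_min at the 5th
    percentile of the EdU signal, IC50 at the median ND-CDT1 expression,
    and Hill coefficient 1; on failure a small restart grid around that
    initialization is tried (IC50 x {0.3, 1, 3}, n x {0.5, 1, 2}).

    Raises
    ------
    ValueError
        For too few cells, a dose range narrower than one decade, or
        degenerate data with no detectable inhibition (EdU_min
        unidentifiable).
    RuntimeError
        If no optimizer start converges to a valid parameter set.
    """
    x = np.asarray(ndcdt1, dtype=float)
    y = np.asarray(edu, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & (x > 0)
    x, y = x[keep], y[keep]
    if x.size < min_cells:
        raise ValueError(f"need >= {min_cells} cells with positive ND-CDT1, got {x.size}")
    if np.max(x) / np.min(x) < 10.0:
        raise ValueError("ND-CDT1 values must span at least one decade for a stable fit")
    if float(np.percentile(y, 5)) > 0.9 * edu_max:
        raise ValueError("degenerate dose-response: no inhibition detected (edu_min unidentifiable)")

    emin0 = float(np.percentile(y, 5))
    emin0 = min(max(emin0, 0.0), edu_max)
    ic500 = float(np.median(x))
    n0 = 1.0

    starts = [(ic500, n0)] + [
        (ic500 * a, n0 * b) for a in (0.3, 1.0, 3.0) for b in (0.5, 1.0, 2.0) if not (a == 1.0 and b == 1.0)
    ]
    best = None
    diagnostics = []
    for ic_start, n_start in starts:
        p0 = [emin0, ic_start, n_start] if fix_edu_min is None else [ic_start, n_start]
        try:
            res = optimize.least_squares(
                _hill_residuals,
                p0,
                args=(x, y, edu_max, fix_edu_min),
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=5000,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failures
            diagnostics.append(str(exc))
            continue
        if fix_edu_min is None:
            emin, ic50, n = res.x
        else:
            emin = fix_edu_min
            ic50, n = res.x
        if res.success and ic50 > 0 and n > 0 and emin <= edu_max + 1e-9:
            best = (res, float(emin), float(ic50), float(n))
            break  # the stated initialization converged; restarts unused
        diagnostics.append(f"start {p0}: success={res.success} params={res.x}")
    if best is None:
        raise RuntimeError("Hill fit did not converge to a valid optimum; tried "
                           f"{len(starts)} starts: {diagnostics[:3]}")

    res, emin, ic50, n = best
    dof = max(x.size - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full((res.x.size, res.x.size), np.nan)
    return DoseResponseFit(
        edu_max=float(edu_max),
        edu_min=max(emin, 0.0) if fix_edu_min is None else float(fix_edu_min),
        ic50=ic50,
        n_hill=n,
        fitted_edu_min=fix_edu_min is None,
        covariance=cov,
        n_cells=int(x.size),
        rss=float(2.0 * res.cost),
    )


def fold_inhibition(fit: DoseResponseFit) -> float:
    """Maximum fold-suppression of EdU from the fitted curve: EdU_max / EdU_min."""
    if fit.edu_min <= 0:
        raise ValueError("fold inhibition undefined for edu_min <= 0")
    return fit.edu_max / fit.edu_min


def stratified_dose_response(
    ndcdt1,
    edu,
    strat_values,
    n_bins: int,
    edu_max: float,
    min_cells_per_bin: int = 660,
    fix_edu_min: float | None = None,
):
    """Fit per-stratum Hill curves and regress IC50 on the stratification level.

    Records are split into ``n_bins`` equal-count bins of ``strat_values``
    (e.g. geminin expression), a Hill curve is fitted per bin, and the
    per-bin IC50 is regressed linearly (OLS with intercept) on the bin
    median stratification level.

    Returns
    -------
    (fits, table, trend) where ``fits`` is a list of per-bin
    DoseResponseFit (None for skipped bins), ``table`` is a DataFrame
    with columns strat_level / ic50 / n_cells, and ``trend`` is a dict
    with slope and intercept of the IC50-vs-level line.
    """
    if n_bins < 2:
        raise ValueError("stratified trend needs at least 2 bins")
    x = np.asarray(ndcdt1, float)
    y = np.asarray(edu, float)
    g = np.asarray(strat_values, float)
    edges = np.quantile(g, np.linspace(0, 1, n_bins + 1))
    fits: list[DoseResponseFit | None] = []
    rows = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        sel = (g >= lo) & (g <= hi if i == n_bins - 1 else g < hi)
        if sel.sum() < min_cells_per_bin:
            import warnings

            warnings.warn(f"bin {i} underpopulated ({int(sel.sum())} cells); skipped")
            fits.append(None)
            continue
        fit = fit_hill(x[sel], y[sel], edu_max=edu_max, fix_edu_min=fix_edu_min,
                       min_cells=min(100, min_cells_per_bin))
        fits.append(fit)
        rows.append({"strat_level": float(np.median(g[sel])), "ic50": fit.ic50,
                     "n_cells": int(sel.sum())})
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("fewer than 2 populated bins; IC50 trend undefined")
    slope, intercept = np.polyfit(table["strat_level"], table["ic50"], 1)
    return fits, table, {"slope": float(slope), "intercept": float(intercept)}


def robust_line_through_origin(x, y, tuning: float = 2.0, max_iter: int = 100,
                               tol: float = 1e-8) -> float:
    """Bisquare (Tukey biweight) IRLS slope of a zero-intercept line.

    Weights are w = (1 - (r / (tuning * s))^2)^2 for |r| < tuning*s and 0
    otherwise, with s a MAD-based robust residual scale re-estimated each
    iteration. Iterates until the slope changes by less than ``tol`` or
    ``max_iter`` iterations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == 0):
        raise ValueError("all x are zero; slope undefined")
    slope = float(np.dot(x, y) / np.dot(x, x))
    for _ in range(max_iter):
        r = y - slope * x
        s = np.median(np.abs(r - np.median(r))) / 0.6745
        if s <= 0:
            break  # exact fit
        u = r / (tuning * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        sw = np.dot(w * x, x)
        if sw <= 0:
            raise ValueError("all bisquare weights are zero; fit failed")
        new = float(np.dot(w * x, y) / sw)
        if abs(new - slope) < tol:
            slope = new
            break
        slope = new
    return slope


def bootstrap_ci(values, statistic, n_boot: int = 1000, level: float = 0.95,
                 seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of ``statistic(values)``."""
    values = np.asarray(values)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 1000:
        raise ValueError("use at least 1000 resamples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = np.array([statistic(values[row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    return (float(np.percentile(boot, 100 * alpha)),
            float(np.percentile(boot, 100 * (1 - alpha))))


def binned_summary(
    times,
    values,
    bin_width_min: float,
    statistic: str = "median",
    min_per_bin: int = 36,
    gate: GateThreshold | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Time-binned population summaries with bootstrap CIs.

    Bins ``times`` (minutes since an annotated event) into consecutive
    ``bin_width_min`` bins and computes per-bin ``median``, ``mean``, or
    ``fraction_below_gate`` (requires ``gate``), with a percentile
    bootstrap CI; bins with fewer than ``min_per_bin`` cells are omitted.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    keep = np.isfinite(t) & np.isfinite(v)
    t, v = t[keep], v[keep]
    if t.size == 0:
        return pd.DataFrame(columns=["t_center", "n", "estimate", "ci_lo", "ci_hi"])
    if statistic == "median":
        stat = np.median
    elif statistic == "mean":
        stat = np.mean
    elif statistic == "fraction_below_gate":
        if gate is None:
            raise ValueError("fraction_below_gate requires a gate")
        stat = lambda a: float(np.mean(a < gate.value))  # noqa: E731
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    first = np.floor(t.min() / bin_width_min)
    idx = np.floor(t / bin_width_min).astype(int)
    rows = []
    for b in range(int(first), int(idx.max()) + 1):
        sel = idx == b
        if sel.sum() < min_per_bin:
            continue
        vals = v[sel]
        lo, hi = bootstrap_ci(vals, stat, n_boot=n_boot, level=level, seed=rng)
        rows.append({"t_center": (b + 0.5) * bin_width_min, "n": int(sel.sum()),
                     "estimate": float(stat(vals)), "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def normalize_values(values, g1_baseline: float, reference: float):
    """(values - G1 baseline) / reference-group statistic."""
    if reference <= 0:
        raise ValueError("reference statistic must be positive")
    return (np.asarray(values, float) - g1_baseline) / reference


def trim_outliers(values, upper_frac: float = 0.01, symmetric: bool = False) -> np.ndarray:
    """Drop the top fraction of values (or both tails if symmetric)."""
    if not 0 < upper_frac < 0.5:
        raise ValueError("upper_frac must be in (0, 0.5)")
    v = np.asarray(values, float)
    hi = np.quantile(v, 1.0 - upper_frac)
    keep = v <= hi
    if symmetric:
        lo = np.quantile(v, upper_frac)
        keep &= v >= lo
    return v[keep]


def subsample_equal(groups: dict, seed: int = 0) -> dict:
    """Randomly subsample each group without replacement to the smallest size."""
    rng = np.random.default_rng(seed)
    sizes = {k: len(v) for k, v in groups.items()}
    if any(s == 0 for s in sizes.values()):
        raise ValueError("all groups must be nonempty")
    n = min(sizes.values())
    out = {}
    for k, v in groups.items():
        v = np.asarray(v)
        out[k] = v[rng.choice(v.shape[0], size=n, replace=False)]
    return out


def t_test(a, b=None, mode: str = "two_sample", mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided t-test: two-sample, paired, or one-sample against ``mu0``."""
    a = np.asarray(a, float)
    if mode == "one_sample":
        if a.size < 2:
            raise ValueError("one-sample test needs >= 2 values")
        if np.ptp(a) == 0:
            raise ValueError("zero variance")
        r = sps.ttest_1samp(a, mu0)
    elif mode == "two_sample":
        b = np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise ValueError("two-sample test needs >= 2 values per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError("zero variance")
        r = sps.ttest_ind(a, b)
    elif mode == "paired":
        b = np.asarray(b, float)
        if a.size != b.size or a.size < 2:
            raise ValueError("paired test needs equal-length samples of >= 2")
        if np.ptp(a - b) == 0:
            raise ValueError("zero variance of differences")
        r = sps.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(r.statistic), float(r.pvalue)
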