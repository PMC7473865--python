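"""Fluorescence-polarization competition assays: relative binding and IC50 fits.

Relative binding at each competitor concentration is
``y = (FP_sample - FP_free) / (FP_no_comp - FP_free)``; titration curves are
fit to ``y = 1 / (1 + [pep] / IC50)`` by nonlinear least squares on a
log10(IC50) parameterization (concentrations span several orders of
magnitude). Two-concentration assays invert the binding equation per point
and combine the two estimates by geometric mean. Predicted-vs-measured
correlations are ordinary least squares on log10 IC50 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress


@dataclass
class CompetitionCurve:
    """One peptide's FP competition data (replicates kept per concentration)."""

    peptide: str
    conc: np.ndarray          # competitor concentrations, nM
    fp: np.ndarray            # polarization readings (mP), aligned with conc
    fp_free: float            # free probe
    fp_nocomp: float          # MHC + probe, no competitor

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.fp = np.asarray(self.fp, dtype=float)
        if self.fp_nocomp <= self.fp_free:
            raise ValueError("invalid assay window: FP_no_comp must exceed FP_free")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(self.conc)) < 2:
            raise ValueError("need >= 2 distinct concentrations")


@dataclass
class IC50Fit:
    peptide: str
    ic50: float               # nM
    ci: tuple[float, float]   # 95% CI, nM
    residual_ss: float
    n_points: int
    method: str               # "curve" | "two_point"
    censored: bool = False
    censored_label: str | None = None


def relative_binding(curve: CompetitionCurve) -> np.ndarray:
    """Per-replicate relative binding values y (not pre-averaged)."""
    return (curve.fp - curve.fp_free) / (curve.fp_nocomp - curve.fp_free)


def _model(conc: np.ndarray, log10_ic50: float) -> np.ndarray:
    return 1.0 / (1.0 + conc / 10.0 ** log10_ic50)


def fit_ic50(conc, y, peptide: str = "") -> IC50Fit:
    """Nonlinear least-squares IC50 fit on the log10(IC50) scale.

    The 95% CI comes from the fit's parameter covariance (log scale). Fits
    falling outside [min(conc)/100, 100*max(conc)] are flagged censored and
    labelled relative to the tested range (e.g. "> 20000 nM").
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need >= 2 distinct concentrations")
    # coarse grid start keeps the fit deterministic and robust
    grid = np.linspace(np.log10(conc.min()) - 2, np.log10(conc.max()) + 2, 41)
    sse = [float(((y - _model(conc, g)) ** 2).sum()) for g in grid]
    p0 = grid[int(np.argmin(sse))]
    try:
        popt, pcov = curve_fit(_model, conc, y, p0=[p0], maxfev=10_000)
    except RuntimeError as e:
        raise ValueError(f"unconstrained fit: {e}") from None
    log_ic50 = float(popt[0])
    ic50 = 10.0 ** log_ic50
    sigma = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    ci = (10.0 ** (log_ic50 - 1.96 * sigma), 10.0 ** (log_ic50 + 1.96 * sigma))
    rss = float(((y - _model(conc, log_ic50)) ** 2).sum())
    lo, hi = conc.min() / 100.0, conc.max() * 100.0
    censored = not (lo <= ic50 <= hi)
    label = None
    if censored:
        label = f"> {conc.max():g} nM" if ic50 > hi else f"< {conc.min():g} nM"
    return IC50Fit(peptide=peptide, ic50=ic50, ci=ci, residual_ss=rss,
                   n_points=len(y), method="curve", censored=censored,
                   censored_label=label)


def two_point_ic50(curve: CompetitionCurve) -> IC50Fit:
    """IC50 from a two-concentration assay.

    Each concentration's mean relative binding is inverted through
    ``IC50_i = c_i * y_i / (1 - y_i)``; the estimate is the geometric mean of
    the two per-point values.
    """
    concs = np.unique(curve.conc)
    if len(concs) != 2:
        raise ValueError("two-point estimation requires exactly 2 distinct concentrations")
    y = relative_binding(curve)
    per_point = []
    for c in concs:
        yi = float(np.mean(y[curve.conc == c]))
        if not 0.0 < yi < 1.0:
            raise ValueError(f"out-of-range binding value y={yi:.3f} at {c:g} nM")
        per_point.append(c * yi / (1.0 - yi))
    est = float(np.sqrt(per_point[0] * per_point[1]))
    ci = (float(min(per_point)), float(max(per_point)))
    yhat = _model(curve.conc, np.log10(est))
    rss = float(((y - yhat) ** 2).sum())
    return IC50Fit(peptide=curve.peptide, ic50=est, ci=ci, residual_ss=rss,
                   n_points=len(y), method="two_point")


def fit_curve(curve: CompetitionCurve) -> IC50Fit:
    """Relative binding + full titration fit for one competition curve."""
    y = relative_binding(curve)
    fit = fit_ic50(curve.conc, y, peptide=curve.peptide)
    return fit


@dataclass
class AffinityCorrelation:
    slope: float
    intercept: float
    r_squared: float
    negative: bool            # True when the correlation is negative
    n: int
    n_censored_excluded: int


def correlate_predictions(pred: dict[str, float], measured: dict[str, IC50Fit | float],
                          transform: str = "log10_ic50") -> AffinityCorrelation:
    """OLS of predicted value against (transformed) measured IC50.

    Censored measurements are excluded (and counted). Negative correlations
    are flagged rather than sign-dropped, mirroring starred R^2 reporting.
    """
    if transform not in ("log10_ic50", "linear"):
        raise ValueError("transform must be log10_ic50 or linear")
    xs, ys = [], []
    n_censored = 0
    for pep, m in measured.items():
        if pep not in pred:
            continue
        if isinstance(m, IC50Fit):
            if m.censored:
                n_censored += 1
                continue
            val = m.ic50
        else:
            val = float(m)
        xs.append(np.log10(val) if transform == "log10_ic50" else val)
        ys.append(pred[pep])
    if len(xs) < 3:
        raise ValueError("insufficient data: need >= 3 shared uncensored peptides")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.allclose(ys, ys[0]) or np.allclose(xs, xs[0]):
        return AffinityCorrelation(0.0, float(np.mean(ys)), 0.0, False,
                                   len(xs), n_censored)
    res = linregress(xs, ys)
    return AffinityCorrelation(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2), negative=bool(res.rvalue < 0),
        n=len(xs), n_censored_excluded=n_censored,
    )
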