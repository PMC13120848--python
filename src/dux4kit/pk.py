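"""Tissue PK/PD curve computations.

Half-life from ln-linear regression of tissue concentration on time,
GraphPad-style log(inhibitor)-vs-response EC50 fitting, specific binding
with Hill slope, stem-loop RT-qPCR standard-curve quantification, and the
RISC-loading ratio.

Sign convention for decay: with concentrations falling over time the OLS
slope of ln(concentration) on time is negative; the decay rate is
lambda = -slope and t_half = ln(2)/lambda, reported only when lambda > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

LN2 = float(np.log(2.0))


@dataclass
class HalfLifeFit:
    slope: float        # per day, from OLS of ln(conc) on time
    decay_rate: float   # lambda = -slope, per day
    t_half: float       # ln(2)/lambda (days); NaN when no decay
    decays: bool        # lambda > 0
    r_squared: float


def fit_halflife_lnlinear(
    time, concentration, aggregate: str = "none"
) -> HalfLifeFit:
    """Tissue half-life from a linear regression of ln(concentration) on time.

    Parameters
    ----------
    time, concentration
        Observation arrays (days; any single consistent concentration
        unit).  All concentrations must be > 0.
    aggregate
        "none" (default) regresses on every observation; "mean" first
        averages ln(concentration) per time point.
    """
    t = np.asarray(time, dtype=float)
    c = np.asarray(concentration, dtype=float)
    if t.size != c.size:
        raise ValueError("time and concentration must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 observations")
    if (c <= 0).any():
        raise ValueError("concentrations must be > 0 for ln-linear fitting")
    ln_c = np.log(c)
    if aggregate == "mean":
        df = pd.DataFrame({"t": t, "y": ln_c}).groupby("t")["y"].mean()
        t, ln_c = df.index.to_numpy(), df.to_numpy()
    elif aggregate != "none":
        raise ValueError("aggregate must be 'none' or 'mean'")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct time points")
    fit = stats.linregress(t, ln_c)
    lam = -fit.slope
    decays = lam > 0
    return HalfLifeFit(
        slope=float(fit.slope),
        decay_rate=float(lam),
        t_half=float(LN2 / lam) if decays else float("nan"),
        decays=bool(decays),
        r_squared=float(fit.rvalue**2),
    )


@dataclass
class DoseResponseFit:
    bottom: float       # response plateau at high inhibitor (%)
    top: float          # response plateau at zero inhibitor (%)
    log10_ec50: float
    ec50: float         # same unit as the input concentrations
    emax: float         # maximal reduction, 100 - bottom (control = 100%)
    hill: float         # fixed at 1 for the 3-parameter model
    rss: float
    converged: bool


def _inhibitor_model(x, bottom, top, log10_ec50, hill=1.0):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - log10_ec50)))


def fit_log_inhibitor_response_3p(
    concentration, response, variable_slope: bool = False
) -> DoseResponseFit:
    """Log(inhibitor) vs response fit (three-parameter; Hill slope fixed).

    Fits response = bottom + (top - bottom)/(1 + 10^(x - log10EC50)) with
    x = log10(concentration), by bounded least squares over a deterministic
    grid of starts.  ``variable_slope=True`` frees the Hill slope
    (four-parameter variant).  Responses are percentages of an untreated
    control, so Emax is reported as 100 - bottom.
    """
    conc = np.asarray(concentration, dtype=float)
    resp = np.asarray(response, dtype=float)
    if conc.size != resp.size:
        raise ValueError("concentration and response must have equal length")
    if (conc <= 0).any():
        raise ValueError("concentrations must be > 0")
    if np.unique(conc).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.ptp(resp) == 0:
        raise ValueError("responses show no decline; nothing to fit")
    x = np.log10(conc)
    span = resp.max() - resp.min()

    def residuals(params):
        return _inhibitor_model(x, *params) - resp

    starts = []
    for b0 in (0.0, float(resp.min())):
        for e0 in np.linspace(x.min(), x.max(), 4):
            base = [b0, float(resp.max()), e0]
            starts.append(base + [1.0] if variable_slope else base)
    lo = [resp.min() - span, resp.min(), x.min() - 3.0]
    hi = [resp.max(), resp.max() + span, x.max() + 3.0]
    if variable_slope:
        lo, hi = lo + [0.05], hi + [20.0]

    best = None
    for p0 in starts:
        try:
            sol = optimize.least_squares(residuals, p0, bounds=(lo, hi))
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(
            "dose-response fit failed to converge from any start; "
            f"data span x=[{x.min():.2f}, {x.max():.2f}], "
            f"response=[{resp.min():.2f}, {resp.max():.2f}]"
        )
    bottom, top, log_ec50 = best.x[:3]
    hill = best.x[3] if variable_slope else 1.0
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        log10_ec50=float(log_ec50),
        ec50=float(10.0**log_ec50),
        emax=float(100.0 - bottom),
        hill=float(hill),
        rss=float(2.0 * best.cost),
        converged=True,
    )


def risc_load_ratio(sirna_level, mir16_level):
    """siRNA level relative to miR-16, the RISC-loading readout.

    Accepts scalars or arrays; element-wise ratio.  miR-16 levels must be
    strictly positive.
    """
    s = np.asarray(sirna_level, dtype=float)
    m = np.asarray(mir16_level, dtype=float)
    if (m <= 0).any():
        raise ValueError("miR-16 level must be > 0")
    out = s / m
    return float(out) if out.ndim == 0 else out


@dataclass
class StandardCurveResult:
    slope: float        # signal per log10(concentration)
    intercept: float
    r_squared: float
    concentrations: np.ndarray
    extrapolated: np.ndarray  # True where the sample signal was out of range


def quantify_from_standard_curve(
    standard_concentration, standard_signal, sample_signal
) -> StandardCurveResult:
    """Back-interpolate sample concentrations from a spiked standard curve.

    A line is fit to signal vs log10(concentration) over the standards
    (eight spiked levels in the assay this mirrors); sample signals are
    inverted through the line.  Samples whose signal falls outside the
    standards' signal range are still quantified but flagged extrapolated.
    """
    sc = np.asarray(standard_concentration, dtype=float)
    ss = np.asarray(standard_signal, dtype=float)
    y = np.atleast_1d(np.asarray(sample_signal, dtype=float))
    if sc.size < 3:
        raise ValueError("need >= 3 standards")
    if (sc <= 0).any():
        raise ValueError("standard concentrations must be > 0")
    fit = stats.linregress(np.log10(sc), ss)
    if not np.isfinite(fit.slope) or abs(fit.slope) < 1e-12:
        raise ValueError("degenerate standard curve (zero slope)")
    log_conc = (y - fit.intercept) / fit.slope
    return StandardCurveResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        concentrations=10.0**log_conc,
        extrapolated=(y < ss.min()) | (y > ss.max()),
    )


@dataclass
class HillBindingFit:
    bmax: float
    kd: float
    hill: float
    rss: float
    converged: bool


def fit_specific_binding_hill(concentration, signal) -> HillBindingFit:
    """Specific binding with Hill slope: signal = Bmax*X^h / (Kd^h + X^h)."""
    conc = np.asarray(concentration, dtype=float)
    sig = np.asarray(signal, dtype=float)
    if conc.size != sig.size:
        raise ValueError("concentration and signal must have equal length")
    if (conc < 0).any():
        raise ValueError("concentrations must be >= 0")
    positive = conc > 0
    if np.unique(conc[positive]).size < 5:
        raise ValueError("need >= 5 distinct positive concentrations")

    def model(params):
        bmax, kd, h = params
        return bmax * conc**h / (kd**h + conc**h) - sig

    smax = max(sig.max(), 1e-12)
    kd_grid = np.quantile(conc[positive], [0.25, 0.5, 0.75])
    best = None
    for b0 in (smax, 1.5 * smax):
        for k0 in kd_grid:
            for h0 in (0.5, 1.0, 2.0):
                try:
                    sol = optimize.least_squares(
                        model,
                        [b0, k0, h0],
                        bounds=([1e-12, 1e-12, 0.05], [np.inf, np.inf, 20.0]),
                    )
                except ValueError:
                    continue
                if sol.success and (best is None or sol.cost < best.cost):
                    best = sol
    if best is None:
        raise RuntimeError("Hill binding fit failed to converge from any start")
    bmax, kd, h = best.x
    return HillBindingFit(
        bmax=float(bmax),
        kd=float(kd),
        hill=float(h),
        rss=float(2.0 * best.cost),
        converged=True,
    )
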