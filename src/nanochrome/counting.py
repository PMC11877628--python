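"""Digital counting statistics and assay calibration.

The per-spot chromatic contrasts of a condition form an approximately
Gaussian distribution.  The assay reads out the shift of that distribution
digitally: fit a Normal to the negative control (N.C.), place a cutoff at
its one-sided upper 95% bound (mu + 1.6449 sigma), and compare the rate of
spots exceeding the cutoff between an analyte condition and the N.C.:

    dNP% = 100 * (NP_sample / n_sample - NP_ref / n_ref)

dNP% grows with analyte concentration; regressing it on log10(concentration)
gives the standard curve, from which the limit of detection and of
quantification follow as LOD = DF * 3.3 * sigma_int / S and
LOQ = DF * 10 * sigma_int / S (DF = dilution factor, sigma_int = standard
error of the intercept, S = slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: one-sided 95% standard-normal quantile used for the counting cutoff
Z_95 = 1.6449

__all__ = [
    "GammaFit",
    "CountingResult",
    "CalibrationFit",
    "Z_95",
    "fit_gamma_distribution",
    "counting_cutoff",
    "delta_np_percent",
    "standard_curve",
    "lod_loq",
    "quantify",
]


@dataclass(frozen=True)
class GammaFit:
    """Normal fit of a gamma sample: sample mean and SD (ddof=1)."""

    mu: float
    sigma: float
    n: int

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0


@dataclass(frozen=True)
class CountingResult:
    cutoff: float
    np_ref: int
    np_sample: int
    n_ref: int
    n_sample: int
    delta_np_percent: float


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration of dNP% against (log10-) concentration.

    slope is in %/decade when x_transform is "log10"; sigma_int is the
    standard error of the intercept; df is the sample dilution factor that
    multiplies LOD/LOQ.
    """

    slope: float
    intercept: float
    sigma_int: float
    sigma_slope: float
    r_squared: float
    df: float = 1.0
    x_transform: str = "log10"
    concentrations: tuple = ()
    means: tuple = ()
    sds: tuple = ()

    def predict(self, concentration):
        x = np.log10(concentration) if self.x_transform == "log10" else np.asarray(
            concentration, dtype=float
        )
        return self.intercept + self.slope * x


def fit_gamma_distribution(gammas) -> GammaFit:
    g = np.asarray(gammas, dtype=float)
    g = g[np.isfinite(g)]
    if g.size < 2:
        raise ValueError("need at least 2 finite gamma values to fit")
    return GammaFit(mu=float(g.mean()), sigma=float(g.std(ddof=1)), n=int(g.size))


def counting_cutoff(fit: GammaFit, z: float = Z_95) -> float:
    """Cutoff at the one-sided upper 95% bound of the fitted N.C. Normal,
    mu + z sigma, so 5% of the fitted distribution lies above it."""
    if fit.sigma <= 0:
        raise ValueError("degenerate gamma distribution (sigma = 0); no cutoff")
    return fit.mu + z * fit.sigma


def _tail_count(gammas, cutoff: float) -> tuple[int, int]:
    g = np.asarray(gammas, dtype=float)
    g = g[np.isfinite(g)]
    return int((g > cutoff).sum()), int(g.size)


def delta_np_percent(sample_gammas, reference_gammas, cutoff: float) -> CountingResult:
    """Difference of upper-tail count rates (strict exceedance of the
    cutoff), in percent, between a sample condition and the reference."""
    np_s, n_s = _tail_count(sample_gammas, cutoff)
    np_r, n_r = _tail_count(reference_gammas, cutoff)
    if n_s == 0 or n_r == 0:
        raise ValueError("both groups must contain gamma values")
    return CountingResult(
        cutoff=cutoff,
        np_ref=np_r,
        np_sample=np_s,
        n_ref=n_r,
        n_sample=n_s,
        delta_np_percent=100.0 * (np_s / n_s - np_r / n_r),
    )


def standard_curve(points, df: float = 1.0, x_transform: str = "log10") -> CalibrationFit:
    """Fit the calibration line dNP% = S * x + b by ordinary least squares.

    ``points`` is a sequence of (concentration, replicate_values) pairs;
    replicate means are regressed (their SDs are retained for reporting).
    With the default log10 transform, concentrations must be positive.
    """
    import statsmodels.api as sm

    concs, means, sds = [], [], []
    for conc, reps in points:
        reps = np.atleast_1d(np.asarray(reps, dtype=float))
        concs.append(float(conc))
        means.append(float(reps.mean()))
        sds.append(float(reps.std(ddof=1)) if reps.size > 1 else 0.0)
    concs = np.asarray(concs)
    if np.unique(concs).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if x_transform == "log10":
        if np.any(concs <= 0):
            raise ValueError("log10 transform requires positive concentrations")
        x = np.log10(concs)
    elif x_transform == "linear":
        x = concs
    else:
        raise ValueError(f"unknown x_transform {x_transform!r}")
    model = sm.OLS(np.asarray(means), sm.add_constant(x)).fit()
    return CalibrationFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        sigma_int=float(model.bse[0]),
        sigma_slope=float(model.bse[1]),
        r_squared=float(model.rsquared),
        df=df,
        x_transform=x_transform,
        concentrations=tuple(concs),
        means=tuple(means),
        sds=tuple(sds),
    )


def lod_loq(fit: CalibrationFit) -> dict:
    """Limits of detection and quantification from the calibration fit:
    LOD = DF * 3.3 * sigma_int / S, LOQ = DF * 10 * sigma_int / S.

    The formulas are applied on the fit's own x scale.  When the fit used
    log10(concentration), the back-transformed concentrations 10**value are
    reported alongside (keys lod_concentration / loq_concentration).
    """
    if fit.slope <= 0:
        raise ValueError("invalid calibration: slope must be > 0")
    lod = fit.df * 3.3 * fit.sigma_int / fit.slope
    loq = fit.df * 10.0 * fit.sigma_int / fit.slope
    out = {"lod": lod, "loq": loq, "scale": fit.x_transform}
    if fit.x_transform == "log10":
        out["lod_concentration"] = 10.0**lod
        out["loq_concentration"] = 10.0**loq
    return out


def quantify(delta_np: float, fit: CalibrationFit, expected: float | None = None) -> dict:
    """Invert the calibration: concentration = inverse-fit(dNP%); when an
    expected concentration is supplied, also report the recovery rate
    (measured/expected x 100, acceptable range 80-120%)."""
    if fit.slope == 0:
        raise ValueError("invalid calibration: zero slope")
    x = (delta_np - fit.intercept) / fit.slope
    measured = 10.0**x if fit.x_transform == "log10" else x
    out = {"delta_np_percent": delta_np, "measured_concentration": measured}
    if fit.means:
        lo, hi = min(fit.means), max(fit.means)
        out["extrapolated"] = bool(delta_np < lo or delta_np > hi)
    if expected is not None:
        out["expected_concentration"] = expected
        out["recovery_percent"] = 100.0 * measured / expected
    return out
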