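"""Ordinary least-squares fits of composition on GC content, with CI outliers.

Two uses: the GARP-vs-FYMINK trade-off across taxa (whose pointwise
confidence band flags taxa whose composition departs from the genome-wide
mutational GC bias) and the 20 per-residue frequency-on-GC3 regressions.
Fitting is delegated to statsmodels OLS; this module packages the fit,
the pointwise mean-response band at a configurable level, and the outlier
rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import CompositionProfile, GCProfile
from .seqio import AMINO_ACIDS


class DegenerateFitError(ValueError):
    """Constant x or too few points for a regression."""


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    p_value: float
    n: int
    ci_level: float
    x: np.ndarray
    y: np.ndarray
    residuals: np.ndarray
    ci_lower: np.ndarray  # pointwise mean-response band at the fit's x
    ci_upper: np.ndarray
    labels: tuple[str, ...] = ()

    def predict(self, x: float | np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class OutlierFlag:
    taxon: str
    outside_ci: bool
    residual: float
    standardized_residual: float


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    ci: float = 0.99,
    labels: Sequence[str] | None = None,
) -> RegressionFit:
    """OLS fit of y on x with an F test on (1, n-2) df and a pointwise CI band.

    The band is the confidence interval of the mean response at each observed
    x, at level ``ci``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateFitError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x is constant; slope undefined")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    pred = res.get_prediction(X).conf_int(alpha=1 - ci)
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        n=n,
        ci_level=ci,
        x=x,
        y=y,
        residuals=np.asarray(res.resid),
        ci_lower=pred[:, 0],
        ci_upper=pred[:, 1],
        labels=tuple(labels) if labels is not None else tuple(str(i) for i in range(n)),
    )


def flag_ci_outliers(fit: RegressionFit, leave_one_out: bool = False) -> list[OutlierFlag]:
    """Flag taxa whose y lies outside the pointwise CI band at their x.

    With ``leave_one_out`` each candidate outlier is re-tested against a band
    fitted without it, which avoids the candidate dragging the band toward
    itself.
    """
    sd = float(np.std(fit.residuals, ddof=2)) if fit.n > 2 else 0.0
    flags = []
    for i, taxon in enumerate(fit.labels):
        outside = bool(fit.y[i] < fit.ci_lower[i] or fit.y[i] > fit.ci_upper[i])
        resid = float(fit.residuals[i])
        if outside and leave_one_out and fit.n > 3:
            keep = np.arange(fit.n) != i
            refit = fit_linear(fit.x[keep], fit.y[keep], ci=fit.ci_level)
            band = refit.predict(fit.x[i])
            # re-evaluate against the leave-one-out band at this x
            pred_sd = _mean_response_sd(refit, fit.x[i])
            from scipy.stats import t as t_dist

            crit = t_dist.ppf(1 - (1 - fit.ci_level) / 2, refit.n - 2)
            outside = bool(abs(fit.y[i] - band) > crit * pred_sd)
            resid = float(fit.y[i] - band)
        flags.append(
            OutlierFlag(
                taxon=taxon,
                outside_ci=outside,
                residual=resid,
                standardized_residual=resid / sd if sd > 0 else 0.0,
            )
        )
    return flags


def _mean_response_sd(fit: RegressionFit, x0: float) -> float:
    n = fit.n
    mse = float(np.sum(fit.residuals**2)) / (n - 2)
    xbar = float(np.mean(fit.x))
    sxx = float(np.sum((fit.x - xbar) ** 2))
    return float(np.sqrt(mse * (1 / n + (x0 - xbar) ** 2 / sxx)))


def residue_vs_gc3_profile(
    profiles: Mapping[str, CompositionProfile],
    gc: Mapping[str, GCProfile],
    ci: float = 0.99,
) -> tuple[dict[str, RegressionFit], pd.DataFrame]:
    """Twenty independent OLS fits of residue frequency on GC3 across taxa.

    Returns one fit per residue and a taxa x residues table of residuals,
    whose largest entries point at taxa using a residue in excess of their
    genome-wide GC bias expectation.
    """
    taxa = list(profiles)
    if len(taxa) < 3:
        raise DegenerateFitError("need at least 3 taxa")
    gc3 = np.array([gc[t].gc3 for t in taxa])
    fits: dict[str, RegressionFit] = {}
    resid = pd.DataFrame(index=taxa, columns=list(AMINO_ACIDS), dtype=float)
    for aa in AMINO_ACIDS:
        freqs = np.array([profiles[t].freq(aa) for t in taxa])
        fit = fit_linear(gc3, freqs, ci=ci, labels=taxa)
        fits[aa] = fit
        resid[aa] = fit.residuals
    return fits, resid


def fit_summary_table(fits: Mapping[str, RegressionFit]) -> pd.DataFrame:
    """One row per fit: slope, intercept, r2, F, p, n."""
    rows = {
        name: {
            "slope": f.slope, "intercept": f.intercept, "r2": f.r2,
            "F": f.f_stat, "p": f.p_value, "n": f.n,
        }
        for name, f in fits.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")
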