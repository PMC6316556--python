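"""Profile-likelihood confidence intervals for gene-specific parameters.

For each gene the log-likelihood is profiled over the nuisance parameter
(``mu`` when the interval is for ``gamma`` and vice versa) while the
normalization factors and the shared dispersion stay fixed at their fitted
values — the uncertainty of these shared quantities is deliberately
ignored.  Interval bounds are the parameter values where the deviance
``2 * (l_max - profile(t))`` reaches the chi-square(1 df) quantile of the
requested level, located by bracketing outward from the MLE and root
finding; a side whose profile never crosses the cutoff before the parameter
box bound is reported at the bound and flagged one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

from .fitting import _FRACTION_CODE, FitResult, _scale_vector
from .io import SampleDesign
from .model import (
    GAMMA_MAX,
    GAMMA_MIN,
    MU_MAX,
    MU_MIN,
    Dispersion,
    NormalizationSet,
    _nb_logpmf,
    inverse_logit,
)

__all__ = ["ConfidenceInterval", "profile_loglik", "ci_gene", "ci_all"]


@dataclass(frozen=True)
class ConfidenceInterval:
    gene: str
    parameter: str
    level: float
    estimate: float
    lower: float
    upper: float
    lower_at_bound: bool
    upper_at_bound: bool
    alpha_lower: float | None = None
    alpha_upper: float | None = None

    @property
    def flags(self) -> str:
        parts = []
        if self.lower_at_bound:
            parts.append("lower_at_bound")
        if self.upper_at_bound:
            parts.append("upper_at_bound")
        return ";".join(parts)


def _gene_arrays(counts_g: pd.Series, norm: NormalizationSet, design: SampleDesign):
    samples = list(counts_g.index)
    wkind = np.array([_FRACTION_CODE[design.fraction_of(s)] for s in samples])
    depth = np.array([norm.depth[s] for s in samples])
    base = depth * _scale_vector(wkind, norm.fraction_scale)
    return counts_g.to_numpy(dtype=float), base, wkind


def _profile_over_mu(k, base, wkind, theta, gamma):
    """Max over mu of the gene log-likelihood at fixed gamma."""
    a = inverse_logit(gamma)
    w = np.where(wkind == 0, 1.0, np.where(wkind == 1, a, 1.0 - a))
    c = base * w

    def nll(mu):
        return -float(_nb_logpmf(k, c * np.exp(mu), theta).sum())

    res = minimize_scalar(nll, bounds=(MU_MIN, MU_MAX), method="bounded", options={"xatol": 1e-9})
    return -float(res.fun)


def _profile_over_gamma(k, base, wkind, theta, mu):
    """Max over gamma of the gene log-likelihood at fixed mu."""
    emu = np.exp(mu)

    def nll(g):
        a = inverse_logit(g)
        w = np.where(wkind == 0, 1.0, np.where(wkind == 1, a, 1.0 - a))
        return -float(_nb_logpmf(k, base * emu * w, theta).sum())

    res = minimize_scalar(
        nll, bounds=(GAMMA_MIN, GAMMA_MAX), method="bounded", options={"xatol": 1e-9}
    )
    return -float(res.fun)


def profile_loglik(
    counts_g: pd.Series,
    fixed_gamma: float,
    norm: NormalizationSet,
    disp: Dispersion,
    design: SampleDesign,
) -> float:
    """Gene log-likelihood maximized over mu at fixed gamma (factors, theta fixed)."""
    k, base, wkind = _gene_arrays(counts_g, norm, design)
    return _profile_over_mu(k, base, wkind, disp.size, fixed_gamma)


def ci_gene(
    gene: str,
    fit: FitResult,
    level: float = 0.95,
    parameter: str = "gamma",
) -> ConfidenceInterval:
    """Profile-likelihood interval for one gene's ``gamma`` (or ``mu``).

    Bounds satisfy ``2 * (l_max - profile) == chi2(1).ppf(level)``; the
    alpha-scale interval is the monotone logistic transform of the gamma
    bounds.  Intervals for non-converged genes are computed anyway but the
    caller can consult the fit's flags.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if parameter not in ("gamma", "mu"):
        raise ValueError("parameter must be 'gamma' or 'mu'")
    if gene not in fit.counts.index:
        raise KeyError(f"gene {gene!r} not present in the fitted count table")
    k, base, wkind = _gene_arrays(fit.counts.loc[gene], fit.norm, fit.design)
    theta = fit.dispersion.size
    est = fit.estimates.loc[gene]
    if parameter == "gamma":
        center = float(est["gamma_hat"])
        lo_bound, hi_bound = GAMMA_MIN, GAMMA_MAX
        profile = lambda t: _profile_over_mu(k, base, wkind, theta, t)
    else:
        center = float(est["mu_hat"])
        lo_bound, hi_bound = MU_MIN, MU_MAX
        profile = lambda t: _profile_over_gamma(k, base, wkind, theta, t)

    cutoff = 0.5 * chi2.ppf(level, df=1)
    l_max = max(profile(center), float(est["loglik"]))
    target = l_max - cutoff

    def g(t):
        return profile(t) - target

    def find_bound(direction: int):
        step = 0.25
        t_prev, t = center, center
        for _ in range(64):
            t = t + direction * step
            if direction < 0 and t <= lo_bound:
                t = lo_bound
            if direction > 0 and t >= hi_bound:
                t = hi_bound
            if g(t) < 0:
                root = brentq(g, min(t_prev, t), max(t_prev, t), xtol=1e-10, rtol=1e-14)
                return float(root), False
            if t in (lo_bound, hi_bound):
                return float(t), True
            t_prev = t
            step *= 2.0
        return float(t), True

    lower, lower_at_bound = find_bound(-1)
    upper, upper_at_bound = find_bound(+1)
    a_lo = a_hi = None
    if parameter == "gamma":
        a_lo, a_hi = inverse_logit(lower), inverse_logit(upper)
    return ConfidenceInterval(
        gene=gene,
        parameter=parameter,
        level=level,
        estimate=center,
        lower=lower,
        upper=upper,
        lower_at_bound=lower_at_bound,
        upper_at_bound=upper_at_bound,
        alpha_lower=a_lo,
        alpha_upper=a_hi,
    )


def ci_all(fit: FitResult, level: float = 0.95, parameter: str = "gamma") -> pd.DataFrame:
    """Profile-likelihood intervals for every fitted gene, as a DataFrame."""
    rows = []
    for gene in fit.estimates.index:
        ci = ci_gene(gene, fit, level=level, parameter=parameter)
        rows.append(
            {
                "gene_id": gene,
                "parameter": ci.parameter,
                "level": ci.level,
                "estimate": ci.estimate,
                "lower": ci.lower,
                "upper": ci.upper,
                "alpha_lower": ci.alpha_lower,
                "alpha_upper": ci.alpha_upper,
                "flags": ci.flags,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
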