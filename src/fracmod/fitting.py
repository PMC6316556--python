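"""Maximum-likelihood fitting of the fraction count model.

The joint likelihood over genes and samples is maximized by block
coordinate ascent, alternating three steps until the total log-likelihood
stabilizes:

1. gene-specific parameters ``(mu, gamma)``, one bounded 2-D quasi-Newton
   problem per gene with analytic gradients;
2. the shared fraction normalization factors (eluate and supernatant scale,
   input pinned to 1) — skipped when factors come from spike-ins;
3. the shared negative-binomial size parameter, by bounded search on
   ``log(theta)``.

Per-sample sequencing-depth factors are computed once up front by the
median-of-ratios method within each fraction and held fixed, so the fitted
fraction factors carry the entire between-fraction scale.  Because every
block starts from the previous optimum and can only improve it, the total
log-likelihood trace is non-decreasing across outer iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .io import SampleDesign
from .model import (
    ELUATE,
    GAMMA_MAX,
    GAMMA_MIN,
    INPUT,
    MU_MAX,
    MU_MIN,
    SUPERNATANT,
    Dispersion,
    NormalizationSet,
    _nb_logpmf,
    inverse_logit,
    logit,
)

__all__ = [
    "FitOptions",
    "GeneEstimate",
    "FitResult",
    "estimate_depth_factors",
    "fit_gene",
    "fit_fraction_factors",
    "fit_dispersion",
    "fit",
    "fit_conditions",
]

logger = logging.getLogger(__name__)

_FRACTION_CODE = {INPUT: 0, ELUATE: 1, SUPERNATANT: 2}
_THETA_LOG_BOUNDS = (np.log(1e-3), np.log(1e12))
_BOUND_EPS = 1e-6


@dataclass
class FitOptions:
    """Controls for the outer block-ascent loop.

    ``fixed_norm`` / ``fixed_dispersion`` hold the corresponding blocks at
    the given values instead of fitting them (used e.g. when factors are
    known from an external calibration, or for profile-likelihood work where
    nuisance uncertainty is deliberately ignored).
    """

    max_outer_iterations: int = 50
    rel_tol: float = 1e-8
    seed: int = 0
    mode: str = "no_spikeins"
    #: gene-block / factor-block relaxation sweeps per outer iteration; the
    #: likelihood surface has a shallow ridge between per-gene parameters and
    #: the shared fraction factors, and a few extra sweeps per iteration
    #: traverse it far faster than single alternation.
    inner_cycles: int = 4
    theta0: float = 100.0
    spike_min_count: float = 100.0
    fixed_norm: NormalizationSet | None = None
    fixed_dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.max_outer_iterations < 1:
            raise ValueError("max_outer_iterations must be >= 1")
        if self.mode not in ("no_spikeins", "spikeins"):
            raise ValueError(f"mode must be 'no_spikeins' or 'spikeins', got {self.mode!r}")


@dataclass(frozen=True)
class GeneEstimate:
    gene: str
    mu: float
    gamma: float
    loglik: float
    converged: bool
    at_bound: bool

    @property
    def alpha(self) -> float:
        return inverse_logit(self.gamma)


@dataclass
class FitResult:
    """Fitted model: per-gene estimates, normalization, dispersion, trace."""

    estimates: pd.DataFrame
    norm: NormalizationSet
    dispersion: Dispersion
    loglik_trace: list
    converged: bool
    n_iter: int
    counts: pd.DataFrame
    design: SampleDesign
    options: FitOptions | None = None


# ---------------------------------------------------------------------------
# depth normalization


def estimate_depth_factors(counts: pd.DataFrame, design: SampleDesign) -> pd.Series:
    """Median-of-ratios depth factors, computed within each fraction.

    For the samples of one fraction the reference is the gene-wise geometric
    mean over those samples (genes with any zero count excluded); each
    sample's factor is the median ratio to the reference, rescaled to
    geometric mean 1 within the fraction.  Depth factors of different
    fractions are therefore not comparable — the between-fraction scale is
    carried by the fraction factors.
    """
    factors = {}
    for fraction in sorted(design.fractions_present):
        samples = [s for s in design.samples(fraction=fraction) if s in counts.columns]
        if not samples:
            continue
        sub = counts[samples].to_numpy(dtype=float)
        if not (sub > 0).any():
            raise ValueError(f"all counts are zero in fraction {fraction!r}")
        pos = (sub > 0).all(axis=1)
        if not pos.any():
            raise ValueError(
                f"no gene has positive counts in every {fraction!r} sample; "
                "cannot form a median-of-ratios reference"
            )
        logsub = np.log(sub[pos])
        ref = logsub.mean(axis=1)  # log geometric mean per gene
        logf = np.median(logsub - ref[:, None], axis=0)
        logf -= logf.mean()  # geometric mean 1 within the fraction
        for s, lf in zip(samples, logf):
            factors[s] = float(np.exp(lf))
    return pd.Series(factors, name="depth")


# ---------------------------------------------------------------------------
# array plumbing


def _design_arrays(counts: pd.DataFrame, design: SampleDesign):
    """Sample-aligned (fraction-code, depth-order) arrays for vectorized work."""
    samples = [s for s in counts.columns]
    missing = [s for s in samples if s not in design.table.index]
    if missing:
        raise ValueError(f"count-table samples missing from design: {missing}")
    wkind = np.array([_FRACTION_CODE[design.fraction_of(s)] for s in samples])
    return samples, wkind


def _scale_vector(wkind: np.ndarray, fraction_scale: dict) -> np.ndarray:
    lookup = np.array(
        [
            fraction_scale.get(INPUT, 1.0),
            fraction_scale.get(ELUATE, 1.0),
            fraction_scale.get(SUPERNATANT, 1.0),
        ]
    )
    return lookup[wkind]


def _weights(gamma: np.ndarray, wkind: np.ndarray) -> np.ndarray:
    """Fraction weight matrix: 1 for input, alpha for eluate, 1-alpha for supernatant."""
    a = np.atleast_1d(inverse_logit(gamma))
    W = np.ones((a.size, wkind.size))
    W[:, wkind == 1] = a[:, None]
    W[:, wkind == 2] = (1.0 - a)[:, None]
    return W


def _total_loglik(K, mu, gamma, base, wkind, theta) -> float:
    M = np.exp(np.atleast_1d(mu))[:, None] * _weights(gamma, wkind) * base[None, :]
    return float(_nb_logpmf(K, M, theta).sum())


# ---------------------------------------------------------------------------
# per-gene block


def _fit_gene_core(k, base, wkind, theta, mu0, gamma0):
    """Bounded L-BFGS-B on (mu, gamma) with analytic gradient.

    Returns (mu, gamma, loglik, success); guaranteed no worse than the start.
    """
    k = np.asarray(k, dtype=float)

    def nll_grad(x):
        mu, g = x
        a = inverse_logit(g)
        w = np.where(wkind == 0, 1.0, np.where(wkind == 1, a, 1.0 - a))
        m = base * np.exp(mu) * w
        ll = _nb_logpmf(k, m, theta).sum()
        r = np.where(m > 0, k / np.where(m > 0, m, 1.0), 0.0) - (theta + k) / (theta + m)
        dmu = np.sum(r * m)
        dw = np.where(wkind == 0, 0.0, np.where(wkind == 1, 1.0 - a, -a))
        dg = np.sum(r * m * dw)
        return -ll, -np.array([dmu, dg])

    x0 = np.array(
        [np.clip(mu0, MU_MIN, MU_MAX), np.clip(gamma0, GAMMA_MIN, GAMMA_MAX)]
    )
    f0 = nll_grad(x0)[0]
    res = minimize(
        nll_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(MU_MIN, MU_MAX), (GAMMA_MIN, GAMMA_MAX)],
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 300},
    )
    if res.fun <= f0:
        mu, g, ll, ok = float(res.x[0]), float(res.x[1]), -float(res.fun), bool(res.success)
    else:  # optimizer failure guard: never move downhill
        mu, g, ll, ok = float(x0[0]), float(x0[1]), -float(f0), False
    return mu, g, ll, ok


def fit_gene(
    counts_g,
    norm: NormalizationSet,
    disp: Dispersion,
    design: SampleDesign,
    init,
) -> GeneEstimate:
    """MLE of one gene's (mu, gamma) with normalization and dispersion fixed.

    ``counts_g`` is a pandas Series indexed by sample id (or an array aligned
    with the design's samples); ``init`` is a GeneParams starting point.
    A gene with all counts zero is returned flagged, at the parameter box
    bound for ``mu`` and with an uninformative ``gamma`` of 0.
    """
    if isinstance(counts_g, pd.Series):
        samples = list(counts_g.index)
        k = counts_g.to_numpy(dtype=float)
        name = counts_g.name or "gene"
    else:
        samples = design.sample_ids
        k = np.asarray(counts_g, dtype=float)
        name = "gene"
    wkind = np.array([_FRACTION_CODE[design.fraction_of(s)] for s in samples])
    depth = np.array([norm.depth[s] for s in samples])
    base = depth * _scale_vector(wkind, norm.fraction_scale)
    if not k.any():
        return GeneEstimate(name, MU_MIN, 0.0, float(_nb_logpmf(k, base * np.exp(MU_MIN), disp.size).sum()), False, True)
    mu, g, ll, ok = _fit_gene_core(k, base, wkind, disp.size, init.mu, init.gamma)
    at_bound = (
        min(mu - MU_MIN, MU_MAX - mu) < _BOUND_EPS
        or min(g - GAMMA_MIN, GAMMA_MAX - g) < _BOUND_EPS
    )
    return GeneEstimate(name, mu, g, ll, ok, at_bound)


# ---------------------------------------------------------------------------
# shared blocks


def fit_fraction_factors(
    counts: pd.DataFrame,
    estimates: pd.DataFrame,
    disp: Dispersion,
    design: SampleDesign,
    depth: pd.Series,
    start: NormalizationSet | None = None,
) -> NormalizationSet:
    """MLE of the eluate/supernatant scale factors with gene params and theta fixed.

    Input is the reference fraction (scale pinned to 1); identifiability
    comes from the factors being shared across all genes, so at least two
    genes are required.
    """
    if INPUT not in design.fractions_present:
        raise ValueError("input fraction required to fit fraction factors without spike-ins")
    if len(counts) < 2:
        raise ValueError("fraction factors are not identifiable from a single gene")
    samples, wkind = _design_arrays(counts, design)
    K = counts.to_numpy(dtype=float)
    depth_vec = depth.reindex(samples).to_numpy(dtype=float)
    mu = estimates["mu_hat"].to_numpy(dtype=float)
    gamma = estimates["gamma_hat"].to_numpy(dtype=float)
    W = _weights(gamma, wkind)
    A = np.exp(mu)[:, None] * W * depth_vec[None, :]  # mean = A * scale
    theta = disp.size
    el, su = wkind == 1, wkind == 2

    def nll_grad(logx):
        scale = np.ones_like(depth_vec)
        scale[el] = np.exp(logx[0])
        scale[su] = np.exp(logx[1])
        M = A * scale[None, :]
        ll = _nb_logpmf(K, M, theta).sum()
        R = np.where(M > 0, K / np.where(M > 0, M, 1.0), 0.0) - (theta + K) / (theta + M)
        RM = R * M
        return -ll, -np.array([RM[:, el].sum(), RM[:, su].sum()])

    x0 = np.zeros(2)
    if start is not None:
        x0 = np.log(
            [start.fraction_scale.get(ELUATE, 1.0), start.fraction_scale.get(SUPERNATANT, 1.0)]
        )
    res = minimize(
        nll_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-30, 30), (-30, 30)],
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 300},
    )
    best = res.x if res.fun <= nll_grad(x0)[0] else x0
    return NormalizationSet(
        depth=dict(zip(samples, depth_vec)),
        fraction_scale={INPUT: 1.0, ELUATE: float(np.exp(best[0])), SUPERNATANT: float(np.exp(best[1]))},
    )


def fit_dispersion(
    counts: pd.DataFrame,
    estimates: pd.DataFrame,
    norm: NormalizationSet,
    design: SampleDesign,
) -> Dispersion:
    """MLE of the shared NB size parameter by bounded search on log(theta)."""
    samples, wkind = _design_arrays(counts, design)
    K = counts.to_numpy(dtype=float)
    depth_vec = np.array([norm.depth[s] for s in samples])
    base = depth_vec * _scale_vector(wkind, norm.fraction_scale)
    mu = estimates["mu_hat"].to_numpy(dtype=float)
    gamma = estimates["gamma_hat"].to_numpy(dtype=float)
    M = np.exp(mu)[:, None] * _weights(gamma, wkind) * base[None, :]

    def nll(logtheta):
        return -float(_nb_logpmf(K, M, np.exp(logtheta)).sum())

    res = minimize_scalar(
        nll, bounds=_THETA_LOG_BOUNDS, method="bounded", options={"xatol": 1e-8}
    )
    lt = float(res.x)
    at_bound = min(lt - _THETA_LOG_BOUNDS[0], _THETA_LOG_BOUNDS[1] - lt) < 1e-3
    return Dispersion(float(np.exp(lt)), at_bound=at_bound)


# ---------------------------------------------------------------------------
# full fit


def _initial_params(K, base, wkind):
    """Moment-based starting values: mu0 from depth-normalized reference counts,
    gamma0 from the eluate share of eluate + supernatant."""
    norm_counts = K / base[None, :]
    has_input = (wkind == 0).any()
    if has_input:
        ref_mean = norm_counts[:, wkind == 0].mean(axis=1)
    else:
        ref_mean = norm_counts[:, wkind == 1].mean(axis=1) + norm_counts[:, wkind == 2].mean(axis=1)
    mu0 = np.log(np.clip(ref_mean, np.exp(MU_MIN), np.exp(MU_MAX)))
    e = norm_counts[:, wkind == 1].mean(axis=1)
    s = norm_counts[:, wkind == 2].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(e + s > 0, e / np.where(e + s > 0, e + s, 1.0), 0.5)
    share = np.clip(share, 1e-6, 1.0 - 1e-6)
    gamma0 = np.clip(np.log(share / (1.0 - share)), GAMMA_MIN, GAMMA_MAX)
    return mu0, gamma0


def fit(
    counts: pd.DataFrame,
    design: SampleDesign,
    options: FitOptions | None = None,
    spikeins: list | None = None,
) -> FitResult:
    """Fit the full model to one condition's count table.

    In ``no_spikeins`` mode the input fraction is required and the two
    fraction factors are fitted; in ``spikeins`` mode the factors are
    derived from the spike-in rows (supernatant as reference) and held
    fixed, and the spike-in rows are excluded from the gene estimates.
    """
    options = options or FitOptions()
    if len(design.conditions) > 1:
        raise ValueError(
            "fit() handles one condition; use fit_conditions() for multi-condition designs"
        )
    design = SampleDesign(design.table.loc[[s for s in counts.columns]])
    spike_ids = [s for s in (spikeins or []) if s in counts.index]
    if options.mode == "spikeins":
        if len(spike_ids) < 2:
            raise ValueError(
                "spikeins mode requires >= 2 spike-in rows present in the count table"
            )
        missing = set(spikeins or []) - set(spike_ids)
        if missing:
            raise ValueError(f"spike-in ids absent from count table: {sorted(missing)}")
        # the input fraction plays no role when spike-ins anchor the
        # eluate/supernatant scale: drop its samples from the likelihood
        keep = [s for s in counts.columns if design.fraction_of(s) != INPUT]
        counts = counts[keep]
        design = SampleDesign(design.table.loc[keep])
    genes = counts.loc[~counts.index.isin(spike_ids)]
    if options.mode == "no_spikeins" and INPUT not in design.fractions_present:
        raise ValueError(
            "no input fraction in design: either provide input samples "
            "(no_spikeins mode) or supply spike-ins (spikeins mode)"
        )

    # depth factors: fixed once, from gene rows only
    if options.fixed_norm is not None:
        depth = pd.Series(options.fixed_norm.depth)
    else:
        depth = estimate_depth_factors(genes, design)

    samples, wkind = _design_arrays(genes, design)
    depth_vec = depth.reindex(samples).to_numpy(dtype=float)
    K = genes.to_numpy(dtype=float)

    # fraction factors: spike-derived (fixed) or fitted
    factors_fixed = False
    if options.fixed_norm is not None:
        norm = NormalizationSet(
            depth=dict(zip(samples, depth_vec)),
            fraction_scale=dict(options.fixed_norm.fraction_scale),
        )
        factors_fixed = True
    elif options.mode == "spikeins":
        from .normalization import SpikeInSet, spikein_fraction_factor

        norm = spikein_fraction_factor(
            counts, design, SpikeInSet(ids=spike_ids, min_count=options.spike_min_count),
            depth=depth,
        )
        norm = NormalizationSet(
            depth=dict(zip(samples, depth_vec)), fraction_scale=dict(norm.fraction_scale)
        )
        factors_fixed = True
    else:
        norm = NormalizationSet(
            depth=dict(zip(samples, depth_vec)),
            fraction_scale={INPUT: 1.0, ELUATE: 1.0, SUPERNATANT: 1.0},
        )

    theta = options.fixed_dispersion if options.fixed_dispersion is not None else options.theta0
    disp = Dispersion(theta)

    base = depth_vec * _scale_vector(wkind, norm.fraction_scale)
    mu, gamma = _initial_params(K, base, wkind)
    ll_gene = np.full(len(genes), np.nan)
    ok = np.ones(len(genes), dtype=bool)

    trace: list = []
    converged = False
    n_iter = 0
    prev_ll = -np.inf
    for it in range(options.max_outer_iterations):
        n_iter = it + 1
        sweeps = 1 if factors_fixed else max(1, options.inner_cycles)
        for _ in range(sweeps):
            base = depth_vec * _scale_vector(wkind, norm.fraction_scale)
            # block 1: gene parameters
            for g in range(len(genes)):
                if not K[g].any():
                    mu[g], gamma[g], ok[g] = MU_MIN, 0.0, False
                    ll_gene[g] = float(_nb_logpmf(K[g], base * np.exp(MU_MIN), disp.size).sum())
                    continue
                mu[g], gamma[g], ll_gene[g], ok[g] = _fit_gene_core(
                    K[g], base, wkind, disp.size, mu[g], gamma[g]
                )
            est = pd.DataFrame(
                {"mu_hat": mu, "gamma_hat": gamma}, index=genes.index
            )
            # block 2: fraction factors
            if not factors_fixed:
                norm = fit_fraction_factors(genes, est, disp, design, depth, start=norm)
        base = depth_vec * _scale_vector(wkind, norm.fraction_scale)
        # block 3: dispersion
        if options.fixed_dispersion is None:
            disp = fit_dispersion(genes, est, norm, design)
        total = _total_loglik(K, mu, gamma, base, wkind, disp.size)
        trace.append(total)
        if np.isfinite(prev_ll) and abs(total - prev_ll) <= options.rel_tol * (abs(prev_ll) + 1.0):
            converged = True
            break
        prev_ll = total
    if not converged:
        logger.warning(
            "fit did not reach rel_tol=%g within %d outer iterations",
            options.rel_tol,
            options.max_outer_iterations,
        )

    alpha = inverse_logit(gamma)
    at_bound = (
        (np.minimum(mu - MU_MIN, MU_MAX - mu) < _BOUND_EPS)
        | (np.minimum(gamma - GAMMA_MIN, GAMMA_MAX - gamma) < _BOUND_EPS)
    )
    estimates = pd.DataFrame(
        {
            "mu_hat": mu,
            "gamma_hat": gamma,
            "alpha_hat": np.atleast_1d(alpha),
            "loglik": ll_gene,
            "converged": ok,
            "at_bound": at_bound,
        },
        index=genes.index,
    )
    return FitResult(
        estimates=estimates,
        norm=norm,
        dispersion=disp,
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
        counts=genes,
        design=design,
        options=options,
    )


def fit_conditions(
    counts: pd.DataFrame,
    design: SampleDesign,
    options: FitOptions | None = None,
    spikeins: list | None = None,
) -> dict:
    """Fit each condition independently; returns {condition: FitResult}."""
    out = {}
    for cond in design.conditions:
        sub = design.subset(cond)
        cols = [s for s in counts.columns if s in sub.table.index]
        out[cond] = fit(counts[cols], sub, options=options, spikeins=spikeins)
    return out
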