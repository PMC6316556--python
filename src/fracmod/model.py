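"""Generative model for fraction-separated RNA-seq read counts.

An antibody-based separation experiment splits each RNA sample into three
sequenced fractions: the original pool (*input*), the antibody-bound,
modified molecules (*eluate*) and the unbound, unmodified molecules
(*supernatant*).  For a gene with expected input abundance ``exp(mu)`` and
modification proportion ``alpha = 1 / (1 + exp(-gamma))`` the expected
relative abundances are

    input       = exp(mu)
    eluate      = exp(mu) * alpha
    supernatant = exp(mu) * (1 - alpha)

so eluate and supernatant sum to the input by construction.  Observed read
counts are modelled as negative binomial around these means after scaling
by a per-sample sequencing-depth factor and a per-fraction normalization
factor.  ``gamma`` is the natural-log odds of modification; fitting happens
on this unbounded logit scale and ``alpha`` is derived for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "MU_MIN",
    "MU_MAX",
    "GAMMA_MIN",
    "GAMMA_MAX",
    "INPUT",
    "ELUATE",
    "SUPERNATANT",
    "FRACTIONS",
    "GeneParams",
    "Dispersion",
    "NormalizationSet",
    "logit",
    "inverse_logit",
    "fraction_mean",
    "predicted_mean",
    "nb_loglik",
]

#: Box bounds for the fitted parameters.  ``mu`` is the log expected input
#: count; ``gamma`` is clipped so that alpha stays strictly inside (0, 1)
#: (at +/-20 alpha is within ~2e-9 of the boundary), which keeps the MLE
#: finite for genes with zero counts in one fraction.
MU_MIN: float = float(np.log(0.1))
MU_MAX: float = float(np.log(1e9))
GAMMA_MIN: float = -20.0
GAMMA_MAX: float = 20.0

INPUT = "input"
ELUATE = "eluate"
SUPERNATANT = "supernatant"
FRACTIONS = (INPUT, ELUATE, SUPERNATANT)

# Above this size parameter the naive Gamma-function form of the NB log-pmf
# loses absolute precision (gammaln(theta) ~ 1e13 at theta = 1e12, so double
# rounding alone costs ~1e-3); switch to a stable Stirling-difference form.
_LARGE_THETA = 1e6


def logit(alpha):
    """Natural-log odds ``log(alpha / (1 - alpha))`` of a proportion.

    Raises ``ValueError`` outside the open interval (0, 1).
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0.0) or np.any(a >= 1.0):
        raise ValueError("logit is defined on the open interval (0, 1); got %r" % (alpha,))
    out = np.log(a) - np.log1p(-a)
    return float(out) if np.isscalar(alpha) or out.ndim == 0 else out


def inverse_logit(gamma):
    """Logistic map ``1 / (1 + exp(-gamma))``, overflow-safe for any float."""
    g = np.asarray(gamma, dtype=float)
    out = np.where(g >= 0, 1.0 / (1.0 + np.exp(-np.clip(g, 0, None))),
                   np.exp(np.clip(g, None, 0)) / (1.0 + np.exp(np.clip(g, None, 0))))
    return float(out) if np.isscalar(gamma) or out.ndim == 0 else out


@dataclass(frozen=True)
class GeneParams:
    """Gene-specific parameters: log expression ``mu`` and log-odds ``gamma``."""

    mu: float
    gamma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or not (MU_MIN - 1e-9 <= self.mu <= MU_MAX + 1e-9):
            raise ValueError(f"mu={self.mu} outside fitting box [{MU_MIN:.4g}, {MU_MAX:.4g}]")
        if not np.isfinite(self.gamma) or not (GAMMA_MIN - 1e-9 <= self.gamma <= GAMMA_MAX + 1e-9):
            raise ValueError(f"gamma={self.gamma} outside [{GAMMA_MIN}, {GAMMA_MAX}]")

    @property
    def alpha(self) -> float:
        """Modification proportion implied by ``gamma``."""
        return inverse_logit(self.gamma)


@dataclass(frozen=True)
class Dispersion:
    """Shared negative-binomial size parameter theta (variance = m + m^2/theta)."""

    size: float
    at_bound: bool = False

    def __post_init__(self) -> None:
        if not (self.size > 0):
            raise ValueError(f"NB size parameter must be positive, got {self.size}")


@dataclass
class NormalizationSet:
    """Per-sample depth factors plus per-fraction scale factors.

    ``fraction_scale`` multiplies the predicted mean of every sample of that
    fraction.  One fraction is pinned to 1 as the reference: the input
    fraction in the spike-in-free design, the supernatant when factors are
    derived from post-IP spike-ins.
    """

    depth: dict = field(default_factory=dict)
    fraction_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, d in self.depth.items():
            if not (d > 0):
                raise ValueError(f"depth factor for sample {s!r} must be positive, got {d}")
        for f, x in self.fraction_scale.items():
            if f not in FRACTIONS:
                raise ValueError(f"unknown fraction {f!r}")
            if not (x > 0):
                raise ValueError(f"fraction scale for {f!r} must be positive, got {x}")


def fraction_mean(params: GeneParams, fraction: str) -> float:
    """Expected relative abundance of a gene in one fraction.

    ``input -> exp(mu)``, ``eluate -> exp(mu) * alpha``,
    ``supernatant -> exp(mu) * (1 - alpha)``; eluate and supernatant sum
    to the input mean exactly.
    """
    emu = np.exp(params.mu)
    if fraction == INPUT:
        return float(emu)
    a = inverse_logit(params.gamma)
    if fraction == ELUATE:
        return float(emu * a)
    if fraction == SUPERNATANT:
        return float(emu * (1.0 - a))
    raise ValueError(f"unknown fraction {fraction!r}; expected one of {FRACTIONS}")


def predicted_mean(params: GeneParams, sample: str, norm: NormalizationSet, design) -> float:
    """Expected read count of a gene in one sample.

    Composes the fraction mean with the sample's sequencing-depth factor and
    its fraction's normalization scale.
    """
    if sample not in norm.depth:
        raise KeyError(f"sample {sample!r} has no depth factor")
    fraction = design.fraction_of(sample)
    scale = norm.fraction_scale.get(fraction, 1.0)
    return float(norm.depth[sample] * scale * fraction_mean(params, fraction))


def _nb_logpmf(k: np.ndarray, m: np.ndarray, theta: float) -> np.ndarray:
    """Element-wise NB log-pmf, mean/size parametrization, stable for huge theta.

    For theta >= 1e6 the difference gammaln(k + theta) - gammaln(theta) is
    evaluated through a Stirling expansion written in terms of log1p(k/theta),
    which converges to the Poisson log-pmf as theta -> inf without the
    catastrophic cancellation of the direct Gamma-function form.
    """
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    klogm = np.where(k > 0, k * np.log(np.where(m > 0, m, 1.0)), 0.0)
    if theta < _LARGE_THETA:
        return (
            gammaln(k + theta)
            - gammaln(theta)
            - gammaln(k + 1.0)
            - theta * np.log1p(m / theta)
            + klogm
            - k * np.log(theta + m)
        )
    # gammaln(k+theta) - gammaln(theta) ~ k log theta + (theta+k-1/2) log1p(k/theta)
    #                                     - k + 1/(12(theta+k)) - 1/(12 theta)
    # The k log theta term cancels against k log(m/(theta+m)) = klogm
    # - k log theta - k log1p(m/theta), leaving only stable small quantities.
    delta = (
        (theta + k - 0.5) * np.log1p(k / theta)
        - k
        + 1.0 / (12.0 * (theta + k))
        - 1.0 / (12.0 * theta)
    )
    return delta - gammaln(k + 1.0) - (theta + k) * np.log1p(m / theta) + klogm


def nb_loglik(counts, means, disp: Dispersion) -> float:
    """Total negative-binomial log-likelihood of observed counts.

    Parameters
    ----------
    counts : array-like of non-negative integers
    means : array-like of positive expected counts, same length
    disp : Dispersion
        Shared size parameter theta; variance is ``m + m**2 / theta``.
    """
    k = np.asarray(counts, dtype=float)
    m = np.asarray(means, dtype=float)
    if k.shape != m.shape:
        raise ValueError("counts and means must have the same shape")
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("counts must be non-negative integers")
    if np.any(m <= 0):
        raise ValueError("means must be strictly positive")
    return float(_nb_logpmf(k, m, disp.size).sum())
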