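"""Spike-in-based cross-fraction scaling and the LAIC-seq ratio baseline.

When unmodified spike-ins (e.g. ERCC mixes) are added in equal amounts to
the eluate and supernatant *after* immunoprecipitation, any systematic
difference between their depth-normalized counts in the two fractions
measures the relative library scaling of the fractions.  This yields the
fraction normalization factors directly, without iterative fitting, and
makes the input fraction dispensable.

The LAIC-seq baseline estimates a gene's modification proportion from the
count ratio alone:

    m6A = E / (E + S * 2**R)

where ``E`` and ``S`` are the gene's eluate and supernatant counts and
``R`` is the log2-scale offset between the fractions estimated from the
spike-ins (a paired mean log2-ratio by default, or the intercept of an
ordinary least-squares regression of log2 E on log2 S).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ELUATE, SUPERNATANT, NormalizationSet
from .io import SampleDesign

__all__ = [
    "SpikeInSet",
    "LaicFit",
    "spikein_fraction_factor",
    "laicseq_R",
    "laicseq_m6a",
    "laicseq_estimate",
]


@dataclass
class SpikeInSet:
    """Spike-in row identifiers plus the count threshold for inclusion.

    A spike-in qualifies when its mean raw count across the relevant
    samples is at least ``min_count`` (inclusive, unlike the strict gene
    expression filter).
    """

    ids: list
    min_count: float = 100.0

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("spike-in id list must be non-empty")


@dataclass(frozen=True)
class LaicFit:
    """Fitted cross-fraction offset: ``R`` on the log2 scale."""

    R: float
    slope: float
    n_used: int
    dialect: str


def spikein_fraction_factor(
    counts: pd.DataFrame,
    design: SampleDesign,
    spikes: SpikeInSet,
    depth: pd.Series | None = None,
) -> NormalizationSet:
    """Fraction scale factors from post-IP equal-amount spike-ins.

    The supernatant is the reference fraction (scale 1); the eluate scale is
    the geometric mean over qualifying spike-ins of the ratio of
    depth-normalized mean eluate to mean supernatant counts.  Because equal
    spike amounts went into both fractions, this ratio is exactly the factor
    by which eluate read counts are inflated relative to the supernatant,
    i.e. the multiplier the model applies to predicted eluate means.
    Deterministic — no iterative fitting is involved.
    """
    el = [s for s in design.samples(fraction=ELUATE) if s in counts.columns]
    su = [s for s in design.samples(fraction=SUPERNATANT) if s in counts.columns]
    if not el or not su:
        raise ValueError("both eluate and supernatant samples are required")
    missing = [i for i in spikes.ids if i not in counts.index]
    if missing:
        raise ValueError(f"spike-in ids absent from count table: {missing}")
    if depth is None:
        from .fitting import estimate_depth_factors

        gene_rows = counts.loc[~counts.index.isin(spikes.ids)]
        depth = estimate_depth_factors(gene_rows, design)
    sub = counts.loc[spikes.ids, el + su].astype(float)
    qualifies = sub.mean(axis=1) >= spikes.min_count
    sub = sub.loc[qualifies]
    d = depth.reindex(el + su)
    norm_sub = sub / d
    e_mean = norm_sub[el].mean(axis=1)
    s_mean = norm_sub[su].mean(axis=1)
    usable = (e_mean > 0) & (s_mean > 0)
    if usable.sum() < 2:
        raise ValueError(
            f"fewer than 2 spike-ins pass min_count={spikes.min_count} with "
            "positive counts in both fractions"
        )
    log_ratio = np.log(e_mean[usable]) - np.log(s_mean[usable])
    x_eluate = float(np.exp(log_ratio.mean()))
    scale = {ELUATE: x_eluate, SUPERNATANT: 1.0}
    return NormalizationSet(depth=dict(depth.dropna()), fraction_scale=scale)


def laicseq_R(
    spike_eluate,
    spike_supernatant,
    min_count: float = 100.0,
    dialect: str = "slope1",
) -> LaicFit:
    """log2 offset R between eluate and supernatant from spike-in counts.

    ``slope1`` (default): paired mean of log2(E/S) over qualifying spike-ins,
    so that ``2**R`` is exactly the cross-fraction scale factor the ratio
    formula requires.  ``free_slope``: ordinary least squares of log2 E on
    log2 S; R is the fitted intercept.  Spike-ins qualify when both counts
    are at least ``min_count``; zero counts are excluded.
    """
    e = np.asarray(spike_eluate, dtype=float)
    s = np.asarray(spike_supernatant, dtype=float)
    if e.shape != s.shape:
        raise ValueError("eluate and supernatant spike vectors must be aligned")
    keep = (e >= min_count) & (s >= min_count) & (e > 0) & (s > 0)
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 spike-in pairs pass the threshold min_count={min_count}"
        )
    le, ls = np.log2(e[keep]), np.log2(s[keep])
    if dialect == "slope1":
        return LaicFit(R=float(np.mean(le - ls)), slope=1.0, n_used=int(keep.sum()), dialect=dialect)
    if dialect == "free_slope":
        import statsmodels.api as sm

        res = sm.OLS(le, sm.add_constant(ls)).fit()
        return LaicFit(
            R=float(res.params[0]), slope=float(res.params[1]), n_used=int(keep.sum()), dialect=dialect
        )
    raise ValueError(f"unknown dialect {dialect!r}; expected 'slope1' or 'free_slope'")


def laicseq_m6a(E, S, R: float):
    """Ratio-based modification proportion ``E / (E + S * 2**R)``.

    Scale-invariant in (E, S); returns NaN where both counts are zero.
    """
    E = np.asarray(E, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(E < 0) or np.any(S < 0):
        raise ValueError("counts must be non-negative")
    tot = E + S * 2.0**R
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, E / np.where(tot > 0, tot, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def laicseq_estimate(
    counts: pd.DataFrame,
    design: SampleDesign,
    spikes: SpikeInSet,
    dialect: str = "slope1",
) -> pd.DataFrame:
    """Per-gene ratio-based estimates, one column per eluate/supernatant pair.

    Eluate and supernatant samples are paired by (condition, replicate); R is
    estimated separately for each pair from that pair's spike-in counts, then
    applied gene-wise.  An ``alpha_mean`` column averages the pairs.
    """
    genes = counts.loc[~counts.index.isin(spikes.ids)]
    spike_rows = counts.loc[[i for i in spikes.ids if i in counts.index]]
    if spike_rows.empty:
        raise ValueError("no spike-in rows found in the count table")
    pairs = []
    t = design.table
    for (cond, rep), grp in t.groupby(["condition", "replicate"], sort=False):
        el = [s for s in grp.index[grp["fraction"] == ELUATE] if s in counts.columns]
        su = [s for s in grp.index[grp["fraction"] == SUPERNATANT] if s in counts.columns]
        if el and su:
            pairs.append((cond, rep, el[0], su[0]))
    if not pairs:
        raise ValueError("no eluate/supernatant sample pairs found (matched by condition and replicate)")
    out = pd.DataFrame(index=genes.index)
    cols = []
    for cond, rep, el, su in pairs:
        lf = laicseq_R(
            spike_rows[el].to_numpy(), spike_rows[su].to_numpy(),
            min_count=spikes.min_count, dialect=dialect,
        )
        col = f"alpha_{cond}_rep{rep}"
        out[col] = laicseq_m6a(genes[el].to_numpy(float), genes[su].to_numpy(float), lf.R)
        out[f"R_{cond}_rep{rep}"] = lf.R
        cols.append(col)
    out["alpha_mean"] = out[cols].mean(axis=1)
    return out
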