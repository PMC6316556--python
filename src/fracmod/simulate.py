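"""Synthetic fraction-separated count data with known ground truth.

The generator draws per-gene log expression and modification proportions,
per-sample sequencing-depth factors and per-fraction scales, then emits
negative-binomial counts around the model means for each of the three
fractions.  Unmodified spike-ins are simulated as added post-IP in equal
amounts to the eluate and supernatant only (their expected depth- and
fraction-scaled abundance is identical in both fractions, and they are
absent from the input), matching the equal-amount ERCC protocol.

Defaults mirror a desk-scale version of a two-replicate LAIC-seq-style
experiment: 500 genes with input means log-uniform on [100, 10000] counts,
modification proportions uniform on (0.02, 0.98), shared NB size 100,
depth factors log-uniform on [0.5, 2], unit fraction scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleDesign
from .model import ELUATE, FRACTIONS, INPUT, SUPERNATANT, NormalizationSet, logit

__all__ = ["SimConfig", "SimTruth", "sample_nb", "simulate_dataset"]

# Above this size the NB is numerically Poisson; sample directly from
# Poisson to avoid Gamma draws with huge shape.
_POISSON_SIZE = 1e10


@dataclass
class SimConfig:
    """Generator settings; the seed fully determines the output."""

    n_genes: int = 500
    n_replicates: int = 2
    theta: float = 100.0
    seed: int = 0
    # log-uniform range of expected input counts (exp(mu))
    mu_count_low: float = 100.0
    mu_count_high: float = 10000.0
    # modification proportion distribution: uniform on (low, high) or Beta(a, b)
    alpha_low: float = 0.02
    alpha_high: float = 0.98
    alpha_beta: tuple | None = None
    # per-sample depth factors, log-uniform
    depth_low: float = 0.5
    depth_high: float = 2.0
    # fraction scales (input is the reference, scale 1)
    x_eluate: float = 1.0
    x_supernatant: float = 1.0
    # post-IP spike-ins (eluate/supernatant only), log-uniform abundance
    n_spikeins: int = 0
    spike_count_low: float = 200.0
    spike_count_high: float = 5000.0
    spike_prefix: str = "spike"
    fractions: tuple = FRACTIONS
    condition: str = "cond1"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be >= 1")
        if not (self.theta > 0):
            raise ValueError("theta must be positive")
        if not (0.0 < self.alpha_low < self.alpha_high < 1.0):
            raise ValueError("alpha range must satisfy 0 < low < high < 1")
        if not (0 < self.mu_count_low <= self.mu_count_high):
            raise ValueError("invalid mu count range")
        if not (0 < self.depth_low <= self.depth_high):
            raise ValueError("invalid depth range")
        bad = set(self.fractions) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fractions {sorted(bad)}")


@dataclass
class SimTruth:
    """Ground truth aligned with the emitted count table rows."""

    genes: pd.DataFrame  # index gene id; columns mu, gamma, alpha
    norm: NormalizationSet
    theta: float
    spike_abundance: pd.Series  # index spike id; expected pre-scaling count


def sample_nb(mean, size: float, rng: np.random.Generator):
    """Negative-binomial draw(s) via the Gamma-Poisson mixture.

    ``mean`` may be a scalar or array; for size >= 1e10 the draw is Poisson
    (the NB limit).  A fixed generator state gives identical draws.
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("mean must be non-negative")
    if not (size > 0):
        raise ValueError("size must be positive")
    if size >= _POISSON_SIZE:
        out = rng.poisson(mean)
    else:
        lam = rng.gamma(shape=size, scale=np.maximum(mean, 1e-300) / size)
        out = rng.poisson(np.where(mean > 0, lam, 0.0))
    return int(out) if out.ndim == 0 else out.astype(np.int64)


def simulate_dataset(config: SimConfig):
    """Generate (counts, design, truth) for one synthetic experiment.

    Counts follow ``NB(mean = depth * x_fraction * fraction_mean(mu, gamma),
    size = theta)`` for genes, and ``NB(depth * x_fraction * abundance)`` for
    spike-ins in the eluate and supernatant (zero in the input).
    """
    rng = np.random.default_rng(config.seed)
    G, R = config.n_genes, config.n_replicates

    emu = np.exp(
        rng.uniform(np.log(config.mu_count_low), np.log(config.mu_count_high), size=G)
    )
    if config.alpha_beta is not None:
        a, b = config.alpha_beta
        alpha = np.clip(rng.beta(a, b, size=G), 1e-6, 1.0 - 1e-6)
    else:
        alpha = rng.uniform(config.alpha_low, config.alpha_high, size=G)
    gamma = logit(alpha)
    mu = np.log(emu)

    fractions = [f for f in FRACTIONS if f in config.fractions]
    samples = [f"{f}_rep{r + 1}" for f in fractions for r in range(R)]
    frac_of = {s: s.rsplit("_rep", 1)[0] for s in samples}
    depth = pd.Series(
        np.exp(rng.uniform(np.log(config.depth_low), np.log(config.depth_high), size=len(samples))),
        index=samples,
    )
    x = {INPUT: 1.0, ELUATE: config.x_eluate, SUPERNATANT: config.x_supernatant}

    w = {INPUT: np.ones(G), ELUATE: alpha, SUPERNATANT: 1.0 - alpha}
    gene_ids = [f"gene{g + 1:05d}" for g in range(G)]
    counts = pd.DataFrame(index=gene_ids, columns=samples, dtype=np.int64)
    for s in samples:
        f = frac_of[s]
        mean = depth[s] * x[f] * emu * w[f]
        counts[s] = sample_nb(mean, config.theta, rng)

    spike_ids = []
    spike_abund = pd.Series(dtype=float)
    if config.n_spikeins > 0:
        spike_ids = [f"{config.spike_prefix}-{i + 1:04d}" for i in range(config.n_spikeins)]
        abund = np.exp(
            rng.uniform(
                np.log(config.spike_count_low),
                np.log(config.spike_count_high),
                size=config.n_spikeins,
            )
        )
        spike_abund = pd.Series(abund, index=spike_ids)
        spikes = pd.DataFrame(0, index=spike_ids, columns=samples, dtype=np.int64)
        for s in samples:
            f = frac_of[s]
            if f == INPUT:
                continue  # added after IP: not present in the input library
            spikes[s] = sample_nb(depth[s] * x[f] * abund, config.theta, rng)
        counts = pd.concat([counts, spikes])

    design = SampleDesign(
        pd.DataFrame(
            {
                "fraction": [frac_of[s] for s in samples],
                "replicate": [s.rsplit("_rep", 1)[1] for s in samples],
                "condition": config.condition,
            },
            index=pd.Index(samples, name="sample"),
        )
    )
    truth = SimTruth(
        genes=pd.DataFrame({"mu": mu, "gamma": gamma, "alpha": alpha}, index=gene_ids),
        norm=NormalizationSet(
            depth=dict(depth),
            fraction_scale={f: x[f] for f in fractions},
        ),
        theta=config.theta,
        spike_abundance=spike_abund,
    )
    return counts.astype(np.int64), design, truth


def write_truth(truth: SimTruth, path, sep: str = "\t") -> None:
    """Persist the gene-level ground truth as TSV (mu, gamma, alpha)."""
    truth.genes.to_csv(path, sep=sep, index_label="gene_id")
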