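"""Reading, writing and filtering of count and design tables.

Canonical on-disk formats are plain TSV: a count table with gene ids in the
first column and sample ids in the header, and a design table with columns
``sample``, ``fraction``, ``replicate``, ``condition``.  CSV is accepted via
the ``sep`` argument / CLI flag.  Spike-in identifier lists are one id per
line; configuration files are flat YAML key-value mappings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .model import ELUATE, FRACTIONS, INPUT, SUPERNATANT

__all__ = [
    "SampleDesign",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_spikein_ids",
    "read_config",
    "filter_genes",
    "write_results",
    "save_fit",
    "load_fit",
]

DEFAULT_FILTER_THRESHOLD = 100.0


@dataclass
class SampleDesign:
    """Per-sample fraction / replicate / condition assignment.

    ``table`` is indexed by sample id with columns ``fraction``,
    ``replicate`` and ``condition``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"fraction", "replicate", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table is missing columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in design: {dups}")
        bad = set(self.table["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValueError(
                f"unknown fraction labels {sorted(bad)}; expected one of {FRACTIONS}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.table["condition"]))

    @property
    def fractions_present(self) -> set:
        return set(self.table["fraction"])

    def fraction_of(self, sample: str) -> str:
        try:
            return self.table.at[sample, "fraction"]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in design") from None

    def samples(self, fraction: str | None = None, condition: str | None = None) -> list:
        t = self.table
        if fraction is not None:
            t = t[t["fraction"] == fraction]
        if condition is not None:
            t = t[t["condition"] == condition]
        return list(t.index)

    def subset(self, condition: str) -> "SampleDesign":
        return SampleDesign(self.table[self.table["condition"] == condition].copy())


def _infer_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_counts(path, sep: str | None = None) -> pd.DataFrame:
    """Read a gene x sample count table (TSV by default, CSV by extension or ``sep``).

    Validates that gene and sample ids are unique and that every cell is a
    non-negative integer; errors name the offending cell.
    """
    df = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in count table: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in count table: {dups}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count table contains non-numeric entries")
    bad = (values < 0) | (values != np.floor(values)) | ~np.isfinite(values)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValueError(
            f"count table cell (gene={df.index[g]!r}, sample={df.columns[s]!r}) "
            f"= {values[g, s]} is not a non-negative integer"
        )
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path, sep: str = "\t") -> None:
    counts.to_csv(path, sep=sep, index_label="gene_id")


def read_design(path, sep: str | None = None) -> SampleDesign:
    """Read a sample design table; first column (or a ``sample`` column) holds ids."""
    df = pd.read_csv(path, sep=_infer_sep(path, sep))
    if "sample" in df.columns:
        df = df.set_index("sample")
    else:
        df = df.set_index(df.columns[0])
    df["replicate"] = df["replicate"].astype(str)
    return SampleDesign(df)


def write_design(design: SampleDesign, path, sep: str = "\t") -> None:
    design.table.to_csv(path, sep=sep, index_label="sample")


def read_spikein_ids(path) -> list:
    """One spike-in id per line; blank lines and ``#`` comments ignored."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids


def read_config(path) -> dict:
    """Flat key-value configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must be a flat key-value mapping")
    return cfg


def filter_genes(
    counts: pd.DataFrame,
    design: SampleDesign,
    mode: str = "no_spikeins",
    threshold: float = DEFAULT_FILTER_THRESHOLD,
    spikeins: list | None = None,
) -> pd.DataFrame:
    """Keep genes whose mean count over the mode's reference samples exceeds ``threshold``.

    The reference samples are the input samples in ``no_spikeins`` mode and
    all eluate plus supernatant samples in ``spikeins`` mode.  The inequality
    is strict (a mean of exactly ``threshold`` is dropped).  Spike-in rows
    are exempt: they are retained unconditionally and face their own
    inclusion threshold during normalization.
    """
    if mode not in ("no_spikeins", "spikeins"):
        raise ValueError(f"mode must be 'no_spikeins' or 'spikeins', got {mode!r}")
    if mode == "no_spikeins":
        ref = design.samples(fraction=INPUT)
        if not ref:
            raise ValueError("no input samples in design; required in no_spikeins mode")
    else:
        ref = design.samples(fraction=ELUATE) + design.samples(fraction=SUPERNATANT)
        if not ref:
            raise ValueError("no eluate/supernatant samples in design")
    missing = [s for s in ref if s not in counts.columns]
    if missing:
        raise ValueError(f"design samples missing from count table: {missing}")
    spike_set = set(spikeins or [])
    is_spike = counts.index.isin(spike_set)
    keep = (counts[ref].mean(axis=1) > threshold).to_numpy() | is_spike
    out = counts.loc[keep]
    if (~out.index.isin(spike_set)).sum() == 0:
        raise ValueError(
            f"no genes pass the mean-count filter (> {threshold}); "
            "lower the threshold or check the reference samples"
        )
    return out


def write_results(fit, path, ci: pd.DataFrame | None = None, sep: str = "\t") -> None:
    """Write per-gene estimates (and optional confidence intervals) as TSV.

    Columns: gene_id, mu_hat, gamma_hat, alpha_hat, alpha_lower, alpha_upper,
    converged, flags.
    """
    est = fit.estimates
    out = pd.DataFrame(index=est.index)
    out["mu_hat"] = est["mu_hat"]
    out["gamma_hat"] = est["gamma_hat"]
    out["alpha_hat"] = est["alpha_hat"]
    if ci is not None:
        ci = ci.reindex(est.index)
        out["alpha_lower"] = ci["alpha_lower"]
        out["alpha_upper"] = ci["alpha_upper"]
        flags = ci["flags"].fillna("")
    else:
        out["alpha_lower"] = np.nan
        out["alpha_upper"] = np.nan
        flags = pd.Series("", index=est.index)
    out["converged"] = est["converged"]
    at_bound = est["at_bound"].map({True: "at_bound", False: ""})
    out["flags"] = [
        ";".join(x for x in (a, b) if x) for a, b in zip(at_bound, flags)
    ]
    out.to_csv(path, sep=sep, index_label="gene_id")


def save_fit(fit, path) -> None:
    """Serialize a FitResult (estimates, factors, dispersion, counts) as JSON."""
    payload = {
        "estimates": {
            "index": list(fit.estimates.index),
            "columns": list(fit.estimates.columns),
            "data": fit.estimates.to_numpy().tolist(),
        },
        "depth": {k: float(v) for k, v in fit.norm.depth.items()},
        "fraction_scale": {k: float(v) for k, v in fit.norm.fraction_scale.items()},
        "dispersion": float(fit.dispersion.size),
        "dispersion_at_bound": bool(fit.dispersion.at_bound),
        "loglik_trace": [float(x) for x in fit.loglik_trace],
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "counts": {
            "index": list(fit.counts.index),
            "columns": list(fit.counts.columns),
            "data": fit.counts.to_numpy().tolist(),
        },
        "design": {
            "index": list(fit.design.table.index),
            "columns": list(fit.design.table.columns),
            "data": fit.design.table.astype(str).to_numpy().tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_fit(path):
    """Inverse of :func:`save_fit`; returns a FitResult."""
    from .fitting import FitResult
    from .model import Dispersion, NormalizationSet

    with open(path) as fh:
        p = json.load(fh)
    est = pd.DataFrame(
        p["estimates"]["data"], index=p["estimates"]["index"], columns=p["estimates"]["columns"]
    )
    est["converged"] = est["converged"].astype(bool)
    est["at_bound"] = est["at_bound"].astype(bool)
    counts = pd.DataFrame(
        p["counts"]["data"], index=p["counts"]["index"], columns=p["counts"]["columns"]
    ).astype(np.int64)
    design = SampleDesign(
        pd.DataFrame(p["design"]["data"], index=p["design"]["index"], columns=p["design"]["columns"])
    )
    norm = NormalizationSet(depth=p["depth"], fraction_scale=p["fraction_scale"])
    return FitResult(
        estimates=est,
        norm=norm,
        dispersion=Dispersion(p["dispersion"], at_bound=p["dispersion_at_bound"]),
        loglik_trace=p["loglik_trace"],
        converged=p["converged"],
        n_iter=p["n_iter"],
        counts=counts,
        design=design,
    )
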