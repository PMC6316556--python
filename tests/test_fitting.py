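"""Fitting: depth factors, per-gene MLE, shared blocks, full block ascent."""

import numpy as np
import pandas as pd
import pytest

from fracmod import (
    Dispersion,
    FitOptions,
    GeneParams,
    NormalizationSet,
    SampleDesign,
    SpikeInSet,
    estimate_depth_factors,
    fit,
    fit_dispersion,
    fit_fraction_factors,
    fit_gene,
    nb_loglik,
    fraction_mean,
    inverse_logit,
    simulate_dataset,
    spikein_fraction_factor,
)
from fracmod.simulate import SimConfig


def _design(fractions, condition="c"):
    idx, frac, rep = [], [], []
    for f, n in fractions.items():
        for r in range(n):
            idx.append(f"{f}{r + 1}")
            frac.append(f)
            rep.append(str(r + 1))
    return SampleDesign(
        pd.DataFrame(
            {"fraction": frac, "replicate": rep, "condition": condition},
            index=pd.Index(idx, name="sample"),
        )
    )


class TestDepthFactors:
    def test_identical_replicates(self):
        design = _design({"input": 2})
        counts = pd.DataFrame({"input1": [10, 200, 30], "input2": [10, 200, 30]})
        f = estimate_depth_factors(counts, design)
        assert f.to_numpy() == pytest.approx([1.0, 1.0])

    def test_exact_scalar_multiple(self):
        design = _design({"input": 2})
        a = np.array([11, 50, 400, 90])
        counts = pd.DataFrame({"input1": a, "input2": 2 * a})
        f = estimate_depth_factors(counts, design)
        assert f["input1"] == pytest.approx(1 / np.sqrt(2), rel=1e-9)
        assert f["input2"] == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_recovers_simulated_depths(self):
        """Known depths 0.5 and 2.0 recovered within 5% at 1000 genes."""
        rng = np.random.default_rng(5)
        base = np.exp(rng.uniform(np.log(100), np.log(5000), 1000))
        theta = 100.0
        draw = lambda m: rng.poisson(rng.gamma(theta, m / theta))
        counts = pd.DataFrame({"input1": draw(0.5 * base), "input2": draw(2.0 * base)})
        f = estimate_depth_factors(counts, _design({"input": 2}))
        # geometric-mean-1 scaling maps (0.5, 2.0) to (0.5, 2.0)
        assert f["input1"] == pytest.approx(0.5, rel=0.05)
        assert f["input2"] == pytest.approx(2.0, rel=0.05)

    def test_all_zero_fraction_errors(self):
        counts = pd.DataFrame({"input1": [0, 0], "input2": [0, 0]})
        with pytest.raises(ValueError):
            estimate_depth_factors(counts, _design({"input": 2}))


class TestFitGene:
    def test_saturated_closed_form(self, single_replicate_design, unit_norm):
        """With one sample per fraction, unit factors and near-Poisson noise the
        gene MLE is available in closed form: alpha = e/(e+s), exp(mu) = input."""
        rng = np.random.default_rng(42)
        disp = Dispersion(1e10)
        for _ in range(20):
            e = int(rng.integers(5, 5000))
            s = int(rng.integers(5, 5000))
            counts = pd.Series({"i1": e + s, "e1": e, "s1": s}, name="g")
            est = fit_gene(
                counts, unit_norm, disp, single_replicate_design, GeneParams(np.log(e + s), 0.0)
            )
            assert est.alpha == pytest.approx(e / (e + s), rel=1e-4)
            assert np.exp(est.mu) == pytest.approx(e + s, rel=1e-4)

    def test_symmetric_counts_give_zero_gamma(self, single_replicate_design, unit_norm):
        counts = pd.Series({"i1": 400, "e1": 200, "s1": 200}, name="g")
        est = fit_gene(
            counts, unit_norm, Dispersion(50.0), single_replicate_design, GeneParams(np.log(400), 0.5)
        )
        assert est.gamma == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search(self, single_replicate_design, unit_norm):
        """Brute-force lattice oracle over (mu, gamma), evaluated with scipy's
        independently parametrized NB pmf, agrees with the optimizer."""
        from scipy.stats import nbinom

        rng = np.random.default_rng(3)
        theta = 20.0
        mus = np.linspace(np.log(20), np.log(4000), 200)[:, None]
        gammas = np.linspace(-5, 5, 200)[None, :]
        alphas = 1.0 / (1.0 + np.exp(-gammas))
        for _ in range(10):
            emu = rng.uniform(50, 2000)
            a = rng.uniform(0.1, 0.9)
            counts = pd.Series(
                {
                    "i1": rng.poisson(emu),
                    "e1": rng.poisson(emu * a),
                    "s1": rng.poisson(emu * (1 - a)),
                },
                name="g",
            )
            est = fit_gene(
                counts, unit_norm, Dispersion(theta), single_replicate_design,
                GeneParams(np.log(emu), 0.0),
            )
            grid_ll = np.zeros((200, 200))
            for sample, w in (("i1", np.ones_like(alphas)), ("e1", alphas), ("s1", 1 - alphas)):
                m = np.exp(mus) * w
                grid_ll += nbinom.logpmf(counts[sample], theta, theta / (theta + m))
            i, j = np.unravel_index(np.argmax(grid_ll), grid_ll.shape)
            assert est.mu == pytest.approx(mus[i, 0], abs=2 * (mus[1, 0] - mus[0, 0]))
            assert est.gamma == pytest.approx(gammas[0, j], abs=2 * (gammas[0, 1] - gammas[0, 0]))
            assert est.loglik >= grid_ll[i, j] - 1e-9

    def test_scale_equivariance(self, single_replicate_design):
        """Scaling one sample's counts and its depth factor by c leaves the MLE fixed."""
        disp = Dispersion(80.0)
        base = pd.Series({"i1": 900, "e1": 630, "s1": 270}, name="g")
        norm1 = NormalizationSet(depth={"i1": 1.0, "e1": 1.0, "s1": 1.0}, fraction_scale={})
        est1 = fit_gene(base, norm1, disp, single_replicate_design, GeneParams(np.log(900), 0.0))
        c = 3.0
        scaled = base.copy()
        scaled["e1"] = int(base["e1"] * c)
        norm2 = NormalizationSet(depth={"i1": 1.0, "e1": c, "s1": 1.0}, fraction_scale={})
        est2 = fit_gene(scaled, norm2, disp, single_replicate_design, GeneParams(np.log(900), 0.0))
        assert est2.mu == pytest.approx(est1.mu, abs=1e-5)
        assert est2.gamma == pytest.approx(est1.gamma, abs=1e-5)

    def test_all_zero_gene_flagged(self, single_replicate_design, unit_norm):
        counts = pd.Series({"i1": 0, "e1": 0, "s1": 0}, name="g")
        est = fit_gene(
            counts, unit_norm, Dispersion(10.0), single_replicate_design, GeneParams(1.0, 0.0)
        )
        assert not est.converged
        assert est.at_bound

    def test_zero_eluate_hits_gamma_bound(self, single_replicate_design, unit_norm):
        counts = pd.Series({"i1": 500, "e1": 0, "s1": 500}, name="g")
        est = fit_gene(
            counts, unit_norm, Dispersion(1e6), single_replicate_design, GeneParams(np.log(500), 0.0)
        )
        assert est.at_bound
        assert est.gamma == pytest.approx(-20.0, abs=1e-3)


class TestSharedBlocks:
    def test_fraction_factor_recovery_isolated(self):
        """With gene params and theta held at truth, the factor block recovers
        the simulated scales."""
        cfg = SimConfig(
            n_genes=400, n_replicates=2, theta=100.0, seed=8, x_eluate=1.3, x_supernatant=0.7
        )
        counts, design, truth = simulate_dataset(cfg)
        est = truth.genes.rename(columns={"mu": "mu_hat", "gamma": "gamma_hat"})
        depth = pd.Series(truth.norm.depth)
        norm = fit_fraction_factors(counts, est, Dispersion(100.0), design, depth)
        assert norm.fraction_scale["eluate"] == pytest.approx(1.3, rel=0.05)
        assert norm.fraction_scale["supernatant"] == pytest.approx(0.7, rel=0.05)

    def test_single_gene_not_identifiable(self):
        cfg = SimConfig(n_genes=1, n_replicates=2, theta=100.0, seed=8)
        counts, design, truth = simulate_dataset(cfg)
        est = truth.genes.rename(columns={"mu": "mu_hat", "gamma": "gamma_hat"})
        with pytest.raises(ValueError):
            fit_fraction_factors(counts, est, Dispersion(100.0), design, pd.Series(truth.norm.depth))

    def test_dispersion_recovery(self):
        """theta = 10 recovered from 1000 genes x 6 samples at true gene params."""
        cfg = SimConfig(n_genes=1000, n_replicates=2, theta=10.0, seed=12)
        counts, design, truth = simulate_dataset(cfg)
        est = truth.genes.rename(columns={"mu": "mu_hat", "gamma": "gamma_hat"})
        disp = fit_dispersion(counts, est, truth.norm, design)
        assert 8.0 <= disp.size <= 12.0

    def test_dispersion_poisson_data_hits_upper_bound(self):
        cfg = SimConfig(n_genes=300, n_replicates=2, theta=1e12, seed=13)
        counts, design, truth = simulate_dataset(cfg)
        est = truth.genes.rename(columns={"mu": "mu_hat", "gamma": "gamma_hat"})
        disp = fit_dispersion(counts, est, truth.norm, design)
        assert disp.size > 1e6 or disp.at_bound

    def test_dispersion_permutation_invariant(self):
        cfg = SimConfig(n_genes=200, n_replicates=2, theta=30.0, seed=14)
        counts, design, truth = simulate_dataset(cfg)
        est = truth.genes.rename(columns={"mu": "mu_hat", "gamma": "gamma_hat"})
        d1 = fit_dispersion(counts, est, truth.norm, design)
        perm = counts.index[::-1]
        d2 = fit_dispersion(counts.loc[perm], est.loc[perm], truth.norm, design)
        assert d1.size == pytest.approx(d2.size, rel=1e-6)


class TestFullFit:
    def test_trace_monotone_across_seeds(self):
        """Block coordinate ascent: the total log-likelihood never decreases."""
        for seed in range(1, 6):
            cfg = SimConfig(n_genes=80, n_replicates=2, theta=100.0, seed=seed)
            counts, design, _ = simulate_dataset(cfg)
            fr = fit(counts, design, FitOptions(max_outer_iterations=12, rel_tol=1e-6))
            tr = np.asarray(fr.loglik_trace)
            assert np.all(np.diff(tr) >= -1e-6 * (np.abs(tr[:-1]) + 1))

    def test_alpha_is_logistic_of_gamma(self, recovery_fit):
        fr, _ = recovery_fit
        est = fr.estimates
        assert est["alpha_hat"].to_numpy() == pytest.approx(
            inverse_logit(est["gamma_hat"].to_numpy()), rel=1e-12
        )

    def test_doubling_eluate_doubles_factor(self):
        """Equivariance of the fitted eluate factor under count rescaling."""
        cfg = SimConfig(n_genes=150, n_replicates=2, theta=100.0, seed=21)
        counts, design, _ = simulate_dataset(cfg)
        opts = FitOptions(rel_tol=1e-9)
        f1 = fit(counts, design, opts)
        doubled = counts.copy()
        el = design.samples(fraction="eluate")
        doubled[el] = doubled[el] * 2
        f2 = fit(doubled, design, opts)
        ratio = f2.norm.fraction_scale["eluate"] / f1.norm.fraction_scale["eluate"]
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_spikein_factors_used_verbatim(self, spikein_dataset):
        """In spike-in mode the fraction factors come from the spike-ins and are
        not refitted."""
        counts, design, truth, spike_ids = spikein_dataset
        fr = fit(counts, design, FitOptions(mode="spikeins"), spikeins=spike_ids)
        from fracmod.fitting import estimate_depth_factors

        genes = counts.loc[~counts.index.isin(spike_ids)]
        depth = estimate_depth_factors(genes, design)
        direct = spikein_fraction_factor(counts, design, SpikeInSet(ids=spike_ids), depth=depth)
        assert fr.norm.fraction_scale["eluate"] == direct.fraction_scale["eluate"]
        assert fr.norm.fraction_scale["supernatant"] == 1.0
        assert not any(g in fr.estimates.index for g in spike_ids)

    def test_no_input_and_no_spikeins_errors(self):
        cfg = SimConfig(n_genes=20, n_replicates=2, theta=100.0, seed=3,
                        fractions=("eluate", "supernatant"))
        counts, design, _ = simulate_dataset(cfg)
        with pytest.raises(ValueError, match="input"):
            fit(counts, design, FitOptions())
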