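"""Reproducible end-to-end validation protocols.

Each function here runs one of the package's headline self-checks from
scratch — simulator vs. exact stationary oracle, closed-loop parameter
recovery, perturbation directionality and mechanism-ranking recovery, and
the coverage-binning round trip — and returns plain numbers.  They are used
by the test suite and by ``scripts/acceptance.py``.

All randomness derives from a single integer seed; derived seeds stay below
2³¹ so they are valid for every engine.
"""

from __future__ import annotations

import numpy as np

from . import params
from .binning import cpm_normalize, gene_regions, region_means
from .fitting import default_grid, grid_search
from .minimal import (DEFAULT_GRID, MinimalParams, dwell_grid_comparison,
                      minimal_occupancy_analytic,
                      minimal_occupancy_stochastic)
from .model import GeneArchitecture, GeneClass, RateSet
from .occupancy import (SimulationProtocol, analytic_steady_state,
                        average_occupancy)
from .perturbation import (PerturbationSpec, ensemble_delta, load_catalog,
                           catalog_candidates, rank_perturbations,
                           single_model_ensemble)
from .synth import (NoiseModel, synth_coverage, synth_empirical_occupancy,
                    synth_gene_annotation, synth_perturbation_dataset)

__all__ = ["sample_rate_set", "oracle_equivalence", "recovery_replicates",
           "direction_deltas", "ranking_success", "binning_round_trip",
           "minimal_model_summary"]

_MOD = 2**31 - 1


def _spawn(rng: np.random.Generator) -> int:
    return int(rng.integers(_MOD))


def sample_rate_set(gene_class: GeneClass, rng: np.random.Generator
                    ) -> RateSet:
    """Draw free rates inside their functional ranges (log-uniform for
    strictly positive rates, uniform for zero-anchored ones); fixed rates at
    their published values."""
    gene_class = GeneClass(gene_class)
    if gene_class is GeneClass.STM:
        free = {n: params.FUNCTIONAL_RANGES_CHEC[n]
                for n in params.FREE_RATES_STM}
        make = RateSet.stm
    else:
        free = dict(params.FREE_RATE_RANGES_TFO)
        make = RateSet.tfo
    draws = {}
    for name, (lo, hi) in free.items():
        if name in params.ZERO_ANCHORED_RATES or lo == 0:
            draws[name] = float(rng.uniform(lo, hi))
        else:
            draws[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return make(**draws)


def oracle_equivalence(seed: int = 0, n_sets: int = 5, n_genes: int = 2000
                       ) -> dict:
    """Gillespie population averages vs. the exact stationary distribution.

    Samples ``n_sets`` rate sets inside the functional ranges (alternating
    TFO/STM), simulates each on the full default architecture and compares
    every compartment against the analytic oracle in units of the
    Monte-Carlo standard error.  Returns the maximum |z| over all
    compartments and rate sets.
    """
    rng = np.random.default_rng(seed)
    max_z = 0.0
    details = []
    for i in range(n_sets):
        gene_class = GeneClass.TFO if i % 2 == 0 else GeneClass.STM
        arch = GeneArchitecture(gene_class=gene_class)
        rates = sample_rate_set(gene_class, rng)
        protocol = SimulationProtocol(n_genes=n_genes,
                                      master_seed=_spawn(rng))
        mc = average_occupancy(arch, rates, protocol)
        exact = analytic_steady_state(arch, rates)
        se = np.where(mc.se > 0, mc.se, np.inf)
        z = float(np.max(np.abs(mc.values - exact.values) / se))
        details.append({"gene_class": gene_class.value, "max_z": z})
        max_z = max(max_z, z)
    return {"max_abs_z": max_z, "n_sets": n_sets, "n_genes": n_genes,
            "details": details}


def recovery_replicates(gene_class: GeneClass, n_replicates: int = 10,
                        seed: int = 0, grid_points: int = 6,
                        n_genes: int = 500, sigma: float = 0.05,
                        threshold: float = 0.995,
                        generator_n_genes: int = 1000) -> dict:
    """Closed-loop rate recovery.

    Per replicate: draw a true rate set, generate a noisy empirical-style
    region vector from it, grid-search the free rates, and test whether every
    true free rate falls inside the recovered functional range.  Returns the
    number of successful replicates.
    """
    gene_class = GeneClass(gene_class)
    arch = GeneArchitecture(gene_class=gene_class)
    rng = np.random.default_rng(seed)
    free = (params.FREE_RATES_STM if gene_class is GeneClass.STM
            else params.FREE_RATES_TFO)
    successes = 0
    reps = []
    for _ in range(n_replicates):
        truth = sample_rate_set(gene_class, rng)
        noise = NoiseModel(sigma=sigma, seed=_spawn(rng))
        gen_protocol = SimulationProtocol(n_genes=generator_n_genes,
                                          master_seed=_spawn(rng))
        empirical, _ = synth_empirical_occupancy(truth, arch, noise,
                                                 gen_protocol)
        grid = default_grid(gene_class, n_points=grid_points)
        fit_protocol = SimulationProtocol(n_genes=n_genes,
                                          master_seed=_spawn(rng))
        ensemble = grid_search(grid, empirical, arch, fit_protocol,
                               threshold=threshold)
        if ensemble.members:
            ranges = ensemble.functional_ranges
            ok = all(ranges[n][0] - 1e-12 <= getattr(truth, n)
                     <= ranges[n][1] + 1e-12 for n in free)
        else:
            ok = False
        successes += ok
        reps.append({"n_members": len(ensemble), "recovered": bool(ok)})
    return {"successes": successes, "n_replicates": n_replicates,
            "replicates": reps}


def direction_deltas(seed: int = 0, n_genes: int = 2000) -> dict:
    """Signed region changes for the canonical single-rate perturbations
    (paired seeds, representative baseline rates).

    Returns ΔUAS for STM k2 × 0.2, Δpromoter for a k5 reduction to 0.02 s⁻¹
    in both classes, and Δpromoter for the TFO k3 reduction to 0.0008 s⁻¹.
    """
    rng = np.random.default_rng(seed)
    catalog = load_catalog()
    out = {}

    stm_arch = GeneArchitecture(gene_class=GeneClass.STM)
    stm = single_model_ensemble(RateSet.stm())
    protocol = SimulationProtocol(n_genes=n_genes, master_seed=_spawn(rng))
    k2_down = PerturbationSpec.multipliers("k2_x0.2", k2=0.2)
    out["stm_k2_x0.2_delta_uas"] = ensemble_delta(
        stm, k2_down, stm_arch, protocol)["UAS"]
    out["stm_k5_down_delta_promoter"] = ensemble_delta(
        stm, catalog["kin28_inhibition_stm_1"], stm_arch,
        protocol)["promoter"]

    tfo_arch = GeneArchitecture(gene_class=GeneClass.TFO)
    tfo = single_model_ensemble(RateSet.tfo())
    protocol = SimulationProtocol(n_genes=n_genes, master_seed=_spawn(rng))
    out["tfo_k5_down_delta_promoter"] = ensemble_delta(
        tfo, catalog["kin28_inhibition_tfo_1"], tfo_arch,
        protocol)["promoter"]
    out["tfo_k3_down_delta_promoter"] = ensemble_delta(
        tfo, catalog["sua7_degradation_tfo_1"], tfo_arch,
        protocol)["promoter"]
    return out


def ranking_success(experiment: str, gene_class: GeneClass,
                    generating_model: int = 1, n_seeds: int = 10,
                    seed: int = 0, sigma: float = 0.05,
                    n_genes: int = 1000) -> dict:
    """Closed-loop mechanism ranking.

    Per seed: generate a noisy synthetic Δ vector from one catalog spec,
    then rank all of that experiment's candidate specs against it; success
    means the generating spec ranks first.
    """
    gene_class = GeneClass(gene_class)
    arch = GeneArchitecture(gene_class=gene_class)
    truth = RateSet.stm() if gene_class is GeneClass.STM else RateSet.tfo()
    catalog = load_catalog()
    candidates = catalog_candidates(catalog, experiment, gene_class)
    generating = catalog[
        f"{experiment}_{gene_class.value.lower()}_{generating_model}"]
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_seeds):
        noise = NoiseModel(sigma=sigma, seed=_spawn(rng))
        gen_protocol = SimulationProtocol(n_genes=n_genes,
                                          master_seed=_spawn(rng))
        _, delta, _ = synth_perturbation_dataset(truth, generating, arch,
                                                 noise, gen_protocol)
        model_protocol = SimulationProtocol(n_genes=n_genes,
                                            master_seed=_spawn(rng))
        ensemble = single_model_ensemble(truth)
        ranked = rank_perturbations(candidates, delta, ensemble, arch,
                                    model_protocol)
        wins += ranked[0][0].label == generating.label
    return {"wins": wins, "n_seeds": n_seeds,
            "n_candidates": len(candidates)}


def binning_round_trip(seed: int = 0, weights=(1.0, 4.0, 2.0, 3.0),
                       n_genes: int = 30, depth: int = 200_000,
                       genome_length: int = 300_000) -> dict:
    """Synthetic coverage → CPM → region means, compared with the generating
    weights in units of binomial standard error.

    Region reads are multinomial with probability ∝ weight × total region
    length, so the observed per-region count fraction should match that
    probability to within sampling error.  Returns the max |z| over the four
    regions.
    """
    genes, _ = synth_gene_annotation(n_genes, genome_length, seed=seed)
    track = synth_coverage(genes, weights, depth, seed=seed + 1,
                           genome_length=genome_length)
    cpm = cpm_normalize(track)
    order = ("UAS", "promoter", "transcript", "3'UTR")
    widths = {name: 0.0 for name in order}
    counts = {name: 0.0 for name in order}
    for gene in genes:
        regions = gene_regions(gene)
        means = region_means(track, regions)
        for name in order:
            c, s, e = regions[name]
            widths[name] += e - s
            counts[name] += means[name] * (e - s)
    w = np.asarray(weights, dtype=float)
    lengths = np.array([widths[n] for n in order])
    expected_frac = w * lengths / (w * lengths).sum()
    observed_frac = np.array([counts[n] for n in order]) / depth
    se = np.sqrt(expected_frac * (1 - expected_frac) / depth)
    z = np.abs(observed_frac - expected_frac) / se
    # recovered per-bp intensity ratios (normalized to the UAS weight)
    per_bp = np.array([counts[n] / widths[n] for n in order])
    ratios = per_bp / per_bp[0] * w[0]
    return {"max_abs_z": float(z.max()),
            "recovered_weights": ratios.tolist(),
            "cpm_total": cpm.total}


def minimal_model_summary(seed: int = 0, n_genes: int = 2000) -> dict:
    """Worked minimal-model numbers: the T_p=10 s / v=1000 bp·min⁻¹ /
    T_t=70 s occupancy fractions, stochastic-vs-analytic max |z|, and the
    default dwell grid's comparison counts."""
    p = MinimalParams(promoter_dwell=10.0, elongation_speed=1000.0,
                      terminator_dwell=70.0)
    occ = minimal_occupancy_analytic(p)
    mean, se = minimal_occupancy_stochastic(p, n_genes=n_genes, rng=seed)
    z = float(np.max(np.abs(mean - occ) / np.where(se > 0, se, np.inf)))
    _, summary = dwell_grid_comparison(DEFAULT_GRID)
    return {
        "promoter_fraction": float(occ[0]),
        "per_bin_fraction": float(occ[1]),
        "terminator_fraction": float(occ[-1]),
        "stochastic_max_abs_z": z,
        "grid_counts": summary,
    }
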