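"""Synthetic datasets with known ground truth for every pipeline stage.

Real inputs to this analysis are sequencing-derived: coverage tracks,
gene/site annotations, and per-gene-class region vectors in CPMn units.  The
generators here produce structurally identical inputs from known rates, so
that binning, fitting and perturbation ranking can all be exercised as
closed loops (generate with known truth → analyze → compare to truth).

Noise model: region-level CPMn means are strictly positive with dispersion
roughly proportional to signal, so synthetic empirical vectors apply
multiplicative lognormal noise (default σ = 0.1) plus an optional additive
background floor, then scale to a CPMn-like magnitude (default factor 100 —
arbitrary and irrelevant to cosine scoring).  What the generator does *not*
emulate: nuclease sequence bias, replicate batch structure, and
between-gene rate heterogeneity within a class (every simulated gene of a
class shares one rate set).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binning import CoverageTrack, GeneModel, RegionScheme, Site, \
    gene_regions
from .model import GeneArchitecture, RateSet
from .occupancy import (RegionOccupancy, SimulationProtocol,
                        aggregate_regions, average_occupancy)
from .perturbation import DeltaOccupancy, PerturbationSpec, \
    apply_perturbation

__all__ = ["NoiseModel", "SyntheticDataset", "synth_gene_annotation",
           "synth_coverage", "synth_empirical_occupancy",
           "synth_perturbation_dataset"]

#: Distance from the TSS to the synthetic TATA site, upstream in
#: transcription direction (mimicking the typical TATA-to-TSS geometry of
#: ~50 bp in yeast promoters).
TATA_OFFSET = 50


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise plus an additive background floor."""

    sigma: float = 0.1   # lognormal sigma of the multiplicative factor
    floor: float = 0.0   # additive background, CPMn units
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.floor < 0:
            raise ValueError("sigma and floor must be >= 0")

    def apply(self, values: np.ndarray,
              rng: np.random.Generator | None = None) -> np.ndarray:
        rng = np.random.default_rng(self.seed) if rng is None else rng
        factors = rng.lognormal(mean=0.0, sigma=self.sigma,
                                size=len(values)) if self.sigma > 0 \
            else np.ones(len(values))
        return values * factors + self.floor


@dataclass
class SyntheticDataset:
    """A generated dataset plus the manifest that regenerates it."""

    manifest: dict
    truth: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=1,
                                         default=str))


# ---------------------------------------------------------------------------
# Annotations and coverage
# ---------------------------------------------------------------------------

def synth_gene_annotation(n_genes: int, genome_length: int, seed: int = 0,
                          gene_length_range: tuple[int, int] = (600, 2400),
                          flank: int = 1000, chrom: str = "chrS"
                          ) -> tuple[list[GeneModel], list[Site]]:
    """Non-overlapping genes (with ± ``flank`` clearance) on one contig,
    random strands, plus one TATA-like site 50 bp upstream of each TSS.

    Gene lengths are uniform over ``gene_length_range`` (default 600–2400
    bp, bracketing the ~1.2 kb median yeast transcript).
    """
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    needed = int(lengths.sum()) + (n_genes + 1) * flank
    if needed > genome_length:
        raise ValueError(f"cannot pack {n_genes} genes (+{flank} bp flanks) "
                         f"into {genome_length} bp; need >= {needed}")
    slack = genome_length - needed
    # distribute the slack as random inter-gene gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
    gaps = np.diff(np.concatenate([[0], cuts]))
    genes, sites = [], []
    cursor = flank
    for i in range(n_genes):
        cursor += int(gaps[i])
        start, end = cursor, cursor + int(lengths[i])  # half-open
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        gene = GeneModel(gene_id=f"g{i + 1:04d}", chrom=chrom, strand=strand,
                         tss=tss, tes=tes)
        genes.append(gene)
        tata = tss - TATA_OFFSET if strand == "+" else tss + TATA_OFFSET
        sites.append(Site(chrom=chrom, pos=int(tata), strand=strand,
                          name=f"tata_{gene.gene_id}"))
        cursor = end + flank
    return genes, sites


def synth_coverage(genes: list[GeneModel], region_weights,
                   depth: int, seed: int = 0,
                   scheme: RegionScheme = RegionScheme(),
                   genome_length: int | None = None,
                   chrom: str = "chrS") -> CoverageTrack:
    """Place ``depth`` reads across gene regions, multinomially with
    probability ∝ region weight × region length, uniformly within a region.

    ``region_weights`` are per-region intensities in the order (UAS,
    promoter, transcript, 3'UTR).  Returns a raw-count track.
    """
    weights = np.asarray(region_weights, dtype=float)
    if weights.shape != (4,):
        raise ValueError("region_weights must have 4 entries "
                         "(UAS, promoter, transcript, 3'UTR)")
    if (weights < 0).any():
        raise ValueError("region weights must be >= 0")
    if weights.sum() == 0:
        raise ValueError("all region weights are zero")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    order = ("UAS", "promoter", "transcript", "3'UTR")
    intervals, masses = [], []
    for gene in genes:
        regions = gene_regions(gene, scheme)
        for w, name in zip(weights, order):
            c, s, e = regions[name]
            intervals.append((c, s, e))
            masses.append(w * (e - s))
    masses = np.asarray(masses, dtype=float)
    if genome_length is None:
        genome_length = max(e for _, _, e in intervals) + 1000
    data = {chrom: np.zeros(genome_length)}
    counts = rng.multinomial(depth, masses / masses.sum())
    for (c, s, e), n in zip(intervals, counts):
        if n == 0:
            continue
        pos = rng.integers(s, e, size=n)
        np.add.at(data[c], pos, 1.0)
    return CoverageTrack(data=data, units="raw")


# ---------------------------------------------------------------------------
# Empirical-style region vectors
# ---------------------------------------------------------------------------

def synth_empirical_occupancy(true_rates: RateSet, arch: GeneArchitecture,
                              noise: NoiseModel,
                              protocol: SimulationProtocol,
                              cpmn_scale: float = 100.0,
                              rng: np.random.Generator | None = None,
                              engine: str = "auto"
                              ) -> tuple[RegionOccupancy, dict]:
    """An empirical-style CPMn region vector generated from known rates.

    Pipeline: population-average occupancy → region aggregation →
    multiplicative lognormal noise → background floor → CPMn-like scaling.
    Returns ``(vector, manifest)``; the manifest regenerates it bit for bit.
    """
    rng = np.random.default_rng(noise.seed) if rng is None else rng
    occ = average_occupancy(arch, true_rates, protocol, engine=engine)
    region = aggregate_regions(occ)
    values = noise.apply(region.values, rng=rng) * cpmn_scale
    manifest = {
        "kind": "synthetic_empirical_occupancy",
        "true_rates": true_rates.to_dict(),
        "gene_class": arch.gene_class.value,
        "noise": {"sigma": noise.sigma, "floor": noise.floor,
                  "seed": noise.seed},
        "protocol": {"total_time": protocol.total_time,
                     "record_window": protocol.record_window,
                     "n_genes": protocol.n_genes,
                     "master_seed": protocol.master_seed},
        "cpmn_scale": cpmn_scale,
    }
    vec = RegionOccupancy(gene_class=arch.gene_class, values=values,
                          units="CPMn")
    return vec, manifest


def synth_perturbation_dataset(true_rates: RateSet, spec: PerturbationSpec,
                               arch: GeneArchitecture, noise: NoiseModel,
                               protocol: SimulationProtocol,
                               cpmn_scale: float = 100.0,
                               engine: str = "auto"
                               ) -> tuple[RegionOccupancy, DeltaOccupancy,
                                          dict]:
    """Paired baseline/perturbed vectors and their difference.

    Baseline and perturbed populations share the protocol's master seed
    (paired per-gene substreams); noise is applied independently to each.
    Returns ``(baseline, delta, manifest)`` where ``delta`` is the
    empirical-style perturbed − baseline CPMn vector.
    """
    rng = np.random.default_rng(noise.seed)
    base_vec, _ = synth_empirical_occupancy(
        true_rates, arch, noise, protocol, cpmn_scale=cpmn_scale, rng=rng,
        engine=engine)
    pert_rates = apply_perturbation(true_rates, spec)
    pert_vec, _ = synth_empirical_occupancy(
        pert_rates, arch, noise, protocol, cpmn_scale=cpmn_scale, rng=rng,
        engine=engine)
    delta = DeltaOccupancy(gene_class=arch.gene_class,
                           values=pert_vec.values - base_vec.values,
                           units="CPMn")
    manifest = {
        "kind": "synthetic_perturbation_dataset",
        "true_rates": true_rates.to_dict(),
        "generating_spec": {"label": spec.label,
                            "description": spec.description},
        "gene_class": arch.gene_class.value,
        "noise": {"sigma": noise.sigma, "floor": noise.floor,
                  "seed": noise.seed},
        "protocol": {"total_time": protocol.total_time,
                     "record_window": protocol.record_window,
                     "n_genes": protocol.n_genes,
                     "master_seed": protocol.master_seed},
        "cpmn_scale": cpmn_scale,
    }
    return base_vec, delta, manifest
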