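"""Grid-search ensemble fitting of the transcription-cycle rates.

Free rates are explored on a grid; every grid point is simulated with common
random numbers (one master seed for the whole grid, so neighbouring models
differ only through their rates, not through Monte-Carlo noise), scored by
cosine similarity against the empirical region vector, and every model
scoring above the threshold (default 0.995) enters the ensemble.  The
ensemble is summarized by per-rate *functional ranges* — the min–max of each
free rate across members — rather than a single best fit.

When no model clears the threshold (as happens when fitting crosslinking-
derived occupancy), the ensemble is returned empty with the top-10 models
attached as a diagnostic.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import params
from .model import GeneArchitecture, GeneClass, RateSet
from .occupancy import (RegionOccupancy, SimulationProtocol,
                        aggregate_regions, average_occupancy, l2_scale)

__all__ = ["GridAxis", "GridSpec", "ScoredModel", "ModelEnsemble",
           "cosine_similarity", "grid_search", "functional_ranges", "best_n",
           "default_grid"]

#: Canonical free-rate ordering used for deterministic tie-breaks.
TIE_ORDER = ("k2", "k_minus2", "k_minus3", "k4", "k3")


def cosine_similarity(model, empirical) -> float:
    """cos∠(M, E) = ΣMᵢEᵢ / (√ΣMᵢ² √ΣEᵢ²), in [−1, 1].

    Accepts :class:`RegionOccupancy` or plain arrays; invariant to positive
    rescaling of either argument, so raw and L2-scaled vectors score
    identically.
    """
    m = np.asarray(model.values if isinstance(model, RegionOccupancy)
                   else model, dtype=float)
    e = np.asarray(empirical.values if isinstance(empirical, RegionOccupancy)
                   else empirical, dtype=float)
    if m.shape != e.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {e.shape}")
    nm, ne = np.linalg.norm(m), np.linalg.norm(e)
    if nm == 0 or ne == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(m @ e / (nm * ne), -1.0, 1.0))


@dataclass(frozen=True)
class GridAxis:
    """One free-rate dimension of the search grid."""

    lower: float
    upper: float
    n_points: int = 12
    spacing: str = "linear"  # or "log"

    def __post_init__(self):
        if self.lower < 0 or self.upper < self.lower:
            raise ValueError("need 0 <= lower <= upper")
        if self.n_points < 1:
            raise ValueError("each grid axis needs >= 1 point")
        if self.spacing not in ("linear", "log"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if self.spacing == "log" and self.lower <= 0:
            raise ValueError("log spacing requires lower > 0")

    def points(self) -> np.ndarray:
        if self.spacing == "log":
            return np.geomspace(self.lower, self.upper, self.n_points)
        return np.linspace(self.lower, self.upper, self.n_points)


@dataclass
class GridSpec:
    """Free-rate axes plus the fixed base rate set carried alongside."""

    base_rates: RateSet
    axes: dict[str, GridAxis]

    def __post_init__(self):
        if not self.axes:
            raise ValueError("grid has no free axes")
        # canonical axis order for reproducible enumeration
        self.axes = {n: self.axes[n] for n in TIE_ORDER if n in self.axes} | {
            n: ax for n, ax in self.axes.items() if n not in TIE_ORDER}

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(self.axes)

    @property
    def n_points(self) -> int:
        return int(np.prod([ax.n_points for ax in self.axes.values()]))

    def rate_sets(self):
        """Yield every grid point as a full RateSet."""
        names = self.free_names
        for combo in itertools.product(*(self.axes[n].points() for n in names)):
            yield self.base_rates.replace(**dict(zip(names, combo)))


def default_grid(gene_class: GeneClass, n_points: int = 12,
                 context: str = "chec", base_rates: RateSet | None = None
                 ) -> GridSpec:
    """The default free/fixed split: k2, k_minus2, k_minus3, k4 free for STM;
    k3, k_minus3, k4 free for TFO; everything else fixed at the published
    values.  Axes span the fitted functional ranges, log-spaced for strictly
    positive rates and linear (anchored at 0) for k_minus2 / k_minus3.
    """
    gene_class = GeneClass(gene_class)
    ctx = {"chec": params.FUNCTIONAL_RANGES_CHEC,
           "chip": params.FUNCTIONAL_RANGES_CHIP,
           "gcn4": params.FUNCTIONAL_RANGES_GCN4}[context]
    if gene_class is GeneClass.STM:
        free = params.FREE_RATES_STM
        ranges = ctx
        base = base_rates or RateSet.stm(
            k7=params.K7_GCN4_CONTEXT if context == "gcn4"
            else params.K7_TERMINATOR_RELEASE)
    else:
        free = params.FREE_RATES_TFO
        ranges = dict(ctx) | params.FREE_RATE_RANGES_TFO
        base = base_rates or RateSet.tfo()
    axes = {}
    for name in free:
        lo, hi = ranges[name]
        spacing = "linear" if name in params.ZERO_ANCHORED_RATES else "log"
        axes[name] = GridAxis(lo, hi, n_points, spacing)
    return GridSpec(base_rates=base, axes=axes)


@dataclass
class ScoredModel:
    """A rate set with its similarity to the empirical vector."""

    rates: RateSet
    similarity: float
    model_region: RegionOccupancy  # l2_scaled against the empirical vector

    def __post_init__(self):
        if not -1.0 <= self.similarity <= 1.0:
            raise ValueError("similarity outside [-1, 1]")

    def tie_key(self) -> tuple:
        return tuple(getattr(self.rates, n) if getattr(self.rates, n)
                     is not None else 0.0 for n in TIE_ORDER)


@dataclass
class ModelEnsemble:
    """All models passing the similarity threshold, with functional ranges."""

    members: list[ScoredModel]
    threshold: float | None
    free_names: tuple[str, ...]
    selection_mode: str = "threshold"  # or "best_n"
    empirical: RegionOccupancy | None = None
    diagnostic: list[ScoredModel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def functional_ranges(self) -> dict[str, tuple[float, float]]:
        return functional_ranges(self)

    @property
    def best(self) -> ScoredModel:
        if not self.members:
            raise ValueError("ensemble is empty")
        return max(self.members, key=lambda m: m.similarity)

    def mean_region(self) -> RegionOccupancy:
        """Ensemble-average predicted region vector (as displayed in the
        model/data bar comparisons)."""
        if not self.members:
            raise ValueError("ensemble is empty")
        vals = np.mean([m.model_region.values for m in self.members], axis=0)
        ses = np.std([m.model_region.values for m in self.members],
                     axis=0, ddof=1) / np.sqrt(len(self.members)) \
            if len(self.members) > 1 else np.zeros_like(vals)
        ref = self.members[0].model_region
        return RegionOccupancy(gene_class=ref.gene_class, values=vals, se=ses,
                               units=ref.units,
                               scaling_state=ref.scaling_state)

    # -- serialization ----------------------------------------------------
    def to_json(self, path, *, config: dict | None = None) -> None:
        def member(m):
            return {"rates": m.rates.to_dict(), "similarity": m.similarity,
                    "model_region": m.model_region.values.tolist()}
        doc = {
            "selection_mode": self.selection_mode,
            "threshold": self.threshold,
            "free_names": list(self.free_names),
            "n_members": len(self.members),
            "functional_ranges": {k: list(v) for k, v in
                                  (functional_ranges(self) if self.members
                                   else {}).items()},
            "members": [member(m) for m in self.members],
            "diagnostic": [member(m) for m in self.diagnostic],
            "empirical": None if self.empirical is None else {
                "gene_class": self.empirical.gene_class.value,
                "values": self.empirical.values.tolist(),
                "units": self.empirical.units},
            "config": config or {},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "ModelEnsemble":
        d = json.loads(Path(path).read_text())
        emp = None
        if d.get("empirical"):
            emp = RegionOccupancy(gene_class=d["empirical"]["gene_class"],
                                  values=np.array(d["empirical"]["values"]),
                                  units=d["empirical"].get("units", "CPMn"))
        gc = emp.gene_class if emp is not None else None

        def member(md):
            rates = RateSet.from_dict(md["rates"])
            gene_class = gc or (GeneClass.STM if rates.k3 is None
                                else GeneClass.TFO)
            region = RegionOccupancy(gene_class=gene_class,
                                     values=np.array(md["model_region"]),
                                     units="CPMn" if emp is not None
                                     else "fraction")
            return ScoredModel(rates=rates, similarity=md["similarity"],
                               model_region=region)
        return cls(members=[member(m) for m in d["members"]],
                   threshold=d["threshold"],
                   free_names=tuple(d["free_names"]),
                   selection_mode=d["selection_mode"], empirical=emp,
                   diagnostic=[member(m) for m in d.get("diagnostic", [])])


def _score_grid(grid: GridSpec, empirical: RegionOccupancy,
                arch: GeneArchitecture, protocol: SimulationProtocol,
                engine: str = "auto") -> list[ScoredModel]:
    scored = []
    for rates in grid.rate_sets():
        occ = average_occupancy(arch, rates, protocol, engine=engine)
        region = aggregate_regions(occ)
        if region.norm() == 0:
            continue  # a dead grid point (no recruitment) can never fit
        scaled = l2_scale(region, empirical)
        sim = cosine_similarity(scaled, empirical)
        scored.append(ScoredModel(rates=rates, similarity=sim,
                                  model_region=scaled))
    return scored


def grid_search(grid: GridSpec, empirical: RegionOccupancy,
                arch: GeneArchitecture, protocol: SimulationProtocol,
                threshold: float = 0.995, engine: str = "auto"
                ) -> ModelEnsemble:
    """Simulate every grid point, score it, and keep those above threshold.

    All grid points share ``protocol.master_seed`` (common random numbers).
    An empty result is *not* an error: the ensemble comes back with zero
    members and the ten best-scoring models in ``diagnostic``, mirroring how
    poorly-fitting data are reported.
    """
    want = 4 if arch.has_uas else 3
    if len(empirical.values) != want:
        raise ValueError(f"empirical vector has {len(empirical.values)} "
                         f"regions, architecture needs {want}")
    scored = _score_grid(grid, empirical, arch, protocol, engine=engine)
    members = [m for m in scored if m.similarity > threshold]
    diagnostic = []
    if not members and scored:
        diagnostic = best_n(scored, min(10, len(scored)),
                            free_names=grid.free_names).members
    return ModelEnsemble(members=members, threshold=threshold,
                         free_names=grid.free_names,
                         selection_mode="threshold", empirical=empirical,
                         diagnostic=diagnostic)


def functional_ranges(ensemble: ModelEnsemble) -> dict[str, tuple[float, float]]:
    """Per-free-rate (min, max) across ensemble members."""
    if not ensemble.members:
        raise ValueError("functional ranges undefined for an empty ensemble")
    out = {}
    for name in ensemble.free_names:
        vals = [getattr(m.rates, name) for m in ensemble.members]
        out[name] = (float(min(vals)), float(max(vals)))
    return out


def best_n(scored: list[ScoredModel], n: int,
           free_names: tuple[str, ...] = params.FREE_RATES_STM
           ) -> ModelEnsemble:
    """Top ``n`` models by similarity (ties broken by ascending rates in
    canonical order), as an ensemble with ``selection_mode='best_n'``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(scored):
        warnings.warn(f"requested top {n} of {len(scored)} models; "
                      "returning all", stacklevel=2)
        n = len(scored)
    ranked = sorted(scored, key=lambda m: (-m.similarity,) + m.tie_key())
    return ModelEnsemble(members=ranked[:n], threshold=None,
                         free_names=tuple(free_names),
                         selection_mode="best_n")
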