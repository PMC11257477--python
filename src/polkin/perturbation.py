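"""Rate perturbations, Δ-occupancy predictions and mechanism ranking.

An experimental perturbation (degron depletion of a general transcription
factor, kinase inhibition, activator mutation) is modeled as a change to one
or more rates of a fitted ensemble.  For every ensemble member the baseline
and perturbed occupancies are simulated with *paired seeds* — identical
per-gene random substreams — so the identity perturbation gives exactly zero
change and Monte-Carlo noise largely cancels in the difference.  Candidate
mechanisms are ranked by the cosine similarity between predicted and
observed signed Δ region vectors; the published analysis judged this
agreement visually, and the numeric ranking is this package's extension.

The catalog of published perturbation parameter sets is shipped as
``data/perturbations.json``; ``load_catalog`` turns each row into a runnable
:class:`PerturbationSpec`.  Range-valued entries (re-fitted free rates) are
converted to per-member multipliers by the ratio of representative range
midpoints, so ensemble diversity is preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import params
from .fitting import ModelEnsemble, ScoredModel, cosine_similarity
from .model import GeneArchitecture, GeneClass, RateSet
from .occupancy import (REGION_LABELS_STM, REGION_LABELS_TFO, RegionOccupancy,
                        SimulationProtocol, aggregate_regions,
                        analytic_steady_state, average_occupancy)

__all__ = ["RateChange", "PerturbationSpec", "DeltaOccupancy",
           "apply_perturbation", "ensemble_delta", "score_delta",
           "rank_perturbations", "load_catalog", "single_model_ensemble"]


@dataclass(frozen=True)
class RateChange:
    """Either an absolute override (s⁻¹) or a multiplier of the baseline."""

    override: float | None = None
    multiplier: float | None = None

    def __post_init__(self):
        if (self.override is None) == (self.multiplier is None):
            raise ValueError("exactly one of override/multiplier required")
        v = self.override if self.override is not None else self.multiplier
        if v < 0:
            raise ValueError("rate changes must be nonnegative")

    def apply(self, value: float) -> float:
        return self.override if self.override is not None \
            else value * self.multiplier


@dataclass(frozen=True)
class PerturbationSpec:
    """A labeled set of rate changes (e.g. '↓k5+↑k−3')."""

    label: str
    changes: dict = field(default_factory=dict)  # rate name -> RateChange
    gene_class: GeneClass | None = None
    description: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "changes", dict(self.changes))
        if self.gene_class is not None:
            object.__setattr__(self, "gene_class", GeneClass(self.gene_class))

    @property
    def is_identity(self) -> bool:
        return not self.changes

    @classmethod
    def identity(cls, label: str = "control") -> "PerturbationSpec":
        return cls(label=label)

    @classmethod
    def multipliers(cls, label: str, **mult: float) -> "PerturbationSpec":
        return cls(label=label, changes={
            n: RateChange(multiplier=m) for n, m in mult.items()})

    @classmethod
    def overrides(cls, label: str, **over: float) -> "PerturbationSpec":
        return cls(label=label, changes={
            n: RateChange(override=v) for n, v in over.items()})


def apply_perturbation(rates: RateSet, spec: PerturbationSpec) -> RateSet:
    """Return a modified copy of ``rates``; untouched rates are identical.

    Touching a rate that is structurally unset for the gene class (k3 for
    STM, UAS rates for TFO) is a spec error.
    """
    changes = {}
    for name, change in spec.changes.items():
        current = getattr(rates, name)
        if current is None:
            raise ValueError(
                f"perturbation {spec.label!r} touches {name}, which is unset "
                "for this rate set's gene class")
        changes[name] = change.apply(current)
    return rates.replace(**changes) if changes else rates


@dataclass
class DeltaOccupancy:
    """Per-region signed change (perturbed − baseline), ensemble mean ± SE."""

    gene_class: GeneClass
    values: np.ndarray
    se: np.ndarray | None = None
    units: str = "fraction"

    def __post_init__(self):
        self.gene_class = GeneClass(self.gene_class)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("delta length does not match gene class")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)

    @property
    def labels(self) -> tuple[str, ...]:
        return (REGION_LABELS_STM if self.gene_class is GeneClass.STM
                else REGION_LABELS_TFO)

    def __getitem__(self, region: str) -> float:
        return float(self.values[self.labels.index(region)])


def _member_regions(rates: RateSet, arch: GeneArchitecture,
                    protocol: SimulationProtocol, method: str,
                    engine: str) -> RegionOccupancy:
    if method == "analytic":
        return aggregate_regions(analytic_steady_state(arch, rates))
    return aggregate_regions(average_occupancy(arch, rates, protocol,
                                               engine=engine))


def ensemble_delta(ensemble: ModelEnsemble, spec: PerturbationSpec,
                   arch: GeneArchitecture, protocol: SimulationProtocol,
                   method: str = "simulate", engine: str = "auto"
                   ) -> DeltaOccupancy:
    """Predicted Δ region occupancy for a perturbation, averaged over the
    ensemble.

    For each member, baseline and perturbed populations are simulated with
    the same master seed (paired per-gene substreams).  Both vectors are
    scaled by the member's baseline L2 factor against the ensemble's
    empirical vector (if it has one), so Δ is in empirical units.  With
    ``method='analytic'`` the exact stationary occupancies are used instead
    of simulation (no Monte-Carlo error; used by the test oracle).
    """
    if not ensemble.members:
        raise ValueError("cannot perturb an empty ensemble")
    deltas = []
    for member in ensemble.members:
        base = _member_regions(member.rates, arch, protocol, method, engine)
        pert_rates = apply_perturbation(member.rates, spec)
        pert = _member_regions(pert_rates, arch, protocol, method, engine)
        if ensemble.empirical is not None and base.norm() > 0:
            factor = ensemble.empirical.norm() / base.norm()
        else:
            factor = 1.0
        deltas.append((pert.values - base.values) * factor)
    deltas = np.array(deltas)
    mean = deltas.mean(axis=0)
    se = deltas.std(axis=0, ddof=1) / np.sqrt(len(deltas)) \
        if len(deltas) > 1 else np.zeros_like(mean)
    units = ("fraction" if ensemble.empirical is None
             else ensemble.empirical.units)
    return DeltaOccupancy(gene_class=arch.gene_class, values=mean, se=se,
                          units=units)


def score_delta(model_delta: DeltaOccupancy,
                empirical_delta: DeltaOccupancy) -> float:
    """Cosine similarity between signed Δ vectors, in [−1, 1]."""
    return cosine_similarity(model_delta.values, empirical_delta.values)


def rank_perturbations(candidates: list[PerturbationSpec],
                       empirical_delta: DeltaOccupancy,
                       ensemble: ModelEnsemble, arch: GeneArchitecture,
                       protocol: SimulationProtocol, method: str = "simulate",
                       engine: str = "auto"
                       ) -> list[tuple[PerturbationSpec, float]]:
    """Score every candidate mechanism against the observed Δ and sort by
    descending score (ties broken by label)."""
    if not candidates:
        raise ValueError("need at least one candidate perturbation")
    scored = []
    for spec in candidates:
        delta = ensemble_delta(ensemble, spec, arch, protocol, method=method,
                               engine=engine)
        scored.append((spec, score_delta(delta, empirical_delta)))
    return sorted(scored, key=lambda t: (-t[1], t[0].label))


# ---------------------------------------------------------------------------
# Published perturbation catalog
# ---------------------------------------------------------------------------

def _representative(lo: float, hi: float) -> float:
    return 0.5 * (lo + hi) if lo == 0 else (lo * hi) ** 0.5


def load_catalog(path=None) -> dict[str, PerturbationSpec]:
    """Load the published perturbation table as runnable specs.

    Keys are ``{experiment}_{class}_{model}``, e.g. ``kin28_inhibition_stm_2``.
    Point entries become overrides.  Range entries (re-fitted free rates)
    become multipliers: representative midpoint of the perturbed range over
    the representative midpoint of the baseline context range.
    """
    if path is None:
        text = (resources.files("polkin") / "data" /
                "perturbations.json").read_text()
    else:
        text = Path(path).read_text()
    doc = json.loads(text)
    out = {}
    for row in doc["experiments"]:
        ctx = doc["contexts"][row["context"]]
        changes = {}
        for name, cell in row["changes"].items():
            if "override" in cell:
                changes[name] = RateChange(override=cell["override"])
            else:
                lo, hi = cell["range"]
                base_lo, base_hi = ctx["free_ranges"][name]
                mult = (_representative(lo, hi) /
                        _representative(base_lo, base_hi))
                changes[name] = RateChange(multiplier=mult)
        key = (f"{row['experiment']}_{row['gene_class'].lower()}"
               f"_{row['model']}")
        out[key] = PerturbationSpec(
            label=key, changes=changes, gene_class=row["gene_class"],
            description=row["description"],
            meta={"context": row["context"], "table_cells": row["changes"]})
    return out


def catalog_candidates(catalog: dict[str, PerturbationSpec],
                       experiment: str, gene_class: GeneClass
                       ) -> list[PerturbationSpec]:
    """All catalog specs for one experiment and gene class, in model order."""
    gene_class = GeneClass(gene_class)
    return [s for key, s in sorted(catalog.items())
            if key.startswith(f"{experiment}_{gene_class.value.lower()}_")]


def single_model_ensemble(rates: RateSet,
                          empirical: RegionOccupancy | None = None,
                          free_names=params.FREE_RATES_STM) -> ModelEnsemble:
    """Wrap one rate set as a 1-member ensemble (handy for perturbation
    what-if runs without a prior grid search)."""
    region = RegionOccupancy(
        gene_class=GeneClass.STM if rates.k3 is None else GeneClass.TFO,
        values=np.ones(4 if rates.k3 is None else 3))
    member = ScoredModel(rates=rates, similarity=1.0, model_region=region)
    return ModelEnsemble(members=[member], threshold=None,
                         free_names=tuple(free_names),
                         selection_mode="best_n", empirical=empirical)
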