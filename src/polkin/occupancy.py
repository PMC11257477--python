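"""From single-gene traces to steady-state region occupancy.

The experimental observable is the average RNAPII signal over four gene
regions (UAS, promoter, transcript, 3'UTR) across a large population of
cells.  The model analogue averages many independent single-gene simulations
(``average_occupancy``), collapses the transcript bins to one value
(``aggregate_regions``) and rescales the model vector to the magnitude of the
empirical one (``l2_scale``) before cosine comparison.

``analytic_steady_state`` is an exact oracle: the full exclusion process on
one gene is a finite continuous-time Markov chain (promoter substates ×
transcript-bin configurations × UAS/terminator flags, ≈10⁴ states for the
default architecture), so its stationary distribution can be solved as a
sparse linear system with no Monte-Carlo error.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import breadth_first_order, connected_components

from . import _kernel
from .model import GeneArchitecture, GeneClass, RateSet, _enumerate_transitions

__all__ = [
    "SimulationProtocol", "OccupancyVector", "RegionOccupancy", "ScalingState",
    "average_occupancy", "aggregate_regions", "l2_scale",
    "analytic_steady_state", "REGION_LABELS_STM", "REGION_LABELS_TFO",
]

REGION_LABELS_STM = ("UAS", "promoter", "transcript", "3'UTR")
REGION_LABELS_TFO = ("promoter", "transcript", "3'UTR")


class ScalingState(str, enum.Enum):
    RAW = "raw"
    L2_SCALED = "l2_scaled"


@dataclass(frozen=True)
class SimulationProtocol:
    """How a population-average occupancy is produced.

    ``n_genes`` defaults to 1000 — a desk-scale stand-in for the 100,000
    independent gene copies used for publication-quality averages; standard
    errors scale as 1/√n_genes, nothing else changes.
    """

    total_time: float = 1000.0
    record_window: float = 60.0
    n_genes: int = 1000
    master_seed: int = 0

    def __post_init__(self):
        if self.record_window > self.total_time:
            raise ValueError("record_window must not exceed total_time")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class OccupancyVector:
    """Per-compartment mean occupancy over a gene population (fractions)."""

    arch: GeneArchitecture
    values: np.ndarray
    se: np.ndarray
    n_genes: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        n = self.arch.n_compartments
        if self.values.shape != (n,) or self.se.shape != (n,):
            raise ValueError("occupancy length does not match architecture")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("occupancy fractions must lie in [0, 1]")
        if (self.se < 0).any():
            raise ValueError("standard errors must be >= 0")

    @property
    def labels(self) -> list[str]:
        return self.arch.compartment_labels


@dataclass
class RegionOccupancy:
    """The 3/4-element region vector entering the cosine comparison.

    STM vectors are (UAS, promoter, transcript, 3'UTR); TFO vectors drop the
    UAS.  ``units`` is free-form ("fraction" for model output, "CPMn" for
    sequencing-derived or synthetic-empirical vectors).
    """

    gene_class: GeneClass
    values: np.ndarray
    se: np.ndarray | None = None
    units: str = "fraction"
    scaling_state: ScalingState = ScalingState.RAW

    def __post_init__(self):
        self.gene_class = GeneClass(self.gene_class)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError(
                f"{self.gene_class.value} region vector must have "
                f"{len(self.labels)} entries")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.values.shape:
                raise ValueError("se shape mismatch")
        self.scaling_state = ScalingState(self.scaling_state)

    @property
    def labels(self) -> tuple[str, ...]:
        return (REGION_LABELS_STM if self.gene_class is GeneClass.STM
                else REGION_LABELS_TFO)

    def norm(self) -> float:
        return float(np.linalg.norm(self.values))

    # -- I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"region": self.labels, "value": self.values})
        df["se"] = self.se if self.se is not None else np.nan
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, gene_class=None, units="CPMn") -> "RegionOccupancy":
        df = pd.read_csv(path, sep="\t")
        df["region"] = df["region"].astype(str)
        if gene_class is None:
            gene_class = (GeneClass.STM if "UAS" in set(df["region"])
                          else GeneClass.TFO)
        labels = (REGION_LABELS_STM if GeneClass(gene_class) is GeneClass.STM
                  else REGION_LABELS_TFO)
        df = df.set_index("region").loc[list(labels)]
        se = df["se"].to_numpy() if "se" in df and df["se"].notna().all() else None
        return cls(gene_class=gene_class, values=df["value"].to_numpy(),
                   se=se, units=units)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "gene_class": self.gene_class.value,
            "regions": list(self.labels),
            "values": self.values.tolist(),
            "se": None if self.se is None else self.se.tolist(),
            "units": self.units,
            "scaling_state": self.scaling_state.value,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "RegionOccupancy":
        d = json.loads(Path(path).read_text())
        return cls(gene_class=d["gene_class"], values=np.array(d["values"]),
                   se=None if d["se"] is None else np.array(d["se"]),
                   units=d["units"], scaling_state=d["scaling_state"])


# ---------------------------------------------------------------------------
# Monte-Carlo population average
# ---------------------------------------------------------------------------

def average_occupancy(arch: GeneArchitecture, rates: RateSet,
                      protocol: SimulationProtocol,
                      engine: str = "auto") -> OccupancyVector:
    """Mean compartment occupancy over ``protocol.n_genes`` independent genes.

    Deterministic for a given ``protocol.master_seed``: per-gene substreams
    are derived from the master seed, so splitting the gene population across
    batches cannot change the result.  Standard errors are the between-gene
    standard deviation over √n (within-trace autocorrelation is not
    corrected; see the methods note).
    """
    occ, _ = _kernel.simulate_batch(
        arch, rates, protocol.n_genes, protocol.master_seed,
        total_time=protocol.total_time, record_window=protocol.record_window,
        engine=engine)
    mean = occ.mean(axis=0)
    se = occ.std(axis=0, ddof=1) / np.sqrt(protocol.n_genes) \
        if protocol.n_genes > 1 else np.zeros(occ.shape[1])
    return OccupancyVector(arch=arch, values=mean, se=se,
                           n_genes=protocol.n_genes)


def aggregate_regions(occ: OccupancyVector) -> RegionOccupancy:
    """Collapse the compartment vector to the 3/4-region vector.

    The transcript value is the arithmetic mean over the transcript bins
    (bins are identical in length, so this equals per-bp mean occupancy);
    the terminator compartment is reported as the 3'UTR.  SEs for the
    transcript assume independent bins, a slight underestimate because one
    polymerase visits every bin.
    """
    arch = occ.arch
    i0 = 1 if arch.has_uas else 0
    tx = occ.values[i0 + 1: i0 + 1 + arch.n_transcript_bins]
    tx_se = occ.se[i0 + 1: i0 + 1 + arch.n_transcript_bins]
    vals = ([occ.values[0]] if arch.has_uas else []) + [
        occ.values[i0], tx.mean(), occ.values[-1]]
    ses = ([occ.se[0]] if arch.has_uas else []) + [
        occ.se[i0], float(np.sqrt((tx_se ** 2).sum()) / len(tx)), occ.se[-1]]
    return RegionOccupancy(gene_class=arch.gene_class, values=np.array(vals),
                           se=np.array(ses), units="fraction")


def l2_scale(model: RegionOccupancy, empirical: RegionOccupancy
             ) -> RegionOccupancy:
    """Rescale the model vector to the L2 magnitude of the empirical one.

    Approximates the unit conversion from occupancy fraction to CPMn; it does
    not change the direction of the vector, so cosine similarity is
    unaffected.
    """
    if len(model.values) != len(empirical.values):
        raise ValueError("model and empirical vectors differ in length")
    nm = model.norm()
    if nm == 0:
        raise ValueError("cannot L2-scale an all-zero model vector")
    factor = empirical.norm() / nm
    return RegionOccupancy(
        gene_class=model.gene_class, values=model.values * factor,
        se=None if model.se is None else model.se * factor,
        units=empirical.units, scaling_state=ScalingState.L2_SCALED)


# ---------------------------------------------------------------------------
# Exact stationary distribution (testing oracle)
# ---------------------------------------------------------------------------

def _state_index(u, p, bmask, t, n_bins):
    return ((u * 3 + p) * (1 << n_bins) + bmask) * 2 + t


def analytic_steady_state(arch: GeneArchitecture, rates: RateSet
                          ) -> OccupancyVector:
    """Exact stationary compartment occupancies of the exclusion CTMC.

    Enumerates the full state space, restricts to the states reachable from
    the empty gene, finds the terminal communicating class and solves
    πQ = 0 on it.  For reducible chains (e.g. ``k7 = 0`` with inflow) the
    terminal class is absorbing and the long-run occupancy of that class is
    returned.  Raises if the reachable chain has more than one terminal
    class (stationary occupancy would depend on hitting probabilities).
    """
    rates.validate_for(arch)
    n_bins = arch.n_transcript_bins
    is_stm = arch.has_uas
    k = rates.as_array(arch)
    n_u = 2 if is_stm else 1
    n_states = n_u * 3 * (1 << n_bins) * 2

    rows, cols, vals = [], [], []
    for u in range(n_u):
        for p in range(3):
            for bmask in range(1 << n_bins):
                bins = tuple((bmask >> i) & 1 for i in range(n_bins))
                for t in range(2):
                    i = _state_index(u, p, bmask, t, n_bins)
                    for _, a, (u2, p2, b2, t2) in _enumerate_transitions(
                            u, p, bins, t, k, is_stm, n_bins):
                        m2 = sum(b << j for j, b in enumerate(b2))
                        j2 = _state_index(u2, p2, m2, t2, n_bins)
                        rows.append(i)
                        cols.append(j2)
                        vals.append(a)
    R = sp.csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))

    start = _state_index(0, 0, 0, 0, n_bins)
    reach = breadth_first_order(R, start, return_predecessors=False)
    reach = np.asarray(reach)
    sub = R[reach][:, reach].tocsr()
    n_scc, labels = connected_components(sub, connection="strong")
    # terminal SCCs: no edge leaving the class
    leaving = np.zeros(n_scc, dtype=bool)
    coo = sub.tocoo()
    for i, j in zip(coo.row, coo.col):
        if labels[i] != labels[j]:
            leaving[labels[i]] = True
    terminal = np.flatnonzero(~leaving)
    if len(terminal) != 1:
        raise ValueError("chain has multiple terminal classes; stationary "
                         "occupancy is not unique")
    members = np.flatnonzero(labels == terminal[0])
    C = sub[members][:, members].tocsc()
    m = len(members)
    if m == 1:
        pi = np.ones(1)
    else:
        # Pin π(state 0) = 1, drop its balance equation, solve the remaining
        # sparse system, then normalize.  (Replacing an equation with the
        # dense normalization row would destroy sparsity in the LU factors.)
        Q = C - sp.diags(np.asarray(C.sum(axis=1)).ravel())
        QT = Q.T.tocsr()
        keep = np.arange(1, m)
        A = QT[keep][:, keep].tocsc()
        b = -np.asarray(QT[keep][:, [0]].todense()).ravel()
        x = sp.linalg.spsolve(A, b)
        pi = np.concatenate([[1.0], np.asarray(x).ravel()])
        pi = np.maximum(pi, 0.0)
        pi /= pi.sum()

    occ = np.zeros(arch.n_compartments)
    global_idx = reach[members]
    for w, gi in zip(pi, global_idx):
        t = gi % 2
        rest = gi // 2
        bmask = rest % (1 << n_bins)
        rest //= 1 << n_bins
        p = rest % 3
        u = rest // 3
        c = 0
        if is_stm:
            occ[c] += w * u
            c += 1
        occ[c] += w * (1 if p > 0 else 0)
        for i in range(n_bins):
            occ[c + 1 + i] += w * ((bmask >> i) & 1)
        occ[-1] += w * t
    return OccupancyVector(arch=arch, values=occ,
                           se=np.zeros(arch.n_compartments), n_genes=0)
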