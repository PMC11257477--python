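"""Stochastic model of the RNAPII transcription cycle on a discretized gene.

A gene is a row of 120 bp compartments: an optional UAS (STM genes only), a
promoter, ``n`` transcript bins (default 10, i.e. a 1200 bp transcript) and a
terminator.  Polymerases move through the compartments as a continuous-time
Markov jump process with at most one RNAPII per compartment: a move into an
occupied compartment is *disabled* (propensity zero), the standard exclusion
(TASEP-like) convention, rather than attempted and rejected.

The promoter is a two-substate machine.  An RNAPII arrives (by transfer from
the UAS at k2 for STM genes, or directly at k3 for TFO genes) into the
``AWAITING_TFIIH`` substate, where it may dissociate (k_minus3), revert to the
UAS (k_minus2, STM only, and only if the UAS is empty), or bind TFIIH (k4).
After TFIIH arrival (``PIC_COMPLETE``) the only exit is initiation (k5), which
waits if the first transcript bin is occupied; k4–k7 are irreversible.

This module holds the domain types, the transition enumerator, a single
Gillespie step and a pure-Python single-gene simulator.  The enumerator is
shared with the exact stationary-distribution oracle in
:mod:`polkin.occupancy`; large batches go through the compiled kernel in
:mod:`polkin._kernel`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import params

__all__ = [
    "GeneClass", "PromoterState", "GeneArchitecture", "RateSet", "GeneState",
    "GeneTrace", "elongation_hop_rate", "enabled_transitions",
    "gillespie_step", "simulate_gene", "ABSORBED",
]

#: Sentinel transition id returned when no transition is enabled.
ABSORBED = "absorbed"

RATE_NAMES = ("k1", "k_minus1", "k2", "k_minus2", "k3", "k_minus3",
              "k4", "k5", "k6_speed", "k7")
#: Rates meaningful only for one gene class.
STM_ONLY_RATES = ("k1", "k_minus1", "k2", "k_minus2")
TFO_ONLY_RATES = ("k3",)


class GeneClass(str, enum.Enum):
    """STM genes recruit RNAPII via the UAS; TFO genes directly at the promoter."""
    STM = "STM"
    TFO = "TFO"


class PromoterState(enum.IntEnum):
    EMPTY = 0
    AWAITING_TFIIH = 1
    PIC_COMPLETE = 2


@dataclass(frozen=True)
class GeneArchitecture:
    """Compartment layout of the model gene.

    Parameters
    ----------
    gene_class : GeneClass
        STM (has a UAS compartment) or TFO (no UAS).
    n_transcript_bins : int
        Number of identical transcript compartments (default 10).
    bin_length : float
        Compartment length in bp (default 120), so the default transcript is
        1200 bp — the median length of a transcribed yeast gene.
    """

    gene_class: GeneClass = GeneClass.STM
    n_transcript_bins: int = 10
    bin_length: float = 120.0

    def __post_init__(self):
        object.__setattr__(self, "gene_class", GeneClass(self.gene_class))
        if self.n_transcript_bins < 1:
            raise ValueError("n_transcript_bins must be >= 1")
        if self.bin_length <= 0:
            raise ValueError("bin_length must be > 0")

    @property
    def has_uas(self) -> bool:
        return self.gene_class is GeneClass.STM

    @property
    def transcript_length(self) -> float:
        return self.n_transcript_bins * self.bin_length

    @property
    def n_compartments(self) -> int:
        """UAS (if any) + promoter + transcript bins + terminator."""
        return int(self.has_uas) + 1 + self.n_transcript_bins + 1

    @property
    def compartment_labels(self) -> list[str]:
        labels = ["UAS"] if self.has_uas else []
        labels.append("promoter")
        labels.extend(f"tx_{i + 1}" for i in range(self.n_transcript_bins))
        labels.append("terminator")
        return labels


def elongation_hop_rate(k6_speed: float, bin_length: float) -> float:
    """Convert an elongation speed (bp·min⁻¹) to a per-compartment hop rate (s⁻¹).

    >>> round(elongation_hop_rate(1000, 120), 5)
    0.13889
    """
    if k6_speed <= 0 or bin_length <= 0:
        raise ValueError("k6_speed and bin_length must be positive")
    return (k6_speed / 60.0) / bin_length


@dataclass(frozen=True)
class RateSet:
    """The kinetic constants of the transcription cycle (s⁻¹; k6 as bp·min⁻¹).

    STM rate sets leave ``k3`` unset (None); TFO rate sets leave the four
    UAS rates unset.  Unset rates are structurally absent from the model,
    not merely zero.
    """

    k1: float | None = None
    k_minus1: float | None = None
    k2: float | None = None
    k_minus2: float | None = None
    k3: float | None = None
    k_minus3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6_speed: float = params.K6_ELONGATION_SPEED
    k7: float = 0.0

    def __post_init__(self):
        for name in RATE_NAMES:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.k6_speed is None or self.k6_speed <= 0:
            raise ValueError("k6_speed must be positive")

    # -- construction -----------------------------------------------------
    @classmethod
    def stm(cls, *, k1=params.K1_UAS_ASSOCIATION,
            k_minus1=params.K_MINUS1_UAS_DISSOCIATION,
            k2=None, k_minus2=None, k_minus3=None, k4=None,
            k5=params.K5_INITIATION, k6_speed=params.K6_ELONGATION_SPEED,
            k7=params.K7_TERMINATOR_RELEASE) -> "RateSet":
        """An STM rate set; free rates default to representative midpoints of
        the fitted functional ranges."""
        rep = params.representative_free_rates()
        return cls(k1=k1, k_minus1=k_minus1,
                   k2=rep["k2"] if k2 is None else k2,
                   k_minus2=rep["k_minus2"] if k_minus2 is None else k_minus2,
                   k3=None,
                   k_minus3=rep["k_minus3"] if k_minus3 is None else k_minus3,
                   k4=rep["k4"] if k4 is None else k4,
                   k5=k5, k6_speed=k6_speed, k7=k7)

    @classmethod
    def tfo(cls, *, k3=params.K3_PROMOTER_RECRUITMENT,
            k_minus3=None, k4=None, k5=params.K5_INITIATION,
            k6_speed=params.K6_ELONGATION_SPEED,
            k7=params.K7_TERMINATOR_RELEASE) -> "RateSet":
        rep = params.representative_free_rates()
        return cls(k1=None, k_minus1=None, k2=None, k_minus2=None, k3=k3,
                   k_minus3=rep["k_minus3"] if k_minus3 is None else k_minus3,
                   k4=rep["k4"] if k4 is None else k4,
                   k5=k5, k6_speed=k6_speed, k7=k7)

    # -- validation / views ----------------------------------------------
    def validate_for(self, arch: GeneArchitecture) -> None:
        if arch.has_uas:
            missing = [n for n in STM_ONLY_RATES if getattr(self, n) is None]
            if missing:
                raise ValueError(f"STM rate set requires {missing}")
            if self.k3 is not None:
                raise ValueError("STM rate sets must leave k3 unset")
        else:
            if self.k3 is None:
                raise ValueError("TFO rate set requires k3")
            extra = [n for n in STM_ONLY_RATES if getattr(self, n) is not None]
            if extra:
                raise ValueError(f"TFO rate sets must leave {extra} unset")

    def hop_rate(self, bin_length: float) -> float:
        return elongation_hop_rate(self.k6_speed, bin_length)

    def as_array(self, arch: GeneArchitecture) -> np.ndarray:
        """Dense rate vector for the compiled kernel:
        [k1, k_minus1, k2, k_minus2, k3, k_minus3, k4, k5, hop, k7],
        unset rates as 0 (the gene-class flag disables their transitions)."""
        self.validate_for(arch)
        g = lambda n: getattr(self, n) or 0.0
        return np.array([g("k1"), g("k_minus1"), g("k2"), g("k_minus2"),
                         g("k3"), self.k_minus3, self.k4, self.k5,
                         self.hop_rate(arch.bin_length), self.k7])

    def replace(self, **changes) -> "RateSet":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in RATE_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        return cls(**{n: d.get(n) for n in RATE_NAMES})


@dataclass
class GeneState:
    """Instantaneous configuration of one model gene."""

    arch: GeneArchitecture
    uas_occupied: bool = False
    promoter_state: PromoterState = PromoterState.EMPTY
    transcript_bins: np.ndarray = None  # bool, length n_transcript_bins
    terminator_occupied: bool = False
    clock: float = 0.0
    event_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.transcript_bins is None:
            self.transcript_bins = np.zeros(self.arch.n_transcript_bins, dtype=bool)
        else:
            self.transcript_bins = np.asarray(self.transcript_bins, dtype=bool)
            if self.transcript_bins.shape != (self.arch.n_transcript_bins,):
                raise ValueError("transcript_bins length mismatch")
        if self.uas_occupied and not self.arch.has_uas:
            raise ValueError("TFO gene has no UAS compartment")

    @classmethod
    def empty(cls, arch: GeneArchitecture) -> "GeneState":
        return cls(arch=arch)

    @property
    def n_on_gene(self) -> int:
        """Polymerases currently on the transcript or terminator."""
        return int(self.transcript_bins.sum()) + int(self.terminator_occupied)

    def occupancy_indicators(self) -> np.ndarray:
        """0/1 per compartment; both promoter substates count as occupied."""
        parts = [float(self.uas_occupied)] if self.arch.has_uas else []
        parts.append(float(self.promoter_state != PromoterState.EMPTY))
        parts.extend(self.transcript_bins.astype(float))
        parts.append(float(self.terminator_occupied))
        return np.array(parts)


@dataclass
class GeneTrace:
    """Time-weighted occupancy of one simulated gene over the recording window."""

    arch: GeneArchitecture
    time_weighted_occupancy: np.ndarray  # fractions in [0,1], per compartment
    event_counts: dict
    recorded_interval: tuple[float, float]


# ---------------------------------------------------------------------------
# Transition enumeration (shared by the step function and the CTMC oracle)
# ---------------------------------------------------------------------------

def _enumerate_transitions(u: int, p: int, bins: tuple, t: int,
                           k: np.ndarray, is_stm: bool, n_bins: int):
    """Yield ``(transition_id, propensity, (u, p, bins, t))`` for every enabled
    transition from the compact state ``(u, p, bins, t)``.

    ``k`` is the dense array from :meth:`RateSet.as_array`.  Moves into an
    occupied compartment are disabled; k4–k7 are irreversible (no transition
    leaves PIC_COMPLETE except initiation, none moves a polymerase backward).
    """
    k1, km1, k2, km2, k3, km3, k4, k5, hop, k7 = k
    if is_stm:
        if u == 0 and k1 > 0:
            yield "uas_recruit", k1, (1, p, bins, t)
        if u == 1 and km1 > 0:
            yield "uas_loss", km1, (0, p, bins, t)
        if u == 1 and p == 0 and k2 > 0:
            yield "transfer", k2, (0, 1, bins, t)
        if p == 1 and u == 0 and km2 > 0:     # reversal blocked by occupied UAS
            yield "reversal", km2, (1, 0, bins, t)
    else:
        if p == 0 and k3 > 0:
            yield "promoter_recruit", k3, (u, 1, bins, t)
    if p == 1:
        if km3 > 0:
            yield "promoter_loss", km3, (u, 0, bins, t)
        if k4 > 0:
            yield "tfiih_arrival", k4, (u, 2, bins, t)
    if p == 2 and bins[0] == 0 and k5 > 0:
        yield "initiation", k5, (u, 0, (1,) + bins[1:], t)
    if hop > 0:
        for i in range(n_bins - 1):
            if bins[i] == 1 and bins[i + 1] == 0:
                nb = bins[:i] + (0, 1) + bins[i + 2:]
                yield f"hop_{i + 1}", hop, (u, p, nb, t)
        if bins[-1] == 1 and t == 0:
            yield "terminator_entry", hop, (u, p, bins[:-1] + (0,), 1)
    if t == 1 and k7 > 0:
        yield "release", k7, (u, p, bins, 0)


def _state_key(state: GeneState) -> tuple:
    return (int(state.uas_occupied), int(state.promoter_state),
            tuple(int(b) for b in state.transcript_bins),
            int(state.terminator_occupied))


def enabled_transitions(state: GeneState, rates: RateSet,
                        arch: GeneArchitecture) -> list[tuple[str, float]]:
    """List of ``(transition_id, propensity)`` enabled from ``state``."""
    if state.arch != arch:
        raise ValueError("state does not belong to this architecture")
    rates.validate_for(arch)
    k = rates.as_array(arch)
    u, p, bins, t = _state_key(state)
    return [(tid, a) for tid, a, _ in
            _enumerate_transitions(u, p, bins, t, k, arch.has_uas,
                                   arch.n_transcript_bins)]


_COUNTED = {"uas_recruit": "recruitments", "promoter_recruit": "recruitments",
            "initiation": "initiations", "release": "completions"}


def _apply(state: GeneState, tid: str, nxt: tuple) -> GeneState:
    u, p, bins, t = nxt
    counts = dict(state.event_counts)
    counts[tid] = counts.get(tid, 0) + 1
    if tid in _COUNTED:
        counts[_COUNTED[tid]] = counts.get(_COUNTED[tid], 0) + 1
    return GeneState(arch=state.arch, uas_occupied=bool(u),
                     promoter_state=PromoterState(p),
                     transcript_bins=np.array(bins, dtype=bool),
                     terminator_occupied=bool(t), clock=state.clock,
                     event_counts=counts)


def gillespie_step(state: GeneState, rates: RateSet, arch: GeneArchitecture,
                   rng: np.random.Generator):
    """One exact stochastic-simulation step.

    Returns ``(transition_id, waiting_time, next_state)``.  The waiting time
    is exponential with rate equal to the total propensity and the transition
    is chosen with probability proportional to its propensity.  If nothing is
    enabled, returns ``(ABSORBED, inf, state)``.
    """
    trans = enabled_transitions(state, rates, arch)
    if not trans:
        return ABSORBED, math.inf, state
    props = np.array([a for _, a in trans])
    total = props.sum()
    dt = rng.exponential(1.0 / total)
    idx = int(np.searchsorted(np.cumsum(props), rng.random() * total,
                              side="right"))
    idx = min(idx, len(trans) - 1)
    tid = trans[idx][0]
    k = rates.as_array(arch)
    u, p, bins, t = _state_key(state)
    for cand_tid, _, nxt in _enumerate_transitions(
            u, p, bins, t, k, arch.has_uas, arch.n_transcript_bins):
        if cand_tid == tid:
            new = _apply(state, tid, nxt)
            new.clock = state.clock + dt
            return tid, dt, new
    raise AssertionError("chosen transition vanished")  # pragma: no cover


def simulate_gene(arch: GeneArchitecture, rates: RateSet,
                  total_time: float = 1000.0, record_window: float = 60.0,
                  rng: np.random.Generator | None = None,
                  check_invariants: bool = False) -> GeneTrace:
    """Simulate one gene from the empty state and return its occupancy trace.

    The gene runs for ``total_time`` seconds (default 1000 s, long enough to
    reach steady state from empty) and compartment indicators are integrated
    over the final ``record_window`` seconds (default 60 s, matching the
    length of the chromatin-cleavage reaction the model is compared against).
    Intervals straddling the window boundary are split exactly.
    """
    if record_window > total_time:
        raise ValueError("record_window must not exceed total_time")
    rng = np.random.default_rng() if rng is None else rng
    rates.validate_for(arch)
    state = GeneState.empty(arch)
    rec_start = total_time - record_window
    acc = np.zeros(arch.n_compartments)
    t = 0.0
    while t < total_time:
        tid, dt, nxt = gillespie_step(state, rates, arch, rng)
        t2 = min(t + dt, total_time)
        lo, hi = max(t, rec_start), min(t2, total_time)
        if hi > lo:
            acc += state.occupancy_indicators() * (hi - lo)
        if t + dt >= total_time or tid == ABSORBED:
            break
        if check_invariants:
            ind = nxt.occupancy_indicators()
            assert ind.max() <= 1.0, "exclusion violated"
            assert (nxt.event_counts.get("completions", 0)
                    <= nxt.event_counts.get("initiations", 0))
        t, state = t + dt, nxt
    counts = dict(state.event_counts)
    counts.setdefault("recruitments", 0)
    counts.setdefault("initiations", 0)
    counts.setdefault("completions", 0)
    return GeneTrace(arch=arch, time_weighted_occupancy=acc / record_window,
                     event_counts=counts,
                     recorded_interval=(rec_start, total_time))
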