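"""Published and fitted kinetic constants for the yeast RNAPII transcription cycle.

Rates are first-order constants in s⁻¹ except the elongation speed, which is
kept in bp·min⁻¹ and converted to a per-compartment hop rate at simulation
time.  ``FUNCTIONAL_RANGES_*`` hold the min–max of each free rate across the
fitted model ensembles for the three fitting contexts (ChEC-seq2 under
standard growth, ChIP-seq under standard growth, and the amino-acid-starvation
Gcn4 experiment); the fixed rates come from published single-molecule and
kinetic measurements.
"""

from __future__ import annotations

# Fixed (published) rates, s⁻¹ unless noted.
K1_UAS_ASSOCIATION = 0.002
K1_PUBLISHED_RANGE = (0.0019, 0.0027)
K_MINUS1_UAS_DISSOCIATION = 0.003
K_MINUS1_PUBLISHED_RANGE = (0.001, 0.005)
K3_PROMOTER_RECRUITMENT = 0.002          # no direct measurement; k1 reused
K3_PLAUSIBLE_RANGE = K1_PUBLISHED_RANGE  # by the same convention
K5_INITIATION = 0.1                      # from TFIIH residency
K6_ELONGATION_SPEED = 1000.0             # bp/min, midpoint of 1-3 kb/min
K7_TERMINATOR_RELEASE = 0.037
K7_PUBLISHED_RANGE = (0.009, 0.034)
K7_GCN4_CONTEXT = 0.0614

#: Free-rate functional ranges (min, max over ensemble members), per context.
FUNCTIONAL_RANGES_CHEC = {
    "k2": (0.03, 0.2),
    "k_minus2": (0.0, 0.15),
    "k_minus3": (0.0, 0.03),
    "k4": (0.0075, 0.09),
}
FUNCTIONAL_RANGES_CHIP = {
    "k2": (0.06, 0.2),
    "k_minus2": (0.0, 0.18),
    "k_minus3": (0.0, 0.03),
    "k4": (0.075, 0.2),
}
FUNCTIONAL_RANGES_GCN4 = {
    "k2": (0.03, 0.2),
    "k_minus2": (0.0, 0.04),
    "k_minus3": (0.0, 0.03),
    "k4": (0.01, 0.15),
}

#: Free rates per gene class under the default fitting setup.
FREE_RATES_STM = ("k2", "k_minus2", "k_minus3", "k4")
FREE_RATES_TFO = ("k3", "k_minus3", "k4")

#: Ranges used when a free rate must be sampled or gridded and the ensemble
#: functional range does not define it (k3 has no fitted range of its own).
FREE_RATE_RANGES_TFO = {
    "k3": K3_PLAUSIBLE_RANGE,
    "k_minus3": FUNCTIONAL_RANGES_CHEC["k_minus3"],
    "k4": FUNCTIONAL_RANGES_CHEC["k4"],
}

#: Rates whose fitted range includes zero; grids over these are linear so the
#: boundary value 0 is representable (log grids cannot reach it).
ZERO_ANCHORED_RATES = frozenset({"k_minus2", "k_minus3"})


def _geomid(lo: float, hi: float) -> float:
    return (lo * hi) ** 0.5


def _mid(lo: float, hi: float) -> float:
    return 0.5 * (lo + hi)


def representative_free_rates(context: dict[str, tuple[float, float]] | None = None
                              ) -> dict[str, float]:
    """A single representative rate per free dimension: the geometric midpoint
    of the functional range for strictly positive rates, the arithmetic
    midpoint for zero-anchored ones.  Used for default rate sets and for
    converting range-valued perturbation entries to point multipliers."""
    ranges = dict(FUNCTIONAL_RANGES_CHEC if context is None else context)
    out = {}
    for name, (lo, hi) in ranges.items():
        out[name] = _mid(lo, hi) if name in ZERO_ANCHORED_RATES or lo == 0 else _geomid(lo, hi)
    return out
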