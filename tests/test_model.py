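"""Single-gene transcription-cycle model: transitions, exclusion, stepping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polkin.model import (ABSORBED, GeneArchitecture, GeneClass, GeneState,
                          PromoterState, RateSet, elongation_hop_rate,
                          enabled_transitions, gillespie_step, simulate_gene,
                          _enumerate_transitions)


@pytest.mark.parametrize("speed, bin_len, expected", [
    (1000, 120, (1000 / 60) / 120),   # 0.13889/s
    (3000, 120, (3000 / 60) / 120),   # 0.41667/s
    (60, 60, 1 / 60),                 # 1 bp/s over 60 bp -> 60 s per bin
])
def test_elongation_speed_to_hop_rate(speed, bin_len, expected):
    assert elongation_hop_rate(speed, bin_len) == pytest.approx(expected,
                                                                rel=1e-12)


@pytest.mark.parametrize("speed, bin_len", [(0, 120), (-5, 120), (1000, 0)])
def test_hop_rate_rejects_nonpositive_inputs(speed, bin_len):
    with pytest.raises(ValueError):
        elongation_hop_rate(speed, bin_len)


class TestRateSetValidation:
    def test_stm_leaves_k3_unset(self, stm_rates):
        assert stm_rates.k3 is None

    def test_tfo_leaves_uas_rates_unset(self, tfo_rates):
        assert all(getattr(tfo_rates, n) is None
                   for n in ("k1", "k_minus1", "k2", "k_minus2"))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateSet.tfo(k3=-0.1)

    def test_class_mismatch_rejected(self, stm_rates, tfo_rates,
                                     stm_arch, tfo_arch):
        with pytest.raises(ValueError):
            stm_rates.validate_for(tfo_arch)
        with pytest.raises(ValueError):
            tfo_rates.validate_for(stm_arch)


class TestEnabledTransitions:
    def test_empty_tfo_gene_only_recruitment(self, tfo_arch, tfo_rates):
        state = GeneState.empty(tfo_arch)
        trans = enabled_transitions(state, tfo_rates, tfo_arch)
        assert trans == [("promoter_recruit", tfo_rates.k3)]

    def test_stm_uas_occupied_promoter_empty(self, stm_arch, stm_rates):
        state = GeneState.empty(stm_arch)
        state.uas_occupied = True
        trans = dict(enabled_transitions(state, stm_rates, stm_arch))
        assert trans == {"uas_loss": stm_rates.k_minus1,
                         "transfer": stm_rates.k2}

    def test_all_zero_rates_disable_everything(self, stm_arch):
        rates = RateSet(k1=0, k_minus1=0, k2=0, k_minus2=0, k_minus3=0,
                        k4=0, k5=0, k6_speed=1000, k7=0)
        state = GeneState.empty(stm_arch)
        assert enabled_transitions(state, rates, stm_arch) == []

    def test_state_from_wrong_architecture_rejected(self, stm_arch,
                                                    tfo_arch, tfo_rates):
        state = GeneState.empty(stm_arch)
        with pytest.raises(ValueError):
            enabled_transitions(state, tfo_rates, tfo_arch)

    def test_exclusion_blocks_initiation(self, tfo_arch, tfo_rates):
        state = GeneState.empty(tfo_arch)
        state.promoter_state = PromoterState.PIC_COMPLETE
        state.transcript_bins[0] = True
        ids = [t for t, _ in enabled_transitions(state, tfo_rates, tfo_arch)]
        assert "initiation" not in ids

    def test_reversal_blocked_by_occupied_uas(self, stm_arch, stm_rates):
        state = GeneState.empty(stm_arch)
        state.uas_occupied = True
        state.promoter_state = PromoterState.AWAITING_TFIIH
        ids = [t for t, _ in enabled_transitions(state, stm_rates, stm_arch)]
        assert "reversal" not in ids
        assert "transfer" not in ids  # promoter occupied


@st.composite
def random_states(draw):
    n_bins = draw(st.integers(1, 8))
    is_stm = draw(st.booleans())
    arch = GeneArchitecture(
        gene_class=GeneClass.STM if is_stm else GeneClass.TFO,
        n_transcript_bins=n_bins)
    u = draw(st.booleans()) if is_stm else False
    p = PromoterState(draw(st.integers(0, 2)))
    bins = np.array(draw(st.lists(st.booleans(), min_size=n_bins,
                                  max_size=n_bins)))
    t = draw(st.booleans())
    state = GeneState(arch=arch, uas_occupied=u, promoter_state=p,
                      transcript_bins=bins, terminator_occupied=t)
    return arch, state


@settings(max_examples=150, deadline=None, derandomize=True)
@given(random_states())
def test_transitions_preserve_polymerase_count_and_exclusion(arch_state):
    """Every transition conserves polymerases (±1 only at entry/exit) and
    never places two on one compartment; k4-k7 are irreversible."""
    arch, state = arch_state
    rates = RateSet.stm() if arch.has_uas else RateSet.tfo()
    k = rates.as_array(arch)
    u0 = int(state.uas_occupied)
    p0 = int(state.promoter_state)
    bins0 = tuple(int(b) for b in state.transcript_bins)
    t0 = int(state.terminator_occupied)
    n0 = u0 + (p0 > 0) + sum(bins0) + t0
    for tid, prop, (u, p, bins, t) in _enumerate_transitions(
            u0, p0, bins0, t0, k, arch.has_uas, arch.n_transcript_bins):
        assert prop > 0
        n1 = u + (p > 0) + sum(bins) + t
        if tid in ("uas_recruit", "promoter_recruit"):
            assert n1 == n0 + 1
        elif tid in ("uas_loss", "promoter_loss", "release"):
            assert n1 == n0 - 1
        else:
            assert n1 == n0
        assert max(bins, default=0) <= 1 and u <= 1 and t <= 1
        # irreversibility: nothing leaves PIC_COMPLETE except initiation
        if p0 == 2:
            assert tid in ("initiation",) or p == 2
        # hops move forward only
        if tid.startswith("hop_"):
            i = int(tid.split("_")[1]) - 1
            assert bins0[i] == 1 and bins0[i + 1] == 0
            assert bins[i] == 0 and bins[i + 1] == 1


class TestGillespieStep:
    def test_waiting_time_matches_exponential_law(self, tfo_arch):
        """Single enabled transition of rate r: mean waiting time = 1/r
        within 3 SE over 10^4 draws."""
        rates = RateSet.tfo(k3=0.002)
        state = GeneState.empty(tfo_arch)
        rng = np.random.default_rng(7)
        n = 10_000
        dts = np.array([gillespie_step(state, rates, tfo_arch, rng)[1]
                        for _ in range(n)])
        mean, se = dts.mean(), dts.std(ddof=1) / np.sqrt(n)
        assert abs(mean - 500.0) < 3 * se

    def test_single_transition_chosen_with_certainty(self, tfo_arch,
                                                     tfo_rates):
        state = GeneState.empty(tfo_arch)
        rng = np.random.default_rng(0)
        for _ in range(50):
            tid, _, nxt = gillespie_step(state, tfo_rates, tfo_arch, rng)
            assert tid == "promoter_recruit"
            assert nxt.promoter_state == PromoterState.AWAITING_TFIIH

    def test_equal_propensities_split_evenly(self, tfo_arch):
        """promoter_loss vs TFIIH arrival at equal rates: ~50/50."""
        rates = RateSet.tfo(k3=0.002, k_minus3=0.05, k4=0.05, k5=0)
        state = GeneState.empty(tfo_arch)
        state.promoter_state = PromoterState.AWAITING_TFIIH
        rng = np.random.default_rng(11)
        n = 10_000
        picks = sum(gillespie_step(state, rates, tfo_arch, rng)[0]
                    == "promoter_loss" for _ in range(n))
        assert abs(picks / n - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_absorbed_sentinel_when_nothing_enabled(self, stm_arch):
        rates = RateSet(k1=0, k_minus1=0, k2=0, k_minus2=0, k_minus3=0,
                        k4=0, k5=0, k6_speed=1000, k7=0)
        state = GeneState.empty(stm_arch)
        tid, dt, nxt = gillespie_step(state, rates, stm_arch,
                                      np.random.default_rng(0))
        assert tid == ABSORBED and math.isinf(dt) and nxt is state


class TestSimulateGene:
    def test_no_recruitment_gives_zero_occupancy(self, tfo_arch):
        rates = RateSet.tfo(k3=0.0)
        tr = simulate_gene(tfo_arch, rates, rng=np.random.default_rng(0))
        assert np.all(tr.time_weighted_occupancy == 0)
        assert tr.event_counts["initiations"] == 0

    def test_absorbing_terminator_fills_up(self, small_tfo_arch):
        """k7 = 0 with inflow: the terminator ends up permanently occupied."""
        rates = RateSet.tfo(k3=0.05, k_minus3=0.0, k4=0.5, k5=0.5, k7=0.0)
        tr = simulate_gene(small_tfo_arch, rates, total_time=3000.0,
                           record_window=60.0,
                           rng=np.random.default_rng(5))
        assert tr.time_weighted_occupancy[-1] == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self, tfo_arch, tfo_rates):
        t1 = simulate_gene(tfo_arch, tfo_rates,
                           rng=np.random.default_rng(99))
        t2 = simulate_gene(tfo_arch, tfo_rates,
                           rng=np.random.default_rng(99))
        assert np.array_equal(t1.time_weighted_occupancy,
                              t2.time_weighted_occupancy)
        assert t1.event_counts == t2.event_counts

    def test_record_window_longer_than_run_rejected(self, tfo_arch,
                                                    tfo_rates):
        with pytest.raises(ValueError):
            simulate_gene(tfo_arch, tfo_rates, total_time=30.0,
                          record_window=60.0)

    def test_occupancy_fractions_bounded(self, stm_arch, stm_rates):
        tr = simulate_gene(stm_arch, stm_rates, check_invariants=True,
                           rng=np.random.default_rng(3))
        occ = tr.time_weighted_occupancy
        assert np.all(occ >= 0) and np.all(occ <= 1 + 1e-12)


def test_conservation_of_polymerases(tfo_arch, tfo_rates):
    """initiations - completions = polymerases currently on transcript +
    terminator, at every step of a long trajectory."""
    state = GeneState.empty(tfo_arch)
    rng = np.random.default_rng(17)
    for _ in range(3000):
        tid, dt, state = gillespie_step(state, tfo_rates, tfo_arch, rng)
        if tid == ABSORBED:
            break
        init = state.event_counts.get("initiations", 0)
        comp = state.event_counts.get("completions", 0)
        assert init - comp == state.n_on_gene
        assert comp <= init
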