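import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from letdamage import (
    DepositionEvent,
    EventKind,
    Mechanism,
    StrandBreak,
    classify,
    direct_break_probability,
    generate_pattern,
    indirect_break_probability,
    sample_breaks,
)
from letdamage.breaks import read_breaks_tsv, write_breaks_tsv

from oracles import max_pairing_oracle


def sb(pos, strand, mech=Mechanism.DIRECT):
    return StrandBreak(pos, strand, mech)


class TestDirectBreakProbability:
    @pytest.mark.parametrize(
        "energy,expected",
        [(0.0, 0.0), (5.0, 0.0), (37.5, 1.0), (100.0, 1.0), (21.25, 0.5)],
    )
    def test_ramp_values(self, energy, expected):
        assert direct_break_probability(energy) == expected

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            direct_break_probability(-1.0)

    @given(e=st.floats(0, 200), delta=st.floats(0, 50))
    @settings(max_examples=50)
    def test_monotone_nondecreasing(self, e, delta):
        assert direct_break_probability(e + delta) >= direct_break_probability(e)

    @given(e=st.floats(5.0, 37.5))
    @settings(max_examples=50)
    def test_linear_on_ramp(self, e):
        assert direct_break_probability(e) == pytest.approx((e - 5.0) / 32.5, abs=1e-12)


class TestIndirectBreakProbability:
    def test_constant(self):
        assert indirect_break_probability() == 0.65

    def test_complement(self):
        assert 1.0 - indirect_break_probability() == pytest.approx(0.35)

    def test_monte_carlo_rate(self):
        events = [DepositionEvent(i, 0, EventKind.OH_ATTACK) for i in range(100_000)]
        breaks = sample_breaks(events, seed=11)
        assert len(breaks) / len(events) == pytest.approx(0.65, abs=0.005)


class TestSampleBreaks:
    def test_certain_energy_breaks_all(self):
        events = [DepositionEvent(i, i % 2, EventKind.ENERGY, 37.5 + i) for i in range(50)]
        breaks = sample_breaks(events, seed=0)
        assert len(breaks) == 50
        assert all(b.mechanism is Mechanism.DIRECT for b in breaks)

    def test_subthreshold_energy_breaks_none(self):
        events = [DepositionEvent(i, 0, EventKind.ENERGY, 5.0) for i in range(50)]
        assert sample_breaks(events, seed=0) == []

    def test_same_seed_identical(self):
        events = [DepositionEvent(i, 0, EventKind.ENERGY, 21.25) for i in range(100)]
        assert sample_breaks(events, seed=3) == sample_breaks(events, seed=3)

    def test_mixed_stream_matches_binomial_within_3_sigma(self):
        rng = np.random.default_rng(5)
        events = []
        expected = 0.0
        variance = 0.0
        for i in range(10_000):
            if rng.random() < 0.5:
                e = float(rng.uniform(0, 50))
                events.append(DepositionEvent(i, 0, EventKind.ENERGY, e if e > 0 else 1.0))
                p = direct_break_probability(events[-1].energy_ev)
            else:
                events.append(DepositionEvent(i, 0, EventKind.OH_ATTACK))
                p = 0.65
            expected += p
            variance += p * (1 - p)
        breaks = sample_breaks(events, seed=6)
        assert abs(len(breaks) - expected) <= 3 * math.sqrt(variance)

    def test_energy_event_requires_energy(self):
        with pytest.raises(ValueError):
            DepositionEvent(0, 0, EventKind.ENERGY)


class TestClassifyMicroExamples:
    def test_simple_dsb(self):
        tally = classify([sb(100, 0), sb(105, 1)])
        assert tally.n_dsb == 1
        assert tally.n_ssb == 0
        assert tally.n_dsb_sites == 1
        assert tally.n_dsb_clusters == 0
        assert tally.n_dsb_direct == 1

    def test_two_ssb_beyond_distance(self):
        tally = classify([sb(100, 0), sb(115, 1)])
        assert tally.n_dsb == 0
        assert tally.n_ssb == 2

    def test_boundary_distance_inclusive(self):
        assert classify([sb(100, 0), sb(110, 1)]).n_dsb == 1  # exactly 10 bp
        assert classify([sb(100, 0), sb(111, 1)]).n_dsb == 0

    def test_cluster_of_two_dsbs(self):
        breaks = [sb(100, 0), sb(102, 1), sb(120, 0), sb(121, 1)]
        tally = classify(breaks)
        assert tally.n_dsb == 2
        assert tally.n_dsb_clusters == 1
        assert tally.n_dsb_sites == 1
        assert tally.n_isolated_dsb == 0
        assert tally.n_dsb_per_cluster_mean == 2.0

    def test_cluster_chaining_is_transitive(self):
        # DSB centres at 100, 124, 148: consecutive gaps 24 <= 25, one chain
        breaks = [sb(100, 0), sb(100, 1), sb(124, 0), sb(124, 1), sb(148, 0), sb(148, 1)]
        tally = classify(breaks)
        assert tally.n_dsb == 3
        assert tally.n_dsb_clusters == 1
        assert tally.n_dsb_sites == 1
        assert tally.n_dsb_per_cluster_mean == 3.0

    def test_same_strand_never_pairs(self):
        tally = classify([sb(100, 0), sb(101, 0), sb(103, 0)])
        assert tally.n_dsb == 0
        assert tally.n_ssb == 3

    def test_hybrid_channel(self):
        tally = classify([sb(10, 0, Mechanism.DIRECT), sb(12, 1, Mechanism.INDIRECT)])
        assert tally.n_dsb == 1
        assert tally.n_dsb_hybrid == 1
        assert tally.n_dsb_direct == tally.n_dsb_indirect == 0

    def test_indirect_channel(self):
        tally = classify([sb(10, 0, Mechanism.INDIRECT), sb(12, 1, Mechanism.INDIRECT)])
        assert tally.n_dsb_indirect == 1

    def test_deduplication_counts_once_but_tallies_both_channels(self):
        breaks = [sb(50, 0, Mechanism.DIRECT), sb(50, 0, Mechanism.INDIRECT)]
        tally = classify(breaks)
        assert tally.n_sb_total == 1
        assert tally.n_sb_direct == 1
        assert tally.n_sb_indirect == 1
        assert tally.n_ssb == 1

    def test_doubly_broken_site_makes_hybrid_dsb(self):
        breaks = [
            sb(50, 0, Mechanism.DIRECT),
            sb(50, 0, Mechanism.INDIRECT),
            sb(55, 1, Mechanism.DIRECT),
        ]
        tally = classify(breaks)
        assert tally.n_dsb == 1
        assert tally.n_dsb_hybrid == 1

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify([sb(1, 0)], dsb_distance=-1)

    def test_empty_input(self):
        tally = classify([])
        assert tally.n_sb_total == 0
        assert tally.n_dsb_sites == 0
        assert math.isnan(tally.n_dsb_per_cluster_mean)


def random_breaks(rng, n, span=50):
    offset = int(rng.integers(0, 1000))
    return [
        StrandBreak(
            offset + int(rng.integers(0, span)),
            int(rng.integers(0, 2)),
            Mechanism.DIRECT if rng.random() < 0.5 else Mechanism.INDIRECT,
        )
        for _ in range(n)
    ]


class TestClassifyProperties:
    @pytest.mark.parametrize("seed", range(50))
    def test_pairing_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        breaks = random_breaks(rng, int(rng.integers(2, 13)))
        tally = classify(breaks)
        assert tally.n_dsb == max_pairing_oracle(breaks, 10)

    @pytest.mark.parametrize("seed", range(30))
    def test_conservation_and_ordering_invariants(self, seed):
        rng = np.random.default_rng(1000 + seed)
        breaks = random_breaks(rng, int(rng.integers(0, 40)), span=200)
        tally = classify(breaks)
        deduped = len({(b.position, b.strand) for b in breaks})
        assert tally.n_sb_total == deduped
        assert tally.n_sb_total == tally.n_ssb + 2 * tally.n_dsb
        assert tally.n_dsb_sites <= tally.n_dsb
        assert tally.n_dsb_clusters <= tally.n_dsb_sites
        assert tally.n_dsb_sites == tally.n_isolated_dsb + tally.n_dsb_clusters
        assert tally.n_dsb == tally.n_dsb_direct + tally.n_dsb_indirect + tally.n_dsb_hybrid
        for value in tally.as_dict().values():
            if isinstance(value, int):
                assert value >= 0

    @given(shift=st.integers(0, 10_000), seed=st.integers(0, 100))
    @settings(max_examples=40)
    def test_translation_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        breaks = random_breaks(rng, 15)
        shifted = [StrandBreak(b.position + shift, b.strand, b.mechanism) for b in breaks]
        assert classify(breaks) == classify(shifted)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=40)
    def test_strand_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        breaks = random_breaks(rng, 15)
        swapped = [StrandBreak(b.position, 1 - b.strand, b.mechanism) for b in breaks]
        assert classify(breaks) == classify(swapped)


class TestGeneratePattern:
    def test_same_seed_identical(self):
        a = generate_pattern(20, 2, 5.0, 10_000, seed=4)
        b = generate_pattern(20, 2, 5.0, 10_000, seed=4)
        assert a == b

    def test_sparse_uniform_limit_has_few_dsbs(self):
        # clustering scale huge relative to the pairing distance: near-uniform
        breaks = generate_pattern(
            20, 2, clustering_scale=50_000, genome_span=10_000_000, seed=8
        )
        tally = classify(breaks)
        assert tally.n_dsb / max(tally.n_sb_total, 1) < 0.1

    def test_tight_pairs_on_opposite_strands_mostly_dsb(self):
        n_tracks = 300
        breaks = generate_pattern(
            n_tracks, 2, clustering_scale=2.0, genome_span=10_000_000, seed=9
        )
        tally = classify(breaks)
        # displacement of a pair ~ Normal(0, 2*sqrt(2)); |delta| <= 10 almost surely
        assert tally.n_dsb >= 0.95 * n_tracks

    def test_random_strand_mode(self):
        breaks = generate_pattern(50, 2, 2.0, 10_000, seed=1, strand_mode="random")
        assert {b.strand for b in breaks} == {0, 1}

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            generate_pattern(1, 2, 1.0, 0, seed=0)


class TestBreaksTsvIO:
    def test_round_trip(self, tmp_path):
        breaks = generate_pattern(10, 2, 5.0, 1000, seed=2)
        path = tmp_path / "breaks.tsv"
        write_breaks_tsv(breaks, path, header_lines=["fixture"])
        assert read_breaks_tsv(path) == breaks

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "breaks.tsv"
        path.write_text("position_bp\tstrand\n1\t0\n")
        with pytest.raises(ValueError, match="mechanism"):
            read_breaks_tsv(path)
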