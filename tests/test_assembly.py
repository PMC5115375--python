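import random
from collections import Counter

import pytest

from beaconlogic import (
    G4Config,
    Strand,
    StrandSet,
    brute_force_state,
    enumerate_candidates,
    resolve_state,
    reverse_complement,
)
from beaconlogic.assembly import assemble_state, _split_candidates
from beaconlogic.thermo import best_duplex

from conftest import random_strand_set


class TestEnumerateCandidates:
    def test_half_adder_combinatorics(self, designed_sets, params):
        ss, _ = designed_sets["half_adder"]
        candidates = enumerate_candidates(ss, params)
        inter = [c for c in candidates if not c.intramolecular]
        intra = [c for c in candidates if c.intramolecular]
        assert len(inter) == 3  # every unordered pair of the 3 strands
        assert len(intra) == 1  # the beacon stem

    def test_beacon_alone_yields_hairpin_only(self, designed_sets, params):
        ss, _ = designed_sets["half_adder"]
        sub = ss.subset([])
        candidates = enumerate_candidates(sub, params)
        assert len(candidates) == 1 and candidates[0].intramolecular

    def test_matches_pairwise_best_duplex(self, designed_sets, params):
        ss, _ = designed_sets["half_subtractor"]
        candidates = {
            c.key: c.dg
            for c in enumerate_candidates(ss, params)
            if not c.intramolecular
        }
        strands = list(ss)
        for i in range(len(strands)):
            for j in range(i + 1, len(strands)):
                hit = best_duplex(strands[i], strands[j], params)
                key = tuple(sorted((strands[i].name, strands[j].name)))
                if hit is None:
                    assert key not in candidates
                else:
                    assert candidates[key] == pytest.approx(hit[1])


class TestResolveState:
    def test_single_input_opens_beacon(self, designed_sets):
        ss, _ = designed_sets["half_adder"]
        state = resolve_state(ss.subset(["HA-IN 1"]))
        assert state.matching == (("HA-IN 1", "MB"),)
        assert state.beacon_open and state.g4_count == 0

    def test_input_pair_takes_priority_over_beacon(self, designed_sets):
        ss, _ = designed_sets["half_adder"]
        state = resolve_state(ss.subset(["HA-IN 1", "HA-IN 2"]))
        assert state.matching == (("HA-IN 1", "HA-IN 2"),)
        assert not state.beacon_open  # beacon closes into its hairpin
        assert state.g4_count == 1  # split quadruplex at the duplex junction

    def test_full_adder_triple_dominant_pair(self, designed_sets):
        ss, _ = designed_sets["full_adder"]
        state = resolve_state(ss.subset(["FA-IN 1", "FA-IN 2", "FA-IN 3"]))
        assert state.matching == (("FA-IN 1", "MB"), ("FA-IN 2", "FA-IN 3"))
        assert state.beacon_open and state.g4_count == 1

    def test_equals_brute_force_on_random_sets(self, params):
        rng = random.Random(101)
        for _ in range(60):
            ss = random_strand_set(rng, rng.randint(2, 6))
            fast = resolve_state(ss, params)
            slow = brute_force_state(ss, params)
            assert fast.matching == slow.matching
            assert fast.total_dg == pytest.approx(slow.total_dg)
            assert fast.g4_count == slow.g4_count

    def test_strand_conservation(self, params):
        rng = random.Random(33)
        for _ in range(40):
            ss = random_strand_set(rng, rng.randint(2, 6))
            state = resolve_state(ss, params)
            seen = Counter(state.free_strands)
            for cplx in state.complexes:
                seen.update(set(cplx.strands))
            assert seen == Counter(s.name for s in ss)

    def test_total_dg_is_sum_over_complexes(self, params):
        rng = random.Random(5)
        for _ in range(20):
            ss = random_strand_set(rng, 5)
            state = resolve_state(ss, params)
            assert state.total_dg == pytest.approx(
                sum(c.bound.dg for c in state.complexes)
            )

    def test_brute_force_size_limit(self, params):
        rng = random.Random(0)
        ss = random_strand_set(rng, 8)
        with pytest.raises(ValueError):
            brute_force_state(ss, params)


def make_state(strand_set, matched_keys, params):
    """Assemble a state from an explicit choice of duplexes (test helper)."""
    candidates = enumerate_candidates(strand_set, params)
    inter, hairpin = _split_candidates(candidates)
    by_key = {c.key: c for c in inter}
    matched = [by_key[tuple(sorted(k))] for k in matched_keys]
    return assemble_state(strand_set, matched, hairpin, G4Config(), 0.0)


class TestGQuadruplexCounting:
    def test_split_g4_at_half_adder_junction(self, designed_sets):
        ss, _ = designed_sets["half_adder"]
        state = resolve_state(ss.subset(["HA-IN 1", "HA-IN 2"]))
        # GGGT (1 tract) + TGGGTGGGTGGG (3 tracts) pooled at one junction
        assert state.g4_count == 1

    def test_beacon_with_single_input_no_g4(self, designed_sets):
        ss, _ = designed_sets["half_adder"]
        for name in ("HA-IN 1", "HA-IN 2"):
            assert resolve_state(ss.subset([name])).g4_count == 0

    def test_full_subtractor_two_equivalents(self, designed_sets):
        ss, _ = designed_sets["full_subtractor"]
        state = resolve_state(ss.subset(["FS-IN 2", "FS-IN 3"]))
        assert state.g4_count == 2  # both intramolecular cassettes exposed

    def test_hybridization_sequesters_tracts(self, designed_sets, params):
        # FS-IN 2 free folds one quadruplex; paired with FS-IN 1 over the
        # cassette block it folds none
        ss, _ = designed_sets["full_subtractor"]
        fs2 = ss["FS-IN 2"]
        free = StrandSet([ss.beacon, fs2])
        state_free = make_state(free, [], params)
        assert state_free.g4_count >= 1
        both = ss.subset(["FS-IN 1", "FS-IN 2"])
        state_paired = make_state(both, [("FS-IN 1", "FS-IN 2")], params)
        assert state_paired.g4_count == 0

    def test_monotone_under_additional_pairing(self, designed_sets, params):
        # pairing more strands can only reduce the count, never raise it
        ss, _ = designed_sets["full_subtractor"]
        sub = ss.subset(["FS-IN 1", "FS-IN 2"])
        unpaired = make_state(sub, [], params)
        paired = make_state(sub, [("FS-IN 1", "FS-IN 2")], params)
        assert paired.g4_count <= unpaired.g4_count

    def test_distant_tracts_do_not_pool(self):
        # two tracts far from the junction must not join the split count
        mb = Strand("MB", "GCGCGCGC" + "A" * 20 + "GCGCGCGC", "beacon")
        a = Strand("A", "GGGT" + "ATCATCATCATCATCATCAT" + "AACCTT", "input")
        b = Strand(
            "B",
            "TTAAGG" + reverse_complement("ATCATCATCATCATCATCAT") + "T" + "GGGTGGGTGGG",
            "input",
        )
        # intended duplex leaves A's single tract at one junction but B's
        # three tracts sit on the far side of B's own overhang
        ss = StrandSet([mb, a, b])
        state = resolve_state(ss)
        assert ("A", "B") in state.matching
        # junction pooling: A contributes 1 tract, B's tracts lie > 6 nt
        # away but still within the 15-nt window -> pooled count reaches 4
        assert state.g4_count == 1
        tight = resolve_state(ss, g4_config=G4Config(junction_window=4))
        assert tight.g4_count == 0
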