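import pytest

from beaconlogic import (
    CIRCUIT_KINDS,
    circuit_def,
    decode_arithmetic,
    reference_truth_table,
    simulate_truth_table,
    table_to_dataframe,
    verify_circuit,
)
from beaconlogic.circuits import COMPARATOR, HALF_SUBTRACTOR
from beaconlogic.strands import Strand, StrandSet


class TestReferenceTruthTables:
    def test_half_adder_one_plus_one(self):
        rows = {r.input_bits: r for r in reference_truth_table("half_adder")}
        assert rows[(1, 1)].digits == {"C": 1, "S": 0}
        assert rows[(1, 1)].decimal == 2  # 1 + 1 = 2
        assert rows[(1, 0)].decimal == 1

    def test_half_subtractor_high_borrow(self):
        rows = {r.input_bits: r for r in reference_truth_table("half_subtractor")}
        # 0 - 1: high borrow, 2 - 1 = 1
        assert rows[(0, 1)].digits == {"B": 1, "D": 1}
        assert rows[(0, 1)].high_borrow and rows[(0, 1)].decimal == 1
        assert rows[(1, 1)].digits == {"B": 0, "D": 0}

    def test_full_adder_identity_all_rows(self):
        for r in reference_truth_table("full_adder"):
            assert 2 * r.digits["C_out"] + r.digits["S_out"] == sum(r.input_bits)
        rows = {r.input_bits: r for r in reference_truth_table("full_adder")}
        assert rows[(1, 1, 1)].digits == {"C_out": 1, "S_out": 1}  # 1+1+1 = 3

    def test_full_subtractor_eight_operations(self):
        rows = {r.input_bits: r for r in reference_truth_table("full_subtractor")}
        # the eight printed operations a - b - b_in under high borrow
        assert rows[(1, 1, 1)].digits == {"B_out": 1, "D_out": 1}  # 3-1-1 = 1
        assert rows[(0, 1, 1)].digits == {"B_out": 1, "D_out": 0}  # 2-1-1 = 0
        assert rows[(1, 0, 0)].digits == {"B_out": 0, "D_out": 1}
        for r in rows.values():
            a, b, c = r.input_bits
            assert r.digits["D_out"] - 2 * r.digits["B_out"] == a - b - c

    def test_comparator_relations(self):
        rows = {r.input_bits: r for r in reference_truth_table("comparator")}
        assert rows[(0, 0)].relation == "equal"
        assert rows[(1, 1)].relation == "equal"
        assert rows[(0, 1)].relation == "less"
        assert rows[(1, 0)].relation == "greater"

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            reference_truth_table("ternary_adder")


class TestDecodeArithmetic:
    def test_examples(self):
        assert decode_arithmetic("half_adder", (1, 1), {"C": 1, "S": 0}).decimal == 2
        assert decode_arithmetic("full_adder", (1, 1, 0), {"C_out": 1, "S_out": 0}).decimal == 2
        res = decode_arithmetic("full_subtractor", (0, 1, 1), {"B_out": 1, "D_out": 0})
        assert res.decimal == 0 and res.high_borrow

    def test_inconsistent_digits_flagged_not_raised(self):
        res = decode_arithmetic("half_adder", (1, 1), {"C": 0, "S": 0})
        assert not res.consistent
        res = decode_arithmetic("comparator", (0, 1), {"EQUAL": 1, "LESS": 1})
        assert not res.consistent and res.relation == "inconsistent"


class TestSimulatedTables:
    @pytest.mark.parametrize("kind", CIRCUIT_KINDS)
    def test_simulation_matches_reference(self, kind, designed_sets):
        ss, _ = designed_sets[kind]
        simulated = simulate_truth_table(kind, ss)
        reference = reference_truth_table(kind)
        assert [r.digits for r in simulated] == [r.digits for r in reference]
        assert [r.input_bits for r in simulated] == [r.input_bits for r in reference]

    @pytest.mark.parametrize("kind", ("half_adder", "full_adder"))
    def test_adder_identity_on_simulated_rows(self, kind, designed_sets):
        ss, _ = designed_sets[kind]
        cdef = circuit_def(kind)
        for r in simulate_truth_table(kind, ss):
            assert 2 * r.digits[cdef.nmm_digit] + r.digits[cdef.fam_digit] == sum(
                r.input_bits
            )

    @pytest.mark.parametrize("kind", ("half_subtractor", "full_subtractor"))
    def test_subtractor_identity_on_simulated_rows(self, kind, designed_sets):
        ss, _ = designed_sets[kind]
        cdef = circuit_def(kind)
        for r in simulate_truth_table(kind, ss):
            b_in = r.input_bits[2] if len(r.input_bits) == 3 else 0
            assert r.digits[cdef.fam_digit] - 2 * r.digits[cdef.nmm_digit] == (
                r.input_bits[0] - r.input_bits[1] - b_in
            )

    def test_empty_row_always_zero(self, designed_sets):
        for kind, (ss, _) in designed_sets.items():
            row = simulate_truth_table(kind, ss)[0]
            assert not any(row.input_bits)
            if kind != COMPARATOR:  # comparator reads (0,0) as EQUAL=1
                assert set(row.digits.values()) <= {0}

    def test_comparator_is_negative_logic_half_subtractor(self, designed_sets):
        """On the same strand set, EQUAL = NOT(DIFFERENCE) and LESS = BORROW."""
        ss, _ = designed_sets[HALF_SUBTRACTOR]
        hs = simulate_truth_table(HALF_SUBTRACTOR, ss)
        cmp_rows = simulate_truth_table(COMPARATOR, ss)
        for h, c in zip(hs, cmp_rows):
            assert c.digits["EQUAL"] == 1 - h.digits["D"]
            assert c.digits["LESS"] == h.digits["B"]

    def test_missing_strand_raises(self, designed_sets):
        ss, _ = designed_sets["half_adder"]
        with pytest.raises(KeyError):
            simulate_truth_table("full_adder", ss)


class TestVerifyCircuit:
    @pytest.mark.parametrize("kind", CIRCUIT_KINDS)
    def test_designed_sets_pass_with_margin(self, kind, designed_sets):
        ss, _ = designed_sets[kind]
        report = verify_circuit(kind, ss)
        assert report.passed
        assert report.n_passed == len(report.rows)
        assert report.min_margin >= 0.3

    def test_deleting_g_tracts_breaks_carry_rows(self, designed_sets):
        ss, _ = designed_sets["half_adder"]
        mangled = []
        for s in ss:
            seq = s.sequence.replace("GGG", "ATT") if s.name == "HA-IN 2" else s.sequence
            mangled.append(Strand(s.name, seq, s.role))
        report = verify_circuit("half_adder", StrandSet(mangled))
        assert not report.passed
        failing = [r.input_bits for r in report.rows if not r.passed]
        assert (1, 1) in failing  # the AND row loses its NMM reporter

    def test_report_round_trips_to_dict(self, designed_sets):
        ss, _ = designed_sets["comparator"]
        d = verify_circuit("comparator", ss).to_dict()
        assert d["passed"] and len(d["rows"]) == 4


class TestTableDataFrame:
    def test_tsv_shape_and_columns(self, designed_sets):
        ss, _ = designed_sets["full_adder"]
        frame = table_to_dataframe("full_adder", simulate_truth_table("full_adder", ss))
        assert len(frame) == 8
        for col in ("FA-IN 1", "C_out", "S_out", "fam_norm", "nmm_norm", "decimal"):
            assert col in frame.columns
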