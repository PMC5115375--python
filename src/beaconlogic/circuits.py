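"""Circuit definitions, truth tables, verification, and arithmetic decoding.

Five circuits run on the one beacon platform. Each reads two digits off the
two fluorescence channels:

===============  ======================  ======================
circuit          FAM channel             NMM channel
===============  ======================  ======================
half adder       SUM (XOR)               CARRY (AND)
half subtractor  DIFFERENCE (XOR)        BORROW (INHIBIT, !a&b)
full adder       SUM OUT (a^b^c)         CARRY OUT (majority)
full subtractor  DIFFERENCE OUT          BORROW OUT (a-b-c < 0)
comparator       EQUAL (negative logic)  LESS (positive logic)
===============  ======================  ======================

The comparator is the half subtractor reread under a negative logic
convention on the FAM channel: NOT(XOR) is the equality indicator XNOR,
while the NMM INHIBIT gate already reports a < b. Input bits mean physical
presence (1) or absence (0) of the named strand; rows are enumerated in
binary counting order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

from .assembly import G4Config, resolve_state
from .readout import (
    DEFAULT_FAM_LEAK,
    DecodeConfig,
    NEGATIVE,
    POSITIVE,
    channel_intensities,
    decode_bit,
    decode_margin,
)
from .strands import StrandSet
from .thermo import SearchConfig, ThermoParams

HALF_ADDER = "half_adder"
HALF_SUBTRACTOR = "half_subtractor"
FULL_ADDER = "full_adder"
FULL_SUBTRACTOR = "full_subtractor"
COMPARATOR = "comparator"
CIRCUIT_KINDS = (HALF_ADDER, HALF_SUBTRACTOR, FULL_ADDER, FULL_SUBTRACTOR, COMPARATOR)

BEACON_NAME = "MB"


@dataclass(frozen=True)
class CircuitDef:
    kind: str
    input_names: tuple[str, ...]
    fam_digit: str
    nmm_digit: str
    fam_convention: str = POSITIVE
    nmm_convention: str = POSITIVE

    def __post_init__(self) -> None:
        expected = 3 if self.kind in (FULL_ADDER, FULL_SUBTRACTOR) else 2
        if len(self.input_names) != expected:
            raise ValueError(
                f"{self.kind} takes {expected} inputs, got {len(self.input_names)}"
            )
        if self.fam_digit == self.nmm_digit:
            raise ValueError("channel map must be bijective onto two digits")

    @property
    def digit_names(self) -> tuple[str, str]:
        return (self.nmm_digit, self.fam_digit)


_DEFS = {
    HALF_ADDER: CircuitDef(HALF_ADDER, ("HA-IN 1", "HA-IN 2"), "S", "C"),
    HALF_SUBTRACTOR: CircuitDef(HALF_SUBTRACTOR, ("HS-IN 1", "HS-IN 2"), "D", "B"),
    FULL_ADDER: CircuitDef(FULL_ADDER, ("FA-IN 1", "FA-IN 2", "FA-IN 3"), "S_out", "C_out"),
    FULL_SUBTRACTOR: CircuitDef(
        FULL_SUBTRACTOR, ("FS-IN 1", "FS-IN 2", "FS-IN 3"), "D_out", "B_out"
    ),
    # the comparator reuses the half-subtractor strand set, FAM reread in
    # negative logic
    COMPARATOR: CircuitDef(
        COMPARATOR,
        ("HS-IN 1", "HS-IN 2"),
        "EQUAL",
        "LESS",
        fam_convention=NEGATIVE,
        nmm_convention=POSITIVE,
    ),
}


def circuit_def(kind: str) -> CircuitDef:
    try:
        return _DEFS[kind]
    except KeyError:
        raise ValueError(f"unknown circuit kind {kind!r}") from None


@dataclass(frozen=True)
class ArithmeticResult:
    decimal: int | None = None
    high_borrow: bool | None = None
    relation: str | None = None  # comparator: equal / less / greater
    consistent: bool = True


@dataclass(frozen=True)
class TruthTableRow:
    input_bits: tuple[int, ...]
    digits: dict[str, int]
    fam_norm: float | None = None
    nmm_norm: float | None = None
    decimal: int | None = None
    high_borrow: bool | None = None
    relation: str | None = None


def _reference_digits(kind: str, bits: tuple[int, ...]) -> dict[str, int]:
    if kind == HALF_ADDER:
        a, b = bits
        return {"C": a & b, "S": a ^ b}
    if kind == HALF_SUBTRACTOR:
        a, b = bits
        return {"B": (1 - a) & b, "D": a ^ b}
    if kind == FULL_ADDER:
        a, b, c = bits
        return {"C_out": int(a + b + c >= 2), "S_out": a ^ b ^ c}
    if kind == FULL_SUBTRACTOR:
        a, b, c = bits
        raw = a - b - c
        return {"B_out": int(raw < 0), "D_out": raw % 2}
    if kind == COMPARATOR:
        a, b = bits
        return {"EQUAL": int(a == b), "LESS": int(a < b)}
    raise ValueError(f"unknown circuit kind {kind!r}")


def reference_truth_table(kind: str) -> list[TruthTableRow]:
    """Electronic-logic ground truth, rows in binary counting order."""
    cdef = circuit_def(kind)
    rows = []
    for bits in product((0, 1), repeat=len(cdef.input_names)):
        digits = _reference_digits(kind, bits)
        arith = decode_arithmetic(kind, bits, digits)
        rows.append(
            TruthTableRow(
                input_bits=bits,
                digits=digits,
                decimal=arith.decimal,
                high_borrow=arith.high_borrow,
                relation=arith.relation,
            )
        )
    return rows


def decode_arithmetic(
    kind: str, input_bits: tuple[int, ...], digits: dict[str, int]
) -> ArithmeticResult:
    """Interpret decoded digits as an arithmetic statement.

    Adders: decimal = 2*CARRY + SUM, consistent iff it equals the bit sum.
    Subtractors: decimal = DIFFERENCE with the high-borrow convention (the
    minuend is augmented by 2 when BORROW = 1), consistent iff
    D - 2*B = a - b (- b_in). Comparator: a categorical relation; EQUAL and
    LESS may not both be set.
    """
    cdef = circuit_def(kind)
    nmm_digit, fam_digit = cdef.digit_names
    hi, lo = digits[nmm_digit], digits[fam_digit]
    if kind in (HALF_ADDER, FULL_ADDER):
        decimal = 2 * hi + lo
        return ArithmeticResult(
            decimal=decimal, consistent=(decimal == sum(input_bits))
        )
    if kind in (HALF_SUBTRACTOR, FULL_SUBTRACTOR):
        a, b = input_bits[0], input_bits[1]
        borrow_in = input_bits[2] if len(input_bits) == 3 else 0
        consistent = (lo - 2 * hi) == (a - b - borrow_in)
        return ArithmeticResult(
            decimal=lo, high_borrow=bool(hi), consistent=consistent
        )
    if kind == COMPARATOR:
        eq, less = digits["EQUAL"], digits["LESS"]
        if eq and less:
            return ArithmeticResult(relation="inconsistent", consistent=False)
        relation = "equal" if eq else ("less" if less else "greater")
        a, b = input_bits
        truth = "equal" if a == b else ("less" if a < b else "greater")
        return ArithmeticResult(relation=relation, consistent=(relation == truth))
    raise ValueError(f"unknown circuit kind {kind!r}")


def simulate_truth_table(
    circuit: CircuitDef | str,
    strand_set: StrandSet,
    params: ThermoParams | None = None,
    decode: DecodeConfig = DecodeConfig(),
    search: SearchConfig = SearchConfig(),
    g4_config: G4Config = G4Config(),
    fam_leak: float = DEFAULT_FAM_LEAK,
) -> list[TruthTableRow]:
    """Simulate every input combination and decode both channels.

    For each bit vector the present strands (beacon plus inputs with bit 1)
    are resolved to a minimum-free-energy state; noiseless intensities are
    decoded at the shared threshold under each channel's logic convention.
    """
    cdef = circuit if isinstance(circuit, CircuitDef) else circuit_def(circuit)
    missing = [n for n in cdef.input_names if n not in strand_set]
    if missing:
        raise KeyError(f"strand set lacks circuit inputs: {missing}")
    fam_cfg = DecodeConfig(decode.threshold, decode.strict, cdef.fam_convention)
    nmm_cfg = DecodeConfig(decode.threshold, decode.strict, cdef.nmm_convention)
    rows = []
    for bits in product((0, 1), repeat=len(cdef.input_names)):
        present = [n for n, bit in zip(cdef.input_names, bits) if bit]
        state = resolve_state(
            strand_set.subset(present), params, search, g4_config
        )
        reading = channel_intensities(state, fam_leak=fam_leak)
        digits = {
            cdef.fam_digit: decode_bit(reading.fam_norm, fam_cfg),
            cdef.nmm_digit: decode_bit(reading.nmm_norm, nmm_cfg),
        }
        arith = decode_arithmetic(cdef.kind, bits, digits)
        rows.append(
            TruthTableRow(
                input_bits=bits,
                digits=digits,
                fam_norm=reading.fam_norm,
                nmm_norm=reading.nmm_norm,
                decimal=arith.decimal,
                high_borrow=arith.high_borrow,
                relation=arith.relation,
            )
        )
    return rows


@dataclass(frozen=True)
class RowCheck:
    input_bits: tuple[int, ...]
    expected: dict[str, int]
    simulated: dict[str, int]
    fam_norm: float
    nmm_norm: float
    fam_margin: float
    nmm_margin: float

    @property
    def passed(self) -> bool:
        return self.expected == self.simulated


@dataclass(frozen=True)
class VerificationReport:
    kind: str
    rows: tuple[RowCheck, ...]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rows)

    @property
    def n_passed(self) -> int:
        return sum(r.passed for r in self.rows)

    @property
    def min_margin(self) -> float:
        return min(min(r.fam_margin, r.nmm_margin) for r in self.rows)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "passed": self.passed,
            "rows_passed": f"{self.n_passed}/{len(self.rows)}",
            "min_margin": round(self.min_margin, 4),
            "rows": [
                {
                    "inputs": list(r.input_bits),
                    "expected": r.expected,
                    "simulated": r.simulated,
                    "fam_norm": round(r.fam_norm, 4),
                    "nmm_norm": round(r.nmm_norm, 4),
                    "fam_margin": round(r.fam_margin, 4),
                    "nmm_margin": round(r.nmm_margin, 4),
                    "passed": r.passed,
                }
                for r in self.rows
            ],
        }


def verify_circuit(
    circuit: CircuitDef | str,
    strand_set: StrandSet,
    params: ThermoParams | None = None,
    decode: DecodeConfig = DecodeConfig(),
    **simulate_kwargs,
) -> VerificationReport:
    """Row-by-row comparison of the simulated table against the reference."""
    cdef = circuit if isinstance(circuit, CircuitDef) else circuit_def(circuit)
    simulated = simulate_truth_table(cdef, strand_set, params, decode, **simulate_kwargs)
    reference = reference_truth_table(cdef.kind)
    checks = []
    for sim, ref in zip(simulated, reference):
        checks.append(
            RowCheck(
                input_bits=sim.input_bits,
                expected=ref.digits,
                simulated=sim.digits,
                fam_norm=sim.fam_norm,
                nmm_norm=sim.nmm_norm,
                fam_margin=decode_margin(sim.fam_norm, decode),
                nmm_margin=decode_margin(sim.nmm_norm, decode),
            )
        )
    return VerificationReport(kind=cdef.kind, rows=tuple(checks))


def table_to_dataframe(kind: str, rows: list[TruthTableRow]) -> pd.DataFrame:
    """Truth table as a tidy frame, one row per input combination."""
    cdef = circuit_def(kind)
    records = []
    for row in rows:
        rec = {name: bit for name, bit in zip(cdef.input_names, row.input_bits)}
        if row.fam_norm is not None:
            rec["fam_norm"] = round(row.fam_norm, 4)
            rec["nmm_norm"] = round(row.nmm_norm, 4)
        rec.update(row.digits)
        if row.decimal is not None:
            rec["decimal"] = row.decimal
        if row.high_borrow is not None:
            rec["high_borrow"] = int(row.high_borrow)
        if row.relation is not None:
            rec["relation"] = row.relation
        records.append(rec)
    return pd.DataFrame.from_records(records)
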