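"""Simulate all five circuits and print their decoded truth tables.

Every circuit runs on the same beacon platform and the same 0.4 threshold;
only the input strands (and, for the comparator, the logic convention on
the FAM channel) change. The decimal column is the arithmetic the digits
encode: 2*CARRY + SUM for adders, DIFFERENCE under the high-borrow
convention for subtractors.
"""

from beaconlogic import (
    CIRCUIT_KINDS,
    design_strands,
    simulate_truth_table,
    table_to_dataframe,
)

for kind in CIRCUIT_KINDS:
    strand_set, _ = design_strands(kind, seed=1)
    rows = simulate_truth_table(kind, strand_set)
    print(f"\n=== {kind} ===")
    print(table_to_dataframe(kind, rows).to_string(index=False))

# Expected highlights: half adder (1,1) -> C=1 S=0 (decimal 2); full adder
# (1,1,1) -> C_out=S_out=1 (decimal 3); full subtractor (0,1,1) -> NMM reads
# 2.0 (two quadruplex equivalents) and D_out=0 with a high borrow.
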