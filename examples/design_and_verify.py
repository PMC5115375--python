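"""Design a half-adder strand set and verify it row by row.

The designer builds a hairpin beacon (MB) and two inputs: each input opens
the beacon through a single-mismatch duplex, the two inputs pair perfectly
with each other (outcompeting the beacon), and their junction pools the
split segments GGGT + TGGGTGGGTGGG into a G-quadruplex reporter.
"""

from beaconlogic import design_strands, verify_circuit

strand_set, report = design_strands("half_adder", seed=1)
print(f"accepted after {report.proposals_tried} proposal(s)\n")
for s in strand_set:
    print(f"  {s.name:8s} ({s.role}, {len(s)} nt)  5'-{s.sequence}-3'")

verification = verify_circuit("half_adder", strand_set)
print(f"\nverification: {verification.n_passed}/{len(verification.rows)} rows, "
      f"min decode margin {verification.min_margin:.2f}")
for row in verification.rows:
    print(f"  inputs {row.input_bits}  FAM={row.fam_norm:.2f} NMM={row.nmm_norm:.2f}"
          f"  digits {row.simulated}  {'ok' if row.passed else 'MISMATCH'}")

# The (1,1) row shows the competition: the input-input duplex wins, the
# beacon closes (FAM at leak level), and the split quadruplex lights NMM --
# CARRY=1, SUM=0, i.e. 1 + 1 = 2.
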