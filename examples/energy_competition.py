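"""Inspect the free-energy competition behind the half-adder AND/XOR gates.

Prints every duplex candidate with its nearest-neighbor dG, then resolves
each input combination to its minimum-energy configuration. The mismatch
embedded in each beacon-input duplex is visible as the energy gap to the
perfect input-input duplex that takes priority when both inputs are present.
"""

from beaconlogic import design_strands, enumerate_candidates, resolve_state

strand_set, _ = design_strands("half_adder", seed=1)

print("duplex candidates (winner-take-all competition graph):")
for cand in enumerate_candidates(strand_set):
    label = "hairpin stem" if cand.intramolecular else f"{cand.strand_a} x {cand.strand_b}"
    print(f"  {label:22s} dG = {cand.dg:7.2f} kcal/mol  "
          f"({len(cand.pairing)} bp, {cand.mismatches} mismatch(es))")

for present in ([], ["HA-IN 1"], ["HA-IN 2"], ["HA-IN 1", "HA-IN 2"]):
    state = resolve_state(strand_set.subset(present))
    print(f"\ninputs present: {present or 'none'}")
    print(f"  matching={list(state.matching)} beacon_open={state.beacon_open} "
          f"g4_count={state.g4_count} total dG={state.total_dg:.2f}")

# With both inputs the perfect input-input duplex plus the closed hairpin
# beats either mismatched beacon-input duplex, so the beacon darkens (SUM=0)
# while the junction quadruplex lights the NMM channel (CARRY=1).
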