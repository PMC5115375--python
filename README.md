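# beaconlogic

Simulation and sequence design for DNA logic circuits built on a single
molecular-beacon platform with dual fluorescence readout.

## The system

A molecular beacon (MB) is a hairpin oligonucleotide carrying a fluorophore
(FAM) and a quencher on its termini: closed, it is dark; opened by a
hybridizing input strand, it fluoresces. A second reporter channel comes
from N-methylmesoporphyrin IX (NMM), which lights up when four guanine
tracts assemble into a G-quadruplex (G-4) — either *split* across the
overhangs of two hybridized inputs, or folded *intramolecularly* by a
four-tract cassette on one unpaired strand.

Because every interaction is plain hybridization, circuit behavior is set
entirely by relative duplex stabilities. Each input carries a deliberately
mismatched beacon-binding block (one mismatch for two-input circuits, two
for three-input ones), so a later, fully complementary input–input duplex
always takes priority over the beacon. Reading the FAM channel and the NMM
channel in parallel against one constant threshold (0.4) yields, from the
same platform: a **half adder** (FAM = SUM = a⊕b, NMM = CARRY = a∧b), a
**half subtractor** (FAM = DIFFERENCE, NMM = BORROW = ¬a∧b), a **full
adder** (S = a⊕b⊕c, C = majority), a **full subtractor** (D − 2B = a − b −
b_in), and a **digital comparator** (the half subtractor reread with the
FAM channel under negative logic: XNOR = equality).

`beaconlogic` implements this in silico:

* a nearest-neighbor free-energy model (ΔG°37) with flat mismatch penalties
  and a hairpin loop table;
* a winner-take-all equilibrium: the realized configuration is the
  minimum-free-energy matching of strands into duplexes (each strand in at
  most one), with an unmatched beacon closing into its hairpin — plus an
  exhaustive brute-force oracle for cross-checking;
* G-quadruplex detection on unpaired overhangs (split at duplex junctions,
  intramolecular within a 30-nt span); hybridized tracts never count;
* channel readout, threshold decoding under positive/negative conventions,
  and truth-table verification with arithmetic interpretation;
* a seeded constraint-based **designer** that generates strand sets
  realizing each circuit and certifies them (intended matching optimal with
  an energy margin in every row, correct beacon state and G-4 count per
  row, mismatch budget met, no off-target crosstalk window).

## Worked example

```sh
python examples/design_and_verify.py
```

```
accepted after 1 proposal(s)

  MB       (beacon, 36 nt)  5'-TCCGCGCCTATCCTATACAAATTACTACGGCGCGGA-3'
  HA-IN 1  (input, 48 nt)  5'-GGGTCCTACATACCACTTAATTCATCTTGTAGTAATTTCTATAGGATA-3'
  HA-IN 2  (input, 56 nt)  5'-GTAGTAATTCGTATAGGATAAAGATGAATTAAGTGGTATGTAGGTGGGTGGGTGGG-3'

verification: 4/4 rows, min decode margin 0.30
  inputs (0, 0)  FAM=0.10 NMM=0.00  digits {'S': 0, 'C': 0}  ok
  inputs (0, 1)  FAM=1.00 NMM=0.00  digits {'S': 1, 'C': 0}  ok
  inputs (1, 0)  FAM=1.00 NMM=0.00  digits {'S': 1, 'C': 0}  ok
  inputs (1, 1)  FAM=0.10 NMM=1.00  digits {'S': 0, 'C': 1}  ok
```

HA-IN 1 starts with the split segment `GGGT` and HA-IN 2 ends with
`TGGGTGGGTGGG`. Alone, either input opens the beacon (FAM 1.0 → SUM 1).
Together they pair with each other instead — the energy ledger behind that
priority (`python examples/energy_competition.py`):

```
  MB x HA-IN 1           dG =  -13.62 kcal/mol  (20 bp, 1 mismatch(es))
  MB x HA-IN 2           dG =  -14.06 kcal/mol  (20 bp, 1 mismatch(es))
  HA-IN 1 x HA-IN 2      dG =  -25.17 kcal/mol  (24 bp, 0 mismatch(es))
  hairpin stem           dG =   -3.05 kcal/mol  (8 bp, 0 mismatch(es))
```

so the (1,1) row resolves to the input–input duplex plus the closed beacon:
FAM falls to the 0.10 leak (SUM 0) while the four pooled G-tracts at the
duplex junction fold a quadruplex (NMM 1.0 → CARRY 1), i.e. 1 + 1 = 2.

Other entry points: `examples/truth_tables.py` (all five circuits),
`examples/noisy_readout.py` (replicate datasets), and the `beaconlogic`
CLI (`design`, `energy`, `simulate`, `truthtable`, `verify`, `fixture`).

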