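# Methods

## Scope and abstraction level

`beaconlogic` models enzyme-free, strand-displacement-free DNA logic on a
molecular-beacon platform. The modeled observables are the two normalized
fluorescence channels (FAM for beacon opening, NMM for G-quadruplex
assembly) and the bits they decode to; spectra, kinetics, buffer and
temperature dependence, and gel validation are out of scope. All strands
are treated as present at one equivalent each ("presence" is the input bit),
and the system is resolved as a discrete equilibrium rather than a
mass-action concentration profile.

## Free-energy model

Duplex stability is a nearest-neighbor sum at 37 °C: Watson–Crick stack
terms from the unified ΔG°37 parameter set (packaged in
`data/thermo_dg37.tsv`, source noted in its header), one initiation penalty
(+2.0 kcal/mol), and flat per-mismatch penalties (+1.5 internal, +0.75
terminal). Any non-WC pair, including G·T, counts as a mismatch. The
beacon hairpin scores stem stacks + a loop-closure table (3–30 nt,
log-extrapolated from 5.7 kcal/mol at 3 nt, constant beyond) + initiation.

Mismatches in this system are used *ordinally* — they exist to weaken
beacon–input duplexes below the input–input duplexes — so a flat penalty
preserves every ordering the circuits rely on while keeping the parameter
surface minimal; mismatch-specific NN tables can be substituted through
`ThermoParams` without API changes. No salt correction and no
enthalpy/entropy split: absolute energies are not interpreted, only
orderings and margins. These are acknowledged limitations, not accidents.

Duplex search is gapless and antiparallel (no bulges or loops — the designs
use only contiguous complementary blocks). On each alignment diagonal the
paired positions decompose into WC runs; candidate windows are run-aligned
concatenations within the mismatch budget. Windows with mismatched termini
are never candidates because trimming a terminal mismatch always lowers dG.
Defaults: windows ≥ 6 bp, ≤ 2 mismatches; ties in `best_duplex` break
toward the earlier window.

## Winner-take-all resolution

The realized configuration for a strand subset is the matching (each strand
in ≤ 1 intermolecular duplex) minimizing total dG, where an unmatched
beacon contributes its hairpin dG (when stabilizing) and unmatched inputs
contribute zero. `resolve_state` delegates optimality to a maximum-weight
matching (NetworkX) with edge weights equal to the stabilization relative
to leaving both partners unmatched; edges with no positive benefit are
dropped. Among co-optimal matchings the lexicographically smallest set of
sorted name pairs is selected by greedy fixing, which makes results
deterministic and reproducible. `brute_force_state` enumerates all
matchings (≤ 7 strands) with the same tie-break and serves as the
independent oracle; the test suite checks equivalence on hundreds of random
strand sets.

The beacon counts as *open* iff it is matched to an input whose duplex dG
beats the hairpin dG (configurable margin, default 0). Branched complexes
of three or more strands are not modeled; no circuit here requires them.

## G-quadruplex counting

Tracts are maximal runs of ≥ 3 G. Hybridized positions sequester tracts:
only tracts lying entirely in unpaired regions count. Two formation routes,
scored in a fixed order with each tract consumable once:

1. *intramolecular*: four tracts within a 30-nt span of one unpaired
   stretch (free strands included) → one quadruplex;
2. *split*: at each duplex junction, unconsumed tracts within 15 nt of the
   junction on both strands' overhangs are pooled; ≥ 4 pooled tracts → one
   quadruplex per junction (capped at one to prevent double counting).

The 15-nt window encodes that a split G-4 needs proximal tracts; both
geometry parameters are configurable (`G4Config`). NMM intensity is the
count itself (1.0 = one quadruplex equivalent), which is why the
full-subtractor row exposing two cassettes reads 2.0.

## Readout and decoding

Noiseless FAM is 1.0 (open) or a 0.10 leak (closed) — the leak mimics
residual quencher leakage and sits well below threshold; its exact value is
a documented convention. NMM equals the quadruplex count. Bits are decoded
strictly above the constant threshold 0.4, under a positive or negative
convention per channel; equality at the threshold only arises in non-strict
mode and is then flagged ambiguous (decoded 1). Normalization is
structural: channel values are counts/fractions, not fitted intensities,
because no tabulated spectra exist to fit against. The optional noise model
(multiplicative Gaussian, sd 0.05, seeded) emulates replicate reads; every
designed state sits ≥ 0.3 (six standard deviations) from the threshold, so
replicate decoding is bit-identical to the noiseless table — that is a
*separation* property of the designs, not a claim about real instrument
noise.

## Circuits

Reference tables are the electronic definitions (HA: S=XOR, C=AND; HS:
D=XOR, B=¬a∧b; FA: S=a⊕b⊕c, C=majority; FS: D−2B=a−b−b_in with the
high-borrow convention that a borrow augments the minuend by 2; comparator:
EQUAL=XNOR, LESS=¬a∧b). Rows run in binary counting order. The comparator
is realized on the half-subtractor strand set by decoding FAM under
negative logic — the reading consistent with "apply a negative logic gate
to the half subtractor" — with GREATER derived as ¬EQUAL ∧ ¬LESS; its exact
published output labeling was not available, so this reconstruction is a
design decision of this package.

## Designer

`design_strands(kind, seed)` is seeded propose-and-check. Proposals are
templated: a beacon (8-bp GC-rich stem + 20-nt loop; stems of 6 bp are
net-destabilized by the 20-nt loop penalty in this parameterization, so the
default stem is 8 bp), and inputs assembled from an *opener* (reverse
complement of the loop with k central mismatches; k = 1 for two-input, 2
for three-input circuits), perfect pairing blocks (24 nt; 36 nt for the
block that must dominate three-input rows), and a G-tract plan: the literal
half-adder split segments `GGGT`/`TGGGTGGGTGGG`, three-input circuits
carrying both segments terminally in a cyclic arrangement, and subtractor
cassettes of four G3 tracts with randomized single-base spacers (distinct
cassettes must not cross-hybridize). Filler is drawn from {A, C, T} with
CCC rejected, so guanine — and hence any quadruplex chemistry — appears
only where the plan puts it; a tract audit rejects proposals whose block
boundaries create stray tracts.

`check_design` certifies, for every input combination: the intended
matching is the exhaustive optimum with ≥ 2 kcal/mol margin over the best
alternative; the beacon opens exactly in the intended rows; quadruplex
counts match the per-row plan (including the two-count full-subtractor
rows); every beacon–input duplex embeds exactly k mismatches; and no
perfect window of ≥ 12 bp exists outside the intended interfaces (shifted
registers *inside* an intended interface are allowed — they are weaker
sub-alignments already dominated by the margin check). The full-subtractor
plan places intramolecular cassettes on inputs 2 and 3 so that each alone
opens the beacon and folds one quadruplex, input 1 covers and silences
them, and the 2–3 duplex exposes both (count 2); this is the arrangement
consistent with all eight rows plus the above-one NMM reading, and the
(1,1,1) row therefore also counts 2.

Designs are deterministic per seed; across seeds 0–40 every circuit designs
within ≤ 6 proposals. Lengths and margins are `DesignConstraints` fields.
The designs are functional stand-ins generated from the stated constraints,
not published oligo sequences.

## Problem sizes and numerics

Simulated systems are 3–4 strands of 36–96 nt; the oracle-equivalence
checks run 200 random sets of ≤ 6 strands (12–30 nt); the noise-robustness
check decodes 1000 replicates per row of every circuit. Floating-point
ties in matching totals are grouped at 1e-9 kcal/mol before the
lexicographic tie-break. Degenerate inputs: a strand set must contain
exactly one beacon; beacons without a terminal stem of ≥ 3 bp (or with a
net-destabilized hairpin) simply never close; strand pairs with no
qualifying window contribute no edge.

## What passing tests do and do not show

The synthetic generator reproduces the *logic structure* of the platform —
competition orderings, reporter placement, threshold separation — under the
package's own energy model. Passing tests demonstrate internal consistency
of model + designs, and that the arithmetic truth tables are forced by the
stated design constraints. They do not validate real-world folding
kinetics, G-quadruplex polymorphism, NMM binding specificity, or the
behavior of the original laboratory sequences.
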