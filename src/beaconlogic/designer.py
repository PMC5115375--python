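"""Seeded constraint-based generation of strand sets for each circuit.

The published oligonucleotides behind the beacon circuits are not part of
this package; instead this module *designs* functional stand-ins from the
stated constraints, by seeded propose-and-check: candidate strands are
assembled from templated blocks (random filler drawn from an {A, C, T}
alphabet so guanine appears only where a G-tract plan puts it), and the
first proposal passing :func:`check_design` is accepted.

Every input strand carries up to three functional blocks, mirroring the
three roles an input plays on the platform:

* an *opener* -- the reverse complement of the beacon loop with ``k``
  embedded central mismatches (k = 1 for two-input circuits, k = 2 for
  three-input ones), strong enough to open the hairpin yet weak enough to
  lose against any fully complementary input-input block;
* one or two *pairing blocks* complementary to partner inputs, whose perfect
  duplexes dominate the competition;
* a *G-tract plan*: terminal split segments (``GGGT`` / ``TGGGTGGGTGGG``)
  that pool into a quadruplex across a duplex junction, or an intramolecular
  four-tract cassette that folds on its own and is silenced when a partner
  strand hybridizes over it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import (
    G4Config,
    _baselines,
    _split_candidates,
    assemble_state,
    enumerate_candidates,
    enumerate_matchings,
)
from .circuits import (
    BEACON_NAME,
    COMPARATOR,
    FULL_ADDER,
    FULL_SUBTRACTOR,
    HALF_ADDER,
    HALF_SUBTRACTOR,
    circuit_def,
)
from .readout import NoiseConfig, channel_intensities
from .strands import (
    ROLE_BEACON,
    ROLE_INPUT,
    Strand,
    StrandSet,
    duplex_windows,
    find_g_tracts,
    reverse_complement,
)
from .thermo import SearchConfig, ThermoParams, default_params

SPLIT_5P = "GGGT"  # one-tract split segment carried at a 5' end
SPLIT_3P = "TGGGTGGGTGGG"  # three-tract split segment carried at a 3' end
_FILLER_ALPHABET = "ACT"  # G reserved for tract plans


def _cassette(rng: random.Random) -> str:
    """Intramolecular four-tract cassette, 16 nt: G3 tracts with randomized
    single-base spacers (distinct cassettes must not cross-hybridize)."""
    t = [rng.choice(_FILLER_ALPHABET) for _ in range(4)]
    return t[0] + "GGG" + t[1] + "GGG" + t[2] + "GGG" + t[3] + "GGG"


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable geometry and stringency of the strand designs.

    Lengths are nt; energies kcal/mol. ``beacon_mismatches`` defaults to the
    per-kind rule (1 for two-input circuits, 2 for three-input). The beacon
    stem must be long enough that the closed hairpin is net stabilizing
    under the packaged loop-penalty table.
    """

    stem_len: int = 8
    loop_len: int = 20
    opener_len: int = 20  # equals loop_len: the opener targets the full loop
    beacon_mismatches: int | None = None
    pair_block_len: int = 24  # perfect input-input block (non-dominant)
    dominant_block_len: int = 36  # block that must win three-strand rows
    crosstalk_min_len: int = 12  # no unintended perfect window this long
    crosstalk_max_mismatches: int = 0
    margin: float = 2.0  # required dG gap to the second-best matching
    max_proposals: int = 10000

    def mismatches_for(self, kind: str) -> int:
        if self.beacon_mismatches is not None:
            return self.beacon_mismatches
        return 2 if kind in (FULL_ADDER, FULL_SUBTRACTOR) else 1


@dataclass(frozen=True)
class RowPlan:
    """Intended outcome for one input combination."""

    matching: tuple[tuple[str, str], ...]
    beacon_open: bool
    g4_count: int


@dataclass
class DesignReport:
    kind: str
    seed: int | None
    violations: list[str] = field(default_factory=list)
    row_margins: dict[tuple[int, ...], float] = field(default_factory=dict)
    proposals_tried: int = 0

    @property
    def accepted(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "accepted": self.accepted,
            "proposals_tried": self.proposals_tried,
            "violations": list(self.violations),
            "row_margins": {
                "".join(map(str, bits)): (round(m, 3) if m != float("inf") else None)
                for bits, m in self.row_margins.items()
            },
        }


class DesignError(RuntimeError):
    """Raised when no proposal satisfies the constraints; carries the
    report of the closest candidate."""

    def __init__(self, message: str, report: DesignReport):
        super().__init__(message)
        self.report = report


# ---------------------------------------------------------------------------
# intended behavior per circuit
# ---------------------------------------------------------------------------

def circuit_plan(kind: str) -> dict[tuple[int, ...], RowPlan]:
    """Intended matching, beacon state, and quadruplex count per row."""
    cdef = circuit_def(kind)
    mb = BEACON_NAME
    names = cdef.input_names

    def pair(x: str, y: str) -> tuple[str, str]:
        return tuple(sorted((x, y)))

    if kind in (HALF_ADDER, HALF_SUBTRACTOR, COMPARATOR):
        n1, n2 = names
        # the NMM reporter fires on (1,1) for the adder (split quadruplex at
        # the input-input junction) but on (0,1) for the subtractor family
        # (intramolecular cassette on input 2, silenced by hybridization)
        g4_11 = 1 if kind == HALF_ADDER else 0
        g4_01 = 0 if kind == HALF_ADDER else 1
        return {
            (0, 0): RowPlan((), False, 0),
            (0, 1): RowPlan((pair(mb, n2),), True, g4_01),
            (1, 0): RowPlan((pair(mb, n1),), True, 0),
            (1, 1): RowPlan((pair(n1, n2),), False, g4_11),
        }
    if kind == FULL_ADDER:
        n1, n2, n3 = names
        return {
            (0, 0, 0): RowPlan((), False, 0),
            (0, 0, 1): RowPlan((pair(mb, n3),), True, 0),
            (0, 1, 0): RowPlan((pair(mb, n2),), True, 0),
            (1, 0, 0): RowPlan((pair(mb, n1),), True, 0),
            (0, 1, 1): RowPlan((pair(n2, n3),), False, 1),
            (1, 0, 1): RowPlan((pair(n1, n3),), False, 1),
            (1, 1, 0): RowPlan((pair(n1, n2),), False, 1),
            (1, 1, 1): RowPlan(tuple(sorted((pair(n2, n3), pair(mb, n1)))), True, 1),
        }
    if kind == FULL_SUBTRACTOR:
        n1, n2, n3 = names
        return {
            (0, 0, 0): RowPlan((), False, 0),
            (0, 0, 1): RowPlan((pair(mb, n3),), True, 1),
            (0, 1, 0): RowPlan((pair(mb, n2),), True, 1),
            (1, 0, 0): RowPlan((pair(mb, n1),), True, 0),
            (0, 1, 1): RowPlan((pair(n2, n3),), False, 2),
            (1, 0, 1): RowPlan((pair(n1, n3),), False, 0),
            (1, 1, 0): RowPlan((pair(n1, n2),), False, 0),
            (1, 1, 1): RowPlan(tuple(sorted((pair(n2, n3), pair(mb, n1)))), True, 2),
        }
    raise ValueError(f"unknown circuit kind {kind!r}")


# ---------------------------------------------------------------------------
# proposal construction
# ---------------------------------------------------------------------------

def _rand_block(rng: random.Random, length: int) -> str:
    """Random filler over {A, C, T}; rejects CCC runs (their reverse
    complement would seed an unplanned G-tract)."""
    for _ in range(200):
        block = "".join(rng.choice(_FILLER_ALPHABET) for _ in range(length))
        if "CCC" not in block:
            return block
    raise RuntimeError("filler rejection sampling failed")


def _rand_stem(rng: random.Random, length: int) -> str:
    """GC-rich stem without GGG/CCC on either arm."""
    for _ in range(500):
        stem = "".join(rng.choice("GCGCAT") for _ in range(length))
        if stem.count("G") + stem.count("C") < length - 2:
            continue
        rc = reverse_complement(stem)
        if "GGG" in stem or "CCC" in stem or "GGG" in rc or "CCC" in rc:
            continue
        return stem
    raise RuntimeError("stem rejection sampling failed")


_MM_POSITIONS = {  # central mismatch placements per (k, input index)
    1: ((10,), (9,), (11,)),
    2: ((6, 13), (7, 12), (8, 14)),
}


def _opener(rng: random.Random, loop: str, k: int, input_idx: int) -> str:
    """Reverse complement of the loop with k central substitutions."""
    seq = list(reverse_complement(loop))
    for pos in _MM_POSITIONS[k][input_idx % 3]:
        options = [b for b in _FILLER_ALPHABET if b != seq[pos]]
        rng.shuffle(options)
        for b in options:
            candidate = seq.copy()
            candidate[pos] = b
            window = "".join(candidate[max(0, pos - 2) : pos + 3])
            if "CCC" not in window:
                seq = candidate
                break
    return "".join(seq)


def _propose(kind: str, rng: random.Random, c: DesignConstraints) -> StrandSet | None:
    """One seeded proposal; None when the local G-tract audit fails."""
    cdef = circuit_def(kind)
    k = c.mismatches_for(kind)
    stem = _rand_stem(rng, c.stem_len)
    loop = _rand_block(rng, c.loop_len)
    mb = Strand(BEACON_NAME, stem + loop + reverse_complement(stem), ROLE_BEACON)
    m = [_opener(rng, loop, k, i) for i in range(len(cdef.input_names))]

    if kind == HALF_ADDER:
        p = _rand_block(rng, c.pair_block_len)
        seqs = [
            SPLIT_5P + p + m[0],
            m[1] + reverse_complement(p) + SPLIT_3P,
        ]
    elif kind in (HALF_SUBTRACTOR, COMPARATOR):
        q = _rand_block(rng, 4) + _cassette(rng) + _rand_block(rng, 4)
        seqs = [
            reverse_complement(q) + m[0],
            m[1] + q,
        ]
    elif kind == FULL_ADDER:
        b12 = _rand_block(rng, c.pair_block_len)
        b13 = _rand_block(rng, c.pair_block_len)
        b23 = _rand_block(rng, c.dominant_block_len)
        seqs = [
            SPLIT_5P + b12 + m[0] + reverse_complement(b13) + SPLIT_3P,
            SPLIT_5P + b23 + m[1] + reverse_complement(b12) + SPLIT_3P,
            SPLIT_5P + b13 + m[2] + reverse_complement(b23) + SPLIT_3P,
        ]
    elif kind == FULL_SUBTRACTOR:
        x2 = _rand_block(rng, 4) + _cassette(rng) + _rand_block(rng, 4)
        x3 = _rand_block(rng, 4) + _cassette(rng) + _rand_block(rng, 4)
        b23 = _rand_block(rng, c.dominant_block_len)
        seqs = [
            reverse_complement(x2) + m[0] + reverse_complement(x3),
            x2 + m[1] + b23,
            reverse_complement(b23) + m[2] + x3,
        ]
    else:
        raise ValueError(f"unknown circuit kind {kind!r}")

    strands = [mb] + [
        Strand(name, seq, ROLE_INPUT)
        for name, seq in zip(cdef.input_names, seqs)
    ]
    if not _tract_audit(kind, strands):
        return None
    return StrandSet(strands)


def _tract_audit(kind: str, strands: list[Strand]) -> bool:
    """Every G-tract must be one the plan placed (no stray GGG from block
    boundaries), and the beacon must carry none."""
    planned = {
        HALF_ADDER: {1: 1, 2: 3},
        HALF_SUBTRACTOR: {1: 0, 2: 4},
        COMPARATOR: {1: 0, 2: 4},
        FULL_ADDER: {1: 4, 2: 4, 3: 4},
        FULL_SUBTRACTOR: {1: 0, 2: 4, 3: 4},
    }[kind]
    for idx, strand in enumerate(strands):
        tracts = find_g_tracts(strand.sequence, 3, strand.name)
        expected = 0 if idx == 0 else planned[idx]
        if len(tracts) != expected:
            return False
        if any(t.length != 3 for t in tracts):
            return False
    return True


# ---------------------------------------------------------------------------
# design checking
# ---------------------------------------------------------------------------

def check_design(
    kind: str,
    strand_set: StrandSet,
    constraints: DesignConstraints | None = None,
    params: ThermoParams | None = None,
    search: SearchConfig = SearchConfig(),
    g4_config: G4Config = G4Config(),
) -> DesignReport:
    """Verify a strand set against the intended per-row behavior.

    Checks, for every input combination: (a) the intended matching is the
    exhaustive optimum, beating the best alternative by at least the margin;
    (b) the beacon opens exactly in the intended rows; (c) quadruplex counts
    match the plan; (d) no unintended crosstalk window exceeds the cap;
    (e) every beacon-input duplex embeds exactly k mismatches.
    """
    c = constraints or DesignConstraints()
    params = params or default_params()
    cdef = circuit_def(kind)
    report = DesignReport(kind=kind, seed=None)
    plan = circuit_plan(kind)

    missing = [n for n in cdef.input_names if n not in strand_set]
    if missing:
        report.violations.append(f"missing strands: {missing}")
        return report

    candidates = enumerate_candidates(strand_set, params, search)
    inter_all, hairpin = _split_candidates(candidates)
    k = c.mismatches_for(kind)

    # (e) mismatch budget of each beacon-input duplex
    for cand in inter_all:
        if BEACON_NAME in cand.key and not cand.intramolecular:
            other = cand.strand_a if cand.strand_b == BEACON_NAME else cand.strand_b
            if cand.mismatches != k:
                report.violations.append(
                    f"beacon duplex with {other}: {cand.mismatches} mismatches, expected {k}"
                )

    if hairpin is None or hairpin.dg >= 0:
        report.violations.append("beacon lacks a stabilizing hairpin stem")

    # (a)-(c) per-row optimum, margin, beacon state, quadruplex count
    for bits, row in sorted(plan.items()):
        present = {n for n, b in zip(cdef.input_names, bits) if b}
        subset = strand_set.subset(present)
        names = {s.name for s in subset}
        inter = [c2 for c2 in inter_all if set(c2.key) <= names]
        base = _baselines(subset, hairpin)
        ranked = enumerate_matchings(subset, inter, base)
        best_total, best_key, matched = ranked[0]
        margin = float("inf")
        for total, key, _ in ranked[1:]:
            if key != best_key:
                margin = total - best_total
                break
        report.row_margins[bits] = margin
        if best_key != row.matching:
            report.violations.append(
                f"row {bits}: optimal matching {best_key} != intended {row.matching}"
            )
            continue
        if margin < c.margin:
            report.violations.append(
                f"row {bits}: margin {margin:.2f} < required {c.margin:.2f}"
            )
        state = assemble_state(subset, matched, hairpin, g4_config, 0.0)
        if state.beacon_open != row.beacon_open:
            report.violations.append(
                f"row {bits}: beacon_open={state.beacon_open}, intended {row.beacon_open}"
            )
        if state.g4_count != row.g4_count:
            report.violations.append(
                f"row {bits}: g4_count={state.g4_count}, intended {row.g4_count}"
            )

    # (d) crosstalk: no near-perfect window outside the intended interface.
    # Containment is judged by region on both strands: shifted registers
    # inside the designed interface are weaker sub-alignments the margin
    # check already dominates, whereas any qualifying window touching
    # sequence outside it is off-target.
    intended_span = {
        cand.key: (
            cand.pairing.a_start,
            cand.pairing.a_end,
            cand.pairing.b_start,
            cand.pairing.b_end,
        )
        for cand in inter_all
    }
    strands = strand_set.strands
    for i in range(len(strands)):
        for j in range(i + 1, len(strands)):
            a, b = strands[i], strands[j]
            key = tuple(sorted((a.name, b.name)))
            span = intended_span.get(key)
            for pairing, _ in duplex_windows(
                a, b, min_len=c.crosstalk_min_len, max_mismatches=c.crosstalk_max_mismatches
            ):
                contained = span is not None and (
                    pairing.a_start >= span[0]
                    and pairing.a_end <= span[1]
                    and pairing.b_start >= span[2]
                    and pairing.b_end <= span[3]
                )
                if not contained:
                    report.violations.append(
                        f"crosstalk: {key} window at a[{pairing.a_start}:{pairing.a_end}] "
                        f"outside the intended duplex"
                    )
    return report


# ---------------------------------------------------------------------------
# top-level designer
# ---------------------------------------------------------------------------

def design_strands(
    kind: str,
    seed: int,
    constraints: DesignConstraints | None = None,
    params: ThermoParams | None = None,
) -> tuple[StrandSet, DesignReport]:
    """Seeded propose-and-check design of a strand set for ``kind``.

    Deterministic for a given seed; raises :class:`DesignError` with the
    closest candidate's report after ``max_proposals`` failures.
    """
    c = constraints or DesignConstraints()
    params = params or default_params()
    rng = random.Random(seed)
    best_report: DesignReport | None = None
    for attempt in range(1, c.max_proposals + 1):
        strand_set = _propose(kind, rng, c)
        if strand_set is None:
            continue
        report = check_design(kind, strand_set, c, params)
        report.seed = seed
        report.proposals_tried = attempt
        if report.accepted:
            return strand_set, report
        if best_report is None or len(report.violations) < len(best_report.violations):
            best_report = report
    if best_report is None:
        best_report = DesignReport(kind=kind, seed=seed, proposals_tried=c.max_proposals)
        best_report.violations.append("no proposal survived the G-tract audit")
    raise DesignError(
        f"no satisfying design for {kind} within {c.max_proposals} proposals",
        best_report,
    )


def generate_fixture(
    kind: str,
    seed: int,
    noise_config: NoiseConfig | None = None,
    replicates: int = 3,
    constraints: DesignConstraints | None = None,
) -> pd.DataFrame:
    """Synthetic readout dataset emulating normalized fluorescence panels.

    One designed strand set; per input combination the noiseless channel
    intensities plus ``replicates`` seeded noisy reads. Replicate 0 is
    noiseless.
    """
    from .assembly import resolve_state  # local import to avoid cycle noise

    noise = noise_config or NoiseConfig(seed=seed)
    strand_set, _ = design_strands(kind, seed, constraints)
    cdef = circuit_def(kind)
    rng = np.random.default_rng(noise.seed)
    records = []
    from itertools import product

    for bits in product((0, 1), repeat=len(cdef.input_names)):
        present = [n for n, b in zip(cdef.input_names, bits) if b]
        state = resolve_state(strand_set.subset(present))
        clean = channel_intensities(state, fam_leak=noise.fam_leak)
        row_base = {n: b for n, b in zip(cdef.input_names, bits)}
        records.append(
            {**row_base, "replicate": 0, "fam_norm": clean.fam_norm, "nmm_norm": clean.nmm_norm}
        )
        for r in range(1, replicates + 1):
            noisy = channel_intensities(state, noise_config=noise, rng=rng)
            records.append(
                {**row_base, "replicate": r, "fam_norm": noisy.fam_norm, "nmm_norm": noisy.nmm_norm}
            )
    return pd.DataFrame.from_records(records)
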