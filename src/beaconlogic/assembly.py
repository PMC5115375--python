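"""Resolve which complexes form when inputs meet the beacon.

The platform is strand-displacement-free: all strands are mixed at one
equivalent each and the design guarantees a clear stability ordering, so the
system is modeled as a discrete winner-take-all equilibrium. Each strand
joins at most one intermolecular duplex; the realized configuration is the
matching on the strand graph minimizing total free energy, with an
unmatched beacon falling back to its closed hairpin and unmatched inputs
staying free. This discrete matching abstraction (rather than mass-action
concentrations) makes outputs exact integers and admits an exhaustive
oracle (:func:`brute_force_state`).

Reporter detection: a split G-quadruplex assembles when four G-tracts sit
close to a duplex junction on the unpaired overhangs of the two hybridized
strands; an intramolecular G-quadruplex folds from four tracts within a
short span of a single unpaired stretch. Hybridized (paired) positions
never contribute -- hybridization sequesters G-tracts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import networkx as nx

from .strands import Pairing, Region, Strand, StrandSet, find_g_tracts
from .thermo import (
    SearchConfig,
    ThermoParams,
    best_duplex,
    default_params,
    hairpin_candidate,
)

_TOL = 1e-9


@dataclass(frozen=True)
class DuplexCandidate:
    """Best pairing found for one strand pair (or the beacon's own stem)."""

    strand_a: str
    strand_b: str
    pairing: Pairing
    dg: float
    mismatches: int
    intramolecular: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.strand_a, self.strand_b)))


@dataclass(frozen=True)
class G4Config:
    """Geometry thresholds for G-quadruplex detection."""

    min_tract_len: int = 3
    tracts_required: int = 4
    junction_window: int = 15  # nt of overhang scanned on each side of a junction
    intra_span: int = 30  # max span of four tracts folding intramolecularly


@dataclass(frozen=True)
class Complex:
    """One assembled species: a duplex of two strands, or the closed beacon."""

    strands: tuple[str, ...]
    bound: DuplexCandidate

    def paired_positions(self, name: str) -> set[int]:
        pos: set[int] = set()
        if self.bound.intramolecular:
            if name == self.bound.strand_a:
                for i, j in self.bound.pairing.pairs:
                    pos.add(i)
                    pos.add(j)
            return pos
        if name == self.bound.strand_a:
            pos.update(i for i, _ in self.bound.pairing.pairs)
        if name == self.bound.strand_b:
            pos.update(j for _, j in self.bound.pairing.pairs)
        return pos


@dataclass(frozen=True)
class SystemState:
    """The resolved configuration for one input combination."""

    strand_set: StrandSet
    complexes: tuple[Complex, ...]
    free_strands: tuple[str, ...]
    total_dg: float
    beacon_open: bool
    g4_count: int = 0

    @property
    def matching(self) -> tuple[tuple[str, str], ...]:
        """Sorted name pairs of the intermolecular duplexes."""
        return tuple(
            sorted(
                c.bound.key for c in self.complexes if not c.bound.intramolecular
            )
        )

    def to_dict(self) -> dict:
        return {
            "matching": [list(p) for p in self.matching],
            "free_strands": list(self.free_strands),
            "total_dg": round(self.total_dg, 4),
            "beacon_open": self.beacon_open,
            "g4_count": self.g4_count,
            "complexes": [
                {
                    "strands": list(c.strands),
                    "intramolecular": c.bound.intramolecular,
                    "dg": round(c.bound.dg, 4),
                    "pairs": [list(p) for p in c.bound.pairing.pairs],
                }
                for c in self.complexes
            ],
        }


def enumerate_candidates(
    strand_set: StrandSet,
    params: ThermoParams | None = None,
    search: SearchConfig = SearchConfig(),
) -> list[DuplexCandidate]:
    """Best duplex for every unordered strand pair, plus the beacon stem."""
    params = params or default_params()
    out: list[DuplexCandidate] = []
    strands = strand_set.strands
    for a, b in itertools.combinations(strands, 2):
        hit = best_duplex(a, b, params, search)
        if hit is None:
            continue
        pairing, dg = hit
        out.append(
            DuplexCandidate(a.name, b.name, pairing, dg, len(pairing.mismatches))
        )
    beacon = strand_set.beacon
    stem = hairpin_candidate(beacon, params)
    if stem is not None:
        pairing, dg = stem
        out.append(
            DuplexCandidate(
                beacon.name, beacon.name, pairing, dg, 0, intramolecular=True
            )
        )
    return out


def _split_candidates(
    candidates: list[DuplexCandidate],
) -> tuple[list[DuplexCandidate], DuplexCandidate | None]:
    inter = [c for c in candidates if not c.intramolecular]
    hairpins = [c for c in candidates if c.intramolecular]
    return inter, (hairpins[0] if hairpins else None)


def _baselines(
    strand_set: StrandSet, hairpin: DuplexCandidate | None
) -> dict[str, float]:
    """Per-strand free energy when left unmatched."""
    base = {s.name: 0.0 for s in strand_set}
    if hairpin is not None and hairpin.dg < 0:
        base[strand_set.beacon.name] = hairpin.dg
    return base


def assemble_state(
    strand_set: StrandSet,
    matched: list[DuplexCandidate],
    hairpin: DuplexCandidate | None,
    g4_config: G4Config,
    open_margin: float,
) -> SystemState:
    in_duplex = {n for c in matched for n in (c.strand_a, c.strand_b)}
    complexes = [Complex((c.strand_a, c.strand_b), c) for c in matched]
    beacon = strand_set.beacon
    hairpin_dg = hairpin.dg if hairpin is not None else 0.0
    beacon_open = False
    if beacon.name in in_duplex:
        duplex_dg = next(
            c.bound.dg for c in complexes if beacon.name in c.strands
        )
        beacon_open = duplex_dg < hairpin_dg - open_margin
    elif hairpin is not None and hairpin.dg < 0:
        complexes.append(Complex((beacon.name,), hairpin))
    free = tuple(
        s.name
        for s in strand_set
        if s.name not in in_duplex
        and not (s.name == beacon.name and any(c.bound.intramolecular for c in complexes))
    )
    total = sum(c.bound.dg for c in complexes)
    state = SystemState(
        strand_set=strand_set,
        complexes=tuple(complexes),
        free_strands=free,
        total_dg=total,
        beacon_open=beacon_open,
    )
    return replace(state, g4_count=count_g_quadruplexes(state, g4_config))


def resolve_state(
    strand_set: StrandSet,
    params: ThermoParams | None = None,
    search: SearchConfig = SearchConfig(),
    g4_config: G4Config = G4Config(),
    open_margin: float = 0.0,
) -> SystemState:
    """Minimum-total-free-energy matching on the strand graph.

    Optimality is delegated to a maximum-weight matching (edge weight =
    stabilization relative to leaving both strands unmatched); among
    co-optimal matchings the lexicographically smallest set of sorted name
    pairs is chosen, so results are deterministic.
    """
    params = params or default_params()
    candidates = enumerate_candidates(strand_set, params, search)
    inter, hairpin = _split_candidates(candidates)
    base = _baselines(strand_set, hairpin)

    by_key = {c.key: c for c in inter}
    graph = nx.Graph()
    graph.add_nodes_from(s.name for s in strand_set)
    for c in inter:
        benefit = base[c.strand_a] + base[c.strand_b] - c.dg
        if benefit > _TOL:
            graph.add_edge(*c.key, weight=benefit)

    def opt_benefit(g: nx.Graph) -> float:
        m = nx.max_weight_matching(g)
        return sum(g[u][v]["weight"] for u, v in m)

    target = opt_benefit(graph)
    chosen: list[tuple[str, str]] = []
    used: set[str] = set()
    fixed_benefit = 0.0
    for key in sorted(by_key):
        if key not in graph.edges:
            continue
        a, b = key
        if a in used or b in used:
            continue
        w = graph[a][b]["weight"]
        residual = graph.copy()
        residual.remove_nodes_from(used | {a, b})
        if fixed_benefit + w + opt_benefit(residual) >= target - 1e-6:
            chosen.append(key)
            used.update(key)
            fixed_benefit += w
    matched = [by_key[k] for k in chosen]
    return assemble_state(strand_set, matched, hairpin, g4_config, open_margin)


def brute_force_state(
    strand_set: StrandSet,
    params: ThermoParams | None = None,
    search: SearchConfig = SearchConfig(),
    g4_config: G4Config = G4Config(),
    open_margin: float = 0.0,
    max_strands: int = 7,
) -> SystemState:
    """Exhaustive minimum over all matchings; test oracle for resolve_state."""
    if len(strand_set) > max_strands:
        raise ValueError(f"brute force limited to {max_strands} strands")
    params = params or default_params()
    candidates = enumerate_candidates(strand_set, params, search)
    inter, hairpin = _split_candidates(candidates)
    base = _baselines(strand_set, hairpin)
    ranked = enumerate_matchings(strand_set, inter, base)
    _, _, matched = ranked[0]
    return assemble_state(strand_set, matched, hairpin, g4_config, open_margin)


def enumerate_matchings(
    strand_set: StrandSet,
    inter: list[DuplexCandidate],
    base: dict[str, float],
) -> list[tuple[float, tuple[tuple[str, str], ...], list[DuplexCandidate]]]:
    """All matchings as (total_dg, sorted key tuple, candidates), best first.

    Ordering: ascending total dG, ties broken toward the lexicographically
    smaller key tuple (hence fewer duplexes when a duplex adds nothing).
    """
    inter = sorted(inter, key=lambda c: c.key)
    results: list[tuple[float, tuple[tuple[str, str], ...], list[DuplexCandidate]]] = []

    def recurse(idx: int, used: set[str], taken: list[DuplexCandidate]) -> None:
        if idx == len(inter):
            total = sum(c.dg for c in taken) + sum(
                base[s.name] for s in strand_set if s.name not in used
            )
            key = tuple(sorted(c.key for c in taken))
            results.append((total, key, list(taken)))
            return
        c = inter[idx]
        recurse(idx + 1, used, taken)
        if c.strand_a not in used and c.strand_b not in used:
            taken.append(c)
            recurse(idx + 1, used | {c.strand_a, c.strand_b}, taken)
            taken.pop()

    recurse(0, set(), [])
    # near-equal totals are grouped (1e-9 tolerance) and ordered by key
    results.sort(key=lambda r: r[1])
    results.sort(key=lambda r: r[0])
    out = []
    i = 0
    while i < len(results):
        j = i
        while j < len(results) and results[j][0] - results[i][0] <= _TOL:
            j += 1
        out.extend(sorted(results[i:j], key=lambda r: r[1]))
        i = j
    return out


# ---------------------------------------------------------------------------
# G-quadruplex counting
# ---------------------------------------------------------------------------

def count_g_quadruplexes(state: SystemState, g4_config: G4Config = G4Config()) -> int:
    """Count G-quadruplex equivalents formed in a resolved state.

    Two formation routes are scored, in this order:

    1. *intramolecular*: four unconsumed G-tracts lying in one unpaired
       stretch of a single strand within ``intra_span`` nt fold into one
       quadruplex (free strands included);
    2. *split (junction)*: at each end of an intermolecular duplex, tracts
       on the unpaired overhangs of both strands within ``junction_window``
       nt of the junction are pooled; if together they reach
       ``tracts_required`` the junction contributes exactly one quadruplex.

    Tracts already consumed by one quadruplex never count again, and paired
    positions never contribute.
    """
    cfg = g4_config
    sset = state.strand_set

    paired: dict[str, set[int]] = {s.name: set() for s in sset}
    for cplx in state.complexes:
        for name in set(cplx.strands):
            paired[name] |= cplx.paired_positions(name)

    tracts: dict[str, list[Region]] = {}
    for s in sset:
        tracts[s.name] = [
            t
            for t in find_g_tracts(s.sequence, cfg.min_tract_len, s.name)
            if not any(p in paired[s.name] for p in range(t.start, t.end))
        ]
    consumed: set[tuple[str, int, int]] = set()

    def tract_id(t: Region) -> tuple[str, int, int]:
        return (t.strand_name, t.start, t.end)

    count = 0

    # route 1: intramolecular cassettes, per maximal unpaired run
    for s in sset:
        runs = _unpaired_runs(len(s.sequence), paired[s.name])
        for run_start, run_end in runs:
            inside = [
                t
                for t in tracts[s.name]
                if run_start <= t.start and t.end <= run_end
                and tract_id(t) not in consumed
            ]
            i = 0
            while i + cfg.tracts_required <= len(inside):
                group = inside[i : i + cfg.tracts_required]
                if group[-1].end - group[0].start <= cfg.intra_span:
                    count += 1
                    consumed.update(tract_id(t) for t in group)
                    i += cfg.tracts_required
                else:
                    i += 1

    # route 2: split quadruplexes at duplex junctions
    for cplx in state.complexes:
        b = cplx.bound
        if b.intramolecular:
            continue
        junctions = (
            # (strand, unpaired window) per side; window is half-open
            (
                (b.strand_a, b.pairing.a_start - cfg.junction_window, b.pairing.a_start),
                (b.strand_b, b.pairing.b_end, b.pairing.b_end + cfg.junction_window),
            ),
            (
                (b.strand_a, b.pairing.a_end, b.pairing.a_end + cfg.junction_window),
                (b.strand_b, b.pairing.b_start - cfg.junction_window, b.pairing.b_start),
            ),
        )
        for junction in junctions:
            pooled: list[Region] = []
            for name, lo, hi in junction:
                for t in tracts[name]:
                    if tract_id(t) in consumed:
                        continue
                    if t.start >= lo and t.end <= hi:
                        pooled.append(t)
            if len(pooled) >= cfg.tracts_required:
                count += 1
                consumed.update(tract_id(t) for t in pooled)
    return count


def _unpaired_runs(length: int, paired: set[int]) -> list[tuple[int, int]]:
    """Maximal unpaired stretches as half-open (start, end) intervals."""
    runs = []
    start = None
    for i in range(length):
        if i not in paired:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i))
                start = None
    if start is not None:
        runs.append((start, length))
    return runs
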