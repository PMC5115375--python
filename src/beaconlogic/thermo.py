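"""Free-energy scoring of duplexes and the beacon hairpin.

The model is a nearest-neighbor sum: consecutive Watson-Crick base pairs
contribute a stacking term (negative, stabilizing); every duplex pays one
initiation penalty; each mismatched position pays a flat destabilizing
penalty (internal mismatches cost more than terminal ones). Mismatches are
used ordinally in beacon circuit design -- an embedded mismatch weakens a
beacon-input duplex just enough that a later, fully complementary
input-input duplex outcompetes it -- so a flat penalty preserves every
ordering the designs rely on while keeping the parameter surface small.
Full mismatch-specific tables can be substituted through ``ThermoParams``
without any API change.

Energies are dG at 37 C in kcal/mol; more negative means more stable. No
salt correction is applied: only relative orderings drive the logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .strands import Pairing, Strand, duplex_windows, is_watson_crick

_DEFAULT_PARAM_RESOURCE = "thermo_dg37.tsv"


@dataclass(frozen=True)
class ThermoParams:
    """Nearest-neighbor table plus scalar penalties (kcal/mol)."""

    nn_table: dict[str, float]
    initiation: float
    mismatch_internal: float
    mismatch_terminal: float
    loop_table: dict[int, float]

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.nn_table.values()):
            raise ValueError("all WC stack energies must be negative")
        if min(self.initiation, self.mismatch_internal, self.mismatch_terminal) < 0:
            raise ValueError("penalties must be non-negative")

    def hairpin_loop_penalty(self, loop_len: int) -> float:
        """Loop-closure cost; tabulated 3..30 nt, constant beyond."""
        if loop_len < min(self.loop_table):
            raise ValueError(f"hairpin loop too short: {loop_len} nt")
        return self.loop_table.get(loop_len, self.loop_table[max(self.loop_table)])

    @classmethod
    def load(cls, path=None) -> "ThermoParams":
        """Load from a tab-separated file (``stack``/``scalar``/``loop`` rows)."""
        if path is None:
            ref = resources.files("beaconlogic.data") / _DEFAULT_PARAM_RESOURCE
            text = ref.read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        nn: dict[str, float] = {}
        scalars: dict[str, float] = {}
        loops: dict[int, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, key, value = line.split("\t")
            if kind == "stack":
                nn[key] = float(value)
            elif kind == "scalar":
                scalars[key] = float(value)
            elif kind == "loop":
                loops[int(key)] = float(value)
            else:
                raise ValueError(f"unknown parameter row kind: {kind!r}")
        return cls(
            nn_table=nn,
            initiation=scalars["initiation"],
            mismatch_internal=scalars["mismatch_internal"],
            mismatch_terminal=scalars["mismatch_terminal"],
            loop_table=loops,
        )


@lru_cache(maxsize=1)
def default_params() -> ThermoParams:
    return ThermoParams.load()


@dataclass(frozen=True)
class SearchConfig:
    """Window search bounds used when scoring strand pairs."""

    min_len: int = 6
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.min_len < 4:
            raise ValueError("min_len must be >= 4")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def _wc_flags(seq_a: str, seq_b: str, pairing: Pairing) -> list[bool]:
    flags = []
    for i, j in pairing.pairs:
        if not (0 <= i < len(seq_a) and 0 <= j < len(seq_b)):
            raise IndexError(f"pairing index ({i}, {j}) out of range")
        flags.append(is_watson_crick(seq_a[i], seq_b[j]))
    return flags


def _pairing_energy(seq_a: str, seq_b: str, pairing: Pairing, params: ThermoParams) -> float:
    """Shared stack + mismatch sum (no initiation, no loop term)."""
    wc = _wc_flags(seq_a, seq_b, pairing)
    pairs = pairing.pairs
    dg = 0.0
    for k in range(len(pairs) - 1):
        (i0, j0), (i1, j1) = pairs[k], pairs[k + 1]
        if i1 != i0 + 1 or j1 != j0 - 1:
            raise ValueError("pairing is not gapless antiparallel")
        if wc[k] and wc[k + 1]:
            dg += params.nn_table[seq_a[i0] + seq_a[i1]]
    last = len(pairs) - 1
    for k, flag in enumerate(wc):
        if not flag:
            dg += (
                params.mismatch_terminal
                if k in (0, last)
                else params.mismatch_internal
            )
    return dg


def duplex_free_energy(
    strand_a: Strand | str,
    strand_b: Strand | str,
    pairing: Pairing,
    params: ThermoParams | None = None,
) -> float:
    """dG (kcal/mol) of an intermolecular duplex window.

    Sum of WC nearest-neighbor stacks over consecutive perfectly paired
    steps, plus one initiation penalty, plus flat penalties per mismatch.
    A single isolated base pair scores the initiation penalty alone.
    """
    params = params or default_params()
    seq_a = strand_a.sequence if isinstance(strand_a, Strand) else strand_a
    seq_b = strand_b.sequence if isinstance(strand_b, Strand) else strand_b
    return params.initiation + _pairing_energy(seq_a, seq_b, pairing, params)


def hairpin_free_energy(
    beacon: Strand | str,
    stem_pairing: Pairing,
    params: ThermoParams | None = None,
) -> float:
    """dG of the beacon hairpin: stem stacks + loop penalty + initiation.

    ``stem_pairing`` pairs the 5' arm against the 3' arm of the same strand
    (each pair ``(i, j)`` with ``i < j``); the enclosed loop is the unpaired
    stretch between the innermost pair.
    """
    params = params or default_params()
    seq = beacon.sequence if isinstance(beacon, Strand) else beacon
    max_i = max(i for i, _ in stem_pairing.pairs)
    min_j = min(j for _, j in stem_pairing.pairs)
    if max_i >= min_j:
        raise ValueError("stem arms overlap")
    loop_len = min_j - max_i - 1
    return (
        params.initiation
        + params.hairpin_loop_penalty(loop_len)
        + _pairing_energy(seq, seq, stem_pairing, params)
    )


def best_duplex(
    strand_a: Strand | str,
    strand_b: Strand | str,
    params: ThermoParams | None = None,
    search: SearchConfig = SearchConfig(),
) -> tuple[Pairing, float] | None:
    """Minimum-dG duplex window between two strands, or ``None``.

    Ties (within 1e-9 kcal/mol) break toward the earlier window start on
    strand *a*, then on strand *b*.
    """
    params = params or default_params()
    windows = duplex_windows(
        strand_a, strand_b, min_len=search.min_len, max_mismatches=search.max_mismatches
    )
    if not windows:
        return None
    best: tuple[Pairing, float] | None = None
    for pairing, _ in windows:
        dg = duplex_free_energy(strand_a, strand_b, pairing, params)
        if best is None:
            best = (pairing, dg)
            continue
        if dg < best[1] - 1e-9:
            best = (pairing, dg)
        elif abs(dg - best[1]) <= 1e-9 and (pairing.a_start, pairing.b_start) < (
            best[0].a_start,
            best[0].b_start,
        ):
            best = (pairing, dg)
    return best


def hairpin_candidate(
    beacon: Strand,
    params: ThermoParams | None = None,
    min_stem: int = 3,
    min_loop: int = 3,
) -> tuple[Pairing, float] | None:
    """Terminal-anchored beacon stem and its dG, or ``None`` if no stem.

    Molecular beacons carry the fluorophore and quencher on their termini,
    so the stem is taken as the longest perfect WC pairing of the 5' end
    against the 3' end starting at both termini.
    """
    params = params or default_params()
    seq = beacon.sequence
    n = len(seq)
    s = 0
    while (
        s < (n - min_loop) // 2
        and is_watson_crick(seq[s], seq[n - 1 - s])
    ):
        s += 1
    if s < min_stem:
        return None
    pairs = tuple((i, n - 1 - i) for i in range(s))
    pairing = Pairing(pairs)
    return pairing, hairpin_free_energy(beacon, pairing, params)
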