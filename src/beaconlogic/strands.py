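"""Strand representation, complementarity search, and G-tract detection.

Conventions used throughout the package:

* every sequence is stored 5'->3' over the uppercase alphabet {A, C, G, T};
* coordinates are 0-based, half-open;
* a duplex is antiparallel and gapless: if position ``i`` of strand *a* pairs
  with position ``j`` of strand *b*, then ``i + 1`` pairs with ``j - 1``.
  Equivalently every base pair of one window satisfies ``i + j = const``
  (the alignment "diagonal");
* a mismatch is any paired position that is not a Watson-Crick pair
  (G.T wobbles count as mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

ROLE_BEACON = "beacon"
ROLE_INPUT = "input"
_ROLES = (ROLE_BEACON, ROLE_INPUT)


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise AlphabetError("empty sequence")
    bad = set(sequence) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-ACGT characters in sequence: {sorted(bad)}")


def is_watson_crick(x: str, y: str) -> bool:
    """True iff bases ``x`` and ``y`` form a Watson-Crick pair."""
    return _COMPLEMENT.get(x) == y


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement, returned 5'->3'."""
    _validate_sequence(sequence)
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class Strand:
    """A named DNA oligonucleotide, written 5'->3'."""

    name: str
    sequence: str
    role: str = ROLE_INPUT

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("strand name must be non-empty")
        _validate_sequence(self.sequence)
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Region:
    """Half-open interval ``[start, end)`` on a named strand."""

    strand_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class StrandSet:
    """An ordered collection of strands containing exactly one beacon."""

    def __init__(self, strands: Iterable[Strand]):
        self._strands = tuple(strands)
        names = [s.name for s in self._strands]
        if len(set(names)) != len(names):
            raise ValueError("strand names must be unique")
        beacons = [s for s in self._strands if s.role == ROLE_BEACON]
        if len(beacons) != 1:
            raise ValueError(f"expected exactly one beacon, found {len(beacons)}")
        self._by_name = {s.name: s for s in self._strands}
        self._beacon = beacons[0]

    @property
    def strands(self) -> tuple[Strand, ...]:
        return self._strands

    @property
    def beacon(self) -> Strand:
        return self._beacon

    @property
    def inputs(self) -> tuple[Strand, ...]:
        return tuple(s for s in self._strands if s.role == ROLE_INPUT)

    def __iter__(self) -> Iterator[Strand]:
        return iter(self._strands)

    def __len__(self) -> int:
        return len(self._strands)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Strand:
        return self._by_name[name]

    def subset(self, input_names: Iterable[str]) -> "StrandSet":
        """Beacon plus the named inputs, preserving order."""
        wanted = set(input_names)
        missing = wanted - {s.name for s in self._strands}
        if missing:
            raise KeyError(f"unknown strands: {sorted(missing)}")
        kept = [
            s
            for s in self._strands
            if s.role == ROLE_BEACON or s.name in wanted
        ]
        return StrandSet(kept)


def find_g_tracts(
    sequence: str, min_tract_len: int = 3, strand_name: str = ""
) -> list[Region]:
    """Maximal runs of >= ``min_tract_len`` consecutive G, left to right.

    Returned regions are disjoint, ordered, and not extendable in either
    direction. Four such tracts folding back on one another form a
    G-quadruplex; a "split" quadruplex pools tracts from two strands.
    """
    _validate_sequence(sequence)
    if min_tract_len < 1:
        raise ValueError("min_tract_len must be >= 1")
    tracts: list[Region] = []
    i = 0
    n = len(sequence)
    while i < n:
        if sequence[i] == "G":
            j = i
            while j < n and sequence[j] == "G":
                j += 1
            if j - i >= min_tract_len:
                tracts.append(Region(strand_name, i, j))
            i = j
        else:
            i += 1
    return tracts


@dataclass(frozen=True)
class Pairing:
    """A gapless antiparallel pairing between two strand windows.

    ``pairs`` lists ``(i, j)`` base pairs with ``i`` ascending on strand *a*
    and ``j`` descending on strand *b* (``i + j`` constant). ``mismatches``
    holds the indices into ``pairs`` whose bases are not Watson-Crick.
    For intramolecular pairings (the beacon stem) both indices address the
    same strand and ``i < j`` for every pair.
    """

    pairs: tuple[tuple[int, int], ...]
    mismatches: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("pairing must contain at least one base pair")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_start(self) -> int:
        return self.pairs[0][0]

    @property
    def a_end(self) -> int:
        return self.pairs[-1][0] + 1

    @property
    def b_start(self) -> int:
        return self.pairs[-1][1]

    @property
    def b_end(self) -> int:
        return self.pairs[0][1] + 1

    def mirrored(self) -> "Pairing":
        """The same physical duplex described from strand *b*'s viewpoint."""
        flipped = tuple((j, i) for i, j in reversed(self.pairs))
        n = len(self.pairs)
        mm = tuple(sorted(n - 1 - k for k in self.mismatches))
        return Pairing(flipped, mm)


def _seq_of(strand: "Strand | str") -> str:
    return strand.sequence if isinstance(strand, Strand) else strand


def duplex_windows(
    strand_a: "Strand | str",
    strand_b: "Strand | str",
    min_len: int = 4,
    max_mismatches: int = 0,
) -> list[tuple[Pairing, int]]:
    """Enumerate gapless antiparallel duplex windows between two strands.

    For every alignment diagonal the paired positions decompose into maximal
    Watson-Crick runs separated by mismatches. A window is any concatenation
    of consecutive runs (its termini are therefore always Watson-Crick
    paired; trimming a terminal mismatch never destabilizes a duplex) whose
    internal mismatch total is <= ``max_mismatches`` and whose paired length
    is >= ``min_len``. Every candidate that can minimize the free energy is
    of this form, because extending a window to a full run only adds
    negative stack terms.

    Returns ``(pairing, mismatch_count)`` tuples; empty list if nothing
    qualifies.
    """
    seq_a = _seq_of(strand_a)
    seq_b = _seq_of(strand_b)
    _validate_sequence(seq_a)
    _validate_sequence(seq_b)
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")

    la, lb = len(seq_a), len(seq_b)
    out: list[tuple[Pairing, int]] = []
    for diag in range(la + lb - 1):
        i_lo = max(0, diag - (lb - 1))
        i_hi = min(la - 1, diag)
        # maximal WC runs on this diagonal, as (i_start, i_end) inclusive
        runs: list[tuple[int, int]] = []
        run_start: int | None = None
        for i in range(i_lo, i_hi + 1):
            if is_watson_crick(seq_a[i], seq_b[diag - i]):
                if run_start is None:
                    run_start = i
            else:
                if run_start is not None:
                    runs.append((run_start, i - 1))
                    run_start = None
        if run_start is not None:
            runs.append((run_start, i_hi))
        # windows spanning runs r..s with <= max_mismatches internal defects
        for r in range(len(runs)):
            for s in range(r, len(runs)):
                n_mm = sum(
                    runs[t + 1][0] - runs[t][1] - 1 for t in range(r, s)
                )
                if n_mm > max_mismatches:
                    break
                start, end = runs[r][0], runs[s][1]
                if end - start + 1 < min_len:
                    continue
                pairs = tuple((i, diag - i) for i in range(start, end + 1))
                mm_idx = tuple(
                    k
                    for k, (i, j) in enumerate(pairs)
                    if not is_watson_crick(seq_a[i], seq_b[j])
                )
                out.append((Pairing(pairs, mm_idx), n_mm))
    return out


# ---------------------------------------------------------------------------
# FASTA I/O: record description carries the role, e.g. ">MB role=beacon".
# ---------------------------------------------------------------------------

def read_fasta(path) -> StrandSet:
    """Read a strand set from FASTA; names may contain spaces."""
    strands = []
    for record in SeqIO.parse(str(path), "fasta"):
        tokens = record.description.split()
        role = ROLE_INPUT
        name_tokens = []
        for tok in tokens:
            if tok.startswith("role="):
                role = tok[len("role="):]
            else:
                name_tokens.append(tok)
        name = " ".join(name_tokens)
        strands.append(Strand(name, str(record.seq).upper(), role))
    if not strands:
        raise ValueError(f"no FASTA records found in {path}")
    return StrandSet(strands)


def write_fasta(strand_set: StrandSet, path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.name, description=f"role={s.role}")
        for s in strand_set
    ]
    SeqIO.write(records, str(path), "fasta")
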