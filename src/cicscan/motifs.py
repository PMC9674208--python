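"""Degenerate-motif expansion and exact scanning of peak sequences.

Two probe sets drive the whole analysis:

* the consensus CIC octamer, expanding to the four literal 8-mers
  TGAATGAA, TCAATGAA, TGAATGGA and TCAATGGA.  The motif is conventionally
  typeset ``T(G/C)AAT(G/A)AA`` in the literature, but that shorthand does
  not Cartesian-expand to the four canonical literals; the positionally
  exact pattern is ``T(G/C)AATG(A/G)A`` and that is what is expanded here
  (the literal inventory is what the scan actually uses), and
* the GGAA-repeat element ``[GGAA]n`` with n >= 2 consecutive units
  (minimally the 8-mer GGAAGGAA), the non-consensus binding element.

Scanning is an exact, case-insensitive string search on the forward strand
(reverse-complement probes can be added with ``both_strands=True``); there is
no mismatch tolerance and no position-weight scoring.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

_VALID_BASES = frozenset("ACGT")

# positionally exact form of the consensus octamer (typeset T(G/C)AAT(G/A)AA
# in the literature); expands to TGAATGAA, TCAATGAA, TGAATGGA, TCAATGGA
OCTAMER_PATTERN = "T(G/C)AATG(A/G)A"
GGAA_UNIT = "GGAA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MotifPatternError(ValueError):
    """Raised for a malformed degenerate pattern."""


def expand_degenerate_motif(pattern: str) -> frozenset[str]:
    """Expand a degenerate pattern with ``(X/Y/...)`` alternations.

    Fixed positions must be A/C/G/T; each parenthesised group lists the
    alternative bases separated by ``/``.  The result is the Cartesian
    product of all alternations, as an (order-independent) set of literal
    DNA strings.

    >>> sorted(expand_degenerate_motif("T(G/C)AATG(A/G)A"))
    ['TCAATGAA', 'TCAATGGA', 'TGAATGAA', 'TGAATGGA']
    """
    if not pattern:
        raise MotifPatternError("empty pattern")
    choices: list[tuple[str, ...]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            j = pattern.find(")", i)
            if j < 0:
                raise MotifPatternError(f"unbalanced parenthesis in {pattern!r}")
            alts = tuple(pattern[i + 1 : j].split("/"))
            if len(alts) < 2 or any(a not in _VALID_BASES for a in alts):
                raise MotifPatternError(
                    f"alternation {pattern[i:j + 1]!r} must list 2+ bases from ACGT"
                )
            choices.append(alts)
            i = j + 1
        elif ch == ")":
            raise MotifPatternError(f"unbalanced parenthesis in {pattern!r}")
        elif ch.upper() in _VALID_BASES:
            choices.append((ch.upper(),))
            i += 1
        else:
            raise MotifPatternError(f"non-ACGT symbol {ch!r} in {pattern!r}")
    return frozenset("".join(p) for p in itertools.product(*choices))


@dataclass(frozen=True)
class MotifSet:
    """A named probe set: degenerate pattern plus its expanded literals."""

    name: str
    degenerate_pattern: str
    literals: frozenset[str]
    min_repeat_units: int | None = None

    def __post_init__(self) -> None:
        for lit in self.literals:
            if not lit or set(lit) - _VALID_BASES:
                raise ValueError(f"literal {lit!r} is not a DNA string")


def cic_octamer() -> MotifSet:
    """The consensus CIC octamer probe set (four literal 8-mers)."""
    return MotifSet("CIC_octamer", OCTAMER_PATTERN, expand_degenerate_motif(OCTAMER_PATTERN))


def ggaa_repeat(min_units: int = 2) -> MotifSet:
    """The GGAA-repeat probe set; the probe literal is GGAA x min_units."""
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    return MotifSet(
        "GGAA_repeat",
        f"[{GGAA_UNIT}]n",
        frozenset({GGAA_UNIT * min_units}),
        min_repeat_units=min_units,
    )


def default_motif_sets(min_units: int = 2) -> tuple[MotifSet, MotifSet]:
    return (cic_octamer(), ggaa_repeat(min_units))


def probe_inventory(min_units: int = 2) -> frozenset[str]:
    """All literal probe strings searched for: the octamer expansion plus
    the repeat probe (five strings at the default min_units=2)."""
    sets = default_motif_sets(min_units)
    return frozenset().union(*(m.literals for m in sets))


@dataclass(frozen=True)
class MotifHit:
    """One exact match: an octamer occurrence or a maximal GGAA run."""

    sequence_id: str
    motif_set: str
    literal: str
    start: int
    end: int
    run_units: int | None = None  # only for repeat-run hits

    def __post_init__(self) -> None:
        if self.run_units is None:
            expected = len(self.literal)
        else:
            expected = 4 * self.run_units
        if self.end - self.start != expected:
            raise ValueError(f"hit span [{self.start},{self.end}) inconsistent with match")


def _clean(sequence: str) -> str:
    return sequence.upper()


def find_octamer_hits(
    sequence: str, motif_set: MotifSet | None = None, sequence_id: str = ""
) -> list[MotifHit]:
    """Report every position where any octamer literal matches exactly.

    Overlapping occurrences are all reported; positions containing N never
    match.  Hits are sorted by start, ties by literal.
    """
    if motif_set is None:
        motif_set = cic_octamer()
    seq = _clean(sequence)
    hits: list[MotifHit] = []
    for lit in motif_set.literals:
        start = seq.find(lit)
        while start != -1:
            hits.append(MotifHit(sequence_id, motif_set.name, lit, start, start + len(lit)))
            start = seq.find(lit, start + 1)
    hits.sort(key=lambda h: (h.start, h.literal))
    return hits


def find_ggaa_repeats(
    sequence: str, min_units: int = 2, sequence_id: str = "", unit: str = GGAA_UNIT
) -> list[MotifHit]:
    """Find maximal runs of consecutive GGAA units, greedily left to right.

    A run starts at the leftmost position where a unit matches, extends by
    whole units as far as possible, and is reported once with its unit count
    (the register of the first unit fixes the run's phase).  Only runs of at
    least ``min_units`` units are reported.
    """
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    seq = _clean(sequence)
    u = len(unit)
    hits: list[MotifHit] = []
    i = 0
    n = len(seq)
    while i <= n - u:
        if seq[i : i + u] == unit:
            k = 1
            while seq[i + k * u : i + (k + 1) * u] == unit:
                k += 1
            if k >= min_units:
                hits.append(
                    MotifHit(sequence_id, "GGAA_repeat", unit * k, i, i + k * u, run_units=k)
                )
            i += k * u
        else:
            i += 1
    return hits


@dataclass
class ScanResult:
    """Per-sequence presence flags and hit lists for each probe set."""

    sequence_id: str
    presence: dict[str, bool] = field(default_factory=dict)
    hits: list[MotifHit] = field(default_factory=list)

    def has(self, motif_set_name: str) -> bool:
        return self.presence.get(motif_set_name, False)


def scan_sequence(
    sequence_id: str,
    sequence: str,
    motif_sets: Iterable[MotifSet] | None = None,
    both_strands: bool = False,
) -> ScanResult:
    """Scan one sequence against each probe set; presence = at least one hit.

    With ``both_strands=True`` the reverse-complement probes are also
    searched on the forward sequence (TTCCTTCC etc.); hit coordinates stay
    on the forward strand.
    """
    if motif_sets is None:
        motif_sets = default_motif_sets()
    result = ScanResult(sequence_id)
    for mset in motif_sets:
        if mset.min_repeat_units is not None:
            hits = find_ggaa_repeats(sequence, mset.min_repeat_units, sequence_id)
            if both_strands:
                hits += find_ggaa_repeats(
                    sequence, mset.min_repeat_units, sequence_id,
                    unit=reverse_complement(GGAA_UNIT),
                )
        else:
            hits = find_octamer_hits(sequence, mset, sequence_id)
            if both_strands:
                rc_set = MotifSet(
                    mset.name, mset.degenerate_pattern,
                    frozenset(reverse_complement(l) for l in mset.literals),
                )
                hits += find_octamer_hits(sequence, rc_set, sequence_id)
        result.presence[mset.name] = len(hits) > 0
        result.hits.extend(hits)
    result.hits.sort(key=lambda h: (h.start, h.motif_set, h.literal))
    return result


class CoordinateError(ValueError):
    """Peak interval outside the genome it is being extracted from."""


def extract_peak_sequences(genome: Mapping[str, object], peaks: Sequence) -> dict[str, str]:
    """Extract the uppercased sequence of each peak from a genome mapping.

    ``genome`` maps chromosome name to anything sliceable whose slice
    stringifies to sequence (a plain ``str`` or a ``pyfaidx.FastaRecord``).
    Peaks use 0-based half-open coordinates.
    """
    out: dict[str, str] = {}
    for pk in peaks:
        if pk.chrom not in genome:
            raise CoordinateError(f"peak {pk.name}: unknown chromosome {pk.chrom!r}")
        record = genome[pk.chrom]
        length = len(record)
        if pk.start < 0 or pk.end > length:
            raise CoordinateError(
                f"peak {pk.name}: [{pk.start},{pk.end}) outside {pk.chrom} (length {length})"
            )
        out[pk.name] = str(record[pk.start : pk.end]).upper()
    return out


def hits_to_bed6(hits: Iterable[MotifHit], peak_offsets: Mapping[str, tuple[str, int]]) -> str:
    """Render hits as BED6 text, shifting peak-local offsets to genomic
    coordinates via ``peak_offsets[sequence_id] = (chrom, peak_start)``."""
    lines = []
    for h in hits:
        chrom, off = peak_offsets[h.sequence_id]
        score = h.run_units if h.run_units is not None else 0
        lines.append(f"{chrom}\t{off + h.start}\t{off + h.end}\t{h.literal}\t{score}\t+")
    return "\n".join(lines) + ("\n" if lines else "")
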