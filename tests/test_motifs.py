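"""Motif expansion and exact-scan behaviour against naive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cicscan.motifs import (
    GGAA_UNIT,
    MotifHit,
    MotifPatternError,
    CoordinateError,
    cic_octamer,
    default_motif_sets,
    expand_degenerate_motif,
    extract_peak_sequences,
    find_ggaa_repeats,
    find_octamer_hits,
    ggaa_repeat,
    probe_inventory,
    scan_sequence,
)

FIVE_PROBES = {"GGAAGGAA", "TGAATGAA", "TCAATGGA", "TCAATGAA", "TGAATGGA"}


# ------------------------------------------------------------ expansion ----

@pytest.mark.parametrize(
    "pattern,expected",
    [
        ("T(G/C)AATG(A/G)A", {"TGAATGAA", "TCAATGAA", "TGAATGGA", "TCAATGGA"}),
        ("GGAA", {"GGAA"}),
        ("(A/C)(G/T)", {"AG", "AT", "CG", "CT"}),  # brute-force 2x2 product
        ("A", {"A"}),
    ],
)
def test_expand_degenerate_motif(pattern, expected):
    assert expand_degenerate_motif(pattern) == expected


@pytest.mark.parametrize("bad", ["", "T(G/C", "A)G", "T(GC)A", "T(G/X)A", "TNA", "(G)"])
def test_expand_rejects_malformed_patterns(bad):
    with pytest.raises(MotifPatternError):
        expand_degenerate_motif(bad)


def test_probe_inventory_is_the_five_method_strings():
    """The scanner's literal set is exactly the four octamer expansions
    plus the 2-unit GGAA repeat probe."""
    assert probe_inventory() == FIVE_PROBES
    assert cic_octamer().literals == FIVE_PROBES - {"GGAAGGAA"}
    assert ggaa_repeat(2).literals == {"GGAAGGAA"}


# --------------------------------------------------------------- oracles ---

def oracle_octamer_hits(seq: str, literals) -> list[tuple[int, str]]:
    """Try every offset; overlapping occurrences all count."""
    s = seq.upper()
    return sorted(
        (i, lit)
        for lit in literals
        for i in range(len(s) - len(lit) + 1)
        if s[i : i + len(lit)] == lit
    )


def oracle_ggaa_runs(seq: str, min_units: int) -> list[tuple[int, int]]:
    """Declarative maximal-run rule: a start is reported iff its unit count
    reaches min_units and the run is not left-extendable by a full unit."""
    s = seq.upper()
    u = len(GGAA_UNIT)

    def units(i: int) -> int:
        k = 0
        while s[i + k * u : i + (k + 1) * u] == GGAA_UNIT:
            k += 1
        return k

    return sorted(
        (i, units(i))
        for i in range(len(s) - u + 1)
        if units(i) >= min_units and (i < u or s[i - u : i] != GGAA_UNIT)
    )


def random_sequences(n, max_len, seed, alphabet="ACGT"):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        length = int(rng.integers(0, max_len + 1))
        yield "".join(rng.choice(list(alphabet), size=length))


def test_octamer_hits_match_bruteforce_oracle():
    literals = cic_octamer().literals
    # GGAA-rich alphabet so probes actually occur
    for seq in random_sequences(1000, 300, seed=2024, alphabet="ACGTGGAATGAA"):
        got = [(h.start, h.literal) for h in find_octamer_hits(seq)]
        assert sorted(got) == oracle_octamer_hits(seq, literals)


@pytest.mark.parametrize("min_units", [2, 3])
def test_ggaa_runs_match_maximality_oracle(min_units):
    for seq in random_sequences(1000, 300, seed=77, alphabet="GAGGAATC"):
        got = sorted((h.start, h.run_units) for h in find_ggaa_repeats(seq, min_units))
        assert got == oracle_ggaa_runs(seq, min_units)


@pytest.mark.parametrize(
    "seq,min_units,expected",
    [
        ("GGAAGGAA", 2, [(0, 8, 2)]),
        ("GGAAGAAA", 2, []),  # GGAA -> GAAA point change breaks the run
        ("GGAAGGAAGGAA", 2, [(0, 12, 3)]),  # one 3-unit run, not two 2-unit hits
        ("GGAA", 2, []),
        ("GGAA", 1, [(0, 4, 1)]),
        ("AGGAAGGAATGGAAGGAA", 2, [(1, 9, 2), (10, 18, 2)]),
    ],
)
def test_ggaa_repeat_examples(seq, min_units, expected):
    got = [(h.start, h.end, h.run_units) for h in find_ggaa_repeats(seq, min_units)]
    assert got == expected


def test_octamer_examples():
    hits = find_octamer_hits("TGAATGAA")
    assert [(h.start, h.end, h.literal) for h in hits] == [(0, 8, "TGAATGAA")]
    assert find_octamer_hits("") == []
    assert find_octamer_hits("TGANTGAA") == []  # N never matches


def test_min_units_monotonicity():
    """Raising min_units never adds hits."""
    for seq in random_sequences(200, 200, seed=5, alphabet="GAGGAA"):
        prev = None
        for m in (2, 3, 4):
            starts = {h.start for h in find_ggaa_repeats(seq, m)}
            if prev is not None:
                assert starts <= prev
            prev = starts


def test_bad_min_units():
    with pytest.raises(ValueError):
        find_ggaa_repeats("GGAAGGAA", 0)


# ------------------------------------------------------------------ scan ---

def test_scan_sequence_flags_consistent_with_hits():
    for seq in random_sequences(500, 200, seed=12, alphabet="ACGTGGAATGAA"):
        res = scan_sequence("s", seq)
        for mset in default_motif_sets():
            n = sum(1 for h in res.hits if h.motif_set == mset.name)
            assert res.presence[mset.name] == (n > 0)


def test_scan_sequence_both_motifs_and_neither():
    res = scan_sequence("s", "CCCTCAATGGACCCGGAAGGAACCC")
    assert res.presence == {"CIC_octamer": True, "GGAA_repeat": True}
    res = scan_sequence("s", "A" * 60)
    assert res.presence == {"CIC_octamer": False, "GGAA_repeat": False}


@given(st.text(alphabet="ACGTN", max_size=200))
@settings(max_examples=200, derandomize=True)
def test_scan_case_insensitive(seq):
    up = scan_sequence("s", seq)
    lo = scan_sequence("s", seq.lower())
    assert up.presence == lo.presence and up.hits == lo.hits


def test_both_strands_adds_reverse_complement_probes():
    # reverse complement of TGAATGAA is TTCATTCA; of GGAAGGAA is TTCCTTCC
    res = scan_sequence("s", "CCTTCATTCACC", both_strands=False)
    assert not res.presence["CIC_octamer"]
    res = scan_sequence("s", "CCTTCATTCACC", both_strands=True)
    assert res.presence["CIC_octamer"]
    assert scan_sequence("s", "TTCCTTCC", both_strands=True).presence["GGAA_repeat"]


def test_hits_are_sorted_by_start():
    seq = "GGAAGGAA" + "C" * 10 + "TGAATGAA" + "GGAAGGAA"
    res = scan_sequence("s", seq)
    starts = [h.start for h in res.hits]
    assert starts == sorted(starts)


def test_motifhit_span_validation():
    with pytest.raises(ValueError):
        MotifHit("s", "CIC_octamer", "TGAATGAA", 0, 7)


# --------------------------------------------------------------- extract ---

def test_extract_peak_sequences(toy_annotation_case):
    from cicscan import PeakRecord

    genome = {"c1": "ggaaggaaTTTT"}
    peaks = [PeakRecord("c1", 0, 8, "pk")]
    assert extract_peak_sequences(genome, peaks) == {"pk": "GGAAGGAA"}
    with pytest.raises(CoordinateError, match="pk"):
        extract_peak_sequences(genome, [PeakRecord("c1", 4, 13, "pk")])
    with pytest.raises(CoordinateError, match="unknown chromosome"):
        extract_peak_sequences(genome, [PeakRecord("c9", 0, 4, "pk")])
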