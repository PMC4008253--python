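"""SSR scanner: brute-force oracle equivalence, maximality, motif algebra."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markermine.io_formats import SeqRecord, reverse_complement
from markermine.ssr_miner import (
    SSRThresholds,
    canonical_motif,
    find_ssrs,
    is_primitive,
    ssr_class_distribution,
    ssrs_per_sequence,
)

from conftest import random_dna

ALL_UNITS = [
    "".join(u) for n in range(1, 7) for u in itertools.product("ACGT", repeat=n)
]


def divisor_oracle(unit: str) -> bool:
    n = len(unit)
    return not any(
        n % d == 0 and all(unit[i] == unit[i % d] for i in range(n))
        for d in range(1, n)
    )


def rotation_oracle(unit: str) -> str:
    return sorted(unit[i:] + unit[:i] for i in range(len(unit)))[0].lower()


def brute_force_ssrs(s: str, thresholds: SSRThresholds) -> set[tuple[int, int, str]]:
    """Test every (start, unit length) pair independently of the scanner."""
    found = set()
    for u, thr in thresholds.min_repeats.items():
        for start in range(0, len(s) - u * thr + 1):
            unit = s[start : start + u]
            if "N" in unit or not divisor_oracle(unit):
                continue
            count = 1
            while s[start + count * u : start + (count + 1) * u] == unit:
                count += 1
            if count < thr:
                continue
            # leftmost representative of its run only
            if start > 0 and s[start - 1] == s[start - 1 + u] and s[start - 1] != "N":
                continue
            found.add((start, start + u * count, unit))
    return found


def test_is_primitive_exhaustive():
    for unit in ALL_UNITS:
        assert is_primitive(unit) == divisor_oracle(unit), unit


def test_is_primitive_examples():
    assert not is_primitive("ATAT")
    assert is_primitive("ATA")


def test_canonical_motif_rotation_invariance_exhaustive():
    for unit in ALL_UNITS:
        if len(unit) < 2:
            continue
        expected = rotation_oracle(unit)
        for i in range(len(unit)):
            assert canonical_motif(unit[i:] + unit[:i]) == expected


def test_canonical_motif_examples():
    assert canonical_motif("CAC") == "acc"
    assert canonical_motif("AT") == "at"
    with pytest.raises(ValueError):
        canonical_motif("AN")


def test_find_ssrs_basic_examples():
    loci = find_ssrs(SeqRecord("s", "GG" + "ACC" * 5 + "TT"))
    assert len(loci) == 1
    l = loci[0]
    assert (l.start, l.end, l.unit, l.repeat_count, l.canonical_motif) == (2, 17, "ACC", 5, "acc")
    # below the dinucleotide threshold of five repeats
    assert find_ssrs(SeqRecord("s", "ATATATAT")) == []
    # mononucleotide runs are not SSRs
    assert find_ssrs(SeqRecord("s", "A" * 40)) == []


@pytest.mark.parametrize("seed", range(4))
def test_find_ssrs_oracle_equivalence_random(seed):
    rng = np.random.default_rng(seed)
    thresholds = SSRThresholds()
    for i in range(120):
        # low-entropy alphabets make repeats frequent
        alphabet = ["ACGT", "AT", "ACG", "ACGTN"][i % 4]
        s = random_dna(rng, 150, alphabet)
        rec = SeqRecord(f"r{i}", s)
        got = {(l.start, l.end, l.unit) for l in find_ssrs(rec, thresholds)}
        assert got == brute_force_ssrs(s, thresholds), s


@pytest.mark.parametrize(
    "s",
    [
        "AT" * 30,
        "AT" * 5 + "TG" * 5,            # abutting runs sharing a base
        "ACC" * 4 + "N" + "ACC" * 4,    # N breaks the run
        "ATAT" * 6,                      # representable at unit 2 and (non-primitively) 4
        "GATC" * 3 + "GATC" * 3,
        "N" * 50,
        "ACGTT" * 3 + "ACGTT" * 2,
    ],
)
def test_find_ssrs_oracle_equivalence_adversarial(s):
    thresholds = SSRThresholds()
    got = {(l.start, l.end, l.unit) for l in find_ssrs(SeqRecord("a", s), thresholds)}
    assert got == brute_force_ssrs(s, thresholds)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ATN", min_size=0, max_size=80))
def test_find_ssrs_oracle_equivalence_hypothesis(s):
    """Repeat-dense two-letter strings with N interruptions, fuzzed."""
    if not s:
        return
    thresholds = SSRThresholds()
    got = {(l.start, l.end, l.unit) for l in find_ssrs(SeqRecord("h", s), thresholds)}
    assert got == brute_force_ssrs(s, thresholds)


def test_loci_are_maximal_and_perfect(small_sim):
    _, transcripts, _, _, _ = small_sim
    for rec in transcripts:
        s = rec.residues
        for l in find_ssrs(rec):
            assert s[l.start : l.end] == l.unit * l.repeat_count
            u = l.unit_len
            if l.start >= u:
                assert s[l.start - u : l.start] != l.unit
            if l.end + u <= len(s):
                assert s[l.end : l.end + u] != l.unit


def test_reverse_complement_mirrors_loci():
    rng = np.random.default_rng(5)
    for i in range(50):
        s = random_dna(rng, 200, "ACGT" if i % 2 else "AT")
        L = len(s)
        fwd = find_ssrs(SeqRecord("f", s))
        rev = find_ssrs(SeqRecord("r", reverse_complement(s)))
        assert len(fwd) == len(rev)
        # a maximal run may carry a partial trailing unit, so the reported
        # window of the mirrored locus can shift by up to one unit; match on
        # motif, repeat count and near-identical mirrored interval
        mirrored = sorted(
            (L - l.end, l.repeat_count, canonical_motif(reverse_complement(l.unit)))
            for l in fwd
        )
        got = sorted((l.start, l.repeat_count, canonical_motif(l.unit)) for l in rev)
        for (ms, mc, mm), (gs, gc, gm) in zip(mirrored, got):
            assert (mc, mm) == (gc, gm)
            assert abs(ms - gs) < len(mm)  # shift strictly less than one unit


def test_class_distribution_and_histogram():
    recs = [
        SeqRecord("a", "GG" + "ACC" * 5 + "TTT" + "CA" * 5 + "GG"),
        SeqRecord("b", "TT" + "AGG" * 4 + "CC"),
    ]
    loci = [l for r in recs for l in find_ssrs(r)]
    dist = ssr_class_distribution(loci)
    assert dist[3] == (2, pytest.approx(2 / 3))
    assert dist[2] == (1, pytest.approx(1 / 3))
    assert sum(f for _, f in dist.values()) == pytest.approx(1.0)
    assert ssrs_per_sequence(loci, 2) == {1: 1, 2: 1}
    assert ssr_class_distribution([]) == {u: (0, 0.0) for u in range(2, 7)}
    assert ssrs_per_sequence([], 5) == {}


def test_index_suffixes_follow_position_order():
    rec = SeqRecord("a", "GG" + "CA" * 5 + "T" * 3 + "ACC" * 5 + "GG")
    loci = find_ssrs(rec)
    assert [l.marker_suffix for l in loci] == ["a", "b"]
    assert loci[0].start < loci[1].start


def test_threshold_validation():
    with pytest.raises(ValueError):
        SSRThresholds({2: 5, 3: 4})
    with pytest.raises(ValueError):
        SSRThresholds({2: 1, 3: 4, 4: 3, 5: 3, 6: 3})
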