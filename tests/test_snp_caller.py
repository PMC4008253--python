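"""Pileup construction and the minority-allele confidence filter."""

import itertools

import numpy as np
import pytest

from markermine.io_formats import AlignmentRecord, SeqRecord
from markermine.snp_caller import (
    PileupColumn,
    SNPFilterParams,
    build_pileup,
    call_snp,
    call_snps,
    classify_substitution,
    putative_snp_columns,
    snp_density,
    titv_summary,
)
from markermine.snp_caller import SNPCall


def col(counts, ref="r", pos=0):
    return PileupColumn(ref, pos, counts)


@pytest.mark.parametrize(
    "counts,expect_call",
    [
        ({"A": 26, "G": 4}, True),    # 4 >= 4; 4/30 = 13.3% >= 10%; 30 >= 8
        ({"A": 5, "G": 3}, False),    # minor 3 < 4
        ({"A": 50, "G": 4}, False),   # 4/54 = 7.4% < 10%
        ({"A": 36, "G": 4}, True),    # boundary: 4/40 = 10% exactly (inclusive)
        ({"A": 4, "G": 3}, False),    # depth 7 < 8
        ({"A": 4, "G": 4}, True),     # 8x, 50%: alphabetical tie-break labels A major
        ({"A": 30}, False),           # monomorphic
    ],
)
def test_minority_allele_filter(counts, expect_call):
    call = call_snp(col(counts))
    assert (call is not None) is expect_call


def test_tie_break_and_multiallelic_flag():
    call = call_snp(col({"A": 4, "G": 4}))
    assert (call.major_allele, call.minor_allele) == ("A", "G")
    tri = call_snp(col({"A": 20, "G": 5, "T": 1}))
    assert tri is not None and tri.multiallelic
    assert (tri.major_allele, tri.minor_allele) == ("A", "G")


def test_classify_substitution_exhaustive():
    outcomes = {
        (a, b): classify_substitution(a, b)
        for a, b in itertools.permutations("ACGT", 2)
    }
    transitions = [p for p, k in outcomes.items() if k == "transition"]
    assert sorted(transitions) == [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    assert sum(1 for k in outcomes.values() if k == "transversion") == 8
    with pytest.raises(ValueError):
        classify_substitution("A", "A")
    with pytest.raises(ValueError):
        classify_substitution("A", "N")


def test_titv_summary_reconstructs_published_table():
    """Six published pair counts give 4,080 transitions (65%) and 2,156
    transversions (35%) with the printed per-pair shares."""
    table = {("A", "G"): 2076, ("C", "T"): 2004, ("A", "C"): 548,
             ("C", "G"): 610, ("G", "T"): 570, ("A", "T"): 428}
    calls = [
        SNPCall("r", i, a, b, 10, 5, 15, classify_substitution(a, b))
        for (a, b), n in table.items()
        for i in range(n)
    ]
    s = titv_summary(calls)
    assert s.n_transitions == 4080 and s.n_transversions == 2156
    assert s.total == 6236
    assert (s.transition_percent, s.transversion_percent) == (65, 35)
    assert s.pair_percents == {"A/G": 51, "C/T": 49, "A/C": 25, "C/G": 28, "G/T": 26, "A/T": 20}


def test_titv_single_call_and_empty():
    s = titv_summary([SNPCall("r", 0, "A", "G", 26, 4, 30, "transition")])
    assert (s.n_transitions, s.n_transversions) == (1, 0)
    assert s.transition_percent == 100
    empty = titv_summary([])
    assert empty.total == 0 and empty.transition_percent == 0


def test_snp_density():
    assert snp_density(15_665_000, 6_236) == 2512
    assert snp_density(1000, 0) is None


def _aln(read_id, ref_start, cigar, seq, ref="r"):
    return AlignmentRecord(read_id, ref, ref_start, "+", cigar, seq)


def test_pileup_overlap_depths():
    refs = [SeqRecord("r", "A" * 20)]
    alns = [
        _aln("a", 0, [(10, "M")], "ACGTACGTAC"),
        _aln("b", 5, [(10, "M")], "CGTACGTACG"),
    ]
    cols = {c.pos: c for c in build_pileup(alns, refs)}
    assert set(cols) == set(range(15))
    assert all(cols[p].depth == 2 for p in range(5, 10))
    assert all(cols[p].depth == 1 for p in list(range(5)) + list(range(10, 15)))
    assert cols[5].counts == {"C": 2}  # read a pos 5 = 'C', read b pos 0 = 'C'


def test_pileup_deletion_skips_columns_and_insertion_adds_none():
    refs = [SeqRecord("r", "ACGTACGTACGT")]
    alns = [_aln("d", 0, [(5, "M"), (2, "D"), (5, "M")], "ACGTAACGT" + "A")]
    cols = {c.pos: c for c in build_pileup(alns, refs)}
    assert 5 not in cols and 6 not in cols
    assert set(cols) == set(range(5)) | set(range(7, 12))
    alns_i = [_aln("i", 0, [(4, "M"), (3, "I"), (4, "M")], "ACGTTTTACGT")]
    cols_i = build_pileup(alns_i, refs)
    assert sum(c.depth for c in cols_i) == 8  # insertions contribute nothing


def test_pileup_excludes_n():
    refs = [SeqRecord("r", "ACGTACGT")]
    alns = [_aln("n", 0, [(4, "M")], "ACNT")]
    cols = {c.pos: c for c in build_pileup(alns, refs)}
    assert 2 not in cols
    assert cols[0].counts == {"A": 1}


def test_pileup_bounds_checked():
    refs = [SeqRecord("r", "ACGT")]
    with pytest.raises(ValueError):
        build_pileup([_aln("x", 2, [(5, "M")], "ACGTA")], refs)


@pytest.mark.parametrize("seed", range(3))
def test_filter_monotonicity(seed):
    """Raising any threshold never increases the number of calls."""
    rng = np.random.default_rng(seed)
    cols = []
    for i in range(400):
        counts = {b: int(rng.integers(0, 30)) for b in "ACGT" if rng.random() < 0.7}
        if counts:
            cols.append(PileupColumn("r", i, counts))
    base = SNPFilterParams()
    n0 = len(call_snps(cols, base))
    for stricter in (
        SNPFilterParams(min_coverage=12),
        SNPFilterParams(min_minor_count=6),
        SNPFilterParams(min_minor_fraction=0.2),
    ):
        assert len(call_snps(cols, stricter)) <= n0


def test_calls_agree_with_brute_recount_from_reads(small_sim):
    """Every reported site re-counted directly from the raw aligned reads."""
    _, transcripts, _, _, alignments = small_sim
    cols = build_pileup(alignments, transcripts)
    calls = call_snps(cols)
    assert calls, "fixture should produce calls"
    by_ref = {}
    for a in alignments:
        by_ref.setdefault(a.ref_id, []).append(a)
    for c in calls:
        recount = {}
        for a in by_ref[c.ref_id]:
            # M-only truth alignments in this fixture
            assert all(op == "M" for _, op in a.cigar)
            if a.ref_start <= c.pos < a.ref_end:
                base = a.read_seq[c.pos - a.ref_start]
                recount[base] = recount.get(base, 0) + 1
        assert recount.get(c.major_allele, 0) == c.major_count
        assert recount.get(c.minor_allele, 0) == c.minor_count
        assert sum(v for b, v in recount.items() if b != "N") == c.depth


def test_putative_columns_superset_of_calls(small_sim):
    _, transcripts, _, _, alignments = small_sim
    cols = build_pileup(alignments, transcripts)
    putative = {(c.ref_id, c.pos) for c in putative_snp_columns(cols)}
    called = {(c.ref_id, c.pos) for c in call_snps(cols)}
    assert called <= putative


def test_param_validation():
    with pytest.raises(ValueError):
        SNPFilterParams(min_minor_count=0)
    with pytest.raises(ValueError):
        SNPFilterParams(min_minor_fraction=0.7)
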