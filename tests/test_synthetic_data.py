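"""Simulator determinism, planted-truth exactness and sampling statistics."""

import numpy as np
import pytest

from markermine.io_formats import reverse_complement, write_fasta
from markermine.snp_caller import build_pileup
from markermine.ssr_miner import find_ssrs_many
from markermine.synthetic_data import (
    ConfigError,
    PlantedSNP,
    SimulationConfig,
    SSRPlant,
    TruthTables,
    VariantPlant,
    evaluate_recovery,
    simulate_reads,
    simulate_transcripts,
)


def _cfg(**kw):
    base = dict(
        n_transcripts=5,
        ssr_plants=[SSRPlant("ACC", 5)],
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_planted_ssr_construction():
    txs, truth = simulate_transcripts(_cfg(length_range=(500, 500)))
    for l in truth.planted_ssrs:
        assert l.end - l.start == 15
        rec = next(r for r in txs if r.id == l.seq_id)
        assert rec.residues[l.start : l.end] == "ACC" * 5


def test_same_seed_is_byte_identical(tmp_path):
    cfg = _cfg(auto_variants_per_transcript=1, orf_fraction=0.5, subst_error_rate=0.01)
    out = []
    for name in ("a", "b"):
        txs, truth = simulate_transcripts(cfg)
        reads, alns = simulate_reads(txs, truth, cfg)
        fa = tmp_path / f"{name}.fa"
        write_fasta(txs, fa)
        out.append((fa.read_bytes(), [(r.id, r.residues) for r in reads],
                    [(a.read_id, a.ref_start, a.strand, tuple(map(tuple, a.cigar))) for a in alns]))
    assert out[0] == out[1]


def test_different_seed_differs():
    t1, _ = simulate_transcripts(_cfg(seed=1))
    t2, _ = simulate_transcripts(_cfg(seed=2))
    assert [r.residues for r in t1] != [r.residues for r in t2]


def test_error_free_reads_are_exact_substrings(small_sim):
    _, transcripts, truth, reads, alignments = small_sim
    by_id = {r.id: r for r in transcripts}
    snp_keys = {(v.seq_id, v.position) for v in truth.planted_snps}
    for read, aln in zip(reads, alignments):
        tpl = by_id[aln.ref_id].residues[aln.ref_start : aln.ref_end]
        # forward-oriented alignment sequence differs from the transcript
        # only at planted variant sites
        diffs = [i for i, (a, b) in enumerate(zip(aln.read_seq, tpl)) if a != b]
        assert all((aln.ref_id, aln.ref_start + i) in snp_keys for i in diffs)
        expected = reverse_complement(aln.read_seq) if aln.strand == "-" else aln.read_seq
        assert read.residues == expected


def test_ssr_scanner_recovers_all_planted_loci(small_sim):
    _, transcripts, truth, _, _ = small_sim
    found = find_ssrs_many(transcripts)
    rec = evaluate_recovery(truth, found, "ssr")
    assert rec.recall == 1.0
    assert rec.precision == 1.0  # rejection sampling leaves no accidental SSRs


def test_planted_features_do_not_overlap(small_sim):
    _, _, truth, _, _ = small_sim
    by_tx = {}
    for l in truth.planted_ssrs:
        by_tx.setdefault(l.seq_id, []).append((l.start, l.end))
    for v in truth.planted_snps:
        by_tx.setdefault(v.seq_id, []).append((v.position, v.position + 1))
    for tx, ivs in by_tx.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2, (tx, ivs)


def test_minor_allele_draws_match_binomial_expectation():
    """At minor fraction 0.5 the pooled alt count over seeds matches the
    Binomial mean within three standard errors."""
    alt_total = 0
    depth_total = 0
    for seed in range(60):
        cfg = SimulationConfig(
            n_transcripts=1,
            length_range=(500, 500),
            variant_plants=[VariantPlant(0, 250, "A", "G", 0.5)],
            coverage_target=30.0,
            seed=seed,
        )
        txs, truth = simulate_transcripts(cfg)
        _, alns = simulate_reads(txs, truth, cfg)
        cols = {c.pos: c for c in build_pileup(alns, txs)}
        col = cols[250]
        alt_total += col.counts.get("G", 0)
        depth_total += col.depth
    se = (0.25 * depth_total) ** 0.5
    assert abs(alt_total - 0.5 * depth_total) < 3 * se


def test_read_length_distribution_matches_config():
    cfg = SimulationConfig(
        n_transcripts=4,
        length_range=(2000, 2200),
        read_mean_len=421.0,
        read_len_sd=60.0,
        coverage_target=500.0,
        seed=5,
    )
    txs, truth = simulate_transcripts(cfg)
    reads, _ = simulate_reads(txs, truth, cfg)
    lens = np.array([len(r.residues) for r in reads])
    assert len(lens) >= 10_000
    se = 60.0 / np.sqrt(len(lens))
    assert abs(lens.mean() - 421.0) < 2 * se + 1.0  # +1 for truncation bias at [50, L]


def test_coverage_target_is_approximately_met(small_sim):
    cfg, transcripts, _, _, alignments = small_sim
    cols = build_pileup(alignments, transcripts[: cfg.n_transcripts])
    by_tx = {}
    for c in cols:
        by_tx.setdefault(c.ref_id, []).append(c.depth)
    mean_depths = [np.mean(v) for v in by_tx.values()]
    assert np.mean(mean_depths) == pytest.approx(cfg.coverage_target, rel=0.25)


def test_recovery_evaluator_edge_cases():
    truth = TruthTables(planted_snps=[PlantedSNP("t", 5, "A", "G", 0.3)])
    perfect = evaluate_recovery(truth, [type("C", (), {"ref_id": "t", "pos": 5})()], "snp")
    assert perfect.precision == 1.0 and perfect.recall == 1.0
    empty = evaluate_recovery(truth, [], "snp")
    assert empty.recall == 0.0 and empty.precision is None
    with pytest.raises(ValueError):
        evaluate_recovery(truth, [], "orf")


def test_infeasible_plants_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(length_range=(100, 120), ssr_plants=[SSRPlant("ACC", 5, flank_min=60)])
    with pytest.raises(ConfigError):
        VariantPlant(0, 10, "A", "G", 0.7)
    with pytest.raises(ConfigError):
        SSRPlant("ACCACCA", 3)
    with pytest.raises(ConfigError):
        SimulationConfig(orf_fraction=0.5, orf_length=100)  # not a codon multiple


def test_homopolymer_indels_shape_cigar():
    cfg = _cfg(homopolymer_indel_rate=0.5, length_range=(400, 400), seed=3)
    txs, truth = simulate_transcripts(cfg)
    _, alns = simulate_reads(txs, truth, cfg)
    with_indel = [a for a in alns if any(op in "ID" for _, op in a.cigar)]
    assert with_indel, "expected indels at rate 0.5"
    for a in with_indel:
        assert sum(n for n, op in a.cigar if op in "MI") == len(a.read_seq)
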