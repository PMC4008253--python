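"""End-to-end orchestration of the marker-discovery stages.

Stages run in dependency order: simulate -> mine-ssr -> find-orfs ->
design-primers -> pileup/call-snps -> epcr -> classify-cp -> report. Each
stage is a pure function of its inputs and the seed, so a rerun with the
same configuration is byte-identical. All result tables are TSV with 1-based
inclusive coordinates; the summary is a flat key-value file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cp_partition, insilico_pcr, orf_topography, primer_designer, snp_caller, ssr_miner
from .io_formats import (
    SeqRecord,
    read_fasta,
    write_fasta,
    write_fastq,
    write_sam,
    write_table,
)
from .primer_designer import PrimerConstraints
from .insilico_pcr import EPCRParams
from .report import SummaryReport, ratio
from .snp_caller import SNPFilterParams
from .ssr_miner import SSRThresholds
from .synthetic_data import (
    ConfigError,
    SimulationConfig,
    SSRPlant,
    chloroplast_transcripts,
    evaluate_recovery,
    make_chloroplast_reference,
    simulate_reads,
    simulate_transcripts,
)

log = logging.getLogger("markermine")

STAGES = (
    "simulate",
    "mine-ssr",
    "find-orfs",
    "design-primers",
    "call-snps",
    "epcr",
    "classify-cp",
    "report",
)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one place.

    Marker-filter defaults are the standard EST study settings: SSR minimum
    repeats {2:5, 3:4, 4:3, 5:3, 6:3}; SNP filter coverage >= 8x, minority
    allele >= 4 reads and >= 10%; 100-300 bp products; ePCR >= 3 reads and
    >= 2 bp size difference.
    """

    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        ssr_plants=[SSRPlant("ACC", 5), SSRPlant("AT", 5), SSRPlant("GATC", 3)],
        orf_fraction=0.5,
        auto_variants_per_transcript=1,
    ))
    thresholds: SSRThresholds = field(default_factory=SSRThresholds)
    constraints: PrimerConstraints = field(default_factory=PrimerConstraints)
    snp_params: SNPFilterParams = field(default_factory=SNPFilterParams)
    epcr_params: EPCRParams = field(default_factory=EPCRParams)
    orf_min_len: int = 90
    cp_k: int = 21
    cp_threshold: float = 0.5
    n_cp_transcripts: int = 5
    cp_reference_length: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        self.sim.seed = self.seed


_CONFIG_KEYS = {
    "seed": ("seed", int),
    "sim.n_transcripts": ("sim.n_transcripts", int),
    "sim.gc_fraction": ("sim.gc_fraction", float),
    "sim.coverage_target": ("sim.coverage_target", float),
    "sim.read_mean_len": ("sim.read_mean_len", float),
    "sim.read_len_sd": ("sim.read_len_sd", float),
    "sim.subst_error_rate": ("sim.subst_error_rate", float),
    "sim.homopolymer_indel_rate": ("sim.homopolymer_indel_rate", float),
    "sim.orf_fraction": ("sim.orf_fraction", float),
    "sim.orf_length": ("sim.orf_length", int),
    "sim.auto_variants_per_transcript": ("sim.auto_variants_per_transcript", int),
    "snp.min_coverage": ("snp_params.min_coverage", int),
    "snp.min_minor_count": ("snp_params.min_minor_count", int),
    "snp.min_minor_fraction": ("snp_params.min_minor_fraction", float),
    "epcr.min_reads": ("epcr_params.min_reads", int),
    "epcr.min_size_diff": ("epcr_params.min_size_diff", int),
    "orf.min_len": ("orf_min_len", int),
    "cp.k": ("cp_k", int),
    "cp.threshold": ("cp_threshold", float),
    "cp.n_transcripts": ("n_cp_transcripts", int),
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from a flat key-value YAML file plus overrides (flags win)."""
    cfg = PipelineConfig()
    flat: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a flat key: value mapping")
        flat.update(loaded)
    flat.update(overrides or {})
    for key, value in flat.items():
        if key not in _CONFIG_KEYS:
            raise ConfigError(f"unknown config key {key!r}")
        attr_path, cast = _CONFIG_KEYS[key]
        obj = cfg
        *parents, leaf = attr_path.split(".")
        for p in parents:
            obj = getattr(obj, p)
        setattr(obj, leaf, cast(value))
    cfg.sim.seed = cfg.seed
    # revalidate after overrides
    cfg.sim.__post_init__()
    cfg.snp_params.__post_init__()
    return cfg


@dataclass
class PipelineResult:
    transcripts: list
    truth: object
    ssrs: list
    orfs: dict
    primers: dict
    snp_calls: list
    epcr_calls: list
    compartment: list
    summary: SummaryReport


def _marker_id(ssr) -> str:
    return f"{ssr.seq_id}{ssr.marker_suffix}"


def run_pipeline(config: PipelineConfig, outdir: str | Path, stages=None) -> PipelineResult:
    """Run the selected stages (default: all) and write their artifacts."""
    stages = list(stages) if stages else list(STAGES)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("simulate: %d transcripts, coverage %.0fx, seed %d",
             config.sim.n_transcripts, config.sim.coverage_target, config.seed)
    nuclear, truth = simulate_transcripts(config.sim)
    cp_ref = make_chloroplast_reference(config.cp_reference_length, seed=config.seed)
    cp_txs = chloroplast_transcripts(cp_ref, config.n_cp_transcripts, seed=config.seed)
    transcripts = nuclear + cp_txs
    reads, alignments = simulate_reads(nuclear, truth, config.sim)
    if "simulate" in stages:
        write_fasta(transcripts, outdir / "transcripts.fasta")
        write_fasta([cp_ref], outdir / "cp_reference.fasta")
        write_fastq(reads, outdir / "reads.fastq")
        write_sam(alignments, {r.id: len(r.residues) for r in nuclear}, outdir / "truth.sam")
        write_table(
            [
                {"seq_id": l.seq_id, "motif": l.canonical_motif, "unit": l.unit,
                 "repeats": l.repeat_count, "start": l.start + 1, "stop": l.end}
                for l in truth.planted_ssrs
            ],
            outdir / "truth_ssrs.tsv",
            columns=["seq_id", "motif", "unit", "repeats", "start", "stop"],
        )
        write_table(
            [
                {"seq_id": v.seq_id, "position": v.position + 1, "ref": v.ref,
                 "alt": v.alt, "minor_fraction": v.minor_fraction}
                for v in truth.planted_snps
            ],
            outdir / "truth_snps.tsv",
            columns=["seq_id", "position", "ref", "alt", "minor_fraction"],
        )

    # compartment flags are needed by every nuclear-only summary downstream
    cp_index = cp_partition.build_kmer_index([cp_ref], config.cp_k)
    comp_calls = cp_partition.classify_many(transcripts, cp_index, config.cp_k, config.cp_threshold)
    cp_flag = {c.unigene_id: c.is_chloroplast for c in comp_calls}
    if "classify-cp" in stages:
        write_table(
            [
                {"unigene": c.unigene_id,
                 "containment": "" if c.containment is None else f"{c.containment:.4f}",
                 "chloroplast_belonging": "Y" if c.is_chloroplast else "N",
                 "method": c.method, "status": c.status}
                for c in comp_calls
            ],
            outdir / "compartment.tsv",
            columns=["unigene", "containment", "chloroplast_belonging", "method", "status"],
        )

    ssrs = ssr_miner.find_ssrs_many(transcripts, config.thresholds)
    orfs = {rec.id: orf_topography.find_longest_orf(rec, config.orf_min_len) for rec in transcripts}
    primers = {}
    by_id = {rec.id: rec for rec in transcripts}
    for ssr in ssrs:
        pair = primer_designer.design_primer_pair(by_id[ssr.seq_id], ssr, config.constraints)
        if pair is not None:
            primers[_marker_id(ssr)] = pair
    if "mine-ssr" in stages or "find-orfs" in stages or "design-primers" in stages:
        rows = []
        for ssr in ssrs:
            orf = orfs.get(ssr.seq_id)
            pair = primers.get(_marker_id(ssr))
            rows.append({
                "marker_id": _marker_id(ssr),
                "unigene": ssr.seq_id,
                "seq_length_bp": len(by_id[ssr.seq_id].residues),
                "motif": ssr.canonical_motif,
                "unit_len": ssr.unit_len,
                "n_repeats": ssr.repeat_count,
                "ssr_start": ssr.start + 1,
                "ssr_stop": ssr.end,
                "orf_start": orf.start + 1 if orf else "",
                "orf_stop": orf.end if orf else "",
                "ssr_in_orf": "Y" if orf_topography.classify_ssr_location(ssr, orf) == "IN_ORF" else "N",
                "frame_preserving": "Y" if orf_topography.is_frame_preserving(ssr) else "N",
                "fwd_primer": pair.fwd_seq if pair else "",
                "rev_primer": pair.rev_seq if pair else "",
                "product_size_bp": pair.product_size if pair else "",
                "chloroplast_belonging": "Y" if cp_flag.get(ssr.seq_id) else "N",
            })
        write_table(rows, outdir / "ssr_markers.tsv", columns=[
            "marker_id", "unigene", "seq_length_bp", "motif", "unit_len", "n_repeats",
            "ssr_start", "ssr_stop", "orf_start", "orf_stop", "ssr_in_orf",
            "frame_preserving", "fwd_primer", "rev_primer", "product_size_bp",
            "chloroplast_belonging",
        ])

    columns = snp_caller.build_pileup(alignments, nuclear)
    snp_calls = snp_caller.call_snps(columns, config.snp_params)
    if "call-snps" in stages:
        write_table(
            [
                {"unigene": c.ref_id, "marker_id": f"{c.ref_id}_snp{c.pos + 1}",
                 "snp_position": c.pos + 1, "snp": f"{c.major_allele}/{c.minor_allele}",
                 "reads_with_snp": c.minor_count, "total_coverage": c.depth,
                 "pct_reads_with_snp": round(100 * c.minor_count / c.depth, 1),
                 "klass": c.klass,
                 "chloroplast_belonging": "Y" if cp_flag.get(c.ref_id) else "N"}
                for c in snp_calls
            ],
            outdir / "snp_markers.tsv",
            columns=["unigene", "marker_id", "snp_position", "snp", "reads_with_snp",
                     "total_coverage", "pct_reads_with_snp", "klass", "chloroplast_belonging"],
        )

    read_groups: dict[str, list[SeqRecord]] = {}
    for read, aln in zip(reads, alignments):
        read_groups.setdefault(aln.ref_id, []).append(read)
    panel = [(sid, primers[_marker_id(s)]) for s in ssrs
             for sid in [s.seq_id] if _marker_id(s) in primers and sid in read_groups]
    epcr_calls, epcr_summary = insilico_pcr.epcr_batch(read_groups, panel, config.epcr_params)
    if "epcr" in stages:
        write_table(
            [
                {"marker_id": c.marker_id, "ssr_polym": c.is_flag,
                 "supporting_reads": c.supporting_reads,
                 "product_lengths": ",".join(map(str, sorted(c.product_lengths))),
                 "status": c.status}
                for c in epcr_calls
            ],
            outdir / "epcr.tsv",
            columns=["marker_id", "ssr_polym", "supporting_reads", "product_lengths", "status"],
        )

    summary = _build_summary(
        transcripts, nuclear, reads, truth, ssrs, orfs, primers, columns,
        snp_calls, epcr_calls, epcr_summary, comp_calls, cp_flag, config,
    )
    if "report" in stages:
        summary.write_key_value(outdir / "summary.tsv")
    return PipelineResult(transcripts, truth, ssrs, orfs, primers, snp_calls,
                          epcr_calls, comp_calls, summary)


def _build_summary(transcripts, nuclear, reads, truth, ssrs, orfs, primers,
                   columns, snp_calls, epcr_calls, epcr_summary, comp_calls,
                   cp_flag, config) -> SummaryReport:
    s = SummaryReport()
    nuclear_ssrs = [l for l in ssrs if not cp_flag.get(l.seq_id)]
    s.counts["n_transcripts"] = len(transcripts)
    s.counts["n_reads"] = len(reads)
    s.counts["n_ssrs"] = len(ssrs)
    s.counts["n_nuclear_ssrs"] = len(nuclear_ssrs)
    seqs_with_ssr = len({l.seq_id for l in ssrs})
    s.add_percent("sequences_with_ssr", seqs_with_ssr, len(transcripts))
    if ssrs:
        s.add_percent("ssrs_with_primers", len(primers), len(ssrs))
    in_orf = [l for l in ssrs
              if orf_topography.classify_ssr_location(l, orfs.get(l.seq_id)) == "IN_ORF"]
    if ssrs:
        s.add_percent("ssrs_in_orf", len(in_orf), len(ssrs))
    if in_orf:
        frame_keeping = sum(1 for l in in_orf if orf_topography.is_frame_preserving(l))
        s.add_percent("frame_preserving_in_orf", frame_keeping, len(in_orf))
    dist = ssr_miner.ssr_class_distribution(ssrs)
    s.distributions["ssr_class"] = {f"unit{u}": c for u, (c, _f) in dist.items()}
    s.distributions["ssrs_per_sequence"] = {
        str(k): v for k, v in ssr_miner.ssrs_per_sequence(ssrs, len(transcripts)).items()
    }
    titv = snp_caller.titv_summary(snp_calls)
    s.counts["n_snps"] = len(snp_calls)
    s.counts["n_transitions"] = titv.n_transitions
    s.counts["n_transversions"] = titv.n_transversions
    if snp_calls:
        s.add_percent("transitions", titv.n_transitions, titv.total)
        s.add_percent("transversions", titv.n_transversions, titv.total)
    total_bases = sum(len(r.residues) for r in nuclear)
    s.counts["total_bases_mined"] = total_bases
    dens = snp_caller.snp_density(total_bases, len(snp_calls))
    s.ratios["bases_per_snp"] = dens if dens is not None else ""
    seqs_with_snp = len({c.ref_id for c in snp_calls})
    if seqs_with_snp:
        s.ratios["snps_per_sequence_with_snp"] = ratio(len(snp_calls), seqs_with_snp, 1)
    s.counts["epcr_eligible"] = epcr_summary.n_eligible
    s.counts["epcr_polymorphic"] = epcr_summary.n_polymorphic
    if epcr_summary.n_eligible:
        s.add_percent("epcr_polymorphic", epcr_summary.n_polymorphic, epcr_summary.n_eligible)
    s.counts["n_chloroplast"] = sum(1 for c in comp_calls if c.is_chloroplast)
    rec = evaluate_recovery(truth, [l for l in ssrs if l.seq_id.startswith("tx")], "ssr")
    s.counts["ssr_truth_tp"], s.counts["ssr_truth_fn"] = rec.tp, rec.fn
    rec_snp = evaluate_recovery(truth, snp_calls, "snp")
    s.counts["snp_truth_tp"], s.counts["snp_truth_fp"], s.counts["snp_truth_fn"] = (
        rec_snp.tp, rec_snp.fp, rec_snp.fn,
    )
    return s
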