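"""Pipeline orchestration: simulate -> subtract -> assemble -> scan, with the
summary report and truth-based recovery evaluation.

``run_hdga`` executes the whole subtraction pipeline from a config and writes
the stage outputs (partition TSVs, contigs.fasta, alignments.tsv,
hybrid_calls.tsv, report.json); ``run_hdga_in_memory`` is the same
computation on in-memory inputs, which the file-level entry point wraps.
Reports are reproducible byte-for-byte under a fixed seed and config.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import yaml

from . import assemble, hybridscan, simulate, subtract
from .seqio import (ReadRecord, SequenceRecord, parse_fasta, parse_fastq,
                    write_fasta, write_fastq)

logger = logging.getLogger("gallsift")

LENGTH_BIN_EDGES = (0, 200, 500, 1000, 2000, 2501)
SUPPORT_BIN_EDGES = ((3, 3), (4, 5), (6, 9), (10, 30), (31, 95))


@dataclass
class PipelineParams:
    k_index: int = 31
    k_assembly: int = 31
    min_kmer_count: int = 2
    shared_fraction: float = 0.5
    min_contig_len: int = 200        # published minimum contig length
    derep_identity: float = 0.95     # published homology threshold
    min_mapq: int = 20               # published mapping-quality threshold
    min_anchor: int = 30
    min_core: int = 30
    min_support: int = 3             # "< 3 cover reads" are discarded
    junction_pad: int = 10
    tolerance: int = 10              # truth-matching tolerance, bases

    def __post_init__(self) -> None:
        if not (0 < self.derep_identity <= 1.0):
            raise ValueError("derep_identity must lie in (0, 1]")
        if not (0 < self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must lie in (0, 1]")
        for name in ("k_index", "k_assembly", "min_kmer_count", "min_contig_len",
                     "min_anchor", "min_core", "min_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineConfig:
    reference: str = "host.fasta"
    healthy_reads: str = "healthy.fastq"
    gall_reads: str = "gall.fastq"
    outdir: str = "hdga_out"
    contigs_in: str | None = None
    isolates: list[str] = field(default_factory=list)
    allowlist: str | None = None
    truth: str | None = None
    seed: int = 0
    params: PipelineParams = field(default_factory=PipelineParams)
    simulation: simulate.SimulationConfig | None = None


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = PipelineParams(**raw.pop("params", {}))
    sim = raw.pop("simulation", None)
    sim_cfg = None
    if sim is not None:
        if "insertion_len_range" in sim:
            sim["insertion_len_range"] = tuple(sim["insertion_len_range"])
        sim_cfg = simulate.SimulationConfig(**sim)
    return PipelineConfig(params=params, simulation=sim_cfg, **raw)


@dataclass
class RecoveryMetrics:
    n_truth: int
    n_recovered: int
    n_false: int
    recall: float
    precision: float
    flags: list[str] = field(default_factory=list)
    detail: list[dict] = field(default_factory=list)


def summarize_length_bins(contigs: Sequence[assemble.Contig],
                          edges: Sequence[int] = LENGTH_BIN_EDGES) -> dict[str, int]:
    """Right-closed length histogram; an overflow bin conserves the total."""
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    bins = {f"({edges[i]},{edges[i+1]}]": 0 for i in range(len(edges) - 1)}
    bins[f">{edges[-1]}"] = 0
    for contig in contigs:
        n = contig.length
        for i in range(len(edges) - 1):
            if edges[i] < n <= edges[i + 1]:
                bins[f"({edges[i]},{edges[i+1]}]"] += 1
                break
        else:
            bins[f">{edges[-1]}"] += 1
    return bins


def summarize_support_bins(calls: Sequence[hybridscan.HybridCall],
                           edges: Sequence[tuple[int, int]] = SUPPORT_BIN_EDGES
                           ) -> dict[str, int]:
    """Support histogram over retained calls (allowlisted sub-threshold calls
    land in the '<min' bin so counts always sum to the number of calls)."""
    low = edges[0][0]
    bins: dict[str, int] = {f"<{low}": 0}
    for lo, hi in edges:
        bins[str(lo) if lo == hi else f"{lo}-{hi}"] = 0
    bins[f">{edges[-1][1]}"] = 0
    for call in calls:
        s = call.support
        if s < low:
            bins[f"<{low}"] += 1
            continue
        for lo, hi in edges:
            if lo <= s <= hi:
                bins[str(lo) if lo == hi else f"{lo}-{hi}"] += 1
                break
        else:
            bins[f">{edges[-1][1]}"] += 1
    return bins


def evaluate_against_truth(
    calls: Sequence[hybridscan.HybridCall],
    truth: simulate.SimulationTruth,
    tolerance: int = 10,
) -> RecoveryMetrics:
    """Score recovered insertion sites against the planted truth.

    Recovery uses greedy one-to-one matching: candidate call/event pairs on
    the same chromosome within ``tolerance`` bases are matched nearest-first,
    so one call can recover at most one event.  A call is a false positive
    only if it matches *no* truth site at all — multiple contig fragments
    corroborating the same junction are not penalized.  With no calls,
    precision is reported as 1.0 with a "no_calls" flag.
    """
    sited = [c for c in calls if c.insertion_site is not None]
    pairs: list[tuple[int, int, int]] = []
    near_truth: set[int] = set()
    for i, call in enumerate(sited):
        chrom, point = call.insertion_site
        for j, ev in enumerate(truth.events):
            if ev.chrom == chrom and abs(ev.position - point) <= tolerance:
                pairs.append((abs(ev.position - point), i, j))
                near_truth.add(i)
    pairs.sort()
    used_calls: set[int] = set()
    used_events: set[int] = set()
    detail = []
    for dist, i, j in pairs:
        if i in used_calls or j in used_events:
            continue
        used_calls.add(i)
        used_events.add(j)
        ev = truth.events[j]
        detail.append({
            "chrom": ev.chrom, "truth_position_1based": ev.position + 1,
            "contig_id": sited[i].contig_id, "distance": dist,
            "anchor_class": sited[i].anchor_class,
        })
    n_truth = len(truth.events)
    n_rec = len(used_events)
    n_false = len(sited) - len(near_truth)
    flags = []
    if not sited:
        precision = 1.0
        flags.append("no_calls")
    else:
        precision = len(near_truth) / len(sited)
    recall = n_rec / n_truth if n_truth else 1.0
    return RecoveryMetrics(n_truth, n_rec, n_false, recall, precision,
                           flags, detail)


@dataclass
class HdgaResult:
    healthy_partition: subtract.MappingPartition
    gall_partition: subtract.MappingPartition
    shared_partition: subtract.SharedPartition
    contigs: list[assemble.Contig]
    alignments: dict[str, list[hybridscan.CigarAlignment]]
    calls: list[hybridscan.HybridCall]
    retained_calls: list[hybridscan.HybridCall]
    report: dict


def run_hdga_in_memory(
    reference: Sequence[SequenceRecord],
    healthy_reads: Sequence[ReadRecord],
    gall_reads: Sequence[ReadRecord],
    params: PipelineParams | None = None,
    contigs_in: Sequence[assemble.Contig] | None = None,
    allowlist: Sequence[str] = (),
) -> HdgaResult:
    """Run subtraction -> assembly -> hybrid scan on in-memory inputs."""
    p = params or PipelineParams()

    logger.info("indexing reference (%d records, k=%d)", len(reference), p.k_index)
    index = subtract.build_reference_index(reference, p.k_index)

    logger.info("mapping %d healthy reads", len(healthy_reads))
    healthy_part = subtract.partition_reads(healthy_reads, index, "healthy")
    logger.info("healthy: %.2f%% unmapped", 100 * healthy_part.fraction_unmapped)
    logger.info("mapping %d gall reads", len(gall_reads))
    gall_part = subtract.partition_reads(gall_reads, index, "gall")
    logger.info("gall: %.2f%% unmapped", 100 * gall_part.fraction_unmapped)

    healthy_un = [r for r in healthy_reads if r.id in healthy_part.unmapped_ids]
    gall_un = [r for r in gall_reads if r.id in gall_part.unmapped_ids]
    shared_part = subtract.filter_shared_reads(
        gall_un, healthy_un, k=p.k_index, min_shared_fraction=p.shared_fraction)
    exclusive = [r for r in gall_un if r.id in shared_part.exclusive_ids]
    logger.info("gall-exclusive: %d reads (%.2f%% of unmapped)",
                len(exclusive), 100 * shared_part.fraction_exclusive)

    if contigs_in is not None:
        contigs = list(contigs_in)
    else:
        graph = assemble.build_graph(exclusive, p.k_assembly, p.min_kmer_count)
        contigs = assemble.extract_contigs(graph)
    n_assembled = len(contigs)
    contigs = assemble.dereplicate_contigs(
        contigs, min_identity=p.derep_identity, min_len=p.min_contig_len)
    logger.info("assembly: %d contigs, %d after length/identity dereplication",
                n_assembled, len(contigs))

    alignments: dict[str, list[hybridscan.CigarAlignment]] = {}
    calls: list[hybridscan.HybridCall] = []
    reports: dict[str, hybridscan.SupportReport] = {}
    for contig in contigs:
        alns = hybridscan.align_contig_to_reference(contig, reference)
        alns = hybridscan.mapping_confidence(alns)
        alignments[contig.id] = alns
        call = hybridscan.classify_hybrid(
            contig, alns,
            min_anchor=p.min_anchor, min_core=p.min_core,
            min_identity=p.derep_identity, min_confidence=p.min_mapq)
        calls.append(call)
        if call.anchor_class in (hybridscan.FIVE_PRIME, hybridscan.THREE_PRIME,
                                 hybridscan.BOTH):
            junctions = list(call.foreign_core) if call.foreign_core else []
            reports[contig.id] = hybridscan.count_support(
                contig, exclusive, junctions=junctions,
                junction_pad=p.junction_pad)

    hybrid_calls = [c for c in calls if c.anchor_class in
                    (hybridscan.FIVE_PRIME, hybridscan.THREE_PRIME, hybridscan.BOTH)]
    retained = hybridscan.filter_by_support(
        hybrid_calls, reports, min_support=p.min_support, allowlist=allowlist)
    logger.info("hybrid calls: %d candidates, %d retained (support >= %d)",
                len(hybrid_calls), len(retained), p.min_support)

    class_counts: dict[str, int] = {}
    for call in calls:
        class_counts[call.anchor_class] = class_counts.get(call.anchor_class, 0) + 1
    report = {
        "samples": {
            part.sample: {
                "n_total": part.n_total,
                "n_mapped": len(part.mapped_ids),
                "n_unmapped": len(part.unmapped_ids),
                "pct_unmapped": round(100 * part.fraction_unmapped, 4),
            }
            for part in (healthy_part, gall_part)
        },
        "gall_unmapped": {
            "n_shared": len(shared_part.shared_ids),
            "n_exclusive": len(shared_part.exclusive_ids),
            "pct_exclusive": round(100 * shared_part.fraction_exclusive, 4),
        },
        "assembly": {
            "n_contigs_assembled": n_assembled,
            "n_contigs_after_dereplication": len(contigs),
            "length_bins": summarize_length_bins(contigs),
        },
        "classification": {
            "class_counts": class_counts,
            "n_hybrid_candidates": len(hybrid_calls),
            "n_retained": len(retained),
            "support_bins": summarize_support_bins(retained),
        },
        "insertions": {
            "per_chromosome": _sites_by_chrom(retained),
        },
    }
    return HdgaResult(healthy_part, gall_part, shared_part, contigs,
                      alignments, calls, retained, report)


def _sites_by_chrom(calls: Sequence[hybridscan.HybridCall]) -> dict[str, list[int]]:
    sites: dict[str, list[int]] = {}
    for call in calls:
        if call.insertion_site is None:
            continue
        chrom, point = call.insertion_site
        sites.setdefault(chrom, []).append(point + 1)  # 1-based in reports
    return {k: sorted(v) for k, v in sorted(sites.items())}


def run_simulation(config: simulate.SimulationConfig, outdir: str) -> dict[str, str]:
    """Generate and write all simulated inputs; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    host = simulate.generate_host_genome(config)
    pool = simulate.generate_foreign_pool(config, host)
    gall_genome, truth = simulate.plant_insertions(host, pool, config)
    comps = simulate.sample_compositions(host, gall_genome, pool)
    healthy = simulate.simulate_reads(comps["healthy"], config, "healthy")
    gall = simulate.simulate_reads(comps["gall"], config, "gall")
    paths = {name: os.path.join(outdir, fname) for name, fname in [
        ("host", "host.fasta"), ("gall_genome", "gall.fasta"),
        ("pool", "pool.fasta"), ("healthy_reads", "healthy.fastq"),
        ("gall_reads", "gall.fastq"), ("truth", "truth.tsv"),
    ]}
    write_fasta(host, paths["host"])
    write_fasta(gall_genome, paths["gall_genome"])
    write_fasta(pool, paths["pool"])
    write_fastq(healthy, paths["healthy_reads"])
    write_fastq(gall, paths["gall_reads"])
    simulate.write_truth(truth, paths["truth"])
    return paths


def run_hdga(config: PipelineConfig) -> HdgaResult:
    """File-level pipeline entry point: read inputs, run, write outputs."""
    os.makedirs(config.outdir, exist_ok=True)
    with open(config.reference) as fh:
        reference = parse_fasta(fh)
    with open(config.healthy_reads) as fh:
        healthy = parse_fastq(fh, sample="healthy")
    with open(config.gall_reads) as fh:
        gall = parse_fastq(fh, sample="gall")
    contigs_in = None
    if config.contigs_in:
        with open(config.contigs_in) as fh:
            contigs_in = assemble.records_to_contigs(parse_fasta(fh))
    allowlist: list[str] = []
    if config.allowlist:
        with open(config.allowlist) as fh:
            allowlist = [ln.strip() for ln in fh if ln.strip()]

    result = run_hdga_in_memory(reference, healthy, gall,
                                params=config.params, contigs_in=contigs_in,
                                allowlist=allowlist)

    out = config.outdir
    subtract.write_partition_tsv(os.path.join(out, "healthy_partition.tsv"),
                                 result.healthy_partition)
    subtract.write_partition_tsv(os.path.join(out, "gall_partition.tsv"),
                                 result.gall_partition)
    subtract.write_summary_json(os.path.join(out, "subtraction_summary.json"),
                                [result.healthy_partition, result.gall_partition],
                                result.shared_partition)
    write_fasta(assemble.contigs_to_records(result.contigs),
                os.path.join(out, "contigs.fasta"))
    write_alignments_tsv(os.path.join(out, "alignments.tsv"), result.alignments)
    write_calls_tsv(os.path.join(out, "hybrid_calls.tsv"), result.retained_calls)

    if config.isolates:
        summaries = []
        for iso_path in config.isolates:
            with open(iso_path) as fh:
                for rec in parse_fasta(fh):
                    summaries.append(hybridscan.assess_endophyte_synteny(
                        result.contigs, rec,
                        min_identity=config.params.derep_identity,
                        min_len=config.params.min_contig_len))
        with open(os.path.join(out, "synteny.tsv"), "w") as fh:
            fh.write("isolate_id\tn_qualifying_contigs\ttotal_bases\tverdict\n")
            for s in summaries:
                verdict = ("endophyte-supported" if s["endophyte_supported"]
                           else "not-supported")
                fh.write(f"{s['isolate_id']}\t{s['n_qualifying_contigs']}\t"
                         f"{s['total_bases']}\t{verdict}\n")
        result.report["synteny"] = {
            s["isolate_id"]: s["endophyte_supported"] for s in summaries}

    if config.truth:
        truth = simulate.read_truth(config.truth)
        metrics = evaluate_against_truth(result.retained_calls, truth,
                                         config.params.tolerance)
        result.report["evaluation"] = {
            "n_truth": metrics.n_truth,
            "n_recovered": metrics.n_recovered,
            "n_false": metrics.n_false,
            "recall": round(metrics.recall, 4),
            "precision": round(metrics.precision, 4),
            "flags": metrics.flags,
        }
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


def write_alignments_tsv(path: str,
                         alignments: dict[str, list[hybridscan.CigarAlignment]]
                         ) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tchrom\tref_start_1based\tstrand\tcigar\tscore\tconfidence\n")
        for cid in sorted(alignments):
            for a in alignments[cid]:
                fh.write(f"{cid}\t{a.chrom}\t{a.ref_start + 1}\t{a.strand}\t"
                         f"{a.cigar}\t{a.score:g}\t{a.confidence}\n")


def write_calls_tsv(path: str, calls: Sequence[hybridscan.HybridCall]) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tclass\tchrom\tsite_1based\tcore_start\tcore_end\t"
                 "support\tjunction_support\tallowlisted\n")
        for c in calls:
            chrom, site = (c.insertion_site if c.insertion_site
                           else (".", -1))
            core = c.foreign_core or (-1, -1)
            fh.write(f"{c.contig_id}\t{c.anchor_class}\t{chrom}\t{site + 1}\t"
                     f"{core[0]}\t{core[1]}\t{c.support}\t{c.junction_support}\t"
                     f"{int(c.allowlisted)}\n")
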