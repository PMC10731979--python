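"""Synthetic study generator: host genome, gall genome with planted foreign
insertions, endophyte/core-microbiome genomes, shotgun reads and a truth set.

The generator realizes the study conditions the pipeline is meant to detect:
a multi-chromosome plant host; a gall genome equal to the host except for
foreign DNA segments spliced at known positions (optionally with junction
microhomology); endophyte genomes sequenced only in the gall sample; a core
microbiome shared by both samples; and uniform 150-bp single-end shotgun
reads at ~16x host depth with a substitution-only error model.

Foreign insertion donors are generated as separate plasmid-like sequences
that never produce reads of their own (sample weight 0).  This keeps each
planted junction the unique source of its k-mers, so one hybrid contig per
event is assemblable; free-living endophytes still contribute gall-only
reads through their own genomes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kmers import canonical_set, in_sorted, revcomp, window_kmers
from .seqio import ReadRecord, SequenceRecord

K_EXCLUSION = 31  # foreign pool is host-31-mer-free by construction

ROLE_ENDOPHYTE = "gall_only"
ROLE_SHARED = "shared"
ROLE_DONOR = "insertion_donor"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    gc: float = 0.5
    n_insertions: int = 10
    insertion_len_range: tuple[int, int] = (500, 2000)
    min_flank: int = 300
    microhomology_len: int = 0
    n_endophytes: int = 3
    endophyte_len: int = 30_000
    n_core_microbes: int = 2
    depth_host: float = 16.0
    read_len: int = 150
    paired: bool = False
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        lo, hi = self.insertion_len_range
        if lo < 1 or hi < lo:
            raise ValueError("insertion_len_range must satisfy 1 <= min <= max")
        if self.min_flank < self.read_len:
            raise ValueError("min_flank must be >= read_len")
        if not (0.0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must lie in [0, 0.1)")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must lie in [0, 1]")
        if self.microhomology_len < 0:
            raise ValueError("microhomology_len must be >= 0")


@dataclass
class InsertionEvent:
    chrom: str
    position: int              # 0-based point on the host reference
    foreign_id: str
    foreign_start: int
    foreign_end: int
    microhomology: str = ""    # host bases duplicated at the 3' junction

    @property
    def insert_len(self) -> int:
        return self.foreign_end - self.foreign_start


@dataclass
class SimulationTruth:
    events: list[InsertionEvent] = field(default_factory=list)
    gall_only_taxa: list[str] = field(default_factory=list)
    shared_taxa: list[str] = field(default_factory=list)
    weights: dict[str, dict[str, float]] = field(default_factory=dict)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # one root seed; stable per-stream children derived from the stream name
    entropy = [config.seed] + list(stream.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    codes = rng.choice(4, size=length, p=probs)
    return codes.astype(np.uint8).tobytes().translate(
        bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")).decode("ascii")


def generate_host_genome(config: SimulationConfig) -> list[SequenceRecord]:
    """n_chrom chromosomes of i.i.d. bases at the configured GC content."""
    if config.chrom_len < 2 * config.min_flank:
        raise ValueError("chrom_len must be >= 2 * min_flank")
    rng = _rng(config, "host")
    return [
        SequenceRecord(f"chr{i + 1}", _random_seq(rng, config.chrom_len, config.gc))
        for i in range(config.n_chrom)
    ]


def _host_free_seq(rng: np.random.Generator, length: int, gc: float,
                   forbidden: np.ndarray, max_attempts: int = 50) -> str:
    """Random sequence sharing no canonical 31-mer with ``forbidden``."""
    for _ in range(max_attempts):
        seq = _random_seq(rng, length, gc)
        _, canon, valid = window_kmers(seq, K_EXCLUSION)
        if length < K_EXCLUSION or not in_sorted(canon[valid], forbidden).any():
            return seq
    raise RuntimeError("could not generate a host-k-mer-free sequence")


def generate_foreign_pool(config: SimulationConfig,
                          host: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Endophyte, core-microbiome and insertion-donor sequences.

    Every pool sequence is generated so that it shares no canonical 31-mer
    with the host genome (resampled on collision), which makes the simulated
    truth unambiguous.  Roles are carried in the record description:
    ``gall_only`` (endophytes, sequenced only in the gall sample), ``shared``
    (core microbiome, both samples) and ``insertion_donor`` (spliced into the
    gall genome, never sequenced free).
    """
    rng = _rng(config, "pool")
    forbidden = canonical_set([r.seq for r in host], K_EXCLUSION)
    pool: list[SequenceRecord] = []
    for i in range(config.n_endophytes):
        seq = _host_free_seq(rng, config.endophyte_len, config.gc, forbidden)
        pool.append(SequenceRecord(f"endo_{i + 1}", seq, ROLE_ENDOPHYTE))
        forbidden = np.union1d(forbidden, canonical_set([seq], K_EXCLUSION))
    for i in range(config.n_core_microbes):
        seq = _host_free_seq(rng, config.endophyte_len, config.gc, forbidden)
        pool.append(SequenceRecord(f"core_{i + 1}", seq, ROLE_SHARED))
        forbidden = np.union1d(forbidden, canonical_set([seq], K_EXCLUSION))
    lo, hi = config.insertion_len_range
    for i in range(config.n_insertions):
        length = int(rng.integers(lo, hi + 1))
        seq = _host_free_seq(rng, length, config.gc, forbidden)
        pool.append(SequenceRecord(f"donor_{i + 1}", seq, ROLE_DONOR))
        forbidden = np.union1d(forbidden, canonical_set([seq], K_EXCLUSION))
    return pool


def pool_by_role(pool: Sequence[SequenceRecord], role: str) -> list[SequenceRecord]:
    return [r for r in pool if r.description == role]


def plant_insertions(
    host: Sequence[SequenceRecord],
    pool: Sequence[SequenceRecord],
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], SimulationTruth]:
    """Splice foreign segments into the host at sampled positions.

    At each event the gall chromosome becomes
    ``host[:p] + foreign + host[p-m:p] + host[p:]`` where ``m`` is the
    microhomology length (the m host bases left of the site repeated at the
    foreign segment's 3' junction).  Sites keep ``min_flank`` distance from
    chromosome ends and >= 2*read_len separation on one chromosome.
    """
    donors = pool_by_role(pool, ROLE_DONOR)
    if config.n_insertions > 0 and not donors:
        donors = pool_by_role(pool, ROLE_ENDOPHYTE)
        if not donors:
            raise ValueError("pool has no donor or gall-only sequences to insert")

    rng = _rng(config, "insertions")
    lo, hi = config.insertion_len_range
    min_sep = 2 * config.read_len
    chosen: dict[str, list[int]] = {r.id: [] for r in host}
    events: list[InsertionEvent] = []
    lengths = np.array([len(r) for r in host], dtype=float)
    attempts = 0
    while len(events) < config.n_insertions:
        attempts += 1
        if attempts > 1000 * max(config.n_insertions, 1):
            raise RuntimeError("site exhaustion: cannot place insertions with required spacing")
        ci = int(rng.choice(len(host), p=lengths / lengths.sum()))
        chrom = host[ci]
        pos = int(rng.integers(config.min_flank, len(chrom) - config.min_flank + 1))
        if any(abs(pos - q) < min_sep for q in chosen[chrom.id]):
            continue
        donor = donors[len(events) % len(donors)]
        if donor.description == ROLE_DONOR:
            fstart, fend = 0, len(donor)
        else:  # slice a segment out of a larger foreign genome
            seg = int(rng.integers(lo, min(hi, len(donor)) + 1))
            fstart = int(rng.integers(0, len(donor) - seg + 1))
            fend = fstart + seg
        m = config.microhomology_len
        micro = chrom.seq[pos - m:pos] if m > 0 else ""
        chosen[chrom.id].append(pos)
        events.append(InsertionEvent(chrom.id, pos, donor.id, fstart, fend, micro))

    events.sort(key=lambda e: (e.chrom, e.position))
    donor_seqs = {r.id: r.seq for r in pool}
    gall: list[SequenceRecord] = []
    for chrom in host:
        parts: list[str] = []
        cursor = 0
        for ev in (e for e in events if e.chrom == chrom.id):
            parts.append(chrom.seq[cursor:ev.position])
            parts.append(donor_seqs[ev.foreign_id][ev.foreign_start:ev.foreign_end])
            parts.append(ev.microhomology)
            cursor = ev.position
        parts.append(chrom.seq[cursor:])
        gall.append(SequenceRecord(chrom.id, "".join(parts), chrom.description))

    truth = SimulationTruth(
        events=events,
        gall_only_taxa=[r.id for r in pool
                        if r.description in (ROLE_ENDOPHYTE, ROLE_DONOR)],
        shared_taxa=[r.id for r in pool_by_role(pool, ROLE_SHARED)],
    )
    return gall, truth


def sample_compositions(
    host: Sequence[SequenceRecord],
    gall_genome: Sequence[SequenceRecord],
    pool: Sequence[SequenceRecord],
) -> dict[str, list[tuple[SequenceRecord, float]]]:
    """Genome/weight mixtures for the two sequenced samples."""
    shared = pool_by_role(pool, ROLE_SHARED)
    endo = pool_by_role(pool, ROLE_ENDOPHYTE)
    return {
        "healthy": [(r, 1.0) for r in host] + [(r, 1.0) for r in shared],
        "gall": [(r, 1.0) for r in gall_genome] + [(r, 1.0) for r in endo]
                + [(r, 1.0) for r in shared],
    }


_MUT = {0: "CGT", 1: "AGT", 2: "ACT", 3: "ACG", 255: "ACGT"}
_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3}


def simulate_reads(
    genomes_with_weights: Sequence[tuple[SequenceRecord, float]],
    config: SimulationConfig,
    sample_label: str,
) -> list[ReadRecord]:
    """Uniform shotgun reads with substitution errors.

    Per genome the read count is ``round(weight * depth * genome_len /
    read_len)``; start positions and strands are uniform; each base is
    substituted with probability ``error_rate`` to a uniformly random
    different base.  Quality strings are constant 'I'.

    In paired mode (``config.paired``) reads are emitted as /1 and /2 mates
    from the two ends of a fragment with a fixed 200-bp inner gap (the /2
    mate reverse-complemented); the count formula then applies per pair.
    """
    if not genomes_with_weights or all(w <= 0 for _, w in genomes_with_weights):
        raise ValueError("need at least one genome with positive weight")
    for rec, w in genomes_with_weights:
        if w < 0:
            raise ValueError(f"negative weight for {rec.id}")
        if w > 0 and len(rec) < config.read_len:
            raise ValueError(f"read_len exceeds genome {rec.id} length")

    rng = _rng(config, f"reads:{sample_label}")
    L = config.read_len
    gap = 200  # fixed inner gap in paired mode
    qual = "I" * L

    def _with_errors(seq: str) -> str:
        e = int(rng.binomial(L, config.error_rate)) if config.error_rate > 0 else 0
        if not e:
            return seq
        chars = list(seq)
        for p in rng.choice(L, size=e, replace=False):
            alts = _MUT[_CODE_OF.get(chars[p], 255)]
            chars[p] = alts[int(rng.integers(0, len(alts)))]
        return "".join(chars)

    reads: list[ReadRecord] = []
    for rec, weight in genomes_with_weights:
        n = int(round(weight * config.depth_host * len(rec) / L))
        if n == 0:
            continue
        frag = 2 * L + gap
        if config.paired and len(rec) < frag:
            raise ValueError(f"fragment length exceeds genome {rec.id} length")
        span = frag if config.paired else L
        starts = rng.integers(0, len(rec) - span + 1, size=n)
        strands = rng.integers(0, 2, size=n)
        for i in range(n):
            if config.paired:
                fragment = rec.seq[starts[i]:starts[i] + frag]
                if strands[i]:
                    fragment = revcomp(fragment)
                base = f"{sample_label}:{rec.id}:{i:07d}"
                reads.append(ReadRecord(f"{base}/1", _with_errors(fragment[:L]),
                                        qual, sample=sample_label))
                reads.append(ReadRecord(f"{base}/2",
                                        _with_errors(revcomp(fragment[-L:])),
                                        qual, sample=sample_label))
            else:
                seq = rec.seq[starts[i]:starts[i] + L]
                if strands[i]:
                    seq = revcomp(seq)
                reads.append(ReadRecord(f"{sample_label}:{rec.id}:{i:07d}",
                                        _with_errors(seq), qual,
                                        sample=sample_label))
    return reads


TRUTH_HEADER = ["chrom", "position_1based", "foreign_id", "insert_len", "microhomology"]


def write_truth(truth: SimulationTruth, path: str) -> None:
    """TSV truth table; positions are written 1-based."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_HEADER)
        for ev in truth.events:
            w.writerow([ev.chrom, ev.position + 1, ev.foreign_id,
                        ev.insert_len, ev.microhomology or "."])


def read_truth(path: str) -> SimulationTruth:
    events: list[InsertionEvent] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != TRUTH_HEADER:
            raise ValueError(f"malformed truth file {path!r}: bad header")
        for row in reader:
            if len(row) != len(TRUTH_HEADER):
                raise ValueError(f"malformed truth row: {row!r}")
            chrom, pos1, fid, ilen, micro = row
            micro = "" if micro == "." else micro
            events.append(InsertionEvent(chrom, int(pos1) - 1, fid,
                                         0, int(ilen), micro))
    return SimulationTruth(events=events)
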