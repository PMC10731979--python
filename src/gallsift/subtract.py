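"""Host-read subtraction: semiperfect mapping and shared-read filtering.

Stage 1 places each read on the host reference in *semiperfect* mode: every
on-reference base of the (oriented) read must equal the reference base (N on
either side counts as a match), bases may overhang chromosome ends, and at
least half the read must lie on the reference.  Stage 2 compares the two
samples' unmapped reads by canonical k-mer containment and keeps only the
gall reads absent from the healthy sample — the gall-exclusive set.

Candidate placements come from shared canonical k-mer anchors.  Probing
k-mers at stride ``min_span - k + 1`` guarantees that any valid placement
leaves at least one probed window entirely inside its on-reference span, so
for N-free sequence the anchored search is exact (an optimization, not an
approximation, relative to an all-position scan).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .kmers import encode, in_sorted, revcomp, window_kmers
from .seqio import ReadRecord, SequenceRecord

DEFAULT_K = 31


@dataclass
class SemiperfectHit:
    read_id: str
    chrom: str
    pos: int                # 0-based leftmost on-reference position
    strand: str             # '+' or '-'
    overhang_left: int = 0
    overhang_right: int = 0


@dataclass
class MappingPartition:
    sample: str
    mapped_ids: set[str]
    unmapped_ids: set[str]

    @property
    def n_total(self) -> int:
        return len(self.mapped_ids) + len(self.unmapped_ids)

    @property
    def fraction_unmapped(self) -> float:
        return len(self.unmapped_ids) / self.n_total if self.n_total else 0.0


@dataclass
class SharedPartition:
    shared_ids: set[str]
    exclusive_ids: set[str]

    @property
    def fraction_exclusive(self) -> float:
        n = len(self.shared_ids) + len(self.exclusive_ids)
        return len(self.exclusive_ids) / n if n else 0.0


class KmerIndex:
    """Canonical k-mer index over a reference genome.

    Postings map canonical k-mer -> list of ``(chrom_idx, offset,
    fwd_is_canonical)``; windows containing N are not indexed.
    """

    def __init__(self, genome: Sequence[SequenceRecord], k: int = DEFAULT_K):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        if not (3 <= k <= 63):
            raise ValueError("k must lie in [3, 63]")
        if not genome:
            raise ValueError("genome is empty")
        if k > min(len(r) for r in genome):
            raise ValueError("k exceeds the shortest chromosome")
        self.k = k
        self.chrom_names = [r.id for r in genome]
        self.seqs: dict[str, str] = {r.id: r.seq for r in genome}
        self.postings: dict[int, list[tuple[int, int, bool]]] = {}
        for ci, rec in enumerate(genome):
            fwd, canon, valid = window_kmers(rec.seq, k)
            setdefault = self.postings.setdefault
            offs = np.nonzero(valid)[0]
            fwd_is_canon = fwd[offs] == canon[offs]
            keys = canon[offs]
            for j in range(offs.size):
                setdefault(int(keys[j]), []).append(
                    (ci, int(offs[j]), bool(fwd_is_canon[j])))

    def n_windows(self) -> int:
        return sum(len(v) for v in self.postings.values())

    def lookup(self, kmer: str) -> list[tuple[int, int, bool]]:
        """Postings for a k-mer; identical for a k-mer and its reverse complement."""
        f = encode(kmer)
        if f is None:
            return []
        r = encode(revcomp(kmer))
        return self.postings.get(min(f, r), [])  # type: ignore[type-var]


def build_reference_index(genome: Sequence[SequenceRecord], k: int = DEFAULT_K) -> KmerIndex:
    return KmerIndex(genome, k)


def _verify_semiperfect(oriented: str, chrom_seq: str, pos: int, min_span: int
                        ) -> tuple[int, int] | None:
    """Overhangs if ``oriented`` placed at ``pos`` is a semiperfect match, else None."""
    L = len(oriented)
    cl = len(chrom_seq)
    s, e = max(0, pos), min(cl, pos + L)
    if e - s < min_span:
        return None
    ref = chrom_seq[s:e]
    qry = oriented[s - pos:e - pos]
    if ref != qry:
        if "N" not in ref and "N" not in qry:
            return None
        if any(a != b and a != "N" and b != "N" for a, b in zip(qry, ref)):
            return None
    return (s - pos, pos + L - e)


def map_semiperfect(read: ReadRecord | str, index: KmerIndex) -> list[SemiperfectHit]:
    """All semiperfect placements of a read on the indexed genome.

    Reads shorter than k return no hits.  Results are sorted by
    ``(chrom, pos)`` and deduplicated across anchors.
    """
    seq = read.seq if isinstance(read, ReadRecord) else read
    read_id = read.id if isinstance(read, ReadRecord) else ""
    k = index.k
    L = len(seq)
    if L < k:
        return []
    min_span = (L + 1) // 2
    if "N" in seq:
        # strided probes may all land on N windows; fall back to every window
        # (windows containing N are skipped below and are never indexed, so a
        # placement whose whole on-reference span lacks a clean window is not
        # anchorable by construction)
        probes = list(range(0, L - k + 1))
    else:
        stride = max(1, min_span - k + 1)
        probes = list(range(0, L - k + 1, stride))
        if probes[-1] != L - k:
            probes.append(L - k)

    hits: dict[tuple[str, int, str], SemiperfectHit] = {}
    rc_seq = revcomp(seq)
    for oriented, strand in ((seq, "+"), (rc_seq, "-")):
        rc_oriented = rc_seq if strand == "+" else seq
        for q in probes:
            f = encode(oriented[q:q + k])
            if f is None:
                continue
            r = encode(rc_oriented[L - k - q:L - q])
            canon = f if f <= r else r
            flag = f <= r  # this orientation's window is the canonical form
            for ci, off, ref_canon in index.postings.get(canon, ()):
                if ref_canon != flag:
                    continue
                pos = off - q
                chrom = index.chrom_names[ci]
                key = (chrom, pos, strand)
                if key in hits:
                    continue
                over = _verify_semiperfect(oriented, index.seqs[chrom], pos, min_span)
                if over is not None:
                    hits[key] = SemiperfectHit(read_id, chrom, max(0, pos), strand,
                                               over[0], over[1])
    return sorted(hits.values(), key=lambda h: (h.chrom, h.pos, h.strand))


def partition_reads(reads: Sequence[ReadRecord], index: KmerIndex,
                    sample: str | None = None) -> MappingPartition:
    """Split one sample's reads into host-mapped vs. unmapped."""
    if not reads:
        raise ValueError("empty read set")
    label = sample if sample is not None else reads[0].sample
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for read in reads:
        (mapped if map_semiperfect(read, index) else unmapped).add(read.id)
    return MappingPartition(label, mapped, unmapped)


def filter_shared_reads(
    gall_unmapped: Sequence[ReadRecord],
    healthy_unmapped: Sequence[ReadRecord],
    k: int = DEFAULT_K,
    min_shared_fraction: float = 0.5,
) -> SharedPartition:
    """Split gall-unmapped reads into shared-with-healthy vs. gall-exclusive.

    A gall read is *shared* iff the fraction of its k-mer windows whose
    canonical form occurs anywhere in the healthy unmapped read set reaches
    ``min_shared_fraction``.  Reads shorter than k are exclusive.
    """
    if not gall_unmapped:
        raise ValueError("empty gall read set")
    if not (0.0 < min_shared_fraction <= 1.0):
        raise ValueError("min_shared_fraction must lie in (0, 1]")

    healthy_set = (np.zeros(0, dtype=np.uint64) if not healthy_unmapped
                   else _canon_kmer_set([r.seq for r in healthy_unmapped], k))

    shared: set[str] = set()
    exclusive: set[str] = set()
    for read in gall_unmapped:
        n_windows = len(read.seq) - k + 1
        if n_windows <= 0:
            exclusive.add(read.id)
            continue
        _, canon, valid = window_kmers(read.seq, k)
        n_present = int(in_sorted(canon[valid], healthy_set).sum())
        if n_present / n_windows >= min_shared_fraction:
            shared.add(read.id)
        else:
            exclusive.add(read.id)
    return SharedPartition(shared, exclusive)


def _canon_kmer_set(seqs: list[str], k: int) -> np.ndarray:
    joined = "N".join(seqs)
    _, canon, valid = window_kmers(joined, k)
    return np.unique(canon[valid])


def write_partition_tsv(path: str, partition: MappingPartition) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclass\n")
        for rid in sorted(partition.mapped_ids):
            fh.write(f"{rid}\tmapped\n")
        for rid in sorted(partition.unmapped_ids):
            fh.write(f"{rid}\tunmapped\n")


def write_summary_json(path: str, partitions: Iterable[MappingPartition],
                       shared: SharedPartition | None = None) -> None:
    payload: dict = {"samples": {}}
    for p in partitions:
        payload["samples"][p.sample] = {
            "n_total": p.n_total,
            "n_mapped": len(p.mapped_ids),
            "n_unmapped": len(p.unmapped_ids),
            "fraction_unmapped": round(p.fraction_unmapped, 6),
        }
    if shared is not None:
        payload["gall_unmapped"] = {
            "n_shared": len(shared.shared_ids),
            "n_exclusive": len(shared.exclusive_ids),
            "fraction_exclusive": round(shared.fraction_exclusive, 6),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
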