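"""Minimal de Bruijn assembly of gall-exclusive reads.

Single-k de Bruijn graph over canonical k-mers with abundance pruning, unitig
(maximal non-branching path) extraction, one round of tip clipping with
recompaction, and edit-distance dereplication at the pipeline's length and
identity thresholds (200 bp, >=95%).  Externally assembled contigs can be
substituted for this assembler anywhere downstream via plain FASTA import.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .kmers import canonical_str, decode, revcomp, window_kmers
from .seqio import ReadRecord, SequenceRecord

DEFAULT_K = 31
DEFAULT_MIN_KMER_COUNT = 2


@dataclass
class DeBruijnGraph:
    k: int
    counts: dict[str, int]  # canonical k-mer -> abundance (post-pruning)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class Contig:
    id: str
    seq: str
    mean_kmer_coverage: float

    @property
    def length(self) -> int:
        return len(self.seq)


def build_graph(reads: Sequence[ReadRecord] | Sequence[str], k: int = DEFAULT_K,
                min_kmer_count: int = DEFAULT_MIN_KMER_COUNT) -> DeBruijnGraph:
    """Count canonical k-mers across reads; retain those seen >= min_kmer_count.

    k-mers containing N are dropped.  An empty read list (or nothing
    surviving the abundance filter) yields an empty graph, not an error.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if min_kmer_count < 1:
        raise ValueError("min_kmer_count must be >= 1")
    seqs = [r.seq if isinstance(r, ReadRecord) else r for r in reads]
    seqs = [s for s in seqs if len(s) >= k]
    if not seqs:
        return DeBruijnGraph(k, {})
    joined = "N".join(seqs)
    _, canon, valid = window_kmers(joined, k)
    uniq, n = np.unique(canon[valid], return_counts=True)
    keep = n >= min_kmer_count
    counts = {decode(int(v), k): int(c) for v, c in zip(uniq[keep], n[keep])}
    return DeBruijnGraph(k, counts)


def _exts(nodes: set[str], s: str, forward: bool) -> list[str]:
    if forward:
        stem = s[1:]
        return [b for b in "ACGT" if canonical_str(stem + b) in nodes]
    stem = s[:-1]
    return [b for b in "ACGT" if canonical_str(b + stem) in nodes]


def _walk_unitig(nodes: set[str], start: str) -> list[str]:
    """Oriented k-mer path of the maximal non-branching run through ``start``."""
    # walk backward to the unitig's first node
    cur = start
    seen = {canonical_str(cur)}
    while True:
        back = _exts(nodes, cur, forward=False)
        if len(back) != 1:
            break
        pred = back[0] + cur[:-1]
        if len(_exts(nodes, pred, forward=True)) != 1:
            break
        c = canonical_str(pred)
        if c in seen:  # cycle
            break
        seen.add(c)
        cur = pred
    path = [cur]
    seen = {canonical_str(cur)}
    while True:
        fwd = _exts(nodes, cur, forward=True)
        if len(fwd) != 1:
            break
        nxt = cur[1:] + fwd[0]
        if len(_exts(nodes, nxt, forward=False)) != 1:
            break
        c = canonical_str(nxt)
        if c in seen:
            break
        seen.add(c)
        path.append(nxt)
        cur = nxt
    return path


def _unitigs(counts: dict[str, int], k: int) -> list[tuple[str, list[str]]]:
    nodes = set(counts)
    visited: set[str] = set()
    out: list[tuple[str, list[str]]] = []
    for km in sorted(counts):
        if km in visited:
            continue
        path = _walk_unitig(nodes, km)
        canon_path = [canonical_str(p) for p in path]
        visited.update(canon_path)
        seq = path[0] + "".join(p[-1] for p in path[1:])
        out.append((seq, canon_path))
    return out


def extract_contigs(graph: DeBruijnGraph, min_len: int = 1) -> list[Contig]:
    """Unitigs of the pruned graph, tip-clipped, in canonical orientation.

    Tips (unitigs shorter than 2k with a dead end) are removed and the graph
    recompacted once.  Each contig is reported as the lexicographic minimum
    of itself and its reverse complement; ordering is deterministic by
    (length desc, seq).
    """
    k = graph.k
    if not graph.counts:
        return []
    units = _unitigs(graph.counts, k)

    def is_tip(seq: str, path: list[str]) -> bool:
        if len(seq) >= 2 * k:
            return False
        nodes = set(graph.counts)
        first = seq[:k]
        last = seq[-k:]
        return (len(_exts(nodes, first, forward=False)) == 0
                or len(_exts(nodes, last, forward=True)) == 0)

    tip_kmers: set[str] = set()
    for seq, path in units:
        if is_tip(seq, path):
            tip_kmers.update(path)
    if tip_kmers:
        remaining = {km: c for km, c in graph.counts.items() if km not in tip_kmers}
        units = _unitigs(remaining, k) if remaining else []
        counts = remaining
    else:
        counts = graph.counts

    contigs: list[Contig] = []
    for seq, path in units:
        if len(seq) < max(min_len, 1):
            continue
        cov = float(np.mean([counts[c] for c in path]))
        rc = revcomp(seq)
        contigs.append(Contig("", min(seq, rc), cov))
    contigs.sort(key=lambda c: (-c.length, c.seq))
    for i, c in enumerate(contigs):
        c.id = f"contig_{i + 1:05d}"
    return contigs


def _containment_identity(a: str, b: str) -> float:
    """Best identity of a (either orientation) aligned as an infix of b."""
    best = 0.0
    for q in (a, revcomp(a)):
        res = edlib.align(q, b, mode="HW", task="distance")
        d = res["editDistance"]
        if d >= 0:
            best = max(best, (len(a) - d) / len(a))
    return best


def dereplicate_contigs(
    contigs: Sequence[Contig],
    min_identity: float = 0.95,
    min_len: int = 200,
    containment_fraction: float = 0.9,
) -> list[Contig]:
    """Length filter then greedy redundancy removal by descending length.

    A contig is dropped when it aligns (either orientation) into an already
    retained, longer contig at >= ``min_identity`` over at least
    ``containment_fraction`` of its length; identity is measured as
    ``(len - edit_distance) / len`` over the full contig and, to honour the
    containment fraction, over its central window of that fraction.
    Deterministic and idempotent.
    """
    survivors: list[Contig] = []
    trim_frac = (1.0 - containment_fraction) / 2.0
    for contig in sorted(contigs, key=lambda c: (-c.length, c.seq)):
        if contig.length < min_len:
            continue
        redundant = False
        trim = int(contig.length * trim_frac)
        core = contig.seq[trim:contig.length - trim] if trim else contig.seq
        for kept in survivors:
            if _containment_identity(contig.seq, kept.seq) >= min_identity:
                redundant = True
                break
            if trim and _containment_identity(core, kept.seq) >= min_identity:
                redundant = True
                break
        if not redundant:
            survivors.append(contig)
    return survivors


def contigs_to_records(contigs: Iterable[Contig]) -> list[SequenceRecord]:
    return [SequenceRecord(c.id, c.seq, f"cov={c.mean_kmer_coverage:.2f}")
            for c in contigs]


def records_to_contigs(records: Iterable[SequenceRecord]) -> list[Contig]:
    """Import externally assembled contigs from FASTA records."""
    out = []
    for rec in records:
        cov = 0.0
        for token in rec.description.split():
            if token.startswith("cov="):
                cov = float(token[4:])
        out.append(Contig(rec.id, rec.seq, cov))
    return out
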