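"""Hybrid/fusion contig detection against the host reference.

Contigs assembled from gall-exclusive reads are aligned back to the host
genome by seed-chain-extend (exact 19-mer anchors on both strands, colinear
clustering within a diagonal band, banded local extension with match +1,
mismatch -4, gap 6+L), producing CIGAR alignments with soft-clipped ends.
A mapping-confidence surrogate separates uniquely placed alignments from
ambiguous ones, and contigs whose 5', 3' or both ends anchor to the host
while their core does not are classified as candidate foreign-DNA insertion
sites.  Read-back support counting and a simple containment check against
bacterial isolate genomes complete the stage.

A contig with host anchors at both ends can be encoded either as one
alignment with an internal insertion op ("100M200I100M") or as two
soft-clipped alignments; classification treats the two representations
identically by splitting alignments at insertion ops >= min_core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import re
import warnings
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import Align

from .assemble import Contig
from .kmers import encode, in_sorted, revcomp, window_kmers
from .seqio import ReadRecord, SequenceRecord

DEFAULT_SEED_K = 19
DEFAULT_BAND = 32
DEFAULT_MAX_SEED_GAP = 500
DEFAULT_MIN_SCORE = 30
DEFAULT_MIN_CONFIDENCE = 20
DEFAULT_MIN_ANCHOR = 30
DEFAULT_MIN_CORE = 30
DEFAULT_END_SLACK = 10
DEFAULT_MICROHOMOLOGY_MAX = 30
DEFAULT_MAX_REF_GAP = 200
CONFIDENCE_MAX = 60

FULL_MATCH = "FULL_MATCH"
FIVE_PRIME = "FIVE_PRIME"
THREE_PRIME = "THREE_PRIME"
BOTH = "BOTH"
NONE = "NONE"

_CIGAR_RE = re.compile(r"(\d+)([MIDS])")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -4
    aligner.open_gap_score = -7   # a gap of length L costs 6 + L
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class CigarAlignment:
    """One local alignment of a contig to the reference.

    ``cigar`` is expressed over the oriented contig (reverse-complemented
    when ``strand`` is '-'), SAM-style: M consumes contig and reference
    (match or mismatch), I consumes contig only, D reference only, S marks
    unaligned contig ends.  M+I+S lengths always sum to the contig length.
    """

    contig_id: str
    chrom: str
    ref_start: int
    strand: str
    cigar: str
    n_match: int
    n_mismatch: int
    score: float
    confidence: int | None = None

    @property
    def identity(self) -> float:
        aligned = self.n_match + self.n_mismatch
        return self.n_match / aligned if aligned else 0.0

    def ops(self) -> list[tuple[int, str]]:
        return [(int(n), op) for n, op in _CIGAR_RE.findall(self.cigar)]

    def contig_len(self) -> int:
        return sum(n for n, op in self.ops() if op in "MIS")

    def oriented_blocks(self) -> list[tuple[int, int, int, int]]:
        """(c_start, c_end, r_start, r_end) per M run, oriented contig coords."""
        blocks = []
        c = 0
        r = self.ref_start
        for n, op in self.ops():
            if op == "M":
                blocks.append((c, c + n, r, r + n))
                c += n
                r += n
            elif op in ("I", "S"):
                c += n
            elif op == "D":
                r += n
        return blocks

    def contig_span(self) -> tuple[int, int]:
        """Aligned contig interval in original contig coordinates."""
        blocks = self.oriented_blocks()
        lo, hi = blocks[0][0], blocks[-1][1]
        if self.strand == "-":
            L = self.contig_len()
            return (L - hi, L - lo)
        return (lo, hi)


@dataclass
class Anchor:
    """A host-matching segment of a contig (original contig coordinates)."""

    chrom: str
    ref_start: int
    ref_end: int
    contig_start: int
    contig_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class HybridCall:
    contig_id: str
    anchor_class: str
    host_anchors: list[Anchor] = field(default_factory=list)
    foreign_core: tuple[int, int] | None = None
    insertion_site: tuple[str, int] | None = None          # canonical point
    insertion_points: tuple[str, int, int] | None = None   # (chrom, p5, p3), BOTH only
    support: int = 0
    junction_support: int = 0
    allowlisted: bool = False
    warning: str | None = None


@dataclass
class SupportReport:
    contig_id: str
    support: int
    junction_support: int


# ---------------------------------------------------------------------------
# Alignment: seed, cluster, extend
# ---------------------------------------------------------------------------

def _collect_seeds(
    contig_variants: list[str],
    genome: Sequence[SequenceRecord],
    seed_k: int,
) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Exact seed matches: (chrom_idx, orient) -> [(ref_off, contig_off)]."""
    lookup: dict[int, list[tuple[int, int, int]]] = {}
    for orient, seq in enumerate(contig_variants):
        fwd, canon, valid = window_kmers(seq, seed_k)
        for q in np.nonzero(valid)[0]:
            lookup.setdefault(int(canon[q]), []).append(
                (orient, int(q), int(fwd[q])))
    if not lookup:
        return {}
    keys = np.array(sorted(lookup), dtype=np.uint64)
    seeds: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for ci, rec in enumerate(genome):
        if len(rec.seq) < seed_k:
            continue
        gfwd, gcanon, gvalid = window_kmers(rec.seq, seed_k)
        hit_mask = in_sorted(gcanon, keys) & gvalid
        for off in np.nonzero(hit_mask)[0]:
            g = int(gfwd[off])
            for orient, q, cf in lookup[int(gcanon[off])]:
                if cf == g:  # contig window (in this orientation) equals ref forward
                    seeds.setdefault((ci, orient), []).append((int(off), q))
    return seeds


def _cluster_seeds(seeds: list[tuple[int, int]], band: int, max_gap: int
                   ) -> list[list[tuple[int, int]]]:
    by_diag = sorted(seeds, key=lambda s: (s[0] - s[1], s[1]))
    diag_groups: list[list[tuple[int, int]]] = []
    for s in by_diag:
        d = s[0] - s[1]
        if diag_groups and d - (diag_groups[-1][-1][0] - diag_groups[-1][-1][1]) <= band:
            diag_groups[-1].append(s)
        else:
            diag_groups.append([s])
    clusters: list[list[tuple[int, int]]] = []
    for grp in diag_groups:
        grp.sort(key=lambda s: s[1])
        cur = [grp[0]]
        for s in grp[1:]:
            if s[1] - cur[-1][1] <= max_gap:
                cur.append(s)
            else:
                clusters.append(cur)
                cur = [s]
        clusters.append(cur)
    return clusters


def _extend_cluster(
    contig_id: str,
    oriented: str,
    strand: str,
    chrom: str,
    chrom_seq: str,
    cluster: list[tuple[int, int]],
    seed_k: int,
    band: int,
    min_score: float,
) -> CigarAlignment | None:
    Lc = len(oriented)
    qs = [q for _, q in cluster]
    diags = [r - q for r, q in cluster]
    pad = band + 2 * seed_k
    q_lo = max(0, min(qs) - pad)
    q_hi = min(Lc, max(qs) + seed_k + pad)
    ref_lo = max(0, min(diags) + q_lo - band - 8)
    ref_hi = min(len(chrom_seq), max(diags) + q_hi + band + 8)
    if ref_hi <= ref_lo:
        return None
    window = chrom_seq[ref_lo:ref_hi]
    query = oriented[q_lo:q_hi]
    result = _ALIGNER.align(window, query)
    if result.score < min_score:
        return None
    aln = result[0]
    t_blocks, q_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None

    ops: list[tuple[int, str]] = []
    lead = q_blocks[0][0] + q_lo
    if lead:
        ops.append((int(lead), "S"))
    n_match = n_mismatch = 0
    for bi in range(len(q_blocks)):
        if bi > 0:
            dq = int(q_blocks[bi][0] - q_blocks[bi - 1][1])
            dr = int(t_blocks[bi][0] - t_blocks[bi - 1][1])
            if dq:
                ops.append((dq, "I"))
            if dr:
                ops.append((dr, "D"))
        n = int(q_blocks[bi][1] - q_blocks[bi][0])
        ops.append((n, "M"))
        qseg = query[q_blocks[bi][0]:q_blocks[bi][1]]
        tseg = window[t_blocks[bi][0]:t_blocks[bi][1]]
        eq = sum(a == b for a, b in zip(qseg, tseg))
        n_match += eq
        n_mismatch += n - eq
    tail = Lc - (q_blocks[-1][1] + q_lo)
    if tail:
        ops.append((int(tail), "S"))

    merged: list[tuple[int, str]] = []
    for n, op in ops:  # fuse adjacent equal ops (can arise at window edges)
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    cigar = "".join(f"{n}{op}" for n, op in merged)
    return CigarAlignment(
        contig_id=contig_id,
        chrom=chrom,
        ref_start=int(t_blocks[0][0]) + ref_lo,
        strand=strand,
        cigar=cigar,
        n_match=n_match,
        n_mismatch=n_mismatch,
        score=float(result.score),
    )


def align_contig_to_reference(
    contig: Contig | SequenceRecord | str,
    genome: Sequence[SequenceRecord],
    seed_k: int = DEFAULT_SEED_K,
    band: int = DEFAULT_BAND,
    max_seed_gap: int = DEFAULT_MAX_SEED_GAP,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[CigarAlignment]:
    """Seed-chain-extend alignment of one contig against the reference.

    Returns all alignments scoring >= ``min_score``, sorted by score
    descending.  Contigs shorter than ``seed_k`` (or sharing no exact seed
    with the reference) return an empty list.
    """
    seq = contig if isinstance(contig, str) else contig.seq
    cid = "" if isinstance(contig, str) else contig.id
    if len(seq) < seed_k:
        return []
    variants = [seq, revcomp(seq)]
    seeds = _collect_seeds(variants, genome, seed_k)
    out: dict[tuple, CigarAlignment] = {}
    for (ci, orient), slist in sorted(seeds.items()):
        strand = "+" if orient == 0 else "-"
        for cluster in _cluster_seeds(slist, band, max_seed_gap):
            aln = _extend_cluster(cid, variants[orient], strand,
                                  genome[ci].id, genome[ci].seq, cluster,
                                  seed_k, band, min_score)
            if aln is not None:
                key = (aln.chrom, aln.strand, aln.ref_start, aln.cigar)
                out.setdefault(key, aln)
    return sorted(out.values(), key=lambda a: (-a.score, a.chrom, a.ref_start))


def mapping_confidence(alignments: Sequence[CigarAlignment]) -> list[CigarAlignment]:
    """Assign a 0-60 uniqueness confidence to each alignment.

    Two alignments compete when their contig intervals overlap by more than
    half the shorter interval (placements of *the same* part of the contig);
    host anchors at opposite contig ends do not compete.  The best alignment
    in a competition gets ``round(60 * (s1 - s2) / s1)`` where ``s2`` is the
    best competing score (0 if none); ties and secondary placements get 0.
    """
    alns = sorted(alignments, key=lambda a: (-a.score, a.chrom, a.ref_start))
    spans = [a.contig_span() for a in alns]
    out: list[CigarAlignment] = []
    for i, a in enumerate(alns):
        s2 = 0.0
        tie = False
        for j, b in enumerate(alns):
            if i == j:
                continue
            lo = max(spans[i][0], spans[j][0])
            hi = min(spans[i][1], spans[j][1])
            shorter = min(spans[i][1] - spans[i][0], spans[j][1] - spans[j][0])
            if hi - lo <= 0.5 * shorter:
                continue
            if b.score > s2:
                s2 = b.score
            if b.score >= a.score:
                tie = True
        if tie or a.score <= 0:
            conf = 0
        else:
            conf = int(round(CONFIDENCE_MAX * (a.score - s2) / a.score))
        out.append(replace(a, confidence=conf))
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _anchors_from_alignment(aln: CigarAlignment, min_core: int) -> list[Anchor]:
    """Split an alignment into host anchors at insertion ops >= min_core.

    This merges the two encodings of an internal insertion: a single
    "xM nI yM" alignment yields the same anchors as two soft-clipped ones.
    """
    L = aln.contig_len()
    groups: list[list[tuple[int, int, int, int]]] = []
    for block in aln.oriented_blocks():
        if groups and block[0] - groups[-1][-1][1] < min_core:
            groups[-1].append(block)
        else:
            groups.append([block])
    anchors = []
    for grp in groups:
        c_s, c_e = grp[0][0], grp[-1][1]
        r_s, r_e = grp[0][2], grp[-1][3]
        if aln.strand == "-":
            c_s, c_e = L - c_e, L - c_s
        anchors.append(Anchor(aln.chrom, r_s, r_e, c_s, c_e,
                              aln.strand, aln.identity))
    return anchors


def _junction(anchor: Anchor, side: str) -> int:
    """Reference coordinate where foreign sequence meets this anchor.

    ``side`` is 'prefix' (anchor at the contig 5' end, core to its right) or
    'suffix'.  For a '+' prefix the junction is the anchor's reference end;
    strand and side flips mirror it.
    """
    if (side == "prefix") == (anchor.strand == "+"):
        return anchor.ref_end
    return anchor.ref_start


def classify_hybrid(
    contig: Contig | str,
    alignments: Sequence[CigarAlignment],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_core: int = DEFAULT_MIN_CORE,
    min_identity: float = 0.95,
    min_confidence: int = DEFAULT_MIN_CONFIDENCE,
    end_slack: int = DEFAULT_END_SLACK,
    microhomology_max: int = DEFAULT_MICROHOMOLOGY_MAX,
    max_ref_gap: int = DEFAULT_MAX_REF_GAP,
) -> HybridCall:
    """Classify a contig by its host end-anchoring pattern.

    FULL_MATCH: host-aligned cover >= contig length - 2*end_slack (or the
    unaligned core is below min_core).  FIVE_PRIME / THREE_PRIME / BOTH:
    qualifying anchor(s) of >= min_anchor bases at the respective contig
    end(s) with a >= min_core unanchored core.  NONE otherwise; overlapping
    anchors on different chromosomes yield NONE with a warning.
    """
    seq = contig if isinstance(contig, str) else contig.seq
    cid = "" if isinstance(contig, str) else contig.id
    L = len(seq)

    kept = [a for a in alignments
            if (a.confidence is None or a.confidence >= min_confidence)
            and a.identity >= min_identity]
    anchors: list[Anchor] = []
    for aln in kept:
        anchors.extend(x for x in _anchors_from_alignment(aln, min_core)
                       if x.length >= min_anchor)
    if not anchors:
        return HybridCall(cid, NONE)

    # contradictory placements: same contig bases on different chromosomes
    for i, a in enumerate(anchors):
        for b in anchors[i + 1:]:
            lo = max(a.contig_start, b.contig_start)
            hi = min(a.contig_end, b.contig_end)
            if hi - lo > 0.5 * min(a.length, b.length) and a.chrom != b.chrom:
                return HybridCall(cid, NONE, warning="contradictory_anchors")

    covered = 0
    for s, e in _merge_intervals([(a.contig_start, a.contig_end) for a in anchors]):
        covered += e - s
    if covered >= L - 2 * end_slack:
        return HybridCall(cid, FULL_MATCH, host_anchors=anchors)

    prefixes = [a for a in anchors if a.contig_start <= end_slack]
    suffixes = [a for a in anchors if a.contig_end >= L - end_slack]
    prefix = max(prefixes, key=lambda a: a.contig_end) if prefixes else None
    suffix = min(suffixes, key=lambda a: a.contig_start) if suffixes else None
    if prefix is not None and suffix is not None and prefix is suffix:
        suffix = None  # one anchor cannot bound a core on both sides

    if prefix is not None and suffix is not None:
        core = (prefix.contig_end, suffix.contig_start)
        if core[1] - core[0] < min_core:
            return HybridCall(cid, FULL_MATCH, host_anchors=anchors)
        consistent = (prefix.chrom == suffix.chrom
                      and prefix.strand == suffix.strand)
        if consistent:
            left, right = ((prefix, suffix)
                           if prefix.ref_start <= suffix.ref_start
                           else (suffix, prefix))
            gap = right.ref_start - left.ref_end
            consistent = -microhomology_max <= gap <= max_ref_gap
        if consistent:
            p5 = _junction(prefix, "prefix")
            p3 = _junction(suffix, "suffix")
            call = HybridCall(
                cid, BOTH, host_anchors=[prefix, suffix], foreign_core=core,
                insertion_site=(prefix.chrom, left.ref_end),
                insertion_points=(prefix.chrom, p5, p3),
            )
            return call
        # keep the stronger side as a one-sided call
        if prefix.length >= suffix.length:
            suffix = None
            warning = "discordant_anchors"
        else:
            prefix = None
            warning = "discordant_anchors"
    else:
        warning = None

    if prefix is not None:
        core = (prefix.contig_end, L)
        if core[1] - core[0] < min_core:
            return HybridCall(cid, FULL_MATCH, host_anchors=anchors)
        return HybridCall(cid, FIVE_PRIME, host_anchors=[prefix],
                          foreign_core=core,
                          insertion_site=(prefix.chrom, _junction(prefix, "prefix")),
                          warning=warning)
    if suffix is not None:
        core = (0, suffix.contig_start)
        if core[1] - core[0] < min_core:
            return HybridCall(cid, FULL_MATCH, host_anchors=anchors)
        return HybridCall(cid, THREE_PRIME, host_anchors=[suffix],
                          foreign_core=core,
                          insertion_site=(suffix.chrom, _junction(suffix, "suffix")),
                          warning=warning)
    return HybridCall(cid, NONE, host_anchors=anchors)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def estimate_insertion_site(call: HybridCall) -> tuple:
    """Reference insertion point(s) implied by a hybrid call (0-based).

    One-sided calls return ``(chrom, point)``; BOTH calls return
    ``(chrom, point5, point3)`` — equal points mean a clean junction, a
    negative gap means junction microhomology.
    """
    if call.anchor_class in (FULL_MATCH, NONE):
        raise ValueError(f"not a hybrid: {call.contig_id or '<contig>'} "
                         f"is {call.anchor_class}")
    if call.anchor_class == BOTH:
        return call.insertion_points
    return call.insertion_site


# ---------------------------------------------------------------------------
# Read-back support
# ---------------------------------------------------------------------------

class _ContigPlacer:
    """Approximate read placement on one contig (<= max_mismatch)."""

    def __init__(self, contig_seq: str, k: int = 31, max_mismatch: int = 2):
        self.seq = contig_seq
        self.k = k
        self.max_mismatch = max_mismatch
        self.postings: dict[int, list[tuple[int, bool]]] = {}
        fwd, canon, valid = window_kmers(contig_seq, k)
        for off in np.nonzero(valid)[0]:
            self.postings.setdefault(int(canon[off]), []).append(
                (int(off), bool(fwd[off] == canon[off])))

    def place(self, read_seq: str) -> list[tuple[int, int]]:
        """On-contig intervals of accepted placements (either strand)."""
        k = self.k
        L = len(read_seq)
        if L < k:
            return []
        stride = max(1, k // 2)
        probes = list(range(0, L - k + 1, stride))
        if probes[-1] != L - k:
            probes.append(L - k)
        placements: set[tuple[int, str]] = set()
        rc = revcomp(read_seq)
        for oriented, strand in ((read_seq, "+"), (rc, "-")):
            rc_oriented = rc if strand == "+" else read_seq
            for q in probes:
                f = encode(oriented[q:q + k])
                if f is None:
                    continue
                r = encode(rc_oriented[L - k - q:L - q])
                canon = f if f <= r else r
                flag = f <= r
                for off, ref_canon in self.postings.get(canon, ()):
                    if ref_canon == flag:
                        placements.add((off - q, strand))
        out = []
        for pos, strand in placements:
            oriented = read_seq if strand == "+" else rc
            iv = self._check(oriented, pos)
            if iv is not None:
                out.append(iv)
        return out

    def _check(self, oriented: str, pos: int) -> tuple[int, int] | None:
        L = len(oriented)
        cl = len(self.seq)
        s, e = max(0, pos), min(cl, pos + L)
        if e - s < (L + 1) // 2:
            return None
        ref = self.seq[s:e]
        qry = oriented[s - pos:e - pos]
        if ref != qry:
            mism = 0
            for a, b in zip(qry, ref):
                if a != b and a != "N" and b != "N":
                    mism += 1
                    if mism > self.max_mismatch:
                        return None
        return (s, e)


def count_support(
    contig: Contig | str,
    exclusive_reads: Sequence[ReadRecord],
    junctions: Sequence[int] = (),
    junction_pad: int = 10,
    max_mismatch: int = 2,
    contig_id: str | None = None,
) -> SupportReport:
    """Count exclusive reads placing on a contig, and those spanning junctions.

    A read supports the contig when it has a semiperfect-or-<=max_mismatch
    placement (either strand, half-read overhang allowed); it supports a
    junction when its placement covers the junction with >= junction_pad
    bases on each side.  junction_support <= support by construction.
    """
    seq = contig if isinstance(contig, str) else contig.seq
    cid = contig_id if contig_id is not None else (
        "" if isinstance(contig, str) else contig.id)
    placer = _ContigPlacer(seq, max_mismatch=max_mismatch)
    support = 0
    junction_support = 0
    for read in exclusive_reads:
        ivs = placer.place(read.seq)
        if not ivs:
            continue
        support += 1
        if junctions and any(
            s <= j - junction_pad and j + junction_pad <= e
            for s, e in ivs for j in junctions
        ):
            junction_support += 1
    return SupportReport(cid, support, junction_support)


def filter_by_support(
    calls: Sequence[HybridCall],
    reports: dict[str, SupportReport],
    min_support: int = 3,
    allowlist: Iterable[str] = (),
) -> list[HybridCall]:
    """Retain calls with support >= min_support; allowlisted ids are exempt."""
    allow = set(allowlist)
    known = {c.contig_id for c in calls}
    for missing in sorted(allow - known):
        warnings.warn(f"allowlisted contig {missing!r} not among calls",
                      stacklevel=2)
    retained: list[HybridCall] = []
    for call in calls:
        rep = reports.get(call.contig_id)
        support = rep.support if rep else 0
        jsupport = rep.junction_support if rep else 0
        call = replace(call, support=support, junction_support=jsupport)
        if support >= min_support:
            retained.append(call)
        elif call.contig_id in allow:
            retained.append(replace(call, allowlisted=True))
    return retained


# ---------------------------------------------------------------------------
# Endophyte containment ("synteny") check
# ---------------------------------------------------------------------------

def assess_endophyte_synteny(
    exclusive_contigs: Sequence[Contig],
    isolate_genome: SequenceRecord,
    min_identity: float = 0.95,
    min_len: int = 200,
) -> dict:
    """Containment of gall-exclusive contigs in a bacterial isolate genome.

    A contig qualifies when it is >= min_len long and aligns into the isolate
    (either orientation, edit-distance identity over the full contig) at
    >= min_identity.  Verdict is "endophyte-supported" iff any contig
    qualifies.
    """
    if not isolate_genome.seq:
        raise ValueError("empty isolate genome")
    qualifying: list[str] = []
    total_bases = 0
    for contig in exclusive_contigs:
        if contig.length < min_len:
            continue
        best = 0.0
        for q in (contig.seq, revcomp(contig.seq)):
            res = edlib.align(q, isolate_genome.seq, mode="HW", task="distance")
            d = res["editDistance"]
            if d >= 0:
                best = max(best, (contig.length - d) / contig.length)
        if best >= min_identity:
            qualifying.append(contig.id)
            total_bases += contig.length
    return {
        "isolate_id": isolate_genome.id,
        "n_qualifying_contigs": len(qualifying),
        "total_bases": total_bases,
        "qualifying_ids": qualifying,
        "endophyte_supported": bool(qualifying),
    }
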