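"""Independent reference implementations used only to check the package.

These deliberately avoid the package's k-mer-anchored code paths: the
semiperfect oracle scans every placement via string search, and the
alignment oracle runs full dynamic programming over the whole reference.
"""

from __future__ import annotations

from Bio import Align

from gallsift.seqio import reverse_complement


def _placement_ok(oriented: str, chrom: str, pos: int, min_span: int) -> bool:
    L = len(oriented)
    s, e = max(0, pos), min(len(chrom), pos + L)
    if e - s < min_span:
        return False
    ref, qry = chrom[s:e], oriented[s - pos:e - pos]
    if ref == qry:
        return True
    if "N" not in ref and "N" not in qry:
        return False
    return all(a == b or a == "N" or b == "N" for a, b in zip(qry, ref))


def brute_force_semiperfect(read_seq: str, genome) -> list[tuple[str, int, str]]:
    """All semiperfect placements by exhaustive scan of positions and strands.

    For N-free sequence, interior placements are exact substring occurrences
    (checked with str.find); end overhangs and N-containing inputs fall back
    to the position-by-position check.
    """
    L = len(read_seq)
    min_span = (L + 1) // 2
    hits: set[tuple[str, int, str]] = set()
    for rec in genome:
        chrom = rec.seq
        for oriented, strand in ((read_seq, "+"), (reverse_complement(read_seq), "-")):
            if "N" not in oriented and "N" not in chrom:
                start = chrom.find(oriented)
                while start != -1:
                    hits.add((rec.id, start, strand))
                    start = chrom.find(oriented, start + 1)
                for ov in range(1, L - min_span + 1):  # overhang off either end
                    if _placement_ok(oriented, chrom, -ov, min_span):
                        hits.add((rec.id, 0, strand))
                    pos = len(chrom) - L + ov
                    if pos >= 0 and _placement_ok(oriented, chrom, pos, min_span):
                        hits.add((rec.id, pos, strand))
            else:
                for pos in range(-(L - min_span), len(chrom) - min_span + 1):
                    if _placement_ok(oriented, chrom, pos, min_span):
                        hits.add((rec.id, max(0, pos), strand))
    return sorted(hits)


def full_dp_local_score(ref: str, query: str) -> float:
    """Best local alignment score over both query strands, full-reference DP
    (match +1, mismatch -4, gap of length L costs 6 + L)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -4
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -1
    return max(float(aligner.score(ref, query)),
               float(aligner.score(ref, reverse_complement(query))))


def best_matching_count(call_sites, events, tolerance) -> int:
    """Maximum one-to-one call/event matching size by exhaustive recursion
    (small cases only)."""
    def rec(i: int, used: frozenset[int]) -> int:
        if i == len(call_sites):
            return 0
        best = rec(i + 1, used)
        chrom, point = call_sites[i]
        for j, ev in enumerate(events):
            if j in used or ev.chrom != chrom:
                continue
            if abs(ev.position - point) <= tolerance:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())
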