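"""Electronic PCR: primer-site finding, amplicon prediction, probe checks.

Implements the marker checks for the specific gall fragment (SGF) and the
TaqMan qPCR assay: IUPAC-aware primer annealing with a mismatch budget and a
3'-clamp that must match exactly, convergent-site pairing into predicted
amplicons (the amplicon includes both primer footprints), strict probe
containment between the footprints, and a global percent-identity comparison
against a consensus sequence.

The bundled ``data/primers.yaml`` carries the published primer and probe
sequences; the expected SGF product is 471 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from Bio import Align

from .seqio import IUPAC_SETS, SequenceRecord, SequenceFormatError, reverse_complement

DEFAULT_MAX_MISMATCH = 2
DEFAULT_CLAMP3 = 5
DEFAULT_SIZE_RANGE = (50, 5000)

# 4-bit base-set masks; two codes match iff their masks intersect
_MASK = {code: sum(1 << "ACGT".index(b) for b in bases)
         for code, bases in IUPAC_SETS.items()}
_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in _MASK.items():
    _MASK_LUT[ord(_c)] = _m
    _MASK_LUT[ord(_c.lower())] = _m


@dataclass
class Primer:
    name: str
    seq: str
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    clamp3: int = DEFAULT_CLAMP3

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace(" ", "")
        if not (10 <= len(self.seq) <= 40):
            raise ValueError(f"primer {self.name!r}: length must be 10-40 nt")
        for pos, ch in enumerate(self.seq):
            if ch not in IUPAC_SETS:
                raise SequenceFormatError(
                    f"illegal character {ch!r} at position {pos} in primer {self.name!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AmpliconHit:
    template_id: str
    start: int            # 0-based half-open on the template
    end: int
    fwd_mismatches: int
    rev_mismatches: int
    strand: str           # strand carrying the forward primer
    fwd_len: int
    rev_len: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _seq_masks(seq: str) -> np.ndarray:
    arr = _MASK_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        pos = int(np.nonzero(arr == 0)[0][0])
        raise SequenceFormatError(f"illegal character {seq[pos]!r} at position {pos}")
    return arr


def _scan(template_masks: np.ndarray, pattern: str, max_mismatch: int,
          clamp_positions: range) -> list[tuple[int, int]]:
    """(pos, mismatches) for every window matching ``pattern`` IUPAC-wise."""
    m = len(pattern)
    n = template_masks.size - m + 1
    if n <= 0:
        return []
    pat = _seq_masks(pattern)
    mism = np.zeros(n, dtype=np.int32)
    clamp_bad = np.zeros(n, dtype=bool)
    for j in range(m):
        no_match = (template_masks[j:j + n] & pat[j]) == 0
        mism += no_match
        if j in clamp_positions:
            clamp_bad |= no_match
    ok = np.nonzero((mism <= max_mismatch) & ~clamp_bad)[0]
    return [(int(p), int(mism[p])) for p in ok]


def find_primer_sites(template: SequenceRecord | str, primer: Primer
                      ) -> list[tuple[int, str, int]]:
    """All annealing sites of a primer on both template strands.

    Returns ``(pos, strand, mismatches)`` sorted by position, where ``pos``
    is the leftmost template coordinate of the footprint.  Mismatches are
    IUPAC-aware; the ``clamp3`` 3'-terminal bases must match exactly.
    """
    seq = template if isinstance(template, str) else template.seq
    m = len(primer)
    if m > len(seq):
        return []
    masks = _seq_masks(seq)
    sites: list[tuple[int, str, int]] = []
    # plus strand: primer read 5'->3' along the template; clamp at the right
    for pos, mm in _scan(masks, primer.seq, primer.max_mismatch,
                         range(m - primer.clamp3, m)):
        sites.append((pos, "+", mm))
    # minus strand: template contains the primer's reverse complement;
    # the primer 3' end is the leftmost footprint base
    rc = reverse_complement(primer.seq)
    for pos, mm in _scan(masks, rc, primer.max_mismatch, range(0, primer.clamp3)):
        sites.append((pos, "-", mm))
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def predict_amplicons(
    template: SequenceRecord | str,
    fwd: Primer,
    rev: Primer,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> list[AmpliconHit]:
    """Predicted PCR products from convergent primer sites.

    Every plus-strand forward site is paired with every minus-strand reverse
    site downstream of it (and the mirror orientation with the roles
    swapped); a product is emitted iff its length — both footprints included
    — falls within ``size_range``.  Nested and overlapping products are all
    reported.
    """
    seq = template if isinstance(template, str) else template.seq
    tid = "" if isinstance(template, str) else template.id
    lo, hi = size_range
    fwd_sites = find_primer_sites(seq, fwd)
    rev_sites = find_primer_sites(seq, rev)
    hits: list[AmpliconHit] = []
    for f_pos, f_strand, f_mm in fwd_sites:
        if f_strand != "+":
            continue
        for r_pos, r_strand, r_mm in rev_sites:
            if r_strand != "-" or r_pos < f_pos:
                continue
            length = r_pos + len(rev) - f_pos
            if lo <= length <= hi:
                hits.append(AmpliconHit(tid, f_pos, r_pos + len(rev),
                                        f_mm, r_mm, "+", len(fwd), len(rev)))
    for r_pos, r_strand, r_mm in rev_sites:
        if r_strand != "+":
            continue
        for f_pos, f_strand, f_mm in fwd_sites:
            if f_strand != "-" or f_pos < r_pos:
                continue
            length = f_pos + len(fwd) - r_pos
            if lo <= length <= hi:
                hits.append(AmpliconHit(tid, r_pos, f_pos + len(fwd),
                                        f_mm, r_mm, "-", len(fwd), len(rev)))
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def check_probe(template: SequenceRecord | str, amplicon: AmpliconHit,
                probe: str) -> bool:
    """True iff the probe matches perfectly strictly between the footprints.

    IUPAC-aware with zero mismatches, on either strand of the amplicon
    interior (MGB probes tolerate essentially no mismatch).
    """
    seq = template if isinstance(template, str) else template.seq
    if amplicon.strand == "+":
        inner_start = amplicon.start + amplicon.fwd_len
        inner_end = amplicon.end - amplicon.rev_len
    else:
        inner_start = amplicon.start + amplicon.rev_len
        inner_end = amplicon.end - amplicon.fwd_len
    interior = seq[inner_start:inner_end]
    if len(probe) > len(interior):
        return False
    masks = _seq_masks(interior)
    for pattern in (probe, reverse_complement(probe)):
        if _scan(masks, pattern, max_mismatch=0, clamp_positions=range(0)):
            return True
    return False


_GLOBAL = Align.PairwiseAligner()
_GLOBAL.mode = "global"
_GLOBAL.match_score = 1
_GLOBAL.mismatch_score = -1
_GLOBAL.open_gap_score = -2
_GLOBAL.extend_gap_score = -2


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global alignment identity (match +1, mismatch -1, gap -2), in percent.

    Identity = matching columns / alignment columns x 100, reported to 0.1%.
    100.0 exactly iff the sequences are identical.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty input")
    a, b = seq_a.upper(), seq_b.upper()
    if a == b:
        return 100.0
    aln = _GLOBAL.align(a, b)[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_cols += te - ts
        matches += sum(x == y for x, y in zip(a[ts:te], b[qs:qe]))
    columns = len(a) + len(b) - aligned_cols
    return round(100.0 * matches / columns, 1)


def load_primers(path: str | None = None) -> dict[str, Primer | str]:
    """Load primer/probe definitions from YAML (bundled fixtures by default).

    Entries with a ``probe: true`` flag are returned as plain sequences.
    """
    if path is None:
        text = (resources.files("gallsift.data") / "primers.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out: dict[str, Primer | str] = {}
    for name, entry in raw.items():
        if isinstance(entry, str):
            out[name] = Primer(name, entry)
        elif entry.get("probe"):
            out[name] = entry["seq"].upper().replace(" ", "")
        else:
            out[name] = Primer(
                name, entry["seq"],
                max_mismatch=entry.get("max_mismatch", DEFAULT_MAX_MISMATCH),
                clamp3=entry.get("clamp3", DEFAULT_CLAMP3),
            )
    return out
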